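"""Majority-vote fusion of multiple raters' masks into a ground truth.

Two tie rules are implemented.  ``strict_majority`` marks a pixel positive
only when more than half of the voters marked it — with two raters this is
their intersection, the conservative reading of a two-expert ground truth.
``at_least_half`` marks a pixel positive when at least half did — union for
two raters.  Every report records which rule produced its consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .io_manifest import AlignmentError, AnnotationMask

__all__ = ["VoteRule", "ConsensusMask", "majority_vote", "build_ground_truth"]

VoteRule = Literal["strict_majority", "at_least_half"]


@dataclass(frozen=True)
class ConsensusMask:
    """Fused ground-truth mask plus the provenance of the vote."""

    image_id: str
    mask: np.ndarray
    n_voters: int
    rule: VoteRule

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]


def majority_vote(
    masks: Sequence[AnnotationMask], rule: VoteRule = "strict_majority"
) -> ConsensusMask:
    """Pixelwise vote over aligned masks.

    strict_majority: positive iff votes > n/2; at_least_half: votes >= n/2.
    """
    if not masks:
        raise ValueError("majority_vote needs at least one mask")
    image_id = masks[0].image_id
    shape = masks[0].shape
    for m in masks[1:]:
        if m.image_id != image_id or m.shape != shape:
            raise AlignmentError(
                f"mask ({m.image_id}, {m.rater_id}) does not align with "
                f"image {image_id} {shape}"
            )
    n = len(masks)
    votes = np.zeros(shape, dtype=np.int32)
    for m in masks:
        votes += m.mask
    if rule == "strict_majority":
        fused = votes * 2 > n
    elif rule == "at_least_half":
        fused = votes * 2 >= n
    else:
        raise ValueError(f"unknown vote rule {rule!r}")
    return ConsensusMask(image_id=image_id, mask=fused, n_voters=n, rule=rule)


def build_ground_truth(
    masks: Mapping[tuple[str, str, int], AnnotationMask],
    image_ids: Sequence[str],
    consensus_raters: Sequence[str],
    rule: VoteRule = "strict_majority",
) -> dict[str, ConsensusMask]:
    """Fuse each consensus rater's *last* round per image into ground truth.

    ``masks`` maps (image_id, rater_id, round_id) to the mask.  A rater with
    only one round contributes that round wherever the last round is
    required.  A consensus rater with no mask at all for some image is a
    coverage error.
    """
    if not consensus_raters:
        raise ValueError("need at least one consensus rater")
    out: dict[str, ConsensusMask] = {}
    for image_id in image_ids:
        voters: list[AnnotationMask] = []
        for rater in consensus_raters:
            rounds = sorted(
                rnd for (iid, rid, rnd) in masks
                if iid == image_id and rid == rater
            )
            if not rounds:
                raise ValueError(
                    f"consensus rater {rater!r} has no mask for image "
                    f"{image_id!r}"
                )
            voters.append(masks[(image_id, rater, rounds[-1])])
        out[image_id] = majority_vote(voters, rule=rule)
    return out
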