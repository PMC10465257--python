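"""Chance-corrected and overlap agreement metrics for binary masks.

All metrics derive from pixel-level confusion counts between an annotator's
mask ("pred") and a reference mask (usually the consensus ground truth):

    IoU       = TP / (TP + FP + FN)
    DSC       = 2 TP / (2 TP + FP + FN)
    TNR       = TN / (TN + FP)                (specificity)
    TPR       = TP / (TP + FN)                (sensitivity)
    precision = TP / (TP + FP)

    Cohen's kappa:  po = (TP + TN) / N
                    pe = [(TP+FN)(TP+FP) + (FP+TN)(FN+TN)] / N^2
                    kappa = (po - pe) / (1 - pe)

Gwet's AC1 is computed in two variants that differ only in the chance term:

* ``paper``    — pe = p_pos^2 + p_neg^2 with p_pos = (TP+FP)/N and
  p_neg = (FN+TN)/N, i.e. only the annotator-side marginals.  This form is
  asymmetric in (pred, ref).
* ``standard`` — Gwet's published form: pi = ((TP+FP)/N + (TP+FN)/N)/2,
  pe = 2 pi (1 - pi), which is symmetric.

Both are always reported because the two disagree badly on imbalanced masks
(the usual case here: mostly background).  A metric whose denominator is
zero is *undefined* — represented as NaN and excluded from means — never
silently coerced to 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .io_manifest import AlignmentError, AnnotationMask

__all__ = [
    "ConfusionCounts",
    "AgreementScores",
    "AgreementMatrix",
    "RegionScore",
    "confusion_counts",
    "overlap_metrics",
    "cohens_kappa",
    "kappa_category",
    "gwets_ac1",
    "score_counts",
    "pairwise_matrix",
    "per_region_metrics",
    "UNDEFINED",
]

UNDEFINED = float("nan")


def is_defined(x: float) -> bool:
    return not math.isnan(x)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def _as_bool(mask: object) -> np.ndarray:
    """Unwrap any mask-bearing object (AnnotationMask, ConsensusMask) to a
    boolean array."""
    inner = getattr(mask, "mask", mask)
    return np.asarray(inner, dtype=bool)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN pixel tallies over an evaluation window."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass(frozen=True)
class AgreementScores:
    """Every per-comparison metric in one record; NaN means undefined."""

    iou: float
    dsc: float
    tnr: float
    tpr: float
    precision: float
    kappa: float
    ac1_paper: float
    ac1_standard: float
    po: float
    pe_kappa: float
    pe_ac1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "iou": self.iou, "dsc": self.dsc, "tnr": self.tnr,
            "tpr": self.tpr, "precision": self.precision,
            "kappa": self.kappa, "ac1_paper": self.ac1_paper,
            "ac1_standard": self.ac1_standard, "po": self.po,
            "pe_kappa": self.pe_kappa, "pe_ac1": self.pe_ac1,
        }


def confusion_counts(
    pred: AnnotationMask | np.ndarray,
    ref: AnnotationMask | np.ndarray,
    window: np.ndarray | None = None,
) -> ConfusionCounts:
    """Exact pixel tallies of pred vs ref, optionally restricted to a window."""
    p = _as_bool(pred)
    r = _as_bool(ref)
    if p.shape != r.shape:
        raise AlignmentError(f"shape mismatch {p.shape} vs {r.shape}")
    if window is not None:
        w = np.asarray(window, bool)
        if w.shape != p.shape:
            raise AlignmentError("window shape mismatch")
        p, r = p[w], r[w]
    tp = int(np.count_nonzero(p & r))
    fp = int(np.count_nonzero(p & ~r))
    fn = int(np.count_nonzero(~p & r))
    tn = int(p.size - tp - fp - fn)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def overlap_metrics(c: ConfusionCounts) -> tuple[float, float, float, float, float]:
    """(IoU, DSC, TNR, TPR, precision); zero-denominator metrics are NaN."""
    iou = _ratio(c.tp, c.tp + c.fp + c.fn)
    dsc = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    tnr = _ratio(c.tn, c.tn + c.fp)
    tpr = _ratio(c.tp, c.tp + c.fn)
    precision = _ratio(c.tp, c.tp + c.fp)
    return iou, dsc, tnr, tpr, precision


def cohens_kappa(c: ConfusionCounts) -> tuple[float, float, float]:
    """Cohen's kappa with its observed and chance agreement: (kappa, po, pe)."""
    n = c.total
    if n == 0:
        raise ValueError("cannot compute kappa on an empty window")
    po = (c.tp + c.tn) / n
    pe = ((c.tp + c.fn) * (c.tp + c.fp) + (c.fp + c.tn) * (c.fn + c.tn)) / n**2
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else UNDEFINED
    return kappa, po, pe


_KAPPA_BANDS = [
    (0.0, "none"),
    (0.20, "none-to-slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost-perfect"),
]


def kappa_category(kappa: float) -> str:
    """Interpretation band of a kappa value (none ... almost-perfect)."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    for upper, label in _KAPPA_BANDS:
        if kappa <= upper:
            return label
    return "almost-perfect"  # unreachable


def gwets_ac1(
    c: ConfusionCounts, variant: Literal["paper", "standard"] = "paper"
) -> tuple[float, float, float]:
    """Gwet's AC1 in either chance-term variant: (ac1, po, pe).

    ``paper`` uses pe = p_pos^2 + p_neg^2 from the annotator-side marginals
    only (asymmetric in pred/ref); ``standard`` uses Gwet's published
    pe = 2 pi (1 - pi) with pi the mean positive marginal of both raters.
    """
    n = c.total
    if n == 0:
        raise ValueError("cannot compute AC1 on an empty window")
    po = (c.tp + c.tn) / n
    if variant == "paper":
        p_pos = (c.tp + c.fp) / n
        p_neg = (c.fn + c.tn) / n
        pe = p_pos**2 + p_neg**2
    elif variant == "standard":
        pi = ((c.tp + c.fp) / n + (c.tp + c.fn) / n) / 2.0
        pe = 2.0 * pi * (1.0 - pi)
    else:
        raise ValueError(f"unknown AC1 variant {variant!r}")
    ac1 = (po - pe) / (1.0 - pe) if pe < 1.0 else UNDEFINED
    return ac1, po, pe


def score_counts(c: ConfusionCounts) -> AgreementScores:
    """All metrics from one confusion record."""
    iou, dsc, tnr, tpr, precision = overlap_metrics(c)
    kappa, po, pe_k = cohens_kappa(c)
    ac1_p, _, pe_a = gwets_ac1(c, "paper")
    ac1_s, _, _ = gwets_ac1(c, "standard")
    return AgreementScores(
        iou=iou, dsc=dsc, tnr=tnr, tpr=tpr, precision=precision,
        kappa=kappa, ac1_paper=ac1_p, ac1_standard=ac1_s,
        po=po, pe_kappa=pe_k, pe_ac1=pe_a,
    )


# --------------------------------------------------------------------------
# pairwise inter-rater matrices
# --------------------------------------------------------------------------


@dataclass
class AgreementMatrix:
    """Symmetric rater x rater matrix of one agreement coefficient."""

    rater_ids: list[str]
    values: np.ndarray
    coefficient: str

    def mean_off_diagonal(self) -> float:
        n = len(self.rater_ids)
        if n < 2:
            return UNDEFINED
        mask = ~np.eye(n, dtype=bool)
        vals = self.values[mask]
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else UNDEFINED

    def entry(self, a: str, b: str) -> float:
        i, j = self.rater_ids.index(a), self.rater_ids.index(b)
        return float(self.values[i, j])


def _pair_coefficient(c: ConfusionCounts, coefficient: str) -> float:
    if coefficient == "kappa":
        return cohens_kappa(c)[0]
    if coefficient == "ac1_paper":
        # asymmetric form: average both orientations to keep the matrix
        # symmetric; swapping pred/ref swaps FP and FN
        fwd = gwets_ac1(c, "paper")[0]
        swapped = ConfusionCounts(tp=c.tp, tn=c.tn, fp=c.fn, fn=c.fp)
        bwd = gwets_ac1(swapped, "paper")[0]
        return (fwd + bwd) / 2.0
    if coefficient == "ac1_standard":
        return gwets_ac1(c, "standard")[0]
    raise ValueError(f"unknown coefficient {coefficient!r}")


def pairwise_matrix(
    masks_by_rater: Mapping[str, Sequence[np.ndarray | AnnotationMask]],
    coefficient: str = "kappa",
    pooled: bool = True,
) -> AgreementMatrix:
    """Inter-rater agreement matrix over a common set of images.

    ``masks_by_rater`` maps each rater to its per-image mask list, all
    ordered identically.  With ``pooled`` (default) confusion counts are
    pooled over all images per pair; otherwise the coefficient is averaged
    over per-image values.
    """
    raters = list(masks_by_rater)
    if not raters:
        raise ValueError("need at least one rater")
    n_img = len(masks_by_rater[raters[0]])
    for r in raters:
        if len(masks_by_rater[r]) != n_img:
            raise ValueError(f"rater {r!r} does not cover all images")
    n = len(raters)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if pooled:
                counts = ConfusionCounts(0, 0, 0, 0)
                for a, b in zip(masks_by_rater[raters[i]], masks_by_rater[raters[j]]):
                    counts = counts + confusion_counts(a, b)
                val = _pair_coefficient(counts, coefficient)
            else:
                per_img = [
                    _pair_coefficient(confusion_counts(a, b), coefficient)
                    for a, b in zip(masks_by_rater[raters[i]], masks_by_rater[raters[j]])
                ]
                defined = [v for v in per_img if is_defined(v)]
                val = float(np.mean(defined)) if defined else UNDEFINED
            values[i, j] = values[j, i] = val
    return AgreementMatrix(rater_ids=raters, values=values, coefficient=coefficient)


# --------------------------------------------------------------------------
# per-region evaluation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionScore:
    """Agreement of a rater's annotation with one consensus region."""

    region_id: int
    area_px: int
    centroid: tuple[float, float]
    scores: AgreementScores


def per_region_metrics(
    pred: AnnotationMask | np.ndarray,
    consensus: AnnotationMask | np.ndarray,
    window_margin_px: int = 10,
    connectivity: int = 2,
) -> tuple[list[RegionScore], int]:
    """Score a rater's mask against each consensus region separately.

    The consensus mask is decomposed into connected regions.  Each rater
    component is matched to the consensus region it overlaps most; each
    consensus region is then scored against the union of its matched
    components inside the region's bounding box dilated by
    ``window_margin_px`` (pixels of *other* consensus regions are excluded
    from the window so neighbours never contaminate the tallies).

    Returns the per-region scores and the rater's annotated-area count
    (number of connected components of ``pred``).
    """
    p = _as_bool(pred)
    c = _as_bool(consensus)
    if p.shape != c.shape:
        raise AlignmentError(f"shape mismatch {p.shape} vs {c.shape}")
    structure = ndimage.generate_binary_structure(2, connectivity)
    c_lab, n_regions = ndimage.label(c, structure=structure)
    p_lab, n_pred = ndimage.label(p, structure=structure)

    # match each pred component to the consensus region it overlaps most
    matched_pred: dict[int, list[int]] = {k: [] for k in range(1, n_regions + 1)}
    for comp in range(1, n_pred + 1):
        overlap = c_lab[p_lab == comp]
        overlap = overlap[overlap > 0]
        if overlap.size:
            best = int(np.bincount(overlap).argmax())
            matched_pred[best].append(comp)

    objects = ndimage.find_objects(c_lab)
    h, w = c.shape
    out: list[RegionScore] = []
    for rid in range(1, n_regions + 1):
        sl = objects[rid - 1]
        r0 = max(sl[0].start - window_margin_px, 0)
        r1 = min(sl[0].stop + window_margin_px, h)
        c0 = max(sl[1].start - window_margin_px, 0)
        c1 = min(sl[1].stop + window_margin_px, w)
        win_c_lab = c_lab[r0:r1, c0:c1]
        region_mask = win_c_lab == rid
        other_regions = (win_c_lab > 0) & ~region_mask
        win_p_lab = p_lab[r0:r1, c0:c1]
        pred_here = np.isin(win_p_lab, matched_pred[rid]) if matched_pred[rid] \
            else np.zeros_like(region_mask)
        keep = ~other_regions
        counts = confusion_counts(pred_here[keep], region_mask[keep])
        rows, cols = np.nonzero(c_lab == rid)
        out.append(RegionScore(
            region_id=rid,
            area_px=int(rows.size),
            centroid=(float(rows.mean()), float(cols.mean())),
            scores=score_counts(counts),
        ))
    return out, n_pred


def mean_defined(values: Iterable[float]) -> tuple[float, int]:
    """Mean over defined (non-NaN) values and the count of excluded ones."""
    vals = list(values)
    defined = [v for v in vals if is_defined(v)]
    excluded = len(vals) - len(defined)
    return (float(np.mean(defined)) if defined else UNDEFINED), excluded
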