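"""Shared fixtures: mask factories and the directional synthetic battery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from annotqc.io_manifest import AnnotationMask, BScanImage
from annotqc.pipeline import EvaluationConfig, Study, evaluate_study, round_delta
from annotqc.synthetic import (
    default_phantom_specs,
    default_profiles,
    generate_study,
    subseed,
)


@pytest.fixture
def mk_mask():
    """Factory wrapping a boolean array as an AnnotationMask."""

    def _make(arr, image_id="img", rater_id="r", round_id=1):
        return AnnotationMask(image_id=image_id, rater_id=rater_id,
                              round_id=round_id, mask=np.asarray(arr, bool))

    return _make


@pytest.fixture
def mk_image():
    """Factory wrapping a float array in [0, 1] as a BScanImage."""

    def _make(arr, image_id="img", scale_x_um=10.5, scale_y_um=3.8):
        return BScanImage(image_id=image_id, pixels=np.asarray(arr, float),
                          scale_x_um=scale_x_um, scale_y_um=scale_y_um)

    return _make


N_DIRECTIONAL_SEEDS = 20


@pytest.fixture(scope="session")
def directional_battery():
    """Evaluate the default synthetic study over many seeds.

    Emulates the clinical design: 10 phantom B-scans whose noise spans the
    low/medium/high bins, 2 experts + 3 juniors, 2 rounds, with the first
    expert annotating only once (their single round stands in wherever a
    later round is required).  Returns pooled per-region rows, per-seed
    agreement matrices, intensity summaries and round-delta tallies.
    """
    region_frames: list[pd.DataFrame] = []
    intensity_frames: list[pd.DataFrame] = []
    kappa_ex_ex: list[float] = []
    kappa_ex_jr: list[float] = []
    delta_tallies: list[dict[str, int]] = []

    profiles = default_profiles()
    experts = [p.rater_id for p in profiles if p.tier == "expert"]
    juniors = [p.rater_id for p in profiles if p.tier == "junior"]

    for i in range(N_DIRECTIONAL_SEEDS):
        seed = subseed(971, "directional", i)
        synth = generate_study(default_phantom_specs(10), profiles,
                               rounds=2, seed=seed)
        study = Study.from_synthetic(synth)
        for iid in study.image_ids:  # first expert annotates once
            del study.masks[(iid, experts[0], 2)]
        results = evaluate_study(study, EvaluationConfig())

        last_rounds = {r: study.last_round_of(r) for r in study.rater_ids}
        pr = results.per_region
        pr = pr[pr.apply(lambda r: r["round"] == last_rounds[r["rater"]],
                         axis=1)].copy()
        pr["seed"] = i
        region_frames.append(pr)
        intensity_frames.append(results.intensity_summary.assign(seed=i))

        mat = results.matrices[("kappa", 1)]
        kappa_ex_ex.append(mat.entry(experts[0], experts[1]))
        kappa_ex_jr.extend(mat.entry(e, j) for e in experts for j in juniors)

        _, tally = round_delta(results)
        delta_tallies.append(tally)

    return {
        "per_region": pd.concat(region_frames, ignore_index=True),
        "intensity": pd.concat(intensity_frames, ignore_index=True),
        "kappa_expert_expert": float(np.mean(kappa_ex_ex)),
        "kappa_expert_junior": float(np.mean(kappa_ex_jr)),
        "delta_tallies": delta_tallies,
        "n_seeds": N_DIRECTIONAL_SEEDS,
    }
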