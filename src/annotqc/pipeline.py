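"""End-to-end study evaluation and report rendering.

``evaluate_study`` drives the whole battery: build the consensus ground
truth from the consensus raters' last rounds, score every (rater, round)
against it — both as pooled pixel counts and as means of per-region scores
— build pairwise inter-rater agreement matrices per round, estimate each
image's speckle-noise level, stratify last-round per-region IoU by noise
group and by zone, and summarise annotation boundary intensities per
rater.  Everything is deterministic given the study and the configuration;
evaluation itself draws no random numbers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    AgreementMatrix,
    ConfusionCounts,
    confusion_counts,
    mean_defined,
    pairwise_matrix,
    per_region_metrics,
    score_counts,
)
from .consensus import ConsensusMask, VoteRule, build_ground_truth
from .image_properties import (
    NoiseEstimate,
    NoiseEstimationError,
    ZoneSpec,
    estimate_noise_lambda,
    region_intensity_records,
    stratified_quality,
    zone_of,
)
from .io_manifest import (
    AnnotationMask,
    BScanImage,
    StudyManifest,
    read_image,
    read_mask,
    write_table,
)
from .synthetic import SyntheticStudy

__all__ = [
    "EvaluationConfig",
    "Study",
    "StudyResults",
    "evaluate_study",
    "round_delta",
    "render_report",
]

_METRICS = ["iou", "dsc", "tnr", "tpr", "precision"]
_DELTA_METRICS = _METRICS  # the 5-metric grid used for round deltas


@dataclass(frozen=True)
class EvaluationConfig:
    """All knobs of the evaluation, hashed into the provenance record."""

    consensus_rule: VoteRule = "strict_majority"
    connectivity: int = 2
    window_margin_px: int = 10
    zone_boundaries_mm: tuple[float, ...] = (0.5, 1.5, 3.0)
    pool_matrix_over_images: bool = True
    pooled_intensity: bool = False  # False: per-region means, then mean

    def config_hash(self) -> str:
        doc = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


@dataclass
class Study:
    """In-memory study: images, masks, rater roles."""

    images: dict[str, BScanImage]
    masks: dict[tuple[str, str, int], AnnotationMask]
    rater_tiers: dict[str, str]
    consensus_raters: list[str]

    @property
    def image_ids(self) -> list[str]:
        return list(self.images)

    @property
    def rater_ids(self) -> list[str]:
        return sorted(self.rater_tiers)

    def rounds_of(self, rater: str) -> list[int]:
        return sorted({rnd for (_, rid, rnd) in self.masks if rid == rater})

    def last_round_of(self, rater: str) -> int:
        rounds = self.rounds_of(rater)
        if not rounds:
            raise ValueError(f"rater {rater!r} has no masks")
        return rounds[-1]

    @classmethod
    def from_synthetic(cls, study: SyntheticStudy) -> "Study":
        return cls(
            images=dict(study.images),
            masks=dict(study.masks),
            rater_tiers=study.rater_tiers,
            consensus_raters=study.consensus_raters,
        )

    @classmethod
    def from_manifest(cls, manifest: StudyManifest) -> "Study":
        """Load every raster referenced by a manifest (paths relative to
        the manifest's directory)."""
        root = manifest.root
        images: dict[str, BScanImage] = {}
        for rec in manifest.images:
            images[rec.image_id] = read_image(
                root / rec.path, rec.scale_x_um, rec.scale_y_um,
                image_id=rec.image_id,
            )
        masks: dict[tuple[str, str, int], AnnotationMask] = {}
        for mk in manifest.masks:
            masks[(mk.image_id, mk.rater_id, mk.round_id)] = read_mask(
                root / mk.path, images[mk.image_id],
                rater_id=mk.rater_id, round_id=mk.round_id,
            )
        return cls(images=images, masks=masks,
                   rater_tiers=dict(manifest.rater_tiers),
                   consensus_raters=list(manifest.consensus_raters))


@dataclass
class StudyResults:
    """Every result surface of one evaluated study."""

    per_rater_round: pd.DataFrame       # pooled + region-mean rows, labelled
    per_region: pd.DataFrame            # one row per (rater, round, region)
    matrices: dict[tuple[str, int], AgreementMatrix]
    noise_estimates: dict[str, NoiseEstimate]
    stratified_noise: pd.DataFrame
    stratified_zone: pd.DataFrame
    intensity_summary: pd.DataFrame
    consensus: dict[str, ConsensusMask]
    provenance: dict

    @property
    def total_annotated_areas(self) -> int:
        pooled = self.per_rater_round[
            self.per_rater_round["aggregation"] == "pooled"]
        return int(pooled["n_areas"].sum())


def _round_mask(study: Study, rater: str, image_id: str,
                rnd: int) -> AnnotationMask:
    """Mask for a round, substituting the latest earlier round if absent
    (a rater who annotated once contributes that round everywhere)."""
    for r in range(rnd, 0, -1):
        key = (image_id, rater, r)
        if key in study.masks:
            return study.masks[key]
    raise ValueError(
        f"no mask for rater {rater!r}, image {image_id!r} at or before "
        f"round {rnd}"
    )


def evaluate_study(
    study: Study, config: EvaluationConfig = EvaluationConfig()
) -> StudyResults:
    """Run the full evaluation battery against the consensus ground truth."""
    zone_spec = ZoneSpec(tuple(config.zone_boundaries_mm))
    consensus = build_ground_truth(
        study.masks, study.image_ids, study.consensus_raters,
        rule=config.consensus_rule,
    )

    # per-image noise estimates
    noise: dict[str, NoiseEstimate] = {}
    for iid, image in study.images.items():
        try:
            noise[iid] = estimate_noise_lambda(image)
        except NoiseEstimationError:
            noise[iid] = NoiseEstimate(lambda_hat=float("nan"), group="unknown")

    # per-(rater, round) scoring
    region_rows: list[dict] = []
    table_rows: list[dict] = []
    all_rounds = sorted({rnd for (_, _, rnd) in study.masks})
    for rater in study.rater_ids:
        tier = study.rater_tiers[rater]
        for rnd in study.rounds_of(rater):
            pooled = ConfusionCounts(0, 0, 0, 0)
            n_areas = 0
            rater_region_scores: list[dict] = []
            for iid in study.image_ids:
                pred = study.masks[(iid, rater, rnd)]
                cons = consensus[iid]
                scores, n_pred = per_region_metrics(
                    pred, cons,
                    window_margin_px=config.window_margin_px,
                    connectivity=config.connectivity,
                )
                n_areas += n_pred
                pooled = pooled + confusion_counts(pred, cons.mask)
                for rs in scores:
                    zone = zone_of(rs.centroid, study.images[iid], zone_spec)
                    row = {
                        "image_id": iid, "rater": rater, "tier": tier,
                        "round": rnd, "region_id": rs.region_id,
                        "area_px": rs.area_px,
                        "zone": zone if zone is not None else 0,
                        "noise_group": noise[iid].group,
                        **rs.scores.as_dict(),
                    }
                    region_rows.append(row)
                    rater_region_scores.append(row)
            pooled_scores = score_counts(pooled)
            table_rows.append({
                "rater": rater, "tier": tier, "round": rnd,
                "aggregation": "pooled", **pooled_scores.as_dict(),
                "n_areas": n_areas, "n_undefined_excluded": 0,
            })
            mean_row: dict = {"rater": rater, "tier": tier, "round": rnd,
                              "aggregation": "region_mean"}
            excluded_total = 0
            for m in pooled_scores.as_dict():
                mean_val, excluded = mean_defined(
                    r[m] for r in rater_region_scores)
                mean_row[m] = mean_val
                excluded_total += excluded
            mean_row["n_areas"] = n_areas
            mean_row["n_undefined_excluded"] = excluded_total
            table_rows.append(mean_row)

    per_region = pd.DataFrame(region_rows)
    per_rater_round = pd.DataFrame(table_rows)

    # pairwise matrices per round per coefficient
    matrices: dict[tuple[str, int], AgreementMatrix] = {}
    for rnd in all_rounds:
        masks_by_rater = {
            rater: [_round_mask(study, rater, iid, rnd)
                    for iid in study.image_ids]
            for rater in study.rater_ids
        }
        for coef in ("kappa", "ac1_paper", "ac1_standard"):
            matrices[(coef, rnd)] = pairwise_matrix(
                masks_by_rater, coefficient=coef,
                pooled=config.pool_matrix_over_images,
            )

    # stratified last-round per-region IoU
    last = per_region[per_region.apply(
        lambda r: r["round"] == study.last_round_of(r["rater"]), axis=1)] \
        if len(per_region) else per_region
    stratified_noise = stratified_quality(last, "noise_group")
    stratified_zone = stratified_quality(last, "zone")

    # boundary-intensity summary, per rater's own last-round annotations
    intensity_rows: list[dict] = []
    for rater in study.rater_ids:
        rnd = study.last_round_of(rater)
        recs: list[dict] = []
        for iid in study.image_ids:
            recs.extend(region_intensity_records(
                study.images[iid], study.masks[(iid, rater, rnd)],
                connectivity=config.connectivity,
            ))
        if config.pooled_intensity:
            # pool pixels over all regions: area-weighted means
            def _pooled(key: str, nkey: str) -> float:
                tot = sum(r[key] * r[nkey] for r in recs)
                n = sum(r[nkey] for r in recs)
                return tot / n if n else float("nan")
            mo = _pooled("mean_outer", "n_outer")
            mi = _pooled("mean_inner", "n_inner")
            mr = _pooled("mean_region", "area_px")
        else:
            mo, _ = mean_defined(r["mean_outer"] for r in recs)
            mi, _ = mean_defined(r["mean_inner"] for r in recs)
            mr, _ = mean_defined(r["mean_region"] for r in recs)
        intensity_rows.append({
            "rater": rater, "tier": study.rater_tiers[rater], "round": rnd,
            "mean_outer": mo, "mean_inner": mi,
            "diff_outer_inner": mo - mi, "mean_region": mr,
            "n_regions": len(recs),
        })
    intensity_summary = pd.DataFrame(intensity_rows)

    provenance = {
        "package_version": __version__,
        "consensus_rule": config.consensus_rule,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "n_images": len(study.image_ids),
        "raters": {r: study.rater_tiers[r] for r in study.rater_ids},
        "consensus_raters": list(study.consensus_raters),
    }
    return StudyResults(
        per_rater_round=per_rater_round,
        per_region=per_region,
        matrices=matrices,
        noise_estimates=noise,
        stratified_noise=stratified_noise,
        stratified_zone=stratified_zone,
        intensity_summary=intensity_summary,
        consensus=consensus,
        provenance=provenance,
    )


def round_delta(results: StudyResults) -> tuple[pd.DataFrame, dict[str, int]]:
    """Round-2 minus round-1 pooled metric deltas per two-round rater.

    Returns the signed delta table and the tally of metric-by-rater grid
    cells that increased / stayed the same / decreased.
    """
    pooled = results.per_rater_round[
        results.per_rater_round["aggregation"] == "pooled"]
    rows: list[dict] = []
    tally = {"increased": 0, "same": 0, "decreased": 0}
    for rater, grp in pooled.groupby("rater"):
        rounds = sorted(grp["round"])
        if 1 not in rounds or 2 not in rounds:
            continue
        r1 = grp[grp["round"] == 1].iloc[0]
        r2 = grp[grp["round"] == 2].iloc[0]
        row: dict = {"rater": rater}
        for m in _DELTA_METRICS:
            delta = float(r2[m]) - float(r1[m])
            row[f"delta_{m}"] = delta
            if abs(delta) < 1e-12:
                tally["same"] += 1
            elif delta > 0:
                tally["increased"] += 1
            else:
                tally["decreased"] += 1
        rows.append(row)
    return pd.DataFrame(rows), tally


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


def _matrix_records(mat: AgreementMatrix) -> list[dict]:
    rows = []
    for i, a in enumerate(mat.rater_ids):
        row = {"rater": a}
        for j, b in enumerate(mat.rater_ids):
            row[b] = float(mat.values[i, j])
        rows.append(row)
    return rows


def _df_records(df: pd.DataFrame) -> list[dict]:
    return df.to_dict(orient="records")


def summary_dict(results: StudyResults) -> dict:
    """Machine-readable summary of every result surface."""
    delta_df, tally = round_delta(results)
    return {
        "provenance": results.provenance,
        "per_rater_round": _df_records(results.per_rater_round),
        "matrices": {
            f"{coef}_round{rnd}": {
                "rater_ids": mat.rater_ids,
                "values": mat.values.tolist(),
                "mean_off_diagonal": mat.mean_off_diagonal(),
            }
            for (coef, rnd), mat in results.matrices.items()
        },
        "noise": {
            iid: {"lambda_hat": est.lambda_hat, "group": est.group}
            for iid, est in results.noise_estimates.items()
        },
        "stratified_noise": _df_records(results.stratified_noise),
        "stratified_zone": _df_records(results.stratified_zone),
        "intensity_summary": _df_records(results.intensity_summary),
        "round_delta": {"table": _df_records(delta_df), "tally": tally},
        "total_annotated_areas": results.total_annotated_areas,
    }


def render_report(results: StudyResults, out: str | Path,
                  plots: bool = False) -> list[Path]:
    """Write CSV tables, a JSON summary and (optionally) figures."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _table(name: str, rows: list[dict],
               columns: Sequence[str] | None = None) -> None:
        path = out / name
        write_table(rows, path, columns=columns)
        written.append(path)

    _table("per_rater_round.csv", _df_records(results.per_rater_round))
    _table("per_region.csv", _df_records(results.per_region))
    for (coef, rnd), mat in results.matrices.items():
        _table(f"matrix_{coef}_round{rnd}.csv", _matrix_records(mat))
    _table("noise.csv", [
        {"image_id": iid, "lambda_hat": est.lambda_hat, "group": est.group}
        for iid, est in results.noise_estimates.items()
    ])
    _table("stratified_noise.csv", _df_records(results.stratified_noise))
    _table("stratified_zone.csv", _df_records(results.stratified_zone))
    _table("intensity_summary.csv", _df_records(results.intensity_summary))
    delta_df, tally = round_delta(results)
    _table("round_delta.csv", _df_records(delta_df))

    summary = summary_dict(results)
    spath = out / "summary.json"
    with open(spath, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    written.append(spath)

    if plots:
        written.extend(_render_plots(results, out))
    return written


def _render_plots(results: StudyResults, out: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: list[Path] = []
    for (coef, rnd), mat in results.matrices.items():
        fig, ax = plt.subplots(figsize=(4, 3.5))
        im = ax.imshow(mat.values, vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(len(mat.rater_ids)), mat.rater_ids, rotation=45)
        ax.set_yticks(range(len(mat.rater_ids)), mat.rater_ids)
        ax.set_title(f"{coef} (round {rnd})")
        fig.colorbar(im)
        path = out / f"matrix_{coef}_round{rnd}.png"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    if len(results.per_region):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        data, labels = [], []
        for (rater, rnd), grp in results.per_region.groupby(["rater", "round"]):
            data.append(grp["iou"].dropna().to_numpy())
            labels.append(f"{rater}-r{rnd}")
        ax.boxplot(data, tick_labels=labels)
        ax.set_ylabel("per-region IoU")
        ax.tick_params(axis="x", rotation=45)
        path = out / "iou_boxplot.png"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    if len(results.intensity_summary):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        df = results.intensity_summary
        x = np.arange(len(df))
        ax.bar(x - 0.2, df["mean_outer"], 0.2, label="outer")
        ax.bar(x, df["mean_inner"], 0.2, label="inner")
        ax.bar(x + 0.2, df["mean_region"], 0.2, label="region")
        ax.set_xticks(x, df["rater"])
        ax.set_ylabel("mean normalised intensity")
        ax.legend()
        path = out / "intensity_bars.png"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
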