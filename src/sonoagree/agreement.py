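"""Pooled pairwise agreement scores and summary tables.

For every scan and grouped structure, every unordered pair of retained
human annotators yields one human-human (HH) score, and the AI
annotation yields one AI-human (HAI) score against each retained human.
Region-kind groups are compared by Dice overlap of their union masks;
line-kind groups by the normalized symmetric Hausdorff distance of their
pooled, densely resampled point chains.

A pair in which exactly one side is empty ("not visible") scores the
worst value of its metric: 0 for Dice, 1 for Hausdorff.  A pair in which
both sides are empty is ambiguous (mutual agreement that nothing is
visible) and is excluded from the pooled statistics by default, carried
as a flagged count; the ``both_empty="perfect"`` policy instead scores
such pairs as perfect agreement for sensitivity analysis.

Summaries pool the raw pairwise values across all scans of a structure
(or all structures of a class) and report min / mean / median / max and
the sample standard deviation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from . import metrics
from .curation import ANALYSED_STATUSES
from .model import Annotation, GeometryKind, Status, StudyManifest, ValidationError

Mode = Literal["HH", "HAI"]


@dataclass(frozen=True)
class MetricConfig:
    """Options governing the pairwise metrics.

    resample_spacing : arc-length spacing (px) of polyline densification.
    symmetrize : use the symmetric Hausdorff distance (max of the two
        directed distances) rather than the one-directional form.
    denominator_mode : Hausdorff normalizer — the larger image side
        ("max_side") or the image diagonal ("diagonal").
    both_empty : "exclude" pools nothing for mutually-empty pairs and
        counts them separately; "perfect" scores them 1 (Dice) / 0
        (Hausdorff).
    """

    resample_spacing: float = metrics.DEFAULT_RESAMPLE_SPACING
    symmetrize: bool = True
    denominator_mode: metrics.DenominatorMode = "max_side"
    both_empty: Literal["exclude", "perfect"] = "exclude"


@dataclass(frozen=True)
class PairScore:
    scan_id: str
    group_id: str
    annotator_a: str
    annotator_b: str
    mode: Mode
    metric: Literal["dice", "hausdorff"]
    value: float  # NaN when both_empty and policy is "exclude"
    both_empty: bool = False


def _one_empty_value(metric: str) -> float:
    return 0.0 if metric == "dice" else 1.0


def _perfect_value(metric: str) -> float:
    return 1.0 if metric == "dice" else 0.0


def pairwise_scores(curated: list[Annotation], manifest: StudyManifest,
                    config: MetricConfig = MetricConfig(),
                    *, modes: tuple[Mode, ...] = ("HH", "HAI")) -> list[PairScore]:
    """Compute all pairwise HH and HAI scores on the curated study.

    Entries with a status other than present/absent are excluded from the
    comparison sets entirely (a skipped annotator contributes no pairs on
    that scan).  Requesting HAI without an AI annotator in the manifest is
    a configuration error.
    """
    ai_id = manifest.ai_annotator
    if "HAI" in modes and ai_id is None:
        raise ValidationError("HAI comparisons requested but the manifest declares no AI annotator")
    humans = set(manifest.humans)

    # organize analysable entries per (scan, group)
    cells: dict[tuple[str, str], dict[str, Annotation]] = {}
    for ann in curated:
        if ann.status not in ANALYSED_STATUSES:
            continue
        cells.setdefault((ann.scan_id, ann.structure_id), {})[ann.annotator_id] = ann

    scores: list[PairScore] = []
    for (scan_id, group_id), by_annot in sorted(cells.items()):
        scan = manifest.scan(scan_id)
        kind = manifest.group_kind(group_id)
        metric_name = "dice" if kind is GeometryKind.REGION else "hausdorff"

        # precompute each annotator's comparison object once
        prepared: dict[str, object] = {}
        for aid, ann in by_annot.items():
            if ann.status is Status.ABSENT:
                prepared[aid] = None
            elif kind is GeometryKind.REGION:
                prepared[aid] = metrics.rasterize(
                    ann.components, scan.image_width, scan.image_height, scan_id
                )
            else:
                prepared[aid] = metrics.resample_components(
                    ann.components, config.resample_spacing
                )

        def score_pair(a: str, b: str, mode: Mode) -> PairScore:
            pa, pb = prepared[a], prepared[b]
            if pa is None and pb is None:
                value = _perfect_value(metric_name) if config.both_empty == "perfect" else math.nan
                return PairScore(scan_id, group_id, a, b, mode, metric_name, value, both_empty=True)
            if pa is None or pb is None:
                return PairScore(scan_id, group_id, a, b, mode, metric_name,
                                 _one_empty_value(metric_name))
            if kind is GeometryKind.REGION:
                value = metrics.dice(pa, pb)
            else:
                value = metrics.hausdorff_score(
                    pa, pb, scan.image_width, scan.image_height,
                    symmetrize=config.symmetrize,
                    denominator_mode=config.denominator_mode,
                )
            return PairScore(scan_id, group_id, a, b, mode, metric_name, value)

        retained_humans = sorted(aid for aid in by_annot if aid in humans)
        if "HH" in modes:
            for a, b in itertools.combinations(retained_humans, 2):
                scores.append(score_pair(a, b, "HH"))
        if "HAI" in modes and ai_id in by_annot:
            for b in retained_humans:
                scores.append(score_pair(ai_id, b, "HAI"))
    return scores


def scores_to_frame(scores: list[PairScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scan_id": s.scan_id,
                "group_id": s.group_id,
                "annotator_a": s.annotator_a,
                "annotator_b": s.annotator_b,
                "mode": s.mode,
                "metric": s.metric,
                "value": s.value,
                "both_empty": s.both_empty,
            }
            for s in scores
        ],
        columns=["scan_id", "group_id", "annotator_a", "annotator_b",
                 "mode", "metric", "value", "both_empty"],
    )


def _summary_stats(values: np.ndarray) -> dict:
    n = len(values)
    if n == 0:
        return {"n_pairs": 0, "min": math.nan, "mean": math.nan,
                "median": math.nan, "max": math.nan, "sd": math.nan}
    return {
        "n_pairs": n,
        "min": float(np.min(values)),
        "mean": float(np.mean(values)),
        "median": float(np.median(values)),  # even pools: midpoint of central pair
        "max": float(np.max(values)),
        "sd": float(np.std(values, ddof=1)) if n > 1 else math.nan,  # sample sd
    }


def summarize(scores: list[PairScore], manifest: StudyManifest,
              by: Literal["structure", "class"] = "structure",
              mode: Mode | None = None) -> pd.DataFrame:
    """Pool pairwise scores into min/mean/median/max/sd summary rows.

    Values are pooled over all scans of a structure group (``by="structure"``)
    or over all groups of a structure class (``by="class"``), separately per
    comparison mode.  Both-empty pairs carry no value and are reported in
    the ``n_both_empty`` column.  A scope with zero poolable scores yields
    a row with ``n_pairs=0`` and NaN statistics rather than being dropped.
    """
    if by not in ("structure", "class"):
        raise ValueError(f"unknown pooling scope {by!r}")
    df = scores_to_frame(scores)
    if mode is not None:
        df = df[df["mode"] == mode]
    if df.empty:
        raise ValidationError("no pair scores to summarize")

    if by == "structure":
        df = df.assign(scope=df["group_id"])
        scope_of = {g: g for g in df["scope"].unique()}
    else:
        cls = {g: manifest.group_class(g).value for g in df["group_id"].unique()}
        df = df.assign(scope=df["group_id"].map(cls))
        scope_of = cls

    rows = []
    for (scope, md, metric_name), sub in df.groupby(["scope", "mode", "metric"], sort=True):
        pooled = sub.loc[~sub["value"].isna(), "value"].to_numpy()
        stats = _summary_stats(pooled)
        rows.append(
            {
                "scope": scope,
                "scope_kind": by,
                "mode": md,
                "metric": metric_name,
                "n_both_empty": int((sub["value"].isna() & sub["both_empty"]).sum()),
                **stats,
            }
        )
    out = pd.DataFrame(rows, columns=["scope", "scope_kind", "mode", "metric",
                                      "n_pairs", "n_both_empty",
                                      "min", "mean", "median", "max", "sd"])
    return out.sort_values(["metric", "scope", "mode"]).reset_index(drop=True)


def compare_modes(rows_hh: pd.DataFrame, rows_hai: pd.DataFrame) -> pd.DataFrame:
    """Per scope: which mode has the superior mean and the smaller sd.

    Superior means higher for Dice and lower for Hausdorff; exact ties
    are reported as "equal".
    """
    hh = rows_hh.set_index(["scope", "metric"])
    hai = rows_hai.set_index(["scope", "metric"])
    if set(hh.index) != set(hai.index):
        raise ValidationError("HH and HAI summaries cover different scopes")
    rows = []
    for key in hh.index:
        scope, metric_name = key
        mean_hh, mean_hai = hh.loc[key, "mean"], hai.loc[key, "mean"]
        sd_hh, sd_hai = hh.loc[key, "sd"], hai.loc[key, "sd"]
        higher_better = metric_name == "dice"
        if math.isclose(mean_hh, mean_hai, abs_tol=0.0):
            superior = "equal"
        elif (mean_hh > mean_hai) == higher_better:
            superior = "HH"
        else:
            superior = "HAI"
        if math.isclose(sd_hh, sd_hai, abs_tol=0.0):
            smaller_sd = "equal"
        else:
            smaller_sd = "HH" if sd_hh < sd_hai else "HAI"
        rows.append(
            {
                "scope": scope,
                "metric": metric_name,
                "mean_hh": mean_hh,
                "mean_hai": mean_hai,
                "superior_mean": superior,
                "sd_hh": sd_hh,
                "sd_hai": sd_hai,
                "smaller_sd": smaller_sd,
            }
        )
    return pd.DataFrame(rows).sort_values("scope").reset_index(drop=True)


def format_summary(rows: pd.DataFrame, decimals: int = 2) -> str:
    """Human-readable rendering of a summary table (values rounded only
    here; internal values stay full precision)."""
    disp = rows.copy()
    for col in ("min", "mean", "median", "max", "sd"):
        disp[col] = disp[col].map(lambda v: "-" if pd.isna(v) else f"{v:.{decimals}f}")
    return disp.to_string(index=False)
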