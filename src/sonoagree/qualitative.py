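"""Aggregation of expert qualitative assessments of AI highlighting.

Alongside the geometric agreement analysis, a panel of experts judged,
for each structure in each scan, whether the AI colour overlay was
correct (true positive / true negative / false positive / false
negative), whether the overlay would modify the risk of adverse events
(nerve trauma; intravascular injection / local-anaesthetic systemic
toxicity; pneumothorax via pleural breach; peritoneal violation) and of
block failure, and gave a 0-10 score for overall highlighting
performance per block region.

This module aggregates such assessment records into accuracy rates,
risk-modification tallies and subjective-score summaries.  Percentages
are full precision internally and rendered to one decimal place with
their count fractions alongside.  Missing assessments reduce
denominators explicitly; nothing is imputed.

A reference table of published expert-assessment counts for an AI
ultrasound overlay ships with the package
(``data/qualitative_counts.csv``) as a worked example; its rows can be
expanded into per-expert records with :func:`expand_counts`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import pandas as pd

from .model import Region, ValidationError


class Outcome(str, Enum):
    TP = "TP"
    TN = "TN"
    FP = "FP"
    FN = "FN"


class RiskJudgment(str, Enum):
    INCREASE = "increase"
    NO_CHANGE = "no_change"
    DECREASE = "decrease"


class RiskEvent(str, Enum):
    NERVE_TRAUMA = "nerve_trauma"
    LAST_ARTERIAL = "last_arterial"          # intravascular injection / LAST
    PNEUMOTHORAX_PLEURA = "pneumothorax_pleura"
    PERITONEAL_VIOLATION = "peritoneal_violation"
    BLOCK_FAILURE = "block_failure"


#: adverse events that can meaningfully be judged in each block region
REGION_EVENTS: dict[Region, frozenset[RiskEvent]] = {
    Region.ISB: frozenset({RiskEvent.NERVE_TRAUMA, RiskEvent.LAST_ARTERIAL, RiskEvent.BLOCK_FAILURE}),
    Region.AxB: frozenset({RiskEvent.NERVE_TRAUMA, RiskEvent.LAST_ARTERIAL, RiskEvent.BLOCK_FAILURE}),
    Region.ESPB: frozenset({RiskEvent.PNEUMOTHORAX_PLEURA, RiskEvent.BLOCK_FAILURE}),
    Region.RSB: frozenset({RiskEvent.PERITONEAL_VIOLATION, RiskEvent.BLOCK_FAILURE}),
    Region.ACB: frozenset({RiskEvent.NERVE_TRAUMA, RiskEvent.LAST_ARTERIAL, RiskEvent.BLOCK_FAILURE}),
    Region.SNB: frozenset({RiskEvent.NERVE_TRAUMA, RiskEvent.LAST_ARTERIAL, RiskEvent.BLOCK_FAILURE}),
}


@dataclass
class QualAssessment:
    """One expert's judgment of the AI overlay for one structure on one scan."""

    expert_id: str
    scan_id: str
    structure_id: str
    region: Region
    outcome: Outcome | None = None  # None = not recorded
    risk: dict[RiskEvent, RiskJudgment] = field(default_factory=dict)
    subjective_block_score: int | None = None  # 0-10, per expert per block region

    def __post_init__(self):
        self.region = Region(self.region)
        self.outcome = Outcome(self.outcome) if self.outcome is not None else None
        self.risk = {RiskEvent(k): RiskJudgment(v) for k, v in self.risk.items()}
        applicable = REGION_EVENTS[self.region]
        for event in self.risk:
            if event not in applicable:
                raise ValidationError(
                    f"event {event.value} not applicable in region {self.region.value}"
                )
        if self.subjective_block_score is not None and not (0 <= self.subjective_block_score <= 10):
            raise ValidationError(
                f"subjective score {self.subjective_block_score} outside 0-10"
            )


def accuracy_rates(assessments: list[QualAssessment], structure_id: str) -> dict:
    """(TP+TN)/Total, FP/Total and FN/Total for one structure.

    The denominator is the number of recorded outcomes, which may fall
    short of the nominal panel size.  An empty scope returns NaN rates
    with ``n=0`` rather than raising.
    """
    outcomes = [
        a.outcome for a in assessments
        if a.structure_id == structure_id and a.outcome is not None
    ]
    n = len(outcomes)
    if n == 0:
        return {"structure_id": structure_id, "n": 0,
                "accuracy": math.nan, "fp_rate": math.nan, "fn_rate": math.nan,
                "n_correct": 0, "n_fp": 0, "n_fn": 0}
    n_correct = sum(1 for o in outcomes if o in (Outcome.TP, Outcome.TN))
    n_fp = sum(1 for o in outcomes if o is Outcome.FP)
    n_fn = sum(1 for o in outcomes if o is Outcome.FN)
    return {
        "structure_id": structure_id,
        "n": n,
        "accuracy": n_correct / n,
        "fp_rate": n_fp / n,
        "fn_rate": n_fn / n,
        "n_correct": n_correct,
        "n_fp": n_fp,
        "n_fn": n_fn,
    }


def risk_tally(assessments: list[QualAssessment], scope: str, event: RiskEvent) -> dict:
    """Proportions of increase / no_change / decrease judgments for one
    adverse-event type, over a structure or region scope."""
    event = RiskEvent(event)
    judgments = []
    for a in assessments:
        if a.structure_id == scope or a.region.value == scope:
            if event not in REGION_EVENTS[a.region]:
                raise ValidationError(
                    f"event {event.value} not applicable in region {a.region.value}"
                )
            if event in a.risk:
                judgments.append(a.risk[event])
    n = len(judgments)
    counts = {j: sum(1 for x in judgments if x is j) for j in RiskJudgment}
    props = {j.value: (counts[j] / n if n else math.nan) for j in RiskJudgment}
    return {"scope": scope, "event": event.value, "n": n,
            **props, **{f"n_{j.value}": counts[j] for j in RiskJudgment}}


def subjective_summary(scores: list[int | float]) -> dict:
    """Mean, min-max range and sample sd of 0-10 subjective scores."""
    clean = [s for s in scores if s is not None]
    if any(not (0 <= s <= 10) for s in clean):
        raise ValidationError("subjective scores must lie in 0-10")
    n = len(clean)
    if n == 0:
        return {"n": 0, "mean": math.nan, "min": math.nan, "max": math.nan, "sd": math.nan}
    mean = sum(clean) / n
    sd = math.sqrt(sum((s - mean) ** 2 for s in clean) / (n - 1)) if n > 1 else math.nan
    return {"n": n, "mean": mean, "min": min(clean), "max": max(clean), "sd": sd}


def format_rate(numerator: int, denominator: int) -> str:
    """Percentage with counts alongside, e.g. ``86.7 (13/15)``."""
    pct = 100.0 * numerator / denominator if denominator else math.nan
    return f"{pct:.1f} ({numerator}/{denominator})"


# ---------------------------------------------------------------------------
# CSV interchange and the bundled reference counts
# ---------------------------------------------------------------------------

_RISK_PREFIX = "risk_"


def load_assessments(path: str | Path) -> list[QualAssessment]:
    """Load assessments from CSV: one row per expert x scan x structure,
    with columns expert_id, scan_id, structure_id, region, outcome,
    risk_<event> columns, and score."""
    df = pd.read_csv(path)
    required = {"expert_id", "scan_id", "structure_id", "region"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"assessment CSV missing column(s) {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        risk = {
            col[len(_RISK_PREFIX):]: d[col]
            for col in df.columns
            if col.startswith(_RISK_PREFIX) and isinstance(d[col], str)
        }
        outcome = d.get("outcome")
        score = d.get("score")
        out.append(
            QualAssessment(
                expert_id=str(d["expert_id"]),
                scan_id=str(d["scan_id"]),
                structure_id=str(d["structure_id"]),
                region=Region(d["region"]),
                outcome=None if pd.isna(outcome) else Outcome(outcome),
                risk=risk,
                subjective_block_score=None if score is None or pd.isna(score) else int(score),
            )
        )
    return out


def write_assessments(assessments: list[QualAssessment], path: str | Path) -> None:
    events = sorted({e.value for a in assessments for e in a.risk})
    rows = []
    for a in assessments:
        row = {
            "expert_id": a.expert_id,
            "scan_id": a.scan_id,
            "structure_id": a.structure_id,
            "region": a.region.value,
            "outcome": a.outcome.value if a.outcome else None,
        }
        for e in events:
            row[f"{_RISK_PREFIX}{e}"] = a.risk.get(RiskEvent(e), None)
            if row[f"{_RISK_PREFIX}{e}"] is not None:
                row[f"{_RISK_PREFIX}{e}"] = row[f"{_RISK_PREFIX}{e}"].value
        row["score"] = a.subjective_block_score
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def reference_counts() -> pd.DataFrame:
    """The bundled reference table of expert-assessment counts (per cell:
    numerator k, denominator n, and the percentage as published)."""
    with resources.files("sonoagree.data").joinpath("qualitative_counts.csv").open() as fh:
        return pd.read_csv(fh)


def expand_counts(counts: pd.DataFrame) -> list[QualAssessment]:
    """Expand count cells into synthetic per-expert assessment records.

    Experts are labelled Q01, Q02, ... deterministically: for an accuracy
    triple with k correct of n, the first ``k - n_fp - n_fn`` experts
    are assigned TP, then FP, then FN; risk triples assign increase,
    no_change, decrease in expert order.  Aggregating the expanded
    records therefore reproduces exactly the proportions implied by the
    counts.
    """
    out: list[QualAssessment] = []
    by_scope = counts[counts["scope_kind"] == "structure"].groupby("scope", sort=True)
    for scope, sub in by_scope:
        region = Region(sub["region"].iloc[0])
        n_total = int(sub["n"].max())
        records = [
            QualAssessment(f"Q{i + 1:02d}", scan_id="pooled", structure_id=scope, region=region)
            for i in range(n_total)
        ]
        acc = {row.cell: row for row in sub[sub["cell"].isin(["accuracy", "fp", "fn"])].itertuples()}
        if "accuracy" in acc:
            n = int(acc["accuracy"].n)
            n_fp = int(acc["fp"].k) if "fp" in acc else 0
            n_fn = int(acc["fn"].k) if "fn" in acc else 0
            n_correct = int(acc["accuracy"].k)
            seq = [Outcome.TP] * n_correct + [Outcome.FP] * n_fp + [Outcome.FN] * n_fn
            if len(seq) != n:
                raise ValidationError(f"{scope}: outcome counts do not sum to the denominator")
            for rec, outcome in zip(records[:n], seq):
                rec.outcome = outcome
        for (event,), esub in sub[sub["cell"] == "risk"].groupby(["event"]):
            tri = {row.category: int(row.k) for row in esub.itertuples()}
            n = int(esub["n"].iloc[0])
            seq = (
                [RiskJudgment.INCREASE] * tri.get("increase", 0)
                + [RiskJudgment.NO_CHANGE] * tri.get("no_change", 0)
                + [RiskJudgment.DECREASE] * tri.get("decrease", 0)
            )
            if len(seq) != n:
                raise ValidationError(f"{scope}/{event}: risk counts do not sum to the denominator")
            for rec, judgment in zip(records[:n], seq):
                rec.risk[RiskEvent(event)] = judgment
        out.extend(records)

    # region-level cells (block failure; region-wide adverse events)
    region_rows = counts[counts["scope_kind"] == "region"]
    for scope, sub in region_rows.groupby("scope", sort=True):
        region = Region(sub["region"].iloc[0])
        n_total = int(sub["n"].max())
        records = [
            QualAssessment(f"Q{i + 1:02d}", scan_id="pooled",
                           structure_id=f"{scope}_panel", region=region)
            for i in range(n_total)
        ]
        is_risk = sub["cell"].isin(["risk", "block_failure"])
        for (cell, event), esub in sub[is_risk].groupby(["cell", "event"], dropna=False):
            ev = RiskEvent.BLOCK_FAILURE if cell == "block_failure" else RiskEvent(event)
            tri = {row.category: int(row.k) for row in esub.itertuples()}
            n = int(esub["n"].iloc[0])
            seq = (
                [RiskJudgment.INCREASE] * tri.get("increase", 0)
                + [RiskJudgment.NO_CHANGE] * tri.get("no_change", 0)
                + [RiskJudgment.DECREASE] * tri.get("decrease", 0)
            )
            if len(seq) != n:
                raise ValidationError(f"{scope}/{ev.value}: counts do not sum to the denominator")
            for rec, judgment in zip(records[:n], seq):
                rec.risk[ev] = judgment
        out.extend(records)
    return out
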