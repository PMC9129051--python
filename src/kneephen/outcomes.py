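"""Longitudinal outcome classification and bicluster cross-tabulation.

Outcomes over 96 months of follow-up:

* radiographic OA (rOA) level from the Kellgren-Lawrence grade (KLG)
  history — incident (baseline KLG 0-1 rising to 2+), progressive
  (baseline 2+ worsening), stable, or unclassifiable,
* receipt of total knee arthroplasty (TKA),
* percentage loss of quantitative joint space width (qJSW) per compartment
  from a per-knee linear regression of qJSW (mm) on month, with truncation
  of implausible extrapolations,
* assigned pain-trajectory group.

rOA level codes: 1 baseline KLG 0-1 with no follow-up; 2 KLG 0-1 with no
incident rOA; 3 developed incident rOA; 4 baseline KLG 2+ with no
follow-up; 5 KLG 2+ without progression; 6 progressive rOA; 7 TKA at
baseline; 999 no baseline and no follow-up KLG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ROA_LEVELS",
    "GAIN_CAP_PCT",
    "KneeOutcome",
    "OutcomeSummary",
    "classify_roa_outcome",
    "qjsw_percent_loss",
    "compute_knee_outcomes",
    "crosstab_bicluster_outcomes",
]

ROA_LEVELS = (1, 2, 3, 4, 5, 6, 7, 999)

#: loss is capped at 100%; a fitted *gain* is capped at these magnitudes
GAIN_CAP_PCT = {"medial": 40.0, "lateral": 50.0}

FOLLOWUP_END_MONTH = 96


@dataclass
class KneeOutcome:
    knee_id: object
    roa_level: int
    tka: int
    medial_loss_pct: float
    lateral_loss_pct: float
    traj_group: object = None
    medial_flags: dict = field(default_factory=dict)
    lateral_flags: dict = field(default_factory=dict)


@dataclass
class OutcomeSummary:
    """Per-bicluster outcome summaries plus the full-cohort row.

    ``roa_proportions``/``traj_proportions`` are group x category tables
    whose rows sum to 1; ``loss_quartiles`` holds the (25th, 50th, 75th)
    percentiles of the qJSW loss distributions (linear interpolation).
    """

    roa_proportions: pd.DataFrame
    tka_rate: pd.Series
    loss_quartiles: pd.DataFrame
    traj_proportions: pd.DataFrame
    counts: pd.Series


def _validate_klg(value) -> int:
    v = int(value)
    if not 0 <= v <= 4:
        raise ValueError(f"KLG must be an integer 0-4, got {value!r}")
    return v


def classify_roa_outcome(baseline_klg, followup_klgs, tka_at_baseline: bool = False) -> int:
    """Radiographic-progression level from the KLG history (see module doc).

    ``baseline_klg`` may be None (missing baseline reading);
    ``followup_klgs`` is the sequence of post-baseline readings (possibly
    empty).  A baseline arthroplasty short-circuits to level 7.
    """
    if tka_at_baseline:
        return 7
    followups = [_validate_klg(v) for v in followup_klgs if v is not None and not (
        isinstance(v, float) and np.isnan(v)
    )]
    if baseline_klg is None or (isinstance(baseline_klg, float) and np.isnan(baseline_klg)):
        return 999  # no baseline; follow-up alone cannot classify progression
    b = _validate_klg(baseline_klg)
    if b <= 1:
        if not followups:
            return 1
        return 3 if max(followups) >= 2 else 2
    if not followups:
        return 4
    return 6 if max(followups) > b else 5


def qjsw_percent_loss(series, compartment: str) -> tuple[float, dict]:
    """Percentage of baseline qJSW lost by month 96, from a fitted line.

    ``series`` is an iterable of (month, qJSW mm) pairs.  An ordinary
    least-squares line of width on month gives fitted values at months 0
    and 96; loss_pct = 100*(fitted(0) - fitted(96))/fitted(0).  Fitted
    losses above 100% are truncated to 100; fitted gains beyond the
    compartment threshold (40% medial, 50% lateral) are truncated to the
    threshold (i.e. floored at -40/-50).  Flags report what happened.
    """
    if compartment not in GAIN_CAP_PCT:
        raise ValueError(f"compartment must be 'medial' or 'lateral', got {compartment!r}")
    pts = [(float(m), float(v)) for m, v in series if np.isfinite(v)]
    months = np.array([p[0] for p in pts])
    values = np.array([p[1] for p in pts])
    if np.unique(months).size < 2:
        raise ValueError("need observations at >= 2 distinct months")
    slope, intercept = np.polyfit(months, values, 1)
    fitted0 = intercept
    fitted96 = intercept + slope * FOLLOWUP_END_MONTH
    flags = {"truncated_loss": False, "truncated_gain": False, "invalid": False}
    if fitted0 <= 0:
        flags["invalid"] = True
        return float("nan"), flags
    loss = 100.0 * (fitted0 - fitted96) / fitted0
    cap = GAIN_CAP_PCT[compartment]
    if loss > 100.0:
        loss = 100.0
        flags["truncated_loss"] = True
    elif loss < -cap:
        loss = -cap
        flags["truncated_gain"] = True
    return float(loss), flags


def compute_knee_outcomes(
    outcome_table: pd.DataFrame,
    traj_assignment: dict | None = None,
) -> pd.DataFrame:
    """Per-knee outcomes from a long visit table.

    ``outcome_table`` columns: knee_id, month, klg, tka, qjsw_medial,
    qjsw_lateral (tka is a per-knee 0/1 flag; a knee whose flag is 1 at
    month 0 is a baseline arthroplasty).  Returns one row per knee with
    the rOA level, TKA indicator, truncated qJSW loss percentages and the
    truncation bookkeeping.
    """
    rows = []
    for knee_id, sub in outcome_table.groupby("knee_id", sort=True):
        sub = sub.sort_values("month")
        base = sub[sub["month"] == 0]
        fup = sub[(sub["month"] > 0) & (sub["month"] <= FOLLOWUP_END_MONTH)]
        baseline_klg = None
        if len(base) and pd.notna(base["klg"].iloc[0]):
            baseline_klg = int(base["klg"].iloc[0])
        tka_baseline = bool(len(base) and base["tka"].iloc[0] == 1)
        # per-knee flag: any 1 marks receipt during the window
        tka = int((sub["tka"] == 1).any())
        roa = classify_roa_outcome(
            baseline_klg,
            fup["klg"].dropna().tolist(),
            tka_at_baseline=tka_baseline,
        )
        losses = {}
        lflags = {}
        for comp, col in (("medial", "qjsw_medial"), ("lateral", "qjsw_lateral")):
            pts = sub[["month", col]].dropna()
            if pts["month"].nunique() >= 2:
                losses[comp], lflags[comp] = qjsw_percent_loss(
                    list(pts.itertuples(index=False, name=None)), comp
                )
            else:
                losses[comp], lflags[comp] = float("nan"), {"invalid": True}
        traj = traj_assignment.get(knee_id) if traj_assignment else None
        rows.append(
            {
                "knee_id": knee_id,
                "roa_level": roa,
                "tka": tka,
                "medial_loss_pct": losses["medial"],
                "lateral_loss_pct": losses["lateral"],
                "medial_truncated_loss": bool(lflags["medial"].get("truncated_loss", False)),
                "medial_truncated_gain": bool(lflags["medial"].get("truncated_gain", False)),
                "lateral_truncated_loss": bool(lflags["lateral"].get("truncated_loss", False)),
                "lateral_truncated_gain": bool(lflags["lateral"].get("truncated_gain", False)),
                "traj_group": traj,
            }
        )
    return pd.DataFrame(rows).set_index("knee_id")


def crosstab_bicluster_outcomes(
    membership: pd.Series,
    outcomes: pd.DataFrame,
) -> OutcomeSummary:
    """Summarize outcomes per bicluster and for the full cohort.

    ``membership`` maps knee_id -> bicluster label (use -1 or "na" for
    unassigned); every knee in it must have a row in ``outcomes``.
    """
    missing = [k for k in membership.index if k not in outcomes.index]
    if missing:
        raise ValueError(f"knees without an outcome record: {missing[:5]}")
    df = outcomes.loc[membership.index].copy()
    df["_group"] = membership.values
    groups = ["cohort"] + sorted(df["_group"].unique(), key=str)

    def _subset(g):
        return df if g == "cohort" else df[df["_group"] == g]

    roa = pd.DataFrame(
        {
            g: _subset(g)["roa_level"].value_counts(normalize=True)
            for g in groups
        }
    ).T.fillna(0.0)
    tka = pd.Series({g: _subset(g)["tka"].mean() for g in groups}, name="tka_rate")
    quart_rows = {}
    for g in groups:
        s = _subset(g)
        row = {}
        for comp in ("medial", "lateral"):
            vals = s[f"{comp}_loss_pct"].dropna()
            for q, lab in ((25, "q25"), (50, "q50"), (75, "q75")):
                row[f"{comp}_{lab}"] = (
                    float(np.percentile(vals, q)) if len(vals) else float("nan")
                )
        quart_rows[g] = row
    quartiles = pd.DataFrame(quart_rows).T
    if df["traj_group"].notna().any():
        traj = pd.DataFrame(
            {
                g: _subset(g)["traj_group"].value_counts(normalize=True)
                for g in groups
            }
        ).T.fillna(0.0)
    else:
        traj = pd.DataFrame(index=groups)
    counts = pd.Series({g: len(_subset(g)) for g in groups}, name="n")
    return OutcomeSummary(
        roa_proportions=roa,
        tka_rate=tka,
        loss_quartiles=quartiles,
        traj_proportions=traj,
        counts=counts,
    )
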