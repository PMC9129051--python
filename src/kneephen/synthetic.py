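"""Seeded synthetic cohorts with planted structure for every pipeline stage.

The generator emulates the statistical skeleton the analysis assumes:

* a mixed-type baseline feature matrix whose latent (continuous) values
  contain planted additive biclusters ``mu + r_i + c_j + noise`` on a
  standard-normal background, with binary/ordinal/nominal columns produced
  by thresholding or equal-probability binning of the latents,
* a long-format pain panel drawn from a known mixture of polynomial
  trajectories (change from baseline at months 12..96) with monotone
  dropout whose hazard can rise after month 48,
* per-visit progression outcomes (monotone KLG, TKA flags, linear qJSW
  series) whose probabilities differ by planted bicluster membership.

Everything is a pure function of the spec (including its seed), so reruns
are bit-identical and every downstream stage has ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import FeatureMetadata
from .trajectory import ALL_MONTHS, MODEL_MONTHS, TIME_SCALE

__all__ = [
    "FeatureKind",
    "PlantedBicluster",
    "TrajGroup",
    "OutcomeParams",
    "SyntheticSpec",
    "GroundTruth",
    "default_spec",
    "generate_clinical_matrix",
    "generate_longitudinal_panel",
    "generate_outcomes",
    "write_fixture_bundle",
    "read_fixture_bundle",
]


@dataclass(frozen=True)
class FeatureKind:
    """Kind of one synthetic column: continuous, binary, ordinal:k, nominal:k."""

    kind: str
    levels: int = 0
    binary_quantile: float = 0.5  # latent threshold for binary columns

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "ordinal", "nominal"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind in ("ordinal", "nominal") and self.levels < 2:
            raise ValueError(f"{self.kind} needs >= 2 levels")

    def to_dict(self):
        return {"kind": self.kind, "levels": self.levels,
                "binary_quantile": self.binary_quantile}


@dataclass(frozen=True)
class PlantedBicluster:
    """An additive block: cells = mu + r_i + c_j + N(0, noise_sd^2)."""

    rows: tuple
    cols: tuple
    mu: float
    row_scale: float
    col_scale: float

    def to_dict(self):
        return {"rows": list(self.rows), "cols": list(self.cols), "mu": self.mu,
                "row_scale": self.row_scale, "col_scale": self.col_scale}


@dataclass(frozen=True)
class TrajGroup:
    """One mixture component: weight, polynomial over month/96, residual sd."""

    pi: float
    coef: tuple  # constant term first, on the scaled time axis
    sigma: float

    def mean(self, months) -> np.ndarray:
        t = np.asarray(months, dtype=float) / TIME_SCALE
        return np.vander(t, len(self.coef), increasing=True) @ np.asarray(self.coef)

    def to_dict(self):
        return {"pi": self.pi, "coef": list(self.coef), "sigma": self.sigma}


@dataclass(frozen=True)
class OutcomeParams:
    """Progression parameters for one planted bicluster (or the background).

    ``klg_baseline_probs`` is a length-5 distribution over grades 0-4;
    ``klg_progress_prob`` is the per-visit probability of a one-grade
    increase; qJSW baselines (mm) and slopes (mm/month) are Gaussian.
    """

    klg_baseline_probs: tuple = (0.35, 0.25, 0.2, 0.15, 0.05)
    klg_progress_prob: float = 0.03
    tka_prob: float = 0.05
    qjsw_baseline_mean: tuple = (4.5, 6.0)  # (medial, lateral)
    qjsw_baseline_sd: float = 0.6
    qjsw_slope_mean: tuple = (-0.004, -0.002)
    qjsw_slope_sd: float = 0.002
    qjsw_noise_sd: float = 0.15

    def to_dict(self):
        return {
            "klg_baseline_probs": list(self.klg_baseline_probs),
            "klg_progress_prob": self.klg_progress_prob,
            "tka_prob": self.tka_prob,
            "qjsw_baseline_mean": list(self.qjsw_baseline_mean),
            "qjsw_baseline_sd": self.qjsw_baseline_sd,
            "qjsw_slope_mean": list(self.qjsw_slope_mean),
            "qjsw_slope_sd": self.qjsw_slope_sd,
            "qjsw_noise_sd": self.qjsw_noise_sd,
        }


@dataclass
class SyntheticSpec:
    """Complete, serializable recipe for one synthetic cohort."""

    n_rows: int
    n_cols: int
    feature_kinds: list  # list[FeatureKind], length n_cols
    planted_biclusters: list  # list[PlantedBicluster]
    noise_sd: float
    traj_groups: list  # list[TrajGroup]
    dropout_hazard: dict  # model month -> per-visit dropout probability
    outcome_params: dict  # bicluster id (int) or "background" -> OutcomeParams
    seed: int = 0

    def validate(self):
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("n_rows and n_cols must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if len(self.feature_kinds) != self.n_cols:
            raise ValueError("feature_kinds must have one entry per column")
        seen: set = set()
        for b, blk in enumerate(self.planted_biclusters):
            overlap = seen & set(blk.rows)
            if overlap:
                raise ValueError(
                    f"planted row sets overlap (bicluster {b}, rows {sorted(overlap)[:5]})"
                )
            seen |= set(blk.rows)
            if max(blk.rows) >= self.n_rows or max(blk.cols) >= self.n_cols:
                raise ValueError("planted indices out of range")
        total = sum(g.pi for g in self.traj_groups)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"mixing proportions sum to {total}, not 1")
        for m in self.dropout_hazard:
            if int(m) not in MODEL_MONTHS:
                raise ValueError(f"dropout hazard month {m} is not a model visit")

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "feature_kinds": [k.to_dict() for k in self.feature_kinds],
            "planted_biclusters": [b.to_dict() for b in self.planted_biclusters],
            "noise_sd": self.noise_sd,
            "traj_groups": [g.to_dict() for g in self.traj_groups],
            "dropout_hazard": {str(k): v for k, v in self.dropout_hazard.items()},
            "outcome_params": {str(k): v.to_dict() for k, v in self.outcome_params.items()},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(
            n_rows=d["n_rows"],
            n_cols=d["n_cols"],
            feature_kinds=[FeatureKind(**k) for k in d["feature_kinds"]],
            planted_biclusters=[
                PlantedBicluster(
                    rows=tuple(b["rows"]), cols=tuple(b["cols"]), mu=b["mu"],
                    row_scale=b["row_scale"], col_scale=b["col_scale"],
                )
                for b in d["planted_biclusters"]
            ],
            noise_sd=d["noise_sd"],
            traj_groups=[
                TrajGroup(pi=g["pi"], coef=tuple(g["coef"]), sigma=g["sigma"])
                for g in d["traj_groups"]
            ],
            dropout_hazard={int(k): v for k, v in d["dropout_hazard"].items()},
            outcome_params={
                (k if k == "background" else int(k)): OutcomeParams(
                    klg_baseline_probs=tuple(v["klg_baseline_probs"]),
                    klg_progress_prob=v["klg_progress_prob"],
                    tka_prob=v["tka_prob"],
                    qjsw_baseline_mean=tuple(v["qjsw_baseline_mean"]),
                    qjsw_baseline_sd=v["qjsw_baseline_sd"],
                    qjsw_slope_mean=tuple(v["qjsw_slope_mean"]),
                    qjsw_slope_sd=v["qjsw_slope_sd"],
                    qjsw_noise_sd=v["qjsw_noise_sd"],
                )
                for k, v in d["outcome_params"].items()
            },
            seed=d["seed"],
        )


@dataclass
class GroundTruth:
    """Planted memberships and true longitudinal parameters per knee."""

    row_membership: dict  # knee index -> bicluster id or None
    column_membership: dict  # bicluster id -> column index tuple
    traj_group: dict = field(default_factory=dict)  # knee index -> group id
    true_qjsw_slopes: dict = field(default_factory=dict)  # knee -> (medial, lateral)
    latent: Optional[np.ndarray] = None  # pre-discretization matrix (not serialized)

    def to_dict(self) -> dict:
        return {
            "row_membership": {str(k): v for k, v in self.row_membership.items()},
            "column_membership": {str(k): list(v) for k, v in self.column_membership.items()},
            "traj_group": {str(k): v for k, v in self.traj_group.items()},
            "true_qjsw_slopes": {str(k): list(v) for k, v in self.true_qjsw_slopes.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            row_membership={int(k): v for k, v in d["row_membership"].items()},
            column_membership={int(k): tuple(v) for k, v in d["column_membership"].items()},
            traj_group={int(k): v for k, v in d["traj_group"].items()},
            true_qjsw_slopes={int(k): tuple(v) for k, v in d["true_qjsw_slopes"].items()},
        )


def default_traj_groups() -> list:
    """Four canonical pain-change patterns: stable, improvement, worsening,
    and transient worsening, with weights dominated by the stable group —
    the mixture shape typical of community knee cohorts."""
    return [
        TrajGroup(pi=0.764, coef=(0.0, 0.0), sigma=2.0),            # stable
        TrajGroup(pi=0.112, coef=(-1.0, -4.0), sigma=2.0),          # improvement
        TrajGroup(pi=0.090, coef=(0.5, 3.5), sigma=2.0),            # worsening
        TrajGroup(pi=0.034, coef=(0.0, 12.0, -12.0), sigma=2.0),    # up then down
    ]


def default_spec(seed: int = 0, n_rows: int = 1200, n_cols: int = 86) -> SyntheticSpec:
    """A realistic desk-scale cohort: mixed feature kinds, four planted
    phenotype blocks of decreasing size, four pain trajectories, and
    attrition that steepens after month 48."""
    rng = np.random.default_rng(seed + 990001)  # layout seed, distinct from data seed
    kinds: list[FeatureKind] = []
    for j in range(n_cols):
        r = j % 10
        if r < 5:
            kinds.append(FeatureKind("continuous"))
        elif r < 7:
            kinds.append(FeatureKind("binary", binary_quantile=0.5))
        elif r < 9:
            kinds.append(FeatureKind("ordinal", levels=4))
        else:
            kinds.append(FeatureKind("nominal", levels=3))
    row_fracs = (0.28, 0.22, 0.12, 0.08)
    col_fracs = (0.45, 0.40, 0.35, 0.30)
    perm = rng.permutation(n_rows)
    blocks = []
    start = 0
    for b, (rf, cf) in enumerate(zip(row_fracs, col_fracs)):
        nr = int(round(rf * n_rows))
        rows = tuple(int(i) for i in np.sort(perm[start:start + nr]))
        start += nr
        ncb = int(round(cf * n_cols))
        cols = tuple(int(c) for c in np.sort(rng.choice(n_cols, size=ncb, replace=False)))
        mu = [1.0, -0.8, 1.2, -1.2][b]
        blocks.append(PlantedBicluster(rows=rows, cols=cols, mu=mu,
                                       row_scale=0.5, col_scale=0.5))
    outcome_params = {
        "background": OutcomeParams(),
        0: OutcomeParams(klg_baseline_probs=(0.5, 0.3, 0.12, 0.06, 0.02),
                         klg_progress_prob=0.01, tka_prob=0.02),
        1: OutcomeParams(),
        2: OutcomeParams(klg_baseline_probs=(0.15, 0.15, 0.3, 0.25, 0.15),
                         klg_progress_prob=0.06, tka_prob=0.15,
                         qjsw_slope_mean=(-0.010, -0.004)),
        3: OutcomeParams(klg_baseline_probs=(0.2, 0.2, 0.3, 0.2, 0.1),
                         klg_progress_prob=0.05, tka_prob=0.12,
                         qjsw_slope_mean=(-0.008, -0.004)),
    }
    return SyntheticSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        feature_kinds=kinds,
        planted_biclusters=blocks,
        noise_sd=0.2,
        traj_groups=default_traj_groups(),
        dropout_hazard={12: 0.03, 24: 0.03, 36: 0.03, 48: 0.03, 72: 0.08, 96: 0.08},
        outcome_params=outcome_params,
        seed=seed,
    )


def recovery_benchmark_spec(seed: int = 0) -> SyntheticSpec:
    """300x40 continuous matrix with 3 fully disjoint planted blocks.

    The standard desk-scale benchmark for bicluster recovery: blocks of
    80/70/50 knees over 14/13/12 features, overall effects about one
    standard deviation in size, row/column effect sd 0.5, within-block
    noise sd 0.2.
    """
    n, p = 300, 40
    rows = [tuple(range(0, 80)), tuple(range(80, 150)), tuple(range(150, 200))]
    cols = [tuple(range(0, 14)), tuple(range(14, 27)), tuple(range(27, 39))]
    blocks = [
        PlantedBicluster(rows=r, cols=c, mu=m, row_scale=0.5, col_scale=0.5)
        for r, c, m in zip(rows, cols, (1.0, -0.8, 1.2))
    ]
    return SyntheticSpec(
        n_rows=n,
        n_cols=p,
        feature_kinds=[FeatureKind("continuous")] * p,
        planted_biclusters=blocks,
        noise_sd=0.2,
        traj_groups=default_traj_groups(),
        dropout_hazard={},
        outcome_params={"background": OutcomeParams()},
        seed=seed,
    )


def two_group_panel(seed: int = 0, n: int = 500) -> tuple[pd.DataFrame, GroundTruth]:
    """A 2-group trajectory benchmark panel: 70% flat, 30% rising to +5.

    Residual sd 1, all 7 visits, no dropout — the standard desk-scale
    parameter-recovery setting for the trajectory mixture.
    """
    groups = [
        TrajGroup(pi=0.7, coef=(0.0,), sigma=1.0),
        TrajGroup(pi=0.3, coef=(0.0, 5.0), sigma=1.0),
    ]
    spec = SyntheticSpec(
        n_rows=n,
        n_cols=2,
        feature_kinds=[FeatureKind("continuous")] * 2,
        planted_biclusters=[],
        noise_sd=0.2,
        traj_groups=groups,
        dropout_hazard={},
        outcome_params={"background": OutcomeParams()},
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    truth = GroundTruth(
        row_membership={i: None for i in range(n)},
        column_membership={},
        traj_group={
            i: int(g) for i, g in enumerate(rng.choice(2, size=n, p=[0.7, 0.3]))
        },
    )
    return generate_longitudinal_panel(spec, truth), truth


def generate_clinical_matrix(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, GroundTruth, list]:
    """Baseline feature table with planted additive biclusters.

    Returns ``(raw table, ground truth, metadata list)``.  Latent values
    are iid standard normal outside the planted blocks; inside block b the
    cell is ``mu_b + r_i + c_j + eps`` with block-specific row/column
    effects and ``eps ~ N(0, noise_sd^2)``.  Column kinds then discretize
    the latents: binary by thresholding at a quantile, ordinal/nominal by
    equal-probability binning.  The latent matrix is kept on the ground
    truth for oracle checks.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_rows, spec.n_cols
    Z = rng.standard_normal((n, p))
    row_membership: dict = {i: None for i in range(n)}
    column_membership: dict = {}
    for b, blk in enumerate(spec.planted_biclusters):
        rows = np.asarray(blk.rows, dtype=int)
        cols = np.asarray(blk.cols, dtype=int)
        r = rng.normal(0.0, blk.row_scale, size=rows.size)
        c = rng.normal(0.0, blk.col_scale, size=cols.size)
        eps = rng.normal(0.0, spec.noise_sd, size=(rows.size, cols.size))
        Z[np.ix_(rows, cols)] = blk.mu + r[:, None] + c[None, :] + eps
        for i in rows:
            row_membership[int(i)] = b
        column_membership[b] = tuple(int(x) for x in cols)

    data = {}
    metadata = []
    for j, fk in enumerate(spec.feature_kinds):
        name = f"f{j:03d}"
        z = Z[:, j]
        if fk.kind == "continuous":
            data[name] = z
            metadata.append(FeatureMetadata(name=name, kind="continuous"))
        elif fk.kind == "binary":
            thr = stats.norm.ppf(fk.binary_quantile)
            data[name] = (z > thr).astype(float)
            metadata.append(FeatureMetadata(name=name, kind="binary"))
        elif fk.kind == "ordinal":
            edges = stats.norm.ppf(np.linspace(0, 1, fk.levels + 1)[1:-1])
            codes = np.digitize(z, edges)  # 0..levels-1
            levels = tuple(f"lev{i + 1}" for i in range(fk.levels))
            data[name] = [levels[c] for c in codes]
            metadata.append(FeatureMetadata(name=name, kind="ordinal", levels=levels))
        else:  # nominal
            edges = stats.norm.ppf(np.linspace(0, 1, fk.levels + 1)[1:-1])
            codes = np.digitize(z, edges)
            levels = tuple(chr(ord("A") + i) for i in range(fk.levels))
            data[name] = [levels[c] for c in codes]
            metadata.append(FeatureMetadata(name=name, kind="nominal", levels=levels))
    table = pd.DataFrame(data, index=pd.RangeIndex(n, name="knee_id"))
    truth = GroundTruth(
        row_membership=row_membership,
        column_membership=column_membership,
        latent=Z,
    )
    # trajectory groups: sampled here so one truth object serves all stages;
    # qJSW slopes drawn in generate_outcomes (they need outcome params)
    pis = np.array([g.pi for g in spec.traj_groups])
    groups = rng.choice(len(pis), size=n, p=pis)
    truth.traj_group = {int(i): int(g) for i, g in enumerate(groups)}
    return table, truth, metadata


def generate_longitudinal_panel(
    spec: SyntheticSpec, truth: GroundTruth
) -> pd.DataFrame:
    """Long-format change-from-baseline pain panel with monotone dropout.

    One record per knee and retained visit; the month-0 change is exactly
    0 and every knee has the baseline record.  Once a visit is missed all
    later visits are missed too.
    """
    if not truth.traj_group:
        raise ValueError("ground truth has no trajectory groups")
    rng = np.random.default_rng(spec.seed + 1)
    records = []
    months = np.asarray(MODEL_MONTHS, dtype=float)
    means = np.vstack([g.mean(months) for g in spec.traj_groups])
    hazards = np.array([spec.dropout_hazard.get(int(m), 0.0) for m in MODEL_MONTHS])
    for knee in sorted(truth.traj_group):
        g = truth.traj_group[knee]
        if g >= len(spec.traj_groups):
            raise ValueError(f"unknown trajectory group {g} for knee {knee}")
        sigma = spec.traj_groups[g].sigma
        records.append({"knee_id": knee, "month": 0, "value": 0.0})
        for k, m in enumerate(MODEL_MONTHS):
            if rng.random() < hazards[k]:
                break  # monotone dropout: no later visits either
            records.append(
                {
                    "knee_id": knee,
                    "month": int(m),
                    "value": float(means[g, k] + rng.normal(0.0, sigma)),
                }
            )
    return pd.DataFrame.from_records(records)


def generate_outcomes(spec: SyntheticSpec, truth: GroundTruth) -> pd.DataFrame:
    """Per-visit KLG / TKA / qJSW outcome table linked to planted blocks.

    KLG series are non-decreasing integers 0-4 whose per-visit progression
    probability, the TKA probability, and the qJSW slope distribution all
    come from the outcome parameters of the knee's planted bicluster
    (``"background"`` for unassigned knees).
    """
    if not truth.row_membership:
        raise ValueError("ground truth has no row membership")
    rng = np.random.default_rng(spec.seed + 2)
    records = []
    for knee in sorted(truth.row_membership):
        b = truth.row_membership[knee]
        params = spec.outcome_params.get(
            b if b is not None else "background",
            spec.outcome_params["background"],
        )
        klg = int(rng.choice(5, p=np.asarray(params.klg_baseline_probs)))
        tka = int(rng.random() < params.tka_prob)
        base = [
            float(rng.normal(params.qjsw_baseline_mean[c], params.qjsw_baseline_sd))
            for c in range(2)
        ]
        slope = [
            float(rng.normal(params.qjsw_slope_mean[c], params.qjsw_slope_sd))
            for c in range(2)
        ]
        truth.true_qjsw_slopes[knee] = (slope[0], slope[1])
        for m in ALL_MONTHS:
            if m > 0 and rng.random() < params.klg_progress_prob:
                klg = min(4, klg + 1)
            records.append(
                {
                    "knee_id": knee,
                    "month": int(m),
                    "klg": klg,
                    "tka": tka,
                    "qjsw_medial": base[0] + slope[0] * m
                    + float(rng.normal(0.0, params.qjsw_noise_sd)),
                    "qjsw_lateral": base[1] + slope[1] * m
                    + float(rng.normal(0.0, params.qjsw_noise_sd)),
                }
            )
    return pd.DataFrame.from_records(records)


def write_fixture_bundle(directory, spec: SyntheticSpec) -> dict:
    """Generate everything and write a self-describing delimited-text bundle.

    Files: baseline.csv, metadata.json, panel.csv, outcomes.csv,
    ground_truth.json, spec.json.  Regenerating from the stored spec
    reproduces the stored tables bit-for-bit.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table, truth, metadata = generate_clinical_matrix(spec)
    panel = generate_longitudinal_panel(spec, truth)
    outcomes = generate_outcomes(spec, truth)
    paths = {
        "baseline": directory / "baseline.csv",
        "metadata": directory / "metadata.json",
        "panel": directory / "panel.csv",
        "outcomes": directory / "outcomes.csv",
        "ground_truth": directory / "ground_truth.json",
        "spec": directory / "spec.json",
    }
    table.to_csv(paths["baseline"], index=True)
    paths["metadata"].write_text(
        json.dumps([m.to_dict() for m in metadata], indent=1)
    )
    panel.to_csv(paths["panel"], index=False)
    outcomes.to_csv(paths["outcomes"], index=False)
    paths["ground_truth"].write_text(json.dumps(truth.to_dict(), indent=1))
    paths["spec"].write_text(json.dumps(spec.to_dict(), indent=1))
    return {k: str(v) for k, v in paths.items()}


def read_fixture_bundle(directory) -> dict:
    """Read a bundle back; inverse of :func:`write_fixture_bundle`."""
    directory = Path(directory)
    out = {}
    out["baseline"] = pd.read_csv(directory / "baseline.csv", index_col="knee_id")
    out["metadata"] = [
        FeatureMetadata.from_dict(d)
        for d in json.loads((directory / "metadata.json").read_text())
    ]
    out["panel"] = pd.read_csv(directory / "panel.csv")
    out["outcomes"] = pd.read_csv(directory / "outcomes.csv")
    out["ground_truth"] = GroundTruth.from_dict(
        json.loads((directory / "ground_truth.json").read_text())
    )
    out["spec"] = SyntheticSpec.from_dict(
        json.loads((directory / "spec.json").read_text())
    )
    return out
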