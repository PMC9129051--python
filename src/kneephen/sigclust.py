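"""SigClust significance testing for pairs of clusters.

Tests whether two clusters are better separated than 2-means splits of
data drawn from a single Gaussian fitted to the pooled pair ("a proxy for
unclustered data").  The test statistic is the cluster index

    CI = (within-cluster sum of squares) / (total sum of squares),

low for tight, well-separated clusters.  The null covariance is estimated
as the sample covariance with eigenvalues hard-thresholded from below at a
robust cell-noise variance (MAD-based); replicate datasets are drawn from
the axis-aligned Gaussian with those eigenvalue variances and split by
2-means.  The z-score of the observed CI against the null CI distribution
is reported; z < -2 flags a significant pair (one-sided normal p < 0.023).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NullModel",
    "SigClustResult",
    "cluster_index",
    "estimate_null_model",
    "simulate_null_ci",
    "two_means_ci",
    "sigclust_pair",
    "pairwise_sigclust",
    "mean_difference_projection",
]

#: Phi^-1(0.75): converts a median absolute deviation to a normal sd
_MAD_TO_SD = 0.6744897501960817

Z_SIGNIFICANT = -2.0


@dataclass
class NullModel:
    """Single-Gaussian null: thresholded covariance eigenvalues + noise floor."""

    eigenvalues: np.ndarray  # non-increasing, all >= background_var
    background_var: float
    dim: int
    n: int


@dataclass
class SigClustResult:
    """Observed cluster index vs. the simulated single-Gaussian null."""

    pair: tuple
    ci_observed: float
    null_mean: float
    null_sd: float
    z: float
    p_normal: float
    p_empirical: float
    n_sim: int
    seed: int

    @property
    def significant(self) -> bool:
        return self.z < Z_SIGNIFICANT

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "ci_observed": self.ci_observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "p_normal": self.p_normal,
            "p_empirical": self.p_empirical,
            "n_sim": self.n_sim,
            "seed": self.seed,
            "significant": self.significant,
        }


def cluster_index(data: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster over total sum of squares for a two-class split."""
    X = np.asarray(data, dtype=float)
    lab = np.asarray(labels)
    classes = np.unique(lab)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    total = float(((X - X.mean(axis=0)) ** 2).sum())
    if total == 0.0:
        raise ValueError("all points identical: total variation is zero")
    within = 0.0
    for c in classes:
        mask = lab == c
        if not mask.any():
            raise ValueError(f"class {c!r} is empty")
        within += float(((X[mask] - X[mask].mean(axis=0)) ** 2).sum())
    return within / total


def estimate_null_model(data: np.ndarray) -> NullModel:
    """Fit the single-Gaussian null with hard eigenvalue thresholding.

    The background noise variance is ``(MAD of column-centered cells /
    0.6745)^2``; sample-covariance eigenvalues below it are raised to it,
    and when the dimension exceeds n-1 the trailing eigenvalues are padded
    at the background level.
    """
    X = np.asarray(data, dtype=float)
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    centered = X - X.mean(axis=0)
    mad = float(np.median(np.abs(centered - np.median(centered))))
    if mad == 0.0:
        raise ValueError("degenerate data: MAD of centered cells is zero")
    background_var = (mad / _MAD_TO_SD) ** 2
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eig = np.linalg.eigvalsh(cov)[::-1]  # non-increasing
    eig = np.maximum(eig, background_var)
    if d > n - 1:  # rank deficiency: pad the null spectrum at the noise floor
        eig[n - 1:] = background_var
    return NullModel(eigenvalues=eig, background_var=background_var, dim=d, n=n)


def two_means_ci(X: np.ndarray, rng: np.random.Generator, restarts: int = 10, max_iter: int = 100) -> float:
    """Best (lowest) cluster index over seeded 2-means restarts.

    All restarts run batched Lloyd iterations; initial centers are random
    distinct data points.  Minimizing within-cluster sum of squares is
    equivalent to minimizing the cluster index (total is fixed).
    """
    X = np.asarray(data_matrix(X), dtype=float)
    n = X.shape[0]
    idx = np.empty((restarts, 2), dtype=int)
    for r in range(restarts):
        idx[r] = rng.choice(n, size=2, replace=False)
    centers = X[idx]  # (R, 2, d)
    assign = np.zeros((restarts, n), dtype=int)
    for _ in range(max_iter):
        # squared distances to both centers: (R, n, 2)
        d0 = ((X[None, :, :] - centers[:, 0:1, :]) ** 2).sum(-1)
        d1 = ((X[None, :, :] - centers[:, 1:2, :]) ** 2).sum(-1)
        new_assign = (d1 < d0).astype(int)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for r in range(restarts):
            for k in (0, 1):
                mask = assign[r] == k
                if mask.any():
                    centers[r, k] = X[mask].mean(axis=0)
                else:  # empty cluster: reseed at the farthest point
                    far = np.argmax(((X - centers[r, 1 - k]) ** 2).sum(-1))
                    centers[r, k] = X[far]
    total = float(((X - X.mean(axis=0)) ** 2).sum())
    best = np.inf
    for r in range(restarts):
        lab = assign[r]
        if lab.min() == lab.max():
            continue  # degenerate split
        within = 0.0
        for k in (0, 1):
            pts = X[lab == k]
            within += float(((pts - pts.mean(axis=0)) ** 2).sum())
        best = min(best, within / total)
    if not np.isfinite(best):
        best = 1.0
    return best


def data_matrix(X) -> np.ndarray:
    return np.asarray(X, dtype=float)


def simulate_null_ci(
    null: NullModel, n_sim: int, seed: int, restarts: int = 10
) -> np.ndarray:
    """Cluster indices of 2-means splits of single-Gaussian replicates."""
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100 for stable null moments")
    rng = np.random.default_rng(seed)
    sd = np.sqrt(null.eigenvalues)
    out = np.empty(n_sim)
    for s in range(n_sim):
        Z = rng.standard_normal((null.n, null.dim)) * sd
        out[s] = two_means_ci(Z, rng, restarts=restarts)
    return out


def sigclust_pair(
    data: np.ndarray,
    labels: np.ndarray,
    n_sim: int = 1000,
    seed: int = 0,
    restarts: int = 10,
    use_given_labels: bool = True,
    pair=("a", "b"),
) -> SigClustResult:
    """Run the SigClust test for one two-class split.

    The observed CI uses the given cluster labels by default (the tested
    hypothesis is the clusters' separation); set ``use_given_labels=False``
    to re-split the observed data by 2-means as the original procedure does.
    """
    X = np.asarray(data, dtype=float)
    if use_given_labels:
        ci_obs = cluster_index(X, labels)
    else:
        ci_obs = two_means_ci(X, np.random.default_rng(seed + 1), restarts=restarts)
    null = estimate_null_model(X)
    null_cis = simulate_null_ci(null, n_sim=n_sim, seed=seed, restarts=restarts)
    mu, sd = float(null_cis.mean()), float(null_cis.std(ddof=1))
    z = (ci_obs - mu) / sd
    return SigClustResult(
        pair=tuple(pair),
        ci_observed=float(ci_obs),
        null_mean=mu,
        null_sd=sd,
        z=float(z),
        p_normal=float(stats.norm.cdf(z)),
        p_empirical=float(np.mean(null_cis <= ci_obs)),
        n_sim=n_sim,
        seed=seed,
    )


def pairwise_sigclust(
    prepared_values: np.ndarray,
    bicluster_set,
    n_sim: int = 1000,
    seed: int = 0,
    restarts: int = 10,
) -> list[SigClustResult]:
    """SigClust over every unordered pair of biclusters.

    For each pair the data are the pooled rows of the two biclusters over
    ALL prepared columns (not the biclusters' own column subsets), so the
    test asks whether the knee groups separate in the full feature space.
    """
    X = np.asarray(prepared_values, dtype=float)
    bcs = bicluster_set.biclusters
    if len(bcs) < 2:
        raise ValueError("need at least 2 biclusters for pairwise testing")
    results = []
    for a, b in combinations(range(len(bcs)), 2):
        rows_a = list(bcs[a].rows)
        rows_b = list(bcs[b].rows)
        if len(rows_a) < 2 or len(rows_b) < 2:
            continue
        rows = rows_a + rows_b
        labels = np.array([0] * len(rows_a) + [1] * len(rows_b))
        # per-pair seed keeps pairs independent and the whole table reproducible
        pair_seed = (seed + 104729 * (a * len(bcs) + b)) % (2**31)
        results.append(
            sigclust_pair(
                X[rows], labels, n_sim=n_sim, seed=pair_seed, restarts=restarts,
                pair=(a + 1, b + 1),
            )
        )
    return results


def results_table(results: list[SigClustResult]) -> pd.DataFrame:
    rows = [r.to_dict() for r in results]
    df = pd.DataFrame(rows)
    df[["bicluster_a", "bicluster_b"]] = pd.DataFrame(df["pair"].tolist(), index=df.index)
    return df.drop(columns=["pair"])


def mean_difference_projection(
    data: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto (mean-difference direction, orthogonal first PC).

    Axis 1 is the unit vector between the two class means; axis 2 is the
    leading principal component of the data after removing the axis-1
    component.  Returns ``(coords (n, 2), axes (2, d))``.
    """
    X = np.asarray(data, dtype=float)
    lab = np.asarray(labels)
    classes = np.unique(lab)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    m0 = X[lab == classes[0]].mean(axis=0)
    m1 = X[lab == classes[1]].mean(axis=0)
    diff = m1 - m0
    norm = np.linalg.norm(diff)
    if norm == 0:
        raise ValueError("identical class means: mean-difference direction undefined")
    a1 = diff / norm
    Xc = X - X.mean(axis=0)
    resid = Xc - np.outer(Xc @ a1, a1)
    # leading right singular vector of the residual = orthogonal first PC
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    a2 = vt[0]
    coords = np.column_stack([Xc @ a1, Xc @ a2])
    return coords, np.vstack([a1, a2])
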