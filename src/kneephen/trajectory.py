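"""Group-based trajectory modeling of change-from-baseline pain.

Fits a finite mixture of polynomial mean trajectories to a long-format
longitudinal panel by maximum likelihood (EM).  The response is the change
from baseline at months 12, 24, 36, 48, 72 and 96; the month-0 change is
identically zero and is excluded from the likelihood.  Months are rescaled
by /96 inside the polynomial basis for numerical conditioning.

An optional dropout extension models the per-visit probability of first
missingness with a per-group logistic in (intercept, previous observed
response), so that informative monotone attrition contributes to both the
likelihood and the posterior group probabilities.

Model choice follows the usual recipe: fit G = 1..G_max starting from
cubic means, prune the highest-order polynomial term of any group whose
Wald test is non-significant (p > 0.05), and pick the fit minimizing
BIC = -2*loglik + k*log(n_knees).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logsumexp

__all__ = [
    "GbtmModel",
    "TrajectoryAssignment",
    "MODEL_MONTHS",
    "ALL_MONTHS",
    "gbtm_loglik",
    "fit_gbtm",
    "select_model",
    "posterior_assign",
    "group_proportion_ci",
]

ALL_MONTHS = (0, 12, 24, 36, 48, 72, 96)
MODEL_MONTHS = (12, 24, 36, 48, 72, 96)
TIME_SCALE = 96.0
GOOD_FIT_THRESHOLD = 0.8

_LOG_2PI = float(np.log(2 * np.pi))


@dataclass
class GbtmModel:
    """A fitted polynomial-trajectory mixture.

    ``beta[g]`` are the polynomial coefficients of group g (constant term
    first) on the scaled time axis month/96; ``sigma`` is the shared
    residual sd; ``dropout_coef[g]`` is (intercept, slope on previous
    response) when the dropout extension is on, else None.
    """

    G: int
    beta: list
    sigma: float
    pi: np.ndarray
    dropout_coef: Optional[list]
    loglik: float
    bic: float
    n_knees: int
    converged: bool
    n_iter: int
    loglik_history: list = field(default_factory=list)
    knee_ids: list = field(default_factory=list)
    # component likelihood matrix (n_knees x G, likelihood excluding pi)
    # kept from the final E-step for posterior work and profile CIs
    log_component_lik_: Optional[np.ndarray] = None
    selection_path: list = field(default_factory=list)

    @property
    def degrees(self) -> list:
        return [len(b) - 1 for b in self.beta]

    @property
    def n_params(self) -> int:
        k = (self.G - 1) + sum(len(b) for b in self.beta) + 1
        if self.dropout_coef is not None:
            k += 2 * self.G
        return k

    def mean_trajectory(self, g: int, months=MODEL_MONTHS) -> np.ndarray:
        t = np.asarray(months, dtype=float) / TIME_SCALE
        return _design(t, len(self.beta[g]) - 1) @ self.beta[g]

    def to_dict(self) -> dict:
        return {
            "G": self.G,
            "beta": [list(map(float, b)) for b in self.beta],
            "sigma": self.sigma,
            "pi": list(map(float, self.pi)),
            "dropout_coef": None
            if self.dropout_coef is None
            else [list(map(float, c)) for c in self.dropout_coef],
            "loglik": self.loglik,
            "bic": self.bic,
            "n_knees": self.n_knees,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "selection_path": self.selection_path,
        }


@dataclass
class TrajectoryAssignment:
    """Posterior group probabilities and hard assignments per knee."""

    knee_ids: list
    posterior: np.ndarray  # (n, G), rows sum to 1
    assigned_group: np.ndarray  # argmax, ties -> lowest group id
    max_prob: np.ndarray
    good_fit: np.ndarray  # max_prob >= 0.8

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.posterior,
            index=self.knee_ids,
            columns=[f"p_group{g + 1}" for g in range(self.posterior.shape[1])],
        )
        df["assigned_group"] = self.assigned_group + 1
        df["max_prob"] = self.max_prob
        df["good_fit"] = self.good_fit
        df.index.name = "knee_id"
        return df


def _design(t: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(t, degree + 1, increasing=True)


def _panel_to_wide(panel: pd.DataFrame):
    """Pivot the long panel to a (knees x model-months) response matrix.

    Knees with a month-0 record but no post-baseline observation are kept
    out with a warning count (they carry no likelihood information).
    """
    df = panel[panel["month"].isin(MODEL_MONTHS)]
    wide = df.pivot_table(index="knee_id", columns="month", values="value", aggfunc="first")
    wide = wide.reindex(columns=list(MODEL_MONTHS))
    n_obs = wide.notna().sum(axis=1)
    kept = wide.loc[n_obs > 0]
    knee_ids = list(kept.index)
    Y = kept.to_numpy(dtype=float)
    mask = np.isfinite(Y)
    return knee_ids, Y, mask


def _first_missing_index(mask: np.ndarray) -> np.ndarray:
    """Index of the first missing model visit per knee (K if fully observed)."""
    n, K = mask.shape
    first = np.full(n, K, dtype=int)
    for k in range(K - 1, -1, -1):
        first[~mask[:, k]] = k
    return first


def _prev_response(Y: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Previous observed change per visit; month-0 change (0) before visit 1."""
    prev = np.zeros_like(Y)
    prev[:, 1:] = np.where(mask[:, :-1], Y[:, :-1], 0.0)
    return prev


def _log_component_lik(
    Y, mask, beta, sigma, dropout_coef, first_miss, prev
) -> np.ndarray:
    """log likelihood of each knee under each group (mixing weights excluded)."""
    n, K = Y.shape
    G = len(beta)
    t = np.asarray(MODEL_MONTHS, dtype=float) / TIME_SCALE
    out = np.zeros((n, G))
    for g in range(G):
        mu = _design(t, len(beta[g]) - 1) @ beta[g]
        r = np.where(mask, Y - mu[None, :], 0.0)
        ll = -0.5 * (r / sigma) ** 2 - np.log(sigma) - 0.5 * _LOG_2PI
        out[:, g] = np.where(mask, ll, 0.0).sum(axis=1)
        if dropout_coef is not None:
            a0, a1 = dropout_coef[g]
            eta = a0 + a1 * prev
            # survived visits contribute log(1-p); the first missing visit log(p)
            logp = -np.logaddexp(0.0, -eta)  # log sigmoid
            log1mp = -np.logaddexp(0.0, eta)
            at_risk = np.arange(K)[None, :] <= first_miss[:, None]
            dropped = np.arange(K)[None, :] == first_miss[:, None]
            contrib = np.where(dropped, logp, log1mp)
            out[:, g] += np.where(at_risk, contrib, 0.0).sum(axis=1)
    return out


def gbtm_loglik(model: GbtmModel, panel: pd.DataFrame) -> float:
    """Mixture log-likelihood of a panel under a fitted model."""
    _, Y, mask = _panel_to_wide(panel)
    first_miss = _first_missing_index(mask)
    prev = _prev_response(Y, mask)
    lc = _log_component_lik(
        Y, mask, model.beta, model.sigma, model.dropout_coef, first_miss, prev
    )
    return float(logsumexp(lc + np.log(model.pi)[None, :], axis=1).sum())


def _weighted_logistic(x: np.ndarray, y: np.ndarray, w: np.ndarray, n_iter: int = 30):
    """Newton-Raphson weighted logistic fit of (intercept, slope); ridge 1e-6."""
    X = np.column_stack([np.ones_like(x), x])
    coef = np.zeros(2)
    for _ in range(n_iter):
        p = expit(X @ coef)
        grad = X.T @ (w * (y - p)) - 1e-6 * coef
        Wd = w * p * (1 - p)
        H = X.T @ (X * Wd[:, None]) + 1e-6 * np.eye(2)
        step = np.linalg.solve(H, grad)
        coef = coef + step
        if np.abs(step).max() < 1e-10:
            break
    return coef


def _m_step(Y, mask, w, degrees, dropout, first_miss, prev, per_group_sigma=False):
    n, K = Y.shape
    G = w.shape[1]
    t = np.asarray(MODEL_MONTHS, dtype=float) / TIME_SCALE
    pi = w.mean(axis=0)
    beta = []
    sse = 0.0
    wsum = 0.0
    for g in range(G):
        X = _design(t, degrees[g])  # (K, d+1)
        # stack observed cells: weight w[i,g] per cell
        Wc = (w[:, g][:, None] * mask).ravel()
        Xc = np.tile(X, (n, 1))
        yc = np.where(mask, Y, 0.0).ravel()
        XtW = Xc.T * Wc
        A = XtW @ Xc + 1e-10 * np.eye(degrees[g] + 1)
        b = XtW @ yc
        bg = np.linalg.solve(A, b)
        beta.append(bg)
        mu = X @ bg
        r = np.where(mask, Y - mu[None, :], 0.0)
        sse += float((w[:, g][:, None] * mask * r**2).sum())
        wsum += float((w[:, g][:, None] * mask).sum())
    sigma = float(np.sqrt(max(sse / wsum, 1e-12)))
    dropout_coef = None
    if dropout:
        dropout_coef = []
        at_risk = np.arange(K)[None, :] <= first_miss[:, None]
        dropped = (np.arange(K)[None, :] == first_miss[:, None]).astype(float)
        xs = prev[at_risk]
        ys = dropped[at_risk]
        for g in range(G):
            wg = np.broadcast_to(w[:, g][:, None], at_risk.shape)[at_risk]
            dropout_coef.append(_weighted_logistic(xs, ys, wg))
    return pi, beta, sigma, dropout_coef


def _run_em(
    Y, mask, degrees, dropout, rng, max_iter=500, tol=1e-6, debug=False
):
    n, K = Y.shape
    G = len(degrees)
    first_miss = _first_missing_index(mask)
    prev = _prev_response(Y, mask)
    # hard random initial assignment (every group non-empty)
    assign = rng.integers(0, G, size=n)
    for g in range(G):
        if not (assign == g).any():
            assign[rng.integers(0, n)] = g
    w = np.zeros((n, G))
    w[np.arange(n), assign] = 1.0
    pi, beta, sigma, dcoef = _m_step(Y, mask, w, degrees, dropout, first_miss, prev)
    history = []
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lc = _log_component_lik(Y, mask, beta, sigma, dcoef, first_miss, prev)
        logw = lc + np.log(np.maximum(pi, 1e-300))[None, :]
        lse = logsumexp(logw, axis=1)
        new_loglik = float(lse.sum())
        if debug and new_loglik < loglik - 1e-8:
            raise AssertionError("EM log-likelihood decreased")
        history.append(new_loglik)
        delta_ll = abs(new_loglik - loglik) if np.isfinite(loglik) else np.inf
        if delta_ll < tol:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
        w = np.exp(logw - lse[:, None])
        pi, beta, sigma, dcoef = _m_step(Y, mask, w, degrees, dropout, first_miss, prev)
    else:
        # near-degenerate mixtures can crawl below any strict tolerance;
        # a small final improvement is accepted as practical convergence
        converged = delta_ll < 2e-2
    lc = _log_component_lik(Y, mask, beta, sigma, dcoef, first_miss, prev)
    return {
        "pi": pi,
        "beta": beta,
        "sigma": sigma,
        "dropout_coef": dcoef,
        "loglik": loglik,
        "history": history,
        "converged": converged,
        "n_iter": it,
        "log_component_lik": lc,
    }


def fit_gbtm(
    panel: pd.DataFrame,
    G: int,
    degrees=3,
    dropout: bool = False,
    seed: int = 0,
    n_starts: int = 10,
    max_iter: int = 400,
    tol: float = 1e-6,
    debug: bool = False,
) -> GbtmModel:
    """Fit a G-group trajectory mixture by EM, best of ``n_starts`` restarts.

    ``degrees`` is a single polynomial degree for all groups or a per-group
    sequence.  Raises if no restart converges (carrying the best attempt in
    the exception arguments).
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    if isinstance(degrees, int):
        degrees = [degrees] * G
    degrees = list(degrees)
    if len(degrees) != G:
        raise ValueError("degrees must have one entry per group")
    knee_ids, Y, mask = _panel_to_wide(panel)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_starts if G > 1 else 1)):
        res = _run_em(Y, mask, degrees, dropout, rng, max_iter=max_iter, tol=tol, debug=debug)
        better = best is None or res["loglik"] > best["loglik"]
        # a converged local maximum beats a higher but unconverged crawl
        if best is not None and res["converged"] != best["converged"]:
            better = res["converged"]
        if better:
            best = res
    if not best["converged"]:
        raise RuntimeError("EM did not converge on any restart", best)
    n = len(knee_ids)
    k = (G - 1) + sum(d + 1 for d in degrees) + 1 + (2 * G if dropout else 0)
    bic = -2.0 * best["loglik"] + k * np.log(n)
    return GbtmModel(
        G=G,
        beta=best["beta"],
        sigma=best["sigma"],
        pi=best["pi"],
        dropout_coef=best["dropout_coef"],
        loglik=best["loglik"],
        bic=float(bic),
        n_knees=n,
        converged=True,
        n_iter=best["n_iter"],
        loglik_history=best["history"],
        knee_ids=knee_ids,
        log_component_lik_=best["log_component_lik"],
    )


def _wald_p_top_coef(model: GbtmModel, panel: pd.DataFrame) -> list:
    """Wald p-value of each group's highest-order polynomial coefficient.

    Uses the weighted-least-squares covariance at the EM fixed point:
    Cov(beta_g) = sigma^2 (X' W_g X)^-1 with posterior weights W_g.
    """
    _, Y, mask = _panel_to_wide(panel)
    logw = model.log_component_lik_ + np.log(model.pi)[None, :]
    w = np.exp(logw - logsumexp(logw, axis=1)[:, None])
    t = np.asarray(MODEL_MONTHS, dtype=float) / TIME_SCALE
    ps = []
    for g in range(model.G):
        d = len(model.beta[g]) - 1
        X = _design(t, d)
        n = Y.shape[0]
        Wc = (w[:, g][:, None] * mask).ravel()
        Xc = np.tile(X, (n, 1))
        A = (Xc.T * Wc) @ Xc + 1e-10 * np.eye(d + 1)
        cov = model.sigma**2 * np.linalg.inv(A)
        se = np.sqrt(max(cov[d, d], 1e-300))
        zstat = model.beta[g][d] / se
        ps.append(float(2 * stats.norm.sf(abs(zstat))))
    return ps


def select_model(
    panel: pd.DataFrame,
    G_max: int,
    seed: int = 0,
    dropout: bool = False,
    n_starts: int = 10,
    start_degree: int = 3,
    alpha: float = 0.05,
) -> GbtmModel:
    """BIC-based group-number selection with polynomial-term pruning.

    For each G the fit starts from degree-``start_degree`` means; any group
    whose highest-order coefficient has Wald p > alpha loses that term and
    the model is refit, until all top terms are significant (or constant).
    The BIC-minimizing fit over G = 1..G_max is returned with its full
    selection path logged.
    """
    if G_max < 1:
        raise ValueError("G_max must be >= 1")
    path = []
    best = None
    for G in range(1, G_max + 1):
        degrees = [start_degree] * G
        while True:
            model = fit_gbtm(
                panel, G, degrees=degrees, dropout=dropout,
                seed=seed + G, n_starts=n_starts,
            )
            ps = _wald_p_top_coef(model, panel)
            prune = [
                g for g in range(G)
                if degrees[g] > 0 and ps[g] > alpha
            ]
            path.append({"G": G, "degrees": list(degrees), "bic": model.bic,
                         "top_term_p": ps})
            if not prune:
                break
            for g in prune:
                degrees[g] -= 1
        if best is None or model.bic < best.bic:
            best = model
    best.selection_path = path
    return best


def posterior_assign(model: GbtmModel, panel: pd.DataFrame) -> TrajectoryAssignment:
    """Posterior group probabilities; argmax assignment; 0.8 good-fit rule."""
    knee_ids, Y, mask = _panel_to_wide(panel)
    first_miss = _first_missing_index(mask)
    prev = _prev_response(Y, mask)
    lc = _log_component_lik(
        Y, mask, model.beta, model.sigma, model.dropout_coef, first_miss, prev
    )
    logw = lc + np.log(model.pi)[None, :]
    post = np.exp(logw - logsumexp(logw, axis=1)[:, None])
    assigned = np.argmax(post, axis=1)  # argmax takes the lowest index on ties
    max_prob = post[np.arange(post.shape[0]), assigned]
    return TrajectoryAssignment(
        knee_ids=knee_ids,
        posterior=post,
        assigned_group=assigned,
        max_prob=max_prob,
        good_fit=max_prob >= GOOD_FIT_THRESHOLD,
    )


def group_proportion_ci(model: GbtmModel, level: float = 0.95):
    """Normal-approximation CI for each mixing proportion.

    Profiles the mixture log-likelihood in the logit-transformed mixing
    weights (other parameters held at their estimates), takes the observed
    information by central finite differences, and maps the variance to
    the proportion scale by the softmax Jacobian.  Returns a list of
    (estimate, lower, upper); bounds clipped to [0, 1].  A singular
    information matrix falls back to the trivial interval with a flag.
    """
    if model.G == 1:
        return [(1.0, 1.0, 1.0)]
    lc = model.log_component_lik_
    if lc is None:
        raise ValueError("model carries no component-likelihood matrix")
    Gm1 = model.G - 1
    pi_hat = np.asarray(model.pi, dtype=float)
    gamma0 = np.log(pi_hat[:-1] / pi_hat[-1])

    def loglik_gamma(gamma):
        e = np.concatenate([np.exp(gamma), [1.0]])
        pi = e / e.sum()
        return float(logsumexp(lc + np.log(pi)[None, :], axis=1).sum())

    h = 1e-5
    H = np.zeros((Gm1, Gm1))
    for a in range(Gm1):
        for b in range(a, Gm1):
            ea, eb = np.zeros(Gm1), np.zeros(Gm1)
            ea[a] = h
            eb[b] = h
            fpp = loglik_gamma(gamma0 + ea + eb)
            fpm = loglik_gamma(gamma0 + ea - eb)
            fmp = loglik_gamma(gamma0 - ea + eb)
            fmm = loglik_gamma(gamma0 - ea - eb)
            H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    info = -H
    z = stats.norm.ppf(0.5 + level / 2)
    try:
        cov_gamma = np.linalg.inv(info)
        if not np.all(np.isfinite(cov_gamma)) or np.any(np.diag(cov_gamma) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        return [(float(p), 0.0, 1.0) for p in pi_hat]
    # softmax Jacobian with the last logit fixed at 0
    J = np.zeros((model.G, Gm1))
    for g in range(model.G):
        for hcol in range(Gm1):
            J[g, hcol] = pi_hat[g] * ((g == hcol) - pi_hat[hcol])
    var_pi = np.clip(np.diag(J @ cov_gamma @ J.T), 0.0, None)
    se = np.sqrt(var_pi)
    out = []
    for g in range(model.G):
        lo = float(np.clip(pi_hat[g] - z * se[g], 0.0, 1.0))
        hi = float(np.clip(pi_hat[g] + z * se[g], 0.0, 1.0))
        out.append((float(pi_hat[g]), lo, hi))
    return out
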