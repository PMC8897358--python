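"""Maximum-likelihood population-effects (MLPE) mixed models.

Pairwise genetic distances are regressed on standardized pairwise
effective distances with a random intercept per population. Each pair
(i, j) carries the two population effects u_i + u_j, absorbing the
non-independence of pairwise distances that share a population:

    y_ij = beta0 + x_ij' beta + u_i + u_j + eps_ij,
    u ~ N(0, sigma_u^2), eps ~ N(0, sigma_e^2).

Writing Z for the pair-to-population incidence (two unit entries per
row), the response covariance is sigma_e^2 I + sigma_u^2 Z Z'. Variance
components are estimated by full maximum likelihood — a profile search
over the variance ratio with generalized least squares for the fixed
effects — so that AICc comparisons across fixed-effect structures are
valid. Goodness of fit is summarized by the marginal and conditional R²
for mixed models (fixed, and fixed plus random, variance shares).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = ["PairDesign", "MLPEFit", "build_design", "fit_mlpe", "aicc", "r2_nakagawa"]

_VARIANCE_FLOOR = 1e-10


@dataclass
class PairDesign:
    """Vectorized upper-triangle design for MLPE fitting."""

    y: np.ndarray                  # (n_pairs,)
    X: np.ndarray                  # (n_pairs, p) standardized predictors
    predictor_names: list[str]
    pop_ids: list
    pair_index: np.ndarray         # (n_pairs, 2) population indices i < j

    @property
    def n_pops(self) -> int:
        return len(self.pop_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.y)

    def incidence(self) -> np.ndarray:
        Z = np.zeros((self.n_pairs, self.n_pops))
        rows = np.arange(self.n_pairs)
        Z[rows, self.pair_index[:, 0]] = 1.0
        Z[rows, self.pair_index[:, 1]] = 1.0
        return Z

    def subset(self, pop_positions: np.ndarray) -> "PairDesign":
        """Restrict to a subset of populations (bootstrap support)."""
        pop_positions = np.sort(np.asarray(pop_positions))
        keep_pos = {int(p): k for k, p in enumerate(pop_positions)}
        sel = np.array([
            (a in keep_pos and b in keep_pos) for a, b in self.pair_index
        ])
        new_pairs = np.array(
            [[keep_pos[int(a)], keep_pos[int(b)]] for a, b in self.pair_index[sel]]
        )
        X = self.X[sel]
        # re-standardize predictors over the retained pairs
        if X.size:
            sd = X.std(axis=0, ddof=0)
            if np.any(sd == 0):
                raise ValueError("a predictor is constant over the retained pairs")
            X = (X - X.mean(axis=0)) / sd
        return PairDesign(
            y=self.y[sel],
            X=X,
            predictor_names=list(self.predictor_names),
            pop_ids=[self.pop_ids[int(p)] for p in pop_positions],
            pair_index=new_pairs,
        )


@dataclass
class MLPEFit:
    beta0: float
    beta: np.ndarray
    sigma2_u: float
    sigma2_e: float
    logLik: float
    k: int
    aicc: float
    r2m: float
    r2c: float
    sigma_u_boundary: bool = False
    predictor_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta": dict(zip(self.predictor_names, np.atleast_1d(self.beta).tolist())),
            "sigma2_u": self.sigma2_u,
            "sigma2_e": self.sigma2_e,
            "logLik": self.logLik,
            "k": self.k,
            "AICc": self.aicc,
            "R2m": self.r2m,
            "R2c": self.r2c,
            "sigma_u_boundary": self.sigma_u_boundary,
        }


def _upper_triangle(df: pd.DataFrame, ids: list) -> np.ndarray:
    m = df.loc[ids, ids].to_numpy(dtype=float)
    iu = np.triu_indices(len(ids), k=1)
    return m[iu]


def build_design(
    gd: pd.DataFrame,
    dists: list[pd.DataFrame] | dict[str, pd.DataFrame],
    linearize: bool = False,
) -> PairDesign:
    """Vectorize matched distance matrices into an MLPE design.

    ``gd`` is the square pairwise genetic-distance matrix (index = columns
    = population ids); each entry of ``dists`` is a square effective-
    distance matrix on the same ids. Predictors are centered and scaled to
    unit standard deviation. ``linearize`` regresses Fst/(1 - Fst) instead
    of raw Fst; the default regresses the raw values.
    """
    if isinstance(dists, dict):
        names = list(dists.keys())
        mats = list(dists.values())
    else:
        mats = list(dists)
        names = [getattr(m, "name", None) or f"dist{i}" for i, m in enumerate(mats)]
    ids = list(gd.index)
    for m in mats:
        if set(m.index) != set(ids) or set(m.columns) != set(ids):
            diff = set(m.index).symmetric_difference(ids)
            raise ValueError(f"population id mismatch between matrices: {sorted(diff)}")
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    y = _upper_triangle(gd, ids)
    if linearize:
        if np.any(y >= 1.0):
            raise ValueError("cannot linearize: some Fst values are >= 1")
        y = y / (1.0 - y)
    cols = []
    for nm, m in zip(names, mats):
        x = _upper_triangle(m, ids)
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"predictor {nm!r} has zero variance; cannot standardize")
        cols.append((x - x.mean()) / sd)
    X = np.column_stack(cols) if cols else np.empty((len(y), 0))
    return PairDesign(
        y=y,
        X=X,
        predictor_names=names,
        pop_ids=ids,
        pair_index=np.column_stack(iu),
    )


@lru_cache(maxsize=64)
def _pair_eigh(n_pops: int):
    """Eigendecomposition of Z Z' for the complete pair set of n_pops."""
    n_pairs = n_pops * (n_pops - 1) // 2
    iu = np.triu_indices(n_pops, k=1)
    Z = np.zeros((n_pairs, n_pops))
    rows = np.arange(n_pairs)
    Z[rows, iu[0]] = 1.0
    Z[rows, iu[1]] = 1.0
    K = Z @ Z.T
    d, Q = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    return d, Q


def _profile_loglik(lam, d, yt, Xt):
    """Profile log-likelihood at variance ratio lam; returns (ll, beta, s2e)."""
    w = 1.0 + lam * d
    Wi = 1.0 / w
    XtW = Xt * Wi[:, None]
    G = XtW.T @ Xt
    beta = np.linalg.solve(G, XtW.T @ yt)
    r = yt - Xt @ beta
    n = len(yt)
    s2e = max(float(r @ (Wi * r)) / n, _VARIANCE_FLOOR)
    ll = -0.5 * n * np.log(2.0 * np.pi * s2e) - 0.5 * float(np.log(w).sum()) - 0.5 * n
    return ll, beta, s2e


def fit_mlpe(
    d: PairDesign, n_optimized: int = 0, n_effective: int | None = None
) -> MLPEFit:
    """Fit the MLPE model by profile maximum likelihood.

    ``n_optimized`` counts surfaces whose two transformation parameters
    were tuned upstream; they enter the AICc parameter count. The AICc
    sample size ``n_effective`` defaults to the number of populations
    (pairs are not independent observations).
    """
    if d.n_pops < 4:
        raise ValueError("MLPE requires at least 4 populations")
    iu = np.triu_indices(d.n_pops, k=1)
    if d.n_pairs != len(iu[0]) or not np.array_equal(
        d.pair_index, np.column_stack(iu)
    ):
        raise ValueError("design must cover the complete pair set in i<j order")
    evals, Q = _pair_eigh(d.n_pops)
    Xfull = np.column_stack([np.ones(d.n_pairs), d.X])
    yt = Q.T @ d.y
    Xt = Q.T @ Xfull

    def neg(t: float) -> float:
        return -_profile_loglik(10.0 ** t, evals, yt, Xt)[0]

    res = minimize_scalar(neg, bounds=(-10.0, 6.0), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"MLPE profile search failed to converge: {res}")
    candidates = [0.0, 10.0 ** float(res.x)]
    lls = [_profile_loglik(lam, evals, yt, Xt) for lam in candidates]
    best = int(np.argmax([l[0] for l in lls]))
    lam = candidates[best]
    ll, beta, s2e = lls[best]
    s2u = lam * s2e
    p = d.X.shape[1]
    k = 1 + p + 2 + 2 * n_optimized
    n_eff = d.n_pops if n_effective is None else n_effective
    fit = MLPEFit(
        beta0=float(beta[0]),
        beta=np.asarray(beta[1:]),
        sigma2_u=float(s2u),
        sigma2_e=float(s2e),
        logLik=float(ll),
        k=k,
        aicc=aicc(float(ll), k, n_eff),
        r2m=0.0,
        r2c=0.0,
        sigma_u_boundary=bool(lam == 0.0),
        predictor_names=list(d.predictor_names),
    )
    fit.r2m, fit.r2c = r2_nakagawa(fit, d)
    return fit


def aicc(logLik: float, k: int, n_effective: int) -> float:
    """Small-sample corrected Akaike criterion.

    AICc = -2 logLik + 2k + 2k(k+1) / (n_effective - k - 1).
    """
    if n_effective <= k + 1:
        raise ValueError(
            f"AICc undefined: n_effective={n_effective} must exceed k+1={k + 1}"
        )
    return -2.0 * logLik + 2.0 * k + 2.0 * k * (k + 1) / (n_effective - k - 1)


def r2_nakagawa(fit: MLPEFit, d: PairDesign) -> tuple[float, float]:
    """Marginal and conditional R² for the MLPE model.

    The random-effect variance enters twice (each pair carries two
    population effects): R²m = s²_f / (s²_f + 2 s²_u + s²_e) and
    R²c = (s²_f + 2 s²_u) / (s²_f + 2 s²_u + s²_e), with s²_f the variance
    of the fixed-effect predictions over pairs.
    """
    fixed = d.X @ np.atleast_1d(fit.beta) if d.X.size else np.zeros(d.n_pairs)
    s2f = float(np.var(fixed))
    denom = s2f + 2.0 * fit.sigma2_u + fit.sigma2_e
    return s2f / denom, (s2f + 2.0 * fit.sigma2_u) / denom
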