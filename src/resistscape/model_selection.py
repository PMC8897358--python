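"""Candidate-model enumeration, AICc ranking, and bootstrap rank stability.

The candidate set holds every non-empty subset of the retained covariates
plus two reference models: the intercept-only null and the distance-only
(isolation-by-distance) model whose resistance is 1 everywhere. Models
are ranked by AICc; the top set is everything within ``delta_threshold``
(default 2) of the best. Rank stability is assessed by repeatedly
subsampling a fraction of the populations without replacement,
refitting every candidate's MLPE on the restricted pairwise matrices with
its previously optimized surfaces (no re-optimization), and aggregating
the frequency each model reaches the top rank and its mean rank; tied
models are all awarded the top rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .mlpe import MLPEFit, build_design, fit_mlpe

__all__ = [
    "Candidate",
    "CandidateSet",
    "SelectionReport",
    "enumerate_candidates",
    "rank_models",
    "bootstrap_ranking",
    "BootstrapCandidate",
]


@dataclass(frozen=True)
class Candidate:
    name: str
    kind: str                       # "null" | "ibd" | "surface"
    covariates: tuple[str, ...] = ()


@dataclass
class CandidateSet:
    models: list[Candidate]

    def __len__(self) -> int:
        return len(self.models)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.models]


def enumerate_candidates(
    covariate_names: list[str], max_subset_size: int | None = None
) -> CandidateSet:
    """All non-empty covariate subsets plus null and distance-only models.

    With v covariates and no subset-size cap the set has 2**v - 1 + 2
    members. Ordering is deterministic: null, distance-only, then subsets
    by (size, lexicographic).
    """
    if not covariate_names:
        raise ValueError("need at least one covariate name")
    if len(set(covariate_names)) != len(covariate_names):
        raise ValueError("covariate names must be unique")
    models = [Candidate("null", "null"), Candidate("distance", "ibd")]
    cap = len(covariate_names) if max_subset_size is None else max_subset_size
    for size in range(1, cap + 1):
        for combo in combinations(sorted(covariate_names), size):
            models.append(Candidate("+".join(combo), "surface", combo))
    return CandidateSet(models)


@dataclass
class SelectionReport:
    table: pd.DataFrame             # per model: k, AICc, dAICc, R2m, R2c, top
    delta_threshold: float
    top_models: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "delta_threshold": self.delta_threshold,
            "top_models": self.top_models,
            "table": self.table.reset_index().to_dict(orient="records"),
        }


def rank_models(
    fits: dict[str, MLPEFit], delta_threshold: float = 2.0
) -> SelectionReport:
    """Rank fitted candidates by AICc; ΔAICc < threshold defines the top set.

    Ties are broken by fewer parameters, then lexicographic name.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fitted models to rank")
    rows = []
    for name, f in fits.items():
        rows.append({
            "model": name, "k": f.k, "logLik": f.logLik, "AICc": f.aicc,
            "R2m": f.r2m, "R2c": f.r2c,
        })
    df = pd.DataFrame(rows)
    df["dAICc"] = df["AICc"] - df["AICc"].min()
    df = df.sort_values(["AICc", "k", "model"], kind="stable").set_index("model")
    df["top"] = df["dAICc"] < delta_threshold
    return SelectionReport(
        table=df,
        delta_threshold=delta_threshold,
        top_models=df.index[df["top"]].tolist(),
    )


@dataclass(frozen=True)
class BootstrapCandidate:
    """What a candidate needs for refitting: its (already optimized)
    effective-distance predictors and its AICc parameter count inputs."""

    name: str
    predictors: tuple[str, ...] = ()   # keys into the dists mapping
    n_optimized: int = 0


def bootstrap_ranking(
    gd: pd.DataFrame,
    dists: dict[str, pd.DataFrame],
    candidates: list[BootstrapCandidate],
    frac: float = 0.75,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Population-subsampling stability of the AICc ranking.

    Per replicate, ``round(frac * n_pops)`` populations are drawn without
    replacement, all pairwise matrices are restricted to them, and every
    candidate is refit (variance components and all) on the subset.
    Returns a table with the top-rank percentage and mean rank per model.
    """
    if not (0 < frac <= 1):
        raise ValueError("frac must lie in (0, 1]")
    ids = list(gd.index)
    n_sub = int(round(frac * len(ids)))
    if n_sub < 4:
        raise ValueError(
            f"subset of {n_sub} populations is too small for MLPE (need >= 4)"
        )
    rng = np.random.default_rng(seed)
    names = [c.name for c in candidates]
    top_counts = np.zeros(len(candidates))
    rank_sums = np.zeros(len(candidates))
    for _rep in range(n_boot):
        keep = sorted(rng.choice(len(ids), size=n_sub, replace=False).tolist())
        sub_ids = [ids[i] for i in keep]
        gd_sub = gd.loc[sub_ids, sub_ids]
        sub_dists = {
            k: v.loc[sub_ids, sub_ids] for k, v in dists.items()
        }
        aiccs = np.empty(len(candidates))
        for ci, cand in enumerate(candidates):
            d = build_design(gd_sub, {p: sub_dists[p] for p in cand.predictors})
            aiccs[ci] = fit_mlpe(d, n_optimized=cand.n_optimized).aicc
        # competition ranks; ties share the better (minimum) rank
        ranks = np.array([1 + np.sum(aiccs < a - 1e-12) for a in aiccs])
        top_counts += ranks == 1
        rank_sums += ranks
    return pd.DataFrame(
        {
            "model": names,
            "bootstrap_pct": 100.0 * top_counts / n_boot,
            "mean_rank": rank_sums / n_boot,
            "n_populations": n_sub,
            "n_pairs": n_sub * (n_sub - 1) // 2,
        }
    ).set_index("model")
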