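"""Iterative random-forest imputation of a gene's sample-by-tissue matrix.

Each gene's N x K expression matrix is completed column by column: tissues
are sorted by ascending missingness, missing entries start at the column
mean, and each sweep retrains a regression forest per column on the rows
observed in that column (all other columns, in their current imputed state,
as predictors) and re-predicts that column's missing rows. Sweeps repeat
until the relative change over imputed entries first increases, at which
point the previous sweep's values are kept, or until ``max_iter``. Genotype
data are never consulted. Observed entries are returned bit-exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .types import ExpressionTensor

log = logging.getLogger(__name__)


@dataclass
class ImputeConfig:
    n_trees: int = 100
    max_iter: int = 10
    min_obs_per_tissue: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_iter < 1:
            raise ValueError("n_trees and max_iter must be >= 1")


def stopping_rule(deltas: list[float], max_iter: int) -> bool:
    """True after the sweep whose relative change first exceeds the previous
    sweep's (the caller then rolls back to the earlier iterate), or at
    ``max_iter``."""
    if len(deltas) >= 2 and deltas[-1] > deltas[-2]:
        return True
    return len(deltas) >= max_iter


def _sweep_delta(prev: np.ndarray, curr: np.ndarray, miss: np.ndarray) -> float:
    denom = float(np.sum(curr[miss] ** 2))
    if denom == 0.0:
        return 0.0
    return float(np.sum((curr[miss] - prev[miss]) ** 2)) / denom


def impute_gene(e: ExpressionTensor, cfg: ImputeConfig) -> ExpressionTensor:
    """missForest-style completion of one gene's expression tensor.

    Tissues with fewer than ``cfg.min_obs_per_tissue`` observed samples are
    dropped for this gene (logged). A single remaining tissue with missing
    entries is an error: there are no donor columns to regress on.
    """
    n_obs = e.n_obs()
    keep = [t for t in range(e.n_tissues) if n_obs[t] >= cfg.min_obs_per_tissue]
    dropped = [e.tissues[t] for t in range(e.n_tissues) if t not in keep]
    if dropped:
        log.info("gene %s: dropping tissue(s) %s (< %d observed samples)",
                 e.gene.id, dropped, cfg.min_obs_per_tissue)
    out = ExpressionTensor(
        gene=e.gene, samples=list(e.samples),
        tissues=[e.tissues[t] for t in keep],
        values=e.values[:, keep].copy(),
        observed_mask=e.observed_mask[:, keep].copy())

    mask = out.observed_mask
    if mask.all():
        return out
    if out.n_tissues == 1:
        raise ValueError("cannot impute with a single tissue (no donor columns)")

    vals = out.values
    n, k = vals.shape
    miss = ~mask
    # ascending-missingness column order; stable so ties keep input order
    order = np.argsort(miss.sum(axis=0), kind="stable")

    # initial fill: per-column observed mean
    for t in range(k):
        if mask[:, t].any():
            vals[miss[:, t], t] = vals[mask[:, t], t].mean()
        else:
            raise ValueError(f"tissue {out.tissues[t]} fully missing")

    max_features = k - 1 if k - 1 <= 10 else "sqrt"
    deltas: list[float] = []
    prev_state = vals.copy()
    for sweep in range(cfg.max_iter):
        for t in order:
            col_miss = miss[:, t]
            if not col_miss.any():
                continue
            predictors = np.delete(vals, t, axis=1)
            rf = RandomForestRegressor(
                n_estimators=cfg.n_trees, max_features=max_features,
                min_samples_leaf=5,  # missForest regression default node size
                random_state=(cfg.seed * 1009 + sweep * 31 + int(t)) % (2**31),
                n_jobs=1)
            rf.fit(predictors[mask[:, t]], vals[mask[:, t], t])
            vals[col_miss, t] = rf.predict(predictors[col_miss])
        deltas.append(_sweep_delta(prev_state, vals, miss))
        if len(deltas) >= 2 and deltas[-1] > deltas[-2]:
            vals[:] = prev_state  # roll back to the pre-increase iterate
            break
        if stopping_rule(deltas, cfg.max_iter):
            break
        prev_state = vals.copy()

    vals[mask] = e.values[:, keep][mask]  # bit-exact observed entries
    return out


def mean_impute(e: ExpressionTensor) -> ExpressionTensor:
    """Column-mean fill; the baseline oracle the forest must beat."""
    out = e.copy()
    for t in range(out.n_tissues):
        col = out.values[:, t]
        obs = out.observed_mask[:, t]
        col[~obs] = col[obs].mean()
    return out


def nrmse(imputed: ExpressionTensor, truth: ExpressionTensor) -> float:
    """Normalized RMSE over originally-missing entries against the truth."""
    miss = ~imputed.observed_mask
    cols = [imputed.tissues.index(t) for t in imputed.tissues]
    t_idx = [truth.tissues.index(t) for t in imputed.tissues]
    diff = imputed.values[:, cols][miss] - truth.values[:, t_idx][miss]
    denom = truth.values[:, t_idx][miss].std()
    return float(np.sqrt(np.mean(diff**2)) / denom)
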