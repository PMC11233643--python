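"""eQTL selection by EBIC-penalized constrained stepwise regression.

Cross-tissue eQTLs (ct-eQTLs) are found by regressing the leading principal
components of a gene's imputed sample-by-tissue expression matrix on its
cis-SNP genotypes; tissue-specific eQTLs (ts-eQTLs) are then found per
tissue conditional on the ct set, which enters the selection as a fixed set
that can never be removed. Effects of the combined set are estimated by
weighted least squares that down-weights imputed samples.

The selection criterion for a candidate set S (always a superset of the
fixed set S0) is the extended Bayesian information criterion

    EBIC_lambda(S) = -2 l_N(beta_S) + |S| log N + 2 lambda |S| log M

with the Gaussian profile log-likelihood l_N = -(N/2)[log(2 pi RSS/N) + 1]
and M the number of cis-SNP candidates. The search is a forward pass (add
the single candidate with the lowest EBIC while it decreases), a backward
pass (remove the non-fixed term with the lowest EBIC while it decreases),
and a final exhaustive enumeration of all subsets of the surviving non-fixed
terms, capped at ``max_enumeration`` terms.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .types import EqtlModel, ExpressionTensor, GenotypeMatrix, TissueWeights

log = logging.getLogger(__name__)

_RSS_FLOOR_REL = 1e-12  # guard against a numerically perfect fit inside the search


@dataclass
class EbicConfig:
    lambda_: float = 0.5
    eigenvalue_cutoff: float = 2.0
    min_pcs: int = 1
    max_enumeration: int = 15

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")
        if self.eigenvalue_cutoff <= 0:
            raise ValueError("eigenvalue_cutoff must be > 0")


@dataclass
class SelectionResult:
    fixed_set: frozenset[int]
    selected: frozenset[int]
    ebic_value: float
    trace: list[tuple[str, int, float]] = field(default_factory=list)
    enumeration_skipped: bool = False


def ebic(rss: float, n: int, k_selected: int, m_candidates: int, lambda_: float) -> float:
    """Extended BIC of a Gaussian linear model with residual sum of squares
    ``rss`` on ``n`` observations, ``k_selected`` selected terms out of
    ``m_candidates``."""
    if rss <= 0:
        raise ValueError("rss must be positive (perfect fit is degenerate)")
    if n < k_selected + 2:
        raise ValueError("need n >= k_selected + 2")
    if m_candidates < 1:
        raise ValueError("m_candidates must be >= 1")
    loglik = -(n / 2.0) * (np.log(2 * np.pi * rss / n) + 1.0)
    return float(-2.0 * loglik + k_selected * np.log(n)
                 + 2.0 * lambda_ * k_selected * np.log(m_candidates))


class _FitCache:
    """Weighted least-squares RSS for arbitrary SNP subsets, via the Gram
    matrix of the (intercept-augmented, sqrt-weight-scaled) design."""

    def __init__(self, y: np.ndarray, X: np.ndarray, weights: np.ndarray | None):
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        if weights is not None:
            sw = np.sqrt(np.asarray(weights, float))
            y = y * sw
            X = X * sw[:, None]
            ones = sw
        else:
            ones = np.ones(len(y))
        self.design = np.column_stack([ones, X])
        self.n = len(y)
        self.G = self.design.T @ self.design
        self.gy = self.design.T @ y
        self.yy = float(y @ y)
        self.rss_floor = max(_RSS_FLOOR_REL * self.yy, 1e-300)

    def rss(self, subset: tuple[int, ...]) -> float:
        """RSS of y on [intercept, X[:, subset]]; min-norm fit if singular."""
        cols = (0,) + tuple(j + 1 for j in subset)
        G = self.G[np.ix_(cols, cols)]
        gy = self.gy[list(cols)]
        try:
            beta = np.linalg.solve(G, gy)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(G, gy, rcond=None)[0]
        rss = self.yy - float(gy @ beta)
        return max(rss, self.rss_floor)


def stepwise_select(
    y: np.ndarray, X: np.ndarray, s0: set[int] | frozenset[int] | None,
    cfg: EbicConfig, weights: np.ndarray | None = None,
) -> SelectionResult:
    """Forward/backward/enumeration EBIC search constrained to contain s0.

    Returns the selected index set (a superset of s0), the attained EBIC,
    and a trace of every accepted move. Ties in EBIC break to the lowest
    SNP index for determinism.
    """
    s0 = frozenset() if s0 is None else frozenset(int(i) for i in s0)
    n, m = X.shape
    if any(j < 0 or j >= m for j in s0):
        raise ValueError("fixed set indices out of range")
    if n <= len(s0) + 2:
        raise ValueError("need N > |s0| + 2")
    cache = _FitCache(y, X, weights)
    lam = cfg.lambda_

    def crit(subset: frozenset[int]) -> float:
        return ebic(cache.rss(tuple(sorted(subset))), n, len(subset), m, lam)

    trace: list[tuple[str, int, float]] = []
    current = s0
    current_ebic = crit(current)
    trace.append(("init", -1, current_ebic))

    # forward
    while True:
        best_j, best_val = None, current_ebic
        for j in range(m):  # ascending index => lowest index wins ties
            if j in current:
                continue
            val = crit(current | {j})
            if val < best_val:  # strict < with ascending j: lowest index wins ties
                best_j, best_val = j, val
        if best_j is None:
            break
        current = current | {best_j}
        current_ebic = best_val
        trace.append(("forward_add", best_j, current_ebic))

    # backward
    while True:
        best_j, best_val = None, current_ebic
        for j in sorted(current - s0):
            val = crit(current - {j})
            if val < best_val:
                best_j, best_val = j, val
        if best_j is None:
            break
        current = current - {best_j}
        current_ebic = best_val
        trace.append(("backward_drop", best_j, current_ebic))

    # exhaustive enumeration over the surviving non-fixed terms
    free = sorted(current - s0)
    skipped = False
    if len(free) > cfg.max_enumeration:
        log.info("enumeration skipped: %d non-fixed terms > cap %d",
                 len(free), cfg.max_enumeration)
        skipped = True
    else:
        best_set, best_val = current, current_ebic
        for r in range(len(free) + 1):
            for comb in combinations(free, r):
                cand = s0 | set(comb)
                val = crit(cand)
                if val < best_val:
                    best_set, best_val = cand, val
        if best_set != current:
            trace.append(("enumeration", -1, best_val))
        current, current_ebic = frozenset(best_set), best_val

    return SelectionResult(fixed_set=s0, selected=frozenset(current),
                           ebic_value=current_ebic, trace=trace,
                           enumeration_skipped=skipped)


def select_pcs(e_imputed: ExpressionTensor, cfg: EbicConfig) -> tuple[np.ndarray, np.ndarray]:
    """Leading PCs of the standardized tissue columns.

    Returns (scores: N x P, eigenvalues: P) for eigenvalues of the tissue
    correlation matrix >= ``cfg.eigenvalue_cutoff``, with at least
    ``cfg.min_pcs`` components. Each PC's sign is fixed so it correlates
    nonnegatively with the per-sample mean expression.
    """
    if e_imputed.n_tissues < 2:
        raise ValueError("need at least 2 tissues for PCA")
    V = e_imputed.values
    sd = V.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant tissue column; should not survive QC")
    Z = (V - V.mean(axis=0)) / sd
    corr = Z.T @ Z / Z.shape[0]
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_keep = max(int((evals >= cfg.eigenvalue_cutoff).sum()), cfg.min_pcs)
    scores = Z @ evecs[:, :n_keep]
    row_mean = V.mean(axis=1)
    for p in range(n_keep):
        if np.dot(scores[:, p] - scores[:, p].mean(), row_mean - row_mean.mean()) < 0:
            scores[:, p] *= -1
    return scores, evals[:n_keep]


def select_ct_eqtls(
    e_imputed: ExpressionTensor, g: GenotypeMatrix, cfg: EbicConfig,
) -> tuple[frozenset[int], int, list[SelectionResult]]:
    """ct-eQTL indices: stepwise selection on each qualifying PC in turn,
    with previously selected ct-eQTLs entering as the fixed set.

    Fits are unweighted: imputed rows enter PC construction and selection at
    full weight. Returns (indices, number of PCs used, per-PC results).
    """
    scores, _ = select_pcs(e_imputed, cfg)
    X = g.dosages
    s0: frozenset[int] = frozenset()
    results = []
    for p in range(scores.shape[1]):
        res = stepwise_select(scores[:, p], X, s0, cfg)
        results.append(res)
        s0 = s0 | res.selected
    return s0, scores.shape[1], results


def select_ts_eqtls(
    e_imputed: ExpressionTensor, g: GenotypeMatrix, ct_set: frozenset[int],
    tissue: int, cfg: EbicConfig,
) -> frozenset[int]:
    """ts-eQTL indices for one tissue: stepwise selection on that tissue's
    expression (observed + imputed rows) with the ct set fixed; the ct set
    itself is excluded from the returned set."""
    y = e_imputed.values[:, tissue]
    res = stepwise_select(y, g.dosages, ct_set, cfg)
    return frozenset(res.selected - ct_set)


def wls_fit(
    y: np.ndarray, X: np.ndarray, n_obs: int, n_imp: int, mask: np.ndarray,
) -> tuple[np.ndarray, float, float]:
    """Weighted least squares with observed rows at weight 1 and imputed
    rows at min(1, N_obs/N_imp); returns (beta, intercept, sigma_hat).

    With N_obs >= N_imp every weight is 1 and the result is ordinary least
    squares. A singular system falls back to a logged ridge with 1e-8 on
    the normal-equation diagonal.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    mask = np.asarray(mask, bool)
    n, k = X.shape
    if n_obs < k + 2:
        raise ValueError("need n_obs >= number of selected SNPs + 2")
    w_imp = min(1.0, n_obs / n_imp) if n_imp > 0 else 1.0
    w = np.where(mask, 1.0, w_imp)
    design = np.column_stack([np.ones(n), X])
    sw = np.sqrt(w)
    A = design * sw[:, None]
    b = y * sw
    G = A.T @ A
    try:
        coef = np.linalg.solve(G, A.T @ b)
        if not np.all(np.isfinite(coef)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        log.warning("singular weighted normal equations; ridge fallback (1e-8)")
        coef = np.linalg.solve(G + 1e-8 * np.eye(k + 1), A.T @ b)
    resid = y - design @ coef
    dof = max(w.sum() - (k + 1), 1.0)
    sigma = float(np.sqrt(np.sum(w * resid**2) / dof))
    return coef[1:], float(coef[0]), sigma


def train_gene(
    e_imputed: ExpressionTensor, g: GenotypeMatrix, cfg: EbicConfig,
) -> EqtlModel:
    """Full per-gene training: ct selection on PCs, ts selection per tissue,
    then weighted least squares on ct union ts for each tissue."""
    ct_idx, n_pcs, _ = select_ct_eqtls(e_imputed, g, cfg)
    snp_ids = g.snp_ids
    ts_sets: dict[str, list[str]] = {}
    weights: dict[str, TissueWeights] = {}
    for t, tissue in enumerate(e_imputed.tissues):
        ts_idx = select_ts_eqtls(e_imputed, g, ct_idx, t, cfg)
        sel = sorted(ct_idx) + sorted(ts_idx)
        classes = ["ct"] * len(ct_idx) + ["ts"] * len(ts_idx)
        mask = e_imputed.observed_mask[:, t]
        n_obs = int(mask.sum())
        n_imp = int((~mask).sum())
        if sel:
            beta, intercept, sigma = wls_fit(
                e_imputed.values[:, t], g.dosages[:, sel], n_obs, n_imp, mask)
        else:
            w_imp = min(1.0, n_obs / n_imp) if n_imp > 0 else 1.0
            w = np.where(mask, 1.0, w_imp)
            intercept = float(np.average(e_imputed.values[:, t], weights=w))
            resid = e_imputed.values[:, t] - intercept
            beta = np.zeros(0)
            sigma = float(np.sqrt(np.sum(w * resid**2) / max(w.sum() - 1, 1.0)))
        ts_sets[tissue] = [snp_ids[j] for j in sorted(ts_idx)]
        weights[tissue] = TissueWeights(
            tissue=tissue, snp_ids=[snp_ids[j] for j in sel],
            beta=np.asarray(beta), intercept=intercept, sigma_hat=sigma,
            classes=classes, n_obs=n_obs, n_imp=n_imp)
    return EqtlModel(gene=e_imputed.gene, ct_set=[snp_ids[j] for j in sorted(ct_idx)],
                     ts_sets=ts_sets, weights=weights, pc_count=n_pcs)
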