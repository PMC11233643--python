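"""Five-fold cross-validated evaluation of expression prediction.

Each fold's held-out samples are never imputed: imputation, eQTL selection
and effect estimation all run on the training folds alone, and the model is
scored on the held-out samples whose expression was actually observed.
Per-fold prediction R^2 values are averaged across folds.

Three training routes are evaluated side by side for ablation:

- ``mtwas``        — imputation, ct-eQTL selection on expression PCs,
                     per-tissue ts-eQTL selection conditional on the ct set,
                     weighted least squares.
- ``mtwas_tissue`` — imputation, then one unconstrained stepwise selection
                     per tissue (no ct/ts partition), weighted least squares.
- ``single_tissue``— no imputation; per-tissue stepwise selection and OLS on
                     the tissue's observed training samples only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .associate import evaluate_prediction
from .impute import ImputeConfig, impute_gene
from .select_eqtl import EbicConfig, stepwise_select, train_gene, wls_fit
from .types import ExpressionTensor, GenotypeMatrix

METHODS = ("mtwas", "mtwas_tissue", "single_tissue")


@dataclass
class CvPlan:
    n_folds: int
    assignment: np.ndarray  # fold index per sample
    seed: int

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, int)
        counts = np.bincount(self.assignment, minlength=self.n_folds)
        if (counts == 0).any():
            raise ValueError("every fold must be nonempty")


def make_cv_plan(e: ExpressionTensor, n_folds: int = 5, seed: int = 0) -> CvPlan:
    """Fold assignment stratified by each sample's observed-tissue count, so
    every fold keeps observed test entries for every tissue."""
    rng = np.random.default_rng(seed)
    n = e.n_samples
    obs_count = e.observed_mask.sum(axis=1)
    assignment = np.empty(n, dtype=int)
    slot = 0
    for level in np.unique(obs_count):
        idx = np.flatnonzero(obs_count == level)
        rng.shuffle(idx)
        for i in idx:
            assignment[i] = slot % n_folds
            slot += 1
    return CvPlan(n_folds=n_folds, assignment=assignment, seed=seed)


def _subset_rows(e: ExpressionTensor, rows: np.ndarray) -> ExpressionTensor:
    return ExpressionTensor(
        gene=e.gene, samples=[e.samples[i] for i in rows],
        tissues=list(e.tissues), values=e.values[rows].copy(),
        observed_mask=e.observed_mask[rows].copy())


def _fit_per_tissue_stepwise(
    e_imp: ExpressionTensor, g_train: GenotypeMatrix, ebic_cfg: EbicConfig,
    weighted: bool,
) -> dict[str, tuple[list[int], np.ndarray, float]]:
    """One unconstrained stepwise + (weighted) LS fit per tissue."""
    out = {}
    for t, tissue in enumerate(e_imp.tissues):
        y = e_imp.values[:, t]
        res = stepwise_select(y, g_train.dosages, None, ebic_cfg)
        sel = sorted(res.selected)
        mask = e_imp.observed_mask[:, t]
        n_obs, n_imp = int(mask.sum()), int((~mask).sum())
        if sel:
            if weighted:
                beta, icpt, _ = wls_fit(y, g_train.dosages[:, sel], n_obs, n_imp, mask)
            else:
                beta, icpt, _ = wls_fit(y, g_train.dosages[:, sel], n_obs, 0,
                                        np.ones(len(y), bool))
        else:
            beta, icpt = np.zeros(0), float(y.mean())
        out[tissue] = (sel, beta, icpt)
    return out


def _predict(g: GenotypeMatrix, rows: np.ndarray, sel: list[int],
             beta: np.ndarray, intercept: float) -> np.ndarray:
    if not sel:
        return np.full(len(rows), intercept)
    return g.dosages[np.ix_(rows, sel)] @ beta + intercept


def run_cv(
    expr: ExpressionTensor, geno: GenotypeMatrix, impute_cfg: ImputeConfig,
    ebic_cfg: EbicConfig, plan: CvPlan, methods: tuple[str, ...] = METHODS,
) -> pd.DataFrame:
    """Cross-validated per-tissue prediction metrics for one gene.

    Returns a tidy frame with columns gene, tissue, method, r2, signed_r2,
    f_pvalue, n_test (fold-averaged; folds lacking >= 4 observed test
    entries for a tissue are skipped for that tissue).
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s): {sorted(unknown)}")
    records: dict[tuple[str, str], list] = {}
    for fold in range(plan.n_folds):
        test_rows = np.flatnonzero(plan.assignment == fold)
        train_rows = np.flatnonzero(plan.assignment != fold)
        e_train = _subset_rows(expr, train_rows)
        g_train = geno.subset_samples(train_rows)

        fits: dict[str, dict[str, tuple[list[int], np.ndarray, float]]] = {}
        if "mtwas" in methods or "mtwas_tissue" in methods:
            e_imp = impute_gene(e_train, impute_cfg)
            if "mtwas" in methods:
                model = train_gene(e_imp, g_train, ebic_cfg)
                snp_col = {s: j for j, s in enumerate(g_train.snp_ids)}
                fits["mtwas"] = {
                    tissue: ([snp_col[s] for s in w.snp_ids], w.beta, w.intercept)
                    for tissue, w in model.weights.items()}
            if "mtwas_tissue" in methods:
                fits["mtwas_tissue"] = _fit_per_tissue_stepwise(
                    e_imp, g_train, ebic_cfg, weighted=True)
        if "single_tissue" in methods:
            fits["single_tissue"] = {}
            for t, tissue in enumerate(expr.tissues):
                obs = e_train.observed_mask[:, t]
                rows = np.flatnonzero(obs)
                sub = ExpressionTensor(
                    gene=expr.gene, samples=[e_train.samples[i] for i in rows],
                    tissues=[tissue], values=e_train.values[rows][:, [t]],
                    observed_mask=np.ones((len(rows), 1), bool))
                fits["single_tissue"].update(_fit_per_tissue_stepwise(
                    sub, g_train.subset_samples(rows), ebic_cfg, weighted=False))

        for t, tissue in enumerate(expr.tissues):
            test_obs = test_rows[expr.observed_mask[test_rows, t]]
            if len(test_obs) < 4:
                continue
            y_true = expr.values[test_obs, t]
            for method in methods:
                if tissue not in fits.get(method, {}):
                    continue  # tissue dropped during imputation for this fold
                sel, beta, icpt = fits[method][tissue]
                y_pred = _predict(geno, test_obs, sel, beta, icpt)
                m = evaluate_prediction(y_true, y_pred)
                records.setdefault((tissue, method), []).append(
                    (m.r2, m.signed_r2, m.f_pvalue, len(test_obs)))

    rows = []
    for (tissue, method), vals in sorted(records.items()):
        arr = np.asarray(vals, float)
        rows.append({
            "gene": expr.gene.id, "tissue": tissue, "method": method,
            "r2": arr[:, 0].mean(), "signed_r2": arr[:, 1].mean(),
            "f_pvalue": arr[:, 2].mean(), "n_test": arr[:, 3].sum(),
        })
    return pd.DataFrame(rows)
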