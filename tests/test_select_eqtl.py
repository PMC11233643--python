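import itertools

import numpy as np
import pytest

from mtwas.select_eqtl import (
    EbicConfig,
    ebic,
    select_ct_eqtls,
    select_pcs,
    select_ts_eqtls,
    stepwise_select,
    train_gene,
    wls_fit,
)
from mtwas.simulate import SimConfig, simulate_expression, simulate_genotypes
from conftest import make_tensor


def brute_force_min_ebic(y, X, lambda_):
    """Independent oracle: exhaustive EBIC minimum over all SNP subsets,
    each fit by numpy lstsq on the intercept-augmented design."""
    n, m = X.shape
    best = np.inf
    for r in range(m + 1):
        for subset in itertools.combinations(range(m), r):
            design = np.column_stack([np.ones(n), X[:, list(subset)]])
            resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
            rss = float(resid @ resid)
            if rss <= 0:
                continue
            best = min(best, ebic(rss, n, len(subset), m, lambda_))
    return best


class TestEbic:
    def test_empty_set_is_minus_two_loglik(self):
        # with |S| = 0 the penalty vanishes
        n, rss = 50, 12.5
        loglik = -(n / 2) * (np.log(2 * np.pi * rss / n) + 1)
        assert ebic(rss, n, 0, 30, 0.5) == pytest.approx(-2 * loglik, abs=1e-12)

    def test_hand_computed_value(self):
        # rss/n = 1/(2 pi) makes the log-likelihood -n/2 exactly:
        # 100 + 3 log 100 + 2(0.5)(3) log 50 = 125.5516...
        val = ebic(100 / (2 * np.pi), 100, 3, 50, 0.5)
        assert val == pytest.approx(100 + 3 * np.log(100) + 3 * np.log(50), abs=1e-9)
        assert val == pytest.approx(125.5516, abs=1e-4)

    def test_increasing_in_lambda(self):
        vals = [ebic(5.0, 40, 2, 25, lam) for lam in (0.0, 0.25, 0.5, 1.0)]
        assert np.all(np.diff(vals) > 0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ebic(0.0, 50, 1, 10, 0.5)
        with pytest.raises(ValueError):
            ebic(1.0, 3, 5, 10, 0.5)


class TestStepwise:
    def test_signal_recovery(self):
        """SNPs {3, 17} with unit slopes and small noise are recovered
        exactly in >= 95% of replicates."""
        hits = 0
        for rep in range(100):
            cfg = SimConfig(seed=8000 + rep, n_samples=400, n_snps=10,
                            n_tissues=1, n_ct_eqtls=0, n_ts_eqtls_per_tissue=0)
            g = simulate_genotypes(cfg)
            rng = np.random.default_rng(rep)
            y = g.dosages[:, 3] + g.dosages[:, 7] + 0.2 * rng.standard_normal(400)
            res = stepwise_select(y, g.dosages, None, EbicConfig())
            hits += res.selected == frozenset({3, 7})
        assert hits >= 95

    def test_null_selection_mostly_empty(self):
        """Pure-noise response: the EBIC penalty keeps the model empty in
        the large majority of replicates (familywise add-probability over
        M = 50 candidates is ~0.1 at these sizes)."""
        empty = 0
        for rep in range(100):
            cfg = SimConfig(seed=7000 + rep, n_samples=300, n_snps=50,
                            n_tissues=1, n_ct_eqtls=0, n_ts_eqtls_per_tissue=0)
            g = simulate_genotypes(cfg)
            y = np.random.default_rng(rep).standard_normal(300)
            res = stepwise_select(y, g.dosages, None, EbicConfig())
            empty += len(res.selected) == 0
        assert empty >= 85

    def test_fixed_noise_member_retained(self, rng):
        X = rng.standard_normal((200, 12))
        y = rng.standard_normal(200)  # SNP 5 is pure noise
        res = stepwise_select(y, X, {5}, EbicConfig())
        assert 5 in res.selected
        assert res.selected >= res.fixed_set

    def test_oracle_equivalence_small(self, rng):
        for rep in range(10):
            cfg = SimConfig(seed=900 + rep, n_samples=120, n_snps=8,
                            n_tissues=1, n_ct_eqtls=0, n_ts_eqtls_per_tissue=0)
            X = simulate_genotypes(cfg).dosages
            beta = np.zeros(8)
            beta[rng.choice(8, rep % 3, replace=False)] = rng.normal(0, 1, rep % 3)
            y = X @ beta + rng.standard_normal(120)
            res = stepwise_select(y, X, None, EbicConfig())
            assert res.ebic_value == pytest.approx(
                brute_force_min_ebic(y, X, 0.5), abs=1e-9)

    def test_trace_monotone_within_phases(self, rng):
        cfg = SimConfig(seed=42, n_samples=250, n_snps=15, n_tissues=1,
                        n_ct_eqtls=0, n_ts_eqtls_per_tissue=0)
        X = simulate_genotypes(cfg).dosages
        y = X[:, 2] - 0.8 * X[:, 9] + 0.5 * rng.standard_normal(250)
        res = stepwise_select(y, X, None, EbicConfig())
        fwd = [v for phase, _, v in res.trace if phase in ("init", "forward_add")]
        bwd = [v for phase, _, v in res.trace if phase == "backward_drop"]
        assert np.all(np.diff(fwd) < 0)
        if bwd:
            assert np.all(np.diff([fwd[-1]] + bwd) < 0)

    def test_ebic_value_recomputes(self, rng):
        X = rng.standard_normal((100, 6))
        y = X[:, 1] + 0.3 * rng.standard_normal(100)
        res = stepwise_select(y, X, None, EbicConfig())
        sel = sorted(res.selected)
        design = np.column_stack([np.ones(100), X[:, sel]])
        resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        assert res.ebic_value == pytest.approx(
            ebic(float(resid @ resid), 100, len(sel), 6, 0.5), abs=1e-9)


class TestSelectPcs:
    def test_eigenvalue_threshold_and_floor(self, rng):
        # one strong shared factor among K = 6 tissues -> 1 qualifying PC
        n, k = 400, 6
        F = rng.standard_normal((n, 1))
        vals = 1.5 * F + rng.standard_normal((n, k))
        scores, evals = select_pcs(make_tensor(vals), EbicConfig())
        assert scores.shape == (n, 1)
        assert evals[0] >= 2.0
        # independent tissues: all eigenvalues ~1 -> min_pcs floor applies
        scores2, _ = select_pcs(make_tensor(rng.standard_normal((n, k))), EbicConfig())
        assert scores2.shape[1] == 1

    def test_sign_convention(self, rng):
        F = rng.standard_normal((300, 1))
        vals = 2.0 * F + 0.5 * rng.standard_normal((300, 4))
        scores, _ = select_pcs(make_tensor(vals), EbicConfig())
        assert np.corrcoef(scores[:, 0], vals.mean(axis=1))[0, 1] > 0


class TestCtTs:
    def test_identical_tissues_match_single_tissue_selection(self, rng):
        """PCA of a rank-1 tissue matrix makes PC1 proportional to the common
        column, so ct selection equals single-column stepwise selection."""
        cfg = SimConfig(seed=77, n_samples=300, n_snps=12, n_tissues=1,
                        n_ct_eqtls=0, n_ts_eqtls_per_tissue=0)
        g = simulate_genotypes(cfg)
        y = g.dosages[:, 4] + 0.4 * rng.standard_normal(300)
        e = make_tensor(np.column_stack([y, y, y]))
        ct, n_pcs, _ = select_ct_eqtls(e, g, EbicConfig())
        single = stepwise_select(y, g.dosages, None, EbicConfig()).selected
        assert ct == single

    def test_ts_excludes_ct_and_full_ct_forces_empty(self, rng):
        cfg = SimConfig(seed=78, n_samples=200, n_snps=6, n_tissues=1,
                        n_ct_eqtls=0, n_ts_eqtls_per_tissue=0)
        g = simulate_genotypes(cfg)
        y = g.dosages[:, 0] + rng.standard_normal(200)
        e = make_tensor(y[:, None].repeat(2, axis=1))
        full = frozenset(range(6))
        assert select_ts_eqtls(e, g, full, 0, EbicConfig()) == frozenset()
        some = select_ts_eqtls(e, g, frozenset({0}), 0, EbicConfig())
        assert 0 not in some


class TestWls:
    def test_all_observed_equals_ols(self, rng):
        n = 80
        X = rng.standard_normal((n, 3))
        y = X @ [1.0, -0.5, 0.2] + rng.standard_normal(n)
        beta, icpt, _ = wls_fit(y, X, n_obs=n, n_imp=0, mask=np.ones(n, bool))
        design = np.column_stack([np.ones(n), X])
        ols = np.linalg.lstsq(design, y, rcond=None)[0]
        np.testing.assert_allclose(np.r_[icpt, beta], ols, atol=1e-10)

    def test_more_observed_than_imputed_is_unweighted(self, rng):
        """N_obs = 100 >= N_imp = 50 gives weight min(1, 2) = 1: identical
        to pretending every row was observed."""
        n = 150
        X = rng.standard_normal((n, 2))
        y = X @ [0.7, 0.1] + rng.standard_normal(n)
        mask = np.zeros(n, bool)
        mask[:100] = True
        b1, i1, s1 = wls_fit(y, X, 100, 50, mask)
        b2, i2, s2 = wls_fit(y, X, n, 0, np.ones(n, bool))
        np.testing.assert_allclose(b1, b2, atol=1e-12)
        assert i1 == pytest.approx(i2, abs=1e-12)

    def test_duplication_oracle_for_half_weight(self, rng):
        """n_obs = 50, n_imp = 100 -> imputed weight 0.5; doubling every
        observed row and fitting OLS reproduces the coefficients."""
        n_obs, n_imp = 50, 100
        n = n_obs + n_imp
        X = rng.standard_normal((n, 3))
        y = X @ [1.0, 0.5, -0.3] + rng.standard_normal(n)
        mask = np.zeros(n, bool)
        mask[:n_obs] = True
        beta, icpt, _ = wls_fit(y, X, n_obs, n_imp, mask)
        X_dup = np.vstack([X[mask], X[mask], X[~mask]])
        y_dup = np.concatenate([y[mask], y[mask], y[~mask]])
        design = np.column_stack([np.ones(len(y_dup)), X_dup])
        ols = np.linalg.lstsq(design, y_dup, rcond=None)[0]
        np.testing.assert_allclose(np.r_[icpt, beta], ols, atol=1e-10)


def test_train_gene_shapes_and_classes():
    cfg = SimConfig(seed=5, n_samples=300, n_snps=15, n_tissues=3,
                    n_ct_eqtls=1, n_ts_eqtls_per_tissue=1)
    g = simulate_genotypes(cfg)
    e, _ = simulate_expression(g, cfg)
    model = train_gene(e, g, EbicConfig())
    assert set(model.weights) == set(e.tissues)
    for tissue, w in model.weights.items():
        assert len(w.snp_ids) == len(w.beta) == len(w.classes)
        assert w.n_obs + w.n_imp == 300
        ct_ids = [s for s, c in zip(w.snp_ids, w.classes) if c == "ct"]
        assert ct_ids == model.ct_set
        assert all(np.isfinite(w.beta))
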