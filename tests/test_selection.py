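"""SPA, random frog and NCA selectors: hand-computed cases, oracles, recovery."""

import numpy as np
import pytest
from sklearn.linear_model import LinearRegression

import grainspec as gs
from tests.conftest import make_table


# ---------------------------------------------------------------------------
# SPA chain + MLR scoring
# ---------------------------------------------------------------------------

class TestSpaChain:
    def test_orthogonal_columns_picked_by_norm(self):
        """With mutually orthogonal columns of norms 3, 2, 1, a chain started
        at the norm-2 column picks norm-3 next, then norm-1."""
        X = np.zeros((4, 3))
        X[0, 0], X[1, 1], X[2, 2] = 3.0, 2.0, 1.0
        chain = gs.spa_chain(X, start_index=1, max_len=3)
        assert chain == [1, 0, 2]

    def test_max_len_one_returns_start(self):
        X = np.random.default_rng(0).normal(size=(10, 5))
        assert gs.spa_chain(X, 3, 1) == [3]

    def test_selected_columns_mutually_orthogonalized(self):
        """Each selected column's residual is orthogonal to all previously
        selected columns (the defining projection property)."""
        X = np.random.default_rng(1).normal(size=(30, 8))
        X -= X.mean(axis=0)
        chain = gs.spa_chain(X, 0, 6)
        # recompute residuals by explicit Gram-Schmidt over the chain
        basis = []
        for idx in chain:
            v = X[:, idx].copy()
            for b in basis:
                v -= (v @ b) * b
            for b in basis:
                assert abs(v @ b) < 1e-9
            basis.append(v / np.linalg.norm(v))

    def test_out_of_range_start(self):
        with pytest.raises(ValueError, match="start_index"):
            gs.spa_chain(np.ones((3, 2)), 5, 1)


class TestMlrRmsev:
    def test_exact_linear_fit_gives_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        beta = np.array([1.5, -2.0, 0.5])
        y = X @ beta + 4.0
        Xv = rng.normal(size=(5, 3))
        assert gs.mlr_rmsev(X, y, Xv, Xv @ beta + 4.0) < 1e-9

    def test_intercept_only_closed_form(self):
        y_cal = np.array([1.0, 2.0, 3.0, 6.0])
        y_val = np.array([4.0, 0.0])
        got = gs.mlr_rmsev(np.empty((4, 0)), y_cal, np.empty((2, 0)), y_val)
        expected = np.sqrt(np.mean((y_cal.mean() - y_val) ** 2))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_one_column_toy(self):
        """x_cal=[1,2,3,4], y_cal=[1,2,3,4], x_val=[5], y_val=[4] -> RMSEV 1."""
        got = gs.mlr_rmsev(np.array([1.0, 2.0, 3.0, 4.0]),
                           np.array([1.0, 2.0, 3.0, 4.0]),
                           np.array([5.0]), np.array([4.0]))
        assert got == pytest.approx(1.0, abs=1e-12)

    def test_rank_deficient_design_raises(self):
        X = np.ones((10, 2))
        X[:, 1] = 2 * X[:, 0]  # collinear with each other and the intercept
        with pytest.raises(ValueError, match="rank"):
            gs.mlr_rmsev(X, np.arange(10.0), X[:2], np.arange(2.0))


def _brute_force_spa_oracle(table, m_min, m_max, val_fraction, seed):
    """Independent exhaustive search over all (start, prefix-size) subsets.

    Chains are rebuilt here with a naive Gram-Schmidt loop and scored with
    scikit-learn's LinearRegression — sharing no code with the library path.
    """
    X, y = table.x, table.labels.astype(float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(n * val_fraction)))
    val, fit = perm[:n_val], perm[n_val:]
    Xc = X[fit] - X[fit].mean(axis=0)

    def naive_chain(start):
        chain, basis = [start], []
        v0 = Xc[:, start]
        basis.append(v0 / np.linalg.norm(v0))
        while len(chain) < m_max:
            best_j, best_norm = None, -1.0
            for j in range(p):
                if j in chain:
                    continue
                r = Xc[:, j].copy()
                for b in basis:
                    r -= (r @ b) * b
                nrm = r @ r
                if nrm > best_norm + 1e-15:
                    best_j, best_norm = j, nrm
            if best_j is None or best_norm < 1e-24:
                break
            chain.append(best_j)
            r = Xc[:, best_j].copy()
            for b in basis:
                r -= (r @ b) * b
            basis.append(r / np.linalg.norm(r))
        return chain

    best = None
    for start in range(p):
        chain = naive_chain(start)
        for m in range(m_min, m_max + 1):
            if m > len(chain):
                break
            sel = chain[:m]
            model = LinearRegression().fit(X[fit][:, sel], y[fit])
            resid = model.predict(X[val][:, sel]) - y[val]
            rmsev = float(np.sqrt(np.mean(resid ** 2)))
            key = (rmsev, m, start)
            if best is None or key < best[:3]:
                best = (rmsev, m, start, tuple(sorted(sel)))
    return best


class TestSpaSelect:
    def test_matches_exhaustive_prefix_oracle(self):
        """On a 6-band, 30-row table the library SPA and an independent
        brute-force prefix search crown the same winner."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 6))
        y = np.clip(np.round(1.5 + X[:, 2] - 0.5 * X[:, 4]), 1, 4).astype(int)
        table = make_table(X, labels=y)
        res = gs.spa_select(table, m_min=1, m_max=4, seed=3)
        oracle = _brute_force_spa_oracle(table, 1, 4, 0.25, seed=3)
        assert res.diagnostics["best_rmsev"] == pytest.approx(oracle[0], rel=1e-9)
        assert res.diagnostics["best_m"] == oracle[1]
        assert res.diagnostics["best_start"] == oracle[2]
        assert tuple(res.indices) == oracle[3]

    def test_planted_linear_bands_recovered(self):
        """y is an exact linear function of 3 known bands: the winning subset
        contains them and reaches RMSEV < 1e-6."""
        rng = np.random.default_rng(4)
        n, p = 48, 12
        planted = (2, 6, 9)
        X = rng.normal(size=(n, p))
        y = rng.integers(1, 5, size=n)
        # planted columns carry dominant variance, the regime SPA's
        # projection-norm criterion is built for
        a, b = 3 * rng.normal(size=n), 3 * rng.normal(size=n)
        X[:, planted[0]] = a
        X[:, planted[1]] = b
        X[:, planted[2]] = y - a - b
        table = make_table(X, labels=y)
        res = gs.spa_select(table, m_min=1, m_max=6, seed=0)
        assert set(planted) <= set(res.indices.tolist())
        assert res.diagnostics["best_rmsev"] < 1e-6

    def test_reduction_bookkeeping(self):
        """8 bands kept of 220 reports a 96.36% reduction."""
        res = gs.SelectionResult(
            method="spa", indices=np.arange(8), wavelengths=np.arange(8.0),
            scores=np.zeros(8), score_kind="rmsev_per_size")
        assert res.reduction_percent(220) == 96.36

    def test_m_max_exceeding_rank_budget(self):
        table = make_table(np.random.default_rng(0).normal(size=(10, 30)),
                           labels=np.tile([1, 2], 5))
        with pytest.raises(ValueError, match="rank budget"):
            gs.spa_select(table, m_max=20, seed=0)


# ---------------------------------------------------------------------------
# Random frog
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def frog_planted_result():
    """One seeded frog run on 2 planted + 30 noise bands (N=1000)."""
    rng = np.random.default_rng(11)
    n, p = 120, 32
    X = rng.normal(size=(n, p))
    latent = X[:, 5] - 0.8 * X[:, 20] + rng.normal(0, 0.15, n)
    y = np.digitize(latent, np.quantile(latent, [0.25, 0.5, 0.75])) + 1
    table = make_table(X, labels=y)
    params = gs.RandomFrogParams(rng_seed=0)
    return table, params, gs.random_frog_select(table, params)


class TestRandomFrog:
    def test_planted_bands_have_top_two_probabilities(self, frog_planted_result):
        _, _, res = frog_planted_result
        top2 = set(np.argsort(-res.scores)[:2].tolist())
        assert top2 == {5, 20}

    def test_probabilities_are_counting_frequencies(self, frog_planted_result):
        """All p_j in [0,1]; their sum equals (sum of subset sizes)/N."""
        _, params, res = frog_planted_result
        assert np.all((res.scores >= 0) & (res.scores <= 1))
        sizes = np.asarray(res.diagnostics["subset_sizes"])
        assert sizes.size == params.n_iterations
        assert res.scores.sum() == pytest.approx(
            sizes.sum() / params.n_iterations, abs=1e-12)

    def test_threshold_has_exact_set_semantics(self, frog_planted_result):
        _, params, res = frog_planted_result
        expected = np.nonzero(res.scores >= params.threshold)[0]
        assert np.array_equal(res.indices, expected)

    def test_seed_determinism(self, frog_planted_result):
        table, params, res = frog_planted_result
        res2 = gs.random_frog_select(table, params)
        assert np.array_equal(res.scores, res2.scores)

    def test_unreachable_threshold_warns_with_empty_result(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.normal(size=(40, 16)),
                           labels=rng.integers(1, 5, 40))
        # pure-noise bands with a churning walk: no band survives every
        # iteration, so a threshold of 1.0 selects nothing
        params = gs.RandomFrogParams(n_iterations=40, threshold=1.0,
                                     theta=0.8, rng_seed=0)
        with pytest.warns(UserWarning, match="no band"):
            res = gs.random_frog_select(table, params)
        assert res.n_selected == 0 and res.warning is not None

    @pytest.mark.parametrize("kwargs", [
        dict(n_iterations=0), dict(q_init=0), dict(threshold=0.0),
        dict(threshold=1.5), dict(n_latent_max=0),
    ])
    def test_param_validation(self, kwargs):
        with pytest.raises(ValueError):
            gs.RandomFrogParams(**kwargs)


# ---------------------------------------------------------------------------
# NCA
# ---------------------------------------------------------------------------

class TestNca:
    def test_constant_feature_weight_vanishes(self):
        """A feature with zero spread carries no information; the ridge term
        drives its weight to (numerical) zero at the optimum."""
        rng = np.random.default_rng(0)
        n = 60
        X = rng.normal(size=(n, 5))
        X[:, 2] = 4.2  # constant
        y = np.repeat([1, 2], n // 2)
        X[:, 0] = y + rng.normal(0, 0.2, n)
        w, _, _ = gs.nca_fit(make_table(X, labels=y), gs.NcaParams())
        assert abs(w[2]) < 1e-3

    def test_planted_separating_feature_dominates(self):
        """2-class data separable by one feature among noise: its squared
        weight is the maximum and >= 10x the median of the noise weights."""
        rng = np.random.default_rng(7)
        n, p = 80, 21
        X = rng.normal(size=(n, p))
        y = np.repeat([1, 2], n // 2)
        X[:, 3] = y + rng.normal(0, 0.1, n)
        w, _, _ = gs.nca_fit(make_table(X, labels=y), gs.NcaParams())
        w2 = w ** 2
        noise = np.delete(w2, 3)
        assert w2[3] == w2.max()
        assert w2[3] >= 10 * max(np.median(noise), 1e-12)

    def test_objective_trace_stabilizes_before_max_iter(self):
        """The trace rises and flattens (|dF| < tol) well before the
        iteration cap, mirroring the few-tens-of-iterations convergence the
        method shows on real spectra."""
        cfg = gs.SceneConfig(grains_per_class=25)
        table = gs.trim_bands(gs.simulate_spectra_table(cfg), 931.8, 1653.8)
        params = gs.NcaParams(max_iter=100)
        w, trace, converged = gs.nca_fit(table, params)
        assert converged
        assert len(trace) < params.max_iter
        assert trace[-1] >= trace[0]
        assert abs(trace[-1] - trace[-2]) < 1e-3

    def test_huge_regularization_kills_all_weights(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 6))
        y = np.repeat([1, 2], 20)
        w, _, _ = gs.nca_fit(make_table(X, labels=y),
                             gs.NcaParams(lam=100.0))
        assert np.all(np.abs(w) < 1e-3)

    def test_needs_two_classes(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="2 classes"):
            gs.nca_fit(make_table(X, labels=np.ones(10, int)), gs.NcaParams())


class TestSelectByScore:
    def test_relative_rule_arithmetic(self):
        res = gs.select_by_score(np.array([0.0, 0.0, 5.0, 0.01]),
                                 rule="relative", threshold=0.05)
        assert res.indices.tolist() == [2]  # 0.01 < 0.25 = 0.05 * 5

    def test_all_zero_scores_warn_empty(self):
        with pytest.warns(UserWarning, match="threshold"):
            res = gs.select_by_score(np.zeros(4))
        assert res.n_selected == 0

    def test_relative_rule_scale_invariant(self):
        scores = np.array([0.3, 0.01, 0.8, 0.05])
        a = gs.select_by_score(scores, rule="relative", threshold=0.1)
        b = gs.select_by_score(scores * 137.0, rule="relative", threshold=0.1)
        assert np.array_equal(a.indices, b.indices)

    def test_absolute_rule(self):
        res = gs.select_by_score(np.array([0.1, 0.8, 0.75]), rule="absolute",
                                 threshold=0.7)
        assert res.indices.tolist() == [1, 2]


def test_all_selectors_reduce_default_table(table_400):
    """Each selector returns strictly fewer bands than it was given on the
    default-condition table (after MSC, as in the analysis chain)."""
    cal, _ = gs.split_calibration_prediction(
        gs.trim_bands(table_400, 931.8, 1653.8), (3, 1), seed=0)
    calp = gs.msc_apply(cal, gs.msc_fit(cal))
    spa = gs.spa_select(calp, m_max=20, seed=0)
    nca = gs.nca_select(calp, gs.NcaParams(rng_seed=0))
    frog = gs.random_frog_select(calp, gs.RandomFrogParams(rng_seed=0))
    for res in (spa, nca, frog):
        assert 0 < res.n_selected < calp.n_bands
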