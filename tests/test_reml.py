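"""REML engine: closed-form oracles, likelihood consistency, BLUPs, LR test."""

import numpy as np
import pytest

from asvlmm import (
    ModelSpec,
    RandomTerm,
    ResidualSpec,
    build_kasv,
    compute_blups,
    fit_reml,
    lr_test,
    reml_loglik,
)
from asvlmm.simulate import simulate_genotypes


def balanced_oneway(q=3, r=2, sig_u=4.0, sig_e=1.0, seed=0):
    rng = np.random.default_rng(seed)
    codes = np.repeat(np.arange(q), r)
    y = np.sqrt(sig_u) * rng.standard_normal(q)[codes] + np.sqrt(
        sig_e
    ) * rng.standard_normal(q * r)
    return codes, y


class TestOracles:
    def test_null_model_residual_is_sample_variance(self):
        y = np.random.default_rng(1).normal(10, 3, 25)
        fit = fit_reml(ModelSpec(terms=[]), y)
        assert fit.converged
        assert fit.components["residual"] == pytest.approx(np.var(y, ddof=1), rel=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_balanced_oneway_matches_anova(self, seed):
        """On a balanced one-way design REML equals the ANOVA estimators
        (MSB - MSW)/r and MSW whenever those are interior."""
        q, r = 4, 3
        codes, y = balanced_oneway(q, r, sig_u=6.0, sig_e=1.0, seed=seed)
        fit = fit_reml(ModelSpec(terms=[RandomTerm("u", codes=codes)]), y)
        ybar = np.array([y[codes == i].mean() for i in range(q)])
        msw = sum(((y[codes == i] - ybar[i]) ** 2).sum() for i in range(q)) / (
            q * (r - 1)
        )
        msb = r * ((ybar - ybar.mean()) ** 2).sum() / (q - 1)
        if (msb - msw) / r > 0:
            assert fit.components["u"] == pytest.approx((msb - msw) / r, rel=1e-6)
            assert fit.components["residual"] == pytest.approx(msw, rel=1e-6)

    def test_two_kernel_fit_matches_grid_search(self, small_markers):
        """A kernel + residual fit on n=20 agrees with a zoomed grid search
        of the restricted likelihood to 1e-4."""
        n = 20
        md = simulate_genotypes(n, 60, 0.38, 0.8, seed=42)
        K = build_kasv(md)
        rng = np.random.default_rng(5)
        L = np.linalg.cholesky(K.values + 1e-8 * np.eye(n))
        y = 2.0 * (L @ rng.standard_normal(n)) + rng.standard_normal(n)
        spec = ModelSpec(terms=[RandomTerm("g", codes=np.arange(n), kernel=K)])
        fit = fit_reml(spec, y, tol=1e-10)

        lo = np.array([1e-4, 1e-4])
        hi = np.array([20.0, 20.0])
        best = None
        for _ in range(8):  # zooming grid
            gs = [np.linspace(lo[i], hi[i], 21) for i in range(2)]
            vals = [
                (reml_loglik(spec, y, {"g": a, "residual": b}), a, b)
                for a in gs[0]
                for b in gs[1]
            ]
            best = max(vals)
            span = (hi - lo) / 10
            lo = np.maximum([best[1] - span[0], best[2] - span[1]], 1e-6)
            hi = [best[1] + span[0], best[2] + span[1]]
        assert fit.components["g"] == pytest.approx(best[1], abs=1e-4)
        assert fit.components["residual"] == pytest.approx(best[2], abs=1e-4)
        assert fit.loglik >= best[0] - 1e-8

    def test_identity_kernel_matches_statsmodels(self):
        """One-factor random-intercept model agrees with an independent
        mixed-model implementation (unbalanced data)."""
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        codes = np.array([0, 0, 0, 1, 1, 2, 2, 2, 2, 3, 3, 4, 4, 4, 5])
        y = 1.5 * rng.standard_normal(6)[codes] + rng.standard_normal(len(codes))
        fit = fit_reml(ModelSpec(terms=[RandomTerm("u", codes=codes)]), y, tol=1e-10)
        md = statsmodels.MixedLM(y, np.ones((len(y), 1)), groups=codes)
        sm = md.fit(reml=True, method="lbfgs")
        assert fit.components["u"] == pytest.approx(float(np.asarray(sm.cov_re)[0, 0]), abs=1e-4)
        assert fit.components["residual"] == pytest.approx(float(sm.scale), abs=1e-4)


class TestLoglik:
    def test_consistency_and_local_optimality(self, small_markers, small_kasv):
        rng = np.random.default_rng(11)
        n = small_markers.n
        L = np.linalg.cholesky(small_kasv.values + 1e-8 * np.eye(n))
        y = 2 * (L @ rng.standard_normal(n)) + rng.standard_normal(n)
        spec = ModelSpec(terms=[RandomTerm("g", codes=np.arange(n), kernel=small_kasv)])
        fit = fit_reml(spec, y, tol=1e-10)
        assert reml_loglik(spec, y, fit.components) == pytest.approx(fit.loglik, abs=1e-8)
        for nm in ("g", "residual"):
            for f in (0.9, 1.1):
                pert = dict(fit.components)
                pert[nm] *= f
                assert reml_loglik(spec, y, pert) <= fit.loglik + 1e-8

    def test_em_trace_is_monotone(self, small_markers, small_kasv):
        rng = np.random.default_rng(13)
        n = small_markers.n
        y = rng.standard_normal(n) * 2
        spec = ModelSpec(terms=[RandomTerm("g", codes=np.arange(n), kernel=small_kasv)])
        fit = fit_reml(spec, y, algorithm="em", max_iter=60)
        lls = [t["loglik"] for t in fit.trace]
        assert all(b >= a - 1e-7 * max(abs(a), 1) for a, b in zip(lls, lls[1:]))

    def test_fixed_component_is_respected(self):
        y = np.random.default_rng(3).normal(0, 2, 30)
        spec = ModelSpec(
            terms=[RandomTerm("u", codes=np.arange(30) % 5, fixed_value=1.5)]
        )
        fit = fit_reml(spec, y)
        assert fit.components["u"] == 1.5
        assert fit.constraints["u"] == "fixed"

    def test_weighted_residual_scaling_consistency(self):
        """Fixed unit residual with weight matrix c*I equals the free-residual
        identity fit up to the scale c."""
        rng = np.random.default_rng(21)
        codes = np.arange(40) % 8
        y = 2.0 * rng.standard_normal(8)[codes] + rng.standard_normal(40)
        free = fit_reml(ModelSpec(terms=[RandomTerm("u", codes=codes)]), y, tol=1e-10)
        c = 1.0 / free.components["residual"]
        fixed = fit_reml(
            ModelSpec(
                terms=[RandomTerm("u", codes=codes)],
                residual=ResidualSpec(
                    "full", weight_matrix=c * np.eye(40), fixed_value=1.0
                ),
            ),
            y,
            tol=1e-10,
        )
        assert fixed.components["u"] == pytest.approx(free.components["u"], rel=1e-5)
        assert fixed.components["residual"] == 1.0

    def test_permutation_invariance(self, small_markers, small_kasv):
        rng = np.random.default_rng(17)
        n = small_markers.n
        codes = rng.integers(0, 4, n)
        y = rng.standard_normal(4)[codes] * 2 + rng.standard_normal(n)
        spec = ModelSpec(
            terms=[
                RandomTerm("g", codes=np.arange(n), kernel=small_kasv),
                RandomTerm("u", codes=codes),
            ]
        )
        fit = fit_reml(spec, y, tol=1e-10)
        perm = rng.permutation(n)
        Kp = type(small_kasv)(
            labels=[small_kasv.labels[i] for i in perm],
            values=small_kasv.values[np.ix_(perm, perm)],
            kind=small_kasv.kind,
            scale_const=small_kasv.scale_const,
        )
        spec_p = ModelSpec(
            terms=[
                RandomTerm("g", codes=np.arange(n), kernel=Kp),
                RandomTerm("u", codes=codes[perm]),
            ]
        )
        fit_p = fit_reml(spec_p, y[perm], tol=1e-10)
        assert fit_p.loglik == pytest.approx(fit.loglik, abs=1e-6)
        for nm in ("g", "u", "residual"):
            assert fit_p.components[nm] == pytest.approx(fit.components[nm], rel=1e-5)


class TestBlups:
    def test_zero_component_gives_zero_blups(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(30)
        spec = ModelSpec(
            terms=[RandomTerm("u", codes=np.arange(30) % 5, fixed_value=0.0)]
        )
        fit = fit_reml(spec, y)
        assert np.allclose(fit.blups["u"], 0.0)

    def test_balanced_shrinkage_closed_form(self):
        """Identity-kernel BLUPs on balanced data equal classical shrinkage
        of the group-mean deviations."""
        q, r = 3, 2
        codes, y = balanced_oneway(q, r, sig_u=5.0, sig_e=1.0, seed=4)
        fit = fit_reml(ModelSpec(terms=[RandomTerm("u", codes=codes)]), y, tol=1e-12)
        su, se = fit.components["u"], fit.components["residual"]
        ybar = np.array([y[codes == i].mean() for i in range(q)])
        shrink = su / (su + se / r) * (ybar - ybar.mean())
        np.testing.assert_allclose(fit.blups["u"], shrink, atol=1e-6)

    def test_blups_invariant_to_kernel_rescaling(self, small_markers, small_kasv):
        """Rescaling K is absorbed by the variance component: BLUPs unchanged."""
        rng = np.random.default_rng(31)
        n = small_markers.n
        L = np.linalg.cholesky(small_kasv.values + 1e-8 * np.eye(n))
        y = 2 * (L @ rng.standard_normal(n)) + rng.standard_normal(n)
        spec1 = ModelSpec(terms=[RandomTerm("g", codes=np.arange(n), kernel=small_kasv)])
        K2 = type(small_kasv)(
            labels=small_kasv.labels,
            values=small_kasv.values * 3.7,
            kind=small_kasv.kind,
            scale_const=small_kasv.scale_const * 3.7,
        )
        spec2 = ModelSpec(terms=[RandomTerm("g", codes=np.arange(n), kernel=K2)])
        f1 = fit_reml(spec1, y, tol=1e-11)
        f2 = fit_reml(spec2, y, tol=1e-11)
        np.testing.assert_allclose(f1.blups["g"], f2.blups["g"], rtol=1e-4, atol=1e-8)
        assert f2.components["g"] == pytest.approx(f1.components["g"] / 3.7, rel=1e-4)

    def test_centered_kernel_blups_sum_to_zero(self, small_markers, small_kasv):
        rng = np.random.default_rng(37)
        n = small_markers.n
        L = np.linalg.cholesky(small_kasv.values + 1e-8 * np.eye(n))
        y = 3 * (L @ rng.standard_normal(n)) + rng.standard_normal(n)
        fit = fit_reml(
            ModelSpec(terms=[RandomTerm("g", codes=np.arange(n), kernel=small_kasv)]), y
        )
        assert abs(fit.blups["g"].sum()) < 1e-6 * np.abs(fit.blups["g"]).max()


class TestLrTest:
    def test_identical_models(self):
        y = np.random.default_rng(6).normal(0, 1, 40)
        spec = ModelSpec(terms=[RandomTerm("u", codes=np.arange(40) % 4)])
        f1 = fit_reml(spec, y)
        lr, p = lr_test(f1, f1)
        assert lr == 0.0 and p == 1.0

    def test_differing_fixed_effects_rejected(self):
        y = np.random.default_rng(6).normal(0, 1, 40)
        f1 = fit_reml(ModelSpec(terms=[]), y)
        X = np.column_stack([np.ones(40), np.arange(40.0)])
        f2 = fit_reml(ModelSpec(terms=[], fixed=X), y)
        with pytest.raises(ValueError):
            lr_test(f1, f2)

    def test_lr_grows_with_signal(self):
        """A real extra variance component yields growing LR with n."""
        lrs = []
        for n in (60, 240):
            rng = np.random.default_rng(n)
            codes = np.arange(n) % (n // 6)
            y = 2.0 * rng.standard_normal(n // 6)[codes] + rng.standard_normal(n)
            null = fit_reml(ModelSpec(terms=[]), y)
            alt = fit_reml(ModelSpec(terms=[RandomTerm("u", codes=codes)]), y)
            lrs.append(lr_test(null, alt)[0])
        assert lrs[1] > lrs[0] > 0
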