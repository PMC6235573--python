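"""Grid Bayes-factor machinery: likelihoods, priors, and oracles."""

import numpy as np
import pytest
from scipy import stats

import peakshift as ps
from peakshift.bayes import (
    DEFAULT_STEP,
    GridError,
    ThetaGrid,
    make_grid,
)


@pytest.fixture()
def grid():
    return ThetaGrid.span(-120.0, 120.0, 0.05)


class TestPooledSD:
    def test_equal_sd_fixed_point(self):
        a = np.array([0.0, 2.0, 4.0])   # sd 2
        b = np.array([10.0, 12.0, 14.0])
        assert ps.pooled_sd(a, b) == pytest.approx(2.0)

    def test_direct_formula(self):
        assert ps.pooled_sd([1, 2, 3], [4, 6, 8]) == pytest.approx(np.sqrt(2.5))

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            ps.pooled_sd([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])

    def test_within_group_pooling_ignores_mean_separation(self):
        a = np.array([0.0, 2.0, 4.0])
        b = a + 1000.0
        assert ps.pooled_sd(a, b) == pytest.approx(2.0)
        assert ps.pooled_sd(a, b, method="concatenated") > 100


class TestMarginalLikelihood:
    def test_mode_at_single_value(self, grid):
        ml = ps.marginal_likelihood([12.3], 5.0, grid)
        assert grid.theta[np.argmax(ml.values)] == pytest.approx(12.3, abs=grid.step)

    def test_normalized_to_unit_mass(self, grid):
        ml = ps.marginal_likelihood([3.0, -4.0, 7.0], 6.0, grid)
        assert ml.values.sum() * grid.step == pytest.approx(1.0, abs=1e-12)

    def test_matches_conjugate_closed_form(self, grid):
        # product of iid normal likelihoods is Normal(mean, sd/sqrt(n))
        rng = np.random.default_rng(2)
        values = rng.normal(5, 4, size=8)
        sd = 4.0
        ml = ps.marginal_likelihood(values, sd, grid)
        closed = stats.norm.pdf(grid.theta, values.mean(), sd / np.sqrt(len(values)))
        mask = closed > closed.max() * 1e-6
        assert np.allclose(ml.values[mask], closed[mask], rtol=1e-6)

    def test_truncating_grid_raises(self):
        tight = ThetaGrid.span(-1.0, 1.0, 0.05)
        with pytest.raises(GridError):
            ps.marginal_likelihood([30.0], 5.0, tight)


class TestNullPrior:
    def test_mean_is_zero_within_half_step(self, grid):
        p = ps.null_prior([4.0, 9.0, -1.0], 5.0, grid)
        mean = np.sum(grid.theta * p.values) * grid.step
        assert abs(mean) <= grid.step / 2

    def test_is_translation_of_likelihood(self, grid):
        values = np.array([10.0, 14.0, 18.0])
        sd = 5.0
        like = ps.marginal_likelihood(values, sd, grid)
        null = ps.null_prior(values, sd, grid)
        # cross-correlation peak: the null is the likelihood shifted by -mean
        lag = np.argmax(np.correlate(null.values, like.values, mode="full"))
        shift = (lag - (len(grid.theta) - 1)) * grid.step
        assert shift == pytest.approx(-values.mean(), abs=grid.step)

    def test_mean_zero_data_identical_to_likelihood(self, grid):
        values = np.array([-6.0, 0.0, 6.0])
        like = ps.marginal_likelihood(values, 5.0, grid)
        null = ps.null_prior(values, 5.0, grid)
        assert np.array_equal(like.values, null.values)


class TestIncrementalPrior:
    def test_zero_halfwidth_is_the_null(self, grid):
        null = ps.null_prior([3.0, -3.0], 4.0, grid)
        inc = ps.incremental_prior(null, 0.0)
        assert np.array_equal(inc.values, null.values)
        assert inc.kind == "incremental"

    def test_support_widens_by_halfwidth(self, grid):
        # compactly supported null (uniform on ±a): the convolution support
        # is exactly ±(a + h), up to one grid step
        a, h = 10.0, 20.0
        vals = np.where(np.abs(grid.theta) <= a, 1.0, 0.0)
        null = ps.Prior(grid=grid, values=vals / (vals.sum() * grid.step),
                        kind="null")
        inc = ps.incremental_prior(null, h)
        support = grid.theta[inc.values > 1e-12]
        assert support[0] == pytest.approx(-(a + h), abs=grid.step + 1e-9)
        assert support[-1] == pytest.approx(a + h, abs=grid.step + 1e-9)

    def test_matches_analytic_uniform_normal_convolution(self, grid):
        # null ~ Normal(0, s) discretized; uniform(±h) ⊛ normal has closed
        # form (Φ((θ+h)/s) − Φ((θ−h)/s)) / 2h
        s, h = 6.0, 15.0
        null_vals = stats.norm.pdf(grid.theta, 0, s)
        null_vals /= null_vals.sum() * grid.step
        null = ps.Prior(grid=grid, values=null_vals, kind="null")
        inc = ps.incremental_prior(null, h)
        analytic = (stats.norm.cdf((grid.theta + h) / s)
                    - stats.norm.cdf((grid.theta - h) / s)) / (2 * h)
        assert np.max(np.abs(inc.values - analytic)) < 1e-6

    def test_overflowing_support_raises(self):
        tight = ThetaGrid.span(-10.0, 10.0, 0.05)
        vals = stats.norm.pdf(tight.theta, 0, 2.0)
        vals /= vals.sum() * tight.step
        null = ps.Prior(grid=tight, values=vals, kind="null")
        with pytest.raises(GridError):
            ps.incremental_prior(null, 30.0)


class TestReferencePrior:
    def test_definitional_equality_with_marginal_likelihood(self, grid):
        vals = [-50.0, -44.0, -47.0]
        ml = ps.marginal_likelihood(vals, 5.0, grid)
        p = ps.reference_prior(vals, 5.0, grid)
        assert np.array_equal(p.values, ml.values)
        assert p.kind == "reference"

    def test_mode_near_reference_mean(self, grid):
        p = ps.reference_prior([-50.0, -44.0, -47.0], 5.0, grid)
        assert grid.theta[np.argmax(p.values)] == pytest.approx(-47.0, abs=0.1)


class TestBayesFactor:
    def test_identical_priors_give_exactly_one(self, grid):
        like = ps.marginal_likelihood([1.0, 2.0], 5.0, grid)
        null = ps.null_prior([1.0, 2.0], 5.0, grid)
        alt = ps.Prior(grid=grid, values=null.values.copy(), kind="reference")
        assert ps.bayes_factor(like, null, alt).bf == 1.0

    def test_separated_reference_strongly_favors_null(self):
        data = [0.5, -1.0, 0.2, 1.1, -0.6]
        ref = [-50.0, -44.0, -47.0, -45.0, -52.0]
        res = ps.no_shift_evidence(data, ref, prior="reference")
        assert res.bf > 100
        assert res.band == "decisive"

    def test_grid_refinement_stability(self):
        data = [2.0, -1.0, 4.0, 0.5]
        ref = [30.0, 42.0, 38.0, 35.0]
        coarse = ps.no_shift_evidence(data, ref, prior="incremental", step=0.05)
        fine = ps.no_shift_evidence(data, ref, prior="incremental", step=0.005)
        assert coarse.bf == pytest.approx(fine.bf, rel=1e-3)

    def test_conjugate_closed_form_oracle(self, grid):
        # replace both priors by discretized normals: the grid BF must match
        # the normal-normal marginal ratio
        # m_i = Normal(mean(v); mu_i, s_n^2 + tau_i^2)
        rng = np.random.default_rng(4)
        values = rng.normal(3, 5, size=6)
        sd = 5.0
        s_n2 = sd**2 / len(values)
        like = ps.marginal_likelihood(values, sd, grid)
        for mu0, tau0, mu1, tau1 in [(0, 4, -10, 8), (0, 2, 5, 3), (1, 6, -4, 2)]:
            p0 = stats.norm.pdf(grid.theta, mu0, tau0)
            p1 = stats.norm.pdf(grid.theta, mu1, tau1)
            null = ps.Prior(grid, p0 / (p0.sum() * grid.step), "null")
            alt = ps.Prior(grid, p1 / (p1.sum() * grid.step), "reference")
            res = ps.bayes_factor(like, null, alt)
            closed = (stats.norm.pdf(values.mean(), mu0, np.sqrt(s_n2 + tau0**2))
                      / stats.norm.pdf(values.mean(), mu1, np.sqrt(s_n2 + tau1**2)))
            assert res.bf == pytest.approx(closed, rel=5e-3)

    def test_grid_mismatch_rejected(self, grid):
        other = ThetaGrid.span(-50.0, 50.0, 0.05)
        like = ps.marginal_likelihood([0.0, 1.0], 5.0, grid)
        null = ps.null_prior([0.0, 1.0], 5.0, grid)
        alt = ps.null_prior([0.0, 1.0], 5.0, other)
        with pytest.raises(ValueError):
            ps.bayes_factor(like, null, ps.Prior(other, alt.values, "reference"))

    def test_translation_invariance_of_grid_machinery(self):
        # shifting the data and both priors' construction inputs by the same
        # constant leaves the BF unchanged (priors built directly as marginal
        # likelihoods, without mean-centering)
        data = np.array([1.0, 3.0, -2.0, 0.5])
        p0_vals = np.array([0.0, 1.0, -1.0])
        p1_vals = np.array([20.0, 25.0, 22.0])
        sd = 4.0

        def bf_at(c):
            allv = np.concatenate([data, p0_vals, p1_vals]) + c
            g = make_grid(allv, sd, len(data), step=0.05)
            like = ps.marginal_likelihood(data + c, sd, g)
            null = ps.Prior(g, ps.marginal_likelihood(p0_vals + c, sd, g).values, "null")
            alt = ps.Prior(g, ps.marginal_likelihood(p1_vals + c, sd, g).values, "reference")
            return ps.bayes_factor(like, null, alt).bf

        assert bf_at(0.0) == pytest.approx(bf_at(7.0), abs=1e-9, rel=1e-9)


class TestNullCalibration:
    def test_no_change_groups_favor_null(self):
        # simulated no-transfer groups (true shift 0) vs a -50% reference:
        # the incremental-prior BF should usually exceed 1 and the
        # reference-prior BF should be decisive in most replicates
        rng = np.random.default_rng(11)
        n, reps = 10, 200
        inc_hits = ref_hits = 0
        for _ in range(reps):
            data = 5.0 * rng.standard_normal(n)          # no-shift group
            ref = -50.0 + 6.0 * rng.standard_normal(n)   # shifted group
            inc = ps.no_shift_evidence(data, ref, prior="incremental")
            refbf = ps.no_shift_evidence(data, ref, prior="reference")
            inc_hits += inc.bf > 1
            ref_hits += refbf.bf > 100
        assert inc_hits / reps >= 0.80
        assert ref_hits / reps >= 0.80

    def test_heuristic_band_labels(self):
        r = ps.BFResult(1, 1, 5.0, 0, 0, 0.05)
        assert r.band == "substantial"
        assert ps.BFResult(1, 1, 50.0, 0, 0, 0.05).band == "strong"
        assert ps.BFResult(1, 1, 500.0, 0, 0, 0.05).band == "decisive"
        assert ps.BFResult(1, 1, 0.2, 0, 0, 0.05).band == "favors-alternative"
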