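"""Scheme generation: region sampling, conditional matrices, ensembles."""

import numpy as np
import pytest
from scipy import stats

from seamsim import (
    ARMS,
    ArmLabel,
    ProbTriple,
    build_scheme_ensemble,
    ensemble_to_json,
    sample_conditional,
    sample_outcome_pair,
    sample_x_marginals,
    sample_y_marginal,
    substream,
    table1_scheme,
)
from seamsim.outcomes import MARGIN_TOL
from seamsim.schemes import (
    RegionInfeasibleError,
    XRegionSpec,
    YRegionSpec,
    conditional_candidate_ok,
    sample_outcome_batch,
)


def _oracle_simplex(rng, size):
    """Uniform triples on the simplex via sorted uniforms — independent of
    the dirichlet-based implementation under test."""
    u = np.sort(rng.random((size, 2)), axis=1)
    return np.column_stack([u[:, 0], u[:, 1] - u[:, 0], 1.0 - u[:, 1]])


class TestMarginalSampling:
    def test_degenerate_x_region_forces_the_point(self, rng):
        (t,) = sample_x_marginals(
            1, XRegionSpec(ich=(0.06, 0.06), mni=(0.26, 0.26)), rng
        )
        assert np.allclose(t.as_array(), [0.06, 0.68, 0.26])

    def test_degenerate_y_region_forces_the_point(self, rng):
        t = sample_y_marginal(YRegionSpec(poor=(0.40, 0.40), good=(0.35, 0.35)), rng)
        assert np.allclose(t.as_array(), [0.40, 0.25, 0.35])

    def test_draws_lie_in_region_and_sum_to_one(self, rng):
        region = XRegionSpec()
        triples = sample_x_marginals(10, region, rng)
        for t in triples:
            assert region.ich[0] <= t.p0 <= region.ich[1]
            assert region.mni[0] <= t.p2 <= region.mni[1]
            assert abs(sum(t) - 1.0) <= 1e-12

    def test_uniformity_matches_rejection_oracle(self, rng):
        """The conditional-uniform law over the admissible sub-simplex is
        checked against a brute-force rejection sampler built on an
        independent flat-simplex generator."""
        region = XRegionSpec(ich=(0.01, 0.12), mni=(0.05, 0.45))
        n = 10_000
        draws = np.array([list(t) for t in sample_x_marginals(n, region, rng)])

        oracle_rng = np.random.default_rng(987654321)
        cand = _oracle_simplex(oracle_rng, 200_000)
        keep = (
            (cand[:, 0] >= 0.01) & (cand[:, 0] <= 0.12)
            & (cand[:, 2] >= 0.05) & (cand[:, 2] <= 0.45)
        )
        oracle = cand[keep][:n]
        assert len(oracle) == n
        for j in range(3):
            se = np.sqrt(draws[:, j].var() / n + oracle[:, j].var() / n)
            assert abs(draws[:, j].mean() - oracle[:, j].mean()) < 4 * se

    def test_zero_area_region_raises(self, rng):
        with pytest.raises(RegionInfeasibleError):
            sample_x_marginals(
                1, XRegionSpec(ich=(0.90, 0.95), mni=(0.90, 0.95)), rng, max_tries=50_000
            )


class TestConditionalSampling:
    def test_independence_candidate_accepted(self):
        x = np.array([0.06, 0.64, 0.30])
        y = np.array([0.40, 0.25, 0.35])
        ok, reason, row_nei = conditional_candidate_ok(y.copy(), y.copy(), x, y)
        assert ok and reason is None
        assert np.allclose(row_nei, y)

    def test_marginalization_postcondition(self, rng):
        x = ProbTriple(0.05, 0.60, 0.35)
        y = ProbTriple(0.45, 0.25, 0.30)
        for _ in range(20):
            m = sample_conditional(x, y, rng)
            implied = x.as_array() @ m.as_array()
            assert np.max(np.abs(implied - y.as_array())) <= MARGIN_TOL

    def test_acceptance_predicate_matches_independent_oracle(self):
        """Dual-implementation check: the packaged acceptance test and a
        plain-Python re-derivation must agree candidate by candidate."""

        def oracle_ok(ri, rm, x, y):
            if not (ri[0] >= rm[0] - 1e-12 and ri[2] <= rm[2] + 1e-12):
                return False
            rn = [(y[j] - x[0] * ri[j] - x[2] * rm[j]) / x[1] for j in range(3)]
            if any(v < -1e-12 or v > 1 + 1e-12 for v in rn):
                return False
            if not (ri[0] >= rn[0] - 1e-12 and rn[0] >= rm[0] - 1e-12):
                return False
            if not (ri[2] <= rn[2] + 1e-12 and rn[2] <= rm[2] + 1e-12):
                return False
            return True

        x = np.array([0.05, 0.60, 0.35])
        y = np.array([0.45, 0.25, 0.30])
        g = np.random.default_rng(13)
        n_acc = 0
        for _ in range(1000):
            ri = g.dirichlet((1, 1, 1))
            rm = g.dirichlet((1, 1, 1))
            ok, _, _ = conditional_candidate_ok(ri, rm, x, y)
            assert ok == oracle_ok(ri, rm, x, y)
            n_acc += ok
        assert 0 < n_acc < 1000  # the test exercises both branches

    def test_infeasible_pair_raises_named_error(self, rng):
        # Rankin marginal far outside anything the conditional rows can
        # average to under this X marginal and monotone ordering.
        x = ProbTriple(0.98, 0.01, 0.01)
        y = ProbTriple(0.0, 0.0, 1.0)
        with pytest.raises(RegionInfeasibleError, match="violation"):
            sample_conditional(x, y, rng, max_tries=2000)


class TestEnsemble:
    def test_counts_and_invariants(self):
        ens = build_scheme_ensemble(2, 3, 2, rng=substream(5, "schemes"))
        assert len(ens) == 12
        for s in ens:
            s.validate()  # marginalization + null Y-marginal identity
            assert s.is_null
            y0 = s.y_marginal[ArmLabel.A]
            assert all(s.y_marginal[a] == y0 for a in ARMS)

    def test_single_cell_ensemble(self):
        ens = build_scheme_ensemble(1, 1, 1, rng=substream(6, "schemes"))
        assert len(ens) == 1

    def test_fixed_seed_reproduces_byte_identical_ensemble(self):
        a = build_scheme_ensemble(2, 2, 2, rng=substream(42, "schemes"))
        b = build_scheme_ensemble(2, 2, 2, rng=substream(42, "schemes"))
        assert ensemble_to_json(a) == ensemble_to_json(b)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            build_scheme_ensemble(0, 1, 1)


class TestOutcomeSampling:
    def test_point_mass_x(self, fixture_schemes, rng):
        s = fixture_schemes[0]
        import dataclasses

        one_hot = ProbTriple(1.0, 0.0, 0.0)
        y = s.y_marginal[ArmLabel.A]
        from seamsim import CondMatrix, DistributionScheme

        scheme = DistributionScheme(
            x_marginal={a: one_hot for a in ARMS},
            y_marginal={a: y for a in ARMS},
            conditional={a: CondMatrix((y, y, y)) for a in ARMS},
            is_null=True,
        )
        x, _ = sample_outcome_batch(scheme, ArmLabel.A, 500, rng)
        assert np.all(x == 0)

    def test_joint_frequencies_match_tabulation_oracle(self, rng):
        """Empirical joint (X, Y) cell frequencies against the brute-force
        product P[X = x] * P[Y = y | X = x] (chi-square GOF, alpha 0.001)."""
        (scheme,) = build_scheme_ensemble(1, 1, 1, rng=substream(77, "schemes"))
        n = 100_000
        x, y = sample_outcome_batch(scheme, ArmLabel.B, n, rng)
        observed = np.zeros((3, 3))
        np.add.at(observed, (x.astype(int), y.astype(int)), 1)
        expected = (
            scheme.x_marginal[ArmLabel.B].as_array()[:, None]
            * scheme.conditional[ArmLabel.B].as_array()
        ) * n
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=8)
        assert p > 0.001
        # X marginal separately, within 3 standard errors per category
        for j, pj in enumerate(scheme.x_marginal[ArmLabel.B].as_array()):
            se = np.sqrt(pj * (1 - pj) / n)
            assert abs((x == j).mean() - pj) < 3.5 * se

    def test_sample_outcome_pair_types(self, fixture_schemes, rng):
        x, y = sample_outcome_pair(fixture_schemes[0], ArmLabel.D, rng)
        from seamsim import RankinCategory, RapidResponse

        assert isinstance(x, RapidResponse) and isinstance(y, RankinCategory)

    def test_unknown_arm_rejected(self, fixture_schemes, rng):
        with pytest.raises(KeyError):
            sample_outcome_batch(fixture_schemes[0], "E", 1, rng)


class TestTable1Scheme:
    def test_best_arm_marginal(self):
        xm = table1_scheme((0.36, 0.06), (0.16, 0.06), (0.16, 0.06))
        assert np.allclose(xm[ArmLabel.A].as_array(), [0.06, 0.58, 0.36])

    def test_equal_doses_give_identical_marginals(self):
        xm = table1_scheme((0.26, 0.06), (0.26, 0.06), (0.26, 0.06))
        assert xm[ArmLabel.A] == xm[ArmLabel.B] == xm[ArmLabel.C]

    def test_zero_intermediate_category(self):
        xm = table1_scheme((0.7, 0.3), (0.2, 0.1), (0.2, 0.1))
        assert xm[ArmLabel.A].p1 == 0.0

    def test_invalid_pair_rejected(self):
        with pytest.raises(ValueError):
            table1_scheme((0.8, 0.3), (0.2, 0.1), (0.2, 0.1))
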