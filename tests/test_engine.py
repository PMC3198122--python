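"""Trial engine: full-trial simulation, OC estimation, error accounting."""

import numpy as np
import pytest

from seamsim import (
    ArmLabel,
    ArmSummary,
    GSConfig,
    Phase2Config,
    SelectionConfig,
    assess_promise,
    build_scheme_ensemble,
    estimate_selection_ocs,
    estimate_type1_errors,
    simulate_fss_trial,
    simulate_full_trial,
    substream,
    table1_scheme,
)
from seamsim.engine import _simulate_trial_batch, STAGE_NAMES
from seamsim.outcomes import TNK_ARMS
from seamsim.phase2 import PROMISING

SEL = SelectionConfig()
GS = GSConfig()
P2 = Phase2Config()


@pytest.fixture(scope="module")
def small_ensemble():
    return build_scheme_ensemble(2, 2, 1, rng=substream(314, "schemes"))


class TestGSConfig:
    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            GSConfig(interim_totals=(500, 400, 1500))
        with pytest.raises(ValueError):
            GSConfig(terminal_total=1907)
        with pytest.raises(ValueError):
            GSConfig(interim_totals=(500, 1000, 2000))

    def test_per_arm_schedule(self):
        assert GS.per_arm_looks == (250, 500, 750)
        assert GS.terminal_per_arm == 954


class TestSingleTrial:
    def test_deterministic_under_fixed_stream(self, fixture_schemes):
        a = simulate_full_trial(fixture_schemes[0], rng=substream(9, "trial"))
        b = simulate_full_trial(fixture_schemes[0], rng=substream(9, "trial"))
        assert a == b

    def test_degenerate_rankin_never_rejects(self, fixture_schemes):
        """All Rankin mass on the middle category: zero-variance endpoints
        can never reject, whatever stage the trial reaches."""
        degenerate = fixture_schemes[5]
        for s in range(25):
            res = simulate_full_trial(degenerate, rng=substream(s, "deg"))
            assert not res.any_type1
            assert not any(
                f for d in res.rejections.values() for f in d.values()
            )

    def test_safety_imbalance_stops_for_futility(self, fixture_schemes):
        """Tenecteplase ICH probability far above rt-PA's: Scenario 3 is
        near-certain, so almost every replication is declared unpromising
        with no error."""
        risky = fixture_schemes[6]
        stops = [
            simulate_full_trial(risky, rng=substream(s, "risky")).stop_stage
            for s in range(30)
        ]
        assert stops.count("phase2_futility") >= 28
        assert all(s in STAGE_NAMES for s in stops)

    def test_selection_result_accounting(self, fixture_schemes):
        res = simulate_full_trial(fixture_schemes[0], rng=substream(2, "acct"))
        sel = res.selection
        m = SEL.truncation_m
        n1 = sel.n_first_elim if sel.n_first_elim is not None else m
        n = sel.n_final if sel.n_final is not None else m
        assert sel.tnk_patients == 2 * min(n, m) + min(n1, m)

    def test_fss_trial_always_terminal(self, fixture_schemes):
        res = simulate_fss_trial(fixture_schemes[0], rng=substream(4, "fss"))
        assert res.stop_stage == "terminal"
        assert res.decision is None
        assert res.holm_rejected is not None


class TestBatchAgainstScalarRules:
    """Dual-route check: the vectorized engine's phase II decisions must
    reproduce the scalar clinical-rules module on the same counts."""

    def test_promise_decisions_match_assess_promise(self, small_ensemble):
        scheme = small_ensemble[0]
        res = _simulate_trial_batch(
            scheme, 400, SEL, GS, P2, "gs", substream(55, "dual"), collect_details=True
        )
        d = res.details
        checked = 0
        for i in range(400):
            if res.no_winner[i]:
                continue
            a1 = int(d["a1"][i])
            tnk = ArmSummary(
                n_rapid=a1, ich_count=int(d["ich_t"][i]), n_rankin=a1,
                poor_count=int(d["poor_t"][i]),
                neither_count=a1 - int(d["poor_t"][i]) - int(d["good_t"][i]),
                good_count=int(d["good_t"][i]),
            )
            rtpa = ArmSummary(
                n_rapid=a1, ich_count=int(d["ich_r"][i]), n_rankin=a1,
                poor_count=int(d["poor_r"][i]),
                neither_count=a1 - int(d["poor_r"][i]) - int(d["good_r"][i]),
                good_count=int(d["good_r"][i]),
            )
            dec = assess_promise(tnk, rtpa, GS.alpha_interim, P2)
            assert (dec.status == PROMISING) == bool(d["prom1"][i])
            assert dec.scenario == int(d["scen1"][i])
            assert ("poor" in dec.significant_endpoints) == bool(d["rej1_poor"][i])
            assert ("good" in dec.significant_endpoints) == bool(d["rej1_good"][i])
            checked += 1
        assert checked > 300

    def test_futility_stop_implies_no_interim1_rejection(self, small_ensemble):
        res = _simulate_trial_batch(
            small_ensemble[1], 2000, SEL, GS, P2, "gs", substream(56, "dual")
        )
        futility = res.stage == 0
        assert not (futility & res.any_type1).any()

    def test_stage_consistency(self, small_ensemble):
        res = _simulate_trial_batch(
            small_ensemble[2], 2000, SEL, GS, P2, "gs", substream(57, "dual")
        )
        assert np.all(res.stage >= 0)
        # rejections at interims 2-4 only occur for trials that continued
        continued = res.stage >= 2
        assert res.reached_terminal.sum() <= continued.sum()
        # terminal Holm rejections only where the trial reached terminal
        assert not (res.holm_poor & ~res.reached_terminal).any()


class TestEstimateSelectionOCs:
    def test_equal_arms_are_exchangeable_and_probs_sum(self):
        xm = table1_scheme((0.26, 0.06), (0.26, 0.06), (0.26, 0.06))
        row = estimate_selection_ocs(
            [xm[a] for a in TNK_ARMS], reps=20_000, seed=777
        )
        probs = np.array(row.arm_selection_probs)
        assert abs(probs.sum() + row.p_no_winner - 1.0) < 1e-12
        se = np.sqrt(2 * probs.mean() * (1 - probs.mean()) / row.reps)
        for i in range(3):
            for j in range(i + 1, 3):
                assert abs(probs[i] - probs[j]) < 3 * se

    def test_pcs_monotone_in_best_arm_advantage(self):
        """Raising the best arm's MNI probability cannot hurt correct
        selection (checked on a 3-point grid within Monte-Carlo error)."""
        pcs = []
        for p_mni in (0.26, 0.31, 0.36):
            xm = table1_scheme((p_mni, 0.06), (0.21, 0.06), (0.21, 0.06))
            row = estimate_selection_ocs(
                [xm[a] for a in TNK_ARMS], reps=20_000, seed=778
            )
            pcs.append(row.p_cs)
        mc = 3 * np.sqrt(0.25 / 20_000)
        assert pcs[1] >= pcs[0] - mc and pcs[2] >= pcs[1] - mc

    def test_invalid_inputs(self):
        xm = table1_scheme((0.26, 0.06), (0.26, 0.06), (0.26, 0.06))
        with pytest.raises(ValueError):
            estimate_selection_ocs([xm[a] for a in TNK_ARMS], reps=0)


class TestEstimateType1Errors:
    def test_rate_bounds_and_structure(self, small_ensemble):
        s = estimate_type1_errors(small_ensemble, 400, mode="gs", seed=91)
        ps = s.per_scheme
        assert len(ps) == len(small_ensemble)
        # either-rate is bounded by the endpoint rates (Bonferroni both ways)
        assert (ps.either <= ps.poor + ps.good + 1e-12).all()
        assert (ps.either >= np.maximum(ps.poor, ps.good) - 1e-12).all()
        assert list(s.stats.index) == ["poor", "good", "either"]
        assert s.stats.loc["either", "Range"] == pytest.approx(
            s.stats.loc["either", "Maximum"] - s.stats.loc["either", "Minimum"]
        )

    def test_deterministic_under_fixed_seed(self, small_ensemble):
        a = estimate_type1_errors(small_ensemble[:2], 300, seed=92)
        b = estimate_type1_errors(small_ensemble[:2], 300, seed=92)
        assert a.per_scheme.equals(b.per_scheme)
        c = estimate_type1_errors(small_ensemble[:2], 300, seed=93)
        assert not c.per_scheme.equals(a.per_scheme)

    def test_non_null_scheme_rejected(self, small_ensemble):
        import dataclasses

        bad = dataclasses.replace(small_ensemble[0], is_null=False)
        with pytest.raises(ValueError, match="null"):
            estimate_type1_errors([bad], 10, seed=1)

    def test_zero_reps_rejected(self, small_ensemble):
        with pytest.raises(ValueError, match="reps"):
            estimate_type1_errors(small_ensemble, 0)

    def test_unknown_mode_rejected(self, small_ensemble):
        with pytest.raises(ValueError, match="mode"):
            estimate_type1_errors(small_ensemble, 10, mode="bayes")
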