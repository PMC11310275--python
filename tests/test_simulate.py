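import numpy as np
import pytest

from armloss.metrics import profiles_for_arm
from armloss.simulate import (
    SimulationConfig,
    expected_cindex,
    group_median_years,
    simulate_cohort,
    simulated_arm_table,
    truth_recovery_report,
)


def mc_cindex_oracle(strata, censoring_rate, n_pairs, rng):
    """Brute-force Monte-Carlo oracle: draw subject pairs from the exponential
    strata, apply the comparability/tie rules pairwise, count."""
    probs = np.array([s[0] for s in strata])
    lams = np.array([s[1] for s in strata])
    scores = np.array([s[2] for s in strata])
    conc = disc = tied = 0
    for _ in range(n_pairs):
        si, sj = rng.choice(len(strata), size=2, p=probs)
        ti = rng.exponential(1 / lams[si])
        tj = rng.exponential(1 / lams[sj])
        ci = rng.exponential(1 / censoring_rate)
        cj = rng.exponential(1 / censoring_rate)
        xi, ei = min(ti, ci), ti <= ci
        xj, ej = min(tj, cj), tj <= cj
        if xi < xj and ei:
            first, second = si, sj
        elif xj < xi and ej:
            first, second = sj, si
        else:
            continue
        if scores[first] > scores[second]:
            conc += 1
        elif scores[first] < scores[second]:
            disc += 1
        else:
            tied += 1
    return (conc + 0.5 * tied) / (conc + disc + tied)


class TestConfig:
    def test_default_config_is_valid(self):
        SimulationConfig().validate()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p_no_loss": 0.5, "p_complete": 0.4, "p_segmental": 0.2},
            {"hr_loss": -1},
            {"baseline_hazard": 0},
            {"p_artifact": 1.5},
            {"mc_mixture": {"none": (1, 0, 0, 0, 0, 0), "complete": (0.5, 0, 0, 0, 0, 0)}},
            {"grade_probs_loss": (0.5, 0.5, 0.5)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs).validate()


class TestSimulateCohort:
    def test_degenerate_all_neutral(self):
        cfg = SimulationConfig(
            n_subjects=50, n_cohorts=1, p_no_loss=1.0, p_complete=0.0,
            p_segmental=0.0, p_artifact=0.0, noise_sd=0.0, seed=1,
        )
        cohort = simulate_cohort(cfg)
        profiles = profiles_for_arm(cohort.segments, cohort.arm_table.get("chr1", "p"))
        assert all(p.loss_percent == 0 for p in profiles)

    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(n_subjects=40, n_cohorts=2, seed=99)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert a.segments == b.segments
        assert a.clinical == b.clinical
        assert a.truth.equals(b.truth)

    def test_different_seed_differs(self):
        a = simulate_cohort(SimulationConfig(n_subjects=40, seed=1))
        b = simulate_cohort(SimulationConfig(n_subjects=40, seed=2))
        assert a.segments != b.segments

    def test_every_sample_has_segments_and_truth(self):
        cohort = simulate_cohort(SimulationConfig(n_subjects=30, n_cohorts=2, seed=5))
        clin_ids = {r.sample_id for r in cohort.clinical}
        assert clin_ids == set(cohort.truth["sample_id"])
        assert clin_ids == {s.sample_id for s in cohort.segments}

    def test_artifact_rate_law_of_large_numbers(self):
        """The measured 1-5% loss rate converges to p_no_loss * p_artifact
        (artifacts arise only in truly intact samples)."""
        cfg = SimulationConfig(n_subjects=2000, n_cohorts=1, seed=12)
        cohort = simulate_cohort(cfg)
        profiles = profiles_for_arm(cohort.segments, cohort.arm_table.get("chr1", "p"))
        frac = np.mean([1 <= p.loss_percent <= 5 for p in profiles])
        assert frac == pytest.approx(cfg.p_no_loss * cfg.p_artifact, abs=0.01)

    def test_extent_mixture_marginals(self):
        cfg = SimulationConfig(n_subjects=3000, n_cohorts=1, seed=8)
        truth = simulate_cohort(cfg).truth
        e = truth["true_extent"].to_numpy()
        assert np.mean(e == 0) == pytest.approx(cfg.p_no_loss, abs=0.03)
        assert np.mean(e >= 0.96) == pytest.approx(cfg.p_complete, abs=0.03)
        assert np.mean((e > 0.05) & (e < 0.96)) == pytest.approx(cfg.p_segmental, abs=0.03)

    def test_telomere_anchored_partials(self):
        """Partial losses anchor at the 1p telomere (coordinate 0), so loss
        coverage is non-increasing toward the centromere."""
        cfg = SimulationConfig(n_subjects=500, n_cohorts=1, p_no_loss=0.0,
                               p_complete=0.0, p_segmental=1.0, seed=3)
        cohort = simulate_cohort(cfg)
        arm = cohort.arm_table.get("chr1", "p")
        loss_starts = [
            s.start for s in cohort.segments
            if s.chrom == "chr1" and s.start < arm.end and s.log2_ratio < -0.15
        ]
        assert all(st == arm.start for st in loss_starts)

    def test_mc_composition_anchors(self):
        """~94% benign classes at 0% loss; ~72% Int/Mal at complete loss."""
        cfg = SimulationConfig(n_subjects=4000, n_cohorts=1, seed=21)
        cohort = simulate_cohort(cfg)
        mc = {r.sample_id: r.mc_class for r in cohort.clinical}
        truth = cohort.truth.set_index("sample_id")
        ben = {"Ben-1", "Ben-2", "Ben-3"}
        zero = [mc[s] for s in truth.index[truth["true_extent"] == 0]]
        comp = [mc[s] for s in truth.index[truth["true_extent"] >= 0.96]]
        assert np.mean([m in ben for m in zero]) == pytest.approx(0.94, abs=0.03)
        assert np.mean([m not in ben for m in comp]) == pytest.approx(0.72, abs=0.03)

    def test_censoring_fraction_matches_rates(self):
        """P(censored) for exponentials is c / (lambda + c) per stratum."""
        cfg = SimulationConfig(n_subjects=4000, n_cohorts=1, seed=17)
        cohort = simulate_cohort(cfg)
        truth = cohort.truth.set_index("sample_id")
        events = {r.sample_id: r.event for r in cohort.clinical}
        no_loss = [events[s] for s in truth.index[~truth["true_loss_1p"]]]
        expected_event = cfg.baseline_hazard / (cfg.baseline_hazard + cfg.censoring_rate)
        assert np.mean(no_loss) == pytest.approx(expected_event, abs=0.03)


class TestAnalyticOracles:
    def test_single_stratum_median_closed_form(self):
        assert group_median_years([1.0], [0.1]) == pytest.approx(np.log(2) / 0.1)

    def test_mixture_median_bracketed_by_components(self):
        med = group_median_years([0.5, 0.5], [0.05, 0.2])
        assert np.log(2) / 0.2 < med < np.log(2) / 0.05

    def test_null_strata_give_half(self):
        c = expected_cindex([(0.5, 0.1, 0.0), (0.5, 0.1, 1.0)], censoring_rate=0.05)
        assert c == pytest.approx(0.5)

    def test_expected_cindex_matches_mc_bruteforce(self):
        """Closed form vs 10^5-pair Monte-Carlo enumeration oracle."""
        strata = [(0.6, 0.045, 0.0), (0.25, 0.18, 1.0), (0.15, 0.27, 1.0)]
        analytic = expected_cindex(strata, censoring_rate=0.04)
        mc = mc_cindex_oracle(strata, 0.04, 100_000, np.random.default_rng(4))
        assert analytic == pytest.approx(mc, abs=0.01)


class TestTruthRecovery:
    def test_zero_noise_perfect_confusion_matrix(self):
        cfg = SimulationConfig(n_subjects=300, n_cohorts=1, noise_sd=0.0,
                               p_artifact=0.0, seed=6)
        cohort = simulate_cohort(cfg)
        profiles = profiles_for_arm(cohort.segments, cohort.arm_table.get("chr1", "p"))
        report = truth_recovery_report(cohort, profiles, cutoff_percent=5)
        assert report["confusion"]["fp"] == 0
        assert report["confusion"]["fn"] == 0
        assert report["accuracy"] == 1.0

    def test_null_hazard_cindex_near_half(self):
        cfg = SimulationConfig(n_subjects=2000, n_cohorts=1, hr_loss=1.0,
                               hr_co_loss=1.0, seed=13)
        cohort = simulate_cohort(cfg)
        profiles = profiles_for_arm(cohort.segments, cohort.arm_table.get("chr1", "p"))
        report = truth_recovery_report(cohort, profiles, cutoff_percent=5)
        assert report["c_index"] == pytest.approx(0.5, abs=0.02)
        assert report["c_index_analytic"] == pytest.approx(0.5)

    def test_elevated_hazard_matches_analytic_cindex(self):
        cfg = SimulationConfig(n_subjects=2000, n_cohorts=1, seed=14)
        cohort = simulate_cohort(cfg)
        profiles = profiles_for_arm(cohort.segments, cohort.arm_table.get("chr1", "p"))
        report = truth_recovery_report(cohort, profiles, cutoff_percent=5)
        assert report["c_index"] == pytest.approx(report["c_index_analytic"], abs=0.02)

    def test_median_difference_near_analytic(self):
        """KM medians approach the closed-form exponential(-mixture) medians;
        the stated world puts the difference near 12 years."""
        cfg = SimulationConfig(n_subjects=2000, n_cohorts=1, seed=15)
        cohort = simulate_cohort(cfg)
        profiles = profiles_for_arm(cohort.segments, cohort.arm_table.get("chr1", "p"))
        report = truth_recovery_report(cohort, profiles, cutoff_percent=5)
        measured = report["km_median_no_loss"] - report["km_median_loss"]
        assert measured == pytest.approx(report["analytic_median_difference"], rel=0.15)
        assert 9 < report["analytic_median_difference"] < 15

    def test_missing_profiles_rejected(self):
        cfg = SimulationConfig(n_subjects=20, n_cohorts=1, seed=6)
        cohort = simulate_cohort(cfg)
        profiles = profiles_for_arm(cohort.segments, cohort.arm_table.get("chr1", "p"))
        with pytest.raises(ValueError, match="missing"):
            truth_recovery_report(cohort, profiles[:-1])


def test_simulated_arm_table_is_valid():
    table = simulated_arm_table()
    table.validate()
    assert table.get("chr1", "p").length == 125_000_000
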