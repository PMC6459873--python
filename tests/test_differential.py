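"""Difference profiles, pooled-SD CI, hybrid rule, residue consolidation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hdxpipe as hp
from hdxpipe.differential import _consecutive_run


@pytest.fixture()
def pep(toy_protein):
    return hp.PeptideRecord.from_bounds(toy_protein, 1, 4)


def _series(pep, state, times, means, sds=None, n=3):
    times = np.asarray(times, float)
    return hp.UptakeSeries(
        peptide=pep,
        state=state,
        times=times,
        mean_D=np.asarray(means, float),
        sd_D=np.full(times.size, np.nan) if sds is None else np.asarray(sds, float),
        n=np.full(times.size, n),
    )


class TestDifferenceProfile:
    def test_identical_series_all_zero(self, pep):
        a = _series(pep, "Na", [0.25, 1, 10], [1.0, 2.0, 3.0])
        b = _series(pep, "K", [0.25, 1, 10], [1.0, 2.0, 3.0])
        prof = hp.difference_profile(a, b)
        np.testing.assert_allclose(prof.delta_D, 0.0)

    def test_sign_convention_positive_means_decreased_hdx_in_test(self, pep):
        a = _series(pep, "Na", [10], [3.0])
        b = _series(pep, "K", [10], [2.4])
        prof = hp.difference_profile(a, b)
        assert prof.delta_D[0] == pytest.approx(0.6)

    def test_only_shared_times_kept(self, pep):
        a = _series(pep, "Na", [0.25, 1, 10], [1.0, 2.0, 3.0])
        b = _series(pep, "K", [1, 10, 60], [1.5, 2.5, 3.5])
        prof = hp.difference_profile(a, b)
        np.testing.assert_allclose(prof.times, [1, 10])

    def test_no_shared_times_is_error(self, pep):
        a = _series(pep, "Na", [0.25, 1], [1.0, 2.0])
        b = _series(pep, "K", [10, 60], [1.0, 2.0])
        with pytest.raises(hp.ValidationError, match="no shared time points"):
            hp.difference_profile(a, b)


class TestCiThreshold:
    def test_all_zero_sds_give_zero_ci(self):
        assert hp.ci_threshold([0.0, 0.0], [0.0], n=3).ci == 0.0

    def test_critical_value_for_triplicates(self):
        ci = hp.ci_threshold([0.1], [0.1], n=3, confidence=0.95)
        assert ci.t_crit == pytest.approx(4.303, abs=5e-4)

    def test_threshold_from_measured_precision(self):
        # sigma_bar 0.079 D at n = 3 -> 0.34 D band
        ci = hp.ci_threshold([0.0790], [0.0790], n=3)
        assert ci.ci == pytest.approx(0.340, abs=5e-4)

    def test_nan_sds_ignored(self):
        ci = hp.ci_threshold([0.1, np.nan], [np.nan, 0.3], n=3)
        assert ci.sigma_bar == pytest.approx(0.2)

    def test_no_sds_is_informative_error(self):
        with pytest.raises(hp.ValidationError, match="replicates"):
            hp.ci_threshold([np.nan], [np.nan], n=3)

    @settings(max_examples=50, deadline=None)
    @given(
        sds=st.lists(st.floats(0.0, 2.0), min_size=1, max_size=20),
        n=st.integers(2, 6),
        conf=st.floats(0.5, 0.999),
    )
    def test_closed_form_identity(self, sds, n, conf):
        """CI equals t * sigma_bar exactly, and sigma_ave = sqrt(n) * sigma_bar."""
        ci = hp.ci_threshold(sds, [], n=n, confidence=conf)
        assert ci.ci == pytest.approx(ci.t_crit * ci.sigma_bar, rel=1e-12)
        assert ci.sigma_ave == pytest.approx(np.sqrt(n) * ci.sigma_bar, rel=1e-12)


def _profile(pep, times, deltas):
    times = np.asarray(times, float)
    return hp.DifferenceProfile(
        peptide=pep,
        state_ref="Na",
        state_test="K",
        times=times,
        delta_D=np.asarray(deltas, float),
        n_ref=np.full(times.size, 3),
        n_test=np.full(times.size, 3),
    )


class TestHybridRule:
    @pytest.fixture()
    def ci(self):
        return hp.ci_threshold([0.0790], [0.0790], n=3)  # 0.340 D

    def test_all_below_ci_is_none(self, pep, ci):
        call = hp.classify_significance(_profile(pep, [0.25, 1, 10, 60, 480], [0.1] * 5), ci)
        assert call.verdict == "none"
        assert call.rule_fired == "none"

    def test_two_consecutive_points_above_ci(self, pep, ci):
        deltas = [0.1, 0.1, 1.2 * ci.ci, 1.2 * ci.ci, 0.1]
        call = hp.classify_significance(_profile(pep, [0.25, 1, 10, 60, 480], deltas), ci)
        assert call.verdict == "decrease"
        assert call.rule_fired == "consecutive_CI"
        assert call.supporting_times == [10.0, 60.0]

    def test_nonconsecutive_exceedances_do_not_fire(self, pep, ci):
        deltas = [1.2 * ci.ci, 0.1, 1.2 * ci.ci, 0.1, 0.1]
        call = hp.classify_significance(_profile(pep, [0.25, 1, 10, 60, 480], deltas), ci)
        assert call.verdict == "none"

    def test_last_point_double_ci_exemption(self, pep, ci):
        deltas = [0.1, 0.1, 0.1, 0.1, -2.5 * ci.ci]
        call = hp.classify_significance(_profile(pep, [0.25, 1, 10, 60, 480], deltas), ci)
        assert call.verdict == "increase"  # negative delta = increased HDX
        assert call.rule_fired == "last_point_2xCI"
        assert call.supporting_times == [480.0]

    def test_t_test_branch_fires_below_ci(self, pep):
        """Small but hyper-consistent differences trigger the t-test branch
        even when they stay inside a wide CI band."""
        wide_ci = hp.ci_threshold([0.2], [0.2], n=3)  # 0.86 D band
        prof = _profile(pep, [0.25, 10, 60], [0.0, -0.1, -0.1])
        reps = {
            10.0: (np.array([2.00, 2.01, 1.99]), np.array([2.10, 2.11, 2.09])),
            60.0: (np.array([2.50, 2.51, 2.49]), np.array([2.60, 2.61, 2.59])),
        }
        call = hp.classify_significance(prof, wide_ci, replicate_data=reps, alpha=0.01)
        assert call.rule_fired == "t_test"
        assert call.verdict == "increase"

    def test_missing_replicates_disable_t_test_only(self, pep):
        wide_ci = hp.ci_threshold([0.2], [0.2], n=3)
        prof = _profile(pep, [0.25, 10, 60], [0.0, -0.1, -0.1])
        call = hp.classify_significance(prof, wide_ci, replicate_data=None)
        assert call.verdict == "none"

    def test_ci_rule_takes_priority_over_t_test(self, pep, ci):
        prof = _profile(pep, [10, 60], [1.5 * ci.ci, 1.5 * ci.ci])
        reps = {
            10.0: (np.array([2.0, 2.0, 2.0]), np.array([1.5, 1.5, 1.5])),
            60.0: (np.array([2.0, 2.0, 2.0]), np.array([1.5, 1.5, 1.5])),
        }
        call = hp.classify_significance(prof, ci, replicate_data=reps)
        assert call.rule_fired == "consecutive_CI"

    def test_mixed_signs_flagged_direction_unstable(self, pep, ci):
        prof = _profile(pep, [10, 60], [1.2 * ci.ci, -1.5 * ci.ci])
        call = hp.classify_significance(prof, ci)
        assert call.direction_unstable
        assert call.verdict == "increase"  # larger |delta| is negative

    def test_antisymmetry_under_state_swap(self, pep, ci):
        times = [0.25, 1, 10, 60, 480]
        deltas = [0.1, -0.2, 0.5, 0.6, -0.1]
        a = _profile(pep, times, deltas)
        b = hp.DifferenceProfile(
            peptide=pep,
            state_ref="K",
            state_test="Na",
            times=np.asarray(times, float),
            delta_D=-np.asarray(deltas),
            n_ref=a.n_test,
            n_test=a.n_ref,
        )
        ca, cb = hp.classify_significance(a, ci), hp.classify_significance(b, ci)
        flip = {"increase": "decrease", "decrease": "increase", "none": "none"}
        assert cb.verdict == flip[ca.verdict]
        assert cb.rule_fired == ca.rule_fired
        assert cb.max_abs_delta_D == pytest.approx(ca.max_abs_delta_D)


def test_consecutive_run_helper():
    assert _consecutive_run(np.array([False, True, True, False]), 2).tolist() == [1, 2]
    assert _consecutive_run(np.array([True, False, True]), 2) is None


class TestConsolidateResidues:
    def _call(self, pep, verdict):
        rule = "consecutive_CI" if verdict != "none" else "none"
        return hp.SignificanceCall(peptide=pep, verdict=verdict, rule_fired=rule)

    def test_significant_verdict_takes_precedence(self):
        protein = hp.ProteinContext("A" * 40)
        p1 = hp.PeptideRecord.from_bounds(protein, 1, 10)
        p2 = hp.PeptideRecord.from_bounds(protein, 5, 20)
        calls = {p1.key: self._call(p1, "increase"), p2.key: self._call(p2, "none")}
        res = hp.consolidate_residues(calls, {p1.key: p1, p2.key: p2}, protein)
        assert res.labels[0:10] == ["increase"] * 10
        assert res.labels[10:20] == ["none"] * 10
        assert res.labels[20:] == ["no_coverage"] * 20

    def test_conflicting_verdicts_are_mixed(self):
        protein = hp.ProteinContext("A" * 20)
        p1 = hp.PeptideRecord.from_bounds(protein, 1, 10)
        p2 = hp.PeptideRecord.from_bounds(protein, 8, 12)
        calls = {p1.key: self._call(p1, "increase"), p2.key: self._call(p2, "decrease")}
        res = hp.consolidate_residues(calls, {p1.key: p1, p2.key: p2}, protein)
        assert res.labels[7:10] == ["mixed"] * 3
        assert res.labels[0:7] == ["increase"] * 7
        assert res.labels[10:12] == ["decrease"] * 2

    def test_coverage_from_interval_union(self):
        protein = hp.ProteinContext("A" * 40)
        p1 = hp.PeptideRecord.from_bounds(protein, 1, 10)
        p2 = hp.PeptideRecord.from_bounds(protein, 5, 20)
        assert hp.coverage_percent([p1, p2], protein) == pytest.approx(50.0)


class TestEndToEnd:
    def test_designed_shift_recovered_at_all_times(self, study_comparison, study_truth):
        """Peptides in the designed +1.5 D region show dD near -1.5 and are
        called as increased HDX; their profiles recover the designed shift."""
        region = study_truth.designed_regions[0]
        keys = [
            k
            for k in study_comparison.calls
            if not (k[1] < region.start or k[0] > region.end)
        ]
        assert keys, "designed region must cover peptides"
        for k in keys:
            call = study_comparison.calls[k]
            assert call.verdict == "increase"
            prof = study_comparison.profiles[k]
            # the full designed shift is visible while the test state is off
            # its saturation ceiling (guaranteed at the early/mid time points);
            # at late times clipping can only shrink it, never flip its sign
            early = prof.times <= 10.0
            np.testing.assert_allclose(prof.delta_D[early], -region.delta_D, atol=0.3)
            assert np.all(prof.delta_D <= 0.3)

    def test_comparison_antisymmetry_on_study(self, study_data, study_series):
        fwd = hp.compare_states(study_data.measurements, study_series, "Na", "K")
        rev = hp.compare_states(study_data.measurements, study_series, "K", "Na")
        assert rev.ci.ci == pytest.approx(fwd.ci.ci)
        flip = {"increase": "decrease", "decrease": "increase", "none": "none"}
        for key in fwd.calls:
            np.testing.assert_allclose(
                rev.profiles[key].delta_D, -fwd.profiles[key].delta_D, atol=1e-12
            )
            assert rev.calls[key].verdict == flip[fwd.calls[key].verdict]
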