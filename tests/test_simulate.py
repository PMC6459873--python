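"""Forward simulator: kinetics, envelopes, study generation, binding assay."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hdxpipe as hp
from hdxpipe.simulate import (
    AmideKinetics,
    deuteron_distribution,
    default_peptide_intervals,
    ex2_probabilities,
    thin_probabilities,
)


class TestEx2Uptake:
    def test_zero_time_gives_zero(self):
        kin = AmideKinetics.from_protection([10.0, 100.0])
        assert hp.simulate_ex2_uptake(kin, 0.0, 0.85) == 0.0

    def test_saturation_limit(self):
        kin = AmideKinetics.from_protection(np.full(10, 50.0))
        assert hp.simulate_ex2_uptake(kin, 1e9, 0.85) == pytest.approx(8.5)

    def test_half_life_closed_form(self):
        # one amide with k_obs = ln 2 per min at full deuterium: uptake(1) = 1/2
        kin = AmideKinetics(k_int=[np.log(2.0)], pf=[1.0])
        assert hp.simulate_ex2_uptake(kin, 1.0, 1.0) == pytest.approx(0.5)

    def test_negative_time_rejected(self):
        kin = AmideKinetics.from_protection([10.0])
        with pytest.raises(hp.ValidationError):
            hp.simulate_ex2_uptake(kin, -0.1, 0.85)

    @settings(max_examples=40, deadline=None)
    @given(
        log_pf=st.lists(st.floats(0.0, 6.0), min_size=1, max_size=8),
        t1=st.floats(0.0, 500.0),
        t2=st.floats(0.0, 500.0),
    )
    def test_monotone_in_time_and_protection(self, log_pf, t1, t2):
        """Uptake never decreases with time, and protection only slows it."""
        pf = 10.0 ** np.asarray(log_pf)
        kin = AmideKinetics.from_protection(pf)
        lo, hi = sorted([t1, t2])
        assert hp.simulate_ex2_uptake(kin, lo, 0.85) <= hp.simulate_ex2_uptake(kin, hi, 0.85) + 1e-12
        kin_more = AmideKinetics.from_protection(pf * 10.0)
        assert hp.simulate_ex2_uptake(kin_more, hi, 0.85) <= hp.simulate_ex2_uptake(kin, hi, 0.85) + 1e-12


class TestEx1Mixture:
    @pytest.fixture()
    def spec(self):
        k_closed = np.array([0.0] * 6 + [5.0] * 2)
        correlated = np.array([True] * 6 + [False] * 2)
        return hp.Ex1Spec(k_open_per_min=np.log(2.0), k_closed=k_closed, correlated=correlated)

    def test_zero_time_fraction_zero(self, spec):
        f, _, _ = hp.simulate_ex1_mixture(spec, 0.0, 0.85)
        assert f == 0.0

    def test_half_life_fraction_half(self, spec):
        f, _, _ = hp.simulate_ex1_mixture(spec, 1.0, 0.85)  # k_open * t = ln 2
        assert f == pytest.approx(0.5)

    def test_mixture_mean_is_closed_plus_half_separation(self, spec):
        # six correlated amides at d_frac 1 -> separation 6 D; at fraction 1/2
        # the mixture centroid sits exactly 3 D above the closed population
        f, closed, open_ = hp.simulate_ex1_mixture(spec, 1.0, 1.0)
        assert open_.sum() - closed.sum() == pytest.approx(6.0)
        mix = (1 - f) * closed.sum() + f * open_.sum()
        assert mix == pytest.approx(closed.sum() + 3.0)

    def test_open_population_dominates_amide_wise(self, spec):
        _, closed, open_ = hp.simulate_ex1_mixture(spec, 2.5, 0.85)
        assert np.all(open_ >= closed - 1e-12)


class TestDeuteronDistribution:
    def test_matches_exhaustive_enumeration(self, rng):
        """Poisson-binomial via convolution vs brute force over all 2^N outcomes."""
        for n in (1, 3, 6, 10):
            probs = rng.uniform(0.0, 1.0, size=n)
            brute = np.zeros(n + 1)
            for bits in itertools.product((0, 1), repeat=n):
                p = np.prod([probs[i] if b else 1 - probs[i] for i, b in enumerate(bits)])
                brute[sum(bits)] += p
            np.testing.assert_allclose(deuteron_distribution(probs), brute, atol=1e-12)

    def test_invalid_probability_rejected(self):
        with pytest.raises(hp.ValidationError):
            deuteron_distribution([0.5, 1.2])


class TestEnvelopeFromUptake:
    @pytest.fixture()
    def pep(self, toy_protein):
        return hp.PeptideRecord.from_bounds(toy_protein, 1, 8)  # N = 7

    def test_all_zero_probs_single_undeuterated_peak(self, pep):
        env = hp.envelope_from_uptake(pep, np.zeros(7), charge=2)
        from hdxpipe.constants import MASS_PROTON

        assert env.intensity[0] == 1.0
        assert np.all(env.intensity[1:] == 0.0)
        assert env.mz[0] == pytest.approx((pep.m0 + 2 * MASS_PROTON) / 2)

    def test_all_one_probs_shifted_by_n_deuterons(self, toy_protein):
        pep = hp.PeptideRecord.from_bounds(toy_protein, 1, 7)  # N = 6
        env = hp.envelope_from_uptake(pep, np.ones(6), charge=2)
        from hdxpipe.constants import MASS_DH

        peak = int(np.argmax(env.intensity))
        assert peak == 6
        assert env.mz[peak] - env.mz[0] == pytest.approx(6 * MASS_DH / 2)

    def test_binomial_intensities(self, toy_protein):
        pep = hp.PeptideRecord.from_bounds(toy_protein, 1, 4)  # N = 3
        env = hp.envelope_from_uptake(pep, [0.5, 0.5, 0.5], charge=1)
        # pmf (1,3,3,1)/8 normalized to base peak 1 -> (1/3, 1, 1, 1/3), zero padding
        np.testing.assert_allclose(env.intensity, [1 / 3, 1, 1, 1 / 3, 0.0], atol=1e-12)

    def test_mixture_is_weighted_sum_of_populations(self, pep):
        closed = np.full(7, 0.1)
        open_ = np.full(7, 0.8)
        w = 0.3
        env = hp.envelope_from_uptake(pep, closed, charge=2, mixing=(open_, w))
        manual = (1 - w) * deuteron_distribution(closed) + w * deuteron_distribution(open_)
        np.testing.assert_allclose(env.intensity, manual / manual.max(), atol=1e-12)


class TestBackExchange:
    def test_identity_at_zero(self):
        assert hp.apply_back_exchange(3.3, 0.0) == 3.3

    def test_hand_arithmetic(self):
        assert hp.apply_back_exchange(8.5, 0.2) == pytest.approx(6.8)

    def test_full_loss_rejected(self):
        with pytest.raises(hp.ValidationError):
            hp.apply_back_exchange(1.0, 1.0)

    def test_extreme_thinning_collapses_envelope(self, toy_protein):
        pep = hp.PeptideRecord.from_bounds(toy_protein, 1, 8)
        probs = thin_probabilities(np.full(7, 0.9), 1.0 - 1e-9)
        env = hp.envelope_from_uptake(pep, probs, charge=2)
        assert int(np.argmax(env.intensity)) == 0


class TestStudyGeneration:
    def test_default_map_shape_and_coverage(self):
        intervals = default_peptide_intervals()
        assert len(intervals) == 62
        covered = set()
        for a, b in intervals:
            covered.update(range(a, b + 1))
        assert len(covered) == 448
        truth = hp.default_study_truth(seed=0)
        assert len(truth.protein) == 648
        assert (99, 109) in {(p.start, p.end) for p in truth.peptides}

    def test_same_seed_gives_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            truth = hp.default_study_truth(seed=11, include_ex1=True)
            hp.generate_study(truth, out_dir=tmp_path / sub)
        for name in ("uptake.csv", "max_label.csv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
        envs_a = sorted((tmp_path / "a" / "envelopes").iterdir())
        envs_b = sorted((tmp_path / "b" / "envelopes").iterdir())
        assert [p.name for p in envs_a] == [p.name for p in envs_b]
        assert all(x.read_bytes() == y.read_bytes() for x, y in zip(envs_a, envs_b))

    def test_region_must_map_onto_peptides(self):
        truth = hp.default_study_truth(seed=0)
        with pytest.raises(hp.ValidationError, match="maps onto no peptide"):
            hp.StudyTruth(
                protein=truth.protein,
                peptides=truth.peptides,
                pf=truth.pf,
                designed_regions=(hp.DesignedRegion(1, 5, 1.0),),  # uncovered N-terminus
                seed=0,
            )

    def test_generated_means_recover_kinetics(self, study_data, study_truth):
        """Replicated cell means sit within the expected sampling error of the
        noiseless kinetics (parameter-recovery smoke test)."""
        from hdxpipe.simulate import expected_observed_uptake

        d_frac = study_data.design.d_frac
        grouped = study_data.measurements.groupby(
            ["start", "end", "sequence", "state", "exposure_min"]
        )["uptake_D"].agg(["mean", "count"])
        z = []
        for (start, end, seq, state, t), row in grouped.iterrows():
            if row["count"] < 3:
                continue
            pep = study_data.peptide_records()[(start, end, seq)]
            expected = expected_observed_uptake(study_truth, pep, state, t, d_frac)
            se = study_truth.noise_sd / np.sqrt(row["count"])
            z.append(abs(row["mean"] - max(expected, 0.0)) / se)
        z = np.array(z)
        assert (z < 3.0).mean() > 0.98
        assert z.max() < 6.0


class TestBindingAssay:
    def test_half_saturation_noiseless(self):
        table = hp.simulate_binding_assay(
            kd_nM=7.5, bmax=100.0, ns_slope=0.0, conc_grid_nM=(7.5,), n_rep=1, noise_cv=0.0
        )
        assert table["total"].iloc[0] == pytest.approx(50.0)

    def test_no_nonspecific_means_total_equals_specific(self):
        table = hp.simulate_binding_assay(ns_slope=0.0, noise_cv=0.0, n_rep=1)
        np.testing.assert_allclose(table["nonspecific"], 0.0)

    def test_closed_form_fraction_at_top_concentration(self):
        table = hp.simulate_binding_assay(
            kd_nM=7.5, bmax=1.0, ns_slope=0.0, conc_grid_nM=(48.0,), n_rep=1, noise_cv=0.0
        )
        assert table["total"].iloc[0] == pytest.approx(48.0 / 55.5)

    def test_noise_is_unit_mean(self):
        table = hp.simulate_binding_assay(noise_cv=0.05, n_rep=200, seed=4)
        by_conc = table.groupby("concentration_nM")["total"].mean()
        clean = hp.simulate_binding_assay(noise_cv=0.0, n_rep=1)
        clean_by = clean.groupby("concentration_nM")["total"].mean()
        np.testing.assert_allclose(by_conc, clean_by, rtol=0.02)
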