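"""Envelope centroids, bimodal deconvolution, EX1/EX2 calling."""

from __future__ import annotations

import numpy as np
import pytest

import hdxpipe as hp
from hdxpipe.constants import MASS_DH, MASS_PROTON
from hdxpipe.ex1 import BimodalFit
from hdxpipe.simulate import deuteron_distribution


@pytest.fixture()
def pep10(toy_protein):
    return hp.PeptideRecord.from_bounds(toy_protein, 1, 11)  # N = 10


def _env_from_neutral_masses(pep, masses, intensities, charge=2):
    mz = (np.asarray(masses, float) + charge * MASS_PROTON) / charge
    return hp.IsotopeEnvelope(
        mz=mz, intensity=np.asarray(intensities, float), charge=charge, peptide=pep
    )


class TestCentroid:
    def test_single_peak_at_undeuterated_mass(self, pep10):
        masses = pep10.m0 + np.arange(5) * MASS_DH
        _, uptake = hp.envelope_centroid(
            _env_from_neutral_masses(pep10, masses, [1, 0, 0, 0, 0])
        )
        assert uptake == pytest.approx(0.0, abs=1e-9)

    def test_two_equal_peaks_average(self, pep10):
        masses = pep10.m0 + np.array([0.0, 2.0, 4.0, 6.0, 8.0])
        _, uptake = hp.envelope_centroid(
            _env_from_neutral_masses(pep10, masses, [0, 1, 0, 0, 1])
        )
        assert uptake == pytest.approx(5.0)

    def test_binomial_envelope_mean(self, toy_protein):
        pep = hp.PeptideRecord.from_bounds(toy_protein, 1, 4)  # N = 3
        env = hp.envelope_from_uptake(pep, [0.5] * 3, charge=2)
        _, uptake = hp.envelope_centroid(env)
        assert uptake == pytest.approx(1.5 * MASS_DH, abs=1e-9)

    def test_all_zero_intensities_error(self, pep10):
        env = _env_from_neutral_masses(pep10, pep10.m0 + np.arange(5.0), [0] * 5)
        with pytest.raises(hp.ValidationError):
            hp.envelope_centroid(env)


class TestBimodalFit:
    def test_noiseless_unimodal_never_qualifies_as_ex1(self, pep10):
        """A clean single population must not satisfy the joint EX1 criteria.

        The two-population fit may soak up the slight skew of a binomial
        envelope (the populations land almost on top of each other), but the
        conjunction of resolvable separation, balanced fractions and large
        residual improvement used for EX1 detection must not hold."""
        env = hp.envelope_from_uptake(pep10, np.full(10, 0.4), charge=2)
        fit = hp.fit_bimodal(env)
        assert fit.residual <= fit.unimodal_residual + 1e-15
        qualifies = (
            fit.separation_D >= 2.0
            and min(fit.fraction_high, 1 - fit.fraction_high) >= 0.15
            and fit.improvement >= 3.0
        )
        assert not qualifies

    def _gaussian_mixture_envelope(self, pep, c_lo, c_hi, w, width, rng):
        """Model-matched oracle data: a shared-width Gaussian mixture sampled
        on the deuteron stick grid, with 1% intensity noise."""
        from hdxpipe.constants import MASS_PROTON

        d = np.arange(pep.n_amides + 1, dtype=float)
        y = w * np.exp(-0.5 * ((d - c_hi) / width) ** 2) + (1 - w) * np.exp(
            -0.5 * ((d - c_lo) / width) ** 2
        )
        y = y + rng.normal(0.0, 0.01 * y.max(), y.size)
        mz = (pep.m0 + d * MASS_DH + 2 * MASS_PROTON) / 2
        return hp.IsotopeEnvelope(
            mz=mz, intensity=np.clip(y, 0, None), charge=2, peptide=pep
        )

    @pytest.mark.parametrize("w", [0.5, 0.3])
    def test_recovers_gaussian_mixture_parameters(self, pep10, w):
        """Centers 2 D and 8 D at 1% noise: separation within 0.3 D and
        fraction within 0.05 of truth, across seeds."""
        for seed in range(5):
            rng = np.random.default_rng([seed, 55])
            env = self._gaussian_mixture_envelope(pep10, 2.0, 8.0, w, 1.1, rng)
            fit = hp.fit_bimodal(env)
            assert fit.separation_D == pytest.approx(6.0, abs=0.3)
            assert fit.fraction_high == pytest.approx(w, abs=0.05)

    @pytest.mark.parametrize("w", [0.5, 0.3])
    def test_robust_to_binomial_population_shapes(self, pep10, w):
        """Binomial-shaped populations (skewed, unequal widths) are still
        recovered, with a modest shape-mismatch allowance on the separation."""
        for seed in range(5):
            rng = np.random.default_rng([seed, 55])
            env = hp.envelope_from_uptake(
                pep10,
                np.full(10, 0.2),
                charge=2,
                mixing=(np.full(10, 0.8), w),
                noise_sd=0.01,
                rng=rng,
            )
            fit = hp.fit_bimodal(env)
            assert fit.separation_D == pytest.approx(6.0, abs=0.5)
            assert fit.fraction_high == pytest.approx(w, abs=0.05)

    def test_nested_model_inequality_random_envelopes(self, pep10, rng):
        for _ in range(10):
            probs = rng.uniform(0, 1, 10)
            env = hp.envelope_from_uptake(pep10, probs, charge=2, noise_sd=0.02, rng=rng)
            fit = hp.fit_bimodal(env)
            assert fit.residual <= fit.unimodal_residual + 1e-12

    def test_mixture_centroid_matches_envelope_centroid(self, pep10):
        rng = np.random.default_rng(9)
        env = hp.envelope_from_uptake(
            pep10, np.full(10, 0.2), charge=2, mixing=(np.full(10, 0.8), 0.4),
            noise_sd=0.005, rng=rng,
        )
        fit = hp.fit_bimodal(env)
        _, uptake_da = hp.envelope_centroid(env)
        assert fit.mixture_centroid_D * MASS_DH == pytest.approx(uptake_da, abs=0.25)


def _fake_fit(separation, fraction, improvement):
    c_lo = 1.0
    return BimodalFit(
        center_low_D=c_lo,
        center_high_D=c_lo + separation,
        fraction_high=fraction,
        width_D=1.0,
        residual=1.0,
        unimodal_residual=improvement,
    )


class TestCallEx1:
    def test_all_unimodal_is_ex2(self, pep10):
        fits = [(t, _fake_fit(0.2, 0.5, 1.1)) for t in (0.25, 1, 10, 60)]
        assert hp.call_ex1(fits, pep10).verdict == "EX2"

    def test_single_qualifying_time_point_is_ex2(self, pep10):
        fits = [
            (0.25, _fake_fit(0.1, 0.5, 1.0)),
            (10.0, _fake_fit(6.0, 0.5, 20.0)),
            (60.0, _fake_fit(0.1, 0.5, 1.0)),
        ]
        call = hp.call_ex1(fits, pep10)
        assert call.verdict == "EX2"

    def test_two_consecutive_qualifying_points_is_ex1(self, pep10):
        fits = [
            (0.25, _fake_fit(0.1, 0.02, 1.0)),
            (10.0, _fake_fit(6.0, 0.3, 20.0)),
            (60.0, _fake_fit(6.0, 0.8, 20.0)),
            (480.0, _fake_fit(0.5, 0.99, 1.2)),
        ]
        call = hp.call_ex1(fits, pep10)
        assert call.verdict == "EX1"
        assert call.supporting_times == [10.0, 60.0]
        assert call.k_open_per_min is not None and call.k_open_per_min > 0

    def test_needs_two_time_points(self, pep10):
        with pytest.raises(hp.ValidationError):
            hp.call_ex1([(1.0, _fake_fit(6.0, 0.5, 20.0))], pep10)

    def test_generator_ex1_peptide_detected_end_to_end(self, study_data):
        by_state: dict[str, list] = {}
        for env in study_data.envelopes:
            by_state.setdefault(env.state, []).append(env)
        calls = {}
        for state, envs in by_state.items():
            fits = [(e.exposure_min, hp.fit_bimodal(e)) for e in envs]
            calls[state] = hp.call_ex1(fits, envs[0].peptide)
        assert calls["K"].verdict == "EX1"
        assert calls["Na"].verdict == "EX2"
        # observed separation: 7 correlated amides at 85% D less 25% back-exchange
        assert calls["K"].mean_separation_D == pytest.approx(7 * 0.85 * 0.75, abs=0.5)
        assert calls["K"].k_open_per_min == pytest.approx(0.03, rel=0.5)


def test_envelope_validation():
    pep = hp.PeptideRecord(start=1, end=4, sequence="MKTA", n_amides=3, m0=435.0)
    with pytest.raises(hp.ValidationError, match="5 points"):
        hp.IsotopeEnvelope(mz=[1.0, 2.0], intensity=[1.0, 1.0], charge=1, peptide=pep)
    with pytest.raises(hp.ValidationError, match="ascending"):
        hp.IsotopeEnvelope(
            mz=[1, 2, 3, 2.5, 5], intensity=[1] * 5, charge=1, peptide=pep
        )
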