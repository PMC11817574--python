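"""Phantom generators: determinism, noise models, copula coupling, bias."""

import numpy as np
import pytest
from scipy import stats

import petadc as pa
from petadc.phantom import _default_lesion, child_seed


def grids_equal(a, b):
    return np.array_equal(a.values, b.values)


class TestDeterminism:
    def test_same_seed_bit_identical_subject(self, default_spec):
        s1 = pa.generate_subject(default_spec, 0.8, 12.0, seed=42)
        s2 = pa.generate_subject(default_spec, 0.8, 12.0, seed=42)
        for attr in ("true_adc", "true_suv", "dwi_b0", "dwi_b800"):
            assert grids_equal(getattr(s1, attr), getattr(s2, attr))
        for label in s1.pet_by_method:
            assert grids_equal(s1.pet_by_method[label], s2.pet_by_method[label])
        assert s1.dose == s2.dose

    def test_subjects_individually_reproducible(self, default_spec):
        cohort = pa.generate_cohort(
            default_spec, n_subjects=4, n_pz=2, seed=5, methods=["CT_reference"]
        )
        lone = pa.generate_subject(
            default_spec,
            cohort[1].truth["adc_mean"],
            cohort[1].truth["suv_mean"],
            child_seed(5, 101),
            subject_id=cohort[1].subject_id,
            methods=["CT_reference"],
        )
        assert grids_equal(cohort[1].dwi_b0, lone.dwi_b0)
        assert grids_equal(cohort[1].pet_by_method["CT_reference"], lone.pet_by_method["CT_reference"])


class TestNoiselessRecovery:
    def test_adc_and_suv_recovered_exactly(self, noiseless_subject):
        spec, subj = noiseless_subject
        adc = pa.compute_adc(subj.dwi_b0, subj.dwi_b800, spec.b_value_s_mm2)
        lesion = subj.roi.mask
        assert np.allclose(adc.values[lesion], subj.truth["adc_mean"], rtol=1e-10)
        body = subj.dwi_b0.values > 0
        assert np.allclose(adc.values[body & ~lesion], spec.background_adc, rtol=1e-10)
        suv = pa.compute_suv(subj.pet_by_method["CT_reference"], subj.dose)
        assert np.allclose(suv.values[lesion], subj.truth["suv_mean"], rtol=1e-10)

    def test_noiseless_dwi_follows_exponential_decay(self, noiseless_subject):
        spec, subj = noiseless_subject
        lesion = subj.roi.mask
        ratio = subj.dwi_b800.values[lesion] / subj.dwi_b0.values[lesion]
        expected = np.exp(-0.8 * subj.truth["adc_mean"])
        assert np.allclose(ratio, expected, rtol=1e-12)

    def test_smoothed_reference_suv_mean_near_programmed_value(self, noiseless_subject):
        # with 3 mm smoothing restored, SUV_mean in the ROI is pulled toward
        # the background by edge voxels; the documented tolerance is 12%
        spec, _ = noiseless_subject
        import dataclasses

        spec3 = dataclasses.replace(spec, smoothing_fwhm_mm=3.0)
        subj = pa.generate_subject(spec3, 0.8, 16.75, seed=11)
        suv = pa.compute_suv(subj.pet_by_method["CT_reference"], subj.dose)
        fs = pa.histogram_features(pa.extract_values(suv, subj.roi), modality="SUV")
        assert fs.mean == pytest.approx(16.75, rel=0.12)
        assert fs.max <= 16.75 * 1.01


class TestRicianNoise:
    def test_sigma_zero_is_identity_and_seeds_reproduce(self):
        g = pa.VoxelGrid(np.random.default_rng(0).uniform(0, 10, (6, 6, 3)), (1, 1, 1))
        assert grids_equal(pa.add_rician_noise(g, 0.0, 1), g)
        n1 = pa.add_rician_noise(g, 0.5, 7)
        n2 = pa.add_rician_noise(g, 0.5, 7)
        assert grids_equal(n1, n2)
        assert not grids_equal(n1, pa.add_rician_noise(g, 0.5, 8))

    def test_output_nonnegative(self):
        g = pa.VoxelGrid(np.zeros((10, 10, 10)), (1, 1, 1))
        noisy = pa.add_rician_noise(g, 2.0, 3)
        assert np.all(noisy.values >= 0)

    def test_zero_signal_rayleigh_mean(self):
        # at s = 0 the Rician becomes Rayleigh with mean sigma*sqrt(pi/2)
        g = pa.VoxelGrid(np.zeros((40, 40, 40)), (1, 1, 1))
        sigma = 3.0
        noisy = pa.add_rician_noise(g, sigma, 12)
        assert noisy.values.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.01)


class TestCopulaCoupling:
    def test_antimonotone_limit_exact(self):
        adc, suv = pa.draw_lesion_parameters(27, -1.0, (0.6, 1.1), (5.0, 17.0), seed=4)
        # ranks are exactly reversed: the comonotone limit of the copula
        assert np.array_equal(stats.rankdata(adc), 28 - stats.rankdata(suv))
        rho, _ = pa.spearman_rho(adc, suv)
        assert rho == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("target", [0.0, -0.3, -0.5, -0.8])
    def test_mean_sample_spearman_tracks_programmed_rho(self, target):
        rhos = [
            stats.spearmanr(
                *pa.draw_lesion_parameters(27, target, (0.6, 1.1), (5.0, 17.0), seed=1000 + r)
            ).statistic
            for r in range(200)
        ]
        assert np.mean(rhos) == pytest.approx(target, abs=0.03)

    def test_null_spread_matches_large_sample_sd(self):
        rhos = [
            stats.spearmanr(
                *pa.draw_lesion_parameters(27, 0.0, (0.6, 1.1), (5.0, 17.0), seed=5000 + r)
            ).statistic
            for r in range(200)
        ]
        assert np.mean(rhos) == pytest.approx(0.0, abs=0.03)
        assert np.std(rhos) == pytest.approx(1 / np.sqrt(26), rel=0.25)

    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValueError):
            pa.draw_lesion_parameters(2, -0.5, (0.6, 1.1), (5.0, 17.0), seed=0)
        with pytest.raises(ValueError):
            pa.draw_lesion_parameters(10, -1.5, (0.6, 1.1), (5.0, 17.0), seed=0)


class TestBiasEmulator:
    @staticmethod
    def _ref():
        rng = np.random.default_rng(0)
        return pa.VoxelGrid(
            rng.uniform(1000, 5000, (32, 32, 16)),
            (2.604, 2.604, 3.12),
            units="activity_Bq_per_mL",
        )

    def test_amplitude_zero_returns_input_unchanged(self):
        ref = self._ref()
        out = pa.emulate_ac_method(ref, pa.BiasSpec("CT_reference", 0.0), seed=1)
        assert grids_equal(out, ref)

    def test_expected_avg_rae_closed_form(self):
        # f Gaussian with sd = amplitude -> E|f| = amplitude * sqrt(2/pi)
        ref = self._ref()
        amp = 0.08
        out = pa.emulate_ac_method(ref, pa.BiasSpec("MRI_like", amp, 4.0), seed=2)
        expected = amp * np.sqrt(2 / np.pi) * 100
        assert pa.avg_rae(out.values.ravel(), ref.values.ravel()) == pytest.approx(
            expected, rel=0.10
        )

    def test_avg_rae_monotone_in_amplitude(self):
        ref = self._ref()
        raes = [
            pa.avg_rae(
                pa.emulate_ac_method(ref, pa.BiasSpec("MRI_like", a, 4.0), seed=3).values.ravel(),
                ref.values.ravel(),
            )
            for a in (0.0, 0.02, 0.05, 0.1, 0.2)
        ]
        assert raes == sorted(raes)
        assert raes[0] == 0.0

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            pa.BiasSpec("MRI_like", -0.1)
        with pytest.raises(ValueError):
            pa.BiasSpec("CT_reference", 0.5)


class TestGeometryAndValidation:
    def test_cohort_zone_split(self, default_spec):
        cohort = pa.generate_cohort(
            default_spec, n_subjects=5, n_pz=3, seed=2, methods=["CT_reference"]
        )
        zones = [s.roi.zone for s in cohort]
        assert zones == ["PZ", "PZ", "PZ", "TZ", "TZ"]
        assert len({s.subject_id for s in cohort}) == 5

    def test_zone_changes_lesion_placement(self, default_spec):
        pz = _default_lesion(default_spec.prostate_ellipsoid, "PZ")
        tz = _default_lesion(default_spec.prostate_ellipsoid, "TZ")
        assert pz.center_mm != tz.center_mm

    def test_lesion_outside_prostate_rejected(self, default_spec):
        bad = pa.Ellipsoid(
            tuple(c + 40 for c in default_spec.prostate_ellipsoid.center_mm), (9.0, 9.0, 6.5)
        )
        with pytest.raises(ValueError, match="strictly inside"):
            pa.PhantomSpec(lesion_ellipsoid=bad)

    def test_invalid_spec_parameters_rejected(self):
        with pytest.raises(ValueError):
            pa.PhantomSpec(b0_signal=0.0)
        with pytest.raises(ValueError):
            pa.PhantomSpec(lesion_adc_range=(1.1, 0.6))
        with pytest.raises(ValueError):
            pa.PhantomSpec(coupling_rho=-1.5)

    def test_lesion_values_outside_ranges_rejected(self, default_spec):
        with pytest.raises(ValueError, match="outside range"):
            pa.generate_subject(default_spec, 5.0, 12.0, seed=0)
        with pytest.raises(ValueError, match="outside range"):
            pa.generate_subject(default_spec, 0.8, 100.0, seed=0)
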