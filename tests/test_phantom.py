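import dataclasses
import math

import numpy as np
import pytest
from scipy.integrate import quad

from fibropet.ct_quant import fibrosis_fraction
from fibropet.imaging_core import AcquisitionMeta, resample_mask
from fibropet.pet_quant import percent_id_per_gram, window_uptake
from fibropet.phantom import (
    KineticParams,
    PhantomConfig,
    build_thorax_ct,
    default_study_design,
    dynamic_frame_schedule,
    lung_concentration,
    measured_lung_concentration,
    pilot_tac_design,
    render_pet_series,
    simulate_cohort,
    static_frame_schedule,
)


class TestBuildThoraxCT:
    def test_deterministic_for_same_seed(self, tiny_config):
        a = build_thorax_ct(tiny_config, 0.25, seed=9)
        b = build_thorax_ct(tiny_config, 0.25, seed=9)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].membership, b[1].membership)
        assert a[2].true_fibrosis_fraction == b[2].true_fibrosis_fraction

    def test_zero_burden_has_clean_dense_band(self, tiny_config):
        ct, lung, truth = build_thorax_ct(tiny_config, 0.0, seed=3)
        assert truth.true_fibrosis_fraction == 0.0
        assert fibrosis_fraction(ct, lung) < 0.02  # distribution tails only

    def test_achieved_fraction_close_to_target(self, tiny_config):
        _, _, truth = build_thorax_ct(tiny_config, 0.3, seed=5)
        assert abs(truth.true_fibrosis_fraction - 0.3) <= 0.02

    def test_collagen_zero_outside_lesions(self, tiny_config):
        ct, lung, truth = build_thorax_ct(tiny_config, 0.2, seed=6)
        assert truth.collagen_map.min() >= 0.0
        assert truth.collagen_map[~lung.membership].max() == 0.0

    def test_burden_out_of_range_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            build_thorax_ct(tiny_config, 0.9, seed=0)


class TestLungConcentration:
    def test_zero_burden_single_exponential(self, kinetics, meta):
        t = np.linspace(0, 75, 50)
        c = lung_concentration(t, kinetics, 0.0, meta)
        expect = (
            meta.injected_activity_MBq
            * kinetics.perfusion_amplitude
            * np.exp(-kinetics.washout_rate * t)
        )
        assert np.allclose(c, expect)
        assert np.all(np.diff(c) < 0)

    def test_asymptote_with_burden(self, kinetics, meta):
        c_inf = lung_concentration(1e6, kinetics, 1.0, meta)
        expect = meta.injected_activity_MBq * kinetics.binding_amplitude
        assert c_inf == pytest.approx(expect, rel=1e-6)

    def test_default_washout_and_retention_landmarks(self, kinetics, meta):
        # control falls below 10% of its 2-min value by 12 min; a fully
        # fibrotic lung retains more than half
        c0 = lung_concentration(2.0, kinetics, 0.0, meta)
        c1 = lung_concentration(12.0, kinetics, 0.0, meta)
        assert c1 / c0 < 0.10
        b0 = lung_concentration(2.0, kinetics, 1.0, meta)
        b1 = lung_concentration(12.0, kinetics, 1.0, meta)
        assert b1 / b0 > 0.50

    def test_negative_time_rejected(self, kinetics, meta):
        with pytest.raises(ValueError):
            lung_concentration(-1.0, kinetics, 0.0, meta)

    def test_measured_never_exceeds_decay_free(self, kinetics, meta):
        t = np.linspace(0.0, 75.0, 30)
        free = lung_concentration(t, kinetics, 0.5, meta)
        meas = measured_lung_concentration(t, kinetics, 0.5, meta)
        assert np.all(meas <= free)
        ratio = meas / free
        assert np.allclose(ratio, 2.0 ** (-t / meta.half_life_min))

    def test_blocking_scales_specific_term(self, kinetics, meta):
        blocked = dataclasses.replace(kinetics, blocking_factor=0.1)
        t = 60.0
        full = lung_concentration(t, kinetics, 1.0, meta)
        blk = lung_concentration(t, blocked, 1.0, meta)
        ns = lung_concentration(t, kinetics, 0.0, meta)
        assert (blk - ns) == pytest.approx(0.1 * (full - ns), rel=1e-12)


class TestRenderPetSeries:
    def test_noise_free_lung_matches_quadrature_frame_average(
        self, tiny_config_noisefree, kinetics, meta
    ):
        # independent oracle: numerically integrate the decayed two-term
        # kinetic curve over the frame
        ct, lung, truth = build_thorax_ct(tiny_config_noisefree, 0.0, seed=7)
        u = 0.6
        truth.collagen_map = np.where(lung.membership, u, 0.0)
        frames = render_pet_series(
            truth, lung, kinetics, meta, [(15.0, 10.0)],
            tiny_config_noisefree, noise="none",
        )
        k, lam = kinetics, math.log(2) / meta.half_life_min

        def decayed(t):
            c = meta.injected_activity_MBq * (
                k.perfusion_amplitude * math.exp(-k.washout_rate * t)
                + k.binding_amplitude * u * (1 - math.exp(-k.binding_rate * t))
            )
            return c * math.exp(-lam * t)

        expect, _ = quad(decayed, 15.0, 25.0)
        expect /= 10.0
        from scipy.ndimage import binary_erosion

        lung_pet = resample_mask(lung, ct, frames[0])
        core = binary_erosion(lung_pet.membership, iterations=2)
        assert core.any()
        interior = frames[0].values[core]
        assert np.allclose(interior, expect, rtol=1e-9)

    def test_poisson_high_counts_close_to_truth(
        self, tiny_config_noisefree, kinetics, meta
    ):
        cfg = dataclasses.replace(
            tiny_config_noisefree, sensitivity_cps_per_Bq=5.0
        )
        ct, lung, truth = build_thorax_ct(cfg, 0.3, seed=8)
        clean = render_pet_series(
            truth, lung, kinetics, meta, [(15.0, 10.0)], cfg, noise="none"
        )[0]
        noisy = render_pet_series(
            truth, lung, kinetics, meta, [(15.0, 10.0)], cfg,
            noise="poisson", seed=1,
        )[0]
        lung_pet = resample_mask(lung, ct, clean)
        m_clean = clean.values[lung_pet.membership].mean()
        m_noisy = noisy.values[lung_pet.membership].mean()
        assert abs(m_noisy - m_clean) / m_clean < 0.01

    def test_overlapping_frames_rejected(
        self, tiny_config_noisefree, kinetics, meta
    ):
        _, lung, truth = build_thorax_ct(tiny_config_noisefree, 0.1, seed=1)
        with pytest.raises(ValueError, match="overlap"):
            render_pet_series(
                truth, lung, kinetics, meta, [(2.0, 5.0), (4.0, 5.0)],
                tiny_config_noisefree, noise="none",
            )

    def test_window_uptake_monotone_in_burden(
        self, tiny_config_noisefree, kinetics, meta
    ):
        vals = []
        for b in (0.0, 0.2, 0.4):
            ct, lung, truth = build_thorax_ct(tiny_config_noisefree, b, seed=12)
            frames = render_pet_series(
                truth, lung, kinetics, meta, static_frame_schedule(),
                tiny_config_noisefree, noise="none",
            )
            lung_pet = resample_mask(lung, ct, frames[0])
            vals.append(
                window_uptake(frames, lung_pet, meta).whole_lung_pct_id_g
            )
        assert vals[0] < vals[1] < vals[2]


@pytest.fixture(scope="module")
def small_cohort(tiny_config):
    design = default_study_design(
        n_per_group=3,
        groups=("NaCl", "BLM", "BLM+nintedanib", "BLM+blocking"),
    )
    return design, simulate_cohort(design, config=tiny_config, seed=77)


class TestSimulateCohort:
    def _median_uptake(self, records, tiny_config, group, day):
        vals = []
        for rec in records:
            if rec.group != group:
                continue
            tp = rec.timepoints[day]
            lung_pet = resample_mask(tp.lung, tp.ct, tp.frames[0])
            vals.append(
                window_uptake(tp.frames, lung_pet, tp.meta).whole_lung_pct_id_g
            )
        return float(np.median(vals))

    def test_controls_stay_clear(self, small_cohort, tiny_config):
        _, records = small_cohort
        for rec in records:
            if rec.group == "NaCl":
                for tp in rec.timepoints.values():
                    assert tp.ground_truth.true_fibrosis_fraction == 0.0

    def test_blm_uptake_increases_over_time(self, small_cohort, tiny_config):
        _, records = small_cohort
        u = [
            self._median_uptake(records, tiny_config, "BLM", d)
            for d in (8, 15, 22)
        ]
        assert u[0] < u[1] < u[2]

    def test_treatment_lowers_late_uptake(self, small_cohort, tiny_config):
        design, records = small_cohort
        assert design.trajectory("BLM")[8] == design.trajectory("BLM+nintedanib")[8]
        for day in (15, 22):
            blm = self._median_uptake(records, tiny_config, "BLM", day)
            nin = self._median_uptake(records, tiny_config, "BLM+nintedanib", day)
            assert nin < blm

    def test_blocking_suppresses_uptake(self, small_cohort, tiny_config):
        _, records = small_cohort
        blm = self._median_uptake(records, tiny_config, "BLM", 22)
        blk = self._median_uptake(records, tiny_config, "BLM+blocking", 22)
        assert blk < 0.5 * blm

    def test_determinism(self, tiny_config):
        design = pilot_tac_design(n_control=1, n_blm=1)
        a = simulate_cohort(design, config=tiny_config, seed=5)
        b = simulate_cohort(design, config=tiny_config, seed=5)
        for ra, rb in zip(a, b):
            tpa, tpb = ra.timepoints[21], rb.timepoints[21]
            assert np.array_equal(tpa.ct.values, tpb.ct.values)
            for fa, fb in zip(tpa.frames, tpb.frames):
                assert np.array_equal(fa.values, fb.values)
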