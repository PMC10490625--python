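"""Spectral features: Parseval, band integration, relative power, pdBSI, ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegharx import (
    SimulationConfig,
    build_feature_table,
    generate_recording,
    pdbsi,
    relative_power,
    spectral_ratios,
    welch_psd,
)
from eegharx.features import (
    BandPowerSet,
    DEFAULT_BANDS,
    band_powers,
    feature_columns,
    integrate_band,
)
from eegharx.preprocess import EpochSet, segment_epochs
from eegharx.simulate import ACTIVITIES, BANDS, artifact_free

FS = 250.0


class TestWelch:
    def test_parseval_for_sinusoid(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t)
        spec = welch_psd(x, FS)
        total = integrate_band(spec.frequencies, spec.psd[0], 0.0, FS / 2)
        assert total == pytest.approx(0.5, rel=0.05)
        alpha = integrate_band(spec.frequencies, spec.psd[0], 8.0, 13.0)
        assert alpha >= 0.95 * total

    def test_zero_signal_zero_psd(self):
        spec = welch_psd(np.zeros(2500), FS)
        np.testing.assert_array_equal(spec.psd, 0.0)

    def test_white_noise_integrates_to_variance(self, rng):
        totals = []
        for _ in range(30):
            x = rng.standard_normal(2500) * 3.0
            spec = welch_psd(x, FS)
            totals.append(integrate_band(spec.frequencies, spec.psd[0], 0.0, FS / 2))
        assert np.mean(totals) == pytest.approx(9.0, rel=0.1)

    def test_segment_longer_than_epoch_raises(self):
        from eegharx.features import WelchParams

        with pytest.raises(ValueError, match="segment"):
            welch_psd(np.zeros(100), FS, WelchParams(segment_length_s=2.0))


class TestBandPowers:
    def _flat_spectrum(self, value=1.0):
        from eegharx.features import SpectrumEstimate

        f = np.arange(0.0, FS / 2 + 0.25, 0.5)
        psd = np.full((1, len(f)), value)
        return SpectrumEstimate(f, psd, ["Fz"])

    def test_flat_spectrum_band_powers_proportional_to_width(self):
        bp = band_powers(self._flat_spectrum(1.0))
        expected = {"delta": 3.5, "theta": 4.0, "alpha": 5.0, "beta": 17.0, "gamma": 14.0}
        for band, val in expected.items():
            assert bp.power[("Fz", band)] == pytest.approx(val)

    def test_zero_psd_zero_powers(self):
        bp = band_powers(self._flat_spectrum(0.0))
        assert all(v == 0 for v in bp.power.values())

    def test_band_outside_grid_raises(self):
        from eegharx.features import BandDefinition, SpectrumEstimate

        f = np.arange(0.0, 20.0, 0.5)
        spec = SpectrumEstimate(f, np.ones((1, len(f))), ["Fz"])
        with pytest.raises(ValueError, match="outside"):
            band_powers(spec, [BandDefinition("gamma", 30.0, 44.0)])

    def test_region_averaging(self):
        from eegharx.features import SpectrumEstimate

        f = np.arange(0.0, FS / 2 + 0.25, 0.5)
        psd = np.vstack([np.full(len(f), v) for v in (1.0, 2.0, 4.0)])
        spec = SpectrumEstimate(f, psd, ["Fz", "C1", "C2"])
        bp = band_powers(spec)
        assert bp.region_power[("C", "alpha")] == pytest.approx(
            (bp.power[("C1", "alpha")] + bp.power[("C2", "alpha")]) / 2
        )


class TestRelativePower:
    def _bp(self, powers):
        return BandPowerSet(power={}, region_power={("F", b): p for b, p in powers.items()})

    def test_hand_example(self):
        rp = relative_power(self._bp({"delta": 2, "theta": 1, "alpha": 4, "beta": 2, "gamma": 1}))
        assert rp[("F", "alpha")] == pytest.approx(0.4)
        assert sum(rp[("F", b)] for b in BANDS) == pytest.approx(1.0)

    def test_equal_powers_symmetric(self):
        rp = relative_power(self._bp({b: 3.0 for b in BANDS}))
        assert all(rp[("F", b)] == pytest.approx(0.2) for b in BANDS)

    def test_single_band_boundary(self):
        rp = relative_power(self._bp({"delta": 0, "theta": 0, "alpha": 5, "beta": 0, "gamma": 0}))
        assert rp[("F", "alpha")] == 1.0
        assert rp[("F", "delta")] == 0.0

    def test_zero_region_flagged_nan(self):
        rp = relative_power(self._bp({b: 0.0 for b in BANDS}))
        assert all(np.isnan(rp[("F", b)]) for b in BANDS)


class TestPdbsi:
    def test_identical_spectra_give_zero(self):
        r = np.linspace(1.0, 5.0, 10)
        assert pdbsi(r, r) == 0.0

    def test_one_sided_zero_gives_one(self):
        r = np.linspace(1.0, 5.0, 10)
        assert pdbsi(r, np.zeros(10)) == 1.0

    def test_single_bin_hand_value(self):
        assert pdbsi(np.array([3.0]), np.array([1.0])) == pytest.approx(0.5)

    def test_zero_sum_bins_skipped(self):
        r = np.array([3.0, 0.0])
        l = np.array([1.0, 0.0])
        assert pdbsi(r, l) == pytest.approx(0.5)
        assert np.isnan(pdbsi(np.zeros(3), np.zeros(3)))

    @settings(deadline=None, max_examples=30)
    @given(st.floats(min_value=1.0, max_value=100.0))
    def test_scaling_one_side_never_decreases_pdbsi(self, lam):
        rng = np.random.default_rng(12)
        r = rng.uniform(0.5, 2.0, size=16)
        l = rng.uniform(0.5, 2.0, size=16)
        base = pdbsi(np.maximum(r, l), np.minimum(r, l))
        scaled = pdbsi(np.maximum(r, l) * lam, np.minimum(r, l))
        assert scaled >= base - 1e-12

    def test_four_bin_toy_matches_brute_force(self):
        r = np.array([2.0, 1.0, 4.0, 0.5])
        l = np.array([1.0, 1.0, 2.0, 1.5])
        expected = np.mean(np.abs(r - l) / (r + l))
        assert pdbsi(r, l) == pytest.approx(expected, abs=1e-12)


class TestRatios:
    def _bp(self, **powers):
        return BandPowerSet(power={}, region_power={("F", b): p for b, p in powers.items()})

    def test_hand_values(self):
        bp = self._bp(delta=4.0, theta=2.0, alpha=2.0, beta=2.0, gamma=1.0)
        dar, dtr, dtabr = spectral_ratios(bp, "F")
        assert dar == pytest.approx(2.0)
        assert dtr == pytest.approx(2.0)
        assert dtabr == pytest.approx(1.5)

    def test_dtr_and_dtabr_definitions(self):
        bp = self._bp(delta=2.0, theta=4.0, alpha=2.0, beta=2.0, gamma=0.0)
        _, dtr, _ = spectral_ratios(bp, "F")
        assert dtr == pytest.approx(0.5)
        bp = self._bp(delta=3.0, theta=1.0, alpha=2.0, beta=2.0, gamma=0.0)
        _, _, dtabr = spectral_ratios(bp, "F")
        assert dtabr == pytest.approx(1.0)

    def test_zero_denominator_flagged_missing(self):
        bp = self._bp(delta=1.0, theta=0.0, alpha=0.0, beta=0.0, gamma=0.0)
        dar, dtr, dtabr = spectral_ratios(bp, "F")
        assert np.isnan(dar) and np.isnan(dtr) and np.isnan(dtabr)


class TestFeatureTable:
    def test_rp_round_trip_recovers_targets(self, clean_recovery_recording, clean_feature_table):
        cfg, _ = clean_recovery_recording
        profs = {p.activity: p for p in cfg.profiles}
        tab = clean_feature_table
        for act, group in tab.groupby("label"):
            for region in "FCTO":
                for band in BANDS:
                    est = group[f"RP_{band.capitalize()}_{region}"].mean()
                    assert est == pytest.approx(
                        profs[act].target_rp[region][band], abs=0.05
                    ), (act, region, band)

    def test_symmetric_recording_has_small_pdbsi(self, clean_feature_table):
        for col in ("pdBSI_C", "pdBSI_T", "pdBSI_Alpha_C", "pdBSI_Beta_T"):
            assert clean_feature_table[col].mean() <= 0.15

    def test_rp_rows_sum_to_one_exactly(self, clean_feature_table):
        for region in ("F", "C", "T", "O", "G"):
            cols = [f"RP_{b.capitalize()}_{region}" for b in BANDS]
            np.testing.assert_allclose(
                clean_feature_table[cols].sum(axis=1), 1.0, atol=1e-9
            )

    def test_pdbsi_columns_bounded(self, clean_feature_table):
        pd_cols = [c for c in clean_feature_table.columns if c.startswith("pdBSI")]
        vals = clean_feature_table[pd_cols].to_numpy()
        assert (vals >= 0).all() and (vals <= 1).all()

    def test_column_order_fixed_and_complete(self, clean_feature_table):
        cols = feature_columns()
        assert len(cols) == 49
        assert list(clean_feature_table.columns) == cols + ["label"]

    def test_empty_epochs_give_empty_table(self):
        eps = EpochSet(
            epochs=np.empty((0, 6, 2500)), labels=[], starts_s=[],
            channel_labels=list("abcdef"), sampling_rate_hz=FS, epoch_length_s=10.0,
        )
        tab = build_feature_table(eps)
        assert tab.empty

    def test_asymmetric_generator_raises_pdbsi(self):
        from eegharx.simulate import ActivityProfile, default_profiles

        base = [p for p in default_profiles() if p.activity == "resting"][0]
        profs = [ActivityProfile("resting", base.target_rp, asymmetry=2.0)]
        cfg = artifact_free(SimulationConfig(
            profiles=profs, epochs_per_activity={"resting": 10}, seed=9,
        ))
        rec = generate_recording(cfg)
        tab = build_feature_table(segment_epochs(rec))
        assert tab["pdBSI_C"].mean() > 0.2
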