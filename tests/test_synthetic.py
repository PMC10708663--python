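import numpy as np
import pytest

from hsicalib.baseline_models import PLSRModel
from hsicalib.evaluation import EvaluationPair, r_squared
from hsicalib.hsi_core import calibrate_reflectance, to_absorbance
from hsicalib.segmentation import build_mask
from hsicalib.synthetic import (
    SyntheticConfig,
    generate_dataset,
    make_endmembers,
    render_cube,
    sample_concentrations,
)


class TestConcentrations:
    def test_all_values_within_configured_bounds(self):
        cfg = SyntheticConfig(seed=2)
        table = sample_concentrations(cfg, n_samples=500)
        for name, (lo, hi, _) in cfg.concentration_bounds.items():
            assert table[name].min() >= lo
            assert table[name].max() <= hi

    def test_moisture_within_panel_bounds(self):
        table = sample_concentrations(SyntheticConfig(seed=3), n_samples=300)
        assert table["moisture"].between(0.057, 0.085).all()

    def test_embedded_correlation_recovered(self):
        cfg = SyntheticConfig(seed=4)
        table = sample_concentrations(cfg, n_samples=2000)
        i, j = cfg.correlated_pair
        r = np.corrcoef(table.iloc[:, i], table.iloc[:, j])[0, 1]
        assert abs(r - cfg.cross_correlation) <= 0.05

    def test_same_seed_same_table(self):
        cfg = SyntheticConfig(seed=9)
        a = sample_concentrations(cfg, n_samples=50)
        b = sample_concentrations(cfg, n_samples=50)
        assert a.equals(b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_samples=2)
        with pytest.raises(ValueError):
            SyntheticConfig(cross_correlation=1.0)
        with pytest.raises(ValueError):
            SyntheticConfig(concentration_bounds={"a": (1.0, 0.5, 0.7)})


class TestEndmembers:
    def test_non_negative_and_seeded(self):
        cfg = SyntheticConfig(seed=5)
        ems = make_endmembers(cfg)
        assert len(ems) == 5
        for e in ems:
            assert np.all(e.absorptivity >= 0)
            assert e.absorptivity.max() > 0
        again = make_endmembers(cfg)
        for a, b in zip(ems, again):
            np.testing.assert_array_equal(a.absorptivity, b.absorptivity)


class TestRenderCube:
    def test_forward_inverse_round_trip_noiseless(self):
        cfg = SyntheticConfig(seed=6, noise_sd=0.0, spatial_field_sd=0.0)
        ems = make_endmembers(cfg)
        conc = np.array([v[2] for v in cfg.concentration_bounds.values()])
        raw, refs, truth = render_cube(conc, ems, cfg)
        refl = calibrate_reflectance(raw, refs)
        eps = np.stack([e.absorptivity for e in ems])
        expected_R = 10.0 ** (-(conc @ eps + cfg.baseline_absorbance))
        tissue = truth > 0
        np.testing.assert_allclose(
            refl.data[tissue],
            np.broadcast_to(expected_R, (int(tissue.sum()), len(expected_R))),
            atol=1e-6,
        )
        absorb = to_absorbance(refl)
        expected_A = conc @ eps + cfg.baseline_absorbance
        np.testing.assert_allclose(
            absorb.data[tissue],
            np.broadcast_to(expected_A, (int(tissue.sum()), len(expected_A))),
            atol=1e-5,
        )

    def test_truth_mask_has_thirty_segments(self):
        cfg = SyntheticConfig(seed=6, noise_sd=0.0)
        _, _, truth = render_cube(
            np.full(5, 0.05), make_endmembers(cfg), cfg
        )
        assert truth.max() == 30
        assert len(np.unique(truth)) == 31

    def test_doubling_concentration_darkens_peak_band(self):
        cfg = SyntheticConfig(seed=6, noise_sd=0.0, spatial_field_sd=0.0)
        ems = make_endmembers(cfg)
        peak = int(np.argmax(ems[0].absorptivity))
        base = np.array([v[2] for v in cfg.concentration_bounds.values()])
        doubled = base.copy()
        doubled[0] *= 2
        raw1, refs, truth = render_cube(base, ems, cfg)
        raw2, _, _ = render_cube(doubled, ems, cfg)
        r1 = calibrate_reflectance(raw1, refs).data[truth > 0][:, peak]
        r2 = calibrate_reflectance(raw2, refs).data[truth > 0][:, peak]
        assert np.all(r2 < r1)

    def test_negative_concentration_rejected(self):
        cfg = SyntheticConfig(seed=6)
        with pytest.raises(ValueError):
            render_cube(np.array([-1, 0, 0, 0, 0.0]), make_endmembers(cfg), cfg)


class TestGenerateDataset:
    def test_record_count_and_band_count(self, full_dataset):
        cfg, records, _ = full_dataset
        assert len(records) == 187
        assert records[0].mean_spectrum.shape == (128,)
        assert records[0].patch.shape == (8, 8, 128)

    def test_mask_agrees_with_truth_at_zero_noise(self):
        cfg = SyntheticConfig(seed=8, noise_sd=0.0, spatial_field_sd=0.0)
        ems = make_endmembers(cfg)
        conc = np.array([v[2] for v in cfg.concentration_bounds.values()])
        raw, refs, truth = render_cube(conc, ems, cfg)
        refl = calibrate_reflectance(raw, refs)
        mask = build_mask(refl)
        agreement = np.mean((mask.labels > 0) == (truth > 0))
        assert agreement >= 0.99

    def test_plsr_parameter_recovery_on_noiseless_spectra(self):
        """The forward model is linear in absorbance, so PLSR must be exact."""
        cfg = SyntheticConfig(n_samples=60, seed=10, noise_sd=0.0,
                              spatial_field_sd=0.0)
        records, _ = generate_dataset(cfg, with_patches=False)
        X = np.stack([r.mean_spectrum for r in records])
        A = np.log10(1.0 / np.maximum(X, 1e-4))
        Y = np.stack([r.concentrations for r in records])
        model = PLSRModel(6).fit(A, Y)
        pred = model.predict(A)
        for k in range(5):
            assert r_squared(EvaluationPair(Y[:, k], pred[:, k])) >= 0.999

    def test_spectrum_monotone_in_dominant_analyte_at_zero_noise(self):
        from scipy.stats import spearmanr

        cfg = SyntheticConfig(n_samples=40, seed=12, noise_sd=0.0,
                              spatial_field_sd=0.0)
        records, truth = generate_dataset(cfg, with_patches=False)
        X = np.stack([r.mean_spectrum for r in records])
        Y = np.stack([r.concentrations for r in records])
        eps = np.stack([e.absorptivity for e in truth.endmembers])
        # most identifiable analyte: largest absorptivity-x-spread contribution
        contrib = Y.std(axis=0) * eps.max(axis=1)
        k = int(np.argmax(contrib))
        band = int(np.argmax(eps[k]))
        rho = spearmanr(Y[:, k], X[:, band]).statistic
        assert abs(rho) >= 0.9

    def test_same_seed_bit_identical_files(self, tmp_path):
        cfg = SyntheticConfig(n_samples=5, seed=13)
        generate_dataset(cfg, out_dir=str(tmp_path / "a"))
        generate_dataset(cfg, out_dir=str(tmp_path / "b"))
        import h5py

        with h5py.File(tmp_path / "a" / "sample_0003.h5") as fa, \
                h5py.File(tmp_path / "b" / "sample_0003.h5") as fb:
            np.testing.assert_array_equal(fa["cube"][...], fb["cube"][...])

    def test_reference_csv_written(self, tmp_path):
        cfg = SyntheticConfig(n_samples=5, seed=13)
        generate_dataset(cfg, out_dir=str(tmp_path / "d"), with_patches=False)
        import pandas as pd

        table = pd.read_csv(tmp_path / "d" / "reference_concentrations.csv",
                            index_col=0)
        assert table.shape == (5, 5)
        assert (tmp_path / "d" / "ground_truth.json").exists()
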