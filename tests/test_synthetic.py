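"""Synthetic data generator: pure spectra, trajectories, spectra, cubes."""

import numpy as np
import pytest

from teaspec import SpectralAxis
from teaspec.cube_io import correct_reflectance, extract_roi_mean
from teaspec.synthetic import (NoiseModel, SamplingSchedule, default_library,
                               default_schedules, default_trajectory_params,
                               make_pure_spectra, simulate_dataset,
                               simulate_trajectories, synthesize_cube,
                               synthesize_spectra)


class TestPureSpectra:
    def test_single_peak_maximal_at_center(self, axis20):
        lib = make_pure_spectra(axis20, {"tps": [(700, 30, 1.0)],
                                         "faa": [(500, 30, 1.0)],
                                         "caf": [(900, 30, 1.0)]})
        profile = lib.analytes["tps"]
        assert np.argmax(profile) == axis20.nearest_index(700)

    def test_zero_height_gives_zero_profile(self, axis20):
        lib = make_pure_spectra(axis20, {"tps": [(700, 30, 0.0)],
                                         "faa": [(500, 30, 1.0)],
                                         "caf": [(900, 30, 1.0)]})
        assert np.allclose(lib.analytes["tps"], 0.0)

    def test_two_peaks_superpose(self, axis20):
        one = make_pure_spectra(axis20, {"tps": [(500, 30, 1.0)],
                                         "faa": [(600, 30, 1.0)],
                                         "caf": [(900, 30, 1.0)]})
        two = make_pure_spectra(axis20, {"tps": [(500, 30, 1.0), (800, 40, 0.5)],
                                         "faa": [(600, 30, 1.0)],
                                         "caf": [(900, 30, 1.0)]})
        single = make_pure_spectra(axis20, {"tps": [(800, 40, 0.5)],
                                            "faa": [(600, 30, 1.0)],
                                            "caf": [(900, 30, 1.0)]})
        assert np.allclose(two.analytes["tps"],
                           one.analytes["tps"] + single.analytes["tps"])

    def test_analyte_without_peaks_rejected(self, axis20):
        with pytest.raises(ValueError, match="invisible|without peak"):
            make_pure_spectra(axis20, {"tps": [], "faa": [(500, 30, 1.0)],
                                       "caf": [(900, 30, 1.0)]})

    def test_out_of_range_center_rejected(self, axis20):
        with pytest.raises(ValueError, match="outside axis"):
            make_pure_spectra(axis20, {"tps": [(2000, 30, 1.0)],
                                       "faa": [(500, 30, 1.0)],
                                       "caf": [(900, 30, 1.0)]})

    def test_default_library_well_conditioned(self):
        lib = default_library()
        assert lib.condition_number() < 1e3
        assert set(lib.analytes) == {"tps", "faa", "caf"}
        assert len(lib.interferents) >= 1


class TestSchedules:
    def test_study_layout(self):
        w, f = default_schedules()
        assert w.n_samples == 76 and f.n_samples == 40
        assert w.n_samples + f.n_samples == 116
        assert len(w.time_points_h) == 19
        assert np.allclose(np.diff(w.time_points_h), 1.0)
        assert len(f.time_points_h) == 10
        assert np.allclose(np.diff(f.time_points_h), 0.5)


class TestTrajectories:
    def test_noise_free_means_follow_processing_kinetics(self):
        params = default_trajectory_params()
        t_w = np.arange(1.0, 20.0)
        tps = params.mean("withering", "tps", t_w)
        faa = params.mean("withering", "faa", t_w)
        caf = params.mean("withering", "caf", t_w)
        assert np.all(np.diff(tps) <= 0)            # nonincreasing
        assert np.allclose(tps[15:], tps[15])       # flat after 16 h
        assert tps[15] < tps[0]
        assert np.all(np.diff(faa) >= 0)
        assert faa.argmax() == 15                   # maximum reached at 16 h
        assert np.allclose(faa[15:], faa[15])
        assert np.ptp(caf) == 0.0
        t_f = 0.5 * np.arange(1, 11)
        tps_f = params.mean("fermentation", "tps", t_f)
        assert np.all(np.diff(tps_f) <= 0)
        assert np.allclose(tps_f[t_f >= 3.0], tps_f[-1])  # lowest at 3 h
        assert np.ptp(params.mean("fermentation", "faa", t_f)) == 0.0
        assert np.ptp(params.mean("fermentation", "caf", t_f)) == 0.0

    def test_envelopes_respected(self):
        params = default_trajectory_params()
        for seed in (0, 1, 2):
            for sch in default_schedules():
                chem = simulate_trajectories(sch, params, seed=seed)
                for a, (lo, hi) in params.envelopes.items():
                    vals = chem.data[a].to_numpy()
                    assert vals.min() >= lo - 1e-12
                    assert vals.max() <= hi + 1e-12

    def test_deterministic_under_seed(self):
        sch = SamplingSchedule.withering()
        a = simulate_trajectories(sch, seed=7)
        b = simulate_trajectories(sch, seed=7)
        assert a.data.equals(b.data)


class TestSynthesizeSpectra:
    def test_single_component_beer_lambert(self, axis20):
        lib = make_pure_spectra(axis20, {"tps": [(700, 50, 0.1)]},
                                analytes=("tps",))
        import pandas as pd
        from teaspec import ChemistryTable
        chem = ChemistryTable(pd.DataFrame({
            "sample_id": ["a", "b"], "stage": "withering",
            "time_h": [1.0, 2.0], "replicate": 1, "tps": [1.0, 3.0]}))
        sm = synthesize_spectra(chem, lib, NoiseModel.none(), seed=0)
        A = -np.log(sm.values)
        assert np.allclose(A[1], 3 * A[0], atol=1e-9)
        assert np.allclose(A[0], 1.0 * lib.analytes["tps"], atol=1e-9)

    def test_zero_noise_ols_recovers_concentrations(self, rng):
        axis = SpectralAxis.default(60)
        lib = make_pure_spectra(axis, {
            "tps": [(540, 45, 0.05)], "faa": [(760, 55, 0.08)],
            "caf": [(610, 50, 0.07)]})
        import pandas as pd
        from teaspec import ChemistryTable
        n = 12
        conc = rng.uniform(1, 10, (n, 3))
        chem = ChemistryTable(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)], "stage": "withering",
            "time_h": 1.0, "replicate": 1,
            "tps": conc[:, 0], "faa": conc[:, 1], "caf": conc[:, 2]}))
        sm = synthesize_spectra(chem, lib, NoiseModel.none(), seed=0)
        A = -np.log(sm.values)
        S = np.vstack([lib.analytes[a] for a in ("tps", "faa", "caf")])
        rec = np.linalg.lstsq(S.T, A.T, rcond=None)[0].T
        assert np.max(np.abs(rec - conc) / conc) < 1e-8

    def test_superposition_in_absorbance_space(self, rng):
        """Zero-noise synthesis is linear: A(c1 + c2) = A(c1) + A(c2)."""
        axis = SpectralAxis.default(40)
        lib = make_pure_spectra(axis, {
            "tps": [(540, 45, 0.05)], "faa": [(760, 55, 0.08)],
            "caf": [(610, 50, 0.07)]})
        import pandas as pd
        from teaspec import ChemistryTable

        def spectra_for(conc):
            chem = ChemistryTable(pd.DataFrame({
                "sample_id": ["s0"], "stage": "withering", "time_h": 1.0,
                "replicate": 1, "tps": [conc[0]], "faa": [conc[1]],
                "caf": [conc[2]]}))
            return -np.log(synthesize_spectra(chem, lib, NoiseModel.none(),
                                              seed=0).values[0])

        c1, c2 = rng.uniform(0.5, 3, 3), rng.uniform(0.5, 3, 3)
        assert np.allclose(spectra_for(c1 + c2),
                           spectra_for(c1) + spectra_for(c2), atol=1e-9)

    def test_same_seed_bit_identical(self):
        chem, s1 = simulate_dataset(seed=11)
        _, s2 = simulate_dataset(seed=11)
        assert np.array_equal(s1.values, s2.values)
        _, s3 = simulate_dataset(seed=12)
        assert not np.array_equal(s1.values, s3.values)

    def test_default_dataset_dimensions(self):
        chem, spectra = simulate_dataset(seed=5)
        assert spectra.values.shape == (116, 360)
        assert chem.n_samples == 116
        assert list(chem.sample_ids) == list(spectra.sample_ids)
        assert spectra.values.min() > 0
        assert spectra.values.max() <= 1.0 + 5e-4  # noise may peek above 1


class TestSynthesizeCube:
    def test_fixed_points(self, axis20):
        dn = 65552
        full = np.full(20, float(dn))
        raw, white, black = synthesize_cube(full, axis20, shape=(3, 3))
        assert np.array_equal(raw.data, white.data)
        raw, white, black = synthesize_cube(np.zeros(20), axis20, shape=(3, 3))
        assert np.array_equal(raw.data, black.data)

    def test_round_trip_within_half_dn(self, axis20, rng):
        spectrum = rng.uniform(0, 65552, 20)
        raw, white, black = synthesize_cube(spectrum, axis20, shape=(4, 5),
                                            seed=3)
        img = correct_reflectance(raw, white, black)
        mean = extract_roi_mean(img, np.ones((4, 5), bool))
        assert np.max(np.abs(mean - spectrum)) <= 0.5

    def test_degenerate_references_rejected(self, axis20):
        with pytest.raises(ValueError, match="white reference"):
            synthesize_cube(np.zeros(20), axis20, white_level=0.0,
                            black_level=0.0)

    def test_out_of_range_reflectance_rejected(self, axis20):
        with pytest.raises(ValueError, match="reflectance"):
            synthesize_cube(np.full(20, 70000.0), axis20)
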