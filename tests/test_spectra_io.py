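"""Plate I/O, replicate averaging and band extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenolmetry.errors import (
    FormatError,
    LookupErrorPh,
    RangeError,
    ValidationError,
)
from phenolmetry.simulate import PhenolRedBandModel, plate_from_model, spectrum, write_plate
from phenolmetry.spectra import (
    PlateSpectra,
    WellMeta,
    average_replicates,
    band_absorbance,
    read_plate,
    write_plate as write_plate_files,
)


def small_plate(values_by_well, wavelengths=None):
    wl = np.arange(300.0, 801.0) if wavelengths is None else np.asarray(wavelengths)
    traces = {w: np.full(wl.shape, v) if np.isscalar(v) else np.asarray(v)
              for w, v in values_by_well.items()}
    return PlateSpectra(wavelengths=wl, traces=traces)


class TestReadWrite:
    def test_round_trip_is_identity(self, tmp_path, noisy_model):
        plate = plate_from_model(noisy_model, [5.5, 7.4, 9.5], replicates=2,
                                 stock_ph=7.4)
        p, m = tmp_path / "p.csv", tmp_path / "m.csv"
        write_plate_files(plate, p, m)
        back = read_plate(p, m)
        assert back.wells == plate.wells
        np.testing.assert_array_equal(back.wavelengths, plate.wavelengths)
        for w in plate.wells:
            np.testing.assert_array_equal(back.traces[w], plate.traces[w])
            assert back.metadata[w] == plate.metadata[w]

    def test_simulated_fixture_round_trip(self, tmp_path, noisy_model):
        p, m = tmp_path / "p.csv", tmp_path / "m.csv"
        generated = write_plate(noisy_model, [6.0, 7.4, 9.0], 3, p, m, stock_ph=7.4)
        back = read_plate(p, m)
        for w in generated.wells:
            np.testing.assert_allclose(back.traces[w], generated.traces[w],
                                       atol=1e-12)

    def test_descending_wavelengths_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("wavelength_nm,A1\n800,0.1\n300,0.2\n")
        with pytest.raises(FormatError, match="increasing"):
            read_plate(path)

    def test_duplicate_well_ids_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        rows = "\n".join(f"{w},0.1,0.2" for w in range(300, 801))
        path.write_text("wavelength_nm,A1,A1\n" + rows + "\n")
        with pytest.raises(FormatError, match="duplicated well id"):
            read_plate(path)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        rows = [f"{w},0.1" for w in range(300, 801)]
        rows[5] = "305,oops"
        path.write_text("wavelength_nm,A1\n" + "\n".join(rows) + "\n")
        with pytest.raises(FormatError, match=r"row 7.*'A1'"):
            read_plate(path)

    def test_wells_missing_metadata_become_steps(self, tmp_path, caplog):
        path, meta = tmp_path / "p.csv", tmp_path / "m.csv"
        rows = "\n".join(f"{w},0.1,0.2" for w in range(300, 801))
        path.write_text("wavelength_nm,A1,A2\n" + rows + "\n")
        meta.write_text(
            "well,sample_label,role,replicate_group,reference_ph,"
            "titrant_name,titrant_molarity_M,titrant_volume_uL\n"
            "A1,stock,stock,g1,7.4,,,\n"
        )
        plate = read_plate(path, meta)
        assert plate.metadata["A2"].role == "step"
        assert plate.metadata["A2"].replicate_group == "A2"


class TestInvariants:
    def test_span_must_cover_both_bands(self):
        with pytest.raises(ValidationError, match="430"):
            small_plate({"A": 0.1}, wavelengths=np.arange(500.0, 801.0))

    def test_negative_beyond_tolerance_rejected(self):
        with pytest.raises(ValidationError, match="negative tolerance"):
            small_plate({"A": -0.06})

    def test_small_negative_baseline_noise_allowed(self):
        plate = small_plate({"A": -0.04})
        assert plate.traces["A"][0] == -0.04

    def test_extreme_roles_enforce_reference_ph(self):
        with pytest.raises(ValidationError, match="acid_extreme"):
            WellMeta(role="acid_extreme", replicate_group="g", reference_ph=7.0)
        with pytest.raises(ValidationError, match="base_extreme"):
            WellMeta(role="base_extreme", replicate_group="g", reference_ph=8.0)

    def test_baseline_correction_zeroes_the_red_tail(self, noiseless_model):
        plate = plate_from_model(noiseless_model, [7.4], 1, stock_ph=7.4)
        plate.traces[plate.wells[0]] += 0.02  # flat instrument offset
        corrected = plate.baseline_corrected()
        tail = corrected.wavelengths >= 700
        trace = corrected.traces[corrected.wells[0]]
        assert abs(trace[tail].mean()) < 1e-4


class TestAverageReplicates:
    def test_single_well_group_is_identity(self, noiseless_plate):
        group = "ph7.40"
        wells = [w for w in noiseless_plate.wells
                 if noiseless_plate.metadata[w].replicate_group == group]
        assert len(wells) == 1
        np.testing.assert_array_equal(
            average_replicates(noiseless_plate, group),
            noiseless_plate.traces[wells[0]],
        )

    def test_mean_of_a_and_3a_is_2a(self):
        a = np.linspace(0.1, 1.0, 501)
        plate = small_plate({"W1": a, "W2": 3 * a})
        meta = {w: WellMeta(replicate_group="g") for w in ("W1", "W2")}
        plate.metadata.update(meta)
        np.testing.assert_allclose(average_replicates(plate, "g"), 2 * a)

    def test_noisy_replicates_converge_to_truth(self):
        model = PhenolRedBandModel(noise_sd=0.002, seed=7)
        plate = plate_from_model(model, [7.4], replicates=25, stock_ph=7.4)
        clean = spectrum(PhenolRedBandModel(noise_sd=0.0), 7.4, plate.wavelengths)
        mean = average_replicates(plate, "ph7.40")
        # 5 sd / sqrt(n) tolerance at every wavelength
        assert np.max(np.abs(mean - clean)) < 5 * 0.002 / np.sqrt(25)

    def test_empty_group_and_mixed_roles(self, noiseless_plate):
        with pytest.raises(LookupErrorPh):
            average_replicates(noiseless_plate, "nope")
        plate = small_plate({"W1": 0.1, "W2": 0.2})
        plate.metadata["W1"] = WellMeta(replicate_group="g", role="step")
        plate.metadata["W2"] = WellMeta(replicate_group="g", role="stock")
        with pytest.raises(ValidationError, match="mixes roles"):
            average_replicates(plate, "g")

    @settings(deadline=None, max_examples=25)
    @given(
        values=st.lists(
            st.floats(min_value=0.0, max_value=3.0), min_size=2, max_size=5
        ),
        seed=st.integers(0, 2**16),
    )
    def test_permutation_invariance_and_linearity(self, values, seed):
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(values))
        wl = np.arange(300.0, 801.0, 50.0)

        def build(vals):
            plate = small_plate(
                {f"W{i}": v for i, v in enumerate(vals)}, wavelengths=wl
            )
            for w in list(plate.traces):
                plate.metadata[w] = WellMeta(replicate_group="g")
            return plate

        base = average_replicates(build(values), "g")
        permuted = average_replicates(build([values[i] for i in order]), "g")
        np.testing.assert_allclose(base, permuted, atol=1e-12)
        doubled = average_replicates(build([2 * v for v in values]), "g")
        np.testing.assert_allclose(doubled, 2 * base, atol=1e-12)


class TestBandAbsorbance:
    def test_exact_grid_hit(self):
        wl = np.arange(300.0, 801.0)
        tr = wl / 1000.0
        assert band_absorbance(wl, tr, 430.0) == pytest.approx(0.430)

    def test_nearest_and_tie_rules(self):
        wl = np.array([300.0, 428.0, 431.0, 600.0])
        tr = np.array([0.0, 1.0, 2.0, 3.0])
        assert band_absorbance(wl, tr, 430.0) == 2.0  # 431 is closer
        wl_tie = np.array([300.0, 429.0, 431.0, 600.0])
        assert band_absorbance(wl_tie, tr, 430.0) == 1.0  # tie -> lower

    def test_outside_grid_raises(self):
        wl = np.arange(300.0, 801.0)
        with pytest.raises(RangeError):
            band_absorbance(wl, wl, 250.0)

    def test_window_max_close_to_nearest_on_fine_grid(self, noiseless_model):
        wl = np.arange(300.0, 801.0)
        tr = spectrum(noiseless_model, 4.0, wl)
        nearest = band_absorbance(wl, tr, 430.0, "at_nearest")
        widest = band_absorbance(wl, tr, 430.0, "window_max", half_window=10.0)
        assert widest >= nearest
        assert widest - nearest < 0.005 * tr.max()

    def test_at_nearest_invariant_under_grid_refinement(self, noiseless_model):
        coarse = np.arange(300.0, 801.0, 2.0)
        fine = np.arange(300.0, 800.6, 0.5)
        a_coarse = band_absorbance(coarse, spectrum(noiseless_model, 7.2, coarse), 430.0)
        a_fine = band_absorbance(fine, spectrum(noiseless_model, 7.2, fine), 430.0)
        assert a_coarse == pytest.approx(a_fine, abs=1e-12)
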