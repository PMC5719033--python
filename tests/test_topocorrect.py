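"""Reference tracking, correction factor, shift correction, topography."""

import numpy as np
import pytest
import scipy.sparse as sp

import topotof as tt
from topotof.simulate import RawSpectrumImage, SpeciesLayer, SyntheticScene
from topotof.topocorrect import CorrectionField
from tests.conftest import all_species

CS = tt.IonSpecies("Cs+", tt.CS_MONOISOTOPIC)


def dual_reference_scene(nx=32, ny=32, height=200e-6):
    """K+ and Cs+ both present everywhere, on root topography."""
    base = tt.make_root_scene(height=height, nx=nx, ny=ny, seed=3)
    layers = [
        SpeciesLayer(tt.IonSpecies("K+", tt.K_MONOISOTOPIC), 150.0,
                     np.ones((ny, nx))),
        SpeciesLayer(CS, 300.0, np.ones((ny, nx))),
    ]
    return SyntheticScene(nx=nx, ny=ny, pixel_pitch=base.pixel_pitch,
                          topography=base.topography, layers=layers, seed=3)


def compressed(scene, geom, lineshape="gaussian", threshold=500):
    raw = tt.render(scene, geom, noiseless=True, lineshape=lineshape)
    segs = tt.assign_labels(
        tt.find_segments(tt.sum_spectrum(raw), threshold=threshold),
        all_species(), geom)
    return tt.compress_cube(raw, segs)


class TestTrackReference:
    def test_flat_scene_constant_tof(self, geom):
        scene = dual_reference_scene(height=0.0, nx=8, ny=8)
        comp = compressed(scene, geom, lineshape="delta")
        track = tt.track_reference(comp, comp.segment_by_label("Cs+"))
        T = tt.total_tof(tt.CS_MONOISOTOPIC, 0.0, geom)
        assert np.all(track.valid)
        assert np.allclose(track.t_ref, track.t_ref[0, 0])
        assert abs(track.t_ref[0, 0] - T) <= 0.5 * geom.tof_bin

    def test_root_crest_arrives_early(self, corrected_gauss64, geom):
        track = corrected_gauss64["track"]
        crest = track.t_ref[3, track.t_ref.shape[1] // 2]
        substrate = track.t_ref[3, 0]
        assert substrate - crest == pytest.approx(3.8441e-9, rel=5e-3)

    def test_low_count_pixels_invalid(self, geom):
        counts = sp.csr_matrix((np.array([2, 50]), (np.array([0, 1]),
                                np.array([758887, 758887]))),
                               shape=(4, geom.n_bins))
        raw = RawSpectrumImage(counts=counts.astype(np.int64), nx=2, ny=2,
                               geom=geom)
        track = tt.track_reference(raw, tt.MassSegment(758800, 758950),
                                   min_counts=5)
        assert track.valid.ravel().tolist() == [False, True, False, False]

    def test_empty_segment_everywhere_rejected(self, raw_delta32):
        with pytest.raises(ValueError):
            tt.track_reference(raw_delta32, tt.MassSegment(10, 20))


class TestSubstrateEstimate:
    def test_flat_scene_returns_common_value(self, geom):
        scene = dual_reference_scene(height=0.0, nx=8, ny=8)
        comp = compressed(scene, geom, lineshape="delta")
        track = tt.track_reference(comp, comp.segment_by_label("Cs+"))
        assert tt.estimate_substrate_tof(track) == track.t_ref[0, 0]

    def test_max_exceeds_crest_value(self, corrected_gauss64):
        track = corrected_gauss64["track"]
        t_sub = corrected_gauss64["t_sub"]
        assert t_sub > track.t_ref[3, track.t_ref.shape[1] // 2]
        assert t_sub == track.t_ref[track.valid].max()

    def test_percentile_is_monotone(self, corrected_gauss64):
        track = corrected_gauss64["track"]
        q = tt.estimate_substrate_tof(track, percentile=0.999)
        assert q <= tt.estimate_substrate_tof(track, percentile=1.0)

    def test_bad_percentile_rejected(self, corrected_gauss64):
        with pytest.raises(ValueError):
            tt.estimate_substrate_tof(corrected_gauss64["track"], percentile=0.0)


class TestCorrectionField:
    def test_substrate_pixels_have_unit_factor(self, corrected_gauss64):
        fld = corrected_gauss64["field"]
        assert fld.D[3, 0] == pytest.approx(1.0, abs=1e-9)

    def test_crest_factor_value(self, corrected_gauss64):
        """D at 200 µm ≈ 1 + 3.844 ns / 37.944 µs."""
        fld = corrected_gauss64["field"]
        crest = fld.D[:, fld.D.shape[1] // 2].max()
        assert crest == pytest.approx(1.0001013, abs=2e-6)

    def test_mass_independence_of_factor(self, geom):
        """Cs+-derived and K+-derived correction fields coincide."""
        scene = dual_reference_scene()
        comp = compressed(scene, geom)
        fields = {}
        for label in ("Cs+", "K+"):
            track = tt.track_reference(comp, comp.segment_by_label(label))
            t_sub = tt.estimate_substrate_tof(track)
            fields[label] = tt.correction_field(track, t_sub)
        both = fields["Cs+"].valid & fields["K+"].valid
        rel = np.abs(fields["Cs+"].D[both] / fields["K+"].D[both] - 1.0)
        assert rel.max() < 1e-9


class TestApplyCorrection:
    def test_unit_field_is_identity(self, comp_delta32):
        ny, nx = comp_delta32.ny, comp_delta32.nx
        fld = CorrectionField(D=np.ones((ny, nx)), t_ref_sub=1.0,
                              dT=np.zeros((ny, nx)),
                              valid=np.ones((ny, nx), dtype=bool))
        out = tt.apply_correction(comp_delta32, fld)
        assert np.array_equal(out.matrix, comp_delta32.matrix)

    def test_per_pixel_totals_preserved_integer_mode(self, comp_delta32, geom):
        ref = comp_delta32.segment_by_label("Cs+")
        track = tt.track_reference(comp_delta32, ref)
        fld = tt.correction_field(track, tt.estimate_substrate_tof(track))
        out = tt.apply_correction(comp_delta32, fld, integer=True)
        assert out.info["lost_counts"] == 0
        assert np.array_equal(out.matrix.sum(axis=1),
                              comp_delta32.matrix.sum(axis=1))
        assert np.issubdtype(out.matrix.dtype, np.integer)

    def test_delta_mode_restores_substrate_centroid_within_one_bin(
            self, comp_delta32, geom):
        """Quantized single-bin peaks: corrected K+ centroid lands within
        one 50 ps bin of the substrate-level K+ position."""
        ref = comp_delta32.segment_by_label("Cs+")
        track = tt.track_reference(comp_delta32, ref)
        fld = tt.correction_field(track, tt.estimate_substrate_tof(track))
        out = tt.apply_correction(comp_delta32, fld)
        kt = tt.track_reference(out, out.segment_by_label("K+"), min_counts=1)
        T_sub = tt.tof_from_mass(tt.K_MONOISOTOPIC, geom)
        dev = np.abs(kt.t_ref[kt.valid] - T_sub)
        assert dev.max() <= 1.0 * geom.tof_bin + 1e-15

    def test_corrected_potassium_mass_within_residual_bound(
            self, corrected_gauss64, geom):
        """Residual |corrected K+ mass − 38.9637 u| stays ≤ 1.5e-4 u."""
        out = corrected_gauss64["corrected"]
        kt = tt.track_reference(out, out.segment_by_label("K+"), min_counts=1)
        masses = tt.mass_from_tof(kt.t_ref[kt.valid], geom)
        assert np.abs(masses - tt.K_MONOISOTOPIC).max() <= 1.5e-4

    def test_out_of_window_counts_dropped_and_counted(self, geom):
        last = geom.n_bins - 1
        counts = sp.csr_matrix((np.array([10]), (np.array([0]),
                                np.array([last]))), shape=(1, geom.n_bins),
                               dtype=np.int64)
        raw = RawSpectrumImage(counts=counts, nx=1, ny=1, geom=geom)
        fld = CorrectionField(D=np.array([[1.001]]), t_ref_sub=1.0,
                              dT=np.zeros((1, 1)),
                              valid=np.ones((1, 1), dtype=bool))
        out = tt.apply_correction(raw, fld)
        assert out.metadata["lost_counts"] == pytest.approx(10, rel=1e-9)
        assert out.total_counts == 0

    def test_idempotence_after_correction(self, corrected_gauss64):
        """Re-tracking the reference on corrected data gives D ≈ 1."""
        out = corrected_gauss64["corrected"]
        track = tt.track_reference(out, out.segment_by_label("Cs+"))
        fld = tt.correction_field(track, tt.estimate_substrate_tof(track))
        assert np.abs(fld.D[fld.valid] - 1.0).max() < 1e-7


class TestTopographyReconstruction:
    def test_zero_shift_zero_height(self, geom):
        fld = CorrectionField(D=np.ones((2, 2)), t_ref_sub=1.0,
                              dT=np.zeros((2, 2)),
                              valid=np.ones((2, 2), dtype=bool))
        topo = tt.reconstruct_topography(fld, CS, geom)
        assert np.all(topo.dh == 0)

    @pytest.mark.parametrize("dh_true", [5e-6, 50e-6, 200e-6, 400e-6])
    def test_closed_form_roundtrip(self, geom, dh_true):
        dt = tt.tof_shift(CS.mass, dh_true, geom)
        fld = CorrectionField(D=np.ones((1, 1)), t_ref_sub=1.0,
                              dT=np.full((1, 1), dt),
                              valid=np.ones((1, 1), dtype=bool))
        topo = tt.reconstruct_topography(fld, CS, geom)
        assert abs(topo.dh[0, 0] - dh_true) < 1e-12

    def test_root_height_recovered_within_quantization_floor(
            self, comp_delta32, root_scene32, geom):
        """Delta-mode (single-bin) render: peak height 200 µm ± 5 µm."""
        ref = comp_delta32.segment_by_label("Cs+")
        track = tt.track_reference(comp_delta32, ref)
        fld = tt.correction_field(track, tt.estimate_substrate_tof(track))
        topo = tt.reconstruct_topography(fld, CS, geom)
        assert topo.dh[topo.valid].max() == pytest.approx(200e-6, abs=5e-6)

    def test_unphysical_shift_invalidates_pixel(self, geom):
        t_ac = tt.acceleration_time(CS.mass, geom)
        fld = CorrectionField(D=np.ones((1, 2)), t_ref_sub=1.0,
                              dT=np.array([[0.0, 1.5 * t_ac]]),
                              valid=np.ones((1, 2), dtype=bool))
        topo = tt.reconstruct_topography(fld, CS, geom)
        assert topo.valid.tolist() == [[True, False]]

    def test_stochastic_recovery_rmse(self, geom):
        """Seeded Poisson render: RMSE of Δh ≤ 10 µm over the root."""
        scene = tt.make_root_scene(height=200e-6, nx=64, ny=64, seed=13)
        raw = tt.render(scene, geom)
        segs = tt.assign_labels(
            tt.find_segments(tt.sum_spectrum(raw), threshold=1000),
            all_species(), geom)
        comp = tt.compress_cube(raw, segs)
        track = tt.track_reference(comp, comp.segment_by_label("Cs+"))
        t_sub = tt.estimate_substrate_tof(track, percentile=0.9)
        fld = tt.correction_field(track, t_sub)
        topo = tt.reconstruct_topography(fld, CS, geom)
        err = topo.dh[topo.valid] - scene.topography[topo.valid]
        rmse = np.sqrt(np.mean(err**2))
        assert rmse <= 10e-6
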