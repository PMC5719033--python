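"""Segment finding, lossless compression, calibration maps, peak maps."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

import topotof as tt
from topotof.simulate import RawSpectrumImage
from tests.conftest import all_species


def toy_raw(geom, pixel_spectra):
    """Build a RawSpectrumImage from a list of {bin: count} dicts."""
    n = len(pixel_spectra)
    rows, cols, vals = [], [], []
    for p, spec in enumerate(pixel_spectra):
        for b, c in spec.items():
            rows.append(p)
            cols.append(b)
            vals.append(c)
    counts = sp.coo_matrix((vals, (rows, cols)),
                           shape=(n, geom.n_bins), dtype=np.int64).tocsr()
    return RawSpectrumImage(counts=counts, nx=n, ny=1, geom=geom)


class TestSumSpectrum:
    def test_zero_cube(self, geom):
        raw = toy_raw(geom, [{}, {}])
        assert tt.sum_spectrum(raw).sum() == 0

    def test_single_pixel_identity(self, geom):
        raw = toy_raw(geom, [{100: 7, 5000: 3}])
        total = tt.sum_spectrum(raw)
        assert total[100] == 7 and total[5000] == 3 and total.sum() == 10

    def test_conserves_counts_on_fixture(self, raw_delta32):
        assert tt.sum_spectrum(raw_delta32).sum() == raw_delta32.total_counts


class TestFindSegments:
    def test_empty_spectrum(self):
        assert tt.find_segments(np.zeros(10000), threshold=100) == []

    def test_isolated_peak_retained(self):
        total = np.zeros(10000)
        total[4000:4003] = 400  # 1200 counts
        segs = tt.find_segments(total, threshold=1000)
        assert len(segs) == 1
        assert segs[0].start_bin <= 4000 and segs[0].end_bin > 4002
        assert segs[0].total_counts == 1200

    def test_gap_merging_controls_retention(self):
        """Two 600-count peaks 30 bins apart: one 1200-count segment when
        the gap merges, none when it does not."""
        total = np.zeros(10000)
        total[4000] = 600
        total[4030] = 600
        merged = tt.find_segments(total, threshold=1000, min_gap=40, pad=10)
        assert len(merged) == 1 and merged[0].total_counts == 1200
        split = tt.find_segments(total, threshold=1000, min_gap=10, pad=10)
        assert split == []

    def test_threshold_below_one_rejected(self):
        with pytest.raises(ValueError):
            tt.find_segments(np.zeros(10), threshold=0)

    @given(st.lists(st.tuples(st.integers(0, 9999), st.integers(1, 500)),
                    min_size=0, max_size=30),
           st.integers(1, 2000))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_threshold_monotonicity(self, spikes, threshold):
        """Raising the threshold never increases segments or points."""
        total = np.zeros(10000)
        for b, c in spikes:
            total[b] += c
        low = tt.find_segments(total, threshold=threshold)
        high = tt.find_segments(total, threshold=threshold * 2)
        assert len(high) <= len(low)
        assert sum(map(len, high)) <= sum(map(len, low))

    def test_segments_sorted_and_disjoint_on_fixture(self, comp_delta32):
        segs = comp_delta32.segments
        for a, b in zip(segs, segs[1:]):
            assert a.end_bin <= b.start_bin


class TestCompressCube:
    def test_whole_axis_is_identity(self, geom):
        raw = toy_raw(geom, [{100: 7}, {5000: 3}])
        comp = tt.compress_cube(raw, [tt.MassSegment(0, geom.n_bins)])
        assert comp.n_points == geom.n_bins
        assert comp.matrix[0, 100] == 7 and comp.matrix[1, 5000] == 3
        assert comp.matrix.sum() == 10

    def test_empty_segment_list(self, geom):
        raw = toy_raw(geom, [{100: 7}])
        assert tt.compress_cube(raw, []).n_points == 0

    def test_overlapping_segments_rejected(self, geom):
        raw = toy_raw(geom, [{100: 7}])
        with pytest.raises(ValueError):
            tt.compress_cube(raw, [tt.MassSegment(0, 200), tt.MassSegment(150, 300)])

    def test_lossless_roundtrip(self, raw_delta32, comp_delta32):
        """Decompress → recompress is the identity on the matrix."""
        back = tt.compress_cube(comp_delta32.decompress(), comp_delta32.segments)
        assert np.array_equal(back.matrix, comp_delta32.matrix)
        assert np.array_equal(back.index_map, comp_delta32.index_map)
        # and the scattered cube agrees with the original inside segments
        diff = (comp_delta32.decompress().counts != raw_delta32.counts).nnz
        assert diff == 0  # noiseless peaks lie wholly inside segments

    def test_hundredfold_reduction(self, comp_delta32, geom):
        assert 100 < comp_delta32.n_points < 20000
        assert geom.n_bins / comp_delta32.n_points > 100

    def test_calibration_map_hits_species_masses(self, comp_delta32, geom):
        """mz_map at each species' centroid point ≈ its mass (within one bin)."""
        for label, mass in [("Na+", 22.9898), ("Cs+", tt.CS_MONOISOTOPIC)]:
            seg = comp_delta32.segment_by_label(label)
            pts = comp_delta32.segment_points(seg)
            w = comp_delta32.matrix[:, pts].sum(axis=0)
            centroid_mz = (w * comp_delta32.mz_map[pts]).sum() / w.sum()
            one_bin = 2 * mass * geom.tof_bin / tt.tof_from_mass(mass, geom)
            # topographic shift spreads the peak low; allow the shift scale
            assert abs(centroid_mz - mass) < 100 * one_bin
            sub_pts = pts[np.argmax(comp_delta32.index_map[pts])]
            assert abs(comp_delta32.mz_map[sub_pts] - mass) < 50 * one_bin

    def test_index_map_strictly_increasing(self, comp_delta32):
        assert np.all(np.diff(comp_delta32.index_map) > 0)


class TestPeakMap:
    def test_uniform_layer_constant_map(self, geom):
        raw = toy_raw(geom, [{410900: 5}] * 4)
        m = tt.peak_map(raw, tt.MassSegment(410890, 410910))
        assert np.all(m == 5)

    def test_potassium_confined_to_root(self, comp_delta32, root_scene32):
        seg = comp_delta32.segment_by_label("K+")
        m = tt.peak_map(comp_delta32, seg)
        root = root_scene32.topography > 0
        assert np.all(m[root] > 0)
        assert np.all(m[~root] == 0)

    def test_normalized_single_species_is_unity(self, geom):
        raw = toy_raw(geom, [{410900: 5}, {}, {410901: 2}])
        m = tt.peak_map(raw, tt.MassSegment(410890, 410910), normalize=True)
        assert m[0, 0] == 1.0 and m[0, 2] == 1.0
        assert m.mask[0, 1]  # zero-total pixel flagged invalid


class TestLabels:
    def test_fixture_labels_cover_palette(self, comp_delta32):
        labels = {s.label for s in comp_delta32.segments if s.label}
        for expected in ["Na+", "Mg+", "K+", "Ca+", "Si+", "Cs+", "Cs2+"]:
            assert any(expected in l for l in labels)

    def test_unknown_label_lists_known(self, comp_delta32):
        with pytest.raises(KeyError, match="Cs"):
            comp_delta32.segment_by_label("Xe+")


def test_threshold_sparsity_rule():
    """1000 counts over 65,536 pixels ≈ one ion per 65 spatial points."""
    assert int(tt.ions_per_n_pixels(65536, 1000)) == 65
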