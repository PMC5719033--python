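"""Threshold-based spectrum compression and per-peak mapping.

A raw ToF-SIMS cube carries millions of time bins per pixel but only a
few dozen peaks of real signal.  Compression works from the summed
(averaged) spectrum: maximal runs of occupied bins are merged across
small gaps, padded, and retained when their integrated count exceeds a
preset threshold.  The cube is then restricted to the concatenation of
the retained segments — losslessly, at full 50 ps resolution — which
typically shrinks the spectral axis from 2,000,000 raw bins to a few
thousand points.  A point-index → raw-bin → m/z calibration map travels
with the compressed data so every point keeps its physical identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp

from .geometry import InstrumentGeometry, IonSpecies, mass_from_tof, tof_from_mass
from .simulate import RawSpectrumImage


@dataclass
class MassSegment:
    """Half-open run of raw time bins ``[start_bin, end_bin)`` kept as signal."""

    start_bin: int
    end_bin: int
    total_counts: int = 0
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 <= self.start_bin < self.end_bin:
            raise ValueError("need 0 <= start_bin < end_bin")

    def __len__(self) -> int:
        return self.end_bin - self.start_bin

    def mz_range(self, geom: InstrumentGeometry) -> tuple:
        """(low, high) m/z covered by the segment (bin-center convention)."""
        t_lo = (self.start_bin + 0.5) * geom.tof_bin
        t_hi = (self.end_bin - 0.5) * geom.tof_bin
        return (mass_from_tof(t_lo, geom), mass_from_tof(t_hi, geom))


@dataclass
class CompressedSpectra:
    """Cube restricted to retained segments, with calibration maps.

    ``matrix`` is dense (n_pixels × n_points) with pixels row-major,
    x fastest; ``index_map[i]`` is the raw bin of point i (strictly
    increasing) and ``mz_map[i]`` its m/z at the bin-center time
    ``(index_map[i] + 0.5) * tof_bin``.
    """

    matrix: np.ndarray
    index_map: np.ndarray
    mz_map: np.ndarray
    segments: List[MassSegment]
    geom: InstrumentGeometry
    nx: int
    ny: int
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        self.index_map = np.asarray(self.index_map, dtype=np.int64)
        self.mz_map = np.asarray(self.mz_map, dtype=float)
        n_points = self.matrix.shape[1]
        if len(self.index_map) != n_points or len(self.mz_map) != n_points:
            raise ValueError("index_map/mz_map length must equal n_points")
        if n_points and np.any(np.diff(self.index_map) <= 0):
            raise ValueError("index_map must be strictly increasing")
        if self.matrix.shape[0] != self.nx * self.ny:
            raise ValueError("matrix rows must equal nx*ny")

    @property
    def n_points(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    def pixel_totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1).reshape(self.ny, self.nx)

    def segment_points(self, segment: MassSegment) -> np.ndarray:
        """Indices of compressed points lying inside ``segment``."""
        return np.flatnonzero(
            (self.index_map >= segment.start_bin) & (self.index_map < segment.end_bin)
        )

    def segment_by_label(self, label: str) -> MassSegment:
        for seg in self.segments:
            if seg.label == label or (
                seg.label and label in seg.label.split(";")
            ):
                return seg
        known = sorted({s.label for s in self.segments if s.label})
        raise KeyError(f"no segment labelled {label!r}; known labels: {known}")

    def decompress(self) -> RawSpectrumImage:
        """Scatter the compressed points back onto the full raw axis."""
        n_bins = self.geom.n_bins
        rows, cols = np.nonzero(self.matrix)
        counts = sp.coo_matrix(
            (self.matrix[rows, cols], (rows, self.index_map[cols])),
            shape=(self.n_pixels, n_bins),
            dtype=np.int64,
        ).tocsr()
        return RawSpectrumImage(counts=counts, nx=self.nx, ny=self.ny,
                                geom=self.geom, metadata={"decompressed": True})


def sum_spectrum(raw: RawSpectrumImage) -> np.ndarray:
    """Spectrum summed over all pixels (the averaged reference spectrum ×N)."""
    return np.asarray(raw.counts.sum(axis=0)).ravel()


def find_segments(
    total: np.ndarray,
    threshold: float = 1000,
    min_gap: int = 40,
    pad: int = 40,
) -> List[MassSegment]:
    """Identify mass segments of useful signal in a summed spectrum.

    Candidate segments are maximal runs of nonzero bins, merged when
    separated by fewer than ``min_gap`` empty bins, then padded by
    ``pad`` bins on each side (clipped to the axis, overlaps re-merged).
    A candidate is retained iff its integrated count reaches
    ``threshold`` — the "total number of counts" reading of the signal
    threshold, under which a 1000-count cut on a 256×256 image keeps
    peaks down to roughly a single ion per 65 pixels.

    The default ``min_gap`` and ``pad`` (40 bins = 2 ns each) cover the
    topographic shift scale, so a peak, its height-shifted copies *and*
    its corrected (substrate-level) position all stay inside one
    segment.  The pad matters for species absent from the substrate:
    their unshifted position is never observed directly and must still
    fall inside the segment after correction.
    """
    if threshold < 1:
        raise ValueError("threshold must be at least 1 count")
    total = np.asarray(total)
    n_bins = len(total)
    nz = np.flatnonzero(total)
    if nz.size == 0:
        return []
    # maximal runs of nonzero bins, merging gaps < min_gap
    breaks = np.flatnonzero(np.diff(nz) > min_gap)
    starts = np.r_[nz[0], nz[breaks + 1]]
    ends = np.r_[nz[breaks], nz[-1]] + 1
    # pad and clip, then re-merge overlapping/abutting candidates
    starts = np.clip(starts - pad, 0, n_bins)
    ends = np.clip(ends + pad, 0, n_bins)
    merged: List[list] = []
    for s, e in zip(starts, ends):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        tc = int(total[s:e].sum())
        if tc >= threshold:
            out.append(MassSegment(int(s), int(e), tc))
    return out


def assign_labels(
    segments: Sequence[MassSegment],
    species: Sequence[IonSpecies],
    geom: InstrumentGeometry,
) -> List[MassSegment]:
    """Label each segment with the species whose substrate TOF falls in it."""
    out = []
    for seg in segments:
        label = None
        for sp_ in species:
            b = tof_from_mass(sp_.mass, geom) / geom.tof_bin
            if seg.start_bin <= b < seg.end_bin:
                # multiple species in one segment are ';'-joined
                label = sp_.label if label is None else f"{label};{sp_.label}"
        out.append(replace(seg, label=label))
    return out


def compress_cube(
    raw: RawSpectrumImage, segments: Sequence[MassSegment]
) -> CompressedSpectra:
    """Losslessly restrict a raw cube to the retained segments."""
    segs = sorted(segments, key=lambda s: s.start_bin)
    for a, b in zip(segs, segs[1:]):
        if b.start_bin < a.end_bin:
            raise ValueError("segments must be disjoint")
    n_bins = raw.n_bins
    if segs and (segs[0].start_bin < 0 or segs[-1].end_bin > n_bins):
        raise ValueError("segment outside the raw bin range")
    if segs:
        index_map = np.concatenate(
            [np.arange(s.start_bin, s.end_bin, dtype=np.int64) for s in segs]
        )
        csc = raw.counts.tocsc()
        matrix = np.hstack(
            [np.asarray(csc[:, s.start_bin:s.end_bin].todense()) for s in segs]
        )
    else:
        index_map = np.zeros(0, dtype=np.int64)
        matrix = np.zeros((raw.n_pixels, 0), dtype=np.int64)
    t = (index_map + 0.5) * raw.geom.tof_bin
    mz_map = mass_from_tof(t, raw.geom) if len(t) else np.zeros(0)
    return CompressedSpectra(
        matrix=matrix,
        index_map=index_map,
        mz_map=np.atleast_1d(mz_map),
        segments=list(segs),
        geom=raw.geom,
        nx=raw.nx,
        ny=raw.ny,
        info={"n_raw_bins": n_bins},
    )


def peak_map(
    data: Union[CompressedSpectra, RawSpectrumImage],
    segment: MassSegment,
    normalize: bool = False,
) -> np.ndarray:
    """Spatial map of the integrated counts in one mass segment.

    With ``normalize`` the per-pixel segment area is divided by the
    pixel's total count; pixels with zero total map to 0 and are masked
    (the result is a masked array flagging invalid pixels).
    """
    if isinstance(data, CompressedSpectra):
        pts = data.segment_points(segment)
        area = data.matrix[:, pts].sum(axis=1).astype(float)
        totals = data.matrix.sum(axis=1).astype(float)
        ny, nx = data.ny, data.nx
    else:
        if segment.end_bin > data.n_bins:
            raise ValueError("segment outside the raw bin range")
        area = np.asarray(
            data.counts[:, segment.start_bin:segment.end_bin].sum(axis=1)
        ).ravel().astype(float)
        totals = np.asarray(data.counts.sum(axis=1)).ravel().astype(float)
        ny, nx = data.ny, data.nx
    if not normalize:
        return area.reshape(ny, nx)
    ok = totals > 0
    out = np.zeros_like(area)
    out[ok] = area[ok] / totals[ok]
    return np.ma.masked_array(out.reshape(ny, nx), mask=~ok.reshape(ny, nx))


def ions_per_n_pixels(n_pixels: int, threshold: float) -> float:
    """Spatial sparsity a count threshold corresponds to.

    A total-count threshold of ``threshold`` on an image of ``n_pixels``
    pixels retains peaks down to one detected ion per
    ``n_pixels / threshold`` spatial points (e.g. 65,536 pixels at a
    1000-count threshold ≈ one ion per 65 points).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return n_pixels / threshold
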