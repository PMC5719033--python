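"""Topography-induced peak-shift correction and topography reconstruction.

Ions emitted from elevated surface regions spend less time in the
extraction gap and arrive early; crucially, both the acceleration time
and the total TOF scale as √m, so the *relative* shift
``T(m, dh)/T(m, 0)`` is mass-independent.  A single reference peak
(here Cs+, the most intense peak, implanted everywhere by the sputter
source) therefore yields a per-pixel multiplicative correction factor

    D(x, y) = T_ref_sub / T_ref(x, y)

that restores every species' substrate-level TOF at once.  The same
reference-peak shift ΔT(x, y) = T_ref_sub − T_ref(x, y) inverts in
closed form to the emission height,

    Δh(x, y) = h_ex * (1 − ((t_ac(0) − ΔT)/t_ac(0))²),

turning the mass spectrometer into a (coarse) profilometer: with 50 ps
timing the minimum detectable feature is about 5 µm, and the method is
useful from roughly 10 µm up to hundreds of µm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Union

import numpy as np
import scipy.sparse as sp

from .compress import CompressedSpectra, MassSegment
from .geometry import InstrumentGeometry, IonSpecies, acceleration_time
from .simulate import RawSpectrumImage

logger = logging.getLogger(__name__)

Cube = Union[RawSpectrumImage, CompressedSpectra]


@dataclass
class ReferenceTrack:
    """Per-pixel TOF of the reference peak, with a validity mask."""

    t_ref: np.ndarray
    valid: np.ndarray
    ref_species: Optional[IonSpecies]
    ref_segment: MassSegment

    def __post_init__(self) -> None:
        self.t_ref = np.asarray(self.t_ref, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.t_ref.shape != self.valid.shape:
            raise ValueError("t_ref and valid must share a shape")
        if np.any(self.t_ref[self.valid] <= 0):
            raise ValueError("t_ref must be positive where valid")


@dataclass
class CorrectionField:
    """Per-pixel multiplicative TOF correction factor D and shift ΔT."""

    D: np.ndarray
    t_ref_sub: float
    dT: np.ndarray
    valid: np.ndarray


@dataclass
class TopographyMap:
    """Reconstructed emission height Δh (m) per pixel."""

    dh: np.ndarray
    valid: np.ndarray
    ref_species: Optional[IonSpecies]
    geom: InstrumentGeometry


def track_reference(
    data: Cube, ref_segment: MassSegment, min_counts: int = 5
) -> ReferenceTrack:
    """Per-pixel intensity-weighted centroid TOF of the reference peak.

    The centroid over bin-center times gives sub-bin precision — needed
    to approach the ~5 µm height floor implied by 50 ps timing — once
    the peak spans several bins.  Pixels with fewer than ``min_counts``
    counts in the segment are marked invalid.
    """
    if isinstance(data, CompressedSpectra):
        pts = data.segment_points(ref_segment)
        if pts.size == 0:
            raise ValueError("reference segment contains no compressed points")
        times = (data.index_map[pts] + 0.5) * data.geom.tof_bin
        w = data.matrix[:, pts].astype(float)
        ny, nx = data.ny, data.nx
    else:
        if ref_segment.end_bin > data.n_bins:
            raise ValueError("reference segment outside the raw axis")
        sub = data.counts[:, ref_segment.start_bin:ref_segment.end_bin]
        times = (
            np.arange(ref_segment.start_bin, ref_segment.end_bin) + 0.5
        ) * data.geom.tof_bin
        w = np.asarray(sub.todense(), dtype=float)
        ny, nx = data.ny, data.nx
    totals = w.sum(axis=1)
    if not np.any(totals > 0):
        raise ValueError("reference segment is empty in every pixel")
    valid = totals >= min_counts
    t_ref = np.zeros_like(totals)
    ok = totals > 0
    t_ref[ok] = (w[ok] @ times) / totals[ok]
    return ReferenceTrack(
        t_ref=t_ref.reshape(ny, nx),
        valid=valid.reshape(ny, nx),
        ref_species=None,
        ref_segment=ref_segment,
    )


def estimate_substrate_tof(track: ReferenceTrack, percentile: float = 1.0) -> float:
    """Substrate-level reference TOF from the tracked field.

    The default (``percentile=1.0``) is the strict maximum of the
    per-pixel reference TOF — the longest flight comes from the lowest
    emission point.  On noisy data the maximum of many noisy centroids
    is biased high; ``percentile < 1`` returns that quantile instead as
    a robust alternative.
    """
    if not 0 < percentile <= 1.0:
        raise ValueError("percentile must lie in (0, 1]")
    vals = track.t_ref[track.valid]
    if vals.size == 0:
        raise ValueError("no valid pixels in the reference track")
    if percentile == 1.0:
        return float(vals.max())
    return float(np.quantile(vals, percentile))


def correction_field(track: ReferenceTrack, t_ref_sub: float) -> CorrectionField:
    """Per-pixel correction factor ``D = T_ref_sub / T_ref(x, y)``."""
    if not t_ref_sub > 0:
        raise ValueError("t_ref_sub must be positive")
    valid = track.valid.copy()
    D = np.ones_like(track.t_ref)
    dT = np.zeros_like(track.t_ref)
    D[valid] = t_ref_sub / track.t_ref[valid]
    dT[valid] = t_ref_sub - track.t_ref[valid]
    return CorrectionField(D=D, t_ref_sub=float(t_ref_sub), dT=dT, valid=valid)


def _rebin_row(idx: np.ndarray, counts: np.ndarray, D: float):
    """Scale the time support of one pixel's bins by D and rebin.

    Each source bin's support ``[i, i+1) * tof_bin`` maps to
    ``[i*D, (i+1)*D)``; its counts are split over the output bins in
    proportion to overlap length (count-conserving linear rebinning).
    Returns (target_bins, float_values).
    """
    lo = idx * D
    n_span = int(math.ceil(D)) + 1
    tb = []
    tv = []
    for k in range(n_span):
        j = np.floor(lo).astype(np.int64) + k
        overlap = np.minimum(j + 1, lo + D) - np.maximum(j, lo)
        w = np.clip(overlap, 0.0, None) / D
        keep = w > 0
        if keep.any():
            tb.append(j[keep])
            tv.append(counts[keep] * w[keep])
    if not tb:
        return np.zeros(0, dtype=np.int64), np.zeros(0)
    return np.concatenate(tb), np.concatenate(tv)


def _largest_remainder(values: np.ndarray, target_total: int) -> np.ndarray:
    """Round a non-negative float vector to integers preserving the total."""
    floors = np.floor(values).astype(np.int64)
    deficit = int(target_total - floors.sum())
    if deficit > 0:
        order = np.argsort(values - floors)[::-1]
        floors[order[:deficit]] += 1
    elif deficit < 0:  # can happen only through caller rounding of the target
        order = np.argsort(values - floors)
        take = order[floors[order] > 0][: -deficit]
        floors[take] -= 1
    return floors


def apply_correction(
    data: Cube, fld: CorrectionField, integer: Optional[bool] = None
) -> Cube:
    """Rescale every pixel's TOF axis by its correction factor D.

    Each raw bin's time support is stretched by D and its counts are
    redistributed onto the fixed output grid in proportion to overlap —
    a count-conserving linear rebinning (the histogram analogue of
    ``T' = T × D``).  With ``integer=True`` counts stay integral via
    largest-remainder rounding, preserving each pixel's total exactly;
    the default follows the input dtype (integer cubes stay integer,
    float expectation cubes stay float).  Counts scaled beyond the
    acquisition window (or, for compressed data, outside every retained
    segment) are dropped and tallied in the result's
    ``info['lost_counts']``.  Invalid pixels pass through unchanged.
    """
    ny_d = data.ny
    if fld.D.shape != (ny_d, data.nx):
        raise ValueError("correction field grid does not match the data grid")
    if integer is None:
        dtype = (data.matrix.dtype if isinstance(data, CompressedSpectra)
                 else data.counts.dtype)
        integer = bool(np.issubdtype(dtype, np.integer))
    Dflat = fld.D.ravel()
    validflat = fld.valid.ravel()
    lost = 0.0

    if isinstance(data, CompressedSpectra):
        n_bins = data.geom.n_bins
        pos = np.full(n_bins + 1, -1, dtype=np.int64)
        pos[data.index_map] = np.arange(data.n_points)
        out = np.zeros_like(data.matrix, dtype=np.int64 if integer else float)
        for p in range(data.n_pixels):
            row = data.matrix[p]
            nz = np.flatnonzero(row)
            if nz.size == 0:
                continue
            if not validflat[p] or Dflat[p] == 1.0:
                out[p, nz] = row[nz]
                continue
            tb, tv = _rebin_row(data.index_map[nz], row[nz].astype(float), Dflat[p])
            inside = (tb >= 0) & (tb < n_bins)
            tb2 = np.where(inside, tb, 0)
            tpos = np.where(inside, pos[tb2], -1)
            keep = tpos >= 0
            lost += float(tv[~keep].sum())
            acc = np.zeros(data.n_points)
            np.add.at(acc, tpos[keep], tv[keep])
            if integer:
                out[p] = _largest_remainder(acc, int(round(acc.sum())))
            else:
                out[p] = acc
        if lost:
            logger.warning("apply_correction: %.1f counts fell outside the "
                           "retained segments/window", lost)
        info = dict(data.info)
        info["lost_counts"] = lost
        return CompressedSpectra(
            matrix=out, index_map=data.index_map.copy(), mz_map=data.mz_map.copy(),
            segments=[replace(s) for s in data.segments], geom=data.geom,
            nx=data.nx, ny=data.ny, info=info,
        )

    # raw cube
    n_bins = data.n_bins
    csr = data.counts
    rows_out: List[np.ndarray] = []
    cols_out: List[np.ndarray] = []
    vals_out: List[np.ndarray] = []
    for p in range(data.n_pixels):
        start, end = csr.indptr[p], csr.indptr[p + 1]
        if start == end:
            continue
        idx = csr.indices[start:end].astype(np.int64)
        cts = csr.data[start:end].astype(float)
        if not validflat[p] or Dflat[p] == 1.0:
            tb, tv = idx, cts
        else:
            tb, tv = _rebin_row(idx, cts, Dflat[p])
        inside = (tb >= 0) & (tb < n_bins)
        lost += float(tv[~inside].sum())
        tb, tv = tb[inside], tv[inside]
        if integer:
            tv = _largest_remainder(tv, int(round(tv.sum()))).astype(float)
            keep = tv > 0
            tb, tv = tb[keep], tv[keep]
        if tb.size:
            rows_out.append(np.full(tb.size, p, dtype=np.int64))
            cols_out.append(tb)
            vals_out.append(tv)
    if rows_out:
        counts = sp.coo_matrix(
            (np.concatenate(vals_out),
             (np.concatenate(rows_out), np.concatenate(cols_out))),
            shape=(data.n_pixels, n_bins),
        ).tocsr()
        counts.sum_duplicates()
        if integer:
            counts = counts.astype(np.int64)
    else:
        counts = sp.csr_matrix((data.n_pixels, n_bins), dtype=np.int64)
    if lost:
        logger.warning("apply_correction: %.1f counts fell beyond the window", lost)
    meta = dict(data.metadata)
    meta["lost_counts"] = lost
    return RawSpectrumImage(counts=counts, nx=data.nx, ny=data.ny,
                            geom=data.geom, metadata=meta)


def reconstruct_topography(
    fld: CorrectionField, ref: IonSpecies, geom: InstrumentGeometry
) -> TopographyMap:
    """Invert the reference-peak shift into an emission-height map.

    ``dh = h_ex * (1 − ((t_ac(0) − ΔT)/t_ac(0))²)`` with ``t_ac(0)``
    computed from the instrument geometry for the reference species
    (it cannot be measured directly).  Negative shifts — centroid noise
    around the substrate level — are clamped to zero height; shifts at
    or beyond ``t_ac(0)`` are unphysical and invalidate the pixel.
    """
    t_ac0 = acceleration_time(ref.mass, geom)
    dT = np.where(fld.dT < 0, 0.0, fld.dT)
    valid = fld.valid.copy()
    bad = valid & (fld.dT >= t_ac0)
    if bad.any():
        logger.warning("reconstruct_topography: %d pixels with unphysical "
                       "shift >= t_ac(0) invalidated", int(bad.sum()))
        valid[bad] = False
    dT = np.where(valid, dT, 0.0)
    dh = geom.h_ex * (1.0 - ((t_ac0 - dT) / t_ac0) ** 2)
    return TopographyMap(dh=dh, valid=valid, ref_species=ref, geom=geom)
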