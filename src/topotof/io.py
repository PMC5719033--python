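"""On-disk containers and interchange formats.

The native container is HDF5: raw cubes are stored as compressed sparse
rows (the 2,000,000-bin raw axis is overwhelmingly empty), compressed
cubes as dense matrices with their calibration maps and segment table,
and the instrument geometry as an embedded JSON block.  Every write
records a processing log.  Interchange with other MSI software goes
through continuous-mode imzML (one shared m/z axis for all pixels);
maps export as 32-bit float TIFF and CSV, tables as CSV with a fixed
9-significant-digit numeric format so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import json
import warnings
from typing import List, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp
import tifffile

from .compress import CompressedSpectra, MassSegment
from .geometry import InstrumentGeometry, tof_from_mass
from .simulate import RawSpectrumImage

FORMAT_VERSION = 1
_FLOAT_FMT = "%.9g"


# --- HDF5 container ----------------------------------------------------------

def write_container(
    path,
    raw: Optional[RawSpectrumImage] = None,
    compressed: Optional[CompressedSpectra] = None,
    log: Optional[List[dict]] = None,
) -> None:
    """Write raw and/or compressed cubes to an HDF5 container."""
    if raw is None and compressed is None:
        raise ValueError("nothing to write: provide raw and/or compressed data")
    geom = raw.geom if raw is not None else compressed.geom
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["geometry"] = geom.to_json()
        f.attrs["log"] = json.dumps(log or [], sort_keys=True)
        if raw is not None:
            g = f.create_group("raw")
            csr = raw.counts.tocsr()
            g.create_dataset("data", data=csr.data, compression="gzip")
            g.create_dataset("indices", data=csr.indices, compression="gzip")
            g.create_dataset("indptr", data=csr.indptr, compression="gzip")
            g.attrs["nx"] = raw.nx
            g.attrs["ny"] = raw.ny
            g.attrs["n_bins"] = raw.n_bins
            g.attrs["metadata"] = json.dumps(raw.metadata, sort_keys=True, default=str)
        if compressed is not None:
            g = f.create_group("compressed")
            g.create_dataset("matrix", data=np.asarray(compressed.matrix),
                             compression="gzip")
            g.create_dataset("index_map", data=compressed.index_map)
            g.create_dataset("mz_map", data=compressed.mz_map)
            g.attrs["nx"] = compressed.nx
            g.attrs["ny"] = compressed.ny
            g.attrs["info"] = json.dumps(compressed.info, sort_keys=True, default=str)
            seg = np.array(
                [(s.start_bin, s.end_bin, s.total_counts, s.label or "")
                 for s in compressed.segments],
                dtype=[("start_bin", "i8"), ("end_bin", "i8"),
                       ("total_counts", "i8"), ("label", "S64")],
            )
            g.create_dataset("segments", data=seg)


def read_container(
    path,
) -> Tuple[Optional[RawSpectrumImage], Optional[CompressedSpectra]]:
    """Read a container back; returns (raw, compressed), either may be None."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ValueError(
                f"container format version mismatch: found {version}, "
                f"expected {FORMAT_VERSION}"
            )
        if "geometry" not in f.attrs:
            raise ValueError("container is missing the 'geometry' metadata block")
        geom = InstrumentGeometry.from_json(f.attrs["geometry"])
        raw = compressed = None
        if "raw" in f:
            g = f["raw"]
            nx, ny = int(g.attrs["nx"]), int(g.attrs["ny"])
            counts = sp.csr_matrix(
                (g["data"][:], g["indices"][:], g["indptr"][:]),
                shape=(nx * ny, int(g.attrs["n_bins"])),
            )
            raw = RawSpectrumImage(
                counts=counts, nx=nx, ny=ny, geom=geom,
                metadata=json.loads(g.attrs.get("metadata", "{}")),
            )
        if "compressed" in f:
            g = f["compressed"]
            seg_rows = g["segments"][:]
            segments = [
                MassSegment(int(r["start_bin"]), int(r["end_bin"]),
                            int(r["total_counts"]),
                            r["label"].decode() or None)
                for r in seg_rows
            ]
            compressed = CompressedSpectra(
                matrix=g["matrix"][:],
                index_map=g["index_map"][:],
                mz_map=g["mz_map"][:],
                segments=segments,
                geom=geom,
                nx=int(g.attrs["nx"]),
                ny=int(g.attrs["ny"]),
                info=json.loads(g.attrs.get("info", "{}")),
            )
        return raw, compressed


# --- imzML interchange -------------------------------------------------------

def export_imzml(c: CompressedSpectra, path) -> None:
    """Write continuous-mode imzML: one shared m/z axis, one spectrum per pixel.

    Internal pixel (0, 0) maps to imzML coordinate (1, 1) per the imzML
    1-based convention.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if c.n_points == 0:
        # imzML cannot hold 0-length spectra; emit a 1-point placeholder axis
        warnings.warn("exporting imzML with 0 spectral points: writing a "
                      "single-point placeholder axis", stacklevel=2)
        mz = np.array([1.0])
        matrix = np.zeros((c.n_pixels, 1), dtype=np.float32)
    else:
        mz = c.mz_map.astype(np.float64)
        matrix = c.matrix
    with ImzMLWriter(str(path), mode="continuous") as w:
        for iy in range(c.ny):
            for ix in range(c.nx):
                inten = np.asarray(matrix[iy * c.nx + ix], dtype=np.float32)
                w.addSpectrum(mz, inten, (ix + 1, iy + 1))


def import_imzml(
    path, geom: Optional[InstrumentGeometry] = None,
    mz_tolerance: float = 1e-6,
) -> CompressedSpectra:
    """Read an imzML file back into compressed spectra.

    All pixels must share one m/z axis (continuous mode, or processed
    mode whose per-pixel axes agree within ``mz_tolerance`` relative).
    When the instrument geometry is supplied, the raw-bin index map is
    rebuilt from the inverse TOF calibration; segments are reformed as
    the maximal contiguous runs of the recovered bin indices.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    geom = geom or InstrumentGeometry()
    parser = ImzMLParser(str(path))
    coords = np.asarray([(x, y) for x, y, *_ in parser.coordinates])
    nx = int(coords[:, 0].max())
    ny = int(coords[:, 1].max())
    mz0, _ = parser.getspectrum(0)
    mz0 = np.asarray(mz0, dtype=float)
    matrix = np.zeros((nx * ny, len(mz0)))
    for i, (x, y) in enumerate(coords):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=float)
        if len(mz) != len(mz0) or (
            len(mz0) and np.max(np.abs(mz - mz0) / np.maximum(mz0, 1e-300))
            > mz_tolerance
        ):
            raise ValueError(
                "per-pixel m/z axes differ beyond tolerance; only a shared "
                "(continuous-mode) axis is supported"
            )
        matrix[(y - 1) * nx + (x - 1)] = inten
    # rebuild raw-bin indices from the inverse calibration
    t = tof_from_mass(mz0, geom) if len(mz0) else np.zeros(0)
    index_map = np.round(np.atleast_1d(t) / geom.tof_bin - 0.5).astype(np.int64)
    segments = []
    if len(index_map):
        brk = np.flatnonzero(np.diff(index_map) > 1)
        starts = np.r_[index_map[0], index_map[brk + 1]]
        ends = np.r_[index_map[brk], index_map[-1]] + 1
        for s, e in zip(starts, ends):
            segments.append(MassSegment(int(s), int(e)))
    return CompressedSpectra(
        matrix=matrix, index_map=index_map, mz_map=mz0, segments=segments,
        geom=geom, nx=nx, ny=ny, info={"source": str(path)},
    )


# --- flat exports ------------------------------------------------------------

def export_tiff(path, map2d: np.ndarray) -> None:
    """Write a 2-D map as 32-bit float TIFF."""
    tifffile.imwrite(str(path), np.asarray(map2d, dtype=np.float32))


def map_to_csv(path, map2d: np.ndarray, valid: Optional[np.ndarray] = None) -> None:
    """Write a 2-D map as long-form CSV (x, y, value, valid)."""
    m = np.asarray(map2d, dtype=float)
    ny, nx = m.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    v = np.ones_like(m, dtype=bool) if valid is None else np.asarray(valid, bool)
    df = pd.DataFrame({
        "x": xx.ravel(), "y": yy.ravel(),
        "value": m.ravel(), "valid": v.ravel().astype(int),
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def segments_to_csv(path, segments: Sequence[MassSegment],
                    geom: InstrumentGeometry) -> None:
    rows = []
    for s in segments:
        lo, hi = s.mz_range(geom)
        rows.append({
            "start_bin": s.start_bin, "end_bin": s.end_bin,
            "start_mz": lo, "end_mz": hi,
            "total_counts": s.total_counts, "label": s.label or "",
        })
    pd.DataFrame(rows, columns=["start_bin", "end_bin", "start_mz", "end_mz",
                                "total_counts", "label"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def eigenvectors_to_csv(path, result) -> None:
    """Eigenvectors as CSV: point index, m/z, one column per component."""
    data = {"point": np.flatnonzero(result.included),
            "mz": result.mz_included}
    for i in range(result.n_components):
        data[f"component_{i + 1}"] = result.eigenvectors[i]
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def scree_to_csv(path, result) -> None:
    pd.DataFrame({
        "component": np.arange(1, result.n_components + 1),
        "explained_variance_fraction": result.explained_variance,
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


def profile_to_csv(path, positions: np.ndarray, values: np.ndarray) -> None:
    """Two-column CSV line profile (position in meters, value)."""
    pd.DataFrame({"position": positions, "value": values}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)
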