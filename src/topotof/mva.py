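"""Principal component analysis of compressed (corrected) spectra.

Each pixel's compressed spectrum is a vector in point space; PCA
deconvolves the cube into orthonormal eigenvectors (spectral
signatures) and loading maps (their spatial abundances).  The default
follows the uncentered, unwhitened convention: without centering, the
first component tracks the averaged mass spectrum and the later ones
capture compositional contrast.  Peaks known to be saturated (K+) or
instrument-injected (Cs+, Cs2+ from the sputter source) are excluded
before the decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .compress import CompressedSpectra


@dataclass
class SpectraMatrix:
    """Pixel-by-point data matrix with a point-inclusion mask."""

    matrix: np.ndarray
    included: np.ndarray
    nx: int
    ny: int
    mz_map: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.included = np.asarray(self.included, dtype=bool)
        if self.included.shape != (self.matrix.shape[1],):
            raise ValueError("inclusion mask length must equal n_points")
        if self.matrix.shape[0] != self.nx * self.ny:
            raise ValueError("matrix rows must equal nx*ny")
        if not self.included.any():
            raise ValueError("all spectral points excluded — nothing to analyse")

    @property
    def n_included(self) -> int:
        return int(self.included.sum())


@dataclass
class PCAResult:
    """Eigenvectors over included points, loading maps, variance fractions."""

    eigenvectors: np.ndarray          # (k, n_included), orthonormal rows
    loadings: np.ndarray              # (k, ny, nx)
    explained_variance: np.ndarray    # fractions, non-increasing, sum <= 1
    singular_values: np.ndarray
    centered: bool
    mean_: Optional[np.ndarray]
    included: np.ndarray
    mz_included: np.ndarray
    nx: int
    ny: int

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[0]


def as_matrix(data: CompressedSpectra) -> SpectraMatrix:
    """Wrap compressed spectra as an analysis matrix with all points included."""
    return SpectraMatrix(
        matrix=data.matrix.astype(float),
        included=np.ones(data.n_points, dtype=bool),
        nx=data.nx,
        ny=data.ny,
        mz_map=data.mz_map.copy(),
    )


def exclude_species(data: CompressedSpectra, labels: Sequence[str]) -> SpectraMatrix:
    """Mask out all points of the segments carrying the given labels.

    Typical exclusions: the saturated K+ peak and the sputter-source
    Cs+/Cs2+ peaks, none of which reflect sample chemistry.  Unknown
    labels raise with the list of known ones.
    """
    m = as_matrix(data)
    known = sorted({s.label for s in data.segments if s.label})
    for label in labels:
        seg = None
        for s in data.segments:
            if s.label is not None and label in s.label.split(";"):
                seg = s
                break
        if seg is None:
            raise KeyError(f"unknown species label {label!r}; known: {known}")
        m.included[data.segment_points(seg)] = False
    if not m.included.any():
        raise ValueError("all spectral points excluded — nothing to analyse")
    return m


def _fix_signs(vectors: np.ndarray, scores: np.ndarray):
    """Resolve SVD sign ambiguity: largest-|·| element of each eigenvector > 0."""
    for i in range(vectors.shape[0]):
        j = np.argmax(np.abs(vectors[i]))
        if vectors[i, j] < 0:
            vectors[i] *= -1.0
            scores[:, i] *= -1.0
    return vectors, scores


def pca(m: SpectraMatrix, n_components: int = 6, center: bool = False) -> PCAResult:
    """Deterministic SVD-based PCA of the included points.

    With ``center=False`` (default) the decomposition is of the raw
    data matrix, so explained-variance fractions are fractions of the
    total sum of squares and component 1 aligns with the mean spectrum.
    Signs are fixed so each eigenvector's largest-magnitude element is
    positive.
    """
    X = m.matrix[:, m.included]
    n_pixels, n_inc = X.shape
    if not 1 <= n_components <= min(n_pixels, n_inc):
        raise ValueError(
            f"n_components must lie in [1, {min(n_pixels, n_inc)}]"
        )
    mean = None
    if center:
        mean = X.mean(axis=0)
        X = X - mean
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2))
    k = n_components
    vectors = Vt[:k].copy()
    scores = U[:, :k] * s[:k]
    vectors, scores = _fix_signs(vectors, scores)
    ev = (s[:k] ** 2 / total) if total > 0 else np.zeros(k)
    return PCAResult(
        eigenvectors=vectors,
        loadings=scores.T.reshape(k, m.ny, m.nx),
        explained_variance=ev,
        singular_values=s[:k].copy(),
        centered=center,
        mean_=mean,
        included=m.included.copy(),
        mz_included=m.mz_map[m.included],
        nx=m.nx,
        ny=m.ny,
    )


def scree(r: PCAResult) -> np.ndarray:
    """Explained-variance fraction per component (non-increasing)."""
    return r.explained_variance.copy()


def reconstruct(r: PCAResult, k: int) -> SpectraMatrix:
    """Rank-k reconstruction of the included part of the data matrix.

    Returns a matrix over the included points only (all-true mask);
    with k equal to the retained rank of a low-rank input this recovers
    the input to numerical precision.
    """
    if not 1 <= k <= r.n_components:
        raise ValueError(f"k must lie in [1, {r.n_components}]")
    scores = r.loadings[:k].reshape(k, -1).T
    X = scores @ r.eigenvectors[:k]
    if r.centered:
        X = X + r.mean_
    return SpectraMatrix(
        matrix=X,
        included=np.ones(X.shape[1], dtype=bool),
        nx=r.nx,
        ny=r.ny,
        mz_map=r.mz_included.copy(),
    )


def point_biserial(map2d: np.ndarray, mask: np.ndarray) -> float:
    """Point-biserial correlation between a loading map and a binary mask.

    Measures how cleanly a component's spatial loading separates two
    regions (e.g. substrate vs sample); |r| near 1 means the loading is
    essentially the region indicator.
    """
    x = np.asarray(map2d, dtype=float).ravel()
    g = np.asarray(mask, dtype=bool).ravel()
    if g.all() or not g.any():
        raise ValueError("mask must contain both classes")
    n = x.size
    p = g.mean()
    sd = x.std()
    if sd == 0:
        return 0.0
    return float((x[g].mean() - x[~g].mean()) * np.sqrt(p * (1 - p)) / sd)
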