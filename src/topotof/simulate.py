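"""Forward simulator of reflectron ToF-SIMS imaging with known ground truth.

The simulator renders a synthetic scene — a 2-D grid of pixels, each
carrying a surface height and a set of species abundances — into a raw
hyperspectral cube of per-pixel time-of-flight histograms, applying the
same flight physics the correction stage later inverts.  Because the
topography and composition are known exactly, every downstream stage
(compression, shift correction, topography reconstruction, PCA) can be
validated against ground truth.

The default scene emulates a dried seedling root on a flat silica
substrate: a half-cylindrical ridge ≈200 µm tall carrying the root
chemistry (Na+, Mg+, K+, Ca+ and a few organic masses at 150–300 u),
Si+/Si2+ confined to the substrate, and Cs+/Cs2+ everywhere (implanted
by the sputter gun; Cs+ is globally the most intense peak and serves as
the shift-correction reference).

Counting statistics follow a Poisson model — the conventional choice for
ion-counting detectors — with per-ion Gaussian arrival-time jitter that
realises a finite mass resolving power m/Δm, and floor quantization to
the 50 ps time-to-digital grid.  Two deterministic noiseless modes
exist: delta lines (all expected counts at the centroid bin, exact
integer bookkeeping) and Gaussian lines (the expectation of the
stochastic render — broadened peaks on the quantized grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import scipy.sparse as sp

from .geometry import (
    CA_MONOISOTOPIC,
    CS2_MONOISOTOPIC,
    CS_MONOISOTOPIC,
    InstrumentGeometry,
    IonSpecies,
    K_MONOISOTOPIC,
    MG_MONOISOTOPIC,
    NA_MONOISOTOPIC,
    SI2_MONOISOTOPIC,
    SI_MONOISOTOPIC,
    total_tof,
)

#: FWHM/sigma ratio of a Gaussian.
FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class SpeciesLayer:
    """One species with an expected per-pixel yield and an abundance map.

    The expected count at a pixel is ``mean_yield * abundance``;
    abundance is dimensionless in [0, 1] on the scene grid.
    """

    species: IonSpecies
    mean_yield: float
    abundance: np.ndarray

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.mean_yield < 0:
            raise ValueError("mean_yield must be non-negative")
        if np.any(self.abundance < 0) or np.any(self.abundance > 1):
            raise ValueError("abundance values must lie in [0, 1]")


@dataclass
class SyntheticScene:
    """Pixel grid, topography and composition of a simulated sample.

    ``topography`` holds the emission height dh (m) per pixel, shape
    (ny, nx); layer abundance maps share that shape.  ``resolution_R``
    is the mass resolving power m/Δm (FWHM convention).
    """

    nx: int = 256
    ny: int = 256
    pixel_pitch: float = 500e-6 / 256
    topography: np.ndarray = field(default_factory=lambda: np.zeros((256, 256)))
    layers: List[SpeciesLayer] = field(default_factory=list)
    resolution_R: float = 7000.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.topography = np.asarray(self.topography, dtype=float)
        if self.topography.shape != (self.ny, self.nx):
            raise ValueError("topography shape must be (ny, nx)")
        if np.any(self.topography < 0):
            raise ValueError("topography must be non-negative")
        if not 500.0 <= self.resolution_R <= 50000.0:
            raise ValueError("resolution_R outside the sane range [500, 50000]")
        for layer in self.layers:
            if layer.abundance.shape != (self.ny, self.nx):
                raise ValueError(
                    f"abundance map of {layer.species.label!r} does not match the grid"
                )

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    def to_descriptor(self) -> dict:
        """JSON-serializable scene summary (species table, grid, seed)."""
        return {
            "nx": self.nx,
            "ny": self.ny,
            "pixel_pitch": self.pixel_pitch,
            "resolution_R": self.resolution_R,
            "seed": self.seed,
            "max_height": float(self.topography.max()) if self.topography.size else 0.0,
            "species": [
                {
                    "label": layer.species.label,
                    "mass": layer.species.mass,
                    "mean_yield": layer.mean_yield,
                }
                for layer in self.layers
            ],
        }


@dataclass
class RawSpectrumImage:
    """Raw hyperspectral cube: a TOF histogram per pixel.

    ``counts`` is a sparse CSR matrix of shape (nx*ny, n_bins) holding
    non-negative counts; pixels are row-major with x fastest.  Event
    cubes carry integers; expectation cubes (noiseless Gaussian-line
    renders) carry floats.  At the default 100 µs window and 50 ps bins
    the raw axis has 2,000,000 samples per pixel, so the cube is kept
    sparse throughout.
    """

    counts: sp.csr_matrix
    nx: int
    ny: int
    geom: InstrumentGeometry
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.shape != (self.nx * self.ny, self.geom.n_bins):
            raise ValueError("counts shape must be (nx*ny, n_bins)")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.geom.n_bins

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())

    def pixel_spectrum(self, ix: int, iy: int) -> np.ndarray:
        """Dense TOF histogram of pixel (ix, iy)."""
        return np.asarray(self.counts[iy * self.nx + ix].todense()).ravel()

    def pixel_totals(self) -> np.ndarray:
        """Per-pixel total counts on the (ny, nx) grid."""
        return np.asarray(self.counts.sum(axis=1)).reshape(self.ny, self.nx)


# --- default species palette -------------------------------------------------
# Yields chosen so Cs+ is globally the most intense peak (it is the
# shift-correction reference); organics spaced >1 u apart so all peaks
# are resolved at the default R = 7000.

ROOT_SPECIES = (
    (IonSpecies("Na+", NA_MONOISOTOPIC), 80.0),
    (IonSpecies("Mg+", MG_MONOISOTOPIC), 40.0),
    (IonSpecies("K+", K_MONOISOTOPIC), 150.0),
    (IonSpecies("Ca+", CA_MONOISOTOPIC), 60.0),
    (IonSpecies("org185+", 185.0), 30.0),
    (IonSpecies("org231+", 231.0), 25.0),
    (IonSpecies("org279+", 279.0), 20.0),
)
SUBSTRATE_SPECIES = (
    (IonSpecies("Si+", SI_MONOISOTOPIC), 200.0),
    (IonSpecies("Si2+", SI2_MONOISOTOPIC), 50.0),
)
GLOBAL_SPECIES = (
    (IonSpecies("Cs+", CS_MONOISOTOPIC), 300.0),
    (IonSpecies("Cs2+", CS2_MONOISOTOPIC), 60.0),
)


def half_cylinder_profile(nx: int, pixel_pitch: float, height: float,
                          width_px: int) -> np.ndarray:
    """Height profile across a half-cylindrical ridge centred on the grid.

    ``dh(d) = height * sqrt(1 - (2 d / w)^2)`` inside the footprint of
    width ``width_px`` pixels, 0 outside; symmetric about the
    centerline.
    """
    if width_px > nx:
        raise ValueError("root footprint wider than the grid")
    x = np.arange(nx) - (nx - 1) / 2.0
    half_w = width_px / 2.0
    u = x / half_w
    profile = np.zeros(nx)
    inside = np.abs(u) < 1.0
    profile[inside] = height * np.sqrt(1.0 - u[inside] ** 2)
    return profile


def make_root_scene(
    height: float = 200e-6,
    root_width_px: Optional[int] = None,
    seed: int = 0,
    nx: int = 256,
    ny: int = 256,
    pixel_pitch: Optional[float] = None,
    resolution_R: float = 7000.0,
    geom: Optional[InstrumentGeometry] = None,
) -> SyntheticScene:
    """Build the reference scene: a root-like half-cylinder on a flat substrate.

    The ridge runs along y with a half-cylindrical cross-section of peak
    height ``height`` (default 200 µm, the height contrast of the study
    sample).  By default the footprint width is the geometric
    half-cylinder width ``2*height/pixel_pitch``.  Root chemistry (Na,
    Mg, K, Ca, organics) is confined to the ridge, Si to the substrate,
    Cs everywhere.  Deterministic given ``seed``.
    """
    geom = geom or InstrumentGeometry()
    if not 0 <= height < geom.h_ex:
        raise ValueError("height must lie in [0, h_ex)")
    if pixel_pitch is None:
        pixel_pitch = 500e-6 / nx
    if root_width_px is None:
        root_width_px = max(2, int(round(2.0 * height / pixel_pitch))) if height > 0 else nx // 2
    profile = half_cylinder_profile(nx, pixel_pitch, height, root_width_px)
    topo = np.tile(profile, (ny, 1))
    root_mask = (profile > 0)[None, :] * np.ones((ny, 1))
    substrate_mask = 1.0 - root_mask

    layers = [
        SpeciesLayer(species, y, root_mask) for species, y in ROOT_SPECIES
    ]
    layers += [
        SpeciesLayer(species, y, substrate_mask) for species, y in SUBSTRATE_SPECIES
    ]
    layers += [
        SpeciesLayer(species, y, np.ones((ny, nx))) for species, y in GLOBAL_SPECIES
    ]
    return SyntheticScene(
        nx=nx,
        ny=ny,
        pixel_pitch=pixel_pitch,
        topography=topo,
        layers=layers,
        resolution_R=resolution_R,
        seed=seed,
    )


def two_region_scene(
    nx: int = 64,
    ny: int = 64,
    seed: int = 0,
    resolution_R: float = 7000.0,
) -> SyntheticScene:
    """Flat two-region scene (substrate Si vs root chemistry), no topography.

    Useful for chemically driven PCA tests with no confounding peak
    shifts: the compositional contrast is the only source of variance.
    """
    scene = make_root_scene(
        height=0.0, root_width_px=nx // 2, seed=seed, nx=nx, ny=ny,
        resolution_R=resolution_R,
    )
    # height=0 leaves the root mask empty; paint the central band instead
    band = np.zeros((ny, nx))
    lo, hi = nx // 4, nx - nx // 4
    band[:, lo:hi] = 1.0
    for layer in scene.layers:
        label = layer.species.label
        if label.startswith(("Si",)):
            layer.abundance = 1.0 - band
        elif label.startswith(("Cs",)):
            layer.abundance = np.ones((ny, nx))
        else:
            layer.abundance = band
    return scene


def _expected_counts(scene: SyntheticScene) -> np.ndarray:
    """Stack of per-layer expected-count maps, shape (n_layers, ny, nx)."""
    return np.stack([l.mean_yield * l.abundance for l in scene.layers])


def render(
    scene: SyntheticScene,
    geom: Optional[InstrumentGeometry] = None,
    noiseless: bool = False,
    lineshape: str = "delta",
) -> RawSpectrumImage:
    """Render a scene into a raw TOF cube.

    Per pixel and species, the arrival-time centroid is the
    height-dependent total TOF; expected counts are
    ``mean_yield * abundance``.

    noiseless
        Fully deterministic render.  With ``lineshape="delta"`` (the
        default) ``round(λ)`` counts are deposited at the centroid bin
        with no jitter — exact integer bookkeeping, but each peak
        occupies a single 50 ps bin, the worst case for centroid
        quantization.  With ``lineshape="gaussian"`` the cube is the
        *expectation* of the stochastic render: λ spread over bins by
        the integrated Gaussian line shape at the scene's resolving
        power (float counts, still quantized to the TDC grid) — the
        infinite-statistics limit, matching how a real instrument's
        broadened peaks sample the 50 ps grid.
    stochastic (default)
        Counts ~ Poisson(λ); each ion's arrival time receives Gaussian
        jitter with ``σ_t = T / (2 R · 2.3548)`` so the peak FWHM
        realises the scene's mass resolving power (Δt/t = Δm/2m), then
        is floor-quantized to the TDC grid.  Reproducible from
        ``scene.seed``; ``lineshape`` is ignored.
    """
    if lineshape not in ("delta", "gaussian"):
        raise ValueError("lineshape must be 'delta' or 'gaussian'")
    geom = geom or InstrumentGeometry()
    if np.any(scene.topography >= geom.h_ex):
        raise ValueError("scene topography exceeds the extractor gap")
    n_pix = scene.n_pixels
    n_bins = geom.n_bins
    rng = np.random.default_rng(scene.seed)

    rows: list = []
    cols: list = []
    vals: list = []
    for layer in scene.layers:
        lam = (layer.mean_yield * layer.abundance).ravel()
        active = lam > 0
        if not active.any():
            continue
        dh = scene.topography.ravel()[active]
        T = total_tof(layer.species.mass, dh, geom)
        if np.any(T >= geom.t_window) or np.any(T < 0):
            raise ValueError(
                f"species {layer.species.label!r} arrives outside the "
                "acquisition window"
            )
        pix_idx = np.flatnonzero(active)
        if noiseless and lineshape == "delta":
            n = np.round(lam[active]).astype(np.int64)
            bins = np.floor(T / geom.tof_bin).astype(np.int64)
            keep = n > 0
            rows.append(pix_idx[keep])
            cols.append(bins[keep])
            vals.append(n[keep])
        elif noiseless:
            # expected histogram: per-bin integral of the Gaussian line
            from scipy.special import ndtr

            sigma = T / (2.0 * scene.resolution_R * FWHM_SIGMA)
            kmax = int(np.ceil(8.0 * sigma.max() / geom.tof_bin)) + 1
            b0 = np.floor(T / geom.tof_bin).astype(np.int64)
            offs = np.arange(-kmax, kmax + 1)
            bins = b0[:, None] + offs[None, :]
            edges_lo = bins * geom.tof_bin
            z_lo = (edges_lo - T[:, None]) / sigma[:, None]
            z_hi = (edges_lo + geom.tof_bin - T[:, None]) / sigma[:, None]
            w = lam[active][:, None] * (ndtr(z_hi) - ndtr(z_lo))
            keep = (w > 1e-12) & (bins >= 0) & (bins < n_bins)
            rows.append(np.repeat(pix_idx, keep.sum(axis=1)))
            cols.append(bins[keep])
            vals.append(w[keep])
        else:
            n = rng.poisson(lam[active])
            total = int(n.sum())
            if total == 0:
                continue
            t_centroid = np.repeat(T, n)
            sigma = t_centroid / (2.0 * scene.resolution_R * FWHM_SIGMA)
            t = t_centroid + rng.normal(0.0, 1.0, total) * sigma
            bins = np.floor(t / geom.tof_bin).astype(np.int64)
            ok = (bins >= 0) & (bins < n_bins)  # jitter tails beyond the window are dropped
            rows.append(np.repeat(pix_idx, n)[ok])
            cols.append(bins[ok])
            vals.append(np.ones(int(ok.sum()), dtype=np.int64))

    dtype = float if (noiseless and lineshape == "gaussian") else np.int64
    if rows:
        counts = sp.coo_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_pix, n_bins),
            dtype=dtype,
        ).tocsr()
        counts.sum_duplicates()
    else:
        counts = sp.csr_matrix((n_pix, n_bins), dtype=dtype)

    meta = {
        "scene": scene.to_descriptor(),
        "noiseless": bool(noiseless),
        "lineshape": lineshape if noiseless else "gaussian",
    }
    return RawSpectrumImage(counts=counts, nx=scene.nx, ny=scene.ny,
                            geom=geom, metadata=meta)
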