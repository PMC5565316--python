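"""Synthetic TMRE stacks with known mitochondrial ground truth.

Ellipsoidal mitochondria are scattered inside a ganglion-shaped ellipsoid,
rasterized on an anisotropic voxel grid, modulated over time by an
independent mean-reverting (Ornstein-Uhlenbeck) intensity process per
mitochondrion, blurred by a Gaussian PSF, offset by a constant background
and dimmed by a multiplicative per-frame bleach factor (first frame
brightest). Centres, voxelized volumes and per-frame true mean intensities
are returned as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from calmito.mito.stack import GanglionMask, MitoStack


@dataclass
class MitoSimParams:
    """Study conditions for one simulated stack.

    shape_vox is (T, Z, Y, X); the ganglion ellipsoid defaults to a centred
    ellipsoid filling 80% of each half-extent. Radii are sampled per axis
    from N(mean, sd), clipped below at 0.15 um.
    """

    n_mito: int = 150
    mito_radii_um: tuple[float, float] = (0.5, 0.08)  # (mean, sd) per axis
    base_intensity: float = 1000.0
    fluctuation_cv_pct: float = 8.0
    fluctuation_tau_s: float = 5.0
    psf_sigma_um: tuple[float, float, float] = (0.6, 0.25, 0.25)  # (z, y, x)
    background_level: float = 100.0
    bleach_rate_per_frame: float = 0.0
    noise_sd: float = 0.0
    voxel_size_um: tuple[float, float, float] = (0.5, 0.25, 0.25)
    shape_vox: tuple[int, int, int, int] = (1, 40, 160, 160)
    ganglion_center_um: tuple[float, float, float] | None = None
    ganglion_radii_um: tuple[float, float, float] | None = None
    min_separation_um: float = 0.0
    frame_interval_s: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_mito < 1:
            raise ValueError("n_mito must be >= 1")
        mean_r, sd_r = self.mito_radii_um
        if mean_r <= 0 or sd_r < 0:
            raise ValueError("mitochondrion radii must be positive")
        if any(s < 0 for s in self.psf_sigma_um):
            raise ValueError("PSF sigma must be >= 0")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if len(self.shape_vox) != 4 or min(self.shape_vox) < 1:
            raise ValueError("shape_vox must be a positive (T, Z, Y, X)")
        if not (0.0 <= self.bleach_rate_per_frame < 1.0):
            raise ValueError("bleach_rate_per_frame must lie in [0, 1)")
        if self.fluctuation_cv_pct < 0 or self.background_level < 0:
            raise ValueError("fluctuation CV and background must be >= 0")
        if self.fluctuation_tau_s <= 0 or self.frame_interval_s <= 0:
            raise ValueError("time constants must be positive")

    def extent_um(self) -> tuple[float, float, float]:
        _, nz, ny, nx = self.shape_vox
        vz, vy, vx = self.voxel_size_um
        return nz * vz, ny * vy, nx * vx

    def ganglion(self) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
        ext = self.extent_um()
        center = self.ganglion_center_um or tuple(e / 2 for e in ext)
        radii = self.ganglion_radii_um or tuple(0.8 * e / 2 for e in ext)
        if any(r <= 0 for r in radii):
            raise ValueError("ganglion radii must be positive")
        return center, radii


@dataclass
class MitoGroundTruth:
    """One record per simulated mitochondrion, plus process metadata.

    mitochondria columns: mito_id, center (z/y/x um), radii (z/y/x um),
    voxel_volume_um3 (rasterized), n_voxels.
    true_mean_intensity: (N, T) per-frame true intensity of each
    mitochondrion (OU modulation and bleach included, background excluded).
    """

    mitochondria: pd.DataFrame
    true_mean_intensity: np.ndarray
    ganglion_center_um: tuple[float, float, float]
    ganglion_radii_um: tuple[float, float, float]
    params: MitoSimParams = field(repr=False, default=None)  # type: ignore[assignment]


def _sample_centres(
    params: MitoSimParams,
    rng: np.random.Generator,
    center: np.ndarray,
    radii: np.ndarray,
) -> np.ndarray:
    """Uniform centres inside the ganglion ellipsoid, optionally separated."""
    centres: list[np.ndarray] = []
    max_tries = 20000 * params.n_mito
    tries = 0
    while len(centres) < params.n_mito:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {params.n_mito} mitochondria with "
                f"min_separation_um={params.min_separation_um} inside the ganglion"
            )
        p = center + radii * rng.uniform(-1.0, 1.0, 3)
        if (((p - center) / radii) ** 2).sum() > 1.0:
            continue
        if params.min_separation_um > 0 and centres:
            tree = cKDTree(np.array(centres))
            if tree.query_ball_point(p, r=params.min_separation_um):
                continue
        centres.append(p)
    return np.array(centres)


def _ou_paths(
    n: int, t: int, cv: float, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """AR(1) discretization of an OU process, mean 1, stationary sd cv.

    x[t+1] = 1 + phi (x[t] - 1) + sqrt(1 - phi^2) cv e, starting from the
    stationary law; clipped at 0.05 so intensities stay positive.
    """
    x = np.empty((n, t))
    x[:, 0] = 1.0 + cv * rng.standard_normal(n)
    innov_sd = cv * np.sqrt(1.0 - phi**2)
    for k in range(1, t):
        x[:, k] = 1.0 + phi * (x[:, k - 1] - 1.0) + innov_sd * rng.standard_normal(n)
    return np.clip(x, 0.05, None)


def simulate_mito_stack(
    params: MitoSimParams,
) -> tuple[MitoStack, GanglionMask, MitoGroundTruth]:
    """Render a stack under the stated conditions and return its truth.

    Ground-truth volumes are the rasterized (voxel-count) volumes, i.e.
    exactly what a perfect thresholding segmentation of the unblurred image
    would measure.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_t, nz, ny, nx = params.shape_vox
    vsize = np.asarray(params.voxel_size_um)
    g_center, g_radii = params.ganglion()
    centres = _sample_centres(params, rng, np.asarray(g_center), np.asarray(g_radii))

    mean_r, sd_r = params.mito_radii_um
    radii = np.clip(rng.normal(mean_r, sd_r, (params.n_mito, 3)), 0.15, None)

    # rasterize each ellipsoid on its bounding sub-grid (voxel-centre test)
    base = np.zeros((nz, ny, nx))
    masks: list[tuple[tuple[slice, slice, slice], np.ndarray]] = []
    n_vox = np.zeros(params.n_mito, dtype=int)
    shape3 = np.array([nz, ny, nx])
    for i in range(params.n_mito):
        lo = np.maximum(np.floor((centres[i] - radii[i]) / vsize).astype(int), 0)
        hi = np.minimum(np.ceil((centres[i] + radii[i]) / vsize).astype(int) + 1, shape3)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        grids = np.ogrid[sl]
        acc = np.zeros(tuple(b - a for a, b in zip(lo, hi)))
        for g, v, c, r in zip(grids, vsize, centres[i], radii[i]):
            acc = acc + (((g + 0.5) * v - c) / r) ** 2
        m = acc <= 1.0
        masks.append((sl, m))
        n_vox[i] = int(m.sum())

    # temporal modulation: OU fluctuation x bleach decay
    cv = params.fluctuation_cv_pct / 100.0
    if cv > 0 and n_t > 1:
        phi = float(np.exp(-params.frame_interval_s / params.fluctuation_tau_s))
        fluct = _ou_paths(params.n_mito, n_t, cv, phi, rng)
    else:
        fluct = np.ones((params.n_mito, n_t))
    bleach = (1.0 - params.bleach_rate_per_frame) ** np.arange(n_t)
    true_intensity = params.base_intensity * fluct * bleach[None, :]  # (N, T)

    sigma_vox = np.asarray(params.psf_sigma_um) / vsize
    frames = np.empty((n_t, nz, ny, nx), dtype=np.float64)
    for t in range(n_t):
        vol = base.copy()
        for i, (sl, m) in enumerate(masks):
            vol[sl][m] += true_intensity[i, t]
        if np.any(sigma_vox > 0):
            vol = ndi.gaussian_filter(vol, sigma_vox, mode="nearest")
        # background = detector offset + stray light; it does not bleach
        vol = vol + params.background_level
        if params.noise_sd > 0:
            vol = np.clip(vol + rng.normal(0.0, params.noise_sd, vol.shape), 0.0, None)
        frames[t] = vol

    stack = MitoStack(
        voxels=frames.astype(np.float32),
        voxel_size_um=params.voxel_size_um,
        frame_interval_s=params.frame_interval_s,
    )
    mask = GanglionMask.from_ellipsoid(
        (nz, ny, nx), params.voxel_size_um, g_center, g_radii
    )
    voxvol = float(np.prod(vsize))
    truth = MitoGroundTruth(
        mitochondria=pd.DataFrame(
            {
                "mito_id": np.arange(params.n_mito),
                "center_z_um": centres[:, 0],
                "center_y_um": centres[:, 1],
                "center_x_um": centres[:, 2],
                "radius_z_um": radii[:, 0],
                "radius_y_um": radii[:, 1],
                "radius_x_um": radii[:, 2],
                "n_voxels": n_vox,
                "voxel_volume_um3": n_vox * voxvol,
            }
        ),
        true_mean_intensity=true_intensity,
        ganglion_center_um=g_center,
        ganglion_radii_um=g_radii,
        params=params,
    )
    return stack, mask, truth
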