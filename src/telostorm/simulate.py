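"""Seeded synthetic data for every pipeline input.

Emulates the acquisition statistics of 3D STORM telomere imaging: each
telomere is a ground-truth structure (uniform ball, triaxial ellipsoid for
the irregular "compact in one dimension" class, or a segmented path) whose
emitters blink a geometric number of times; every localization is the emitter
position plus independent Gaussian localization error (σ_xy in X and Y, σ_z
axially), assigned a uniform random frame over the acquisition, optionally
displaced by a per-frame drift function, with spurious background
localizations added as a homogeneous Poisson process.  Defaults follow the
imaging conditions the pipeline was designed for: σ_xy = 30 nm (the ~30 nm
XY precision taken as 1σ), σ_z = 70/2.355 ≈ 29.7 nm (the ~70 nm Z resolution
taken as a FWHM), 35,000 frames, 700 nm z-depth.

Also generates two-channel nuclear foci images with planted overlap plans,
gel lane profiles with ladder calibrations, and dot-blot grids — all with
recorded ground truth and bit-reproducible seeded randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from telostorm.densitometry import DotBlotGrid, LadderCalibration, LaneProfile
from telostorm.localizations import TRUTH_COLUMN, LocalizationTable

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # 1/2.355

SHAPES = ("sphere", "ellipsoid", "segmented-path")


def rg_uniform_ball(radius: float) -> float:
    """Closed-form radius of gyration of a uniform solid ball, √(3/5)·R."""
    return math.sqrt(3.0 / 5.0) * radius


def rg_uniform_ellipsoid(axes: Sequence[float]) -> float:
    """Rg of a uniform solid ellipsoid with semi-axes (a, b, c): √((a²+b²+c²)/5)."""
    a, b, c = (float(v) for v in axes)
    return math.sqrt((a * a + b * b + c * c) / 5.0)


@dataclass
class StructureModel:
    """Parametric ground-truth structure for one telomere.

    ``axes`` are semi-axis lengths in nm (a sphere uses three equal axes; the
    convenience ``radius`` argument sets them).  ``orientation`` is either
    None (axis-aligned) or a 3×3 rotation matrix.  ``segmented-path``
    structures place emitters along a random polyline spanning the axes box
    with radial jitter — an alternative model of the irregular class.
    """

    structure_id: int
    center: np.ndarray
    shape: str = "sphere"
    axes: np.ndarray | None = None
    radius: float | None = None
    orientation: np.ndarray | None = None
    n_emitters: int = 200

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"shape must be one of {SHAPES}, got {self.shape!r}")
        self.center = np.asarray(self.center, float)
        if self.center.shape != (3,) or not np.isfinite(self.center).all():
            raise ValueError("center must be a finite 3-vector (nm)")
        if self.axes is None:
            if self.radius is None:
                raise ValueError("provide either axes (3 semi-axes) or radius")
            self.axes = np.full(3, float(self.radius))
        self.axes = np.asarray(self.axes, float)
        if self.axes.shape != (3,) or np.any(~np.isfinite(self.axes)) or np.any(self.axes <= 0):
            raise ValueError("axes must be three positive finite semi-axis lengths (nm)")
        if self.shape == "sphere" and not np.allclose(self.axes, self.axes[0]):
            raise ValueError("a sphere requires equal semi-axes")
        if self.orientation is not None:
            self.orientation = np.asarray(self.orientation, float)
            if self.orientation.shape != (3, 3):
                raise ValueError("orientation must be a 3x3 rotation matrix")
            if not np.allclose(self.orientation @ self.orientation.T, np.eye(3), atol=1e-8):
                raise ValueError("orientation matrix must be orthogonal")
        if self.n_emitters < 1:
            raise ValueError("n_emitters must be >= 1")

    def sample_emitters(self, rng: np.random.Generator) -> np.ndarray:
        """Draw the underlying fluorophore positions, (n_emitters, 3) in nm."""
        n = self.n_emitters
        if self.shape in ("sphere", "ellipsoid"):
            # uniform in the unit ball, then anisotropic scaling
            v = rng.standard_normal((n, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            r = rng.random(n) ** (1.0 / 3.0)
            pts = v * r[:, None] * self.axes
        else:  # segmented-path
            n_way = 5
            way = rng.uniform(-self.axes, self.axes, size=(n_way, 3))
            seg = np.diff(way, axis=0)
            seg_len = np.linalg.norm(seg, axis=1)
            cum = np.concatenate([[0.0], np.cumsum(seg_len)])
            s = rng.uniform(0.0, cum[-1], size=n)
            idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, n_way - 2)
            frac = (s - cum[idx]) / np.maximum(seg_len[idx], 1e-12)
            pts = way[idx] + seg[idx] * frac[:, None]
            pts += rng.normal(scale=0.15 * self.axes.min(), size=(n, 3))
        if self.orientation is not None:
            pts = pts @ self.orientation.T
        return pts + self.center


@dataclass
class AcquisitionParams:
    """STORM acquisition statistics for the localization generator.

    sigma_xy / sigma_z
        Per-axis localization error s.d. in nm.  Defaults interpret the
        nominal "~30 nm XY precision" as 1σ and "~70 nm Z resolution" as a
        FWHM (÷2.355); both are configurable since neither convention is
        universal.
    n_frames, z_depth
        Acquisition length (frames) and axial imaging window (nm, centered
        on the focal plane at z = 0).
    blink_mean
        Mean localizations per emitter; blink counts are geometric on
        {1, 2, …} (heavy-tailed enough to reproduce the broad observed spread
        of localizations per telomere).
    background_density
        Spurious localizations per µm³ of imaged volume (homogeneous
        Poisson).
    drift
        Optional vectorized function frame-array → (n, 3) displacement in nm
        added to every localization (the quantity drift correction must
        recover).
    photon_mean
        Mean of the exponential photon-count distribution.
    """

    sigma_xy: float = 30.0
    sigma_z: float = 70.0 * FWHM_TO_SIGMA
    n_frames: int = 35_000
    z_depth: float = 700.0
    blink_mean: float = 3.0
    background_density: float = 0.0
    drift: Callable[[np.ndarray], np.ndarray] | None = None
    photon_mean: float = 5000.0
    fov: tuple[tuple[float, float], tuple[float, float]] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_xy", "sigma_z", "z_depth", "blink_mean", "background_density"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.sigma_xy < 0 or self.sigma_z < 0:
            raise ValueError("sigma_xy and sigma_z must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.blink_mean < 1:
            raise ValueError("blink_mean must be >= 1 (geometric blink counts start at 1)")
        if self.background_density < 0:
            raise ValueError("background_density must be >= 0")
        if self.z_depth <= 0:
            raise ValueError("z_depth must be > 0")


class SimulationResult(NamedTuple):
    """Localization table plus per-structure ground truth."""

    table: LocalizationTable
    truth: pd.DataFrame  # structure_id, n_locs, rg_emitters_nm, rg_noise_free_nm, cx..cz


def _blink_counts(rng: np.random.Generator, n: int, mean: float) -> np.ndarray:
    if mean <= 1.0:
        return np.ones(n, dtype=np.int64)
    return rng.geometric(1.0 / mean, size=n)


def _rg(points: np.ndarray) -> float:
    com = points.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((points - com) ** 2, axis=1))))


def simulate_localizations(
    structures: Sequence[StructureModel],
    acq: AcquisitionParams,
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Simulate a molecule list from ground-truth structures.

    Every emitter of every structure blinks a geometric number of times; each
    blink becomes one localization at the emitter position plus independent
    N(0, σ) error per axis, assigned a uniform random frame.  Background
    localizations (truth label -1) are a homogeneous Poisson process over the
    field of view × z-depth.  Drift, when configured, is added last as a
    function of frame.

    Returns the table (with a ``truth_cluster`` column) and a per-structure
    truth frame recording the localization count, the Rg of the emitter
    positions, and the Rg of the noise-free (blink-weighted, zero-error)
    point set — the reference quantity for the noise-additivity law
    E[Rg_obs²] = Rg_nf² + 2σ_xy² + σ_z².
    """
    if not structures:
        raise ValueError("structures must be non-empty")
    half_z = acq.z_depth / 2.0
    for s in structures:
        if abs(s.center[2]) > half_z:
            raise ValueError(
                f"structure {s.structure_id} center z={s.center[2]:.1f} nm outside "
                f"the ±{half_z:.0f} nm z-depth window"
            )
    if rng is None:
        rng = np.random.default_rng(acq.seed)

    frames_chunks: list[np.ndarray] = []
    pos_chunks: list[np.ndarray] = []
    labels_chunks: list[np.ndarray] = []
    truth_rows = []
    for s in structures:
        emitters = s.sample_emitters(rng)
        counts = _blink_counts(rng, s.n_emitters, acq.blink_mean)
        pts = np.repeat(emitters, counts, axis=0)
        rg_nf = _rg(pts)
        noise = rng.normal(size=pts.shape) * np.array([acq.sigma_xy, acq.sigma_xy, acq.sigma_z])
        pts = pts + noise
        pos_chunks.append(pts)
        frames_chunks.append(rng.integers(0, acq.n_frames, size=len(pts)))
        labels_chunks.append(np.full(len(pts), s.structure_id, dtype=np.int64))
        truth_rows.append(
            {
                "structure_id": s.structure_id,
                "n_locs": len(pts),
                "rg_emitters_nm": _rg(emitters),
                "rg_noise_free_nm": rg_nf,
                "cx_nm": s.center[0],
                "cy_nm": s.center[1],
                "cz_nm": s.center[2],
            }
        )

    if acq.background_density > 0:
        if acq.fov is not None:
            (x0, x1), (y0, y1) = acq.fov
        else:
            allpos = np.concatenate(pos_chunks)
            margin = 500.0
            x0, x1 = allpos[:, 0].min() - margin, allpos[:, 0].max() + margin
            y0, y1 = allpos[:, 1].min() - margin, allpos[:, 1].max() + margin
        volume_um3 = (x1 - x0) * (y1 - y0) * acq.z_depth / 1e9
        n_bg = int(rng.poisson(acq.background_density * volume_um3))
        if n_bg:
            bg = np.column_stack(
                [
                    rng.uniform(x0, x1, n_bg),
                    rng.uniform(y0, y1, n_bg),
                    rng.uniform(-half_z, half_z, n_bg),
                ]
            )
            pos_chunks.append(bg)
            frames_chunks.append(rng.integers(0, acq.n_frames, size=n_bg))
            labels_chunks.append(np.full(n_bg, -1, dtype=np.int64))

    pos = np.concatenate(pos_chunks)
    frames = np.concatenate(frames_chunks)
    labels = np.concatenate(labels_chunks)
    if acq.drift is not None:
        disp = np.asarray(acq.drift(frames), float)
        if disp.shape != pos.shape:
            raise ValueError("drift function must return an (n, 3) displacement array")
        pos = pos + disp
    photons = np.maximum(1, rng.exponential(acq.photon_mean, size=len(pos))).astype(np.int64)

    df = pd.DataFrame(
        {
            "x_nm": pos[:, 0],
            "y_nm": pos[:, 1],
            "z_nm": pos[:, 2],
            "frame": frames,
            "photons": photons,
            TRUTH_COLUMN: labels,
        }
    )
    table = LocalizationTable(df, n_frames=acq.n_frames, z_depth=acq.z_depth).sorted_by_frame()
    return SimulationResult(table, pd.DataFrame(truth_rows))


def noise_variance_3d(acq: AcquisitionParams) -> float:
    """Total localization-error variance 2σ_xy² + σ_z² (nm²)."""
    return 2.0 * acq.sigma_xy**2 + acq.sigma_z**2


def radius_for_target_rg(
    target_rg_nm: float, acq: AcquisitionParams, size_cv: float = 0.0
) -> float:
    """Ball radius whose *observed* root-mean-square Rg matches a target.

    Inverts the additivity law E[Rg_obs²] = (3/5)·E[R²] + 2σ_xy² + σ_z² for a
    population of uniform balls whose radii have coefficient of variation
    ``size_cv`` about the returned mean radius.
    """
    rg2 = target_rg_nm**2 - noise_variance_3d(acq)
    if rg2 <= 0:
        raise ValueError(
            f"target Rg {target_rg_nm} nm is below the localization-noise floor "
            f"({math.sqrt(noise_variance_3d(acq)):.1f} nm)"
        )
    return math.sqrt(rg2 * 5.0 / 3.0 / (1.0 + size_cv**2))


def sample_cluster_rgs(
    n_clusters: int,
    acq: AcquisitionParams,
    rng: np.random.Generator,
    radius_mean: float,
    radius_cv: float = 0.0,
    n_emitters: int = 200,
    axes_ratio: Sequence[float] = (1.0, 1.0, 1.0),
) -> pd.DataFrame:
    """Vectorized per-telomere Rg sampler for group-level simulations.

    Draws ``n_clusters`` independent telomeres (uniform ellipsoids with
    semi-axes ``radius_mean × axes_ratio`` scaled by a per-telomere lognormal
    size factor of CV ``radius_cv``), applies geometric blinking and Gaussian
    localization error, and returns observed Rg and localization count per
    telomere — identical statistics to :func:`simulate_localizations` without
    materializing molecule lists, so whole study arms simulate in
    milliseconds.

    Returns a frame with columns ``rg_nm, n_locs, rg_noise_free_nm``.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    axes = radius_mean * np.asarray(axes_ratio, float)
    if np.any(axes <= 0):
        raise ValueError("axes_ratio entries must be > 0")
    ne = int(n_emitters)
    if radius_cv > 0:
        s2 = math.log(1.0 + radius_cv**2)
        scale = rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=n_clusters)
    else:
        scale = np.ones(n_clusters)

    v = rng.standard_normal((n_clusters, ne, 3))
    v /= np.linalg.norm(v, axis=2, keepdims=True)
    r = rng.random((n_clusters, ne)) ** (1.0 / 3.0)
    emitters = v * r[..., None] * axes * scale[:, None, None]

    counts = _blink_counts(rng, n_clusters * ne, acq.blink_mean).reshape(n_clusters, ne)
    flat_counts = counts.ravel()
    cluster_idx = np.repeat(np.repeat(np.arange(n_clusters), ne), flat_counts)
    pts = np.repeat(emitters.reshape(-1, 3), flat_counts, axis=0)

    n_locs = np.bincount(cluster_idx, minlength=n_clusters).astype(np.int64)

    def grouped_rg(points: np.ndarray) -> np.ndarray:
        sums = np.column_stack(
            [np.bincount(cluster_idx, weights=points[:, d], minlength=n_clusters) for d in range(3)]
        )
        sq = np.bincount(
            cluster_idx, weights=np.sum(points**2, axis=1), minlength=n_clusters
        )
        mean = sums / n_locs[:, None]
        return np.sqrt(np.maximum(sq / n_locs - np.sum(mean**2, axis=1), 0.0))

    rg_nf = grouped_rg(pts)
    noise = rng.normal(size=pts.shape) * np.array([acq.sigma_xy, acq.sigma_xy, acq.sigma_z])
    rg_obs = grouped_rg(pts + noise)
    return pd.DataFrame({"rg_nm": rg_obs, "n_locs": n_locs, "rg_noise_free_nm": rg_nf})


def render_conventional_image(
    table: LocalizationTable,
    pixel_size: float,
    psf_sigma: float,
    extent: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> tuple[np.ndarray, tuple[tuple[float, float], tuple[float, float]]]:
    """Render a diffraction-limited 2D image from a molecule list.

    Each localization contributes one unit of integrated intensity as a 2D
    Gaussian of s.d. ``psf_sigma`` (nm); total image intensity equals the
    localization count up to edge truncation.  This is the widefield-like
    overlay used to gate out nontelomeric background.

    Returns (image, ((x0, x1), (y0, y1))) with image indexed [row=y, col=x].
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if extent is None:
        if len(table) == 0:
            extent = ((0.0, pixel_size), (0.0, pixel_size))
        else:
            pos = table.positions
            pad = 4.0 * psf_sigma + pixel_size
            extent = (
                (pos[:, 0].min() - pad, pos[:, 0].max() + pad),
                (pos[:, 1].min() - pad, pos[:, 1].max() + pad),
            )
    (x0, x1), (y0, y1) = extent
    nx = max(1, int(np.ceil((x1 - x0) / pixel_size)))
    ny = max(1, int(np.ceil((y1 - y0) / pixel_size)))
    if len(table) == 0:
        return np.zeros((ny, nx)), extent
    pos = table.positions
    hist, _, _ = np.histogram2d(
        pos[:, 1], pos[:, 0], bins=(ny, nx), range=((y0, y0 + ny * pixel_size), (x0, x0 + nx * pixel_size))
    )
    img = ndimage.gaussian_filter(hist, sigma=psf_sigma / pixel_size, mode="constant")
    return img, extent


# ---------------------------------------------------------------------------
# Two-channel foci scenes
# ---------------------------------------------------------------------------


@dataclass
class FociScene:
    """Plan for a two-channel nuclear foci image with known overlap truth.

    ``foci_a`` / ``foci_b`` are lists of ((row, col), amplitude, sigma_px);
    all centroids must lie inside ``nucleus_mask``.  ``overlap_a`` holds the
    indices of a-foci planned to coincide with a b-focus; the planned overlap
    fraction is ground truth for colocalization recovery tests.
    """

    image_shape: tuple[int, int]
    pixel_size: float
    nucleus_mask: np.ndarray
    foci_a: list
    foci_b: list
    overlap_a: frozenset = frozenset()
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.nucleus_mask = np.asarray(self.nucleus_mask, bool)
        if self.nucleus_mask.shape != tuple(self.image_shape):
            raise ValueError("nucleus_mask shape must match image_shape")
        for name, foci in (("foci_a", self.foci_a), ("foci_b", self.foci_b)):
            for (r, c), amp, sig in foci:
                ri, ci = int(round(r)), int(round(c))
                if not (0 <= ri < self.image_shape[0] and 0 <= ci < self.image_shape[1]):
                    raise ValueError(f"{name} centroid ({r}, {c}) outside the image")
                if not self.nucleus_mask[ri, ci]:
                    raise ValueError(f"{name} centroid ({r}, {c}) outside the nucleus mask")
                if amp < 0 or sig <= 0:
                    raise ValueError("focus amplitude must be >= 0 and sigma > 0")
        self.overlap_a = frozenset(self.overlap_a)
        if any(i < 0 or i >= len(self.foci_a) for i in self.overlap_a):
            raise ValueError("overlap_a indices out of range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def planned_overlap_fraction(self) -> float:
        if not self.foci_a:
            return float("nan")
        return len(self.overlap_a) / len(self.foci_a)

    @classmethod
    def random(
        cls,
        n_a: int,
        n_overlap: int,
        n_b_extra: int = 0,
        image_shape: tuple[int, int] = (256, 256),
        pixel_size: float = 80.0,
        amplitude: float = 1000.0,
        sigma_px: float = 2.0,
        min_separation_px: float = 12.0,
        noise_sd: float = 0.0,
        seed: int | None = None,
        nucleus_mask: np.ndarray | None = None,
    ) -> "FociScene":
        """Plant ``n_a`` reference foci, of which ``n_overlap`` coincide with a
        b-focus, plus ``n_b_extra`` b-foci placed away from every a-focus."""
        if not 0 <= n_overlap <= n_a:
            raise ValueError("need 0 <= n_overlap <= n_a")
        rng = np.random.default_rng(seed)
        if nucleus_mask is None:
            yy, xx = np.mgrid[0 : image_shape[0], 0 : image_shape[1]]
            cy, cx = (image_shape[0] - 1) / 2, (image_shape[1] - 1) / 2
            rad = 0.45 * min(image_shape)
            nucleus_mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
        inside = np.argwhere(nucleus_mask)
        placed: list[np.ndarray] = []
        for _ in range(n_a + n_b_extra):
            for _attempt in range(10_000):
                cand = inside[rng.integers(len(inside))].astype(float)
                if all(np.hypot(*(cand - p)) >= min_separation_px for p in placed):
                    placed.append(cand)
                    break
            else:
                raise RuntimeError("could not place foci with the requested separation")
        a_pos = placed[:n_a]
        b_extra = placed[n_a:]
        overlap_idx = rng.choice(n_a, size=n_overlap, replace=False) if n_overlap else []
        foci_a = [((p[0], p[1]), amplitude, sigma_px) for p in a_pos]
        foci_b = [((a_pos[i][0], a_pos[i][1]), amplitude, sigma_px) for i in overlap_idx]
        foci_b += [((p[0], p[1]), amplitude, sigma_px) for p in b_extra]
        return cls(
            image_shape=image_shape,
            pixel_size=pixel_size,
            nucleus_mask=nucleus_mask,
            foci_a=foci_a,
            foci_b=foci_b,
            overlap_a=frozenset(int(i) for i in overlap_idx),
            noise_sd=noise_sd,
            seed=seed,
        )


class FociImages(NamedTuple):
    channel_a: np.ndarray
    channel_b: np.ndarray
    nucleus_mask: np.ndarray
    overlap_truth: np.ndarray  # bool per a-focus


def _render_spots(shape: tuple[int, int], foci: list) -> np.ndarray:
    img = np.zeros(shape)
    for (r, c), amp, sig in foci:
        half = int(math.ceil(4 * sig))
        r0, r1 = max(0, int(r) - half), min(shape[0], int(r) + half + 1)
        c0, c1 = max(0, int(c) - half), min(shape[1], int(c) + half + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += amp * np.exp(
            -((yy - r) ** 2 + (xx - c) ** 2) / (2.0 * sig**2)
        )
    return img


def simulate_foci_image(scene: FociScene) -> FociImages:
    """Render the two channels of a foci scene plus per-focus overlap truth."""
    rng = np.random.default_rng(scene.seed)
    img_a = _render_spots(scene.image_shape, scene.foci_a)
    img_b = _render_spots(scene.image_shape, scene.foci_b)
    if scene.noise_sd > 0:
        img_a = np.clip(img_a + rng.normal(scale=scene.noise_sd, size=img_a.shape), 0, None)
        img_b = np.clip(img_b + rng.normal(scale=scene.noise_sd, size=img_b.shape), 0, None)
    truth = np.zeros(len(scene.foci_a), bool)
    truth[list(scene.overlap_a)] = True
    return FociImages(img_a, img_b, scene.nucleus_mask.copy(), truth)


# ---------------------------------------------------------------------------
# Gel lanes and dot blots
# ---------------------------------------------------------------------------


@dataclass
class GelLaneSpec:
    """Composition of a synthetic Southern-blot lane.

    ``bands`` is a list of (mw_kb, total_intensity, sigma_positions); the
    optional ``smear`` is (mw_lo_kb, mw_hi_kb, total_intensity), spread
    uniformly in log-MW.  ``ladder`` is a list of (mw_kb, position) anchors,
    strictly monotone (MW decreasing with position).
    """

    bands: list
    ladder: list
    smear: tuple | None = None
    profile_length: int = 500
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.bands and self.smear is None:
            raise ValueError("lane needs at least one band or a smear")
        for mw, inten, sig in self.bands:
            if mw <= 0:
                raise ValueError("band molecular weights must be > 0")
            if inten < 0 or sig <= 0:
                raise ValueError("band intensity must be >= 0 and sigma > 0")
        lad = sorted(self.ladder, key=lambda t: t[1])
        if len(lad) < 2:
            raise ValueError("ladder needs >= 2 anchors")
        pos = [p for _, p in lad]
        mws = [m for m, _ in lad]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("ladder migration positions must be strictly increasing")
        if any(b >= a for a, b in zip(mws, mws[1:])):
            raise ValueError("ladder MW must strictly decrease with migration position")
        self.ladder = lad
        if self.profile_length < 2:
            raise ValueError("profile_length must be >= 2")


class GelSimulation(NamedTuple):
    profile: LaneProfile
    ladder: LadderCalibration
    true_mean_kb: float


def simulate_gel_profile(spec: GelLaneSpec) -> GelSimulation:
    """Render a lane profile as a sum of Gaussian bands in migration space.

    Band centers are located by inverting the lane's own ladder calibration
    (log-linear).  The ground-truth intensity-weighted mean length
    ΣI/Σ(I/MW) over the band/smear composition is returned alongside.
    """
    rng = np.random.default_rng(spec.seed)
    mws = np.array([m for m, _ in spec.ladder])
    lpos = np.array([p for _, p in spec.ladder])
    neg_logmw = -np.log10(mws)  # increasing with position

    def mw_to_position(mw: np.ndarray) -> np.ndarray:
        return np.interp(-np.log10(mw), neg_logmw, lpos)

    components: list[tuple[float, float, float]] = [
        (float(mw), float(inten), float(sig)) for mw, inten, sig in spec.bands
    ]
    if spec.smear is not None:
        lo, hi, inten = spec.smear
        if lo <= 0 or hi <= lo or inten < 0:
            raise ValueError("smear must be (mw_lo>0, mw_hi>mw_lo, intensity>=0)")
        sub = np.logspace(math.log10(lo), math.log10(hi), 50)
        components += [(float(m), float(inten) / 50.0, 2.0) for m in sub]

    positions = np.arange(spec.profile_length, dtype=float)
    profile = np.zeros_like(positions)
    num = 0.0
    den = 0.0
    for mw, inten, sig in components:
        center = float(mw_to_position(np.array([mw]))[0])
        g = np.exp(-0.5 * ((positions - center) / sig) ** 2)
        s = g.sum()
        if s > 0:
            profile += inten * g / s
        num += inten
        den += inten / mw
    if spec.noise_sd > 0:
        profile = np.clip(profile + rng.normal(scale=spec.noise_sd, size=profile.shape), 0, None)
    true_mean = num / den if den > 0 else float("nan")
    return GelSimulation(
        LaneProfile(positions, profile),
        LadderCalibration(lpos, mws),
        true_mean,
    )


@dataclass
class DotBlotSpec:
    """Ground-truth design of a ChIP dot blot.

    ``true_ratio[(group, antibody)]`` is the spot signal relative to that
    group's input spot; the IgG antibody's ratio is the background level.
    Spot intensities are input_level × ratio × multiplicative log-normal
    noise of coefficient of variation ``noise_cv``, in ``n_replicates``
    independent replicates.
    """

    groups: list
    antibodies: list
    true_ratio: dict
    noise_cv: float = 0.0
    n_replicates: int = 3
    input_level: float = 1000.0
    input_label: str = "input"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.input_level <= 0:
            raise ValueError("input_level must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for g in self.groups:
            for ab in self.antibodies:
                if ab == self.input_label:
                    continue
                if (g, ab) not in self.true_ratio:
                    raise ValueError(f"true_ratio missing entry for ({g!r}, {ab!r})")
                if self.true_ratio[(g, ab)] < 0:
                    raise ValueError("true_ratio values must be >= 0")


def simulate_dot_blot(spec: DotBlotSpec) -> DotBlotGrid:
    """Generate a tidy dot-blot grid from a ground-truth ratio design."""
    rng = np.random.default_rng(spec.seed)
    if spec.noise_cv > 0:
        s2 = math.log(1.0 + spec.noise_cv**2)
        mu, sig = -s2 / 2.0, math.sqrt(s2)
    rows = []
    for rep in range(1, spec.n_replicates + 1):
        for g in spec.groups:
            for ab in spec.antibodies:
                ratio = 1.0 if ab == spec.input_label else spec.true_ratio[(g, ab)]
                noise = rng.lognormal(mu, sig) if spec.noise_cv > 0 else 1.0
                rows.append(
                    {
                        "group": g,
                        "antibody": ab,
                        "replicate": rep,
                        "intensity": spec.input_level * ratio * noise,
                    }
                )
    return DotBlotGrid(pd.DataFrame(rows), input_label=spec.input_label)
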