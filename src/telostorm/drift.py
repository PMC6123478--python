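"""Drift correction by image correlation analysis.

Stage drift over a long STORM acquisition is estimated by temporally binning
the molecule list, rendering each bin to a 2D histogram image, and locating
the cross-correlation peak of each bin against the first (reference) bin with
parabolic sub-pixel interpolation.  The per-bin XY displacement is linearly
interpolated across frames and subtracted from the coordinates.  Axial (Z)
drift, usually an order of magnitude smaller than lateral drift in a
focus-locked system, can optionally be estimated the same way from 1D
z-histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from telostorm.localizations import LocalizationTable


@dataclass
class DriftTrace:
    """Estimated per-bin displacement relative to the reference (first) bin.

    ``bin_edges`` has length n_bins+1 (frame indices); ``displacement`` is
    (n_bins, 2) or (n_bins, 3) in nm, with the first row exactly zero.
    """

    bin_edges: np.ndarray
    displacement: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.displacement = np.asarray(self.displacement, float)
        if len(self.bin_edges) != len(self.displacement) + 1:
            raise ValueError("bin_edges must have len(displacement) + 1 entries")
        if self.displacement.ndim != 2 or self.displacement.shape[1] not in (2, 3):
            raise ValueError("displacement must be (n_bins, 2) or (n_bins, 3)")
        if not np.allclose(self.displacement[0], 0.0):
            raise ValueError("reference-bin displacement must be zero")
        if not np.isfinite(self.displacement).all():
            raise ValueError("displacements must be finite")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def at_frames(self, frames: np.ndarray) -> np.ndarray:
        """Per-frame displacement by linear interpolation between bin centers."""
        frames = np.asarray(frames, float)
        return np.column_stack(
            [np.interp(frames, self.bin_centers, self.displacement[:, d])
             for d in range(self.displacement.shape[1])]
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = {"frame_bin_start": self.bin_edges[:-1].astype(int),
                "dx_nm": self.displacement[:, 0],
                "dy_nm": self.displacement[:, 1]}
        if self.displacement.shape[1] == 3:
            cols["dz_nm"] = self.displacement[:, 2]
        pd.DataFrame(cols).to_csv(path, index=False)


def _parabolic_offset(cm1: float, c0: float, cp1: float) -> float:
    denom = cm1 - 2.0 * c0 + cp1
    if denom >= 0:  # not a local maximum; fall back to the integer peak
        return 0.0
    return 0.5 * (cm1 - cp1) / denom


def _xcorr_peak_2d(img: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Shift (dy, dx) of ``img`` relative to ``ref`` in pixels.

    Linear (zero-padded) cross-correlation via FFT; the peak lag is refined
    independently per axis with a parabolic fit through its neighbors.
    """
    shape = tuple(2 * np.array(img.shape))
    f_img = np.fft.rfft2(img, shape)
    f_ref = np.fft.rfft2(ref, shape)
    cc = np.fft.irfft2(f_img * np.conj(f_ref), shape)
    peak = np.unravel_index(np.argmax(cc), cc.shape)
    shift = np.empty(2)
    for ax, p in enumerate(peak):
        n = shape[ax]
        lag = p if p < n // 2 else p - n
        lo = cc[(p - 1) % n, peak[1]] if ax == 0 else cc[peak[0], (p - 1) % n]
        hi = cc[(p + 1) % n, peak[1]] if ax == 0 else cc[peak[0], (p + 1) % n]
        shift[ax] = lag + _parabolic_offset(lo, cc[peak], hi)
    return shift  # (dy, dx)


def _xcorr_peak_1d(vec: np.ndarray, ref: np.ndarray) -> float:
    n = 2 * len(vec)
    cc = np.fft.irfft(np.fft.rfft(vec, n) * np.conj(np.fft.rfft(ref, n)), n)
    p = int(np.argmax(cc))
    lag = p if p < n // 2 else p - n
    return lag + _parabolic_offset(cc[(p - 1) % n], cc[p], cc[(p + 1) % n])


def correct_drift(
    table: LocalizationTable,
    frames_per_bin: int,
    pixel_size: float = 30.0,
    smooth_px: float = 2.0,
    correct_z: bool = False,
    min_bin_count: int = 10,
) -> tuple[LocalizationTable, DriftTrace]:
    """Estimate and subtract sample drift by image correlation analysis.

    Parameters
    ----------
    table
        The molecule list to correct.
    frames_per_bin
        Temporal bin width in frames; the table must span at least two bins.
    pixel_size
        Rendering pixel size in nm for the correlation images (of the order
        of the localization precision).
    smooth_px
        Gaussian blur (pixels) applied to the binned histograms so the
        correlation peak is smooth enough for parabolic interpolation.
    correct_z
        Also estimate axial drift from 1D z-histograms.
    min_bin_count
        Bins with fewer localizations are treated as empty: their
        displacement is interpolated from neighboring bins, with a warning.

    Returns the corrected table and the drift trace.  Raises ``ValueError``
    if fewer than two bins are usable.
    """
    if frames_per_bin < 1:
        raise ValueError("frames_per_bin must be >= 1")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    frames = table.df["frame"].to_numpy()
    n_bins = int(np.ceil(table.n_frames / frames_per_bin))
    if n_bins < 2:
        raise ValueError(
            f"table spans {n_bins} bin(s) at {frames_per_bin} frames/bin; need >= 2"
        )
    edges = np.arange(n_bins + 1) * frames_per_bin
    edges[-1] = max(edges[-1], table.n_frames)
    bin_of = np.clip(frames // frames_per_bin, 0, n_bins - 1)

    pos = table.positions
    pad = 2.0 * pixel_size
    x0, x1 = pos[:, 0].min() - pad, pos[:, 0].max() + pad
    y0, y1 = pos[:, 1].min() - pad, pos[:, 1].max() + pad
    nx = max(4, int(np.ceil((x1 - x0) / pixel_size)))
    ny = max(4, int(np.ceil((y1 - y0) / pixel_size)))
    rng_xy = ((y0, y0 + ny * pixel_size), (x0, x0 + nx * pixel_size))

    def render(sel: np.ndarray) -> np.ndarray:
        hist, _, _ = np.histogram2d(pos[sel, 1], pos[sel, 0], bins=(ny, nx), range=rng_xy)
        return ndimage.gaussian_filter(hist, smooth_px)

    ndim = 3 if correct_z else 2
    disp = np.full((n_bins, ndim), np.nan)
    counts = np.bincount(bin_of, minlength=n_bins)
    usable = counts >= min_bin_count
    if usable.sum() < 2:
        raise ValueError("fewer than 2 bins contain enough localizations for correlation")
    if not usable[0]:
        raise ValueError("the reference (first) bin is empty; choose a larger frames_per_bin")

    ref_sel = bin_of == 0
    ref_img = render(ref_sel)
    if correct_z:
        z = pos[:, 2]
        z_edges = np.arange(z.min() - pad, z.max() + pad + pixel_size, pixel_size)
        ref_z = ndimage.gaussian_filter1d(
            np.histogram(z[ref_sel], bins=z_edges)[0].astype(float), smooth_px
        )

    disp[0] = 0.0
    for b in range(1, n_bins):
        if not usable[b]:
            continue
        sel = bin_of == b
        dy, dx = _xcorr_peak_2d(render(sel), ref_img)
        disp[b, 0] = dx * pixel_size
        disp[b, 1] = dy * pixel_size
        if correct_z:
            hz = ndimage.gaussian_filter1d(
                np.histogram(z[sel], bins=z_edges)[0].astype(float), smooth_px
            )
            disp[b, 2] = _xcorr_peak_1d(hz, ref_z) * pixel_size

    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} empty frame bin(s); interpolating their drift "
            "from neighboring bins",
            stacklevel=2,
        )
        good = np.where(usable)[0]
        centers = 0.5 * (edges[:-1] + edges[1:])
        for d in range(ndim):
            disp[~usable, d] = np.interp(centers[~usable], centers[good], disp[good, d])

    trace = DriftTrace(edges, disp)
    per_frame = trace.at_frames(frames)
    xyz = pos.copy()
    xyz[:, 0] -= per_frame[:, 0]
    xyz[:, 1] -= per_frame[:, 1]
    if correct_z:
        xyz[:, 2] -= per_frame[:, 2]
    return table.with_positions(xyz), trace
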