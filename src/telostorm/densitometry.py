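"""Gel densitometry and dot-blot arithmetic.

Two small, exact computations live here:

* **TRF mean length** — the intensity-weighted harmonic mean of molecular
  weight along a Southern-blot lane,

  .. math:: \\bar L = \\frac{\\sum_i \\mathrm{Int}_i}{\\sum_i \\mathrm{Int}_i / \\mathrm{MW}_i},

  where ``Int_i`` is the background-subtracted signal at migration position
  *i* and ``MW_i`` the molecular weight (kb) at that position from a ladder
  calibration.  Shorter fragments migrate further, so the formula weights the
  *number* of molecules (intensity is proportional to mass, mass/MW to count)
  — hence the harmonic form.

* **ChIP dot-blot normalization** — IP spot intensity over the input spot
  (e.g. 10% of total chromatin), per replicate, then averaged; optionally a
  second normalization of H3K9me3 per H3, and fold changes against a control
  group (single or pooled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class LaneProfile:
    """A densitometry trace: intensity vs migration position for one lane.

    Positions must be strictly increasing; intensities are expected to be
    background-subtracted and non-negative — negative samples are clipped to
    zero with a warning (small negatives are common after backgrounding).
    """

    positions: np.ndarray
    intensities: np.ndarray
    label: str = "lane"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.positions.ndim != 1 or self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must be equal-length 1D arrays")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("migration positions must be strictly increasing")
        if np.any(self.intensities < 0):
            warnings.warn(
                f"lane {self.label!r}: clipping negative intensities to zero", stacklevel=2
            )
            self.intensities = np.clip(self.intensities, 0.0, None)

    def to_csv(self, path) -> None:
        pd.DataFrame({"position": self.positions, "intensity": self.intensities}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, label: str = "lane") -> "LaneProfile":
        df = pd.read_csv(path)
        return cls(df["position"].to_numpy(), df["intensity"].to_numpy(), label=label)


@dataclass
class LadderCalibration:
    """Migration-position → molecular-weight anchors from a size ladder.

    Anchors must be strictly monotone: MW strictly decreasing as migration
    position increases (small fragments run further).
    """

    positions: np.ndarray
    mw_kb: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.mw_kb = np.asarray(self.mw_kb, float)
        if self.positions.shape != self.mw_kb.shape or self.positions.ndim != 1:
            raise ValueError("ladder positions and mw_kb must be equal-length 1D arrays")
        if len(self.positions) < 2:
            raise ValueError("ladder needs at least 2 anchor points")
        order = np.argsort(self.positions)
        self.positions = self.positions[order]
        self.mw_kb = self.mw_kb[order]
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("ladder migration positions must be distinct")
        if np.any(self.mw_kb <= 0):
            raise ValueError("ladder molecular weights must be > 0")
        if np.any(np.diff(self.mw_kb) >= 0):
            raise ValueError("ladder MW must strictly decrease with migration position")

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.positions[0]), float(self.positions[-1])

    def to_csv(self, path) -> None:
        pd.DataFrame({"position": self.positions, "mw_kb": self.mw_kb}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LadderCalibration":
        df = pd.read_csv(path)
        return cls(df["position"].to_numpy(), df["mw_kb"].to_numpy())


def calibrate_migration(ladder: LadderCalibration) -> Callable[[np.ndarray], np.ndarray]:
    """Build a position → MW (kb) map by piecewise-linear interpolation in log10(MW).

    Gel migration is close to linear in log molecular weight between anchors,
    so interpolation is done on log10(MW).  Anchor positions are reproduced
    exactly.  Queries outside the anchor range trigger a warning and are
    linearly extrapolated from the nearest segment (in log MW).
    """
    pos = ladder.positions
    logmw = np.log10(ladder.mw_kb)
    lo, hi = ladder.domain
    # slopes of the outermost segments, for explicit extrapolation
    slope_lo = (logmw[1] - logmw[0]) / (pos[1] - pos[0])
    slope_hi = (logmw[-1] - logmw[-2]) / (pos[-1] - pos[-2])

    def position_to_mw(p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, float)
        scalar = p.ndim == 0
        p = np.atleast_1d(p)
        if np.any((p < lo) | (p > hi)):
            warnings.warn(
                "query positions outside ladder anchors; extrapolating log-linearly",
                stacklevel=2,
            )
        out = np.interp(p, pos, logmw)
        below = p < lo
        above = p > hi
        out[below] = logmw[0] + slope_lo * (p[below] - lo)
        out[above] = logmw[-1] + slope_hi * (p[above] - hi)
        mw = 10.0**out
        return float(mw[0]) if scalar else mw

    return position_to_mw


def subtract_background(intensities: np.ndarray, window: int = 51) -> np.ndarray:
    """Rolling-minimum background subtraction for a lane trace.

    The background at each position is the minimum intensity within a
    centered window of ``window`` samples; it is subtracted and the result
    clipped at zero.  A window larger than the trace degrades to subtracting
    the global minimum.
    """
    x = np.asarray(intensities, float)
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(x)
    if n == 0:
        return x.copy()
    half = window // 2
    bg = np.empty_like(x)
    for i in range(n):
        bg[i] = x[max(0, i - half) : min(n, i + half + 1)].min()
    return np.clip(x - bg, 0.0, None)


def mean_telomere_length(
    profile: LaneProfile,
    cal: Callable[[np.ndarray], np.ndarray] | LadderCalibration,
    allow_extrapolation: bool = False,
) -> float:
    """Intensity-weighted mean fragment length, ΣInt_i / Σ(Int_i / MW_i), in kb.

    ``cal`` may be a :class:`LadderCalibration` (calibrated internally) or an
    already-built position→MW function.  The result is invariant under
    uniform intensity scaling and bounded by the MW range spanned by the
    supported (nonzero-intensity) positions.

    Raises
    ------
    ValueError
        If total intensity is zero, or if supported positions fall outside
        the calibration anchors and ``allow_extrapolation`` is False.
    """
    if isinstance(cal, LadderCalibration):
        lo, hi = cal.domain
        support = profile.positions[profile.intensities > 0]
        if len(support) and not allow_extrapolation:
            if support.min() < lo or support.max() > hi:
                raise ValueError(
                    "profile support extends beyond the ladder calibration; "
                    "pass allow_extrapolation=True to permit log-linear extrapolation"
                )
        cal_fn = calibrate_migration(cal)
    else:
        cal_fn = cal
    total = float(profile.intensities.sum())
    if total <= 0:
        raise ValueError("zero total intensity: mean length undefined")
    # extrapolation policy was already decided on the nonzero-intensity support;
    # zero-weight tail positions may extrapolate silently
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mw = np.asarray(cal_fn(profile.positions), float)
    if np.any(mw <= 0):
        raise ValueError("calibration returned non-positive molecular weights")
    return total / float(np.sum(profile.intensities / mw))


@dataclass
class DotBlotGrid:
    """Background-subtracted spot intensities of a ChIP dot blot.

    ``data`` is tidy: one row per (group, antibody, replicate) with an
    ``intensity`` column.  Every group must include a spot for the input
    antibody label (a fixed fraction of total chromatin, e.g. 10%).
    """

    data: pd.DataFrame
    input_label: str = "input"
    input_fraction: float = 0.1

    def __post_init__(self) -> None:
        required = {"group", "antibody", "replicate", "intensity"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"dot-blot grid missing columns: {sorted(missing)}")
        if (self.data["intensity"] < 0).any():
            raise ValueError("dot-blot intensities must be >= 0 (background-subtracted)")
        for group, sub in self.data.groupby("group"):
            if self.input_label not in set(sub["antibody"]):
                raise ValueError(f"group {group!r} has no {self.input_label!r} spot")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, input_label: str = "input", input_fraction: float = 0.1):
        return cls(pd.read_csv(path), input_label=input_label, input_fraction=input_fraction)


def normalize_dot_blot(
    grid: DotBlotGrid,
    control_groups: Sequence[str] | None = None,
    per_h3: bool = False,
    h3_label: str = "H3",
    target_label: str = "H3K9me3",
) -> pd.DataFrame:
    """Normalize ChIP dot-blot spots to input and summarize per (group, antibody).

    Per replicate, each IP spot is divided by that group/replicate's input
    spot (``ratio_to_input``).  With ``per_h3=True`` an additional column
    gives the ``target_label`` ratio further normalized to the ``h3_label``
    ratio within the same replicate.  When ``control_groups`` is given, fold
    changes are reported against the mean of the control groups' mean ratios
    (pooled-control convention).

    Returns a tidy frame with columns ``group, antibody, ratio_mean,
    ratio_sem, n`` plus ``fold_vs_control`` and, if requested,
    ``per_h3_mean``/``per_h3_sem`` rows for the target antibody.
    """
    df = grid.data.copy()
    inputs = (
        df[df["antibody"] == grid.input_label]
        .set_index(["group", "replicate"])["intensity"]
        .rename("input_intensity")
    )
    if (inputs <= 0).any():
        raise ValueError("zero or negative input intensity; cannot normalize")
    ip = df[df["antibody"] != grid.input_label].join(
        inputs, on=["group", "replicate"], how="left"
    )
    if ip["input_intensity"].isna().any():
        raise ValueError("missing input spot for some (group, replicate)")
    ip["ratio_to_input"] = ip["intensity"] / ip["input_intensity"]

    if per_h3:
        have = set(ip["antibody"])
        if h3_label not in have or target_label not in have:
            raise ValueError(f"per-H3 normalization needs both {h3_label!r} and {target_label!r}")
        h3 = ip[ip["antibody"] == h3_label].set_index(["group", "replicate"])["ratio_to_input"]
        tgt = ip[ip["antibody"] == target_label].copy()
        tgt = tgt.join(h3.rename("h3_ratio"), on=["group", "replicate"])
        tgt["ratio_to_input"] = tgt["ratio_to_input"] / tgt["h3_ratio"]
        tgt["antibody"] = f"{target_label}_per_{h3_label}"
        ip = pd.concat([ip, tgt.drop(columns="h3_ratio")], ignore_index=True)

    def _sem(x: pd.Series) -> float:
        x = np.asarray(x, float)
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    out = (
        ip.groupby(["group", "antibody"])["ratio_to_input"]
        .agg(ratio_mean="mean", ratio_sem=_sem, n="size")
        .reset_index()
    )
    if control_groups is not None:
        control_groups = list(control_groups)
        absent = set(control_groups) - set(out["group"])
        if absent:
            raise ValueError(f"control groups not in grid: {sorted(absent)}")
        ctrl = (
            out[out["group"].isin(control_groups)]
            .groupby("antibody")["ratio_mean"]
            .mean()
            .rename("control_mean")
        )
        out = out.join(ctrl, on="antibody")
        out["fold_vs_control"] = out["ratio_mean"] / out["control_mean"]
        out = out.drop(columns="control_mean")
    return out
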