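"""Molecule-list container: per-localization 3D coordinates, frame and photons.

The molecule list is the pipeline's entry point — the tabular output of STORM
single-molecule fitting, one row per blinking event with drift-correctable
coordinates in nanometres, the camera frame of appearance, and the fitted
photon count.  The on-disk dialect is a delimited text file with header
``x_nm,y_nm,z_nm,frame,photons[,truth_cluster]``; the optional
``truth_cluster`` column carries ground-truth membership for synthetic data
(-1 marks background localizations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("x_nm", "y_nm", "z_nm", "frame", "photons")
TRUTH_COLUMN = "truth_cluster"


@dataclass
class LocalizationTable:
    """A molecule list plus the acquisition descriptors needed downstream.

    Parameters
    ----------
    df
        One row per localization with columns ``x_nm, y_nm, z_nm, frame,
        photons`` and optionally ``truth_cluster``.  Coordinates in nm,
        frame a 0-based integer.
    n_frames
        Number of camera frames in the acquisition; must exceed the largest
        frame index present.
    z_depth
        Imaged axial range in nm (the focal plane sits at z = 0, the window
        spans ±z_depth/2).
    """

    df: pd.DataFrame
    n_frames: int
    z_depth: float = 700.0

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"molecule list is missing columns: {missing}")
        coords = self.df[["x_nm", "y_nm", "z_nm"]].to_numpy(float)
        if coords.size and not np.isfinite(coords).all():
            raise ValueError("molecule list contains non-finite coordinates")
        frames = self.df["frame"].to_numpy()
        if len(frames):
            if frames.min() < 0:
                raise ValueError("frame indices must be >= 0")
            if self.n_frames < frames.max() + 1:
                raise ValueError(
                    f"n_frames={self.n_frames} but the table contains frame {frames.max()}"
                )
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of coordinates in nm."""
        return self.df[["x_nm", "y_nm", "z_nm"]].to_numpy(float)

    @property
    def has_truth(self) -> bool:
        return TRUTH_COLUMN in self.df.columns

    def sorted_by_frame(self) -> "LocalizationTable":
        out = self.df.sort_values("frame", kind="stable").reset_index(drop=True)
        return LocalizationTable(out, self.n_frames, self.z_depth)

    def with_positions(self, xyz: np.ndarray) -> "LocalizationTable":
        """Return a copy with coordinates replaced (used by drift correction)."""
        xyz = np.asarray(xyz, float)
        if xyz.shape != (len(self.df), 3):
            raise ValueError("replacement coordinates must be (N, 3)")
        out = self.df.copy()
        out[["x_nm", "y_nm", "z_nm"]] = xyz
        return LocalizationTable(out, self.n_frames, self.z_depth)

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.df.to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, n_frames: int | None = None, z_depth: float = 700.0
    ) -> "LocalizationTable":
        """Read a molecule list, sniffing comma vs tab delimiters.

        When ``n_frames`` is omitted it is taken as ``max(frame) + 1``.
        """
        df = pd.read_csv(path, sep=None, engine="python")
        if n_frames is None:
            n_frames = int(df["frame"].max()) + 1 if len(df) else 1
        return cls(df, n_frames=n_frames, z_depth=z_depth)
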