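"""Nuclear foci detection and colocalization scoring.

Scores two-channel fluorescence images of nuclei under an identical-threshold
policy: one fixed global intensity threshold per channel is applied to every
group of an experiment, foci are 8-connected components of supra-threshold
pixels inside the nucleus mask (small components discarded), and the derived
per-nucleus statistics are

* ``percent_area`` — 100 × focus pixels / nucleus pixels (e.g. % EGFP area),
* ``percent_colocalized`` — the fraction of reference-channel foci whose
  pixel set overlaps a partner-channel focus (asymmetric by design: the
  denominator is the reference channel, e.g. telomeres),
* ``percent_tif`` — the same contract with telomere foci as reference and
  DNA-damage (53BP1) foci as partner: the %TIF per telomere of a nucleus.

A permutation null (damage foci repositioned uniformly inside the mask)
estimates the colocalization expected from random, coincidental overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation
from skimage.filters import threshold_otsu


@dataclass
class FociSet:
    """Labeled foci of one channel inside one nucleus.

    ``label_image`` assigns 0 to background and 1..n_foci to the (disjoint)
    focus pixel sets; ``threshold`` records the intensity cutoff used so the
    identical-threshold policy is auditable.
    """

    label_image: np.ndarray
    channel: str = ""
    threshold: float = float("nan")

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if self.label_image.ndim != 2:
            raise ValueError("label_image must be 2D")

    @property
    def n_foci(self) -> int:
        return int(self.label_image.max())

    @property
    def foreground(self) -> np.ndarray:
        return self.label_image > 0

    @property
    def total_area(self) -> int:
        return int(np.count_nonzero(self.label_image))

    def focus_slices(self):
        return ndimage.find_objects(self.label_image)


def detect_foci(
    image: np.ndarray,
    mask: np.ndarray,
    threshold: float,
    min_area: int = 4,
    channel: str = "",
) -> FociSet:
    """Detect foci as 8-connected supra-threshold components inside the mask.

    The threshold is a fixed global intensity cutoff — set once per channel
    per experiment and reused across all groups.  Components smaller than
    ``min_area`` pixels are discarded.  A threshold at or above the image
    maximum yields an empty set (not an error); an empty mask is an error.
    """
    image = np.asarray(image, float)
    mask = np.asarray(mask, bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("nucleus mask is empty")
    binary = (image > threshold) & mask
    labels = measure.label(binary, connectivity=2)
    if min_area > 1 and labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        small = sizes < min_area
        small[0] = False
        binary[small[labels]] = False
        labels = measure.label(binary, connectivity=2)
    return FociSet(labels, channel=channel, threshold=float(threshold))


def count_foci(foci: FociSet) -> int:
    """Number of labeled foci (touching planted spots merge into one)."""
    return foci.n_foci


def percent_area(foci: FociSet, mask: np.ndarray) -> float:
    """100 × (pixels in foci) / (pixels in the nucleus mask)."""
    mask = np.asarray(mask, bool)
    denom = int(np.count_nonzero(mask))
    if denom == 0:
        raise ValueError("nucleus mask is empty")
    return 100.0 * foci.total_area / denom


def percent_colocalized(
    reference: FociSet, partner: FociSet, overlap_min: int = 1
) -> float:
    """Percent of reference foci overlapping ≥ ``overlap_min`` partner pixels.

    Asymmetric: the denominator is the reference channel's focus count.
    Raises if the reference set is empty (the statistic is undefined).
    """
    if reference.n_foci == 0:
        raise ValueError("percent_colocalized undefined: reference has zero foci")
    if overlap_min < 1:
        raise ValueError("overlap_min must be >= 1")
    if reference.label_image.shape != partner.label_image.shape:
        raise ValueError("reference and partner label images differ in shape")
    partner_fg = partner.foreground
    hits = 0
    # find_objects yields the bounding slice of label i+1 at list index i
    for i, sl in enumerate(reference.focus_slices()):
        if sl is None:
            continue
        focus_pixels = reference.label_image[sl] == (i + 1)
        if np.count_nonzero(focus_pixels & partner_fg[sl]) >= overlap_min:
            hits += 1
    return 100.0 * hits / reference.n_foci


def percent_tif(telomeres: FociSet, damage: FociSet, overlap_min: int = 1) -> float:
    """%TIF per telomere: telomere foci overlapping a damage (53BP1) focus.

    With no damage foci at all the result is 0% (no telomere can overlap);
    with zero telomere foci the statistic is undefined and raises.
    """
    if telomeres.n_foci == 0:
        raise ValueError("percent_tif undefined: no telomere foci")
    if damage.n_foci == 0:
        return 0.0
    return percent_colocalized(telomeres, damage, overlap_min=overlap_min)


def permutation_null_percent(
    reference: FociSet,
    partner: FociSet,
    mask: np.ndarray,
    n_shuffles: int = 200,
    overlap_min: int = 1,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, np.ndarray]:
    """Random-overlap null for colocalization: shuffle partner foci in the mask.

    Each shuffle translates every partner focus (its full pixel set) to a
    uniformly random position whose pixels all fall inside the mask, then
    scores ``percent_colocalized``.  Under independence with point-like
    reference foci the mean approaches 100 × (partner-covered area fraction
    of the mask).  Returns (mean_percent, per-shuffle percents).
    """
    rng = np.random.default_rng(rng)
    mask = np.asarray(mask, bool)
    shape = mask.shape
    # footprint (row, col offsets) of each partner focus, centered at origin
    footprints = []
    for i, sl in enumerate(partner.focus_slices()):
        if sl is None:
            continue
        rr, cc = np.nonzero(partner.label_image[sl] == (i + 1))
        footprints.append((rr - rr.min(), cc - cc.min(), rr.max() - rr.min(), cc.max() - cc.min()))
    inside = np.argwhere(mask)
    results = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shuffled = np.zeros(shape, bool)
        for rr, cc, h, w in footprints:
            for _ in range(10_000):
                r0, c0 = inside[rng.integers(len(inside))]
                if r0 + h >= shape[0] or c0 + w >= shape[1]:
                    continue
                if mask[rr + r0, cc + c0].all():
                    shuffled[rr + r0, cc + c0] = True
                    break
            else:
                raise RuntimeError("could not place a shuffled focus inside the mask")
        fake = FociSet(shuffled.astype(np.int32), channel=partner.channel)
        results[s] = percent_colocalized(reference, fake, overlap_min=overlap_min)
    return float(results.mean()), results


def segment_nuclei(
    dapi: np.ndarray,
    min_area: int = 500,
    split_touching: bool = True,
) -> np.ndarray:
    """Segment nuclei from a DAPI image: Otsu threshold, hole filling, and an
    optional watershed split of touching nuclei.  Returns a label image
    (0 = background); masks may equally be supplied directly downstream.
    """
    dapi = np.asarray(dapi, float)
    binary = dapi > threshold_otsu(dapi)
    binary = ndimage.binary_fill_holes(binary)
    lab = measure.label(binary, connectivity=2)
    if lab.max() > 0:
        sizes = np.bincount(lab.ravel())
        small = sizes < min_area
        small[0] = False
        binary[small[lab]] = False
    if not split_touching:
        return measure.label(binary, connectivity=2)
    distance = ndimage.distance_transform_edt(binary)
    smoothed = ndimage.gaussian_filter(distance, 4.0)
    peaks = morphology.local_maxima(smoothed) & binary
    markers = measure.label(peaks, connectivity=2)
    if markers.max() == 0:
        return measure.label(binary, connectivity=2)
    labels = segmentation.watershed(-smoothed, markers, mask=binary)
    return labels
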