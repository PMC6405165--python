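"""Embryo segmentation and masked intensity measurement.

The embryo outline is segmented per image by Otsu's automatic threshold
(histogram of 256 bins over the observed intensity range; foreground is
strictly above the threshold). For the dual-channel assay, each channel is
cropped by the intersection of both channels' Otsu foregrounds, so the
same region is measured in both channels. Statistics are computed over
masked pixels only — background is excluded, not subtracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateImageError, EmptyMaskError

log = logging.getLogger("fishscreen")

OTSU_BINS = 256


@dataclass(frozen=True)
class RegionStats:
    """Intensity statistics of one masked region.

    ``sd`` is the sample (n-1) standard deviation, defined as 0 for a
    single-pixel region. ``bg_mean`` is the mean of the pixels outside the
    mask (NaN when the mask covers the whole image); it feeds well QC.
    """

    mean: float
    median: float
    sd: float
    area: int
    bg_mean: float = float("nan")


def otsu_threshold(image: np.ndarray) -> float:
    """Otsu's threshold of an intensity image.

    Maximizes the between-class variance over a 256-bin histogram spanning
    the observed range; ties take the lowest threshold. Foreground is
    defined as pixels strictly greater than the returned value (the centre
    of the highest-scoring background bin).

    Raises
    ------
    DegenerateImageError
        If the image is constant (no separable classes).
    """
    values = np.asarray(image, dtype=float).ravel()
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        raise DegenerateImageError("constant image has no Otsu threshold")
    hist, edges = np.histogram(values, bins=OTSU_BINS, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = hist.astype(float)
    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    m = np.cumsum(hist * centers)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m / w0
        mu1 = (m[-1] - m) / w1
        sigma_b = w0[:-1] * w1[:-1] * (mu0[:-1] - mu1[:-1]) ** 2
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    k = int(np.argmax(sigma_b))
    return float(centers[k])


def otsu_mask(image: np.ndarray) -> np.ndarray:
    """Boolean foreground mask: pixels strictly above the Otsu threshold."""
    return np.asarray(image) > otsu_threshold(image)


def dual_channel_mask(channel_a: np.ndarray, channel_b: np.ndarray) -> np.ndarray:
    """Intersection of the two channels' Otsu foregrounds.

    The same mask is applied to both channels downstream. If either
    channel is constant the intersection is empty; the empty mask is
    returned (not raised) so that well QC can flag the well.
    """
    a = np.asarray(channel_a)
    b = np.asarray(channel_b)
    if a.shape != b.shape:
        raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
    try:
        mask_a = otsu_mask(a)
        mask_b = otsu_mask(b)
    except DegenerateImageError:
        log.debug("dual_channel_mask: constant channel, empty mask")
        return np.zeros(a.shape, dtype=bool)
    return mask_a & mask_b


def measure_masked(image: np.ndarray, mask: np.ndarray) -> RegionStats:
    """Mean/median/sample-sd/area over masked pixels, background excluded.

    Raises
    ------
    EmptyMaskError
        If the mask selects no pixels (measurement unavailable).
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    pixels = image[mask]
    if pixels.size == 0:
        raise EmptyMaskError("empty mask: measurement unavailable")
    outside = image[~mask]
    return RegionStats(
        mean=float(pixels.mean()),
        median=float(np.median(pixels)),
        sd=float(pixels.std(ddof=1)) if pixels.size > 1 else 0.0,
        area=int(pixels.size),
        bg_mean=float(outside.mean()) if outside.size else float("nan"),
    )


def aggregate_z(per_slice: Sequence[RegionStats]) -> RegionStats:
    """Combine per-z-slice measurements of one well/channel/timepoint.

    The aggregate mean is the area-weighted mean of slice means, which
    equals the mean over all pooled masked pixels; the sd is the pooled
    sample sd reconstructed from per-slice moments. The aggregate median
    is the area-weighted mean of slice medians (a pooled median is not
    recoverable from slice statistics). The background mean is pooled by
    unweighted average across slices.
    """
    if len(per_slice) == 0:
        raise EmptyMaskError("no valid slice measurements to aggregate")
    areas = np.array([s.area for s in per_slice], dtype=float)
    means = np.array([s.mean for s in per_slice])
    medians = np.array([s.median for s in per_slice])
    sds = np.array([s.sd for s in per_slice])
    n_total = areas.sum()
    grand_mean = float((areas * means).sum() / n_total)
    # pooled sum of squares: within-slice + between-slice components
    ss = ((areas - 1) * sds**2 + areas * (means - grand_mean) ** 2).sum()
    sd = float(np.sqrt(ss / (n_total - 1))) if n_total > 1 else 0.0
    bg = np.array([s.bg_mean for s in per_slice])
    bg = bg[np.isfinite(bg)]
    return RegionStats(
        mean=grand_mean,
        median=float((areas * medians).sum() / n_total),
        sd=sd,
        area=int(n_total),
        bg_mean=float(bg.mean()) if bg.size else float("nan"),
    )


def spim_ratio_measure(
    stack: Sequence[np.ndarray],
    control_stack: Sequence[np.ndarray],
) -> list[tuple[int, RegionStats]]:
    """Per-slice ratio-image measurement for light-sheet verification.

    For each aligned z-slice the test image is divided by the control
    image (control-zero pixels excluded so no non-finite values
    propagate), the ratio image is masked by its own Otsu foreground and
    the ratio statistics are computed within the mask. A constant ratio
    image (e.g. a stack divided by itself) has no Otsu threshold; all
    control-positive pixels are measured instead. Slices whose control is
    entirely zero are skipped and logged.

    Returns
    -------
    list of (z index, RegionStats)
        One measurement per usable z-slice — the "n = z-slices" unit of
        the group comparisons.
    """
    if len(stack) != len(control_stack):
        raise ValueError("stacks must have the same number of z-slices")
    out: list[tuple[int, RegionStats]] = []
    for z, (img, ctrl) in enumerate(zip(stack, control_stack)):
        img = np.asarray(img, dtype=float)
        ctrl = np.asarray(ctrl, dtype=float)
        if img.shape != ctrl.shape:
            raise ValueError(f"slice {z}: shapes differ")
        valid = ctrl > 0
        if not valid.any():
            log.warning("spim_ratio_measure: slice %d control entirely zero, skipped", z)
            continue
        ratio = np.zeros_like(img)
        ratio[valid] = img[valid] / ctrl[valid]
        try:
            thr = otsu_threshold(ratio[valid])
            mask = valid & (ratio > thr)
            if not mask.any():
                mask = valid
        except DegenerateImageError:
            mask = valid
        pixels = ratio[mask]
        out.append(
            (z, RegionStats(
                mean=float(pixels.mean()),
                median=float(np.median(pixels)),
                sd=float(pixels.std(ddof=1)) if pixels.size > 1 else 0.0,
                area=int(pixels.size),
            ))
        )
    return out
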