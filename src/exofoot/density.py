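"""Motif-density profiles around summits and the characteristic width.

The characteristic width is a resolution statistic for a summit set: motif
starts are histogrammed by offset from the summits over +/-250 bp,
normalized by the total motif count, smoothed with an isosceles-triangle
moving average over a 20 bp window, and the width of the contiguous
above-threshold region (threshold: 1 motif per 500 bp) around the profile
maximum is reported.  Sharper summit calling concentrates motif mass near
offset zero and narrows this region.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .motifs import MotifHit

WIDTH_THRESHOLD = 1.0 / 500.0


@dataclasses.dataclass
class DensityProfile:
    """Offset histogram, normalized/smoothed density and its width."""

    offsets: np.ndarray
    raw_counts: np.ndarray
    density: np.ndarray
    smoothed: np.ndarray
    characteristic_width: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "raw": self.raw_counts,
                "density": self.density,
                "smoothed": self.smoothed,
            }
        )


def raw_motif_counts(
    summits: Sequence[int],
    hits: Sequence[MotifHit],
    halfwidth: int = 250,
    position: str = "start",
) -> np.ndarray:
    """Counts of motif positions per offset from the summits.

    The motif position is its interval start by default ("start"), or the
    interval midpoint ("center").  Offsets are inclusive on both ends; a
    hit near several summits contributes to each.
    """
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    if position not in ("start", "center"):
        raise ValueError("position must be 'start' or 'center'")
    counts = np.zeros(2 * halfwidth + 1, dtype=np.int64)
    pos = np.array(
        sorted(
            h.start if position == "start" else (h.start + h.end) // 2 for h in hits
        ),
        dtype=np.int64,
    )
    for s in summits:
        lo = int(np.searchsorted(pos, s - halfwidth, side="left"))
        hi = int(np.searchsorted(pos, s + halfwidth, side="right"))
        if hi > lo:
            counts += np.bincount(pos[lo:hi] - s + halfwidth, minlength=len(counts))
    return counts


def triangle_kernel(window: int = 20) -> np.ndarray:
    """Symmetric isosceles-triangle weights over +/-window/2 positions.

    For the default 20 bp window this is a 21-tap kernel with the maximum
    weight (11) at the central point and weight ``window/2 + 1 - |k|`` at
    lag ``k``.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    half = window // 2
    lags = np.arange(-half, half + 1)
    return (half + 1 - np.abs(lags)).astype(float)


def normalize_and_smooth(
    raw_counts: np.ndarray, window: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Density (counts / total) and its triangle-smoothed version.

    Smoothing is a weighted moving average whose weights are renormalized
    at the profile edges (the mean is always over the taps that exist).
    An all-zero profile stays all-zero.
    """
    raw = np.asarray(raw_counts, dtype=float)
    total = raw.sum()
    density = raw / total if total > 0 else np.zeros_like(raw)
    w = triangle_kernel(window)
    num = np.convolve(density, w, mode="same")
    den = np.convolve(np.ones_like(density), w, mode="same")
    return density, num / den


def characteristic_width(
    smoothed: np.ndarray, threshold: float = WIDTH_THRESHOLD
) -> int:
    """Width (bases) of the contiguous above-threshold region at the peak.

    The region is the maximal run of offsets with ``smoothed > threshold``
    (strictly) that contains the profile's global maximum; 0 when even the
    maximum does not exceed the threshold.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if len(smoothed) == 0:
        return 0
    peak = int(smoothed.argmax())
    if not smoothed[peak] > threshold:
        return 0
    above = smoothed > threshold
    lo = peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak
    while hi + 1 < len(above) and above[hi + 1]:
        hi += 1
    return hi - lo + 1


def motif_density_profile(
    summits: Sequence[int],
    hits: Sequence[MotifHit],
    halfwidth: int = 250,
    window: int = 20,
    threshold: float = WIDTH_THRESHOLD,
    position: str = "start",
) -> DensityProfile:
    """End-to-end profile: counts -> density -> smoothing -> width."""
    raw = raw_motif_counts(summits, hits, halfwidth, position)
    density, smoothed = normalize_and_smooth(raw, window)
    return DensityProfile(
        offsets=np.arange(-halfwidth, halfwidth + 1),
        raw_counts=raw,
        density=density,
        smoothed=smoothed,
        characteristic_width=characteristic_width(smoothed, threshold),
    )
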