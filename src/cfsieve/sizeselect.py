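"""In-silico fragment size selection.

Models the automated gel extraction of library subfractions as a retention
window over insert size with an asymmetric leak: retention is 1 inside
[low, high], 0 below the window (the lower gel boundary is sharp), and decays
exponentially above it with scale ``leak_scale_bp`` — longer fragments
co-migrate with a shorter target range, but not the other way around.

A densitometry-style smoothed length profile with its peak is reported per
fraction; when expressing the peak on the *library* scale the full-length
adapter mass (~135 bp) is added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

ADAPTER_OFFSET_BP = 135

# Default extraction windows: the short window targets the sub-mononucleosome
# range (median insert near 142 bp after selection), the long window covers
# the 167 bp mononucleosome peak.
DEFAULT_WINDOWS = {
    "short": (100, 160),
    "medium": (150, 170),
    "long": (160, 200),
}
DEFAULT_LEAK_SCALE_BP = 5.0


@dataclass(frozen=True)
class SizeWindow:
    label: str
    low_bp: int = 0
    high_bp: int = 10 ** 9
    leak_scale_bp: float = DEFAULT_LEAK_SCALE_BP

    def __post_init__(self) -> None:
        if self.label != "unselected" and self.low_bp >= self.high_bp:
            raise ValueError("low_bp must be < high_bp")
        if self.leak_scale_bp < 0:
            raise ValueError("leak_scale_bp must be >= 0")

    @classmethod
    def unselected(cls) -> "SizeWindow":
        return cls("unselected", 0, 10 ** 9, 0.0)

    @classmethod
    def default(cls, label: str, leak_scale_bp: float = DEFAULT_LEAK_SCALE_BP
                ) -> "SizeWindow":
        if label == "unselected":
            return cls.unselected()
        low, high = DEFAULT_WINDOWS[label]
        return cls(label, low, high, leak_scale_bp)


@dataclass
class FractionReport:
    label: str
    peak_fragment_length_bp: float | None
    peak_library_length_bp: float | None
    median_insert_bp: float | None
    n_selected: int


def _insert_of(record) -> int:
    for attr in ("insert_length_bp", "insert_size_bp", "insert_size"):
        if hasattr(record, attr):
            return int(getattr(record, attr))
    return int(record)


def retention_probability(insert_bp: int, window: SizeWindow) -> float:
    """Probability a fragment of the given insert size survives extraction."""
    if insert_bp <= 0:
        raise ValueError("insert_bp must be positive")
    if window.label == "unselected":
        return 1.0
    if insert_bp < window.low_bp:
        return 0.0
    if insert_bp <= window.high_bp:
        return 1.0
    if window.leak_scale_bp == 0:
        return 0.0
    return math.exp(-(insert_bp - window.high_bp) / window.leak_scale_bp)


def select_fraction(records, window: SizeWindow, seed=0,
                    bandwidth_bp: float = 3.0):
    """Keep each record independently with its retention probability.

    Works on anything exposing an insert size (fragments, consensus reads,
    molecules, or plain integers).  Selection only decides membership; the
    records themselves are untouched.  Returns (selected, FractionReport).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    records = list(records)
    if window.label == "unselected":
        selected = records
    else:
        inserts = np.array([_insert_of(r) for r in records])
        probs = np.array([retention_probability(int(i), window) for i in inserts])
        keep = rng.random(len(records)) < probs
        selected = [r for r, k in zip(records, keep) if k]
    if selected:
        lengths = [_insert_of(r) for r in selected]
        prof = densitometry_profile(lengths, bandwidth_bp)
        report = FractionReport(window.label, prof.peak_bp,
                                prof.peak_library_bp,
                                float(np.median(lengths)), len(selected))
    else:
        report = FractionReport(window.label, None, None, None, 0)
    return selected, report


@dataclass
class DensitometryProfile:
    lengths_bp: np.ndarray
    density: np.ndarray
    peak_bp: float
    peak_library_bp: float  # includes full-length adapters


def densitometry_profile(lengths, bandwidth_bp: float = 3.0
                         ) -> DensitometryProfile:
    """Kernel-smoothed insert-length density and its mode.

    A histogram at 1-bp resolution is smoothed with a Gaussian kernel of the
    given bandwidth; the peak is the argmax of the smoothed density.
    """
    lengths = np.asarray([_insert_of(x) for x in lengths], dtype=int)
    if lengths.size == 0:
        raise ValueError("densitometry requires a non-empty set")
    lo = int(lengths.min() - 4 * bandwidth_bp - 1)
    hi = int(lengths.max() + 4 * bandwidth_bp + 2)
    grid = np.arange(lo, hi)
    hist = np.bincount(lengths - lo, minlength=len(grid)).astype(float)
    density = gaussian_filter1d(hist, sigma=max(bandwidth_bp, 1e-6))
    density /= max(density.sum(), 1e-300)
    peak = float(grid[int(np.argmax(density))])
    return DensitometryProfile(grid, density, peak, peak + ADAPTER_OFFSET_BP)
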