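"""Sphericity indicators computed from FSC distributions.

Biconcave (discocytic) erythrocytes scatter forward light in two
orientation-dependent regimes, so their FSC histogram is bimodal; cells
swollen toward spheres give a monomodal histogram.  Three scalar
indicators quantify where a sample sits on that axis:

* **excess kurtosis** (β₂ − 3) of the raw event values — 0 for a normal
  law, −2 for the extreme symmetric two-point law; it *decreases* toward
  bimodality;
* **PCD**, Pearson's second skewness coefficient of dissymmetry,
  3·(mean − median)/SD — a skewness surrogate;
* **SphI**, the Spherical Index — the ratio of the medians of the two
  parts of the histogram after splitting it between the modes; it
  *increases* with bimodality and is undefined for monomodal samples
  (unless a fixed cutoff is configured).

Kurtosis and PCD operate on raw events; SphI is a histogram-peak
procedure and operates on the binned channel counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .fcs_io import EventSample, Histogram, to_histogram

__all__ = [
    "DegenerateSampleError",
    "SphIConfig",
    "SphIDecomposition",
    "ShapeIndicators",
    "excess_kurtosis",
    "pcd",
    "sphi",
    "classify_modality",
    "indicators",
]

Estimator = Literal["g2", "G2", "b2"]


class DegenerateSampleError(ValueError):
    """Sample has zero variance or too few events for the requested statistic."""


# ---------------------------------------------------------------------------
# Moment-based indicators


def _central_moments(x: np.ndarray) -> tuple[int, float, float]:
    n = x.size
    mean = float(np.mean(x))
    d = x - mean
    m2 = float(np.mean(d * d))
    m4 = float(np.mean(d ** 4))
    return n, m2, m4


def excess_kurtosis(events: Sequence[float], estimator: Estimator = "G2") -> float:
    """Excess kurtosis (β₂ − 3 scale) of a sample.

    Three standard estimators are offered, differing only in small-sample
    correction.  With central moments ``m_k = mean((x - x̄)^k)``:

    * ``g2 = m4/m2² − 3`` — the plain moment estimator;
    * ``G2 = ((n+1)·g2 + 6)·(n−1)/((n−2)(n−3))`` — the bias-adjusted
      estimator (the default of R's ``e1071::kurtosis`` type-2 setting,
      and of SAS/SPSS); requires n ≥ 4;
    * ``b2 = m4/s⁴ − 3`` with ``s² = n·m2/(n−1)`` — the MINITAB/BMDP
      variant.

    All three converge for large n; the package default is G2.
    """
    x = np.asarray(events, dtype=float)
    if estimator not in ("g2", "G2", "b2"):
        raise ValueError(f"unknown kurtosis estimator {estimator!r}")
    min_n = 4 if estimator == "G2" else 2
    if x.size < min_n:
        raise DegenerateSampleError(
            f"estimator {estimator} needs at least {min_n} events, got {x.size}"
        )
    n, m2, m4 = _central_moments(x)
    if m2 <= 0.0:
        raise DegenerateSampleError("zero variance: kurtosis undefined")
    g2 = m4 / (m2 * m2) - 3.0
    if estimator == "g2":
        return g2
    if estimator == "G2":
        return ((n + 1.0) * g2 + 6.0) * (n - 1.0) / ((n - 2.0) * (n - 3.0))
    s2 = n * m2 / (n - 1.0)
    return m4 / (s2 * s2) - 3.0


def pcd(events: Sequence[float], ddof: int = 1) -> float:
    """Pearson's second skewness coefficient of dissymmetry.

    ``PCD = 3·(mean − median)/SD``; the SD uses the n−1 denominator by
    default (``ddof=0`` selects the population form).  Zero for any
    symmetric sample; its sign is the sign of mean − median.
    """
    x = np.asarray(events, dtype=float)
    if x.size < 2:
        raise DegenerateSampleError("PCD needs at least two events")
    sd = float(np.std(x, ddof=ddof))
    if sd <= 0.0:
        raise DegenerateSampleError("zero variance: PCD undefined")
    return 3.0 * (float(np.mean(x)) - float(np.median(x))) / sd


# ---------------------------------------------------------------------------
# Spherical Index


@dataclass(frozen=True)
class SphIConfig:
    """Tunables of the SphI peak-splitting procedure.

    ``smoothing_window``: width (channels, odd) of the centered moving
    sum used before peak detection; ``min_prominence_fraction``: a local
    maximum counts as a mode only if its prominence exceeds this fraction
    of the global smoothed maximum; ``min_events``: minimum total events
    for the procedure to be attempted; ``monomodal_policy``: what to do
    when fewer than two modes are detectable — ``"undefined"`` leaves
    SphI absent, ``"fixed_cutoff"`` splits at ``fixed_cutoff_channel``
    regardless (the fixed-channel convention seen in practice, e.g. a
    cutoff pinned at channel 101).
    """

    smoothing_window: int = 9
    min_prominence_fraction: float = 0.05
    min_events: int = 1000
    monomodal_policy: Literal["undefined", "fixed_cutoff"] = "undefined"
    fixed_cutoff_channel: Optional[float] = None

    def __post_init__(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")
        if not 0.0 <= self.min_prominence_fraction < 1.0:
            raise ValueError("min_prominence_fraction must be in [0, 1)")
        if self.monomodal_policy == "fixed_cutoff" and self.fixed_cutoff_channel is None:
            raise ValueError("fixed_cutoff policy requires fixed_cutoff_channel")


@dataclass
class SphIDecomposition:
    """Intermediate quantities of the SphI computation for one histogram."""

    bimodal: bool
    split_channel: Optional[int] = None
    mode_lower: Optional[int] = None
    mode_upper: Optional[int] = None
    cutoff_channel: Optional[float] = None
    median_lower: Optional[int] = None
    median_upper: Optional[int] = None
    config: SphIConfig = field(default_factory=SphIConfig)


def _smooth_counts(counts: np.ndarray, window: int) -> np.ndarray:
    """Centered moving sum with reflected ends.

    An integer moving *sum* (not average) is used: peak positions,
    prominences relative to the global maximum, and inter-mode minima are
    invariant to the positive scale factor, and exact int64 arithmetic
    makes plateau and tie handling deterministic.
    """
    if window == 1:
        return counts.astype(np.int64)
    half = window // 2
    padded = np.pad(counts.astype(np.int64), half, mode="reflect")
    kernel = np.ones(window, dtype=np.int64)
    return np.convolve(padded, kernel, mode="valid")


def _detect_modes(smoothed: np.ndarray, config: SphIConfig) -> list[int]:
    """Channels of qualifying modes: local maxima of the smoothed counts
    whose prominence exceeds the configured fraction of the global
    smoothed maximum.  Returns the two most prominent (ties broken toward
    the lower channel), in channel order; fewer if not detectable.
    """
    peaks, props = find_peaks(smoothed.astype(float), prominence=0)
    if peaks.size == 0:
        return []
    threshold = config.min_prominence_fraction * float(smoothed.max())
    qual = [(p, pr) for p, pr in zip(peaks, props["prominences"]) if pr > threshold]
    qual.sort(key=lambda t: (-t[1], t[0]))
    top = sorted(p for p, _ in qual[:2])
    return [int(p) for p in top]


def _binned_median(channels: np.ndarray, counts: np.ndarray) -> Optional[int]:
    """Lower median of binned data: the smallest channel whose cumulative
    count reaches half the total.  Integer arithmetic throughout."""
    total = int(counts.sum())
    if total == 0:
        return None
    csum = np.cumsum(counts)
    idx = int(np.searchsorted(2 * csum, total, side="left"))
    return int(channels[idx])


def _split_medians(hist: Histogram, cutoff: float) -> tuple[Optional[int], Optional[int]]:
    """Event-weighted medians of channels ≤ cutoff and > cutoff.

    A channel equal to ``floor(cutoff)`` belongs to the lower part.
    """
    channels = np.arange(hist.n_channels)
    boundary = math.floor(cutoff)
    lower = channels <= boundary
    med_lo = _binned_median(channels[lower], hist.counts[lower])
    med_hi = _binned_median(channels[~lower], hist.counts[~lower])
    return med_lo, med_hi


def sphi(hist: Histogram, config: SphIConfig | None = None) -> tuple[Optional[float], SphIDecomposition]:
    """Spherical Index of an FSC histogram, with its decomposition.

    The procedure: (1) smooth the counts; (2) locate the two most
    prominent modes and the minimum of the smoothed counts strictly
    between them (the provisional split); (3) re-find the mode of the
    *raw* counts on each side of the split; (4) set the final cutoff at
    the arithmetic mean of the two part modes (kept fractional); (5) take
    the event-weighted median of each final part; (6) SphI is the ratio
    upper median / lower median, > 1 whenever the upper part sits higher.

    Monomodal histograms follow ``config.monomodal_policy``: by default
    SphI is returned as ``None`` with ``bimodal=False`` in the
    decomposition; with the fixed-cutoff policy the split is imposed at
    ``config.fixed_cutoff_channel`` and SphI is still computed.
    """
    config = config or SphIConfig()
    if hist.n_events < config.min_events:
        raise DegenerateSampleError(
            f"histogram has {hist.n_events} events; SphI requires at least "
            f"{config.min_events}"
        )
    smoothed = _smooth_counts(hist.counts, config.smoothing_window)
    modes = _detect_modes(smoothed, config)
    decomp = SphIDecomposition(bimodal=len(modes) == 2, config=config)

    if len(modes) < 2:
        if config.monomodal_policy == "undefined":
            return None, decomp
        cutoff = float(config.fixed_cutoff_channel)
        decomp.cutoff_channel = cutoff
        med_lo, med_hi = _split_medians(hist, cutoff)
        decomp.median_lower, decomp.median_upper = med_lo, med_hi
        if med_lo is None or med_hi is None or med_lo == 0:
            return None, decomp
        return med_hi / med_lo, decomp

    p1, p2 = modes
    between = smoothed[p1 + 1 : p2]
    split = p1 + 1 + int(np.argmin(between))  # argmin → lowest channel on ties
    decomp.split_channel = split

    # Part modes from the *raw* counts; lowest channel on ties.
    mode_lower = int(np.argmax(hist.counts[: split + 1]))
    mode_upper = split + 1 + int(np.argmax(hist.counts[split + 1 :]))
    decomp.mode_lower, decomp.mode_upper = mode_lower, mode_upper

    cutoff = (mode_lower + mode_upper) / 2.0
    decomp.cutoff_channel = cutoff
    med_lo, med_hi = _split_medians(hist, cutoff)
    decomp.median_lower, decomp.median_upper = med_lo, med_hi
    if med_lo is None or med_hi is None or med_lo == 0:
        return None, decomp
    return med_hi / med_lo, decomp


def classify_modality(hist: Histogram, config: SphIConfig | None = None) -> str:
    """``"bimodal"`` if two sufficiently prominent modes are detectable in
    the smoothed histogram, else ``"monomodal"``."""
    config = config or SphIConfig()
    smoothed = _smooth_counts(hist.counts, config.smoothing_window)
    return "bimodal" if len(_detect_modes(smoothed, config)) == 2 else "monomodal"


# ---------------------------------------------------------------------------
# Composite


@dataclass
class ShapeIndicators:
    """The indicator triple for one sample, plus provenance details."""

    kurtosis_excess: float
    pcd: float
    sphi: Optional[float]
    estimator: Estimator
    decomposition: SphIDecomposition
    n_events: int
    meta: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flat dict for one CSV row of a batch report."""
        d = self.decomposition
        return {
            "kurtosis_excess": self.kurtosis_excess,
            "estimator": self.estimator,
            "pcd": self.pcd,
            "sphi": self.sphi,
            "bimodal": d.bimodal,
            "split_channel": d.split_channel,
            "cutoff_channel": d.cutoff_channel,
            "median_lower": d.median_lower,
            "median_upper": d.median_upper,
            "n_events": self.n_events,
            "n_clamped": self.meta.get("n_clamped"),
        }


def indicators(
    sample: EventSample,
    config: SphIConfig | None = None,
    estimator: Estimator = "G2",
) -> ShapeIndicators:
    """Compute all three sphericity indicators for one sample.

    Kurtosis and PCD are taken from the raw event values, SphI from the
    binned channel histogram.
    """
    config = config or SphIConfig()
    hist = to_histogram(sample)
    value, decomp = sphi(hist, config)
    return ShapeIndicators(
        kurtosis_excess=excess_kurtosis(sample.events, estimator=estimator),
        pcd=pcd(sample.events),
        sphi=value,
        estimator=estimator,
        decomposition=decomp,
        n_events=sample.n_events,
        meta={**sample.meta, "n_clamped": hist.meta.get("n_clamped")},
    )
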