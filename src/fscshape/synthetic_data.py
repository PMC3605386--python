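"""Seeded generators for FSC event samples and longitudinal cohorts.

No public FSC dataset accompanies the analyses this package implements,
so every stage is exercised on synthetic material with the same
structure:

* single acquisitions — two-component Gaussian mixtures on the linear
  1024-channel scale, ranging from clearly bimodal (discocyte-like, two
  orientation modes) to monomodal (spherocyte-like) as the component
  separation shrinks;
* an osmolarity series — per subject, one sample per buffer osmolarity,
  with the mode separation an increasing function of osmolarity (lower
  osmolarity swells cells toward spheres and merges the modes);
* longitudinal cohorts — repeated indicator measurements per subject
  generated from the random-intercept model
  ``y_ij = μ + b_i + ε_ij``, ``b_i ~ N(0, σ²_between)``,
  ``ε_ij ~ N(0, σ²_within)``,
  which is exactly the model the variance-component analysis fits.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fcs_io import EventSample

__all__ = [
    "MixtureSpec",
    "OsmolarityScenario",
    "CohortSpec",
    "simulate_fsc",
    "simulate_osmolarity_series",
    "simulate_cohort",
    "DEFAULT_OSMOLARITIES",
    "DEFAULT_TIME_POINTS",
]

#: Buffer osmolarities (mosmol/kg) of the standard osmotic-stress series.
DEFAULT_OSMOLARITIES: tuple[float, ...] = (259.0, 285.0, 300.0, 315.0, 335.0)

#: Sampling days of the standard longitudinal design (relative to an
#: intervention at day 0).
DEFAULT_TIME_POINTS: tuple[str, ...] = ("d-1", "d3", "d7")


@dataclass(frozen=True)
class MixtureSpec:
    """Two-component Gaussian mixture on the linear channel scale.

    Defaults emulate a clearly bimodal discocyte acquisition: modes near
    channels 60 and 148 with equal weight.  ``weight_upper`` is the
    mixing fraction of the upper component; 0 or 1 gives a monomodal
    sample.
    """

    mu_lower: float = 60.0
    mu_upper: float = 148.0
    sigma_lower: float = 10.0
    sigma_upper: float = 10.0
    weight_upper: float = 0.5
    n_events: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu_lower <= self.mu_upper <= 1023.0:
            raise ValueError("require 0 <= mu_lower <= mu_upper <= 1023")
        if self.sigma_lower <= 0 or self.sigma_upper <= 0:
            raise ValueError("sigmas must be positive")
        if not 0.0 <= self.weight_upper <= 1.0:
            raise ValueError("weight_upper must be in [0, 1]")
        if self.n_events < 1:
            raise ValueError("n_events must be at least 1")

    @property
    def separation(self) -> float:
        return self.mu_upper - self.mu_lower


def simulate_fsc(spec: MixtureSpec) -> EventSample:
    """Draw one FSC event sample from a two-Gaussian mixture.

    The number of upper-component events is binomial in
    ``weight_upper``; values are clipped (not rejected) at the channel
    bounds [0, 1023], matching the clamp semantics of histogram binning.
    """
    rng = np.random.default_rng(spec.seed)
    n_upper = int(rng.binomial(spec.n_events, spec.weight_upper))
    lower = rng.normal(spec.mu_lower, spec.sigma_lower, spec.n_events - n_upper)
    upper = rng.normal(spec.mu_upper, spec.sigma_upper, n_upper)
    events = np.clip(np.concatenate([lower, upper]), 0.0, 1023.0)
    rng.shuffle(events)
    meta = {
        "generator": "two_gaussian_mixture",
        "mu_lower": spec.mu_lower,
        "mu_upper": spec.mu_upper,
        "sigma_lower": spec.sigma_lower,
        "sigma_upper": spec.sigma_upper,
        "weight_upper": spec.weight_upper,
        "seed": spec.seed,
    }
    return EventSample(events=events, meta=meta)


@dataclass(frozen=True)
class OsmolarityScenario:
    """Osmotic-stress series: subjects × osmolarities.

    The mixture separation is affine in osmolarity,
    ``separation(osm) = separation_min + slope·(osm − osmolarities[0])``,
    strictly increasing, so kurtosis falls (and SphI rises) with
    osmolarity.  Per-subject offsets on separation and mixture center
    emulate biological between-subject variation.  Defaults: 10 subjects
    × 5 osmolarities (50 samples) at 50 000 events each.
    """

    osmolarities: tuple[float, ...] = DEFAULT_OSMOLARITIES
    n_subjects: int = 10
    n_events: int = 50_000
    separation_min: float = 12.0
    separation_max: float = 88.0
    center_channel: float = 104.0
    sigma: float = 14.0
    subject_sd_separation: float = 3.0
    subject_sd_center: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.osmolarities) < 2 or np.any(np.diff(self.osmolarities) <= 0):
            raise ValueError("osmolarities must be strictly increasing")
        if self.separation_max <= self.separation_min:
            raise ValueError("separation must increase with osmolarity")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")

    def separation(self, osmolarity: float) -> float:
        osm = np.asarray(self.osmolarities, dtype=float)
        slope = (self.separation_max - self.separation_min) / (osm[-1] - osm[0])
        return float(self.separation_min + slope * (osmolarity - osm[0]))


def simulate_osmolarity_series(scenario: OsmolarityScenario) -> list[EventSample]:
    """One EventSample per subject × osmolarity, bimodality increasing
    with osmolarity; sample metadata carries subject and osmolarity."""
    rng = np.random.default_rng(scenario.seed)
    samples: list[EventSample] = []
    for subj in range(1, scenario.n_subjects + 1):
        d_sep = float(rng.normal(0.0, scenario.subject_sd_separation))
        d_center = float(rng.normal(0.0, scenario.subject_sd_center))
        for osm in scenario.osmolarities:
            sep = max(scenario.separation(osm) + d_sep, 0.0)
            center = scenario.center_channel + d_center
            spec = MixtureSpec(
                mu_lower=center - sep / 2.0,
                mu_upper=center + sep / 2.0,
                sigma_lower=scenario.sigma,
                sigma_upper=scenario.sigma,
                weight_upper=0.5,
                n_events=scenario.n_events,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            sample = simulate_fsc(spec)
            sample.meta.update(subject=subj, osmolarity=float(osm))
            samples.append(sample)
    return samples


@dataclass(frozen=True)
class CohortSpec:
    """Longitudinal cohort under the random-intercept model.

    ``mu`` is the population mean of the indicator, ``sigma_between``
    the SD of the subject effects ``b_i``, ``sigma_within`` the residual
    SD across repeated visits.  Defaults give 10 subjects at 3 visits —
    the design of a typical small repeated-measures reliability study.
    """

    mu: float = 0.0
    sigma_between: float = 0.2
    sigma_within: float = 0.1
    n_subjects: int = 10
    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_between < 0 or self.sigma_within < 0:
            raise ValueError("sigmas must be non-negative")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if len(self.time_points) < 2:
            raise ValueError("need at least 2 time points")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Long-format cohort table with columns (subject, time_point, value)
    drawn from ``y_ij = μ + b_i + ε_ij``."""
    rng = np.random.default_rng(spec.seed)
    b = rng.normal(0.0, spec.sigma_between, spec.n_subjects)
    rows = []
    for i in range(spec.n_subjects):
        eps = rng.normal(0.0, spec.sigma_within, len(spec.time_points))
        for j, tp in enumerate(spec.time_points):
            rows.append(
                {"subject": f"S{i + 1:02d}", "time_point": tp,
                 "value": spec.mu + b[i] + eps[j]}
            )
    return pd.DataFrame(rows, columns=["subject", "time_point", "value"])
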