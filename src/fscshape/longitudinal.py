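"""Repeated-measures statistics: variance components, reliability, and
between-indicator agreement.

The reliability analysis decomposes an indicator measured repeatedly in
several subjects into inter-individual and intra-individual variation by
fitting the random-intercept model ``y_ij = μ + b_i + ε_ij`` by maximum
likelihood.  From the fit it reports:

* ``sd_between`` = σ̂_b and ``sd_within`` = σ̂_ε;
* the Harris ``r`` ratio σ̂²_ε/σ̂²_b of intra- to inter-individual
  variance — when r < 0.6, population-based reference ranges are
  insensitive for monitoring an individual, so the indicator is a
  candidate for longitudinal (within-subject) monitoring;
* the standard error of measurement SEM = σ̂_ε/√(number of subjects).

Condition effects across repeated within-subject measurements are tested
with the Friedman rank test plus adjusted pairwise Wilcoxon signed-rank
comparisons, and agreement between indicators with Spearman's ρ.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceComponents",
    "FriedmanResult",
    "validate_cohort_table",
    "read_cohort_csv",
    "write_cohort_csv",
    "variance_components",
    "standard_error_of_measurement",
    "spearman",
    "friedman_adjusted",
    "indicator_comparison",
]


class DesignError(ValueError):
    """Raised for cohort tables that cannot support the requested analysis."""


@dataclass
class VarianceComponents:
    """Variance decomposition of one indicator over a cohort."""

    mean: float
    sd_between: float
    sd_within: float
    r_ratio: float
    sem: float
    n_subjects: int
    ratio_scale: str = "variance"

    def to_row(self) -> dict:
        return {
            "mean": self.mean,
            "sem": self.sem,
            "sd_between": self.sd_between,
            "sd_within": self.sd_within,
            "r_ratio": self.r_ratio,
            "n_subjects": self.n_subjects,
            "ratio_scale": self.ratio_scale,
        }


def validate_cohort_table(data: pd.DataFrame) -> pd.DataFrame:
    """Check the (subject, time_point, value) long-format contract."""
    required = {"subject", "time_point", "value"}
    missing = required - set(data.columns)
    if missing:
        raise DesignError(f"cohort table lacks columns: {sorted(missing)}")
    if data.duplicated(subset=["subject", "time_point"]).any():
        raise DesignError("duplicate (subject, time_point) pairs")
    per_subject = data.groupby("subject")["time_point"].nunique()
    if len(per_subject) < 2:
        raise DesignError("need at least 2 subjects")
    if (per_subject < 2).all():
        raise DesignError("every subject has fewer than 2 time points")
    if not np.all(np.isfinite(data["value"].to_numpy(dtype=float))):
        raise DesignError("non-finite indicator values")
    return data


def read_cohort_csv(path) -> pd.DataFrame:
    data = pd.read_csv(path)
    return validate_cohort_table(data)


def write_cohort_csv(data: pd.DataFrame, path) -> None:
    data.to_csv(path, index=False, columns=["subject", "time_point", "value"])


def standard_error_of_measurement(sd_within: float, n_subjects: int) -> float:
    """SEM = intra-individual SD / √(number of subjects)."""
    return sd_within / math.sqrt(n_subjects)


def variance_components(
    data: pd.DataFrame,
    ratio_scale: Literal["variance", "sd"] = "variance",
) -> VarianceComponents:
    """Fit ``y_ij = μ + b_i + ε_ij`` by maximum likelihood and report the
    variance decomposition.

    Balanced and unbalanced designs are both accepted.  ``ratio_scale``
    selects whether the Harris r ratio is reported on the variance scale
    (σ²_within/σ²_between, the default) or on the SD scale.  A singular
    fit (σ̂_b → 0) yields ``r_ratio = inf`` rather than an exception.
    All components are returned at full precision; round only for
    presentation.
    """
    import warnings

    from statsmodels.regression.mixed_linear_model import MixedLM

    data = validate_cohort_table(data)
    y = data["value"].to_numpy(dtype=float)
    groups = data["subject"].to_numpy()
    exog = np.ones((len(y), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = MixedLM(y, exog, groups=groups).fit(reml=False)
    var_within = float(fit.scale)
    var_between = float(np.asarray(fit.cov_re).ravel()[0])
    sd_within = math.sqrt(max(var_within, 0.0))
    sd_between = math.sqrt(max(var_between, 0.0))
    n_subjects = int(pd.unique(groups).size)
    if ratio_scale == "variance":
        r = var_within / var_between if var_between > 0 else math.inf
    elif ratio_scale == "sd":
        r = sd_within / sd_between if sd_between > 0 else math.inf
    else:
        raise ValueError(f"unknown ratio_scale {ratio_scale!r}")
    return VarianceComponents(
        mean=float(fit.params[0]),
        sd_between=sd_between,
        sd_within=sd_within,
        r_ratio=r,
        sem=standard_error_of_measurement(sd_within, n_subjects),
        n_subjects=n_subjects,
        ratio_scale=ratio_scale,
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; two-sided p.

    Constant input leaves the correlation undefined and raises."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rank correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class FriedmanResult:
    chi2: float
    p_value: float
    pairwise: list  # [((cond_i, cond_j), adjusted_p), ...]
    adjust: str = "bonferroni"


def _friedman_two_conditions(matrix: np.ndarray) -> tuple[float, float]:
    # Tie-corrected Friedman rank statistic, valid for k = 2 where it
    # coincides with the two-sided sign test's chi-square form.
    n, k = matrix.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    col_sums = ranks.sum(axis=0)
    ties = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    denom = 1.0 - ties / (n * k * (k * k - 1))
    if denom <= 0:  # all rows fully tied
        return 0.0, 1.0
    chi2 = (12.0 / (n * k * (k + 1)) * float(np.sum(col_sums**2)) - 3.0 * n * (k + 1)) / denom
    return chi2, float(stats.chi2.sf(chi2, k - 1))


def friedman_adjusted(
    matrix,
    conditions: Optional[Sequence] = None,
    adjust: Literal["bonferroni", "holm"] = "bonferroni",
) -> FriedmanResult:
    """Friedman omnibus test across conditions with adjusted pairwise
    Wilcoxon signed-rank comparisons.

    ``matrix`` is subjects × conditions with complete blocks (missing
    cells are a design error; no imputation).  Pairwise two-sided
    Wilcoxon tests are adjusted by Bonferroni (p × number of pairs,
    capped at 1) or Holm.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise DesignError("expected a subjects × conditions matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise DesignError("need at least 2 subjects and 2 conditions")
    if not np.all(np.isfinite(m)):
        raise DesignError("missing or non-finite cells (complete blocks required)")
    if conditions is None:
        conditions = list(range(k))
    if len(conditions) != k:
        raise DesignError("condition labels do not match the number of columns")

    if k == 2:
        chi2, p = _friedman_two_conditions(m)
    elif all(len(np.unique(row)) == 1 for row in m):
        chi2, p = 0.0, 1.0  # every block fully tied: statistic degenerate
    else:
        res = stats.friedmanchisquare(*(m[:, j] for j in range(k)))
        chi2, p = float(res.statistic), float(res.pvalue)
        if math.isnan(chi2):
            chi2, p = 0.0, 1.0

    pairs = list(itertools.combinations(range(k), 2))
    raw = []
    for i, j in pairs:
        diff = m[:, i] - m[:, j]
        if np.all(diff == 0):
            raw.append(1.0)
        else:
            raw.append(float(stats.wilcoxon(m[:, i], m[:, j]).pvalue))
    if adjust == "bonferroni":
        adj = [min(1.0, pv * len(pairs)) for pv in raw]
    elif adjust == "holm":
        order = np.argsort(raw)
        adj = [0.0] * len(raw)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, raw[idx] * (len(pairs) - rank))
            adj[idx] = min(1.0, running)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    pairwise = [((conditions[i], conditions[j]), a) for (i, j), a in zip(pairs, adj)]
    return FriedmanResult(chi2=chi2, p_value=p, pairwise=pairwise, adjust=adjust)


def indicator_comparison(samples: Iterable) -> pd.DataFrame:
    """Pairwise Spearman agreement between SphI, PCD and kurtosis.

    ``samples`` is an iterable of ShapeIndicators with all three values
    defined.  Returns a 3×3 symmetric DataFrame of ρ (unit diagonal);
    the companion p-values are attached as ``.attrs["p_values"]``.  Rows
    and columns are ordered (sphi, pcd, kurtosis).
    """
    rows = []
    for s in samples:
        if s.sphi is None:
            continue
        rows.append((s.sphi, s.pcd, s.kurtosis_excess))
    if len(rows) < 3:
        raise ValueError("need at least 3 samples with all indicators defined")
    arr = np.asarray(rows, dtype=float)
    names = ["sphi", "pcd", "kurtosis"]
    rho = np.eye(3)
    pval = np.zeros((3, 3))
    for i, j in itertools.combinations(range(3), 2):
        r, p = spearman(arr[:, i], arr[:, j])
        rho[i, j] = rho[j, i] = r
        pval[i, j] = pval[j, i] = p
    out = pd.DataFrame(rho, index=names, columns=names)
    out.attrs["p_values"] = pd.DataFrame(pval, index=names, columns=names)
    return out
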