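"""Univariate rank statistics and effect-size conversions.

The battery screens each sequence covariate against measured efficiency
the way heavily tied qPCR data demand: asymptotic Spearman tests for
quantitative covariates (Z = rho * sqrt(n-1), two-sided normal p),
Kruskal-Wallis for categorical ones (tie-corrected H, chi-square p), and
asymptotic Wilcoxon-Mann-Whitney for two-group post-hocs (U with
tie-corrected variance, no continuity correction).  Ties can be handled by
deterministic midranks (default) or by seeded random assignment of
distinct ranks within tie groups.

Effect sizes are linked by the standard conversion chain
d = 2*rho/sqrt(1-rho^2), logOdds = d*pi/sqrt(3), g = d*(1 - 3/(4n-9)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ConstantInputError

__all__ = [
    "TestResult",
    "d_to_g",
    "d_to_logodds",
    "kruskal_wallis_asymptotic",
    "r_to_d",
    "rank_with_ties",
    "spearman_asymptotic",
    "univariate_battery",
    "wilcoxon_mw_asymptotic",
    "z_to_p",
]


@dataclass(frozen=True)
class TestResult:
    """One univariate test with its effect-size chain."""

    variable: str
    statistic_type: str        # "Z" or "chi2"
    statistic: float
    p_value: float
    n: int
    df: int | None = None      # chi2 only
    rho: float | None = None
    cohen_d: float | None = None
    hedges_g: float | None = None
    log_odds: float | None = None


def rank_with_ties(
    values, tie_policy: str = "midrank", rng: np.random.Generator | None = None
) -> np.ndarray:
    """Rank a vector, resolving ties by midranks or by seeded random splits.

    ``random`` assigns each tie group the distinct integer ranks it spans,
    permuted uniformly at random ("random rank averaging"); it requires an
    *rng*.
    """
    values = np.asarray(values, dtype=float)
    if tie_policy == "midrank":
        return stats.rankdata(values, method="average")
    if tie_policy == "random":
        if rng is None:
            raise ConfigurationError("tie_policy='random' requires a seeded rng")
        order = np.lexsort((rng.random(len(values)), values))
        ranks = np.empty(len(values))
        ranks[order] = np.arange(1, len(values) + 1)
        return ranks
    raise ConfigurationError(f"unknown tie policy {tie_policy!r}")


def _effects(rho: float, n: int) -> dict:
    # conversions need |rho| < 1; perfect correlations map to huge finite d
    clipped = min(max(rho, -0.999999), 0.999999)
    d = r_to_d(clipped)
    return dict(rho=rho, cohen_d=d, log_odds=d_to_logodds(d),
                hedges_g=d_to_g(d, n) if n > 3 else None)


def spearman_asymptotic(
    x, y, tie_policy: str = "midrank", seed: int | None = None, name: str = "x~y"
) -> TestResult:
    """Asymptotic Spearman rank correlation test.

    rho is the Pearson correlation of the (tie-resolved) ranks, the
    statistic is Z = rho * sqrt(n - 1), and p is two-sided normal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ConfigurationError("x and y must have equal length")
    n = len(x)
    if n < 10:
        raise ConfigurationError(f"asymptotic Spearman needs n >= 10, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    rng = np.random.default_rng(seed) if tie_policy == "random" else None
    rx = rank_with_ties(x, tie_policy, rng)
    ry = rank_with_ties(y, tie_policy, rng)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    z = rho * math.sqrt(n - 1)
    return TestResult(
        variable=name, statistic_type="Z", statistic=z, p_value=z_to_p(z),
        n=n, **_effects(rho, n),
    )


def kruskal_wallis_asymptotic(values, groups, name: str = "values~groups") -> TestResult:
    """Kruskal-Wallis H test with tie correction and chi-square p (df = k-1)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ConfigurationError("values and groups must have equal length")
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ConfigurationError("need at least 2 groups")
    small = [len(s) for s in samples if len(s) < 2]
    if small:
        raise ConfigurationError("every group needs at least 2 observations")
    if np.ptp(values) == 0:
        # identical distributions: H = 0 by definition, scipy raises instead
        return TestResult(variable=name, statistic_type="chi2", statistic=0.0,
                          p_value=1.0, n=len(values), df=len(samples) - 1)
    h, p = stats.kruskal(*samples)
    return TestResult(
        variable=name, statistic_type="chi2", statistic=float(h),
        p_value=float(p), n=len(values), df=len(samples) - 1,
    )


def wilcoxon_mw_asymptotic(
    a, b, tie_policy: str = "midrank", seed: int | None = None, name: str = "a~b"
) -> TestResult:
    """Asymptotic Wilcoxon-Mann-Whitney test.

    Z standardizes U with the tie-corrected variance and a 0.5 continuity
    correction (the null is discrete; the correction brings the normal tail
    close to the permutation p).  The reported ``rho`` is the
    rank-biserial-style correlation Z/sqrt(n).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("both samples need at least 2 observations")
    n1, n2 = len(a), len(b)
    n = n1 + n2
    combined = np.concatenate([a, b])
    rng = np.random.default_rng(seed) if tie_policy == "random" else None
    ranks = rank_with_ties(combined, tie_policy, rng)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult(variable=name, statistic_type="Z", statistic=0.0,
                          p_value=1.0, n=n, **_effects(0.0, n))
    shift = u - mu
    corrected = max(abs(shift) - 0.5, 0.0) * math.copysign(1.0, shift) if shift else 0.0
    z = corrected / math.sqrt(var)
    rho = z / math.sqrt(n)
    return TestResult(
        variable=name, statistic_type="Z", statistic=float(z),
        p_value=z_to_p(z), n=n, **_effects(rho, n),
    )


# ---------------------------------------------------------------------------
# effect-size conversion chain

def r_to_d(rho: float) -> float:
    """Cohen's d from a correlation: d = 2*rho / sqrt(1 - rho^2)."""
    if abs(rho) >= 1:
        raise ConfigurationError(f"|rho| must be < 1, got {rho}")
    return 2.0 * rho / math.sqrt(1.0 - rho * rho)


def d_to_logodds(d: float) -> float:
    """Log odds ratio from Cohen's d: d * pi / sqrt(3)."""
    return d * math.pi / math.sqrt(3.0)


def d_to_g(d: float, n: int) -> float:
    """Hedges' g, the small-sample unbiased d: g = d * (1 - 3/(4n - 9))."""
    if n <= 3:
        raise ConfigurationError(f"Hedges' g needs n > 3, got {n}")
    return d * (1.0 - 3.0 / (4.0 * n - 9.0))


def z_to_p(z: float) -> float:
    """Two-sided normal p-value, accurate far into the tails."""
    if not math.isfinite(z):
        raise ConfigurationError(f"Z must be finite, got {z}")
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# the battery

QUANTITATIVE_DEFAULT = [
    "primersLength", "lengthSequence", "gcSequence",
    "aRepeats", "tRepeats", "cRepeats", "gRepeats",
    "primersSelfcom", "primerDimers", "gcImbalance", "gcPrimers",
    "sequencePalindromes",
]
CATEGORICAL_DEFAULT = ["machine", "template", "source", "operator", "species", "var"]


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def univariate_battery(
    table: pd.DataFrame,
    response: str = "efficiency",
    quantitative: list[str] | None = None,
    categorical: list[str] | None = None,
    tie_policy: str = "midrank",
    seed: int | None = None,
    adjust: str = "none",
) -> pd.DataFrame:
    """Screen every covariate against the response; one row per variable.

    Quantitative covariates (booleans are coerced to 0/1) get the Spearman
    test, categorical ones the Kruskal-Wallis test.  Columns follow the
    conventional univariate-summary layout: variable, test, statistic, df,
    rho, d, logOdds, p (plus p_adj with ``adjust='holm'``).  Raw p-values
    are reported by default; no multiplicity correction is applied.
    """
    if adjust not in ("none", "holm"):
        raise ConfigurationError(f"unknown adjustment {adjust!r}")
    quantitative = QUANTITATIVE_DEFAULT if quantitative is None else quantitative
    categorical = CATEGORICAL_DEFAULT if categorical is None else categorical
    y = table[response].to_numpy(dtype=float)
    rows = []
    for var in quantitative:
        if var not in table.columns:
            continue
        x = table[var].astype(float).to_numpy()
        res = spearman_asymptotic(x, y, tie_policy=tie_policy, seed=seed, name=var)
        rows.append(res)
    for var in categorical:
        if var not in table.columns:
            continue
        g = table[var].astype(str).to_numpy()
        counts = pd.Series(g).value_counts()
        if len(counts) < 2 or counts.min() < 2:
            continue
        rows.append(kruskal_wallis_asymptotic(y, g, name=var))
    out = pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "test": [r.statistic_type for r in rows],
            "statistic": [r.statistic for r in rows],
            "df": [r.df for r in rows],
            "rho": [r.rho for r in rows],
            "d": [r.cohen_d for r in rows],
            "logOdds": [r.log_odds for r in rows],
            "p": [r.p_value for r in rows],
        }
    )
    if adjust == "holm":
        out["p_adj"] = holm_adjust(out["p"].to_numpy())
    return out
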