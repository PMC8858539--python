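"""Fisher's combined-probability meta-analysis and multiplicity thresholds.

Fisher's method combines k independent p-values through
``X2 = -2 * sum(ln p_i)``, which is chi-square with 2k degrees of freedom
under the joint null.  For even df the upper tail has the closed form
``exp(-x/2) * sum_{i<k} (x/2)^i / i!``; the implementation evaluates the
series and cross-checks it against the continuous chi-square survival
function.  The module also carries the study-wide Bonferroni thresholds and
the conventional exome-wide significance constant 2.5e-6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .datatypes import ConfigError

EXOME_WIDE_SIGNIFICANCE = 2.5e-6


@dataclass
class MetaResult:
    p_values: list[float]
    labels: list[str]
    statistic: float
    df: int
    combined_p: float

    @property
    def k(self) -> int:
        return len(self.p_values)


def chi2_sf_even_df(x: float, k: int) -> float:
    """Upper tail of chi-square with 2k df via the finite Poisson series."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    h = x / 2.0
    term = 1.0
    total = 1.0
    for i in range(1, k):
        term *= h / i
        total += term
    return math.exp(-h) * total


def fisher_combine(p_values, labels=None, p_floor: float | None = None) -> MetaResult:
    """Fisher's method: X2 = -2 sum(ln p) ~ chi2(2k) under the null.

    ``p_floor`` (optional) clips tiny p-values before taking logs; by default
    a zero p-value is an error rather than silently floored.
    """
    ps = [float(p) for p in np.atleast_1d(np.asarray(p_values, dtype=float))]
    if not ps:
        raise ConfigError("no p-values to combine")
    if labels is None:
        labels = [f"p{i + 1}" for i in range(len(ps))]
    if len(labels) != len(ps):
        raise ConfigError("labels length must match p_values")
    for p in ps:
        if not np.isfinite(p) or p > 1.0:
            raise ConfigError(f"invalid p-value {p}")
        if p <= 0.0 and p_floor is None:
            raise ConfigError("p-value of 0; supply p_floor to proceed")
    if p_floor is not None:
        ps = [max(p, p_floor) for p in ps]
    k = len(ps)
    x2 = -2.0 * sum(math.log(p) for p in ps)
    p_series = chi2_sf_even_df(x2, k)
    p_sf = float(chi2.sf(x2, 2 * k))
    if abs(p_series - p_sf) > 1e-9 * max(p_sf, 1e-300):
        rel = abs(p_series - p_sf) / max(p_sf, 1e-300)
        if rel > 1e-6:  # pragma: no cover - defensive
            raise AssertionError(
                f"even-df series and chi2.sf disagree (rel {rel:.2e})")
    return MetaResult(ps, list(labels), x2, 2 * k, p_series)


def bonferroni_threshold(factor_counts, alpha: float = 0.05) -> float:
    """alpha divided by the product of independent test counts."""
    counts = list(np.atleast_1d(np.asarray(factor_counts, dtype=float)))
    if not counts:
        raise ConfigError("factor_counts must be non-empty")
    if any(c < 1 for c in counts):
        raise ConfigError("all counts must be >= 1")
    return alpha / math.prod(counts)
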