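"""Two-by-two cohort statistics: relative risk, exact test, concordance.

The central comparison is carrier prevalence between family-history
cohorts. For a 2x2 table with ``a`` carriers among ``n1`` exposed
(increased-risk) and ``c`` carriers among ``n2`` unexposed participants,
the relative risk and its log-normal confidence interval follow the
standard epidemiological (Altman) formulas::

    RR        = (a/n1) / (c/n2)
    SE(lnRR)  = sqrt(1/a - 1/n1 + 1/c - 1/n2)
    CI        = exp(ln RR +/- z * SE)

with z = 1.959964 for a 95% interval. With a zero cell the point estimate
and interval are reported as undefined (no continuity correction by
default; a Haldane-Anscombe +0.5 correction is available by flag).

The significance test is Fisher's exact test, two-tailed by the
probability-summation method, computed with exact integer arithmetic so
that ties between table probabilities are decided exactly rather than to
floating-point tolerance. A chi-square option is provided.

Display conventions (kept separate from the numeric results): ratio
estimates and their interval bounds are *truncated* toward zero at the
displayed precision, so a displayed bound never overstates the estimate;
proportions are percentages *rounded* half away from zero to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as _scipy_stats

from .errors import DataError

Z_95 = 1.959964


# ---------------------------------------------------------------------------
# display helpers


def trunc_ratio(x: float, decimals: int = 1) -> float:
    """Truncate a non-negative ratio toward zero at ``decimals`` places.

    A tiny epsilon guards against binary representation pushing an exactly
    representable decimal (6.39 stored as 6.38999...) below its boundary.
    """
    if math.isnan(x) or math.isinf(x):
        return x
    scale = 10**decimals
    return math.floor(x * scale + 1e-9) / scale


def round_pct(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded half away from zero."""
    if denominator == 0:
        raise DataError("percentage with zero denominator")
    x = 100.0 * numerator / denominator
    scale = 10**decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def one_in_n(total: int, carriers: int) -> str | None:
    """Display-only '1 in N' string, N rounded half away from zero."""
    if carriers <= 0:
        return None
    return f"1 in {math.floor(total / carriers + 0.5)}"


# ---------------------------------------------------------------------------
# relative risk


@dataclass
class ContingencyResult:
    """Relative risk of a 2x2 exposure/outcome table with CI and p-value."""

    a: int  # exposed carriers
    n1: int  # exposed total
    c: int  # unexposed carriers
    n2: int  # unexposed total
    rr: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    undefined: bool = False  # zero cell, no correction applied

    @property
    def one_in_exposed(self) -> str | None:
        return one_in_n(self.n1, self.a)

    @property
    def one_in_unexposed(self) -> str | None:
        return one_in_n(self.n2, self.c)

    def formatted(self, decimals: int = 1, ci_decimals: int | None = None) -> str:
        """'RR (low-high)' with ratio truncation; CI precision defaults to
        the RR precision but may differ (reports show both 1- and 2-decimal
        renderings of the point estimate)."""
        if self.undefined:
            return "undefined"
        if ci_decimals is None:
            ci_decimals = min(decimals, 1)
        fmt = f"{{:.{decimals}f}}"
        cfmt = f"{{:.{ci_decimals}f}}"
        return (
            f"{fmt.format(trunc_ratio(self.rr, decimals))} "
            f"({cfmt.format(trunc_ratio(self.ci_low, ci_decimals))}-"
            f"{cfmt.format(trunc_ratio(self.ci_high, ci_decimals))})"
        )


def _validate_counts(a: int, n1: int, c: int, n2: int) -> None:
    if n1 <= 0 or n2 <= 0:
        raise DataError("group totals must be positive")
    if a < 0 or c < 0:
        raise DataError("cell counts must be non-negative")
    if a > n1 or c > n2:
        raise DataError("cell count exceeds its group total")


def relative_risk(
    a: int,
    n1: int,
    c: int,
    n2: int,
    z: float = Z_95,
    haldane: bool = False,
    p_method: str = "fisher",
) -> ContingencyResult:
    """Relative risk with log-normal CI for a 2x2 cohort table.

    ``haldane`` applies the +0.5 continuity correction to all four cells
    when a zero cell would otherwise leave the estimate undefined.
    ``p_method`` is ``fisher`` (exact, default) or ``chi2``.
    """
    _validate_counts(a, n1, c, n2)
    p_value = exact_test(a, n1, c, n2) if p_method == "fisher" else chi2_test(a, n1, c, n2)
    if (a == 0 or c == 0) and not haldane:
        return ContingencyResult(
            a, n1, c, n2, math.nan, math.nan, math.nan, z, p_value, undefined=True
        )
    if haldane and (a == 0 or c == 0):
        fa, fn1, fc, fn2 = a + 0.5, n1 + 1.0, c + 0.5, n2 + 1.0
    else:
        fa, fn1, fc, fn2 = float(a), float(n1), float(c), float(n2)
    rr = (fa / fn1) / (fc / fn2)
    se = math.sqrt(1 / fa - 1 / fn1 + 1 / fc - 1 / fn2)
    ci_low = math.exp(math.log(rr) - z * se)
    ci_high = math.exp(math.log(rr) + z * se)
    return ContingencyResult(a, n1, c, n2, rr, ci_low, ci_high, z, p_value)


# ---------------------------------------------------------------------------
# exact test


def exact_test(a: int, n1: int, c: int, n2: int) -> float:
    """Two-tailed Fisher exact p for a 2x2 cohort table.

    Sums, over the fixed-margin family of tables, the probabilities of all
    tables no more probable than the observed one. Table weights are exact
    integers (``C(n1, k) * C(n2, K-k)``), so ties are exact; the ratio of
    integer sums is converted to float only at the end.
    """
    _validate_counts(a, n1, c, n2)
    K = a + c  # carrier margin
    lo = max(0, K - n2)
    hi = min(K, n1)
    weights = {k: math.comb(n1, k) * math.comb(n2, K - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    numerator = sum(w for w in weights.values() if w <= w_obs)
    denominator = sum(weights.values())
    return numerator / denominator


def chi2_test(a: int, n1: int, c: int, n2: int) -> float:
    """Pearson chi-square (with Yates continuity correction) alternative."""
    _validate_counts(a, n1, c, n2)
    table = [[a, n1 - a], [c, n2 - c]]
    res = _scipy_stats.chi2_contingency(table, correction=True)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# concordance


@dataclass
class ConcordanceTable:
    """Carrier-status x family-history-risk partition of the FH-available
    cohort."""

    carrier_increased: int
    carrier_average: int
    noncarrier_increased: int
    noncarrier_average: int

    @property
    def total(self) -> int:
        return (
            self.carrier_increased
            + self.carrier_average
            + self.noncarrier_increased
            + self.noncarrier_average
        )

    @property
    def concordant(self) -> int:
        """Carrier with increased-risk history, or non-carrier with average."""
        return self.carrier_increased + self.noncarrier_average

    @property
    def discordant(self) -> int:
        return self.carrier_average + self.noncarrier_increased

    def percentages(self) -> dict[str, float]:
        t = self.total
        return {
            "carrier_increased": round_pct(self.carrier_increased, t),
            "carrier_average": round_pct(self.carrier_average, t),
            "noncarrier_increased": round_pct(self.noncarrier_increased, t),
            "noncarrier_average": round_pct(self.noncarrier_average, t),
            "concordant": round_pct(self.concordant, t),
            "discordant": round_pct(self.discordant, t),
        }


def concordance_table(cells: tuple[int, int, int, int]) -> ConcordanceTable:
    """Build the concordance partition from cells (carrier & increased,
    carrier & average, non-carrier & increased, non-carrier & average)."""
    table = ConcordanceTable(*cells)
    if min(cells) < 0:
        raise DataError("negative cell count")
    return table
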