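"""Case-control association statistics for 2x2 carrier tables.

Conventions follow the classical epidemiological layout::

                 carrier   non-carrier
    cases            a          b
    controls         c          d

Odds ratio ad/bc with the Woolf (log-normal) confidence interval
exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)); Pearson chi-square on one
degree of freedom, uncorrected by default (Yates continuity correction is
available as a flag); Fisher's exact two-sided p by hypergeometric
enumeration; and the Bayesian positive predictive value of carrier status
given a prevalence prior and carrier rates in affected and unaffected
populations.

Zero cells make the odds ratio and Woolf interval undefined; the
Haldane-Anscombe correction (add 0.5 to every cell) can be enabled
explicitly and is flagged in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

from scipy import stats

from .errors import AssociationError

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "BayesInputs",
    "odds_ratio",
    "woolf_ci",
    "pearson_chi_square",
    "fisher_exact",
    "bayes_ppv",
    "associate",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a (case-carrier), b (case-non), c (control-carrier), d (control-non)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise AssociationError(
                    f"cell {name}={v!r} must be a nonnegative integer"
                )

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def adjusted(self) -> tuple[float, float, float, float]:
        """Haldane-Anscombe +0.5 to every cell when any cell is zero."""
        if 0 in self.cells():
            return tuple(v + 0.5 for v in self.cells())  # type: ignore[return-value]
        return tuple(float(v) for v in self.cells())  # type: ignore[return-value]


@dataclass(frozen=True)
class AssociationResult:
    table: ContingencyTable2x2
    odds_ratio: float
    log_or_se: float
    ci_low: float
    ci_high: float
    confidence: float
    chi_square: float
    p_chi_square: float
    p_fisher: float
    yates: bool
    haldane: bool


@dataclass(frozen=True)
class BayesInputs:
    """Prevalence prior and carrier rates for the Bayes PPV computation."""

    prevalence: float
    p_carrier_given_affected: float
    p_carrier_given_unaffected: float

    def __post_init__(self) -> None:
        for name in (
            "prevalence",
            "p_carrier_given_affected",
            "p_carrier_given_unaffected",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise AssociationError(f"{name}={v} must lie in [0, 1]")


def _zero_cell_name(t: ContingencyTable2x2) -> str:
    return ", ".join(n for n, v in zip("abcd", t.cells()) if v == 0)


def odds_ratio(table: ContingencyTable2x2, haldane: bool = False) -> float:
    """Cross-product odds ratio ad/bc."""
    a, b, c, d = table.adjusted() if haldane else table.cells()
    if b * c == 0:
        raise AssociationError(
            f"odds ratio undefined: zero cell(s) {_zero_cell_name(table)}; "
            "enable the Haldane-Anscombe adjustment"
        )
    return (a * d) / (b * c)


def log_or_se(table: ContingencyTable2x2, haldane: bool = False) -> float:
    """Woolf standard error of ln OR: sqrt(1/a + 1/b + 1/c + 1/d)."""
    cells = table.adjusted() if haldane else table.cells()
    if 0 in cells:
        raise AssociationError(
            f"Woolf SE undefined: zero cell(s) {_zero_cell_name(table)}; "
            "enable the Haldane-Anscombe adjustment"
        )
    return math.sqrt(sum(1.0 / v for v in cells))


def woolf_ci(
    table: ContingencyTable2x2,
    confidence: float = 0.95,
    haldane: bool = False,
) -> tuple[float, float]:
    """Woolf log-normal confidence interval for the odds ratio."""
    if not 0.0 < confidence < 1.0:
        raise AssociationError(f"confidence {confidence} must lie in (0, 1)")
    or_ = odds_ratio(table, haldane=haldane)
    se = log_or_se(table, haldane=haldane)
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se)


def pearson_chi_square(
    table: ContingencyTable2x2, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on 1 df, uncorrected by default, with its p-value.

    chi2 = N (|ad - bc| - correction)^2 / (r1 r2 c1 c2), correction = N/2
    under Yates (clipped at |ad - bc|).
    """
    a, b, c, d = table.cells()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise AssociationError(
            "chi-square undefined: a row or column margin is zero"
        )
    n = table.n
    delta = abs(a * d - b * c)
    if yates:
        delta = max(delta - n / 2.0, 0.0)
    chi2 = n * delta * delta / (r1 * r2 * c1 * c2)
    return chi2, float(stats.chi2.sf(chi2, df=1))


@lru_cache(maxsize=4096)
def _fisher_p(r1: int, c1: int, n: int, a_obs: int) -> Fraction:
    """Two-sided Fisher p for fixed margins, by exact rational enumeration.

    Sums the hypergeometric probabilities of every table (with the same
    margins) whose probability does not exceed the observed table's.
    Exact Fraction arithmetic makes the probability-ordering tie-break
    unambiguous.
    """
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    denom = math.comb(n, c1)
    pmf = {
        a: Fraction(math.comb(r1, a) * math.comb(n - r1, c1 - a), denom)
        for a in range(lo, hi + 1)
    }
    p_obs = pmf[a_obs]
    return sum((p for p in pmf.values() if p <= p_obs), Fraction(0))


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Fisher's exact two-sided p-value by hypergeometric enumeration."""
    a, b, c, d = table.cells()
    n = table.n
    if n == 0:
        return 1.0
    return float(_fisher_p(a + b, a + c, n, a))


def bayes_ppv(inputs: BayesInputs) -> float:
    """P(affected | carrier) from prevalence and the two carrier rates.

    prev * P(carrier|affected) /
    [prev * P(carrier|affected) + (1 - prev) * P(carrier|unaffected)]
    """
    num = inputs.prevalence * inputs.p_carrier_given_affected
    denom = num + (1.0 - inputs.prevalence) * inputs.p_carrier_given_unaffected
    if denom == 0.0:
        raise AssociationError(
            "Bayes PPV undefined: carrier probability is zero in both "
            "affected and unaffected populations"
        )
    return num / denom


def associate(
    table: ContingencyTable2x2,
    confidence: float = 0.95,
    yates: bool = False,
    haldane: bool = False,
) -> AssociationResult:
    """Full association report for one 2x2 table."""
    haldane_applied = haldane and 0 in table.cells()
    chi2, p_chi = pearson_chi_square(table, yates=yates)
    return AssociationResult(
        table=table,
        odds_ratio=odds_ratio(table, haldane=haldane),
        log_or_se=log_or_se(table, haldane=haldane),
        ci_low=woolf_ci(table, confidence, haldane=haldane)[0],
        ci_high=woolf_ci(table, confidence, haldane=haldane)[1],
        confidence=confidence,
        chi_square=chi2,
        p_chi_square=p_chi,
        p_fisher=fisher_exact(table),
        yates=yates,
        haldane=haldane_applied,
    )
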