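"""Case-control odds ratios of exposure, with exact conditional intervals.

Each video type T in a network yields a 2x2 table crossing type membership
against exposed/unexposed status (exposed = at least one antivaccine
neighbor)::

                exposed   unexposed
    type T         a          b
    not type T     c          d

The odds ratio is ad/bc.  Three interval methods are provided:

* ``woolf`` — the large-sample log interval exp(ln OR +/- z * sqrt(1/a + 1/b
  + 1/c + 1/d)); requires all cells positive.
* ``cornfield_approx`` — Cornfield's approximation: limits psi solve
  a = E_psi(X) -/+ z * sqrt(Var_psi(X)) under the conditional (noncentral
  hypergeometric) distribution of the a-cell given the margins.
* ``exact_conditional`` — equal-tail inversion of the noncentral
  hypergeometric tail probabilities; the only construction that yields a
  finite one-sided bound when a cell is zero, which is exactly where the
  study's tables need it.

Zero-cell point estimates are reported as 0 or +inf, never silently
continuity-corrected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from .graph_core import RecNetwork, VideoNode

logger = logging.getLogger(__name__)

__all__ = [
    "TwoByTwo",
    "ORResult",
    "build_table",
    "odds_ratio",
    "woolf_ci",
    "cornfield_approx_ci",
    "exact_ci",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Exposed-by-type contingency table (a: type & exposed, b: type &
    unexposed, c: other & exposed, d: other & unexposed)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swap_rows(self) -> "TwoByTwo":
        return TwoByTwo(self.c, self.d, self.a, self.b)

    def swap_cols(self) -> "TwoByTwo":
        return TwoByTwo(self.b, self.a, self.d, self.c)


@dataclass(frozen=True)
class ORResult:
    """An odds-ratio point estimate with a confidence interval."""

    or_point: float
    ci_low: float
    ci_high: float
    method: str
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def build_table(
    network: RecNetwork,
    type_predicate: Callable[[VideoNode], bool],
    exposed: Mapping[str, bool],
) -> TwoByTwo:
    """Cross-tabulate type membership against exposed status over all nodes.

    ``exposed`` must cover every node; the complement class is all other
    nodes of the same network.
    """
    a = b = c = d = 0
    for node in network.nodes():
        try:
            is_exposed = exposed[node.id]
        except KeyError:
            raise KeyError(f"exposed mapping does not cover node {node.id!r}") from None
        if type_predicate(node):
            if is_exposed:
                a += 1
            else:
                b += 1
        else:
            if is_exposed:
                c += 1
            else:
                d += 1
    if a == 0 and b == 0:
        logger.warning("type predicate matched no node; odds ratio undefined")
    return TwoByTwo(a, b, c, d)


def odds_ratio(table: TwoByTwo) -> float:
    """Sample odds ratio ad/bc; 0 or +inf with a single zero product.

    Raises when both ad and bc are zero (doubly degenerate table).
    """
    ad = table.a * table.d
    bc = table.b * table.c
    if ad == 0 and bc == 0:
        raise ValueError(f"odds ratio undefined for table {table}")
    if bc == 0:
        return math.inf
    return ad / bc


def woolf_ci(table: TwoByTwo, alpha: float = 0.05) -> ORResult:
    """Large-sample log-scale interval; refuses tables with a zero cell."""
    cells = (table.a, table.b, table.c, table.d)
    if any(v == 0 for v in cells):
        raise ValueError(
            "woolf_ci requires all cells > 0; use exact_ci for zero cells"
        )
    point = odds_ratio(table)
    z = norm.ppf(1.0 - alpha / 2.0)
    se = math.sqrt(sum(1.0 / v for v in cells))
    log_or = math.log(point)
    return ORResult(
        or_point=point,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        method="woolf",
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Conditional (noncentral hypergeometric) machinery
# ---------------------------------------------------------------------------


def _support(table: TwoByTwo) -> np.ndarray:
    n1 = table.a + table.b
    n2 = table.c + table.d
    m1 = table.a + table.c
    lo = max(0, m1 - n2)
    hi = min(n1, m1)
    return np.arange(lo, hi + 1)


def _log_binom_terms(table: TwoByTwo) -> tuple[np.ndarray, np.ndarray]:
    """Support and log binomial weights log C(n1,k) + log C(n2, m1-k)."""
    n1 = table.a + table.b
    n2 = table.c + table.d
    m1 = table.a + table.c
    ks = _support(table)
    lw = (
        gammaln(n1 + 1)
        - gammaln(ks + 1)
        - gammaln(n1 - ks + 1)
        + gammaln(n2 + 1)
        - gammaln(m1 - ks + 1)
        - gammaln(n2 - (m1 - ks) + 1)
    )
    return ks, lw


def _conditional_pmf(table: TwoByTwo, psi: float) -> tuple[np.ndarray, np.ndarray]:
    """pmf of the a-cell given both margins, at odds ratio psi > 0."""
    ks, lw = _log_binom_terms(table)
    logp = lw + ks * math.log(psi)
    logp -= logsumexp(logp)
    return ks, np.exp(logp)


def _tail_ge(table: TwoByTwo, psi: float) -> float:
    """P_psi(X >= a)."""
    ks, p = _conditional_pmf(table, psi)
    return float(p[ks >= table.a].sum())


def _tail_le(table: TwoByTwo, psi: float) -> float:
    """P_psi(X <= a)."""
    ks, p = _conditional_pmf(table, psi)
    return float(p[ks <= table.a].sum())


def _tail_ge_mid(table: TwoByTwo, psi: float) -> float:
    ks, p = _conditional_pmf(table, psi)
    return float(p[ks > table.a].sum() + 0.5 * p[ks == table.a].sum())


def _tail_le_mid(table: TwoByTwo, psi: float) -> float:
    ks, p = _conditional_pmf(table, psi)
    return float(p[ks < table.a].sum() + 0.5 * p[ks == table.a].sum())


def _solve_monotone(f: Callable[[float], float], target: float, increasing: bool) -> float:
    """Solve f(psi) = target for psi > 0 on the log scale.

    ``increasing`` declares the monotonicity of f in psi, used to direct the
    bracket expansion.
    """

    def g(log_psi: float) -> float:
        return f(math.exp(log_psi)) - target

    lo, hi = -1.0, 1.0
    for _ in range(200):
        if g(lo) == 0.0:
            return math.exp(lo)
        if (g(lo) < 0) != (g(hi) < 0):
            break
        if increasing:
            if g(lo) > 0:
                lo -= 2.0
            else:
                hi += 2.0
        else:
            if g(lo) < 0:
                lo -= 2.0
            else:
                hi += 2.0
    else:  # pragma: no cover - bracket failure
        raise RuntimeError("failed to bracket the confidence limit")
    root = brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16)
    return math.exp(root)


def exact_ci(table: TwoByTwo, alpha: float = 0.05, *, mid_p: bool = False) -> ORResult:
    """Exact conditional (noncentral hypergeometric) odds-ratio interval.

    Equal-tail inversion: the lower limit solves P_psi(X >= a) = alpha/2 and
    the upper solves P_psi(X <= a) = alpha/2.  When the a-cell sits at the
    bottom of its conditional support the lower limit is exactly 0 (and the
    upper limit remains finite); at the top of the support the upper limit is
    +inf.  ``mid_p`` switches to the mid-P tails (half weight on the observed
    table).
    """
    n1 = table.a + table.b
    n2 = table.c + table.d
    m1 = table.a + table.c
    m2 = table.b + table.d
    if m1 == 0 or m2 == 0 or n1 == 0 or n2 == 0:
        raise ValueError(f"degenerate margins in table {table}")
    ks = _support(table)
    lo_sup, hi_sup = int(ks[0]), int(ks[-1])

    tail_ge = _tail_ge_mid if mid_p else _tail_ge
    tail_le = _tail_le_mid if mid_p else _tail_le

    if table.a == lo_sup:
        ci_low = 0.0
    else:
        # P(X >= a) increases with psi
        ci_low = _solve_monotone(lambda p: tail_ge(table, p), alpha / 2.0, True)
    if table.a == hi_sup:
        ci_high = math.inf
    else:
        # P(X <= a) decreases with psi
        ci_high = _solve_monotone(lambda p: tail_le(table, p), alpha / 2.0, False)

    ad, bc = table.a * table.d, table.b * table.c
    if ad == 0 and bc == 0:
        point = math.nan
    else:
        point = odds_ratio(table)
    return ORResult(
        or_point=point,
        ci_low=ci_low,
        ci_high=ci_high,
        method="exact_mid_p" if mid_p else "exact_conditional",
        alpha=alpha,
    )


def _conditional_moments(table: TwoByTwo, psi: float) -> tuple[float, float]:
    ks, p = _conditional_pmf(table, psi)
    mean = float((ks * p).sum())
    var = float(((ks - mean) ** 2 * p).sum())
    return mean, var


def cornfield_approx_ci(table: TwoByTwo, alpha: float = 0.05) -> ORResult:
    """Cornfield's approximate limits from the conditional mean and variance.

    Normal approximation with continuity correction to the exact tails: the
    lower limit solves a - 1/2 = E_psi(X) + z*sqrt(Var_psi(X)) and the upper
    solves a + 1/2 = E_psi(X) - z*sqrt(Var_psi(X)).  Requires the a-cell
    strictly inside its conditional support (use :func:`exact_ci` at the
    boundary).
    """
    z = float(norm.ppf(1.0 - alpha / 2.0))
    ks = _support(table)
    if table.a in (int(ks[0]), int(ks[-1])):
        raise ValueError("a-cell at support boundary; use exact_ci")

    def upper_edge(psi: float) -> float:
        mean, var = _conditional_moments(table, psi)
        return mean + z * math.sqrt(var) + 0.5

    def lower_edge(psi: float) -> float:
        mean, var = _conditional_moments(table, psi)
        return mean - z * math.sqrt(var) - 0.5

    # E_psi(X) (hence both edges) increases with psi
    ci_low = _solve_monotone(upper_edge, float(table.a), True)
    ci_high = _solve_monotone(lower_edge, float(table.a), True)
    return ORResult(
        or_point=odds_ratio(table),
        ci_low=ci_low,
        ci_high=ci_high,
        method="cornfield_approx",
        alpha=alpha,
    )
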