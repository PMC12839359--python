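"""Exact 2x2 enrichment statistics.

Given a 2x2 contingency table

    =============  ==========  ============
                   in set      not in set
    in network     a           b
    not network    c           d
    =============  ==========  ============

this module computes the two-sided Fisher exact p-value under the
"probability-mass" rule (sum the hypergeometric probabilities of all tables
with the same margins that are no more probable than the observed one, with a
(1 + 1e-7) relative slack on the comparison — the convention of the classical
R implementation whose "< 2.2e-16" floor is widely quoted), the sample odds
ratio ad/bc, and the conditional maximum-likelihood odds ratio under the
noncentral (Fisher) hypergeometric model.  All mass computations run in log
space via log-gamma, so p-values far below double-precision underflow are
still reported as bounded quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, TextIO

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.optimize import brentq

__all__ = [
    "ContingencyTable",
    "FisherResult",
    "from_counts",
    "fisher_exact",
    "two_sided_log_p",
    "format_p",
    "write_enrichment_tsv",
]

_REL_SLACK = math.log1p(1e-7)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; margins are derived properties."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def row1(self) -> int:  # network size
        return self.a + self.b

    @property
    def col1(self) -> int:  # disease-set size
        return self.a + self.c

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transposed(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d)


def from_counts(network_n: int, overlap_k: int, disease_n: int, background_n: int) -> ContingencyTable:
    """Build the table from the margins as reported in enrichment tables.

    ``a = k``, ``b = network_n - k``, ``c = disease_n - k``,
    ``d = background_n - a - b - c``.  Raises ``ValueError`` naming the
    inconsistent margin when the counts cannot coexist.
    """
    if overlap_k > network_n:
        raise ValueError(f"overlap ({overlap_k}) exceeds network size ({network_n})")
    if overlap_k > disease_n:
        raise ValueError(f"overlap ({overlap_k}) exceeds disease-set size ({disease_n})")
    d = background_n - network_n - disease_n + overlap_k
    if d < 0:
        raise ValueError(
            f"background ({background_n}) smaller than the union of the two sets "
            f"({network_n + disease_n - overlap_k})"
        )
    return ContingencyTable(overlap_k, network_n - overlap_k, disease_n - overlap_k, d)


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float  # may underflow to 0.0 — log_p is always finite
    log_p: float  # natural log of the two-sided p
    odds_ratio_sample: float  # ad/bc, inf when bc == 0
    odds_ratio_cmle: float  # conditional MLE under the noncentral hypergeometric


def _support(t: ContingencyTable) -> np.ndarray:
    lo = max(0, t.row1 + t.col1 - t.n)
    hi = min(t.row1, t.col1)
    return np.arange(lo, hi + 1)


def _log_weights(t: ContingencyTable, log_theta: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized log P(A=x) over the support, at odds ratio exp(log_theta)."""
    x = _support(t)
    r1, c1, n = t.row1, t.col1, t.n
    r2 = n - r1
    lw = (
        gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
        + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - (c1 - x) + 1)
        + x * log_theta
    )
    return x, lw


def _log_pmf(t: ContingencyTable, log_theta: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    x, lw = _log_weights(t, log_theta)
    return x, lw - logsumexp(lw)

def _expected_a(t: ContingencyTable, log_theta: float) -> float:
    x, lp = _log_pmf(t, log_theta)
    return float(np.exp(logsumexp(lp, b=x.astype(float) - x[0])) + x[0]) if len(x) > 1 else float(x[0])


def _cmle_odds_ratio(t: ContingencyTable, tol: float = 1e-10) -> float:
    """Conditional MLE: the odds ratio whose noncentral-hypergeometric mean
    equals the observed ``a`` cell.  Boundary tables return 0 or inf."""
    x = _support(t)
    if len(x) == 1:
        return math.nan  # degenerate margins: OR not identifiable
    if t.a == x[0]:
        return 0.0
    if t.a == x[-1]:
        return math.inf

    def f(log_theta: float) -> float:
        return _expected_a(t, log_theta) - t.a

    lo, hi = -1.0, 1.0
    while f(lo) > 0:
        lo *= 2
        if lo < -745:  # exp underflow guard; mean is still above a
            return 0.0
    while f(hi) < 0:
        hi *= 2
        if hi > 745:
            return math.inf
    log_theta = brentq(f, lo, hi, xtol=tol, rtol=4 * np.finfo(float).eps, maxiter=200)
    return math.exp(log_theta)


def two_sided_log_p(t: ContingencyTable) -> float:
    """Natural log of the two-sided probability-mass p-value."""
    x, lp = _log_pmf(t, 0.0)
    obs = lp[np.searchsorted(x, t.a)]
    mask = lp <= obs + _REL_SLACK
    return min(float(logsumexp(lp[mask])), 0.0)


def fisher_exact(t: ContingencyTable, compute_cmle: bool = True) -> FisherResult:
    """Two-sided Fisher exact test and both odds-ratio flavors.

    The p-value sums, in log space, the central hypergeometric probabilities
    of every table (same margins) whose probability is at most
    ``(1 + 1e-7) ×`` that of the observed table.  ``compute_cmle=False``
    skips the iterative conditional-MLE solve (NaN is reported instead) when
    only the p-value is needed.
    """
    log_p = two_sided_log_p(t)

    if t.b * t.c == 0:
        sample = math.inf if t.a * t.d > 0 else math.nan
    else:
        sample = (t.a * t.d) / (t.b * t.c)
    cmle = _cmle_odds_ratio(t) if compute_cmle else math.nan
    return FisherResult(
        p_two_sided=math.exp(log_p),
        log_p=log_p,
        odds_ratio_sample=sample,
        odds_ratio_cmle=cmle,
    )


def format_p(result: FisherResult) -> str:
    """Human-readable p; values below double-precision underflow are reported
    as a bound ("< 1e-300"), never as 0."""
    if result.p_two_sided > 0.0:
        return f"{result.p_two_sided:.3g}"
    return "< 1e-300"


def write_enrichment_tsv(
    rows: Iterable[tuple[str, ContingencyTable, FisherResult]],
    stream: TextIO,
    header_comments: Iterable[str] = (),
) -> None:
    """Report in the dataset / n / overlap / background / OR / p layout."""
    for line in header_comments:
        stream.write(f"# {line}\n")
    stream.write("dataset\tn\toverlap\tset_n\tbackground\todds_ratio_cmle\todds_ratio_sample\tfisher_p\n")
    for name, t, res in rows:
        stream.write(
            f"{name}\t{t.row1}\t{t.a}\t{t.col1}\t{t.n}\t"
            f"{res.odds_ratio_cmle:.4g}\t{res.odds_ratio_sample:.4g}\t{format_p(res)}\n"
        )
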