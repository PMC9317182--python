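"""Agreement, enrichment and correlation statistics for 2x2 tables and
per-patient abnormality counts.

`fisher_exact_2x2` is an exact hypergeometric enumeration with integer
arithmetic: conditioning on the table margins, the two-sided p-value sums
the probabilities of all tables whose probability does not exceed the
observed one.  With both margins fixed a table is determined by its (0,0)
cell, and since P(k) = C(r1,k) C(r2,c1-k) / C(n,c1), comparing integer
numerators is exact — no floating-point tolerance is required.  The
per-margin enumeration is cached, which keeps large table sweeps cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n < 1:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def _as_table(t) -> ContingencyTable2x2:
    if isinstance(t, ContingencyTable2x2):
        return t
    (a, b), (c, d) = t
    return ContingencyTable2x2(int(a), int(b), int(c), int(d))


# ----------------------------------------------------------- Cohen's kappa

def cohen_kappa(table) -> tuple[float, float]:
    """Cohen's kappa for two binary classifiers plus a one-sided p-value
    from the large-sample z test of kappa = 0 (standard error under H0).

    kappa = (po - pe) / (1 - pe) with po the observed agreement and pe the
    chance agreement from the margins.
    """
    t = _as_table(table)
    n = t.n
    if n < 2:
        raise ValueError("kappa requires n >= 2")
    po = (t.a + t.d) / n
    pe = ((t.a + t.b) * (t.a + t.c) + (t.c + t.d) * (t.b + t.d)) / n**2
    if pe >= 1.0:
        raise ValueError("degenerate margins: chance agreement is 1")
    kappa = (po - pe) / (1 - pe)
    # Var0(kappa) = pe / (n (1 - pe)) under independence
    z = kappa * math.sqrt(n * (1 - pe) / pe)
    p = float(sps.norm.sf(z))
    return kappa, p


# ------------------------------------------------------------ Fisher exact

@lru_cache(maxsize=100_000)
def _fisher_margin_p(n: int, r1: int, c1: int) -> tuple:
    """For fixed margins, the table-count numerators C(r1,k) C(n-r1,c1-k)
    and, per observed k, the two-sided p-value (as a float)."""
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    ks = range(lo, hi + 1)
    numer = {k: math.comb(r1, k) * math.comb(n - r1, c1 - k) for k in ks}
    denom = math.comb(n, c1)
    pvals = {}
    for k in ks:
        mass = sum(v for v in numer.values() if v <= numer[k])
        pvals[k] = mass / denom
    return (lo, hi, tuple(pvals[k] for k in ks))


@dataclass
class FisherResult:
    p_value: float
    table: ContingencyTable2x2

    @property
    def odds_ratio(self) -> float:
        """Conditional maximum-likelihood odds ratio (noncentral
        hypergeometric), delegated to scipy; inf/0 on empty diagonals."""
        res = sps.contingency.odds_ratio(self.table.as_array(), kind="conditional")
        return float(res.statistic)

    def __iter__(self):  # (p, odds_ratio) unpacking
        return iter((self.p_value, self.odds_ratio))


def fisher_exact_2x2(table) -> FisherResult:
    """Two-sided Fisher exact test by exhaustive enumeration of tables with
    the observed margins; p sums the probability of every table at most as
    probable as the observed one.  An empty margin gives p = 1."""
    t = _as_table(table)
    r1, c1 = t.a + t.b, t.a + t.c
    if r1 == 0 or c1 == 0 or r1 == t.n or c1 == t.n:
        return FisherResult(1.0, t)
    lo, _hi, pvals = _fisher_margin_p(t.n, r1, c1)
    return FisherResult(min(1.0, pvals[t.a - lo]), t)


# ------------------------------------------------- rank-based statistics

def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman correlation on mid-ranks with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman_rho needs equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: Spearman correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def mann_whitney_u(g1, g2) -> tuple[float, float]:
    """Mann–Whitney U (U of the first group) with a two-sided p-value:
    exact when min(n1,n2) <= 8 and there are no ties, otherwise the normal
    approximation with tie correction.  Identical pooled values give p = 1."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    if np.ptp(pooled) == 0:
        return g1.size * g2.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(g1.size, g2.size) <= 8 and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for a 2x2 table."""
    t = _as_table(table)
    chi2, p, _, _ = sps.chi2_contingency(t.as_array(), correction=False)
    return float(chi2), float(p)


def expected_counts(table) -> np.ndarray:
    t = _as_table(table)
    arr = t.as_array()
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / t.n
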