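"""Read-count differential expression between the four libraries.

The pairwise test is the exact conditional binomial underlying the
random-sampling (MARS-type) null: given the pooled count k1+k2 for a gene,
k1 is binomial with success probability N1/(N1+N2) under no differential
expression. The four-library test compares observed counts to totals-based
expectations with a chi-square statistic (3 df). P values are adjusted with
Benjamini-Hochberg and with a fixed-lambda Storey estimate side by side, and
gene-set enrichment uses the hypergeometric upper tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CountTable


def _log2_pseudo(k: int) -> float:
    return math.log2(k) if k > 0 else math.log2(0.5)


@dataclass
class DeResult:
    gene_id: str
    contrast: tuple[str, str]
    k1: int
    k2: int
    M: float  # log2 count difference (0.5 pseudo-count when a count is 0)
    A: float  # mean log2 intensity
    p_value: float
    testable: bool = True
    q_bh: float | None = None
    q_storey: float | None = None


def mars_test(
    k1: int, k2: int, N1: int, N2: int, gene_id: str = "", contrast=("C.1", "C.2")
) -> DeResult:
    """Exact two-sided binomial test of k1 vs k2 given library totals.

    Two-sided probability sums all outcomes whose point probability does not
    exceed the observed one. M and A use a 0.5 pseudo-count for zero counts;
    the test itself uses raw counts.
    """
    if N1 < 1 or N2 < 1:
        raise ValueError("library totals must be positive")
    M = _log2_pseudo(k1) - _log2_pseudo(k2)
    A = (_log2_pseudo(k1) + _log2_pseudo(k2)) / 2.0
    n = k1 + k2
    if n == 0:
        return DeResult(gene_id, contrast, k1, k2, 0.0, A, 1.0, testable=False)
    p0 = N1 / (N1 + N2)
    p = stats.binomtest(k1, n, p0, alternative="two-sided").pvalue
    return DeResult(gene_id, contrast, k1, k2, M, A, float(min(1.0, p)))


@dataclass
class Chi2Result:
    gene_id: str
    statistic: float
    p_value: float
    testable: bool = True
    low_count_warning: bool = False


def chi2_test(
    counts, totals, gene_id: str = ""
) -> Chi2Result:
    """Observed vs totals-proportional expected counts, chi-square with 3 df."""
    obs = np.asarray(counts, dtype=float)
    tot = np.asarray(totals, dtype=float)
    if obs.shape != (4,) or tot.shape != (4,):
        raise ValueError("need counts and totals for the four libraries")
    n = obs.sum()
    if n == 0:
        return Chi2Result(gene_id, 0.0, 1.0, testable=False)
    expected = n * tot / tot.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=3))
    return Chi2Result(gene_id, statistic, p, low_count_warning=bool((expected < 1).any()))


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up with enforced monotonicity."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def adjust_storey(p_values, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a single fixed lambda.

    pi0 = #{p > lambda} / (m * (1 - lambda)), clipped to (0, 1]; q = pi0 * BH.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if not 0.0 <= lam < 1.0:
        raise ValueError("lambda must be in [0, 1)")
    pi0 = (p > lam).sum() / (p.size * (1.0 - lam))
    pi0 = min(1.0, max(pi0, 1.0 / p.size))
    return np.minimum(1.0, pi0 * adjust_bh(p))


CONTRAST_LIBS = {"C.1": "n1", "C.2": "n2", "C.3": "n3", "C.4": "n4"}


def de_table(
    table: CountTable, contrast: tuple[str, str], lam: float = 0.5
) -> list[DeResult]:
    """MARS tests for every gene in one library contrast, with both adjustments."""
    a, b = contrast
    ia, ib = CONTRAST_LIBS[a], CONTRAST_LIBS[b]
    Na = table.totals[list(CONTRAST_LIBS).index(a)]
    Nb = table.totals[list(CONTRAST_LIBS).index(b)]
    results = [
        mars_test(int(row[ia]), int(row[ib]), Na, Nb, gene_id=str(gid), contrast=contrast)
        for gid, row in table.counts.iterrows()
    ]
    p = np.array([r.p_value for r in results])
    q_bh = adjust_bh(p)
    q_st = adjust_storey(p, lam)
    for r, qb, qs in zip(results, q_bh, q_st):
        r.q_bh = float(qb)
        r.q_storey = float(qs)
    return results


@dataclass
class EnrichmentResult:
    term: str
    overlap: int
    set_size: int  # term members within the background
    selected_size: int
    background_size: int
    p_value: float
    fdr: float | None = None


def enrich(
    selected, background, gmt: dict[str, set[str]]
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment of each term in the selection.

    ``selected`` must be a subset of ``background``; term membership is
    intersected with the background before testing. FDR is BH across terms.
    """
    selected = set(selected)
    background = set(background)
    if not selected <= background:
        raise ValueError("selected genes must be a subset of the background")
    M, N = len(background), len(selected)
    results = []
    for term in sorted(gmt):
        members = gmt[term] & background
        k = len(members & selected)
        n = len(members)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        results.append(EnrichmentResult(term, k, n, N, M, min(1.0, p)))
    if results:
        fdr = adjust_bh([r.p_value for r in results])
        for r, q in zip(results, fdr):
            r.fdr = float(q)
    return results
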