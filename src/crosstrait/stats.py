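"""Trait-overlap and gene-set enrichment statistics.

Pairwise trait overlap is tested per unordered trait pair with a
one-sided Fisher exact test on a 2x2 table over the universe of
independent genetic signals; raw p-values are corrected across all
C(T, 2) pairs by Benjamini-Hochberg. Gene-set enrichment uses the
one-sided hypergeometric upper tail over a stated gene universe.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "enumerate_trait_pairs",
    "overlap_table",
    "fisher_one_sided",
    "bh_adjust",
    "trait_overlap_tests",
    "enrichment_test",
]

ALPHA = 0.05


class ContingencyTable(NamedTuple):
    """Signal counts: both traits / trait A only / trait B only / neither."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric overlap of a target gene set with a reference set."""

    target_set: str
    reference_set: str
    universe_size: int
    reference_size: int
    target_size: int
    overlap: int
    p: float


def enumerate_trait_pairs(traits: Iterable[str]) -> list[tuple[str, str]]:
    """All C(T, 2) unordered trait pairs in lexicographic order."""
    tset = sorted(set(traits))
    if len(tset) < 2:
        raise ValueError("need at least two traits to form pairs")
    return list(itertools.combinations(tset, 2))


def overlap_table(signal_traits: Sequence[frozenset[str] | set[str]],
                  trait_a: str, trait_b: str) -> ContingencyTable:
    """2x2 table of signals containing both, one, or neither trait.

    ``signal_traits`` is the universe of independent signals, one trait
    set per signal (clusters and, by default upstream, singletons).
    """
    present = set().union(*signal_traits) if signal_traits else set()
    for t in (trait_a, trait_b):
        if t not in present:
            raise ValueError(f"trait {t!r} absent from the signal universe")
    a = b = c = d = 0
    for ts in signal_traits:
        in_a, in_b = trait_a in ts, trait_b in ts
        if in_a and in_b:
            a += 1
        elif in_a:
            b += 1
        elif in_b:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def fisher_one_sided(table: ContingencyTable) -> tuple[float, float]:
    """One-sided ("greater") Fisher exact test on the 2x2 table.

    Returns (odds ratio, p). The p-value is the hypergeometric upper tail
    P(X >= a) conditional on the table margins; the odds ratio is the
    sample estimate a*d / (b*c), +inf when b*c = 0.
    """
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    _, p = _st.fisher_exact([[a, b], [c, d]], alternative="greater")
    odds = float("inf") if b * c == 0 else a * d / (b * c)
    return odds, float(min(p, 1.0))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in p_adj]


def trait_overlap_tests(signal_traits: Sequence[frozenset[str] | set[str]],
                        traits: Iterable[str] | None = None,
                        alpha: float = ALPHA) -> pd.DataFrame:
    """Fisher overlap test for every trait pair, BH-corrected.

    ``traits`` defaults to every trait observed in the universe.
    Returns one row per pair with the table cells, odds ratio, raw and
    adjusted p, and significance at ``alpha`` on the adjusted p.
    """
    if traits is None:
        traits = sorted(set().union(*signal_traits)) if signal_traits else []
    pairs = enumerate_trait_pairs(traits)
    rows = []
    for ta, tb in pairs:
        tab = overlap_table(signal_traits, ta, tb)
        odds, p = fisher_one_sided(tab)
        rows.append(dict(trait_a=ta, trait_b=tb, a=tab.a, b=tab.b, c=tab.c,
                         d=tab.d, odds_ratio=odds, p=p))
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].tolist())
    df["significant"] = df["p_adj"] < alpha
    return df


def enrichment_test(target: Iterable[str], reference: Iterable[str],
                    universe: Iterable[str], target_name: str = "target",
                    reference_name: str = "reference") -> EnrichmentResult:
    """One-sided hypergeometric enrichment of ``target`` in ``reference``.

    With N = |universe|, K = |reference|, n = |target| and overlap k, the
    p-value is P(X >= k) for X ~ Hypergeometric(N, K, n). Both sets must
    be subsets of the universe.
    """
    uni = set(universe)
    tgt, ref = set(target), set(reference)
    if not tgt <= uni or not ref <= uni:
        raise ValueError("target and reference must be subsets of the universe")
    N, K, n = len(uni), len(ref), len(tgt)
    k = len(tgt & ref)
    p = float(min(1.0, _st.hypergeom.sf(k - 1, N, K, n)))
    return EnrichmentResult(target_name, reference_name, N, K, n, k, p)
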