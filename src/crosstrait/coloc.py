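"""Enumeration-based colocalisation of two GWAS loci.

Given per-variant summary statistics for two traits over a shared window,
the method assumes at most one causal variant per trait and enumerates
all causal configurations to score five hypotheses:

* H0 — neither trait is associated in the window,
* H1 / H2 — only trait 1 / only trait 2 is associated,
* H3 — both traits are associated through two distinct causal variants,
* H4 — both traits share a single causal variant.

Per-variant evidence enters through Wakefield log approximate Bayes
factors; the configuration sums reduce to log-sum-exp expressions so the
whole posterior is computed in log space without enumerating pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .expansion import SummaryStatsWindow, W_QUANT, log_abf_vector

__all__ = ["ColocPriors", "ColocResult", "coloc_abf", "coloc_edge"]

#: posterior probability of a shared causal variant (H4) required to call
#: two associations the same signal (inclusive)
H4_MIN = 0.8

HYPOTHESES = ("h0", "h1", "h2", "h3", "h4")


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of association.

    ``p1``/``p2`` — association with trait 1 / trait 2 only; ``p12`` —
    association with both. Defaults are the conventional single-causal
    enumeration values.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        for name, v in (("p1", self.p1), ("p2", self.p2), ("p12", self.p12)):
            if not (0 < v < 1):
                raise ValueError(f"prior {name} must be in (0, 1), got {v}")
        if self.p12 > min(self.p1, self.p2):
            raise ValueError("p12 must not exceed min(p1, p2)")


@dataclass(frozen=True)
class ColocResult:
    """Posterior over H0..H4 for one pair of loci.

    ``pp`` is None when the two windows share no variants — the pair is
    *not colocalisable*, which is a distinct outcome rather than an error.
    """

    study_a: str
    lead_a: str
    study_b: str
    lead_b: str
    pp: tuple[float, float, float, float, float] | None
    n_shared: int

    @property
    def colocalisable(self) -> bool:
        return self.pp is not None

    @property
    def pp_h4(self) -> float | None:
        return None if self.pp is None else self.pp[4]


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)), guarded to -inf when b >= a within rounding."""
    if b >= a:
        return -math.inf
    d = b - a
    # 1 - exp(d) can underflow to 0 for d ~ 0-
    x = -math.expm1(d)
    if x <= 0.0:
        return -math.inf
    return a + math.log(x)


def coloc_abf(
    window1: SummaryStatsWindow,
    window2: SummaryStatsWindow,
    priors: ColocPriors | None = None,
    W1: float = W_QUANT,
    W2: float = W_QUANT,
) -> ColocResult:
    """Five-hypothesis colocalisation posterior for two loci.

    Windows are intersected on variant id (ids encode alleles, so no
    further harmonisation is attempted). With per-variant log Bayes
    factors lbf1, lbf2 over the shared variants and S1 = logsumexp(lbf1),
    S2 = logsumexp(lbf2), S12 = logsumexp(lbf1 + lbf2), the unnormalised
    log posteriors are::

        H0 = 0
        H1 = ln p1 + S1
        H2 = ln p2 + S2
        H3 = ln p1 + ln p2 + log( exp(S1 + S2) - exp(S12) )
        H4 = ln p12 + S12

    where the H3 difference removes the same-variant configurations from
    the independent-causal sum. Zero shared variants yields a
    "not colocalisable" result with ``pp = None``.
    """
    priors = priors or ColocPriors()
    shared = [v for v in window1.variants if v in set(window2.variants)]
    result_ids = dict(
        study_a=window1.study_id, lead_a=window1.lead,
        study_b=window2.study_id, lead_b=window2.lead,
    )
    if not shared:
        return ColocResult(**result_ids, pp=None, n_shared=0)

    i1 = [window1.variants.index(v) for v in shared]
    i2 = [window2.variants.index(v) for v in shared]
    lbf1 = log_abf_vector(np.asarray(window1.beta)[i1], np.asarray(window1.se)[i1], W1)
    lbf2 = log_abf_vector(np.asarray(window2.beta)[i2], np.asarray(window2.se)[i2], W2)

    S1 = float(logsumexp(lbf1))
    S2 = float(logsumexp(lbf2))
    S12 = float(logsumexp(lbf1 + lbf2))

    lp1, lp2, lp12 = math.log(priors.p1), math.log(priors.p2), math.log(priors.p12)
    logpost = np.array([
        0.0,
        lp1 + S1,
        lp2 + S2,
        lp1 + lp2 + _logdiffexp(S1 + S2, S12),
        lp12 + S12,
    ])
    pp = np.exp(logpost - logsumexp(logpost))
    pp = pp / pp.sum()
    return ColocResult(**result_ids, pp=tuple(float(p) for p in pp), n_shared=len(shared))


def coloc_edge(result: ColocResult, h4_min: float = H4_MIN) -> bool:
    """True iff the pair's shared-causal posterior reaches the cut-off.

    The threshold is inclusive: pp(H4) = h4_min counts as sharing. A
    non-colocalisable result never yields an edge from this rule (callers
    may fall back to tag overlap).
    """
    if result.pp is None:
        return False
    return result.pp[4] >= h4_min
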