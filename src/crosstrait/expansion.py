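"""Expand GWAS lead variants into candidate-causal (tag) sets.

A lead variant is only the best single representative of an association
signal; the true causal variant is usually one of its close LD proxies.
Three expansion routes are supported, in decreasing order of information:

* ``abf`` — single-causal fine-mapping from full summary statistics using
  Wakefield approximate Bayes factors over a +/- 500 kb window.
* ``pics`` — fine-mapping from the lead p-value and LD to the lead only
  (Probabilistic Identification of Causal SNPs), when per-variant betas
  are unavailable.
* ``ld`` — plain LD expansion: every variant with r^2 >= 0.7 to the lead.

Fine-mapped credible sets are normalised over the window and then
thresholded at posterior probability > 0.1%; retained probabilities are
*not* re-normalised by default, so downstream overlap logic sees exactly
the retained variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "SummaryStatsWindow",
    "CredibleSet",
    "TagSet",
    "wakefield_log_abf",
    "abf_credible_set",
    "pics_posteriors",
    "ld_expand",
    "expand_association",
]

#: default half-width of a fine-mapping window around the lead, in bp
WINDOW_BP = 500_000

#: default prior standard deviation of the effect size (quantitative traits)
W_QUANT = 0.15
#: prior standard deviation conventionally used for binary traits
W_BINARY = 0.2

#: minimum r^2 with the lead for LD expansion (inclusive)
R2_MIN = 0.7
#: minimum credible-set posterior for a variant to be retained (exclusive)
PP_MIN = 0.001

#: floor on the PICS posterior standard deviation
PICS_SIGMA_FLOOR = 1e-4
#: exponent of |r| in the PICS standard-deviation term
PICS_R_EXPONENT = 3.2


@dataclass(frozen=True)
class SummaryStatsWindow:
    """Per-variant effect estimates within a window around one lead.

    ``variants``, ``positions``, ``beta`` and ``se`` are parallel arrays;
    the lead must be one of the variants and every position must fall
    within ``window_bp`` of the lead position.
    """

    study_id: str
    lead: str
    variants: tuple[str, ...]
    positions: tuple[int, ...]
    beta: tuple[float, ...]
    se: tuple[float, ...]
    window_bp: int = WINDOW_BP

    def __post_init__(self) -> None:
        n = len(self.variants)
        if n == 0:
            raise ValueError("empty summary-statistics window")
        if not (len(self.positions) == len(self.beta) == len(self.se) == n):
            raise ValueError("window arrays must have equal length")
        if self.lead not in self.variants:
            raise ValueError(f"lead {self.lead!r} absent from its window")
        if any(s <= 0 for s in self.se):
            raise ValueError("standard errors must be positive")
        lead_pos = self.positions[self.variants.index(self.lead)]
        if any(abs(p - lead_pos) > self.window_bp for p in self.positions):
            raise ValueError("window contains positions outside +/- window_bp of the lead")

    @property
    def lead_index(self) -> int:
        return self.variants.index(self.lead)


@dataclass(frozen=True)
class CredibleSet:
    """Normalised single-causal posterior over a window of variants."""

    variants: tuple[str, ...]
    pp: tuple[float, ...]
    method: str  # "abf" or "pics"
    prior_sd: float | None = None  # W, abf only

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.pp):
            raise ValueError("posterior probabilities must be non-negative")
        total = float(sum(self.pp))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posterior probabilities sum to {total}, not 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.variants, self.pp))


@dataclass(frozen=True)
class TagSet:
    """The expanded candidate-causal set attached to one association.

    Each tag is ``(variant, r2, pp)`` where exactly one of ``r2`` / ``pp``
    is populated depending on ``source``. The lead is always a member.
    """

    study_id: str
    lead: str
    tags: tuple[tuple[str, float | None, float | None], ...]
    source: str  # "ld" | "abf" | "pics"

    def __post_init__(self) -> None:
        if self.source not in ("ld", "abf", "pics"):
            raise ValueError(f"unknown tag source {self.source!r}")
        if self.lead not in self.variants:
            raise ValueError("lead must be included among its own tags")

    @property
    def variants(self) -> frozenset[str]:
        return frozenset(t[0] for t in self.tags)


def wakefield_log_abf(beta: float, se: float, W: float = W_QUANT) -> float:
    """Natural-log approximate Bayes factor for a single-variant association.

    Under a N(0, W^2) prior on the true effect and an approximately normal
    estimate ``beta`` with variance ``se**2``, the log Bayes factor in
    favour of association is

        0.5 * [ ln(V / (V + W^2)) + z^2 * W^2 / (V + W^2) ]

    with V = se^2 and z = beta / se.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if W <= 0:
        raise ValueError("prior sd W must be positive")
    V = se * se
    z2 = (beta / se) ** 2
    shrink = W * W / (V + W * W)
    return 0.5 * (math.log(V / (V + W * W)) + z2 * shrink)


def log_abf_vector(beta: Sequence[float], se: Sequence[float], W: float) -> np.ndarray:
    """Vectorised :func:`wakefield_log_abf` for a whole window."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    V = se**2
    shrink = W * W / (V + W * W)
    return 0.5 * (np.log(V / (V + W * W)) + (beta / se) ** 2 * shrink)


def abf_credible_set(window: SummaryStatsWindow, W: float = W_QUANT) -> CredibleSet:
    """Single-causal credible set from Wakefield ABFs over a window.

    Posterior probability of variant j being causal, assuming exactly one
    causal variant in the window with a flat prior over variants:
    PP_j = ABF_j / sum_k ABF_k, evaluated in log space.
    """
    lbf = log_abf_vector(window.beta, window.se, W)
    pp = np.exp(lbf - logsumexp(lbf))
    pp = pp / pp.sum()  # kill residual float error so the invariant holds
    return CredibleSet(window.variants, tuple(float(p) for p in pp), "abf", prior_sd=W)


def pics_posteriors(lead_log10p: float, ld_r: Iterable[tuple[str, float]]) -> CredibleSet:
    """PICS single-causal posteriors from the lead -log10 p and LD alone.

    Candidate i, with correlation r_i to the lead, is expected to show an
    association strength of r_i^2 * S when the lead carries S = -log10 p,
    with a dispersion that grows as LD decays. Each candidate is weighted
    by the normal density of the observed S under

        mu_i    = r_i^2 * S
        sigma_i = max(eps, sqrt(1 - |r_i|^3.2) * sqrt(S) / 2)

    and the weights are normalised. The lead itself (r = 1) collapses to a
    point mass at S up to the sigma floor eps = 1e-4.
    """
    S = float(lead_log10p)
    if S <= 0:
        raise ValueError("lead -log10(p) must be positive")
    pairs = list(ld_r)
    if not pairs:
        raise ValueError("no LD candidates supplied")
    if not any(abs(r - 1.0) < 1e-12 for _, r in pairs):
        raise ValueError("the lead (r = 1) must be among the candidates")
    variants = tuple(v for v, _ in pairs)
    r = np.array([x for _, x in pairs], dtype=float)
    mu = r**2 * S
    sigma = np.maximum(PICS_SIGMA_FLOOR, np.sqrt(1.0 - np.abs(r) ** PICS_R_EXPONENT) * math.sqrt(S) / 2.0)
    # log normal density of S at (mu, sigma); constants cancel in the ratio
    logw = -np.log(sigma) - 0.5 * ((S - mu) / sigma) ** 2
    pp = np.exp(logw - logsumexp(logw))
    pp = pp / pp.sum()
    return CredibleSet(variants, tuple(float(p) for p in pp), "pics")


def ld_expand(lead: str, ld, r2_min: float = R2_MIN, study_id: str = "") -> TagSet:
    """All variants with r^2(lead, v) >= r2_min (inclusive), plus the lead.

    ``ld`` is an :class:`~crosstrait.synthetic.LDMatrix`-like object with
    ``variants`` and a square correlation matrix ``r``. The result does not
    depend on the ordering of variants in the matrix.
    """
    variants = list(ld.variants)
    if lead not in variants:
        raise KeyError(f"lead {lead!r} not present in the LD matrix")
    i = variants.index(lead)
    r2 = np.asarray(ld.r)[i] ** 2
    tags = tuple(
        (v, float(r2[j]), None)
        for j, v in enumerate(variants)
        if r2[j] >= r2_min or v == lead
    )
    return TagSet(study_id=study_id, lead=lead, tags=tags, source="ld")


def _threshold(cs: CredibleSet, pp_min: float, renormalise: bool) -> list[tuple[str, float]]:
    kept = [(v, p) for v, p in zip(cs.variants, cs.pp) if p > pp_min]
    if not kept:  # degenerate: keep the single most probable variant
        j = int(np.argmax(cs.pp))
        kept = [(cs.variants[j], cs.pp[j])]
    if renormalise:
        total = sum(p for _, p in kept)
        kept = [(v, p / total) for v, p in kept]
    return kept


def expand_association(
    study_id: str,
    lead: str,
    *,
    window: SummaryStatsWindow | None = None,
    lead_log10p: float | None = None,
    ld_r: Mapping[str, float] | None = None,
    ld=None,
    W: float = W_QUANT,
    pp_min: float = PP_MIN,
    r2_min: float = R2_MIN,
    renormalise: bool = False,
) -> TagSet:
    """Expand one association using the best available evidence.

    Precedence: summary statistics (ABF fine-mapping) > lead p-value with
    LD-to-lead correlations (PICS) > LD matrix alone (r^2 expansion).
    Fine-mapped sets are thresholded at pp > ``pp_min`` after
    normalisation. With no evidence at all the association is returned as
    an unexpandable lead-only LD tag set.
    """
    if window is not None:
        cs = abf_credible_set(window, W)
        kept = _threshold(cs, pp_min, renormalise)
        return TagSet(study_id, lead, tuple((v, None, p) for v, p in kept), "abf")
    if lead_log10p is not None and ld_r is not None:
        pairs = list(ld_r.items())
        if lead not in ld_r:
            pairs.append((lead, 1.0))
        cs = pics_posteriors(lead_log10p, pairs)
        kept = _threshold(cs, pp_min, renormalise)
        return TagSet(study_id, lead, tuple((v, None, p) for v, p in kept), "pics")
    if ld is not None:
        ts = ld_expand(lead, ld, r2_min=r2_min, study_id=study_id)
        return ts
    # no evidence: unexpandable, lead-only
    return TagSet(study_id, lead, ((lead, 1.0, None),), "ld")
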