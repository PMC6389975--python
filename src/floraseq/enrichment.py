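"""Cumulative-binomial over/under-representation of annotation terms.

For each SDEG set the "sample size" n is the number of set members that are
valid genes (expressed above the FPKM floor and carrying at least one term of
the annotation type), and for each term the "number of observation" k is how
many of those carry that term.  The background probability p0 of a term is its
frequency among all valid genes.  Under a Binomial(n, p0) model the cumulative
probability P(X <= k) is computed exactly; a single significance level alpha is
derived per annotation type by the Benjamini-Hochberg step-up rule at FDR q
applied to the pooled family of both one-sided p-values across all sets and
terms.  A term is underrepresented when P(X <= k) < alpha and overrepresented
when P(X <= k) > 1 - alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, ContractError
from .expression import ExpressionMatrix
from .sdeg import SDEGSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Background:
    """Valid genes of one annotation type with per-term counts and expected
    probabilities p0 = count(term) / |valid genes|."""

    valid_genes: frozenset[str]
    per_term_counts: dict[str, int]
    expected_probability: dict[str, float]


@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    term: str
    sample_size: int          # n
    observed: int             # k
    p0: float
    cumulative_probability: float   # P(X <= k)
    p_under: float            # P(X <= k)
    p_over: float             # P(X >= k)
    call: str                 # underrepresented | overrepresented | not_significant


@dataclass(frozen=True)
class EnrichmentResult:
    records: list[EnrichmentRecord]
    alpha: float
    q: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                (
                    r.set_name,
                    r.term,
                    r.sample_size,
                    r.observed,
                    r.p0,
                    r.cumulative_probability,
                    r.call,
                )
                for r in self.records
            ],
            columns=["set_name", "term", "n", "k", "p0", "cumulative_probability", "call"],
        )
        df["alpha_used"] = self.alpha
        return df


def build_background(
    gene_terms: Mapping[str, set[str]],
    em: ExpressionMatrix,
    fpkm_floor: float = 5.0,
) -> Background:
    """Valid genes = annotated genes with FPKM strictly above ``fpkm_floor`` in
    at least one sample; p0 per term is its frequency among them."""
    expressed = set(em.values.index[(em.values > fpkm_floor).any(axis=1)])
    valid = frozenset(g for g, terms in gene_terms.items() if terms and g in expressed)
    if not valid:
        raise ComputationError("no valid genes: background would be empty")
    counts: dict[str, int] = {}
    for g in valid:
        for t in gene_terms[g]:
            counts[t] = counts.get(t, 0) + 1
    p0 = {t: c / len(valid) for t, c in counts.items()}
    return Background(valid_genes=valid, per_term_counts=counts, expected_probability=p0)


def binomial_cdf(k: int, n: int, p: float) -> float:
    """Exact P(X <= k) for X ~ Binomial(n, p); stable up to n >= 1e5."""
    if not (0 <= k <= n):
        raise ContractError(f"k={k} outside [0, n={n}]")
    if not (0.0 <= p <= 1.0):
        raise ContractError(f"p={p} outside [0, 1]")
    return float(stats.binom.cdf(k, n, p))


def fdr_significance_level(p_values: Sequence[float], q: float = 0.01) -> float:
    """Benjamini-Hochberg step-up critical value: the largest p(i) (ascending
    order) with p(i) <= (i/m) * q, or 0.0 when none qualifies."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ContractError("empty p-value family")
    if ((p < 0) | (p > 1)).any():
        raise ContractError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ContractError(f"q={q} outside (0, 1)")
    p = np.sort(p)
    m = p.size
    crit = (np.arange(1, m + 1) / m) * q
    ok = np.flatnonzero(p <= crit)
    return float(p[ok[-1]]) if ok.size else 0.0


def _tail_probabilities(k: int, n: int, p0: float) -> tuple[float, float]:
    """(P(X <= k), P(X >= k)) with the stable CDF; P(X >= 0) = 1."""
    p_under = binomial_cdf(k, n, p0)
    p_over = 1.0 if k == 0 else 1.0 - binomial_cdf(k - 1, n, p0)
    return p_under, p_over


def enrich_sets(
    sdeg_sets: Sequence[SDEGSet],
    gene_terms: Mapping[str, set[str]],
    bg: Background,
    q: float = 0.01,
) -> EnrichmentResult:
    """Score every background term in every SDEG set and call significance
    against the single BH-derived alpha of the pooled p-value family."""
    terms = sorted(bg.expected_probability)
    raw: list[tuple[str, str, int, int, float, float, float]] = []
    family: list[float] = []
    for s in sdeg_sets:
        members = sorted(set(s.gene_ids) & bg.valid_genes)
        n = len(members)
        if n == 0:
            log.warning("SDEG set %s has no valid annotated genes (n=0)", s.name)
        for t in terms:
            p0 = bg.expected_probability[t]
            k = sum(1 for g in members if t in gene_terms[g])
            p_under, p_over = _tail_probabilities(k, n, p0)
            raw.append((s.name, t, n, k, p0, p_under, p_over))
            family.extend((p_under, p_over))
    if not raw:
        return EnrichmentResult(records=[], alpha=0.0, q=q)
    alpha = fdr_significance_level(family, q)
    records = []
    for set_name, t, n, k, p0, p_under, p_over in raw:
        if n == 0:
            call = "not_significant"
        elif p_under < alpha:
            call = "underrepresented"
        elif p_under > 1.0 - alpha:
            call = "overrepresented"
        else:
            call = "not_significant"
        records.append(
            EnrichmentRecord(set_name, t, n, k, p0, p_under, p_under, p_over, call)
        )
    return EnrichmentResult(records=records, alpha=alpha, q=q)
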