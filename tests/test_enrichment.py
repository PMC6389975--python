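"""Cumulative-binomial enrichment with the BH-derived significance level."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import floraseq as fs
from floraseq.errors import ComputationError, ContractError


from oracles import bh_brute_force, binom_cdf_enumeration


def em_stub(values: dict, genes):
    df = pd.DataFrame(values, index=genes, dtype=float)
    return fs.ExpressionMatrix(
        values=df,
        library_size=pd.Series(1, index=df.columns),
        samples=pd.DataFrame(index=df.columns),
        gene_lengths=pd.Series(1000, index=df.index),
    )


def test_background_expected_probabilities():
    genes = [f"g{i}" for i in range(12)]
    gene_terms = {g: {"T1"} for g in genes[:2]}
    gene_terms.update({g: {"T2"} for g in genes[2:10]})
    gene_terms["g10"] = set()          # annotated with nothing: not valid
    # g11 expressed but absent from gene_terms entirely
    em = em_stub({"s1": [10.0] * 11 + [0.1]}, genes)
    bg = fs.build_background(gene_terms, em, fpkm_floor=5.0)
    assert bg.valid_genes == frozenset(genes[:10])
    assert bg.expected_probability["T1"] == pytest.approx(0.2)
    # saturation: a term on every valid gene has p0 = 1
    gene_terms_sat = {g: {"ALL"} for g in genes[:10]}
    bg2 = fs.build_background(gene_terms_sat, em, fpkm_floor=5.0)
    assert bg2.expected_probability["ALL"] == 1.0
    # counting identity
    total = sum(bg.per_term_counts.values())
    assert total == sum(len(gene_terms[g]) for g in bg.valid_genes)


def test_background_empty_is_error():
    em = em_stub({"s1": [0.0]}, ["g0"])
    with pytest.raises(ComputationError):
        fs.build_background({"g0": {"T"}}, em)


def test_binomial_cdf_examples_and_edges():
    assert fs.binomial_cdf(1, 3, 0.5) == pytest.approx(0.5)
    assert fs.binomial_cdf(0, 10, 0.1) == pytest.approx(0.9 ** 10)
    assert fs.binomial_cdf(7, 7, 0.3) == 1.0
    assert fs.binomial_cdf(4, 9, 0.0) == 1.0
    assert fs.binomial_cdf(4, 9, 1.0) == 0.0
    with pytest.raises(ContractError):
        fs.binomial_cdf(5, 3, 0.5)
    with pytest.raises(ContractError):
        fs.binomial_cdf(1, 3, 1.5)


@pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
def test_binomial_cdf_matches_enumeration(p):
    for n in range(0, 13):
        for k in range(n + 1):
            assert fs.binomial_cdf(k, n, p) == pytest.approx(
                binom_cdf_enumeration(k, n, p), abs=1e-12
            )


def test_binomial_cdf_stable_large_n():
    v = fs.binomial_cdf(100_000, 100_000, 0.3)
    assert v == 1.0
    assert 0.0 < fs.binomial_cdf(29_800, 100_000, 0.3) < 0.5


def test_fdr_level_hand_trace_and_oracle():
    assert fs.fdr_significance_level([0.001, 0.005, 0.02, 0.8], 0.01) == pytest.approx(0.005)
    assert fs.fdr_significance_level([1.0, 1.0, 1.0]) == 0.0
    assert fs.fdr_significance_level([0.001], 0.01) == pytest.approx(0.001)
    rng = np.random.default_rng(2)
    for _ in range(200):
        fam = rng.beta(0.3, 3, size=int(rng.integers(1, 80))).tolist()
        assert fs.fdr_significance_level(fam, 0.01) == pytest.approx(
            bh_brute_force(fam, 0.01), abs=0.0
        )
    with pytest.raises(ContractError):
        fs.fdr_significance_level([])


def _toy_enrichment(k_hot, n=50, p0=0.02, n_decoy_terms=30):
    """One SDEG set of n genes; term HOT on k_hot of them; decoy terms at
    their background rates so the BH family is realistic."""
    rng = np.random.default_rng(0)
    n_bg = 500
    genes = [f"g{i}" for i in range(n_bg)]
    gene_terms = {g: set() for g in genes}
    for i in range(n_bg):
        if i < int(p0 * n_bg):
            gene_terms[genes[i]].add("HOT")
        for t in range(n_decoy_terms):
            if rng.random() < 0.1:
                gene_terms[genes[i]].add(f"D{t}")
        if not gene_terms[genes[i]]:
            gene_terms[genes[i]].add("D0")
    em = em_stub({"s1": [10.0] * n_bg}, genes)
    bg = fs.build_background(gene_terms, em)
    members = [g for g in genes if "HOT" in gene_terms[g]][:k_hot]
    members += [g for g in genes if "HOT" not in gene_terms[g]][: n - k_hot]
    contrast = fs.Contrast("pistil", "postmeiotic", "female", "supermale")
    s = fs.SDEGSet(contrast, "female", frozenset(members))
    return fs.enrich_sets([s], gene_terms, bg, q=0.01), gene_terms


def test_enrich_overrepresentation_call():
    """n=50, p0~0.02, k=10: P(X <= 10) is so close to 1 that the term is
    called overrepresented at the family's BH alpha."""
    res, _ = _toy_enrichment(k_hot=10)
    rec = {r.term: r for r in res.records}["HOT"]
    assert rec.sample_size == 50 and rec.observed == 10
    assert rec.cumulative_probability > 1 - res.alpha > 0.5
    assert rec.call == "overrepresented"


def test_enrich_null_consistent_observation():
    res, _ = _toy_enrichment(k_hot=1)  # k = n*p0 = 1 exactly
    rec = {r.term: r for r in res.records}["HOT"]
    assert rec.call == "not_significant"


def test_enrich_calls_mutually_exclusive_and_monotone():
    for k in range(0, 12):
        res, _ = _toy_enrichment(k_hot=k)
        rec = {r.term: r for r in res.records}["HOT"]
        assert rec.call in {"underrepresented", "overrepresented", "not_significant"}
    # monotone in k: cumulative probability never decreases
    probs = []
    for k in range(0, 12):
        res, _ = _toy_enrichment(k_hot=k)
        probs.append({r.term: r for r in res.records}["HOT"].cumulative_probability)
    assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))


def test_enrich_empty_set_not_significant(caplog):
    contrast = fs.Contrast("pistil", "postmeiotic", "female", "supermale")
    genes = [f"g{i}" for i in range(20)]
    gene_terms = {g: {"T"} for g in genes}
    em = em_stub({"s1": [10.0] * 20}, genes)
    bg = fs.build_background(gene_terms, em)
    s = fs.SDEGSet(contrast, "female", frozenset({"absent_gene"}))
    res = fs.enrich_sets([s], gene_terms, bg)
    assert all(r.call == "not_significant" for r in res.records)


def test_planted_terms_recovered(fixture_bundle, sim_data, small_config):
    """Round trip: enrichment on the synthetic bundle flags the planted terms
    of each contrast as overrepresented."""
    cm, truth = sim_data
    em = fs.compute_fpkm(cm)
    hits = fs.read_blast_tab(fixture_bundle["blast"])
    m = fs.assign_one_to_one(hits)
    from floraseq.homology import read_term_associations

    protein_terms = read_term_associations(fixture_bundle["go_terms"])
    gene_terms = fs.transfer_annotations(m, protein_terms)
    bg = fs.build_background(gene_terms, em)
    sets = []
    for c in truth.contrasts:
        sets.extend(fs.extract_sdegs(em, c))
    res = fs.enrich_sets(sets, gene_terms, bg, q=0.01)
    by_key = {(r.set_name, r.term): r for r in res.records}
    found = total = 0
    for c in truth.contrasts:
        for sex in (c.sex_a, c.sex_b):
            name = f"{sex}_{c.organ}_{c.stage}"
            for t in truth.enriched_terms["GO"][c]:
                if t not in bg.expected_probability:
                    continue
                total += 1
                rec = by_key[(name, t)]
                found += rec.call == "overrepresented"
    # planted terms are split between the two sex-directions of a contrast,
    # so at least half of the (direction, term) pairs must light up
    assert total > 0
    assert found / total >= 0.5
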