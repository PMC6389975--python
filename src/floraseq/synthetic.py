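"""Synthetic floral-organ RNA-seq fixtures with planted ground truth.

The generator emulates the study design the pipeline targets: two sexes
(female and a YY "supermale") times three floral organs (tepal, pistil,
stamen) with two biological replicates each, plus staged whole-bud samples.
Counts follow a negative-binomial model with variance mu + mu^2/theta; a
configurable fraction of genes per sex contrast carries a planted
multiplicative fold change in one sex of exactly one organ/stage.  A matching
BLAST-style hit table (true hits plus decoys) and GO-like / pathway-like term
catalogs (with terms planted among biased genes) complete a runnable fixture
bundle, written in exactly the file formats the pipeline readers consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .expression import CountMatrix, write_counts
from .sdeg import Contrast, derive_contrasts

DEFAULT_DESIGN: tuple[tuple[str, str, str, int], ...] = tuple(
    [(sex, organ, "postmeiotic", 2) for sex in ("female", "supermale") for organ in ("tepal", "pistil", "stamen")]
    + [(sex, "bud", stage, 2) for sex in ("female", "male") for stage in ("premeiotic", "meiotic", "postmeiotic")]
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic experiment.

    ``design`` lists (sex, organ, stage, n_replicates) blocks; the default is
    the floral-organ layout above.  ``nb_dispersion`` is the negative-binomial
    size theta (variance = mu + mu^2/theta).  ``fold_change_range`` should stay
    above the 5x detection rule so planted genes are recoverable.
    """

    n_genes: int = 2000
    design: tuple[tuple[str, str, str, int], ...] = DEFAULT_DESIGN
    gene_length_range: tuple[int, int] = (300, 5000)
    baseline_mean_log10_range: tuple[float, float] = (0.0, 2.5)
    frac_sex_biased_per_contrast: float = 0.05
    fold_change_range: tuple[float, float] = (10.0, 50.0)
    nb_dispersion: float = 10.0
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    frac_annotated: float = 0.6
    n_terms: int = 100
    planted_terms_per_contrast: int = 3
    term_prob_range: tuple[float, float] = (0.01, 0.20)
    planted_term_prob: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not self.design:
            raise ConfigError("design must list at least one sample block")
        for frac_name in ("frac_sex_biased_per_contrast", "frac_annotated"):
            v = getattr(self, frac_name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{frac_name} must lie in [0, 1]")
        for rng_name in (
            "gene_length_range",
            "baseline_mean_log10_range",
            "fold_change_range",
            "library_size_range",
            "term_prob_range",
        ):
            lo, hi = getattr(self, rng_name)
            if lo > hi:
                raise ConfigError(f"{rng_name} must be ordered (min <= max)")
        if self.gene_length_range[0] <= 0:
            raise ConfigError("gene_length_range must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.library_size_range[0] <= 0:
            raise ConfigError("library_size_range must be positive")
        if self.n_terms < 0 or self.planted_terms_per_contrast < 0:
            raise ConfigError("n_terms and planted_terms_per_contrast must be >= 0")
        if not (0.0 <= self.planted_term_prob <= 1.0):
            raise ConfigError("planted_term_prob must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth of one simulated experiment.

    ``biased_genes`` maps each Contrast to {gene_id: (biased sex, fold)};
    ``homolog_truth`` is the injective gene -> protein assignment;
    ``enriched_terms`` maps annotation kind ("GO"/"pathway") to
    {Contrast: planted term set}; ``expected_baseline_fpkm`` is the noise-free
    FPKM each gene would have in an unbiased sample.
    """

    biased_genes: dict[Contrast, dict[str, tuple[str, float]]]
    homolog_truth: dict[str, str]
    expected_baseline_fpkm: dict[str, float]
    contrasts: list[Contrast]
    enriched_terms: dict[str, dict[Contrast, set[str]]] = field(default_factory=dict)

    def biased_union(self, contrast: Contrast) -> set[str]:
        return set(self.biased_genes.get(contrast, {}))


def _sample_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for sex, organ, stage, n_rep in config.design:
        if n_rep < 1:
            raise ConfigError("design replicate counts must be >= 1")
        for r in range(1, n_rep + 1):
            rows.append((f"{sex}_{organ}_{stage}_rep{r}", sex, organ, stage, r))
    df = pd.DataFrame(rows, columns=["sample_id", "sex", "organ", "stage", "replicate"])
    return df.set_index("sample_id")


def generate_counts(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Negative-binomial counts with planted sex-biased genes.

    Expected counts are proportional to (baseline expression) x (gene length),
    scaled per sample to the drawn library size, so a planted fold change on a
    sex's mean propagates to FPKM space at (approximately) its nominal value.
    Identical config (including seed) reproduces identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    lengths = rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, size=config.n_genes)
    lo, hi = config.baseline_mean_log10_range
    baseline = 10.0 ** rng.uniform(lo, hi, size=config.n_genes)

    samples = _sample_table(config)
    contrasts = derive_contrasts(samples)

    n_biased = int(round(config.frac_sex_biased_per_contrast * config.n_genes))
    biased_genes: dict[Contrast, dict[str, tuple[str, float]]] = {}
    # fold multipliers per gene x sample, applied on the biased sex's side only
    fold = np.ones((config.n_genes, len(samples)))
    sample_sex = samples["sex"].to_numpy()
    sample_organ = samples["organ"].to_numpy()
    sample_stage = samples["stage"].astype(str).to_numpy()
    for c in contrasts:
        picked = rng.choice(config.n_genes, size=n_biased, replace=False)
        sexes = rng.choice([c.sex_a, c.sex_b], size=n_biased)
        folds = rng.uniform(config.fold_change_range[0], config.fold_change_range[1], size=n_biased)
        entry: dict[str, tuple[str, float]] = {}
        for gi, sx, fc in zip(picked, sexes, folds):
            entry[genes[gi]] = (str(sx), float(fc))
            cols = (sample_sex == sx) & (sample_organ == c.organ) & (sample_stage == c.stage)
            fold[gi, cols] *= fc
        biased_genes[c] = entry

    mean_expr = baseline[:, None] * fold
    weights = mean_expr * lengths[:, None]  # expected fragments before depth scaling
    lib_sizes = rng.integers(config.library_size_range[0], config.library_size_range[1] + 1, size=len(samples))
    mu = weights / weights.sum(axis=0, keepdims=True) * lib_sizes[None, :]

    theta = config.nb_dispersion
    p = theta / (theta + mu)
    counts = rng.negative_binomial(theta, p)

    counts_df = pd.DataFrame(
        counts.astype(np.int64), index=pd.Index(genes, name="gene_id"), columns=list(samples.index)
    )
    cm = CountMatrix(
        counts=counts_df,
        gene_lengths=pd.Series(lengths.astype(np.int64), index=counts_df.index, name="gene_length_bp"),
        samples=samples,
    )

    n_annot = int(round(config.frac_annotated * config.n_genes))
    annotated = rng.choice(config.n_genes, size=n_annot, replace=False)
    homolog_truth = {genes[gi]: f"AT{1 + gi % 5}G{gi:05d}" for gi in sorted(annotated)}

    # noise-free FPKM of an unbiased sample: 1e9 * baseline / sum(baseline * L)
    base_fpkm = 1e9 * baseline / float((baseline * lengths).sum())
    truth = GroundTruth(
        biased_genes=biased_genes,
        homolog_truth=homolog_truth,
        expected_baseline_fpkm=dict(zip(genes, base_fpkm)),
        contrasts=contrasts,
    )
    return cm, truth


def generate_blast_hits(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Outfmt-6-style hit table: one strong true hit per annotated gene
    (E-value log-uniform in 1e-180..1e-50) plus decoy hits to wrong proteins
    with E-values log-uniform in 1e-40..1e-5, so both the < 1e-20 cutoff and
    the greedy ranking are exercised."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    rows = []
    proteins = sorted(set(truth.homolog_truth.values()))

    def row(q: str, s: str, log10_e: float) -> tuple:
        e = 10.0 ** log10_e
        bits = max(30.0, -1.9 * log10_e + rng.normal(0, 3))
        aln = int(rng.integers(80, 600))
        return (
            q, s,
            round(float(rng.uniform(40, 100)), 2),
            aln,
            int(rng.integers(0, 30)),
            int(rng.integers(0, 5)),
            1, aln, 1, aln,
            f"{e:.2e}",
            round(bits, 1),
        )

    for gene, protein in sorted(truth.homolog_truth.items()):
        rows.append(row(gene, protein, rng.uniform(-180, -50)))
        for _ in range(rng.poisson(1.5)):
            decoy = proteins[int(rng.integers(len(proteins)))]
            if decoy == protein:
                decoy = f"DECOY{rng.integers(10_000):05d}"
            rows.append(row(gene, decoy, rng.uniform(-40, -5)))
    df = pd.DataFrame(
        rows,
        columns=[
            "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        ],
    )
    if len(df):
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    return df


def generate_term_catalog(
    truth: GroundTruth, config: SimConfig, kind: str = "GO"
) -> pd.DataFrame:
    """Protein -> term association table with planted enrichment.

    Every protein carries each term independently with a term-specific
    background probability; for each contrast, ``planted_terms_per_contrast``
    reserved terms are additionally given to the proteins of that contrast's
    biased genes with probability ``planted_term_prob``.  The planted term ids
    are recorded in ``truth.enriched_terms[kind]``.
    """
    config.validate()
    if kind not in ("GO", "pathway"):
        raise ConfigError(f"kind must be 'GO' or 'pathway', got {kind!r}")
    rng = np.random.default_rng([config.seed, 2 if kind == "GO" else 3])
    if kind == "GO":
        term_ids = [f"GO:{7000000 + i:07d}" for i in range(config.n_terms)]
    else:
        term_ids = [f"PWY-{1000 + i}" for i in range(config.n_terms)]

    proteins = sorted(set(truth.homolog_truth.values()))
    gene_of = {p: g for g, p in truth.homolog_truth.items()}
    term_prob = 10.0 ** rng.uniform(
        np.log10(config.term_prob_range[0]), np.log10(config.term_prob_range[1]), size=config.n_terms
    )

    # reserve planted term ids from the front, round-robin over contrasts
    planted: dict[Contrast, set[str]] = {}
    cursor = 0
    for c in truth.contrasts:
        chosen = {term_ids[(cursor + i) % config.n_terms] for i in range(config.planted_terms_per_contrast)} if config.n_terms else set()
        cursor += config.planted_terms_per_contrast
        planted[c] = chosen
    truth.enriched_terms[kind] = planted

    planted_of_gene: dict[str, set[str]] = {}
    for c, entry in truth.biased_genes.items():
        for g in entry:
            planted_of_gene.setdefault(g, set()).update(planted[c])

    rows = []
    for prot in proteins:
        has = rng.random(config.n_terms) < term_prob
        terms = {term_ids[i] for i in np.flatnonzero(has)}
        for t in sorted(planted_of_gene.get(gene_of[prot], ())):
            if rng.random() < config.planted_term_prob:
                terms.add(t)
        for t in sorted(terms):
            rows.append((prot, t))
    return pd.DataFrame(rows, columns=["protein_id", "term_id"])


def _truth_to_json(truth: GroundTruth) -> dict:
    def ckey(c: Contrast) -> str:
        return f"{c.sex_a}_vs_{c.sex_b}|{c.organ}|{c.stage}"

    return {
        "contrasts": [ckey(c) for c in truth.contrasts],
        "biased_genes": {
            ckey(c): {g: {"sex": s, "fold": f} for g, (s, f) in sorted(entry.items())}
            for c, entry in truth.biased_genes.items()
        },
        "homolog_truth": truth.homolog_truth,
        "expected_baseline_fpkm": truth.expected_baseline_fpkm,
        "enriched_terms": {
            kind: {ckey(c): sorted(terms) for c, terms in per.items()}
            for kind, per in truth.enriched_terms.items()
        },
    }


def make_fixture(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete runnable fixture bundle and return its file paths.

    Produces counts.tsv, samples.tsv, blast_hits.tsv, go_terms.tsv,
    pathway_terms.tsv and ground_truth.json in ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, truth = generate_counts(config)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "samples.tsv",
        "blast": outdir / "blast_hits.tsv",
        "go_terms": outdir / "go_terms.tsv",
        "pathway_terms": outdir / "pathway_terms.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_counts(cm, paths["counts"], paths["metadata"])
    hits = generate_blast_hits(truth, config)
    hits.to_csv(paths["blast"], sep="\t", index=False, header=False)
    generate_term_catalog(truth, config, kind="GO").to_csv(paths["go_terms"], sep="\t", index=False)
    generate_term_catalog(truth, config, kind="pathway").to_csv(paths["pathway_terms"], sep="\t", index=False)
    with open(paths["ground_truth"], "w") as fh:
        json.dump(_truth_to_json(truth), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
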