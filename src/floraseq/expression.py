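"""Count-matrix IO and FPKM quantification.

FPKM (fragments per kilobase of exon per million mapped fragments) for gene g in
sample s is

    FPKM_gs = c_gs * 1e9 / (L_g * N_s)

where ``c_gs`` is the fragment count, ``L_g`` the gene length in bp and ``N_s``
the sample's library size.  By default ``N_s`` is the column sum of the counts
themselves, so the matrix is self-contained; an optional ``library_size`` column
in the sample metadata overrides it for fidelity to externally reported mapped-
fragment totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ComputationError, ContractError, LoadError

SEXES = ("female", "male", "supermale")
ORGANS = ("tepal", "pistil", "stamen", "bud", "speartip")

META_COLUMNS = ["sample_id", "sex", "organ", "stage", "replicate"]


@dataclass(frozen=True)
class CountMatrix:
    """Integer fragment counts (genes x samples) with gene lengths and metadata.

    ``counts`` is a genes-by-samples integer DataFrame; ``gene_lengths`` a bp
    Series aligned to its index; ``samples`` a metadata DataFrame indexed by
    sample_id with columns sex, organ, stage, replicate (and optionally
    library_size).
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self):
        if list(self.counts.index) != list(self.gene_lengths.index):
            raise ContractError("gene order of counts and gene_lengths differ")
        if list(self.counts.columns) != list(self.samples.index):
            raise ContractError("sample order of counts and metadata differ")
        if (self.gene_lengths <= 0).any():
            bad = self.gene_lengths.index[self.gene_lengths <= 0][0]
            raise ContractError(f"non-positive gene length for {bad!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ContractError("negative count encountered")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class ExpressionMatrix:
    """FPKM values aligned to the source CountMatrix."""

    values: pd.DataFrame
    library_size: pd.Series
    samples: pd.DataFrame
    gene_lengths: pd.Series = field(repr=False)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return replace(
            self,
            values=self.values.loc[list(gene_ids)],
            gene_lengths=self.gene_lengths.loc[list(gene_ids)],
        )


def read_counts(counts_path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Load a counts TSV (gene_id, gene_length_bp, one column per sample) joined
    with a sample-metadata TSV (sample_id, sex, organ, stage, replicate).

    Raises LoadError naming the sample if a counts column is absent from the
    metadata, or giving row/column coordinates for a non-integer count.
    """
    counts_path, metadata_path = Path(counts_path), Path(metadata_path)
    raw = pd.read_csv(counts_path, sep="\t", dtype={0: str})
    if raw.columns[0] != "gene_id" or raw.columns[1] != "gene_length_bp":
        raise LoadError(
            f"{counts_path}: first two columns must be gene_id, gene_length_bp "
            f"(got {list(raw.columns[:2])})"
        )
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str, "stage": str})
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise LoadError(f"{metadata_path}: missing metadata columns {missing_cols}")

    sample_cols = list(raw.columns[2:])
    known = set(meta["sample_id"])
    for s in sample_cols:
        if s not in known:
            raise LoadError(f"sample {s!r} in {counts_path.name} has no metadata row")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise LoadError(f"duplicate sample_id {dup!r} in metadata")

    for s in sample_cols:
        col = pd.to_numeric(raw[s], errors="coerce")
        bad = col.isna() | (col != np.floor(col))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise LoadError(
                f"non-integer count at gene {raw['gene_id'].iloc[row]!r}, sample {s!r}"
            )
    counts = raw[sample_cols].astype(np.int64)
    counts.index = pd.Index(raw["gene_id"], name="gene_id")
    lengths = pd.Series(
        raw["gene_length_bp"].astype(np.int64).to_numpy(),
        index=counts.index,
        name="gene_length_bp",
    )
    # metadata reordered to the counts' column order; extra metadata rows dropped
    meta = meta.set_index("sample_id").loc[sample_cols]
    return CountMatrix(counts=counts, gene_lengths=lengths, samples=meta)


def write_counts(cm: CountMatrix, counts_path: str | Path, metadata_path: str | Path) -> None:
    """Inverse of :func:`read_counts`; used by the synthetic fixture writer."""
    out = cm.counts.copy()
    out.insert(0, "gene_length_bp", cm.gene_lengths)
    out.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.samples.to_csv(metadata_path, sep="\t", index_label="sample_id")


def compute_fpkm(cm: CountMatrix) -> ExpressionMatrix:
    """FPKM_gs = c_gs * 1e9 / (L_g * N_s), N_s = column sum of counts (or the
    metadata ``library_size`` column when present)."""
    if "library_size" in cm.samples.columns:
        n = cm.samples["library_size"].astype(np.int64)
        n.index = cm.counts.columns
    else:
        n = cm.counts.sum(axis=0)
    zero = n.index[n <= 0]
    if len(zero) > 0:
        raise ComputationError(f"sample {zero[0]!r} has zero total counts")
    values = cm.counts * 1e9
    values = values.div(cm.gene_lengths, axis=0).div(n, axis=1)
    return ExpressionMatrix(
        values=values,
        library_size=n.rename("library_size"),
        samples=cm.samples,
        gene_lengths=cm.gene_lengths,
    )


def log_transform(em: ExpressionMatrix | pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log10(FPKM + pseudocount).

    A pseudocount of 1 maps FPKM 0 to 0 on the log scale.  A zero pseudocount is
    only legal when every value is strictly positive.
    """
    values = em.values if isinstance(em, ExpressionMatrix) else em
    if pseudocount < 0:
        raise ContractError("pseudocount must be non-negative")
    if pseudocount == 0 and (values.to_numpy() <= 0).any():
        raise ComputationError("zero/negative expression with zero pseudocount")
    return np.log10(values + pseudocount)


def filter_min_fpkm(
    em: ExpressionMatrix, threshold: float, mode: str = "any_sample"
) -> ExpressionMatrix:
    """Genes whose FPKM strictly exceeds ``threshold`` in at least one sample
    (``any_sample``) or in every sample (``all_samples``)."""
    if threshold < 0:
        raise ContractError("threshold must be >= 0")
    exceeds = em.values > threshold
    if mode == "any_sample":
        keep = exceeds.any(axis=1)
    elif mode == "all_samples":
        keep = exceeds.all(axis=1)
    else:
        raise ContractError(f"unknown filter mode {mode!r}")
    return em.subset_genes(em.values.index[keep])
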