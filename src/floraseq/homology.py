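"""One-to-one homolog assignment from BLAST tabular output.

Genes are related to proteins "using the lowest E-values": hits with
E >= 1e-20 are discarded, the rest are processed in ascending E-value order
(ties: descending bitscore, then query ID, then subject ID) and a hit is
accepted only when both its gene and its protein are still unassigned.  The
result is injective in both directions.  Term annotations (GO, pathways) are
transferred from protein to gene through the resulting map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .errors import LoadError


class BlastHit(NamedTuple):
    query_gene: str
    subject_protein: str
    e_value: float
    bitscore: float


@dataclass(frozen=True)
class OneToOneMap:
    """Injective gene -> (protein, e_value) assignment with an inverse view."""

    pairs: dict[str, tuple[str, float]]

    @property
    def inverse(self) -> dict[str, str]:
        return {protein: gene for gene, (protein, _) in self.pairs.items()}

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, gene: str) -> bool:
        return gene in self.pairs


def read_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse 12-column outfmt-6-style TSV: query (1), subject (2), E-value (11),
    bitscore (12); the middle columns are ignored."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise LoadError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                e_value = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise LoadError(f"{path}: line {lineno}: {exc}") from exc
            if e_value < 0:
                raise LoadError(f"{path}: line {lineno}: negative E-value")
            hits.append(BlastHit(fields[0], fields[1], e_value, bitscore))
    return hits


def assign_one_to_one(hits: Iterable[BlastHit], e_cutoff: float = 1e-20) -> OneToOneMap:
    """Greedy sequential assignment by ascending E-value (strictly below the
    cutoff), deterministic under any input ordering."""
    kept = [h for h in hits if h.e_value < e_cutoff]
    kept.sort(key=lambda h: (h.e_value, -h.bitscore, h.query_gene, h.subject_protein))
    pairs: dict[str, tuple[str, float]] = {}
    taken_proteins: set[str] = set()
    for h in kept:
        if h.query_gene in pairs or h.subject_protein in taken_proteins:
            continue
        pairs[h.query_gene] = (h.subject_protein, h.e_value)
        taken_proteins.add(h.subject_protein)
    return OneToOneMap(pairs)


def transfer_annotations(
    m: OneToOneMap, protein_terms: Mapping[str, set[str]]
) -> dict[str, set[str]]:
    """Each assigned gene inherits exactly its protein's term set (possibly
    empty); unassigned genes are absent from the output."""
    return {gene: set(protein_terms.get(protein, set())) for gene, (protein, _) in m.pairs.items()}


def read_term_associations(path: str | Path) -> dict[str, set[str]]:
    """protein_id <tab> term_id, one pair per line, header optional."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["protein_id", "term_id"]:
        # headerless two-column file
        df = pd.read_csv(path, sep="\t", header=None, names=["protein_id", "term_id"], dtype=str)
    out: dict[str, set[str]] = {}
    for protein, term in zip(df["protein_id"], df["term_id"]):
        out.setdefault(protein, set()).add(term)
    return out


def write_one_to_one(m: OneToOneMap, path: str | Path) -> None:
    rows = [(g, p, e) for g, (p, e) in sorted(m.pairs.items())]
    pd.DataFrame(rows, columns=["gene_id", "protein_id", "e_value"]).to_csv(
        path, sep="\t", index=False
    )
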