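"""Sex-dependently expressed gene (SDEG) extraction and Jaccard set comparison.

A gene is an SDEG for sex X in a given organ/stage contrast when its mean FPKM
across that side's replicates is strictly above ``fpkm_threshold`` (default 5)
AND strictly more than ``fold_threshold`` times (default 5x) the mean FPKM on
the other side.  Only the contrast's own samples are consulted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError
from .expression import ExpressionMatrix


@dataclass(frozen=True)
class Contrast:
    organ: str
    stage: str
    sex_a: str
    sex_b: str

    def __post_init__(self):
        if self.sex_a == self.sex_b:
            raise ContractError("contrast sides must be different sexes")

    @property
    def label(self) -> str:
        return f"{self.organ}_{self.stage}"


@dataclass(frozen=True)
class SDEGSet:
    """Genes biased toward ``favored_sex`` in one contrast."""

    contrast: Contrast
    favored_sex: str
    gene_ids: frozenset[str]
    fpkm_threshold: float = 5.0
    fold_threshold: float = 5.0

    @property
    def name(self) -> str:
        return f"{self.favored_sex}_{self.contrast.label}"

    def __len__(self) -> int:
        return len(self.gene_ids)


def _side_mean(em: ExpressionMatrix, contrast: Contrast, sex: str) -> pd.Series:
    meta = em.samples
    mask = (
        (meta["organ"] == contrast.organ)
        & (meta["stage"].astype(str) == str(contrast.stage))
        & (meta["sex"] == sex)
    )
    ids = meta.index[mask]
    if len(ids) == 0:
        raise ContractError(
            f"no samples for side sex={sex!r} of contrast {contrast.organ}/{contrast.stage}"
        )
    return em.values[ids].mean(axis=1)


def extract_sdegs(
    em: ExpressionMatrix,
    contrast: Contrast,
    fpkm_threshold: float = 5.0,
    fold_threshold: float = 5.0,
) -> tuple[SDEGSet, SDEGSet]:
    """Both directional SDEG sets of one contrast (sex_a-biased, sex_b-biased).

    Replicate FPKMs are combined by arithmetic mean per side before testing.
    Both inequalities are strict ("higher than 5", "more than 5 times higher").
    """
    mean_a = _side_mean(em, contrast, contrast.sex_a)
    mean_b = _side_mean(em, contrast, contrast.sex_b)

    def biased(favored: pd.Series, other: pd.Series) -> frozenset[str]:
        hit = (favored > fpkm_threshold) & (favored > fold_threshold * other)
        return frozenset(favored.index[hit])

    set_a = SDEGSet(contrast, contrast.sex_a, biased(mean_a, mean_b), fpkm_threshold, fold_threshold)
    set_b = SDEGSet(contrast, contrast.sex_b, biased(mean_b, mean_a), fpkm_threshold, fold_threshold)
    return set_a, set_b


def jaccard_index(a, b) -> float:
    """|a & b| / |a | b|; 0.0 when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def jaccard_matrix(sets: list[SDEGSet]) -> pd.DataFrame:
    """Pairwise Jaccard indices of SDEG sets, labeled by set name."""
    if len(sets) == 0:
        raise ContractError("need at least one SDEG set")
    names = [s.name for s in sets]
    n = len(sets)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            v = jaccard_index(sets[i].gene_ids, sets[j].gene_ids)
            m[i, j] = m[j, i] = v
    return pd.DataFrame(m, index=names, columns=names)


def derive_contrasts(samples: pd.DataFrame) -> list[Contrast]:
    """All pairwise sex contrasts available in the metadata: one Contrast per
    sex pair within each (organ, stage) having two or more sexes."""
    out: list[Contrast] = []
    for (organ, stage), grp in samples.groupby(["organ", "stage"], sort=True):
        sexes = sorted(grp["sex"].unique())
        for i in range(len(sexes)):
            for j in range(i + 1, len(sexes)):
                out.append(Contrast(organ=organ, stage=str(stage), sex_a=sexes[i], sex_b=sexes[j]))
    return out


def write_sdeg_sets(sets: list[SDEGSet], path: str | Path) -> None:
    rows = [(s.name, g) for s in sets for g in sorted(s.gene_ids)]
    pd.DataFrame(rows, columns=["set_name", "gene_id"]).to_csv(path, sep="\t", index=False)
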