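"""Genome de-duplication by Jaccard distance on protein-ID sets.

Closely related strains inflate apparent sample size without adding
independent polymorphism.  Each genome is summarized by its set of
chromosomal non-redundant protein identifiers; two genomes are considered
distinct when the Jaccard distance between these sets is at least a
threshold (default 1%), and a greedy pass retains a subset in which every
pair clears it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ProteinSet", "jaccard_distance", "pairwise_distances", "select_strains"]


@dataclass(frozen=True)
class ProteinSet:
    genome_id: str
    ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError(f"{self.genome_id}: empty protein set")


def jaccard_distance(a: ProteinSet, b: ProteinSet) -> float:
    """d_J = 1 - |A ∩ B| / |A ∪ B|; a metric on non-empty finite sets."""
    inter = len(a.ids & b.ids)
    union = len(a.ids | b.ids)
    return 1.0 - inter / union


def pairwise_distances(sets: list[ProteinSet]) -> pd.DataFrame:
    """Symmetric matrix of Jaccard distances, genomes in input order."""
    n = len(sets)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = jaccard_distance(sets[i], sets[j])
    ids = [s.genome_id for s in sets]
    return pd.DataFrame(mat, index=ids, columns=ids)


def select_strains(sets: list[ProteinSet], min_dist: float = 0.01) -> list[str]:
    """Greedy de-replication: keep a genome iff its distance to every
    already-kept genome is >= ``min_dist``.

    Deterministic given input order.  The retained set is a maximal (not
    necessarily maximum) collection in which all pairs differ by at least
    the threshold.
    """
    if not sets:
        raise ValueError("no protein sets supplied")
    kept: list[ProteinSet] = []
    for s in sets:
        if all(jaccard_distance(s, k) >= min_dist for k in kept):
            kept.append(s)
    return [s.genome_id for s in kept]


def read_protein_sets(path: str | Path) -> list[ProteinSet]:
    """Read a two-column TSV (genome_id, protein_id) into per-genome sets."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (genome_id, protein_id)")
    gcol, pcol = df.columns
    out = []
    for gid, grp in df.groupby(gcol, sort=False):
        out.append(ProteinSet(str(gid), frozenset(grp[pcol])))
    return out
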