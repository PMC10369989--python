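"""Per-site classification and nucleotide diversity of codon alignments.

For each alignment column we record the gap fraction, a consensus base, the
codon degeneracy implied by the consensus codon, the non-gap/non-N depth,
and per-site nucleotide diversity

    pi = 2 * sum_{i<j} f_i f_j / (N (N - 1)),

the probability that two sequences drawn without replacement differ at the
site (f_i are base counts, N their sum).  Columns with over 70% gaps are
excluded; the consensus base must reach 60% of counted characters;
degeneracy is defined only where the full consensus codon is defined and is
not a stop.  Diversity is then summarized over 4-fold degenerate (silent)
sites, whose variation is the closest proxy for neutral polymorphism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .align_io import CodonAlignment

__all__ = [
    "SiteThresholds",
    "gap_filter",
    "consensus",
    "classify_degeneracy",
    "site_pi",
    "gene_site_table",
    "gene_mean_diversity",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_CODE = {c: i for i, c in enumerate("ACGTN-")}


@dataclass(frozen=True)
class SiteThresholds:
    """Column-filtering and classification thresholds.

    max_gap: columns with gap fraction strictly above this are excluded.
    min_consensus: minimum frequency (among non-gap, non-N characters,
        inclusive) for a consensus base to be called.
    min_depth: minimum non-gap/non-N count for pi to be reported.
    translation_table: NCBI genetic-code id (11 = bacterial).
    coordinate_mode: "nucleotide" indexes l over retained columns;
        "silent" indexes l over retained 4-fold columns only.
    """

    max_gap: float = 0.70
    min_consensus: float = 0.60
    min_depth: int = 4
    translation_table: int = 11
    coordinate_mode: str = "nucleotide"

    def __post_init__(self) -> None:
        if not 0 <= self.max_gap < 1:
            raise ValueError("max_gap must be in [0, 1)")
        if not 0 < self.min_consensus <= 1:
            raise ValueError("min_consensus must be in (0, 1]")
        if self.min_depth < 2:
            raise ValueError("min_depth must be >= 2")
        if self.coordinate_mode not in ("nucleotide", "silent"):
            raise ValueError(f"unknown coordinate_mode {self.coordinate_mode!r}")


def _encode(aln: CodonAlignment) -> np.ndarray:
    """Alignment as (n_seqs, length) uint8 matrix over the 6-letter code."""
    flat = "".join(aln.sequences).encode("ascii")
    arr = np.frombuffer(flat, dtype=np.uint8).reshape(aln.n_strains, aln.length)
    lut = np.zeros(128, dtype=np.uint8)
    for ch, code in _CODE.items():
        lut[ord(ch)] = code
    return lut[arr]


def column_counts(aln: CodonAlignment) -> np.ndarray:
    """(length, 6) matrix of per-column counts of A, C, G, T, N, gap."""
    enc = _encode(aln)
    n, L = enc.shape
    out = np.zeros((L, 6), dtype=np.int64)
    flat = enc + 6 * np.arange(L, dtype=np.int64)[None, :]
    np.add.at(out.reshape(-1), flat.ravel(), 1)
    return out


def gap_filter(aln: CodonAlignment, max_gap: float = 0.70) -> np.ndarray:
    """Indices of columns whose gap fraction is not over ``max_gap``.

    The inequality is strict: a column at exactly the threshold is kept.
    """
    counts = column_counts(aln)
    gap_frac = counts[:, 5] / aln.n_strains
    return np.flatnonzero(~(gap_frac > max_gap))


def consensus(aln: CodonAlignment, min_consensus: float = 0.60) -> list[str | None]:
    """Per-column consensus base, or None where no base reaches the threshold.

    The consensus is the most frequent of A/C/G/T among non-gap, non-N
    characters, called iff its frequency among those counted characters is
    >= ``min_consensus``; ties for the most frequent base yield None.
    """
    counts = column_counts(aln)[:, :4]
    return _consensus_from_counts(counts, min_consensus)


def _consensus_from_counts(counts: np.ndarray, min_consensus: float) -> list[str | None]:
    depth = counts.sum(axis=1)
    out: list[str | None] = []
    for row, n in zip(counts, depth):
        if n == 0:
            out.append(None)
            continue
        top = row.max()
        if top / n < min_consensus or (row == top).sum() > 1:
            out.append(None)
        else:
            out.append(_BASES[int(row.argmax())])
    return out


@lru_cache(maxsize=8)
def _forward_table(table_id: int) -> tuple[dict[str, str], set[str]]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return table.forward_table, set(table.stop_codons)


@lru_cache(maxsize=1024)
def classify_degeneracy(codon: str, position: int, translation_table: int = 11) -> int | None:
    """Number of bases at ``position`` encoding the consensus amino acid.

    Holding the other two bases fixed, counts how many of the four bases
    give the same amino acid as the consensus codon.  Returns None for
    incomplete codons (any base not in ACGT) and for stop codons.
    """
    if position not in (0, 1, 2):
        raise ValueError(f"codon position must be 0, 1 or 2, got {position}")
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        return None
    fwd, stops = _forward_table(translation_table)
    if codon in stops:
        return None
    aa = fwd[codon]
    deg = 0
    for b in _BASES:
        alt = codon[:position] + b + codon[position + 1 :]
        if alt not in stops and fwd[alt] == aa:
            deg += 1
    return deg


def site_pi(base_counts) -> float:
    """Nucleotide diversity of one column from its A/C/G/T counts.

    Equals the fraction of mismatching unordered sequence pairs:
    pi = (N^2 - sum f_i^2) / (N (N - 1)).  Requires N >= 2.
    """
    f = np.asarray(base_counts, dtype=np.float64)
    n = f.sum()
    if n < 2:
        raise ValueError(f"site_pi needs at least 2 counted bases, got {int(n)}")
    return float((n * n - (f * f).sum()) / (n * (n - 1)))


def _site_pi_vec(counts: np.ndarray) -> np.ndarray:
    """Vectorized pi over rows of a (L, 4) count matrix; NaN where N < 2."""
    n = counts.sum(axis=1).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = (n * n - (counts.astype(np.float64) ** 2).sum(axis=1)) / (n * (n - 1))
    pi[n < 2] = np.nan
    return pi


def gene_site_table(aln: CodonAlignment, thresholds: SiteThresholds | None = None) -> pd.DataFrame:
    """Classify every retained column of one gene and compute per-site pi.

    Degeneracy is determined from the consensus codon in original alignment
    coordinates (codon = columns 3i..3i+2), so a gap-heavy column inside a
    codon does not shift frame.  The returned table has one row per column
    passing the gap filter, with the offset ``l`` indexed per the
    configured coordinate mode; pi is NaN where depth < min_depth.

    Columns: gene_id, column_index, offset_l, codon_position, consensus,
    degeneracy, depth, pi, fourfold.
    """
    th = thresholds or SiteThresholds()
    counts6 = column_counts(aln)
    base_counts = counts6[:, :4]
    cons = _consensus_from_counts(base_counts, th.min_consensus)

    # per-codon degeneracy from the consensus sequence
    degeneracy: list[int | None] = [None] * aln.length
    for ci in range(aln.n_codons):
        triplet = cons[3 * ci : 3 * ci + 3]
        if any(b is None for b in triplet):
            continue
        codon = "".join(triplet)  # type: ignore[arg-type]
        for pos in range(3):
            degeneracy[3 * ci + pos] = classify_degeneracy(codon, pos, th.translation_table)

    retained = gap_filter(aln, th.max_gap)
    depth = base_counts.sum(axis=1)
    pi = _site_pi_vec(base_counts)
    shallow = depth < th.min_depth
    pi[shallow] = np.nan
    n_shallow = int(shallow[retained].sum())
    if n_shallow:
        logger.info("%s: %d retained sites below min_depth=%d skipped",
                    aln.gene_id, n_shallow, th.min_depth)

    deg_ret = np.array([-1 if degeneracy[i] is None else degeneracy[i] for i in retained])
    fourfold = deg_ret == 4
    if th.coordinate_mode == "nucleotide":
        offset = np.arange(len(retained))
    else:  # silent: rank among retained 4-fold columns, others get -1
        offset = np.full(len(retained), -1)
        offset[fourfold] = np.arange(int(fourfold.sum()))

    return pd.DataFrame(
        {
            "gene_id": aln.gene_id,
            "column_index": retained,
            "offset_l": offset,
            "codon_position": retained % 3,
            "consensus": [cons[i] for i in retained],
            "degeneracy": deg_ret,
            "depth": depth[retained],
            "pi": pi[retained],
            "fourfold": fourfold,
        }
    )


def gene_mean_diversity(table: pd.DataFrame, alignment_length: int | None = None) -> tuple[int, float]:
    """(gene length in bases, unweighted mean pi over 4-fold sites).

    Gene length is the alignment length before column filtering when known
    (``alignment_length``), else the count of rows in the table.  Raises if
    the gene has no 4-fold site with a defined pi.
    """
    four = table[table["fourfold"] & table["pi"].notna()]
    if four.empty:
        raise ValueError(f"{table['gene_id'].iat[0] if len(table) else '?'}: no usable 4-fold site")
    length = alignment_length if alignment_length is not None else len(table)
    return int(length), float(four["pi"].mean())
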