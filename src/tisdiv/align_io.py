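"""Reading, validation and writing of the pipeline's standard-format inputs.

Codon alignments arrive as aligned FASTA (one file per ortholog group);
ortholog presence/copy-number matrices and all tabular outputs are
tab-delimited UTF-8 text with a header row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CodonAlignment",
    "AlignmentFormatError",
    "read_codon_alignment",
    "write_codon_alignment",
    "read_presence_matrix",
    "filter_orthologs",
]

# IUPAC ambiguity codes other than N collapse to N: per-site diversity
# counts only the four unambiguous bases.
_AMBIGUOUS = set("RYSWKMBDHV")
_ALPHABET = set("ACGTN-")


class AlignmentFormatError(ValueError):
    """Raised when a FASTA file does not hold a valid codon alignment."""


@dataclass
class CodonAlignment:
    """An in-frame nucleotide alignment of one gene across strains.

    ``sequences`` are equal-length strings over ``{A,C,G,T,N,-}``; the
    first alignment column is the first base of the start codon (TIS).
    """

    gene_id: str
    strain_ids: list[str]
    sequences: list[str]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise AlignmentFormatError(
                f"{self.gene_id}: need at least 2 sequences, got {len(self.sequences)}"
            )
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"{self.gene_id}: ragged alignment, sequence lengths {sorted(lengths)}"
            )
        (self.length,) = lengths
        if self.length % 3 != 0:
            raise AlignmentFormatError(
                f"{self.gene_id}: alignment length {self.length} not divisible by 3"
            )
        if len(self.strain_ids) != len(self.sequences):
            raise AlignmentFormatError(
                f"{self.gene_id}: {len(self.strain_ids)} ids for {len(self.sequences)} sequences"
            )

    @property
    def n_strains(self) -> int:
        return len(self.sequences)

    @property
    def n_codons(self) -> int:
        return self.length // 3


def _normalize(seq: str, *, context: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _ALPHABET
    if bad & _AMBIGUOUS:
        warnings.warn(
            f"{context}: ambiguity codes {sorted(bad & _AMBIGUOUS)} mapped to N",
            stacklevel=3,
        )
        for ch in bad & _AMBIGUOUS:
            s = s.replace(ch, "N")
        bad -= _AMBIGUOUS
    if bad:
        raise AlignmentFormatError(f"{context}: invalid characters {sorted(bad)}")
    return s


def read_codon_alignment(path: str | Path, gene_id: str | None = None) -> CodonAlignment:
    """Read and validate one aligned FASTA file.

    Characters are uppercased and U is mapped to T; IUPAC ambiguity codes
    other than N are mapped to N with a warning.  Raises
    :class:`AlignmentFormatError` naming the file on ragged records, a
    length not divisible by 3, or fewer than two records.
    """
    path = Path(path)
    if gene_id is None:
        gene_id = path.stem
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(_normalize(str(rec.seq), context=f"{path.name}:{rec.id}"))
    if not ids:
        raise AlignmentFormatError(f"{path}: no FASTA records")
    try:
        return CodonAlignment(gene_id=gene_id, strain_ids=ids, sequences=seqs)
    except AlignmentFormatError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from None


def write_codon_alignment(aln: CodonAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.strain_ids, aln.sequences)
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


def read_alignment_dir(directory: str | Path, pattern: str = "*.fasta") -> Iterable[CodonAlignment]:
    """Yield alignments from every FASTA file in ``directory`` (sorted)."""
    directory = Path(directory)
    paths = sorted(directory.glob(pattern))
    if not paths:
        raise AlignmentFormatError(f"no {pattern} files under {directory}")
    for p in paths:
        yield read_codon_alignment(p)


def read_presence_matrix(path: str | Path) -> pd.DataFrame:
    """Read an ortholog presence matrix: rows genes, columns genomes, integer copy number."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative copy numbers")
    return df.astype(int)


def filter_orthologs(presence: pd.DataFrame, min_presence: float = 0.75) -> list[str]:
    """Select single-copy orthologs present in at least ``min_presence`` of genomes.

    A gene qualifies when its copy number is exactly 1 in every genome where
    it occurs and it occurs in >= ``min_presence`` (inclusive) of all genomes.
    """
    if not 0 < min_presence <= 1:
        raise ValueError(f"min_presence must be in (0, 1], got {min_presence}")
    if presence.empty:
        raise ValueError("empty presence matrix")
    counts = presence.to_numpy()
    keep: list[str] = []
    n_genomes = presence.shape[1]
    for gene, row in zip(presence.index, counts):
        occ = row > 0
        if occ.sum() / n_genomes >= min_presence and (row[occ] == 1).all():
            keep.append(str(gene))
    return keep


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, index_col: int | str | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
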