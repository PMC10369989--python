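"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the data the pipeline consumes — per-gene codon
alignments whose 4-fold-site diversity follows the asymptotic curve
pibar(l) = dmax + (dmin - dmax) exp(-c l), TIS unpaired-probability
matrices with a decaying 5' openness signal, and species trait tables
evolving on a pure-birth tree under a Pagel's-lambda covariance — so the
estimators can be validated by parameter recovery.

Polymorphic sites are biallelic with derived-allele count k drawn
proportional to 1/k, the neutral site-frequency spectrum.  This gives a
closed-form calibration: for a site with n sequences the expected
diversity of a polymorphic site is

    E[pi | polymorphic] = 1 / H(n-1),   H(m) = sum_{k=1..m} 1/k,

since pi(k) = 2 k (n-k) / (n (n-1)) averaged over the 1/k spectrum
telescopes to 1/H(n-1).  A site is therefore made polymorphic with
probability q = pi_target * H(n-1), making the unconditional expectation
exactly pi_target.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .align_io import CodonAlignment, write_codon_alignment
from .profile_model import DiversityProfile

__all__ = [
    "ProfileParams",
    "SimConfig",
    "harmonic_number",
    "simulate_site_alleles",
    "simulate_site_pi",
    "simulate_codon_alignments",
    "simulate_profile",
    "simulate_gene_summaries",
    "simulate_tree_traits",
    "simulate_unpaired_profiles",
    "write_species_bundle",
    "FOURFOLD_PREFIXES",
    "TWOFOLD_CODONS",
]

# codon families under the bacterial code (table 11): NNx with any third
# base encoding one amino acid (4-fold), and representative 2-fold codons
FOURFOLD_PREFIXES = ["GC", "GG", "GT", "CC", "CG", "CT", "TC", "AC"]
TWOFOLD_CODONS = ["AAA", "GAA", "TTT", "TAT", "AAT", "GAT", "CAT", "CAA"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ProfileParams:
    """Ground-truth parameters of the diversity-vs-position curve.

    dmin: mean silent diversity at the TIS (l = 0); dmax: asymptotic
    diversity; c: relative rate of increase per base.  Implied effect
    length Le = ln2/c and effect size Se = log2(dmax/dmin).
    """

    dmin: float
    dmax: float
    c: float

    def __post_init__(self) -> None:
        if not (0 < self.dmin <= self.dmax < 1):
            raise ValueError(f"need 0 < dmin <= dmax < 1, got ({self.dmin}, {self.dmax})")
        if self.c <= 0:
            raise ValueError(f"need c > 0, got {self.c}")

    @property
    def Le(self) -> float:
        return math.log(2) / self.c

    @property
    def Se(self) -> float:
        return math.log2(self.dmax / self.dmin)

    def pi_at(self, l):
        return self.dmax + (self.dmin - self.dmax) * np.exp(-self.c * np.asarray(l, dtype=float))

    @classmethod
    def from_effects(cls, Le: float, Se: float, dmax: float) -> "ProfileParams":
        """Construct from effect length/size and the asymptote."""
        return cls(dmin=dmax / 2**Se, dmax=dmax, c=math.log(2) / Le)


@dataclass(frozen=True)
class SimConfig:
    """Alignment-simulation settings.

    gene_length_distribution is (min, max, shape) in codons; lengths are
    min + (max - min) * Beta(1, shape), so shape = 1 is uniform and larger
    shapes skew toward short genes.
    """

    n_strains: int = 96
    n_genes: int = 300
    gene_length_distribution: tuple[int, int, float] = (50, 400, 1.0)
    fraction_fourfold_codons: float = 0.6
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")
        lo, hi, shape = self.gene_length_distribution
        if lo < 50 or hi < lo or shape <= 0:
            raise ValueError(f"bad gene_length_distribution {self.gene_length_distribution}")
        if not 0 <= self.gap_rate < 0.3:
            raise ValueError("gap_rate must be in [0, 0.3)")
        if not 0 < self.fraction_fourfold_codons <= 1:
            raise ValueError("fraction_fourfold_codons must be in (0, 1]")


@lru_cache(maxsize=64)
def harmonic_number(m: int) -> float:
    """H(m) = sum_{k=1..m} 1/k."""
    return float(np.sum(1.0 / np.arange(1, m + 1)))


@lru_cache(maxsize=64)
def _sfs_probs(n: int) -> np.ndarray:
    k = np.arange(1, n)
    p = 1.0 / k
    return p / p.sum()


def _check_pi_target(pi_target: float, n: int) -> float:
    if not 0 <= pi_target < 1:
        raise ValueError(f"pi_target must be in [0, 1), got {pi_target}")
    q = pi_target * harmonic_number(n - 1)
    if q > 1:
        raise ValueError(
            f"pi_target={pi_target} too large for n={n}: polymorphism "
            f"probability q = pi_target * H(n-1) = {q:.3f} exceeds 1"
        )
    return q


def simulate_site_alleles(pi_target: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Base counts over (A, C, G, T) for one site of ``n`` sequences.

    Monomorphic with probability 1 - q, q = pi_target * H(n-1); otherwise
    biallelic with derived count k in 1..n-1 drawn proportional to 1/k and
    a uniformly chosen alternative base.  The expected diversity over
    draws equals ``pi_target`` exactly.
    """
    if n < 2:
        raise ValueError("need n >= 2 sequences")
    q = _check_pi_target(pi_target, n)
    counts = np.zeros(4, dtype=np.int64)
    ref = rng.integers(4)
    if rng.random() >= q:
        counts[ref] = n
        return counts
    k = int(rng.choice(n - 1, p=_sfs_probs(n))) + 1
    alt = (ref + 1 + rng.integers(3)) % 4
    counts[ref] = n - k
    counts[alt] = k
    return counts


def simulate_site_pi(pi_targets, n: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized per-site diversity draws under the same allele model.

    Returns realized pi values (not counts) for an array of target means;
    distributionally identical to running :func:`simulate_site_alleles`
    and scoring each site, which lets profile-scale recovery experiments
    run at realistic gene counts.
    """
    t = np.asarray(pi_targets, dtype=float).ravel()
    H = harmonic_number(n - 1)
    q = t * H
    if (q > 1).any():
        raise ValueError("some pi_target too large for n (q > 1)")
    poly = rng.random(t.shape) < q
    pi = np.zeros_like(t)
    m = int(poly.sum())
    if m:
        k = rng.choice(n - 1, size=m, p=_sfs_probs(n)) + 1
        pi[poly] = 2.0 * k * (n - k) / (n * (n - 1))
    return pi.reshape(np.shape(pi_targets))


def _gene_lengths(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi, shape = config.gene_length_distribution
    u = rng.beta(1.0, shape, size=config.n_genes)
    return (lo + np.floor(u * (hi - lo))).astype(int)


def simulate_codon_alignments(params: ProfileParams, config: SimConfig) -> list[CodonAlignment]:
    """Generate per-gene codon alignments with the target diversity curve.

    Codons are drawn from 4-fold families with probability
    ``fraction_fourfold_codons`` (2-fold families otherwise); each third
    position of a 4-fold codon at nucleotide offset l carries alleles from
    :func:`simulate_site_alleles` with target dmax + (dmin-dmax) e^{-cl}.
    First/second codon positions and 2-fold third positions are
    monomorphic.  Gaps are injected independently per cell at
    ``gap_rate``.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_strains
    out = []
    for g, n_codons in enumerate(_gene_lengths(config, rng)):
        L = 3 * n_codons
        mat = np.empty((n, L), dtype="U1")
        is4 = rng.random(n_codons) < config.fraction_fourfold_codons
        for ci in range(n_codons):
            if is4[ci]:
                prefix = FOURFOLD_PREFIXES[rng.integers(len(FOURFOLD_PREFIXES))]
                l = 3 * ci + 2
                target = float(params.pi_at(l))
                counts = simulate_site_alleles(target, n, rng)
                third = np.repeat(_BASES, counts)
                rng.shuffle(third)
            else:
                codon = TWOFOLD_CODONS[rng.integers(len(TWOFOLD_CODONS))]
                prefix, third = codon[:2], np.full(n, codon[2], dtype="U1")
            mat[:, 3 * ci] = prefix[0]
            mat[:, 3 * ci + 1] = prefix[1]
            mat[:, 3 * ci + 2] = third
        if config.gap_rate > 0:
            mat[rng.random(mat.shape) < config.gap_rate] = "-"
        seqs = ["".join(row) for row in mat]
        ids = [f"strain{s:03d}" for s in range(n)]
        out.append(CodonAlignment(gene_id=f"gene{g:04d}", strain_ids=ids, sequences=seqs))
    return out


def simulate_profile(
    params: ProfileParams,
    n_strains: int,
    n_genes: int,
    rng: np.random.Generator,
    max_l: int = 500,
    noise_sd: float | None = None,
) -> DiversityProfile:
    """Mean-diversity profile at 4-fold third-position offsets (2, 5, 8...).

    Each position's mean is the average of ``n_genes`` per-site diversity
    draws (the same allele model as the alignment generator), or — when
    ``noise_sd`` is given — the exact curve plus Gaussian noise, for
    fit-coverage experiments with a known error model.
    """
    ls = np.arange(2, max_l + 1, 3, dtype=float)
    truth = params.pi_at(ls)
    if noise_sd is not None:
        mean = truth + rng.normal(0.0, noise_sd, size=len(ls))
    else:
        draws = simulate_site_pi(np.tile(truth, (n_genes, 1)), n_strains, rng)
        mean = draws.mean(axis=0)
    return DiversityProfile(ls, np.clip(mean, 0.0, 1.0), np.full(len(ls), n_genes, dtype=float))


def simulate_gene_summaries(
    params: ProfileParams,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[int, float]]:
    """(gene length in bases, mean 4-fold diversity) per gene, drawn at the
    site level under the positional curve.

    Short genes sample only the low-diversity head of the curve, so a
    TIS-proximal reduction (dmin < dmax) induces a positive
    diversity-length correlation; a flat curve does not.
    """
    out = []
    for n_codons in _gene_lengths(config, rng):
        ls = np.arange(2, 3 * n_codons, 3, dtype=float)
        is4 = rng.random(len(ls)) < config.fraction_fourfold_codons
        if not is4.any():
            continue
        pis = simulate_site_pi(params.pi_at(ls[is4]), config.n_strains, rng)
        out.append((3 * n_codons, float(np.mean(pis))))
    return out


# ---------------------------------------------------------------------------
# comparative-layer generators


class _Node:
    __slots__ = ("children", "birth", "end", "label")

    def __init__(self, birth: float):
        self.children: list["_Node"] = []
        self.birth = birth
        self.end = birth
        self.label: str | None = None


def _yule_tree(n_species: int, rng: np.random.Generator) -> str:
    """Pure-birth (Yule) tree as newick, root-to-tip depth scaled to 1.

    The process starts with two lineages at the root split; waiting times
    between splits are exponential with rate equal to the number of active
    lineages, and the splitting lineage is chosen uniformly.
    """
    root = _Node(0.0)
    root.children = [_Node(0.0), _Node(0.0)]
    active = list(root.children)
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active[i]
        node.end = t
        node.children = [_Node(t), _Node(t)]
        active[i] = node.children[0]
        active.append(node.children[1])
    t += rng.exponential(1.0 / len(active))
    depth = t if t > 0 else 1.0
    for i, tip in enumerate(active):
        tip.label = f"s{i + 1}"
        tip.end = depth

    def render(node: _Node) -> str:
        edge = (node.end - node.birth) / depth
        if node.children:
            inner = "(" + ",".join(render(c) for c in node.children) + ")"
            return f"{inner}:{edge:.10f}"
        return f"{node.label}:{edge:.10f}"

    return "(" + ",".join(render(c) for c in root.children) + ");"


def simulate_tree_traits(
    n_species: int,
    lambda_true: float,
    beta,
    sigma2: float,
    seed: int,
    n_predictors: int | None = None,
) -> tuple[str, pd.DataFrame]:
    """Traits on a pure-birth tree under a Pagel's-lambda error structure.

    Predictors are iid standard normal; the response is X beta plus
    multivariate normal error with covariance sigma2 * V(lambda_true),
    V(lambda) being the Brownian tree covariance with off-diagonals scaled
    by lambda.  Returns (newick, table) with species s1..sn as index.
    """
    if n_species < 10:
        raise ValueError("need n_species >= 10")
    if not 0 <= lambda_true <= 1:
        raise ValueError("lambda_true must be in [0, 1]")
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    p = n_predictors or len(beta)
    rng = np.random.default_rng(seed)
    newick = _yule_tree(n_species, rng)

    from .comparative import tree_covariance, pagel_covariance  # local: avoid cycle

    taxa = [f"s{i + 1}" for i in range(n_species)]
    C = tree_covariance(newick, taxa=taxa).to_numpy()
    V = pagel_covariance(C, lambda_true)
    X = rng.standard_normal((n_species, p))
    eps = rng.multivariate_normal(np.zeros(n_species), sigma2 * V, method="cholesky")
    y = X @ np.resize(beta, p) + eps
    df = pd.DataFrame(X, index=taxa, columns=[f"x{j + 1}" for j in range(p)])
    df["y"] = y
    return newick, df


def simulate_unpaired_profiles(
    n_genes: int,
    effect_size: float,
    decay_length: float,
    noise_sd: float,
    seed: int,
    baseline: float = 0.5,
) -> pd.DataFrame:
    """Gene x position unpaired-probability matrix over -100..+200.

    Baseline openness plus an exponentially decaying bump downstream of
    the TIS plus iid Gaussian noise, clamped to [0, 1].  ``effect_size``
    sets the approximate peak of the downstream z-profile: the bump
    amplitude is effect_size times the flank SD of the cross-gene mean
    (noise_sd / sqrt(n_genes)), falling back to probability units
    (0.01 * effect_size) when noise_sd = 0.
    """
    rng = np.random.default_rng(seed)
    pos = np.arange(-100, 201)
    amp_unit = noise_sd / math.sqrt(n_genes) if noise_sd > 0 else 0.01
    bump = np.where(pos >= 0, effect_size * amp_unit * np.exp(-np.maximum(pos, 0) / decay_length), 0.0)
    mat = baseline + bump[None, :] + rng.normal(0.0, noise_sd, size=(n_genes, len(pos)))
    mat = np.clip(mat, 0.0, 1.0)
    return pd.DataFrame(mat, index=[f"gene{i:04d}" for i in range(n_genes)], columns=pos)


def write_species_bundle(
    directory: str | Path,
    params: ProfileParams,
    config: SimConfig,
    structure: dict | None = None,
) -> Path:
    """Write a complete synthetic species input set under ``directory``.

    Produces one FASTA per gene under alignments/, an unpaired-probability
    TSV, and a manifest.json recording every ground-truth parameter and
    the seed.  Returns the manifest path.
    """
    directory = Path(directory)
    (directory / "alignments").mkdir(parents=True, exist_ok=True)
    for aln in simulate_codon_alignments(params, config):
        write_codon_alignment(aln, directory / "alignments" / f"{aln.gene_id}.fasta")
    structure = structure or dict(effect_size=5.0, decay_length=40.0, noise_sd=0.05)
    mat = simulate_unpaired_profiles(n_genes=config.n_genes, seed=config.seed, **structure)
    mat.to_csv(directory / "unpaired.tsv", sep="\t", index_label="gene_id")
    manifest = {
        "params": asdict(params),
        "Le_true": params.Le,
        "Se_true": params.Se,
        "config": asdict(config),
        "structure": structure,
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
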