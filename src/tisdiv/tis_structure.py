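"""TIS mRNA-structure openness profiles and their effect length/size.

Genes under selection against stable mRNA secondary structure near the
translation initiation site show elevated base-unpairing probabilities
just downstream of the start codon.  Given a gene x position matrix of
unpaired probabilities over -100..+200 (position 0 = first base of the
start codon), the cross-gene mean profile is converted to z-scores against
the mean and SD of the two flank windows (-90..-51 and +151..+190, 40
positions each), where no TIS-specific signal is expected.  The structure
effect length Lss is the first position >= +5 at which the z-score is no
longer positive, and the effect size Sss is the maximum z over +5..+200.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["POSITIONS", "FLANK_POSITIONS", "ZProfile", "zscore_profile", "structure_effects"]

POSITIONS = np.arange(-100, 201)
FLANK_POSITIONS = np.concatenate([np.arange(-90, -50), np.arange(151, 191)])


@dataclass
class ZProfile:
    positions: np.ndarray
    z: np.ndarray
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "z": self.z})


def _validate(matrix: pd.DataFrame) -> pd.DataFrame:
    cols = np.asarray(matrix.columns, dtype=int)
    missing = sorted(set(POSITIONS) - set(cols))
    if missing:
        raise ValueError(f"unpaired matrix missing positions {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    m = matrix.copy()
    m.columns = cols
    m = m.loc[:, POSITIONS]
    vals = m.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("unpaired probabilities must lie in [0, 1]")
    return m


def zscore_profile(matrix: pd.DataFrame, per_gene: bool = False) -> ZProfile:
    """Convert an unpaired-probability matrix to a positional z-profile.

    Default ("aggregate") variant: average probabilities across genes per
    position, then z-normalize the mean profile by the mean and SD over the
    80 flank positions.  With ``per_gene=True`` each gene's profile is
    flank-normalized first and the per-gene z-scores averaged.  If the
    flank SD is zero the z-profile is defined as identically zero.

    Genes with missing values (e.g. genes shorter than +200) contribute
    only their defined positions.
    """
    m = _validate(matrix)
    if m.shape[0] < 10:
        raise ValueError(f"need >= 10 genes, got {m.shape[0]}")
    vals = m.to_numpy(dtype=float)
    flank_idx = np.searchsorted(POSITIONS, FLANK_POSITIONS)
    if per_gene:
        fl = vals[:, flank_idx]
        mu = np.nanmean(fl, axis=1, keepdims=True)
        sd = np.nanstd(fl, axis=1, ddof=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            zg = (vals - mu) / sd
        zg[np.broadcast_to(sd == 0, zg.shape)] = 0.0
        z = np.nanmean(zg, axis=0)
    else:
        pbar = np.nanmean(vals, axis=0)
        mu = float(np.mean(pbar[flank_idx]))
        sd = float(np.std(pbar[flank_idx], ddof=0))
        z = np.zeros_like(pbar) if sd == 0 else (pbar - mu) / sd
    return ZProfile(POSITIONS.copy(), z, n_genes=m.shape[0])


def structure_effects(profile: ZProfile) -> tuple[int, float]:
    """(Lss, Sss) from a z-profile.

    Lss is the smallest position i >= +5 with z(i) <= 0 ("drops to zero"),
    or the end of the region (+200) if the z-score stays positive; Sss is
    the maximum z over +5..+200.
    """
    sel = profile.positions >= 5
    pos = profile.positions[sel]
    z = profile.z[sel]
    nonpos = np.flatnonzero(z <= 0)
    lss = int(pos[nonpos[0]]) if nonpos.size else int(pos[-1])
    return lss, float(np.max(z))
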