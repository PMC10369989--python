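"""End-to-end orchestration: alignments in, species/comparative reports out.

Stages per species: optional strain de-duplication, per-gene site tables,
gene summaries and the diversity-length correlation, the positional
diversity profile, the asymptotic-regression fit with effect estimates,
and optionally the TIS-structure z-profile.  A comparative stage relates
per-species effect lengths to their covariates across a phylogeny.  Every
run writes its configuration and input digests into a manifest so
deterministic stages can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import align_io, comparative, dedup, profile_model, site_stats, tis_structure

__all__ = ["RunConfig", "run_species", "run_comparative"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for a species run; serialized into the manifest."""

    alignments_dir: str | None = None
    presence_matrix: str | None = None
    protein_sets: str | None = None
    unpaired_matrix: str | None = None
    tree: str | None = None
    covariate_table: str | None = None
    out_dir: str = "run_output"

    max_gap: float = 0.70
    min_consensus: float = 0.60
    min_depth: int = 4
    min_presence: float = 0.75
    dedup_min_dist: float = 0.01
    fit_window: int = 500
    min_genes: int = 20
    translation_table: int = 11
    coordinate_mode: str = "nucleotide"
    seed: int = 0

    def thresholds(self) -> site_stats.SiteThresholds:
        return site_stats.SiteThresholds(
            max_gap=self.max_gap,
            min_consensus=self.min_consensus,
            min_depth=self.min_depth,
            translation_table=self.translation_table,
            coordinate_mode=self.coordinate_mode,
        )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _write_manifest(config: RunConfig, out: Path, extra: dict) -> None:
    manifest = {"config": dataclasses.asdict(config), **extra}
    for key in ("presence_matrix", "unpaired_matrix", "tree", "covariate_table"):
        p = getattr(config, key)
        if p and Path(p).is_file():
            manifest.setdefault("input_digests", {})[key] = _digest(Path(p))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_species(config: RunConfig, species: str = "species") -> dict:
    """Run the per-species pipeline and write a one-row report.

    Non-convergence of the profile fit is a reported state (converged
    False, effect columns NaN), not an error; missing or malformed inputs
    raise with a stage-tagged message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timers: dict[str, float] = {}
    counts: dict[str, int] = {}

    retained_strains: list[str] | None = None
    if config.protein_sets:
        t0 = time.perf_counter()
        sets = dedup.read_protein_sets(config.protein_sets)
        mat = dedup.pairwise_distances(sets)
        align_io.write_tsv(mat.reset_index().rename(columns={"index": "genome_id"}),
                           out / "jaccard_distances.tsv")
        retained_strains = dedup.select_strains(sets, config.dedup_min_dist)
        pd.DataFrame({"genome_id": retained_strains}).to_csv(
            out / "retained_strains.tsv", sep="\t", index=False)
        counts["strains_retained"] = len(retained_strains)
        timers["dedup"] = time.perf_counter() - t0

    if not config.alignments_dir:
        raise ValueError("stage site_stats: no alignments_dir configured")
    t0 = time.perf_counter()
    try:
        alignments = list(align_io.read_alignment_dir(config.alignments_dir))
    except align_io.AlignmentFormatError as exc:
        raise align_io.AlignmentFormatError(f"stage site_stats: {exc}") from None

    keep_genes: set[str] | None = None
    if config.presence_matrix:
        presence = align_io.read_presence_matrix(config.presence_matrix)
        keep_genes = set(align_io.filter_orthologs(presence, config.min_presence))
        alignments = [a for a in alignments if a.gene_id in keep_genes]

    th = config.thresholds()
    tables = []
    summaries = []
    skipped = 0
    for aln in alignments:
        if retained_strains is not None:
            idx = [i for i, s in enumerate(aln.strain_ids) if s in retained_strains]
            if len(idx) >= 2:
                aln = align_io.CodonAlignment(
                    aln.gene_id, [aln.strain_ids[i] for i in idx],
                    [aln.sequences[i] for i in idx])
        tab = site_stats.gene_site_table(aln, th)
        tables.append(tab)
        try:
            summaries.append(site_stats.gene_mean_diversity(tab, aln.length))
        except ValueError:
            skipped += 1
    counts["genes"] = len(tables)
    counts["genes_without_fourfold"] = skipped
    pd.concat(tables).to_csv(out / "site_tables.tsv", sep="\t", index=False)
    pd.DataFrame(summaries, columns=["length", "mean_pi"]).to_csv(
        out / "gene_summaries.tsv", sep="\t", index=False)
    timers["site_stats"] = time.perf_counter() - t0

    rho_l = p_rho = float("nan")
    if len(summaries) >= 10:
        try:
            rho_l, p_rho = profile_model.diversity_length_correlation(summaries)
        except ValueError as exc:
            logger.warning("diversity-length correlation undefined: %s", exc)

    t0 = time.perf_counter()
    profile = profile_model.aggregate_profile(tables, max_l=config.fit_window,
                                              min_genes=min(config.min_genes, len(tables)))
    align_io.write_tsv(profile.to_frame(), out / "profile.tsv")
    fit = profile_model.fit_asr(profile)
    timers["fit"] = time.perf_counter() - t0

    report: dict = {
        "species": species,
        "n_genes": counts["genes"],
        "n_strains": retained_strains and len(retained_strains) or alignments[0].n_strains,
        "rho_l": rho_l,
        "rho_l_p": p_rho,
        "converged": fit.converged,
        "dmin": fit.dmin, "dmax": fit.dmax, "c": fit.c,
        "Le": float("nan"), "Se": float("nan"),
        "sigma_Le": float("nan"), "sigma_Se": float("nan"),
        "saturation_point": float("nan"), "positive_effect": False,
        "Lss": float("nan"), "Sss": float("nan"),
    }
    if fit.converged and fit.dmin > 0:
        eff = profile_model.effect_estimates(fit)
        report.update(Le=eff.Le, Se=eff.Se, sigma_Le=eff.sigma_Le,
                      sigma_Se=eff.sigma_Se, saturation_point=eff.saturation_point,
                      positive_effect=eff.positive_effect)
    fit_report = {
        "dmin": fit.dmin, "dmax": fit.dmax, "c": fit.c,
        "covariance": None if fit.cov is None else fit.cov.tolist(),
        "resid_var": fit.resid_var, "converged": fit.converged,
        "n_positions": fit.n_positions, "window": config.fit_window,
        "Se": report["Se"], "Le": report["Le"],
        "sigma_Se": report["sigma_Se"], "sigma_Le": report["sigma_Le"],
        "saturation_point": report["saturation_point"],
    }
    (out / "fit.json").write_text(json.dumps(fit_report, indent=2))

    if config.unpaired_matrix:
        t0 = time.perf_counter()
        mat = pd.read_csv(config.unpaired_matrix, sep="\t", index_col=0)
        z = tis_structure.zscore_profile(mat)
        align_io.write_tsv(z.to_frame(), out / "zprofile.tsv")
        lss, sss = tis_structure.structure_effects(z)
        report.update(Lss=lss, Sss=sss)
        timers["zprofile"] = time.perf_counter() - t0

    pd.DataFrame([report]).to_csv(out / "species_report.tsv", sep="\t", index=False)
    _write_manifest(config, out, {"stage": "species", "timers": timers, "counts": counts})
    for stage, dt in timers.items():
        logger.info("stage %s: %.2fs", stage, dt)
    return report


def run_comparative(
    config: RunConfig,
    species_table: pd.DataFrame,
    tree: str,
    predictors: list[str] | None = None,
    response: str = "Le",
    cv_reps: int = 100,
) -> dict:
    """Cross-species layer: transforms, correlations, VIF, scaled OLS,
    PGLS with Pagel's lambda, and the backward-elimination CV ladder."""
    if len(species_table) < 10:
        raise ValueError(f"need >= 10 species rows, got {len(species_table)}")
    out = Path(config.out_dir) / "comparative"
    out.mkdir(parents=True, exist_ok=True)
    predictors = predictors or [c for c in species_table.columns if c != response]

    data = species_table[[response, *predictors]].dropna()
    logger.info("complete-case rows: %d of %d", len(data), len(species_table))
    X = data[predictors]
    y = data[response]

    corr = comparative.correlation_matrix(data)
    corr.to_csv(out / "correlations.tsv", sep="\t")
    vifs = comparative.vif(X)
    vifs.rename("vif").to_csv(out / "vif.tsv", sep="\t")
    ols = comparative.scaled_ols(y, X)
    gls = comparative.pgls_pagel(y, X, tree, lambda_mode="ML")
    ladder = comparative.backward_elimination_cv(y, X, reps=cv_reps, seed=config.seed)
    ladder.to_csv(out / "model_ladder.tsv", sep="\t", index=False)
    best = ladder[ladder["selected"]].iloc[0]

    report = {
        "n_species": len(data),
        "lambda_hat": gls.lam,
        "lambda_ci": gls.lam_ci,
        "gls_loglik": gls.loglik,
        "ols_coefficients": dict(zip(["const", *predictors], ols.params)),
        "gls_coefficients": gls.params.to_dict(),
        "best_model": [c for c in predictors if best[c]],
        "best_rmse": float(best["rmse"]),
        "best_r2": float(best["r2"]),
        "best_mae": float(best["mae"]),
    }
    (out / "comparative_report.json").write_text(json.dumps(report, indent=2, default=str))
    _write_manifest(config, out, {"stage": "comparative"})
    return report
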