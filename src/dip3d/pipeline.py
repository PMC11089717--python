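"""End-to-end orchestration: simulate -> impute -> reconstruct -> metrics.

One :class:`RunConfig` (YAML-loadable) drives a deterministic run that
writes per-stage artifacts (contact lists, 3DG structures, metric tables)
plus a JSON manifest recording inputs, seeds and per-stage counts, so any
stage can be re-run from its predecessor's files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import mannwhitneyu

from . import io as dio
from .contact_metrics import contacting_cpg, compartment_pca, interchrom_stats
from .impute import ImputationParams, impute_pipeline
from .reconstruct import AnnealSchedule, ReconstructionConfig, reconstruct_pipeline
from .simulate import (
    NAIVE_LIKE, PRIMED_LIKE, cohort_manifest, make_toy_genome, simulate_cohort,
)
from .structure_metrics import (
    NeighborContext, compartment_score, intermingling_index,
    radial_cpg_correlation,
)

__all__ = ["RunConfig", "run_pipeline", "compare_cohorts"]

logger = logging.getLogger(__name__)

_ARCHETYPES = {"naive_like": NAIVE_LIKE, "primed_like": PRIMED_LIKE}


@dataclass
class RunConfig:
    """Everything a full run needs; every field has a stated default."""

    outdir: str = "dip3d_run"
    base_seed: int = 0
    # toy genome
    n_chrom: int = 3
    chrom_length: int = 2_000_000
    bin_size: int = 20_000
    cpg_sigma: float = 0.6
    # cohort
    n_cells: int = 5
    archetypes: tuple[str, ...] = ("naive_like", "primed_like")
    # stages
    imputation: ImputationParams = field(default_factory=ImputationParams)
    reconstruction: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    reconstruct_structures: bool = False
    # metrics
    neighbor_radius: float = 3.0
    analysis_bin_size: int = 200_000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "imputation" in kwargs:
            kwargs["imputation"] = ImputationParams(**kwargs["imputation"])
        if "reconstruction" in kwargs:
            rec = dict(kwargs["reconstruction"])
            if "schedule" in rec:
                rec["schedule"] = AnnealSchedule(**rec["schedule"])
            kwargs["reconstruction"] = ReconstructionConfig(**rec)
        if "archetypes" in kwargs:
            kwargs["archetypes"] = tuple(kwargs["archetypes"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in self.archetypes:
            if name not in _ARCHETYPES:
                raise ValueError(f"unknown archetype {name!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage simulate: %d cells x %d archetypes",
                config.n_cells, len(config.archetypes))
    genome, cpg = make_toy_genome(
        n_chrom=config.n_chrom, chrom_length=config.chrom_length,
        bin_size=config.bin_size, cpg_sigma=config.cpg_sigma,
        seed=config.base_seed,
    )
    dio.write_cpg_bedgraph(cpg, outdir / "cpg.bedgraph")
    archetypes = [_ARCHETYPES[a] for a in config.archetypes]
    cells = simulate_cohort(config.n_cells, archetypes, genome, cpg,
                            base_seed=config.base_seed)

    manifest: dict = {
        "base_seed": config.base_seed,
        "config": _config_dict(config),
        "cells": cohort_manifest(cells),
        "artifacts": {},
    }

    metric_rows = []
    ctx = NeighborContext(radius_particle_units=config.neighbor_radius)
    vectors = []
    for cell in cells:
        cdir = outdir / cell.cell_id
        cdir.mkdir(exist_ok=True)
        arts = {}

        dio.write_contacts(cell.contacts, cdir / "contacts_raw.txt")
        dio.write_3dg(cell.structure, cdir / "structure_truth.3dg")
        arts["contacts_raw"] = str(cdir / "contacts_raw.txt")
        arts["structure_truth"] = str(cdir / "structure_truth.3dg")

        logger.info("stage impute: %s", cell.cell_id)
        result = impute_pipeline(cell.contacts, config.imputation)
        dio.write_contacts(result.contacts, cdir / "contacts_cleaned.txt")
        arts["contacts_cleaned"] = str(cdir / "contacts_cleaned.txt")
        with open(cdir / "impute_log.json", "w") as fh:
            json.dump(result.log, fh, indent=1)

        structure = cell.structure
        if config.reconstruct_structures:
            logger.info("stage reconstruct: %s", cell.cell_id)
            assigned = cell.contacts.copy()
            assigned.hap_a = result.hap_a.copy()
            assigned.hap_b = result.hap_b.copy()
            assigned.stage = "cleaned"
            structure = reconstruct_pipeline(
                assigned, genome, config.bin_size, config.reconstruction
            )
            dio.write_3dg(structure, cdir / "structure_reconstructed.3dg")
            arts["structure_reconstructed"] = str(cdir / "structure_reconstructed.3dg")

        logger.info("stage metrics: %s", cell.cell_id)
        _, interm = intermingling_index(structure, ctx)
        comp, _ = compartment_score(structure, cpg, ctx)
        rcc, _ = radial_cpg_correlation(structure, cpg, config.analysis_bin_size)
        frac, _ = interchrom_stats(cell.contacts)
        metric_rows.append({
            "cell_id": cell.cell_id, "cohort": cell.archetype.name,
            "intermingling": interm, "compartment_score": comp,
            "radial_cpg_correlation": rcc, "interchrom_fraction": frac,
        })
        vectors.append(contacting_cpg(cell.contacts, cpg, mode="celltype",
                                      bin_size=config.analysis_bin_size))
        manifest["artifacts"][cell.cell_id] = arts

    metrics = pd.DataFrame(metric_rows)
    metrics.to_csv(outdir / "cell_metrics.tsv", sep="\t", index=False)

    if len(cells) >= 4:
        rep = compartment_pca(
            vectors, seed=config.base_seed,
            true_labels=[c.archetype.name for c in cells],
        )
        pd.DataFrame(
            rep.embedding, index=rep.cell_ids,
            columns=[f"PC{i+1}" for i in range(rep.embedding.shape[1])],
        ).to_csv(outdir / "pca_embedding.tsv", sep="\t")
        manifest["pca_agreement"] = rep.agreement

    if len(set(config.archetypes)) == 2 and config.n_cells >= 3:
        report = compare_cohorts(metrics)
        report.to_csv(outdir / "cohort_comparison.tsv", sep="\t", index=False)
        manifest["artifacts"]["cohort_comparison"] = str(outdir / "cohort_comparison.tsv")

    manifest["wall_time_s"] = round(time.time() - t_start, 2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("run complete in %.1fs -> %s", manifest["wall_time_s"], outdir)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["imputation"] = dataclasses.asdict(config.imputation)
    rec = dataclasses.asdict(config.reconstruction)
    d["reconstruction"] = rec
    return d


def compare_cohorts(
    metrics: pd.DataFrame,
    group_col: str = "cohort",
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Rank-based two-cohort comparison of per-cell metrics.

    One row per numeric metric column: cohort means, difference, and the
    Wilcoxon rank-sum (Mann-Whitney) p value, exact for small samples.
    ``alternative`` is interpreted as first-listed cohort vs second.
    """
    groups = sorted(metrics[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 cohorts, got {groups}")
    a = metrics[metrics[group_col] == groups[0]]
    b = metrics[metrics[group_col] == groups[1]]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 cells per cohort")
    rows = []
    for col in metrics.columns:
        if col in (group_col, "cell_id") or not np.issubdtype(
            metrics[col].dtype, np.number
        ):
            continue
        x = a[col].dropna()
        y = b[col].dropna()
        if len(x) < 3 or len(y) < 3:
            logger.warning("metric %s missing in a cohort; omitted", col)
            continue
        method = "exact" if max(len(x), len(y)) <= 20 else "asymptotic"
        stat = mannwhitneyu(x, y, alternative=alternative, method=method)
        rows.append({
            "metric": col,
            f"mean_{groups[0]}": x.mean(),
            f"mean_{groups[1]}": y.mean(),
            "difference": x.mean() - y.mean(),
            "p_value": stat.pvalue,
        })
    return pd.DataFrame(rows)
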