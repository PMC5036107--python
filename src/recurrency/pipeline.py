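"""End-to-end orchestration: census -> spectra -> excess test -> model fits
-> mappability strata -> privacy test, with a machine-readable JSON report.

Every stochastic step derives from the run seed, so rerunning a config
reproduces the report byte for byte.  Human-readable tables round for
display (fold ratios to 1 decimal, reductions to integer percent); the JSON
keeps full precision alongside.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .genome_context import FRACTION_LABELS, GenomePartition
from .mappability import compute_mappability, filter_unique, stratified_excess_report
from .mixture_models import model_comparison_table
from .privacy import build_lab_matrix, fisher_heterogeneity_test
from .recurrence import (
    aggregate_spectrum,
    build_spectrum,
    excess_summary,
    excess_test,
    expected_from_spectra,
    read_snvs,
)

__all__ = ["RunConfig", "run_full_analysis"]

log = logging.getLogger("recurrency")


@dataclass
class RunConfig:
    """Inputs and knobs of one full analysis run."""

    fasta: str
    snv_table: str
    ssr_mask: str | None = None
    te_mask: str | None = None
    exon_mask: str | None = None
    out_dir: str = "recurrency_out"
    k_values: Tuple[int, ...] = (100, 20)
    pool_min: float = 5.0
    models: Tuple[str, ...] = ("1a", "1b", "2a", "2b")
    min_hits: int = 3
    privacy_cancer_types: Tuple[str, ...] = ()
    seed: int = 0
    n_starts: int = 3
    force: bool = False

    def __post_init__(self) -> None:
        if len(set(self.k_values)) != len(self.k_values) or any(k <= 0 for k in self.k_values):
            raise ValueError("k values must be distinct positive integers")

    def config_hash(self) -> str:
        """Hash of the analysis-relevant fields (where output lands is excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        d.pop("force", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [h for h in log.handlers if not isinstance(h, logging.FileHandler)]
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler(sys.stderr))
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)


def _spectra_block(spectra_by_fraction: Dict[str, object], pool_min: float) -> Dict[str, object]:
    """Observed/expected spectra and the chi-square excess test per fraction."""
    block: Dict[str, object] = {}
    for frac, cells in spectra_by_fraction.items():
        if not cells:
            continue
        obs = aggregate_spectrum(cells, frac)
        exp = expected_from_spectra(cells, frac)
        entry: Dict[str, object] = {
            "observed": obs.counts.tolist(),
            "expected": exp.counts.tolist(),
            "expected_tail_mass": exp.tail_mass,
            "sites": obs.l,
            "snvs": obs.m,
        }
        try:
            t = excess_test(obs, exp, pool_min=pool_min)
            entry["excess_test"] = {
                "statistic": t.statistic,
                "df": t.df,
                "p_value": t.p_value,
                "n_cells": t.n_cells,
            }
        except ValueError as exc:
            entry["excess_test"] = {"error": str(exc)}
        block[frac] = entry
    return block


def run_full_analysis(config: RunConfig) -> Dict[str, object]:
    """Run the whole analysis and write report.json plus TSV tables.

    Stages: partition + census, spectra + excess tests, excess summary with
    fold ratios, mixture-model comparison per fraction, mappability
    stratification at the configured k values, and the lab-heterogeneity
    test per requested cancer type.  Any stage failure aborts with the stage
    name; partial outputs written so far are preserved.
    """
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    report: Dict[str, object] = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    stage = "setup"
    try:
        stage = "partition"
        log.info("partitioning genome")
        partition = GenomePartition.from_files(
            config.fasta, config.ssr_mask, config.te_mask, config.exon_mask
        )
        sizes = partition.fraction_sizes()
        report["fraction_sizes_bp"] = sizes

        stage = "snv ingestion"
        snvs, ingest = read_snvs(config.snv_table, fasta=None)
        report["ingest"] = dataclasses.asdict(ingest)
        log.info("ingested %d SNVs (%d rejected)", ingest.n_accepted, ingest.n_rejected)

        stage = "spectra"
        spectra, dropped = build_spectrum(snvs, partition)
        report["snv_drops"] = dropped
        report["spectra"] = {"all": _spectra_block(spectra, config.pool_min)}

        stage = "excess summary"
        frac_specs = {
            f: aggregate_spectrum(cells, f) for f, cells in spectra.items() if cells
        }
        summary = excess_summary(frac_specs, sizes, min_hits=config.min_hits)
        summary.to_csv(out / "excess_summary.tsv", sep="\t")
        report["excess_summary"] = json.loads(summary.to_json(orient="index"))

        stage = "model fitting"
        fits_block: Dict[str, object] = {}
        for frac in FRACTION_LABELS:
            if not spectra.get(frac):
                continue
            table, _ = model_comparison_table(
                spectra[frac],
                models=config.models,
                n_starts=config.n_starts,
                seed=config.seed,
                fraction=frac,
            )
            table.to_csv(out / f"model_comparison_{frac}.tsv", sep="\t", index=False)
            fits_block[frac] = json.loads(table.to_json(orient="records"))
            log.info("fitted models for %s", frac)
        report["model_comparison"] = fits_block

        stage = "mappability"
        strata = {"all": frac_specs}
        mapp_block: Dict[str, object] = {}
        for k in config.k_values:
            log.info("mappability at k=%d", k)
            track = compute_mappability(partition, k)
            filtered, excluded = filter_unique(partition, track)
            spectra_k, _ = build_spectrum(snvs, filtered)
            strata[f"unique@{k}"] = {
                f: aggregate_spectrum(cells, f) for f, cells in spectra_k.items() if cells
            }
            mapp_block[f"unique@{k}"] = {"excluded_positions": excluded}
        strat_report = stratified_excess_report(strata, baseline="all", min_hits=config.min_hits)
        strat_report.to_csv(out / "stratified_excess.tsv", sep="\t", index=False)
        report["mappability"] = mapp_block
        report["stratified_excess"] = json.loads(strat_report.to_json(orient="records"))

        stage = "privacy"
        privacy_block: Dict[str, object] = {}
        for ct in config.privacy_cancer_types:
            try:
                matrix = build_lab_matrix(snvs, ct, min_hits=config.min_hits)
                if matrix.n_sites == 0:
                    privacy_block[ct] = {"skipped": "no excess sites"}
                    continue
                res = fisher_heterogeneity_test(matrix, seed=config.seed)
                matrix.to_frame().to_csv(out / f"lab_matrix_{ct}.tsv", sep="\t")
                privacy_block[ct] = {
                    "p_value": res.p_value,
                    "method": res.method,
                    "std_error": res.std_error,
                    "n_sites": matrix.n_sites,
                    "labs": list(matrix.labs),
                    "margins_note": "conditioned on raw per-lab SNV totals",
                }
            except ValueError as exc:
                privacy_block[ct] = {"skipped": str(exc)}
        report["privacy"] = privacy_block
    except Exception:
        log.exception("stage %r failed", stage)
        report["failed_stage"] = stage
        (out / "report.partial.json").write_text(json.dumps(report, indent=2, default=str))
        raise

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    log.info("report written to %s", out / "report.json")
    return report
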