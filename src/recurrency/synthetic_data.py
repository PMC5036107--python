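"""Synthetic genomes, masks and pooled SNV call sets with known ground truth.

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* a random genome with TE / EX / SSR mask layout (tiled intervals) and
  optionally planted duplicated segments — exact copies create mappability
  < 1; diverged copies are the substrate for collapsed-duplication
  artefacts;
* pooled SNVs from the two-process model: at every censusable site the
  constant process contributes Poisson(mu_i * eps) hits and the variable
  process Poisson(mu_i * (1 - eps) * alpha) hits with a site-level
  alpha ~ Gamma(mean 1, shape k); hits are assigned to distinct samples;
* laboratory structure: samples are split across labs, and optional
  lab-private error sites receive recurrent SNVs from a single lab's
  samples;
* collapsed-duplication artefacts: divergence positions of a planted copy
  produce recurrent pseudo-SNVs at the original locus.

Default parameters are the study-scale values: a pooled SNV density of
about 1.2e-3 per site (3.3M SNVs over 2.8 Gb), a constant-process share
eps = 0.96, gamma shape 3e-4, 507 samples in 2 labs at roughly 3:1 — with a
200 kb genome standing in for the 2.8 Gb one.  Every draw flows from the
config seed, so output is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .genome_context import CANONICAL_TRIPLETS, GenomePartition
from .recurrence import RecurrenceSpectrum

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genome",
    "simulate_snvs",
    "simulate_dataset",
    "simulate_spectra",
    "ground_truth_report",
    "write_fasta",
    "write_bed",
]

_BASES = np.array(list("ACGT"))
_COMPL_IDX = np.array([3, 2, 1, 0])


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study; the seed is mandatory.

    Proportions are genome-wide target fractions for the mask layout
    (hg19-like defaults: ~48% TE, ~4% exon, ~3% SSR; the remainder is NTE);
    ``mu`` is the pooled SNV density per censusable site, split between the
    constant (eps) and gamma-variable (1 - eps, shape) processes of the
    two-process model.
    """

    seed: int
    genome_length: int = 200_000
    n_chroms: int = 1
    gc_content: float = 0.41
    tile: int = 1_000
    ssr_prop: float = 0.03
    te_prop: float = 0.48
    ex_prop: float = 0.04
    mu: float = 1.2e-3
    eps: float = 0.96
    shape: float = 3e-4
    context_multipliers: Dict[str, float] = field(default_factory=dict)
    cpg_boost: float = 8.0
    n_samples: int = 507
    cancer_type: str = "LIVER"
    n_labs: int = 2
    lab_split: Tuple[float, ...] = (0.75, 0.25)
    lab_private_sites: int = 0
    lab_private_hits: int = 4
    dup_count: int = 0
    dup_length: int = 500
    dup_divergence: float = 0.0
    collapse_intensity: float = 4.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if not 0 <= self.ssr_prop + self.te_prop + self.ex_prop <= 1:
            raise ValueError("mask proportions must lie in [0, 1] and sum to <= 1")
        if not 0 <= self.eps <= 1:
            raise ValueError("eps must lie in [0, 1]")
        if self.shape <= 0:
            raise ValueError("gamma shape must be positive")
        if len(self.lab_split) != self.n_labs:
            raise ValueError("lab_split must have one weight per lab")

    def multiplier(self, context: str) -> float:
        """Relative rate of a context; CpG-gaining contexts (xCG) boosted."""
        if context in self.context_multipliers:
            return self.context_multipliers[context]
        return self.cpg_boost if context.endswith("CG") else 1.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    sequences: Dict[str, str]
    masks: Dict[str, Dict[str, list]]
    partition: GenomePartition
    snvs: pd.DataFrame
    site_truth: pd.DataFrame
    duplications: pd.DataFrame


# ---------------------------------------------------------------------------
# genome


def _tile_layout(cfg: SimulationConfig, length: int, rng: np.random.Generator) -> np.ndarray:
    """Per-tile mask label: 0 none, 1 TE, 2 EX, 3 SSR (tile granularity)."""
    n_tiles = max(1, int(np.ceil(length / cfg.tile)))
    labels = np.zeros(n_tiles, dtype=np.int8)
    n_ssr = int(round(cfg.ssr_prop * n_tiles))
    n_te = int(round(cfg.te_prop * n_tiles))
    n_ex = int(round(cfg.ex_prop * n_tiles))
    order = rng.permutation(n_tiles)
    labels[order[:n_ssr]] = 3
    labels[order[n_ssr : n_ssr + n_te]] = 1
    labels[order[n_ssr + n_te : n_ssr + n_te + n_ex]] = 2
    return labels


def simulate_genome(
    config: SimulationConfig,
) -> Tuple[Dict[str, str], Dict[str, Dict[str, list]], pd.DataFrame]:
    """Draw a random genome and mask layout.

    Returns (sequences, masks, duplications): masks maps "ssr"/"te"/"exon"
    to per-chromosome 0-based half-open interval lists; duplications records
    any planted segmental duplications (source, copy, divergence positions).
    Bases are i.i.d. at the configured GC content.
    """
    rng = np.random.default_rng(config.seed)
    probs = np.array(
        [
            (1 - config.gc_content) / 2,
            config.gc_content / 2,
            config.gc_content / 2,
            (1 - config.gc_content) / 2,
        ]
    )
    sequences: Dict[str, str] = {}
    masks: Dict[str, Dict[str, list]] = {"ssr": {}, "te": {}, "exon": {}}
    dup_rows = []
    per_chrom = config.genome_length // max(config.n_chroms, 1)
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        length = per_chrom if ci < config.n_chroms - 1 else config.genome_length - per_chrom * (config.n_chroms - 1)
        if length <= 0:
            continue
        codes = rng.choice(4, size=length, p=probs)

        # planted duplications: copy a source segment elsewhere, optionally diverged
        n_dups = config.dup_count if ci == 0 else 0
        for d in range(n_dups):
            if length < 2 * config.dup_length + 2:
                break
            src = int(rng.integers(0, length - 2 * config.dup_length))
            dst = int(rng.integers(src + config.dup_length, length - config.dup_length))
            segment = codes[src : src + config.dup_length].copy()
            div_pos = []
            if config.dup_divergence > 0:
                n_div = rng.binomial(config.dup_length, config.dup_divergence)
                div_off = rng.choice(config.dup_length, size=n_div, replace=False)
                for off in div_off:
                    segment[off] = (segment[off] + int(rng.integers(1, 4))) % 4
                    div_pos.append(int(off))
            codes[dst : dst + config.dup_length] = segment
            dup_rows.append(
                {
                    "chrom": chrom,
                    "source_start": src,
                    "copy_start": dst,
                    "length": config.dup_length,
                    "divergence_offsets": sorted(div_pos),
                }
            )

        sequences[chrom] = "".join(_BASES[codes])
        tiles = _tile_layout(config, length, rng)
        for code, name in ((3, "ssr"), (1, "te"), (2, "exon")):
            ivs = [
                (int(t * config.tile), int(min((t + 1) * config.tile, length)))
                for t in np.flatnonzero(tiles == code)
            ]
            if ivs:
                masks[name][chrom] = ivs
    return sequences, masks, pd.DataFrame(dup_rows)


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(intervals: Mapping[str, list], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in intervals:
            for s, e in intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# SNVs


def _sample_labs(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Lab index per sample, deterministic proportions from lab_split."""
    weights = np.asarray(cfg.lab_split, dtype=float)
    weights = weights / weights.sum()
    counts = np.floor(weights * cfg.n_samples).astype(int)
    while counts.sum() < cfg.n_samples:
        counts[int(np.argmax(weights * cfg.n_samples - counts))] += 1
    labs = np.repeat(np.arange(cfg.n_labs), counts)
    rng.shuffle(labs)
    return labs


def simulate_snvs(
    sequences: Mapping[str, str],
    masks: Mapping[str, Mapping[str, list]],
    config: SimulationConfig,
    duplications: pd.DataFrame | None = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, GenomePartition]:
    """Draw pooled SNVs over a genome under the two-process model.

    Per censusable (non-SSR, context-defined) site with context rate
    mu_i = mu * w_i / mean(w): constant-process hits ~ Poisson(mu_i * eps)
    and variable-process hits ~ Poisson(mu_i * (1 - eps) * alpha) with one
    alpha ~ Gamma(mean 1, shape) per site.  Hits at a site go to distinct
    samples; demanded hits beyond the sample count are truncated and
    reported in the site truth table.  Lab-private error sites and
    collapsed-duplication pseudo-SNVs are then injected per config.

    Returns (snv table, per-site truth table, the genome partition used).
    """
    rng = np.random.default_rng(config.seed + 1)
    partition = GenomePartition.from_files(
        sequences,
        ssr_mask=masks.get("ssr", {}),
        te_mask=masks.get("te", {}),
        exon_mask=masks.get("exon", {}),
    )
    sample_labs = _sample_labs(config, rng)
    lab_names = [f"LAB{i + 1}" for i in range(config.n_labs)]
    sample_names = np.array([f"S{i:04d}" for i in range(config.n_samples)])

    # context weights normalised over the censusable genome
    mult = np.array([config.multiplier(c) for c in CANONICAL_TRIPLETS])
    rows: list = []
    truth_rows: list = []

    for chrom, seq in partition.sequences.items():
        trip = partition._triplet_codes(chrom)
        censusable = (partition.labels[chrom] >= 0) & (trip >= 0)
        pos0 = np.flatnonzero(censusable)
        if pos0.size == 0:
            continue
        w = mult[trip[pos0]]
        mu_site = config.mu * w / w.mean()

        alpha = rng.gamma(config.shape, 1.0 / config.shape, size=pos0.size)
        hits_const = rng.poisson(mu_site * config.eps)
        hits_var = rng.poisson(mu_site * (1.0 - config.eps) * alpha)

        hit_idx = np.flatnonzero((hits_const + hits_var) > 0)
        for i in hit_idx:
            p0 = int(pos0[i])
            n_c, n_v = int(hits_const[i]), int(hits_var[i])
            total = n_c + n_v
            truncated = max(0, total - config.n_samples)
            total = min(total, config.n_samples)
            n_c = min(n_c, total)
            n_v = total - n_c
            chosen = rng.choice(config.n_samples, size=total, replace=False)
            ref = seq[p0]
            for j, s_idx in enumerate(chosen):
                alt = rng.choice([b for b in "ACGT" if b != ref])
                rows.append(
                    (
                        chrom,
                        p0 + 1,
                        ref,
                        alt,
                        sample_names[s_idx],
                        config.cancer_type,
                        lab_names[sample_labs[s_idx]],
                        "mutation" if j < n_c else "error",
                    )
                )
            truth_rows.append(
                {
                    "chrom": chrom,
                    "pos": p0 + 1,
                    "alpha": float(alpha[i]),
                    "hits_constant": n_c,
                    "hits_variable": n_v,
                    "truncated": truncated,
                    "lab_private": False,
                    "process": "mutation" if n_v == 0 else "error",
                }
            )

    # lab-private error sites: all SNVs from one lab's samples
    if config.lab_private_sites > 0:
        chrom = next(iter(partition.sequences))
        trip = partition._triplet_codes(chrom)
        ok = np.flatnonzero((partition.labels[chrom] >= 0) & (trip >= 0))
        taken = {(r["chrom"], r["pos"]) for r in truth_rows}
        candidates = [p for p in ok if (chrom, int(p) + 1) not in taken]
        picks = rng.choice(len(candidates), size=min(config.lab_private_sites, len(candidates)), replace=False)
        for pi in picks:
            p0 = int(candidates[pi])
            lab_i = int(rng.integers(config.n_labs))
            members = np.flatnonzero(sample_labs == lab_i)
            n_hits = min(config.lab_private_hits, members.size)
            chosen = rng.choice(members, size=n_hits, replace=False)
            ref = partition.sequences[chrom][p0]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            for s_idx in chosen:
                rows.append(
                    (
                        chrom,
                        p0 + 1,
                        ref,
                        alt,
                        sample_names[s_idx],
                        config.cancer_type,
                        lab_names[lab_i],
                        "lab_private_error",
                    )
                )
            truth_rows.append(
                {
                    "chrom": chrom,
                    "pos": p0 + 1,
                    "alpha": np.nan,
                    "hits_constant": 0,
                    "hits_variable": n_hits,
                    "truncated": 0,
                    "lab_private": True,
                    "process": "lab_private_error",
                }
            )

    # collapsed duplications: divergence positions of the copy yield
    # recurrent pseudo-SNVs at the source locus (reads mis-assigned there)
    if duplications is not None and len(duplications):
        for _, dup in duplications.iterrows():
            offsets = dup["divergence_offsets"]
            chrom = dup["chrom"]
            seq = partition.sequences[chrom]
            for off in offsets:
                src0 = int(dup["source_start"]) + int(off)
                copy0 = int(dup["copy_start"]) + int(off)
                if partition.labels[chrom][src0] < 0:
                    continue
                n_hits = min(int(rng.poisson(config.collapse_intensity)), config.n_samples)
                if n_hits == 0:
                    continue
                chosen = rng.choice(config.n_samples, size=n_hits, replace=False)
                ref = seq[src0]
                alt = seq[copy0]
                if alt == ref:
                    continue
                for s_idx in chosen:
                    rows.append(
                        (
                            chrom,
                            src0 + 1,
                            ref,
                            alt,
                            sample_names[s_idx],
                            config.cancer_type,
                            lab_names[sample_labs[s_idx]],
                            "collapse",
                        )
                    )
                truth_rows.append(
                    {
                        "chrom": chrom,
                        "pos": src0 + 1,
                        "alpha": np.nan,
                        "hits_constant": 0,
                        "hits_variable": n_hits,
                        "truncated": 0,
                        "lab_private": False,
                        "process": "collapse",
                    }
                )

    snvs = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "sample", "cancer_type", "lab", "true_process"],
    )
    snvs = snvs.sort_values(["chrom", "pos", "sample"], kind="stable").reset_index(drop=True)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom",
            "pos",
            "alpha",
            "hits_constant",
            "hits_variable",
            "truncated",
            "lab_private",
            "process",
        ],
    )
    truth = truth.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return snvs, truth, partition


def simulate_dataset(config: SimulationConfig, outdir: str | Path | None = None) -> SimulatedDataset:
    """Genome + masks + SNVs + truth in one call; optionally written to disk
    (FASTA, BED masks, SNV TSV, truth TSV, config JSON echo)."""
    sequences, masks, dups = simulate_genome(config)
    snvs, truth, partition = simulate_snvs(sequences, masks, config, dups)
    ds = SimulatedDataset(config, sequences, masks, partition, snvs, truth, dups)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(sequences, outdir / "genome.fa")
        for name in ("ssr", "te", "exon"):
            write_bed(masks.get(name, {}), outdir / f"{name}.bed")
        snvs.to_csv(outdir / "snvs.tsv", sep="\t", index=False)
        truth.to_csv(outdir / "site_truth.tsv", sep="\t", index=False)
        (outdir / "config.json").write_text(config.to_json())
    return ds


# ---------------------------------------------------------------------------
# direct spectrum simulation (no genome)


def simulate_spectra(
    l_per_context: int,
    mu: float,
    shape: float,
    eps: float,
    n_contexts: int = 32,
    seed: int = 0,
    x_max: int | None = None,
    fraction: str = "SIM",
) -> Dict[str, RecurrenceSpectrum]:
    """Simulate per-context recurrence spectra directly at the site level.

    Every context holds ``l_per_context`` sites sharing (mu, shape, eps);
    per-site counts follow the two-process model exactly (one gamma draw per
    site).  This is the fast path for parameter-recovery and calibration
    studies at 10^6-10^7 sites per context.
    """
    rng = np.random.default_rng(seed)
    out: Dict[str, RecurrenceSpectrum] = {}
    for ctx in CANONICAL_TRIPLETS[:n_contexts]:
        counts_c = rng.poisson(mu * eps, size=l_per_context)
        if eps < 1.0:
            alpha = rng.gamma(shape, 1.0 / shape, size=l_per_context)
            counts_c = counts_c + rng.poisson(mu * (1.0 - eps) * alpha)
        hist = np.bincount(counts_c)
        xm = x_max if x_max is not None else max(7, hist.size - 1 + 3)
        counts = np.zeros(xm + 1, dtype=np.int64)
        counts[: min(hist.size, xm + 1)] = hist[: xm + 1]
        if hist.size > xm + 1:  # clip improbable overflow into the top cell
            counts[xm] += hist[xm + 1 :].sum()
        out[ctx] = RecurrenceSpectrum(fraction, ctx, counts)
    return out


# ---------------------------------------------------------------------------
# truth reporting


def ground_truth_report(dataset: SimulatedDataset, min_hits: int = 3) -> Dict[str, object]:
    """Summaries of the simulated truth, for recovery tests.

    Includes realised per-context SNV densities, the realised excess-site
    list (sites with >= min_hits SNVs), per-process SNV totals and the
    lab-private site list.
    """
    snvs = dataset.snvs
    truth = dataset.site_truth
    per_site = snvs.groupby(["chrom", "pos"]).size() if len(snvs) else pd.Series(dtype=int)
    excess = per_site[per_site >= min_hits] if len(per_site) else per_site
    census_total: Dict[str, int] = {}
    for lab in ("TE", "NTE", "EX"):
        for ctx, l in dataset.partition.census(lab).counts.items():
            census_total[ctx] = census_total.get(ctx, 0) + l
    ctx_counts: Dict[str, int] = {}
    for chrom, pos in zip(snvs.get("chrom", []), snvs.get("pos", [])):
        ctx = dataset.partition.context_at(chrom, int(pos))
        if ctx is not None:
            ctx_counts[ctx] = ctx_counts.get(ctx, 0) + 1
    realised_mu = {
        ctx: ctx_counts.get(ctx, 0) / l for ctx, l in census_total.items() if l > 0
    }
    return {
        "n_snvs": int(len(snvs)),
        "n_sites_hit": int(len(per_site)),
        "excess_sites": [(c, int(p)) for c, p in excess.index] if len(excess) else [],
        "n_excess_sites": int(len(excess)) if len(excess) else 0,
        "snvs_by_process": snvs["true_process"].value_counts().to_dict() if len(snvs) else {},
        "lab_private_sites": [
            (r["chrom"], int(r["pos"])) for _, r in truth.iterrows() if r["lab_private"]
        ]
        if len(truth)
        else [],
        "realised_mu": realised_mu,
        "n_truncated_sites": int((truth["truncated"] > 0).sum()) if len(truth) else 0,
    }
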