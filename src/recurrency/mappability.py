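"""Exact k-mer mappability tracks and mappability-stratified recurrence.

A position's mappability score is 1 / (number of genomic occurrences of the
k-mer starting at that position): 1 for a unique k-mer, 0.5 for one that
occurs twice, and so on.  Occurrences are counted exactly over the whole
genome, by default on both strands (a read maps to either strand; for a
palindromic k-mer the two strands give the same loci, which are not double
counted).  K-mers containing non-ACGT characters, and start positions within
k-1 of a contig end, carry no score.

Filtering to uniquely-mappable sites and rebuilding the site census and
recurrence spectra on the retained set quantifies how much of the recurrence
excess lives in duplicated sequence — the stratification behind the
"mappable at 100 bp" / "mappable at 20 bp" comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .genome_context import GenomePartition, reverse_complement
from .recurrence import EXCESS_MIN_HITS, RecurrenceSpectrum

__all__ = [
    "MappabilityTrack",
    "compute_mappability",
    "filter_unique",
    "stratified_excess_report",
]


@dataclass
class MappabilityTrack:
    """Per-position 1/occurrences scores for one k; NaN where undefined."""

    k: int
    scores: Dict[str, np.ndarray]

    def to_bedgraph(self, path: str | Path) -> None:
        """Write as BedGraph (0-based half-open), merging equal-score runs."""
        with open(path, "w") as fh:
            for chrom, sc in self.scores.items():
                start = None
                for i in range(sc.size + 1):
                    val = sc[i] if i < sc.size else np.nan
                    if start is not None and (i == sc.size or val != sc[start]):
                        if not np.isnan(sc[start]):
                            fh.write(f"{chrom}\t{start}\t{i}\t{sc[start]:.6g}\n")
                        start = None
                    if start is None and i < sc.size and not np.isnan(val):
                        start = i


def compute_mappability(
    fasta: str | Path | Mapping[str, str] | GenomePartition,
    k: int,
    count_reverse_complement: bool = True,
) -> MappabilityTrack:
    """Exact k-mer occurrence counting over a genome.

    With reverse-complement counting on (default), the occurrence count of a
    k-mer is the number of genomic start positions matching it on either
    strand, i.e. forward occurrences of the k-mer plus forward occurrences of
    its reverse complement (counted once for palindromes).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(fasta, GenomePartition):
        sequences = fasta.sequences
    else:
        from .genome_context import _load_sequences  # noqa: PLC0415

        sequences = _load_sequences(fasta)

    def valid_starts(seq: str) -> np.ndarray:
        """Boolean array: k-mer starting here is all-ACGT and fits the contig."""
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        bad = ~np.isin(codes, np.frombuffer(b"ACGT", dtype=np.uint8))
        n = codes.size
        ok = np.zeros(n, dtype=bool)
        if n >= k:
            bad_cum = np.concatenate([[0], np.cumsum(bad)])
            ok[: n - k + 1] = (bad_cum[k:] - bad_cum[: n - k + 1]) == 0
        return ok

    counts: Dict[str, int] = {}
    start_masks: Dict[str, np.ndarray] = {}
    for chrom, seq in sequences.items():
        mask = valid_starts(seq)
        start_masks[chrom] = mask
        get = counts.get
        for i in np.flatnonzero(mask):
            kmer = seq[i : i + k]
            counts[kmer] = get(kmer, 0) + 1

    scores: Dict[str, np.ndarray] = {}
    for chrom, seq in sequences.items():
        n = len(seq)
        sc = np.full(n, np.nan)
        # reverse-complement the contig once; rc of seq[i:i+k] is a slice of it
        rcseq = seq[::-1].translate(str.maketrans("ACGT", "TGCA")) if count_reverse_complement else ""
        for i in np.flatnonzero(start_masks[chrom]):
            kmer = seq[i : i + k]
            occ = counts[kmer]
            if count_reverse_complement:
                rc = rcseq[n - i - k : n - i]
                if rc != kmer:
                    occ += counts.get(rc, 0)
            sc[i] = 1.0 / occ
        scores[chrom] = sc
    return MappabilityTrack(k, scores)


def _keep_mask(track: MappabilityTrack, chrom: str, n: int, min_score: float, mode: str) -> np.ndarray:
    sc = track.scores[chrom]
    if sc.size != n:
        raise ValueError(f"track does not cover {chrom} (length mismatch)")
    with np.errstate(invalid="ignore"):
        ok = sc >= min_score  # NaN compares False: unscored positions drop
    if mode == "start":
        return ok
    if mode == "cover":
        # keep position p if any k-mer covering p (start in [p-k+1, p]) passes
        okf = np.zeros(n, dtype=bool)
        padded = np.concatenate([np.zeros(track.k - 1, dtype=bool), ok])
        for off in range(track.k):
            okf |= padded[track.k - 1 - off : padded.size - off if off else padded.size]
        return okf
    raise ValueError(f"unknown uniqueness mode {mode!r}")


def filter_unique(
    partition: GenomePartition,
    track: MappabilityTrack,
    min_score: float = 1.0,
    mode: str = "start",
) -> Tuple[GenomePartition, Dict[str, int]]:
    """Exclude positions that fail the uniqueness rule and return the
    filtered partition plus exclusion counts per chromosome.

    The default rule ("start") keeps a position when the score of the k-mer
    *starting* at it reaches ``min_score``; the alternative "cover" rule
    keeps a position when *any* k-mer covering it does.  Unscored positions
    (contig edges, Ns) are always excluded and counted.  Site censuses and
    spectra are then rebuilt on the returned partition by the usual
    operations.
    """
    keep: Dict[str, np.ndarray] = {}
    excluded: Dict[str, int] = {}
    for chrom, seq in partition.sequences.items():
        mask = _keep_mask(track, chrom, len(seq), min_score, mode)
        keep[chrom] = mask
        excluded[chrom] = int((~mask & (partition.labels[chrom] >= 0)).sum())
    return partition.exclude_positions(keep), excluded


def stratified_excess_report(
    strata: Mapping[str, Mapping[str, RecurrenceSpectrum]],
    baseline: str | None = None,
    min_hits: int = EXCESS_MIN_HITS,
) -> pd.DataFrame:
    """Interrogable sites, SNVs and excess sites per stratum and fraction,
    with percent reductions relative to the baseline (first) stratum.

    ``strata`` maps stratum name (e.g. "all", "unique@100", "unique@20") to
    fraction-level spectra.  Reductions are rounded to integer percent; the
    unrounded values stay available as *_reduction_raw columns.
    """
    names = list(strata)
    if baseline is None:
        baseline = names[0]
    rows = []
    base = strata[baseline]
    for name in names:
        fracs = strata[name]
        for frac, spec in fracs.items():
            row = {
                "stratum": name,
                "fraction": frac,
                "sites": spec.l,
                "snvs": spec.m,
                "excess_sites": spec.excess_sites(min_hits),
            }
            rows.append(row)
        total = {
            "stratum": name,
            "fraction": "Total",
            "sites": sum(s.l for s in fracs.values()),
            "snvs": sum(s.m for s in fracs.values()),
            "excess_sites": sum(s.excess_sites(min_hits) for s in fracs.values()),
        }
        rows.append(total)
    df = pd.DataFrame(rows)

    base_tot = {
        frac: (spec.l, spec.m, spec.excess_sites(min_hits)) for frac, spec in base.items()
    }
    base_tot["Total"] = (
        sum(v[0] for v in base_tot.values()),
        sum(v[1] for v in base_tot.values()),
        sum(v[2] for v in base_tot.values()),
    )
    for col, idx in (("sites", 0), ("snvs", 1), ("excess_sites", 2)):
        raw = [
            100.0 * (1.0 - row[col] / base_tot[row["fraction"]][idx])
            if base_tot.get(row["fraction"], (0, 0, 0))[idx]
            else np.nan
            for row in df.to_dict("records")
        ]
        df[f"{col}_reduction_raw"] = raw
        df[f"{col}_reduction_pct"] = [
            int(round(v)) if np.isfinite(v) else pd.NA for v in raw
        ]
    return df
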