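"""Recurrence spectra of pooled somatic SNVs and the context-aware Poisson test.

The central object is the *recurrence spectrum*: for a set of l genomic sites
(one genomic fraction, one triplet context) hit by m SNVs pooled across
cancers, the counts n_x of sites hit exactly x times, x = 0, 1, 2, ...
If SNVs land independently and uniformly within a context, the expected
number of sites with x hits is Poisson,

    P_i(x) = l_i * exp(-mu_i) * mu_i**x / x!,      mu_i = m_i / l_i,

and summing P_i(x) over contexts gives the context-adjusted genome-wide
expectation.  Departures from it — an excess of sites hit 3+ times — are the
signal of interest, tested with a chi-square goodness-of-fit statistic on the
pooled spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genome_context import FRACTION_LABELS, GenomePartition, SiteCensus

__all__ = [
    "SNV_COLUMNS",
    "RecurrenceSpectrum",
    "ExpectedSpectrum",
    "SpectrumSet",
    "ExcessTestResult",
    "read_snvs",
    "build_spectrum",
    "expected_spectrum",
    "aggregate_expected",
    "excess_test",
    "excess_summary",
    "EXCESS_MIN_HITS",
]

SNV_COLUMNS = ("chrom", "pos", "ref", "alt", "sample", "cancer_type")
#: A site is an "excess site" when hit by at least this many SNVs.
EXCESS_MIN_HITS = 3

_BASES = frozenset("ACGT")


@dataclass
class RecurrenceSpectrum:
    """Observed counts n_x of sites hit exactly x times (x = 0..x_max).

    ``context`` is None for a fraction-level spectrum aggregated over contexts.
    Invariants: sum(n_x) = l (sites) and sum(x * n_x) = m (SNVs).
    """

    fraction: str
    context: str | None
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be non-negative")

    @property
    def l(self) -> int:
        return int(self.counts.sum())

    @property
    def m(self) -> int:
        return int((np.arange(self.counts.size) * self.counts).sum())

    @property
    def x_max(self) -> int:
        return self.counts.size - 1

    def excess_sites(self, min_hits: int = EXCESS_MIN_HITS) -> int:
        return int(self.counts[min_hits:].sum())


@dataclass
class ExpectedSpectrum:
    """Real-valued expected site counts P(x), same shape as a RecurrenceSpectrum.

    ``tail_mass`` is the expected number of sites with x > x_max, reported so
    truncation error is visible: sum(counts) + tail_mass = l.
    """

    fraction: str
    context: str | None
    counts: np.ndarray
    tail_mass: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)


#: Per-fraction, per-context observed spectra.
SpectrumSet = Dict[str, Dict[str, RecurrenceSpectrum]]


@dataclass
class IngestReport:
    """Row-level bookkeeping from SNV ingestion."""

    n_rows: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    n_duplicates: int = 0
    reject_reasons: Dict[str, int] = field(default_factory=dict)


def read_snvs(
    table: str | Path | pd.DataFrame,
    fasta: str | Path | Mapping[str, str] | None = None,
) -> Tuple[pd.DataFrame, IngestReport]:
    """Read and validate a tab-separated SNV table.

    Required columns: chrom, pos (1-based), ref, alt, sample, cancer_type;
    ``lab`` is optional.  Rows with non-single-base or identical alleles are
    rejected row-wise; duplicate (chrom, pos, sample) rows are collapsed so a
    sample contributes at most one SNV per site.  When a reference is given,
    rows whose ref base mismatches it are rejected.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep="\t", dtype={"chrom": str})
    missing = [c for c in SNV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNV table is missing required columns: {missing}")
    if "lab" not in df.columns:
        df["lab"] = ""

    report = IngestReport(n_rows=len(df))
    if len(df) == 0:
        return df, report

    df["ref"] = df["ref"].astype(str).str.upper()
    df["alt"] = df["alt"].astype(str).str.upper()
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")

    def reject(mask: np.ndarray, reason: str) -> None:
        n = int(mask.sum())
        if n:
            report.reject_reasons[reason] = report.reject_reasons.get(reason, 0) + n

    bad_pos = df["pos"].isna() | (df["pos"] < 1)
    bad_allele = ~df["ref"].isin(_BASES) | ~df["alt"].isin(_BASES)
    same_allele = (df["ref"] == df["alt"]) & ~bad_allele
    reject(bad_pos.to_numpy(), "bad position")
    reject((bad_allele & ~bad_pos).to_numpy(), "non-single-base allele")
    reject((same_allele & ~bad_pos).to_numpy(), "ref equals alt")
    bad = bad_pos | bad_allele | same_allele
    df = df.loc[~bad].copy()
    df["pos"] = df["pos"].astype(np.int64)

    if fasta is not None:
        from .genome_context import _load_sequences  # noqa: PLC0415

        seqs = _load_sequences(fasta)
        ok = np.ones(len(df), dtype=bool)
        for i, (chrom, pos, ref) in enumerate(zip(df["chrom"], df["pos"], df["ref"])):
            seq = seqs.get(chrom)
            ok[i] = seq is not None and pos <= len(seq) and seq[pos - 1] == ref
        reject(~ok, "ref mismatch")
        df = df.loc[ok].copy()

    before = len(df)
    df = df.drop_duplicates(subset=["chrom", "pos", "sample"], keep="first")
    report.n_duplicates = before - len(df)
    if report.n_duplicates:
        warnings.warn(
            f"collapsed {report.n_duplicates} duplicate (chrom, pos, sample) rows",
            stacklevel=2,
        )
    report.n_accepted = len(df)
    report.n_rejected = report.n_rows - report.n_duplicates - report.n_accepted
    return df.reset_index(drop=True), report


def _default_x_max(max_hits: int) -> int:
    # covers the printed 0..7 range with head-room above the observed maximum
    return max(7, max_hits + 3)


def build_spectrum(
    snvs: pd.DataFrame,
    partition: GenomePartition,
    x_max: int | None = None,
    n_samples: int | None = None,
) -> Tuple[SpectrumSet, Dict[str, int]]:
    """Tally per-site hit counts into per-(fraction, context) spectra.

    Each SNV is assigned to the fraction and canonical context of its
    position; SNVs in SSR-excluded positions or with undefined context are
    dropped and counted in the returned drop report.  n_0 is filled in from
    the partition's census (l_i minus the number of hit sites).
    """
    dropped = {"ssr_or_excluded": 0, "no_context": 0}
    hits: Dict[Tuple[str, str], Dict[Tuple[str, int], int]] = {}
    for chrom, pos in zip(snvs["chrom"], snvs["pos"]):
        frac = partition.fraction_at(chrom, int(pos))
        if frac is None:
            dropped["ssr_or_excluded"] += 1
            continue
        ctx = partition.context_at(chrom, int(pos))
        if ctx is None:
            dropped["no_context"] += 1
            continue
        cell = hits.setdefault((frac, ctx), {})
        site = (chrom, int(pos))
        cell[site] = cell.get(site, 0) + 1

    max_hits = max((h for cell in hits.values() for h in cell.values()), default=0)
    if n_samples is not None and max_hits > n_samples:
        raise ValueError(
            f"a site is hit {max_hits} times but only {n_samples} samples exist"
        )
    xm = x_max if x_max is not None else _default_x_max(max_hits)

    spectra: SpectrumSet = {lab: {} for lab in FRACTION_LABELS}
    censuses = {lab: partition.census(lab) for lab in FRACTION_LABELS}
    for lab in FRACTION_LABELS:
        for ctx, l_i in censuses[lab].counts.items():
            counts = np.zeros(xm + 1, dtype=np.int64)
            cell = hits.get((lab, ctx), {})
            for h in cell.values():
                counts[min(h, xm)] += 1
            counts[0] = l_i - len(cell)
            if counts[0] < 0:
                raise ValueError(
                    f"more hit sites than censused sites in {lab}/{ctx}; "
                    "SNV table and genome are inconsistent"
                )
            spectra[lab][ctx] = RecurrenceSpectrum(lab, ctx, counts)
    return spectra, dropped


def aggregate_spectrum(cells: Mapping[str, RecurrenceSpectrum], fraction: str) -> RecurrenceSpectrum:
    """Sum per-context observed spectra into one fraction-level spectrum."""
    xm = max(s.x_max for s in cells.values())
    counts = np.zeros(xm + 1, dtype=np.int64)
    for s in cells.values():
        counts[: s.counts.size] += s.counts
    return RecurrenceSpectrum(fraction, None, counts)


def expected_spectrum(
    l: int, m: int, x_max: int, fraction: str = "", context: str | None = None
) -> ExpectedSpectrum:
    """Poisson expectation P(x) = l * exp(-mu) * mu**x / x! with mu = m / l."""
    if l <= 0:
        if m > 0:
            raise ValueError("cannot expect SNVs (m > 0) over zero sites (l = 0)")
        return ExpectedSpectrum(fraction, context, np.zeros(x_max + 1), 0.0)
    mu = m / l
    xs = np.arange(x_max + 1)
    pmf = stats.poisson.pmf(xs, mu)
    return ExpectedSpectrum(fraction, context, l * pmf, float(l * stats.poisson.sf(x_max, mu)))


def aggregate_expected(cells: Sequence[ExpectedSpectrum], fraction: str = "") -> ExpectedSpectrum:
    """Sum per-context expectations: genome-wide P(x) = sum_i P_i(x)."""
    xm = max(c.counts.size for c in cells) - 1
    counts = np.zeros(xm + 1)
    tail = 0.0
    for c in cells:
        counts[: c.counts.size] += c.counts
        tail += c.tail_mass
    return ExpectedSpectrum(fraction, None, counts, tail)


def expected_from_spectra(
    cells: Mapping[str, RecurrenceSpectrum], fraction: str = ""
) -> ExpectedSpectrum:
    """Context-stratified Poisson expectation matching a set of observed cells."""
    parts = [
        expected_spectrum(s.l, s.m, s.x_max, fraction, ctx) for ctx, s in cells.items() if s.l > 0
    ]
    if not parts:
        return ExpectedSpectrum(fraction, None, np.zeros(1), 0.0)
    return aggregate_expected(parts, fraction)


@dataclass
class ExcessTestResult:
    statistic: float
    df: int
    p_value: float
    n_cells: int  # cells after pooling


def _pool_tail(observed: np.ndarray, expected: np.ndarray, pool_min: float) -> Tuple[np.ndarray, np.ndarray]:
    """Pool the sub-threshold upper tail into a single cell.

    All trailing cells whose individual expectation is below ``pool_min``
    (a contiguous suffix when the expectation is decreasing) are summed into
    one tail cell.  The pooled tail may still have a small expectation: that
    is what carries the extreme-recurrence signal.
    """
    obs = observed.astype(float)
    exp = expected.astype(float)
    below = exp < pool_min
    cut = obs.size
    while cut > 0 and below[cut - 1]:
        cut -= 1
    if cut >= obs.size - 1:  # suffix of length <= 1: nothing to pool
        return obs.copy(), exp.copy()
    obs_p = np.concatenate([obs[:cut], [obs[cut:].sum()]])
    exp_p = np.concatenate([exp[:cut], [exp[cut:].sum()]])
    return obs_p, exp_p


def excess_test(
    observed: RecurrenceSpectrum | np.ndarray,
    expected: ExpectedSpectrum | np.ndarray,
    pool_min: float = 5.0,
) -> ExcessTestResult:
    """Chi-square goodness-of-fit test of an observed spectrum against its
    Poisson expectation.

    Upper-tail cells are pooled until the pooled expectation reaches
    ``pool_min`` (default 5, the usual validity threshold); the statistic is
    sum((O - E)^2 / E) over the pooled cells with df = cells - 1.  No df
    deduction is made for the plug-in means mu_i = m_i / l_i.
    """
    obs = observed.counts if isinstance(observed, RecurrenceSpectrum) else np.asarray(observed, float)
    exp = expected.counts if isinstance(expected, ExpectedSpectrum) else np.asarray(expected, float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected spectra have different shapes")
    obs_p, exp_p = _pool_tail(np.asarray(obs, float), exp, pool_min)
    if obs_p.size < 2:
        raise ValueError("fewer than 2 cells after pooling; test undefined")
    if (exp_p <= 0).any():
        raise ValueError("zero expected count in a pooled cell; test undefined")
    stat = float(((obs_p - exp_p) ** 2 / exp_p).sum())
    df = obs_p.size - 1
    return ExcessTestResult(stat, df, float(stats.chi2.sf(stat, df)), obs_p.size)


def excess_summary(
    spectra: Mapping[str, RecurrenceSpectrum],
    fraction_sizes: Mapping[str, int],
    min_hits: int = EXCESS_MIN_HITS,
    reference: str = "TE",
) -> pd.DataFrame:
    """Excess-site counts, densities and fold ratios per genomic fraction.

    ``fold_vs_{reference}`` is the reference fraction's excess density divided
    by the row's density, rounded to 1 decimal (NA when undefined).  A
    ``Total`` row sums counts over fractions.
    """
    rows = []
    for frac, spec in spectra.items():
        size = int(fraction_sizes.get(frac, 0))
        excess = spec.excess_sites(min_hits)
        rows.append(
            {
                "fraction": frac,
                "sites": spec.l,
                "snvs": spec.m,
                "excess_sites": excess,
                "fraction_bp": size,
                "excess_density": excess / size if size else np.nan,
            }
        )
    df = pd.DataFrame(rows).set_index("fraction")
    ref_density = df["excess_density"].get(reference, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = ref_density / df["excess_density"]
    df[f"fold_vs_{reference}"] = np.round(fold.astype(float), 1)
    total = {
        "sites": df["sites"].sum(),
        "snvs": df["snvs"].sum(),
        "excess_sites": df["excess_sites"].sum(),
        "fraction_bp": df["fraction_bp"].sum(),
        "excess_density": np.nan,
        f"fold_vs_{reference}": np.nan,
    }
    df.loc["Total"] = total
    for col in ("sites", "snvs", "excess_sites", "fraction_bp"):
        df[col] = df[col].astype(np.int64)
    return df
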