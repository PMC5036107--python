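"""Genome partitioning and trinucleotide-context census.

The mutation rate of a site depends strongly on its immediate 5' and 3'
neighbours, so all downstream recurrence statistics are stratified by the
3-mer centred on the site.  By strand complementarity the 64 possible 3-mers
collapse to 32 classes with a pyrimidine (C or T) central base.

The genome is additionally partitioned, after excluding simple sequence
repeats (SSR), into three disjoint fractions:

* ``EX``  – exonic sequence,
* ``TE``  – non-exonic transposable-element sequence,
* ``NTE`` – everything else (non-exonic, non-TE).

Masks are consumed as BED3 interval files (0-based, half-open); SNV positions
elsewhere in the package are 1-based (VCF convention).  All coordinate
conversions happen here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from pyfaidx import Fasta

__all__ = [
    "CANONICAL_TRIPLETS",
    "FRACTION_LABELS",
    "NonCanonicalBaseError",
    "BedParseError",
    "GenomeFraction",
    "SiteCensus",
    "GenomePartition",
    "canonicalise_triplet",
    "reverse_complement",
    "load_fractions",
    "census_triplets",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Integer codes used in per-position label arrays.
LABEL_SSR = -1  #: excluded by the SSR mask (or by downstream filters)
LABEL_NTE = 0
LABEL_TE = 1
LABEL_EX = 2

FRACTION_LABELS = ("TE", "NTE", "EX")
_LABEL_CODE = {"NTE": LABEL_NTE, "TE": LABEL_TE, "EX": LABEL_EX}

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


class NonCanonicalBaseError(ValueError):
    """Raised when a triplet contains a base outside {A, C, G, T}."""


class BedParseError(ValueError):
    """Raised for malformed interval files; carries the offending line number."""


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise NonCanonicalBaseError(f"non-canonical base in {seq!r}") from exc


def canonicalise_triplet(triplet: str) -> str:
    """Collapse a 3-mer to its pyrimidine-centred representative.

    A triplet whose central base is C or T is returned as-is (upper-cased);
    otherwise the reverse complement of the whole triplet is returned, which
    always has a pyrimidine centre.  A triplet and its reverse complement
    therefore map to the same one of 32 canonical values.

    Raises
    ------
    NonCanonicalBaseError
        If the triplet is not length 3 or contains a non-ACGT character
        (including N).
    """
    if len(triplet) != 3:
        raise NonCanonicalBaseError(f"triplet must have length 3, got {triplet!r}")
    t = triplet.upper()
    if any(b not in _COMPLEMENT for b in t):
        raise NonCanonicalBaseError(f"non-canonical base in {triplet!r}")
    return t if t[1] in "CT" else reverse_complement(t)


def _all_canonical() -> Tuple[str, ...]:
    seen: List[str] = []
    for a in "ACGT":
        for b in "CT":
            for c in "ACGT":
                seen.append(a + b + c)
    return tuple(sorted(seen))


#: The 32 canonical pyrimidine-centred triplet contexts, sorted.
CANONICAL_TRIPLETS: Tuple[str, ...] = _all_canonical()
_CONTEXT_INDEX = {t: i for i, t in enumerate(CANONICAL_TRIPLETS)}

# 64 -> 32 lookup on base codes: code = 16*left + 4*centre + 1*right.
_CANON64 = np.empty(64, dtype=np.int8)
for _l in range(4):
    for _c in range(4):
        for _r in range(4):
            trip = "ACGT"[_l] + "ACGT"[_c] + "ACGT"[_r]
            _CANON64[16 * _l + 4 * _c + _r] = _CONTEXT_INDEX[canonicalise_triplet(trip)]


@dataclass(frozen=True)
class GenomeFraction:
    """One genomic fraction: a label and 0-based half-open intervals per sequence."""

    label: str
    intervals: Mapping[str, Tuple[Tuple[int, int], ...]]

    def size(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)


@dataclass
class SiteCensus:
    """Per-context site totals l_i for one genomic fraction.

    ``skipped_edge`` counts fraction positions at contig edges (no full 3-mer)
    and ``skipped_nonacgt`` counts positions whose 3-mer contains a non-ACGT
    base; neither group is censused or imputed.
    """

    fraction: str
    counts: Dict[str, int] = field(default_factory=dict)
    skipped_edge: int = 0
    skipped_nonacgt: int = 0

    def total(self) -> int:
        return int(sum(self.counts.values()))

    def __getitem__(self, context: str) -> int:
        return self.counts.get(context, 0)


def read_bed3(path: str | Path) -> Dict[str, List[Tuple[int, int]]]:
    """Read a BED3 file into per-chromosome sorted interval lists."""
    out: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end < start:
                raise BedParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            out.setdefault(parts[0], []).append((start, end))
    for ivs in out.values():
        ivs.sort()
    return out


def _apply_mask(labels: np.ndarray, intervals: Iterable[Tuple[int, int]], code: int) -> None:
    n = labels.shape[0]
    for start, end in intervals:
        labels[start : min(end, n)] = code


def _runs(mask: np.ndarray) -> Tuple[Tuple[int, int], ...]:
    """Maximal runs of True in a boolean array as half-open intervals."""
    if not mask.any():
        return ()
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return tuple(zip(starts.tolist(), ends.tolist()))


def _load_sequences(fasta: str | Path | Mapping[str, str]) -> Dict[str, str]:
    if isinstance(fasta, Mapping):
        return {name: str(seq).upper() for name, seq in fasta.items()}
    fa = Fasta(str(fasta), rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


class GenomePartition:
    """A genome with every position assigned to SSR-excluded, TE, NTE or EX.

    Precedence when masks overlap: SSR excludes first, then EX claims, then
    TE; the remainder is NTE.  Positions excluded by downstream filters
    (e.g. mappability) share the SSR exclusion code.
    """

    def __init__(self, sequences: Mapping[str, str], labels: Mapping[str, np.ndarray]):
        self.sequences: Dict[str, str] = dict(sequences)
        self.labels: Dict[str, np.ndarray] = {c: np.asarray(a, dtype=np.int8) for c, a in labels.items()}
        for chrom, seq in self.sequences.items():
            if len(seq) != self.labels[chrom].shape[0]:
                raise ValueError(f"label array length mismatch for {chrom}")

    @classmethod
    def from_files(
        cls,
        fasta: str | Path | Mapping[str, str],
        ssr_mask: str | Path | Mapping[str, Sequence[Tuple[int, int]]] | None = None,
        te_mask: str | Path | Mapping[str, Sequence[Tuple[int, int]]] | None = None,
        exon_mask: str | Path | Mapping[str, Sequence[Tuple[int, int]]] | None = None,
    ) -> "GenomePartition":
        sequences = _load_sequences(fasta)

        def as_intervals(mask) -> Dict[str, List[Tuple[int, int]]]:
            if mask is None:
                return {}
            if isinstance(mask, (str, Path)):
                return read_bed3(mask)
            return {c: sorted((int(s), int(e)) for s, e in ivs) for c, ivs in mask.items()}

        ssr, te, ex = as_intervals(ssr_mask), as_intervals(te_mask), as_intervals(exon_mask)
        for mask, name in ((ssr, "ssr"), (te, "te"), (ex, "exon")):
            unknown = set(mask) - set(sequences)
            if unknown:
                raise ValueError(f"{name} mask names sequences absent from the FASTA: {sorted(unknown)}")

        labels: Dict[str, np.ndarray] = {}
        for chrom, seq in sequences.items():
            lab = np.full(len(seq), LABEL_NTE, dtype=np.int8)
            _apply_mask(lab, te.get(chrom, ()), LABEL_TE)
            _apply_mask(lab, ex.get(chrom, ()), LABEL_EX)  # EX beats TE
            _apply_mask(lab, ssr.get(chrom, ()), LABEL_SSR)  # SSR beats all
            labels[chrom] = lab
        return cls(sequences, labels)

    def fraction(self, label: str) -> GenomeFraction:
        code = _LABEL_CODE[label]
        return GenomeFraction(
            label,
            {c: _runs(self.labels[c] == code) for c in self.sequences if (self.labels[c] == code).any()},
        )

    def fractions(self) -> Tuple[GenomeFraction, GenomeFraction, GenomeFraction]:
        """The (TE, NTE, EX) fractions of this partition."""
        return self.fraction("TE"), self.fraction("NTE"), self.fraction("EX")

    def fraction_sizes(self) -> Dict[str, int]:
        return {
            lab: int(sum((self.labels[c] == _LABEL_CODE[lab]).sum() for c in self.labels))
            for lab in FRACTION_LABELS
        }

    # -- per-position lookups (1-based positions, VCF convention) ----------

    def fraction_at(self, chrom: str, pos: int) -> str | None:
        """Fraction label at a 1-based position, or None if excluded."""
        code = int(self.labels[chrom][pos - 1])
        for lab, c in _LABEL_CODE.items():
            if c == code:
                return lab
        return None

    def context_at(self, chrom: str, pos: int) -> str | None:
        """Canonical triplet context at a 1-based position, or None at edges/N."""
        seq = self.sequences[chrom]
        i = pos - 1
        if i < 1 or i > len(seq) - 2:
            return None
        try:
            return canonicalise_triplet(seq[i - 1 : i + 2])
        except NonCanonicalBaseError:
            return None

    def base_at(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos - 1]

    # -- census ------------------------------------------------------------

    def _triplet_codes(self, chrom: str) -> np.ndarray:
        """Per-position canonical context index (0..31), -1 where undefined."""
        seq = self.sequences[chrom]
        codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        n = codes.shape[0]
        out = np.full(n, -1, dtype=np.int8)
        if n < 3:
            return out
        left, centre, right = codes[:-2], codes[1:-1], codes[2:]
        valid = (left >= 0) & (centre >= 0) & (right >= 0)
        trip = (16 * left + 4 * centre + right)[valid]
        inner = np.full(n - 2, -1, dtype=np.int8)
        inner[valid] = _CANON64[trip]
        out[1:-1] = inner
        return out

    def census(self, label: str) -> SiteCensus:
        """Census triplet contexts over all positions carrying ``label``."""
        code = _LABEL_CODE[label]
        census = SiteCensus(label)
        tallies = np.zeros(32, dtype=np.int64)
        for chrom in self.sequences:
            in_frac = self.labels[chrom] == code
            trip = self._triplet_codes(chrom)
            n = in_frac.shape[0]
            edge = np.zeros(n, dtype=bool)
            edge[:1] = True
            edge[max(n - 1, 0) :] = True
            census.skipped_edge += int((in_frac & edge).sum())
            interior = in_frac & ~edge
            census.skipped_nonacgt += int((interior & (trip < 0)).sum())
            ok = interior & (trip >= 0)
            tallies += np.bincount(trip[ok], minlength=32)
        census.counts = {
            CANONICAL_TRIPLETS[i]: int(tallies[i]) for i in range(32) if tallies[i] > 0
        }
        return census

    def exclude_positions(self, keep: Mapping[str, np.ndarray]) -> "GenomePartition":
        """A copy where positions with ``keep[chrom] == False`` are excluded."""
        labels = {}
        for chrom, lab in self.labels.items():
            new = lab.copy()
            new[~np.asarray(keep[chrom], dtype=bool)] = LABEL_SSR
            labels[chrom] = new
        return GenomePartition(self.sequences, labels)


def load_fractions(
    fasta: str | Path | Mapping[str, str],
    ssr_mask=None,
    te_mask=None,
    exon_mask=None,
) -> Tuple[GenomeFraction, GenomeFraction, GenomeFraction]:
    """Partition a genome into (TE, NTE, EX) after SSR exclusion."""
    return GenomePartition.from_files(fasta, ssr_mask, te_mask, exon_mask).fractions()


def census_triplets(
    fraction: GenomeFraction, fasta: str | Path | Mapping[str, str]
) -> SiteCensus:
    """Census triplet contexts over one fraction's intervals.

    Each censused position contributes the canonical form of the 3-mer
    centred on it; contig-edge positions and 3-mers containing non-ACGT
    bases are skipped and reported on the returned census.
    """
    sequences = _load_sequences(fasta)
    labels = {c: np.full(len(s), LABEL_SSR, dtype=np.int8) for c, s in sequences.items()}
    code = _LABEL_CODE.get(fraction.label, LABEL_NTE)
    for chrom, ivs in fraction.intervals.items():
        _apply_mask(labels[chrom], ivs, code)
    part = GenomePartition(sequences, labels)
    return part.census(fraction.label if fraction.label in _LABEL_CODE else "NTE")
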