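"""Lab-heterogeneity ("privacy") testing of recurrently hit sites.

If the SNVs at a recurrently hit site reflect a hypermutable position, every
sequencing laboratory should observe them at comparable rates; if they are
pipeline artefacts, they should cluster within the laboratory whose pipeline
produces them.  For one cancer type sequenced by two laboratories, the sites
hit >= 3 times form a 2 x C contingency table (labs x sites, cells = SNVs
contributed), and heterogeneity is assessed with Fisher's exact test
conditioned on the raw SNV margins.

The exact conditional p-value is computed by enumerating tables with fixed
margins up to a work bound; beyond it a seeded Monte-Carlo estimate over
fixed-margin tables is used, with the table's conditional (multiple
hypergeometric) probability as the extremity statistic — the standard Fisher
convention — and a binomial standard error reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "LabSiteMatrix",
    "FisherResult",
    "build_lab_matrix",
    "fisher_heterogeneity_test",
]


@dataclass
class LabSiteMatrix:
    """SNV counts at excess sites split by laboratory (rows) and site (columns)."""

    cancer_type: str
    labs: Tuple[str, str]
    sites: Tuple[Tuple[str, int], ...]  # (chrom, 1-based pos) per column
    table: np.ndarray  # shape (2, C)

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.int64)
        if self.table.ndim != 2 or self.table.shape[0] != 2:
            raise ValueError("lab-site matrix must have exactly 2 rows")
        if (self.table < 0).any():
            raise ValueError("lab-site matrix cells must be non-negative")

    @property
    def n_sites(self) -> int:
        return self.table.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{c}:{p}" for c, p in self.sites]
        return pd.DataFrame(self.table, index=list(self.labs), columns=cols)


def build_lab_matrix(
    snvs: pd.DataFrame, cancer_type: str, min_hits: int = 3
) -> LabSiteMatrix:
    """Cross-tabulate SNVs at the cancer type's excess sites by laboratory.

    Columns are the sites with at least ``min_hits`` SNVs within that cancer
    type; cells count the SNVs each lab contributed there.  Requires exactly
    two labs with SNVs in the cancer type (the two-cohort design this test
    addresses).
    """
    sub = snvs.loc[snvs["cancer_type"] == cancer_type]
    if "lab" not in sub.columns:
        raise ValueError("SNV table has no 'lab' column; privacy test undefined")
    labs = sorted(x for x in sub["lab"].unique() if str(x))
    if len(labs) < 2:
        raise ValueError(
            f"cancer type {cancer_type!r} has {len(labs)} lab(s); privacy test undefined"
        )
    if len(labs) > 2:
        raise ValueError(
            f"cancer type {cancer_type!r} has {len(labs)} labs; only the "
            "two-laboratory design is supported"
        )
    per_site = sub.groupby(["chrom", "pos"]).size()
    excess = per_site[per_site >= min_hits]
    sites: List[Tuple[str, int]] = [(str(c), int(p)) for c, p in excess.index]
    table = np.zeros((2, len(sites)), dtype=np.int64)
    if sites:
        counts = sub.groupby(["chrom", "pos", "lab"]).size()
        for j, (chrom, pos) in enumerate(sites):
            for i, lab in enumerate(labs):
                table[i, j] = int(counts.get((chrom, pos, lab), 0))
    return LabSiteMatrix(cancer_type, (labs[0], labs[1]), tuple(sites), table)


@dataclass
class FisherResult:
    p_value: float
    method: str  # "exact" | "monte_carlo" | "degenerate"
    std_error: float | None = None
    n_mc: int | None = None


def _log_table_prob(row1: np.ndarray, col_sums: np.ndarray, r1: int, r2: int, n: int) -> float:
    """log multiple-hypergeometric probability of a 2 x C table given margins."""
    row2 = col_sums - row1
    return float(
        gammaln(r1 + 1)
        + gammaln(r2 + 1)
        - gammaln(n + 1)
        + np.sum(gammaln(col_sums + 1))
        - np.sum(gammaln(row1 + 1))
        - np.sum(gammaln(row2 + 1))
    )


def _exact_p(table: np.ndarray, work_limit: int) -> float | None:
    """Exact conditional p by depth-first enumeration; None if over budget."""
    col_sums = table.sum(axis=0)
    r1, r2 = (int(v) for v in table.sum(axis=1))
    n = r1 + r2
    log_obs = _log_table_prob(table[0], col_sums, r1, r2, n)
    tol = 1e-7 * max(1.0, abs(log_obs))

    # per-column log-factorial terms; constant part added at the end
    const = gammaln(r1 + 1) + gammaln(r2 + 1) - gammaln(n + 1) + float(np.sum(gammaln(col_sums + 1)))
    cols = col_sums.tolist()
    c = len(cols)
    suffix = np.concatenate([np.cumsum(np.array(cols[::-1]))[::-1], [0]])

    work = 0
    total_le = 0.0

    def rec(j: int, rem1: int, log_terms: float) -> bool:
        nonlocal work, total_le
        if j == c:
            if rem1 == 0:
                logp = const + log_terms
                if logp <= log_obs + tol:
                    total_le += np.exp(logp)
            return True
        lo = max(0, rem1 - int(suffix[j + 1]))
        hi = min(int(cols[j]), rem1)
        for x in range(lo, hi + 1):
            work += 1
            if work > work_limit:
                return False
            term = -gammaln(x + 1) - gammaln(cols[j] - x + 1)
            if not rec(j + 1, rem1 - x, log_terms + term):
                return False
        return True

    if not rec(0, r1, 0.0):
        return None
    return min(1.0, float(total_le))


def _sample_row1(
    col_sums: np.ndarray, r1: int, n: int, n_mc: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample row-1 allocations of fixed-margin 2 x C tables.

    Columns are filled sequentially; conditioned on what remains, each
    column's row-1 count is hypergeometric, which yields draws from the exact
    multiple-hypergeometric law (the r2dtable construction).
    """
    c = col_sums.size
    out = np.empty((n_mc, c), dtype=np.int64)
    rem1 = np.full(n_mc, r1, dtype=np.int64)
    rem = n
    for j in range(c):
        cj = int(col_sums[j])
        rem_after = rem - cj
        x = rng.hypergeometric(cj, rem_after, rem1) if cj > 0 else np.zeros(n_mc, dtype=np.int64)
        out[:, j] = x
        rem1 = rem1 - x
        rem = rem_after
    return out


def fisher_heterogeneity_test(
    matrix: LabSiteMatrix | np.ndarray,
    method: str = "auto",
    n_mc: int = 1_000_000,
    seed: int | None = None,
    work_limit: int = 2_000_000,
) -> FisherResult:
    """Fisher's exact test of lab-by-site heterogeneity.

    ``method="auto"`` attempts exact enumeration within ``work_limit`` table
    cells visited and falls back to Monte Carlo over fixed-margin tables
    (``n_mc`` draws from ``seed``).  The Monte-Carlo p-value uses the
    add-one estimator (1 + #{prob <= observed}) / (1 + n_mc) with its
    binomial standard error.  Degenerate margins (a single positive column or
    an empty row) carry no heterogeneity information and return p = 1 with a
    warning.
    """
    table = matrix.table if isinstance(matrix, LabSiteMatrix) else np.asarray(matrix, np.int64)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x C table")
    col_sums = table.sum(axis=0)
    table = table[:, col_sums > 0]
    col_sums = col_sums[col_sums > 0]
    r1, r2 = (int(v) for v in table.sum(axis=1))
    n = r1 + r2
    if table.shape[1] < 2 or r1 == 0 or r2 == 0:
        warnings.warn("degenerate lab-site matrix margins; p = 1", stacklevel=2)
        return FisherResult(1.0, "degenerate")

    if method not in ("auto", "exact", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")

    if method in ("auto", "exact"):
        p = _exact_p(table, work_limit)
        if p is not None:
            return FisherResult(p, "exact")
        if method == "exact":
            raise RuntimeError(
                f"exact enumeration exceeded the work limit ({work_limit}); "
                "use method='monte_carlo'"
            )

    rng = np.random.default_rng(seed)
    log_obs = _log_table_prob(table[0], col_sums, r1, r2, n)
    tol = 1e-7 * max(1.0, abs(log_obs))
    hits = 0
    chunk = 100_000
    done = 0
    lg_cols = gammaln(col_sums + 1)
    const = float(gammaln(r1 + 1) + gammaln(r2 + 1) - gammaln(n + 1) + lg_cols.sum())
    while done < n_mc:
        size = min(chunk, n_mc - done)
        row1 = _sample_row1(col_sums, r1, n, size, rng)
        logp = const - gammaln(row1 + 1).sum(axis=1) - gammaln(col_sums[None, :] - row1 + 1).sum(axis=1)
        hits += int((logp <= log_obs + tol).sum())
        done += size
    p = (1 + hits) / (1 + n_mc)
    se = float(np.sqrt(p * (1 - p) / n_mc))
    return FisherResult(float(p), "monte_carlo", std_error=se, n_mc=n_mc)
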