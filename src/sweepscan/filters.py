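"""Post-calling variant filters.

Three filters, applied in a fixed order, clean a called variant set whose
study panels were sequenced at much higher coverage than the controls:

1. **Clustered rejects** — any run of >= 10 consecutive caller-rejected
   SNPs marks a problem region (mapping artifacts, structural variation);
   the whole interval, including clean sites inside it, is removed from
   every panel.
2. **Coverage** — sites with mean depth above twice the genome-wide
   median (likely duplications) or below 2x per person (too shallow to
   call) are removed.  Both bounds are strict: a site exactly at the
   bound is retained.
3. **Heterozygote excess** — an exact one-sided Hardy–Weinberg test on
   the diploid genotype counts; sites whose upper-tail probability of the
   observed-or-more heterozygotes falls below alpha are removed.

Each step reports the number of sites removed so a run can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .sites import SiteTable

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Accounting of sites removed per filter step, per panel."""

    steps: list[dict] = field(default_factory=list)

    def add(self, step: str, panel: str, removed: int, remaining: int) -> None:
        self.steps.append({"step": step, "panel": panel,
                           "sites_removed": int(removed),
                           "sites_remaining": int(remaining)})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps,
                            columns=["step", "panel", "sites_removed", "sites_remaining"])

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _ln_factorial(x) -> np.ndarray:
    return gammaln(np.asarray(x, dtype=float) + 1.0)


def hwe_het_probability(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact probability of a heterozygote count under Hardy–Weinberg.

    For ``n = n_AA + n_Aa + n_aa`` diploids with allele counts
    ``n_A = 2 n_AA + n_Aa`` and ``n_a = 2 n_aa + n_Aa``::

        P(n_Aa) = n! / (n_AA! n_Aa! n_aa!) * n_A! n_a! / (2n)! * 2**n_Aa

    i.e. the probability of the genotype configuration conditional on the
    allele counts.  Computed in log space (log-gamma), exact to ~1e-12
    relative error for n up to 1e4.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    logp = (
        _ln_factorial(n) - _ln_factorial(n_AA) - _ln_factorial(n_Aa) - _ln_factorial(n_aa)
        + _ln_factorial(n_A) + _ln_factorial(n_a) - _ln_factorial(2 * n)
        + n_Aa * np.log(2.0)
    )
    return float(np.exp(logp))


def hwe_excess_het_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-sided exact P for heterozygote *excess*.

    Sums P(h) over every heterozygote count h >= the observed n_Aa that is
    compatible with the same sample size and allele counts (h must share
    the parity of n_A and satisfy the non-negativity of the implied
    homozygote counts).  A point probability alone is not a test; the
    upper tail is what "excess of heterozygotes" means.
    """
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    h_max = min(n_A, n_a)
    p = 0.0
    for h in range(n_Aa, h_max + 1):
        if (n_A - h) % 2:
            continue
        aa_hom = (n_A - h) // 2
        a_hom = (n_a - h) // 2
        if aa_hom < 0 or a_hom < 0:
            continue
        p += hwe_het_probability(aa_hom, h, a_hom)
    return min(p, 1.0)


def filter_clustered_rejects(table: SiteTable, run_length: int = 10,
                             report: FilterReport | None = None):
    """Remove regions defined by runs of >= run_length caller-rejected SNPs.

    Runs are found per panel within each chromosome (they never span
    chromosomes); every maximal qualifying run defines a closed interval
    [first.pos, last.pos].  All sites — rejected or clean — falling inside
    any removed interval are dropped from *every* panel.

    Returns ``(filtered_table, removed_intervals)`` where the intervals
    are ``(chrom, start_pos, end_pos)`` 1-based inclusive.
    """
    intervals: list[tuple[str, int, int]] = []
    for label, df in table.panels.items():
        for chrom, sub in df.groupby("chrom", sort=False):
            flags = sub["caller_filtered"].to_numpy(dtype=bool)
            pos = sub["pos"].to_numpy()
            i = 0
            while i < len(flags):
                if flags[i]:
                    j = i
                    while j + 1 < len(flags) and flags[j + 1]:
                        j += 1
                    if j - i + 1 >= run_length:
                        intervals.append((str(chrom), int(pos[i]), int(pos[j])))
                    i = j + 1
                else:
                    i += 1
    out = table.copy()
    for label, df in out.panels.items():
        keep = np.ones(len(df), dtype=bool)
        for chrom, start, end in intervals:
            keep &= ~((df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] <= end))
        removed = len(df) - int(keep.sum())
        out.panels[label] = df[keep].reset_index(drop=True)
        if report is not None:
            report.add("clustered_rejects", label, removed, int(keep.sum()))
    return out, intervals


def filter_coverage(table: SiteTable, min_per_person: float = 2.0,
                    max_multiple_of_median: float = 2.0,
                    report: FilterReport | None = None) -> SiteTable:
    """Drop likely-duplicated (deep) and poorly covered (shallow) sites.

    Strict inequalities on both sides: depth must exceed
    ``max_multiple_of_median * median`` to be removed as too deep, and be
    below ``min_per_person`` to be removed as too shallow.  Panels whose
    sites carry no depth information pass through unchanged.
    """
    out = table.copy()
    for label, df in out.panels.items():
        depth = df["depth"].to_numpy(dtype=float)
        if np.all(np.isnan(depth)):
            if report is not None:
                report.add("coverage", label, 0, len(df))
            continue
        med = table.median_depth.get(label)
        if med is None or not np.isfinite(med):
            raise ValueError(f"panel {label!r}: median_depth required for coverage filter")
        with np.errstate(invalid="ignore"):
            drop = (depth > max_multiple_of_median * med) | (depth < min_per_person)
        drop &= ~np.isnan(depth)
        out.panels[label] = df[~drop].reset_index(drop=True)
        if report is not None:
            report.add("coverage", label, int(drop.sum()), int((~drop).sum()))
    return out


def hwe_filter(table: SiteTable, alpha: float = 0.05,
               report: FilterReport | None = None) -> SiteTable:
    """Drop sites with a significant excess of heterozygotes (P < alpha).

    Panels without genotype counts (frequency-only input, genotype columns
    all zero while haplotypes are present) are skipped with a warning.
    """
    out = table.copy()
    for label, df in out.panels.items():
        geno_n = df[["n_AA", "n_Aa", "n_aa"]].sum(axis=1)
        if len(df) and (geno_n == 0).all():
            logger.warning("hwe_filter: panel %r has no genotype counts; skipped", label)
            if report is not None:
                report.add("hwe", label, 0, len(df))
            continue
        pvals = np.array([
            hwe_excess_het_pvalue(int(r.n_AA), int(r.n_Aa), int(r.n_aa))
            if (r.n_AA + r.n_Aa + r.n_aa) > 0 else 1.0
            for r in df.itertuples(index=False)
        ])
        keep = pvals >= alpha
        out.panels[label] = df[keep].reset_index(drop=True)
        if report is not None:
            report.add("hwe", label, int((~keep).sum()), int(keep.sum()))
    return out


def apply_all_filters(table: SiteTable, run_length: int = 10,
                      min_per_person: float = 2.0, max_multiple_of_median: float = 2.0,
                      alpha: float = 0.05):
    """Run the three filters in their canonical order.

    Returns ``(filtered_table, removed_intervals, FilterReport)``.
    """
    report = FilterReport()
    t1, intervals = filter_clustered_rejects(table, run_length, report)
    t2 = filter_coverage(t1, min_per_person, max_multiple_of_median, report)
    t3 = hwe_filter(t2, alpha, report)
    return t3, intervals, report


def intervals_to_bed(intervals, path: str) -> None:
    """Write removed intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")
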