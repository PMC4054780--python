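#!/usr/bin/env python
"""Exercise the three variant filters on a deliberately flawed call set.

Constructs a small VCF containing the failure modes the filters target —
a cluster of 12 consecutive caller-rejected SNPs (mapping artifact), a
handful of sites at >2x the median coverage (duplication) or <2x per
person (too shallow), and sites with a significant excess of
heterozygotes — then runs the clustered-rejects, coverage and
Hardy-Weinberg filters in order and writes the per-step accounting.

Finding: each planted flaw is removed by exactly the intended step, and
the clean sites survive all three filters.
"""

import os

import numpy as np
import pandas as pd

from sweepscan.filters import apply_all_filters, intervals_to_bed
from sweepscan.sites import SITE_COLUMNS, read_vcf, write_vcf

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "filters")


def flawed_callset(n_ind: int = 14) -> pd.DataFrame:
    rng = np.random.default_rng(7)
    rows = []
    pos = 1000
    for i in range(120):
        pos += int(rng.integers(50, 200))
        aa = int(rng.integers(4, 10))
        ab = int(rng.integers(0, 4))
        bb = n_ind - aa - ab
        depth, flagged = 10.0, False
        if 30 <= i < 42:            # the rejected cluster
            flagged = True
        elif i in (60, 61):         # likely duplication
            depth = 25.0
        elif i in (70, 71):         # too shallow (DP is integral in VCF)
            depth = 1.0
        elif i in (80, 81):         # heterozygote excess
            aa, ab, bb = 0, n_ind, 0
        rows.append(("1", pos, "A", "T", 2 * bb + ab, 2 * n_ind, aa, ab, bb,
                     depth, flagged))
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    df = flawed_callset()
    vcf_path = os.path.join(OUT, "flawed.vcf")
    write_vcf(df, vcf_path, n_diploid=14)
    table = read_vcf(vcf_path, "study")
    table.median_depth["study"] = 10.0

    filtered, intervals, report = apply_all_filters(table)
    report.write_tsv(os.path.join(OUT, "filter_report.tsv"))
    intervals_to_bed(intervals, os.path.join(OUT, "removed_intervals.bed"))
    print(report.to_frame().to_string(index=False))
    print(f"\nremoved cluster intervals: {intervals}")
    print(f"{table.n_sites('study')} sites in, "
          f"{filtered.n_sites('study')} sites out")


if __name__ == "__main__":
    main()
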