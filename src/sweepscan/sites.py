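"""Per-site variant tables and VCF input.

A :class:`SiteTable` holds one pandas DataFrame per population panel,
aligned on chromosome and 1-based position, with the columns the filter
and scan stages need: alternate-allele counts on the haplotype scale,
diploid genotype counts, mean per-sample depth, and the upstream
caller's pass/fail flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: Column schema of one panel's site frame.
SITE_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "alt_count", "n_hap", "n_AA", "n_Aa", "n_aa",
    "depth", "caller_filtered",
]


@dataclass
class SiteTable:
    """Position-sorted variant records for one or more population panels.

    ``panels`` maps a panel label to a DataFrame with :data:`SITE_COLUMNS`;
    within a chromosome positions are strictly increasing.  ``median_depth``
    carries each panel's genome-wide median coverage (needed by the
    coverage filter).
    """

    panels: dict[str, pd.DataFrame] = field(default_factory=dict)
    median_depth: dict[str, float] = field(default_factory=dict)

    @property
    def populations(self) -> list[str]:
        return list(self.panels)

    def panel(self, label: str) -> pd.DataFrame:
        return self.panels[label]

    def n_sites(self, label: str | None = None) -> int:
        if label is not None:
            return len(self.panels[label])
        return sum(len(df) for df in self.panels.values())

    def copy(self) -> "SiteTable":
        return SiteTable(
            panels={k: df.copy() for k, df in self.panels.items()},
            median_depth=dict(self.median_depth),
        )

    def merged(self, other: "SiteTable") -> "SiteTable":
        """Combine panels from two tables (labels must not collide)."""
        dup = set(self.panels) & set(other.panels)
        if dup:
            raise ValueError(f"duplicate panel labels: {sorted(dup)}")
        out = self.copy()
        out.panels.update({k: df.copy() for k, df in other.panels.items()})
        out.median_depth.update(other.median_depth)
        return out

    def frequencies(self, label: str) -> pd.DataFrame:
        """Per-site alternate-allele frequency table (chrom, pos, freq, n_hap)."""
        df = self.panels[label]
        out = df[["chrom", "pos"]].copy()
        out["freq"] = df["alt_count"] / df["n_hap"]
        out["n_hap"] = df["n_hap"]
        return out

    def validate(self) -> None:
        for label, df in self.panels.items():
            for chrom, sub in df.groupby("chrom", sort=False):
                if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                    raise ValueError(
                        f"panel {label!r}, chromosome {chrom!r}: positions must be "
                        "strictly increasing"
                    )
            bad = (df["alt_count"] < 0) | (df["alt_count"] > df["n_hap"])
            if bad.any():
                raise ValueError(f"panel {label!r}: alt_count outside [0, n_hap]")


def _sorted(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def read_vcf(path: str, panel_label: str) -> SiteTable:
    """Read biallelic SNPs from a VCF into a single-panel :class:`SiteTable`.

    Multi-allelic and non-SNP records are dropped (counted and logged).
    ``caller_filtered`` is set for any FILTER other than PASS/missing; the
    sites themselves are retained so the clustered-reject filter can see
    them.  Depth is the mean per-sample DP when present, else NaN.
    """
    rows = []
    dropped = 0
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                dropped += 1
                continue
            n_hap = alt = 0
            n_AA = n_Aa = n_aa = 0
            depths = []
            for sample in rec.samples.values():
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                n_hap += len(gt)
                alt += sum(1 for a in gt if a == 1)
                if len(gt) == 2:
                    na = sum(1 for a in gt if a == 1)
                    if na == 0:
                        n_AA += 1
                    elif na == 1:
                        n_Aa += 1
                    else:
                        n_aa += 1
                dp = sample.get("DP")
                if dp is not None:
                    depths.append(dp)
            if n_hap == 0:
                dropped += 1
                continue
            filters = list(rec.filter.keys())
            caller_filtered = bool(filters) and filters != ["PASS"]
            rows.append((
                rec.chrom, rec.pos, rec.ref, alts[0],
                alt, n_hap, n_AA, n_Aa, n_aa,
                float(np.mean(depths)) if depths else float("nan"),
                caller_filtered,
            ))
    if dropped:
        logger.info("read_vcf(%s): dropped %d non-biallelic/non-SNP or uncalled records",
                    path, dropped)
    df = _sorted(pd.DataFrame(rows, columns=SITE_COLUMNS))
    has_depth = len(df) and df["depth"].notna().any()
    med = float(np.nanmedian(df["depth"])) if has_depth else float("nan")
    return SiteTable(panels={panel_label: df}, median_depth={panel_label: med})


def write_vcf(df: pd.DataFrame, path: str, n_diploid: int | None = None,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a panel frame back out as an uncompressed VCF with GT calls.

    Genotypes are reconstructed from the diploid genotype counts when
    present (hom-ref, then het, then hom-alt individuals), which is
    sufficient for round-tripping allele counts; phasing is not recorded.
    """
    if n_diploid is None:
        n_diploid = int(df["n_hap"].max()) // 2 if len(df) else 1
    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=LowQual,Description="Rejected by the upstream caller">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    chroms = list(dict.fromkeys(df["chrom"])) if len(df) else ["1"]
    for chrom in chroms:
        ln = None if contig_lengths is None else contig_lengths.get(str(chrom))
        if ln is None:
            sub = df[df["chrom"] == chrom]
            ln = int(sub["pos"].max()) + 1000 if len(sub) else 1000
        header.contigs.add(str(chrom), length=ln)
    samples = [f"s{i}" for i in range(n_diploid)]
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for row in df.itertuples(index=False):
            rec = vf.new_record(contig=str(row.chrom), start=int(row.pos) - 1,
                                alleles=(row.ref, row.alt))
            rec.filter.add("PASS" if not row.caller_filtered else "LowQual")
            gts = ([(0, 0)] * int(row.n_AA) + [(0, 1)] * int(row.n_Aa)
                   + [(1, 1)] * int(row.n_aa))
            gts += [(0, 0)] * (n_diploid - len(gts))
            for s, gt in zip(samples, gts):
                rec.samples[s]["GT"] = gt
                if np.isfinite(row.depth):
                    rec.samples[s]["DP"] = int(round(row.depth))
            vf.write(rec)


def read_freq_tsv(path: str) -> pd.DataFrame:
    """Read a per-site frequency table (chrom, pos, ref, alt, freq, n)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "freq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_freq_tsv(df: pd.DataFrame, path: str) -> None:
    """Write a panel frame as a frequency TSV (chrom, pos, ref, alt, freq, n)."""
    out = df[["chrom", "pos", "ref", "alt"]].copy()
    out["freq"] = df["alt_count"] / df["n_hap"]
    out["n"] = df["n_hap"]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def integer_positions(positions: np.ndarray, length: float) -> np.ndarray:
    """Map continuous simulator coordinates to unique 1-based integers.

    Floors each coordinate, then bumps collisions upward so order is
    preserved; assumes sites are sparse relative to the region length.
    """
    ints = np.floor(np.sort(np.asarray(positions, dtype=float))).astype(np.int64) + 1
    for i in range(1, len(ints)):
        if ints[i] <= ints[i - 1]:
            ints[i] = ints[i - 1] + 1
    return ints


def table_from_counts(chrom, positions, alt_counts, n_hap: int, panel_label: str,
                      depth: float = float("nan")) -> SiteTable:
    """Build a single-panel SiteTable from bare counts (simulation output).

    Genotype counts are left at zero-het Hardy–Weinberg-agnostic values
    (n_AA/n_Aa/n_aa unset, encoded as 0) — stages that need genotypes
    should come from VCF input instead.
    """
    positions = np.asarray(positions, dtype=int)
    alt_counts = np.asarray(alt_counts, dtype=int)
    df = pd.DataFrame({
        "chrom": str(chrom), "pos": positions,
        "ref": "A", "alt": "T",
        "alt_count": alt_counts, "n_hap": int(n_hap),
        "n_AA": 0, "n_Aa": 0, "n_aa": 0,
        "depth": depth, "caller_filtered": False,
    })
    return SiteTable(panels={panel_label: _sorted(df)},
                     median_depth={panel_label: depth})
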