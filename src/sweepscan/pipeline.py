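"""End-to-end orchestration: filter -> scan -> cutoff -> prioritize, and
the simulation/power experiments, as reproducible runs.

Every run writes its exact configuration next to its outputs, logs
per-stage site/region counts, and derives all randomness from one seed,
so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import filters, prioritize, scan as scan_mod
from .power import sample_size_sweep
from .simulate import SimParams
from .sites import SiteTable, read_freq_tsv, read_vcf

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a scan or power run (JSON-serializable)."""

    # inputs
    vcf: dict[str, str] = field(default_factory=dict)       # panel label -> VCF path
    roles: dict[str, str] = field(default_factory=dict)     # study/control/outgroup -> label
    chrom_lengths: dict[str, int] | None = None             # inferred from data if absent
    panels: dict[str, str] = field(default_factory=dict)    # extra control freq TSVs
    external: str | None = None                             # external genotype freq TSV
    n_external: int = 0
    transcripts: str | None = None                          # BED or GTF
    mask: str | None = None                                 # BED of assayed sites
    # windows & cutoff
    window: int = 50_000
    step: int = 2_000
    quantile: float = 0.001
    min_sites: int = 10
    # filters
    run_length: int = 10
    min_per_person: float = 2.0
    max_multiple_of_median: float = 2.0
    hwe_alpha: float = 0.05
    # prioritization
    min_block: int = 10
    min_differential: float = 0.10
    ci_level: float = 0.95
    merge_gap: int = 0
    # simulation / power
    sim: dict = field(default_factory=dict)                 # SimParams overrides
    taus: list[int] = field(default_factory=lambda: [45, 70, 100, 150])
    sizes: list[int] = field(default_factory=lambda: [12, 14])
    gold: int = 400
    statistic: str = "s_pi"
    replicates: int = 100
    seed: int = 0

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def snapshot(self, outdir: str) -> None:
        with open(os.path.join(outdir, "config.json"), "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def sim_params(self) -> SimParams:
        base = SimParams().desk_scale()
        return dataclasses.replace(base, **self.sim) if self.sim else base


def _load_transcripts(path: str) -> pd.DataFrame:
    if path.endswith((".gtf", ".gff")):
        return prioritize.read_transcripts_gtf(path)
    return prioritize.read_transcripts_bed(path)


def run_scan(config: RunConfig, outdir: str,
             table: SiteTable | None = None) -> pd.DataFrame:
    """Filter -> scan -> cutoff -> merge -> prioritize; write all artifacts.

    ``table`` may supply a prebuilt SiteTable instead of reading the
    configured VCFs.  Returns the candidate-region report frame; writes
    windows.tsv, significant.bed, cutoffs.json, regions.tsv,
    filter_report.tsv, removed_intervals.bed, stage_counts.tsv and
    config.json under ``outdir``.
    """
    os.makedirs(outdir, exist_ok=True)
    config.snapshot(outdir)
    stages: list[dict] = []

    if table is None:
        if not config.vcf:
            raise ValueError("run_scan needs either a SiteTable or configured VCFs")
        table = SiteTable()
        for label, path in config.vcf.items():
            table = table.merged(read_vcf(path, label))
    table.validate()
    stages.append({"stage": "input", "count": table.n_sites()})

    filtered, removed, report = filters.apply_all_filters(
        table, run_length=config.run_length, min_per_person=config.min_per_person,
        max_multiple_of_median=config.max_multiple_of_median, alpha=config.hwe_alpha)
    report.write_tsv(os.path.join(outdir, "filter_report.tsv"))
    filters.intervals_to_bed(removed, os.path.join(outdir, "removed_intervals.bed"))
    stages.append({"stage": "filtered", "count": filtered.n_sites()})

    if config.mask:
        filtered = scan_mod.apply_mask(filtered, scan_mod.read_bed(config.mask))
        stages.append({"stage": "masked", "count": filtered.n_sites()})

    study = config.roles["study"]
    if config.chrom_lengths:
        lengths = {str(k): int(v) for k, v in config.chrom_lengths.items()}
    else:
        df = filtered.panels[study]
        lengths = {str(c): int(s["pos"].max()) for c, s in df.groupby("chrom")}
    windows = scan_mod.make_windows(lengths, config.window, config.step)

    ws = scan_mod.scan(filtered, config.roles, windows, min_sites=config.min_sites)
    cutoffs = scan_mod.genomewide_cutoff(ws, config.quantile)
    ws = scan_mod.significant_windows(ws, cutoffs)
    scan_mod.write_window_tsv(ws, os.path.join(outdir, "windows.tsv"))
    scan_mod.write_significant_bed(ws, os.path.join(outdir, "significant.bed"))
    scan_mod.write_cutoffs_json(cutoffs, os.path.join(outdir, "cutoffs.json"))
    stages.append({"stage": "significant_windows", "count": int(ws["significant"].sum())})

    regions = prioritize.merge_windows(ws, gap=config.merge_gap)
    stages.append({"stage": "candidate_regions", "count": len(regions)})

    study_freqs = filtered.frequencies(study)
    n_hap = int(filtered.panels[study]["n_hap"].iloc[0]) if len(filtered.panels[study]) else 0
    primary_controls = {}
    for role in ("control", "outgroup"):
        label = config.roles.get(role)
        if label and label in filtered.panels:
            primary_controls[label] = filtered.frequencies(label)
    extra_panels = {lab: read_freq_tsv(p) for lab, p in config.panels.items()}
    external = read_freq_tsv(config.external) if config.external else None
    transcripts = _load_transcripts(config.transcripts) if config.transcripts else None

    regions = prioritize.prioritize_regions(
        regions, study_freqs, n_hap, primary_controls,
        extra_panels=extra_panels, external=external, n_external=config.n_external,
        transcripts=transcripts, min_block=config.min_block,
        min_differential=config.min_differential, ci_level=config.ci_level)
    report_df = prioritize.regions_to_frame(regions)
    report_df.to_csv(os.path.join(outdir, "regions.tsv"), sep="\t", index=False,
                     float_format="%.6g")
    stages.append({"stage": "prioritized_regions",
                   "count": int(report_df["prioritized"].sum()) if len(report_df) else 0})

    pd.DataFrame(stages).to_csv(os.path.join(outdir, "stage_counts.tsv"),
                                sep="\t", index=False)
    for s in stages:
        logger.info("run_scan stage %-20s %d", s["stage"], s["count"])
    return report_df


def run_power(config: RunConfig, outdir: str, mode: str = "sample_size") -> pd.DataFrame:
    """Run the power experiments and write their tables.

    ``mode="sample_size"`` runs the paired sample-size sweep for the
    configured statistic; ``mode="statistics"`` estimates power of all
    four statistics at each tau at the first configured sample size.
    """
    os.makedirs(outdir, exist_ok=True)
    config.snapshot(outdir)
    params = config.sim_params()
    if mode == "sample_size":
        out = sample_size_sweep(params, config.taus, sizes=config.sizes,
                                statistic=config.statistic,
                                replicates=config.replicates, seed=config.seed,
                                gold=config.gold)
        out.to_csv(os.path.join(outdir, "power_vs_sample_size.tsv"),
                   sep="\t", index=False, float_format="%.6g")
        return out
    if mode == "statistics":
        from .power import STATISTICS, power_from_values, replicate_statistics
        rows = []
        for i, tau in enumerate(config.taus):
            df = replicate_statistics(params, int(tau), [config.sizes[0]],
                                      list(STATISTICS), config.replicates,
                                      config.seed + 104729 * i)
            for stat, sub in df.groupby("statistic"):
                power, cutoff = power_from_values(sub["obs"].to_numpy(),
                                                  sub["null"].to_numpy())
                rows.append({"statistic": stat, "tau": int(tau),
                             "n_sampled": int(sub["n"].iloc[0]), "power": power,
                             "replicates": config.replicates, "cutoff": cutoff})
        out = pd.DataFrame(rows)
        out.to_csv(os.path.join(outdir, "power_by_statistic.tsv"),
                   sep="\t", index=False, float_format="%.6g")
        return out
    raise ValueError(f"unknown mode {mode!r}")
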