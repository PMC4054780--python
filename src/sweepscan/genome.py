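"""Assembly of multi-region synthetic genomes for end-to-end runs.

A synthetic chromosome is a concatenation of independently simulated
regions (each its own source population, three-way split, and forward
evolution), exactly one of which may carry the selected locus.  The
result is a three-panel :class:`~sweepscan.sites.SiteTable` plus the
ground truth needed to score a scan: the interval of the swept region
and the position of the selected site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .power import _align_counts, simulate_trio
from .simulate import SimParams, sample_haplotypes
from .sites import SiteTable, integer_positions


@dataclass
class PlantedGenome:
    table: SiteTable              # panels: study / control / outgroup
    chrom: str
    length: int
    sweep_interval: tuple[int, int] | None   # 1-based inclusive, or None
    selected_pos: int | None
    n_hap: int


def planted_sweep_genome(params: SimParams, n_regions: int = 12,
                         sweep_region: int | None = None, tau: int = 100,
                         n_sample: int | None = None, seed: int = 0,
                         chrom: str = "sim1") -> PlantedGenome:
    """Build a chromosome of ``n_regions`` independent regions.

    ``sweep_region`` indexes the region receiving the selected locus
    (None = all-neutral genome).  Each region simulates its own
    study/cont1/cont2 trio; samples of ``n_sample`` haplotypes (census
    by default) populate the three panels, with cont1 as "control" and
    cont2 as "outgroup".
    """
    rng = np.random.default_rng(seed)
    L = int(params.L)
    n_sample = n_sample or 2 * params.N_e
    frames = {lab: [] for lab in ("study", "control", "outgroup")}
    sweep_interval = None
    selected_pos = None
    for region in range(n_regions):
        offset = region * L
        selected = region == sweep_region
        pops = dict(zip(("study", "control", "outgroup"),
                        simulate_trio(params, tau, rng, selected=selected)))
        samples = {lab: (*sample_haplotypes(pop, n_sample, rng), pop.fixed_positions)
                   for lab, pop in pops.items()}
        nmap = {lab: n_sample for lab in samples}
        labels = list(samples)
        aligned = _align_counts(samples, nmap, labels)
        union = np.unique(np.concatenate(
            [samples[lab][0] for lab in labels]
            + [samples[lab][2] for lab in labels]))
        ints = integer_positions(union, L) + offset  # one shared coordinate map
        for lab in labels:
            frames[lab].append(pd.DataFrame({
                "chrom": chrom, "pos": ints, "ref": "A", "alt": "T",
                "alt_count": aligned[lab], "n_hap": n_sample,
                "n_AA": 0, "n_Aa": 0, "n_aa": 0,
                "depth": np.nan, "caller_filtered": False,
            }))
        if selected:
            sweep_interval = (offset + 1, offset + L)
            selected_pos = offset + L // 2
    panels = {lab: pd.concat(dfs, ignore_index=True) for lab, dfs in frames.items()}
    table = SiteTable(panels=panels,
                      median_depth={lab: float("nan") for lab in panels})
    return PlantedGenome(table=table, chrom=chrom, length=n_regions * L,
                         sweep_interval=sweep_interval,
                         selected_pos=selected_pos, n_hap=n_sample)


def neutral_panel_tables(genome: PlantedGenome, labels=("HAP1", "HAP2"),
                         seed: int = 1) -> dict[str, pd.DataFrame]:
    """Extra control panels derived from the genome's outgroup/control.

    Emulates independent lowlander panels by jittering the control
    panel's frequencies with binomial resampling noise; used by the
    prioritization stage's all-panels criterion.
    """
    rng = np.random.default_rng(seed)
    out = {}
    base = genome.table.panels["control"]
    for label in labels:
        n = int(base["n_hap"].iloc[0])
        freq = rng.binomial(n, base["alt_count"] / n) / n
        out[label] = pd.DataFrame({"chrom": base["chrom"], "pos": base["pos"],
                                   "freq": freq})
    return out
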