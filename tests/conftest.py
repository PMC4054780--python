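import os

import numpy as np
import pandas as pd
import pytest

from sweepscan.simulate import SimParams


@pytest.fixture(scope="session")
def desk_params() -> SimParams:
    """Desk-scale simulation parameters (N_e=100, L=10 kbp, scaled rates)."""
    return SimParams().desk_scale()


CALIBRATION_REPLICATES = 120


@pytest.fixture(scope="session")
def null_powers(desk_params):
    """Empirical power under s=0 for all four statistics at their 5%
    cutoffs (shared neutral replicates): the false-positive calibration."""
    from sweepscan.power import STATISTICS, power_from_values, replicate_statistics
    df = replicate_statistics(desk_params, tau=60, n_samples=[28],
                              statistics=list(STATISTICS),
                              replicates=CALIBRATION_REPLICATES, seed=404,
                              selected=False)
    out = {}
    for stat, sub in df.groupby("statistic"):
        out[stat], _ = power_from_values(sub["obs"].to_numpy(),
                                         sub["null"].to_numpy())
    return out


@pytest.fixture(scope="session")
def planted_fixture(desk_params, tmp_path_factory):
    """A 120 kbp synthetic chromosome with one planted sweep plus the
    side files the prioritization stage needs (transcripts, extra
    control panels, an external genotyping cohort), and a RunConfig.

    The sweep sits in region 5 of 12 (50,001-60,000) with the selected
    site at 55,000; panels sample n=14 haplotypes, matching the scale of
    a small whole-genome study.
    """
    from sweepscan.genome import neutral_panel_tables, planted_sweep_genome
    from sweepscan.pipeline import RunConfig

    d = tmp_path_factory.mktemp("planted")
    genome = planted_sweep_genome(desk_params, n_regions=12, sweep_region=5,
                                  tau=100, n_sample=14, seed=77)
    tx = pd.DataFrame({
        "chrom": "sim1",
        "start": [3_000, 52_000, 55_000, 101_000],
        "end": [4_500, 54_500, 56_500, 103_000],
        "name": ["GENEA", "SWEEP1", "SWEEP2", "GENEB"],
    })
    tx_path = str(d / "transcripts.bed")
    tx.to_csv(tx_path, sep="\t", header=False, index=False)

    panel_paths = {}
    for lab, df in neutral_panel_tables(genome, seed=3).items():
        path = str(d / f"{lab}.freq.tsv")
        df.to_csv(path, sep="\t", index=False)
        panel_paths[lab] = path

    rng = np.random.default_rng(5)
    sdf = genome.table.panels["study"]
    ext = pd.DataFrame({"chrom": sdf["chrom"], "pos": sdf["pos"],
                        "freq": rng.binomial(126, sdf["alt_count"] / 14) / 126})
    ext_path = str(d / "external.freq.tsv")
    ext.to_csv(ext_path, sep="\t", index=False)

    config = RunConfig(
        roles={"study": "study", "control": "control", "outgroup": "outgroup"},
        chrom_lengths={"sim1": genome.length}, window=10_000, step=2_000,
        quantile=0.001, min_sites=10, panels=panel_paths,
        external=ext_path, n_external=126, transcripts=tx_path, seed=1)
    return genome, config, str(d)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240217)


def brute_force_pairwise_pi(haplotypes: np.ndarray) -> float:
    """Mean count of pairwise differences over all haplotype pairs.

    Independent oracle for theta_pi: explicit enumeration of all
    C(n, 2) pairs on a 0/1 matrix.
    """
    n = haplotypes.shape[0]
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(haplotypes[i] != haplotypes[j]))
            pairs += 1
    return total / pairs


def enumerate_het_configs(n: int, n_A: int):
    """All genotype configurations (n_AA, n_Aa, n_aa) with given n, n_A.

    Yields (config, multiplicity) where multiplicity is the number of
    ways to assign alleles: the count of distinct ways n individuals can
    be arranged into the genotype classes times 2**n_Aa orderings of
    alleles within heterozygotes.  Used to verify the exact HWE
    distribution by full enumeration.
    """
    from math import comb
    n_a = 2 * n - n_A
    for h in range(min(n_A, n_a) + 1):
        if (n_A - h) % 2:
            continue
        aa = (n_A - h) // 2
        bb = (n_a - h) // 2
        if aa + h + bb != n or aa < 0 or bb < 0:
            continue
        mult = comb(n, aa) * comb(n - aa, h) * (2 ** h)
        yield (aa, h, bb), mult
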