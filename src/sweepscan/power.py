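"""Power estimation for the selection statistics on simulated sweeps.

Per replicate, a neutral source population is split into study/cont1/
cont2; the study evolves with a selected locus for tau generations and
the controls evolve neutrally.  A statistic's power at the 5% false
positive rate is the fraction of study-vs-cont1 values exceeding the top
5% of the null distribution, where the null is the same statistic
applied to the neutral pair cont1-vs-cont2 (pooled across replicates).
The three-population PBS needs an outgroup in its null as well.  With
only three simulated populations the null PBS uses the study
population in the outgroup role (``null_outgroup="study"``, the
default): under neutrality the trio is exchangeable, and under
selection the study branch enters both outgroup T terms and cancels in
expectation — though it does inflate the null's variance.  Setting
``null_outgroup="neutral"`` evolves a fourth neutral population, cont3,
used only as the null's outgroup, removing that contamination at extra
cost.

The sample-size sweep reuses the same evolved replicates across sample
sizes (paired design), so power differences between sizes reflect
sampling alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .simulate import SimParams, evolve, neutral_source, sample_haplotypes, \
    split_populations

STATISTICS = ("s_f", "s_pi", "fst", "pbs")


@dataclass
class PowerResult:
    statistic: str
    tau: int
    n_sampled: int
    power: float
    replicates: int
    cutoff: float
    restarts: int = 0


def _align_counts(samples: dict, n: dict, labels):
    """Union-of-positions alignment across panels.

    ``samples[label]`` is ``(positions, counts)`` or
    ``(positions, counts, fixed_positions)``.  A position absent from a
    panel counts 0 unless it is among that panel's fixed positions, in
    which case the derived allele is fixed there and counts ``n[label]``
    — a fixed difference, the strongest divergence signal.
    """
    all_pos = np.unique(np.concatenate(
        [samples[lab][0] for lab in labels]
        + [samples[lab][2] for lab in labels if len(samples[lab]) > 2]))
    out = {}
    for lab in labels:
        pos, counts = samples[lab][0], samples[lab][1]
        arr = np.zeros(len(all_pos), dtype=np.int64)
        if len(samples[lab]) > 2 and len(samples[lab][2]):
            fixed_idx = np.searchsorted(all_pos, samples[lab][2])
            arr[fixed_idx] = n[lab]
        arr[np.searchsorted(all_pos, pos)] = counts
        out[lab] = arr
    return out


def statistic_value(name: str, samples: dict, n: dict,
                    study: str, control: str, outgroup: str | None = None) -> float:
    """Region-level statistic from per-population (positions, counts).

    ``samples[label] = (positions, alt_counts)``; ``n[label]`` the
    sampled haplotype count.  The whole simulated region is treated as
    one window.
    """
    labels = [study, control] + ([outgroup] if name == "pbs" else [])
    counts = _align_counts(samples, n, labels)
    if name == "s_f":
        return stats._log_ratio(stats.theta_f(counts[control], n[control]),
                                stats.theta_f(counts[study], n[study]))
    if name == "s_pi":
        return stats._log_ratio(stats.theta_pi(counts[control], n[control]),
                                stats.theta_pi(counts[study], n[study]))
    p = {lab: counts[lab] / n[lab] for lab in labels}
    if name == "fst":
        return stats.hudson_fst(p[study], p[control], n[study], n[control])
    if name == "pbs":
        f_sn = stats.hudson_fst(p[study], p[control], n[study], n[control])
        f_so = stats.hudson_fst(p[study], p[outgroup], n[study], n[outgroup])
        f_no = stats.hudson_fst(p[control], p[outgroup], n[control], n[outgroup])
        return stats.pbs(stats.branch_length(f_sn), stats.branch_length(f_so),
                         stats.branch_length(f_no))
    raise ValueError(f"unknown statistic {name!r}")


def simulate_trio(params: SimParams, tau: int, rng: np.random.Generator,
                  selected: bool = True, standing_freq: float | None = None,
                  n_neutral: int = 2):
    """One replicate: source -> split -> evolve (study selected or not).

    Returns (study, cont1, cont2[, cont3...]) SimPopulations after tau
    generations; ``n_neutral`` controls how many neutral populations are
    split off alongside the study.
    """
    src_seed = int(rng.integers(1, 2**31 - 1))
    source = neutral_source(params, seed=src_seed)
    pops = split_populations(source, rng, n_populations=1 + n_neutral)
    study = evolve(pops[0], params, tau, selected=selected, rng=rng,
                   standing_freq=standing_freq)
    conts = [evolve(p, params, tau, selected=False, rng=rng) for p in pops[1:]]
    return (study, *conts)


def replicate_statistics(params: SimParams, tau: int, n_samples, statistics,
                         replicates: int, seed: int, selected: bool = True,
                         null_outgroup: str = "study") -> pd.DataFrame:
    """Observed and null statistic values for paired replicates.

    Returns a long DataFrame with columns (replicate, statistic, n, obs,
    null, restarts).  Sample sizes above the population census 2*N_e are
    clipped to the census (exact population frequencies).
    """
    if null_outgroup not in ("study", "neutral"):
        raise ValueError(f"unknown null_outgroup {null_outgroup!r}")
    rng = np.random.default_rng(seed)
    n_samples = sorted({min(int(n), 2 * params.N_e) for n in n_samples})
    extra_neutral = null_outgroup == "neutral" and "pbs" in statistics
    rows = []
    for rep in range(replicates):
        pops = simulate_trio(params, tau, rng, selected=selected,
                             n_neutral=3 if extra_neutral else 2)
        labels = ["study", "cont1", "cont2"] + (["cont3"] if extra_neutral else [])
        null_og = "cont3" if extra_neutral else "study"
        for n in n_samples:
            samples = {lab: (*sample_haplotypes(pop, n, rng), pop.fixed_positions)
                       for lab, pop in zip(labels, pops)}
            nmap = {lab: n for lab in samples}
            for stat in statistics:
                obs = statistic_value(stat, samples, nmap, "study", "cont1",
                                      outgroup="cont2")
                null = statistic_value(stat, samples, nmap, "cont1", "cont2",
                                       outgroup=null_og if stat == "pbs" else None)
                rows.append((rep, stat, n, obs, null, pops[0].restarts))
    return pd.DataFrame(rows, columns=["replicate", "statistic", "n",
                                       "obs", "null", "restarts"])


def power_from_values(obs: np.ndarray, null: np.ndarray,
                      fpr: float = 0.05) -> tuple[float, float]:
    """(power, cutoff): cutoff is the top-``fpr`` of the pooled null.

    Non-finite null values cannot anchor the quantile and are dropped;
    +inf observed values always exceed the cutoff.
    """
    finite_null = null[np.isfinite(null)]
    if len(finite_null) == 0:
        return float("nan"), float("nan")
    cutoff = float(np.quantile(finite_null, 1.0 - fpr))
    obs = obs[~np.isnan(obs)]
    power = float(np.mean(obs >= cutoff)) if len(obs) else float("nan")
    return power, cutoff


def power_experiment(params: SimParams, statistic: str, n_sample: int,
                     tau: int, replicates: int, seed: int,
                     fpr: float = 0.05, selected: bool = True) -> PowerResult:
    """Power of one statistic at one (tau, sample size)."""
    df = replicate_statistics(params, tau, [n_sample], [statistic],
                              replicates, seed, selected=selected)
    power, cutoff = power_from_values(df["obs"].to_numpy(), df["null"].to_numpy(),
                                      fpr)
    return PowerResult(statistic=statistic, tau=tau,
                       n_sampled=min(n_sample, 2 * params.N_e), power=power,
                       replicates=replicates, cutoff=cutoff,
                       restarts=int(df["restarts"].max()))


def sample_size_sweep(params: SimParams, taus, sizes=None, statistic: str = "s_pi",
                      replicates: int = 100, seed: int = 0, gold: int = 400,
                      fpr: float = 0.05) -> pd.DataFrame:
    """Power versus sample size, relative to a gold-standard large sample.

    For each tau, the same replicates are sampled at every size in
    ``sizes`` plus the gold standard (clipped to the census when it
    exceeds 2*N_e), and relative power power(n)/power(gold) is reported.
    """
    if sizes is None:
        sizes = [12, 14]
    rows = []
    for i, tau in enumerate(taus):
        df = replicate_statistics(params, int(tau), list(sizes) + [gold],
                                  [statistic], replicates, seed + 7919 * i)
        gold_eff = min(gold, 2 * params.N_e)
        powers = {}
        for n, sub in df.groupby("n"):
            powers[n], _ = power_from_values(sub["obs"].to_numpy(),
                                             sub["null"].to_numpy(), fpr)
        for n in sorted(powers):
            rel = powers[n] / powers[gold_eff] if powers[gold_eff] > 0 else float("nan")
            rows.append({"statistic": statistic, "tau": int(tau), "n": int(n),
                         "power": powers[n], "gold_n": gold_eff,
                         "relative_power": rel})
    return pd.DataFrame(rows)
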