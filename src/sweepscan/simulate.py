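"""Synthetic populations: neutral sources, splits, and forward evolution.

The study design being emulated: a neutral-equilibrium source population
of N_e diploids is sampled with replacement into three populations —
``study``, ``cont1`` and ``cont2`` — which then evolve independently
under the Wright–Fisher model.  Only the study population carries a
locus under positive selection (homozygote fitness ∝ 1 + s); the two
controls evolve neutrally and provide both the comparison panel and the
null distribution for the tests.

The neutral source comes from a coalescent sampler at exact
mutation–drift equilibrium (the normative contract is the neutral site
frequency spectrum, E[#alleles at frequency f] ∝ theta/f); a forward
burn-in alternative is available.  Forward evolution uses an
infinite-sites model on continuous coordinates in [0, L), per-base
mutation and crossover rates, and codominant selection by default
(het fitness 1 + h·s with h = 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import msprime
import numpy as np

__all__ = [
    "SimParams",
    "SimPopulation",
    "BeneficialAlleleLost",
    "neutral_source",
    "split_populations",
    "evolve",
    "sample_haplotypes",
]


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters.

    Defaults are the full-scale study conditions: N_e = 1000 diploids,
    mu = 2.4e-7 and r = 3.784e-8 per base per generation over a 50 kbp
    region, selection coefficient s = 0.02 (codominant, h = 1/2).
    ``desk_scale`` rescales to N_e = 100 while preserving the population
    scaled rates 4*N_e*mu*L and 4*N_e*r*L, the strength of selection
    2*N_e*s, and time in units of N_e generations.
    """

    N_e: int = 1000
    mu: float = 2.4e-7
    r: float = 3.784e-8
    s: float = 0.02
    h: float = 0.5
    L: float = 50_000.0
    replicates: int = 200

    def __post_init__(self):
        if self.N_e < 2:
            raise ValueError("N_e must be >= 2")
        if min(self.mu, self.r, self.L) < 0 or self.s < 0:
            raise ValueError("rates must be non-negative")

    @property
    def theta_region(self) -> float:
        """4 * N_e * mu * L, the region-wide scaled mutation rate."""
        return 4.0 * self.N_e * self.mu * self.L

    @property
    def rho_region(self) -> float:
        return 4.0 * self.N_e * self.r * self.L

    def desk_scale(self, N_e: int = 100, L: float = 10_000.0) -> "SimParams":
        """Rescaled parameters for desk-size experiments.

        mu and r preserve theta_region and rho_region; s preserves
        2*N_e*s.  Generation counts at full scale should be divided by
        the same factor N_e_full / N_e when used with these parameters.
        """
        factor = self.N_e / N_e
        return replace(
            self, N_e=N_e, L=L,
            mu=self.theta_region / (4.0 * N_e * L),
            r=self.rho_region / (4.0 * N_e * L),
            s=self.s * factor,
        )

    def scale_time(self, generations_full_scale: float, N_e_full: int = 1000) -> int:
        """Convert a full-scale generation count to this parameter set."""
        return max(1, int(round(generations_full_scale * self.N_e / N_e_full)))


class BeneficialAlleleLost(RuntimeError):
    """Raised internally when the selected allele drifts out; triggers restart."""


@dataclass
class SimPopulation:
    """Haplotype matrix over segregating positions.

    ``haplotypes`` is a (2*N, S) 0/1 array; rows 2i and 2i+1 form diploid
    individual i.  ``positions`` are continuous coordinates in [0, L),
    strictly increasing.  ``selected_pos`` marks the site under
    selection, if any; once it fixes the column is purged and
    ``selected_fixed_at`` records the generation.

    Monomorphic columns are purged every generation, but positions whose
    *derived* allele fixed are remembered in ``fixed_positions``: for
    cross-population comparisons a fixed derived allele (count 2N) is a
    fixed difference, not an absent one, and erasing it would blind the
    divergence statistics to the strongest sweep signature.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    generation: int = 0
    selected_pos: float | None = None
    selected_origin: int | None = None
    selected_fixed_at: int | None = None
    restarts: int = 0
    fixed_positions: np.ndarray | None = None

    def __post_init__(self):
        if self.fixed_positions is None:
            self.fixed_positions = np.zeros(0, dtype=float)

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def allele_counts(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0)

    def selected_count(self) -> int:
        """Copies of the beneficial allele (2N if fixed, 0 if absent)."""
        if self.selected_fixed_at is not None:
            return self.n_hap
        if self.selected_pos is None:
            return 0
        j = int(np.searchsorted(self.positions, self.selected_pos))
        if j < self.n_sites and self.positions[j] == self.selected_pos:
            return int(self.haplotypes[:, j].sum())
        return 0

    def copy(self) -> "SimPopulation":
        return SimPopulation(self.haplotypes.copy(), self.positions.copy(),
                             self.generation, self.selected_pos,
                             self.selected_origin, self.selected_fixed_at,
                             self.restarts, self.fixed_positions.copy())


def _purge_monomorphic(pop: SimPopulation) -> None:
    counts = pop.haplotypes.sum(axis=0)
    keep = (counts > 0) & (counts < pop.n_hap)
    if pop.selected_pos is not None and pop.selected_fixed_at is None:
        j = int(np.searchsorted(pop.positions, pop.selected_pos))
        present = j < pop.n_sites and pop.positions[j] == pop.selected_pos
        if present:
            if counts[j] == 0:
                raise BeneficialAlleleLost
            if counts[j] == pop.n_hap:
                pop.selected_fixed_at = pop.generation
        else:
            raise BeneficialAlleleLost
    if not keep.all():
        newly_fixed = pop.positions[counts == pop.n_hap]
        if len(newly_fixed):
            pop.fixed_positions = np.sort(
                np.concatenate([pop.fixed_positions, newly_fixed]))
        pop.haplotypes = pop.haplotypes[:, keep]
        pop.positions = pop.positions[keep]


def neutral_source(params: SimParams, seed: int, method: str = "coalescent",
                   burnin_generations: int | None = None) -> SimPopulation:
    """Draw a source population of 2*N_e haplotypes at neutral equilibrium.

    ``method="coalescent"`` (default) samples the whole population from a
    coalescent with recombination and infinite-sites mutations.
    ``method="forward"`` runs a neutral forward burn-in (>= 10*N_e
    generations by default) from a monomorphic start — slower, provided
    as an independent route to the same equilibrium contract.
    """
    if method == "forward":
        pop = SimPopulation(
            haplotypes=np.zeros((2 * params.N_e, 0), dtype=np.uint8),
            positions=np.zeros(0, dtype=float),
        )
        gens = burnin_generations or 10 * params.N_e
        neutral = replace(params, s=0.0)
        rng = np.random.default_rng(seed)
        return evolve(pop, neutral, gens, selected=False, rng=rng)
    if method != "coalescent":
        raise ValueError(f"unknown method {method!r}")
    seed = int(seed) % (2**31 - 2) + 1
    ts = msprime.sim_ancestry(
        samples=params.N_e, population_size=params.N_e, ploidy=2,
        sequence_length=params.L, recombination_rate=params.r,
        discrete_genome=False, random_seed=seed,
    )
    ts = msprime.sim_mutations(ts, rate=params.mu, discrete_genome=False,
                               model=msprime.BinaryMutationModel(),
                               random_seed=seed + 1)
    g = ts.genotype_matrix()  # (sites, 2N); binary model can revisit: clip
    hap = np.ascontiguousarray((g.T > 0).astype(np.uint8))
    positions = np.array([s.position for s in ts.sites()], dtype=float)
    pop = SimPopulation(haplotypes=hap, positions=positions)
    _purge_monomorphic(pop)
    return pop


def split_populations(source: SimPopulation, rng: np.random.Generator,
                      n_populations: int = 3) -> tuple[SimPopulation, ...]:
    """Sample with replacement from the source into daughter populations.

    Each daughter receives 2*N_e haplotypes drawn with replacement
    (individual haplotypes, emulating a large panmictic founding draw).
    """
    out = []
    for _ in range(n_populations):
        rows = rng.integers(0, source.n_hap, size=source.n_hap)
        pop = SimPopulation(haplotypes=source.haplotypes[rows].copy(),
                            positions=source.positions.copy(),
                            fixed_positions=source.fixed_positions.copy())
        _purge_monomorphic(pop)
        out.append(pop)
    return tuple(out)


def _inject_beneficial(pop: SimPopulation, params: SimParams,
                       rng: np.random.Generator,
                       standing_freq: float | None) -> None:
    """Place the beneficial allele: de novo single copy at the region
    midpoint, or mark an existing allele near ``standing_freq``."""
    if standing_freq is not None:
        counts = pop.allele_counts()
        if pop.n_sites:
            target = standing_freq * pop.n_hap
            j = int(np.argmin(np.abs(counts - target)))
            pop.selected_pos = float(pop.positions[j])
            pop.selected_origin = pop.generation
            return
        # no standing variation available: fall through to de novo
    pos = params.L / 2.0
    carrier = int(rng.integers(0, pop.n_hap))
    col = np.zeros((pop.n_hap, 1), dtype=np.uint8)
    col[carrier, 0] = 1
    j = int(np.searchsorted(pop.positions, pos))
    pop.haplotypes = np.concatenate(
        [pop.haplotypes[:, :j], col, pop.haplotypes[:, j:]], axis=1)
    pop.positions = np.insert(pop.positions, j, pos)
    pop.selected_pos = pos
    pop.selected_origin = pop.generation


def _wright_fisher_generation(pop: SimPopulation, params: SimParams,
                              rng: np.random.Generator, selected: bool) -> None:
    H = pop.haplotypes
    n_hap = H.shape[0]
    n_ind = n_hap // 2

    # fitness of parents
    if selected and pop.selected_pos is not None and pop.selected_fixed_at is None:
        j = int(np.searchsorted(pop.positions, pop.selected_pos))
        carriers = H[:, j].reshape(n_ind, 2).sum(axis=1)
        w = 1.0 + np.where(carriers == 2, params.s,
                           np.where(carriers == 1, params.h * params.s, 0.0))
        p = w / w.sum()
        parents = rng.choice(n_ind, size=n_hap, p=p)
    else:
        parents = rng.integers(0, n_ind, size=n_hap)

    start = rng.integers(0, 2, size=n_hap)
    n_cross = rng.poisson(params.r * params.L, size=n_hap)
    gametes = H[2 * parents + start]  # no-crossover meiosis for everyone
    for g in np.flatnonzero(n_cross):
        points = np.sort(rng.uniform(0.0, params.L, size=n_cross[g]))
        phase = (np.searchsorted(points, pop.positions) + start[g]) % 2
        a = H[2 * parents[g]]
        b = H[2 * parents[g] + 1]
        gametes[g] = np.where(phase == 0, a, b)

    # infinite-sites mutation on continuous coordinates
    n_mut = rng.poisson(params.mu * params.L * n_hap)
    if n_mut:
        new_pos = rng.uniform(0.0, params.L, size=n_mut)
        rows = rng.integers(0, n_hap, size=n_mut)
        block = np.zeros((n_hap, n_mut), dtype=np.uint8)
        block[rows, np.arange(n_mut)] = 1
        all_pos = np.concatenate([pop.positions, new_pos])
        order = np.argsort(all_pos, kind="mergesort")
        pop.positions = all_pos[order]
        pop.haplotypes = np.concatenate([gametes, block], axis=1)[:, order]
    else:
        pop.haplotypes = gametes
    pop.generation += 1
    _purge_monomorphic(pop)


def evolve(pop: SimPopulation, params: SimParams, generations: int,
           selected: bool = False, rng: np.random.Generator | None = None,
           standing_freq: float | None = None,
           max_restarts: int = 10_000) -> SimPopulation:
    """Evolve a population for ``generations`` Wright–Fisher generations.

    With ``selected=True`` a beneficial allele is placed at the start
    (de novo single copy at the region midpoint, or standing variation
    near ``standing_freq``) and genotype fitnesses are
    1 : 1 + h*s : 1 + s.  Replicates in which the allele is lost restart
    from the initial state with fresh randomness (conditioning on
    establishment); the restart count is recorded on the result.
    """
    if rng is None:
        rng = np.random.default_rng()
    initial = pop.copy()
    restarts = 0
    while True:
        cur = initial.copy()
        if selected and cur.selected_pos is None:
            _inject_beneficial(cur, params, rng, standing_freq)
        try:
            for _ in range(generations):
                _wright_fisher_generation(cur, params, rng, selected)
            cur.restarts = restarts
            return cur
        except BeneficialAlleleLost:
            restarts += 1
            if restarts > max_restarts:
                raise RuntimeError(
                    f"beneficial allele lost in {max_restarts} consecutive attempts")


def sample_haplotypes(pop: SimPopulation, n: int, rng: np.random.Generator):
    """Without-replacement sample of ``n`` haplotypes.

    Returns ``(positions, alt_counts)`` restricted to sites segregating
    in the full population (the sample's own fixed sites keep counts 0/n
    and are retained so cross-population alignment stays simple).
    ``n == 2*N_e`` returns the exact population counts.
    """
    if n > pop.n_hap:
        raise ValueError(f"cannot sample {n} haplotypes from {pop.n_hap}")
    if n == pop.n_hap:
        return pop.positions.copy(), pop.allele_counts().astype(np.int64)
    rows = rng.choice(pop.n_hap, size=n, replace=False)
    return pop.positions.copy(), pop.haplotypes[rows].sum(axis=0).astype(np.int64)
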