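"""Candidate-region prioritization by frequency-block differentials.

Significant scan windows are merged into maximal candidate regions, and
each region is pushed through four criteria, in order:

1. A frequency block — >= 10 SNPs near a common study-population
   frequency f — whose mean frequency differs from the *closer* of the
   two primary lowlander controls by more than the 95% sampling CI
   half-width at the study sample size.
2. The same differential test against *every* additional control panel.
3. Refinement with an external genotyping study: the block frequency is
   replaced by the sample-size-weighted average over both studies, and
   the revised differential must exceed 10% against all controls.
4. Overlap with at least one annotated transcript.

Each criterion can only shrink the surviving set; a region is
"prioritized" iff all four pass.  Regions that a criterion cannot
evaluate (no overlapping panel or external sites) are carried forward
flagged rather than silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class FrequencyBlock:
    """A run of SNPs near a common study frequency.

    ``f`` is the grid frequency (k/n); ``positions`` the member sites;
    ``mean_freq`` the observed mean study frequency over members.
    """

    f: float
    chrom: str
    positions: np.ndarray
    mean_freq: float
    n_hap: int

    @property
    def n_members(self) -> int:
        return len(self.positions)


@dataclass
class CandidateRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    tests: list[str] = field(default_factory=list)
    block: FrequencyBlock | None = None
    criteria: dict[str, object] = field(default_factory=dict)
    genes: list[str] = field(default_factory=list)

    @property
    def prioritized(self) -> bool:
        flags = [self.criteria.get(k) for k in
                 ("differential", "panels", "external", "transcript")]
        return all(f is True or f == "not_evaluable" for f in flags) and \
            any(f is True for f in flags)


def merge_windows(significant: pd.DataFrame, gap: int = 0) -> list[CandidateRegion]:
    """Union overlapping/adjacent significant windows into regions.

    Windows whose intervals overlap or lie within ``gap`` bp of each
    other merge; the statistics that triggered any member window are
    recorded on the region.
    """
    sig = significant[significant["significant"]].sort_values(["chrom", "start"])
    regions: list[CandidateRegion] = []
    for row in sig.itertuples(index=False):
        tests = [s for s in ("s_f", "s_pi", "fst", "pbs")
                 if getattr(row, f"sig_{s}", False)]
        if regions and regions[-1].chrom == row.chrom and \
                row.start <= regions[-1].end + gap + 1:
            regions[-1].end = max(regions[-1].end, row.end)
            regions[-1].tests = sorted(set(regions[-1].tests) | set(tests))
        else:
            regions.append(CandidateRegion(str(row.chrom), int(row.start),
                                           int(row.end), tests=sorted(set(tests))))
    return regions


def find_frequency_blocks(positions, freqs, n_hap: int, min_block: int = 10,
                          genome_consecutive: bool = False) -> list[FrequencyBlock]:
    """Find runs of SNPs near a common frequency on the grid k/n.

    For each grid frequency f = 1/n .. (n-1)/n, sites with
    |freq - f| <= 1/n are selected; maximal runs of >= ``min_block``
    consecutive sites form blocks.  By default "consecutive" means
    consecutive within the f-selected subsequence (sites at other
    frequencies in between do not break a block — post-sweep de novo
    singletons inside a swept haplotype must not fragment it); with
    ``genome_consecutive=True`` intervening sites break runs.  Blocks
    duplicated across adjacent f values are de-duplicated by member-set
    identity, keeping the most-member (then lowest-f) block.
    """
    positions = np.asarray(positions)
    freqs = np.asarray(freqs, dtype=float)
    order = np.argsort(positions, kind="mergesort")
    positions, freqs = positions[order], freqs[order]
    best: dict[frozenset, FrequencyBlock] = {}
    for k in range(1, n_hap):
        f = k / n_hap
        sel = np.abs(freqs - f) <= 1.0 / n_hap + 1e-12
        idx = np.flatnonzero(sel)
        if len(idx) < min_block:
            continue
        if genome_consecutive:
            breaks = np.flatnonzero(np.diff(idx) != 1)
            runs = np.split(idx, breaks + 1)
        else:
            runs = [idx]
        for run in runs:
            if len(run) < min_block:
                continue
            members = frozenset(positions[run].tolist())
            blk = FrequencyBlock(f=f, chrom="", positions=positions[run],
                                 mean_freq=float(freqs[run].mean()), n_hap=n_hap)
            prev = best.get(members)
            # identical member set at adjacent f: label with the grid f
            # closest to the members' mean frequency (ties -> lower f)
            if prev is None or abs(blk.f - blk.mean_freq) < abs(prev.f - prev.mean_freq):
                best[members] = blk
    # overlapping grid values can yield nested member sets; keep maximal blocks
    blocks = sorted(best.values(), key=lambda b: (-b.n_members, b.f))
    kept: list[FrequencyBlock] = []
    seen: list[frozenset] = []
    for b in blocks:
        mem = frozenset(b.positions.tolist())
        if any(mem < s for s in seen):
            continue
        kept.append(b)
        seen.append(mem)
    return kept


def block_differential(block: FrequencyBlock,
                       control_freqs: dict[str, pd.DataFrame]) -> tuple[float, dict]:
    """Absolute mean-frequency difference to the *closer* control.

    ``control_freqs`` maps a control label to a per-site frequency frame
    with columns (pos, freq); member sites absent from a control are
    excluded pairwise for that control (logged).  Returns
    ``(min over controls of |mean_study - mean_control|, per-control means)``.
    """
    diffs = {}
    means = {}
    member = set(block.positions.tolist())
    for label, table in control_freqs.items():
        sub = table[table["pos"].isin(member)]
        if len(sub) == 0:
            logger.warning("block_differential: control %r covers no member sites", label)
            continue
        if len(sub) < block.n_members:
            logger.info("block_differential: control %r missing %d member sites",
                        label, block.n_members - len(sub))
        m_ctrl = float(sub["freq"].mean())
        means[label] = m_ctrl
        diffs[label] = abs(block.mean_freq - m_ctrl)
    if not diffs:
        return float("nan"), means
    return min(diffs.values()), means


def sampling_ci_threshold(n_hap: int, f: float, level: float = 0.95) -> float:
    """Minimum believable differential at sample size ``n_hap``.

    The half-width of the central exact-binomial interval of the observed
    frequency when drawing ``n_hap`` haplotypes from a population at true
    frequency ``f``: differences inside it are explainable by sampling
    alone.  For X-chromosome regions callers should pass the halved
    haplotype count (the threshold roughly doubles at intermediate f).
    """
    if n_hap < 2:
        raise ValueError("n_hap must be >= 2")
    if not 0.0 < f < 1.0:
        raise ValueError("f must be in (0, 1)")
    lo0, hi0 =(int(v) for v in sps.binom.interval(level, n_hap, f))
    # the guaranteed-coverage equal-tail interval overshoots badly at small
    # n; among it and its one-step shrinkages pick the central set whose
    # exact coverage is closest to the requested level (ties -> wider)
    best = None
    for lo in (lo0, lo0 + 1):
        for hi in (hi0 - 1, hi0):
            if lo > hi:
                continue
            cov = sps.binom.cdf(hi, n_hap, f) - sps.binom.cdf(lo - 1, n_hap, f)
            key = (abs(cov - level), -cov)
            if best is None or key < best[0]:
                best = (key, lo, hi)
    _, lo, hi = best
    return float(max(f - lo / n_hap, hi / n_hap - f))


def check_against_panels(block: FrequencyBlock,
                         panels: dict[str, pd.DataFrame],
                         threshold: float) -> tuple[object, dict]:
    """Pass iff the block differential exceeds ``threshold`` vs every panel.

    Panels with no member-site overlap are skipped with a warning; if no
    panel overlaps at all the criterion is not evaluable and the region
    is carried forward flagged.
    """
    member = set(block.positions.tolist())
    results = {}
    for label, table in panels.items():
        sub = table[table["pos"].isin(member)]
        if len(sub) == 0:
            logger.warning("check_against_panels: panel %r covers no member sites", label)
            continue
        results[label] = abs(block.mean_freq - float(sub["freq"].mean())) > threshold
    if not results:
        return "not_evaluable", results
    return all(results.values()), results


def refine_with_external(f_internal: float, n_internal: int,
                         f_external: float, n_external: int) -> float:
    """Sample-size-weighted average of internal and external frequencies.

    A convex combination: the revised frequency always lies between the
    two inputs.  ``n_external = 0`` leaves the frequency unchanged.
    """
    if n_internal <= 0:
        raise ValueError("n_internal must be positive")
    if n_external < 0:
        raise ValueError("n_external must be non-negative")
    if n_external == 0:
        return float(f_internal)
    return float((n_internal * f_internal + n_external * f_external)
                 / (n_internal + n_external))


def external_refinement_check(block: FrequencyBlock,
                              external: pd.DataFrame | None,
                              n_external: int,
                              controls: dict[str, pd.DataFrame],
                              min_differential: float = 0.10):
    """Criterion 3: revised differential > ``min_differential`` vs all controls.

    ``external`` is a per-site frequency frame from the larger genotyping
    cohort; only member sites it covers enter the weighted average.
    Regions with no overlapping external sites are unaffected (flagged
    not_evaluable, carried forward).
    """
    member = set(block.positions.tolist())
    if external is None:
        return "not_evaluable", block.mean_freq
    sub = external[external["pos"].isin(member)]
    if len(sub) == 0 or n_external == 0:
        return "not_evaluable", block.mean_freq
    f_ext = float(sub["freq"].mean())
    revised = refine_with_external(block.mean_freq, block.n_hap, f_ext, n_external)
    ok = True
    for label, table in controls.items():
        csub = table[table["pos"].isin(member)]
        if len(csub) == 0:
            continue
        if abs(revised - float(csub["freq"].mean())) <= min_differential:
            ok = False
    return ok, revised


def read_transcripts_bed(path: str) -> pd.DataFrame:
    """Read transcript annotations from BED (chrom, start, end[, name])."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else "."))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def read_transcripts_gtf(path: str, feature: str = "transcript") -> pd.DataFrame:
    """Read transcript intervals from a GTF, extracting gene names.

    Returns the same (chrom, start, end, name) frame as the BED reader,
    with start converted to 0-based half-open.
    """
    import re
    rows = []
    pat = re.compile(r'gene_name "([^"]+)"|gene_id "([^"]+)"')
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != feature:
                continue
            m = pat.search(f[8])
            name = (m.group(1) or m.group(2)) if m else "."
            rows.append((f[0], int(f[3]) - 1, int(f[4]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def transcript_overlap(region: CandidateRegion,
                       transcripts: pd.DataFrame) -> tuple[bool, list[str]]:
    """Pass iff >= 1 transcript overlaps the region by >= 1 bp.

    Transcripts use BED coordinates (0-based half-open); the region is
    1-based inclusive.  Abutting without overlap does not count.
    """
    tree = IntervalTree()
    for row in transcripts[transcripts["chrom"] == region.chrom].itertuples(index=False):
        if row.end > row.start:
            tree.addi(row.start, row.end, row.name)
    hits = tree.overlap(region.start - 1, region.end)
    genes = sorted({iv.data for iv in hits})
    return bool(hits), genes


def enrichment_test(tested: int, hits: int, background_tested: int,
                    background_hits: int) -> float:
    """One-sided Fisher exact (hypergeometric upper tail) on the 2x2 table.

    Probability of observing >= ``hits`` successes when drawing
    ``tested`` items from a pool of ``tested + background_tested`` items
    containing ``hits + background_hits`` successes.
    """
    if not (0 <= hits <= tested and 0 <= background_hits <= background_tested):
        raise ValueError("hit counts must not exceed tested counts")
    total = tested + background_tested
    successes = hits + background_hits
    return float(sps.hypergeom.sf(hits - 1, total, successes, tested))


def prioritize_regions(regions: list[CandidateRegion],
                       study_freqs: pd.DataFrame,
                       n_hap: int,
                       primary_controls: dict[str, pd.DataFrame],
                       extra_panels: dict[str, pd.DataFrame] | None = None,
                       external: pd.DataFrame | None = None,
                       n_external: int = 0,
                       transcripts: pd.DataFrame | None = None,
                       min_block: int = 10,
                       min_differential: float = 0.10,
                       ci_level: float = 0.95) -> list[CandidateRegion]:
    """Apply the four prioritization criteria in order to each region.

    ``study_freqs`` is the study panel's (chrom, pos, freq) frame.  Each
    criterion records True/False/"not_evaluable" under
    ``region.criteria``; once a region fails a criterion, later criteria
    are not evaluated (monotone narrowing).
    """
    extra_panels = extra_panels or {}
    for region in regions:
        sub = study_freqs[(study_freqs["chrom"] == region.chrom)
                          & (study_freqs["pos"] >= region.start)
                          & (study_freqs["pos"] <= region.end)]
        blocks = find_frequency_blocks(sub["pos"].to_numpy(), sub["freq"].to_numpy(),
                                       n_hap, min_block=min_block)
        # criterion 1: differential vs closer primary control, per block;
        # keep the best-differential qualifying block
        best = None
        best_diff = -np.inf
        for blk in blocks:
            blk.chrom = region.chrom
            diff, _ = block_differential(blk, primary_controls)
            if np.isnan(diff):
                continue
            thr = sampling_ci_threshold(n_hap, min(max(blk.mean_freq, 1 / n_hap),
                                                   1 - 1 / n_hap), ci_level)
            if diff > thr and diff > best_diff:
                best, best_diff = blk, diff
        region.block = best
        region.criteria["differential"] = best is not None
        if best is None:
            continue
        thr = sampling_ci_threshold(n_hap, min(max(best.mean_freq, 1 / n_hap),
                                               1 - 1 / n_hap), ci_level)
        # criterion 2: vs all extra panels
        if extra_panels:
            ok, per_panel = check_against_panels(best, extra_panels, thr)
        else:
            ok, per_panel = "not_evaluable", {}
        region.criteria["panels"] = ok
        if ok is False:
            continue
        # criterion 3: external refinement
        ok3, revised = external_refinement_check(best, external, n_external,
                                                 {**primary_controls, **extra_panels},
                                                 min_differential)
        region.criteria["external"] = ok3
        region.criteria["revised_freq"] = revised
        if ok3 is False:
            continue
        # criterion 4: transcript overlap
        if transcripts is not None:
            ok4, genes = transcript_overlap(region, transcripts)
            region.criteria["transcript"] = ok4
            region.genes = genes
        else:
            region.criteria["transcript"] = "not_evaluable"
    return regions


def regions_to_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append({
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "tests": ",".join(r.tests),
            "block_f": r.block.f if r.block else np.nan,
            "block_size": r.block.n_members if r.block else 0,
            "block_mean_freq": r.block.mean_freq if r.block else np.nan,
            "crit_differential": r.criteria.get("differential"),
            "crit_panels": r.criteria.get("panels"),
            "crit_external": r.criteria.get("external"),
            "crit_transcript": r.criteria.get("transcript"),
            "revised_freq": r.criteria.get("revised_freq", np.nan),
            "genes": ",".join(r.genes),
            "prioritized": r.prioritized,
        })
    return pd.DataFrame(rows)
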