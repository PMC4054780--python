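"""Sliding-window genome scan for the four cross-population statistics.

Windows are 50 kbp sliding at 2 kbp by default.  Each window with enough
segregating sites receives theta_f and theta_pi for the study and control
panels, the log-ratio statistics S_f and S_pi, the Hudson F_st between
study and control (ratio-of-sums across the window's sites), and —
when an outgroup panel is supplied — the population branch statistic.
Per-statistic significance cutoffs are the empirical top-q genome-wide
quantile (default q = 0.1%) over finite window values; +inf sentinel
windows (zero study diversity) cannot anchor a quantile but are always
flagged significant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import stats
from .sites import SiteTable

STATISTICS = ["s_f", "s_pi", "fst", "pbs"]


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive


def make_windows(chrom_lengths: dict[str, int], window: int = 50_000,
                 step: int = 2_000) -> list[Window]:
    """Tile chromosomes with sliding windows.

    Full windows start at 1, 1+step, ... while they fit.  A chromosome
    shorter than one window yields a single truncated window; otherwise a
    final truncated window is emitted only when the uncovered tail beyond
    the last full window is at least one step long.
    """
    if step > window:
        raise ValueError(f"step ({step}) must not exceed window ({window})")
    if step < 1 or window < 1:
        raise ValueError("window and step must be positive")
    out: list[Window] = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r}: non-positive length {length}")
        chrom = str(chrom)
        if length < window:
            out.append(Window(chrom, 1, int(length)))
            continue
        start = 1
        while start + window - 1 <= length:
            out.append(Window(chrom, start, start + window - 1))
            start += step
        last_end = out[-1].end
        if length - last_end >= step:
            out.append(Window(chrom, start, int(length)))
    return out


def _window_index(pos: np.ndarray, windows: list[Window], chrom: str):
    """Yield (window_i, site_index_array) for windows on one chromosome."""
    for i, w in enumerate(windows):
        if w.chrom != chrom:
            continue
        lo = np.searchsorted(pos, w.start, side="left")
        hi = np.searchsorted(pos, w.end, side="right")
        yield i, np.arange(lo, hi)


def scan(table: SiteTable, roles: dict[str, str], windows: list[Window],
         min_sites: int = 10) -> pd.DataFrame:
    """Compute per-window statistics for a study/control(/outgroup) trio.

    ``roles`` maps {"study": label, "control": label, "outgroup": label};
    the outgroup is optional (PBS is NaN without it).  Panels must share a
    site universe: statistics are computed on the intersection of the
    panels' positions (a site missing from one panel cannot be compared).
    Caller-rejected sites are excluded.

    Returns one row per window: chrom, start, end, n_sites, theta
    estimates, the four statistics, and a ``sufficient`` flag (windows
    with fewer than ``min_sites`` segregating sites get NaN statistics).
    """
    study = roles["study"]
    control = roles["control"]
    outgroup = roles.get("outgroup")
    labels = [study, control] + ([outgroup] if outgroup else [])

    frames = {}
    for lab in labels:
        df = table.panels[lab]
        frames[lab] = df[~df["caller_filtered"]][["chrom", "pos", "alt_count", "n_hap"]]

    # shared site universe = intersection of positions across panels
    keys = None
    for lab in labels:
        k = frames[lab].set_index(["chrom", "pos"]).index
        keys = k if keys is None else keys.intersection(k)
    aligned = {lab: frames[lab].set_index(["chrom", "pos"]).loc[keys].reset_index()
               for lab in labels}

    n_windows = len(windows)
    cols = {
        "n_sites": np.zeros(n_windows, dtype=int),
        "theta_f_study": np.full(n_windows, np.nan),
        "theta_f_control": np.full(n_windows, np.nan),
        "theta_pi_study": np.full(n_windows, np.nan),
        "theta_pi_control": np.full(n_windows, np.nan),
        "s_f": np.full(n_windows, np.nan),
        "s_pi": np.full(n_windows, np.nan),
        "fst": np.full(n_windows, np.nan),
        "pbs": np.full(n_windows, np.nan),
        "sufficient": np.zeros(n_windows, dtype=bool),
    }

    base = aligned[study]
    for chrom in dict.fromkeys(base["chrom"]):
        sel = base["chrom"] == chrom
        pos = base.loc[sel, "pos"].to_numpy()
        counts = {lab: aligned[lab].loc[sel, "alt_count"].to_numpy() for lab in labels}
        nhap = {lab: int(aligned[lab].loc[sel, "n_hap"].iloc[0]) for lab in labels}
        freqs = {lab: counts[lab] / nhap[lab] for lab in labels}
        # restrict to sites segregating in at least one panel
        seg = np.zeros(len(pos), dtype=bool)
        for lab in labels:
            seg |= (counts[lab] > 0) & (counts[lab] < nhap[lab])
        for i, idx in _window_index(pos, windows, str(chrom)):
            idx = idx[seg[idx]]
            n = len(idx)
            cols["n_sites"][i] = n
            if n < min_sites:
                continue
            cols["sufficient"][i] = True
            cs, cc = counts[study][idx], counts[control][idx]
            tf_s = stats.theta_f(cs, nhap[study])
            tf_c = stats.theta_f(cc, nhap[control])
            tp_s = stats.theta_pi(cs, nhap[study])
            tp_c = stats.theta_pi(cc, nhap[control])
            cols["theta_f_study"][i] = tf_s
            cols["theta_f_control"][i] = tf_c
            cols["theta_pi_study"][i] = tp_s
            cols["theta_pi_control"][i] = tp_c
            cols["s_f"][i] = stats._log_ratio(tf_c, tf_s)
            cols["s_pi"][i] = stats._log_ratio(tp_c, tp_s)
            f_sc = stats.hudson_fst(freqs[study][idx], freqs[control][idx],
                                    nhap[study], nhap[control])
            cols["fst"][i] = f_sc
            if outgroup:
                f_so = stats.hudson_fst(freqs[study][idx], freqs[outgroup][idx],
                                        nhap[study], nhap[outgroup])
                f_co = stats.hudson_fst(freqs[control][idx], freqs[outgroup][idx],
                                        nhap[control], nhap[outgroup])
                cols["pbs"][i] = stats.pbs(stats.branch_length(f_sc),
                                           stats.branch_length(f_so),
                                           stats.branch_length(f_co))

    out = pd.DataFrame({
        "chrom": [w.chrom for w in windows],
        "start": [w.start for w in windows],
        "end": [w.end for w in windows],
        **cols,
    })
    return out


def genomewide_cutoff(window_stats: pd.DataFrame, quantile: float = 0.001,
                      statistics: list[str] | None = None) -> dict[str, float]:
    """Empirical top-``quantile`` genome-wide cutoff per statistic.

    +/-inf sentinels are excluded from the quantile (a zero-diversity
    window cannot anchor an empirical threshold) but infinite windows are
    still flagged by :func:`significant_windows`.
    """
    cutoffs: dict[str, float] = {}
    for stat in statistics or STATISTICS:
        vals = window_stats[stat].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            cutoffs[stat] = float("nan")
            continue
        cutoffs[stat] = float(np.quantile(vals, 1.0 - quantile))
    return cutoffs


def significant_windows(window_stats: pd.DataFrame, cutoffs: dict[str, float]) -> pd.DataFrame:
    """Annotate windows with per-statistic significance flags.

    A window is significant for a statistic when its (finite or +inf)
    value is >= the cutoff; +inf always qualifies.
    """
    out = window_stats.copy()
    for stat, cut in cutoffs.items():
        vals = out[stat].to_numpy(dtype=float)
        sig = np.zeros(len(out), dtype=bool)
        if np.isfinite(cut):
            sig = vals >= cut
        sig |= np.isposinf(vals)
        out[f"sig_{stat}"] = sig & out["sufficient"].to_numpy(dtype=bool)
    sig_cols = [f"sig_{s}" for s in cutoffs]
    out["significant"] = out[sig_cols].any(axis=1)
    return out


def read_bed(path: str) -> list[tuple[str, int, int]]:
    """Read BED intervals as (chrom, start, end), 0-based half-open."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def mask_trees(intervals) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        if end > start:
            trees.setdefault(str(chrom), IntervalTree()).addi(start, end)
    return trees


def apply_mask(table: SiteTable, intervals) -> SiteTable:
    """Restrict a table to sites inside BED intervals (0-based half-open)."""
    trees = mask_trees(intervals)
    out = table.copy()
    for label, df in out.panels.items():
        keep = np.array([
            bool(trees.get(str(c), IntervalTree())[p - 1])
            for c, p in zip(df["chrom"], df["pos"])
        ], dtype=bool) if len(df) else np.array([], dtype=bool)
        out.panels[label] = df[keep].reset_index(drop=True)
    return out


def masked_rescan(table: SiteTable, mask_intervals, roles: dict[str, str],
                  windows: list[Window], quantile: float = 0.001,
                  min_sites: int = 10):
    """Re-run the scan restricted to masked-in sites, recomputing cutoffs.

    Emulates what an exome-capture or genotyping-array study would see:
    both the statistics and the genome-wide cutoffs are recomputed using
    only the assayed sites.  Returns (window_stats, cutoffs).
    """
    masked = apply_mask(table, mask_intervals)
    ws = scan(masked, roles, windows, min_sites=min_sites)
    cutoffs = genomewide_cutoff(ws, quantile)
    return significant_windows(ws, cutoffs), cutoffs


def write_window_tsv(window_stats: pd.DataFrame, path: str) -> None:
    window_stats.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_significant_bed(window_stats: pd.DataFrame, path: str) -> None:
    sig = window_stats[window_stats.get("significant", False)]
    with open(path, "w") as fh:
        for row in sig.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\n")


def write_cutoffs_json(cutoffs: dict[str, float], path: str) -> None:
    with open(path, "w") as fh:
        json.dump(cutoffs, fh, indent=2)
        fh.write("\n")
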