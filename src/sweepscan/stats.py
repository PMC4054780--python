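"""Diversity estimators and cross-population selection statistics.

The scan is built on two estimators of the scaled mutation rate
theta = 4*Ne*mu summed over a genomic window:

* ``theta_pi`` — average pairwise heterozygosity (nucleotide diversity),
  with the small-sample correction n/(n-1);
* ``theta_f`` — the sum of non-fixed alternate-allele frequencies, which
  down-weights low-frequency alleles and therefore retains power long
  after a sweep has fixed.

A loss of diversity in a study population relative to a control is scored
by the log-ratios S_f = log(theta_f_control / theta_f_study) and
S_pi = log(theta_pi_control / theta_pi_study).  Frequency differentiation
is scored by Hudson's fixation index F_st = 1 - pi_w/pi_b, the derived
branch length T = -log(1 - F_st), and the population branch statistic
PBS = (T_SN + T_SO - T_NO)/2, which isolates the study population's
private branch against a close control (N) and a distant outgroup (O).

All logs are natural; windows where the study diversity is exactly zero
yield +inf sentinels (total diversity loss — the strongest sweep signal,
but unusable for quantile estimation).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "theta_pi",
    "theta_f",
    "s_statistics",
    "fst_components",
    "hudson_fst",
    "branch_length",
    "pbs",
]


def theta_pi(alt_counts, n_hap: int) -> float:
    """Average pairwise heterozygosity summed over sites.

    Parameters
    ----------
    alt_counts
        Alternate-allele counts (haplotypes), one per site.
    n_hap
        Total haplotypes genotyped (same for all sites).

    Returns
    -------
    float
        ``sum_sites 2*p*(1-p) * n/(n-1)`` with ``p = count/n_hap``.  This
        equals the mean number of pairwise differences over all
        ``C(n_hap, 2)`` haplotype pairs.  Fixed sites contribute zero.
    """
    if n_hap < 2:
        raise ValueError(f"theta_pi requires n_hap >= 2, got {n_hap}")
    c = np.asarray(alt_counts, dtype=float)
    if c.size == 0:
        return 0.0
    if c.min() < 0 or c.max() > n_hap:
        raise ValueError("allele counts must lie in [0, n_hap]")
    p = c / n_hap
    return float(np.sum(2.0 * p * (1.0 - p)) * n_hap / (n_hap - 1))


def theta_f(alt_counts, n_hap: int) -> float:
    """Summed non-fixed alternate-allele frequencies.

    Sites fixed for either allele (count 0 or ``n_hap``) are excluded;
    the remainder contribute ``count/n_hap`` each.
    """
    c = np.asarray(alt_counts, dtype=float)
    if c.size == 0:
        return 0.0
    seg = (c > 0) & (c < n_hap)
    return float(np.sum(c[seg]) / n_hap)


def _log_ratio(num: float, den: float) -> float:
    if den > 0 and num > 0:
        return float(np.log(num / den))
    if den == 0 and num > 0:
        return float("inf")
    if den > 0 and num == 0:
        return float("-inf")
    return float("nan")


def s_statistics(counts_study, counts_control, n_study: int, n_control: int):
    """(S_f, S_pi) log-ratio statistics for one window.

    Both panels must be evaluated on the shared post-filter site set.
    Returns +inf when the study diversity is zero but the control's is
    positive, and NaN when both are zero (undefined).
    """
    sf = _log_ratio(theta_f(counts_control, n_control), theta_f(counts_study, n_study))
    spi = _log_ratio(theta_pi(counts_control, n_control), theta_pi(counts_study, n_study))
    return sf, spi


def fst_components(p1, p2, n1: int, n2: int):
    """Per-site Hudson F_st components (pi_w, pi_b) as arrays.

    pi_w is the unweighted mean of the two within-panel heterozygosities,
    each with its n/(n-1) correction; pi_b = p1*(1-p2) + p2*(1-p1).
    Components are meant to be summed over a window before the ratio is
    formed (ratio-of-sums), which is the stable form of Hudson's
    estimator at low diversity.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = 2.0 * p1 * (1.0 - p1) * n1 / (n1 - 1)
    h2 = 2.0 * p2 * (1.0 - p2) * n2 / (n2 - 1)
    pi_w = 0.5 * (h1 + h2)
    pi_b = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return pi_w, pi_b


def hudson_fst(p1, p2, n1: int, n2: int) -> float:
    """Window-level Hudson F_st = 1 - sum(pi_w)/sum(pi_b) (ratio-of-sums).

    NaN when the between-population heterozygosity sums to zero (both
    panels monomorphic for the same allele at every site).
    """
    pi_w, pi_b = fst_components(p1, p2, n1, n2)
    sw, sb = float(np.sum(pi_w)), float(np.sum(pi_b))
    if sb == 0.0:
        return float("nan")
    return 1.0 - sw / sb


def branch_length(fst: float) -> float:
    """Divergence-time transform T = -log(1 - F_st); +inf at F_st >= 1."""
    if np.isnan(fst):
        return float("nan")
    if fst >= 1.0:
        return float("inf")
    return float(-np.log1p(-fst))


def pbs(t_sn: float, t_so: float, t_no: float) -> float:
    """Population branch statistic (T_SN + T_SO - T_NO) / 2.

    S = study, N = close control, O = outgroup.  May be negative
    (diversification on the control branches); reported as-is.
    """
    return (t_sn + t_so - t_no) / 2.0
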