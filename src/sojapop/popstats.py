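"""Sliding-window nucleotide diversity, Weir–Cockerham F_ST and pi-ratio.

Window grid: for a chromosome of length L, windows start at 0, step, 2*step,
... while start < L; the nominal span is ``window_bp`` (the last window may be
truncated by the chromosome end, but per-bp diversity is still normalized by
the nominal span, the usual fixed-window convention).  The identical grid is
used for every statistic so the pi and F_ST columns of a scan always align.

Windowed F_ST is the ratio-of-sums estimator sum(a) / sum(a+b+c) over the
per-site Weir–Cockerham (1984) variance components, the behaviour of
VCFtools ``--weir-fst-pop`` with windows.  Negative windowed values are
legitimate small-differentiation estimates and are retained: empirical-tail
sweep calling needs the full distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sojapop.errors import SojapopError
from sojapop.genotypes import MISSING, GenotypeMatrix


@dataclass
class ScanParams:
    window_bp: int = 500_000
    step_bp: int = 100_000
    min_snps_per_window: int = 10

    def __post_init__(self):
        if self.window_bp <= 0 or self.step_bp <= 0:
            raise SojapopError("window_bp and step_bp must be positive")
        if self.step_bp > self.window_bp:
            raise SojapopError("step_bp must not exceed window_bp")


def window_grid(chrom_lengths: dict, params: ScanParams) -> pd.DataFrame:
    rows = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + params.window_bp, int(length))))
            start += params.step_bp
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def site_pi(gm: GenotypeMatrix, sample_idx) -> np.ndarray:
    """Per-site unbiased heterozygosity 2*c_ref*c_alt / (n*(n-1)) over the
    non-missing allele counts of the chosen samples."""
    ref, alt = gm.allele_counts(sample_idx)
    n = ref + alt
    out = np.zeros(gm.n_sites)
    ok = n >= 2
    out[ok] = 2.0 * ref[ok] * alt[ok] / (n[ok] * (n[ok] - 1.0))
    return out


def site_wc_components(gm: GenotypeMatrix, idx_a, idx_b):
    """Per-site Weir–Cockerham (1984) variance components (a, b, c) for two
    populations, from sample sizes, allele frequencies and observed
    heterozygosity.  Sites lacking genotyped individuals in either population
    (or with nbar <= 1) contribute zeros."""
    d_a, d_b = gm.dosage[idx_a], gm.dosage[idx_b]
    comps = []
    for d in (d_a, d_b):
        obs = d != MISSING
        n_i = obs.sum(axis=0).astype(float)                 # genotyped individuals
        alt = np.where(obs, d, 0).sum(axis=0)
        het = np.where(obs, d == 1, False).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(n_i > 0, alt / (2.0 * np.maximum(n_i, 1)), 0.0)
            h_i = np.where(n_i > 0, het / np.maximum(n_i, 1), 0.0)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps

    valid = (n1 >= 1) & (n2 >= 1)
    nbar = (n1 + n2) / 2.0
    valid &= nbar > 1.0
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    valid &= nc > 0
    zero = ~valid
    for arr in (a, b, c):
        arr[zero] = 0.0
    return a, b, c


def _window_sums(gm: GenotypeMatrix, grid: pd.DataFrame, values: np.ndarray):
    """Sum per-site ``values`` (and count sites) inside each grid window."""
    sums = np.zeros(len(grid))
    counts = np.zeros(len(grid), dtype=int)
    chrom_arr = gm.sites["chrom"].to_numpy()
    pos0 = gm.sites["pos"].to_numpy() - 1     # 0-based
    for chrom, sub in grid.groupby("chrom", sort=False):
        on = np.flatnonzero(chrom_arr == chrom)
        p = pos0[on]
        csum = np.concatenate([[0.0], np.cumsum(values[on])])
        starts = sub["start"].to_numpy()
        lo = np.searchsorted(p, starts, side="left")
        hi = np.searchsorted(p, sub["end"].to_numpy(), side="left")
        sums[sub.index] = csum[hi] - csum[lo]
        counts[sub.index] = hi - lo
    return sums, counts


def window_pi(gm: GenotypeMatrix, group_samples, params: ScanParams | None = None,
              grid: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-window nucleotide diversity for one group of samples.

    Window pi is the sum of per-site pi divided by the nominal window span in
    bp, so monomorphic and absent sites contribute zero.
    """
    params = params or ScanParams()
    idx = gm.sample_index(group_samples)
    if len(idx) < 2:
        raise SojapopError("window_pi needs >= 2 samples in the group")
    sp = site_pi(gm, idx)
    if not sp.any():
        warnings.warn("group is monomorphic or lacks genotypes at every site; pi = 0")
    if grid is None:
        grid = window_grid(gm.chrom_lengths, params)
    sums, counts = _window_sums(gm, grid, sp)
    out = grid.copy()
    out["n_snps"] = counts
    out["pi"] = sums / params.window_bp
    return out


def window_fst(gm: GenotypeMatrix, group_a, group_b,
               params: ScanParams | None = None,
               grid: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-window ratio-of-sums Weir–Cockerham F_ST between two groups."""
    params = params or ScanParams()
    idx_a, idx_b = gm.sample_index(group_a), gm.sample_index(group_b)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise SojapopError("window_fst needs >= 2 samples per group")
    if set(idx_a) == set(idx_b):
        raise SojapopError("the two groups contain identical samples")
    a, b, c = site_wc_components(gm, idx_a, idx_b)
    if grid is None:
        grid = window_grid(gm.chrom_lengths, params)
    num, counts = _window_sums(gm, grid, a)
    den, _ = _window_sums(gm, grid, a + b + c)
    out = grid.copy()
    out["n_snps"] = counts
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fst"] = np.where(den != 0.0, num / np.where(den != 0.0, den, 1.0), np.nan)
    return out


def global_fst(gm: GenotypeMatrix, group_a, group_b) -> float:
    """Multilocus (genome-wide ratio-of-sums) Weir–Cockerham F_ST."""
    idx_a, idx_b = gm.sample_index(group_a), gm.sample_index(group_b)
    a, b, c = site_wc_components(gm, idx_a, idx_b)
    den = (a + b + c).sum()
    if den == 0:
        return float("nan")
    return float(a.sum() / den)


def scan_pair(gm: GenotypeMatrix, group_a, group_b,
              params: ScanParams | None = None) -> pd.DataFrame:
    """Joint per-window table: pi for both groups, F_ST, ln(pi_a/pi_b).

    Windows with fewer than ``min_snps_per_window`` sites, or with zero
    diversity in either group (log-ratio undefined), are flagged ``excluded``
    so downstream empirical-tail calling can skip them; their statistics are
    still reported where defined.
    """
    params = params or ScanParams()
    grid = window_grid(gm.chrom_lengths, params)
    pa = window_pi(gm, group_a, params, grid)
    pb = window_pi(gm, group_b, params, grid)
    fs = window_fst(gm, group_a, group_b, params, grid)
    out = grid.copy()
    out["n_snps"] = fs["n_snps"]
    out["pi_a"], out["pi_b"] = pa["pi"], pb["pi"]
    out["fst"] = fs["fst"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["log_pi_ratio"] = np.where(
            (pa["pi"] > 0) & (pb["pi"] > 0),
            np.log(np.where(pa["pi"] > 0, pa["pi"], 1.0)
                   / np.where(pb["pi"] > 0, pb["pi"], 1.0)),
            np.nan,
        )
    out["excluded"] = (
        (out["n_snps"] < params.min_snps_per_window)
        | (out["pi_a"] <= 0.0)
        | (out["pi_b"] <= 0.0)
        | out["fst"].isna()
    )
    return out
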