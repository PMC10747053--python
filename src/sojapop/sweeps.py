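"""Empirical-tail selective-sweep calling from windowed scan tables.

A window is a sweep candidate when it sits in the upper ``fst_tail`` of the
empirical F_ST distribution AND in either one-sided ``pi_tail`` of the
log pi-ratio distribution (diversity loss in one of the two groups).
Thresholds are empirical quantiles (linear interpolation, the common type-7
default) over the non-excluded windows of the comparison at hand; overlapping
or book-ended selected windows on one chromosome with the same direction are
merged into regions.  Windows from opposite pi tails are never merged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from sojapop.errors import SojapopError

#: direction labels: which group lost diversity
A_REDUCED = "a_reduced"   # log pi-ratio lower tail: pi_a << pi_b
B_REDUCED = "b_reduced"   # upper tail: pi_b << pi_a

REGION_COLUMNS = ["chrom", "start", "end", "n_windows", "direction",
                  "max_fst", "extreme_log_pi_ratio"]


def merge_windows(windows: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Merge overlapping/touching [start, end) windows per chromosome."""
    rows = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values(["start", "end"])
        cur = None
        for w in sub.itertuples():
            if cur is None or w.start > cur["end"]:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": chrom, "start": int(w.start), "end": int(w.end),
                       "n_windows": 1, "direction": direction,
                       "max_fst": w.fst, "extreme_log_pi_ratio": w.log_pi_ratio}
            else:
                cur["end"] = max(cur["end"], int(w.end))
                cur["n_windows"] += 1
                cur["max_fst"] = max(cur["max_fst"], w.fst)
                if abs(w.log_pi_ratio) > abs(cur["extreme_log_pi_ratio"]):
                    cur["extreme_log_pi_ratio"] = w.log_pi_ratio
        if cur is not None:
            rows.append(cur)
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def call_sweeps(windows: pd.DataFrame, fst_tail: float = 0.05,
                pi_tail: float = 0.05) -> pd.DataFrame:
    """Call sweep regions from a :func:`sojapop.popstats.scan_pair` table.

    Returns a region table (0-based half-open) with the diversity-loss
    direction, the number of merged windows and the extreme statistics.
    Thresholds used are attached as ``DataFrame.attrs['thresholds']``.
    """
    if not 0.0 < fst_tail < 1.0 or not 0.0 < pi_tail < 1.0:
        raise SojapopError("tail fractions must lie in (0, 1)")
    usable = windows.loc[~windows["excluded"].astype(bool)].copy()
    usable = usable.loc[np.isfinite(usable["fst"]) & np.isfinite(usable["log_pi_ratio"])]
    if usable.empty:
        warnings.warn("all windows excluded; no sweeps can be called")
        out = pd.DataFrame(columns=REGION_COLUMNS)
        out.attrs["thresholds"] = {}
        return out
    min_windows = 20.0 / min(fst_tail, pi_tail)
    if len(usable) < min_windows:
        warnings.warn(
            f"only {len(usable)} usable windows; empirical {min(fst_tail, pi_tail):.0%} "
            f"tails are unstable below ~{min_windows:.0f}"
        )
    fst_thr = float(np.quantile(usable["fst"], 1.0 - fst_tail))
    lpr = usable["log_pi_ratio"].to_numpy()
    lo_thr = float(np.quantile(lpr, pi_tail))
    hi_thr = float(np.quantile(lpr, 1.0 - pi_tail))

    in_fst = usable["fst"] >= fst_thr
    lower = usable.loc[in_fst & (usable["log_pi_ratio"] <= lo_thr)]
    upper = usable.loc[in_fst & (usable["log_pi_ratio"] >= hi_thr)]
    parts = [m for m in (merge_windows(lower, A_REDUCED),
                         merge_windows(upper, B_REDUCED)) if not m.empty]
    out = (pd.concat(parts, ignore_index=True) if parts
           else pd.DataFrame(columns=REGION_COLUMNS))
    out = out.sort_values(["chrom", "start", "direction"]).reset_index(drop=True)
    out.attrs["thresholds"] = {
        "fst_upper": fst_thr, "log_pi_ratio_lower": lo_thr,
        "log_pi_ratio_upper": hi_thr, "n_usable_windows": int(len(usable)),
    }
    return out


def overlaps_region(regions: pd.DataFrame, chrom, start, end) -> bool:
    """True when [start, end) on ``chrom`` overlaps any called region by >= 1 bp."""
    sub = regions.loc[regions["chrom"] == chrom]
    return bool(((sub["start"] < end) & (sub["end"] > start)).any())
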