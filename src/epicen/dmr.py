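"""Windowed methylation summaries and the suppressor hyper-DMR rule.

Total methylation in a fixed-grid window is the sum of the three
context-level weighted means (CG + CHG + CHH, each in [0, 1], so the total is
in [0, 3]). A window is a suppressor hyper-DMR when the quadruple mutant
retains less than 40% of the triple mutant's total level (retention < 0.4,
strict) and the suppressor recovers more than 60% of it (recovery > 0.6,
strict). DMRs shared by all suppressor lines are intersected on the window
grid and adjacent shared windows are merged into maximal runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meth_io import CONTEXTS

__all__ = [
    "window_methylation",
    "call_suppressor_dmrs",
    "intersect_dmrs",
    "boxplot_summary",
    "SharedDmrResult",
]

_LEVEL_COLS = [f"level_{c}" for c in CONTEXTS]


def window_methylation(calls: pd.DataFrame, width: int,
                       grid_origin: int = 0) -> pd.DataFrame:
    """Count-weighted methylation per fixed-grid window and context.

    Per window and context, level = sum(n_meth) / sum(n_total) over the
    cytosines of that context in the window. A context with no covered
    cytosines carries NaN; ``total_level`` is the sum over defined contexts.
    Only windows with at least one covered cytosine are emitted (sparse,
    but on a common grid across samples).
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    df = calls[calls["context"].isin(CONTEXTS)]
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", *_LEVEL_COLS,
                                     "total_level"])
    chrom_codes, chrom_index = pd.factorize(df["chrom"].to_numpy(), sort=True)
    win = (df["pos"].to_numpy() - grid_origin) // width
    span = int(win.max()) + 1
    key = chrom_codes.astype(np.int64) * span + win
    ukey, inv = np.unique(key, return_inverse=True)
    ctx_arr = df["context"].to_numpy()
    n_meth = df["n_meth"].to_numpy(float)
    n_total = df["n_total"].to_numpy(float)

    levels = np.full((ukey.size, len(CONTEXTS)), np.nan)
    for i, ctx in enumerate(CONTEXTS):
        m = ctx_arr == ctx
        meth = np.bincount(inv[m], weights=n_meth[m], minlength=ukey.size)
        tot = np.bincount(inv[m], weights=n_total[m], minlength=ukey.size)
        with np.errstate(invalid="ignore", divide="ignore"):
            levels[:, i] = np.where(tot > 0, meth / tot, np.nan)

    out = pd.DataFrame({"chrom": chrom_index[ukey // span],
                        "start": (ukey % span) * width + grid_origin})
    out["end"] = out["start"] + width
    for i, ctx in enumerate(CONTEXTS):
        out[f"level_{ctx}"] = levels[:, i]
    out["total_level"] = np.nansum(levels, axis=1)
    out.loc[np.isnan(levels).all(axis=1), "total_level"] = np.nan
    return (out.sort_values(["chrom", "start"], kind="stable")
            .reset_index(drop=True))


def _check_grid(*profiles: pd.DataFrame) -> int:
    widths: set[int] = set()
    offsets: set[int] = set()
    for p in profiles:
        if len(p) == 0:
            continue
        w = int((p["end"] - p["start"]).iloc[0])
        widths.add(w)
        offsets.add(int(p["start"].iloc[0]) % w)
    if len(widths) > 1:
        raise ValueError(f"window profiles on mismatched grids: {widths}")
    if len(offsets) > 1:
        raise ValueError("window profiles on mismatched grid origins")
    return widths.pop() if widths else 0


def call_suppressor_dmrs(triple: pd.DataFrame, quadruple: pd.DataFrame,
                         suppressor: pd.DataFrame,
                         retention_max: float = 0.4,
                         recovery_min: float = 0.6,
                         recovery_mode: str = "vs_triple") -> pd.DataFrame:
    """Apply the hypo/recovery rule per window.

    retention = quadruple/triple total level; recovery = suppressor/triple
    ("vs_triple", default) or (suppressor - quadruple)/(triple - quadruple)
    ("rescaled"). A window passes iff retention < retention_max AND
    recovery > recovery_min (both strict). Windows with missing or zero
    triple total level are skipped (``skipped`` flag set, ``passed`` False).
    """
    width = _check_grid(triple, quadruple, suppressor)
    cols = ["chrom", "start", "end", "total_level"]
    m = (triple[cols]
         .merge(quadruple[cols], on=["chrom", "start", "end"],
                how="outer", suffixes=("_triple", "_quadruple"))
         .merge(suppressor[cols].rename(
             columns={"total_level": "total_level_suppressor"}),
             on=["chrom", "start", "end"], how="outer"))
    t = m["total_level_triple"].to_numpy(float)
    q = m["total_level_quadruple"].to_numpy(float)
    s = m["total_level_suppressor"].to_numpy(float)

    skipped = np.isnan(t) | (t == 0) | np.isnan(q) | np.isnan(s)
    with np.errstate(divide="ignore", invalid="ignore"):
        retention = np.where(skipped, np.nan, q / t)
        if recovery_mode == "vs_triple":
            recovery = np.where(skipped, np.nan, s / t)
        elif recovery_mode == "rescaled":
            denom = t - q
            recovery = np.where(skipped | (denom == 0), np.nan,
                                (s - q) / denom)
        else:
            raise ValueError(f"unknown recovery_mode {recovery_mode!r}")
    passed = (~skipped & ~np.isnan(recovery)
              & (retention < retention_max) & (recovery > recovery_min))

    out = m[["chrom", "start", "end"]].copy()
    out["retention_ratio"] = retention
    out["recovery_ratio"] = recovery
    out["passed"] = passed
    out["skipped"] = skipped
    out.attrs["width"] = width
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


@dataclass
class SharedDmrResult:
    """Windows passing in every suppressor line, merged into regions."""

    shared_windows: pd.DataFrame
    merged_regions: pd.DataFrame  # chrom, start, end, n_windows
    venn: dict[frozenset, int] = field(default_factory=dict)


def intersect_dmrs(dmr_sets: list[pd.DataFrame]) -> SharedDmrResult:
    """Intersect per-suppressor DMR calls on their common grid.

    Returns the windows passed in all sets, the per-subset Venn counts over
    windows passed in at least one set, and maximal runs of adjacent shared
    windows merged into regions.
    """
    if len(dmr_sets) < 2:
        raise ValueError("at least two DMR sets are required")
    width = _check_grid(*dmr_sets)
    passed_sets = []
    for d in dmr_sets:
        p = d[d["passed"]]
        passed_sets.append(set(zip(p["chrom"], p["start"])))

    venn: dict[frozenset, int] = {}
    all_windows = set().union(*passed_sets)
    for w in all_windows:
        member = frozenset(i for i, s in enumerate(passed_sets) if w in s)
        venn[member] = venn.get(member, 0) + 1

    shared = sorted(set.intersection(*passed_sets))
    shared_df = pd.DataFrame(shared, columns=["chrom", "start"])
    shared_df["end"] = shared_df["start"] + width

    regions = []
    for chrom, grp in shared_df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        run_start = prev = None
        n = 0
        for s in starts:
            if prev is not None and s == prev + width:
                prev = s
                n += 1
            else:
                if run_start is not None:
                    regions.append((chrom, run_start, prev + width, n))
                run_start, prev, n = s, s, 1
        if run_start is not None:
            regions.append((chrom, run_start, prev + width, n))
    merged = pd.DataFrame(regions,
                          columns=["chrom", "start", "end", "n_windows"])
    return SharedDmrResult(shared_df, merged, venn)


def boxplot_summary(profiles: dict[str, pd.DataFrame],
                    region: tuple[str, int, int],
                    column: str = "total_level") -> pd.DataFrame:
    """Five-number summary of window levels inside a region, per genotype."""
    chrom, start, end = region
    rows = {}
    for genotype, prof in profiles.items():
        sel = prof[(prof["chrom"] == chrom) & (prof["start"] < end)
                   & (prof["end"] > start)][column].dropna().to_numpy()
        if sel.size == 0:
            raise ValueError(f"region {region} contains no windows for "
                             f"{genotype!r}")
        rows[genotype] = {
            "min": float(np.min(sel)),
            "q1": float(np.percentile(sel, 25)),
            "median": float(np.median(sel)),
            "q3": float(np.percentile(sel, 75)),
            "max": float(np.max(sel)),
            "n_windows": int(sel.size),
        }
    return pd.DataFrame(rows).T
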