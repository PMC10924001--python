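"""Consensus table assembly, exponential smoothing, and context-rate correlations.

The consensus table joins per-window methylated-cytosine counts (CG/CHG/CHH)
with the per-window recombination rate, then applies simple exponential
smoothing (s1 = x1; s_t = a*x_t + (1-a)*s_{t-1}, default a = 0.1)
independently per chromosome and per track to damp window-to-window noise.
Correlations between each smoothed context track and the smoothed rate are
reported per chromosome with two-sided Pearson p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

CONTEXTS = ("cg", "chg", "chh")
SMOOTHED = ("cg_s", "chg_s", "chh_s", "rate_s")


def smooth(x, alpha: float = 0.1) -> np.ndarray:
    """Simple (forward, single-pass) exponential smoothing of an ordered track."""
    if not (0 < alpha <= 1):
        raise ValidationError("alpha must be in (0, 1]")
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    return pd.Series(x).ewm(alpha=alpha, adjust=False).mean().to_numpy()


@dataclass
class ConsensusInfo:
    n_rows: int
    n_dropped_undefined_rate: int
    alpha: float


def _infer_window_size(df: pd.DataFrame) -> int | None:
    if "start" not in df.columns or "end" not in df.columns:
        return None
    sizes = (df["end"] - df["start"] + 1).to_numpy()
    if len(sizes) == 0:
        return None
    # trailing partial windows are shorter; the modal size is the grid size
    vals, cnts = np.unique(sizes, return_counts=True)
    return int(vals[np.argmax(cnts)])


def build_consensus(
    windows: pd.DataFrame,
    rates: pd.DataFrame,
    alpha: float = 0.1,
    smooth_after_join: bool = True,
) -> tuple[pd.DataFrame, ConsensusInfo]:
    """Inner-join window counts with rates and add smoothed tracks.

    Rows whose rate is undefined (NaN, e.g. the trailing window) are dropped
    and counted. Smoothing runs per chromosome after the join by default;
    ``smooth_after_join=False`` smooths each input on its full grid first
    (differs only at dropped windows).
    """
    ws_w = _infer_window_size(windows)
    ws_r = _infer_window_size(rates)
    if ws_w is not None and ws_r is not None and ws_w != ws_r:
        raise ValidationError(
            f"window grids disagree: counts use {ws_w} bp windows, rates {ws_r} bp"
        )

    w = windows[["chrom", "window_index", "start", "end", "cg", "chg", "chh"]]
    r = rates[["chrom", "window_index", "rate"]]
    if not smooth_after_join:
        w = w.copy()
        r = r.copy()
        for col in CONTEXTS:
            w[col + "_s"] = w.groupby("chrom")[col].transform(lambda s: smooth(s, alpha))
        r["rate_s"] = r.groupby("chrom")["rate"].transform(lambda s: smooth(s, alpha))

    ct = w.merge(r, on=["chrom", "window_index"], how="inner")
    if len(ct) == 0:
        raise ValidationError("window counts and rates share no (chrom, window) rows")
    n_undef = int(ct["rate"].isna().sum())
    ct = ct[ct["rate"].notna()].reset_index(drop=True)
    ct = ct.sort_values(["chrom", "window_index"], kind="stable", ignore_index=True)
    if smooth_after_join:
        for col in (*CONTEXTS, "rate"):
            ct[(col if col != "rate" else "rate") + "_s"] = ct.groupby("chrom")[col].transform(
                lambda s: smooth(s, alpha)
            )
    return ct, ConsensusInfo(n_rows=len(ct), n_dropped_undefined_rate=n_undef, alpha=alpha)


def correlate(
    consensus: pd.DataFrame,
    significance_level: float = 0.05,
    use_smoothed: bool = True,
) -> pd.DataFrame:
    """Per-chromosome Pearson correlation of each context track vs the rate.

    Returns rows (chrom, context, r, p, n, significant, note); zero-variance
    tracks yield NaN r with an explanatory note.
    """
    suffix = "_s" if use_smoothed else ""
    rows = []
    for chrom, sub in consensus.groupby("chrom", sort=True):
        y = sub["rate" + suffix].to_numpy(dtype=float)
        for ctx in CONTEXTS:
            x = sub[ctx + suffix].to_numpy(dtype=float)
            note = ""
            if len(sub) < 3:
                r_val, p_val, note = np.nan, np.nan, "fewer than 3 windows"
            elif np.std(x) == 0 or np.std(y) == 0:
                r_val, p_val, note = np.nan, np.nan, "zero variance"
            else:
                r_val, p_val = stats.pearsonr(x, y)
            rows.append(
                {
                    "chrom": chrom,
                    "context": ctx.upper(),
                    "r": r_val,
                    "p": p_val,
                    "n": len(sub),
                    "significant": bool(p_val < significance_level)
                    if not np.isnan(p_val)
                    else False,
                    "note": note,
                }
            )
    return pd.DataFrame(rows)


def write_consensus(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, sep="\t", index=False)


def read_consensus(path) -> pd.DataFrame:
    from .errors import InputError

    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot parse consensus table {path}: {exc}") from None
    missing = {"chrom", "window_index", "rate_s"} - set(df.columns)
    if missing:
        raise InputError(f"consensus table {path} lacks columns {sorted(missing)}")
    return df
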