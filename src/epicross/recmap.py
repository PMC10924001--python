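"""Recombination landscapes from genotype matrices or pre-built genetic maps.

The genotype path follows the classical mapping-population workflow: impute a
row of parental-origin calls at every grid position from the nearest marker,
estimate recombination fractions between consecutive grid rows, convert them
to centimorgans with the Kosambi mapping function

    cM = 25 * ln((1 + 2r) / (1 - 2r)) = 50 * artanh(2r),

accumulate into a genetic map, and difference consecutive window positions to
obtain cM-per-window rates. A pre-built map (bp -> cM anchors) enters the
same differencing step after nearest-anchor imputation onto the window grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

#: recombination fractions are clamped to 0.5 - EPS before Kosambi mapping
R_CLAMP_EPS = 1e-6
#: negative rates smaller than this (imputation artifacts) are clipped to 0
NEG_RATE_TOL = 1e-6

MISSING_TOKENS = {"NA", "-", ".", "", "nan", "NaN"}

# integer encoding of calls: 0 = A, 1 = B, -1 = missing
_CALL_CODE = {"A": 0, "B": 1}


def kosambi_cm(r):
    """Kosambi map distance in cM for recombination fraction 0 <= r < 0.5."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValidationError("recombination fraction must lie in [0, 0.5)")
    out = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(out) if out.ndim == 0 else out


def kosambi_inverse(cm):
    """Recombination fraction recovering ``cm`` under the Kosambi function."""
    cm = np.asarray(cm, dtype=float)
    out = 0.5 * np.tanh(cm / 50.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class GenotypeMatrix:
    """Ordered markers x individuals parental-origin calls, per chromosome.

    ``calls`` maps chromosome -> int8 array (markers x individuals) with
    0 = A, 1 = B, -1 = missing; ``positions`` holds the strictly increasing
    marker bp positions.
    """

    positions: dict[str, np.ndarray]
    calls: dict[str, np.ndarray]
    individuals: list[str]
    marker_ids: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, pos in self.positions.items():
            if len(pos) == 0:
                raise ValidationError(f"{chrom}: no markers")
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(f"{chrom}: marker positions must be strictly increasing")
            arr = self.calls[chrom]
            if arr.shape != (len(pos), len(self.individuals)):
                raise ValidationError(f"{chrom}: call matrix shape mismatch")

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)


def read_genotypes(
    path: str | Path,
    missing_tokens: set[str] | None = None,
    strict_calls: bool = False,
) -> GenotypeMatrix:
    """Read a genotype TSV: marker_id, chrom, pos, then one column per individual.

    Unrecognized calls (anything outside A/B/missing tokens) are treated as
    missing unless ``strict_calls``, in which case they raise.
    """
    tokens = MISSING_TOKENS if missing_tokens is None else missing_tokens
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        df["pos"] = df["pos"].astype(np.int64)
    except (ValueError, KeyError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot parse genotype table {path}: {exc}") from None
    ind_cols = [c for c in df.columns if c not in ("marker_id", "chrom", "pos")]
    if not ind_cols:
        raise InputError(f"genotype table {path} has no individual columns")

    positions, calls, ids = {}, {}, {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="stable")
        raw = sub[ind_cols].to_numpy(dtype=object)
        coded = np.full(raw.shape, -1, dtype=np.int8)
        for sym, code in _CALL_CODE.items():
            coded[raw == sym] = code
        unknown = (coded == -1) & ~np.isin(raw, list(tokens))
        if unknown.any():
            if strict_calls:
                bad = sorted(set(raw[unknown].ravel()))
                raise ValidationError(f"{path}: unrecognized genotype calls {bad}")
            logger.warning("%s: %d unrecognized calls treated as missing", chrom, unknown.sum())
        positions[chrom] = sub["pos"].to_numpy()
        calls[chrom] = coded
        ids[chrom] = sub["marker_id"].tolist()
    return GenotypeMatrix(positions=positions, calls=calls, individuals=ind_cols,
                          marker_ids=ids)


def genotype_matrix_from_frame(df: pd.DataFrame, strict_calls: bool = False) -> GenotypeMatrix:
    """Build a GenotypeMatrix from an in-memory genotype table.

    Expects the on-disk layout: marker_id, chrom, pos, then one column per
    individual with A/B/missing calls.
    """
    ind_cols = [c for c in df.columns if c not in ("marker_id", "chrom", "pos")]
    if not ind_cols:
        raise ValidationError("genotype frame has no individual columns")
    positions, calls, ids = {}, {}, {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="stable")
        raw = sub[ind_cols].to_numpy(dtype=object)
        coded = np.full(raw.shape, -1, dtype=np.int8)
        for sym, code in _CALL_CODE.items():
            coded[raw == sym] = code
        unknown = (coded == -1) & ~np.isin(raw, list(MISSING_TOKENS))
        if unknown.any() and strict_calls:
            raise ValidationError(
                f"{chrom}: unrecognized genotype calls {sorted(set(raw[unknown].ravel()))}"
            )
        positions[chrom] = sub["pos"].to_numpy(dtype=np.int64)
        calls[chrom] = coded
        ids[chrom] = sub["marker_id"].tolist() if "marker_id" in sub.columns else []
    return GenotypeMatrix(positions=positions, calls=calls, individuals=ind_cols,
                          marker_ids=ids)


def nearest_indices(anchors_bp: np.ndarray, query_bp: np.ndarray) -> np.ndarray:
    """Index of the nearest anchor for each query; midpoint ties -> lower anchor."""
    anchors_bp = np.asarray(anchors_bp, dtype=np.int64)
    query_bp = np.asarray(query_bp, dtype=np.int64)
    if len(anchors_bp) == 0:
        raise ValidationError("no anchors to impute from")
    left = np.clip(np.searchsorted(anchors_bp, query_bp, side="right") - 1, 0, None)
    right = np.clip(left + 1, None, len(anchors_bp) - 1)
    d_left = np.abs(query_bp - anchors_bp[left])
    d_right = np.abs(anchors_bp[right] - query_bp)
    return np.where(d_right < d_left, right, left)


def impute_rows(
    positions: np.ndarray, calls: np.ndarray, step: int, chrom_length: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Impute full call rows at grid positions step, 2*step, ... from nearest markers.

    Returns (grid positions, imputed call matrix). Rows are whole copies of
    the nearest marker's row, missing entries included; grid positions beyond
    the marker range copy the first/last marker.
    """
    if step <= 0:
        raise ValidationError("step must be positive")
    positions = np.asarray(positions, dtype=np.int64)
    if len(positions) == 0:
        raise ValidationError("chromosome has no markers")
    end = chrom_length if chrom_length is not None else int(positions[-1])
    grid = np.arange(step, end + 1, step, dtype=np.int64)
    if len(grid) == 0:
        grid = np.array([end], dtype=np.int64)
    src = nearest_indices(positions, grid)
    return grid, calls[src]


def recombination_fraction(row_i: np.ndarray, row_j: np.ndarray) -> tuple[float, int]:
    """Recombination fraction between two call rows.

    Counts individuals informative in both rows (non-missing); r = differing /
    informative, clamped below 0.5 for Kosambi. Returns (r, n_informative);
    r is NaN when no individual is informative.
    """
    if row_i.shape != row_j.shape:
        raise ValidationError("rows must cover the same individuals")
    both = (row_i >= 0) & (row_j >= 0)
    n = int(both.sum())
    if n == 0:
        return float("nan"), 0
    d = int((row_i[both] != row_j[both]).sum())
    r = min(d / n, 0.5 - R_CLAMP_EPS)
    return r, n


@dataclass
class GeneticMap:
    """Monotone cM positions at bp anchors, per chromosome."""

    anchors: dict[str, pd.DataFrame]  # columns: pos (bp), cM
    n_uninformative: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, df in self.anchors.items():
            cm = df["cM"].to_numpy(dtype=float)
            if len(cm) and cm[0] < 0:
                raise ValidationError(f"{chrom}: negative starting cM")
            drops = np.diff(cm)
            if len(drops) and drops.min() < -NEG_RATE_TOL:
                k = int(np.argmin(drops))
                raise ValidationError(
                    f"{chrom}: genetic map not monotone between anchors "
                    f"{df['pos'].iat[k]} and {df['pos'].iat[k + 1]} "
                    f"({cm[k]:.6f} -> {cm[k + 1]:.6f} cM)"
                )

    def total_length(self, chrom: str) -> float:
        cm = self.anchors[chrom]["cM"]
        return float(cm.iloc[-1] - cm.iloc[0]) if len(cm) else 0.0


def map_from_genotypes(
    gm: GenotypeMatrix, step: int = 100_000, chrom_lengths: dict[str, int] | None = None
) -> GeneticMap:
    """Genetic map on the bp grid: cumulative Kosambi distances between
    consecutive imputed grid rows. Intervals with no informative individual
    contribute 0 cM and are counted per chromosome."""
    chrom_lengths = chrom_lengths or {}
    anchors, gaps = {}, {}
    for chrom in gm.chroms:
        grid, rows = impute_rows(
            gm.positions[chrom], gm.calls[chrom], step, chrom_lengths.get(chrom)
        )
        cm = np.zeros(len(grid))
        n_gap = 0
        for k in range(len(grid) - 1):
            r, n = recombination_fraction(rows[k], rows[k + 1])
            if n == 0:
                n_gap += 1
                d = 0.0
            else:
                d = kosambi_cm(r)
            cm[k + 1] = cm[k] + d
        if n_gap:
            logger.warning("%s: %d grid intervals had no informative individuals", chrom, n_gap)
        anchors[chrom] = pd.DataFrame({"pos": grid, "cM": cm})
        gaps[chrom] = n_gap
    return GeneticMap(anchors=anchors, n_uninformative=gaps)


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a marker-level genetic map TSV: marker_id, chrom, pos, cM."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        df["pos"] = df["pos"].astype(np.int64)
        df["cM"] = df["cM"].astype(float)
    except (ValueError, KeyError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot parse genetic map {path}: {exc}") from None
    anchors = {
        chrom: sub.sort_values("pos", kind="stable")[["pos", "cM"]].reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False)
    }
    return GeneticMap(anchors=anchors)


def rates_from_map(
    gmap: GeneticMap, window_size: int = 100_000, chrom_lengths: dict[str, int] | None = None
) -> pd.DataFrame:
    """cM-per-window rate track by differencing window-grid genetic positions.

    cM is first imputed onto window boundaries (0, W, 2W, ...) from the
    nearest map anchor; rate(window k) = cM((k+1)W) - cM(kW). Negative
    differences within ``NEG_RATE_TOL`` are clipped to 0 (and counted); the
    trailing window beyond the last boundary is reported with NaN rate.
    """
    if window_size <= 0:
        raise ValidationError("window_size must be positive")
    chrom_lengths = chrom_lengths or {}
    frames = []
    for chrom, df in gmap.anchors.items():
        end = chrom_lengths.get(chrom, int(df["pos"].iloc[-1]))
        n_win = math.ceil(end / window_size)
        bounds = np.arange(0, (n_win + 1) * window_size, window_size, dtype=np.int64)
        bounds = bounds[bounds <= end]
        src = nearest_indices(df["pos"].to_numpy(), bounds)
        cm = df["cM"].to_numpy(dtype=float)[src]
        diff = np.diff(cm)
        n_clip = int(((diff < 0) & (diff >= -NEG_RATE_TOL)).sum())
        if np.any(diff < -NEG_RATE_TOL):
            raise ValidationError(f"{chrom}: non-monotone imputed map (beyond tolerance)")
        if n_clip:
            logger.info("%s: clipped %d tiny negative rates to 0", chrom, n_clip)
        diff = np.clip(diff, 0.0, None)
        rate = np.full(n_win, np.nan)
        rate[: len(diff)] = diff
        idx = np.arange(n_win)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "window_index": idx,
                    "start": idx * window_size + 1,
                    "end": np.minimum((idx + 1) * window_size, end),
                    "rate": rate,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def rates_from_genotypes(
    gm: GenotypeMatrix, window_size: int = 100_000, chrom_lengths: dict[str, int] | None = None
) -> tuple[pd.DataFrame, GeneticMap]:
    """Convenience composition: genotype matrix -> genetic map -> rate track."""
    gmap = map_from_genotypes(gm, step=window_size, chrom_lengths=chrom_lengths)
    return rates_from_map(gmap, window_size=window_size, chrom_lengths=chrom_lengths), gmap


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    rows = []
    for chrom, df in gmap.anchors.items():
        out = df.rename(columns={"pos": "grid_bp"}).copy()
        out.insert(0, "chrom", chrom)
        rows.append(out)
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_rates(rates: pd.DataFrame, path: str | Path) -> None:
    rates.rename(columns={"rate": "rate_cM"}).to_csv(path, sep="\t", index=False)


def read_rates(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot parse rate track {path}: {exc}") from None
    if "rate_cM" in df.columns:
        df = df.rename(columns={"rate_cM": "rate"})
    missing = {"chrom", "window_index", "rate"} - set(df.columns)
    if missing:
        raise InputError(f"rate track {path} lacks columns {sorted(missing)}")
    return df
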