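"""Windowed counts of highly methylated cytosines from Bismark-style reports.

Per-cytosine methylation calls are filtered by methylation level (default:
retain level >= 0.75, inclusive) and read coverage, then counted per context
(CG / CHG / CHH) in fixed windows (default 100 kb) along each chromosome.
A separate tally resolves retained CHH cytosines into their nine
trinucleotide sub-context motifs (CAA ... CTT).
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

REPORT_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "trinucleotide"]

#: The 9 CHH trinucleotide motifs (C followed by two of A/C/T), 5'->3' on the
#: cytosine's strand.
CHH_MOTIFS = ("CAA", "CAC", "CAT", "CCA", "CCC", "CCT", "CTA", "CTC", "CTT")

_CONTEXT_ALIASES = {"CpG": "CG", "CG": "CG", "CHG": "CHG", "CHH": "CHH"}
_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    """Read a 7-column Bismark cytosine/CX report TSV (no header)."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=REPORT_COLUMNS,
            dtype={"chrom": str, "strand": str, "context": str, "trinucleotide": str},
        )
        df["pos"] = df["pos"].astype(np.int64)
        df["n_meth"] = df["n_meth"].astype(np.int64)
        df["n_unmeth"] = df["n_unmeth"].astype(np.int64)
    except (ValueError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot parse cytosine report {path}: {exc}") from None
    return df


def methylation_level(n_meth, n_unmeth):
    """Fraction of reads calling the cytosine methylated; requires coverage >= 1."""
    n_meth = np.asarray(n_meth, dtype=float)
    n_unmeth = np.asarray(n_unmeth, dtype=float)
    cov = n_meth + n_unmeth
    if np.any(cov < 1):
        raise ValidationError("methylation level undefined at zero coverage")
    out = n_meth / cov
    return float(out) if out.ndim == 0 else out


def _context_ok(context: pd.Series, tri: pd.Series) -> np.ndarray:
    """Vectorized check that context agrees with the trinucleotide."""
    t = tri.str.upper().fillna("")
    good_len = t.str.len() == 3
    b1, b2, b3 = t.str[0], t.str[1], t.str[2]
    h = {"A", "C", "T"}
    is_cg = b2 == "G"
    is_chg = b2.isin(h) & (b3 == "G")
    is_chh = b2.isin(h) & b3.isin(h)
    ctx = context.map(_CONTEXT_ALIASES)
    ok = (b1 == "C") & good_len & (
        ((ctx == "CG") & is_cg) | ((ctx == "CHG") & is_chg) | ((ctx == "CHH") & is_chh)
    )
    return ok.to_numpy()


@dataclass
class WindowingResult:
    """Window table plus the filter bookkeeping downstream stages may log."""

    windows: pd.DataFrame  # chrom, window_index, start, end, cg, chg, chh
    n_retained: int
    n_low_level: int
    n_low_coverage: int
    n_rejected: int  # malformed context/trinucleotide
    inferred_lengths: dict[str, int] = field(default_factory=dict)


def filter_and_count(
    records: pd.DataFrame,
    window_size: int = 100_000,
    level_threshold: float = 0.75,
    min_coverage: int = 10,
    level_threshold_inclusive: bool = True,
    chrom_lengths: dict[str, int] | None = None,
) -> WindowingResult:
    """Filter cytosines and count the retained ones per context per window.

    A record is retained iff coverage >= ``min_coverage`` and level passes
    ``level_threshold`` (>= when inclusive, > otherwise). Both strands pool
    into the same windows. Window k is the 1-based closed interval
    [k*W+1, (k+1)*W]; empty windows appear with zero counts. When a
    chromosome's length is unknown it is inferred from the maximum observed
    position and reported in ``inferred_lengths``.
    """
    if window_size <= 0:
        raise ValidationError("window_size must be positive")
    df = records.copy()
    ok = _context_ok(df["context"], df["trinucleotide"])
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("rejected %d records with context/trinucleotide mismatch", n_rejected)
    df = df[ok]

    cov = df["n_meth"] + df["n_unmeth"]
    covered = cov >= max(min_coverage, 1)
    level = df["n_meth"] / cov.where(cov > 0, 1)
    passed = level >= level_threshold if level_threshold_inclusive else level > level_threshold
    n_low_coverage = int((~covered).sum())
    n_low_level = int((covered & ~passed).sum())
    kept = df[covered & passed]

    chrom_lengths = dict(chrom_lengths or {})
    inferred: dict[str, int] = {}
    frames = []
    for chrom in sorted(df["chrom"].unique()):
        sub = kept[kept["chrom"] == chrom]
        if chrom in chrom_lengths:
            length = chrom_lengths[chrom]
        else:
            length = int(df.loc[df["chrom"] == chrom, "pos"].max())
            inferred[chrom] = length
        n_win = math.ceil(length / window_size)
        idx = np.arange(n_win)
        tab = pd.DataFrame(
            {
                "chrom": chrom,
                "window_index": idx,
                "start": idx * window_size + 1,
                "end": np.minimum((idx + 1) * window_size, length),
            }
        )
        widx = (sub["pos"].to_numpy() - 1) // window_size
        ctx = sub["context"].map(_CONTEXT_ALIASES)
        for name, col in (("CG", "cg"), ("CHG", "chg"), ("CHH", "chh")):
            counts = np.bincount(widx[(ctx == name).to_numpy()], minlength=n_win)[:n_win]
            tab[col] = counts.astype(np.int64)
        frames.append(tab)

    windows = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "window_index", "start", "end", "cg", "chg", "chh"])
    )
    return WindowingResult(
        windows=windows,
        n_retained=int(len(kept)),
        n_low_level=n_low_level,
        n_low_coverage=n_low_coverage,
        n_rejected=n_rejected,
        inferred_lengths=inferred,
    )


@dataclass
class MotifTally:
    counts: pd.Series  # indexed by CHH_MOTIFS
    proportions: pd.Series
    n_rejected: int  # trinucleotides outside the 9 motifs (N, malformed)


def tally_chh_motifs(
    records: pd.DataFrame, genome=None
) -> MotifTally:
    """Census of CHH sub-context motifs among retained CHH cytosines.

    Motifs are read 5'->3' on the cytosine's strand. If ``genome`` (a mapping
    of chromosome name to sequence, e.g. a ``pyfaidx.Fasta``) is given, the
    trinucleotide is looked up there — reverse-complemented for minus-strand
    records — otherwise the report's trinucleotide column is used.
    """
    chh = records[records["context"].map(_CONTEXT_ALIASES) == "CHH"]
    if genome is not None:
        tris = []
        for chrom, pos, strand in zip(chh["chrom"], chh["pos"], chh["strand"]):
            seq = genome[chrom]
            if strand == "+":
                tri = str(seq[pos - 1 : pos + 2])
            else:
                tri = str(seq[pos - 3 : pos]).encode().translate(_COMPLEMENT)[::-1].decode()
            tris.append(tri.upper())
        tri_series = pd.Series(tris, index=chh.index, dtype=object)
    else:
        tri_series = chh["trinucleotide"].str.upper()

    valid = tri_series.isin(CHH_MOTIFS)
    counts = tri_series[valid].value_counts().reindex(CHH_MOTIFS, fill_value=0)
    total = int(counts.sum())
    props = counts / total if total > 0 else counts.astype(float)
    return MotifTally(counts=counts, proportions=props, n_rejected=int((~valid).sum()))


def write_window_table(windows: pd.DataFrame, path: str | Path, bed: bool = False) -> None:
    """Write the window table; ``bed=True`` emits 0-based half-open starts."""
    out = windows.copy()
    if bed:
        out["start"] = out["start"] - 1
    out.to_csv(path, sep="\t", index=False)


def read_window_table(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot parse window table {path}: {exc}") from None
    missing = {"chrom", "window_index", "cg", "chg", "chh"} - set(df.columns)
    if missing:
        raise InputError(f"window table {path} lacks columns {sorted(missing)}")
    return df
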