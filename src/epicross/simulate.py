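"""Synthetic plant methylome / recombination landscapes with known ground truth.

The generator produces every input the pipeline consumes — genome FASTA,
Bismark-style per-cytosine reports, parental-origin genotype matrices — from a
single :class:`LandscapeSpec`, together with the true per-window recombination
rate track, so each downstream stage can be validated against a known answer.

The emulated biology: crossovers concentrate on chromosome arms and are
suppressed at the centromere; methylated-cytosine counts in the CG and CHG
contexts are enriched pericentromerically (hence anti-correlated with
recombination); CHH counts track the recombination landscape with a tunable
coupling strength. Counts are negative-binomially dispersed; crossovers per
gamete are Poisson with mean equal to the map length in Morgans.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InputError, ValidationError

DEFAULT_WINDOW = 100_000

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def _revcomp(s: str) -> str:
    return s.encode().translate(_COMPLEMENT)[::-1].decode()


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of one synthetic chromosome's coupled landscapes.

    Rates are cM per window; count parameters are mean retained methylated
    cytosines per window; ``chh_coupling`` is the fraction of the CHH mean
    profile driven by the true recombination landscape (0 = independent,
    1 = fully coupled). ``noise_dispersion`` d gives negative-binomial count
    noise with variance mu*(1 + d*mu); d = 0 falls back to Poisson.

    ``arm_peak`` places the crossover maximum along each arm as a fraction of
    arm length from the telomere: the default 0.25 emulates distal-arm
    recombination concentration; values near 1 give a pericentromere-peaked
    landscape.
    """

    chrom_length: int
    seed: int
    window_size: int = DEFAULT_WINDOW
    centromere_center: int | None = None
    centromere_halfwidth: int | None = None
    base_rate: float = 0.05
    arm_amplitude: float = 0.9
    arm_peak: float = 0.25
    cg_base: float = 300.0
    chg_base: float = 180.0
    chh_base: float = 80.0
    cg_peri_enrich: float = 3.0
    chg_peri_enrich: float = 3.0
    chh_coupling: float = 0.8
    noise_dispersion: float = 0.15

    def __post_init__(self):
        if self.chrom_length < 10 * self.window_size:
            raise ValidationError(
                f"chrom_length {self.chrom_length} must be >= 10 windows "
                f"({10 * self.window_size})"
            )
        if self.window_size <= 0:
            raise ValidationError("window_size must be positive")
        if self.centromere_center is None:
            object.__setattr__(self, "centromere_center", self.chrom_length // 2)
        if self.centromere_halfwidth is None:
            object.__setattr__(
                self, "centromere_halfwidth", max(self.chrom_length // 12, self.window_size)
            )
        if not (0 < self.centromere_center < self.chrom_length):
            raise ValidationError("centromere_center must lie inside the chromosome")
        if self.centromere_halfwidth <= 0:
            raise ValidationError("centromere_halfwidth must be positive")
        if not (0.0 <= self.chh_coupling <= 1.0):
            raise ValidationError("chh_coupling must be in [0, 1]")
        for name in ("base_rate", "arm_amplitude", "cg_base", "chg_base", "chh_base",
                     "noise_dispersion"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("cg_peri_enrich", "chg_peri_enrich"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not (0.0 < self.arm_peak < 1.0):
            raise ValidationError("arm_peak must be in (0, 1)")

    @property
    def n_windows(self) -> int:
        return math.ceil(self.chrom_length / self.window_size)


def load_spec_yaml(path: str | Path) -> LandscapeSpec:
    """Read a flat-key YAML config mapping 1:1 onto LandscapeSpec fields."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InputError(f"{path}: expected a flat mapping of spec fields")
    if "seed" not in cfg:
        raise InputError(f"{path}: 'seed' is mandatory in simulation configs")
    known = {f.name for f in dataclasses.fields(LandscapeSpec)}
    unknown = set(cfg) - known
    if unknown:
        raise InputError(f"{path}: unknown spec fields {sorted(unknown)}")
    return LandscapeSpec(**cfg)


def window_bounds(chrom_length: int, window_size: int) -> pd.DataFrame:
    """1-based closed windows [k*W+1, min((k+1)*W, L)] tiling the chromosome."""
    n = math.ceil(chrom_length / window_size)
    idx = np.arange(n)
    start = idx * window_size + 1
    end = np.minimum((idx + 1) * window_size, chrom_length)
    return pd.DataFrame({"window_index": idx, "start": start, "end": end})


def make_landscape(spec: LandscapeSpec) -> np.ndarray:
    """True recombination rate (cM per window) along one chromosome.

    rate = clip(base + amplitude * arm_profile * suppression, 0) where the
    arm profile is a warped half-sine peaking at ``arm_peak`` of each arm's
    length (measured from the telomere) and the suppression factor is
    1 - exp(-(|x-c|/h)^4): flat near 0 across the centromere core, 1 on arms.
    """
    w = window_bounds(spec.chrom_length, spec.window_size)
    x = (w["start"].to_numpy() + w["end"].to_numpy()) / 2.0
    c = float(spec.centromere_center)
    h = float(spec.centromere_halfwidth)
    suppress = 1.0 - np.exp(-((np.abs(x - c) / h) ** 4))
    # distance from the nearer telomere as a fraction of that arm's length
    u = np.where(x < c, x / c, (spec.chrom_length - x) / max(spec.chrom_length - c, 1))
    u = np.clip(u, 0.0, 1.0)
    p = spec.arm_peak
    warped = np.where(u <= p, u / (2 * p), 0.5 + (u - p) / (2 * (1 - p)))
    arm = np.clip(np.sin(np.pi * warped), 0.0, None)
    rate = spec.base_rate + spec.arm_amplitude * arm * suppress
    return np.clip(rate, 0.0, None)


def _peri_profile(spec: LandscapeSpec, x: np.ndarray) -> np.ndarray:
    # broad pericentromeric bump; width tied to chromosome scale so the
    # enrichment spans the chromosome core, not just the crossover-dead zone
    sd = max(spec.chrom_length / 6.0, 2.0 * spec.centromere_halfwidth)
    return np.exp(-0.5 * ((x - spec.centromere_center) / sd) ** 2)


def expected_window_means(spec: LandscapeSpec, true_rate: np.ndarray) -> pd.DataFrame:
    """Noise-free per-window mean counts for CG/CHG/CHH given the true rates."""
    w = window_bounds(spec.chrom_length, spec.window_size)
    if len(true_rate) != len(w):
        raise ValidationError("true_rate length does not match the window grid")
    x = (w["start"].to_numpy() + w["end"].to_numpy()) / 2.0
    peri = _peri_profile(spec, x)
    w["cg_mean"] = spec.cg_base * (1.0 + (spec.cg_peri_enrich - 1.0) * peri)
    w["chg_mean"] = spec.chg_base * (1.0 + (spec.chg_peri_enrich - 1.0) * peri)
    mean_rate = float(np.mean(true_rate))
    scaled = true_rate * (spec.chh_base / mean_rate) if mean_rate > 0 else np.zeros_like(true_rate)
    w["chh_mean"] = (1.0 - spec.chh_coupling) * spec.chh_base + spec.chh_coupling * scaled
    return w


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
    else:
        size = 1.0 / dispersion  # var = mu + d*mu^2
        p = size / (size + mean[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_window_counts(
    spec: LandscapeSpec, true_rate: np.ndarray, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Noisy retained-methylated-cytosine counts per window and context.

    Fast path used when per-cytosine records are not needed; the full report
    simulator (:func:`simulate_methylome`) places exactly these counts onto
    genomic cytosine sites.
    """
    rng = rng or np.random.default_rng(spec.seed)
    w = expected_window_means(spec, true_rate)
    out = w[["window_index", "start", "end"]].copy()
    out["cg"] = _nb_draw(rng, w["cg_mean"].to_numpy(), spec.noise_dispersion)
    out["chg"] = _nb_draw(rng, w["chg_mean"].to_numpy(), spec.noise_dispersion)
    out["chh"] = _nb_draw(rng, w["chh_mean"].to_numpy(), spec.noise_dispersion)
    return out


def simulate_genome(
    length: int, rng: np.random.Generator, gc: float = 0.36
) -> str:
    """I.i.d. nucleotide sequence with the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return codes.tobytes().decode()


def _context_sites(seq: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """1-based cytosine positions and strands per context, both strands.

    Position is the plus-strand coordinate of the cytosine (the G base for
    minus-strand cytosines), matching Bismark report conventions.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    C, G = ord("C"), ord("G")
    n = len(arr)
    sites: dict[str, list[tuple[np.ndarray, str]]] = {"CpG": [], "CHG": [], "CHH": []}
    # plus strand: cytosine at i with downstream bases i+1, i+2
    b1, b2, b3 = arr[: n - 2], arr[1 : n - 1], arr[2:]
    isc = b1 == C
    sites["CpG"].append((np.nonzero(isc & (b2 == G))[0] + 1, "+"))
    sites["CHG"].append((np.nonzero(isc & (b2 != G) & (b3 == G))[0] + 1, "+"))
    sites["CHH"].append((np.nonzero(isc & (b2 != G) & (b3 != G))[0] + 1, "+"))
    # minus strand: cytosine pairs with a plus-strand G at j; its downstream
    # bases on the minus strand are complements of j-1, j-2
    j3, j2, j1 = arr[: n - 2], arr[1 : n - 1], arr[2:]
    isg = j1 == G  # j >= 2
    sites["CpG"].append((np.nonzero(isg & (j2 == C))[0] + 3, "-"))
    sites["CHG"].append((np.nonzero(isg & (j2 != C) & (j3 == C))[0] + 3, "-"))
    sites["CHH"].append((np.nonzero(isg & (j2 != C) & (j3 != C))[0] + 3, "-"))
    out = {}
    for ctx, parts in sites.items():
        pos = np.concatenate([p for p, _ in parts])
        strand = np.concatenate(
            [np.full(len(p), 1 if s == "+" else 0, dtype=np.int8) for p, s in parts]
        )
        order = np.argsort(pos, kind="stable")
        out[ctx] = (pos[order], strand[order])
    return out


def _trinucleotide(seq: str, pos: int, strand: str) -> str:
    """3-mer read 5'->3' on the cytosine's strand (1-based plus coordinate)."""
    if strand == "+":
        return seq[pos - 1 : pos + 2]
    return _revcomp(seq[pos - 3 : pos])


def simulate_methylome(
    spec: LandscapeSpec,
    true_rate: np.ndarray,
    genome: str,
    rng: np.random.Generator | None = None,
    chrom: str = "chr1",
    level_threshold: float = 0.75,
    min_coverage: int = 10,
    background_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cytosine report records plus the retained window counts behind them.

    Retained cytosines (coverage >= min_coverage, level >= level_threshold)
    are drawn per window per context from the landscape-coupled count model
    and placed on real context sites of ``genome``. Extra background records
    — low methylation level or low coverage — are emitted interleaved and
    must be removed by the downstream filter without changing the retained
    counts.

    Returns (records, window_counts); records have the seven Bismark cytosine
    report columns.
    """
    if len(genome) != spec.chrom_length:
        raise ValidationError("genome length does not match spec.chrom_length")
    rng = rng or np.random.default_rng(spec.seed)
    counts = simulate_window_counts(spec, true_rate, rng)
    sites = _context_sites(genome)

    rows: list[tuple] = []
    strand_chr = {1: "+", 0: "-"}
    ctx_name = {"CpG": "CpG", "CHG": "CHG", "CHH": "CHH"}
    col_for = {"CpG": "cg", "CHG": "chg", "CHH": "chh"}
    min_meth_frac = level_threshold  # inclusive threshold downstream

    for _, wrow in counts.iterrows():
        lo, hi = int(wrow["start"]), int(wrow["end"])
        for ctx in ("CpG", "CHG", "CHH"):
            pos_all, strand_all = sites[ctx]
            i0, i1 = np.searchsorted(pos_all, [lo, hi + 1])
            avail = i1 - i0
            if avail == 0:
                continue
            want = int(wrow[col_for[ctx]])
            n_bg = int(rng.poisson(background_fraction * want)) if want else 0
            n_ret = min(want, avail)
            take = min(n_ret + n_bg, avail)
            pick = i0 + rng.choice(avail, size=take, replace=False)
            for k, si in enumerate(pick):
                pos = int(pos_all[si])
                strand = strand_chr[int(strand_all[si])]
                tri = _trinucleotide(genome, pos, strand)
                if k < n_ret:  # retained: coverage and level above both cutoffs
                    cov = min_coverage + int(rng.poisson(min_coverage))
                    m_min = math.ceil(min_meth_frac * cov)
                    n_meth = m_min + int(rng.binomial(cov - m_min, 0.85))
                else:  # background: low level, or low coverage with any level
                    if rng.random() < 0.5:
                        cov = max(int(rng.integers(1, min_coverage)), 1)
                        n_meth = int(rng.binomial(cov, 0.5))
                    else:
                        cov = min_coverage + int(rng.poisson(min_coverage))
                        cap = math.ceil(min_meth_frac * cov) - 1
                        n_meth = min(int(rng.binomial(cov, 0.2)), max(cap, 0))
                rows.append(
                    (chrom, pos, strand, n_meth, cov - n_meth, ctx_name[ctx], tri)
                )

    records = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "trinucleotide"],
    ).sort_values(["pos", "strand"], kind="stable", ignore_index=True)
    return records, counts


def simulate_genotypes(
    true_rate: np.ndarray,
    window_size: int,
    n_individuals: int,
    marker_positions: np.ndarray,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    chrom: str = "chr1",
) -> tuple[pd.DataFrame, list[np.ndarray]]:
    """Parental-origin genotype matrix of a haploid-phase (DH-like) population.

    Crossovers per individual are Poisson with mean = total map length (cM)
    / 100; breakpoints land in windows with probability proportional to the
    true rate, uniformly within a window. Founder phase is A at the left
    telomere, flipping at each breakpoint. Calls are masked to missing at
    ``missing_rate``.

    Returns (genotype table with marker_id/chrom/pos columns plus one column
    per individual, list of per-individual breakpoint arrays in bp).
    """
    if n_individuals < 2:
        raise ValidationError("n_individuals must be >= 2")
    marker_positions = np.asarray(marker_positions, dtype=np.int64)
    if len(marker_positions) == 0 or np.any(np.diff(marker_positions) <= 0):
        raise ValidationError("marker positions must be non-empty, strictly increasing")
    rng = rng if rng is not None else np.random.default_rng(seed)
    rate = np.asarray(true_rate, dtype=float)
    total_cm = float(rate.sum())
    n_win = len(rate)
    probs = rate / total_cm if total_cm > 0 else None

    breakpoints: list[np.ndarray] = []
    calls = np.zeros((len(marker_positions), n_individuals), dtype=np.int8)
    for ind in range(n_individuals):
        k = int(rng.poisson(total_cm / 100.0)) if total_cm > 0 else 0
        if k == 0:
            bps = np.empty(0, dtype=np.int64)
        else:
            for _ in range(20):  # bp ties at single-base resolution: redraw
                wins = rng.choice(n_win, size=k, p=probs)
                offs = rng.integers(0, window_size, size=k)
                bps = np.sort(wins.astype(np.int64) * window_size + offs + 1)
                if len(np.unique(bps)) == k:
                    break
        breakpoints.append(bps)
        n_flips = np.searchsorted(bps, marker_positions, side="left")
        calls[:, ind] = (n_flips % 2).astype(np.int8)  # 0 = A, 1 = B

    sym = np.where(calls == 0, "A", "B").astype(object)
    if missing_rate > 0:
        mask = rng.random(sym.shape) < missing_rate
        sym[mask] = "NA"
    gt = pd.DataFrame(
        sym, columns=[f"ind{j + 1}" for j in range(n_individuals)]
    )
    gt.insert(0, "pos", marker_positions)
    gt.insert(0, "chrom", chrom)
    gt.insert(0, "marker_id", [f"{chrom}_m{i + 1}" for i in range(len(marker_positions))])
    return gt, breakpoints


# ---------------------------------------------------------------------------
# writers — everything the pipeline reads back is plain TSV / FASTA

def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_cytosine_report(records: pd.DataFrame, path: str | Path) -> None:
    """Bismark-style cytosine report: 7 tab-separated columns, no header."""
    records.to_csv(path, sep="\t", header=False, index=False)


def write_genotypes(gt: pd.DataFrame, path: str | Path) -> None:
    gt.to_csv(path, sep="\t", index=False)


def write_truth(true_rate: np.ndarray, spec: LandscapeSpec, path: str | Path,
                chrom: str = "chr1") -> None:
    w = window_bounds(spec.chrom_length, spec.window_size)
    pd.DataFrame(
        {"chrom": chrom, "window_start": w["start"], "true_rate_cM": true_rate}
    ).to_csv(path, sep="\t", index=False)


@dataclass
class SpeciesData:
    """One synthetic species: per-chromosome truth and simulated inputs."""

    specs: dict[str, LandscapeSpec]
    true_rate: dict[str, np.ndarray]
    window_counts: pd.DataFrame  # chrom, window_index, start, end, cg, chg, chh
    genotypes: dict[str, pd.DataFrame]
    breakpoints: dict[str, list[np.ndarray]]

    def rate_track(self) -> pd.DataFrame:
        """Ground-truth rates in the rate-track layout consumed downstream."""
        frames = []
        for chrom, rate in self.true_rate.items():
            spec = self.specs[chrom]
            w = window_bounds(spec.chrom_length, spec.window_size)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "window_index": w["window_index"],
                        "start": w["start"],
                        "end": w["end"],
                        "rate": rate,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def simulate_species(
    n_chromosomes: int,
    seed: int,
    chrom_length: int = 20_000_000,
    n_individuals: int = 500,
    marker_spacing: int = DEFAULT_WINDOW,
    missing_rate: float = 0.02,
    count_scale: float = 1.0,
    **spec_overrides,
) -> SpeciesData:
    """Multi-chromosome synthetic species (fast path: window counts, no FASTA).

    ``count_scale`` multiplies all three context base counts — used to build
    transfer-test species with different methylome depths.
    """
    root = np.random.default_rng(seed)
    specs, rates, gts, bps = {}, {}, {}, {}
    tables = []
    for c in range(n_chromosomes):
        chrom = f"chr{c + 1}"
        sub = int(root.integers(0, 2**31 - 1))
        spec = LandscapeSpec(
            chrom_length=chrom_length,
            seed=sub,
            cg_base=300.0 * count_scale,
            chg_base=180.0 * count_scale,
            chh_base=80.0 * count_scale,
            **spec_overrides,
        )
        rng = np.random.default_rng(sub)
        rate = make_landscape(spec)
        counts = simulate_window_counts(spec, rate, rng)
        counts.insert(0, "chrom", chrom)
        markers = np.arange(marker_spacing, spec.chrom_length + 1, marker_spacing)
        gt, bp = simulate_genotypes(
            rate, spec.window_size, n_individuals, markers,
            missing_rate=missing_rate, rng=rng, chrom=chrom,
        )
        specs[chrom], rates[chrom], gts[chrom], bps[chrom] = spec, rate, gt, bp
        tables.append(counts)
    return SpeciesData(
        specs=specs,
        true_rate=rates,
        window_counts=pd.concat(tables, ignore_index=True),
        genotypes=gts,
        breakpoints=bps,
    )
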