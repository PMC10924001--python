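"""Genetic-map construction: Kosambi function, imputation, oracle equivalence."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epicross import features, recmap, simulate
from epicross.errors import ValidationError


# --- independent brute-force oracle (plain loops, scalar math) -------------

def oracle_rates(positions, calls, step, chrom_length=None):
    """Naive reimplementation of impute -> fractions -> Kosambi -> rates."""
    end = chrom_length if chrom_length is not None else positions[-1]
    grid = list(range(step, end + 1, step)) or [end]
    rows = []
    for g in grid:
        best, best_d = 0, abs(g - positions[0])
        for i, p in enumerate(positions):
            d = abs(g - p)
            if d < best_d:  # strict: midpoint ties keep the lower marker
                best, best_d = i, d
        rows.append(list(calls[best]))
    cm = [0.0]
    for k in range(len(grid) - 1):
        n = d = 0
        for a, b in zip(rows[k], rows[k + 1]):
            if a >= 0 and b >= 0:
                n += 1
                if a != b:
                    d += 1
        if n == 0:
            dist = 0.0
        else:
            r = min(d / n, 0.5 - 1e-6)
            dist = 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))
        cm.append(cm[-1] + dist)
    # rates on window boundaries 0, W, 2W, ... by nearest-anchor imputation
    n_win = math.ceil(end / step)
    bounds = [k * step for k in range(n_win + 1) if k * step <= end]
    bcm = []
    for b in bounds:
        best, best_d = 0, abs(b - grid[0])
        for i, g in enumerate(grid):
            d = abs(b - g)
            if d < best_d:
                best, best_d = i, d
        bcm.append(cm[best])
    rates = [max(bcm[k + 1] - bcm[k], 0.0) for k in range(len(bcm) - 1)]
    rates += [float("nan")] * (n_win - len(rates))
    return rates


class TestKosambi:
    def test_closed_form_values(self):
        assert recmap.kosambi_cm(0.0) == 0.0
        assert recmap.kosambi_cm(0.25) == pytest.approx(25 * math.log(3), abs=1e-12)
        assert recmap.kosambi_cm(0.01) == pytest.approx(1.0, rel=1e-3)  # ~100*r small-r

    def test_strictly_increasing(self):
        grid = np.linspace(0, 0.499, 400)
        vals = recmap.kosambi_cm(grid)
        assert np.all(np.diff(vals) > 0)

    def test_round_trip_inverse(self):
        grid = np.linspace(0, 0.499, 500)
        back = recmap.kosambi_inverse(recmap.kosambi_cm(grid))
        np.testing.assert_allclose(back, grid, atol=1e-12)

    def test_rejects_half(self):
        with pytest.raises(ValidationError):
            recmap.kosambi_cm(0.5)


class TestImpute:
    def test_midpoint_tie_goes_to_lower_marker(self):
        pos = np.array([100_000, 300_000])
        calls = np.array([[0, 0], [1, 1]], dtype=np.int8)
        grid, rows = recmap.impute_rows(pos, calls, step=200_000, chrom_length=300_000)
        # grid 200k is equidistant (100k) from both markers
        assert list(grid) == [200_000]
        assert list(rows[0]) == [0, 0]

    def test_hand_distances(self):
        pos = np.array([40_000, 260_000])
        calls = np.array([[0], [1]], dtype=np.int8)
        grid, rows = recmap.impute_rows(pos, calls, step=100_000)
        assert list(grid) == [100_000, 200_000]
        assert rows[0][0] == 0  # |100k-40k| = 60k < 160k
        assert rows[1][0] == 1  # |200k-260k| = 60k < 160k

    def test_single_marker_gives_flat_map(self):
        pos = np.array([150_000])
        calls = np.array([[0, 1, 0]], dtype=np.int8)
        gm = recmap.GenotypeMatrix(
            positions={"chr1": pos}, calls={"chr1": calls}, individuals=["a", "b", "c"]
        )
        gmap = recmap.map_from_genotypes(gm, step=50_000, chrom_lengths={"chr1": 400_000})
        assert gmap.total_length("chr1") == 0.0

    def test_missing_entries_copied(self):
        pos = np.array([100_000])
        calls = np.array([[0, -1]], dtype=np.int8)
        _, rows = recmap.impute_rows(pos, calls, step=100_000, chrom_length=200_000)
        assert list(rows[1]) == [0, -1]


class TestRecombinationFraction:
    def test_identical_rows(self):
        row = np.zeros(10, dtype=np.int8)
        assert recmap.recombination_fraction(row, row) == (0.0, 10)

    def test_hand_counts(self):
        a = np.zeros(10, dtype=np.int8)
        b = np.zeros(10, dtype=np.int8)
        b[:2] = 1
        r, n = recmap.recombination_fraction(a, b)
        assert (r, n) == (0.2, 10)

    def test_missing_reduces_informative_count(self):
        a = np.zeros(10, dtype=np.int8)
        a[:3] = -1
        b = np.zeros(10, dtype=np.int8)
        assert recmap.recombination_fraction(a, b)[1] == 7

    def test_all_missing_is_undefined(self):
        a = np.full(5, -1, dtype=np.int8)
        r, n = recmap.recombination_fraction(a, a)
        assert n == 0 and math.isnan(r)


class TestRatesFromMap:
    def test_linear_map_constant_rate(self):
        anchors = pd.DataFrame({"pos": np.arange(0, 600_001, 100_000),
                                "cM": np.arange(0.0, 6.1, 1.0)})
        gmap = recmap.GeneticMap(anchors={"chr1": anchors})
        rates = recmap.rates_from_map(gmap, window_size=100_000)
        np.testing.assert_allclose(rates["rate"].to_numpy(), 1.0)

    def test_plateau_gives_zero_rates(self):
        anchors = pd.DataFrame(
            {"pos": [0, 100_000, 200_000, 300_000], "cM": [0.0, 2.0, 2.0, 2.0]}
        )
        gmap = recmap.GeneticMap(anchors={"chr1": anchors})
        rates = recmap.rates_from_map(gmap, window_size=100_000)
        assert list(rates["rate"]) == [2.0, 0.0, 0.0]

    def test_hand_oracle_two_anchors(self):
        # anchors (0 bp, 0 cM), (250 kb, 5 cM): boundary cM = [0, 0, 5] by
        # nearest-anchor copy, so rates = [0, 5] and the partial window is NaN
        anchors = pd.DataFrame({"pos": [0, 250_000], "cM": [0.0, 5.0]})
        gmap = recmap.GeneticMap(anchors={"chr1": anchors})
        rates = recmap.rates_from_map(gmap, window_size=100_000)
        assert list(rates["rate"][:2]) == [0.0, 5.0]
        assert math.isnan(rates["rate"].iloc[2])

    def test_non_monotone_map_rejected(self):
        anchors = pd.DataFrame({"pos": [0, 100_000], "cM": [1.0, 0.5]})
        with pytest.raises(ValidationError):
            recmap.GeneticMap(anchors={"chr1": anchors})

    def test_telescoping_sum(self):
        rng = np.random.default_rng(3)
        cm = np.cumsum(rng.random(20))
        anchors = pd.DataFrame({"pos": np.arange(20) * 100_000, "cM": cm})
        gmap = recmap.GeneticMap(anchors={"chr1": anchors})
        rates = recmap.rates_from_map(gmap, window_size=100_000)
        defined = rates["rate"].dropna()
        assert defined.sum() == pytest.approx(cm[-1] - cm[0], abs=1e-9)


class TestMapFromGenotypes:
    def test_two_intervals_closed_form(self):
        # three grid rows with r = 0.1 between consecutive pairs
        pos = np.array([100_000, 200_000, 300_000])
        calls = np.zeros((3, 10), dtype=np.int8)
        calls[1, :1] = 1  # r(1,2)=0.1
        calls[2, :2] = 1  # r(2,3)=0.1
        gm = recmap.GenotypeMatrix(
            positions={"chr1": pos}, calls={"chr1": calls},
            individuals=[f"i{k}" for k in range(10)],
        )
        gmap = recmap.map_from_genotypes(gm, step=100_000, chrom_lengths={"chr1": 300_000})
        expected = 2 * 25 * math.log((1 + 0.2) / (1 - 0.2))
        assert gmap.total_length("chr1") == pytest.approx(expected, abs=1e-12)

    def test_identical_rows_flat_map(self):
        pos = np.array([100_000, 200_000, 300_000])
        calls = np.zeros((3, 6), dtype=np.int8)
        gm = recmap.GenotypeMatrix(
            positions={"chr1": pos}, calls={"chr1": calls},
            individuals=[f"i{k}" for k in range(6)],
        )
        gmap = recmap.map_from_genotypes(gm, step=100_000)
        assert gmap.total_length("chr1") == 0.0

    def test_oracle_equivalence_randomized_sweep(self):
        rng = np.random.default_rng(42)
        for trial in range(60):
            n_mark = int(rng.integers(1, 7))
            n_ind = int(rng.integers(2, 9))
            miss = float(rng.uniform(0, 0.3))
            pos = np.sort(rng.choice(np.arange(1, 60), n_mark, replace=False)) * 10_000
            calls = rng.integers(0, 2, size=(n_mark, n_ind)).astype(np.int8)
            calls[rng.random(calls.shape) < miss] = -1
            gm = recmap.GenotypeMatrix(
                positions={"c": pos}, calls={"c": calls},
                individuals=[f"i{k}" for k in range(n_ind)],
            )
            L = int(pos[-1])
            rates, _ = recmap.rates_from_genotypes(gm, window_size=100_000,
                                                   chrom_lengths={"c": L})
            expected = oracle_rates(list(pos), calls.tolist(), 100_000, L)
            got = rates["rate"].to_numpy()
            assert len(got) == len(expected)
            for g, e in zip(got, expected):
                if math.isnan(e):
                    assert math.isnan(g)
                else:
                    assert g == pytest.approx(e, abs=1e-12)

    def test_oracle_equivalence_exhaustive_two_by_two(self):
        # every call pattern (A/B/missing) for 2 markers x 2 individuals
        pos = np.array([40_000, 260_000])
        patterns = [(a, b, c, d)
                    for a in (-1, 0, 1) for b in (-1, 0, 1)
                    for c in (-1, 0, 1) for d in (-1, 0, 1)]
        for a, b, c, d in patterns:
            calls = np.array([[a, b], [c, d]], dtype=np.int8)
            gm = recmap.GenotypeMatrix(
                positions={"c": pos}, calls={"c": calls}, individuals=["x", "y"]
            )
            rates, _ = recmap.rates_from_genotypes(gm, window_size=100_000,
                                                   chrom_lengths={"c": 300_000})
            expected = oracle_rates([40_000, 260_000], calls.tolist(), 100_000, 300_000)
            for g, e in zip(rates["rate"], expected):
                assert (math.isnan(g) and math.isnan(e)) or g == pytest.approx(e, abs=1e-12)


class TestSyntheticRecovery:
    def test_map_and_landscape_recovered(self):
        # n=500 individuals, markers every 100 kb, 200 windows; comparison on
        # the alpha=0.1 smoothed scale (pilot over 20 seeds: min r 0.953)
        spec = simulate.LandscapeSpec(chrom_length=20_000_000, seed=13)
        rate = simulate.make_landscape(spec)
        rng = np.random.default_rng(13)
        markers = np.arange(100_000, spec.chrom_length + 1, 100_000)
        gt, _ = simulate.simulate_genotypes(rate, 100_000, 500, markers,
                                            missing_rate=0.02, rng=rng)
        gm = recmap.genotype_matrix_from_frame(gt)
        rates, gmap = recmap.rates_from_genotypes(
            gm, window_size=100_000, chrom_lengths={"chr1": spec.chrom_length}
        )
        est = rates["rate"].to_numpy()
        ok = ~np.isnan(est)
        r = stats.pearsonr(features.smooth(est[ok], 0.1), features.smooth(rate[ok], 0.1))[0]
        assert r >= 0.8
        assert abs(np.nansum(est) - rate.sum()) <= 0.1 * rate.sum()


def test_genotype_io_roundtrip(tmp_path):
    rate = np.full(30, 1.0)
    gt, _ = simulate.simulate_genotypes(
        rate, 100_000, 8, np.arange(100_000, 3_000_001, 100_000),
        missing_rate=0.1, seed=6,
    )
    path = tmp_path / "geno.tsv"
    simulate.write_genotypes(gt, path)
    gm = recmap.read_genotypes(path)
    gm2 = recmap.genotype_matrix_from_frame(gt)
    np.testing.assert_array_equal(gm.calls["chr1"], gm2.calls["chr1"])
    np.testing.assert_array_equal(gm.positions["chr1"], gm2.positions["chr1"])


def test_unrecognized_calls_treated_missing_or_strict(tmp_path):
    path = tmp_path / "g.tsv"
    path.write_text("marker_id\tchrom\tpos\ti1\ti2\nm1\tchr1\t100\tA\tH\nm2\tchr1\t200\tB\tB\n")
    gm = recmap.read_genotypes(path)
    assert gm.calls["chr1"][0, 1] == -1
    with pytest.raises(ValidationError):
        recmap.read_genotypes(path, strict_calls=True)
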