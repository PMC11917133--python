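"""Windowed pi / d_XY / FST against independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from divscan import windows as win
from divscan.io import MISSING
from conftest import make_vt, make_pm


# ---------------------------------------------------------------- oracles

def haplotypes(g):
    """Expand unphased genotypes to a haplotype matrix (2N x S).

    Per-site allele counts are phase-invariant, so an arbitrary phase
    (alt allele on the first haplotype of each heterozygote) is exact for
    count-based statistics.
    """
    g = np.asarray(g)
    h = np.zeros((2 * g.shape[1], g.shape[0]), dtype=int)
    for j in range(g.shape[1]):
        h[2 * j] = (g[:, j] >= 1).astype(int)
        h[2 * j + 1] = (g[:, j] == 2).astype(int)
    return h


def brute_pi(g, length):
    """Mean pairwise haplotype difference over all C(n,2) pairs, per bp."""
    h = haplotypes(g)
    total = sum(np.sum(h[i] != h[j]) for i, j in
                itertools.combinations(range(len(h)), 2))
    npairs = len(h) * (len(h) - 1) / 2
    return total / npairs / length

def brute_dxy(gA, gB, length):
    """Mean between-population haplotype-pair difference, per bp."""
    hA, hB = haplotypes(gA), haplotypes(gB)
    total = sum(np.sum(a != b) for a in hA for b in hB)
    return total / (len(hA) * len(hB)) / length

def wc_1984_theta(gA, gB):
    """Independent transcription of the 1984 variance components, r=2,
    computed site by site with plain Python scalars."""
    num = den = 0.0
    for sA, sB in zip(gA, gB):
        sA = [x for x in sA if x != MISSING]
        sB = [x for x in sB if x != MISSING]
        n1, n2 = len(sA), len(sB)
        if n1 < 2 or n2 < 2:
            continue
        p1 = sum(sA) / (2 * n1)
        p2 = sum(sB) / (2 * n2)
        h1 = sum(1 for x in sA if x == 1) / n1
        h2 = sum(1 for x in sB if x == 1) / n2
        r = 2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        if a + b + c != 0:
            num += a
            den += a + b + c
    return num / den

def brute_tau_b(x, y):
    """Tau-b from explicit concordant/discordant pair counts."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - tx) * (n0 - ty))


# ----------------------------------------------------------------- windows

class TestMakeWindows:
    def test_partial_final_window(self):
        w = win.make_windows({"c": 1_200_000}, 500_000)
        assert len(w) == 3
        assert (w.loc[2, "start"], w.loc[2, "end"]) == (1_000_000, 1_200_000)
        assert list(w["partial"]) == [False, False, True]

    def test_genome_scale_window_count(self):
        # 31 contigs, 435.6 Mb total at 500 kb -> each window ~0.125% of
        # the genome, i.e. ~880 windows within partial-window rounding
        rng = np.random.default_rng(5)
        sizes = rng.multinomial(435_600_000 - 31 * 2_000_000,
                                np.ones(31) / 31) + 2_000_000
        w = win.make_windows({f"c{i}": int(s) for i, s in enumerate(sizes)},
                             500_000)
        assert 872 <= len(w) <= 903

    def test_window_larger_than_contig(self):
        w = win.make_windows({"c": 100}, 500_000)
        assert len(w) == 1 and w.loc[0, "partial"]


class TestSitePi:
    @pytest.mark.parametrize("j,n,expected", [
        (1, 2, 1.0),              # two chromosomes, one difference
        (0, 20, 0.0),             # monomorphic
        (20, 20, 0.0),
        (5, 20, 150.0 / 380.0),   # 75 differing of C(20,2)=190 pairs
    ])
    def test_closed_form(self, j, n, expected):
        assert win.site_pi(np.array([j]), np.array([n]))[0] == pytest.approx(expected, abs=1e-15)

    def test_single_chromosome_undefined(self):
        assert np.isnan(win.site_pi(np.array([1]), np.array([1]))[0])


class TestWindowPi:
    def test_single_het_pair(self):
        vt = make_vt([[1, 1]], pos=[500])
        pm = make_pm(vt, {"P": 2})
        w = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        # j=2 of n=4: pi_site = 2*2*2/(4*3) = 2/3
        res = win.window_pi(vt, pm, w)
        assert res.loc[0, "pi_P"] == pytest.approx((2 / 3) / 1000)

    def test_zero_variants_zero_pi(self):
        vt = make_vt(np.zeros((0, 4)).astype(int).reshape(0, 4))
        pm = make_pm(vt, {"P": 4})
        w = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        assert win.window_pi(vt, pm, w).loc[0, "pi_P"] == 0.0

    def test_brute_force_oracle(self, rng):
        g = rng.integers(0, 3, size=(100, 6)).astype(np.int8)
        vt = make_vt(g, pos=rng.choice(np.arange(1, 2001), 100, replace=False))
        pm = make_pm(vt, {"P": 6})
        w = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2000]})
        res = win.window_pi(vt, pm, w)
        assert res.loc[0, "pi_P"] == pytest.approx(brute_pi(g, 2000), abs=1e-12)


class TestWindowDxy:
    def _setup(self, gA, gB, length=1000):
        g = np.hstack([gA, gB]).astype(np.int8)
        vt = make_vt(g, pos=np.arange(1, len(g) + 1))
        pm = make_pm(vt, {"A": gA.shape[1], "B": gB.shape[1]})
        w = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [length]})
        return vt, pm, w

    def test_fixed_difference(self):
        vt, pm, w = self._setup(np.zeros((1, 3)), np.full((1, 3), 2))
        assert win.window_dxy(vt, pm, w, "A", "B").loc[0, "dxy"] == pytest.approx(1e-3)

    def test_identical_fixed_sites_zero(self):
        vt, pm, w = self._setup(np.full((5, 3), 2), np.full((5, 3), 2))
        assert win.window_dxy(vt, pm, w, "A", "B").loc[0, "dxy"] == 0.0

    def test_brute_force_oracle_and_symmetry(self, rng):
        gA = rng.integers(0, 3, size=(50, 4))
        gB = rng.integers(0, 3, size=(50, 5))
        vt, pm, w = self._setup(gA, gB)
        ab = win.window_dxy(vt, pm, w, "A", "B").loc[0, "dxy"]
        ba = win.window_dxy(vt, pm, w, "B", "A").loc[0, "dxy"]
        assert ab == ba  # exact symmetry
        assert ab == pytest.approx(brute_dxy(gA, gB, 1000), abs=1e-12)


class TestWcFst:
    def test_fixed_difference_theta_one(self):
        g = np.hstack([np.zeros((3, 4)), np.full((3, 4), 2)]).astype(np.int8)
        vt = make_vt(g)
        pm = make_pm(vt, {"A": 4, "B": 4})
        assert win.wc_fst(vt, pm, "A", "B") == pytest.approx(1.0)

    def test_identical_configurations_nonpositive(self):
        block = np.array([[0, 1, 2, 1], [1, 1, 0, 2], [2, 0, 1, 1]])
        g = np.hstack([block, block]).astype(np.int8)
        vt = make_vt(g)
        pm = make_pm(vt, {"A": 4, "B": 4})
        assert win.wc_fst(vt, pm, "A", "B") <= 0.0

    def test_independent_formula_transcription(self, rng):
        gA = rng.integers(0, 3, size=(3, 4))
        gB = rng.integers(0, 3, size=(3, 4))
        g = np.hstack([gA, gB]).astype(np.int8)
        vt = make_vt(g)
        pm = make_pm(vt, {"A": 4, "B": 4})
        assert win.wc_fst(vt, pm, "A", "B") == pytest.approx(
            wc_1984_theta(gA.tolist(), gB.tolist()), abs=1e-10)

    def test_too_few_called_diploids_undefined(self):
        g = np.array([[0, MISSING, MISSING, 2, 2, 2]], dtype=np.int8)
        vt = make_vt(g)
        pm = make_pm(vt, {"A": 3, "B": 3})
        w = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        assert np.isnan(win.wc_fst(vt, pm, "A", "B", w).loc[0, "fst"])


class TestKendallTau:
    def test_perfect_orders(self):
        x = np.arange(10.0)
        assert win.kendall_tau(x, x * 2 + 1)[0] == pytest.approx(1.0)
        assert win.kendall_tau(x, -x)[0] == pytest.approx(-1.0)

    def test_brute_force_n7(self, rng):
        for _ in range(5):
            x = rng.integers(0, 5, 7).astype(float)  # ties likely
            y = rng.integers(0, 5, 7).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            tau, _ = win.kendall_tau(x, y)
            assert tau == pytest.approx(brute_tau_b(x, y), abs=1e-12)

    def test_all_tied_undefined(self):
        tau, p = win.kendall_tau(np.ones(5), np.arange(5.0))
        assert np.isnan(tau) and np.isnan(p)


class TestAggregation:
    def test_coarse_equals_weighted_fine(self, rng):
        # 500-kb pi computed natively equals the length-weighted mean of
        # its five 100-kb windows
        g = rng.integers(0, 3, size=(400, 6)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 1_000_001), 400, replace=False))
        vt = make_vt(g, pos=pos)
        pm = make_pm(vt, {"P": 6})
        ci = {"chr1": 1_000_000}
        fine = win.window_pi(vt, pm, win.make_windows(ci, 100_000))
        coarse_native = win.window_pi(vt, pm, win.make_windows(ci, 500_000))
        agg = win.aggregate_windows(fine, win.make_windows(ci, 500_000), ["pi_P"])
        np.testing.assert_allclose(agg["pi_P"], coarse_native["pi_P"], atol=1e-12)


def test_panmixia_dxy_matches_mean_pi():
    # with essentially no differentiation, between-population divergence
    # equals average within-population diversity (cf. the d_XY-pi link)
    from divscan.simulate import SimScenario, simulate_structured_genotypes
    scn = SimScenario(pop_names=("A", "B"), diploids_per_pop=(10, 10),
                      F=(1e-4, 1e-4), n_chrom=1, chrom_length=500_000,
                      n_sites=5000, seed=11)
    vt, pm, ci = simulate_structured_genotypes(scn)
    w = win.make_windows(ci, 100_000)
    dxy = win.window_dxy(vt, pm, w, "A", "B")["dxy"].mean()
    pi = win.window_pi(vt, pm, w)
    mean_pi = (pi["pi_A"] + pi["pi_B"]).mean() / 2
    assert abs(dxy - mean_pi) / mean_pi < 0.05
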