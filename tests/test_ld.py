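"""LD engine checks against independent brute-force oracles.

The oracles re-derive the two-locus multinomial likelihood by explicit
haplotype-pair enumeration, never through the package's probability code.
"""

import itertools
import math

import numpy as np
import pytest

import dsnchip as dc
from dsnchip import ld
from dsnchip.variants import MISSING

from conftest import make_genotype_matrix

_HAPS = [(0, 0), (0, 1), (1, 0), (1, 1)]  # (allele at A, allele at B)


def oracle_loglik(counts33, freqs):
    """Log-likelihood by summing over ordered haplotype pairs."""
    ll = 0.0
    for ga in range(3):
        for gb in range(3):
            if counts33[ga][gb] == 0:
                continue
            p = 0.0
            for (a1, b1), f1 in zip(_HAPS, freqs):
                for (a2, b2), f2 in zip(_HAPS, freqs):
                    if a1 + a2 == ga and b1 + b2 == gb:
                        p += f1 * f2
            ll += counts33[ga][gb] * math.log(max(p, 1e-300))
    return ll


def pair_counts33(g1, g2):
    counts = [[0] * 3 for _ in range(3)]
    for a, b in zip(g1, g2):
        if a != MISSING and b != MISSING:
            counts[a][b] += 1
    return counts


def sample_allele_freqs(counts33):
    n = sum(sum(row) for row in counts33)
    pa = sum((i) * sum(counts33[i]) for i in range(3)) / (2 * n)
    pb = sum((j) * sum(counts33[i][j] for i in range(3)) for j in range(3)) / (2 * n)
    return pa, pb


def freqs_from(pa, pb, faa):
    return (1 - pa - pb + faa, pb - faa, pa - faa, faa)


def random_pair(rng, n_animals, missing_rate=0.0):
    """A random polymorphic genotype pair (haplotype-based, so LD varies)."""
    while True:
        f = rng.dirichlet(np.ones(4))
        h = rng.choice(4, size=(n_animals, 2), p=f)
        alleles = np.array(_HAPS)
        g1 = alleles[h[:, 0], 0] + alleles[h[:, 1], 0]
        g2 = alleles[h[:, 0], 1] + alleles[h[:, 1], 1]
        g1, g2 = g1.astype(np.int8), g2.astype(np.int8)
        if missing_rate:
            g1[rng.random(n_animals) < missing_rate] = MISSING
            g2[rng.random(n_animals) < missing_rate] = MISSING
        ok = (g1 != MISSING) & (g2 != MISSING)
        if ok.sum() >= 5 and 0 < g1[ok].sum() < 2 * ok.sum() and 0 < g2[ok].sum() < 2 * ok.sum():
            return g1, g2


class TestEMHaplotypeFreqs:
    def test_no_double_het_equals_direct_counting(self):
        g1 = np.array([0, 0, 1, 2, 2, 1, 0], dtype=np.int8)
        g2 = np.array([0, 0, 0, 2, 2, 2, 0], dtype=np.int8)
        assert not np.any((g1 == 1) & (g2 == 1)), "fixture must avoid double heterozygotes"
        # phase unambiguous: tally each animal's two haplotypes directly
        tally = {h: 0 for h in _HAPS}
        for a, b in zip(g1, g2):
            ha = [0, 0] if a == 0 else [1, 1] if a == 2 else [0, 1]
            hb = [0, 0] if b == 0 else [1, 1] if b == 2 else [0, 1]
            tally[(ha[0], hb[0])] += 1
            tally[(ha[1], hb[1])] += 1
        total = sum(tally.values())
        expected = [tally[h] / total for h in _HAPS]
        result = dc.em_haplotype_freqs(g1, g2)
        np.testing.assert_allclose(result, expected, atol=1e-9)

    def test_perfect_ld_identical_vectors(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1, 1], dtype=np.int8)  # AAF 0.5
        freqs = dc.em_haplotype_freqs(g, g)
        np.testing.assert_allclose(freqs, (0.5, 0.0, 0.0, 0.5), atol=1e-7)
        stats = dc.dprime_ci(g, g)
        assert stats.dprime == pytest.approx(1.0, abs=1e-9)
        assert stats.r2 == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(12))
    def test_em_beats_fine_grid_oracle(self, seed):
        """EM solution maximises the likelihood over the single free
        parameter (f_aa), checked on a 1e-5 grid: the EM frequencies sit
        within 1e-4 of the grid argmax and never score a lower likelihood."""
        rng = np.random.default_rng(seed)
        g1, g2 = random_pair(rng, n_animals=int(rng.integers(8, 31)), missing_rate=0.1)
        counts = pair_counts33(g1, g2)
        pa, pb = sample_allele_freqs(counts)
        lo, hi = max(0.0, pa + pb - 1.0), min(pa, pb)
        grid = np.linspace(lo, hi, max(2, int((hi - lo) / 1e-5)))
        lls = [oracle_loglik(counts, freqs_from(pa, pb, faa)) for faa in grid]
        best = grid[int(np.argmax(lls))]
        em = dc.em_haplotype_freqs(g1, g2)
        assert abs(em[3] - best) < 1e-4
        # slack reflects the EM stopping rule (1e-8 on frequencies)
        assert oracle_loglik(counts, em) >= max(lls) - 1e-6

    def test_monomorphic_flagged(self):
        g1 = np.array([0, 0, 0, 0], dtype=np.int8)
        g2 = np.array([0, 1, 2, 1], dtype=np.int8)
        with pytest.raises(dc.LDUndefinedError):
            dc.em_haplotype_freqs(g1, g2)
        with pytest.raises(dc.LDUndefinedError):
            dc.dprime_ci(g2, g1)


def oracle_ci(counts33, grid_points=101):
    """Brute-force CI: normalise the likelihood over the |D'| grid."""
    pa, pb = sample_allele_freqs(counts33)
    # point estimate sign via fine-grid MLE of f_aa
    lo, hi = max(0.0, pa + pb - 1.0), min(pa, pb)
    grid_f = np.linspace(lo, hi, 2000)
    best_faa = grid_f[int(np.argmax([oracle_loglik(counts33, freqs_from(pa, pb, f)) for f in grid_f]))]
    d = best_faa - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
        sign = 1.0
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
        sign = -1.0
    lls = []
    for k in range(grid_points):
        dp = k / (grid_points - 1)
        faa = pa * pb + sign * dp * dmax
        f = np.clip(freqs_from(pa, pb, faa), 1e-12, None)
        lls.append(oracle_loglik(counts33, f))
    w = np.exp(np.array(lls) - max(lls))
    cdf = np.cumsum(w) / w.sum()
    ci_low = np.argmax(cdf >= 0.05) / (grid_points - 1)
    ci_high = np.argmax(cdf >= 0.95) / (grid_points - 1)
    return ci_low, ci_high


class TestDPrimeCI:
    def test_six_animal_toy_equals_direct_summation(self):
        g1 = np.array([0, 1, 1, 2, 0, 1], dtype=np.int8)
        g2 = np.array([0, 1, 0, 2, 0, 2], dtype=np.int8)
        stats = dc.dprime_ci(g1, g2)
        lo, hi = oracle_ci(pair_counts33(g1, g2))
        assert stats.ci_low == pytest.approx(lo, abs=1e-12)
        assert stats.ci_high == pytest.approx(hi, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_pairs_match_oracle_within_grid_step(self, seed):
        rng = np.random.default_rng(100 + seed)
        g1, g2 = random_pair(rng, 20, missing_rate=0.05)
        stats = dc.dprime_ci(g1, g2)
        lo, hi = oracle_ci(pair_counts33(g1, g2))
        assert abs(stats.ci_low - lo) <= 0.01 + 1e-9
        assert abs(stats.ci_high - hi) <= 0.01 + 1e-9

    def test_perfect_ld_pair_has_tight_high_ci(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, 100).astype(np.int8)
        stats = dc.dprime_ci(g, g)
        assert stats.ci_low > 0.9

    def test_independent_loci_ci_high_below_strong_threshold(self):
        """Loci simulated at linkage equilibrium with 1000 animals: point D'
        near 0 and the CI upper bound well below 0.85 in most seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            g1 = rng.binomial(2, 0.4, 1000).astype(np.int8)
            g2 = rng.binomial(2, 0.5, 1000).astype(np.int8)
            stats = dc.dprime_ci(g1, g2)
            if stats.dprime < 0.15 and stats.ci_high < 0.85:
                hits += 1
        assert hits >= 9

    @pytest.mark.parametrize("seed", range(15))
    def test_r2_bounded_by_dprime_squared(self, seed):
        rng = np.random.default_rng(200 + seed)
        g1, g2 = random_pair(rng, 30, missing_rate=0.1)
        stats = dc.dprime_ci(g1, g2)
        assert stats.r2 <= stats.dprime**2 + 1e-9

    @pytest.mark.parametrize("seed", range(8))
    def test_allele_label_swap_invariance(self, seed):
        rng = np.random.default_rng(300 + seed)
        g1, g2 = random_pair(rng, 25)
        base = dc.dprime_ci(g1, g2)
        swapped = dc.dprime_ci((2 - g1).astype(np.int8), g2)
        assert swapped.dprime == pytest.approx(base.dprime, abs=1e-6)
        assert swapped.r2 == pytest.approx(base.r2, abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_duplicating_animals_fixes_point_never_widens_ci(self, seed):
        rng = np.random.default_rng(400 + seed)
        g1, g2 = random_pair(rng, 20)
        base = dc.dprime_ci(g1, g2)
        doubled = dc.dprime_ci(np.tile(g1, 2), np.tile(g2, 2))
        assert doubled.dprime == pytest.approx(base.dprime, abs=1e-6)
        assert doubled.r2 == pytest.approx(base.r2, abs=1e-6)
        assert doubled.ci_high - doubled.ci_low <= base.ci_high - base.ci_low + 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_scalar_and_batched_paths_agree(self, seed):
        rng = np.random.default_rng(500 + seed)
        g1, g2 = random_pair(rng, 40, missing_rate=0.1)
        s = dc.dprime_ci(g1, g2)
        out = dc.pairwise_ld(np.vstack([g1, g2]), np.array([0]), np.array([1]))
        assert out["defined"][0]
        assert out["dprime"][0] == pytest.approx(s.dprime, abs=1e-9)
        assert out["r2"][0] == pytest.approx(s.r2, abs=1e-9)
        assert out["ci_low"][0] == pytest.approx(s.ci_low, abs=1e-9)
        assert out["ci_high"][0] == pytest.approx(s.ci_high, abs=1e-9)


def oracle_blocks(codes, positions, cfg):
    """Exhaustive enumeration of admissible spans under the pair classes
    derived from the scalar LD path, resolved longest-span-first."""
    n = len(positions)
    cls = {}
    for i, j in itertools.combinations(range(n), 2):
        try:
            s = dc.dprime_ci(codes[i], codes[j], cfg)
        except dc.LDUndefinedError:
            cls[(i, j)] = None
            continue
        if s.n_informative < cfg.min_informative_animals:
            cls[(i, j)] = None
        elif s.ci_low >= cfg.strong_ci_low and s.ci_high >= cfg.strong_ci_high:
            cls[(i, j)] = "strong"
        elif s.ci_high < cfg.recomb_ci_high:
            cls[(i, j)] = "recomb"
        else:
            cls[(i, j)] = None
    spans = []
    for i, j in itertools.combinations(range(n), 2):
        if positions[j] - positions[i] > cfg.window_bp:
            continue
        pairs = [cls[(a, b)] for a, b in itertools.combinations(range(i, j + 1), 2)]
        informative = [c for c in pairs if c is not None]
        if not informative:
            continue
        if sum(c == "strong" for c in informative) >= cfg.informative_fraction * len(informative):
            spans.append((positions[j] - positions[i], i, j))
    spans.sort(key=lambda t: (-t[0], t[1], t[2]))
    used = set()
    blocks = []
    for _, i, j in spans:
        if any(x in used for x in range(i, j + 1)):
            continue
        used.update(range(i, j + 1))
        blocks.append((i, j))
    return sorted(blocks)


class TestCallBlocks:
    def test_perfect_ld_run_is_one_block(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, 100).astype(np.int8)
        gm = make_genotype_matrix(np.tile(g, (5, 1)))
        blocks = dc.call_blocks(gm, "1", [1000, 3000, 5000, 8000, 11000])
        assert len(blocks) == 1
        assert blocks[0].variant_ids == tuple(gm.variant_ids)

    def test_window_cap_never_merges_distant_triplets(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, 100).astype(np.int8)
        gm = make_genotype_matrix(np.tile(g, (6, 1)))
        positions = [1000, 2000, 3000, 303000, 304000, 305000]
        blocks = dc.call_blocks(gm, "1", positions)
        assert len(blocks) == 2
        assert {len(b.variant_ids) for b in blocks} == {3}

    def test_unsorted_positions_rejected(self):
        gm = make_genotype_matrix(np.zeros((2, 4), dtype=np.int8))
        with pytest.raises(ValueError, match="sorted"):
            dc.call_blocks(gm, "1", [500, 100])

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_enumeration(self, seed):
        """Block set identical to brute-force enumeration on 8-SNP instances."""
        rng = np.random.default_rng(seed)
        n_snp, n_animals = 8, 60
        # a mix of shared-haplotype structure and independent noise
        f = rng.dirichlet(np.ones(3))
        founders = (rng.random((3, n_snp)) < rng.beta(0.8, 0.8, n_snp)).astype(np.int8)
        h = rng.choice(3, size=(n_animals, 2), p=f)
        codes = (founders[h[:, 0]] + founders[h[:, 1]]).T.astype(np.int8)
        noise = rng.random((n_snp, n_animals)) < 0.15
        codes[noise] = rng.integers(0, 3, int(noise.sum()))
        positions = np.sort(rng.choice(150_000, n_snp, replace=False)) + 1
        keep = []
        for i in range(n_snp):
            col = codes[i]
            if 0 < col.sum() < 2 * n_animals:
                keep.append(i)
        codes, positions = codes[keep], positions[keep]
        gm = make_genotype_matrix(codes)
        cfg = dc.BlockConfig()
        result = dc.call_blocks(gm, "1", positions, cfg)
        got = sorted(
            (gm.variant_ids.index(b.variant_ids[0]), gm.variant_ids.index(b.variant_ids[-1]))
            for b in result
        )
        assert got == oracle_blocks(codes, positions, cfg)


class TestSimulatedCohortLD:
    def test_within_block_dprime_exceeds_between_block(self, small_cohort):
        gm = small_cohort.genotypes
        pos = np.array([v.pos for v in small_cohort.variants])
        block_of = {}
        for bi, b in enumerate(small_cohort.true_blocks):
            for vid in b.variant_ids:
                block_of[vid] = bi
        rng = np.random.default_rng(0)
        within_a, within_b, across_a, across_b = [], [], [], []
        ids = gm.variant_ids
        for _ in range(3000):
            i, j = rng.integers(0, len(ids), 2)
            if i == j or abs(pos[i] - pos[j]) > 200_000:
                continue
            bi, bj = block_of.get(ids[i]), block_of.get(ids[j])
            if bi is None or bj is None:
                continue
            if bi == bj:
                within_a.append(i)
                within_b.append(j)
            else:
                across_a.append(i)
                across_b.append(j)
        w = dc.pairwise_ld(gm.codes, np.array(within_a), np.array(within_b))
        a = dc.pairwise_ld(gm.codes, np.array(across_a), np.array(across_b))
        assert w["dprime"][w["defined"]].mean() > a["dprime"][a["defined"]].mean()

    def test_blocks_det_output(self, small_cohort, tmp_path):
        blocks = small_cohort.true_blocks[:3]
        path = tmp_path / "out.blocks.det"
        ld.write_blocks(blocks, str(path))
        lines = path.read_text().strip().split("\n")
        assert lines[0].split("\t") == ["CHR", "BP1", "BP2", "KB", "NSNPS", "SNPS"]
        assert len(lines) == 4
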