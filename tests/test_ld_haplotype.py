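"""EM haplotype frequencies vs a direct numerical ML oracle, pairwise LD,
four-gamete blocks vs an exhaustive partition oracle, window association."""

import itertools
import warnings

import numpy as np
import pytest
from scipy.optimize import minimize

from locusfine import ld_haplotype as ldh
from locusfine.synthetic_cohort import (
    BlockSpec,
    SimulationConfig,
    build_haplotype_pool,
    simulate_cohort,
)
from locusfine.types import MISSING

from tests.conftest import make_gm


# ----------------------------------------------------------------------
# EM haplotype frequencies
# ----------------------------------------------------------------------

def direct_ml_freqs(genotypes, hap_labels):
    """Multi-start direct likelihood maximization over the haplotype
    frequency simplex — an oracle route independent of the EM updates."""
    genos = np.asarray(genotypes)
    v = genos.shape[1]
    haps = [tuple(int(c) for c in lab) for lab in hap_labels]
    index = {h: k for k, h in enumerate(haps)}
    pairs_per_row = []
    for row in genos:
        pairs = []
        for combo in itertools.product(*[
            [(0, 0)] if g == 0 else [(1, 1)] if g == 2 else [(0, 1), (1, 0)]
            for g in row
        ]):
            h1 = tuple(c[0] for c in combo)
            h2 = tuple(c[1] for c in combo)
            if h1 <= h2 and h1 in index and h2 in index:
                pairs.append((index[h1], index[h2]))
        pairs_per_row.append(sorted(set(pairs)))

    def nll(z):
        f = np.exp(z - z.max())
        f = f / f.sum()
        tot = 0.0
        for pairs in pairs_per_row:
            like = sum(f[a] * f[b] * (1 if a == b else 2) for a, b in pairs)
            tot -= np.log(max(like, 1e-300))
        return tot

    best = None
    rng = np.random.default_rng(0)
    for r in range(8):
        z0 = np.zeros(len(haps)) if r == 0 else rng.normal(0, 1, len(haps))
        m = minimize(nll, z0, method="Nelder-Mead",
                     options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        if best is None or m.fun < best.fun:
            best = m
    f = np.exp(best.x - best.x.max())
    return f / f.sum(), -best.fun


class TestEMHaplotypes:
    def test_unambiguous_phase_equals_gamete_counts(self):
        # nobody is doubly heterozygous: phase is certain
        genos = np.array([[0, 0], [1, 0], [2, 2], [2, 1]])
        em = ldh.em_haplotype_freqs(genos, seed=0)
        freqs = dict(zip(em.labels(), em.frequencies))
        assert freqs["00"] == pytest.approx(3 / 8, abs=1e-9)
        assert freqs["10"] == pytest.approx(2 / 8, abs=1e-9)
        assert freqs["11"] == pytest.approx(3 / 8, abs=1e-9)

    def test_monomorphic_window_single_haplotype(self):
        genos = np.zeros((20, 3), dtype=int)
        em = ldh.em_haplotype_freqs(genos, seed=0)
        assert len(em.frequencies) == 1
        assert em.frequencies[0] == pytest.approx(1.0)

    def test_three_variant_double_heterozygotes_match_ml_oracle(self):
        rng = np.random.default_rng(5)
        true_haps = np.array([[0, 0, 0], [1, 1, 0], [1, 0, 1], [0, 1, 1]])
        true_f = np.array([0.4, 0.3, 0.2, 0.1])
        picks = rng.choice(4, size=(120, 2), p=true_f)
        genos = true_haps[picks[:, 0]] + true_haps[picks[:, 1]]
        em = ldh.em_haplotype_freqs(genos, tol=1e-12, seed=0)
        f_oracle, ll_oracle = direct_ml_freqs(genos, em.labels())
        assert em.loglik >= ll_oracle - 1e-6
        assert np.abs(em.frequencies - f_oracle).max() < 1e-4

    def test_window_cap_enforced(self):
        with pytest.raises(ValueError):
            ldh.em_haplotype_freqs(np.zeros((4, 13), dtype=int), seed=0)

    def test_loglik_non_decreasing_and_simplex(self):
        rng = np.random.default_rng(6)
        genos = rng.binomial(2, 0.4, (80, 4))
        em = ldh.em_haplotype_freqs(genos, seed=0)
        assert em.frequencies.min() >= 0
        assert em.frequencies.sum() == pytest.approx(1.0, abs=1e-9)


# ----------------------------------------------------------------------
# Pairwise LD
# ----------------------------------------------------------------------

class TestLDPair:
    def test_duplicated_variant_perfect_ld(self):
        rng = np.random.default_rng(7)
        g = rng.binomial(2, 0.3, 200).astype(np.int8)
        gm = make_gm(np.column_stack([g, g]))
        lp = ldh.ld_pair(gm, 0, 1)
        assert lp.r2 == pytest.approx(1.0, abs=1e-6)
        assert lp.d_prime == pytest.approx(1.0, abs=1e-6)

    def test_independent_variants_near_zero(self):
        rng = np.random.default_rng(8)
        gm = make_gm(rng.binomial(2, 0.4, (10_000, 2)).astype(np.int8))
        assert ldh.ld_pair(gm, 0, 1).r2 < 0.01

    def test_hand_haplotype_counts(self):
        # gametes AB=40, Ab=10, aB=10, ab=40 (allele 1 = A/B)
        haps = np.array([(1, 1)] * 40 + [(1, 0)] * 10 + [(0, 1)] * 10 + [(0, 0)] * 40)
        rng = np.random.default_rng(9)
        rng.shuffle(haps)
        genos = haps[0::2] + haps[1::2]
        gm = make_gm(genos)
        d = 0.4 - 0.5 * 0.5
        expect_r2 = d**2 / (0.5 * 0.5 * 0.5 * 0.5)
        expect_dp = d / min(0.5 * 0.5, 0.5 * 0.5)
        lp = ldh.ld_pair(gm, 0, 1)
        assert lp.r2 == pytest.approx(expect_r2, abs=0.01)
        assert lp.d_prime == pytest.approx(expect_dp, abs=0.01)

    def test_monomorphic_sentinel(self):
        gm = make_gm(np.column_stack([np.zeros(50, dtype=np.int8),
                                      np.random.default_rng(1).binomial(2, 0.3, 50)]))
        lp = ldh.ld_pair(gm, 0, 1)
        assert np.isnan(lp.r2)

    def test_matches_phased_truth_correlation(self):
        pool = build_haplotype_pool(5000, 6, BlockSpec(sizes=(6,), n_templates=6), seed=10)
        rng = np.random.default_rng(11)
        idx = rng.choice(len(pool.frequencies), size=(3000, 2), p=pool.frequencies)
        h = pool.haplotypes
        genos = (h[idx[:, 0]] + h[idx[:, 1]]).astype(np.int8)
        gm = make_gm(genos)
        alle = np.vstack([h[idx[:, 0]], h[idx[:, 1]]]).astype(float)
        for a, b in [(0, 1), (1, 3), (2, 5)]:
            if len(np.unique(genos[:, a])) < 2 or len(np.unique(genos[:, b])) < 2:
                continue
            truth = np.corrcoef(alle[:, a], alle[:, b])[0, 1] ** 2
            assert ldh.ld_pair(gm, a, b).r2 == pytest.approx(truth, abs=0.02)


# ----------------------------------------------------------------------
# Four-gamete blocks
# ----------------------------------------------------------------------

def brute_force_blocks(gm, freq_epsilon=0.01, hap_min=0.03, r2_min=0.8):
    """Enumerate every contiguous partition and apply the same validity
    rules and objective as the implementation, independently."""
    V = gm.n_variants
    boundary = ldh.four_gamete_boundaries(gm, freq_epsilon)
    r2 = ldh.r2_matrix(gm)

    def valid(i, j):
        if j <= i or boundary[i:j].any():
            return False
        iu = np.triu_indices(j - i + 1, k=1)
        vals = r2[i : j + 1, i : j + 1][iu]
        vals = vals[np.isfinite(vals)]
        return len(vals) > 0 and vals.mean() >= r2_min

    best_key, best_blocks = None, None
    for cuts in itertools.product([0, 1], repeat=V - 1):
        bounds = [0] + [k + 1 for k, c in enumerate(cuts) if c] + [V]
        segs = [(a, b - 1) for a, b in zip(bounds[:-1], bounds[1:])]
        blocks = tuple(s for s in segs if valid(*s))
        ok = all(valid(*s) or (s[1] == s[0]) for s in segs)
        if not ok:
            continue
        covered = sum(b - a + 1 for a, b in blocks)
        key = (covered, -len(blocks), tuple((-a, -b) for a, b in blocks))
        # maximize covered, then fewest blocks, then lexicographically
        # smallest block list
        if best_key is None or (covered, -len(blocks)) > best_key[:2] or (
            (covered, -len(blocks)) == best_key[:2] and blocks < best_blocks
        ):
            best_key, best_blocks = key, blocks
    return list(best_blocks)


class TestFourGameteBlocks:
    def _pool_gm(self, sizes, seed, n=800, n_templates=4):
        pool = build_haplotype_pool(4000, sum(sizes),
                                    BlockSpec(sizes=sizes, n_templates=n_templates),
                                    seed=seed)
        rng = np.random.default_rng(seed + 1)
        idx = rng.choice(len(pool.frequencies), size=(n, 2), p=pool.frequencies)
        genos = (pool.haplotypes[idx[:, 0]] + pool.haplotypes[idx[:, 1]]).astype(np.int8)
        return make_gm(genos, positions=pool.positions)

    def test_no_recombination_single_block(self):
        # two templates: every pair in perfect LD, no recombination evidence
        gm = self._pool_gm((8,), seed=21, n_templates=2)
        blocks = ldh.four_gamete_blocks(gm)
        assert len(blocks) == 1
        assert (blocks[0].start_idx, blocks[0].end_idx) == (0, 7)

    def test_hotspot_splits_exactly_there(self):
        gm = self._pool_gm((5, 5), seed=23, n_templates=2)
        boundary = ldh.four_gamete_boundaries(gm)
        assert boundary[4]
        assert not boundary[:4].any() and not boundary[5:].any()
        blocks = ldh.four_gamete_blocks(gm)
        spans = [(b.start_idx, b.end_idx) for b in blocks]
        assert spans == [(0, 4), (5, 9)]

    @pytest.mark.parametrize("sizes,seed", [((5, 5), 31), ((4, 3, 3), 33), ((10,), 35)])
    def test_matches_exhaustive_partition_oracle(self, sizes, seed):
        gm = self._pool_gm(sizes, seed)
        blocks = ldh.four_gamete_blocks(gm)
        expected = brute_force_blocks(gm)
        assert [(b.start_idx, b.end_idx) for b in blocks] == expected

    def test_invariant_to_allele_relabeling(self):
        gm = self._pool_gm((4, 4), seed=41)
        flipped = gm.copy()
        for j in (0, 2, 5):
            col = flipped.calls[:, j]
            nm = col != MISSING
            col[nm] = 2 - col[nm]
        b1 = ldh.four_gamete_blocks(gm)
        b2 = ldh.four_gamete_blocks(flipped)
        assert [(b.start_idx, b.end_idx) for b in b1] == [
            (b.start_idx, b.end_idx) for b in b2
        ]

    def test_reported_haplotypes_above_frequency_floor(self):
        gm = self._pool_gm((6,), seed=43)
        for b in ldh.four_gamete_blocks(gm):
            for _, f in b.haplotypes:
                assert f > 0.03


# ----------------------------------------------------------------------
# Sliding-window haplotype association
# ----------------------------------------------------------------------

class TestSlidingWindows:
    def test_windows_cover_region_and_skip_thin_ones(self, ea_cohort):
        gm, _, _ = ea_cohort
        cov = gm.admixture_covariates()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            windows, haps = ldh.sliding_window_hap_assoc(gm, cov)
        assert len(windows) >= 2
        tested = windows[windows["skip_reason"] == ""]
        assert len(tested) >= 1
        assert ((tested["p_omnibus"] > 0) & (tested["p_omnibus"] <= 1)).all()
        assert (haps["frequency"] >= 0.03).all()

    def test_causal_window_significant(self, ea_cohort):
        gm, _, cfg = ea_cohort
        cov = gm.admixture_covariates()
        pos = gm.positions()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            windows, _ = ldh.sliding_window_hap_assoc(gm, cov)
        cpos = pos[cfg.causal_index]
        carrying = windows[(windows["start_bp"] <= cpos) & (windows["end_bp"] > cpos)
                           & (windows["skip_reason"] == "")]
        others = windows[~((windows["start_bp"] <= cpos) & (windows["end_bp"] > cpos))
                         & (windows["skip_reason"] == "")]
        assert (carrying["p_omnibus"] < 1e-3).any()
        if len(others):
            assert carrying["p_omnibus"].min() < others["p_omnibus"].min()

    def test_single_common_haplotype_window_skipped(self):
        genos = np.zeros((200, 3), dtype=np.int8)
        genos[:2, 0] = 1  # one rare haplotype only
        gm = make_gm(genos, status=[0, 1] * 100, positions=[100, 200, 300])
        windows, _ = ldh.sliding_window_hap_assoc(gm, None, window_bp=1000, step_bp=1000)
        assert (windows["skip_reason"] == "single_common_haplotype").any()
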