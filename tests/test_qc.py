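"""QC filters: exact HWE vs an independent rational-arithmetic oracle,
differential missingness, IBD estimation, relatedness pruning rules,
sample filters, imputation info scores, and hard calling."""

from fractions import Fraction
from math import factorial

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locusfine import qc
from locusfine.types import MISSING, GenotypeProbabilities, SampleRecord, VariantRecord

from tests.conftest import make_gm


# ----------------------------------------------------------------------
# HWE exact test
# ----------------------------------------------------------------------

def hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact rational enumeration over all heterozygote counts."""
    n = n_AA + n_Aa + n_aa
    nm = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    nM = 2 * n - nm
    ks = [k for k in range(nm + 1) if (nm - k) % 2 == 0 and (nM - k) % 2 == 0]
    weights = {
        k: Fraction(2**k * factorial(n),
                    factorial((nm - k) // 2) * factorial(k) * factorial((nM - k) // 2))
        for k in ks
    }
    tot = sum(weights.values())
    probs = {k: w / tot for k, w in weights.items()}
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHweExact:
    def test_monomorphic_p_one(self):
        assert qc.hwe_exact_test(57, 0, 0) == 1.0

    def test_published_style_counts_match_oracle(self):
        for counts in [(57, 14, 50), (10, 20, 10), (0, 5, 95), (30, 40, 30)]:
            assert qc.hwe_exact_test(*counts) == pytest.approx(
                hwe_oracle(*counts), rel=1e-10, abs=1e-300
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            qc.hwe_exact_test(-1, 2, 3)

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(st.integers(0, 120), st.integers(0, 120), st.integers(0, 120))
    def test_matches_oracle_for_all_counts(self, a, b, c):
        if a + b + c == 0:
            return
        p = qc.hwe_exact_test(a, b, c)
        assert 0 < p <= 1
        assert p == pytest.approx(hwe_oracle(a, b, c), rel=1e-10, abs=1e-300)

    def test_all_margins_up_to_n200_match_oracle_distribution(self):
        """Vectorized check of every attainable margin up to n = 200
        against a direct log-factorial oracle distribution."""
        from scipy.special import gammaln

        rng = np.random.default_rng(1)
        for n in rng.choice(np.arange(1, 201), size=40, replace=False):
            for n_minor in rng.choice(np.arange(0, 2 * n + 1), size=min(2 * n + 1, 12), replace=False):
                nm = min(n_minor, 2 * n - n_minor)
                ks, logp = qc.hwe_het_log_probs(int(n), int(nm))
                nM = 2 * n - nm
                ref = (ks * np.log(2) + gammaln(n + 1)
                       - gammaln((nm - ks) / 2 + 1) - gammaln(ks + 1)
                       - gammaln((nM - ks) / 2 + 1))
                ref = ref - ref.max()
                ref = ref - np.log(np.exp(ref).sum())
                assert np.allclose(logp, ref, atol=1e-10)


# ----------------------------------------------------------------------
# Differential missingness
# ----------------------------------------------------------------------

class TestDifferentialMissingness:
    def test_no_missing_p_one(self):
        assert qc.differential_missingness_test(0, 100, 0, 120) == 1.0

    def test_equal_proportions_p_one(self):
        assert qc.differential_missingness_test(10, 90, 10, 90) == pytest.approx(1.0)

    def test_sparse_cells_match_fisher(self):
        from scipy.stats import fisher_exact

        p = qc.differential_missingness_test(10, 90, 0, 100)
        expected = fisher_exact([[10, 90], [0, 100]])[1]
        assert p == pytest.approx(expected)

    def test_large_imbalance_significant(self):
        assert qc.differential_missingness_test(80, 920, 20, 980) < 1e-6


# ----------------------------------------------------------------------
# Variant QC ordering
# ----------------------------------------------------------------------

class TestVariantQC:
    def _gm(self):
        rng = np.random.default_rng(0)
        n = 400
        status = [1] * 200 + [0] * 200
        calls = rng.binomial(2, 0.3, size=(n, 5)).astype(np.int8)
        calls[: int(n * 0.15), 0] = MISSING          # call rate 0.85
        calls[:, 1] = rng.binomial(2, 0.004, n)      # rare
        calls[:30, 2] = MISSING                      # case-only missing, call rate kept >90%
        calls[:, 3] = 1                              # all-het: HWE failure
        gm = make_gm(calls, status)
        return gm

    def test_first_failing_filter_reported(self):
        rep = qc.variant_qc(self._gm())
        assert rep.variant_fail["v0"] == "callrate"
        assert rep.variant_fail["v1"] == "maf"
        assert rep.variant_fail["v2"] == "diffmiss"
        assert rep.variant_fail["v3"] == "hwe"
        assert "v4" not in rep.variant_fail

    def test_idempotent(self):
        gm = self._gm()
        rep1 = qc.variant_qc(gm)
        filtered = qc.apply_qc(gm, rep1)
        rep2 = qc.variant_qc(filtered)
        assert rep2.variant_fail == {}

    def test_requires_controls(self):
        gm = make_gm([[0, 1], [1, 2]], status=[1, 1])
        with pytest.raises(ValueError):
            qc.variant_qc(gm)


# ----------------------------------------------------------------------
# Sample QC
# ----------------------------------------------------------------------

class TestSampleQC:
    def test_low_call_rate_removed(self):
        rng = np.random.default_rng(3)
        calls = rng.binomial(2, 0.3, size=(20, 50)).astype(np.int8)
        calls[0, :20] = MISSING  # 60% call rate
        rep = qc.sample_qc(make_gm(calls))
        assert rep.sample_fail.get("s0000") == "callrate"

    def test_identical_samples_no_het_flags(self):
        calls = np.tile(np.array([0, 1, 2, 1, 0] * 10, dtype=np.int8), (12, 1))
        rep = qc.sample_qc(make_gm(calls))
        assert all(r != "het" for r in rep.sample_fail.values())

    def test_all_het_sample_flagged(self):
        rng = np.random.default_rng(4)
        calls = rng.binomial(2, 0.15, size=(40, 60)).astype(np.int8)
        calls[0] = 1  # fully heterozygous
        rep = qc.sample_qc(make_gm(calls))
        assert rep.sample_fail.get("s0000") == "het"


# ----------------------------------------------------------------------
# Relatedness pruning
# ----------------------------------------------------------------------

def kin(a, b, pi):
    return qc.KinshipEstimate(pair=(a, b), ibd0=1 - pi, ibd1=0.0, ibd2=pi)


class TestPruneRelated:
    def _gm(self, samples):
        calls = np.ones((len(samples), 200), dtype=np.int8)
        from locusfine.types import GenotypeMatrix, VariantRecord

        return GenotypeMatrix(
            calls, [VariantRecord(id=f"v{j}") for j in range(200)], samples
        )

    def test_case_control_duplicate_removes_control(self):
        samples = [
            SampleRecord(id="case", status=1, sex="female"),
            SampleRecord(id="ctrl", status=0, sex="female"),
        ]
        rep = qc.prune_related(self._gm(samples), [kin("case", "ctrl", 0.95)])
        assert "ctrl" in rep.sample_fail and "case" not in rep.sample_fail

    def test_lower_call_rate_removed_first(self):
        samples = [
            SampleRecord(id="case", status=1),
            SampleRecord(id="ctrl", status=0),
        ]
        gm = self._gm(samples)
        gm.calls[0, :20] = MISSING  # the case has the lower call rate
        rep = qc.prune_related(gm, [kin("case", "ctrl", 0.95)])
        assert "case" in rep.sample_fail

    def test_male_removed_before_female(self):
        samples = [
            SampleRecord(id="m", status=0, sex="male", age=50),
            SampleRecord(id="f", status=0, sex="female", age=50),
        ]
        rep = qc.prune_related(self._gm(samples), [kin("m", "f", 0.5)])
        assert "m" in rep.sample_fail

    def test_younger_control_removed(self):
        samples = [
            SampleRecord(id="young", status=0, sex="female", age=30),
            SampleRecord(id="old", status=0, sex="female", age=60),
        ]
        rep = qc.prune_related(self._gm(samples), [kin("young", "old", 0.5)])
        assert "young" in rep.sample_fail

    def test_less_complete_case_removed(self):
        samples = [
            SampleRecord(id="full", status=1, sex="female", phenotype_completeness=1.0),
            SampleRecord(id="sparse", status=1, sex="female", phenotype_completeness=0.4),
        ]
        rep = qc.prune_related(self._gm(samples), [kin("full", "sparse", 0.5)])
        assert "sparse" in rep.sample_fail

    def test_never_removes_both_members(self):
        samples = [SampleRecord(id=f"x{i}", status=i % 2) for i in range(4)]
        kins = [kin("x0", "x1", 0.9), kin("x1", "x2", 0.8), kin("x2", "x3", 0.7)]
        rep = qc.prune_related(self._gm(samples), kins)
        for k in kins:
            assert not (k.pair[0] in rep.sample_fail and k.pair[1] in rep.sample_fail)

    def test_below_threshold_untouched(self):
        samples = [SampleRecord(id="a", status=1), SampleRecord(id="b", status=0)]
        rep = qc.prune_related(self._gm(samples), [kin("a", "b", 0.3)])
        assert rep.sample_fail == {}


# ----------------------------------------------------------------------
# Info score and hard calls
# ----------------------------------------------------------------------

class TestInfoScore:
    def test_certain_triplets_info_one(self):
        t = np.zeros((50, 3))
        t[:25, 0] = 1.0
        t[25:, 2] = 1.0
        assert qc.info_score(t) == pytest.approx(1.0)

    def test_uniform_triplets_info_zero(self):
        t = np.full((30, 3), 1 / 3)
        assert qc.info_score(t) == 0.0

    def test_half_half_triplets_match_formula(self):
        t = np.tile([0.5, 0.5, 0.0], (40, 1))
        assert qc.info_score(t) == pytest.approx(1 / 3, abs=1e-9)

    def test_monomorphic_expectation_zero(self):
        t = np.tile([1.0, 0.0, 0.0], (10, 1))
        assert qc.info_score(t) == 0.0


class TestHardCall:
    def test_confident_homozygote(self):
        t = np.array([[[0.9, 0.05, 0.05]]])
        p = GenotypeProbabilities(t, [VariantRecord(id="v")], [SampleRecord(id="s")])
        assert qc.hard_call(p).calls[0, 0] == 0

    def test_exact_tie_at_threshold_missing(self):
        t = np.array([[[0.5, 0.5, 0.0]]])
        p = GenotypeProbabilities(t, [VariantRecord(id="v")], [SampleRecord(id="s")])
        assert qc.hard_call(p).calls[0, 0] == MISSING
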