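"""Variant- and sample-level quality control and relatedness pruning.

Variant filters run in a fixed order — call rate, MAF, differential
missingness between cases and controls, Hardy-Weinberg exact test in
controls — and every removed variant carries the first reason that failed.
Sample filters are call rate, then heterozygosity outliers.  Cryptic
relatedness is estimated by a method-of-moments identity-by-descent (IBD)
estimator and resolved by a greedy prune with a five-rule tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2, fisher_exact

from .types import MISSING, GenotypeMatrix, GenotypeProbabilities


# ----------------------------------------------------------------------
# Reports
# ----------------------------------------------------------------------

@dataclass
class QCReport:
    """Pass/fail bookkeeping; each removal has exactly one primary reason."""

    variant_fail: dict[str, str] = field(default_factory=dict)
    sample_fail: dict[str, str] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def variant_passes(self, gm: GenotypeMatrix) -> np.ndarray:
        return np.array([v.id not in self.variant_fail for v in gm.variants])

    def sample_passes(self, gm: GenotypeMatrix) -> np.ndarray:
        return np.array([s.id not in self.sample_fail for s in gm.samples])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"entity": "variant", "id": k, "reason": v} for k, v in self.variant_fail.items()
        ] + [
            {"entity": "sample", "id": k, "reason": v} for k, v in self.sample_fail.items()
        ]
        return pd.DataFrame(rows, columns=["entity", "id", "reason"])


@dataclass
class KinshipEstimate:
    pair: tuple[str, str]
    ibd0: float
    ibd1: float
    ibd2: float
    n_variants: int = 0

    @property
    def pi_hat(self) -> float:
        return self.ibd2 + 0.5 * self.ibd1


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test
# ----------------------------------------------------------------------

def hwe_het_log_probs(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the heterozygote count given the allele margin.

    Returns the attainable heterozygote counts (same parity as ``n_minor``)
    and their log probabilities conditional on ``n`` diploid genotypes with
    ``n_minor`` minor alleles.
    """
    n_major = 2 * n - n_minor
    k_min = max(0, n_minor - n) if (max(0, n_minor - n) % 2 == n_minor % 2) else max(0, n_minor - n) + 1
    ks = np.arange(k_min, min(n_minor, n_major) + 1, 2)
    # log weight: 2^k / ((nm-k)/2)! k! ((nM-k)/2)!
    with np.errstate(divide="ignore"):
        logw = (
            ks * np.log(2.0)
            - gammaln((n_minor - ks) / 2 + 1)
            - gammaln(ks + 1)
            - gammaln((n_major - ks) / 2 + 1)
        )
    return ks, logw - logsumexp(logw)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    The p-value sums, over all heterozygote counts consistent with the
    observed allele counts, the probabilities no larger than the observed
    configuration's.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype required")
    n_minor = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    ks, logp = hwe_het_log_probs(n, n_minor)
    obs = np.nonzero(ks == n_Aa)[0]
    if len(obs) == 0:  # inconsistent input cannot happen for valid counts
        raise ValueError("observed heterozygote count inconsistent with margin")
    p_obs = logp[obs[0]]
    keep = logp <= p_obs + 1e-12
    p = float(np.exp(logsumexp(logp[keep])))
    return min(p, 1.0)


# ----------------------------------------------------------------------
# Differential missingness
# ----------------------------------------------------------------------

def differential_missingness_test(
    missing_case: int, called_case: int, missing_ctrl: int, called_ctrl: int
) -> float:
    """2x2 case/control vs missing/called test; exact when cells are sparse."""
    table = np.array([[missing_case, called_case], [missing_ctrl, called_ctrl]], dtype=float)
    n = table.sum()
    if n == 0 or called_case + called_ctrl == 0:
        raise ValueError("variant has no called genotypes")
    if missing_case + missing_ctrl == 0:
        return 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected <= 5).any():
        return float(fisher_exact(table.astype(int))[1])
    with np.errstate(invalid="ignore"):
        stat = ((table - expected) ** 2 / expected).sum()
    return float(chi2.sf(stat, df=1))


# ----------------------------------------------------------------------
# Variant QC
# ----------------------------------------------------------------------

def variant_qc(
    gm: GenotypeMatrix,
    callrate_min: float = 0.90,
    maf_min: float = 0.01,
    diffmiss_alpha: float = 0.05,
    hwe_alpha: float = 1e-4,
    exempt_maf: list[str] | None = None,
) -> QCReport:
    """Apply the variant filters in order: callrate, maf, diffmiss, hwe.

    The HWE test runs in controls only.  ``exempt_maf`` lists variant ids
    (e.g. rare-variant candidates) excused from the MAF filter.
    """
    if gm.n_samples == 0 or gm.n_variants == 0:
        raise ValueError("empty genotype matrix")
    status = gm.status_array()
    if (status == 0).sum() == 0:
        raise ValueError("variant QC requires at least one control for the HWE test")
    report = QCReport(
        thresholds={
            "callrate_min": callrate_min,
            "maf_min": maf_min,
            "diffmiss_alpha": diffmiss_alpha,
            "hwe_alpha": hwe_alpha,
        }
    )
    exempt = set(exempt_maf or ())
    call_rates = gm.variant_call_rates()
    mafs = gm.maf()
    is_case = status == 1
    is_ctrl = ~is_case
    for j, v in enumerate(gm.variants):
        if call_rates[j] < callrate_min:
            report.variant_fail[v.id] = "callrate"
            continue
        if v.id not in exempt and not mafs[j] > maf_min:
            report.variant_fail[v.id] = "maf"
            continue
        col = gm.calls[:, j]
        miss = col == MISSING
        p_dm = differential_missingness_test(
            int((miss & is_case).sum()), int((~miss & is_case).sum()),
            int((miss & is_ctrl).sum()), int((~miss & is_ctrl).sum()),
        )
        if p_dm <= diffmiss_alpha:
            report.variant_fail[v.id] = "diffmiss"
            continue
        ctrl = col[is_ctrl & ~miss]
        if len(ctrl) > 0:
            p_hwe = hwe_exact_test(
                int((ctrl == 0).sum()), int((ctrl == 1).sum()), int((ctrl == 2).sum())
            )
            if p_hwe < hwe_alpha:
                report.variant_fail[v.id] = "hwe"
    return report


# ----------------------------------------------------------------------
# Sample QC
# ----------------------------------------------------------------------

def sample_qc(gm: GenotypeMatrix, callrate_min: float = 0.90, het_sd: float = 3.0) -> QCReport:
    """Remove samples with low call rate or outlying heterozygosity."""
    if gm.n_samples < 10:
        raise ValueError("sample QC needs at least 10 samples")
    report = QCReport(thresholds={"callrate_min": callrate_min, "het_sd": het_sd})
    call_rates = gm.sample_call_rates()
    called = gm.calls != MISSING
    with np.errstate(invalid="ignore"):
        het = np.where(called.sum(axis=1) > 0, (gm.calls == 1).sum(axis=1) / np.maximum(called.sum(axis=1), 1), np.nan)
    mean, sd = np.nanmean(het), np.nanstd(het)
    for i, s in enumerate(gm.samples):
        if call_rates[i] < callrate_min:
            report.sample_fail[s.id] = "callrate"
            continue
        if sd > 0 and abs(het[i] - mean) > het_sd * sd:
            report.sample_fail[s.id] = "het"
    return report


# ----------------------------------------------------------------------
# IBD estimation and relatedness pruning
# ----------------------------------------------------------------------

def estimate_ibd(gm: GenotypeMatrix, pair: tuple[int, int], maf_min: float = 0.05) -> KinshipEstimate:
    """Method-of-moments IBD estimate for one sample pair.

    Identity-by-state counts are compared with their expectations under
    IBD states 0/1/2 given allele frequencies; negative moment estimates
    are clamped to [0, 1] and renormalized.
    """
    i, j = pair
    g1, g2 = gm.calls[i].astype(float), gm.calls[j].astype(float)
    freqs = gm.allele_frequencies()
    ok = (gm.calls[i] != MISSING) & (gm.calls[j] != MISSING) & (np.minimum(freqs, 1 - freqs) >= maf_min)
    if ok.sum() < 100:
        raise ValueError(
            f"only {int(ok.sum())} informative variants shared by the pair; need >= 100"
        )
    p = freqs[ok]
    q = 1.0 - p
    ibs = 2 - np.abs(g1[ok] - g2[ok])
    n0, n1 = float((ibs == 0).sum()), float((ibs == 1).sum())
    n2 = float((ibs == 2).sum())

    e0_ibs0 = float((2 * p**2 * q**2).sum())
    e0_ibs1 = float((4 * p**3 * q + 4 * p * q**3).sum())
    e0_ibs2 = float((p**4 + q**4 + 4 * p**2 * q**2).sum())
    e1_ibs1 = float((2 * p * q).sum())
    e1_ibs2 = float((p**2 + q**2).sum())
    V = float(ok.sum())

    z0 = n0 / e0_ibs0 if e0_ibs0 > 0 else 0.0
    z1 = (n1 - z0 * e0_ibs1) / e1_ibs1 if e1_ibs1 > 0 else 0.0
    z2 = (n2 - z0 * e0_ibs2 - z1 * e1_ibs2) / V
    z = np.clip([z0, z1, z2], 0.0, 1.0)
    z = z / z.sum() if z.sum() > 0 else np.array([1.0, 0.0, 0.0])
    return KinshipEstimate(
        pair=(gm.samples[i].id, gm.samples[j].id),
        ibd0=float(z[0]), ibd1=float(z[1]), ibd2=float(z[2]),
        n_variants=int(V),
    )


def estimate_ibd_all_pairs(gm: GenotypeMatrix, maf_min: float = 0.05) -> list[KinshipEstimate]:
    out = []
    for i in range(gm.n_samples):
        for j in range(i + 1, gm.n_samples):
            try:
                out.append(estimate_ibd(gm, (i, j), maf_min=maf_min))
            except ValueError:
                continue
    return out


def _prune_choice(sa, sb, cr_a: float, cr_b: float) -> tuple[str, int]:
    """Which of a related pair to remove; returns (removed id, rule index).

    Rules, in order, the first discriminating one deciding:
      1. lower call rate; 2. control over case; 3. male over female;
      4. younger control over older; 5. case with less complete phenotype.
    A deterministic id-based fallback covers fully tied pairs.
    """
    if not np.isclose(cr_a, cr_b):
        return (sa.id, 1) if cr_a < cr_b else (sb.id, 1)
    if sa.status != sb.status:
        return (sa.id, 2) if sa.status == 0 else (sb.id, 2)
    if {sa.sex, sb.sex} == {"male", "female"}:
        return (sa.id, 3) if sa.sex == "male" else (sb.id, 3)
    if sa.status == 0 and sb.status == 0 and sa.age is not None and sb.age is not None and sa.age != sb.age:
        return (sa.id, 4) if sa.age < sb.age else (sb.id, 4)
    if sa.status == 1 and sb.status == 1:
        ca = sa.phenotype_completeness if sa.phenotype_completeness is not None else 1.0
        cb = sb.phenotype_completeness if sb.phenotype_completeness is not None else 1.0
        if ca != cb:
            return (sa.id, 5) if ca < cb else (sb.id, 5)
    return (max(sa.id, sb.id), 0)


def prune_related(
    gm: GenotypeMatrix, kinship_list: list[KinshipEstimate], pi_hat_max: float = 0.4
) -> QCReport:
    """Greedy relatedness prune over pairs with pi-hat above the cut-off.

    Pairs are visited in descending pi-hat; if both members are still
    present, one is removed by the five-rule tie-break.  Never removes both
    members of a pair.
    """
    report = QCReport(thresholds={"pi_hat_max": pi_hat_max})
    by_id = {s.id: (s, float(cr)) for s, cr in zip(gm.samples, gm.sample_call_rates())}
    flagged = [k for k in kinship_list if k.pi_hat > pi_hat_max]
    flagged.sort(key=lambda k: (-k.pi_hat, k.pair))
    for k in flagged:
        a, b = k.pair
        if a in report.sample_fail or b in report.sample_fail:
            continue
        sa, cr_a = by_id[a]
        sb, cr_b = by_id[b]
        removed, rule = _prune_choice(sa, sb, cr_a, cr_b)
        report.sample_fail[removed] = "ibd" if rule == 0 else f"ibd:rule{rule}"
    return report


# ----------------------------------------------------------------------
# Imputation quality and hard calls
# ----------------------------------------------------------------------

def info_score(probs_for_variant: np.ndarray) -> float:
    """Ratio-of-variances imputation information measure, clamped to [0, 1].

    info = 1 - sum(f_i - e_i^2) / (2N theta (1-theta)) with e_i the expected
    dosage and f_i the expected squared dosage of sample i, and theta the
    mean allele frequency.  Defined as 0 for an expected-monomorphic site.
    """
    t = np.asarray(probs_for_variant, dtype=float)
    if t.ndim != 2 or t.shape[1] != 3 or t.shape[0] < 2:
        raise ValueError("need a (samples, 3) probability array with >= 2 samples")
    e = t[:, 1] + 2 * t[:, 2]
    f = t[:, 1] + 4 * t[:, 2]
    n = len(e)
    theta = e.sum() / (2 * n)
    if theta <= 0 or theta >= 1:
        return 0.0
    info = 1.0 - (f - e**2).sum() / (2 * n * theta * (1 - theta))
    return float(np.clip(info, 0.0, 1.0))


def info_scores(probs: GenotypeProbabilities) -> np.ndarray:
    return np.array([info_score(probs.triplets[:, j, :]) for j in range(probs.triplets.shape[1])])


def hard_call(probs: GenotypeProbabilities, threshold: float = 0.5) -> GenotypeMatrix:
    """Call the genotype whose probability meets the threshold, else missing.

    A tie between two categories that both reach the threshold is left
    missing.
    """
    t = probs.triplets
    best = t.argmax(axis=2)
    best_p = t.max(axis=2)
    # tie: more than one category attains the max
    n_at_max = (np.abs(t - best_p[:, :, None]) < 1e-12).sum(axis=2)
    calls = np.where((best_p >= threshold) & (n_at_max == 1), best, MISSING).astype(np.int8)
    return GenotypeMatrix(calls, probs.variants, probs.samples)


def apply_qc(gm: GenotypeMatrix, report: QCReport) -> GenotypeMatrix:
    """Drop the samples and variants a report marks as failed."""
    si = np.nonzero(report.sample_passes(gm))[0]
    vi = np.nonzero(report.variant_passes(gm))[0]
    return gm.subset(si, vi)
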