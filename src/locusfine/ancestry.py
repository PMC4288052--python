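"""Population-stratification tools built on ancestry-informative markers.

Principal components are computed from AIM genotypes standardized the way
GWAS stratification analyses do (center by 2p, scale by sqrt(p(1-p))).
Per-sample admixture proportions over the four ancestral populations
(African, European, American Indian, East Asian) are maximum-likelihood
mixing weights under binomial allele sampling against a known ancestral
allele-frequency panel, fitted by EM; the first three proportions serve as
regression covariates downstream.  Genetic outliers are flagged by an
iterated SD rule on the first three PCs within each declared ancestry
group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix


@dataclass
class PCAResult:
    scores: np.ndarray  # (samples, k)
    eigenvalues: np.ndarray  # (k,) non-increasing
    loadings: np.ndarray  # (variants, k)


def pca_aims(gm_aims: GenotypeMatrix, n_components: int = 3) -> PCAResult:
    """PC scores from AIM genotypes.

    Genotypes are centered at twice the allele frequency and scaled by
    sqrt(p(1-p)); missing cells are mean-imputed (zero after centering).
    Component signs are fixed by making each component's largest-magnitude
    loading positive, so scores are fully deterministic.
    """
    if gm_aims.n_samples < n_components + 1:
        raise ValueError("need more samples than components")
    g = gm_aims.calls.astype(float)
    g[gm_aims.calls == MISSING] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    if np.isnan(p).any():
        bad = [gm_aims.variants[j].id for j in np.nonzero(np.isnan(p))[0]]
        raise ValueError(f"all-missing AIMs: {bad[:5]}")
    keep = (p > 0) & (p < 1)
    g = g[:, keep]
    p = p[keep]
    x = (g - 2 * p) / np.sqrt(p * (1 - p))
    x[np.isnan(x)] = 0.0
    x -= x.mean(axis=0)  # re-center after imputation

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    eigenvalues = (s[:k] ** 2) / max(gm_aims.n_samples - 1, 1)
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    for c in range(k):
        lead = np.argmax(np.abs(loadings[:, c]))
        if loadings[lead, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    if k < n_components:  # degenerate: pad with zero variance components
        pad = n_components - k
        scores = np.hstack([scores, np.zeros((scores.shape[0], pad))])
        eigenvalues = np.concatenate([eigenvalues, np.zeros(pad)])
        loadings = np.hstack([loadings, np.zeros((loadings.shape[0], pad))])
    return PCAResult(scores=scores, eigenvalues=eigenvalues, loadings=loadings)


@dataclass
class AdmixtureEstimate:
    proportions: np.ndarray  # full simplex over panel populations
    identifiable: bool = True

    def covariates(self, k: int = 3) -> tuple[float, ...]:
        return tuple(float(x) for x in self.proportions[:k])


def estimate_admixture(
    genotypes_at_aims: np.ndarray,
    panel: pd.DataFrame,
    tol: float = 1e-7,
    max_iter: int = 2000,
    min_aims: int = 50,
) -> AdmixtureEstimate:
    """EM maximum-likelihood admixture proportions for one sample.

    Each of the sample's two allele copies at each AIM is modeled as drawn
    from ancestral population k with probability q_k and then from that
    population's allele frequency.  ``genotypes_at_aims`` is a vector of
    minor/alt-allele counts in {0,1,2} with -1 for missing, aligned to the
    panel's marker columns.
    """
    g = np.asarray(genotypes_at_aims)
    freqs = panel.to_numpy(dtype=float)  # (K, M)
    K, M = freqs.shape
    if len(g) != M:
        raise ValueError("genotype vector does not match panel markers")
    ok = g != MISSING
    if ok.sum() < min_aims:
        raise ValueError(f"only {int(ok.sum())} non-missing AIMs; need >= {min_aims}")
    if np.allclose(freqs, freqs[0], atol=1e-12):
        return AdmixtureEstimate(np.full(K, 1.0 / K), identifiable=False)

    f = np.clip(freqs[:, ok], 1e-6, 1 - 1e-6)  # (K, m)
    n1 = g[ok].astype(float)  # copies of the counted allele
    n0 = 2.0 - n1
    q = np.full(K, 1.0 / K)
    for _ in range(max_iter):
        a1 = q[:, None] * f  # (K, m) responsibilities, allele = 1
        a0 = q[:, None] * (1 - f)
        r1 = a1 / a1.sum(axis=0, keepdims=True)
        r0 = a0 / a0.sum(axis=0, keepdims=True)
        counts = (r1 * n1).sum(axis=1) + (r0 * n0).sum(axis=1)
        q_new = counts / counts.sum()
        delta = np.abs(q_new - q).max()
        q = q_new
        if delta < tol:
            break
    return AdmixtureEstimate(q, identifiable=True)


def admixture_loglik(q: np.ndarray, genotypes: np.ndarray, panel: pd.DataFrame) -> float:
    """Binomial allele-sampling log-likelihood of mixing weights ``q``."""
    g = np.asarray(genotypes)
    ok = g != MISSING
    f = np.clip(panel.to_numpy(dtype=float)[:, ok], 1e-6, 1 - 1e-6)
    p = q @ f
    n1 = g[ok].astype(float)
    return float((n1 * np.log(p) + (2 - n1) * np.log1p(-p)).sum())


def flag_outliers(
    pc_scores: np.ndarray,
    ancestry_groups: np.ndarray | list,
    sd_threshold: float = 6.0,
    max_rounds: int = 5,
) -> np.ndarray:
    """Iterated SD-rule outlier flags on the first three PCs, per group.

    Within each ancestry group, samples beyond ``sd_threshold`` standard
    deviations from the group mean on any PC are flagged; means and SDs
    are recomputed after each removal round (at most ``max_rounds``).
    Groups smaller than 3 are skipped.
    """
    scores = np.asarray(pc_scores, dtype=float)[:, :3]
    groups = np.asarray(ancestry_groups)
    if len(groups) != scores.shape[0]:
        raise ValueError("one group label per sample required")
    flags = np.zeros(len(groups), dtype=bool)
    for gname in sorted(set(groups.tolist()), key=str):
        idx = np.nonzero(groups == gname)[0]
        if len(idx) < 3:
            continue
        active = idx.copy()
        for _ in range(max_rounds):
            sub = scores[active]
            mean = sub.mean(axis=0)
            sd = sub.std(axis=0)
            sd[sd == 0] = np.inf
            out = (np.abs(sub - mean) > sd_threshold * sd).any(axis=1)
            if not out.any():
                break
            flags[active[out]] = True
            active = active[~out]
            if len(active) < 3:
                break
    return flags


def annotate_samples(
    gm: GenotypeMatrix, aims: GenotypeMatrix, panel: pd.DataFrame, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Attach estimated PCs and admixture proportions to sample records.

    Returns the (samples, 3) PC score matrix and the (samples, K) admixture
    matrix, and writes both into ``gm.samples`` in place.
    """
    pca = pca_aims(aims, n_components=n_components)
    props = np.vstack(
        [
            estimate_admixture(aims.calls[i], panel).proportions
            for i in range(aims.n_samples)
        ]
    )
    for i, s in enumerate(gm.samples):
        s.pcs = tuple(float(x) for x in pca.scores[i, :3])
        s.admixture = tuple(float(x) for x in props[i])
    return pca.scores, props
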