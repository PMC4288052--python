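"""Linkage disequilibrium, EM haplotype frequencies, block finding, and
sliding-window haplotype association.

Haplotype frequencies over short windows (at most 12 variants) come from
the classic EM algorithm on unphased genotypes, with seeded random
restarts against local maxima.  Pairwise r-squared and D' derive from
two-locus EM frequencies.  Blocks combine the four-gamete rule (a
boundary wherever all four two-locus gametes are observed above a
frequency floor) with a mean pairwise r-squared requirement inside each
block; the partition is the exact optimum of a deterministic objective.
Window-level association uses expected haplotype dosages in a logistic
model with an omnibus likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .assoc import fit_logistic
from .types import MISSING, GenotypeMatrix

MAX_WINDOW_VARIANTS = 12


# ----------------------------------------------------------------------
# EM haplotype frequency estimation
# ----------------------------------------------------------------------

@dataclass
class EMHaplotypes:
    haplotypes: np.ndarray  # (H, v) binary
    frequencies: np.ndarray  # (H,)
    loglik: float
    n_iter: int
    converged: bool

    def labels(self) -> list[str]:
        return ["".join(str(int(a)) for a in h) for h in self.haplotypes]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"haplotype": self.labels(), "frequency": self.frequencies})


def _compatible_pairs(geno: np.ndarray) -> list[tuple[int, int]]:
    """Unordered haplotype-pair bitmasks compatible with one genotype row."""
    hom1 = 0
    hets = []
    for j, g in enumerate(geno):
        if g == 2:
            hom1 |= 1 << j
        elif g == 1:
            hets.append(j)
    if not hets:
        return [(hom1, hom1)]
    pairs = []
    first, rest = hets[0], hets[1:]
    for mask in range(1 << len(rest)):
        h1 = hom1 | (1 << first)
        h2 = hom1
        for b, j in enumerate(rest):
            if mask >> b & 1:
                h1 |= 1 << j
            else:
                h2 |= 1 << j
        pairs.append((h1, h2))
    return pairs


def em_haplotype_freqs(
    genotypes: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 3,
    seed: int = 0,
) -> EMHaplotypes:
    """EM estimate of haplotype frequencies from unphased genotypes.

    ``genotypes`` is (samples, v) with alleles counted 0/1/2; rows with a
    missing call are dropped.  The window is capped at 12 variants (4096
    possible haplotypes).  The log-likelihood is non-decreasing across
    iterations; the best of ``n_restarts`` seeded initializations is kept.
    """
    g = np.asarray(genotypes)
    if g.ndim == 1:
        g = g[:, None]
    v = g.shape[1]
    if v > MAX_WINDOW_VARIANTS:
        raise ValueError(f"window of {v} variants exceeds the {MAX_WINDOW_VARIANTS}-variant cap")
    g = g[(g != MISSING).all(axis=1)]
    if len(g) == 0:
        raise ValueError("no complete genotype rows in the window")

    uniq, counts = np.unique(g, axis=0, return_counts=True)
    pair_lists = [_compatible_pairs(row) for row in uniq]
    hap_ids = sorted({h for pl in pair_lists for p in pl for h in p})
    index = {h: k for k, h in enumerate(hap_ids)}
    H = len(hap_ids)
    n = counts.sum()

    pair_idx = [
        (np.array([index[a] for a, b in pl]), np.array([index[b] for a, b in pl]))
        for pl in pair_lists
    ]

    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(n_restarts, 1)):
        f = np.full(H, 1.0 / H) if r == 0 else rng.dirichlet(np.ones(H))
        ll_prev = -np.inf
        n_iter = 0
        converged = False
        for n_iter in range(1, max_iter + 1):
            new = np.zeros(H)
            ll = 0.0
            for (ia, ib), cnt in zip(pair_idx, counts):
                w = f[ia] * f[ib] * np.where(ia == ib, 1.0, 2.0)
                tot = w.sum()
                if tot <= 0:
                    w = np.full(len(ia), 1.0 / len(ia))
                    tot = 1.0
                    ll += -np.inf
                else:
                    w = w / tot
                    ll += cnt * np.log(tot)
                np.add.at(new, ia, cnt * w)
                np.add.at(new, ib, cnt * w)
            f = new / (2 * n)
            if abs(ll - ll_prev) < tol:
                converged = True
                ll_prev = ll
                break
            ll_prev = ll
        if best is None or ll_prev > best.loglik:
            best = EMHaplotypes(
                haplotypes=np.array(
                    [[h >> j & 1 for j in range(v)] for h in hap_ids], dtype=np.uint8
                ),
                frequencies=f,
                loglik=float(ll_prev),
                n_iter=n_iter,
                converged=converged,
            )
    return best


def expected_haplotype_dosages(genotypes: np.ndarray, em: EMHaplotypes) -> np.ndarray:
    """Posterior expected count of each haplotype per sample (rows sum to 2).

    Samples with a missing call in the window get their dosages from the
    population frequencies (2f).
    """
    g = np.asarray(genotypes)
    if g.ndim == 1:
        g = g[:, None]
    v = g.shape[1]
    hap_mask = {tuple(h): k for k, h in enumerate(em.haplotypes)}
    f = em.frequencies
    out = np.tile(2 * f, (len(g), 1))
    for i, row in enumerate(g):
        if (row == MISSING).any():
            continue
        dos = np.zeros(len(f))
        wsum = 0.0
        for a, b in _compatible_pairs(row):
            ha = tuple((a >> j) & 1 for j in range(v))
            hb = tuple((b >> j) & 1 for j in range(v))
            ka, kb = hap_mask.get(ha), hap_mask.get(hb)
            if ka is None or kb is None:
                continue
            w = f[ka] * f[kb] * (1.0 if ka == kb else 2.0)
            dos[ka] += w
            dos[kb] += w
            wsum += w
        if wsum > 0:
            out[i] = dos / wsum
    return out


# ----------------------------------------------------------------------
# Pairwise LD
# ----------------------------------------------------------------------

@dataclass
class LDPair:
    id1: str
    id2: str
    r2: float
    d_prime: float


def two_locus_gamete_freqs(gm: GenotypeMatrix, v1: int, v2: int) -> np.ndarray:
    """EM two-locus haplotype frequencies [f00, f01, f10, f11]."""
    g = gm.calls[:, [v1, v2]]
    em = em_haplotype_freqs(g, seed=0)
    f = np.zeros(4)
    for h, fr in zip(em.haplotypes, em.frequencies):
        f[int(h[0]) * 2 + int(h[1])] = fr
    return f


def ld_pair(gm: GenotypeMatrix, v1: int, v2: int) -> LDPair:
    """r-squared and D' between two variants from two-locus EM frequencies."""
    id1, id2 = gm.variants[v1].id, gm.variants[v2].id
    col1, col2 = gm.calls[:, v1], gm.calls[:, v2]
    ok = (col1 != MISSING) & (col2 != MISSING)
    if len(np.unique(col1[ok])) < 2 or len(np.unique(col2[ok])) < 2:
        return LDPair(id1, id2, float("nan"), float("nan"))
    f = two_locus_gamete_freqs(gm, v1, v2)
    pa = f[2] + f[3]  # allele 1 at first site
    pb = f[1] + f[3]
    d = f[3] - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    r2 = d**2 / denom if denom > 0 else float("nan")
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dp = abs(d) / dmax if dmax > 0 else float("nan")
    return LDPair(id1, id2, float(min(r2, 1.0)), float(min(dp, 1.0)))


def r2_matrix(gm: GenotypeMatrix, indices: list[int] | None = None) -> np.ndarray:
    idx = indices if indices is not None else list(range(gm.n_variants))
    k = len(idx)
    out = np.full((k, k), np.nan)
    np.fill_diagonal(out, 1.0)
    for a in range(k):
        for b in range(a + 1, k):
            out[a, b] = out[b, a] = ld_pair(gm, idx[a], idx[b]).r2
    return out


# ----------------------------------------------------------------------
# Four-gamete blocks
# ----------------------------------------------------------------------

@dataclass
class HaplotypeBlock:
    start_idx: int
    end_idx: int  # inclusive
    start_bp: int
    end_bp: int
    haplotypes: list[tuple[str, float]] = field(default_factory=list)

    @property
    def n_variants(self) -> int:
        return self.end_idx - self.start_idx + 1


def four_gamete_boundaries(gm: GenotypeMatrix, freq_epsilon: float = 0.01) -> np.ndarray:
    """True at j when all four gametes between variants j and j+1 exceed epsilon."""
    out = np.zeros(max(gm.n_variants - 1, 0), dtype=bool)
    for j in range(gm.n_variants - 1):
        f = two_locus_gamete_freqs(gm, j, j + 1)
        out[j] = bool((f > freq_epsilon).all())
    return out


def _block_partition(valid: np.ndarray) -> list[tuple[int, int]]:
    """Exact-optimum contiguous partition into valid blocks.

    ``valid[i, j]`` says variants i..j (inclusive, j > i) may form a block.
    Maximizes variants covered by blocks, then minimizes the number of
    blocks, then prefers the lexicographically smallest block list.
    Uncovered variants remain singletons.
    """
    V = valid.shape[0]

    def better(a, b):
        if a is None:
            return False
        if b is None:
            return True
        ca, na, ba = a
        cb, nb, bb = b
        if ca != cb:
            return ca > cb
        if na != nb:
            return na < nb
        return ba < bb

    best: list = [None] * (V + 1)
    best[0] = (0, 0, ())
    for i in range(1, V + 1):
        cand = None
        prev = best[i - 1]
        if prev is not None:
            cand = (prev[0], prev[1], prev[2])  # variant i-1 left uncovered
        for j in range(i - 1):
            if valid[j, i - 1] and best[j] is not None:
                c, nb, bl = best[j]
                trial = (c + (i - j), nb + 1, bl + ((j, i - 1),))
                if better(trial, cand):
                    cand = trial
        best[i] = cand
    return list(best[V][2])


def four_gamete_blocks(
    gm: GenotypeMatrix,
    freq_epsilon: float = 0.01,
    hap_min: float = 0.03,
    r2_min: float = 0.8,
) -> list[HaplotypeBlock]:
    """Haplotype blocks under the four-gamete rule with an r-squared floor.

    A candidate block is a contiguous run of at least two variants with no
    internal adjacent-pair four-gamete violation and mean pairwise
    r-squared of at least ``r2_min``; the reported partition is the exact
    optimum (most variants covered, then fewest blocks).  Haplotypes of
    each block with frequency above ``hap_min`` are listed when the block
    fits the EM window cap.
    """
    V = gm.n_variants
    if V < 2:
        return []
    boundary = four_gamete_boundaries(gm, freq_epsilon)
    r2 = r2_matrix(gm)
    valid = np.zeros((V, V), dtype=bool)
    for i in range(V):
        for j in range(i + 1, V):
            if boundary[i:j].any():
                continue
            sub = r2[i : j + 1, i : j + 1]
            iu = np.triu_indices(j - i + 1, k=1)
            vals = sub[iu]
            vals = vals[np.isfinite(vals)]
            if len(vals) and vals.mean() >= r2_min:
                valid[i, j] = True
    blocks = []
    pos = gm.positions()
    for i, j in _block_partition(valid):
        haps: list[tuple[str, float]] = []
        if j - i + 1 <= MAX_WINDOW_VARIANTS:
            em = em_haplotype_freqs(gm.calls[:, i : j + 1], seed=0)
            haps = [
                (lab, float(fr))
                for lab, fr in zip(em.labels(), em.frequencies)
                if fr > hap_min
            ]
            haps.sort(key=lambda t: -t[1])
        blocks.append(
            HaplotypeBlock(
                start_idx=i, end_idx=j,
                start_bp=int(pos[i]), end_bp=int(pos[j]),
                haplotypes=haps,
            )
        )
    return blocks


# ----------------------------------------------------------------------
# Sliding-window haplotype association
# ----------------------------------------------------------------------

def sliding_window_hap_assoc(
    gm: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    window_bp: int = 200_000,
    step_bp: int | None = None,
    hap_min: float = 0.03,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Haplotype association in sliding windows.

    Expected haplotype dosages (EM posterior counts) of the common
    haplotypes enter a logistic model next to the covariates; the rarest
    retained haplotype is the reference, and the window-level omnibus test
    is a likelihood-ratio chi-square against the covariates-only model.
    Windows wider than the EM cap are thinned to evenly spaced variants.
    """
    step = step_bp if step_bp is not None else window_bp // 2
    pos = gm.positions()
    y = gm.status_array().astype(float)
    Cov = None
    if covariates is not None:
        Cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Cov.shape[0] != gm.n_samples:
            Cov = Cov.T
    window_rows, hap_rows = [], []
    start = int(pos.min())
    last = int(pos.max())
    w = start
    widx = 0
    while w <= last:
        sel = np.nonzero((pos >= w) & (pos < w + window_bp))[0]
        row = {"window": widx, "start_bp": w, "end_bp": w + window_bp, "n_variants": len(sel)}
        widx += 1
        w += step
        if len(sel) < 2:
            row.update(p_omnibus=np.nan, skip_reason="too_few_variants", n_haplotypes=0)
            window_rows.append(row)
            continue
        if len(sel) > MAX_WINDOW_VARIANTS:
            sel = sel[np.linspace(0, len(sel) - 1, MAX_WINDOW_VARIANTS).round().astype(int)]
            row["n_variants_used"] = len(sel)
        g = gm.calls[:, sel]
        em = em_haplotype_freqs(g, seed=seed)
        common = np.nonzero(em.frequencies >= hap_min)[0]
        if len(common) < 2:
            row.update(p_omnibus=np.nan, skip_reason="single_common_haplotype",
                       n_haplotypes=len(common))
            window_rows.append(row)
            continue
        dos = expected_haplotype_dosages(g, em)[:, common]
        order = np.argsort(em.frequencies[common])  # rarest first -> reference
        ref = common[order[0]]
        keep = [c for c in common[order[1:]]]
        cols = [np.ones(gm.n_samples)]
        if Cov is not None:
            cols.append(Cov)
        X0 = np.column_stack(cols)
        labels = em.labels()
        Xh = dos[:, [list(common).index(c) for c in keep]]
        X1 = np.column_stack([X0, Xh])
        fit0 = fit_logistic(y, X0)
        fit1 = fit_logistic(y, X1)
        df = X1.shape[1] - X0.shape[1]
        lrt = 2 * (fit1.loglik - fit0.loglik)
        p = float(chi2.sf(max(lrt, 0.0), df=df)) if df > 0 else np.nan
        row.update(p_omnibus=p, skip_reason="", n_haplotypes=len(common),
                   reference_haplotype=labels[ref])
        window_rows.append(row)
        off = X0.shape[1]
        for k, c in enumerate(keep):
            hap_rows.append(
                {
                    "window": row["window"],
                    "haplotype": labels[c],
                    "frequency": float(em.frequencies[c]),
                    "beta": float(fit1.beta[off + k]),
                    "or": float(np.exp(fit1.beta[off + k])),
                    "se": float(fit1.se[off + k]),
                }
            )
    return pd.DataFrame(window_rows), pd.DataFrame(hap_rows)
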