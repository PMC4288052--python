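"""Synthetic admixed case-control cohorts over a single fine-mapping region.

The generator emulates a large multi-ancestral candidate-locus study: a
~400 kb region of tens of genotyped variants organised in haplotype blocks,
four ancestral haplotype pools mixed per individual with Dirichlet
proportions, one causal variant acting additively on the logit of disease
risk, ancestry-informative markers (AIMs) for stratification adjustment,
missingness (optionally differential between cases and controls), cryptic
relatedness, rare variants, imputation-style genotype probabilities, and
flow-cytometry / qPCR assay tables.

Haplotype pools are built by a copying-with-recombination scheme over a
small set of template haplotypes whose alleles follow an infinite-sites
mutation tree, so that within a block no pair of variants ever shows all
four gametes (|D'| = 1) while recombination between blocks breaks the
correlation.  This is deliberately not a coalescent simulation: it is the
minimal structure needed to exercise LD-based block finding, single-causal
fine-mapping, and haplotype association.

All generators are pure functions of their inputs and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .types import MISSING, GenotypeMatrix, GenotypeProbabilities, SampleRecord, VariantRecord

REGION_START = 58_100_000
REGION_SPAN = 400_000
ANCESTRIES = ("european", "african", "amerindian", "east_asian")


# ----------------------------------------------------------------------
# Haplotype pools
# ----------------------------------------------------------------------

@dataclass
class BlockSpec:
    """Contiguous LD-block layout for a haplotype pool.

    ``sizes`` partitions the variants; recombination (template re-draw)
    probability is ``rho_within`` between adjacent variants inside a block
    and ``rho_between`` at block boundaries.
    """

    sizes: tuple[int, ...]
    rho_within: float = 0.0
    rho_between: float = 0.5
    n_templates: int = 8
    freq_concentration: float = 1.0

    def boundaries(self) -> np.ndarray:
        """Indices j such that a boundary lies between variants j-1 and j."""
        return np.cumsum(self.sizes)[:-1]


@dataclass
class HaplotypePool:
    """Distinct haplotypes with sampling probabilities over one region."""

    haplotypes: np.ndarray  # (H, V) uint8
    frequencies: np.ndarray  # (H,) sums to 1
    positions: np.ndarray  # (V,) strictly increasing bp
    variant_ids: list[str] = field(default_factory=list)
    label: str = "pool"

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if len(self.frequencies) != self.haplotypes.shape[0]:
            raise ValueError("one frequency per haplotype required")
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ValueError("haplotype frequencies must sum to 1")
        if len(self.positions) != self.haplotypes.shape[1]:
            raise ValueError("one position per variant required")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not self.variant_ids:
            self.variant_ids = [f"var{j + 1:04d}" for j in range(self.haplotypes.shape[1])]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        return self.frequencies @ self.haplotypes


def _infinite_sites_templates(n_templates: int, n_variants: int, rng) -> np.ndarray:
    """Binary template alleles whose carrier sets form a laminar family.

    Templates are related by a random copying tree; each variant mutates on
    exactly one non-root node and is carried by that node's subtree, so no
    variant pair can show all four gametes among templates.
    """
    parents = np.array([0] + [int(rng.integers(0, t)) for t in range(1, n_templates)])
    # descendants (incl. self) per node
    children: list[list[int]] = [[] for _ in range(n_templates)]
    for t in range(1, n_templates):
        children[parents[t]].append(t)

    def subtree(t: int) -> list[int]:
        out, stack = [], [t]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(children[u])
        return out

    alleles = np.zeros((n_templates, n_variants), dtype=np.uint8)
    nodes = rng.integers(1, n_templates, size=n_variants)
    for j, t in enumerate(nodes):
        alleles[subtree(int(t)), j] = 1
    return alleles


def make_templates(n_variants: int, block_spec: BlockSpec, seed: int) -> np.ndarray:
    """Template haplotypes for a region, independent per block."""
    rng = np.random.default_rng(seed)
    m = block_spec.n_templates
    templates = np.empty((m, n_variants), dtype=np.uint8)
    start = 0
    for size in block_spec.sizes:
        templates[:, start : start + size] = _infinite_sites_templates(m, size, rng)
        start += size
    return templates


def build_haplotype_pool(
    n_haplotypes: int,
    n_variants: int,
    block_spec: BlockSpec,
    seed: int,
    positions: np.ndarray | None = None,
    label: str = "pool",
    templates: np.ndarray | None = None,
) -> HaplotypePool:
    """Emit a reproducible haplotype pool with block-structured LD.

    Passing pre-built ``templates`` lets several ancestral pools share one
    haplotype structure while drawing their own template frequencies — the
    usual situation for human continental populations, which share common
    haplotypes at very different frequencies.
    """
    if n_variants < 2:
        raise ValueError("a haplotype pool needs at least 2 variants")
    if sum(block_spec.sizes) != n_variants:
        raise ValueError("block sizes must partition the variants")
    rng = np.random.default_rng(seed)

    m = block_spec.n_templates
    if templates is None:
        templates = make_templates(n_variants, block_spec, seed)
    elif templates.shape != (m, n_variants):
        raise ValueError("templates shape inconsistent with the block spec")
    weights = rng.dirichlet(np.full(m, block_spec.freq_concentration))

    rho = np.full(n_variants, block_spec.rho_within)
    rho[0] = 0.0
    rho[block_spec.boundaries()] = block_spec.rho_between

    # copy templates with per-step re-draw probability rho[j]
    idx = rng.choice(m, size=n_haplotypes, p=weights)
    haps = np.empty((n_haplotypes, n_variants), dtype=np.uint8)
    haps[:, 0] = templates[idx, 0]
    for j in range(1, n_variants):
        if rho[j] > 0:
            switch = rng.random(n_haplotypes) < rho[j]
            if switch.any():
                idx = idx.copy()
                idx[switch] = rng.choice(m, size=int(switch.sum()), p=weights)
        haps[:, j] = templates[idx, j]

    uniq, counts = np.unique(haps, axis=0, return_counts=True)
    freqs = counts / counts.sum()

    if positions is None:
        positions = default_positions(n_variants, seed=seed)
    return HaplotypePool(uniq, freqs, positions, label=label)


def default_positions(
    n_variants: int, start: int = REGION_START, span: int = REGION_SPAN, seed: int = 0
) -> np.ndarray:
    rng = np.random.default_rng(seed + 777)
    pos = np.sort(rng.choice(span - 2, size=n_variants, replace=False)) + start + 1
    return pos.astype(np.int64)


def set_variant_frequency(pool: HaplotypePool, index: int, freq: float) -> HaplotypePool:
    """Rescale haplotype probabilities so one variant hits an exact frequency."""
    if not 0 < freq < 1:
        raise ValueError("target frequency must be in (0, 1)")
    carrier = pool.haplotypes[:, index] == 1
    cur = pool.frequencies[carrier].sum()
    if cur <= 0 or cur >= 1:
        raise ValueError(f"variant {index} is monomorphic in the pool; cannot rescale")
    new = pool.frequencies.copy()
    new[carrier] *= freq / cur
    new[~carrier] *= (1 - freq) / (1 - cur)
    new /= new.sum()
    return HaplotypePool(pool.haplotypes, new, pool.positions, list(pool.variant_ids), pool.label)


# ----------------------------------------------------------------------
# Cohort simulation
# ----------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study design of the simulated cohort.

    Defaults mirror the European-ancestry arm of the emulated study: 4220
    cases and 3803 controls, a single causal variant with risk-allele
    frequency 0.30 and odds ratio 0.81, three recorded admixture
    proportions, overall missingness under 5%, 347 AIMs, and rare variants
    below 1% frequency.
    """

    n_cases: int = 4220
    n_controls: int = 3803
    causal_index: int = 28
    causal_or: float = 0.81
    causal_raf: float = 0.30
    admixture_dirichlet: tuple[float, ...] = (10.0, 1.0, 0.5, 0.5)
    missing_rate: float = 0.02
    n_aims: int = 347
    rare_variant_count: int = 20
    rare_enrichment: float = 1.0  # multiplies rare carrier frequency in cases
    ancestry_logit_shift: tuple[float, ...] | None = None  # per-pool baseline risk shift
    female_fraction: float = 0.79
    seed: int = 0

    def __post_init__(self):
        if self.causal_or <= 0:
            raise ValueError("causal_or must be positive")
        if not 0 < self.causal_raf < 1:
            raise ValueError("causal_raf must be in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def _solve_intercept(beta, g_sample, shift_sample, target, tol=1e-6):
    """Bisection for the logit intercept giving the target case fraction."""
    lo, hi = -25.0, 25.0

    def mean_risk(mu):
        return float(np.mean(expit(mu + beta * g_sample + shift_sample)))

    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mean_risk(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(
    pool_per_ancestry: list[HaplotypePool],
    config: SimulationConfig,
    max_batches: int = 400,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw an admixed case-control cohort from ancestral haplotype pools.

    Disease status follows logit P(case) = mu + beta*G_causal (+ optional
    per-ancestry baseline shifts), with beta = log(causal_or) and mu solved
    by bisection so the expected case fraction matches the design ratio;
    exact case/control counts are then filled by rejection sampling.
    """
    K = len(pool_per_ancestry)
    if K == 0:
        raise ValueError("at least one ancestral pool required")
    V = pool_per_ancestry[0].n_variants
    for p in pool_per_ancestry:
        if p.n_variants != V:
            raise ValueError("all ancestral pools must cover the same variants")
    ci = config.causal_index
    if not 0 <= ci < V:
        raise ValueError("causal_index outside the region")

    pools = [set_variant_frequency(p, ci, config.causal_raf) for p in pool_per_ancestry]
    rng = np.random.default_rng(config.seed)
    beta = float(np.log(config.causal_or))
    alpha = np.asarray(config.admixture_dirichlet[:K], dtype=float)
    shift = np.zeros(K) if config.ancestry_logit_shift is None else np.asarray(
        config.ancestry_logit_shift[:K], dtype=float
    )
    n_total = config.n_cases + config.n_controls
    target = config.n_cases / n_total

    causal_allele = [p.haplotypes[:, ci].astype(float) for p in pools]

    def draw_batch(n):
        q = rng.dirichlet(alpha, size=n)  # (n, K)
        origin = np.empty((n, 2), dtype=np.int64)
        hap_idx = np.empty((n, 2), dtype=np.int64)
        for copy in range(2):
            if K == 1:
                origin[:, copy] = 0
            else:
                origin[:, copy] = (rng.random(n)[:, None] > np.cumsum(q, axis=1)[:, :-1]).sum(axis=1)
            for k in range(K):
                mask = origin[:, copy] == k
                if mask.any():
                    hap_idx[mask, copy] = rng.choice(
                        len(pools[k].frequencies), size=int(mask.sum()), p=pools[k].frequencies
                    )
        g_causal = np.zeros(n)
        for copy in range(2):
            for k in range(K):
                mask = origin[:, copy] == k
                if mask.any():
                    g_causal[mask] += causal_allele[k][hap_idx[mask, copy]]
        return q, origin, hap_idx, g_causal

    # calibrate the intercept on a generative pre-sample
    q0, _, _, g0 = draw_batch(20_000)
    mu = _solve_intercept(beta, g0, q0 @ shift, target)

    kept_q, kept_origin, kept_hap, kept_status = [], [], [], []
    n_case = n_ctrl = 0
    batch = max(2 * n_total, 1000)
    for _ in range(max_batches):
        if n_case >= config.n_cases and n_ctrl >= config.n_controls:
            break
        q, origin, hap_idx, g_causal = draw_batch(batch)
        p_case = expit(mu + beta * g_causal + q @ shift)
        status = (rng.random(len(p_case)) < p_case).astype(int)
        for s in (1, 0):
            need = (config.n_cases - n_case) if s == 1 else (config.n_controls - n_ctrl)
            if need <= 0:
                continue
            idx = np.nonzero(status == s)[0][:need]
            kept_q.append(q[idx])
            kept_origin.append(origin[idx])
            kept_hap.append(hap_idx[idx])
            kept_status.append(np.full(len(idx), s))
            if s == 1:
                n_case += len(idx)
            else:
                n_ctrl += len(idx)
    else:
        raise RuntimeError(
            "could not fill the requested case/control counts; the disease "
            "model parameters make one class too rare"
        )

    q = np.concatenate(kept_q)
    origin = np.concatenate(kept_origin)
    hap_idx = np.concatenate(kept_hap)
    status = np.concatenate(kept_status)
    n = len(status)
    order = rng.permutation(n)  # interleave cases and controls
    q, origin, hap_idx, status = q[order], origin[order], hap_idx[order], status[order]

    calls = np.zeros((n, V), dtype=np.int8)
    for copy in range(2):
        for k in range(K):
            mask = origin[:, copy] == k
            if mask.any():
                calls[mask] += pools[k].haplotypes[hap_idx[mask, copy]].astype(np.int8)

    pos = pools[0].positions
    variants = [
        VariantRecord(id=pools[0].variant_ids[j], chrom="3", pos=int(pos[j]), ref="A", alt="G")
        for j in range(V)
    ]
    sexes = np.where(rng.random(n) < config.female_fraction, "female", "male")
    ages = rng.integers(18, 81, size=n)
    samples = [
        SampleRecord(
            id=f"S{i + 1:06d}",
            sex=str(sexes[i]),
            status=int(status[i]),
            admixture=tuple(float(x) for x in q[i]),
            age=float(ages[i]),
            phenotype_completeness=1.0,
        )
        for i in range(n)
    ]
    gm = GenotypeMatrix(calls, variants, samples)
    if config.rare_variant_count > 0:
        gm = add_rare_variants(
            gm,
            config.rare_variant_count,
            enrichment=config.rare_enrichment,
            seed=int(rng.integers(2**31)),
        )
    mafs = gm.maf()
    for j, v in enumerate(gm.variants):
        v.maf = float(mafs[j])
    return gm, gm.sample_table()


def add_rare_variants(
    gm: GenotypeMatrix, count: int, enrichment: float = 1.0, seed: int = 0
) -> GenotypeMatrix:
    """Append independent rare sites (MAF uniform on [0.0005, 0.01]).

    ``enrichment`` > 1 multiplies the carrier allele frequency in cases,
    creating the aggregate case excess a rare-variant burden test should
    detect.
    """
    rng = np.random.default_rng(seed)
    n = gm.n_samples
    freqs = rng.uniform(0.0005, 0.01, size=count)
    status = gm.status_array()
    calls = np.zeros((n, count), dtype=np.int8)
    for j, f in enumerate(freqs):
        f_case = min(f * enrichment, 0.5)
        p = np.where(status == 1, f_case, f)
        calls[:, j] = rng.binomial(2, p).astype(np.int8)
    last_pos = int(gm.variants[-1].pos) if gm.variants else REGION_START
    step = rng.integers(50, 500, size=count)
    pos = last_pos + np.cumsum(step)
    variants = [
        VariantRecord(id=f"rare{j + 1:03d}", chrom="3", pos=int(pos[j]), ref="A", alt="T")
        for j in range(count)
    ]
    return GenotypeMatrix(
        np.hstack([gm.calls, calls]), gm.variants + variants, gm.samples
    )


# ----------------------------------------------------------------------
# Missingness, probabilities, relatedness
# ----------------------------------------------------------------------

def inject_missingness(
    gm: GenotypeMatrix,
    missing_rate: float,
    differential_rate: float = 0.0,
    seed: int = 0,
    flagged_variants: list[int] | None = None,
) -> GenotypeMatrix:
    """Mask calls at random; optionally excess case missingness at flagged sites."""
    if not (0 <= missing_rate < 1 and 0 <= differential_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    if missing_rate == 0 and differential_rate == 0:
        return gm
    rng = np.random.default_rng(seed)
    out = gm.copy()
    rate = np.full(out.calls.shape, missing_rate)
    if differential_rate > 0 and flagged_variants:
        is_case = out.status_array() == 1
        for j in flagged_variants:
            rate[is_case, j] = min(missing_rate + differential_rate, 0.999)
    mask = rng.random(out.calls.shape) < rate
    out.calls[mask] = MISSING
    return out


def simulate_probabilities(
    gm: GenotypeMatrix, certainty: float, seed: int = 0
) -> GenotypeProbabilities:
    """Imputation-style genotype posteriors around the true calls.

    Mass ``certainty`` sits on the true genotype; the remainder is split at
    random between the other two categories.  Missing truths get a uniform
    triplet.
    """
    if not (1.0 / 3.0 < certainty <= 1.0):
        raise ValueError("certainty must be in (1/3, 1]")
    rng = np.random.default_rng(seed)
    n, v = gm.calls.shape
    t = np.empty((n, v, 3))
    u = rng.random((n, v))
    rem = 1.0 - certainty
    g = gm.calls
    for cat in range(3):
        others = [c for c in range(3) if c != cat]
        sel = g == cat
        t[sel, cat] = certainty
        t[sel, others[0]] = rem * u[sel]
        t[sel, others[1]] = rem * (1.0 - u[sel])
    t[g == MISSING] = 1.0 / 3.0
    t /= t.sum(axis=2, keepdims=True)
    return GenotypeProbabilities(
        t, [v_ for v_ in gm.variants], [s for s in gm.samples]
    )


def simulate_relatives_and_duplicates(
    gm: GenotypeMatrix, n_pairs: int, relationship: str, seed: int = 0
) -> GenotypeMatrix:
    """Overwrite samples so that pairs (2i, 2i+1) are related as requested."""
    if relationship not in ("duplicate", "parent_offspring", "full_sib"):
        raise ValueError(f"unknown relationship {relationship!r}")
    if 2 * n_pairs > gm.n_samples:
        raise ValueError("not enough samples for the requested pairs")
    rng = np.random.default_rng(seed)
    out = gm.copy()
    freqs = np.clip(gm.allele_frequencies(), 0.01, 0.99)
    for i in range(n_pairs):
        a, b = 2 * i, 2 * i + 1
        ga = out.calls[a].astype(float)
        ga[ga == MISSING] = 0
        if relationship == "duplicate":
            out.calls[b] = out.calls[a]
            continue
        # split a's genotype into two allele vectors
        coin = rng.random(gm.n_variants) < 0.5
        a1 = np.where(ga == 2, 1, np.where((ga == 1) & coin, 1, 0))
        a2 = ga - a1
        pop = lambda: (rng.random(gm.n_variants) < freqs).astype(float)  # noqa: E731
        if relationship == "parent_offspring":
            transmit = np.where(rng.random(gm.n_variants) < 0.5, a1, a2)
            child = transmit + pop()
        else:  # full_sib: per parent, share a's allele with prob 1/2
            s1 = np.where(rng.random(gm.n_variants) < 0.5, a1, pop())
            s2 = np.where(rng.random(gm.n_variants) < 0.5, a2, pop())
            child = s1 + s2
        out.calls[b] = child.astype(np.int8)
    return out


# ----------------------------------------------------------------------
# AIMs and ancestral panel
# ----------------------------------------------------------------------

def make_ancestral_panel(n_aims: int = 347, n_pops: int = 4, seed: int = 0) -> pd.DataFrame:
    """Ancestral allele-frequency table for AIMs (populations x markers).

    AIMs are, by construction, markers with large between-population
    frequency differentials; frequencies are drawn from a bimodal Beta so
    each marker tends to be near-fixed for different alleles in different
    populations.
    """
    rng = np.random.default_rng(seed)
    freqs = np.clip(rng.beta(0.25, 0.25, size=(n_pops, n_aims)), 0.02, 0.98)
    return pd.DataFrame(
        freqs,
        index=list(ANCESTRIES[:n_pops]),
        columns=[f"AIM{j + 1:04d}" for j in range(n_aims)],
    )


def simulate_aims(
    samples: list[SampleRecord], panel: pd.DataFrame, seed: int = 0
) -> GenotypeMatrix:
    """AIM genotypes: each allele copy drawn from an ancestral pool by admixture."""
    rng = np.random.default_rng(seed)
    freqs = panel.to_numpy()  # (K, M)
    K, M = freqs.shape
    n = len(samples)
    q = np.array([s.admixture[:K] for s in samples], dtype=float)
    q = q / q.sum(axis=1, keepdims=True)
    calls = np.zeros((n, M), dtype=np.int8)
    cum = np.cumsum(q, axis=1)[:, :-1]  # (n, K-1)
    for copy in range(2):
        # AIMs are unlinked: each allele copy draws its ancestral origin
        # independently per marker
        origin = (rng.random((n, M))[:, :, None] > cum[:, None, :]).sum(axis=2)
        p = freqs.T[np.arange(M)[None, :], origin]
        calls += (rng.random((n, M)) < p).astype(np.int8)
    variants = [
        VariantRecord(id=str(c), chrom="AIM", pos=j + 1, ref="A", alt="C")
        for j, c in enumerate(panel.columns)
    ]
    return GenotypeMatrix(calls, variants, samples)


# ----------------------------------------------------------------------
# Assay tables
# ----------------------------------------------------------------------

def simulate_assay_tables(
    genotype_groups: tuple[str, str] = ("protective", "risk"),
    effect: float = 0.5,
    noise_sd: float = 3.0,
    n_lines: int = 10,
    timepoints: tuple[float, ...] = (2, 5, 10, 20, 30),
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Receptor-internalization time courses for two genotype groups.

    The protective group follows a saturating mean curve of percent
    internalization; the risk group's curve is ``effect`` times it at every
    timepoint (before noise), encoding a multiplicative kinetic deficit.
    gMFI columns are reconstructed so the percent-internalization formula
    recovers the simulated percentages exactly.
    """
    if effect <= 0:
        raise ValueError("effect must be positive")
    if not timepoints:
        raise ValueError("timepoints must be non-empty")
    rng = np.random.default_rng(seed)
    base_curve = lambda t: 70.0 * (1.0 - np.exp(-np.asarray(t, dtype=float) / 10.0))  # noqa: E731
    rows = []
    for g, group in enumerate(genotype_groups):
        scale = 1.0 if g == 0 else effect
        for line in range(n_lines):
            line_id = f"{group[:4]}_line{line + 1:02d}"
            for t in timepoints:
                mean_pct = scale * float(base_curve(t))
                for rep in range(n_replicates):
                    pct = mean_pct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    pct = min(pct, 99.99)
                    gmfi_4c = 1000.0
                    rows.append(
                        {
                            "cell_line": line_id,
                            "genotype_group": group,
                            "timepoint": float(t),
                            "replicate": rep + 1,
                            "gmfi_4c": gmfi_4c,
                            "gmfi_37c": gmfi_4c * (1.0 - pct / 100.0),
                            "true_mean_pct": mean_pct,
                        }
                    )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Convenience study builder
# ----------------------------------------------------------------------

def build_study_pools(
    n_variants: int = 57,
    block_sizes: tuple[int, ...] | None = None,
    n_haplotypes: int = 10_000,
    seed: int = 0,
    n_templates: int = 4,
) -> list[HaplotypePool]:
    """Four ancestral pools over shared positions and haplotype templates.

    The pools share one template structure per block — emulating a locus
    whose common haplotypes are ancient and population-shared — but draw
    independent template frequencies, so allele frequencies and LD
    strength differ by ancestry.  The default of four templates per block
    produces the tight within-block LD characteristic of a locus carrying
    a single large risk haplotype.
    """
    if block_sizes is None:
        third = n_variants // 3
        block_sizes = (third, third, n_variants - 2 * third)
    positions = default_positions(n_variants, seed=seed)
    spec = BlockSpec(sizes=tuple(block_sizes), n_templates=n_templates)
    templates = make_templates(n_variants, spec, seed=seed * 4 + 101)
    pools = []
    for k, label in enumerate(ANCESTRIES):
        pools.append(
            build_haplotype_pool(
                n_haplotypes, n_variants, spec, seed=seed * 4 + k + 1,
                positions=positions, label=label, templates=templates,
            )
        )
    return pools
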