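"""Core in-memory containers shared by every analysis stage.

Genotypes are stored as minor-allele counts in a dense ``int8`` matrix
(samples x variants) with ``-1`` marking a missing call.  Imputed variants
carry a parallel ``(samples, variants, 3)`` array of genotype posterior
probabilities.  Small per-variant / per-sample metadata live in plain
dataclasses; tabular views are pandas DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class VariantRecord:
    """Metadata for one biallelic site.

    ``alt`` is the counted (minor) allele after orientation; ``ref`` the
    other allele.  ``info`` is the imputation information score (NaN for
    directly genotyped sites).
    """

    id: str
    chrom: str = "3"
    pos: int = 1
    ref: str = "A"
    alt: str = "G"
    maf: float = float("nan")
    genotyped: bool = True
    info: float = float("nan")


@dataclass
class SampleRecord:
    id: str
    sex: str = "unknown"  # male / female / unknown
    status: int = 0  # 1 = case, 0 = control
    call_rate: float = float("nan")
    admixture: tuple[float, ...] | None = None  # proportions over ancestral pools
    pcs: tuple[float, ...] | None = None  # first three PC scores
    age: float | None = None
    phenotype_completeness: float | None = None  # fraction of phenotype fields present


class GenotypeMatrix:
    """Samples x variants matrix of minor-allele counts with metadata."""

    def __init__(
        self,
        calls: np.ndarray,
        variants: Sequence[VariantRecord],
        samples: Sequence[SampleRecord],
    ):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        if calls.shape != (len(samples), len(variants)):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        bad = ~np.isin(calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype calls must be in {-1, 0, 1, 2}")
        self.calls = calls
        self.variants = list(variants)
        self.samples = list(samples)

    # -- shape ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    # -- summaries -----------------------------------------------------
    def allele_frequencies(self) -> np.ndarray:
        """Frequency of the counted allele per variant, ignoring missing."""
        g = self.calls.astype(float)
        g[self.calls == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(g, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_frequencies()
        return np.minimum(f, 1.0 - f)

    def variant_call_rates(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def sample_call_rates(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def status_array(self) -> np.ndarray:
        return np.array([s.status for s in self.samples], dtype=int)

    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def admixture_covariates(self, k: int = 3) -> np.ndarray:
        """First ``k`` recorded admixture proportions as a covariate matrix."""
        rows = []
        for s in self.samples:
            if s.admixture is None:
                raise ValueError(f"sample {s.id} has no admixture proportions")
            rows.append(s.admixture[:k])
        return np.asarray(rows, dtype=float)

    # -- subsetting ----------------------------------------------------
    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            self.calls[np.ix_(si, vi)],
            [self.variants[j] for j in vi],
            [self.samples[i] for i in si],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls.copy(),
            [replace(v) for v in self.variants],
            [replace(s) for s in self.samples],
        )

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            adm = s.admixture or (np.nan, np.nan, np.nan)
            pcs = s.pcs or (np.nan, np.nan, np.nan)
            rows.append(
                {
                    "id": s.id,
                    "sex": s.sex,
                    "status": s.status,
                    "admix1": adm[0],
                    "admix2": adm[1],
                    "admix3": adm[2],
                    "pc1": pcs[0],
                    "pc2": pcs[1],
                    "pc3": pcs[2],
                }
            )
        return pd.DataFrame(rows)


@dataclass
class GenotypeProbabilities:
    """Per sample-variant genotype posterior triplets (hom-ref, het, hom-alt)."""

    triplets: np.ndarray  # (samples, variants, 3)
    variants: list[VariantRecord] = field(default_factory=list)
    samples: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self):
        t = np.asarray(self.triplets, dtype=float)
        if t.ndim != 3 or t.shape[2] != 3:
            raise ValueError("triplets must have shape (samples, variants, 3)")
        if (t < 0).any() or (t > 1 + 1e-9).any():
            raise ValueError("probabilities must lie in [0, 1]")
        sums = t.sum(axis=2)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("each probability triplet must sum to 1")
        self.triplets = t

    def dosages(self) -> np.ndarray:
        """Expected minor-allele count per sample-variant, in [0, 2]."""
        return self.triplets[:, :, 1] + 2.0 * self.triplets[:, :, 2]


@dataclass
class AssociationResult:
    variant_id: str
    model: str  # additive / dominant / recessive / genotypic / trend
    beta: float
    se: float
    p: float
    n_eff: int
    conditioned_on: tuple[str, ...] = ()
    note: str = ""

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        lo = float(np.exp(self.beta - 1.96 * self.se))
        hi = float(np.exp(self.beta + 1.96 * self.se))
        return lo, hi

    def to_row(self) -> dict:
        lo, hi = self.ci95
        return {
            "variant_id": self.variant_id,
            "model": self.model,
            "beta": self.beta,
            "se": self.se,
            "or": self.or_,
            "ci95_low": lo,
            "ci95_high": hi,
            "p": self.p,
            "neglog10_p": neglog10(self.p),
            "n_eff": self.n_eff,
            "conditioned_on": ",".join(self.conditioned_on),
            "note": self.note,
        }


def neglog10(p: float) -> float:
    """-log10(p) computed safely; underflowed p reported via the log scale."""
    if p <= 0:
        return float("inf")
    return float(-np.log10(p))


@dataclass
class CredibleSet:
    """Single-causal-variant credible set over a region."""

    variant_ids: list[str]
    log_bf: np.ndarray
    posterior: np.ndarray
    members: np.ndarray  # boolean flags
    level: float
    span_bp: int
    cumulative: float

    @property
    def member_ids(self) -> list[str]:
        return [v for v, m in zip(self.variant_ids, self.members) if m]

    @property
    def size(self) -> int:
        return int(self.members.sum())

    def to_frame(self, positions=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "log_bf": self.log_bf,
                "posterior": self.posterior,
                "member": self.members.astype(int),
            }
        )
        if positions is not None:
            df.insert(1, "pos", positions)
        return df
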