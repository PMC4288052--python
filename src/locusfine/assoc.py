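"""Frequentist association engine for a case-control fine-mapping region.

Logistic regression is fitted by iteratively reweighted least squares
(IRLS/Newton) with collinear-column dropping and separation detection.
Single-variant tests support additive, dominant, recessive, genotypic
(2 df) and Cochran-Armitage trend codings, take imputed dosages in [0, 2],
and include admixture-proportion covariates by default.  Stepwise
conditional analysis isolates independent signals, and an analytic power
calculator covers the trend test under the same retrospective sampling
design the synthetic cohorts use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

from .types import MISSING, AssociationResult, GenotypeMatrix

MODELS = ("additive", "dominant", "recessive", "genotypic", "trend")


# ----------------------------------------------------------------------
# Logistic regression (IRLS)
# ----------------------------------------------------------------------

@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    separation: bool
    kept_columns: np.ndarray  # indices into the original design
    n: int

    def wald_p(self, idx: int) -> float:
        if not np.isfinite(self.se[idx]) or self.se[idx] == 0:
            return float("nan")
        z = self.beta[idx] / self.se[idx]
        return float(2 * norm.sf(abs(z)))


def _drop_collinear(X: np.ndarray) -> np.ndarray:
    """Indices of a full-rank column subset, keeping earlier columns.

    Later columns collinear with earlier ones are the ones dropped, so a
    tested term placed last never silently displaces its conditioning
    columns.
    """
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    kept: list[int] = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, j] / scale[j]
        resid = col - basis @ (basis.T @ col)
        nrm = np.linalg.norm(resid)
        if nrm > 1e-8 * max(1.0, np.linalg.norm(col)):
            basis = np.column_stack([basis, resid / nrm])
            kept.append(j)
    return np.array(kept, dtype=int)


def fit_logistic(
    response: np.ndarray,
    design_matrix: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
    prior_precision: np.ndarray | None = None,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by Newton/IRLS.

    Collinear columns are dropped (with a warning) before fitting;
    separation is detected and reported rather than silently diverging.
    ``prior_precision`` adds an optional diagonal Gaussian penalty (used by
    the Bayesian module); zero entries mean flat.
    """
    y = np.asarray(response, dtype=float)
    X = np.atleast_2d(np.asarray(design_matrix, dtype=float))
    if X.shape[0] != len(y):
        raise ValueError("response and design matrix lengths differ")
    if len(np.unique(y)) < 2 and prior_precision is None:
        raise ValueError("both outcome classes must be present")

    kept = _drop_collinear(X)
    if len(kept) < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - len(kept)} collinear design column(s)",
            stacklevel=2,
        )
    Xk = X[:, kept]
    prec = np.zeros(len(kept))
    if prior_precision is not None:
        prec = np.asarray(prior_precision, dtype=float)[kept]

    p_ = X.shape[1]
    beta = np.zeros(len(kept))
    converged = False
    separation = False
    loglik = -np.inf
    for _ in range(max_iter):
        eta = Xk @ beta
        mu = expit(eta)
        grad = Xk.T @ (y - mu) - prec * beta
        if np.linalg.norm(grad) <= tol:
            converged = True
            break
        w = np.clip(mu * (1 - mu), 1e-12, None)
        H = (Xk * w[:, None]).T @ Xk + np.diag(prec)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            separation = True
            break
        # step-halving on the penalized log-likelihood
        ll0 = _penalized_loglik(y, Xk, beta, prec)
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            if _penalized_loglik(y, Xk, cand, prec) >= ll0 - 1e-12:
                break
            t /= 2
        beta = beta + t * step
        if np.abs(beta).max() > 1e3:
            separation = True
            break

    eta = Xk @ beta
    mu = expit(eta)
    loglik = float(np.sum(y * np.log(np.clip(mu, 1e-300, None)) + (1 - y) * np.log(np.clip(1 - mu, 1e-300, None))))
    if not separation and len(beta):
        # a huge coefficient on an unpenalized column means (quasi-)separation
        # even when the gradient has flattened out enough to "converge"
        free = prec == 0
        if free.any() and np.abs(beta[free]).max() > 15:
            separation = True
    w = np.clip(mu * (1 - mu), 1e-12, None)
    H = (Xk * w[:, None]).T @ Xk + np.diag(prec)
    try:
        cov_k = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_k = np.full((len(kept), len(kept)), np.nan)
    full_beta = np.zeros(p_)
    full_se = np.full(p_, np.nan)
    full_cov = np.full((p_, p_), np.nan)
    full_beta[kept] = beta
    if separation:
        full_beta[kept] = np.sign(beta) * np.where(np.abs(beta) > 50, np.inf, np.abs(beta))
        full_se[kept] = np.inf
    else:
        full_se[kept] = np.sqrt(np.clip(np.diag(cov_k), 0, None))
        full_cov[np.ix_(kept, kept)] = cov_k
    return LogisticFit(
        beta=full_beta, se=full_se, cov=full_cov, loglik=loglik,
        converged=converged, separation=separation,
        kept_columns=kept, n=len(y),
    )


def _penalized_loglik(y, X, beta, prec):
    eta = X @ beta
    # log-likelihood via the numerically safe log(1+exp) form
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return ll - 0.5 * float(np.sum(prec * beta**2))


# ----------------------------------------------------------------------
# Genotype codings and single-variant tests
# ----------------------------------------------------------------------

def _code_genotype(g: np.ndarray, model: str) -> np.ndarray:
    if model in ("additive", "trend"):
        return g.astype(float)
    if model == "dominant":
        return (g >= 1).astype(float)
    if model == "recessive":
        return (g == 2).astype(float)
    raise ValueError(f"unknown model {model!r}")


def test_variant(
    gm: GenotypeMatrix,
    variant: int | str,
    covariates: np.ndarray | None = None,
    model: str = "additive",
    dosage: np.ndarray | None = None,
    conditioned_on: tuple[str, ...] = (),
    extra_columns: np.ndarray | None = None,
) -> AssociationResult:
    """Association test of one variant against case-control status.

    ``dosage`` (expected allele counts in [0, 2]) replaces hard calls for
    imputed variants; the genotypic model uses two indicator columns and a
    2-df likelihood-ratio test.  The trend model is the Cochran-Armitage
    test on the 2x3 table and ignores covariates.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    j = variant if isinstance(variant, int) else [v.id for v in gm.variants].index(variant)
    vid = gm.variants[j].id
    y_all = gm.status_array().astype(float)
    g_all = dosage if dosage is not None else gm.calls[:, j].astype(float)
    ok = ~np.isnan(np.asarray(g_all, dtype=float))
    if dosage is None:
        ok &= gm.calls[:, j] != MISSING
    y, g = y_all[ok], np.asarray(g_all, dtype=float)[ok]
    n_eff = int(ok.sum())
    if len(np.unique(g)) < 2:
        return AssociationResult(vid, model, np.nan, np.nan, np.nan, n_eff,
                                 conditioned_on, note="monomorphic")

    if model == "trend":
        table = np.array(
            [[(g[y == 1] == k).sum() for k in (0, 1, 2)],
             [(g[y == 0] == k).sum() for k in (0, 1, 2)]],
            dtype=float,
        )
        stat, p = catt_trend(table)
        return AssociationResult(vid, model, np.nan, np.nan, p, n_eff,
                                 conditioned_on, note=f"catt_stat={stat:.6g}")

    # conditioning and covariate columns come first; the tested genotype
    # term is last so collinearity resolves in the null model's favour
    base_cols = [np.ones(n_eff)]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != gm.n_samples:
            C = C.T
        base_cols.append(C[ok])
    if extra_columns is not None:
        E = np.atleast_2d(np.asarray(extra_columns, dtype=float))
        if E.shape[0] != gm.n_samples:
            E = E.T
        base_cols.append(E[ok])
    X0 = np.column_stack(base_cols)
    width0 = X0.shape[1]
    if model == "genotypic":
        geno_cols = [(g == 1).astype(float), (g == 2).astype(float)]
    else:
        geno_cols = [_code_genotype(g, model)]
    X = np.column_stack([X0] + geno_cols)
    gidx = width0 if model != "genotypic" else width0 + 1
    fit = fit_logistic(y, X)
    if gidx not in fit.kept_columns:
        return AssociationResult(vid, model, np.nan, np.nan, np.nan, n_eff,
                                 conditioned_on, note="collinear")
    if fit.separation:
        return AssociationResult(vid, model, float(fit.beta[gidx]), float("inf"),
                                 np.nan, n_eff, conditioned_on, note="separation")
    if model == "genotypic":
        fit0 = fit_logistic(y, X0)
        k_geno = int(np.isin([width0, width0 + 1], fit.kept_columns).sum())
        lrt = 2 * (fit.loglik - fit0.loglik)
        p = float(chi2.sf(max(lrt, 0.0), df=max(k_geno, 1)))
        return AssociationResult(
            vid, model, float(fit.beta[gidx]), float(fit.se[gidx]), p, n_eff,
            conditioned_on, note=f"beta_het={fit.beta[width0]:.6g}",
        )
    p = fit.wald_p(gidx)
    return AssociationResult(vid, model, float(fit.beta[gidx]), float(fit.se[gidx]),
                             p, n_eff, conditioned_on)


def scan_region(
    gm: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    model: str = "additive",
    dosages: np.ndarray | None = None,
    conditioned_on: tuple[str, ...] = (),
    extra_columns: np.ndarray | None = None,
) -> list[AssociationResult]:
    out = []
    for j in range(gm.n_variants):
        d = dosages[:, j] if dosages is not None else None
        out.append(
            test_variant(gm, j, covariates, model, dosage=d,
                         conditioned_on=conditioned_on, extra_columns=extra_columns)
        )
    return out


# ----------------------------------------------------------------------
# Cochran-Armitage trend test
# ----------------------------------------------------------------------

def catt_trend(table_2x3: np.ndarray, weights=(0.0, 1.0, 2.0)) -> tuple[float, float]:
    """Cochran-Armitage trend statistic (1 df) for a case/control x genotype table.

    Identical to the score test of the additive logistic model without
    covariates.
    """
    t = np.asarray(table_2x3, dtype=float)
    if t.shape != (2, 3):
        raise ValueError("expected a 2x3 table")
    w = np.asarray(weights, dtype=float)
    n = t.sum()
    r1 = t[0].sum()  # cases
    r0 = t[1].sum()
    col = t.sum(axis=0)
    if n == 0 or r1 == 0 or r0 == 0:
        raise ValueError("table has a zero margin")
    u = float(w @ t[0] - r1 * (w @ col) / n)
    v = (r1 * r0 / n**2) * float((w**2) @ col - (w @ col) ** 2 / n)
    if v <= 0:
        return 0.0, 1.0
    stat = u**2 / v
    return float(stat), float(chi2.sf(stat, df=1))


# ----------------------------------------------------------------------
# Stepwise conditional analysis
# ----------------------------------------------------------------------

def stepwise_conditional(
    gm: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    p_in: float = 0.01,
    dosages: np.ndarray | None = None,
    max_signals: int = 10,
    profile_candidates: list[int] | None = None,
) -> tuple[list[AssociationResult], pd.DataFrame]:
    """Forward stepwise conditioning on allelic dosage.

    Repeatedly adds the most significant variant to the model as a
    covariate until no remaining variant reaches ``p_in``.  Also emits, for
    each candidate conditioning variant, the strongest residual signal in
    the region after conditioning on that variant alone — the profile of
    each variant's ability to account for the association.
    """
    def variant_column(j: int) -> np.ndarray:
        if dosages is not None:
            return dosages[:, j]
        col = gm.calls[:, j].astype(float)
        col[gm.calls[:, j] == MISSING] = np.nan
        # mean-impute so conditioning does not shrink the sample
        m = np.nanmean(col)
        col[np.isnan(col)] = m
        return col

    signals: list[AssociationResult] = []
    chosen: list[int] = []
    while len(signals) < max_signals:
        extra = (
            np.column_stack([variant_column(j) for j in chosen]) if chosen else None
        )
        results = scan_region(
            gm, covariates, "additive", dosages=dosages,
            conditioned_on=tuple(gm.variants[j].id for j in chosen),
            extra_columns=extra,
        )
        candidates = [
            (r.p, j) for j, r in enumerate(results)
            if j not in chosen and np.isfinite(r.p)
        ]
        if not candidates:
            break
        best_p, best_j = min(candidates)
        if best_p >= p_in:
            break
        chosen.append(best_j)
        signals.append(results[best_j])

    prof_rows = []
    cand = profile_candidates if profile_candidates is not None else list(range(gm.n_variants))
    for c in cand:
        extra = variant_column(c)[:, None]
        results = scan_region(
            gm, covariates, "additive", dosages=dosages,
            conditioned_on=(gm.variants[c].id,), extra_columns=extra,
        )
        ps = [r.p for j, r in enumerate(results) if j != c and np.isfinite(r.p)]
        max_neglog = float(-np.log10(min(ps))) if ps else 0.0
        prof_rows.append(
            {
                "conditioning_variant": gm.variants[c].id,
                "max_residual_neglog10_p": max_neglog,
                "min_residual_p": min(ps) if ps else np.nan,
            }
        )
    return signals, pd.DataFrame(prof_rows)


# ----------------------------------------------------------------------
# Power
# ----------------------------------------------------------------------

def case_control_genotype_distributions(
    raf: float, or_: float, case_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype distributions in cases and controls under the logistic model.

    Hardy-Weinberg genotype frequencies at risk-allele frequency ``raf``;
    logit disease risk additive in allele count with log-odds log(or_);
    the intercept is solved by bisection so the marginal case probability
    equals ``case_fraction`` (the retrospective sampling design).
    """
    f = np.array([(1 - raf) ** 2, 2 * raf * (1 - raf), raf**2])
    beta = np.log(or_)
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(f @ expit(mid + beta * np.arange(3))) < case_fraction:
            lo = mid
        else:
            hi = mid
    mu = 0.5 * (lo + hi)
    pi = expit(mu + beta * np.arange(3))
    p_case = f * pi / float(f @ pi)
    p_ctrl = f * (1 - pi) / float(f @ (1 - pi))
    return p_case, p_ctrl


def power_case_control(
    n_case: int, n_ctrl: int, raf: float, or_: float, alpha: float,
    model: str = "additive",
) -> float:
    """Analytic power of the 1-df trend test at the given design.

    Normal approximation with the alternative-hypothesis variance of the
    case-control difference in mean allele score.
    """
    if model != "additive":
        raise ValueError("power is computed for the additive (trend) model")
    if or_ == 1.0:
        return float(alpha)
    p_case, p_ctrl = case_control_genotype_distributions(
        raf, or_, n_case / (n_case + n_ctrl)
    )
    w = np.arange(3, dtype=float)
    n = n_case + n_ctrl
    pooled = (n_case * p_case + n_ctrl * p_ctrl) / n
    delta = float(w @ p_case - w @ p_ctrl)
    var_null = float((w**2) @ pooled - (w @ pooled) ** 2) * (1 / n_case + 1 / n_ctrl)
    var_case = float((w**2) @ p_case - (w @ p_case) ** 2)
    var_ctrl = float((w**2) @ p_ctrl - (w @ p_ctrl) ** 2)
    var_alt = var_case / n_case + var_ctrl / n_ctrl
    zcrit = norm.isf(alpha / 2)
    m = delta / np.sqrt(var_null)
    sd = np.sqrt(var_alt / var_null)
    power = norm.sf((zcrit - m) / sd) + norm.cdf((-zcrit - m) / sd)
    return float(np.clip(power, 0.0, 1.0))
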