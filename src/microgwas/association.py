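"""Covariate-adjusted association testing and meta-analysis.

Microbiome traits (relative abundances, module profiles, diversity indices)
are inverse rank-normal transformed (IRNT) before association, so per-allele
effect sizes are in standard deviations of the transformed trait.  Single-
variant tests are ordinary least squares with covariate adjustment under an
additive genetic model; meta-analysis follows the METAL conventions
(fixed-effect inverse-variance weighting, or sample-size weighting of signed
z-scores when effect sizes are on incompatible scales).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GENOME_WIDE_ALPHA = 5e-8

SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "EA", "NEA", "EAF", "BETA", "SE", "P", "N"]


# ---------------------------------------------------------------------------
# Inverse rank-normal transform
# ---------------------------------------------------------------------------

def irnt(values: np.ndarray | pd.Series, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Inverse rank-normal transform with the Blom offset.

    Ties get average ranks; rank r of n maps to the standard-normal quantile
    of (r - 3/8) / (n + 1/4).  Monotone in the input; roughly zero mean and
    unit variance.  Raises on constant or too-short input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("irnt needs a 1-D vector of at least 3 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("irnt input must be finite")
    if np.min(x) == np.max(x):
        raise ValueError("irnt input is constant (untransformable)")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (x.size + 1 - 2 * offset))


# ---------------------------------------------------------------------------
# Design-matrix plumbing
# ---------------------------------------------------------------------------

def _as_matrix(covariates) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((0, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), list(covariates.columns)
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"cov{i}" for i in range(arr.shape[1])]


def build_design(n: int, covariates=None, extra: np.ndarray | None = None,
                 extra_names: Sequence[str] = ()) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariates (+ conditioned-on dosages), with a rank check.

    Raises naming the offending columns when the design is collinear.
    """
    cov, names = _as_matrix(covariates)
    cols = [np.ones(n)]
    colnames = ["intercept"]
    if cov.size:
        cols.extend(cov.T)
        colnames.extend(names)
    if extra is not None and extra.size:
        cols.extend(np.atleast_2d(extra.T if extra.ndim > 1 else extra))
        colnames.extend(extra_names or [f"extra{i}" for i in range(np.atleast_2d(extra).shape[0])])
    X = np.column_stack(cols)
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify offending columns by incremental rank growth
        bad = []
        kept = X[:, [0]]
        for j in range(1, X.shape[1]):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(colnames[j])
            else:
                kept = cand
        raise ValueError(f"collinear covariates: {bad}")
    return X, colnames


def _residualize(X: np.ndarray, *vectors: np.ndarray):
    """Project out the column space of X (Frisch-Waugh-Lovell)."""
    Q, _ = np.linalg.qr(X)
    return tuple(v - Q @ (Q.T @ v) for v in vectors)


def _pvalue(z_or_t: np.ndarray, dof: int, n: int) -> np.ndarray:
    """Two-sided p. Normal approximation for n >= 1000, Student t below."""
    if n >= 1000:
        return 2 * stats.norm.sf(np.abs(z_or_t))
    return 2 * stats.t.sf(np.abs(z_or_t), dof)


# ---------------------------------------------------------------------------
# Single-variant GWAS
# ---------------------------------------------------------------------------

def gwas_linear(
    dosages: pd.DataFrame,
    trait: np.ndarray | pd.Series,
    covariates=None,
    condition_on: Sequence[str] | None = None,
    variants: pd.DataFrame | None = None,
    maf_min: float = 0.01,
) -> pd.DataFrame:
    """Per-SNP covariate-adjusted OLS of a (typically IRNT) trait on dosage.

    ``dosages`` is samples x SNPs (effect-allele counts 0..2);
    ``condition_on`` adds those SNPs' dosages to the covariates (conditional
    analysis).  SNPs with MAF < ``maf_min`` are excluded.  Returns a
    GWAS-Catalog-style summary table (SNP, CHR, BP, EA, NEA, EAF, BETA, SE,
    P, N); positional metadata comes from ``variants`` when given.
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    if dosages.shape[0] != n:
        raise ValueError("trait and dosage sample counts differ")
    condition_on = list(condition_on or [])
    extra = dosages[condition_on].to_numpy(dtype=float) if condition_on else None
    X, _ = build_design(n, covariates, extra, [f"cond:{s}" for s in condition_on])
    if n <= X.shape[1] + 2:
        raise ValueError("too few samples for the covariate design")

    eaf = dosages.mean(axis=0).to_numpy() / 2.0
    maf = np.minimum(eaf, 1 - eaf)
    # conditioned-on SNPs are part of the design; testing them against their
    # own residual is degenerate, so they leave the scan
    keep = (maf >= maf_min) & ~dosages.columns.isin(condition_on)
    snps = dosages.columns[keep]
    G = dosages.loc[:, keep].to_numpy(dtype=float)

    Q, _ = np.linalg.qr(X)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)
    gg = (G_r * G_r).sum(axis=0)
    beta = G_r.T @ y_r / gg
    dof = n - X.shape[1] - 1
    rss = (y_r * y_r).sum() - beta**2 * gg
    se = np.sqrt(rss / dof / gg)
    p = _pvalue(beta / se, dof, n)

    out = pd.DataFrame(
        {
            "SNP": snps,
            "CHR": 0,
            "BP": 0,
            "EA": "A",
            "NEA": "G",
            "EAF": eaf[keep],
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": n,
        }
    )
    if variants is not None:
        meta = variants.reindex(snps)
        out["CHR"] = meta["chr"].to_numpy()
        out["BP"] = meta["pos"].to_numpy()
        out["EA"] = meta["ea"].to_numpy()
        out["NEA"] = meta["nea"].to_numpy()
    return out.set_index("SNP", drop=False)


def conditional_scan(
    dosages: pd.DataFrame,
    trait,
    covariates=None,
    variants: pd.DataFrame | None = None,
    entry_threshold: float = GENOME_WIDE_ALPHA,
    max_signals: int = 10,
    maf_min: float = 0.01,
) -> list[pd.Series]:
    """Stepwise conditional scan: repeatedly take the most significant SNP,
    add it as a covariate, and rescan, stopping when no SNP passes the entry
    threshold.  Returns the index-SNP records in discovery order.
    """
    signals: list[pd.Series] = []
    index_snps: list[str] = []
    for _ in range(max_signals):
        res = gwas_linear(dosages, trait, covariates, condition_on=index_snps,
                          variants=variants, maf_min=maf_min)
        res = res.drop(index=[s for s in index_snps if s in res.index])
        if res.empty or res["P"].min() >= entry_threshold:
            break
        top = res.loc[res["P"].idxmin()]
        signals.append(top)
        index_snps.append(top["SNP"])
    return signals


def interaction_test(
    snp1: np.ndarray, snp2: np.ndarray, trait, covariates=None
) -> dict[str, float]:
    """SNP x SNP interaction: OLS with both main effects and their product;
    the reported statistic is the product-term coefficient."""
    g1 = np.asarray(snp1, dtype=float)
    g2 = np.asarray(snp2, dtype=float)
    y = np.asarray(trait, dtype=float)
    n = y.size
    inter = g1 * g2
    X, _ = build_design(n, covariates, np.column_stack([g1, g2, inter]),
                        ["snp1", "snp2", "snp1:snp2"])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    beta, se = coef[-1], np.sqrt(cov[-1, -1])
    p = float(_pvalue(np.array(beta / se), dof, n))
    return {"beta": float(beta), "se": float(se), "p": p}


# ---------------------------------------------------------------------------
# Meta-analysis (METAL conventions)
# ---------------------------------------------------------------------------

@dataclass
class StudyRecord:
    beta: float | None = None
    se: float | None = None
    p: float | None = None
    n: float | None = None
    direction: int | None = None   # +1 / -1, required for sample-size method
    scale: str = "irnt"            # trait transformation label


@dataclass
class MetaRecord:
    beta: float | None
    se: float | None
    z: float
    p: float
    method: str
    k: int


def meta_analyze(records: Sequence[StudyRecord], method: str = "fixed-ivw") -> MetaRecord:
    """Fixed-effect inverse-variance-weighted or sample-size-weighted meta.

    IVW: beta = sum(w b)/sum(w), w = se^-2, se = sum(w)^-1/2.  Sample-size:
    z = sum(z_i sqrt(n_i)) / sqrt(sum n_i) with z_i recovered from p_i and
    the direction of effect.  IVW refuses studies whose effect sizes are on
    different trait scales (those must use the sample-size method).
    """
    if len(records) < 2:
        raise ValueError("meta-analysis needs at least two studies")
    if method in ("fixed-ivw", "ivw"):
        scales = {r.scale for r in records}
        if len(scales) > 1:
            raise ValueError(
                f"effect sizes on different scales {sorted(scales)}: IVW is invalid, "
                "use the sample-size-weighted method"
            )
        b = np.array([r.beta for r in records], dtype=float)
        s = np.array([r.se for r in records], dtype=float)
        if np.any(s <= 0):
            raise ValueError("IVW requires positive standard errors")
        w = s**-2
        beta = float((w * b).sum() / w.sum())
        se = float(w.sum() ** -0.5)
        z = beta / se
        return MetaRecord(beta, se, z, float(2 * stats.norm.sf(abs(z))), "fixed-ivw", len(records))
    if method in ("sample-size", "samplesize"):
        zs, ns = [], []
        for r in records:
            if r.n is None or r.n <= 0:
                raise ValueError("sample-size method requires n > 0")
            if r.direction is not None:
                sign = float(np.sign(r.direction))
                z_i = sign * stats.norm.isf(r.p / 2)
            elif r.beta is not None and r.se is not None:
                z_i = r.beta / r.se
            else:
                raise ValueError("need (p, direction) or (beta, se) per study")
            zs.append(z_i)
            ns.append(r.n)
        zs, ns = np.array(zs), np.array(ns)
        z = float((zs * np.sqrt(ns)).sum() / np.sqrt(ns.sum()))
        return MetaRecord(None, None, z, float(2 * stats.norm.sf(abs(z))), "sample-size", len(records))
    raise ValueError(f"unknown meta-analysis method: {method!r}")


# ---------------------------------------------------------------------------
# Multiple-testing thresholds
# ---------------------------------------------------------------------------

def effective_tests(trait_matrix: pd.DataFrame | np.ndarray) -> float:
    """Effective number of independent tests from the trait correlation
    spectrum (Li-Ji): sum over eigenvalues of 1(lambda >= 1) + frac(lambda)."""
    X = np.asarray(trait_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need >= 2 traits and >= 3 samples")
    corr = np.corrcoef(X, rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    lam = np.maximum(lam, 0.0)  # floor tiny negative eigenvalues of rank-deficient corr
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def study_wide_threshold(
    trait_matrix=None, alpha_gw: float = GENOME_WIDE_ALPHA, m_eff: float | None = None
) -> tuple[float, float]:
    """(M_eff, genome-wide alpha / M_eff).  ``m_eff`` overrides estimation so
    printed thresholds are reproducible from a reported effective-test count."""
    if m_eff is None:
        if trait_matrix is None:
            raise ValueError("need a trait matrix or an explicit m_eff")
        m_eff = effective_tests(trait_matrix)
    return float(m_eff), alpha_gw / m_eff


def bonferroni(alpha: float, k: int) -> float:
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / k


# ---------------------------------------------------------------------------
# Replication decisions
# ---------------------------------------------------------------------------

def replication_decision(discovery, replication, k_comparisons: int,
                         alpha: float = 0.05) -> bool:
    """Replicated iff the replication effect has the same (non-zero) sign as
    the discovery effect and replication P < alpha / k_comparisons."""
    b_disc = float(discovery["BETA"] if not np.isscalar(discovery) else discovery)
    b_rep = float(replication["BETA"])
    p_rep = float(replication["P"])
    if b_disc == 0 or b_rep == 0:
        return False
    return bool(np.sign(b_disc) == np.sign(b_rep) and p_rep < bonferroni(alpha, k_comparisons))


# ---------------------------------------------------------------------------
# Observational analyses
# ---------------------------------------------------------------------------

def logistic_assoc(exposure, outcome, covariates=None, standardize: bool = True) -> dict[str, float]:
    """Logistic regression of a binary outcome on an exposure.

    By default the exposure is standardized, so the returned odds ratio is
    per s.d. of exposure (set ``standardize=False`` for a unit-scale OR,
    e.g. with a binary exposure).  95% Wald CI; raises on perfect separation.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    xz = (x - x.mean()) / x.std(ddof=0) if standardize else x
    X, names = build_design(y.size, covariates, xz[None, :].T, ["exposure"])
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(f"logistic fit failed (perfect separation?): {exc}") from exc
    j = names.index("exposure")
    beta, se = fit.params[j], fit.bse[j]
    if not np.isfinite(se) or se > 1e3:
        raise ValueError("perfect separation: exposure coefficient diverged")
    return {
        "or": float(np.exp(beta)),
        "ci_low": float(np.exp(beta - 1.96 * se)),
        "ci_high": float(np.exp(beta + 1.96 * se)),
        "beta": float(beta),
        "se": float(se),
        "p": float(fit.pvalues[j]),
    }


def partial_spearman(x, y, covariates=None) -> tuple[float, float]:
    """Partial Spearman correlation: rank-transform x and y, residualize both
    on the covariates, Pearson-correlate the residuals; t-based two-sided p
    with n - 2 - #covariates degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if np.min(x) == np.max(x) or np.min(y) == np.max(y):
        raise ValueError("constant input to partial_spearman")
    cov, _ = _as_matrix(covariates)
    k = cov.shape[1] if cov.size else 0
    if n <= k + 3:
        raise ValueError("too few samples for the covariate count")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    X, _ = build_design(n, covariates)
    rx_r, ry_r = _residualize(X, rx, ry)
    rho = float(np.corrcoef(rx_r, ry_r)[0, 1])
    dof = n - 2 - k
    t = rho * np.sqrt(dof / max(1e-300, 1 - rho**2))
    return rho, float(2 * stats.t.sf(abs(t), dof))
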