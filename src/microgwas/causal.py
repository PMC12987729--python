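"""Two-sample Mendelian randomization, the BMI->microbiome screen, and
Bayesian colocalization.

MR estimators operate on harmonized per-instrument summary statistics
(exposure beta/se, outcome beta/se).  Instrument selection keeps independent
(r^2 < 0.01), common (MAF > 1%), genome-wide-significant (P < 5e-8) variants.
The inverse-variance-weighted (IVW) estimate is a weighted regression of
outcome on exposure betas through the origin; heterogeneity (Cochran's Q)
switches it to multiplicative random effects.  MR-Egger adds an intercept as
a directional-pleiotropy sensitivity check; the weighted median tolerates up
to 50% invalid instruments.  Colocalization follows the standard
approximate-Bayes-factor framework: per-variant Wakefield ABFs combined into
posterior probabilities over the five sharing hypotheses H0-H4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

GENOME_WIDE_P = 5e-8
INSTRUMENT_R2_MAX = 0.01
INSTRUMENT_MAF_MIN = 0.01

STRAND_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


# ---------------------------------------------------------------------------
# Harmonization and instrument selection
# ---------------------------------------------------------------------------

def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Align outcome effect alleles to the exposure's.

    Both inputs are GWAS-Catalog-style tables indexed by SNP with EA, NEA,
    EAF, BETA, SE, P, N columns.  When the outcome's alleles are swapped the
    outcome beta is negated (and EAF flipped); strand-ambiguous (A/T, C/G)
    SNPs are dropped and counted.  Returns (merged table, n_dropped).
    """
    common = exposure.index.intersection(outcome.index)
    exp = exposure.loc[common]
    out = outcome.loc[common]
    ambiguous = exp.apply(lambda r: frozenset((r["EA"], r["NEA"])) in STRAND_AMBIGUOUS, axis=1)
    same = (out["EA"] == exp["EA"]) & (out["NEA"] == exp["NEA"])
    flipped = (out["EA"] == exp["NEA"]) & (out["NEA"] == exp["EA"])
    usable = (same | flipped) & ~ambiguous
    n_dropped = int(len(common) - usable.sum())
    exp, out = exp[usable], out[usable]
    sign = np.where(same[usable], 1.0, -1.0)
    merged = pd.DataFrame(
        {
            "beta_exp": exp["BETA"],
            "se_exp": exp["SE"],
            "p_exp": exp["P"],
            "eaf": exp["EAF"],
            "n_exp": exp["N"],
            "beta_out": out["BETA"].to_numpy() * sign,
            "se_out": out["SE"].to_numpy(),
            "n_out": out["N"].to_numpy(),
        },
        index=exp.index,
    )
    return merged, n_dropped


@dataclass
class InstrumentSet:
    """Retained instruments plus per-instrument strength diagnostics."""

    table: pd.DataFrame            # beta_exp, se_exp, p_exp, eaf, beta_out, se_out, ...
    r2: np.ndarray = field(default_factory=lambda: np.array([]))
    f_stat: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def k(self) -> int:
        return len(self.table)


def select_instruments(
    stats_table: pd.DataFrame,
    panel: pd.DataFrame | np.ndarray | None = None,
    p_threshold: float = GENOME_WIDE_P,
    maf_min: float = INSTRUMENT_MAF_MIN,
    r2_max: float = INSTRUMENT_R2_MAX,
    trait_variance: float = 1.0,
) -> InstrumentSet:
    """Select MR instruments from (harmonized) exposure summary statistics.

    Filters to MAF > ``maf_min`` and exposure P < ``p_threshold``, then
    greedily prunes by ascending p, dropping any SNP whose squared genotype
    correlation in ``panel`` with an already-retained SNP is >= ``r2_max``.
    Per-instrument R^2 = 2 p (1-p) beta^2 / Var(trait) and
    F = R^2 (n-2) / (1 - R^2).  An empty result is returned (not raised).
    """
    t = stats_table.copy()
    maf = np.minimum(t["eaf"], 1 - t["eaf"])
    t = t[(maf > maf_min) & (t["p_exp"] < p_threshold)]
    t = t.sort_values("p_exp")
    if panel is not None and len(t) > 1:
        G = panel[t.index].to_numpy(dtype=float) if isinstance(panel, pd.DataFrame) else np.asarray(panel, dtype=float)
        corr2 = np.corrcoef(G, rowvar=False) ** 2
        kept: list[int] = []
        for i in range(len(t)):
            if all(corr2[i, j] < r2_max for j in kept):
                kept.append(i)
        t = t.iloc[kept]
    if t.empty:
        return InstrumentSet(t)
    p = t["eaf"].to_numpy()
    r2 = 2 * p * (1 - p) * t["beta_exp"].to_numpy() ** 2 / trait_variance
    n = t["n_exp"].to_numpy(dtype=float)
    f = r2 * (n - 2) / (1 - r2)
    return InstrumentSet(t, r2, f)


# ---------------------------------------------------------------------------
# MR estimators
# ---------------------------------------------------------------------------

@dataclass
class MrResult:
    method: str
    estimate: float
    se: float
    p: float
    k: int
    q: float | None = None
    q_p: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None


def _wald(bx, sx, by, sy) -> tuple[float, float]:
    est = by / bx
    # first-order delta: var = sy^2/bx^2 + by^2 sx^2 / bx^4
    se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    return float(est), float(se)


def _ivw(bx, by, sy) -> tuple[float, float, float]:
    """Weighted regression through the origin; returns (beta, fixed se, Q)."""
    w = sy**-2.0
    beta = float((w * bx * by).sum() / (w * bx * bx).sum())
    se = float(((w * bx * bx).sum()) ** -0.5)
    q = float((w * (by - beta * bx) ** 2).sum())
    return beta, se, q


def mr_estimate(
    instruments: InstrumentSet | pd.DataFrame,
    method: str = "auto",
    seed: int = 0,
    n_boot: int = 1000,
) -> MrResult:
    """Causal effect of exposure on outcome from summary-level instruments.

    ``auto`` uses the Wald ratio for a single instrument and IVW otherwise,
    inflating the IVW standard error multiplicatively (max(1, sqrt(Q/(k-1))))
    when Cochran's Q indicates heterogeneity at p < 0.05.  ``egger`` and
    ``weighted-median`` need k >= 3; the weighted-median se is a fixed-seed
    bootstrap.
    """
    t = instruments.table if isinstance(instruments, InstrumentSet) else instruments
    k = len(t)
    if k == 0:
        raise ValueError("no instruments")
    bx = t["beta_exp"].to_numpy(dtype=float)
    sx = t["se_exp"].to_numpy(dtype=float)
    by = t["beta_out"].to_numpy(dtype=float)
    sy = t["se_out"].to_numpy(dtype=float)

    if method == "auto":
        method = "wald" if k == 1 else "ivw"

    if method == "wald":
        if k != 1:
            raise ValueError("wald ratio requires exactly one instrument")
        est, se = _wald(bx[0], sx[0], by[0], sy[0])
        p = 2 * stats.norm.sf(abs(est / se))
        return MrResult("wald", est, se, float(p), 1)

    if method in ("ivw", "ivw-fixed", "ivw-random"):
        if k < 2:
            if k == 1 and method in ("ivw", "ivw-fixed"):
                # IVW through the origin with one instrument is the Wald ratio
                est, se = _wald(bx[0], sx[0], by[0], sy[0])
                p = 2 * stats.norm.sf(abs(est / se))
                return MrResult("ivw-fixed", est, se, float(p), 1)
            raise ValueError(f"{method} requires >= 2 instruments")
        beta, se_fixed, q = _ivw(bx, by, sy)
        q_p = float(stats.chi2.sf(q, k - 1))
        # "ivw" follows the Q-dependent rule; "-fixed"/"-random" force a mode
        random_effects = method == "ivw-random" or (method == "ivw" and q_p < 0.05)
        label, se = "ivw-fixed", se_fixed
        if random_effects:
            label, se = "ivw-random", se_fixed * max(1.0, np.sqrt(q / (k - 1)))
        p = 2 * stats.norm.sf(abs(beta / se))
        return MrResult(label, beta, float(se), float(p), k, q=q, q_p=q_p)

    if method == "egger":
        if k < 3:
            raise ValueError("egger requires >= 3 instruments")
        # orient so all exposure effects are positive (InSIDE convention)
        sign = np.sign(bx)
        bx_o, by_o = bx * sign, by * sign
        w = sy**-2.0
        X = np.column_stack([np.ones(k), bx_o])
        W = np.diag(w)
        XtWX_inv = np.linalg.inv(X.T @ W @ X)
        coef = XtWX_inv @ X.T @ (w * by_o)
        resid = by_o - X @ coef
        # multiplicative overdispersion, floored at 1
        phi = max(1.0, float((w * resid**2).sum() / (k - 2)))
        cov = XtWX_inv * phi
        slope, slope_se = coef[1], np.sqrt(cov[1, 1])
        ic, ic_se = coef[0], np.sqrt(cov[0, 0])
        p = 2 * stats.t.sf(abs(slope / slope_se), k - 2)
        ip = 2 * stats.t.sf(abs(ic / ic_se), k - 2)
        q = float((w * resid**2).sum())
        return MrResult(
            "egger", float(slope), float(slope_se), float(p), k,
            q=q, q_p=float(stats.chi2.sf(q, k - 2)),
            egger_intercept=float(ic), egger_intercept_se=float(ic_se),
            egger_intercept_p=float(ip),
        )

    if method == "weighted-median":
        if k < 3:
            raise ValueError("weighted-median requires >= 3 instruments")
        est = _weighted_median(by / bx, bx**2 / sy**2)
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bx_b = rng.normal(bx, sx)
            by_b = rng.normal(by, sy)
            boots[b] = _weighted_median(by_b / bx_b, bx_b**2 / sy**2)
        se = float(boots.std(ddof=1))
        p = 2 * stats.norm.sf(abs(est / se))
        return MrResult("weighted-median", float(est), se, float(p), k)

    raise ValueError(f"unknown MR method: {method!r}")


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(0.5, cum, v))


def ivw_screen(bx: np.ndarray, by_matrix: np.ndarray, sy_matrix: np.ndarray) -> pd.DataFrame:
    """IVW estimates for many outcome traits sharing one instrument set.

    ``by_matrix``/``sy_matrix`` are traits x instruments.  Each trait gets the
    same Q-dependent fixed/random-effects rule as :func:`mr_estimate`; this is
    the bulk path used by many-trait screens.
    """
    k = bx.size
    rows = []
    for by, sy in zip(by_matrix, sy_matrix):
        beta, se, q = _ivw(bx, by, sy)
        q_p = float(stats.chi2.sf(q, k - 1))
        if q_p < 0.05:
            se = se * max(1.0, np.sqrt(q / (k - 1)))
        rows.append((beta, se, 2 * stats.norm.sf(abs(beta / se)), q_p))
    return pd.DataFrame(rows, columns=["estimate", "se", "p", "q_p"])


# ---------------------------------------------------------------------------
# Trait screen summary
# ---------------------------------------------------------------------------

@dataclass
class ScreenSummary:
    n_traits: int
    n_nominal: int
    expected: float
    chi2: float
    chi2_p: float
    binom_p: float
    pearson_r: float
    pearson_p: float


def mr_screen_summary(
    obs_betas: np.ndarray, mr_betas: np.ndarray, mr_pvalues: np.ndarray, alpha: float = 0.05
) -> ScreenSummary:
    """Summary of a many-trait MR screen against observational effects.

    Compares the observed count of nominally significant MR p-values with the
    alpha * n expected under the global null via a 1-df chi-square on the
    significant/non-significant split (an exact binomial p is reported
    alongside), and Pearson-correlates observational betas with MR betas.
    """
    obs_betas = np.asarray(obs_betas, dtype=float)
    mr_betas = np.asarray(mr_betas, dtype=float)
    mr_pvalues = np.asarray(mr_pvalues, dtype=float)
    n = obs_betas.size
    if n == 0:
        raise ValueError("empty screen")
    if not (mr_betas.size == n and mr_pvalues.size == n):
        raise ValueError("trait lists differ in length")
    observed = int((mr_pvalues < alpha).sum())
    expected = alpha * n
    chi2 = (observed - expected) ** 2 / expected + ((n - observed) - (n - expected)) ** 2 / (
        n - expected
    )
    chi2_p = float(stats.chi2.sf(chi2, 1))
    binom_p = float(stats.binomtest(observed, n, alpha).pvalue)
    if np.ptp(obs_betas) == 0 or np.ptp(mr_betas) == 0:
        r, r_p = np.nan, np.nan  # correlation undefined for constant betas
    else:
        r, r_p = stats.pearsonr(obs_betas, mr_betas)
    return ScreenSummary(n, observed, float(expected), float(chi2), chi2_p, binom_p,
                         float(r), float(r_p))


# ---------------------------------------------------------------------------
# Colocalization (approximate Bayes factors)
# ---------------------------------------------------------------------------

@dataclass
class ColocResult:
    pp: np.ndarray               # PP0..PP4
    priors: tuple[float, float, float]
    n_variants: int

    def __getitem__(self, h: int) -> float:
        return float(self.pp[h])


def _wakefield_labf(beta: np.ndarray, se: np.ndarray, w: float) -> np.ndarray:
    """log approximate Bayes factor per variant (prior effect variance w)."""
    v = se**2
    z2 = (beta / se) ** 2
    r = w / (v + w)
    return 0.5 * (np.log(1 - r) + r * z2)


def coloc_abf(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    priors: tuple[float, float, float] = (1e-4, 1e-4, 1e-5),
    trait1_type: str = "quant",
    trait2_type: str = "quant",
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    H0 no signal; H1/H2 one trait only; H3 two distinct causal variants; H4 a
    shared causal variant.  Inputs are per-variant summary tables with BETA
    and SE over the *same* variant set; the prior effect s.d. is 0.15 for
    quantitative and 0.2 for binary traits; (p1, p2, p12) are the per-variant
    prior probabilities of association.
    """
    if len(stats1) < 10:
        raise ValueError("region must contain >= 10 variants")
    d1 = set(stats1.index) - set(stats2.index)
    d2 = set(stats2.index) - set(stats1.index)
    if d1 or d2 or len(stats1) != len(stats2):
        raise ValueError(f"variant sets differ: only-in-1={sorted(d1)[:5]}, only-in-2={sorted(d2)[:5]}")
    stats2 = stats2.loc[stats1.index]
    w1 = 0.15**2 if trait1_type == "quant" else 0.2**2
    w2 = 0.15**2 if trait2_type == "quant" else 0.2**2
    l1 = _wakefield_labf(stats1["BETA"].to_numpy(float), stats1["SE"].to_numpy(float), w1)
    l2 = _wakefield_labf(stats2["BETA"].to_numpy(float), stats2["SE"].to_numpy(float), w2)
    p1, p2, p12 = priors

    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # sum over i != j of ABF1_i * ABF2_j, in log space
    both, sgn = logsumexp(
        [s1 + s2, s12], b=[1.0, -1.0], return_sign=True
    )
    h = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            (np.log(p1) + np.log(p2) + both) if sgn > 0 else -np.inf,
            np.log(p12) + s12,
        ]
    )
    pp = np.exp(h - logsumexp(h))
    return ColocResult(pp / pp.sum(), priors, len(stats1))
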