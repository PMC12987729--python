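"""SNP heritability: GRM construction and single-component REML.

The genetic relationship matrix (GRM) uses the standard allele-frequency-
standardized estimator A_jk = (1/m) sum_i (x_ij - 2p_i)(x_ik - 2p_i) /
(2 p_i (1 - p_i)).  Heritability of a (typically IRNT) trait is estimated
under y = X b + g + e with Var(g) = A Vg, Var(e) = I Ve, by average-
information REML with an EM fallback, and cross-checked by Haseman-Elston
regression of trait cross-products on relatedness.

Because the model involves only one GRM, V = Vg A + Ve I diagonalizes in the
eigenbasis of A; all REML quantities are computed there, so each iteration
costs O(n^2) after one O(n^3) eigendecomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class Grm:
    """n x n genetic relationship matrix and bookkeeping."""

    matrix: np.ndarray
    m_snps: int
    sample_ids: list
    n_monomorphic_excluded: int = 0

    def to_triplets(self, path) -> None:
        """Persist as a plain-text (i, j, value) lower-triangle triplet TSV
        plus a sample id list at ``<path>.ids``."""
        n = self.matrix.shape[0]
        i, j = np.tril_indices(n)
        pd.DataFrame({"i": i, "j": j, "value": self.matrix[i, j]}).to_csv(
            path, sep="\t", index=False
        )
        pd.Series(self.sample_ids, name="sample_id").to_csv(f"{path}.ids", sep="\t", index=False)

    @classmethod
    def from_triplets(cls, path, m_snps: int = 0) -> "Grm":
        trip = pd.read_csv(path, sep="\t")
        ids = pd.read_csv(f"{path}.ids", sep="\t")["sample_id"].tolist()
        n = len(ids)
        A = np.zeros((n, n))
        A[trip["i"], trip["j"]] = trip["value"]
        A[trip["j"], trip["i"]] = trip["value"]
        return cls(A, m_snps, ids)


def compute_grm(dosages: pd.DataFrame | np.ndarray) -> Grm:
    """GCTA-style GRM from a samples x SNPs dosage matrix.

    Monomorphic SNPs carry no relatedness information and are excluded
    (counted in the result).  Under HWE the mean diagonal is ~1.
    """
    if isinstance(dosages, pd.DataFrame):
        ids = list(dosages.index)
        X = dosages.to_numpy(dtype=float)
    else:
        X = np.asarray(dosages, dtype=float)
        ids = list(range(X.shape[0]))
    if X.shape[1] < 2:
        raise ValueError("need at least 2 SNPs")
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    X = X[:, poly]
    p = p[poly]
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    m = Z.shape[1]
    A = Z @ Z.T / m
    return Grm(A, m, ids, n_mono)


def prune_related(grm: Grm, threshold: float = 0.05) -> list[int]:
    """Indices of samples to keep after greedily dropping one of any pair
    with relatedness above ``threshold`` (parity with kinship-based QC)."""
    A = grm.matrix
    n = A.shape[0]
    keep = np.ones(n, dtype=bool)
    off = np.abs(A - np.diag(np.diag(A)))
    while True:
        sub = off[np.ix_(keep, keep)]
        if sub.size == 0 or sub.max() <= threshold:
            break
        idx = np.flatnonzero(keep)
        counts = (off[np.ix_(idx, idx)] > threshold).sum(axis=1)
        keep[idx[np.argmax(counts)]] = False
    return np.flatnonzero(keep).tolist()


@dataclass
class H2Result:
    vg: float
    ve: float
    h2: float
    se_vg: float
    se_ve: float
    se_h2: float
    converged: bool
    iterations: int
    loglik: float
    method: str = "ai-reml"

    @property
    def vp(self) -> float:
        return self.vg + self.ve


def _reml_pieces(d: np.ndarray, Xt: np.ndarray, yt: np.ndarray, vg: float, ve: float):
    """REML building blocks in the eigenbasis of A (D = eigenvalues).

    Returns (Py, loglik, trP_fun) where trP_fun(w) = tr(P diag(w)).
    """
    v = vg * d + ve                      # diagonal of V
    vinv = 1.0 / v
    XtVi = Xt * vinv[:, None]            # V^-1 X
    XtViX = Xt.T @ XtVi
    XtViX_inv = np.linalg.inv(XtViX)
    XtViy = XtVi.T @ yt
    beta = XtViX_inv @ XtViy
    Py = vinv * (yt - Xt @ beta)
    # tr(P W) for diagonal W: tr(V^-1 W) - tr((X'V^-1X)^-1 X'V^-1 W V^-1 X)
    def trP(w):
        t1 = float((vinv * w).sum())
        M = XtVi.T @ (XtVi * w[:, None])
        return t1 - float(np.trace(XtViX_inv @ M))
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    loglik = -0.5 * (np.log(v).sum() + logdet_XtViX + float(yt @ Py))
    return Py, loglik, trP


def reml_h2(
    grm: Grm,
    trait,
    covariates=None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> H2Result:
    """Average-information REML for y = Xb + g + e, Var(g) = A Vg.

    Variance components are constrained non-negative (floored at 1e-6 Vp as
    in standard GREML practice); an EM step replaces any AI update that
    leaves the parameter space or fails to increase the likelihood.
    Non-convergence is flagged on the result, not raised.
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    if grm.matrix.shape[0] != n:
        raise ValueError("GRM and trait dimensions differ")
    if covariates is None:
        X = np.ones((n, 1))
    else:
        cov = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        X = np.column_stack([np.ones(n), cov])

    d, U = np.linalg.eigh(grm.matrix)
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    Xt = U.T @ X

    vp = float(np.var(y, ddof=1))
    floor = 1e-6 * vp
    vg, ve = 0.5 * vp, 0.5 * vp
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Py, ll, trP = _reml_pieces(d, Xt, yt, vg, ve)
        # scores: dL/dv_i = -0.5 [tr(P A_i) - y'P A_i P y]; A_g = diag(d), A_e = I
        APy_g = d * Py
        APy_e = Py
        score_g = -0.5 * (trP(d) - float(Py @ APy_g))
        score_e = -0.5 * (trP(np.ones(n)) - float(Py @ APy_e))
        # average information: 0.5 y'P A_i P A_j P y
        v = vg * d + ve
        vinv = 1.0 / v
        XtVi = Xt * vinv[:, None]
        XtViX_inv = np.linalg.inv(Xt.T @ XtVi)

        def apply_P(u):
            return vinv * u - XtVi @ (XtViX_inv @ (XtVi.T @ u))

        PAg = apply_P(APy_g)
        PAe = apply_P(APy_e)
        AI = 0.5 * np.array(
            [
                [float(APy_g @ PAg), float(APy_g @ PAe)],
                [float(APy_e @ PAg), float(APy_e @ PAe)],
            ]
        )
        score = np.array([score_g, score_e])
        step_ok = False
        try:
            delta = np.linalg.solve(AI, score)
            cand = np.array([vg, ve]) + delta
            if np.all(np.isfinite(cand)) and np.all(cand > -0.5 * vp):
                step_ok = True
        except np.linalg.LinAlgError:
            pass
        if not step_ok:
            # EM fallback: v_i' = v_i + v_i^2/n (y'P A_i P y - tr(P A_i))
            cand = np.array(
                [
                    vg + vg**2 / n * (float(Py @ APy_g) - trP(d)),
                    ve + ve**2 / n * (float(Py @ APy_e) - trP(np.ones(n))),
                ]
            )
        vg, ve = np.maximum(cand, floor)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll

    Py, ll, trP = _reml_pieces(d, Xt, yt, vg, ve)
    # SEs from the inverse AI matrix at the optimum
    v = vg * d + ve
    vinv = 1.0 / v
    XtVi = Xt * vinv[:, None]
    XtViX_inv = np.linalg.inv(Xt.T @ XtVi)

    def apply_P(u):
        return vinv * u - XtVi @ (XtViX_inv @ (XtVi.T @ u))

    APy_g, APy_e = d * Py, Py
    PAg, PAe = apply_P(APy_g), apply_P(APy_e)
    AI = 0.5 * np.array(
        [
            [float(APy_g @ PAg), float(APy_g @ PAe)],
            [float(APy_e @ PAg), float(APy_e @ PAe)],
        ]
    )
    try:
        cov_v = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov_v = np.full((2, 2), np.nan)
    vp_hat = vg + ve
    h2 = vg / vp_hat
    # delta method for h2 = vg / (vg + ve)
    grad = np.array([ve, -vg]) / vp_hat**2
    se_h2 = float(np.sqrt(max(grad @ cov_v @ grad, 0.0)))
    return H2Result(
        vg=float(vg),
        ve=float(ve),
        h2=float(np.clip(h2, 0.0, 1.0)),
        se_vg=float(np.sqrt(max(cov_v[0, 0], 0.0))),
        se_ve=float(np.sqrt(max(cov_v[1, 1], 0.0))),
        se_h2=se_h2,
        converged=converged,
        iterations=it,
        loglik=float(ll),
    )


def he_regression(grm: Grm, trait, covariates=None) -> H2Result:
    """Haseman-Elston regression: moment-based h2 as the slope of pairwise
    trait cross-products z_j z_k on off-diagonal relatedness A_jk.

    The trait is residualized on the covariates and standardized first; for
    a standardized trait the regression slope estimates Vg/Vp directly.
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    if covariates is not None:
        cov = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        X = np.column_stack([np.ones(n), cov])
        Q, _ = np.linalg.qr(X)
        y = y - Q @ (Q.T @ y)
    z = (y - y.mean()) / y.std(ddof=0)
    iu = np.triu_indices(n, k=1)
    a = grm.matrix[iu]
    prod = z[iu[0]] * z[iu[1]]
    # simple regression with intercept
    a_c = a - a.mean()
    slope = float(a_c @ (prod - prod.mean()) / (a_c @ a_c))
    resid = prod - prod.mean() - slope * a_c
    se = float(np.sqrt(resid @ resid / (a.size - 2) / (a_c @ a_c)))
    h2 = float(np.clip(slope, 0.0, 1.0))
    return H2Result(
        vg=h2, ve=1.0 - h2, h2=h2, se_vg=se, se_ve=se, se_h2=se,
        converged=True, iterations=0, loglik=np.nan, method="he-regression",
    )
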