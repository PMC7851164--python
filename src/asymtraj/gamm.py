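"""Penalized-spline additive mixed models with REML smoothness selection.

The engine fits Gaussian additive models of the form

    y = X beta + eps,   beta penalized by  sum_i  lambda_i * beta' S_i beta

where each penalty block S_i is either a spline roughness penalty (with a
linear null space) or an identity ridge over grouping-factor dummies — the
latter is exactly a random intercept, with sigma^2_group = sigma^2 / lambda.
Smoothing parameters and variance components are selected by minimizing the
(profiled) restricted maximum likelihood criterion over log smoothing
parameters; sigma^2 is profiled out analytically.

On top of the engine, :class:`FactorSmoothGAMM` implements the
hemisphere-by-age factor-smooth model: a shared (average) smooth of age, a
difference smooth in +/- 1/2 hemisphere coding so that its fitted curve is
directly the LH-RH trajectory, a hemisphere fixed effect, linear covariates,
and a subject random intercept.  A Wald F test on the difference-smooth
coefficients (numerator df = the smooth's effective degrees of freedom)
tests whether the two hemispheres' age trajectories differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .basis import SmoothBasis, build_basis


# ---------------------------------------------------------------------------
# penalized REML engine


@dataclass
class PenaltyBlock:
    """One penalized coefficient block of the design."""

    name: str
    sl: slice
    S: np.ndarray            # penalty on the block (scaled)
    rank: int
    logdet_plus: float       # log pseudo-determinant of scaled S
    is_random: bool = False
    scale: float = 1.0       # scaling applied to the raw penalty


@dataclass
class PenalizedFit:
    beta: np.ndarray
    cov: np.ndarray                      # Bayesian covariance of beta
    sigma2: float
    lambdas: dict[str, float]
    edf: dict[str, float]
    edf1: dict[str, float]
    edf_total: float
    n_obs: int
    reml: float
    reml_trace: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def df_residual(self) -> float:
        return self.n_obs - self.edf_total

    def sigma2_random(self, name: str, blocks_scale: float = 1.0) -> float:
        return self.sigma2 / (self.lambdas[name] * blocks_scale)


def _schur_structure(XtX, blocks):
    """Detect the eliminable random-intercept block.

    When a single random block sits contiguously at the end of the design,
    its penalty is (scaled) identity and its normal-equation block is
    diagonal (each row belongs to one group), the REML criterion can be
    evaluated by eliminating that block analytically — cost then scales
    with the small dense dimension, not the number of subjects.
    """
    rand = [(i, b) for i, b in enumerate(blocks) if b.is_random]
    if len(rand) != 1:
        return None
    ri, rb = rand[0]
    p = XtX.shape[0]
    if rb.sl.stop != p:
        return None
    m = rb.sl.stop - rb.sl.start
    if m < 2:
        return None
    S_off = rb.S - np.diag(np.diag(rb.S))
    if np.abs(S_off).max() > 0:
        return None
    RR = XtX[rb.sl, rb.sl]
    if np.abs(RR - np.diag(np.diag(RR))).max() > 1e-10:
        return None
    d = rb.sl.start
    return {
        "ri": ri,
        "d": d,
        "XtX_DD": XtX[:d, :d].copy(),
        "XtX_DR": XtX[:d, rb.sl].copy(),
        "c": np.diag(RR).copy(),
        "s_r": np.diag(rb.S).copy(),
    }


def _reml_criterion_schur(rho, st_, Xty, yty, n, blocks, Mp):
    lam = np.exp(np.clip(rho, -25.0, 25.0))
    d, ri = st_["d"], st_["ri"]
    A_DD = st_["XtX_DD"].copy()
    for lb, b in zip(lam, blocks):
        if not b.is_random:
            A_DD[b.sl, b.sl] += lb * b.S
    arr = st_["c"] + lam[ri] * st_["s_r"]
    M = st_["XtX_DR"] / arr[None, :]
    S_d = A_DD - M @ st_["XtX_DR"].T
    try:
        L = cho_factor(S_d, lower=True)
    except np.linalg.LinAlgError:
        return np.inf
    Xty_D, Xty_R = Xty[:d], Xty[d:]
    rhs = Xty_D - M @ Xty_R
    beta_D = cho_solve(L, rhs)
    beta_R = (Xty_R - st_["XtX_DR"].T @ beta_D) / arr
    rss_pen = max(yty - beta_D @ Xty_D - beta_R @ Xty_R, 1e-300)
    sigma2 = rss_pen / (n - Mp)
    logdetA = float(np.sum(np.log(arr)) + 2.0 * np.sum(np.log(np.diag(L[0]))))
    rho_c = np.clip(rho, -25, 25)
    logdetS = sum(b.rank * r + b.logdet_plus for r, b in zip(rho_c, blocks))
    reml = 0.5 * (
        (n - Mp) * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdetA - logdetS
    )
    excess = np.maximum(np.abs(np.asarray(rho, float)) - 18.0, 0.0)
    return reml + 0.5 * np.sum(excess ** 2)


def _reml_criterion(rho, XtX, Xty, yty, n, blocks, Mp):
    lam = np.exp(np.clip(rho, -25.0, 25.0))
    A = XtX.copy()
    for lb, b in zip(lam, blocks):
        A[b.sl, b.sl] += lb * b.S
    try:
        L = cho_factor(A, lower=True)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    beta = cho_solve(L, Xty)
    rss_pen = max(yty - beta @ Xty, 1e-300)
    sigma2 = rss_pen / (n - Mp)
    logdetA = 2.0 * np.sum(np.log(np.diag(L[0])))
    logdetS = sum(
        b.rank * r + b.logdet_plus for r, b in zip(np.clip(rho, -25, 25), blocks)
    )
    reml = 0.5 * (
        (n - Mp) * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdetA - logdetS
    )
    # gentle barrier on extreme log smoothing parameters: the criterion is
    # asymptotically flat there (linear/unshrunk limits), which stalls the
    # simplex; the barrier adds curvature without moving interior optima
    excess = np.maximum(np.abs(np.asarray(rho, float)) - 18.0, 0.0)
    reml = reml + 0.5 * np.sum(excess ** 2)
    return reml, beta, sigma2


def fit_penalized(
    X: np.ndarray,
    y: np.ndarray,
    blocks: list[PenaltyBlock],
    rho0: np.ndarray | None = None,
    tol: float = 1e-8,
    maxiter: int = 1500,
) -> PenalizedFit:
    """Fit the penalized model, selecting log smoothing parameters by REML."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    # null-space dimension of the total penalty: unpenalized columns plus
    # each block's nullity
    penalized_cols = sum(b.sl.stop - b.sl.start for b in blocks)
    Mp = (p - penalized_cols) + sum((b.sl.stop - b.sl.start) - b.rank for b in blocks)

    trace: list[float] = []
    schur = _schur_structure(XtX, blocks)

    def obj(rho):
        if schur is not None:
            val = _reml_criterion_schur(rho, schur, Xty, yty, n, blocks, Mp)
        else:
            val = _reml_criterion(rho, XtX, Xty, yty, n, blocks, Mp)[0]
        if not trace or val < trace[-1]:
            trace.append(val)  # accepted (improving) evaluations
        return val

    if rho0 is None:
        rho0 = np.zeros(len(blocks))
    res = optimize.minimize(
        obj, rho0, method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": tol * max(1.0, abs(obj(rho0))),
                 "maxiter": maxiter, "maxfev": maxiter},
    )
    converged = bool(res.success)
    if not converged:
        # coarse multi-start fallback, then a fresh-simplex polish
        best = res
        for start in ([-5.0] * len(blocks), [5.0] * len(blocks)):
            alt = optimize.minimize(
                obj, np.array(start), method="Nelder-Mead",
                options={"xatol": 1e-5, "maxiter": maxiter},
            )
            if alt.fun < best.fun:
                best = alt
        res = optimize.minimize(
            obj, best.x, method="Nelder-Mead",
            options={"xatol": 1e-5, "maxiter": maxiter},
        )
        if best.fun < res.fun:
            res = best
        converged = bool(res.success)

    rho = np.clip(res.x, -25.0, 25.0)
    lam = np.exp(rho)
    A = XtX.copy()
    for lb, b in zip(lam, blocks):
        A[b.sl, b.sl] += lb * b.S
    L = cho_factor(A, lower=True)
    beta = cho_solve(L, Xty)
    rss_pen = max(yty - beta @ Xty, 1e-300)
    sigma2 = rss_pen / (n - Mp)
    Ainv = cho_solve(L, np.eye(p))
    Fmat = Ainv @ XtX
    Fdiag = np.diag(Fmat)
    # alternative EDF 2*tr(F) - tr(F F), the appropriate rank for Wald tests
    F2diag = np.einsum("ij,ji->i", Fmat, Fmat)
    edf: dict[str, float] = {}
    edf1: dict[str, float] = {}
    for b in blocks:
        edf[b.name] = float(Fdiag[b.sl].sum())
        edf1[b.name] = float(2.0 * Fdiag[b.sl].sum() - F2diag[b.sl].sum())
    edf_total = float(Fdiag.sum())
    lambdas = {b.name: float(lb) for lb, b in zip(lam, blocks)}
    return PenalizedFit(
        beta=beta,
        cov=Ainv * sigma2,
        sigma2=float(sigma2),
        lambdas=lambdas,
        edf=edf,
        edf1=edf1,
        edf_total=edf_total,
        n_obs=n,
        reml=float(res.fun),
        reml_trace=trace,
        converged=converged,
    )


def scale_penalty(S: np.ndarray, XtX_block: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale a raw penalty to the magnitude of its design block (conditioning)."""
    s_norm = np.abs(S).sum()
    x_norm = np.abs(XtX_block).sum()
    scale = x_norm / s_norm if s_norm > 0 else 1.0
    return S * scale, scale


def _penalty_rank_logdet(S: np.ndarray) -> tuple[int, float]:
    ev = np.linalg.eigvalsh((S + S.T) / 2.0)
    thresh = max(ev.max(), 1.0) * 1e-10
    pos = ev[ev > thresh]
    return len(pos), float(np.sum(np.log(pos)))


# ---------------------------------------------------------------------------
# Wald tests


@dataclass
class DifferenceTest:
    """Wald-type F test that the two hemispheres' age smooths differ."""

    statistic: float
    df_num: float
    df_den: float
    pvalue: float


def _liu_tail(x: float, weights: np.ndarray) -> float:
    """P(sum_i w_i * chi2_1 > x) by moment-matching to a noncentral chi2."""
    lam = np.asarray(weights, float)
    muQ = lam.sum()
    s_lh2 = np.sum(lam ** 2)
    if s_lh2 <= 0:
        return 1.0
    s1 = np.sum(lam ** 3) / s_lh2 ** 1.5
    s2 = np.sum(lam ** 4) / s_lh2 ** 2
    sigQ = np.sqrt(2.0 * s_lh2)
    t = (x - muQ) / sigQ
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        dof = a ** 2 - 2.0 * delta
    else:
        a = 1.0 / s1
        delta = 0.0
        dof = 1.0 / s1 ** 2
    muX = dof + delta
    sigX = np.sqrt(2.0) * a
    return float(stats.ncx2.sf(t * sigX + muX, dof, delta))


def _mixture_f_tail(x: float, weights: np.ndarray, res_df: float,
                    nq: int = 50) -> float:
    """Tail of T = (sum_i w_i chi2_1) / (chi2_d / d) by quadrature over
    the denominator chi-square."""
    probs = (np.arange(1, nq + 1) - 0.5) / nq
    q = stats.chi2.ppf(probs, res_df)
    vals = [_liu_tail(x * qq / res_df, weights) for qq in q]
    return float(np.mean(vals))


def wald_smooth_test(
    beta_block: np.ndarray,
    cov_block: np.ndarray,
    edf: float,
    df_den: float,
    X_block: np.ndarray | None = None,
) -> DifferenceTest:
    """Wald test of H0: a penalized smooth is identically zero.

    The statistic is a rank-truncated quadratic form in the smooth's fitted
    values (or raw coefficients when ``X_block`` is None), with the
    truncation rank tied to the smooth's effective degrees of freedom; the
    fractional part of the EDF is absorbed by a 2x2 correction of the last
    retained eigen-direction, and the reference distribution is the matching
    chi-square mixture scaled by the residual chi-square.  The sign
    ambiguity of the fractional correction is resolved by averaging the two
    p-values.
    """
    q = len(beta_block)
    edf = float(np.clip(edf, 1.0, q))
    if X_block is not None:
        R = np.linalg.qr(X_block, mode="r")
        V = R @ cov_block @ R.T
        bvec = R @ beta_block
    else:
        V = cov_block.copy()
        bvec = beta_block.copy()
    V = (V + V.T) / 2.0
    ev, vecs = np.linalg.eigh(V)
    order = np.argsort(ev)[::-1]
    ev, vecs = ev[order], vecs[:, order]
    if ev[0] <= 0:
        warnings.warn("singular covariance block; returning F=0")
        return DifferenceTest(0.0, edf, df_den, 1.0)

    k = max(0, int(np.floor(edf)))
    nu = abs(edf - k)
    k1 = k + 1 if nu > 0 else k
    r_est = int(np.sum(ev > ev.max() * np.finfo(float).eps ** 0.9))
    if r_est < k1:
        k1 = k = r_est
        nu = 0.0
        edf = float(r_est)
        warnings.warn("covariance block numerically singular; rank reduced")
    vec = vecs[:, :k1].copy()
    if nu > 0 and k > 0:
        if k > 1:
            vec[:, : k - 1] /= np.sqrt(ev[: k - 1])
        b12 = max(0.5 * nu * (1.0 - nu), 0.0) ** 0.5
        B = np.array([[1.0, b12], [b12, nu]])
        evh = np.diag(ev[k - 1: k1] ** -0.5)
        B = evh @ B @ evh
        ebv, ebw = np.linalg.eigh(B)
        rB = ebw @ np.diag(np.sqrt(np.maximum(ebv, 0.0))) @ ebw.T
        vec1 = vec.copy()
        vec1[:, k - 1: k1] = (rB @ np.diag([-1.0, 1.0]) @ vec[:, k - 1: k1].T).T
        vec[:, k - 1: k1] = (rB @ vec[:, k - 1: k1].T).T
    else:
        vec = vec / np.sqrt(ev[:k1]) if k1 > 0 else vec
        vec1 = vec
    d0 = float(np.sum((vec.T @ bvec) ** 2))
    d1 = float(np.sum((vec1.T @ bvec) ** 2))

    if nu > 0:
        if k1 == 1:
            weights = np.array([1.0])
        else:
            weights = np.ones(k1)
            rp = nu + 1.0
            weights[k - 1] = (rp + np.sqrt(max(rp * (2.0 - rp), 0.0))) / 2.0
            weights[k1 - 1] = rp - weights[k - 1]
        if df_den > 0:
            p = 0.5 * (_mixture_f_tail(d0, weights, df_den)
                       + _mixture_f_tail(d1, weights, df_den))
        else:
            p = 0.5 * (_liu_tail(d0, weights) + _liu_tail(d1, weights))
    else:
        rank1 = max(k1, 1)
        if df_den > 0:
            p = 0.5 * (stats.f.sf(d0 / rank1, rank1, df_den)
                       + stats.f.sf(d1 / rank1, rank1, df_den))
        else:
            p = 0.5 * (stats.chi2.sf(d0, rank1) + stats.chi2.sf(d1, rank1))
    stat = 0.5 * (d0 + d1) / edf
    return DifferenceTest(
        float(stat), edf, float(df_den),
        float(np.clip(p, np.finfo(float).tiny, 1.0)),
    )


# ---------------------------------------------------------------------------
# factor-smooth GAMM estimator


@dataclass
class FactorSmoothDesign:
    """Assembled factor-smooth design, reusable across responses.

    The design matrix and penalty blocks depend only on ages, hemisphere
    labels, covariates and subjects — not on thickness — so a vertex-wise
    analysis assembles this once and refits per-vertex responses against it.
    """

    Xfull: np.ndarray
    XtX: np.ndarray
    blocks: list[PenaltyBlock]
    slices: dict[str, slice]
    basis: SmoothBasis
    hemi: np.ndarray
    Xdiff: np.ndarray
    cov_names: list[str]
    subject_levels: np.ndarray
    age_range: tuple[float, float]


def build_factor_smooth_design(
    X: pd.DataFrame, k: int = 6, covariates: list[str] | None = None
) -> FactorSmoothDesign:
    X = X.reset_index(drop=True)
    ages = X["age"].to_numpy(dtype=float)
    h = _hemi_code(X["hemisphere"])
    subjects = X["subject"].to_numpy()
    n_subj = len(pd.unique(subjects))
    if n_subj < 20:
        warnings.warn(f"only {n_subj} subjects; fit may be unstable")
    n = len(X)
    basis = build_basis(ages, k)
    B = basis.evaluate(ages)
    q = B.shape[1]
    cov_design, cov_names = _covariate_design(X, covariates)
    fixed = [np.ones((n, 1)), h[:, None]]
    if cov_design.shape[1]:
        fixed.append(cov_design)
    Xf = np.hstack(fixed)
    n_fixed = Xf.shape[1]
    subj_codes, subject_levels = pd.factorize(subjects)
    Z = np.zeros((n, len(subject_levels)))
    Z[np.arange(n), subj_codes] = 1.0
    Xdiff = h[:, None] * B
    Xfull = np.hstack([Xf, B, Xdiff, Z])
    sl_avg = slice(n_fixed, n_fixed + q)
    sl_diff = slice(n_fixed + q, n_fixed + 2 * q)
    sl_subj = slice(n_fixed + 2 * q, n_fixed + 2 * q + Z.shape[1])
    XtX = Xfull.T @ Xfull
    blocks = []
    for name, sl, S_raw, is_rand in (
        ("avg", sl_avg, basis.penalty, False),
        ("diff", sl_diff, basis.penalty, False),
        ("subject", sl_subj, np.eye(Z.shape[1]), True),
    ):
        S, scale = scale_penalty(S_raw, XtX[sl, sl])
        rank, ld = _penalty_rank_logdet(S)
        blocks.append(PenaltyBlock(name, sl, S, rank, ld, is_rand, scale))
    return FactorSmoothDesign(
        Xfull=Xfull, XtX=XtX, blocks=blocks,
        slices={"fixed": slice(0, n_fixed), "avg": sl_avg,
                "diff": sl_diff, "subject": sl_subj},
        basis=basis, hemi=h, Xdiff=Xdiff, cov_names=cov_names,
        subject_levels=subject_levels,
        age_range=(float(ages.min()), float(ages.max())),
    )


@dataclass
class TrajectoryEstimate:
    """Hemispheric age trajectories and their difference on an age grid."""

    ages: np.ndarray
    f_left: np.ndarray
    f_right: np.ndarray
    asymmetry: np.ndarray      # f_left - f_right (demeaned scale)
    se_left: np.ndarray
    se_right: np.ndarray
    se_asymmetry: np.ndarray
    intercept_added: bool = False


class FactorSmoothGAMM:
    """Hemisphere-specific smooth age-trajectory model of cortical thickness.

    Model (one LH and one RH row per scan):

        thickness = b0 + bH*h + covariates + f_avg(age) + h*f_diff(age)
                    + subject intercept + noise,   h = +1/2 (LH), -1/2 (RH)

    so ``f_diff`` is directly the LH-RH trajectory and ``bH`` the mean LH-RH
    difference.  Both smooths are centered cubic regression splines with
    basis dimension ``k`` (default 6, i.e. 5 identifiable coefficients each);
    smoothing parameters and the subject-intercept variance are estimated by
    REML.  Follows the scikit-learn estimator protocol.

    Parameters
    ----------
    k : int
        Spline basis dimension per smooth.
    covariates : list of str or None
        Columns of the design frame entered as fixed linear/categorical
        covariates (e.g. sex, scanner).
    """

    def __init__(self, k: int = 6, covariates: list[str] | None = None,
                 tol: float = 1e-8):
        self.k = k
        self.covariates = covariates
        self.tol = tol

    # -- sklearn protocol -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k, "covariates": self.covariates, "tol": self.tol}

    def set_params(self, **params) -> "FactorSmoothGAMM":
        for key, val in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, val)
        return self

    # -- fitting -----------------------------------------------------------
    def fit(self, X: pd.DataFrame, y: np.ndarray,
            rho0: np.ndarray | None = None) -> "FactorSmoothGAMM":
        """Fit to a long design frame.

        ``X`` must contain columns ``age``, ``hemisphere`` (values 'L'/'R'
        or +-1/2) and ``subject``, plus any configured covariate columns;
        ``y`` is thickness in mm, one value per row.
        """
        y = np.asarray(y, float)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite response values")
        design = build_factor_smooth_design(X, self.k, self.covariates)
        self.basis_ = design.basis
        self.cov_names_ = design.cov_names
        self.subject_levels_ = design.subject_levels
        fit = fit_penalized(design.Xfull, y, design.blocks, rho0=rho0,
                            tol=self.tol)
        self.fit_ = fit
        self.blocks_ = design.blocks
        self.slices_ = design.slices
        self._Xdiff_ = design.Xdiff
        self._moments_ = (design.XtX, design.Xfull.T @ y, float(y @ y), len(y))
        if hasattr(self, "_free_diff_fit_"):
            del self._free_diff_fit_
        self.coef_ = fit.beta
        self.intercept_ = float(fit.beta[0])
        self.hemisphere_effect_ = float(fit.beta[1])
        self.hemisphere_se_ = float(np.sqrt(fit.cov[1, 1]))
        self.sigma2_residual_ = fit.sigma2
        subj_block = next(b for b in self.blocks_ if b.name == "subject")
        self.sigma2_subject_ = fit.sigma2 / (fit.lambdas["subject"] * subj_block.scale)
        self.edf_ = dict(fit.edf)
        self.edf_total_ = fit.edf_total
        self.lambda_ = dict(fit.lambdas)
        self.converged_ = fit.converged
        self.n_obs_ = len(y)
        self.age_range_ = design.age_range
        self.rho_ = np.log(np.array([fit.lambdas[b.name] for b in self.blocks_]))
        return self

    # -- inference ---------------------------------------------------------
    def difference_test(self, method: str = "unpenalized") -> DifferenceTest:
        """F test of the age-by-hemisphere smooth interaction.

        ``method="unpenalized"`` (default) refits the difference-smooth
        block without its roughness penalty and applies the classical Wald
        F test on the full block.  Because every scan contributes one LH and
        one RH row, the difference block is exactly orthogonal to all
        hemisphere-symmetric terms (average smooth, subject intercepts,
        covariates), so the test reduces to a classical regression F test
        and its null p-values are exactly uniform — no dependence on the
        data-driven smoothing parameter.  ``method="penalized"`` gives the
        EDF-based Wald test on the penalized fit (rank-truncated
        pseudo-inverse with fractional-EDF correction); its p-values are
        tail-calibrated but mildly non-uniform mid-range because the
        truncation rank is selected from the data.
        """
        self._check_fitted()
        sl = self.slices_["diff"]
        if method == "penalized":
            return wald_smooth_test(
                self.coef_[sl], self.fit_.cov[sl, sl],
                self.fit_.edf1["diff"], self.fit_.df_residual,
                X_block=self._Xdiff_,
            )
        if method != "unpenalized":
            raise ValueError(f"unknown method {method!r}")
        refit = self._refit_free_diff()
        q = sl.stop - sl.start
        beta_d = refit.beta[sl]
        V_d = refit.cov[sl, sl]
        df_den = max(refit.df_residual, 1.0)
        # degenerate exact-fit limit (e.g. perfectly symmetric noiseless
        # data): no difference signal and no residual scale
        if float(beta_d @ beta_d) <= 1e-22 * max(float(refit.beta @ refit.beta), 1.0):
            return DifferenceTest(0.0, float(q), df_den, 1.0)
        try:
            T = float(beta_d @ np.linalg.solve(V_d, beta_d))
        except np.linalg.LinAlgError:
            warnings.warn("singular covariance block; using pseudo-inverse")
            T = float(beta_d @ np.linalg.pinv(V_d) @ beta_d)
        F = T / q
        p = float(stats.f.sf(F, q, df_den))
        return DifferenceTest(F, float(q), df_den, max(p, np.finfo(float).tiny))

    def _refit_free_diff(self) -> PenalizedFit:
        """Refit with the difference smooth unpenalized, other smoothing
        parameters held at their REML estimates."""
        if not hasattr(self, "_free_diff_fit_"):
            XtX, Xty, yty, n = self._moments_
            p = XtX.shape[0]
            A = XtX.copy()
            for b in self.blocks_:
                if b.name != "diff":
                    A[b.sl, b.sl] += self.fit_.lambdas[b.name] * b.S
            L = cho_factor(A, lower=True)
            beta = cho_solve(L, Xty)
            Ainv = cho_solve(L, np.eye(p))
            edf_total = float(np.einsum("ij,ji->i", Ainv, XtX).sum())
            # null-space dim of the reduced penalty set
            Mp = p - sum(
                b.rank for b in self.blocks_ if b.name != "diff"
            )
            rss_pen = max(yty - beta @ Xty, 1e-300)
            sigma2 = rss_pen / max(n - Mp, 1.0)
            self._free_diff_fit_ = PenalizedFit(
                beta=beta, cov=Ainv * sigma2, sigma2=float(sigma2),
                lambdas={**self.fit_.lambdas, "diff": 0.0},
                edf=dict(self.fit_.edf), edf1=dict(self.fit_.edf1),
                edf_total=edf_total, n_obs=n, reml=np.nan,
            )
        return self._free_diff_fit_

    def hemisphere_test(self) -> tuple[float, float]:
        """Two-sided t test of the hemisphere main effect (mean LH-RH)."""
        self._check_fitted()
        t = self.hemisphere_effect_ / self.hemisphere_se_
        p = 2.0 * stats.t.sf(abs(t), max(self.fit_.df_residual, 1.0))
        return float(t), float(max(p, np.finfo(float).tiny))

    def trajectories(self, grid: np.ndarray,
                     include_intercept: bool = False) -> TrajectoryEstimate:
        """Evaluate demeaned hemispheric trajectories on an age grid.

        With ``include_intercept`` the hemisphere main effect (mean LH-RH,
        mm) is added to the asymmetry curve, giving absolute asymmetry.
        """
        self._check_fitted()
        grid = np.asarray(grid, float)
        if grid.size == 0:
            raise ValueError("empty age grid")
        lo, hi = self.age_range_
        if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
            warnings.warn("age grid extrapolates beyond observed range")
        B = self.basis_.evaluate(grid)
        sa, sd = self.slices_["avg"], self.slices_["diff"]
        b_avg, b_diff = self.coef_[sa], self.coef_[sd]
        f_avg = B @ b_avg
        f_diff = B @ b_diff
        f_left = f_avg + 0.5 * f_diff
        f_right = f_avg - 0.5 * f_diff
        V = self.fit_.cov
        Vaa, Vdd, Vad = V[sa, sa], V[sd, sd], V[sa, sd]
        var_avg = np.einsum("ij,jk,ik->i", B, Vaa, B)
        var_diff = np.einsum("ij,jk,ik->i", B, Vdd, B)
        cov_ad = np.einsum("ij,jk,ik->i", B, Vad, B)
        se_d = np.sqrt(np.maximum(var_diff, 0.0))
        se_l = np.sqrt(np.maximum(var_avg + 0.25 * var_diff + cov_ad, 0.0))
        se_r = np.sqrt(np.maximum(var_avg + 0.25 * var_diff - cov_ad, 0.0))
        d = f_diff.copy()
        if include_intercept:
            d = d + self.hemisphere_effect_
        return TrajectoryEstimate(
            ages=grid, f_left=f_left, f_right=f_right, asymmetry=d,
            se_left=se_l, se_right=se_r, se_asymmetry=se_d,
            intercept_added=include_intercept,
        )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Population-level prediction (fixed + smooth terms, no subject BLUP)."""
        self._check_fitted()
        ages = X["age"].to_numpy(dtype=float)
        h = _hemi_code(X["hemisphere"])
        B = self.basis_.evaluate(ages)
        cov_design, _ = _covariate_design(X, self.covariates, self.cov_names_)
        fixed = [np.ones((len(ages), 1)), h[:, None]]
        if cov_design.shape[1]:
            fixed.append(cov_design)
        Xf = np.hstack(fixed)
        sl_f, sa, sd = self.slices_["fixed"], self.slices_["avg"], self.slices_["diff"]
        return (Xf @ self.coef_[sl_f] + B @ self.coef_[sa]
                + h * (B @ self.coef_[sd]))

    def residuals(self, X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
        """Residuals including the subject-intercept BLUPs."""
        self._check_fitted()
        pred = self.predict(X)
        codes = pd.Series(X["subject"].to_numpy()).map(
            {s: i for i, s in enumerate(self.subject_levels_)}
        )
        blup = self.coef_[self.slices_["subject"]]
        known = codes.notna().to_numpy()
        adj = np.zeros(len(pred))
        adj[known] = blup[codes[known].astype(int).to_numpy()]
        return np.asarray(y, float) - pred - adj

    def summary(self) -> dict:
        """JSON-serializable fit summary."""
        self._check_fitted()
        test = self.difference_test()
        t_h, p_h = self.hemisphere_test()
        return {
            "intercept": self.intercept_,
            "hemisphere_effect": self.hemisphere_effect_,
            "hemisphere_se": self.hemisphere_se_,
            "hemisphere_t": t_h,
            "hemisphere_p": p_h,
            "sigma2_residual": self.sigma2_residual_,
            "sigma2_subject": self.sigma2_subject_,
            "edf": self.edf_,
            "edf_total": self.edf_total_,
            "lambda": self.lambda_,
            "difference_F": test.statistic,
            "difference_df": [test.df_num, test.df_den],
            "difference_p": test.pvalue,
            "n_obs": self.n_obs_,
            "converged": self.converged_,
        }

    def _check_fitted(self) -> None:
        if not hasattr(self, "fit_"):
            raise RuntimeError("model is not fitted")


def _hemi_code(col: pd.Series) -> np.ndarray:
    vals = col.to_numpy()
    if vals.dtype.kind in "UOS":
        mapping = {"L": 0.5, "LH": 0.5, "R": -0.5, "RH": -0.5}
        try:
            return np.array([mapping[str(v).upper()] for v in vals])
        except KeyError as e:
            raise ValueError(f"unknown hemisphere label {e}") from None
    out = np.asarray(vals, float)
    if set(np.unique(out)) <= {-1.0, 1.0}:
        out = out / 2.0
    if not set(np.unique(out)) <= {-0.5, 0.5}:
        raise ValueError("hemisphere must code two levels (+-1/2)")
    return out


def _covariate_design(
    X: pd.DataFrame, covariates: list[str] | None,
    expect_names: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    if not covariates:
        return np.zeros((len(X), 0)), []
    parts, names = [], []
    for c in covariates:
        col = X[c]
        if col.dtype.kind in "UOSb" or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, prefix=c, drop_first=True)
            parts.append(dummies.to_numpy(dtype=float))
            names.extend(dummies.columns.tolist())
        else:
            parts.append(col.to_numpy(dtype=float)[:, None])
            names.append(c)
    design = np.hstack(parts) if parts else np.zeros((len(X), 0))
    if expect_names is not None and names != expect_names:
        # align prediction-time dummies with the training layout
        full = pd.DataFrame(design, columns=names)
        design = np.column_stack(
            [full[n].to_numpy() if n in full else np.zeros(len(X))
             for n in expect_names]
        )
        names = list(expect_names)
    # drop rank-deficient columns
    if design.shape[1] and expect_names is None:
        keep, seen = [], []
        for j in range(design.shape[1]):
            trial = design[:, keep + [j]]
            if np.linalg.matrix_rank(
                np.column_stack([np.ones(len(design)), trial])
            ) == len(keep) + 2:
                keep.append(j)
            else:
                seen.append(names[j])
        if seen:
            warnings.warn(f"dropping rank-deficient covariate columns: {seen}")
            design = design[:, keep]
            names = [names[j] for j in keep]
    return design, names


# ---------------------------------------------------------------------------
# thin functional wrappers (spec module surface)


def fit_factor_smooth(
    y, ages, hemispheres, subjects, covariates: pd.DataFrame | None = None,
    k: int = 6,
) -> FactorSmoothGAMM:
    """Fit the factor-smooth model from plain arrays."""
    X = pd.DataFrame({"age": ages, "hemisphere": hemispheres, "subject": subjects})
    cov_names = None
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        for c in covariates.columns:
            X[c] = covariates[c].to_numpy()
        cov_names = list(covariates.columns)
    return FactorSmoothGAMM(k=k, covariates=cov_names).fit(X, y)


def test_smooth_difference(model: FactorSmoothGAMM) -> DifferenceTest:
    return model.difference_test()


def predict_trajectories(model: FactorSmoothGAMM, grid,
                         include_intercept: bool = False) -> TrajectoryEstimate:
    return model.trajectories(np.asarray(grid, float), include_intercept)


# ---------------------------------------------------------------------------
# random-intercept LME (Wald inference) for the clinical models


@dataclass
class LMEFit:
    """Random-intercept linear mixed model fit (REML, Wald inference)."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    sigma2_subject: float
    sigma2_residual: float
    converged: bool
    n_obs: int


def fit_lme(
    response: np.ndarray,
    design: pd.DataFrame,
    subjects: np.ndarray,
) -> LMEFit:
    """Random-intercept LME via REML with Wald z tests on fixed effects.

    ``design`` holds the fixed-effect columns (an intercept is added if no
    constant column is present).  If the subject variance collapses to zero
    the model is refit as OLS with a warning.
    """
    import statsmodels.api as sm

    y = np.asarray(response, float)
    Xd = design.reset_index(drop=True).astype(float)
    if not (Xd.nunique() == 1).any():
        Xd.insert(0, "Intercept", 1.0)
    groups = pd.Series(subjects).reset_index(drop=True)
    counts = groups.value_counts()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 subjects with >= 2 observations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, Xd, groups=groups)
        try:
            res = model.fit(reml=True, method=["lbfgs", "powell"])
            singular = res.cov_re.iloc[0, 0] < 1e-10
        except Exception:
            res, singular = None, True
    if res is None or singular:
        warnings.warn(
            "singular random-intercept variance; falling back to OLS with "
            "cluster-robust standard errors"
        )
        ols = sm.OLS(y, Xd).fit(cov_type="cluster", cov_kwds={"groups": groups})
        return LMEFit(
            params=ols.params, bse=ols.bse,
            pvalues=ols.pvalues.clip(lower=np.finfo(float).tiny),
            cov=pd.DataFrame(ols.cov_params(), index=Xd.columns, columns=Xd.columns),
            sigma2_subject=0.0, sigma2_residual=float(ols.mse_resid),
            converged=True, n_obs=len(y),
        )
    k_fe = Xd.shape[1]
    return LMEFit(
        params=res.params.iloc[:k_fe],
        bse=res.bse.iloc[:k_fe],
        pvalues=res.pvalues.iloc[:k_fe].clip(lower=np.finfo(float).tiny),
        cov=pd.DataFrame(np.asarray(res.cov_params())[:k_fe, :k_fe],
                         index=Xd.columns, columns=Xd.columns),
        sigma2_subject=float(res.cov_re.iloc[0, 0]),
        sigma2_residual=float(res.scale),
        converged=bool(res.converged),
        n_obs=len(y),
    )
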