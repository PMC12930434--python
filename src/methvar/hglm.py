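"""Per-region Gaussian hierarchical GLM with joint mean-variance estimation.

Model, for CpG ``j`` of sample ``i`` within one region::

    y_ij | b_i  ~  N(mu_ij, sigma2_ij)
    mu_ij        =  x_i' beta + delta * G_i + b_i          (identity link)
    log sigma2_ij =  x_i' gamma + kappa * G_i               (log link)
    b_i          ~  N(0, sigma_b2)

``G`` is the phenotype (binary, continuous or discrete), ``x_i`` the shared
covariate vector (intercept first). ``delta`` carries the differential-
methylation (mean) effect, ``kappa`` the variable-methylation (log-variance)
effect, and the subject random intercept ``b_i`` absorbs the correlation of
CpGs measured on the same individual.

Estimation maximizes the hierarchical likelihood

    h = sum_ij [ -log(2 pi sigma2_ij)/2 - (y_ij - mu_ij)^2 / (2 sigma2_ij) ]
      + sum_i  [ -log(2 pi sigma_b2)/2 - b_i^2 / (2 sigma_b2) ]

by alternating (a) a weighted mixed-model solve for (beta, delta, b) with
per-observation precisions 1/sigma2_ij, (b) a gamma-type log-link GLM for
(gamma, kappa) whose response is the squared (optionally leverage-corrected)
residual, and (c) a REML-type adjusted-profile update of sigma_b2, until the
parameters stabilize.

The same machinery is exposed both as module functions (``fit_region`` and
friends) and as the scikit-learn estimator :class:`MeanVarianceHGLM`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import DegenerateRegionError, NonEstimableRegionError, ValidationError

__all__ = [
    "FitConfig", "RegionDesign", "RegionFit", "MeanVarianceHGLM",
    "build_region_design", "solve_mean_model", "solve_variance_model",
    "update_sigma_b2", "fit_region", "h_likelihood",
]

#: sigma_b2 below this is treated as exactly zero (random intercept off).
_SIGMA_B2_ZERO = 1e-12
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class FitConfig:
    """Tuning knobs for the alternating h-likelihood fit.

    tol / abs_tol
        Outer convergence: every parameter must move by less than
        ``tol * |old| + abs_tol`` between consecutive outer iterations.
    max_iter / inner_max_iter
        Outer alternation cap and inner variance-GLM scoring cap.
    leverage_correction
        Use d = e^2/(1-q) with prior weight (1-q)/2 for the variance GLM
        (REML-type debiasing); with the flag off the response is e^2 with
        weight 1/2, which makes the alternation a coordinate ascent of the
        joint likelihood (useful against brute-force ML oracles).
    eta_clamp
        The log-variance linear predictor is clipped to [-eta_clamp,
        eta_clamp] to keep the working weights finite.
    pin_sigma_b2
        If not None, hold the random-intercept variance at this value
        instead of updating it.
    on_nonconverged
        "report" keeps the last iterate (flagged converged=False);
        "na" replaces estimates with NaN.
    """

    tol: float = 1e-6
    abs_tol: float = 1e-8
    max_iter: int = 100
    inner_max_iter: int = 50
    inner_tol: float = 1e-10
    leverage_correction: bool = True
    eta_clamp: float = 30.0
    pin_sigma_b2: float | None = None
    on_nonconverged: str = "report"
    track_history: bool = False


@dataclass
class RegionDesign:
    """Stacked per-observation design for one region.

    Observations are ordered sample-major, CpG-minor: observation
    ``i * n_cpgs + j`` is CpG ``j`` of sample ``i``. ``X_mean`` and ``X_var``
    share the layout [intercept, covariates..., phenotype]; the phenotype is
    always the last column.
    """

    y: np.ndarray
    X_mean: np.ndarray
    X_var: np.ndarray
    subject: np.ndarray
    n_subjects: int
    region_id: str = ""
    cpg_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.X_mean = np.asarray(self.X_mean, dtype=float)
        self.X_var = np.asarray(self.X_var, dtype=float)
        self.subject = np.asarray(self.subject, dtype=np.intp)
        n = self.y.shape[0]
        if self.X_mean.shape[0] != n or self.X_var.shape[0] != n \
                or self.subject.shape[0] != n:
            raise ValidationError("RegionDesign arrays have inconsistent lengths")
        if n and (self.subject.min() < 0 or self.subject.max() >= self.n_subjects):
            raise ValidationError("subject codes out of range")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.X_mean))
                and np.all(np.isfinite(self.X_var))):
            raise ValidationError("RegionDesign contains non-finite values")

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def Z(self) -> np.ndarray:
        """Dense subject-incidence matrix (n_obs x n_subjects)."""
        Z = np.zeros((self.n_obs, self.n_subjects))
        Z[np.arange(self.n_obs), self.subject] = 1.0
        return Z

    @property
    def obs_per_subject(self) -> np.ndarray:
        return np.bincount(self.subject, minlength=self.n_subjects)


@dataclass
class RegionFit:
    """All per-region estimates from the alternating h-likelihood fit."""

    beta_hat: np.ndarray          # mean-model coefficients excl. phenotype
    delta_hat: float              # phenotype mean effect
    gamma_hat: np.ndarray         # variance-model coefficients excl. phenotype
    kappa_hat: float              # phenotype log-variance effect
    b_hat: np.ndarray             # subject random-intercept predictions
    sigma_b2: float
    se_delta: float
    se_kappa: float
    cov_mean: np.ndarray          # covariance of (beta, delta)
    cov_var: np.ndarray           # covariance of (gamma, kappa)
    mu_hat: np.ndarray
    eta_hat: np.ndarray           # log sigma2 per observation
    residuals: np.ndarray
    h_lik: float
    converged: bool
    n_iter: int
    message: str = ""
    history: list = field(default_factory=list)

    @property
    def theta(self) -> np.ndarray:
        return np.append(self.beta_hat, self.delta_hat)

    @property
    def phi(self) -> np.ndarray:
        return np.append(self.gamma_hat, self.kappa_hat)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_region_design(region_cpgs, matrix, design, region_id: str = "") -> RegionDesign:
    """Stack one region's data into a :class:`RegionDesign`.

    ``matrix`` is an :class:`methvar.io.MValueMatrix`, ``design`` a
    :class:`methvar.io.SampleDesign` already aligned to the matrix columns.
    """
    region_cpgs = list(region_cpgs)
    if not region_cpgs:
        raise ValidationError(f"region {region_id!r} has zero usable CpGs")
    rows = matrix.rows(region_cpgs)
    V = matrix.values[rows, :]                   # (n_cpgs, N)
    n_cpgs, N = V.shape
    y = V.T.reshape(-1)                          # sample-major, CpG-minor
    Xs = np.column_stack([design.covariates, design.phenotype])   # (N, p)
    X = np.repeat(Xs, n_cpgs, axis=0)
    subject = np.repeat(np.arange(N), n_cpgs)
    return RegionDesign(
        y=y, X_mean=X, X_var=X.copy(), subject=subject, n_subjects=N,
        region_id=region_id, cpg_ids=region_cpgs, sample_ids=list(design.sample_ids),
    )


# ---------------------------------------------------------------------------
# mean model: penalized weighted least squares (Henderson system)
# ---------------------------------------------------------------------------

@dataclass
class MeanSolve:
    theta: np.ndarray             # fixed effects (beta, delta)
    b: np.ndarray                 # random-intercept predictions
    cov_theta: np.ndarray         # fixed-effect covariance block
    leverage_obs: np.ndarray      # augmented-hat diagonal, data rows
    leverage_subj: np.ndarray     # augmented-hat diagonal, pseudo rows


def solve_mean_model(rd: RegionDesign, weights: np.ndarray,
                     sigma_b2: float) -> MeanSolve:
    """Solve the joint (fixed + random) penalized WLS system.

    ``weights`` are per-observation precisions 1/sigma2_ij (strictly
    positive); ``sigma_b2 >= 0``. The subject block of the Henderson system
    is diagonal, so the solve goes through a p x p Schur complement.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValidationError("weights must be strictly positive and finite")
    if sigma_b2 < 0:
        raise ValidationError("sigma_b2 must be >= 0")
    X, y, s, N = rd.X_mean, rd.y, rd.subject, rd.n_subjects
    p = X.shape[1]
    WX = X * w[:, None]
    A = X.T @ WX
    rhs_x = WX.T @ y

    if sigma_b2 <= _SIGMA_B2_ZERO:
        try:
            V = np.linalg.inv(A)
        except np.linalg.LinAlgError as exc:
            raise NonEstimableRegionError(str(exc)) from exc
        theta = V @ rhs_x
        q_obs = w * np.einsum("ij,jk,ik->i", X, V, X)
        # the pseudo-observations pin b at 0 exactly: leverage 1 by convention
        return MeanSolve(theta, np.zeros(N), V, q_obs, np.ones(N))

    lam = 1.0 / sigma_b2
    dz = np.bincount(s, weights=w, minlength=N) + lam
    B = np.empty((p, N))
    for k in range(p):
        B[k] = np.bincount(s, weights=WX[:, k], minlength=N)
    rz = np.bincount(s, weights=w * y, minlength=N)
    Dinv = 1.0 / dz
    BD = B * Dinv                                    # B D^{-1}, (p, N)
    S = A - BD @ B.T
    try:
        V = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise NonEstimableRegionError(str(exc)) from exc
    theta = V @ (rhs_x - BD @ rz)
    b = Dinv * (rz - B.T @ theta)
    C = V @ BD                                        # V_theta B D^{-1}, (p, N)
    Vb_diag = Dinv + np.einsum("kn,kn->n", BD, C)
    quad_x = np.einsum("ij,jk,ik->i", X, V, X)
    cross = np.einsum("ij,ji->i", X, C[:, s])
    q_obs = w * (quad_x - 2.0 * cross + Vb_diag[s])
    q_subj = lam * Vb_diag
    return MeanSolve(theta, b, V, q_obs, q_subj)


# ---------------------------------------------------------------------------
# variance model: gamma-type log-link GLM on squared residuals
# ---------------------------------------------------------------------------

@dataclass
class VarianceSolve:
    phi: np.ndarray               # (gamma, kappa)
    cov_phi: np.ndarray
    converged: bool
    n_iter: int


def solve_variance_model(rd: RegionDesign, residuals: np.ndarray,
                         leverages: np.ndarray | None = None,
                         use_leverage_correction: bool = True,
                         phi0: np.ndarray | None = None,
                         eta_clamp: float = 30.0,
                         max_iter: int = 50,
                         tol: float = 1e-10) -> VarianceSolve:
    """Fit log sigma2 = X_var' phi by Fisher scoring.

    Response ``d = e^2/(1-q)`` with prior weight ``(1-q)/2`` when the
    leverage correction is on (``d = e^2``, weight ``1/2`` when off),
    consistent with ``e^2 ~ sigma2 * chi2_1``. The score equation at the
    optimum is ``sum w * (d/sigma2 - 1) * x = 0`` per design column.
    """
    Xv = rd.X_var
    e2 = np.asarray(residuals, dtype=float) ** 2
    if not np.any(e2 > 0):
        raise DegenerateRegionError("all residuals are zero")
    if use_leverage_correction:
        if leverages is None:
            raise ValidationError("leverage correction requires leverages")
        om = np.clip(1.0 - np.asarray(leverages, dtype=float), 1e-6, None)
        d = e2 / om
        wp = 0.5 * om
    else:
        d = e2
        wp = np.full(e2.shape, 0.5)

    info = Xv.T @ (Xv * wp[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise NonEstimableRegionError(str(exc)) from exc

    if phi0 is None:
        floor = 1e-8 * max(float(d.mean()), 1e-300)
        phi, *_ = np.linalg.lstsq(Xv, np.log(np.maximum(d, floor)), rcond=None)
    else:
        phi = np.array(phi0, dtype=float)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(Xv @ phi, -eta_clamp, eta_clamp)
        score = Xv.T @ (wp * (d * np.exp(-eta) - 1.0))
        step = cov @ score
        phi = phi + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    return VarianceSolve(phi, cov, converged, it)


def update_sigma_b2(b_hat: np.ndarray, subject_leverages: np.ndarray) -> float:
    """REML-type adjusted-profile update sigma_b2 = sum b^2 / sum (1 - q)."""
    b_hat = np.asarray(b_hat, dtype=float)
    num = float(np.sum(b_hat ** 2))
    if num < _SIGMA_B2_ZERO:
        return 0.0
    den = float(np.sum(1.0 - np.asarray(subject_leverages, dtype=float)))
    if den <= 0.0:
        return 0.0
    return num / den


# ---------------------------------------------------------------------------
# h-likelihood
# ---------------------------------------------------------------------------

def h_likelihood(rd: RegionDesign, fit: RegionFit) -> float:
    """Joint log-likelihood of data and random effects at the fit."""
    return _h_value(rd.y, fit.mu_hat, fit.eta_hat, fit.b_hat, fit.sigma_b2)


def _h_value(y, mu, eta, b, sigma_b2) -> float:
    sig2 = np.exp(eta)
    if np.any(sig2 <= 0) or not np.all(np.isfinite(sig2)):
        raise ValidationError("non-positive or non-finite sigma2 in h-likelihood")
    e = y - mu
    h = float(np.sum(-0.5 * (_LOG_2PI + eta) - e * e / (2.0 * sig2)))
    if sigma_b2 <= _SIGMA_B2_ZERO:
        if np.any(np.abs(b) > 0):
            raise ValidationError("sigma_b2 = 0 requires all-zero random effects")
        return h
    h += float(np.sum(-0.5 * np.log(2.0 * np.pi * sigma_b2)
                      - b * b / (2.0 * sigma_b2)))
    return h


# ---------------------------------------------------------------------------
# the alternating fit
# ---------------------------------------------------------------------------

def _nan_fit(rd: RegionDesign, n_iter: int, message: str) -> RegionFit:
    p = rd.X_mean.shape[1]
    q = rd.X_var.shape[1]
    nan = float("nan")
    n = rd.n_obs
    return RegionFit(
        beta_hat=np.full(p - 1, nan), delta_hat=nan,
        gamma_hat=np.full(q - 1, nan), kappa_hat=nan,
        b_hat=np.full(rd.n_subjects, nan), sigma_b2=nan,
        se_delta=nan, se_kappa=nan,
        cov_mean=np.full((p, p), nan), cov_var=np.full((q, q), nan),
        mu_hat=np.full(n, nan), eta_hat=np.full(n, nan),
        residuals=np.full(n, nan), h_lik=nan,
        converged=False, n_iter=n_iter, message=message,
    )


def fit_region(rd: RegionDesign, config: FitConfig | None = None) -> RegionFit:
    """Alternate mean / variance / sigma_b2 updates until convergence.

    Regions with a single CpG per subject pin sigma_b2 at 0 (the random
    intercept is unidentifiable there) and degrade to a double GLM.
    """
    cfg = config or FitConfig()
    X, Xv, y, s, N = rd.X_mean, rd.X_var, rd.y, rd.subject, rd.n_subjects
    p = X.shape[1]

    pinned = cfg.pin_sigma_b2 is not None
    sigma_b2 = float(cfg.pin_sigma_b2) if pinned else 0.0
    counts = rd.obs_per_subject
    if not pinned and counts.max() <= 1:
        pinned, sigma_b2 = True, 0.0         # single CpG per subject

    # --- initialization -----------------------------------------------------
    try:
        theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    except np.linalg.LinAlgError:
        return _nan_fit(rd, 0, "singular mean design")
    e = y - X @ theta
    e2 = e * e
    if not np.any(e2 > 0):
        return _nan_fit(rd, 0, "degenerate region: all residuals zero")
    floor = 1e-8 * max(float(e2.mean()), 1e-300)
    phi, *_ = np.linalg.lstsq(Xv, np.log(np.maximum(e2, floor)), rcond=None)
    if not pinned:
        m_i = np.bincount(s, weights=e, minlength=N) / np.maximum(counts, 1)
        nbar = rd.n_obs / N
        sigma_b2 = max(0.0, float(np.var(m_i, ddof=1)) - float(e2.mean()) / nbar)

    params = np.concatenate([theta, phi, [sigma_b2]])
    converged = False
    message = ""
    history: list[float] = []
    ms = vs = None
    n_iter = 0
    try:
        for n_iter in range(1, cfg.max_iter + 1):
            eta = np.clip(Xv @ phi, -cfg.eta_clamp, cfg.eta_clamp)
            w = np.exp(-eta)
            ms = solve_mean_model(rd, w, sigma_b2)
            theta = ms.theta
            e = y - X @ theta - ms.b[s]
            vs = solve_variance_model(
                rd, e, ms.leverage_obs, cfg.leverage_correction,
                phi0=phi, eta_clamp=cfg.eta_clamp,
                max_iter=cfg.inner_max_iter, tol=cfg.inner_tol,
            )
            phi = vs.phi
            if not pinned:
                sigma_b2 = update_sigma_b2(ms.b, ms.leverage_subj)
            new = np.concatenate([theta, phi, [sigma_b2]])
            if cfg.track_history:
                eta_h = np.clip(Xv @ phi, -cfg.eta_clamp, cfg.eta_clamp)
                history.append(_h_value(y, X @ theta + ms.b[s], eta_h,
                                        ms.b, sigma_b2))
            if np.all(np.abs(new - params) <= cfg.tol * np.abs(params) + cfg.abs_tol):
                params = new
                converged = True
                break
            params = new
        else:
            message = "iteration cap reached"
    except NonEstimableRegionError as exc:
        return _nan_fit(rd, n_iter, f"non-estimable: {exc}")
    except DegenerateRegionError as exc:
        return _nan_fit(rd, n_iter, f"degenerate: {exc}")

    if not converged and cfg.on_nonconverged == "na":
        return _nan_fit(rd, n_iter, message or "not converged")

    # final consistent solve at the converged variance parameters
    eta = np.clip(Xv @ phi, -cfg.eta_clamp, cfg.eta_clamp)
    w = np.exp(-eta)
    try:
        ms = solve_mean_model(rd, w, sigma_b2)
    except NonEstimableRegionError as exc:
        return _nan_fit(rd, n_iter, f"non-estimable: {exc}")
    theta = ms.theta
    mu = X @ theta + ms.b[s]
    e = y - mu
    se_delta = float(np.sqrt(max(ms.cov_theta[-1, -1], 0.0)))
    se_kappa = float(np.sqrt(max(vs.cov_phi[-1, -1], 0.0))) if vs is not None else float("nan")
    cov_var = vs.cov_phi if vs is not None else np.full((Xv.shape[1],) * 2, np.nan)
    h = _h_value(y, mu, eta, ms.b, sigma_b2)
    return RegionFit(
        beta_hat=theta[:-1], delta_hat=float(theta[-1]),
        gamma_hat=phi[:-1], kappa_hat=float(phi[-1]),
        b_hat=ms.b, sigma_b2=float(sigma_b2),
        se_delta=se_delta, se_kappa=se_kappa,
        cov_mean=ms.cov_theta, cov_var=cov_var,
        mu_hat=mu, eta_hat=eta, residuals=e, h_lik=h,
        converged=converged, n_iter=n_iter, message=message, history=history,
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator facade
# ---------------------------------------------------------------------------

class MeanVarianceHGLM(BaseEstimator):
    """Gaussian HGLM with a subject random intercept and log-linear variance.

    scikit-learn-style estimator over the alternating h-likelihood fit.
    ``X`` holds the covariates *without* an intercept, with the phenotype of
    interest as its **last** column; an intercept is prepended internally and
    the same design drives both the mean and the log-variance model.

    Parameters mirror :class:`FitConfig`. Fitted attributes:

    - ``beta_`` / ``delta_``: mean-model coefficients (intercept +
      covariates) and phenotype mean effect;
    - ``gamma_`` / ``kappa_``: variance-model coefficients and phenotype
      log-variance effect;
    - ``sigma_b2_``, ``random_effects_``: random-intercept variance and
      per-subject predictions;
    - ``se_delta_``, ``se_kappa_``: plug-in Wald standard errors;
    - ``h_likelihood_``, ``converged_``, ``n_iter_``.

    Examples
    --------
    >>> import numpy as np
    >>> from methvar.hglm import MeanVarianceHGLM
    >>> rng = np.random.default_rng(0)
    >>> G = np.repeat([0.0, 1.0], 30)
    >>> groups = np.repeat(np.arange(60), 4)       # 4 CpGs per subject
    >>> y = (0.7 * G + rng.normal(size=60))[groups]
    >>> y = y + rng.normal(scale=0.5, size=y.size)
    >>> m = MeanVarianceHGLM().fit(G[groups, None], y, groups=groups)
    >>> abs(m.delta_ - 0.7) < 0.5
    True
    """

    def __init__(self, tol: float = 1e-6, abs_tol: float = 1e-8,
                 max_iter: int = 100, inner_max_iter: int = 50,
                 leverage_correction: bool = True, eta_clamp: float = 30.0,
                 pin_sigma_b2: float | None = None,
                 on_nonconverged: str = "report"):
        self.tol = tol
        self.abs_tol = abs_tol
        self.max_iter = max_iter
        self.inner_max_iter = inner_max_iter
        self.leverage_correction = leverage_correction
        self.eta_clamp = eta_clamp
        self.pin_sigma_b2 = pin_sigma_b2
        self.on_nonconverged = on_nonconverged

    def _config(self) -> FitConfig:
        return FitConfig(
            tol=self.tol, abs_tol=self.abs_tol, max_iter=self.max_iter,
            inner_max_iter=self.inner_max_iter,
            leverage_correction=self.leverage_correction,
            eta_clamp=self.eta_clamp, pin_sigma_b2=self.pin_sigma_b2,
            on_nonconverged=self.on_nonconverged,
        )

    def fit(self, X, y, groups=None):
        """Fit the joint mean-variance model.

        Parameters
        ----------
        X : array-like (n_obs, k)
            Covariates without intercept; phenotype as the last column.
        y : array-like (n_obs,)
            M-values.
        groups : array-like (n_obs,), optional
            Subject labels; observations sharing a label share a random
            intercept. Without groups every observation is its own subject
            and sigma_b2 is pinned at 0.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValidationError("X must be 2-D with one row per observation")
        if groups is None:
            codes = np.arange(y.shape[0])
            classes = codes
        else:
            classes, codes = np.unique(np.asarray(groups), return_inverse=True)
        Xfull = np.column_stack([np.ones(y.shape[0]), X])
        rd = RegionDesign(y=y, X_mean=Xfull, X_var=Xfull.copy(),
                          subject=codes, n_subjects=len(classes))
        fit = fit_region(rd, self._config())
        self.groups_ = classes
        self.beta_ = fit.theta[:-1]
        self.delta_ = fit.delta_hat
        self.gamma_ = fit.phi[:-1]
        self.kappa_ = fit.kappa_hat
        self.sigma_b2_ = fit.sigma_b2
        self.random_effects_ = fit.b_hat
        self.se_delta_ = fit.se_delta
        self.se_kappa_ = fit.se_kappa
        self.h_likelihood_ = fit.h_lik
        self.converged_ = fit.converged
        self.n_iter_ = fit.n_iter
        self.result_ = fit
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X, groups=None):
        """Fitted mean: fixed-effect part plus b for known groups."""
        X = np.asarray(X, dtype=float)
        mu = np.column_stack([np.ones(X.shape[0]), X]) @ np.append(
            self.beta_, self.delta_)
        if groups is not None:
            lut = {g: i for i, g in enumerate(self.groups_)}
            add = np.array([self.random_effects_[lut[g]] if g in lut else 0.0
                            for g in np.asarray(groups)])
            mu = mu + add
        return mu

    def predict_variance(self, X):
        """Fitted residual variance exp(X_var' phi)."""
        X = np.asarray(X, dtype=float)
        eta = np.column_stack([np.ones(X.shape[0]), X]) @ np.append(
            self.gamma_, self.kappa_)
        return np.exp(np.clip(eta, -self.eta_clamp, self.eta_clamp))
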