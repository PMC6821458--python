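"""Gamma GLMs relating the high-frequency amplitude to phase and amplitude.

The high-frequency amplitude envelope A_high is strictly positive and
right-skewed, so it is modelled as a gamma random variable whose log mean is
linear in the predictors:

* phase model      -- log mu = sum_k beta_k f_k(phi_low), spline basis only;
* amplitude model  -- log mu = beta_1 + beta_2 A_low;
* joint model      -- spline basis + A_low + A_low*sin(phi_low)
  + A_low*cos(phi_low);
* condition models -- the joint model plus interactions with a binary
  condition indicator P (either the full P x (splines, A_low) block or the
  P x A_low term alone).

Fitting uses iteratively reweighted least squares. For the gamma family with
a log link the working weights are identically one, so the Gram matrix X'X is
fixed across iterations and can be factorized once -- fits then cost a few
matrix-vector products each, which is what makes surrogate resampling (many
refits against a fixed design) affordable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy import stats as _st

from .splines import PeriodicSplineBasis, spline_design_matrix

__all__ = [
    "ConvergenceError", "GammaGLMFit",
    "fit_phi_model", "fit_alow_model", "fit_joint_model",
    "fit_condition_models", "aic_select_n", "gamma_gof_check",
]


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries iteration diagnostics."""

    def __init__(self, message: str, n_iter: int, deviance_trace: list[float]):
        super().__init__(f"{message} after {n_iter} iterations; "
                         f"last deviances {deviance_trace[-3:]}")
        self.n_iter = n_iter
        self.deviance_trace = deviance_trace


@dataclass
class GammaGLMFit:
    """A fitted gamma GLM with log link.

    Attributes
    ----------
    model_kind : str
        One of ``phi``, ``alow``, ``joint``, ``joint+condition``,
        ``alow+condition``.
    beta : ndarray
        Coefficients on the log-mean scale.
    cov_beta : ndarray
        Coefficient covariance (dispersion times the inverse Gram matrix).
    nu : float
        Gamma shape; the reciprocal of the Pearson dispersion.
    deviance : float
        Model deviance (twice the log-likelihood gap to the saturated model,
        at unit dispersion).
    aic : float
        ``deviance + 2 * len(beta)``, the criterion used for choosing the
        number of spline control points.
    basis : PeriodicSplineBasis or None
        The phase basis, for models that include spline terms.
    """

    model_kind: str
    beta: np.ndarray
    cov_beta: np.ndarray
    nu: float
    deviance: float
    aic: float
    basis: PeriodicSplineBasis | None = None
    n_obs: int = 0
    n_iter: int = 0

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "beta": self.beta.tolist(),
            "cov_beta": self.cov_beta.tolist(),
            "nu": self.nu,
            "deviance": self.deviance,
            "aic": self.aic,
            "n_obs": self.n_obs,
        }


def floor_positive(y: np.ndarray) -> np.ndarray:
    """Clip non-positive amplitudes to the smallest positive observation.

    The gamma distribution has support on (0, inf); Hilbert envelopes are
    non-negative by construction, and exact zeros (or negatives, for
    amplitude series assembled from spikes plus noise) are floored.
    """
    y = np.asarray(y, dtype=float)
    if np.all(y > 0):
        return y
    pos = y[y > 0]
    if pos.size == 0:
        raise ValueError("amplitude series has no positive values")
    return np.maximum(y, pos.min())


def gamma_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return 2.0 * float(np.sum(-np.log(y / mu) + (y - mu) / mu))


class GramCache:
    """Cholesky factorization of X'X, reusable across refits of one design."""

    def __init__(self, X: np.ndarray):
        self.X = X
        try:
            self.cho = cho_factor(X.T @ X)
        except LinAlgError as err:
            raise ValueError(
                "design matrix is rank deficient (collinear or constant "
                "predictors); cannot fit the gamma GLM"
            ) from err

    def solve(self, v: np.ndarray) -> np.ndarray:
        return cho_solve(self.cho, v)


def irls_gamma(
    X: np.ndarray,
    y: np.ndarray,
    gram: GramCache | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    criterion: str = "deviance",
) -> tuple[np.ndarray, float, int, GramCache]:
    """Fit a gamma GLM with log link by IRLS.

    Returns ``(beta, deviance, n_iter, gram)``. Convergence is declared when
    the relative deviance change falls below ``tol`` (default) or, with
    ``criterion="beta"``, when the coefficient vector stabilizes to 1e-6 --
    a cheaper test used inside surrogate resampling loops, where the
    deviance itself is not needed until the end (and is then computed once).
    Raises :class:`ConvergenceError` otherwise.
    """
    if gram is None:
        gram = GramCache(X)
    # initial values: Gaussian fit on the log scale
    beta = gram.solve(X.T @ np.log(y))
    dev_trace: list[float] = []
    dev = np.inf
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        beta_new = gram.solve(X.T @ z)
        if criterion == "beta":
            if np.max(np.abs(beta_new - beta)) <= 1e-6 * (np.max(np.abs(beta_new)) + 1e-3):
                beta = beta_new
                dev = gamma_deviance(y, np.exp(np.clip(X @ beta, -30.0, 30.0)))
                return beta, dev, it, gram
            beta = beta_new
            dev_trace.append(float(np.max(np.abs(beta))))
            continue
        beta = beta_new
        new_dev = gamma_deviance(y, np.exp(np.clip(X @ beta, -30.0, 30.0)))
        dev_trace.append(new_dev)
        if abs(dev - new_dev) <= tol * (abs(new_dev) + 0.1):
            return beta, new_dev, it, gram
        dev = new_dev
    raise ConvergenceError("gamma GLM IRLS did not converge", max_iter, dev_trace)


def _finish_fit(kind, X, y, beta, dev, n_iter, gram, basis=None) -> GammaGLMFit:
    mu = np.exp(np.clip(X @ beta, -30.0, 30.0))
    resid = (y - mu) / mu
    dof = max(X.shape[0] - X.shape[1], 1)
    dispersion = float(resid @ resid) / dof
    cov = dispersion * cho_solve(gram.cho, np.eye(X.shape[1]))
    cov = (cov + cov.T) / 2.0
    return GammaGLMFit(
        model_kind=kind,
        beta=beta,
        cov_beta=cov,
        nu=1.0 / dispersion,
        deviance=dev,
        aic=dev + 2.0 * X.shape[1],
        basis=basis,
        n_obs=X.shape[0],
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# design matrices

def design_phi(phi_low, basis: PeriodicSplineBasis) -> np.ndarray:
    return spline_design_matrix(phi_low, basis)

def design_alow(a_low) -> np.ndarray:
    a_low = np.asarray(a_low, dtype=float)
    return np.column_stack([np.ones_like(a_low), a_low])

def design_joint(phi_low, a_low, basis: PeriodicSplineBasis) -> np.ndarray:
    B = spline_design_matrix(phi_low, basis)
    a_low = np.asarray(a_low, dtype=float)
    return np.column_stack(
        [B, a_low, a_low * np.sin(phi_low), a_low * np.cos(phi_low)])

def design_condition_full(phi_low, a_low, P, basis) -> np.ndarray:
    """Joint design plus P x (spline block, A_low): 2n + 4 columns."""
    B = spline_design_matrix(phi_low, basis)
    a_low = np.asarray(a_low, dtype=float)
    P = np.asarray(P, dtype=float)
    return np.column_stack([
        B, a_low, a_low * np.sin(phi_low), a_low * np.cos(phi_low),
        P[:, None] * B, P * a_low,
    ])

def design_condition_amp(phi_low, a_low, P, basis) -> np.ndarray:
    """Joint design plus the single P x A_low term: n + 4 columns."""
    B = spline_design_matrix(phi_low, basis)
    a_low = np.asarray(a_low, dtype=float)
    P = np.asarray(P, dtype=float)
    return np.column_stack([
        B, a_low, a_low * np.sin(phi_low), a_low * np.cos(phi_low),
        P * a_low,
    ])


# ---------------------------------------------------------------------------
# model fits

def _check_lengths(*arrays):
    n = {len(a) for a in arrays}
    if len(n) != 1:
        raise ValueError(f"input series have unequal lengths {sorted(n)}")


def fit_phi_model(a_high, phi_low, basis: PeriodicSplineBasis | None = None) -> GammaGLMFit:
    """Gamma GLM of A_high on the spline basis of phi_low (no intercept;
    the basis sums to one)."""
    basis = basis or PeriodicSplineBasis()
    _check_lengths(a_high, phi_low)
    y = floor_positive(a_high)
    X = design_phi(phi_low, basis)
    beta, dev, it, gram = irls_gamma(X, y)
    return _finish_fit("phi", X, y, beta, dev, it, gram, basis)


def fit_alow_model(a_high, a_low) -> GammaGLMFit:
    """Gamma GLM of A_high on {1, A_low}."""
    _check_lengths(a_high, a_low)
    y = floor_positive(a_high)
    X = design_alow(a_low)
    beta, dev, it, gram = irls_gamma(X, y)
    return _finish_fit("alow", X, y, beta, dev, it, gram)


def fit_joint_model(a_high, phi_low, a_low, basis: PeriodicSplineBasis | None = None) -> GammaGLMFit:
    """Gamma GLM of A_high on splines of phi_low, A_low and the
    A_low*sin/cos(phi_low) interactions (n + 3 coefficients)."""
    basis = basis or PeriodicSplineBasis()
    _check_lengths(a_high, phi_low, a_low)
    y = floor_positive(a_high)
    X = design_joint(phi_low, a_low, basis)
    beta, dev, it, gram = irls_gamma(X, y)
    return _finish_fit("joint", X, y, beta, dev, it, gram, basis)


def fit_condition_models(a_high, phi_low, a_low, condition,
                         basis: PeriodicSplineBasis | None = None,
                         ) -> tuple[GammaGLMFit, GammaGLMFit]:
    """Fit the two condition-extended models.

    The first returned fit adds the full ``P x (splines, A_low)`` block to
    the joint model (2n + 4 coefficients); the second adds only ``P x A_low``
    (n + 4 coefficients). Comparing the two isolates the effect of the
    condition on phase-amplitude coupling.
    """
    basis = basis or PeriodicSplineBasis()
    _check_lengths(a_high, phi_low, a_low, condition)
    P = np.asarray(condition)
    vals = np.unique(P)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("condition indicator must be binary (0/1)")
    if vals.size < 2:
        raise ValueError(
            "condition indicator is constant; the P x (spline, A_low) "
            "interaction terms are rank deficient"
        )
    y = floor_positive(a_high)
    X9 = design_condition_full(phi_low, a_low, P, basis)
    X10 = design_condition_amp(phi_low, a_low, P, basis)
    b9, d9, i9, g9 = irls_gamma(X9, y)
    b10, d10, i10, g10 = irls_gamma(X10, y)
    return (
        _finish_fit("joint+condition", X9, y, b9, d9, i9, g9, basis),
        _finish_fit("alow+condition", X10, y, b10, d10, i10, g10, basis),
    )


def aic_select_n(a_high, phi_low, n_range=range(4, 31),
                 tension: float = 0.5) -> tuple[int, dict[int, float]]:
    """Choose the number of spline control points by AIC.

    For each candidate ``n`` the phase model is fit and scored with
    ``AIC = deviance + 2n``; the argmin and the full profile are returned.
    Candidates whose fit fails to converge are skipped with a warning.
    """
    y = floor_positive(a_high)
    profile: dict[int, float] = {}
    for n in n_range:
        try:
            fit = fit_phi_model(y, phi_low, PeriodicSplineBasis(n, tension))
        except (ConvergenceError, ValueError) as err:
            warnings.warn(f"skipping n={n}: {err}", RuntimeWarning, stacklevel=2)
            continue
        profile[n] = fit.deviance + 2.0 * n
    if not profile:
        raise RuntimeError("no spline count produced a convergent fit")
    best = min(profile, key=profile.get)
    return best, profile


@dataclass
class GammaGofResult:
    """Maximum-likelihood gamma fit to the marginal amplitude distribution."""

    shape: float
    scale: float
    mean: float
    ks_stat: float
    ks_p: float


def gamma_gof_check(a_high) -> GammaGofResult:
    """Diagnostic: how gamma-like is the marginal distribution of A_high?

    Fits a two-parameter gamma by maximum likelihood (location fixed at 0)
    and reports the Kolmogorov-Smirnov distance. Intended as a sanity check
    of the response distribution, not a formal test.
    """
    y = floor_positive(a_high)
    shape, _, scale = _st.gamma.fit(y, floc=0)
    ks = _st.kstest(y, "gamma", args=(shape, 0, scale))
    return GammaGofResult(
        shape=float(shape), scale=float(scale), mean=float(shape * scale),
        ks_stat=float(ks.statistic), ks_p=float(ks.pvalue),
    )
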