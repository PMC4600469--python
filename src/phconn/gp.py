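"""Gaussian-process classification and ordinal regression (Laplace, probit).

Both models use the linear kernel k(x, x') = theta * (x . x'), which keeps
the latent function f(x) = x . w with a Gaussian prior w ~ N(0, theta I) —
the exact weight-space dual of the kernel formulation, and the form required
for extracting discriminative weight maps. Posterior inference is by the
Laplace approximation at the posterior mode (Newton iterations with step
halving; the probit likelihoods are log-concave so the mode is unique), and
theta is set by maximising the approximate log marginal likelihood.

Binary model: probit likelihood p(y_i | f_i) = Phi(y_i f_i), y_i in {-1,+1};
the Laplace predictive probability Phi(mu / sqrt(1 + s^2)) integrates the
probit link over the latent Gaussian exactly.

Ordinal model (cumulative probit with ordered cut-points b_1 < .. < b_{C-1}
and unit latent noise): p(y = c | f) = Phi(b_{c+1} - f) - Phi(b_c - f).
Thresholds are parameterised as (b_1, log gaps) so monotonicity is
structural, and optimised jointly with theta by Nelder-Mead on the Laplace
marginal likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

__all__ = [
    "GPClassification",
    "GPClassificationResults",
    "OrdinalGP",
    "OrdinalGPResults",
]

_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _log_phi(z):
    return -0.5 * z * z - np.log(_SQRT_2PI)


def _probit_ratio(z):
    """phi(z) / Phi(z), computed in the log domain for tail stability."""
    return np.exp(_log_phi(z) - log_ndtr(z))


def _newton_probit(X, y, theta, w0=None, tol=1e-10, maxiter=100):
    """Posterior mode of w for the binary probit model.

    Minimises psi(w) = ||w||^2 / (2 theta) - sum_i log Phi(y_i x_i . w).
    Returns (w, psi, A_cho, W, lml) where A = I/theta + X^T W X is the
    negative log-posterior Hessian at the mode.
    """
    n, d = X.shape
    w = np.zeros(d) if w0 is None else w0.copy()

    def _psi_parts(w):
        z = y * (X @ w)
        return z, 0.5 * (w @ w) / theta - log_ndtr(z).sum()

    z, psi = _psi_parts(w)
    for _ in range(maxiter):
        r = _probit_ratio(z)
        grad = w / theta - X.T @ (y * r)
        gnorm = np.max(np.abs(grad))
        Wdiag = r * (r + z)
        A = X.T @ (X * Wdiag[:, None])
        A[np.diag_indices_from(A)] += 1.0 / theta
        cho = linalg.cho_factor(A, lower=True, check_finite=False)
        if gnorm < tol:
            break
        step = linalg.cho_solve(cho, grad, check_finite=False)
        t = 1.0
        for _ in range(30):
            w_new = w - t * step
            z_new, psi_new = _psi_parts(w_new)
            if psi_new <= psi - 1e-4 * t * (grad @ step) or t < 1e-8:
                break
            t *= 0.5
        if abs(psi - psi_new) < 1e-14 * (1 + abs(psi)) and gnorm < 1e-6:
            w, z, psi = w_new, z_new, psi_new
            r = _probit_ratio(z)
            Wdiag = r * (r + z)
            A = X.T @ (X * Wdiag[:, None])
            A[np.diag_indices_from(A)] += 1.0 / theta
            cho = linalg.cho_factor(A, lower=True, check_finite=False)
            break
        w, z, psi = w_new, z_new, psi_new
    # log|I + theta X^T W X| = d log(theta) + log|A|
    logdet = X.shape[1] * np.log(theta) + 2.0 * np.sum(
        np.log(np.diag(cho[0]))
    )
    lml = -psi - 0.5 * logdet
    return w, psi, cho, Wdiag, lml


class GPClassification:
    """Binary GP classifier with probit likelihood and linear kernel.

    Parameters
    ----------
    endog : array of +1 / -1 class labels.
    exog : (n_samples, n_features) feature matrix.

    ``fit`` returns a :class:`GPClassificationResults`.
    """

    def __init__(self, endog, exog):
        y = np.asarray(endog)
        X = np.asarray(exog, dtype=float)
        if X.ndim != 2:
            raise ValueError("exog must be 2-D")
        if y.shape != (X.shape[0],):
            raise ValueError("one label per sample required")
        if not np.all(np.isin(y, (-1, 1))):
            raise ValueError("labels must be +1 or -1")
        if np.sum(y == 1) < 2 or np.sum(y == -1) < 2:
            raise ValueError("need at least 2 samples per class")
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        self.endog = y.astype(float)
        self.exog = X
        # Reference kernel scale: theta0 x mean ||x||^2 ~ unit latent scale.
        msq = float(np.mean(np.sum(X * X, axis=1)))
        self._theta0 = 1.0 / msq if msq > 0 else 1.0

    def loglike(self, theta: float, w0=None) -> float:
        """Laplace approximate log marginal likelihood at kernel scale theta."""
        *_, lml = _newton_probit(self.exog, self.endog, theta, w0=w0)
        return lml

    def fit(
        self,
        theta: float | None = None,
        log_span: float = 8.0,
        xatol: float = 0.15,
        maxiter: int = 40,
        start_weights=None,
    ) -> "GPClassificationResults":
        """Fit the Laplace approximation.

        If ``theta`` is None it is chosen by maximising the approximate log
        marginal likelihood over log(theta) in a bracket of half-width
        ``log_span`` around the unit-latent-scale reference. The optional
        ``start_weights`` only seed the Newton iterations (the posterior
        mode is unique, so they change runtime, never the result).
        Deterministic given inputs.
        """
        carry = {"w": None if start_weights is None
                 else np.asarray(start_weights, dtype=float)}
        if theta is None:
            lt0 = np.log(self._theta0)

            def _neg(lt):
                w, *_, lml = _newton_probit(
                    self.exog, self.endog, np.exp(lt), w0=carry["w"]
                )
                carry["w"] = w
                return -lml

            res = optimize.minimize_scalar(
                _neg,
                bounds=(lt0 - log_span, lt0 + log_span),
                method="bounded",
                options={"xatol": xatol, "maxiter": maxiter},
            )
            theta = float(np.exp(res.x))
        w, psi, cho, Wdiag, lml = _newton_probit(
            self.exog, self.endog, float(theta), w0=carry["w"]
        )
        return GPClassificationResults(self, float(theta), w, cho, lml)


@dataclass
class GPClassificationResults:
    """Fitted Laplace GPC: posterior mode, predictive machinery, summary."""

    model: GPClassification
    theta: float
    weights: np.ndarray
    _cho: tuple
    log_marginal_likelihood: float

    @property
    def dual_coef(self) -> np.ndarray:
        """Dual coefficients alpha with f(x) = sum_i alpha_i k(x, x_i).

        At the posterior mode alpha equals the likelihood gradient
        d log p(y|f) / df, and w = theta X^T alpha exactly.
        """
        z = self.model.endog * (self.model.exog @ self.weights)
        return self.model.endog * _probit_ratio(z)

    def predict_latent(self, exog) -> tuple[np.ndarray, np.ndarray]:
        """Latent predictive mean and variance at new points."""
        Xs = np.asarray(exog, dtype=float)
        if Xs.ndim == 1:
            Xs = Xs[None, :]
        if Xs.shape[1] != self.model.exog.shape[1]:
            raise ValueError(
                f"feature dimension {Xs.shape[1]} does not match training "
                f"dimension {self.model.exog.shape[1]}"
            )
        mu = Xs @ self.weights
        sol = linalg.cho_solve(self._cho, Xs.T, check_finite=False)
        var = np.einsum("ij,ji->i", Xs, sol)
        return mu, np.maximum(var, 0.0)

    def predict_prob(self, exog) -> np.ndarray:
        """Probability of the +1 class (probit-averaged Laplace predictive)."""
        mu, var = self.predict_latent(exog)
        return ndtr(mu / np.sqrt(1.0 + var))

    def summary(self) -> str:
        n, d = self.model.exog.shape
        lines = [
            "Gaussian process classification (Laplace, probit, linear kernel)",
            f"  n samples          : {n}",
            f"  n features         : {d}",
            f"  kernel scale theta : {self.theta:.6g}",
            f"  log marginal lik.  : {self.log_marginal_likelihood:.4f}",
            f"  |w| (weight norm)  : {np.linalg.norm(self.weights):.4g}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Ordinal GP (cumulative probit)
# ---------------------------------------------------------------------------


def _ordinal_terms(f, y, cuts):
    """Log-likelihood, gradient and curvature of the cumulative probit.

    cuts has C-1 finite cut-points; class c in {0..C-1} observes
    Z_c = Phi(hi - f) - Phi(lo - f), hi = b_{c+1}, lo = b_c (b_0 = -inf,
    b_C = +inf). Returns (logZ, dlog/df, -d2log/df2) per sample.
    """
    C = len(cuts) + 1
    hi = np.where(y == C - 1, np.inf, cuts[np.minimum(y, C - 2)] - f)
    lo = np.where(y == 0, -np.inf, cuts[np.maximum(y - 1, 0)] - f)

    # Evaluate in whichever tail is better conditioned.
    flip = (hi + lo) > 0
    a = np.where(flip, -lo, hi)   # upper argument after reflection
    b = np.where(flip, -hi, lo)   # lower argument after reflection
    log_hi = log_ndtr(a)
    log_lo = np.where(np.isneginf(b), -np.inf, log_ndtr(b))
    with np.errstate(divide="ignore"):
        logZ = log_hi + np.log1p(-np.exp(np.minimum(log_lo - log_hi, -1e-12)))
    logZ = np.maximum(logZ, -700.0)

    phi_hi = np.where(np.isposinf(hi), 0.0, np.exp(_log_phi(hi) - logZ))
    phi_lo = np.where(np.isneginf(lo), 0.0, np.exp(_log_phi(lo) - logZ))
    grad = phi_lo - phi_hi
    hi_f = np.where(np.isposinf(hi), 0.0, hi)
    lo_f = np.where(np.isneginf(lo), 0.0, lo)
    # -d2/df2 log Z
    curv = grad * grad - (lo_f * phi_lo - hi_f * phi_hi)
    return logZ, grad, np.maximum(curv, 1e-12)


def _newton_ordinal(X, y, cuts, theta, w0=None, tol=1e-9, maxiter=100):
    n, d = X.shape
    w = np.zeros(d) if w0 is None else w0.copy()

    def _psi(w):
        logZ, *_ = _ordinal_terms(X @ w, y, cuts)
        return 0.5 * (w @ w) / theta - logZ.sum()

    psi = _psi(w)
    for _ in range(maxiter):
        f = X @ w
        _, g, Wdiag = _ordinal_terms(f, y, cuts)
        grad = w / theta - X.T @ g
        gnorm = np.max(np.abs(grad))
        A = X.T @ (X * Wdiag[:, None])
        A[np.diag_indices_from(A)] += 1.0 / theta
        cho = linalg.cho_factor(A, lower=True, check_finite=False)
        if gnorm < tol:
            break
        step = linalg.cho_solve(cho, grad, check_finite=False)
        t = 1.0
        for _ in range(30):
            w_new = w - t * step
            psi_new = _psi(w_new)
            if psi_new <= psi - 1e-4 * t * (grad @ step) or t < 1e-8:
                break
            t *= 0.5
        converged = abs(psi - psi_new) < 1e-13 * (1 + abs(psi))
        w, psi = w_new, psi_new
        if converged and gnorm < 1e-5:
            f = X @ w
            _, g, Wdiag = _ordinal_terms(f, y, cuts)
            A = X.T @ (X * Wdiag[:, None])
            A[np.diag_indices_from(A)] += 1.0 / theta
            cho = linalg.cho_factor(A, lower=True, check_finite=False)
            break
    logdet = d * np.log(theta) + 2.0 * np.sum(np.log(np.diag(cho[0])))
    lml = -psi - 0.5 * logdet
    return w, cho, lml


class OrdinalGP:
    """Ordinal GP regression: cumulative probit over rank-ordered classes.

    Parameters
    ----------
    endog : integer class indices 0 .. C-1 (rank order supplied by caller).
    exog : (n_samples, n_features) feature matrix.
    n_classes : optional explicit C (defaults to max(endog) + 1).
    """

    def __init__(self, endog, exog, n_classes: int | None = None):
        y = np.asarray(endog)
        X = np.asarray(exog, dtype=float)
        if X.ndim != 2:
            raise ValueError("exog must be 2-D")
        if y.shape != (X.shape[0],):
            raise ValueError("one class index per sample required")
        if not np.issubdtype(y.dtype, np.integer):
            yi = y.astype(int)
            if not np.array_equal(yi, y):
                raise ValueError("class indices must be integers")
            y = yi
        if y.min() < 0:
            raise ValueError("class indices must be >= 0")
        C = int(n_classes if n_classes is not None else y.max() + 1)
        if C < 2:
            raise ValueError("need at least 2 ordered classes")
        if np.unique(y).size < 2:
            raise ValueError("training labels contain a single class")
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        self.endog = y
        self.exog = X
        self.n_classes = C
        msq = float(np.mean(np.sum(X * X, axis=1)))
        self._theta0 = 1.0 / msq if msq > 0 else 1.0

    def _initial_cuts(self) -> np.ndarray:
        """Cut-points at standard-normal quantiles of the empirical class CDF."""
        props = np.bincount(self.endog, minlength=self.n_classes) / len(
            self.endog
        )
        cum = np.clip(np.cumsum(props)[:-1], 1e-3, 1 - 1e-3)
        cuts = norm.ppf(cum)
        # Enforce strict increase for degenerate class frequencies.
        for i in range(1, len(cuts)):
            if cuts[i] <= cuts[i - 1]:
                cuts[i] = cuts[i - 1] + 1e-3
        return cuts

    @staticmethod
    def _pack(theta, cuts):
        gaps = np.diff(cuts)
        return np.concatenate(
            [[np.log(theta), cuts[0]], np.log(gaps)]
        ) if len(cuts) > 1 else np.array([np.log(theta), cuts[0]])

    @staticmethod
    def _unpack(params):
        theta = float(np.exp(params[0]))
        b1 = params[1]
        gaps = np.exp(params[2:])
        cuts = np.concatenate([[b1], b1 + np.cumsum(gaps)])
        return theta, cuts

    def fit(
        self,
        theta: float | None = None,
        thresholds=None,
        optimize_hyperparams: bool = True,
        maxfev: int = 200,
    ) -> "OrdinalGPResults":
        """Laplace fit; hyperparameters by Nelder-Mead on the approximate
        marginal likelihood unless fixed values are supplied."""
        if thresholds is not None:
            cuts = np.asarray(thresholds, dtype=float)
            if cuts.shape != (self.n_classes - 1,):
                raise ValueError(
                    f"need {self.n_classes - 1} thresholds, got {cuts.shape}"
                )
            if np.any(np.diff(cuts) <= 0):
                raise ValueError("thresholds must be strictly increasing")
        else:
            cuts = self._initial_cuts()
        theta0 = theta if theta is not None else self._theta0

        if optimize_hyperparams and (theta is None or thresholds is None):
            x0 = self._pack(theta0, cuts)
            carry = {"w": None}

            def _neg_lml(params):
                th, ct = self._unpack(params)
                if not (1e-12 < th < 1e12):
                    return 1e10
                try:
                    w, _, lml = _newton_ordinal(
                        self.exog, self.endog, ct, th, w0=carry["w"]
                    )
                except linalg.LinAlgError:
                    return 1e10
                carry["w"] = w
                return -lml

            res = optimize.minimize(
                _neg_lml,
                x0,
                method="Nelder-Mead",
                options={"maxfev": maxfev, "fatol": 1e-3, "xatol": 1e-3},
            )
            theta_hat, cuts_hat = self._unpack(res.x)
        else:
            theta_hat, cuts_hat = float(theta0), cuts

        w, cho, lml = _newton_ordinal(self.exog, self.endog, cuts_hat, theta_hat)
        return OrdinalGPResults(self, theta_hat, cuts_hat, w, cho, lml)


@dataclass
class OrdinalGPResults:
    """Fitted ordinal GP: thresholds, weights and class-probability predictions."""

    model: OrdinalGP
    theta: float
    thresholds: np.ndarray
    weights: np.ndarray
    _cho: tuple
    log_marginal_likelihood: float

    def predict_latent(self, exog):
        Xs = np.asarray(exog, dtype=float)
        if Xs.ndim == 1:
            Xs = Xs[None, :]
        if Xs.shape[1] != self.model.exog.shape[1]:
            raise ValueError("feature dimension mismatch")
        mu = Xs @ self.weights
        sol = linalg.cho_solve(self._cho, Xs.T, check_finite=False)
        var = np.einsum("ij,ji->i", Xs, sol)
        return mu, np.maximum(var, 0.0)

    def predict_class_prob(self, exog) -> np.ndarray:
        """(m, C) matrix of predictive class probabilities.

        Integrating the cumulative probit over the latent Gaussian gives
        Phi((b_{c+1} - mu)/sqrt(1 + s^2)) - Phi((b_c - mu)/sqrt(1 + s^2)).
        """
        mu, var = self.predict_latent(exog)
        denom = np.sqrt(1.0 + var)
        edges = np.concatenate([[-np.inf], self.thresholds, [np.inf]])
        cdf = ndtr((edges[None, :] - mu[:, None]) / denom[:, None])
        probs = np.diff(cdf, axis=1)
        probs = np.clip(probs, 1e-300, None)
        return probs / probs.sum(axis=1, keepdims=True)

    def summary(self) -> str:
        n, d = self.model.exog.shape
        cuts = ", ".join(f"{b:.4g}" for b in self.thresholds)
        return "\n".join(
            [
                "Ordinal GP regression (Laplace, cumulative probit, linear kernel)",
                f"  n samples          : {n}",
                f"  n features         : {d}",
                f"  n classes          : {self.model.n_classes}",
                f"  kernel scale theta : {self.theta:.6g}",
                f"  thresholds         : [{cuts}]",
                f"  log marginal lik.  : {self.log_marginal_likelihood:.4f}",
            ]
        )
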