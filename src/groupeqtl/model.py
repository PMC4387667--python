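"""Likelihood, gradients and low-rank covariance algebra.

The generative model is a two-layer linear-Gaussian network. Observed
genotypes x (length K) feed M group latent variables y = A x + noise(sigma1);
expression z (length N) is z = B y + C x + W s + mu_B + noise(sigma2) with
s ~ N(0, I_H) confounder latents. Marginalising y and s gives

    z | x ~ N((B A + C) x + mu_B,  Sigma),
    Sigma = sigma1^2 B B^T + W W^T + sigma2^2 I_N.

B A carries group-wise SNP-set -> gene-set associations, C carries
individual SNP -> gene effects, W absorbs non-genetic confounding.

Because Sigma is diagonal-plus-low-rank, its inverse and log-determinant
are computed from (M x M) and (H x H) solves (Woodbury identity and matrix
determinant lemma) instead of an O(N^3) dense inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .data import EQTLDataset

#: floor on sigma1^2 and sigma2^2 keeping Sigma nonsingular
EPS_VAR = 1e-6

#: |coefficient| above this counts as a nonzero association after fitting
NONZERO_TOL = 1e-8


class NumericalDegeneracyError(RuntimeError):
    """Raised when a covariance factorization or likelihood value breaks down."""


@dataclass
class ModelHyper:
    """Structural and penalty hyperparameters.

    M, H are the numbers of group and confounder latent variables;
    lambda_A, gamma_B, alpha_C are the Laplace-prior precisions acting as
    L1 penalty weights on A, B, C. ``variant`` selects the group-only model
    ("model1", C fixed at zero, alpha_C ignored) or the full model
    ("model2") with individual effects.
    """

    M: int
    H: int
    lambda_A: float = 0.0
    gamma_B: float = 0.0
    alpha_C: float = 0.0
    variant: str = "model2"

    def __post_init__(self) -> None:
        if self.M < 0 or self.H < 0:
            raise ValueError("M and H must be nonnegative")
        if min(self.lambda_A, self.gamma_B, self.alpha_C) < 0:
            raise ValueError("penalty weights must be nonnegative")
        if self.variant not in ("model1", "model2"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class ModelParams:
    """All estimated quantities: A (M x K), B (N x M), C (N x K), W (N x H),
    mu_B (length N), and the two variance scalars."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    W: np.ndarray
    mu_B: np.ndarray
    sigma1_sq: float
    sigma2_sq: float

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.mu_B = np.asarray(self.mu_B, dtype=float).ravel()
        if self.sigma1_sq < EPS_VAR or self.sigma2_sq < EPS_VAR:
            raise ValueError(f"variances must be >= {EPS_VAR}")

    @property
    def M(self) -> int:
        return self.B.shape[1]

    @property
    def N(self) -> int:
        return self.B.shape[0]

    @property
    def K(self) -> int:
        return self.A.shape[1] if self.A.size else self.C.shape[1]

    @property
    def H(self) -> int:
        return self.W.shape[1]

    def overall(self) -> np.ndarray:
        """B A + C, the combined association matrix."""
        group = self.B @ self.A if self.M > 0 else 0.0
        return group + self.C

    @staticmethod
    def zeros(N: int, K: int, M: int, H: int,
              sigma1_sq: float = 1.0, sigma2_sq: float = 1.0) -> "ModelParams":
        return ModelParams(
            A=np.zeros((M, K)), B=np.zeros((N, M)), C=np.zeros((N, K)),
            W=np.zeros((N, H)), mu_B=np.zeros(N),
            sigma1_sq=sigma1_sq, sigma2_sq=sigma2_sq,
        )


def covariance(params: ModelParams, N: int) -> np.ndarray:
    """Dense marginal covariance sigma1^2 B B^T + W W^T + sigma2^2 I_N.

    Intended for small N (oracles, diagnostics); the fitting path never
    materialises it.
    """
    if params.N != N:
        raise ValueError(f"params describe N={params.N}, requested N={N}")
    S = params.sigma2_sq * np.eye(N)
    if params.M > 0:
        S += params.sigma1_sq * (params.B @ params.B.T)
    if params.H > 0:
        S += params.W @ params.W.T
    return S


@dataclass
class CovarianceFactors:
    """Implicit factorization of Sigma^-1 = T - T W S^-1 W^T T.

    T = sigma2^-2 (I_N - sigma1^2 B inner_M^-1 B^T) with
    inner_M = sigma2^2 I_M + sigma1^2 B^T B, and S = I_H + W^T T W.
    Only the small inner_M (M x M) and S (H x H) matrices are factorized;
    Sigma^-1 is applied to vectors through matrix-vector products, so the
    factor step costs O(M^3 + H^3) plus O(N (M^2 + H^2)) products.
    """

    B: np.ndarray
    W: np.ndarray
    sigma1_sq: float
    sigma2_sq: float
    inner_M: np.ndarray = field(init=False)
    S: np.ndarray = field(init=False)
    logdet_Sigma: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sigma2_sq <= 0:
            raise ValueError("sigma2_sq must be positive")
        B, W = np.atleast_2d(self.B), np.atleast_2d(self.W)
        self.B, self.W = B, W
        N, M = B.shape
        H = W.shape[1]
        self.inner_M = self.sigma2_sq * np.eye(M) + self.sigma1_sq * (B.T @ B)
        try:
            self._cho_inner = linalg.cho_factor(self.inner_M) if M else None
        except linalg.LinAlgError as exc:  # pragma: no cover - needs var floor breach
            raise NumericalDegeneracyError(
                "inner M-matrix is singular; variance floors were violated"
            ) from exc
        self._TW = self._apply_T(W) if H else np.zeros((N, 0))
        self.S = np.eye(H) + W.T @ self._TW
        try:
            self._cho_S = linalg.cho_factor(self.S) if H else None
        except linalg.LinAlgError as exc:  # pragma: no cover
            raise NumericalDegeneracyError(
                "confounder S-matrix is singular; variance floors were violated"
            ) from exc
        # matrix determinant lemma applied twice:
        # log|Sigma| = N log s2 + log|I_M + (s1/s2) B^T B| + log|S|
        logdet = N * np.log(self.sigma2_sq)
        if M:
            logdet += 2.0 * np.sum(np.log(np.diag(self._cho_inner[0]))) \
                - M * np.log(self.sigma2_sq)
        if H:
            logdet += 2.0 * np.sum(np.log(np.diag(self._cho_S[0])))
        if not np.isfinite(logdet):
            raise NumericalDegeneracyError("non-finite log-determinant")
        self.logdet_Sigma = float(logdet)

    @property
    def N(self) -> int:
        return self.B.shape[0]

    def _apply_T(self, V: np.ndarray) -> np.ndarray:
        """T @ V without forming T."""
        if self._cho_inner is None:
            return V / self.sigma2_sq
        BtV = self.B.T @ V
        return (V - self.sigma1_sq * (self.B @ linalg.cho_solve(self._cho_inner, BtV))) \
            / self.sigma2_sq

    def solve(self, V: np.ndarray) -> np.ndarray:
        """Sigma^-1 @ V via the two-level Woodbury factorization."""
        V = np.asarray(V, dtype=float)
        squeeze = V.ndim == 1
        if squeeze:
            V = V[:, None]
        TV = self._apply_T(V)
        if self._cho_S is not None:
            TV = TV - self._TW @ linalg.cho_solve(self._cho_S, self._TW.T @ V)
        return TV[:, 0] if squeeze else TV

    def trace_inverse(self) -> float:
        """tr(Sigma^-1) from the small factors."""
        N, M = self.B.shape
        tr_T = N / self.sigma2_sq
        if self._cho_inner is not None:
            BtB = (self.inner_M - self.sigma2_sq * np.eye(M)) / self.sigma1_sq \
                if self.sigma1_sq > 0 else self.B.T @ self.B
            tr_T -= self.sigma1_sq / self.sigma2_sq * np.trace(
                linalg.cho_solve(self._cho_inner, BtB))
        if self._cho_S is None:
            return float(tr_T)
        corr = np.sum(self._TW * linalg.cho_solve(self._cho_S, self._TW.T).T)
        return float(tr_T - corr)

    def dense_inverse(self) -> np.ndarray:
        """Materialise Sigma^-1 (small-N diagnostics only)."""
        return self.solve(np.eye(self.N))

    def dense_T(self) -> np.ndarray:
        return self._apply_T(np.eye(self.N))


def fast_inverse(B: np.ndarray, W: np.ndarray,
                 sigma1_sq: float, sigma2_sq: float) -> CovarianceFactors:
    """Factor Sigma = sigma1^2 B B^T + W W^T + sigma2^2 I for fast solves."""
    return CovarianceFactors(B=B, W=W, sigma1_sq=sigma1_sq, sigma2_sq=sigma2_sq)


def fast_logdet(factors: CovarianceFactors) -> float:
    """log|Sigma| from the determinant-lemma factorization."""
    return factors.logdet_Sigma


def mu_B_closed_form(params: ModelParams, data: EQTLDataset) -> np.ndarray:
    """Optimal intercept given A, B, C: the mean residual z_bar - (BA+C) x_bar."""
    return data.z_bar - params.overall() @ data.x_bar


def negative_log_likelihood(params: ModelParams, data: EQTLDataset,
                            mu_B: np.ndarray | None = None,
                            factors: CovarianceFactors | None = None) -> float:
    """Negative log-likelihood of Z | X under the marginal Gaussian.

    With ``mu_B=None`` the intercept is profiled out, which reduces to the
    column-centered residual form; passing the closed-form intercept gives
    an identical value.
    """
    D, N = data.D, data.N
    R = params.overall()
    if mu_B is None:
        Xc, Zc = data.centered()
        resid = Zc - R @ Xc
    else:
        resid = data.Z - R @ data.X - np.asarray(mu_B, float)[:, None]
    if factors is None:
        factors = fast_inverse(params.B, params.W, params.sigma1_sq, params.sigma2_sq)
    quad = float(np.sum(resid * factors.solve(resid)))
    val = 0.5 * D * N * np.log(2 * np.pi) + 0.5 * D * factors.logdet_Sigma + 0.5 * quad
    if not np.isfinite(val):
        raise NumericalDegeneracyError("non-finite likelihood value")
    return val


def penalized_objective(params: ModelParams, data: EQTLDataset,
                        hyper: ModelHyper) -> float:
    """NLL plus D * (lambda ||A||_1 + gamma ||B||_1 + alpha ||C||_1).

    The alpha term is dropped for the group-only variant (C is fixed at 0).
    """
    pen = hyper.lambda_A * np.abs(params.A).sum() + hyper.gamma_B * np.abs(params.B).sum()
    if hyper.variant == "model2":
        pen += hyper.alpha_C * np.abs(params.C).sum()
    return negative_log_likelihood(params, data) + data.D * pen


@dataclass
class SmoothGradient:
    """Gradient blocks of the smooth (unpenalized) loss."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    W: np.ndarray
    log_sigma1_sq: float
    log_sigma2_sq: float | None = None


def smooth_gradient(params: ModelParams, data: EQTLDataset,
                    with_sigma2: bool = False,
                    factors: CovarianceFactors | None = None) -> SmoothGradient:
    """Analytic gradient of the centered negative log-likelihood.

    Differentiates through both the mean term (B A + C)(x_d - x_bar) and the
    covariance term sigma1^2 B B^T + W W^T; the L1 parts are handled by the
    optimizer, not here. sigma1^2 (and optionally sigma2^2) are parameterized
    on the log scale to keep them positive.
    """
    D = data.D
    Xc, Zc = data.centered()
    R = params.overall()
    resid = Zc - R @ Xc
    if factors is None:
        factors = fast_inverse(params.B, params.W, params.sigma1_sq, params.sigma2_sq)
    Pres = factors.solve(resid)                      # Sigma^-1 (N x D residuals)
    G_R = -(Pres @ Xc.T)                             # d J / d (BA + C)
    grad_A = params.B.T @ G_R if params.M else np.zeros_like(params.A)
    grad_C = G_R.copy()

    # covariance part: dJ/dSigma = (D/2) Sigma^-1 - (1/2) Sigma^-1 rr^T Sigma^-1
    def gsigma_times(V: np.ndarray) -> np.ndarray:
        return 0.5 * D * factors.solve(V) - 0.5 * (Pres @ (Pres.T @ V))

    if params.M:
        GsB = gsigma_times(params.B)
        grad_B = G_R @ params.A.T + 2.0 * params.sigma1_sq * GsB
        grad_s1 = float(np.sum(params.B * GsB))
    else:
        grad_B = np.zeros_like(params.B)
        grad_s1 = 0.0
    grad_W = 2.0 * gsigma_times(params.W) if params.H else np.zeros_like(params.W)
    grad_log_s1 = params.sigma1_sq * grad_s1

    grad_log_s2 = None
    if with_sigma2:
        tr_gs = 0.5 * D * factors.trace_inverse() - 0.5 * float(np.sum(Pres * Pres))
        grad_log_s2 = params.sigma2_sq * tr_gs

    for block in (grad_A, grad_B, grad_C, grad_W):
        if not np.isfinite(block).all():
            raise NumericalDegeneracyError("non-finite gradient block")
    return SmoothGradient(A=grad_A, B=grad_B, C=grad_C, W=grad_W,
                          log_sigma1_sq=grad_log_s1, log_sigma2_sq=grad_log_s2)


def dense_value_and_grad(params: ModelParams, data: EQTLDataset):
    """Loss + gradients via an explicit N x N inverse and determinant.

    Reference path for verifying (and timing against) the factorized
    route; cost is O(N^3) so it is only sensible for diagnostics.
    """
    D = data.D
    Xc, Zc = data.centered()
    Sigma = covariance(params, data.N)
    Sinv = np.linalg.inv(Sigma)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise NumericalDegeneracyError("covariance not positive definite")
    R = params.overall()
    resid = Zc - R @ Xc
    Pres = Sinv @ resid
    val = 0.5 * D * data.N * np.log(2 * np.pi) + 0.5 * D * logdet \
        + 0.5 * float(np.sum(resid * Pres))
    G_R = -(Pres @ Xc.T)
    G_Sigma = 0.5 * D * Sinv - 0.5 * Pres @ Pres.T
    grad = SmoothGradient(
        A=params.B.T @ G_R if params.M else np.zeros_like(params.A),
        B=(G_R @ params.A.T + 2.0 * params.sigma1_sq * G_Sigma @ params.B)
        if params.M else np.zeros_like(params.B),
        C=G_R,
        W=2.0 * G_Sigma @ params.W if params.H else np.zeros_like(params.W),
        log_sigma1_sq=params.sigma1_sq * float(
            np.sum(params.B * (G_Sigma @ params.B))) if params.M else 0.0,
        log_sigma2_sq=params.sigma2_sq * float(np.trace(G_Sigma)),
    )
    return val, grad


def _sigma2_spectrum(params: ModelParams, data: EQTLDataset,
                     mu_B: np.ndarray | None = None):
    """Eigen-profile of the loss as a function of sigma2^2 alone.

    The low-rank part sigma1^2 B B^T + W W^T has at most M + H nonzero
    eigenvalues, obtained from the Gram matrix of G = [sigma1 B, W]; the
    residual energy splits into per-eigendirection terms plus a bulk term on
    the zero-eigenvalue complement. Returns (lams, energies, rest_energy,
    n_rest) so the 1-D profile loss can be evaluated cheaply.
    """
    if mu_B is None:
        Xc, Zc = data.centered()
        resid = Zc - params.overall() @ Xc
    else:
        resid = data.Z - params.overall() @ data.X - np.asarray(mu_B, float)[:, None]
    N = data.N
    G = np.hstack([np.sqrt(params.sigma1_sq) * params.B, params.W])
    total = float(np.sum(resid ** 2))
    if G.shape[1] == 0:
        return np.zeros(0), np.zeros(0), total, N
    gram = G.T @ G
    evals, evecs = linalg.eigh(gram)
    keep = evals > max(1e-12, 1e-12 * evals.max())
    lams = evals[keep]
    U = (G @ evecs[:, keep]) / np.sqrt(lams)         # orthonormal eigenvectors
    eta = U.T @ resid
    energies = np.sum(eta ** 2, axis=1)
    rest = max(total - float(energies.sum()), 0.0)
    return lams, energies, rest, N - lams.size


def sigma2_profile(params: ModelParams, data: EQTLDataset,
                   mu_B: np.ndarray | None = None):
    """Return callables (loss, dloss) of sigma2^2 with other parameters fixed.

    loss includes the constant (D N / 2) log 2 pi so it matches the NLL.
    """
    lams, energies, rest, n_rest = _sigma2_spectrum(params, data, mu_B)
    D, N = data.D, data.N
    const = 0.5 * D * N * np.log(2 * np.pi)

    def loss(v: float) -> float:
        return const + 0.5 * D * (np.sum(np.log(lams + v)) + n_rest * np.log(v)) \
            + 0.5 * (np.sum(energies / (lams + v)) + rest / v)

    def dloss(v: float) -> float:
        return 0.5 * D * (np.sum(1.0 / (lams + v)) + n_rest / v) \
            - 0.5 * (np.sum(energies / (lams + v) ** 2) + rest / v ** 2)

    return loss, dloss


def update_sigma2(params: ModelParams, data: EQTLDataset,
                  eps_var: float = EPS_VAR,
                  mu_B: np.ndarray | None = None) -> float:
    """Coordinate minimizer of the loss over sigma2^2, all else fixed.

    Uses the eigen-profile above: a log-spaced scan brackets the minimum and
    a bounded Brent refinement polishes it; the current value is kept when it
    is already optimal, so the step never increases the loss. Returns the
    variance floor when the residuals are (numerically) zero.
    """
    lams, energies, rest, n_rest = _sigma2_spectrum(params, data, mu_B)
    if energies.sum() + rest <= 0:
        return eps_var  # all residuals exactly zero: boundary solution
    loss, _ = sigma2_profile(params, data, mu_B)

    grid = np.geomspace(1e-8, 1e6, 400)
    grid = np.unique(np.append(grid, params.sigma2_sq))
    vals = np.array([loss(v) for v in grid])
    i = int(np.nanargmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(loss, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-12})
    candidates = [max(res.x, eps_var), max(grid[i], eps_var), params.sigma2_sq, eps_var]
    best = min(candidates, key=loss)
    return float(best)
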