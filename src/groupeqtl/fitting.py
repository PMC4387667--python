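"""End-to-end model fitting and model selection.

The penalized objective J + D (lambda ||A||_1 + gamma ||B||_1 + alpha ||C||_1)
is minimized by alternating (i) an OWL-QN pass over the stacked vector
[A, B, C, W, log sigma1^2] — L1 weights D*lambda, D*gamma, D*alpha on the
coefficient blocks, zero on W and the variance coordinate — with (ii) an
exact coordinate update of sigma2^2, until the relative objective change
falls below tolerance. Both stages are individually monotone, so the outer
trace never increases.

Model selection follows the protocol the model was designed for: a two-fold
cross-validated grid search over (lambda, gamma, alpha), and a 50/50
hold-out scan over the latent-variable counts (M, H) with an inner grid
search per combination, both scored by out-of-sample unpenalized loss.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import EQTLDataset
from .model import (EPS_VAR, ModelHyper, ModelParams,
                    NumericalDegeneracyError, mu_B_closed_form,
                    negative_log_likelihood, penalized_objective,
                    smooth_gradient, update_sigma2, fast_inverse)
from .owlqn import OwlqnProblem, owlqn_minimize

#: regularization grid used for tuning (lambda = gamma = alpha swept jointly
#: unless a full product grid is supplied)
DEFAULT_PENALTY_GRID = (0.1, 1.0, 10.0, 50.0, 100.0, 500.0, 1000.0, 2000.0)


@dataclass
class FitOptions:
    """Optimizer schedule and initialization knobs."""

    seed: int = 0
    #: "warm" seeds (A, B) from a truncated SVD of a ridge association
    #: estimate and W from residual principal components, escaping the
    #: saddle the bilinear group pathway has at the origin; "random" uses
    #: small Gaussians.
    init_strategy: str = "warm"
    init_scale: float = 0.01          # sd of the Gaussian initialization
    max_outer: int = 100
    tol_outer: float = 1e-6
    inner_max_iter: int = 150
    inner_tol: float = 1e-7
    memory: int = 10
    eps_var: float = EPS_VAR
    #: noise-variance floor as a fraction of the pooled expression variance.
    #: The likelihood is unbounded below once the coefficient degrees of
    #: freedom reach the sample count (sigma2 -> 0 interpolation); a floor
    #: relative to the data scale, read as a minimal measurement-noise
    #: level, keeps the fit away from that degenerate ray.
    rel_var_floor: float = 1e-3


@dataclass
class FitReport:
    """Diagnostics from one fit."""

    objective_trace: List[float] = field(default_factory=list)
    converged: bool = False
    n_outer_iterations: int = 0
    final_objective: float = float("nan")
    holdout_loss: float | None = None
    seed: int = 0


@dataclass
class AssociationMatrix:
    """Fitted associations: overall = group (B A) + individual (C)."""

    overall: np.ndarray
    group: np.ndarray
    individual: np.ndarray
    snp_ids: Sequence[str]
    gene_ids: Sequence[str]


class _ParamPacker:
    """Flatten/unflatten [A, B, C, W, log sigma1^2] for the optimizer."""

    def __init__(self, N: int, K: int, hyper: ModelHyper):
        self.N, self.K = N, K
        self.M, self.H = hyper.M, hyper.H
        self.with_C = hyper.variant == "model2"
        sizes = [self.M * K, N * self.M,
                 N * K if self.with_C else 0, N * self.H, 1]
        self.offsets = np.cumsum([0] + sizes)
        self.dim = int(self.offsets[-1])
        self.hyper = hyper

    def pack(self, params: ModelParams) -> np.ndarray:
        parts = [params.A.ravel(), params.B.ravel()]
        if self.with_C:
            parts.append(params.C.ravel())
        parts.append(params.W.ravel())
        parts.append([np.log(params.sigma1_sq)])
        return np.concatenate(parts)

    def unpack(self, w: np.ndarray, sigma2_sq: float) -> ModelParams:
        o = self.offsets
        A = w[o[0]:o[1]].reshape(self.M, self.K)
        B = w[o[1]:o[2]].reshape(self.N, self.M)
        C = w[o[2]:o[3]].reshape(self.N, self.K) if self.with_C \
            else np.zeros((self.N, self.K))
        W = w[o[3]:o[4]].reshape(self.N, self.H)
        log_s1 = min(float(w[o[4]]), 50.0)  # overflow guard
        return ModelParams(A=A, B=B, C=C, W=W, mu_B=np.zeros(self.N),
                           sigma1_sq=max(float(np.exp(log_s1)), EPS_VAR),
                           sigma2_sq=sigma2_sq)

    def l1_weights(self, D: int) -> np.ndarray:
        o = self.offsets
        c = np.zeros(self.dim)
        c[o[0]:o[1]] = D * self.hyper.lambda_A
        c[o[1]:o[2]] = D * self.hyper.gamma_B
        if self.with_C:
            c[o[2]:o[3]] = D * self.hyper.alpha_C
        return c


def initial_params(data: EQTLDataset, hyper: ModelHyper,
                   opts: FitOptions) -> ModelParams:
    """Starting point for the alternation.

    The bilinear group pathway B A has a stationary point at the origin
    (the gradient of each factor is proportional to the other), so a tiny
    random start can leave it permanently stuck under an L1 penalty. The
    default warm start therefore factorizes a ridge-regression association
    estimate: its top-M SVD seeds (B, A), the top-H principal components of
    the ridge residual seed W, and C starts at zero so individual effects
    only enter where the penalty lets them.
    """
    rng = np.random.default_rng(opts.seed)
    N, K, M, H = data.N, data.K, hyper.M, hyper.H
    s = opts.init_scale
    if opts.init_strategy == "random":
        return ModelParams(
            A=s * rng.standard_normal((M, K)),
            B=s * rng.standard_normal((N, M)),
            C=s * rng.standard_normal((N, K)) if hyper.variant == "model2"
            else np.zeros((N, K)),
            W=s * rng.standard_normal((N, H)),
            mu_B=np.zeros(N), sigma1_sq=1.0, sigma2_sq=1.0,
        )
    if opts.init_strategy != "warm":
        raise ValueError(f"unknown init_strategy {opts.init_strategy!r}")
    Xc, Zc = data.centered()
    gram = Xc @ Xc.T
    ridge = 1e-2 * max(np.trace(gram) / max(K, 1), 1.0)
    R_hat = np.linalg.solve(gram + ridge * np.eye(K), Xc @ Zc.T).T
    if M > 0:
        U, sv, Vt = np.linalg.svd(R_hat, full_matrices=False)
        r = min(M, sv.size)
        B0 = np.zeros((N, M))
        A0 = np.zeros((M, K))
        B0[:, :r] = U[:, :r] * np.sqrt(sv[:r])
        A0[:r, :] = np.sqrt(sv[:r])[:, None] * Vt[:r, :]
        # unused factor columns get a small random kick
        B0[:, r:] = s * rng.standard_normal((N, M - r))
        A0[r:, :] = s * rng.standard_normal((M - r, K))
    else:
        B0 = np.zeros((N, 0))
        A0 = np.zeros((0, K))
    resid = Zc - (B0 @ A0) @ Xc
    if H > 0:
        Ur, sr, _ = np.linalg.svd(resid / np.sqrt(max(data.D - 1, 1)),
                                  full_matrices=False)
        r = min(H, sr.size)
        W0 = np.zeros((N, H))
        W0[:, :r] = Ur[:, :r] * sr[:r]
        W0[:, r:] = s * rng.standard_normal((N, H - r))
        resid_var = max(float(np.var(resid)) - float(np.sum(sr[:r] ** 2)) / N,
                        EPS_VAR)
    else:
        W0 = np.zeros((N, 0))
        resid_var = max(float(np.var(resid)), EPS_VAR)
    return ModelParams(
        A=A0, B=B0, C=np.zeros((N, K)), W=W0, mu_B=np.zeros(N),
        sigma1_sq=max(s ** 2, EPS_VAR), sigma2_sq=max(resid_var, EPS_VAR),
    )


def fit_model(data: EQTLDataset, hyper: ModelHyper,
              opts: FitOptions | None = None,
              init: ModelParams | None = None
              ) -> Tuple[ModelParams, FitReport]:
    """Fit the model by alternating OWL-QN and the sigma2^2 coordinate step."""
    opts = opts or FitOptions()
    packer = _ParamPacker(data.N, data.K, hyper)
    params = init if init is not None else initial_params(data, hyper, opts)
    var_floor = max(opts.eps_var, opts.rel_var_floor * float(np.var(data.Z)))
    sigma2_sq = max(params.sigma2_sq, var_floor)

    def make_value_and_grad(sig2: float):
        def value_and_grad(w: np.ndarray):
            try:
                p = packer.unpack(w, sig2)
                val = negative_log_likelihood(p, data)
                g = smooth_gradient(p, data)
            except (NumericalDegeneracyError, np.linalg.LinAlgError,
                    ValueError):
                # overshooting line-search trial (e.g. exp(log sigma1^2)
                # overflow): report +inf so the step is rejected
                return np.inf, np.zeros(packer.dim)
            parts = [g.A.ravel(), g.B.ravel()]
            if packer.with_C:
                parts.append(g.C.ravel())
            parts.append(g.W.ravel())
            parts.append([g.log_sigma1_sq])
            return val, np.concatenate(parts)
        return value_and_grad

    report = FitReport(seed=opts.seed)
    w = packer.pack(params)
    obj = penalized_objective(packer.unpack(w, sigma2_sq), data, hyper)
    report.objective_trace.append(obj)

    for outer in range(1, opts.max_outer + 1):
        res = owlqn_minimize(OwlqnProblem(
            dim=packer.dim,
            smooth_value_and_grad=make_value_and_grad(sigma2_sq),
            l1_weight=packer.l1_weights(data.D),
            init=w, memory=opts.memory,
            max_iter=opts.inner_max_iter, tol_rel=opts.inner_tol,
        ))
        w = res.x
        params = packer.unpack(w, sigma2_sq)
        sigma2_new = update_sigma2(params, data, eps_var=var_floor)
        sigma2_sq = max(sigma2_new, var_floor)
        params = packer.unpack(w, sigma2_sq)
        obj_new = penalized_objective(params, data, hyper)
        if not np.isfinite(obj_new):
            raise RuntimeError("objective diverged during fitting")
        report.objective_trace.append(obj_new)
        report.n_outer_iterations = outer
        rel = abs(obj - obj_new) / max(abs(obj_new), 1.0)
        obj = obj_new
        if rel < opts.tol_outer:
            report.converged = True
            break

    params.mu_B = mu_B_closed_form(params, data)
    report.final_objective = obj
    return params, report


def extract_associations(params: ModelParams,
                         snp_ids: Sequence[str] | None = None,
                         gene_ids: Sequence[str] | None = None
                         ) -> AssociationMatrix:
    """Split the fitted effects into group (B A) and individual (C) parts."""
    group = params.B @ params.A if params.M > 0 else np.zeros_like(params.C)
    overall = group + params.C
    N, K = overall.shape
    snp_ids = list(snp_ids) if snp_ids is not None else [f"snp{i}" for i in range(K)]
    gene_ids = list(gene_ids) if gene_ids is not None else [f"gene{j}" for j in range(N)]
    return AssociationMatrix(overall=overall, group=group,
                             individual=params.C.copy(),
                             snp_ids=snp_ids, gene_ids=gene_ids)


def out_of_sample_loss(params: ModelParams, data: EQTLDataset) -> float:
    """Unpenalized loss of held-out samples under a fitted model.

    Uses the training-set intercept mu_B stored in ``params``.
    """
    return negative_log_likelihood(params, data, mu_B=params.mu_B)


def _fold_indices(D: int, folds: int, seed: int) -> List[np.ndarray]:
    """Contiguous blocks of a seeded sample permutation."""
    perm = np.random.default_rng(seed).permutation(D)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


def grid_search(data: EQTLDataset,
                grid: Iterable[Tuple[float, float, float]] | None,
                M: int, H: int, variant: str = "model2",
                folds: int = 2, seed: int = 0,
                opts: FitOptions | None = None
                ) -> Tuple[ModelHyper, pd.DataFrame]:
    """Cross-validated search over (lambda, gamma, alpha).

    For each grid point the model is trained on folds-1 folds and scored by
    the out-of-sample unpenalized loss on the held-out fold; the mean across
    folds is minimized. ``grid=None`` sweeps the default penalty values with
    lambda = gamma = alpha tied.
    """
    if grid is None:
        grid = [(v, v, v) for v in DEFAULT_PENALTY_GRID]
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if data.D < 2 * folds:
        raise ValueError("need at least 2 samples per fold")
    opts = opts or FitOptions()
    fold_idx = _fold_indices(data.D, folds, seed)
    rows = []
    for lam, gam, alp in grid:
        hyper = ModelHyper(M=M, H=H, lambda_A=lam, gamma_B=gam,
                           alpha_C=alp, variant=variant)
        losses = []
        for f in range(folds):
            test_idx = fold_idx[f]
            train_idx = np.sort(np.concatenate(
                [fold_idx[g] for g in range(folds) if g != f]))
            params, _ = fit_model(data.subset_samples(train_idx), hyper, opts)
            losses.append(out_of_sample_loss(params, data.subset_samples(test_idx)))
        rows.append({"lambda_A": lam, "gamma_B": gam, "alpha_C": alp,
                     "mean_holdout_loss": float(np.mean(losses))})
    table = pd.DataFrame(rows)
    best = table["mean_holdout_loss"].idxmin()
    lam, gam, alp = table.loc[best, ["lambda_A", "gamma_B", "alpha_C"]]
    return ModelHyper(M=M, H=H, lambda_A=lam, gamma_B=gam, alpha_C=alp,
                      variant=variant), table


def select_latent_counts(data: EQTLDataset,
                         M_candidates: Sequence[int],
                         H_candidates: Sequence[int],
                         variant: str = "model2",
                         grid: Iterable[Tuple[float, float, float]] | None = None,
                         seed: int = 0,
                         opts: FitOptions | None = None
                         ) -> Tuple[Tuple[int, int], pd.DataFrame]:
    """Hold-out scan over latent-variable counts.

    Samples are split 50/50 (seeded permutation); for every (M, H) pair an
    inner grid search tunes the penalties on the training half, the model is
    refit at the tuned penalties and scored on the held-out half. Returns the
    minimizing pair plus the full loss surface (no pruning).
    """
    if not list(M_candidates) or not list(H_candidates):
        raise ValueError("candidate lists must be nonempty")
    opts = opts or FitOptions()
    half_a, half_b = _fold_indices(data.D, 2, seed)
    train, test = data.subset_samples(half_a), data.subset_samples(half_b)
    rows = []
    for M, H in itertools.product(M_candidates, H_candidates):
        best_hyper, _ = grid_search(train, grid, M=M, H=H, variant=variant,
                                    folds=2, seed=seed, opts=opts)
        params, _ = fit_model(train, best_hyper, opts)
        loss = out_of_sample_loss(params, test)
        rows.append({"M": M, "H": H, "holdout_loss": loss,
                     "lambda_A": best_hyper.lambda_A,
                     "gamma_B": best_hyper.gamma_B,
                     "alpha_C": best_hyper.alpha_C})
    surface = pd.DataFrame(rows)
    best = surface["holdout_loss"].idxmin()
    return (int(surface.loc[best, "M"]), int(surface.loc[best, "H"])), surface


def penalty_path_max(data: EQTLDataset) -> float:
    """Scale of the smallest penalty that zeroes all coefficients.

    The gradient of the centered loss w.r.t. C at zero coefficients and unit
    noise variance is -Zc Xc^T, so max |Zc Xc^T| / D is the lasso-style path
    endpoint used to express penalties as fractions of the path maximum.
    """
    Xc, Zc = data.centered()
    return float(np.abs(Zc @ Xc.T).max() / data.D)
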