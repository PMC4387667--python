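"""Synthetic eQTL data generation.

Emulates the simulation design used to benchmark the model: binomial
genotypes, a block-structured true association matrix beta (dense blocks =
group-wise SNP-set/gene-set links, diagonal entries = individual cis links),
low-rank non-genetic confounding Xi with row covariance rho * F F^T, and
i.i.d. Gaussian noise E with variance eta. Expression is
Z = beta X + Xi + E and the signal-to-noise ratio is
SNR = sqrt(Var(beta X) / Var(Xi + E)).

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .data import EQTLDataset

Block = Tuple[Sequence[int], Sequence[int]]


def default_blocks() -> List[Block]:
    """Four group-wise association blocks of increasing scale (10..25)."""
    sizes = [10, 15, 20, 25]
    blocks: List[Block] = []
    start = 0
    for s in sizes:
        blocks.append((list(range(start, start + s)), list(range(start, start + s))))
        start += s
    return blocks


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults: 100 SNPs with 112 samples (the scale of a yeast segregant
    panel), 100 genes, four group blocks plus diagonal cis links of strength
    1, noise variance eta = 0.1, confounder scale rho = 0.1 with U = 10
    hidden factors.
    """

    K: int = 100
    N: int = 100
    D: int = 112
    maf_range: Tuple[float, float] = (0.05, 0.5)
    blocks: List[Block] = field(default_factory=default_blocks)
    diagonal_cis: bool = True
    strength: float = 1.0
    eta: float = 0.1
    rho: float = 0.1
    U: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strength <= 0:
            raise ValueError("strength must be positive")
        if self.eta < 0 or self.rho < 0 or self.U < 0:
            raise ValueError("eta, rho and U must be nonnegative")
        for snps, genes in self.blocks:
            if min(snps, default=0) < 0 or max(snps, default=0) >= self.K:
                raise ValueError("block SNP indices out of range")
            if min(genes, default=0) < 0 or max(genes, default=0) >= self.N:
                raise ValueError("block gene indices out of range")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated expression matrix."""

    beta: np.ndarray          # N x K true associations
    Xi: np.ndarray            # N x D confounder contribution
    E: np.ndarray             # N x D noise
    F: np.ndarray             # D x U confounder factor matrix
    snr_realized: float

    @property
    def support(self) -> np.ndarray:
        """Boolean N x K mask of true associations."""
        return self.beta != 0


def simulate_genotypes(K: int, D: int,
                       maf_range: Tuple[float, float] = (0.05, 0.5),
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """K x D dosage matrix: per-SNP MAF ~ U(maf_range), dosage ~ Binomial(2, maf)."""
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    maf = rng.uniform(lo, hi, size=K)
    return rng.binomial(2, maf[:, None], size=(K, D)).astype(float)


def make_block_beta(config: SimConfig) -> np.ndarray:
    """True association matrix: dense blocks plus optional diagonal cis entries.

    Overlapping blocks are allowed (a SNP or gene may join several groups);
    entries are set to ``strength``, not summed.
    """
    beta = np.zeros((config.N, config.K))
    for snps, genes in config.blocks:
        beta[np.ix_(list(genes), list(snps))] = config.strength
    if config.diagonal_cis:
        j = np.arange(min(config.N, config.K))
        beta[j, j] = config.strength
    return beta


def snr(beta: np.ndarray, X: np.ndarray, Xi: np.ndarray, E: np.ndarray) -> float:
    """sqrt(Var(beta X) / Var(Xi + E)), variances pooled over all matrix entries."""
    signal_var = float(np.var(beta @ X))
    noise_var = float(np.var(Xi + E))
    if noise_var == 0:
        raise ValueError("noise variance is zero; SNR undefined")
    return float(np.sqrt(signal_var / noise_var))


def simulate_expression(X: np.ndarray, config: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> Tuple[np.ndarray, SimTruth]:
    """Draw Z = beta X + Xi + E with low-rank confounding.

    Xi rows are N(0, rho * F F^T) with F_ij ~ N(0,1), F of shape D x U;
    E entries are N(0, eta).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    D = X.shape[1]
    beta = make_block_beta(config)
    F = rng.standard_normal((D, config.U))
    if config.U > 0 and config.rho > 0:
        # row Xi_j = sqrt(rho) F g_j with g_j ~ N(0, I_U) gives cov rho F F^T
        Xi = np.sqrt(config.rho) * rng.standard_normal((config.N, config.U)) @ F.T
    else:
        Xi = np.zeros((config.N, D))
    E = np.sqrt(config.eta) * rng.standard_normal((config.N, D)) \
        if config.eta > 0 else np.zeros((config.N, D))
    Z = beta @ X + Xi + E
    noise_tot = Xi + E
    realized = snr(beta, X, Xi, E) if np.var(noise_tot) > 0 else np.inf
    return Z, SimTruth(beta=beta, Xi=Xi, E=E, F=F, snr_realized=realized)


def simulate_dataset(config: SimConfig) -> Tuple[EQTLDataset, SimTruth]:
    """Genotypes + expression + truth from a single seed."""
    rng = np.random.default_rng(config.seed)
    X = simulate_genotypes(config.K, config.D, config.maf_range, rng)
    Z, truth = simulate_expression(X, config, rng)
    data = EQTLDataset(X=X, Z=Z)
    return data, truth


def shrinkage_toy(D: int = 100, seed: int = 0
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seven-predictor single-response example for studying L1 shrinkage.

    Predictors x_i ~ N(0, 0.6 I); response
    z = 5 (x1 + x2) - 3 (x3 + x4) + 2 x5 + eps, eps ~ N(0, I):
    two predictor groups ({x1,x2}, {x3,x4}), one individual predictor (x5)
    and two null predictors. Returns (X of shape 7 x D, z of shape 1 x D,
    truth coefficient vector [5, 5, -3, -3, 2, 0, 0]).
    """
    if D < 10:
        raise ValueError("D must be >= 10")
    rng = np.random.default_rng(seed)
    X = np.sqrt(0.6) * rng.standard_normal((7, D))
    eps = rng.standard_normal(D)
    truth = np.array([5.0, 5.0, -3.0, -3.0, 2.0, 0.0, 0.0])
    z = truth @ X + eps
    return X, z[None, :], truth
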