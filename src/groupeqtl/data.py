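"""Paired genotype/expression data container.

Orientation follows the eQTL convention used throughout the package:
features are rows, samples are columns. Genotypes are minor-allele dosages
in {0, 1, 2}; expression values are arbitrary finite reals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

import numpy as np

Position = Tuple[str, int]  # (chromosome, base-pair)


@dataclass
class EQTLDataset:
    """K SNPs x D samples of genotypes paired with N genes x D samples of expression.

    Parameters
    ----------
    X : ndarray of shape (K, D)
        Genotype dosage matrix, entries in {0, 1, 2}, no missing values.
    Z : ndarray of shape (N, D)
        Expression matrix, finite reals.
    snp_ids, gene_ids : sequence of str
        Row identifiers for X and Z.
    snp_pos, gene_pos : mapping id -> (chrom, pos), optional
        Genomic coordinates for cis/trans analysis; 1-based base pairs.
    """

    X: np.ndarray
    Z: np.ndarray
    snp_ids: Sequence[str] = field(default=None)
    gene_ids: Sequence[str] = field(default=None)
    snp_pos: Mapping[str, Position] | None = None
    gene_pos: Mapping[str, Position] | None = None
    #: continuous predictor panels (methodological experiments) may disable
    #: the {0,1,2} dosage check
    validate_genotypes: bool = True

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        if self.X.ndim != 2 or self.Z.ndim != 2:
            raise ValueError("X and Z must be 2-D matrices")
        if self.X.shape[1] != self.Z.shape[1]:
            raise ValueError(
                f"X has {self.X.shape[1]} samples but Z has {self.Z.shape[1]}"
            )
        if not np.isfinite(self.X).all():
            raise ValueError("genotype matrix contains non-finite values")
        if self.validate_genotypes and not np.isin(self.X, (0.0, 1.0, 2.0)).all():
            bad = np.argwhere(~np.isin(self.X, (0.0, 1.0, 2.0)))[0]
            raise ValueError(
                f"genotype entry at row {bad[0]}, column {bad[1]} is not in {{0,1,2}}"
            )
        if not np.isfinite(self.Z).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.snp_ids is None:
            self.snp_ids = [f"snp{i}" for i in range(self.K)]
        if self.gene_ids is None:
            self.gene_ids = [f"gene{j}" for j in range(self.N)]
        self.snp_ids = list(self.snp_ids)
        self.gene_ids = list(self.gene_ids)
        if len(self.snp_ids) != self.K:
            raise ValueError("snp_ids length does not match X rows")
        if len(self.gene_ids) != self.N:
            raise ValueError("gene_ids length does not match Z rows")

    @property
    def K(self) -> int:
        return self.X.shape[0]

    @property
    def N(self) -> int:
        return self.Z.shape[0]

    @property
    def D(self) -> int:
        return self.X.shape[1]

    @property
    def x_bar(self) -> np.ndarray:
        """Per-SNP mean genotype over samples (length K)."""
        return self.X.mean(axis=1)

    @property
    def z_bar(self) -> np.ndarray:
        """Per-gene mean expression over samples (length N)."""
        return self.Z.mean(axis=1)

    def centered(self) -> tuple[np.ndarray, np.ndarray]:
        """Column-centered (X - x_bar, Z - z_bar)."""
        return (self.X - self.x_bar[:, None], self.Z - self.z_bar[:, None])

    def subset_samples(self, idx: np.ndarray) -> "EQTLDataset":
        """Dataset restricted to the sample columns in ``idx`` (order kept)."""
        return EQTLDataset(
            X=self.X[:, idx],
            Z=self.Z[:, idx],
            snp_ids=self.snp_ids,
            gene_ids=self.gene_ids,
            snp_pos=self.snp_pos,
            gene_pos=self.gene_pos,
            validate_genotypes=self.validate_genotypes,
        )
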