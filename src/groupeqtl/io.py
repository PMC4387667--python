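"""TSV exchange formats.

Matrices are stored features-as-rows, samples-as-columns (K x D genotype,
N x D expression) with the feature id in the first column and sample ids in
the header row. Genomic positions use a BED-like three-column TSV
(chrom, pos, id) with 1-based positions. Associations are written as ranked
(snp, gene, weight) tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import EQTLDataset, Position
from .fitting import AssociationMatrix


@dataclass
class RunConfig:
    """A JSON-loadable analysis configuration.

    Referenced paths are checked at load time; the seed is recorded in every
    output the CLI writes.
    """

    genotype: str
    expression: str
    snp_positions: str | None = None
    gene_positions: str | None = None
    output_dir: str = "."
    M: int = 10
    H: int = 10
    variant: str = "model2"
    penalty_grid: list = None
    M_candidates: list = None
    H_candidates: list = None
    seed: int = 0
    nonzero_threshold: float = 1e-8
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        import json

        cfg = cls(**json.loads(Path(path).read_text()))
        for p in (cfg.genotype, cfg.expression, cfg.snp_positions,
                  cfg.gene_positions):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")
        return cfg


def read_matrix_tsv(path: str | Path, kind: str = "expression"
                    ) -> Tuple[np.ndarray, list, list]:
    """Read a feature x sample matrix; returns (matrix, feature_ids, sample_ids).

    ``kind='genotype'`` additionally validates that every entry is in
    {0, 1, 2}, reporting the offending cell on failure.
    """
    if kind not in ("genotype", "expression"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    mat = df.to_numpy(dtype=float)
    if not np.isfinite(mat).all():
        j, k = np.argwhere(~np.isfinite(mat))[0]
        raise ValueError(
            f"non-finite value at row {df.index[j]!r}, column {df.columns[k]!r}")
    if kind == "genotype" and not np.isin(mat, (0.0, 1.0, 2.0)).all():
        j, k = np.argwhere(~np.isin(mat, (0.0, 1.0, 2.0)))[0]
        raise ValueError(
            f"genotype value {mat[j, k]!r} at row {df.index[j]!r}, "
            f"column {df.columns[k]!r} is not in {{0,1,2}}")
    return mat, [str(i) for i in df.index], [str(c) for c in df.columns]


def write_matrix_tsv(path: str | Path, matrix: np.ndarray,
                     feature_ids: Sequence[str], sample_ids: Sequence[str]) -> None:
    pd.DataFrame(matrix, index=list(feature_ids),
                 columns=list(sample_ids)).to_csv(path, sep="\t")


def read_positions(path: str | Path) -> Dict[str, Position]:
    """BED-like TSV (chrom, pos, id; 1-based pos) -> {id: (chrom, pos)}."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["chrom", "pos", "id"], dtype={"chrom": str})
    return {str(r.id): (str(r.chrom), int(r.pos)) for r in df.itertuples()}


def write_positions(path: str | Path, positions: Dict[str, Position]) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom\tpos\tid (1-based positions)\n")
        for fid, (chrom, pos) in positions.items():
            fh.write(f"{chrom}\t{pos}\t{fid}\n")


def write_truth_tsv(path: str | Path, beta: np.ndarray,
                    snp_ids: Sequence[str], gene_ids: Sequence[str]) -> None:
    """Nonzero ground-truth associations as (snp_id, gene_id, beta) rows."""
    rows = [(snp_ids[k], gene_ids[j], beta[j, k])
            for j, k in zip(*np.nonzero(beta))]
    pd.DataFrame(rows, columns=["snp_id", "gene_id", "beta"]).to_csv(
        path, sep="\t", index=False)


def read_truth_tsv(path: str | Path, snp_ids: Sequence[str],
                   gene_ids: Sequence[str]) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    beta = np.zeros((len(gene_ids), len(snp_ids)))
    srow = {s: i for i, s in enumerate(snp_ids)}
    grow = {g: j for j, g in enumerate(gene_ids)}
    for r in df.itertuples():
        beta[grow[str(r.gene_id)], srow[str(r.snp_id)]] = r.beta
    return beta


def associations_frame(assoc: AssociationMatrix,
                       top_k: int | None = None,
                       threshold: float | None = None) -> pd.DataFrame:
    """Ranked association table (descending |overall|, lexicographic ties)."""
    N, K = assoc.overall.shape
    rows = []
    for j in range(N):
        for k in range(K):
            rows.append((assoc.snp_ids[k], assoc.gene_ids[j],
                         assoc.overall[j, k], assoc.group[j, k],
                         assoc.individual[j, k]))
    df = pd.DataFrame(rows, columns=["snp_id", "gene_id", "weight_overall",
                                     "weight_group", "weight_individual"])
    df["abs_weight"] = df["weight_overall"].abs()
    df = df.sort_values(["abs_weight", "snp_id", "gene_id"],
                        ascending=[False, True, True], kind="mergesort")
    df = df.drop(columns="abs_weight").reset_index(drop=True)
    if threshold is not None:
        df = df[df["weight_overall"].abs() > threshold]
    if top_k is not None:
        df = df.head(top_k)
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def write_associations(assoc: AssociationMatrix, path: str | Path,
                       top_k: int | None = None,
                       threshold: float | None = None) -> None:
    associations_frame(assoc, top_k=top_k, threshold=threshold).to_csv(
        path, sep="\t", index=False)


def read_associations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_dataset(genotype_path: str | Path, expression_path: str | Path,
                 snp_pos_path: str | Path | None = None,
                 gene_pos_path: str | Path | None = None) -> EQTLDataset:
    X, snp_ids, samples_x = read_matrix_tsv(genotype_path, kind="genotype")
    Z, gene_ids, samples_z = read_matrix_tsv(expression_path, kind="expression")
    if samples_x != samples_z:
        raise ValueError("genotype and expression sample ids differ")
    return EQTLDataset(
        X=X, Z=Z, snp_ids=snp_ids, gene_ids=gene_ids,
        snp_pos=read_positions(snp_pos_path) if snp_pos_path else None,
        gene_pos=read_positions(gene_pos_path) if gene_pos_path else None,
    )
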