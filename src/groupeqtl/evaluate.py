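"""Scoring fitted associations against truth and enrichment statistics.

Covers the evaluation toolkit around the model: ROC / precision-recall AUCs
of |association weight| against a known support, per-SNP regulatory degrees
and hotspot consistency between two studies, the two-step cis-enrichment
test (per-SNP one-tailed Mann-Whitney on hypothesis ranks, then a paired
two-tailed Wilcoxon signed-rank across SNPs), and a generic permutation
null for FDR curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics

from .data import EQTLDataset, Position
from .fitting import AssociationMatrix, FitOptions, extract_associations, fit_model
from .model import ModelHyper


@dataclass
class RankedAssociations:
    """(snp_id, gene_id, |weight|) triples sorted by descending score.

    Ties are broken by (snp_id, gene_id) lexicographic order so rankings are
    deterministic.
    """

    entries: List[Tuple[str, str, float]]

    def __post_init__(self) -> None:
        if any(s < 0 for _, _, s in self.entries):
            raise ValueError("scores must be nonnegative")
        self.entries = sorted(self.entries, key=lambda t: (-t[2], t[0], t[1]))

    def ranks(self) -> Dict[Tuple[str, str], int]:
        """1-based rank of each (snp, gene) hypothesis; 1 = strongest."""
        return {(s, g): i + 1 for i, (s, g, _) in enumerate(self.entries)}


def rank_associations(assoc: AssociationMatrix) -> RankedAssociations:
    """All N*K hypotheses ranked by |overall weight|."""
    N, K = assoc.overall.shape
    entries = [(assoc.snp_ids[k], assoc.gene_ids[j], float(abs(assoc.overall[j, k])))
               for j in range(N) for k in range(K)]
    return RankedAssociations(entries=entries)


def roc_pr_auc(scores: np.ndarray, truth_support: np.ndarray
               ) -> Tuple[float, float, dict]:
    """ROC-AUC and PR-AUC of |scores| against a binary truth mask.

    ROC area is trapezoidal over the distinct-score threshold sweep; PR area
    uses the standard step interpolation (average precision). Returns the
    curves as well.
    """
    y = np.asarray(truth_support).ravel().astype(int)
    s = np.abs(np.asarray(scores, dtype=float)).ravel()
    if y.min() == y.max():
        raise ValueError("truth must contain at least one positive and one negative")
    if s.shape != y.shape:
        raise ValueError("scores and truth must have the same shape")
    fpr, tpr, roc_thr = skmetrics.roc_curve(y, s)
    precision, recall, pr_thr = skmetrics.precision_recall_curve(y, s)
    roc_auc = float(skmetrics.auc(fpr, tpr))
    pr_auc = float(skmetrics.average_precision_score(y, s))
    curves = {"fpr": fpr, "tpr": tpr, "roc_thresholds": roc_thr,
              "precision": precision, "recall": recall, "pr_thresholds": pr_thr}
    return roc_auc, pr_auc, curves


def regulatory_degree(assoc: AssociationMatrix, threshold: float = 1e-8
                      ) -> Dict[str, int]:
    """Number of genes each SNP is associated with (|overall| > threshold)."""
    counts = (np.abs(assoc.overall) > threshold).sum(axis=0)
    return {sid: int(c) for sid, c in zip(assoc.snp_ids, counts)}


def _top_snps(degrees: Mapping[str, int], T: int) -> set:
    order = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    return {sid for sid, _ in order[:T]}


def trans_consistency(degrees1: Mapping[str, int], degrees2: Mapping[str, int],
                      T: int) -> float:
    """Hotspot overlap |S1^T  intersect  S2^T| / T between two degree rankings."""
    if set(degrees1) != set(degrees2):
        raise ValueError("degree dictionaries must cover the same SNPs")
    if not 1 <= T <= len(degrees1):
        raise ValueError("T must be in [1, number of SNPs]")
    return len(_top_snps(degrees1, T) & _top_snps(degrees2, T)) / T


@dataclass
class EnrichmentResult:
    """Per-SNP cis-vs-trans Mann-Whitney p-values for two models and the
    paired Wilcoxon comparison of those p-value vectors."""

    pvalues1: Dict[str, float]
    pvalues2: Dict[str, float]
    wilcoxon_p: float
    skipped_snps: List[str] = field(default_factory=list)


def is_cis(snp: Position, gene: Position, cis_window: int = 500) -> bool:
    """Same chromosome and |snp pos - gene start| < window (bp)."""
    return snp[0] == gene[0] and abs(int(snp[1]) - int(gene[1])) < cis_window


def _mannwhitney_cis(ranks: Mapping[Tuple[str, str], int], snp: str,
                     cis_genes: Sequence[str], trans_genes: Sequence[str]) -> float:
    cis_r = [ranks[(snp, g)] for g in cis_genes]
    trans_r = [ranks[(snp, g)] for g in trans_genes]
    # smaller rank = stronger association; alternative: cis ranked better
    exact_ok = (len(cis_r) < 25 and len(trans_r) < 25
                and len(set(cis_r + trans_r)) == len(cis_r) + len(trans_r))
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(cis_r, trans_r, alternative="less", method=method)
    return float(res.pvalue)


def cis_trans_enrichment(ranked1: RankedAssociations, ranked2: RankedAssociations,
                         snp_pos: Mapping[str, Position],
                         gene_pos: Mapping[str, Position],
                         cis_window: int = 500) -> EnrichmentResult:
    """Two-step cis-enrichment comparison of two models.

    Step 1: per model and per SNP, a one-tailed Mann-Whitney test of the
    null that the model ranks its cis hypotheses no better than its trans
    hypotheses. Step 2: a two-tailed paired Wilcoxon signed-rank test across
    SNPs on the step-1 p-value pairs; p = 1 is reported when every pair is
    identical (no nonzero differences). SNPs lacking either a cis or a trans
    hypothesis are skipped and recorded.
    """
    ranks1, ranks2 = ranked1.ranks(), ranked2.ranks()
    snps = sorted({s for s, _, _ in ranked1.entries})
    genes = sorted({g for _, g, _ in ranked1.entries})
    p1: Dict[str, float] = {}
    p2: Dict[str, float] = {}
    skipped: List[str] = []
    for snp in snps:
        cis_genes = [g for g in genes if is_cis(snp_pos[snp], gene_pos[g], cis_window)]
        trans_genes = [g for g in genes if g not in set(cis_genes)]
        if not cis_genes or not trans_genes:
            skipped.append(snp)
            continue
        p1[snp] = _mannwhitney_cis(ranks1, snp, cis_genes, trans_genes)
        p2[snp] = _mannwhitney_cis(ranks2, snp, cis_genes, trans_genes)
    if not p1:
        raise ValueError("no SNP has both cis and trans hypotheses")
    d = np.array([p1[s] - p2[s] for s in p1])
    if np.all(d == 0):
        wp = 1.0
    else:
        nz = d[d != 0]
        mode = "exact" if nz.size < 25 and nz.size > 0 else "approx"
        wp = float(stats.wilcoxon(nz, alternative="two-sided", method=mode).pvalue)
    return EnrichmentResult(pvalues1=p1, pvalues2=p2, wilcoxon_p=wp,
                            skipped_snps=skipped)


def permutation_fdr(data: EQTLDataset, hyper: ModelHyper, n_perm: int,
                    seed: int = 0, thresholds: np.ndarray | None = None,
                    opts: FitOptions | None = None) -> pd.DataFrame:
    """Permutation-null FDR curve for association weights.

    Refits the model on datasets whose expression sample columns are
    permuted (breaking genotype-expression links while keeping the
    expression covariance), and estimates
    FDR(t) = mean null count of |weight| > t / observed count of |weight| > t,
    clipped to [0, 1], reported as 0 where the observed count is zero, and
    made monotone nonincreasing in t by a running minimum. This is generic
    permutation plumbing, not a calibrated eQTL FDR procedure.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    opts = opts or FitOptions()
    params, _ = fit_model(data, hyper, opts)
    obs = np.abs(extract_associations(params).overall).ravel()
    if thresholds is None:
        thresholds = np.quantile(obs[obs > 0], np.linspace(0, 0.99, 25)) \
            if (obs > 0).any() else np.array([0.0])
    thresholds = np.sort(np.unique(thresholds))
    rng = np.random.default_rng(seed)
    null_counts = np.zeros_like(thresholds, dtype=float)
    for _ in range(n_perm):
        perm = rng.permutation(data.D)
        permuted = EQTLDataset(X=data.X, Z=data.Z[:, perm],
                               snp_ids=data.snp_ids, gene_ids=data.gene_ids,
                               validate_genotypes=data.validate_genotypes)
        p_null, _ = fit_model(permuted, hyper, opts)
        null = np.abs(extract_associations(p_null).overall).ravel()
        null_counts += np.array([(null > t).sum() for t in thresholds])
    null_counts /= n_perm
    obs_counts = np.array([(obs > t).sum() for t in thresholds], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(obs_counts > 0, null_counts / obs_counts, 0.0)
    fdr = np.clip(fdr, 0.0, 1.0)
    fdr = np.minimum.accumulate(fdr)  # monotone nonincreasing in t
    return pd.DataFrame({"threshold": thresholds, "fdr": fdr,
                         "observed_count": obs_counts, "null_count": null_counts})
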