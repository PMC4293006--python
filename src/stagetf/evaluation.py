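"""Cross-validated prediction of expression and stage-dependent changes.

Both samples and genes are partitioned into k folds (sample folds
stratified by stage).  For fold t the test cell is (gene fold t, sample
fold t): TF activity coefficients are estimated on training genes x
training samples only, per-gene coefficients of held-out genes are then
estimated on training samples with the TF coefficients held fixed, and
predictions are issued for held-out genes on held-out samples.  Held-out
genes therefore never inform the TF coefficients, and held-out samples
never inform any coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import ks_compare
from .errors import ValidationError
from .io_datasets import OmicsDataset, TFTargetMap
from .model import fit_integrative, fit_tf_only
from .synthetic import permute_expression

logger = logging.getLogger(__name__)

MODEL_TAGS = ("integrative", "tf_only", "random")


@dataclass
class CVReport:
    """Per-gene held-out Spearman correlations plus the sparse matrix of
    held-out predictions (NaN where a cell was never predicted)."""

    model: str
    per_gene: pd.DataFrame  # index gene_id, columns rho, n_test
    predicted: np.ndarray  # (genes, samples), NaN outside test cells
    k: int
    seed: int

    @property
    def mean_rho(self) -> float:
        return float(self.per_gene["rho"].mean())

    @property
    def median_rho(self) -> float:
        return float(self.per_gene["rho"].median())

    def summary(self) -> dict:
        return {
            "model": self.model,
            "k": self.k,
            "seed": self.seed,
            "n_genes": int(len(self.per_gene)),
            "mean_spearman": self.mean_rho,
            "median_spearman": self.median_rho,
        }


def _stratified_sample_folds(
    stage: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold label per sample; every fold gets samples from both stages."""
    fold = np.empty(len(stage), dtype=int)
    for label in ("I", "IV"):
        idx = np.flatnonzero(stage == label)
        if idx.size < k:
            raise ValidationError(
                f"cannot build {k} stratified folds with {idx.size} stage-{label} samples"
            )
        idx = rng.permutation(idx)
        fold[idx] = np.arange(idx.size) % k
    return fold


def _gene_folds(n_genes: int, k: int, rng: np.random.Generator) -> np.ndarray:
    if n_genes < k:
        raise ValidationError(f"cannot build {k} gene folds with {n_genes} genes")
    return rng.permutation(np.arange(n_genes) % k)


def _per_gene_fit(
    train: OmicsDataset, tf_shift: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """2-parameter least squares per gene on training samples, with the TF
    contribution (per-gene stage-IV offset) fixed."""
    C, M = train.cnv, train.methylation
    s_iv = train.stage_iv.astype(float)
    y = train.expression - tf_shift[:, None] * s_iv[None, :]
    a11 = (C * C).sum(axis=1)
    a22 = (M * M).sum(axis=1)
    a12 = (C * M).sum(axis=1)
    det = a11 * a22 - a12 * a12
    singular = det <= 1e-12 * np.maximum(a11 * a22, 1e-300)
    det = np.where(singular, det + 1e-8, det)
    b1 = (C * y).sum(axis=1)
    b2 = (M * y).sum(axis=1)
    beta_cn = (a22 * b1 - a12 * b2) / det
    beta_me = (a11 * b2 - a12 * b1) / det
    return beta_cn, beta_me


def _spearman(pred: np.ndarray, obs: np.ndarray) -> float:
    """Spearman rho; defined as 0 when either vector is constant (a constant
    prediction carries no ranking information)."""
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return 0.0
    rho = stats.spearmanr(pred, obs).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def crossval(
    dataset: OmicsDataset,
    tfmap: TFTargetMap,
    k: int = 10,
    seed: int = 0,
    model: str = "integrative",
) -> CVReport:
    """k-fold cross-validation on held-out patients and genes."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    if model not in MODEL_TAGS:
        raise ValueError(f"model must be one of {MODEL_TAGS}")
    rng = np.random.default_rng(seed)
    data = dataset
    if model == "random":
        data = permute_expression(dataset, seed=int(rng.integers(2**31)))
    sample_fold = _stratified_sample_folds(data.stage, k, rng)
    gene_fold = _gene_folds(data.n_genes, k, rng)

    predicted = np.full((data.n_genes, data.n_samples), np.nan)
    rhos = np.full(data.n_genes, np.nan)
    n_test = np.zeros(data.n_genes, dtype=int)

    for t in range(k):
        test_s = sample_fold == t
        test_g = gene_fold == t
        if not test_g.any():
            continue
        train = data.subset_genes(~test_g).subset_samples(~test_s)
        train_map, tf_keep = _restrict_map(tfmap, ~test_g)
        if model in ("integrative", "random"):
            fit = fit_integrative(train, train_map, method="ols")
        else:
            fit = fit_tf_only(train, train_map)
        # TF offsets for held-out genes via their incidence columns (only
        # TFs retained in training carry a coefficient)
        B_test = tfmap.incidence[tf_keep][:, test_g].astype(float)
        tf_shift = B_test.T @ fit.beta_tf

        held = data.subset_genes(test_g)
        held_train = held.subset_samples(~test_s)
        held_test = held.subset_samples(test_s)
        s_iv_test = held_test.stage_iv.astype(float)

        if model in ("integrative", "random"):
            beta_cn, beta_me = _per_gene_fit(held_train, tf_shift)
            preds = (
                beta_cn[:, None] * held_test.cnv
                + beta_me[:, None] * held_test.methylation
                + tf_shift[:, None] * s_iv_test[None, :]
            )
        else:
            preds = tf_shift[:, None] * np.broadcast_to(
                s_iv_test, (held.n_genes, held_test.n_samples)
            )

        g_idx = np.flatnonzero(test_g)
        s_idx = np.flatnonzero(test_s)
        predicted[np.ix_(g_idx, s_idx)] = preds
        for row, gi in enumerate(g_idx):
            rhos[gi] = _spearman(preds[row], held_test.expression[row])
            n_test[gi] = s_idx.size

    per_gene = pd.DataFrame(
        {"rho": rhos, "n_test": n_test},
        index=pd.Index(data.gene_ids, name="gene_id"),
    )
    report = CVReport(model=model, per_gene=per_gene, predicted=predicted, k=k, seed=seed)
    logger.info("%s CV (k=%d): mean rho=%.4f median=%.4f",
                model, k, report.mean_rho, report.median_rho)
    return report


def _restrict_map(
    tfmap: TFTargetMap, keep_genes: np.ndarray
) -> tuple[TFTargetMap, np.ndarray]:
    incidence = tfmap.incidence[:, keep_genes]
    tf_keep = incidence.sum(axis=1) > 0
    restricted = TFTargetMap(
        tf_ids=tfmap.tf_ids[tf_keep],
        gene_ids=tfmap.gene_ids[keep_genes],
        incidence=incidence[tf_keep],
        provenance=tfmap.provenance,
    )
    return restricted, tf_keep


def stage_change_correlation(
    predicted: np.ndarray,
    dataset: OmicsDataset,
    gene_set: Iterable,
) -> float:
    """Spearman correlation between predicted and observed stage log-FC over
    a gene set.

    Predicted log-FC per gene is mean predicted expression over its
    (non-NaN) stage-IV cells minus the stage-I mean; observed log-FC comes
    from the full expression matrix.
    """
    gene_set = list(gene_set)
    if len(gene_set) < 3:
        raise ValidationError("need at least 3 genes for a stage-change correlation")
    pos = {g: i for i, g in enumerate(dataset.gene_ids)}
    missing = [g for g in gene_set if g not in pos]
    if missing:
        raise ValidationError(f"genes absent from dataset: {missing[:5]}")
    idx = np.array([pos[g] for g in gene_set])
    iv = dataset.stage_iv

    pred_fc = np.empty(len(idx))
    obs_fc = np.empty(len(idx))
    with np.errstate(invalid="ignore"):
        for row, gi in enumerate(idx):
            p = predicted[gi]
            pred_fc[row] = np.nanmean(p[iv]) - np.nanmean(p[~iv])
            obs_fc[row] = dataset.expression[gi, iv].mean() - dataset.expression[gi, ~iv].mean()
    ok = np.isfinite(pred_fc)
    if ok.sum() < 3:
        raise ValidationError("fewer than 3 genes have predictions in both stages")
    return _spearman(pred_fc[ok], obs_fc[ok])


def target_shift_test(
    dataset: OmicsDataset,
    target_set: Iterable,
    signed: bool = False,
) -> tuple[float, float]:
    """One-sided KS test asking whether target genes show larger
    stage-dependent expression changes than non-targets.

    Uses |log-FC| per gene by default; ``signed=True`` compares raw log-FC.
    """
    targets = set(target_set)
    if not targets:
        raise ValidationError("target set is empty")
    all_genes = set(dataset.gene_ids)
    if not targets & all_genes:
        raise ValidationError("target set has no overlap with the dataset")
    if targets >= all_genes:
        raise ValidationError("target set must be a strict subset of the genes")
    iv = dataset.stage_iv
    fc = dataset.expression[:, iv].mean(axis=1) - dataset.expression[:, ~iv].mean(axis=1)
    if not signed:
        fc = np.abs(fc)
    in_set = np.array([g in targets for g in dataset.gene_ids])
    return ks_compare(fc[in_set], fc[~in_set], alternative="greater")
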