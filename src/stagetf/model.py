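"""Structured least squares linking expression to copy number, methylation
and stage-gated TF activity.

The stacked regression has one row per (gene, sample) pair.  Each gene
contributes two private columns (its copy-number and methylation values);
every TF contributes one shared column that is 1 exactly on rows of its
target genes in stage-IV samples.  The normal equations therefore have an
arrowhead pattern: independent 2x2 per-gene blocks coupled only through the
TF columns.  The OLS solve below eliminates the gene blocks analytically and
solves a single n_tfs x n_tfs Schur-complement system, so the full design is
never materialised densely.

For the gene block of gene i let

    A_i = [[sum C^2, sum CM], [sum CM, sum M^2]]     (sums over samples)
    g_i = [sum_{j in IV} C_ij, sum_{j in IV} M_ij]
    b_i = [sum_j C_ij y_ij,  sum_j M_ij y_ij]

and let B be the TF x gene incidence with n_IV stage-IV samples.  Then the
TF block of the normal equations is n_IV * B B^T, the gene-TF coupling for
gene i is rank one (g_i outer its incidence column), and the Schur
complement reduces to  B diag(n_IV - q_i) B^T  with  q_i = g_i' A_i^{-1} g_i.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse, stats

from ._stats import bh_adjust
from .errors import ValidationError
from .io_datasets import OmicsDataset, TFTargetMap

logger = logging.getLogger(__name__)

_BLOCK_RIDGE = 1e-8  # fallback jitter for singular per-gene blocks

DEFAULT_TF_FDR = 0.001
DEFAULT_TF_EFFECT = 0.5


@dataclass
class DesignSpec:
    """Shape and sparsity descriptor of the stacked regression design.

    Rows are gene-major: row ``i * n_samples + j`` is (gene i, sample j).
    Columns are ``[cn_0, me_0, cn_1, me_1, ..., tf_0, ..., tf_{T-1}]`` (the
    gene blocks are dropped for the TF-only design).
    """

    n_genes: int
    n_samples: int
    n_tfs: int
    tf_only: bool = False

    @property
    def n_obs(self) -> int:
        return self.n_genes * self.n_samples

    @property
    def n_coef(self) -> int:
        return self.n_tfs + (0 if self.tf_only else 2 * self.n_genes)


def build_design(
    dataset: OmicsDataset, tfmap: TFTargetMap, tf_only: bool = False
) -> DesignSpec:
    """Validate gene alignment and report the design dimensions."""
    if not np.array_equal(dataset.gene_ids, tfmap.gene_ids):
        missing = set(dataset.gene_ids) - set(tfmap.gene_ids)
        raise ValidationError(
            f"dataset and TF map must share the same gene axis "
            f"({len(missing)} dataset genes missing from the map); "
            "run the TF-count filter first"
        )
    return DesignSpec(
        n_genes=dataset.n_genes,
        n_samples=dataset.n_samples,
        n_tfs=tfmap.n_tfs,
        tf_only=tf_only,
    )


def design_matrix(
    dataset: OmicsDataset, tfmap: TFTargetMap, tf_only: bool = False
) -> sparse.csr_matrix:
    """Materialise the sparse design (for oracles, lasso and diagnostics)."""
    spec = build_design(dataset, tfmap, tf_only=tf_only)
    G, S, T = spec.n_genes, spec.n_samples, spec.n_tfs
    s_iv = dataset.stage_iv
    rows, cols, vals = [], [], []
    base = np.arange(S)
    if not tf_only:
        for i in range(G):
            r = i * S + base
            rows.append(r)
            cols.append(np.full(S, 2 * i))
            vals.append(dataset.cnv[i])
            rows.append(r)
            cols.append(np.full(S, 2 * i + 1))
            vals.append(dataset.methylation[i])
    tf_offset = 0 if tf_only else 2 * G
    iv_idx = np.flatnonzero(s_iv)
    for f in range(T):
        genes = np.flatnonzero(tfmap.incidence[f])
        if genes.size == 0 or iv_idx.size == 0:
            continue
        r = (genes[:, None] * S + iv_idx[None, :]).ravel()
        rows.append(r)
        cols.append(np.full(r.size, tf_offset + f))
        vals.append(np.ones(r.size))
    X = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(spec.n_obs, spec.n_coef),
    )
    return X.tocsr()


def stacked_response(dataset: OmicsDataset) -> np.ndarray:
    """Expression stacked gene-major, matching the design row order."""
    return dataset.expression.ravel()


@dataclass
class ModelFit:
    """Fitted coefficients, standard errors and residual diagnostics."""

    gene_ids: np.ndarray
    tf_ids: np.ndarray
    beta_tf: np.ndarray
    beta_cn: np.ndarray | None
    beta_me: np.ndarray | None
    se_tf: np.ndarray | None
    se_cn: np.ndarray | None
    se_me: np.ndarray | None
    sse: float
    sigma2: float | None
    fitted: np.ndarray  # (genes, samples)
    residual_matrix: np.ndarray
    method: str
    lam: float
    n_obs: int
    n_coef: int

    @property
    def residuals(self) -> np.ndarray:
        """Stacked residual vector in design row order."""
        return self.residual_matrix.ravel()

    def tf_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"beta": self.beta_tf}, index=pd.Index(self.tf_ids, name="tf"))
        if self.se_tf is not None:
            df["se"] = self.se_tf
        return df

    def gene_frame(self) -> pd.DataFrame:
        if self.beta_cn is None:
            raise ValidationError("TF-only fit has no per-gene coefficients")
        df = pd.DataFrame(
            {"beta_cn": self.beta_cn, "beta_me": self.beta_me},
            index=pd.Index(self.gene_ids, name="gene_id"),
        )
        if self.se_cn is not None:
            df["se_cn"] = self.se_cn
            df["se_me"] = self.se_me
        return df

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.tf_frame().to_csv(outdir / "tf_coefficients.tsv", sep="\t",
                               float_format="%.8g")
        if self.beta_cn is not None:
            self.gene_frame().to_csv(outdir / "gene_coefficients.tsv", sep="\t",
                                     float_format="%.8g")


def _gene_blocks(dataset: OmicsDataset, lam: float, strict: bool):
    """Per-gene 2x2 Gram blocks and stage-IV sums, with a ridge fallback for
    singular blocks."""
    C, M = dataset.cnv, dataset.methylation
    s_iv = dataset.stage_iv.astype(float)
    a11 = (C * C).sum(axis=1) + lam
    a22 = (M * M).sum(axis=1) + lam
    a12 = (C * M).sum(axis=1)
    det = a11 * a22 - a12 * a12
    scale = np.maximum(a11 * a22, 1e-300)
    singular = det <= 1e-12 * scale
    if singular.any():
        if strict:
            bad = dataset.gene_ids[singular]
            raise np.linalg.LinAlgError(
                f"singular covariate block for gene(s) {list(bad[:5])}"
            )
        warnings.warn(
            f"{int(singular.sum())} gene block(s) singular; applying ridge "
            f"jitter {_BLOCK_RIDGE}",
            RuntimeWarning,
            stacklevel=3,
        )
        a11 = a11 + _BLOCK_RIDGE * singular
        a22 = a22 + _BLOCK_RIDGE * singular
        det = a11 * a22 - a12 * a12
    g1 = C @ s_iv
    g2 = M @ s_iv
    return a11, a12, a22, det, g1, g2


def fit_integrative(
    dataset: OmicsDataset,
    tfmap: TFTargetMap,
    method: str = "ols",
    lam: float | None = None,
    strict: bool = False,
) -> ModelFit:
    """Fit the full model by arrowhead block elimination (ols/ridge) or by
    coordinate descent on the sparse design (lasso).

    ``lam`` is the ridge penalty added to every squared coefficient, or the
    lasso ``alpha`` in scikit-learn's parameterisation; for lasso, ``None``
    selects it by 5-fold cross-validation.
    """
    spec = build_design(dataset, tfmap)
    if method == "lasso":
        return _fit_lasso(dataset, tfmap, lam)
    if method not in ("ols", "ridge"):
        raise ValueError(f"unknown method {method!r}")
    lam = 0.0 if method == "ols" else (1.0 if lam is None else float(lam))
    if method == "ols" and spec.n_coef >= spec.n_obs:
        raise ValidationError(
            f"underdetermined system: {spec.n_coef} coefficients for {spec.n_obs} rows"
        )

    E = dataset.expression
    C, M = dataset.cnv, dataset.methylation
    s_iv = dataset.stage_iv.astype(float)
    n_iv = s_iv.sum()
    B = tfmap.incidence.astype(float)

    a11, a12, a22, det, g1, g2 = _gene_blocks(dataset, lam, strict)
    b1 = (C * E).sum(axis=1)
    b2 = (M * E).sum(axis=1)
    y_iv = E @ s_iv

    # q_i = g' A^{-1} g ; h_i = g' A^{-1} b
    q = (a22 * g1 * g1 - 2.0 * a12 * g1 * g2 + a11 * g2 * g2) / det
    h = (a22 * g1 * b1 - a12 * (g1 * b2 + g2 * b1) + a11 * g2 * b2) / det

    schur = (B * (n_iv - q)) @ B.T
    if lam:
        schur = schur + lam * np.eye(tfmap.n_tfs)
    rhs = B @ (y_iv - h)
    try:
        beta_tf = np.linalg.solve(schur, rhs)
        schur_singular = False
    except np.linalg.LinAlgError:
        if strict:
            raise
        warnings.warn("singular TF system; using least-norm solution", RuntimeWarning)
        beta_tf = np.linalg.lstsq(schur, rhs, rcond=None)[0]
        schur_singular = True

    w = B.T @ beta_tf  # per-gene stage-IV TF offset
    bc1 = b1 - g1 * w
    bc2 = b2 - g2 * w
    beta_cn = (a22 * bc1 - a12 * bc2) / det
    beta_me = (a11 * bc2 - a12 * bc1) / det

    fitted = beta_cn[:, None] * C + beta_me[:, None] * M + w[:, None] * s_iv[None, :]
    resid = E - fitted
    sse = float((resid**2).sum())

    se_tf = se_cn = se_me = None
    sigma2 = None
    if method == "ols" and not schur_singular:
        dof = spec.n_obs - spec.n_coef
        sigma2 = sse / dof if dof > 0 else np.nan
        schur_inv = np.linalg.inv(schur)
        se_tf = np.sqrt(np.maximum(sigma2 * np.diag(schur_inv), 0.0))
        # gene block of (X'X)^{-1}: A^{-1} + s_i (A^{-1} g)(A^{-1} g)'
        s_gene = np.einsum("fi,fg,gi->i", B, schur_inv, B)
        v1 = (a22 * g1 - a12 * g2) / det
        v2 = (a11 * g2 - a12 * g1) / det
        se_cn = np.sqrt(np.maximum(sigma2 * (a22 / det + s_gene * v1 * v1), 0.0))
        se_me = np.sqrt(np.maximum(sigma2 * (a11 / det + s_gene * v2 * v2), 0.0))

    logger.info("%s fit: SSE=%.6g over %d rows, %d coefficients",
                method, sse, spec.n_obs, spec.n_coef)
    return ModelFit(
        gene_ids=dataset.gene_ids,
        tf_ids=tfmap.tf_ids,
        beta_tf=beta_tf,
        beta_cn=beta_cn,
        beta_me=beta_me,
        se_tf=se_tf,
        se_cn=se_cn,
        se_me=se_me,
        sse=sse,
        sigma2=sigma2,
        fitted=fitted,
        residual_matrix=resid,
        method=method,
        lam=lam,
        n_obs=spec.n_obs,
        n_coef=spec.n_coef,
    )


def _fit_lasso(dataset: OmicsDataset, tfmap: TFTargetMap, lam: float | None) -> ModelFit:
    from sklearn.linear_model import Lasso, LassoCV

    spec = build_design(dataset, tfmap)
    X = design_matrix(dataset, tfmap)
    y = stacked_response(dataset)
    if lam is None:
        est = LassoCV(cv=5, fit_intercept=False, n_alphas=30, max_iter=5000)
    else:
        est = Lasso(alpha=float(lam), fit_intercept=False, max_iter=5000)
    est.fit(X, y)
    coef = est.coef_
    lam_used = float(est.alpha_) if lam is None else float(lam)
    G, S = spec.n_genes, spec.n_samples
    beta_cn = coef[0 : 2 * G : 2].copy()
    beta_me = coef[1 : 2 * G : 2].copy()
    beta_tf = coef[2 * G :].copy()
    fitted = np.asarray(X @ coef).reshape(G, S)
    resid = dataset.expression - fitted
    return ModelFit(
        gene_ids=dataset.gene_ids,
        tf_ids=tfmap.tf_ids,
        beta_tf=beta_tf,
        beta_cn=beta_cn,
        beta_me=beta_me,
        se_tf=None,
        se_cn=None,
        se_me=None,
        sse=float((resid**2).sum()),
        sigma2=None,
        fitted=fitted,
        residual_matrix=resid,
        method="lasso",
        lam=lam_used,
        n_obs=spec.n_obs,
        n_coef=spec.n_coef,
    )


def fit_tf_only(dataset: OmicsDataset, tfmap: TFTargetMap) -> ModelFit:
    """Fit the reduced model with only the stage-gated TF columns."""
    spec = build_design(dataset, tfmap, tf_only=True)
    s_iv = dataset.stage_iv.astype(float)
    n_iv = s_iv.sum()
    B = tfmap.incidence.astype(float)
    H = n_iv * (B @ B.T)
    rhs = B @ (dataset.expression @ s_iv)
    try:
        beta_tf = np.linalg.solve(H, rhs)
        H_inv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        warnings.warn("rank-deficient TF-only system; using pseudoinverse",
                      RuntimeWarning)
        H_inv = np.linalg.pinv(H)
        beta_tf = H_inv @ rhs
    w = B.T @ beta_tf
    fitted = w[:, None] * s_iv[None, :]
    resid = dataset.expression - fitted
    sse = float((resid**2).sum())
    dof = spec.n_obs - spec.n_coef
    sigma2 = sse / dof if dof > 0 else np.nan
    se_tf = np.sqrt(np.maximum(sigma2 * np.diag(H_inv), 0.0))
    return ModelFit(
        gene_ids=dataset.gene_ids,
        tf_ids=tfmap.tf_ids,
        beta_tf=beta_tf,
        beta_cn=None,
        beta_me=None,
        se_tf=se_tf,
        se_cn=None,
        se_me=None,
        sse=sse,
        sigma2=sigma2,
        fitted=fitted,
        residual_matrix=resid,
        method="ols",
        lam=0.0,
        n_obs=spec.n_obs,
        n_coef=spec.n_coef,
    )


@dataclass
class TFActivityTable:
    """Per-TF activity change with significance and selection flags."""

    table: pd.DataFrame  # index tf, columns beta, se, p, fdr, selected
    fdr_threshold: float
    effect_threshold: float

    @property
    def selected(self) -> np.ndarray:
        return self.table.index[self.table["selected"]].to_numpy(dtype=object)

    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "tf"
        out.to_csv(path, sep="\t", float_format="%.6g")


def infer_tf_activity(
    fit: ModelFit,
    fdr_threshold: float = DEFAULT_TF_FDR,
    effect_threshold: float = DEFAULT_TF_EFFECT,
) -> TFActivityTable:
    """Two-sided normal p-values for the TF coefficients, BH-adjusted across
    the TF family; selected iff fdr < threshold and |beta| > threshold
    (both strict)."""
    if fit.se_tf is None:
        raise ValidationError(
            "TF activity inference needs OLS standard errors; refit with method='ols'"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = fit.beta_tf / fit.se_tf
    p = 2.0 * stats.norm.sf(np.abs(z))
    fdr = bh_adjust(p)
    selected = (fdr < fdr_threshold) & (np.abs(fit.beta_tf) > effect_threshold)
    table = pd.DataFrame(
        {
            "beta": fit.beta_tf,
            "se": fit.se_tf,
            "p": p,
            "fdr": fdr,
            "selected": selected,
        },
        index=pd.Index(fit.tf_ids, name="tf"),
    ).sort_values("p")
    return TFActivityTable(
        table=table, fdr_threshold=fdr_threshold, effect_threshold=effect_threshold
    )


def residual_diagnostics(fit: ModelFit, n_bins: int = 10) -> dict:
    """Sample skewness, excess kurtosis and binned residual-vs-fitted means."""
    resid = fit.residuals
    fitted = fit.fitted.ravel()
    edges = np.quantile(fitted, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, fitted, side="right") - 1, 0, len(edges) - 2)
    bin_means = [float(resid[idx == b].mean()) if (idx == b).any() else np.nan
                 for b in range(len(edges) - 1)]
    return {
        "skewness": float(stats.skew(resid)),
        "excess_kurtosis": float(stats.kurtosis(resid)),
        "sse": fit.sse,
        "bin_edges": [float(e) for e in edges],
        "residual_bin_means": bin_means,
    }
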