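"""Per-gene dissection of stage-dependent expression alterations into
copy-number, methylation and TF-activity mechanisms.

A covariate explains a gene's alteration when three things line up: the
gene's coefficient for that covariate is individually significant, the
covariate itself shifts between stages (two-sample t-test), and the product
of coefficient and stage shift has the same sign as the observed log fold
change.  TF activity explains a gene when some selected TF binds it with a
coefficient sign matching the gene's direction of change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import pooled_t_test
from .diffexpr import DEResult
from .errors import ValidationError
from .io_datasets import OmicsDataset, TFTargetMap
from .model import ModelFit, TFActivityTable

DEFAULT_P = 0.01

VENN_REGIONS = (
    "cnv_only",
    "methylation_only",
    "tf_only",
    "cnv_methylation",
    "cnv_tf",
    "methylation_tf",
    "cnv_methylation_tf",
)


@dataclass
class AttributionRecord:
    gene_id: str
    log2_fc: float
    explained_by_cnv: bool
    explained_by_methylation: bool
    explained_by_tf: bool
    supporting_tfs: list = field(default_factory=list)

    @property
    def unexplained(self) -> bool:
        return not (
            self.explained_by_cnv or self.explained_by_methylation or self.explained_by_tf
        )


def _coef_p(beta: float, se: float) -> float:
    if se == 0 or not np.isfinite(se):
        return 1.0
    return float(2.0 * stats.norm.sf(abs(beta / se)))


def attribute_gene(
    gene: str,
    fit: ModelFit,
    tf_table: TFActivityTable,
    de: DEResult,
    dataset: OmicsDataset,
    tfmap: TFTargetMap,
    p_threshold: float = DEFAULT_P,
) -> AttributionRecord:
    """Attribute one differentially expressed gene to its mechanisms."""
    gpos = np.flatnonzero(fit.gene_ids == gene)
    if gpos.size == 0:
        raise KeyError(f"gene {gene!r} absent from the fit")
    if fit.beta_cn is None or fit.se_cn is None:
        raise ValidationError("attribution needs an integrative OLS fit")
    status = de.table.at[gene, "status"]
    if status == "ns":
        raise ValidationError(f"gene {gene!r} is not differentially expressed")
    gi = int(gpos[0])
    log2_fc = float(de.table.at[gene, "log2_fc"])
    fc_sign = np.sign(log2_fc)

    dpos = np.flatnonzero(dataset.gene_ids == gene)
    if dpos.size == 0:
        raise KeyError(f"gene {gene!r} absent from the dataset")
    di = int(dpos[0])
    iv = dataset.stage_iv

    def covariate_explains(values: np.ndarray, beta: float, se: float) -> bool:
        p_coef = _coef_p(beta, se)
        shift = values[iv].mean() - values[~iv].mean()
        _, p_shift = pooled_t_test(values[iv][None, :], values[~iv][None, :], axis=1)
        return (
            p_coef < p_threshold
            and float(p_shift[0]) < p_threshold
            and np.sign(beta * shift) == fc_sign
        )

    exp_cnv = covariate_explains(dataset.cnv[di], fit.beta_cn[gi], fit.se_cn[gi])
    exp_meth = covariate_explains(
        dataset.methylation[di], fit.beta_me[gi], fit.se_me[gi]
    )

    mpos = np.flatnonzero(tfmap.gene_ids == gene)
    supporting: list = []
    if mpos.size:
        bound = tfmap.incidence[:, int(mpos[0])].astype(bool)
        sel = tf_table.table[tf_table.table["selected"]]
        for tf in sel.index:
            fidx = np.flatnonzero(tfmap.tf_ids == tf)
            if fidx.size and bound[int(fidx[0])]:
                if np.sign(sel.at[tf, "beta"]) == fc_sign:
                    supporting.append(tf)
    return AttributionRecord(
        gene_id=gene,
        log2_fc=log2_fc,
        explained_by_cnv=bool(exp_cnv),
        explained_by_methylation=bool(exp_meth),
        explained_by_tf=bool(supporting),
        supporting_tfs=supporting,
    )


def attribute_all(
    fit: ModelFit,
    tf_table: TFActivityTable,
    de: DEResult,
    dataset: OmicsDataset,
    tfmap: TFTargetMap,
    p_threshold: float = DEFAULT_P,
) -> list[AttributionRecord]:
    """Attribution records for every differentially expressed gene present
    in the fit."""
    fit_genes = set(fit.gene_ids)
    return [
        attribute_gene(g, fit, tf_table, de, dataset, tfmap, p_threshold)
        for g in de.de_genes
        if g in fit_genes
    ]


def attribution_summary(records: Sequence[AttributionRecord]) -> dict:
    """Counts for the 7 Venn regions plus the unexplained remainder."""
    if not records:
        raise ValidationError("no attribution records")
    counts = {region: 0 for region in VENN_REGIONS}
    unexplained = 0
    for rec in records:
        key_parts = []
        if rec.explained_by_cnv:
            key_parts.append("cnv")
        if rec.explained_by_methylation:
            key_parts.append("methylation")
        if rec.explained_by_tf:
            key_parts.append("tf")
        if not key_parts:
            unexplained += 1
        else:
            region = "_".join(key_parts)
            if len(key_parts) == 1:
                region += "_only"
            counts[region] += 1
    n = len(records)
    explained = n - unexplained
    return {
        **counts,
        "unexplained": unexplained,
        "n_genes": n,
        "n_explained": explained,
        "fraction_explained": explained / n,
    }


def records_frame(records: Iterable[AttributionRecord]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id,
            "log2_fc": r.log2_fc,
            "explained_by_cnv": r.explained_by_cnv,
            "explained_by_methylation": r.explained_by_methylation,
            "explained_by_tf": r.explained_by_tf,
            "supporting_tfs": ",".join(map(str, r.supporting_tfs)),
            "unexplained": r.unexplained,
        }
        for r in records
    ]
    return pd.DataFrame(rows).set_index("gene_id")


def write_attribution(records: Sequence[AttributionRecord], path: str | Path) -> None:
    records_frame(records).to_csv(path, sep="\t", float_format="%.6g")
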