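"""Stage-dependent differential expression.

Per-gene pooled-variance two-sample t-tests on log2 expression between
stage IV and stage I samples, Benjamini-Hochberg adjustment across all
tested genes, and the fold-change / FDR filter.  Fold-change thresholds
are given on the linear scale ("FC > 2" means |log2 FC| > 1, strictly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._stats import bh_adjust, pooled_t_test
from .io_datasets import OmicsDataset

logger = logging.getLogger(__name__)

DEFAULT_FC = 2.0
DEFAULT_FDR = 0.001


@dataclass
class DEResult:
    """Per-gene differential expression table.

    ``table`` is indexed by gene id with columns log2_fc, t, p, fdr and
    status (up / down / ns); the thresholds used to call status are kept
    alongside.
    """

    table: pd.DataFrame
    fc_threshold: float
    fdr_threshold: float

    @property
    def up(self) -> np.ndarray:
        return self.table.index[self.table["status"] == "up"].to_numpy(dtype=object)

    @property
    def down(self) -> np.ndarray:
        return self.table.index[self.table["status"] == "down"].to_numpy(dtype=object)

    @property
    def de_genes(self) -> np.ndarray:
        return self.table.index[self.table["status"] != "ns"].to_numpy(dtype=object)

    def log2_fc(self, gene: str) -> float:
        return float(self.table.at[gene, "log2_fc"])

    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")


def _status(
    log2_fc: np.ndarray, fdr: np.ndarray, fc_threshold: float, fdr_threshold: float
) -> np.ndarray:
    cut = np.log2(fc_threshold)
    status = np.full(log2_fc.shape, "ns", dtype=object)
    status[(log2_fc > cut) & (fdr < fdr_threshold)] = "up"
    status[(log2_fc < -cut) & (fdr < fdr_threshold)] = "down"
    return status


def de_test(
    dataset: OmicsDataset,
    fc_threshold: float = DEFAULT_FC,
    fdr_threshold: float = DEFAULT_FDR,
) -> DEResult:
    """Test every gene for a stage IV vs stage I expression difference.

    log2 fold change is mean(log2 expression, stage IV) - mean(stage I);
    genes that are constant within both groups and have zero fold change
    are degenerate and get p = 1.
    """
    if fc_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    iv = dataset.stage_iv
    expr_iv = dataset.expression[:, iv]
    expr_i = dataset.expression[:, ~iv]
    log2_fc = expr_iv.mean(axis=1) - expr_i.mean(axis=1)
    t, p = pooled_t_test(expr_iv, expr_i, axis=1)
    n_degenerate = int(((p == 1.0) & (t == 0.0)).sum())
    if n_degenerate:
        logger.info("%d degenerate gene(s) with zero variance and zero FC (p set to 1)",
                    n_degenerate)
    fdr = bh_adjust(p)
    table = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "t": t,
            "p": p,
            "fdr": fdr,
            "status": _status(log2_fc, fdr, fc_threshold, fdr_threshold),
        },
        index=pd.Index(dataset.gene_ids, name="gene_id"),
    )
    return DEResult(table=table, fc_threshold=fc_threshold, fdr_threshold=fdr_threshold)


def filter_de(
    result: DEResult,
    fc_threshold: float = DEFAULT_FC,
    fdr_threshold: float = DEFAULT_FDR,
) -> tuple[set, set]:
    """Return (up, down) gene-id sets at the given linear fold-change and
    FDR thresholds (both strict)."""
    if fc_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    t = result.table
    status = _status(
        t["log2_fc"].to_numpy(), t["fdr"].to_numpy(), fc_threshold, fdr_threshold
    )
    return (
        set(t.index[status == "up"]),
        set(t.index[status == "down"]),
    )
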