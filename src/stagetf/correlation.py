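"""Per-gene correlation of CNV/methylation with expression, summary counts
and distribution comparisons between gene sets."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._stats import ks_compare, pearson_rows
from .errors import ValidationError
from .io_datasets import OmicsDataset

LAYERS = ("cnv", "methylation")


@dataclass
class CorrelationProfile:
    """Per-gene Pearson r (and p) between one omics layer and expression,
    computed across all samples pooled.  Genes where either vector is
    constant carry NaN and are excluded from summaries."""

    table: pd.DataFrame  # index gene_id, columns r, p
    layer: str

    @property
    def r(self) -> pd.Series:
        return self.table["r"]

    def defined(self) -> pd.DataFrame:
        return self.table.dropna(subset=["r"])

    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out["layer"] = self.layer
        out.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class CorrelationSummary:
    layer: str
    n_genes: int
    median_r: float
    n_positive: int
    frac_positive: float
    n_positive_significant: int
    frac_positive_significant: float
    n_negative: int
    frac_negative: float
    n_negative_significant: int
    frac_negative_significant: float
    alpha: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def per_gene_correlation(dataset: OmicsDataset, layer: str) -> CorrelationProfile:
    """Pearson correlation of the chosen layer with expression, per gene."""
    if layer not in LAYERS:
        raise ValueError(f"layer must be one of {LAYERS}")
    if dataset.n_samples < 3:
        raise ValidationError("need at least 3 samples for correlations")
    x = getattr(dataset, layer)
    r, p = pearson_rows(x, dataset.expression)
    table = pd.DataFrame(
        {"r": r, "p": p}, index=pd.Index(dataset.gene_ids, name="gene_id")
    )
    return CorrelationProfile(table=table, layer=layer)


def summarize_correlations(
    profile: CorrelationProfile, alpha: float = 0.01
) -> CorrelationSummary:
    """Counts and fractions of positive/negative (and significant) per-gene
    correlations; fractions of significant calls are relative to the genes
    on that side of zero."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    d = profile.defined()
    if d.empty:
        raise ValidationError("no gene has a defined correlation")
    r = d["r"].to_numpy()
    p = d["p"].to_numpy()
    pos = r > 0
    neg = r < 0
    n = len(d)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    n_pos_sig = int((pos & (p < alpha)).sum())
    n_neg_sig = int((neg & (p < alpha)).sum())
    return CorrelationSummary(
        layer=profile.layer,
        n_genes=n,
        median_r=float(np.median(r)),
        n_positive=n_pos,
        frac_positive=n_pos / n,
        n_positive_significant=n_pos_sig,
        frac_positive_significant=n_pos_sig / n_pos if n_pos else 0.0,
        n_negative=n_neg,
        frac_negative=n_neg / n,
        n_negative_significant=n_neg_sig,
        frac_negative_significant=n_neg_sig / n_neg if n_neg else 0.0,
        alpha=alpha,
    )


def compare_distributions(
    profile: CorrelationProfile,
    gene_set: Iterable,
    alternative: str = "two_sided",
) -> tuple[float, float]:
    """Two-sample KS test of the gene set's r values against the r values of
    its complement.  ``alternative='less'`` asks whether the set's values are
    stochastically smaller."""
    d = profile.defined()
    gene_set = set(gene_set)
    if not gene_set:
        raise ValidationError("gene_set is empty")
    in_set = d.index.isin(gene_set)
    if not in_set.any():
        raise ValidationError("gene_set has no overlap with the profile")
    if in_set.all():
        raise ValidationError("gene_set must be a strict subset of the profile genes")
    return ks_compare(
        d["r"].to_numpy()[in_set], d["r"].to_numpy()[~in_set], alternative
    )
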