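"""Reading, validation and alignment of matched multi-omics inputs.

The on-disk dialect is deliberately plain: TSV matrices (first column
``gene_id``, header row of sample ids, ``.`` decimal point), a two-column
clinical TSV (``sample_id``, ``stage`` with values ``I``/``IV``) and
standard GMT gene-set files for TF-target incidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

MATRIX_KINDS = ("expression", "cnv", "methylation")
STAGES = ("I", "IV")


@dataclass
class OmicsDataset:
    """Aligned gene x sample matrices plus per-sample stage labels.

    All three matrices share the same gene and sample ordering.  Expression
    is on the log2 scale, copy number is a linear dosage estimate, and
    methylation holds beta values in [0, 1].
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    expression: np.ndarray
    cnv: np.ndarray
    methylation: np.ndarray
    stage: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.stage = np.asarray(self.stage, dtype=object)
        for name in MATRIX_KINDS:
            m = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, m)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def stage_iv(self) -> np.ndarray:
        """Boolean stage indicator (True for stage IV)."""
        return self.stage == "IV"

    def validate(self) -> "OmicsDataset":
        shape = (self.n_genes, self.n_samples)
        for name in MATRIX_KINDS:
            m = getattr(self, name)
            if m.shape != shape:
                raise ValidationError(f"{name} matrix has shape {m.shape}, expected {shape}")
            if not np.isfinite(m).all():
                raise ValidationError(f"{name} matrix contains non-finite values")
        if len(set(self.gene_ids)) != self.n_genes:
            raise ValidationError("duplicate gene ids")
        if len(set(self.sample_ids)) != self.n_samples:
            raise ValidationError("duplicate sample ids")
        if self.methylation.size and (
            self.methylation.min() < 0 or self.methylation.max() > 1
        ):
            raise ValidationError("methylation beta values must lie in [0, 1]")
        bad = set(self.stage) - set(STAGES)
        if bad:
            raise ValidationError(f"unknown stage labels: {sorted(bad)}")
        for st in STAGES:
            if (self.stage == st).sum() < 2:
                raise ValidationError(f"fewer than 2 samples in stage {st}")
        return self

    def subset_genes(self, keep: np.ndarray) -> "OmicsDataset":
        """Return a dataset restricted to a boolean or index gene selector."""
        return OmicsDataset(
            gene_ids=self.gene_ids[keep],
            sample_ids=self.sample_ids,
            expression=self.expression[keep],
            cnv=self.cnv[keep],
            methylation=self.methylation[keep],
            stage=self.stage,
        )

    def subset_samples(self, keep: np.ndarray) -> "OmicsDataset":
        return OmicsDataset(
            gene_ids=self.gene_ids,
            sample_ids=self.sample_ids[keep],
            expression=self.expression[:, keep],
            cnv=self.cnv[:, keep],
            methylation=self.methylation[:, keep],
            stage=self.stage[keep],
        )

    def with_expression(self, expression: np.ndarray) -> "OmicsDataset":
        return OmicsDataset(
            gene_ids=self.gene_ids,
            sample_ids=self.sample_ids,
            expression=np.asarray(expression, dtype=float),
            cnv=self.cnv,
            methylation=self.methylation,
            stage=self.stage,
        )


@dataclass
class TFTargetMap:
    """Binary TF x gene incidence after duplicate-target merging."""

    tf_ids: np.ndarray
    gene_ids: np.ndarray
    incidence: np.ndarray  # (n_tfs, n_genes), values in {0, 1}
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tf_ids = np.asarray(self.tf_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.incidence = np.asarray(self.incidence)

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def validate(self) -> "TFTargetMap":
        if self.incidence.shape != (self.n_tfs, self.n_genes):
            raise ValidationError("incidence shape does not match tf/gene ids")
        vals = np.unique(self.incidence)
        if not np.isin(vals, [0, 1]).all():
            raise ValidationError("incidence entries must be 0/1")
        degree = self.incidence.sum(axis=1)
        if (degree == 0).any():
            empty = self.tf_ids[degree == 0]
            raise ValidationError(f"TFs without targets: {list(empty[:5])}")
        sets = [frozenset(np.flatnonzero(row)) for row in self.incidence]
        if len(set(sets)) != len(sets):
            raise ValidationError("duplicate TF target sets (merge first)")
        return self

    def targets_of(self, tf_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.tf_ids == tf_id)
        if idx.size == 0:
            raise KeyError(tf_id)
        return self.gene_ids[self.incidence[idx[0]].astype(bool)]

    def tfs_per_gene(self) -> np.ndarray:
        return self.incidence.sum(axis=0)


# ---------------------------------------------------------------------------
# readers / writers


def read_matrix(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a gene x sample TSV matrix into a labeled DataFrame.

    Every cell must parse as a finite float; the offending gene and sample
    are named otherwise.  Duplicate gene ids are rejected.
    """
    if kind not in MATRIX_KINDS:
        raise ValueError(f"kind must be one of {MATRIX_KINDS}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()
        raise ValidationError(
            f"{path.name}: duplicate gene id(s) {list(dups[:5])}; one row per gene required"
        )
    raw = df.to_numpy(dtype=object)
    try:
        # numpy's str->float conversion is correctly rounded (bit-exact
        # round trips); pandas' fast parser is not
        values = raw.astype(float)
        bad_mask = ~np.isfinite(values)
    except ValueError:
        values = np.empty(raw.shape)
        bad_mask = np.zeros(raw.shape, dtype=bool)
        for gi, sj in np.ndindex(*raw.shape):
            try:
                values[gi, sj] = float(raw[gi, sj])
                bad_mask[gi, sj] = not np.isfinite(values[gi, sj])
            except (TypeError, ValueError):
                bad_mask[gi, sj] = True
    if bad_mask.any():
        gi, sj = np.argwhere(bad_mask)[0]
        raise ParseError(
            f"{path.name}: non-numeric value {df.iat[gi, sj]!r} for gene "
            f"{df.index[gi]!r}, sample {df.columns[sj]!r}"
        )
    numeric = pd.DataFrame(values, index=df.index, columns=df.columns)
    numeric.index.name = "gene_id"
    return numeric


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    # default float repr is the shortest string that round-trips exactly
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> pd.Series:
    """Read the sample -> stage table, dropping samples with stages other
    than I/IV (with a warning)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "stage"}
    if not required.issubset(df.columns):
        raise ParseError(f"clinical table must have columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in clinical table")
    keep = df["stage"].isin(STAGES)
    if (~keep).any():
        logger.warning(
            "dropping %d clinical rows with stage not in %s", (~keep).sum(), STAGES
        )
    df = df[keep]
    return pd.Series(df["stage"].to_numpy(), index=df["sample_id"].to_numpy())


def write_clinical(stage: Mapping[str, str] | pd.Series, path: str | Path) -> None:
    s = pd.Series(stage)
    pd.DataFrame({"sample_id": s.index, "stage": s.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: str | Path) -> dict[str, frozenset]:
    """Parse a GMT file into ``{set name: gene set}`` (description dropped)."""
    path = Path(path)
    sets: dict[str, frozenset] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path.name}: line {lineno}: expected name, description and "
                    f"at least one gene (got {len(fields)} fields)"
                )
            name = fields[0]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ParseError(f"{path.name}: line {lineno}: empty gene set {name!r}")
            if name in sets:
                raise ValidationError(f"{path.name}: duplicate set name {name!r}")
            sets[name] = genes
    if not sets:
        raise ParseError(f"{path.name}: no gene sets found")
    return sets


def write_gmt(tfmap: TFTargetMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, tf in enumerate(tfmap.tf_ids):
            genes = tfmap.gene_ids[tfmap.incidence[i].astype(bool)]
            fh.write("\t".join([str(tf), "na", *map(str, genes)]) + "\n")


def merge_duplicate_tfs(
    raw_sets: Mapping[str, frozenset], gene_universe: np.ndarray | list
) -> TFTargetMap:
    """Collapse TFs with identical target sets and build the incidence matrix.

    Target sets are compared after restriction to ``gene_universe``; the
    merged id concatenates the sorted source names with "/".  TFs left with
    no target in the universe are dropped.
    """
    if not raw_sets:
        raise ValidationError("no TF sets supplied")
    universe = np.asarray(list(gene_universe), dtype=object)
    gene_pos = {g: i for i, g in enumerate(universe)}
    grouped: dict[frozenset, list[str]] = {}
    for name, genes in raw_sets.items():
        restricted = frozenset(g for g in genes if g in gene_pos)
        if not restricted:
            logger.warning("TF set %r has no targets in the gene universe; dropped", name)
            continue
        grouped.setdefault(restricted, []).append(name)
    if not grouped:
        raise ValidationError("no TF set overlaps the gene universe")
    entries = sorted(
        ((sorted(names), targets) for targets, names in grouped.items()),
        key=lambda e: "/".join(e[0]),
    )
    tf_ids = ["/".join(names) for names, _ in entries]
    incidence = np.zeros((len(entries), len(universe)), dtype=np.int8)
    provenance = {}
    for row, (names, targets) in enumerate(entries):
        provenance[tf_ids[row]] = list(names)
        for g in targets:
            incidence[row, gene_pos[g]] = 1
    n_merged = len(raw_sets) - len(tf_ids)
    if n_merged:
        logger.info("merged %d duplicate TF sets into %d entries", len(raw_sets), len(tf_ids))
    return TFTargetMap(tf_ids=tf_ids, gene_ids=universe, incidence=incidence,
                       provenance=provenance)


def align_dataset(
    expr: pd.DataFrame,
    cnv: pd.DataFrame,
    meth: pd.DataFrame,
    clinical: pd.Series,
) -> OmicsDataset:
    """Intersect genes and samples across the three matrices and the clinical
    table, ordering both axes lexicographically."""
    genes = sorted(set(expr.index) & set(cnv.index) & set(meth.index))
    samples = sorted(
        set(expr.columns) & set(cnv.columns) & set(meth.columns) & set(clinical.index)
    )
    if not genes or not samples:
        raise ValidationError(
            f"empty intersection: {len(genes)} common genes, {len(samples)} common samples"
        )
    logger.info(
        "aligned dataset: %d genes (of %d/%d/%d), %d samples",
        len(genes), len(expr.index), len(cnv.index), len(meth.index), len(samples),
    )
    ds = OmicsDataset(
        gene_ids=np.asarray(genes, dtype=object),
        sample_ids=np.asarray(samples, dtype=object),
        expression=expr.loc[genes, samples].to_numpy(dtype=float),
        cnv=cnv.loc[genes, samples].to_numpy(dtype=float),
        methylation=meth.loc[genes, samples].to_numpy(dtype=float),
        stage=clinical.loc[samples].to_numpy(dtype=object),
    )
    return ds.validate()


def filter_genes_by_tf_count(
    dataset: OmicsDataset, tfmap: TFTargetMap, min_tfs: int = 5
) -> tuple[OmicsDataset, TFTargetMap]:
    """Keep genes bound by strictly more than ``min_tfs`` TFs.

    TF incidence is restricted to the surviving genes; TFs left without any
    target are removed.
    """
    if min_tfs < 0:
        raise ValueError("min_tfs must be >= 0")
    if not np.array_equal(dataset.gene_ids, tfmap.gene_ids):
        # re-index the incidence onto the dataset's gene axis (zero column
        # for any dataset gene the map does not know about)
        pos = {g: i for i, g in enumerate(tfmap.gene_ids)}
        incidence = np.zeros((tfmap.n_tfs, dataset.n_genes), dtype=tfmap.incidence.dtype)
        for j, g in enumerate(dataset.gene_ids):
            if g in pos:
                incidence[:, j] = tfmap.incidence[:, pos[g]]
        tfmap = TFTargetMap(
            tf_ids=tfmap.tf_ids,
            gene_ids=dataset.gene_ids,
            incidence=incidence,
            provenance=tfmap.provenance,
        )
    degree = tfmap.incidence.sum(axis=0)
    keep = degree > min_tfs
    if not keep.any():
        raise ValidationError(f"no gene has more than {min_tfs} binding TFs")
    sub = dataset.subset_genes(keep)
    incidence = tfmap.incidence[:, keep]
    tf_keep = incidence.sum(axis=1) > 0
    out_map = TFTargetMap(
        tf_ids=tfmap.tf_ids[tf_keep],
        gene_ids=sub.gene_ids,
        incidence=incidence[tf_keep],
        provenance={t: tfmap.provenance.get(t, [t]) for t in tfmap.tf_ids[tf_keep]},
    )
    logger.info(
        "TF-count filter (> %d): kept %d/%d genes, %d/%d TFs",
        min_tfs, sub.n_genes, dataset.n_genes, out_map.n_tfs, tfmap.n_tfs,
    )
    return sub, out_map


# ---------------------------------------------------------------------------
# directory-level convenience (used by the CLI)

DATASET_FILES = {
    "expression": "expression.tsv",
    "cnv": "cnv.tsv",
    "methylation": "methylation.tsv",
}
CLINICAL_FILE = "clinical.tsv"


def write_dataset(dataset: OmicsDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for kind, fname in DATASET_FILES.items():
        df = pd.DataFrame(
            getattr(dataset, kind), index=dataset.gene_ids, columns=dataset.sample_ids
        )
        write_matrix(df, outdir / fname)
    write_clinical(
        pd.Series(dataset.stage, index=dataset.sample_ids), outdir / CLINICAL_FILE
    )


def read_dataset(indir: str | Path) -> OmicsDataset:
    indir = Path(indir)
    mats = {k: read_matrix(indir / f, k) for k, f in DATASET_FILES.items()}
    clinical = read_clinical(indir / CLINICAL_FILE)
    return align_dataset(mats["expression"], mats["cnv"], mats["methylation"], clinical)
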