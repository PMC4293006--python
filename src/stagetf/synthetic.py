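"""Simulation of matched multi-omics datasets with a known generative model.

Expression is generated as
``y_ij = beta_cn_i * C_ij + beta_me_i * M_ij + sum_f beta_f * S_j * B_fi + eps``
with copy number ~ Normal(2, 0.4) clipped at 0, methylation ~ Beta(2, 5),
a random bipartite TF-target incidence and Gaussian noise, so that every
downstream stage of the pipeline can be exercised against ground truth.

Optionally, subsets of genes receive a planted stage-dependent shift in
their copy-number or methylation profile so that mechanism attribution can
be validated against known causes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_datasets import OmicsDataset, TFTargetMap, write_dataset, write_gmt

_MAX_REDRAWS = 200


@dataclass
class SimulationParams:
    """Knobs of the generative model. ``targets_per_tf=None`` defaults to
    75% of the genes, which keeps the >min_tfs degree constraint feasible
    even for small TF counts."""

    n_genes: int = 50
    n_samples: int = 20
    n_tfs: int = 8
    frac_stage_iv: float = 0.3
    targets_per_tf: float | None = None
    beta_cn_dist: tuple[float, float] = (0.8, 0.3)
    beta_me_dist: tuple[float, float] = (-1.0, 0.3)
    n_active_tfs: int = 2
    active_beta_magnitude: float = 1.0
    noise_sd: float = 0.5
    min_tfs: int | None = 5
    n_cnv_shift_genes: int = 0
    cnv_shift_magnitude: float = 0.8
    n_meth_shift_genes: int = 0
    meth_shift_magnitude: float = -0.25
    seed: int = 0

    def validate(self) -> "SimulationParams":
        if min(self.n_genes, self.n_samples, self.n_tfs) < 1:
            raise ConfigurationError("n_genes, n_samples, n_tfs must be positive")
        if not 0.0 < self.frac_stage_iv < 1.0:
            raise ConfigurationError("frac_stage_iv must lie in (0, 1)")
        if self.n_active_tfs > self.n_tfs:
            raise ConfigurationError("n_active_tfs exceeds n_tfs")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.min_tfs is not None and self.min_tfs >= self.n_tfs:
            raise ConfigurationError(
                f"cannot require more than {self.n_tfs - 1} binding TFs with "
                f"{self.n_tfs} TFs"
            )
        if self.n_cnv_shift_genes + self.n_meth_shift_genes > self.n_genes:
            raise ConfigurationError("shifted gene groups exceed n_genes")
        return self


@dataclass
class SyntheticTruth:
    """Planted coefficients and noise level for parameter-recovery tests."""

    true_beta_cn: np.ndarray
    true_beta_me: np.ndarray
    true_beta_tf: np.ndarray
    noise_sd: float
    seed: int
    cnv_shift_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    meth_shift_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def to_frame(self, gene_ids: np.ndarray, tf_ids: np.ndarray) -> pd.DataFrame:
        gene_part = pd.DataFrame(
            {
                "id": gene_ids,
                "kind": "gene",
                "beta_cn": self.true_beta_cn,
                "beta_me": self.true_beta_me,
                "beta_tf": np.nan,
            }
        )
        tf_part = pd.DataFrame(
            {
                "id": tf_ids,
                "kind": "tf",
                "beta_cn": np.nan,
                "beta_me": np.nan,
                "beta_tf": self.true_beta_tf,
            }
        )
        return pd.concat([gene_part, tf_part], ignore_index=True)


def _draw_incidence(rng: np.random.Generator, params: SimulationParams) -> np.ndarray:
    """Random bipartite incidence with the requested mean target-set size,
    redrawing deficient gene columns until every gene has > min_tfs TFs."""
    mean_targets = (
        params.targets_per_tf if params.targets_per_tf is not None
        else 0.75 * params.n_genes
    )
    p = min(1.0, mean_targets / params.n_genes)
    inc = (rng.random((params.n_tfs, params.n_genes)) < p).astype(np.int8)
    if params.min_tfs is None:
        return inc
    for _ in range(_MAX_REDRAWS):
        deficient = np.flatnonzero(inc.sum(axis=0) <= params.min_tfs)
        if deficient.size == 0:
            return inc
        inc[:, deficient] = (rng.random((params.n_tfs, deficient.size)) < p).astype(np.int8)
    raise ConfigurationError(
        f"could not satisfy the >{params.min_tfs} TFs-per-gene constraint after "
        f"{_MAX_REDRAWS} redraws; increase targets_per_tf or n_tfs"
    )


def _dedupe_incidence(rng: np.random.Generator, inc: np.ndarray) -> np.ndarray:
    """Perturb rows until no two TFs share an identical target set."""
    n_tfs, n_genes = inc.shape
    for _ in range(_MAX_REDRAWS):
        seen: dict[bytes, int] = {}
        dup_rows = []
        for f in range(n_tfs):
            key = inc[f].tobytes()
            if key in seen:
                dup_rows.append(f)
            else:
                seen[key] = f
        if not dup_rows:
            return inc
        for f in dup_rows:
            # prefer adding a target: never lowers a gene's TF degree
            zeros = np.flatnonzero(inc[f] == 0)
            if zeros.size:
                inc[f, rng.choice(zeros)] = 1
            else:
                inc[f, rng.integers(n_genes)] = 0
    raise ConfigurationError("could not produce distinct TF target sets")


def simulate_dataset(
    params: SimulationParams,
) -> tuple[OmicsDataset, TFTargetMap, SyntheticTruth]:
    """Draw a dataset, its TF-target map and the ground-truth record.

    The same seed reproduces the output bit-for-bit.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    G, S, T = params.n_genes, params.n_samples, params.n_tfs

    gene_ids = np.array([f"g{i:05d}" for i in range(G)], dtype=object)
    sample_ids = np.array([f"s{j:04d}" for j in range(S)], dtype=object)
    tf_ids = np.array([f"tf{f:03d}" for f in range(T)], dtype=object)

    n_iv = int(round(params.frac_stage_iv * S))
    n_iv = min(max(n_iv, 2), S - 2)
    if S < 4:
        raise ConfigurationError("need at least 4 samples (2 per stage)")
    stage = np.array(["I"] * S, dtype=object)
    stage[rng.choice(S, size=n_iv, replace=False)] = "IV"
    s_iv = stage == "IV"

    cnv = np.maximum(0.0, rng.normal(2.0, 0.4, size=(G, S)))
    meth = rng.beta(2.0, 5.0, size=(G, S))

    incidence = _dedupe_incidence(rng, _draw_incidence(rng, params))

    beta_cn = rng.normal(*params.beta_cn_dist, size=G)
    beta_me = rng.normal(*params.beta_me_dist, size=G)
    beta_tf = np.zeros(T)
    if params.n_active_tfs:
        active = np.sort(rng.choice(T, size=params.n_active_tfs, replace=False))
        signs = np.where(np.arange(params.n_active_tfs) % 2 == 0, 1.0, -1.0)
        beta_tf[active] = signs * params.active_beta_magnitude

    # planted stage-dependent shifts in the covariates themselves (disjoint
    # gene groups), so that attribution has known CNV/methylation mechanisms
    shift_pool = rng.permutation(G)
    cnv_idx = shift_pool[: params.n_cnv_shift_genes]
    meth_idx = shift_pool[
        params.n_cnv_shift_genes : params.n_cnv_shift_genes + params.n_meth_shift_genes
    ]
    if cnv_idx.size:
        cnv[np.ix_(cnv_idx, s_iv)] += params.cnv_shift_magnitude
        cnv[cnv_idx] = np.maximum(cnv[cnv_idx], 0.0)
    if meth_idx.size:
        meth[np.ix_(meth_idx, s_iv)] += params.meth_shift_magnitude
        meth[meth_idx] = np.clip(meth[meth_idx], 0.0, 1.0)

    tf_shift = incidence.T.astype(float) @ beta_tf  # per-gene stage-IV offset
    y = (
        beta_cn[:, None] * cnv
        + beta_me[:, None] * meth
        + tf_shift[:, None] * s_iv[None, :].astype(float)
    )
    if params.noise_sd > 0:
        y = y + rng.normal(0.0, params.noise_sd, size=(G, S))

    dataset = OmicsDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        expression=y,
        cnv=cnv,
        methylation=meth,
        stage=stage,
    ).validate()
    tfmap = TFTargetMap(
        tf_ids=tf_ids,
        gene_ids=gene_ids,
        incidence=incidence,
        provenance={t: [t] for t in tf_ids},
    )
    truth = SyntheticTruth(
        true_beta_cn=beta_cn,
        true_beta_me=beta_me,
        true_beta_tf=beta_tf,
        noise_sd=params.noise_sd,
        seed=params.seed,
        cnv_shift_genes=gene_ids[cnv_idx],
        meth_shift_genes=gene_ids[meth_idx],
    )
    return dataset, tfmap, truth


def permute_expression(
    dataset: OmicsDataset, seed: int, within_genes: bool = False
) -> OmicsDataset:
    """Return a copy of the dataset with expression values permuted.

    By default the permutation runs over the full gene x sample grid; with
    ``within_genes=True`` values are shuffled within each gene's row.
    """
    rng = np.random.default_rng(seed)
    expr = dataset.expression
    if within_genes:
        idx = np.argsort(rng.random(expr.shape), axis=1)
        permuted = np.take_along_axis(expr, idx, axis=1)
    else:
        permuted = rng.permutation(expr.ravel()).reshape(expr.shape)
    return dataset.with_expression(permuted)


def write_simulation(
    dataset: OmicsDataset,
    tfmap: TFTargetMap,
    truth: SyntheticTruth,
    outdir: str | Path,
) -> None:
    """Persist a simulated dataset in the package's on-disk dialect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_dataset(dataset, outdir)
    write_gmt(tfmap, outdir / "tf_targets.gmt")
    truth.to_frame(dataset.gene_ids, tfmap.tf_ids).to_csv(
        outdir / "truth.tsv", sep="\t", index=False, float_format="%.17g"
    )
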