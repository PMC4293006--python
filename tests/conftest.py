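import numpy as np
import pytest

from stagetf import SimulationParams, simulate_dataset
from stagetf.io_datasets import OmicsDataset, TFTargetMap


@pytest.fixture(scope="session")
def small_sim():
    """50 genes x 20 samples x 8 TFs with moderate noise."""
    params = SimulationParams(
        n_genes=50, n_samples=20, n_tfs=8, min_tfs=5, noise_sd=0.3, seed=1
    )
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def noiseless_sim():
    params = SimulationParams(
        n_genes=30, n_samples=16, n_tfs=6, min_tfs=3, noise_sd=0.0,
        n_active_tfs=3, seed=3,
    )
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def medium_sim():
    """Large enough for calibration / power checks, still fast."""
    params = SimulationParams(
        n_genes=400, n_samples=100, n_tfs=20, min_tfs=5, n_active_tfs=4,
        noise_sd=0.5, seed=17,
    )
    return simulate_dataset(params)


def make_dataset(expr, cnv, meth, stage, gene_ids=None, sample_ids=None):
    """Assemble an OmicsDataset from raw arrays without validation of stage
    counts (tests sometimes need degenerate shapes)."""
    expr = np.asarray(expr, dtype=float)
    n_genes, n_samples = expr.shape
    return OmicsDataset(
        gene_ids=np.asarray(
            gene_ids if gene_ids is not None else [f"g{i}" for i in range(n_genes)],
            dtype=object,
        ),
        sample_ids=np.asarray(
            sample_ids if sample_ids is not None else [f"s{j}" for j in range(n_samples)],
            dtype=object,
        ),
        expression=expr,
        cnv=np.asarray(cnv, dtype=float),
        methylation=np.asarray(meth, dtype=float),
        stage=np.asarray(stage, dtype=object),
    )


def attribution_scenario(seed=0, n_genes=240, n_samples=120, noise_sd=0.2):
    """Dataset with mutually exclusive planted mechanisms.

    Gene groups: 0-39 driven by a stage-IV copy-number gain, 40-79 by
    stage-IV hypermethylation, 80-119 by an activating TF, 120-159 by a
    repressing TF; the rest carry no stage signal.  Eight inactive
    background TFs bind (almost) all genes so every gene clears the
    degree filter.  Returns (dataset, tfmap, truth_flags) where
    truth_flags maps gene id -> (cnv, methylation, tf) booleans.
    """
    rng = np.random.default_rng(seed)
    G, S = n_genes, n_samples
    n_iv = S // 2
    stage = np.array(["I"] * (S - n_iv) + ["IV"] * n_iv, dtype=object)
    iv = stage == "IV"

    cnv = np.maximum(0.0, rng.normal(2.0, 0.4, (G, S)))
    meth = rng.beta(2.0, 5.0, (G, S))
    beta_cn = rng.normal(1.0, 0.15, G)
    beta_me = rng.normal(-2.0, 0.2, G)

    cnv_genes = np.arange(0, 40)
    meth_genes = np.arange(40, 80)
    tf_up_genes = np.arange(80, 120)
    tf_down_genes = np.arange(120, 160)

    cnv[np.ix_(cnv_genes, iv)] += 1.0
    meth[np.ix_(meth_genes, iv)] = np.clip(meth[np.ix_(meth_genes, iv)] + 0.4, 0, 1)

    # 8 inactive background TFs, each binding all genes except one
    # (distinct target sets), plus two active TFs with exclusive targets
    n_bg = 8
    inc = np.ones((n_bg + 2, G), dtype=np.int8)
    for f in range(n_bg):
        inc[f, f] = 0
    inc[n_bg] = 0
    inc[n_bg, tf_up_genes] = 1
    inc[n_bg + 1] = 0
    inc[n_bg + 1, tf_down_genes] = 1
    beta_tf = np.zeros(n_bg + 2)
    beta_tf[n_bg] = 1.2
    beta_tf[n_bg + 1] = -1.2

    tf_shift = inc.T.astype(float) @ beta_tf
    expr = (
        beta_cn[:, None] * cnv
        + beta_me[:, None] * meth
        + tf_shift[:, None] * iv[None, :].astype(float)
        + rng.normal(0.0, noise_sd, (G, S))
    )
    gene_ids = [f"g{i:04d}" for i in range(G)]
    dataset = make_dataset(expr, cnv, meth, stage, gene_ids=gene_ids)
    tfmap = make_tfmap(
        inc, gene_ids=gene_ids,
        tf_ids=[f"bg{f}" for f in range(n_bg)] + ["act_up", "act_down"],
    )
    truth_flags = {}
    for i in range(G):
        truth_flags[gene_ids[i]] = (
            i in cnv_genes,
            i in meth_genes,
            i in tf_up_genes or i in tf_down_genes,
        )
    return dataset, tfmap, truth_flags


def make_tfmap(incidence, gene_ids=None, tf_ids=None):
    incidence = np.asarray(incidence)
    n_tfs, n_genes = incidence.shape
    return TFTargetMap(
        tf_ids=np.asarray(
            tf_ids if tf_ids is not None else [f"tf{f}" for f in range(n_tfs)],
            dtype=object,
        ),
        gene_ids=np.asarray(
            gene_ids if gene_ids is not None else [f"g{i}" for i in range(n_genes)],
            dtype=object,
        ),
        incidence=incidence,
    )
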