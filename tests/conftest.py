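import warnings

import numpy as np
import pandas as pd
import pytest

import pbmustrat as pb

warnings.filterwarnings("ignore", message=".*Maximum number of iterations.*")


MID_SUBSET_SIZES = {"NKT": 20, "TH1": 20, "CD4_naive": 20, "CD8_naive": 20}
MID_SUBSET_SHIFT = {"NKT": 1.0, "TH1": -0.8, "CD4_naive": -0.8, "CD8_naive": -0.8}


def mid_config(**overrides) -> pb.SimulationConfig:
    """A medium-scale cohort config shared across tests (fast, well-powered)."""
    base = dict(
        n_cd_peripheral=40,
        frac_pbmu=0.37,
        n_nonibd=6,
        n_genes=3000,
        n_de_genes=300,
        de_log2fc=1.5,
        nb_dispersion=0.1,
        n_postop_pairs=16,
        subset_signature_sizes=dict(MID_SUBSET_SIZES),
        subset_shift=dict(MID_SUBSET_SHIFT),
        seed=11,
    )
    base.update(overrides)
    return pb.SimulationConfig(**base)


@pytest.fixture(scope="session")
def cohort():
    """Surgery + postop cohort at medium scale."""
    return pb.simulate.generate_postop(pb.generate_cohort(mid_config()))


@pytest.fixture(scope="session")
def log2_matrix(cohort):
    normed, _ = pb.median_of_ratios_normalize(cohort.counts)
    return pb.log2_transform(normed)


@pytest.fixture(scope="session")
def peripheral(cohort, log2_matrix):
    """(log2 matrix restricted to peripheral CD surgery samples, subtype labels)."""
    meta = cohort.metadata
    peri = meta[
        (meta["compartment"] == "peripheral")
        & (meta["disease"] == "CD")
        & (meta["timepoint"] == "surgery")
    ]
    return log2_matrix.subset_samples(peri.index), peri["subtype_label"]


@pytest.fixture(scope="session")
def subset_signatures(cohort):
    gt = cohort.gene_truth
    return {
        s: gt.index[gt["subset"] == s].tolist()
        for s in cohort.config.subset_signature_sizes
    }


@pytest.fixture(scope="session")
def subset_scores(peripheral, subset_signatures):
    mat, _ = peripheral
    return pb.enrichment.single_sample_enrichment(mat, subset_signatures, method="gsva")
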