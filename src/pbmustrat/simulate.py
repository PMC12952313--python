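"""Synthetic cohorts with the structure the stratification analysis assumes.

The generator emulates a surgical Crohn's disease (CD) cohort profiled in
CD3+ T cells: peripheral-blood samples split into two planted subtypes
(PBmu, whose profile is shifted toward the mucosal compartment, and PBT,
which resembles non-IBD blood), a mucosal compartment shared by CD and
non-IBD subjects, planted differentially expressed (DE) genes
(predominantly up in PBmu), planted T-cell-subset composition shifts
(NKT up; TH1 and CD4/CD8 memory/naive down in PBmu), paired post-surgery
samples whose PBmu signature reverts toward the PBT profile, an
eQTL risk-direction table whose polarized sum separates the subtypes by
construction, log-normal serologic titers coupled to subset composition,
and Bernoulli clinical covariates with logits linear in subset activity.

Counts are negative-binomial with log-normal gene abundances and log-normal
library sizes; every planted effect acts multiplicatively on the mean
(additively in log2 units) and is recorded in a truth table so recovery can
be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "CohortBundle",
    "generate_cohort",
    "generate_postop",
    "generate_eqtl_risk_table",
    "generate_serology",
    "generate_reference_profiles",
]

DEFAULT_SUBSET_SIZES = {
    "NKT": 50,
    "TH1": 50,
    "CD4_memory": 50,
    "CD4_naive": 50,
    "CD8_memory": 50,
    "CD8_naive": 50,
}

# Mean log2 shift of each subset's signature genes in PBmu relative to PBT.
DEFAULT_SUBSET_SHIFT = {
    "NKT": 1.0,
    "TH1": -0.8,
    "CD4_memory": -0.8,
    "CD4_naive": -0.8,
    "CD8_memory": -0.8,
    "CD8_naive": -0.8,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design: 100 peripheral CD samples with a
    37%/63% PBmu/PBT split, 17 non-IBD subjects, ~1,500 DE genes at
    twofold (log2FC 1) with >90% up in PBmu, 30 post-operative pairs with
    full reversion of the PBmu signature.
    """

    n_cd_peripheral: int = 100
    frac_pbmu: float = 0.37
    n_nonibd: int = 17
    n_genes: int = 10000
    n_de_genes: int = 1500
    de_log2fc: float = 1.0
    frac_de_up_in_pbmu: float = 0.92
    nb_dispersion: float = 0.1
    library_size_mean: int = 20_000_000
    n_postop_pairs: int = 30
    reversion_strength: float = 1.0
    subset_signature_sizes: dict = field(default_factory=lambda: dict(DEFAULT_SUBSET_SIZES))
    subset_shift: dict = field(default_factory=lambda: dict(DEFAULT_SUBSET_SHIFT))
    seed: int = 0
    # Magnitude (log2) of the mucosal-compartment shift on DE genes; PBmu
    # shares its direction, mucosal samples its full magnitude.
    mucosal_log2fc: float = 1.0
    # SD of per-sample subset activity around its subtype mean (log2 units).
    subset_activity_sd: float = 0.3

    def validate(self) -> None:
        for name in ("n_cd_peripheral", "n_nonibd", "n_genes", "n_de_genes",
                     "library_size_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_postop_pairs < 0:
            raise ValueError("n_postop_pairs must be >= 0")
        for name in ("frac_pbmu", "frac_de_up_in_pbmu", "reversion_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        n_sig = sum(self.subset_signature_sizes.values())
        if self.n_de_genes + n_sig > self.n_genes:
            raise ValueError(
                f"n_de_genes ({self.n_de_genes}) + subset signature genes "
                f"({n_sig}) exceed n_genes ({self.n_genes})"
            )
        n_pbmu = round(self.n_cd_peripheral * self.frac_pbmu)
        if n_pbmu < 2 or self.n_cd_peripheral - n_pbmu < 2:
            raise ValueError(
                "frac_pbmu leaves fewer than 2 samples in one subtype class"
            )


@dataclass
class CohortBundle:
    """Counts, metadata and planted ground truth for one synthetic cohort."""

    counts: ExpressionMatrix
    metadata: pd.DataFrame        # indexed by sample_id
    gene_truth: pd.DataFrame      # indexed by gene_id: is_de, de_log2fc, direction, subset
    sample_truth: pd.DataFrame    # indexed by sample_id: subtype + subset activities
    config: SimulationConfig
    # log2 shift applied to each (gene, sample) mean, kept for post-op reuse
    _shifts: pd.DataFrame | None = None
    _base_log2_mean: pd.Series | None = None
    _library_log_sd: float = 0.3

    def __post_init__(self) -> None:
        if not self.counts.sample_ids.equals(self.metadata.index):
            raise ValueError("counts columns and metadata rows must correspond 1:1")
        if not self.counts.gene_ids.equals(self.gene_truth.index):
            raise ValueError("gene truth must cover every gene")


def planted_differential(cohort: "CohortBundle") -> pd.Index:
    """Genes planted to differ between the PBmu and PBT subtypes.

    Covers the explicit DE block and every subset-signature gene whose
    subset carries a nonzero PBmu shift (those genes are genuinely
    differential by construction).
    """
    gt = cohort.gene_truth
    shifted_subsets = {
        s for s, v in cohort.config.subset_shift.items() if v != 0.0
    }
    mask = gt["is_de"] | gt["subset"].isin(shifted_subsets)
    return gt.index[mask]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB counts with var = m + dispersion * m^2 (gamma-Poisson mixture)."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate the surgery-timepoint cohort.

    Peripheral CD samples are split into PBmu/PBT; each CD and non-IBD
    subject also contributes a mucosal sample.  DE genes are shifted by
    ``de_log2fc`` in PBmu (sign per ``frac_de_up_in_pbmu``) and by
    ``mucosal_log2fc`` in the same direction in every mucosal sample, so
    the PBmu profile is mucosal-like in direction.  Subset-signature genes
    shift with a per-sample latent subset activity centred on
    ``subset_shift`` in PBmu.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_pbmu = round(config.n_cd_peripheral * config.frac_pbmu)
    n_pbt = config.n_cd_peripheral - n_pbmu

    genes = pd.Index([f"G{i:05d}" for i in range(config.n_genes)], name="gene_id")

    # --- sample table -------------------------------------------------
    rows = []
    for i in range(config.n_cd_peripheral):
        subj = f"CD{i:03d}"
        subtype = "PBmu" if i < n_pbmu else "PBT"
        rows.append((f"{subj}_P", subj, "peripheral", "CD", "surgery", subtype))
        rows.append((f"{subj}_M", subj, "mucosal", "CD", "surgery", "NA"))
    for i in range(config.n_nonibd):
        subj = f"NI{i:03d}"
        rows.append((f"{subj}_P", subj, "peripheral", "nonIBD", "surgery", "NA"))
        rows.append((f"{subj}_M", subj, "mucosal", "nonIBD", "surgery", "NA"))
    meta = pd.DataFrame(
        rows,
        columns=["sample_id", "subject_id", "compartment", "disease",
                 "timepoint", "subtype_label"],
    ).set_index("sample_id")

    # --- gene truth ---------------------------------------------------
    gene_truth = pd.DataFrame(
        {"is_de": False, "de_log2fc": 0.0, "direction": "", "subset": ""},
        index=genes,
    )
    de_idx = np.arange(config.n_de_genes)
    n_up = round(config.n_de_genes * config.frac_de_up_in_pbmu)
    signs = np.where(de_idx < n_up, 1.0, -1.0)
    gene_truth.iloc[de_idx, gene_truth.columns.get_loc("is_de")] = True
    gene_truth.iloc[de_idx, gene_truth.columns.get_loc("de_log2fc")] = signs * config.de_log2fc
    gene_truth.iloc[de_idx, gene_truth.columns.get_loc("direction")] = np.where(signs > 0, "up", "down")

    pos = config.n_de_genes
    for subset, size in config.subset_signature_sizes.items():
        gene_truth.iloc[pos:pos + size, gene_truth.columns.get_loc("subset")] = subset
        pos += size

    # --- per-sample subset activity (log2 units) ----------------------
    subsets = list(config.subset_signature_sizes)
    is_pbmu = (meta["subtype_label"] == "PBmu").to_numpy()
    act = {}
    for subset in subsets:
        mu = np.where(is_pbmu, config.subset_shift.get(subset, 0.0), 0.0)
        act[subset] = mu + rng.normal(0.0, config.subset_activity_sd, len(meta))
    sample_truth = pd.DataFrame(act, index=meta.index)
    sample_truth.insert(0, "subtype", meta["subtype_label"])

    # --- log2 shift matrix -------------------------------------------
    shifts = np.zeros((config.n_genes, len(meta)))
    de_fc = gene_truth["de_log2fc"].to_numpy()
    is_mucosal = (meta["compartment"] == "mucosal").to_numpy()
    shifts[:config.n_de_genes, :] += np.outer(
        de_fc[:config.n_de_genes], is_pbmu.astype(float)
    )
    # mucosal samples share the direction of the PBmu shift
    muc_mag = np.sign(de_fc[:config.n_de_genes]) * config.mucosal_log2fc
    shifts[:config.n_de_genes, :] += np.outer(muc_mag, is_mucosal.astype(float))
    for subset in subsets:
        sig = (gene_truth["subset"] == subset).to_numpy()
        shifts[sig, :] += sample_truth[subset].to_numpy()[None, :]

    # --- counts -------------------------------------------------------
    rel = rng.lognormal(0.0, 1.0, config.n_genes)
    rel /= rel.sum()
    base_mean = rel * config.library_size_mean          # per-gene mean count
    lib_sd = 0.3  # log-normal CV ~ 0.3 to exercise normalization
    lib = rng.lognormal(-0.5 * np.log(1 + lib_sd**2), np.sqrt(np.log(1 + lib_sd**2)), len(meta))
    mean = base_mean[:, None] * (2.0 ** shifts) * lib[None, :]
    counts = _nb_draw(rng, mean, config.nb_dispersion)

    # --- clinical covariates -----------------------------------------
    nkt = sample_truth.get("NKT", pd.Series(0.0, index=meta.index))
    cd48_cols = [c for c in subsets if c.startswith(("CD4", "CD8"))]
    cd48 = sample_truth[cd48_cols].mean(axis=1) if cd48_cols else pd.Series(0.0, index=meta.index)

    def bern(logit):
        return (rng.uniform(size=len(meta)) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    meta["stricture"] = np.where(bern(-0.5 + 1.5 * nkt.to_numpy()), "Y", "N")
    meta["perianal"] = np.where(bern(-1.0 + 1.5 * nkt.to_numpy()), "Y", "N")
    meta["perianal_penetrating"] = np.where(bern(-1.0 - 1.5 * cd48.to_numpy()), "Y", "N")
    meta["recurrence"] = np.where(bern(-0.5 - 1.5 * cd48.to_numpy()), "Y", "N")
    meta["resection_length"] = np.round(np.clip(rng.normal(15.0, 5.0, len(meta)), 2.0, None), 1)

    counts_em = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=meta.index), "raw_counts"
    )
    return CohortBundle(
        counts=counts_em,
        metadata=meta,
        gene_truth=gene_truth,
        sample_truth=sample_truth,
        config=config,
        _shifts=pd.DataFrame(shifts, index=genes, columns=meta.index),
        _base_log2_mean=pd.Series(np.log2(base_mean), index=genes),
        _library_log_sd=lib_sd,
    )


def generate_postop(cohort: CohortBundle, config: SimulationConfig | None = None) -> CohortBundle:
    """Add paired post-operative peripheral samples.

    The first ``n_postop_pairs`` peripheral CD subjects (covering both
    subtypes) gain a postop sample.  PBT subjects are re-drawn from their
    surgery distribution; PBmu subjects have every planted shift (DE and
    subset activity) attenuated by ``reversion_strength`` toward the PBT
    mean, so at strength 1 the PBmu signature fully reverts.
    """
    config = config or cohort.config
    rng = np.random.default_rng(config.seed + 1_000_003)

    peri = cohort.metadata[
        (cohort.metadata["compartment"] == "peripheral")
        & (cohort.metadata["disease"] == "CD")
        & (cohort.metadata["timepoint"] == "surgery")
    ]
    if peri.empty:
        raise ValueError("cohort has no peripheral surgery samples")
    if config.n_postop_pairs > len(peri):
        raise ValueError(
            f"n_postop_pairs={config.n_postop_pairs} exceeds the "
            f"{len(peri)} available peripheral CD subjects"
        )
    # interleave subtypes so both are represented
    pbmu_ids = peri.index[peri["subtype_label"] == "PBmu"].tolist()
    pbt_ids = peri.index[peri["subtype_label"] == "PBT"].tolist()
    n_pbmu = min(len(pbmu_ids), max(1, round(config.n_postop_pairs * len(pbmu_ids) / len(peri))))
    chosen = pbmu_ids[:n_pbmu] + pbt_ids[: config.n_postop_pairs - n_pbmu]

    genes = cohort.counts.gene_ids
    base_mean = 2.0 ** cohort._base_log2_mean.to_numpy()
    lib_sd = cohort._library_log_sd
    n_genes = len(genes)

    new_rows, new_cols, new_truth = [], [], []
    shifts_new = np.zeros((n_genes, len(chosen)))
    for j, pre_id in enumerate(chosen):
        subj = cohort.metadata.loc[pre_id, "subject_id"]
        subtype = cohort.metadata.loc[pre_id, "subtype_label"]
        post_id = f"{subj}_P_post"
        shift = cohort._shifts[pre_id].to_numpy().copy()
        if subtype == "PBmu":
            shift = shift * (1.0 - config.reversion_strength)
        shifts_new[:, j] = shift
        row = cohort.metadata.loc[pre_id].copy()
        row["timepoint"] = "postop"
        new_rows.append(row.rename(post_id))
        new_cols.append(post_id)
        tr = cohort.sample_truth.loc[pre_id].copy()
        for c in tr.index:
            if c != "subtype":
                tr[c] = tr[c] * (1.0 - config.reversion_strength) if subtype == "PBmu" else tr[c]
        new_truth.append(tr.rename(post_id))

    lib = rng.lognormal(-0.5 * np.log(1 + lib_sd**2), np.sqrt(np.log(1 + lib_sd**2)), len(chosen))
    mean = base_mean[:, None] * (2.0 ** shifts_new) * lib[None, :]
    counts_new = _nb_draw(rng, mean, config.nb_dispersion)

    counts = pd.concat(
        [cohort.counts.data,
         pd.DataFrame(counts_new, index=genes, columns=new_cols)], axis=1
    )
    meta = pd.concat([cohort.metadata, pd.DataFrame(new_rows)])
    meta.index.name = "sample_id"
    truth = pd.concat([cohort.sample_truth, pd.DataFrame(new_truth)])
    shifts = pd.concat(
        [cohort._shifts, pd.DataFrame(shifts_new, index=genes, columns=new_cols)], axis=1
    )
    return CohortBundle(
        counts=ExpressionMatrix(counts, "raw_counts"),
        metadata=meta,
        gene_truth=cohort.gene_truth,
        sample_truth=truth,
        config=config,
        _shifts=shifts,
        _base_log2_mean=cohort._base_log2_mean,
        _library_log_sd=lib_sd,
    )


def postop_pairs(cohort: CohortBundle) -> pd.DataFrame:
    """Pairing table (postop_sample_id, surgery_sample_id) for a cohort."""
    post = cohort.metadata[cohort.metadata["timepoint"] == "postop"]
    pre = cohort.metadata[
        (cohort.metadata["timepoint"] == "surgery")
        & (cohort.metadata["compartment"] == "peripheral")
    ]
    pre_by_subj = {s: i for i, s in pre["subject_id"].items()}
    return pd.DataFrame(
        {
            "postop_sample_id": post.index,
            "surgery_sample_id": [pre_by_subj[s] for s in post["subject_id"]],
        }
    )


def generate_eqtl_risk_table(cohort: CohortBundle, n_egenes: int = 142,
                             frac_risk_up: float = 0.9, seed: int = 0) -> pd.DataFrame:
    """Build an eGene risk-direction table aligned with the planted subtypes.

    A fraction ``frac_risk_up`` of eGenes are drawn from planted PBmu-up DE
    genes with direction +1 (higher expression = risk); the remainder from
    PBmu-down genes with direction -1 (low expression = risk, to be flipped
    by the score).  The polarized sum is therefore higher in PBmu by
    construction.
    """
    if n_egenes > len(cohort.gene_truth):
        raise ValueError("n_egenes exceeds the number of genes")
    if not 0.0 <= frac_risk_up <= 1.0:
        raise ValueError("frac_risk_up must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    up = cohort.gene_truth.index[
        cohort.gene_truth["is_de"] & (cohort.gene_truth["direction"] == "up")
    ].to_numpy()
    down = cohort.gene_truth.index[
        cohort.gene_truth["is_de"] & (cohort.gene_truth["direction"] == "down")
    ].to_numpy()
    n_up = min(round(n_egenes * frac_risk_up), len(up))
    n_down = min(n_egenes - n_up, len(down))
    n_up = n_egenes - n_down  # top up from 'up' pool if 'down' is short
    if n_up > len(up):
        raise ValueError("not enough planted DE genes for the requested table")
    sel_up = rng.choice(up, n_up, replace=False)
    sel_down = rng.choice(down, n_down, replace=False) if n_down else np.array([], dtype=object)
    table = pd.DataFrame(
        {
            "egene_id": np.concatenate([sel_up, sel_down]),
            "direction": np.concatenate([np.ones(n_up, int), -np.ones(n_down, int)]),
        }
    )
    table["snp_id"] = [f"rs{1_000_000 + i}" for i in range(len(table))]
    if table["egene_id"].duplicated().any():
        raise ValueError("duplicate eGene identifiers generated")
    return table.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)


ANALYTES = ("ASCA", "OmpC", "I2", "CBir1", "ANCA")


def generate_serology(cohort: CohortBundle, effect: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Log-normal ELISA titers for ASCA, OmpC, I2, CBir1 and ANCA.

    The (log) titer location of the four microbial analytes rises with the
    planted NKT activity and falls with CD4/CD8 activity, with strength
    ``effect``; ANCA is carried but uncoupled.  Resection length in the
    cohort metadata is re-drawn coupled to the latent titer sum (the Fig-3D
    association structure).
    """
    rng = np.random.default_rng(seed)
    peri = cohort.metadata[cohort.metadata["compartment"] == "peripheral"].index
    truth = cohort.sample_truth.loc[peri]
    nkt = truth["NKT"].to_numpy() if "NKT" in truth else np.zeros(len(peri))
    cd48_cols = [c for c in truth.columns if c.startswith(("CD4", "CD8"))]
    cd48 = truth[cd48_cols].mean(axis=1).to_numpy() if cd48_cols else np.zeros(len(peri))
    latent = effect * (nkt - cd48) + rng.normal(0.0, 0.3, len(peri))
    titers = {}
    for analyte in ANALYTES:
        loc = np.log(25.0)
        coupled = 0.0 if analyte == "ANCA" else latent
        titers[analyte] = np.exp(loc + coupled + rng.normal(0.0, 0.5, len(peri)))
    panel = pd.DataFrame(titers, index=peri)
    panel.index.name = "sample_id"
    # resection length coupled to the latent titer sum
    z = (latent - latent.mean()) / (latent.std() or 1.0)
    cohort.metadata.loc[peri, "resection_length"] = np.round(
        np.clip(15.0 + 4.0 * z + rng.normal(0.0, 2.0, len(peri)), 2.0, None), 1
    )
    return panel


def generate_reference_profiles(cohort: CohortBundle, n_profiles: int = 10,
                                seed: int = 0) -> tuple[pd.DataFrame, str]:
    """Reference mean-expression profiles for co-expression matching.

    One profile ("mucosal_like") is the mean log2 expression of the
    cohort's mucosal samples; the others are gene-permuted decoys of it.
    Returns (genes x profiles DataFrame, target profile id).
    """
    if n_profiles < 2:
        raise ValueError("need at least 2 profiles (target + decoy)")
    rng = np.random.default_rng(seed)
    muc = cohort.metadata.index[cohort.metadata["compartment"] == "mucosal"]
    if muc.empty:
        raise ValueError("cohort has no mucosal samples")
    log2 = np.log2(cohort.counts.data.loc[:, muc].to_numpy() + 1.0)
    target = log2.mean(axis=1)
    cols = {"mucosal_like": target}
    for i in range(n_profiles - 1):
        cols[f"decoy_{i:02d}"] = rng.permutation(target)
    ref = pd.DataFrame(cols, index=cohort.counts.gene_ids)
    return ref, "mucosal_like"
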