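"""Synthetic-data generators emulating the study's statistical structure.

Three kinds of inputs are produced, each with a serialized truth record so
parameter-recovery tests never have to re-read generator internals:

* a discovery methylation set — two groups of buffy-coat-like arrays whose
  beta values are mixtures of five leukocyte-type profiles (B, NK, CD4T,
  CD8T, neutrophils), with cell composition the dominant variance source,
  promoter CpGs spiked by a planted group difference, sex and hemoglobin
  covariate effects on the M scale, and QC blemishes (detection failures,
  SNP overlap, sex-chromosome placement) so the probe filter has work to do;
* a validation cohort — 766 stroke patients with age, sex, three vascular
  risk factors, 13 blood tests and a percent-methylation marker, drawn per
  imaging-feature stratum from configured (mean, SD), with exact per-
  combination counts for the WMH/lacune/microbleed flags and MCAR missing
  cells;
* a cell-type methylation panel — per-patient percent methylation for
  monocytes, T cells, B cells and buffy coat.

Beta noise is Beta-distributed around the mixture mean with a configurable
precision, which yields the bounded, heteroscedastic values that motivate
M-value testing. All draws flow from one ``numpy`` Generator seeded by the
caller: identical (config, seed) gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BetaMatrix, ProbeAnnotation

BETA_TRUNC = 1e-6

COMPARTMENTS = ("B", "NK", "CD4T", "CD8T", "Neu")
#: typical blood leukocyte proportions for the five compartments
BLOOD_PROPORTIONS = (0.08, 0.07, 0.18, 0.12, 0.55)

COMBO_KEYS = ("none", "wmh", "lacune", "microbleed", "wmh_lacune",
              "wmh_microbleed", "lacune_microbleed", "all")

#: printed validation-cohort combination counts (sum 766)
DEFAULT_COMBO_COUNTS = {
    "none": 53, "wmh": 221, "lacune": 24, "microbleed": 5,
    "wmh_lacune": 201, "wmh_microbleed": 81, "lacune_microbleed": 1,
    "all": 180,
}

#: per-variable (mean, SD) for the no-SVD and any-SVD strata
DEFAULT_GROUP_MEANS_SDS = {
    "age":               {"no_svd": (66.1, 5.7),  "any_svd": (71.8, 7.4)},
    "gpt":               {"no_svd": (24.3, 19.4), "any_svd": (23.5, 13.3)},
    "got":               {"no_svd": (27.9, 23.2), "any_svd": (26.3, 12.4)},
    "creatinine":        {"no_svd": (0.8, 0.2),   "any_svd": (0.8, 0.3)},
    "homocysteine":      {"no_svd": (9.2, 2.0),   "any_svd": (11.6, 4.4)},
    "total_cholesterol": {"no_svd": (183.3, 43.8), "any_svd": (179.7, 44.0)},
    "ldl":               {"no_svd": (108.7, 35.3), "any_svd": (108.4, 38.6)},
    "hdl":               {"no_svd": (49.2, 11.6), "any_svd": (46.8, 13.1)},
    "triglyceride":      {"no_svd": (123.1, 78.8), "any_svd": (140.2, 106.3)},
    "hs_crp":            {"no_svd": (2.3, 6.8),   "any_svd": (2.7, 7.1)},
    "wbc":               {"no_svd": (7.5, 2.0),   "any_svd": (7.6, 2.4)},
    "hemoglobin":        {"no_svd": (14.1, 1.4),  "any_svd": (13.7, 1.6)},
    "platelet":          {"no_svd": (237.7, 81.3), "any_svd": (228.7, 57.8)},
    "hba1c":             {"no_svd": (6.4, 1.6),   "any_svd": (6.3, 1.2)},
    "cdh7_methylation":  {"no_svd": (26.0, 9.3),  "any_svd": (23.1, 9.7)},
}

#: probability of the "yes"/"women" level per stratum
DEFAULT_BINARY_PROPS = {
    "sex_female":   {"no_svd": 0.302, "any_svd": 0.384},
    "hypertension": {"no_svd": 0.509, "any_svd": 0.616},
    "diabetes":     {"no_svd": 0.283, "any_svd": 0.320},
    "smoking":      {"no_svd": 0.208, "any_svd": 0.210},
}

BLOOD_TEST_COLUMNS = ("gpt", "got", "creatinine", "homocysteine",
                      "total_cholesterol", "ldl", "hdl", "triglyceride",
                      "hs_crp", "wbc", "hemoglobin", "platelet", "hba1c")

#: the 19 analysis variables of the validation stage
ANALYSIS_COLUMNS = ("age", "sex") + ("hypertension", "diabetes", "smoking") \
    + BLOOD_TEST_COLUMNS + ("cdh7_methylation",)

#: per-cell-type percent methylation (mean, SD) for the marker panel
DEFAULT_CELLTYPE_PARAMS = {
    "monocyte": (6.95, 5.46),
    "t_cell": (41.04, 10.23),
    "b_cell": (36.79, 10.80),
    "buffy_coat": (26.10, 9.80),
}


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside every synthetic dataset."""

    spiked_probe_ids: list = field(default_factory=list)
    planted_delta_beta: dict = field(default_factory=dict)
    cell_fractions: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, sort_keys=True, indent=1)
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(text + "\n", encoding="utf-8", newline="\n")
        return text

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**payload)


@dataclass
class DiscoveryConfig:
    """Generator settings for the discovery methylation set.

    Defaults reproduce the study design scale: 16 vs 16 samples, five
    leukocyte compartments dominating variance, 20 promoter CpGs spiked at
    a planted group difference of +0.125 on the beta scale, and sex and
    hemoglobin effects on the M scale. 20,000 probes keep suites fast; the
    probe count is a plain knob.
    """

    n_per_group: int = 16
    n_probes: int = 20_000
    k: int = 5
    n_spikes: int = 20
    spike_delta_beta: float = 0.125
    dirichlet_concentration: float = 10.0
    noise_precision: float = 300.0
    #: fraction of probes whose methylation differs between cell types
    celltype_informative_frac: float = 0.6
    celltype_logit_sd: float = 2.0
    sex_effect_m: float = 0.8
    sex_effect_frac: float = 0.02
    hb_effect_m: float = 0.25
    hb_effect_frac: float = 0.02
    detection_fail_rate: float = 0.01
    snp_rate: float = 0.015
    sex_chrom_rate: float = 0.02
    region_class_probs: tuple = (0.15, 0.15, 0.50, 0.20)  # TSS200/TSS1500/body/intergenic


def _logit2(p):
    return np.log2(p / (1.0 - p))


def _expit2(m):
    x = np.exp2(m)
    return x / (1.0 + x)


def generate_reference_profiles(
    k: int = 5,
    n_probes: int = 2000,
    seed: int = 0,
    labels=None,
    distinctness_floor: float = 0.05,
) -> pd.DataFrame:
    """Draw ``k`` distinct cell-type methylation profiles (probes x k).

    Columns default to the five leukocyte compartment labels when k == 5.
    Pairwise mean absolute differences between columns are guaranteed to be
    at least ``distinctness_floor`` (the cell-type deviation scale is grown
    until the floor is met).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_probes:
        raise ValueError("k must not exceed n_probes")
    if labels is None:
        labels = list(COMPARTMENTS) if k == 5 else [f"C{i+1}" for i in range(k)]
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.05, 0.95, size=n_probes)
    scale = max(0.8, 2.0 * distinctness_floor)
    for _ in range(60):
        dev = rng.normal(0.0, scale, size=(n_probes, k))
        prof = np.clip(_expit2(_logit2(base)[:, None] + dev), 0.01, 0.99)
        min_diff = min(
            float(np.abs(prof[:, i] - prof[:, j]).mean())
            for i in range(k) for j in range(i + 1, k))
        if min_diff >= distinctness_floor:
            probe_ids = [f"cg{1000000 + i:08d}" for i in range(n_probes)]
            return pd.DataFrame(prof, index=probe_ids, columns=list(labels))
        scale *= 1.4
    raise RuntimeError("could not reach the requested distinctness floor")


def _make_annotation(rng, probe_ids, cfg: DiscoveryConfig,
                     sample_ids) -> ProbeAnnotation:
    n = len(probe_ids)
    region = rng.choice(["TSS200", "TSS1500", "body", "intergenic"],
                        size=n, p=list(cfg.region_class_probs))
    dist = np.empty(n, dtype=int)
    for i, r in enumerate(region):
        if r == "TSS200":
            dist[i] = rng.integers(-200, 201)
        elif r == "TSS1500":
            mag = rng.integers(201, 1501)
            dist[i] = mag * (1 if rng.random() < 0.5 else -1)
        else:
            mag = rng.integers(1501, 100_000)
            dist[i] = mag * (1 if rng.random() < 0.5 else -1)
    chrom = rng.integers(1, 23, size=n).astype(str)
    sex_flag = rng.random(n) < cfg.sex_chrom_rate
    chrom[sex_flag] = rng.choice(["X", "Y"], size=int(sex_flag.sum()))
    snp_maf = np.full(n, np.nan)
    has_snp = rng.random(n) < cfg.snp_rate
    snp_maf[has_snp] = rng.uniform(0.001, 0.3, size=int(has_snp.sum()))
    island = np.where(np.isin(region, ["TSS200", "TSS1500"]),
                      rng.random(n) < 0.8, rng.random(n) < 0.1)
    genes = np.array([f"GENE{i // 3 + 1:05d}" for i in range(n)])

    detection = rng.uniform(0.0, 0.005, size=(n, len(sample_ids)))
    fails = rng.random(n) < cfg.detection_fail_rate
    fail_col = rng.integers(0, len(sample_ids), size=n)
    for i in np.where(fails)[0]:
        detection[i, fail_col[i]] = rng.uniform(0.02, 0.5)

    tab = pd.DataFrame(
        {
            "chrom": chrom,
            "dist_to_tss": dist,
            "region_class": region,
            "island_flag": island,
            "snp_maf": snp_maf,
            "sex_chrom_flag": sex_flag,
            "nearest_gene": genes,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    dp = pd.DataFrame(detection, index=tab.index, columns=list(sample_ids))
    return ProbeAnnotation(tab, detection_p=dp)


def generate_discovery_set(
    config: DiscoveryConfig | None = None, seed: int = 0
) -> tuple[BetaMatrix, pd.DataFrame, ProbeAnnotation, SimulationTruth]:
    """Generate the two-group discovery methylation set.

    Returns (beta matrix, sample sheet, probe annotation, truth record).
    The sample sheet carries group ("no_svd"/"all_svd"), sex and hemoglobin.
    """
    cfg = config or DiscoveryConfig()
    if cfg.n_per_group <= 0 or cfg.n_probes <= 0 or cfg.k <= 0:
        raise ValueError("dimensions must be positive")
    if cfg.n_spikes < 0:
        raise ValueError("n_spikes must be >= 0")
    rng = np.random.default_rng(seed)

    n_samples = 2 * cfg.n_per_group
    sample_ids = [f"S{i+1:03d}" for i in range(n_samples)]
    group = np.array(["no_svd"] * cfg.n_per_group + ["all_svd"] * cfg.n_per_group)

    annot = _make_annotation(rng, [f"cg{i:08d}" for i in range(cfg.n_probes)],
                             cfg, sample_ids)
    probe_ids = annot.probe_ids

    # cell-type profiles: shared base + deviations on an informative subset
    base = rng.uniform(0.05, 0.95, size=cfg.n_probes)
    informative = rng.random(cfg.n_probes) < cfg.celltype_informative_frac
    dev = np.zeros((cfg.n_probes, cfg.k))
    dev[informative] = rng.normal(0.0, cfg.celltype_logit_sd,
                                  size=(int(informative.sum()), cfg.k))
    profiles = np.clip(_expit2(_logit2(base)[:, None] + dev), 0.02, 0.98)

    props = np.array(BLOOD_PROPORTIONS[: cfg.k])
    props = props / props.sum()
    fractions = rng.dirichlet(cfg.dirichlet_concentration * props,
                              size=n_samples)  # samples x k
    mu = profiles @ fractions.T  # probes x samples

    # covariates on the M scale
    sex = np.array(
        [("F" if i % 2 else "M") for i in range(cfg.n_per_group)]
        + [("F" if i % 2 else "M") for i in range(cfg.n_per_group)])
    hemoglobin = np.round(rng.normal(13.9, 1.5, size=n_samples), 2)
    sex_probes = rng.random(cfg.n_probes) < cfg.sex_effect_frac
    hb_probes = rng.random(cfg.n_probes) < cfg.hb_effect_frac
    m = _logit2(np.clip(mu, 0.01, 0.99))
    sex_num = (sex == "F").astype(float) - 0.5
    hb_centered = hemoglobin - hemoglobin.mean()
    m[sex_probes] += cfg.sex_effect_m * sex_num[None, :]
    m[hb_probes] += cfg.hb_effect_m * hb_centered[None, :]
    mu = _expit2(m)

    # spikes: planted group difference at clean promoter probes
    tab = annot.table
    qc_pass = (
        tab["snp_maf"].isna()
        & ~tab["sex_chrom_flag"]
        & (annot.detection_p.to_numpy() < 0.01).all(axis=1)
        & ~sex_probes & ~hb_probes
    ).to_numpy()
    clean = qc_pass & tab["region_class"].isin(["TSS200", "TSS1500"]).to_numpy()
    test_mask = group == "all_svd"
    delta = cfg.spike_delta_beta
    margin = 0.02
    feasible = clean & (mu[:, test_mask].max(axis=1) + delta < 1.0 - margin) \
        & (mu[:, test_mask].min(axis=1) + delta > margin)
    candidates = np.where(feasible)[0]
    if cfg.n_spikes > len(candidates):
        raise ValueError(
            "spike delta beta would push a group mean outside (0,1) at every "
            "available clean promoter probe; reduce spike_delta_beta or "
            "n_spikes")
    spike_idx = np.sort(rng.choice(candidates, size=cfg.n_spikes, replace=False)) \
        if cfg.n_spikes else np.array([], dtype=int)
    mu[np.ix_(spike_idx, np.where(test_mask)[0])] += delta

    # Beta-distributed observation noise around the mixture mean
    nu = cfg.noise_precision
    beta_obs = rng.beta(mu * nu, (1.0 - mu) * nu)
    beta_obs = np.clip(beta_obs, BETA_TRUNC, 1.0 - BETA_TRUNC)

    beta = BetaMatrix(pd.DataFrame(beta_obs, index=probe_ids, columns=sample_ids))
    sheet = pd.DataFrame(
        {"group": group, "sex": sex, "hemoglobin": hemoglobin},
        index=pd.Index(sample_ids, name="sample_id"))

    # marker reference: cell-type-informative, QC-clean, unspiked probes,
    # exposed so a reference-based arm can project onto known profiles
    marker_pool = np.where(informative & qc_pass)[0]
    marker_pool = np.setdiff1d(marker_pool, spike_idx)
    marker_idx = marker_pool[: 2000]
    reference = {probe_ids[i]: [round(float(v), 6) for v in profiles[i]]
                 for i in marker_idx}

    truth = SimulationTruth(
        spiked_probe_ids=[probe_ids[i] for i in spike_idx],
        planted_delta_beta={probe_ids[i]: cfg.spike_delta_beta for i in spike_idx},
        cell_fractions={sid: fractions[j].tolist()
                        for j, sid in enumerate(sample_ids)},
        covariate_effects={"sex_m": cfg.sex_effect_m, "hemoglobin_m": cfg.hb_effect_m},
        seed=int(seed),
        extras={"compartments": list(COMPARTMENTS[: cfg.k]),
                "n_per_group": cfg.n_per_group,
                "reference_profiles": reference},
    )
    return beta, sheet, annot, truth


@dataclass
class CohortGenConfig:
    """Generator settings for the validation cohort.

    Defaults equal the printed cohort description: 766 patients split over
    the eight WMH/lacune/microbleed combinations (exact counts), continuous
    variables drawn per stratum from the published (mean, SD), and 3.8%
    missing cells inserted completely at random.
    """

    group_means_sds: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GROUP_MEANS_SDS.items()})
    binary_props: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BINARY_PROPS.items()})
    combo_counts: dict = field(default_factory=lambda: dict(DEFAULT_COMBO_COUNTS))
    missing_rate: float = 0.038
    multinomial_counts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for key, count in self.combo_counts.items():
            if key not in COMBO_KEYS:
                raise ValueError(f"unknown combination key {key!r}")
            if int(count) != count or count < 0:
                raise ValueError("combo counts must be non-negative integers")
        for var, per_group in self.group_means_sds.items():
            for _, (mean, sd) in per_group.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {var}")


_COMBO_FLAGS = {
    "none": (0, 0, 0), "wmh": (1, 0, 0), "lacune": (0, 1, 0),
    "microbleed": (0, 0, 1), "wmh_lacune": (1, 1, 0),
    "wmh_microbleed": (1, 0, 1), "lacune_microbleed": (0, 1, 1),
    "all": (1, 1, 1),
}


def generate_validation_cohort(
    config: CohortGenConfig | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate the clinical validation cohort with imaging-feature flags.

    Returns (cohort table, truth). The truth record stores the true values
    of every cell later blanked by MCAR missingness under
    ``extras["missing_cells"]`` as [patient_id, column, value] triples.
    """
    cfg = config or CohortGenConfig()
    rng = np.random.default_rng(cfg.seed)

    counts = dict(cfg.combo_counts)
    if cfg.multinomial_counts:
        total = sum(counts.values())
        probs = np.array([counts[k] for k in COMBO_KEYS], dtype=float)
        draw = rng.multinomial(total, probs / probs.sum())
        counts = {k: int(c) for k, c in zip(COMBO_KEYS, draw)}

    rows = []
    for key in COMBO_KEYS:
        w, l, mb = _COMBO_FLAGS[key]
        for _ in range(int(counts.get(key, 0))):
            rows.append((w, l, mb))
    n = len(rows)
    flags = pd.DataFrame(rows, columns=["wmh", "lacune", "microbleed"])
    flags.index = pd.Index([f"P{i+1:04d}" for i in range(n)], name="patient_id")
    stratum = np.where(flags.sum(axis=1) > 0, "any_svd", "no_svd")

    data = {}
    for var, per_group in cfg.group_means_sds.items():
        vals = np.empty(n)
        for g in ("no_svd", "any_svd"):
            mask = stratum == g
            mean, sd = per_group[g]
            vals[mask] = rng.normal(mean, sd, size=int(mask.sum()))
        if var == "cdh7_methylation":
            vals = np.clip(vals, 0.0, 100.0)
        data[var] = np.round(vals, 4)
    for var, per_group in cfg.binary_props.items():
        vals = np.empty(n, dtype=object)
        for g in ("no_svd", "any_svd"):
            mask = stratum == g
            draw = rng.random(int(mask.sum())) < per_group[g]
            if var == "sex_female":
                vals[mask] = np.where(draw, "F", "M")
            else:
                vals[mask] = draw.astype(int)
        data["sex" if var == "sex_female" else var] = vals

    cohort = pd.DataFrame(data, index=flags.index)
    cohort = cohort[list(ANALYSIS_COLUMNS)]
    cohort = pd.concat([cohort, flags], axis=1)

    missing_cells = []
    if cfg.missing_rate > 0:
        mask = rng.random((n, len(ANALYSIS_COLUMNS))) < cfg.missing_rate
        for i, j in zip(*np.where(mask)):
            pid = cohort.index[i]
            col = ANALYSIS_COLUMNS[j]
            missing_cells.append([pid, col, cohort.at[pid, col]])
            cohort.at[pid, col] = np.nan

    truth = SimulationTruth(
        seed=int(cfg.seed),
        extras={
            "combo_counts": {k: int(counts.get(k, 0)) for k in COMBO_KEYS},
            "missing_cells": [[p, c, (v if isinstance(v, str) else float(v))]
                              for p, c, v in missing_cells],
        },
    )
    return cohort, truth


def generate_celltype_panel(
    n_patients: int = 89, seed: int = 0, params: dict | None = None
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Per-patient percent methylation for monocyte / T cell / B cell /
    buffy coat, drawn from configured (mean, SD) truncated to [0, 100]."""
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2 (ANOVA undefined otherwise)")
    p = dict(DEFAULT_CELLTYPE_PARAMS)
    if params:
        p.update(params)
    rng = np.random.default_rng(seed)
    data = {}
    for cell, (mean, sd) in p.items():
        data[cell] = np.clip(rng.normal(mean, sd, size=n_patients), 0.0, 100.0)
    panel = pd.DataFrame(
        data, index=pd.Index([f"P{i+1:03d}" for i in range(n_patients)],
                             name="patient_id"))
    truth = SimulationTruth(seed=int(seed), extras={"params": {k: list(v) for k, v in p.items()}})
    return panel, truth
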