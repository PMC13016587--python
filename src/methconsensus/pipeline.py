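"""End-to-end orchestration of the discovery and validation stages.

Discovery sequences: probe filter -> M-values -> cell-composition
estimation (two arms: reference-free latent components, reference-based
leukocyte fractions) -> per-arm covariate/surrogate-variable design ->
moderated differential testing -> beta-scale effect sizes -> FDR ->
inflation factor -> dual-arm consensus -> variance partition. Validation
sequences: imputation -> group comparisons -> subgroup census ->
hierarchical logistic regression -> multinomial subgroup models. Every
artifact is written with the config hash and seed in a manifest, and a
rerun with identical (config, seed) reproduces identical bytes.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import deconv, design, dmp, io, qc, simulate, transforms
from .config import RunConfig
from .containers import BetaMatrix

log = logging.getLogger(__name__)


@dataclass
class ArmResult:
    name: str
    dmp_table: pd.DataFrame
    lam: float
    design: design.AnalysisDesign
    ebayes: dmp.EBayesParams
    variance: pd.DataFrame
    sv_records: list
    pc_associations: pd.DataFrame
    explained_variance: np.ndarray


@dataclass
class DiscoveryResult:
    consensus: pd.DataFrame
    arms: dict
    filter_report: qc.FilterReport
    strict_hits: dict
    truth: simulate.SimulationTruth | None = None
    manifest: dict = field(default_factory=dict)


def _load_or_simulate_discovery(config: RunConfig):
    if config.beta_path:
        beta = io.read_beta_matrix(config.beta_path)
        sheet = io.read_sample_sheet(config.sample_sheet_path)
        annot = io.read_annotation(config.annotation_path,
                                   config.detection_p_path)
        return beta, sheet, annot, None, None
    gen_cfg = simulate.DiscoveryConfig(
        n_per_group=config.n_per_group, n_probes=config.n_probes,
        k=config.k, n_spikes=config.n_spikes,
        spike_delta_beta=config.spike_delta_beta)
    beta, sheet, annot, truth = simulate.generate_discovery_set(
        gen_cfg, seed=config.seed)
    reference = pd.DataFrame.from_dict(
        truth.extras["reference_profiles"], orient="index",
        columns=truth.extras["compartments"])
    return beta, sheet, annot, truth, reference


def build_arm_design(
    m, sheet: pd.DataFrame, composition: pd.DataFrame, config: RunConfig,
    group_col: str = "group", test_label: str = "all_svd", seed: int = 0,
):
    """Assemble one arm's capped design: group + composition + screened
    metadata covariates + retained surrogate variables."""
    group = (sheet[group_col] == test_label).astype(int)
    group.name = "group"
    n_samples = len(group)

    n_comp = min(10, min(m.values.shape) - 1)
    pca = design.pca_samples(m, n_comp)
    metadata = sheet.drop(columns=[group_col])
    selected, assoc = design.discover_covariates(
        pca.scores, metadata, alpha=config.alpha, max_pcs=config.max_pcs)
    if len(assoc):
        strength = assoc.set_index("variable")["min_p"]
        selected = sorted(selected, key=lambda c: (strength[c], c))

    covariates = pd.concat([composition, metadata[selected]], axis=1)
    priority = list(composition.columns) + selected

    pre = design.AnalysisDesign(
        group=group, covariates=covariates,
        svs=pd.DataFrame(index=sheet.index), cap=n_samples)
    svs = design.build_surrogate_variables(
        m, pre.matrix(), n_sv_max=config.n_sv_max, seed=seed)
    records = design.exclude_confounded_svs(
        svs, group, p_exclude=config.sv_p_exclude,
        eta2_exclude=config.sv_eta2_exclude)
    retained = [r.sv_id for r in records if r.retained]
    arm_design = design.cap_design(
        group, covariates, svs[retained], n_samples,
        cap_fraction=config.cap_fraction, covariate_priority=priority)
    return arm_design, records, assoc, pca


def _run_arm(
    name: str, beta: BetaMatrix, m, sheet, composition, config: RunConfig,
) -> ArmResult:
    arm_design, sv_records, assoc, pca = build_arm_design(
        m, sheet, composition, config, seed=config.seed)
    x = arm_design.matrix()
    fit, ebayes = dmp.moderated_fit(m, x, contrast="group")
    dbeta = dmp.delta_beta(beta, arm_design.group)
    table = dmp.build_dmp_table(fit, dbeta)
    lam = dmp.genomic_lambda(np.clip(table["p"].to_numpy(), 1e-300, 1.0)).lam

    groups = arm_design.term_groups()
    factor_groups = {"group": groups["group"]}
    comp_cols = [c for col in composition.columns for c in groups.get(col, [])]
    if comp_cols:
        factor_groups["composition"] = comp_cols
    for col in arm_design.covariates.columns:
        if col not in composition.columns:
            factor_groups[col] = groups[col]
    sv_cols = [c for col in arm_design.svs.columns for c in groups.get(col, [])]
    if sv_cols:
        factor_groups["SVs"] = sv_cols
    variance = dmp.variance_partition(m, x, factor_groups)

    return ArmResult(name=name, dmp_table=table, lam=lam, design=arm_design,
                     ebayes=ebayes, variance=variance, sv_records=sv_records,
                     pc_associations=assoc,
                     explained_variance=pca.explained_variance)


def run_discovery(config: RunConfig, out_dir=None) -> DiscoveryResult:
    """Run the full discovery stage; write artifacts when ``out_dir`` set."""
    t0 = time.time()
    beta, sheet, annot, truth, reference = _load_or_simulate_discovery(config)
    if reference is None:
        raise ValueError("discovery from external files requires a reference "
                         "profile table; supply one or run in simulate mode")

    filtered, report = qc.filter_probes(
        beta, annot, detection_p_max=config.detection_p_max,
        snp_maf_min=config.snp_maf_min)
    log.info("probe filter: %d -> %d", report.n_input, report.n_retained)
    m = transforms.beta_to_m(filtered, offset=config.m_offset)

    rf = deconv.reference_free_decompose(filtered, k=config.k,
                                         seed=config.seed)
    rb = deconv.reference_based_project(filtered, reference)
    # fractions sum to one, so drop the last compartment to keep the
    # intercept-bearing design full rank
    rb_cov = rb.loadings.iloc[:, :-1]

    arm_a = _run_arm("reference_free", filtered, m, sheet, rf.loadings, config)
    arm_b = _run_arm("reference_based", filtered, m, sheet, rb_cov, config)

    consensus = dmp.call_consensus(
        arm_a.dmp_table, arm_b.dmp_table, annot,
        p_max=config.p_consensus, delta_beta_min=config.delta_beta_min)
    strict = {
        arm.name: dmp.strict_fdr_significance(
            arm.dmp_table, fdr_alpha=config.fdr_alpha,
            delta_beta_min=config.delta_beta_min)
        for arm in (arm_a, arm_b)}

    result = DiscoveryResult(
        consensus=consensus, arms={a.name: a for a in (arm_a, arm_b)},
        filter_report=report, strict_hits=strict, truth=truth)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        outputs = {}

        def _write(key, fn, path):
            fn(out / path)
            outputs[key] = path

        _write("filter_report",
               lambda p: _dump_json(_report_dict(report), p),
               "filter_report.json")
        for arm in (arm_a, arm_b):
            _write(f"dmp_{arm.name}",
                   lambda p, a=arm: io.write_result_table(
                       a.dmp_table.reset_index(names="probe_id"), p),
                   f"dmp_{arm.name}.tsv")
            _write(f"variance_{arm.name}",
                   lambda p, a=arm: io.write_result_table(
                       a.variance.reset_index(names="factor"), p, sep=","),
                   f"variance_partition_{arm.name}.csv")
            _write(f"pc_associations_{arm.name}",
                   lambda p, a=arm: io.write_result_table(
                       a.pc_associations, p, sep=","),
                   f"pc_associations_{arm.name}.csv")
            _write(f"strict_fdr_{arm.name}",
                   lambda p, a=arm: io.write_result_table(
                       strict[a.name].reset_index(names="probe_id"), p),
                   f"strict_fdr_{arm.name}.tsv")
        _write("lambda",
               lambda p: _dump_json({a.name: a.lam for a in (arm_a, arm_b)}, p),
               "genomic_lambda.json")
        _write("consensus",
               lambda p: io.write_result_table(
                   consensus.reset_index(), p),
               "consensus_dmps.tsv")
        if truth is not None:
            _write("truth", lambda p: truth.to_json(p) and None, "truth.json")

        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stage": "discovery",
            "outputs": outputs,
            "n_probes_input": report.n_input,
            "n_probes_retained": report.n_retained,
            "wall_time_s": round(time.time() - t0, 2),
        }
        _dump_json(manifest, out / "manifest_discovery.json")
        result.manifest = manifest
    return result


@dataclass
class ValidationResult:
    comparison: pd.DataFrame
    census: cohort_mod.SubgroupCensus
    labels: pd.DataFrame
    base_fit: cohort_mod.LogisticFit
    augmented_fit: cohort_mod.LogisticFit
    delta_auc: float
    multinomial: dict
    notes: list
    manifest: dict = field(default_factory=dict)


def run_validation(config: RunConfig, cohort: pd.DataFrame | None = None,
                   out_dir=None) -> ValidationResult:
    """Run the full validation stage on a cohort table (simulated when
    none is supplied)."""
    t0 = time.time()
    if cohort is None:
        if config.cohort_path:
            cohort = io.read_cohort(config.cohort_path)
        else:
            cohort, _ = simulate.generate_validation_cohort(
                simulate.CohortGenConfig(missing_rate=config.missing_rate,
                                         seed=config.seed))
    for col in cohort_mod.FLAG_COLUMNS:
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing outcome flag column {col!r}")

    complete, _ = cohort_mod.impute_missing(
        cohort, seed=config.seed, mode=config.imputation_mode)
    labels, census = cohort_mod.build_subgroups(complete[list(cohort_mod.FLAG_COLUMNS)])
    any_svd = labels["any_svd"].astype(int)
    comparison = cohort_mod.compare_groups(complete, any_svd)
    base_fit, aug_fit, d_auc = cohort_mod.hierarchical_logistic(
        complete, any_svd)

    multinomial = {}
    notes = []
    for feature in ("wmh", "lacune", "microbleed"):
        lab = labels[f"{feature}_label"]
        cat = pd.Series(
            np.where(~labels["any_svd"], "no_svd",
                     np.where(lab == "isolated", f"isolated_{feature}",
                              np.where(lab == "coexistence",
                                       f"coexistence_{feature}", "other"))),
            index=labels.index)
        mask = cat != "other"
        try:
            fits, skip = cohort_mod.multinomial_fit(
                complete.loc[mask], cat[mask],
                min_category_n=config.min_multinomial_n)
            multinomial[feature] = fits
            notes.extend(f"{feature}: {s}" for s in skip)
        except ValueError as exc:
            notes.append(f"{feature}: skipped ({exc})")

    result = ValidationResult(
        comparison=comparison, census=census, labels=labels,
        base_fit=base_fit, augmented_fit=aug_fit, delta_auc=d_auc,
        multinomial=multinomial, notes=notes)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        outputs = {}
        io.write_result_table(comparison.reset_index(), out / "group_comparison.csv",
                              sep=",")
        outputs["comparison"] = "group_comparison.csv"
        _dump_json({"combo_counts": census.combo_counts,
                    "subgroup_counts": census.subgroup_counts,
                    "percentages": census.percentages,
                    "n_total": census.n_total,
                    "notes": notes},
                   out / "census.json")
        outputs["census"] = "census.json"
        logit = pd.concat(
            [base_fit.terms.assign(model="base"),
             aug_fit.terms.assign(model="base+methylation")])
        io.write_result_table(logit.reset_index(names="term"),
                              out / "logistic_models.csv", sep=",")
        outputs["logistic"] = "logistic_models.csv"
        _dump_json({"auc_base": base_fit.auc, "auc_base_ci": list(base_fit.auc_ci),
                    "auc_augmented": aug_fit.auc,
                    "auc_augmented_ci": list(aug_fit.auc_ci),
                    "delta_auc": d_auc}, out / "auc.json")
        outputs["auc"] = "auc.json"
        multi_rows = []
        for feature, fits in multinomial.items():
            for cat_name, tab in fits.items():
                multi_rows.append(tab.assign(category=cat_name, feature=feature))
        if multi_rows:
            io.write_result_table(
                pd.concat(multi_rows).reset_index(names="term"),
                out / "multinomial_models.csv", sep=",")
            outputs["multinomial"] = "multinomial_models.csv"
        manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                    "stage": "validation", "outputs": outputs,
                    "wall_time_s": round(time.time() - t0, 2)}
        _dump_json(manifest, out / "manifest_validation.json")
        result.manifest = manifest
    return result


def _report_dict(report: qc.FilterReport) -> dict:
    return {"n_input": report.n_input, "n_retained": report.n_retained,
            "removed_detection_p": report.removed_detection_p,
            "removed_snp": report.removed_snp,
            "removed_sex_chrom": report.removed_sex_chrom}


def _dump_json(payload, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n",
                          encoding="utf-8", newline="\n")
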