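"""Run configuration: one structured file holding every threshold and seed.

Defaults are the screening constants the pipeline is built around
(detection p < 0.01, SNP MAF >= 0.01 removed, M offset 1e-4, K = 5
composition components, covariate-screen alpha 0.01 over up to 5 PCs, SV
exclusion at p < 1e-6 or eta-squared > 0.5, adjustment terms capped at 25%
of n, consensus p < 0.05 with |delta beta| > 0.10, FDR alpha 0.05,
pyrosequencing positivity > 5%). The config round-trips through YAML
unchanged and hashes stably, so a manifest can certify what produced an
output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # probe QC
    detection_p_max: float = 0.01
    snp_maf_min: float = 0.01
    # transforms
    m_offset: float = 1e-4
    # composition
    k: int = 5
    # covariate / SV discovery
    alpha: float = 0.01
    max_pcs: int = 5
    n_sv_max: int = 5
    sv_p_exclude: float = 1e-6
    sv_eta2_exclude: float = 0.5
    cap_fraction: float = 0.25
    # DMP calling
    p_consensus: float = 0.05
    delta_beta_min: float = 0.10
    fdr_alpha: float = 0.05
    # validation
    pyroseq_threshold: float = 5.0
    min_multinomial_n: int = 10
    imputation_mode: str = "forest"
    # synthetic-data scale
    n_per_group: int = 16
    n_probes: int = 20_000
    n_spikes: int = 20
    spike_delta_beta: float = 0.125
    missing_rate: float = 0.038
    # seeds
    seed: int = 0
    # stage toggles
    run_discovery_stage: bool = True
    run_validation_stage: bool = True
    # paths (optional external inputs)
    beta_path: str | None = None
    sample_sheet_path: str | None = None
    annotation_path: str | None = None
    detection_p_path: str | None = None
    cohort_path: str | None = None
    out_dir: str = "results"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8", newline="\n")
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
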