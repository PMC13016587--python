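"""Probe quality filtering.

A probe is retained when it passes all three rules:
  1. detection p-value strictly below the threshold in ALL samples,
  2. no overlap with a common SNP (overlapping SNP allowed only when its
     MAF is strictly below the threshold),
  3. not on a sex chromosome.

The report attributes each removed probe to the first rule it fails, in
the order detection-p, SNP, sex chromosome; attribution order affects the
report only, never the retained set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import BetaMatrix, ProbeAnnotation, is_sex_chrom

DETECTION_P_MAX = 0.01
SNP_MAF_MIN = 0.01


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    removed_detection_p: int
    removed_snp: int
    removed_sex_chrom: int
    removed_probe_ids: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.removed_detection_p + self.removed_snp + self.removed_sex_chrom


def filter_probes(
    beta: BetaMatrix,
    annot: ProbeAnnotation,
    detection_p_max: float = DETECTION_P_MAX,
    snp_maf_min: float = SNP_MAF_MIN,
) -> tuple[BetaMatrix, FilterReport]:
    """Apply the three retention rules; returns the retained matrix and a
    report with per-rule removal counts (first-matching attribution)."""
    annot.require_probes(beta.probe_ids)
    probes = beta.probe_ids
    tab = annot.table.loc[probes]

    if annot.detection_p is not None:
        dp = annot.detection_p.loc[probes, beta.sample_ids].to_numpy(dtype=float)
        pass_detection = (dp < detection_p_max).all(axis=1)
    else:
        pass_detection = np.ones(len(probes), dtype=bool)

    maf = tab["snp_maf"].to_numpy(dtype=float)
    pass_snp = np.isnan(maf) | (maf < snp_maf_min)

    pass_sex = ~np.array(
        [is_sex_chrom(c) or bool(f)
         for c, f in zip(tab["chrom"], tab["sex_chrom_flag"])]
    )

    retained_mask = pass_detection & pass_snp & pass_sex
    reasons: dict[str, str] = {}
    for i, pid in enumerate(probes):
        if retained_mask[i]:
            continue
        if not pass_detection[i]:
            reasons[pid] = "detection_p"
        elif not pass_snp[i]:
            reasons[pid] = "snp"
        else:
            reasons[pid] = "sex_chrom"

    retained = [p for p, keep in zip(probes, retained_mask) if keep]
    report = FilterReport(
        n_input=len(probes),
        n_retained=len(retained),
        removed_detection_p=sum(r == "detection_p" for r in reasons.values()),
        removed_snp=sum(r == "snp" for r in reasons.values()),
        removed_sex_chrom=sum(r == "sex_chrom" for r in reasons.values()),
        removed_probe_ids=reasons,
    )
    return beta.subset_probes(retained), report
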