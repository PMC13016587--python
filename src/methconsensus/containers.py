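"""Core in-memory containers for methylation-array data.

The pipeline's central object is a matrix of beta values (methylation
fractions, probes x samples), accompanied by per-probe genomic annotation
(promoter class, SNP overlap, sex-chromosome placement, per-sample
detection p-values). Both are thin wrappers over pandas DataFrames with
validation at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BETA_FLOOR = 1e-6
BETA_CEIL = 1.0 - 1e-6

REGION_CLASSES = ("TSS200", "TSS1500", "body", "intergenic")


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dup[:5]}")


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta values in the open (0,1).

    Parameters
    ----------
    values
        DataFrame indexed by probe id, one column per sample id.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and (arr <= 0.0).any() or (arr >= 1.0).any():
            raise ValueError(
                "beta values must lie strictly inside (0,1); "
                "use io.clamp_beta or load via io.read_beta_matrix"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids)])


@dataclass
class MValueMatrix:
    """Probes x samples matrix on the M scale (log2 logit of beta).

    ``offset`` is the small positive constant added to numerator and
    denominator of the logit so boundary betas stay finite.
    """

    values: pd.DataFrame
    offset: float = 1e-4

    def __post_init__(self) -> None:
        if self.offset <= 0:
            raise ValueError("offset must be > 0")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("M-values must be finite everywhere")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProbeAnnotation:
    """Per-probe genomic metadata plus per-sample detection p-values.

    ``table`` is indexed by probe id with columns:
      chrom           chromosome name ("1".."22", "X", "Y", chr-prefixed ok)
      dist_to_tss     signed distance to the nearest TSS, base pairs
      region_class    one of TSS200 | TSS1500 | body | intergenic
      island_flag     bool, probe sits in a CpG island
      snp_maf         minor-allele frequency of an overlapping SNP (NaN if none)
      sex_chrom_flag  bool, probe maps to chrX/chrY

    ``detection_p`` is an optional probes x samples DataFrame of detection
    p-values in [0,1].
    """

    table: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    nearest_gene: pd.Series | None = field(default=None)

    REQUIRED = ("chrom", "dist_to_tss", "region_class", "island_flag",
                "snp_maf", "sex_chrom_flag")

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "probe ids")
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        bad = set(self.table["region_class"]) - set(REGION_CLASSES)
        if bad:
            raise ValueError(f"unknown region_class values: {sorted(bad)}")
        dist = self.table["dist_to_tss"].to_numpy(dtype=float)
        cls = self.table["region_class"].to_numpy()
        if ((cls == "TSS200") & (np.abs(dist) > 200)).any():
            raise ValueError("TSS200 probes must have |dist_to_tss| <= 200")
        if ((cls == "TSS1500")
                & ((np.abs(dist) <= 200) | (np.abs(dist) > 1500))).any():
            raise ValueError(
                "TSS1500 probes must have 200 < |dist_to_tss| <= 1500")
        if self.detection_p is not None:
            dp = self.detection_p.to_numpy(dtype=float)
            if ((dp < 0) | (dp > 1)).any():
                raise ValueError("detection p-values must lie in [0,1]")
        if self.nearest_gene is None and "nearest_gene" in self.table.columns:
            self.nearest_gene = self.table["nearest_gene"]

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def require_probes(self, probe_ids) -> None:
        """Raise if any requested probe has no annotation row."""
        missing = [p for p in probe_ids if p not in self.table.index]
        if missing:
            raise KeyError(
                f"probes missing from annotation: {missing[:5]}"
                + ("..." if len(missing) > 5 else ""))

    def is_promoter(self) -> pd.Series:
        """Boolean mask of promoter-proximal probes (TSS200 or TSS1500)."""
        return self.table["region_class"].isin(["TSS200", "TSS1500"])


def is_sex_chrom(chrom: str) -> bool:
    """True for chrX/chrY, case-insensitive, with or without 'chr' prefix."""
    c = str(chrom).lower()
    if c.startswith("chr"):
        c = c[3:]
    return c in ("x", "y")
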