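"""CpG-island classification of a DNA sequence window.

A window is called an island when GC content exceeds 50% and the
observed/expected CpG ratio exceeds 0.6, with the Gardiner-Garden
observed/expected form (N_CpG * L) / (N_C * N_G) counting overlapping
CG dinucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass

GC_MIN = 0.5
OBS_EXP_MIN = 0.6
_ALPHABET = set("ACGT")


@dataclass(frozen=True)
class IslandCall:
    gc_content: float
    obs_exp_ratio: float
    is_island: bool


def classify_cpg_island(sequence: str) -> IslandCall:
    """Classify a DNA window (A/C/G/T, non-empty) as CpG island or not."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("sequence must be non-empty")
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"characters outside A/C/G/T alphabet: {sorted(bad)}")
    length = len(seq)
    n_c = seq.count("C")
    n_g = seq.count("G")
    # str.count is fine for "CG": the pattern cannot overlap itself.
    n_cg = seq.count("CG")
    gc = (n_c + n_g) / length
    obs_exp = (n_cg * length) / (n_c * n_g) if n_c * n_g > 0 else 0.0
    return IslandCall(
        gc_content=gc,
        obs_exp_ratio=obs_exp,
        is_island=(gc > GC_MIN and obs_exp > OBS_EXP_MIN),
    )
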