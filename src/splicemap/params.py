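"""Tunable parameters of the mapping pipeline, with their published defaults.

Seed lengths follow the recommended ranges (initial seed 20-30 nt, window
re-alignment seed 10-15 nt); defaults sit at the midpoints.  Gap-size class
boundaries (insertion <= 10 nt, deletion 1-10 nt, intron 50-300,000 nt), the
mismatch budget (4) and the evidence weight w=0.3 are the published defaults.
Quantities the method leaves user-defined or unspecified (context distances,
window length, support-score windows/weights, candidate/partial distance D)
carry documented defaults; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass
class MappingParams:
    # seeded alignment
    seed_len: int = 25              # initial anchored seed (20-30 nt range)
    window_seed_len: int = 12       # completion seed inside sliding windows (10-15 nt)
    local_seed_len: int = 16        # built-in local-alignment seed
    max_mismatches: int = 4         # m
    mismatch_end_dist: int = 8      # D: candidate-split vs partial boundary distance;
                                    # at ~75% mismatch density beyond a gap, the last
                                    # allowed mismatch sits ~5 nt past it, so D ~ 8 admits
                                    # every candidate whose remainder can host the 12-nt
                                    # completion seed
    max_hits: int = 10              # alignments retained per read per anchor
    local_flank_mismatches: int = 2  # tolerated per flank while extending local blocks

    # gap-size classes
    min_intron: int = 50
    max_intron: int = 300_000
    max_insertion: int = 10
    max_deletion: int = 10
    min_exon: int = 20              # e: minimum (internal) exon size
    min_junction_anchor: int = 8    # read bases required on each side of an intron gap

    # sliding window
    max_window: int = 10_000        # maximum sliding-window length
    avg_intron: int = 1_000         # x: window extension distance

    # contexts
    d_min: int = 1_000
    d_max: int = 300_000
    variant_cap: int = 16           # step-3 variants retained per read per context

    # resolution
    evidence_w: float = 0.3
    support_window: int = 100       # W: flank window for the support score
    support_tie_tolerance: float = 0.02  # supports within this fraction count as tied
    support_lambda_in: float = 1.0
    support_lambda_flank: float = 0.1
    annotation_bonus: float = 1.0

    def validate(self) -> "MappingParams":
        if not (10 <= self.seed_len <= 30):
            raise ValueError("seed_len must be in [10, 30]")
        if not (10 <= self.window_seed_len <= 15):
            raise ValueError("window_seed_len must be in [10, 15]")
        if not (0 < self.evidence_w < 1):
            raise ValueError("evidence_w must be in (0, 1)")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.min_intron <= self.max_deletion:
            raise ValueError("min_intron must exceed max_deletion")
        return self

    def replace(self, **kw) -> "MappingParams":
        return dataclasses.replace(self, **kw).validate()


DEFAULT_PARAMS = MappingParams()
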