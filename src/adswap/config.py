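"""Tunable parameters of the DS-detection pipeline.

Every constant of the method lives here so that each stage can be recalibrated
without touching the algorithms.  Values marked "reference" are the
method's established constants; the remaining defaults are this package's own
calibration and are documented in docs/methods.md.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict


@dataclass
class Config:
    # --- structure_io ---
    min_sse_len: int = 3          # residues; shorter segments carry no direction
    chain_break: float = 2.5      # Å, C(i)-N(i+1) distance above which torsions are undefined

    # --- ad_image ---
    d_norm: float = 25.0          # Å, distance-axis normalization constant (clamped above)
    n_blocks: int = 10            # grid is n_blocks x n_blocks
    block_reach: int = 2          # Chebyshev block distance: own block + nearest 24

    # --- sse_matching: vertex score S_ij = S_c - (k1*d + k2*|Δdihedral| + k3*|Δsep|) ---
    s_c: float = 3.0              # reference threshold
    k1: float = 10.0              # per normalized A-D plane distance unit
    k2: float = 1.0 / 30.0        # per degree of dihedral difference
    k3: float = 1.0 / 20.0        # per residue of connecting-chain length difference

    # --- sse_matching: edge weight exp(-(d/d_t)^2) * (t_d + t_a + t_b + t_g) ---
    d_t: float = 25.0             # Å, reference value
    k_d: float = 10.0             # Å, reference value
    k_alpha: float = 4.0 / math.pi   # rad^-1, reference value
    k_beta: float = 4.0 / math.pi    # rad^-1, reference value
    k_gamma: float = 3.0 / math.pi   # rad^-1, reference value

    # --- rigid_alignment ---
    pair_cutoff: float = 5.0      # Å, equivalent-residue elimination cutoff
    rmsd_tol: float = 0.01        # Å, iteration convergence tolerance
    max_iter: int = 50
    gap_open: float = 1.0         # pair-equivalents; DP maximizes pair count
    q_r0: float = 3.0             # Å, Q-score distance constant

    # --- hinge_detection ---
    theta_u: float = 180.0        # degrees, A-D product angle scale (reference value)
    d_u: float = 25.0             # Å, A-D product distance scale (reference value)
    smooth_width: int = 3         # structuring element of the morphological filter
    confidence: float = 0.80      # two-sided CI level of the transition t-test
    pf_run: int = 5               # PF stage: stop after >pf_run consecutive aligned residues
    t_n: int = 4                  # BL stage: N_u must exceed this (reference T_N)
    t_l: float = 0.5              # unaligned-fraction screen of candidate fragments (reference T_L)
    frag_min_ratio: float = 0.5   # swapped fragments: aligned >= ratio * smaller fragment
    frag_max_rmsd: float = 4.0    # Å, swapped fragment superposition limit
    theta0_base: float = 25.0     # degrees; hinge extension cutoff = theta0_base * n_hl
    ca_stop: float = 2.6          # Å, last-three-aligned-pairs Cα distance stop
    min_swap: int = 10            # residues; extension may not shrink the swapped domain below this

    # --- ds_score ---
    grid_max: float = 5.0         # m0/m1/m2 searched over [0, grid_max]
    grid_step: float = 0.25
    cutoff_grid: tuple[float, float, float] = (0.05, 0.95, 0.05)  # start, stop, step

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT = Config()
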