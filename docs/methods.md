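# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind `adswap`, and what the synthetic test bed does and does not
demonstrate.

## Model and assumptions

The method treats a protein chain as an ordered set of secondary structural
elements (SSEs), each abstracted as a least-squares 3D line through its Cα
atoms (unit direction oriented N→C, centroid, and the projection span of the
first/last Cα as length).  Two assumptions follow:

* an SSE of fewer than 3 residues carries no stable direction and is
  discarded;
* the geometry of a protein is adequately summarized, for the purpose of
  recognizing equivalent substructure, by the pairwise angles and centroid
  distances of its SSEs (the A-D image).  This holds for regular α/β
  architectures and degrades for chains that are mostly coil.

Domain swapping is modeled as a rigid swing of one contiguous region (the
swapped domain) about a short connector (the hinge loop), so that the two
conformers share intra-domain geometry while inter-domain geometry differs.
The SSE matching exploits the first half of that statement; the A·D profile,
hinge detection and DS score exploit the second.

## Parameters

Established constants of the method (all in `adswap.config.Config`):

| parameter | value | role |
|---|---|---|
| S_c | 3 | vertex admission threshold of the pair graph |
| d_t | 25 Å | exponential envelope scale of edge weights |
| k_d | 10 Å | distance-difference scale of the edge term t_d |
| k_α, k_β, k_γ | 4/π, 4/π, 3/π rad⁻¹ | angle-difference scales of t_α, t_β, t_γ |
| θ_u, d_u | 180°, 25 Å | A·D-product normalization |
| confidence | 80% | CI level of the transition t-test |
| T_N | 4 | unaligned-residue count confirming a bifurcation |
| T_L | 0.5 | unaligned fraction required of a candidate fragment |
| fragment rules | ≥50% aligned, RMSD < 4 Å | swapped-domain validation |
| θ₀ | 25°·n_hl | hinge φ/ψ extension cutoff (n_hl = 2 for middle swaps) |
| Cα stop | 2.6 Å | three consecutive close pairs end the extension |
| domain floor | 10 residues | extension may not consume the swapped domain |

Package calibrations where the method leaves the value open:

* **A-D axis normalization**: distances divided by d_norm = 25 Å and clamped
  at 1, matching the 25 Å scale that recurs in d_t and d_u.  A per-protein
  maximum-distance normalization is the plausible alternative; the fixed
  constant keeps images of different proteins commensurable.
* **Vertex score scales** k₁ = 10 per normalized A-D-plane distance unit,
  k₂ = 1/30 per degree of dihedral difference, k₃ = 1/20 per residue of
  connecting-chain difference — each maps a "clearly different" value
  (0.1 plane units, 30°, 20 residues) to one unit of penalty, so the three
  terms cover similar ranges.
* **Edge weight form**: exp(−(d̄/d_t)²)·(t_d + t_α + t_β + t_γ) with
  t_d = 1 − |d_Q − d_S|/k_d and cosine-free linear angle terms
  t_x = 1 − k_x·|x_Q − x_S|.  The six angles are measured per protein
  against the inter-point-center axis: α averages the first component SSE's
  axis angle at both vertices, β the second's, γ the inter-point SSE–SSE
  angles.  Identical local geometry gives the maximal weight
  4·exp(−(d̄/d_t)²).
* **Vote weighting** g = 1 + |ΔL|/max(L) + |Δn|/max(n): 1 for identically
  sized SSEs, growing with length/size dissimilarity.
* **Penalty function** f_p = exp(−[m₀(1−γ_θ) + m₁(1−γ_d) + m₂·μ_sd]):
  an exponential that is 1 for a maximal swap signature and decays for
  common homologs; m₀–m₂ trained on [0, 5] in steps of 0.25, cutoff on
  [0.05, 0.95] in steps of 0.05, ties resolved toward smaller parameters.
* **Alignment numerics**: pair elimination cutoff 5 Å, RMSD convergence
  tolerance 0.01 Å, at most 50 iterations; DP gap-open 1 pair-equivalent
  with free extension and free terminal gaps.  Admissible pairs score
  1 + 0.25·(1 − d/cutoff): the count term dominates (the alignment still
  maximizes equivalent pairs) while the distance bonus breaks register ties
  such as helix alignments shifted by one turn.
* **Q-score constant** R₀ = 3 Å (its standard value).

## Numerical and procedural decisions

* **Two-stage iterative alignment.**  Seeding from matched SSEs of *both*
  domains makes the first Kabsch fit a compromise; pairs are therefore shed
  gradually (at most a quarter per round) until the surviving anchors are
  rigidly consistent, and only then does the DP re-derivation loop start.
  Because the dynamic programming maximizes the number of equivalent pairs,
  the aligner should settle on the larger domain; to guarantee that against
  local optima, alignments are also started from every window of two
  adjacent matched SSE pairs and the result with the most pairs wins.
* **Opening-point refinement.**  The peak-first stage demands more than five
  consecutive aligned residues; the bifurcation-last stage walks back,
  counting unaligned residues, and the candidate is rejected as
  over-extended if the terminus arrives before the count exceeds T_N.  The
  refined opening point is placed at the boundary — the last aligned residue
  before the first run of two or more unaligned residues — because the
  opening point is defined as the border between the superimposable and
  non-superimposable regions; the count beyond it only confirms that the
  bifurcation is real.  Isolated unaligned singletons are treated as local
  noise, symmetric with the morphological smoothing of the profile.
* **Hinge-range extension** walks aligned residue pairs outward from the
  opening point using max(|Δφ|, |Δψ|) with periodic wrapping (the two-sided
  difference of a torsion pair), stops after two adjacent aligned pairs fall
  below θ₀, and treats unaligned residues as evidence-free: they join the
  hinge only when flanked by evidenced residues, and a run longer than T_N
  ends the extension.  Undefined torsions (termini, chain breaks) stop the
  affected end.  When nothing extends, the hinge collapses to the two
  residues flanking the boundary.  The fixed-cutoff variant (θ₀ = 20° or
  30°, no distance/floor stops) is available for comparison via
  `--eisenberg`.
* **Fragment validation** superposes the candidate swapped fragments seeded
  both from the matched swapped-domain SSEs and from index-wise pairing at
  the hinge-proximal end, keeping the larger alignment — the SSE seeding is
  robust to unequal opening points, the index seeding to occasional SSE
  mis-matches.
* **Degenerate inputs**: chains with fewer than two SSEs, empty matches, or
  alignments with no surviving pairs terminate the comparison with a
  stage-named diagnostic; a pair with no detectable hinge is a *successful*
  comparison with η = 0 and DS = 0 (the common-homolog outcome).
  Self-comparison always takes this path.

## The synthetic test bed

`adswap.synthetic` generates chains from ideal backbone internal coordinates
(N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å; helix φ/ψ = −57°/−47°, strand
−120°/+125°, ω = 180°), with loop torsions drawn from common basins and
chosen greedily for compactness.  The default DS fixture has a 45-residue
4-SSE main domain and a 30-residue 3-SSE swapped domain joined by a
6-residue linker (79 residues total, hinge pivot at residue 49); open forms
rotate the swapped segment 120° about an axis through the hinge Cα chosen
perpendicular to the domain's representative directions, so the rotation is
recoverable from the γ_θ vectorizations by construction; both forms carry
seeded Gaussian coordinate noise (default experiments use σ = 0.3 Å,
roughly the coordinate spread between independently solved conformers).
Controls are noise-perturbed copies (σ = 0.5 Å) with no rotation.

What the fixtures emulate: two-domain architecture, rigid domain swing,
hinge-localized conformational change, HELIX/SHEET records consistent with
the coordinates, coordinate noise.  What they do not: sequence variation
(all residues are written as alanine), loop remodeling, sheet pairing across
domains, crystal contacts, or genuinely disordered regions.  Passing the
synthetic suite therefore demonstrates the pipeline's internal consistency
and parameter recovery, not its sensitivity/specificity on real,
evolutionarily divergent DS pairs — on real data, SSE fragmentation and low
sequence identity make all stages noisier.

Observed recovery under these conditions (recomputed by
`scripts/acceptance.py`): hinge opening points within 2–3 residues of the
planted pivot (occasionally 4 when several residues near the rotation axis
remain superimposable — for gentle rotations the boundary is genuinely
blurred); γ_θ within about 0.05 of the planted angle/180° when the swapped
domain is elongated.  When the domain's Cα cloud has two comparable
principal components, the whole-domain line fit is ill-conditioned and γ_θ
is dragged toward smaller values; the opening-point→center vector method is
robust to this, which is why the two are averaged.

## Problem sizes

The shipped experiments use 79–84 residue chains with 6–7 SSEs, 50 positive
and 50 control pairs for training, 100 random instances for the Kabsch
oracle check and 500 draws for score fuzzing.  These sizes exercise every
code path; all of them scale linearly to hundreds of residues per chain
(the DP is quadratic in chain length but vectorized).

## Known limitations

* Middle-domain swaps are detected less reliably than terminal swaps: two
  hinges must both be refined and the doubled θ₀ makes their ranges
  conservative; torsion of the swapped domain between its two hinges can
  defeat the single-vector γ_θ representation.
* The order-independent matching mode is provided, but the hinge logic
  assumes sequential matches when converting profile transitions into
  opening points.
* Only the first model of a multi-model file is read; alternate locations
  collapse to the highest occupancy; mmCIF is not supported.
* The DS-score weights shipped as defaults (m₀ = m₁ = m₂ = 1, cutoff 0.25)
  are placeholders; any serious use should train them on labeled pairs via
  `adswap train`.
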