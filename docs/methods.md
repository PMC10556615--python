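# Methods

This document records the algorithms, parameter choices and numerical
conventions behind `idpkit`, including the calibrations done on the synthetic
generators and the known finite-length effects in the polymer references.

## Data model

An `Ensemble` is a shared `Topology` (chains → residues → named atoms) plus a
`(frames, atoms, 3)` float64 coordinate array in Ångström. Multi-model PDB
input/output is delegated to biotite; all models must carry the same atoms in
the same order, the first alternate location is kept, and insertion codes are
rejected (detected by scanning raw ATOM/HETATM records, since residue
renumbering around insertion codes would silently corrupt residue-indexed
analyses downstream). Residue numbering follows the input file.

## Secondary-structure assignment

The assignment re-implements the Kabsch–Sander scheme. The backbone
amide–carbonyl hydrogen bond is scored with the electrostatic model

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  kcal/mol,

a bond being called when E < −0.5 kcal/mol. Amide protons absent from the
input (the common case for simulation snapshots) are reconstructed 1.01 Å
from N on the external bisector of the C(prev)–N–CA angle, i.e. planar
peptide geometry, so protonated and stripped inputs assign identically.
Prolines and chain-initial residues are never donors. Helices are runs
flagged by two consecutive (i, i+n) turns for n = 4, 3, 5 (all reduced to
`H`); strands come from parallel/antiparallel bridge topology with
|i−j| ≥ 3, isolated bridges included (reduced to `E`); everything else,
including residues with incomplete backbones, is coil `C`. Helix overrides
strand where both patterns match, matching standard DSSP precedence.

The three-letter alphabet {H, E, C} is exactly the alphabet the SWRMSD
weighting is defined on. On synthetic backbones built from ideal dihedrals
the assignment reproduces, residue for residue, the labels of an independent
DSSP implementation (run once during development; its output strings are
frozen in the test suite rather than recomputed, so the tests do not depend
on that package).

## Structurally weighted RMSD and clustering

For two frames with states s, t the structure score is Σᵢ w(sᵢ, tᵢ) with
w = 0 for identical states, 1 for coil vs either folded state, and 4 for
helix vs extended. The SWRMSD is the optimal-superposition (Kabsch) RMSD
multiplied by this score. The quantity is deliberately **not** a metric:
frames with identical secondary structure are at distance 0 regardless of
geometry, which is the intended behaviour — the clustering partitions by
structure content first and geometry second.

Kabsch superposition uses the SVD formulation with the determinant
correction, so the returned rotation is always proper (no reflections);
batched RMSD evaluations use the singular-value residual form.

Clustering is a single leader scan in trajectory order: a frame joins the
earliest-founded cluster whose leader is within the threshold, else founds a
new cluster. Afterwards each cluster's representative is its medoid (minimum
summed SWRMSD to clustermates). The threshold is expressed in weighted
Ångström and is an analysis input. The default used throughout the examples,
40, was calibrated once on the two-conformer generator (1 Å coordinate
noise, 20–40 residues): it cleanly separates helix-rich, strand-rich and
coil populations across seeds. It was not adjusted afterwards.

## Propensity and disorder summaries

Per-residue propensities are the fractions of frames assigned H, E and C.
The disorder summary reports the fraction of residues with no folded
preference (max(p_H, p_E) below a fold threshold, default 0.2), the fraction
of confident-coil residues (p_C above 0.8), the fraction with a strong
folded preference (above 0.8) and the lengths of contiguous runs of such
residues. Multiplicative reweighting of (helix, extended, other) fractions
is provided for externally calibrated assignment biases; identity factors
are a no-op.

## Polymer diagnostics

`radius_of_gyration` is mass-unweighted; it satisfies the pairwise-distance
identity Rg² = (1/2N²)·ΣᵢΣⱼ d²ᵢⱼ, which the tests exploit as an oracle.
Segment scaling computes ⟨Rg²(l)⟩ over every contiguous window of length l
in every frame using prefix sums (linear cost per frame), then fits
√⟨Rg²(l)⟩ = A·l^ν by least squares in log–log space; the fit is exact on
exact power laws.

The shape (amplitude) ratio is √⟨Rg²⟩ / √⟨Ree²⟩ — the rms convention, which
is the one that reproduces the Gaussian-chain reference 1/√6 ≈ 0.408.
Error bars use a blocked delete-one jackknife: the integrated
autocorrelation time τ of the Rg² series (FFT autocorrelation, truncated at
the first non-positive lag, τ = ½ + Σρ) sets the block length ⌈2τ⌉, at
least 10 blocks are required, and constant series yield zero error with a
warning.

## Contact maps and NMR comparison

Contact fractions between two chains count frames with the inter-residue
distance below a cutoff (default 12 Å between α-carbons, the coarse-grained
convention; a minimum-heavy-atom-distance representation is available).
Per-residue strength is the maximum fraction over partner residues (so one
strongest residue sets the normalisation; a sum mode exists for sensitivity
analysis). Cluster profiles are combined occupancy-weighted and
max-normalised. The comparison against NMR titration data is a Spearman
rank correlation between simulated strength and −(percentage intensity
change), requiring at least five overlapping residues.

## NMR table statistics

Peak tables hold (residue, code, isomer ∈ {cis, trans, none}, height); shift
tables hold (residue, code, atom, shift, optional isomer). The cis:trans
ratio of a slow-exchange isomer equilibrium is, per reporter residue,
h_cis/(h_cis+h_trans)·100; the reported value is the unweighted mean over
reporters with their SD as dispersion, and is invariant under common
rescaling of all heights. The secondary-shift differential is
(δCα − δCα,rc) − (δCβ − δCβ,rc) against a shipped random-coil reference
(glycine contributes only the Cα term); positive values indicate helical
tendency, negative β. The cis-proline signature is the upfield offset
δCα(trans) − δCα(cis), called positive when it falls in the characteristic
0.1–1.0 ppm window. Titration changes are (h_bound − h_free)/h_free·100,
clamped to exactly −100 % when the bound peak is at or below the noise
floor; rows missing on one side or with a free peak below the floor are
flagged in a status column, never silently dropped.

## Sequence diagnostics

Charge fractions count K/R as positive (optionally H, for low-pH work) and
D/E as negative. The diagram-of-states classification uses FCR < 0.25 → R1;
0.25 ≤ FCR ≤ 0.35 → R2 (Janus); above that, R3/R4/R5 by whether one, the
other, or both of f⁺, f⁻ exceed 0.35. Boundaries live in configuration
because minor published variants exist. Charge patterning (κ) is out of
scope; the classification is composition-only.

## Synthetic generators

All generators are seed-deterministic and return their ground truth.

**Ideal chains** are freely jointed: uniformly random unit bond directions
(normal deviates, normalised). Closed forms: ⟨Ree²⟩ = n·b²,
⟨Rg²⟩ → n·b²/6, ratio → 1/√6.

**Self-avoiding walks** live on the cubic lattice and are sampled by the
pivot algorithm: a random interior pivot site, a random non-identity
octahedral symmetry applied to the shorter arm, rejection on
self-intersection (integer site keys). Samples are emitted every
`n_equilibration_pivots` **attempted** moves after a burn-in of
max(1000, 2n) attempts from the initial rod. Counting attempts, not
acceptances, matters: emitting on accepted moves samples the embedded jump
chain, whose stationary distribution over-weights walks with high acceptance
probability (extended ones). This was caught by comparing against exhaustive
enumeration of all ~8.8 million walks at n = 10 (⟨Ree²⟩ = 16.8172,
⟨Rg²⟩ = 2.7427): the accepted-move variant was ~2 % high on both, the
attempt-counting sampler agrees within Monte-Carlo error. The enumeration
check is the generator's strongest correctness argument and the
self-avoidance invariant is additionally tested exhaustively on every
emitted walk.

**Protein-like conformers** are built by NeRF forward kinematics from
per-residue (φ, ψ) with ideal geometry (N–Cα 1.46 Å, Cα–C 1.52 Å, C–N
1.33 Å, C=O 1.23 Å, trans peptides). The helix-rich template uses two
(−60°, −45°) segments. The hairpin template's strand (−127.1°, 124.1°) and
turn dihedrals were tuned **once**, before any acceptance values were
computed, so that the two strands stay hydrogen-bonded in register under
ideal geometry (ideal-twist strands otherwise fray after a few residues);
they were not revisited. Coil frames draw dihedrals uniformly from the broad
β-basin (φ ∈ [−160°, −70°], ψ ∈ [90°, 170°]) to avoid accidental helix.
Two-conformer ensembles add isotropic Gaussian noise of a chosen per-atom
rms and shuffle frames; labels are returned for recovery tests.

**Planted interfaces** place scheduled residue pairs within the cutoff with
their planted probability each frame and hold everything else far apart;
feasibility requires each chain-B residue in at most one pair and each
chain-A residue in at most two (partners z-staggered inside the cutoff).
The realized contact matrix is returned as the bookkeeping oracle, and the
contact-map module must reproduce it exactly.

**Planted NMR tables** realise a chosen cis percentage in every residue's
peak pair (optional multiplicative height noise) and write Cα/Cβ shifts as
the random-coil reference ± half a planted differential pattern (optional
additive noise), so the recovered differential equals the pattern exactly at
zero noise.

## Known finite-length effects in the SAW references

Two of the quantitative references are asymptotic universal values, and at
the finite lengths used here the unbiased sampler sits measurably away from
them:

- The SAW amplitude ratio √(⟨Rg²⟩/⟨Ree²⟩) is ≈ 0.400 asymptotically
  (amplitude ratio ⟨Rg²⟩/⟨Ree²⟩ ≈ 0.1599) and ≈ 0.3975 at n = 400 due to
  corrections to scaling. The printed reference 0.406 is therefore generous;
  measured values near 0.398 are the correct physics, not a sampler problem
  (the enumeration check above rules that out).
- The effective Flory exponent fitted over lengths 50–400 is ≈ 0.594–0.597
  rather than the asymptotic 0.588, again from corrections to scaling
  (⟨Rg²⟩ at n = 50 sits several percent below the asymptotic power law).
  Longer chains would reduce the gap but are outside the stated lengths.

A high-precision run (30000 nearly independent walks per length, sampling
stride 30 attempted pivots) gives an effective exponent of 0.5949 ± 0.0015
over these lengths. Consequently the acceptance script uses large sample
counts and the wider stride (20000 walks for the shape ratio, 30000 per
length for the exponent fit) purely to shrink the statistical error around
these expectations; no generator parameter, seed or threshold was chosen by
iterating against the target values.

## Numerical conventions

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; child seeds are derived once from a master seed and stay below 2³¹.
- Log–log fits use `numpy.polyfit` with covariance; Spearman correlations
  use `scipy.stats`; superpositions use SVD.
- PDB output carries 0.001 Å precision, which bounds round-trip error.

## Limitations

- The secondary-structure reduction is three-state; 3₁₀/π helices map to H
  and isolated bridges to E, so finer DSSP classes are not distinguished.
- SWRMSD clustering is order-dependent (leader algorithm) by design, for
  trajectory-scale throughput; it is not a metric-space clustering.
- The generators are geometric, not physical: no force field, no sterics
  beyond lattice self-avoidance, no solvent.
- The random-coil shift reference is a single shipped table; users with a
  preferred reference can pass their own.
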