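# Methods

## Scope and model

`splicesim` simulates two stochastic reaction networks inside a
voxelized model of a spherical mammalian (HeLa-scale) cell:

1. **Splicing-particle formation.** The U1 and U2 snRNPs are built in a
   multi-compartment pipeline: U snRNA genes in the nucleoplasm
   transcribe snRNA (0.285 and 0.224 s⁻¹ per gene copy), the snRNA is
   exported through nuclear-pore sites (first-order, 2×10⁴ s⁻¹ while on
   a pore site), assembled in the cytoplasm (Gemin 5 binding → RNP
   exchange onto the pre-assembled Sm pentamer → addition of the two
   late Sm proteins), re-imported, and matured by binding the
   particle-specific proteins in Cajal bodies or the nucleoplasm.  A
   nucleus-only variant confines every step to the nucleoplasm and adds
   irreversible *misassembly* channels in which the particle-specific
   proteins bind the snRNA·Sm⁵ intermediate before the Sm ring is
   complete.
2. **Spliceosome assembly and splicing.**  Free U1, U2 and tri·U
   (U4/U6·U5) particles assemble step-wise on pre-mRNA
   (E → A → B → B\*), the intron is excised (0.067 s⁻¹) and the
   particles recycle.  An optional co-transcriptional mode treats each
   transcript as a serial chain of 8 intron units (intron 3.4 kb, exons
   137 b; whole gene ≈ 28 kb), each unit requiring a full assembly
   cycle before the next appears.  Nuclear speckles concentrate the
   splicing particles and transcripts.

The dynamics are sampled either on a cubic lattice of subvolumes
(reaction–diffusion master equation, RDME) or in well-mixed coupled
compartments (exact Gillespie SSA).

## Geometry

Constructive solid geometry on a cubic lattice (default 18.432 µm box,
λ = 64 nm spacing, 288³ sites).  Primitives (spheres, spherical shells,
spherocylinders, cone∩shell) are stenciled in depth order — later
shapes overwrite earlier ones — with a site-center inclusion rule.
Defaults: cell radius 8.9 µm (3000 µm³); nucleus radius 4.2 µm
(selectable 3.7–5.3); 128-nm membranes (closed under 6-adjacency for
any thickness ≥ λ, by the triangle inequality); nuclear pores as
0.08-µm spheres at 7/µm² on a Fibonacci-sphere layout (count =
round(density × envelope area) ≈ 1552 at 4.2 µm), punched through the
nuclear membrane only; 20 speckles of radius 0.35 µm and 4 Cajal bodies
of radius 0.5 µm placed uniformly without overlap; 2000 mitochondria as
non-overlapping 0.9 × 0.5 µm spherocylinders (~10% of cell volume), or
a network variant of crossing 2.95-µm rods at matched total volume;
Golgi as a cone from the cell center intersected with five 128-nm
shells off the nuclear envelope; ER grown by a stochastic
cellular-automaton dilation from nucleation patches near the envelope
until it occupies 4.5% of the intracellular volume (trimmed exactly, so
the realized fraction is within one site of target).

Two ER choices matter and were made deliberately:

* the number of nucleation patches is a *physical* density
  (0.9 per µm² of envelope), not a fraction of the voxel count, so the
  grown morphology is comparable across lattice spacings;
* the first cytoplasmic voxel layer around the envelope (the
  perinuclear cleft containing the pore exits) stays clear.  Without
  this, coarse-lattice ER blobs seal a resolution-dependent fraction of
  the pore exits and the crowding experiments do not converge under λ
  refinement.

Active genes are points in a thin shell (default width 0.02 µm) at a
chosen distance d from their speckle's surface, assigned round-robin
over speckles, and constrained to nucleoplasm voxels.

## Engines

**RDME.**  Operator splitting with a fixed step τ = λ²/(6·D_max)
(7.3×10⁻⁵ s for the formation networks where proteins diffuse at
9.35 µm²/s; 3.3×10⁻³ s for the splicing networks where the fastest
species moves at 0.207 µm²/s, both at λ = 64 nm).  Each step, every
tracked molecule attempts one jump to a 6-neighbor with per-direction
probability D·τ/λ² (≤ 1/6 by construction); jumps into site types the
species may not occupy are rejected, and box faces reflect.  Crossings
of the nucleoplasm→speckle boundary are accepted with probability P_n
and the reverse with P_s ≤ P_n; detailed balance then gives an
equilibrium concentration ratio c_s/c_n = P_n/P_s, which is the entire
speckle model (no binding partners inside).  Reactions then fire in an
exact Gillespie sub-loop over [t, t+τ) within each occupied subvolume,
with compartment eligibility read from the site type; bimolecular
propensities use k/(N_A λ³) per reactant pair per subvolume.  With a
single subvolume the scheme reduces to the exact SSA (tested by
two-sample KS), and diffusion-only runs conserve counts exactly.

Very abundant pools (the 10⁵–10⁶ cytoplasmic/nuclear proteins) can be
flagged as *reservoirs*: well-mixed counts consumed via
pseudo-first-order propensities k·c_pool at the lattice-measured
compartment concentration.  This is exact for position-independent
binding but deliberately removes any spatial effect on those binding
steps (see "crowding protocol" below).

**SSA.**  Direct-method Gillespie over compartments (volumes measured
from a built lattice) with first-order exchange.  Speckle partitioning
coarse-grains to k_in = P_n·D·A/(λ·V_n), k_out = P_s·D·A/(λ·V_s) per
species (A = total speckle surface area), reproducing the same
equilibrium ratio.  The SSA is both the oracle for the RDME and the
fast surrogate for the 15-minute speckle experiments.

Reproducibility: every run is determined by (seed, replicate id); the
generator state is derived through `numpy.random.SeedSequence` and the
engines are single-threaded.

## Parameters

All rate constants and concentrations are the published values (see
`splicesim.constants`): G⁵/Sm⁵/Sm² at 0.61 µM in the free cytoplasm,
U1/U2-specific proteins at 0.89/0.56 µM in the nucleus, snRNA gene
copies 30 per species per haploid genome × ploidy (default 2 → 60
copies each), splicing-particle pools 0.1–5 nM (16–803 copies in the
~267 µm³ nucleoplasm; tri·U defaults to the free U1 count since it is
pre-formed in this model).  Protein pools are depletable and not
replenished (quasi-steady cell state; no translation over ≤ 15 min).

Parameters that are *not* printed anywhere and are therefore package
defaults, exposed in the API:

* **Complex-B activation** is published as 6×10⁴ with bimolecular units
  for a unimolecular step; it is implemented as a fast first-order
  conversion (default 380 s⁻¹) so that B\* forms promptly after B.
* **Misassembly rate**: the premature particle-specific-protein binding
  is taken as diffusion-limited with the same constant as the competing
  late-Sm addition at the same intermediate (1.39×10⁸ M⁻¹s⁻¹, shared
  between U1 and U2 as the legitimate reaction is).  A
  literature-derived slow rate (the 1.22×10⁷ maturation constant) would
  make misassembly a ~10% side channel, contradicting the observed
  3:1 dominance of misassembled particles; a competing diffusion-limited
  channel reproduces it.
* **Diffusion defaults** (per-species, per-site-type overridable):
  proteins 9.35 µm²/s; snRNA and cytoplasmic assembly intermediates
  1.0; snRNP particles 0.207; pre-mRNA, spliceosomal complexes and mRNA
  0.1 (nuclear mRNP mobilities are measured at 0.03–0.1 µm²/s).
* **Speckle bias**: experiments pick ρ = P_n/P_s by inverting the
  partition formula for a target localization fraction; the absolute
  P_n defaults to 1.0 in the surrogate and 0.1 in the spatial
  gene-distance runs (entry-limited crossing; the equilibrium is
  unchanged).  Spliced mRNA is unbiased so it can reach the pores;
  pre-mRNA, the E/A/B/B\* complexes and the particles are biased.

## Scaled-down experiment protocols

Full-resolution reproduction (λ = 64 nm, 288³ sites, 15 min, ~10⁶
tracked proteins) is outside this package's scope; the experiments run
at documented reduced scales chosen once:

* **Misassembly (30 s, 20 replicates)** — exact SSA in the
  lattice-measured nuclear volume with the published concentrations.
  No spatial reduction is involved; counts are exact for the model.
* **Speckle sweeps (900 s, 20 replicates)** — two-compartment SSA
  (nucleoplasm + pooled speckles) with lattice-measured volumes and
  exchange rates derived from the bias.  The speckle-anatomy sweep
  varies the exchange surface area as n^(1/3) at constant total
  speckle volume.
* **Pore-count / crowding runs (30 s, λ = 256 nm)** — full-cell RDME.
  For the pore-count direction the protein pools are reservoirs (the
  observable is transport-limited).  For the organelle-removal
  comparison the cytoplasmic pools must be *tracked*, because the
  crowding effect acts through diffusion-limited encounters; pools are
  count-reduced by 2048× with the bimolecular constants scaled up by
  the same factor (pseudo-first-order rates preserved).
* **Gene-distance runs (300 s, λ = 64 nm nucleus-only lattice)** — the
  nucleus with a thin cytoplasmic shell; spliced mRNA exits through
  pore sites and the observable is the cytoplasmic count.

## What the reduced runs do and do not show

The geometry analytics, builder constraints, engine-correctness
properties, misassembly counts, and the no-speckle transcript census
reproduce the published numbers within their tolerances.  Four
published observations are *not* reproduced at these scales, for
reasons the package computes rather than assumes:

* **The ~250-fold speckle enhancement.**  With the printed constants,
  the no-speckle control is not near-zero: at 1 nM U1 the E-complex
  occupancy (K_d ≈ 34 nM) sustains a mean splicing-completion time of
  ~970 s, giving ~28 mRNA per 900 s rather than 0.25.  The
  10%-localization condition does reproduce ~60 mRNA, so the measured
  fold is ~2, dominated by the baseline.  Reproducing a 0.25-mRNA
  baseline would require effective binding ~100× slower than the
  printed diffusion-limited constants.
* **CV monotonicity over the full localization range.**  Because the
  baseline already splices a third of the supply, output saturates at
  the transcription supply by ~25% localization and the mRNA CV
  flattens at its Poisson floor (1/√N ≈ 0.11) instead of decreasing
  further.  The decrease is reproduced over the unsaturated range.
* **The 2× gene-distance effect.**  With transcripts subject to the
  same speckle bias as the particles, the partition equilibrates within
  seconds to minutes for any mRNP diffusivity ≥ 0.03 µm²/s, so the
  0.05-vs-0.1 µm birth position (both sub-voxel) carries no memory over
  the run and the measured ratio is ~1.  A strong distance effect
  requires either much slower transcripts or near-sealed speckles
  (very small absolute P_n), neither of which is printed.
* **The +28% crowding magnitude.**  The direction (organelle removal
  increases 30-s U1 production) is robust and tested.  The magnitude is
  protocol-dependent: count-reduced pools deepen the diffusion-limited
  regime and overshoot (~+100% at 2048× reduction), while mean-field
  pools remove the encounter effect entirely and even reverse the sign
  via a confinement artifact (obstacles keep intermediates near the
  envelope).  The package reports the tracked-pool protocol and treats
  the printed percentage as out of reach at desk scale.

## Numerical notes

* Stochastic-rate conversions: bimolecular k (M⁻¹s⁻¹) → k/(N_A·V) with
  V the subvolume (RDME) or compartment (SSA) in liters; applied
  exactly once per constant.
* Operator-splitting error is O(τ); the τ-halving check is part of the
  test suite.
* The per-subvolume sub-loop resamples propensities after every event;
  products appear in the parent subvolume and first diffuse on the next
  step.
* Negative counts are impossible by construction (reactant counts are
  decremented before products are added, within an exact SSA).
* Voxelized sphere volumes converge to ~1% at r ≥ 10λ (tested);
  membranes of thickness ≥ λ cannot leak under 6-adjacency.
* Degenerate inputs (zero durations, zero rates, zero pores, empty
  shells, unreachable ER targets, infeasible packings) raise or return
  the documented trivial results; all are unit-tested.

## Limitations

No alternative splicing or splice-site choice; no chromatin, nucleolus
or cytoskeleton; organelles are static; no per-site crowding exclusion
beyond site-type permeability; the hybrid deterministic–stochastic
acceleration used for hour-scale questions is out of scope.  The
supplementary tables with the original per-species diffusion
coefficients and the exact ER automaton of the source model are not
public; both are replaced by documented defaults above.
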