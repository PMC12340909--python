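# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generators emulate, and the
limits of what tests on synthetic data can show about real measurements.

## Phosphosite hotspot ranking

A curated phosphosite table assigns each site three counts: LT_LIT
(low-throughput publications), MS_LIT (literature mass-spectrometry
studies) and MS_CST (in-house MS studies).  The observation frequency of
a site is `MS_LIT + MS_CST` and its literature-support ratio is
`(LT_LIT + 1) / (MS_CST + MS_LIT)`; the +1 keeps the ratio defined for
sites without dedicated publications, and the ratio is reported as
missing when a site has no MS observations at all.  Hotspots are the top
`ceil(q * N)` sites by observation count (default `q = 0.001`, the top
0.1%: on a 239,531-site proteome that is 240 sites).  The ceiling is the
documented cutoff rule; round-half-up would give the same count at this
N.  Sorting is stable, so ties at the cutoff keep input-file order — a
documented, reproducible tie-break rather than a statistically motivated
one.  The ranking unit is the (accession, site) row exactly as curated;
isoform accessions are not collapsed, but the parser reports both raw
and deduplicated row counts so the effect of isoform sharing is visible.

Differential tumor tables (site, log2 fold change, significance) are
consumed as published; we do not recompute the underlying statistics.
"Most differentially increased" is operationalised as the largest
|log2FC| among rows passing the significance cutoff with the requested
sign; ranking by significance, or lexicographically by both, is
available because effect-size-first is a choice, not a given.

## HDX-MS differential exchange engine

Inputs are a peptide pool (`id, sequence, start, end, charge`) and a
centroid table of neutral monoisotopic-scale masses per (peptide, state,
timepoint, replicate), with sentinels `UNDEUTERATED` and `FULL_D` for
the two controls.  Conversion from instrument m/z
(`mass = z*(m/z) - z*1.00728`) is provided as an input-preparation
utility since vendor exports differ.

Pool filters mirror standard post-identification practice: peptide
length 3–15, charge at most 3, and, when an observed undeuterated mass
is available, |mass error| ≤ 7 ppm against the theoretical monoisotopic
mass (pyteomics residue masses + one water).  Every rejection is logged
with its reason.

Uptake is `D = mean(replicate centroids at (state, t)) − mean
(undeuterated centroids)`.  Normalisation to percent-of-maximum uses the
full-deuteration control, pooled across replicates *and* protein states
(one `max_D` per peptide shared by all states — the states are the same
protein sequence, so their equilibrium uptake and back-exchange are
shared); when no full-D rows exist the theoretical maximum
`exchangeable amides × D₂O fraction` (default 0.9) is used and the
source is recorded.  Values outside [0, 100] are flagged but not
clipped, preserving the noise structure for the averaging steps.

Exchangeable amides per peptide: `length − 1 − (internal prolines)`.
The first residue is excluded (free amine after digestion), prolines
carry no amide hydrogen; an option additionally excludes residue 2, the
common fast-back-exchange convention.  The convention is explicit and
configurable because reasonable labs differ.

Residue consolidation takes the unweighted mean of `pct_max` over all
peptides whose span covers the residue — no length or redundancy
weighting, no smoothing, and no protection-factor inference: the
procedure is plain averaging, and anything heavier belongs to spectral
tools upstream of this engine.  Differential maps subtract residue
levels between states at matched timepoints (grids must be identical;
no interpolation, since a design uses one grid per experiment) and
average over timepoints to give the pseudo-residue dD̄; t = 0 is
excluded from the average by default because it carries no exchange
information.  dD̄ is antisymmetric under swapping the states.  Segment
calling reports maximal runs of ≥ `min_run` residues (default 3) with
dD̄ beyond ±`threshold` percentage points (default 5); residues without
coverage break runs.  No significance testing is attached to dD̄.

## Synthetic HDX generator

The forward model is a two-state EX2 ensemble: residue protection factor
PF ≥ 1 in the closed state, intrinsic rate `k_int` in the open state,
population-weighted observed rate
`k_eff = p_open·k_int + (1 − p_open)·k_int/PF`, and occupancy
`d2o·(1 − exp(−k_eff·t))`.  Centroids add the back-exchange-scaled
(β, default 0.85) occupancy sum to the undeuterated monoisotopic mass,
with optional Gaussian mass noise per replicate.  Full-D rows carry
occupancy `d2o` at every exchangeable amide, so β cancels exactly in the
percent-of-maximum — which is the point of the control.  Defaults follow
the measurement design the engine targets: timepoints
0–7680 s doubling from 30 s, 90% D₂O, three replicates.  `k_int` is a
single configurable constant (default 1 s⁻¹), not a sequence/pH/
temperature calculation, because the analysis applies no intrinsic-rate
correction; the labelling-temperature correction between exchange and
quench is likewise not modelled.  EX1 bimodality is out of scope: a
centroid-level pipeline cannot represent bimodal envelopes, so
simulating them would only validate an artefact.  What passing the
noiseless round-trip proves is the arithmetic of the engine — real data
additionally contain envelope-fitting error, carry-over, and peptide
misassignment, which live upstream of this engine's inputs.

Validation pools are tiled so that no peptide straddles a planted-region
boundary; with random pools, boundary-straddling peptides dilute the
residue average at region edges and segment edges become a property of
the pool, not the engine.

## Enzyme kinetics and thermal shift

Michaelis–Menten fits minimise least squares of `v = Vmax·S/(Km+S)`
(trust-region reflective, parameters bounded positive, xtol 1e-8, 500
evaluations max) with data-driven initialisation: `Vmax₀` = max observed
velocity, `Km₀` = substrate at the point nearest half of `Vmax₀`.
Non-convergence is flagged in the result, never silently replaced.  [E]
is an input, not a parameter: `kcat = Vmax/[E]`, specificity
`kcat/Km`, and fold changes are plain ratios of specificities (exactly
transitive by construction).  Initial-rate extraction from progress
curves is a least-squares slope over a configurable early window.

Activation profiles divide signal by the zero-activator baseline; the
1.5× activatable threshold is this package's operational default (the
underlying observation is qualitative) and is configurable.

Melting temperatures: the curve is truncated at the global fluorescence
maximum (discarding SYPRO-like post-peak decay), smoothed with a
centered moving quadratic (Savitzky–Golay, window 5 points — instrument
software smoothers are proprietary, so a minimal standard one is used),
and Tm is the temperature of maximal first derivative.  The estimator is
equivariant under temperature shifts and invariant under positive affine
transforms of fluorescence.  On 0.1 °C grids the recovery error is well
below the 0.2 °C reporting precision.

## Structure superposition and conformer classification

PDB parsing keeps ATOM records of the first MODEL; alternate locations
resolve to highest occupancy, ties to altloc 'A' then alphabetical.
Pairing is Cα-by-residue-number intersection (no sequence alignment —
adequate for same-protein comparisons; insertion codes are honoured).
Superposition is the Kabsch algorithm: centroid subtraction, SVD of the
covariance, sign correction on the smallest singular vector so the
rotation is always proper (no reflections), RMSD evaluated on the
transformed coordinates and reported unrounded (report layers round to
one decimal).  Collinear inputs are flagged degenerate.  Classification
against closed/open reference structures is nearest-reference RMSD with
an explicit "ambiguous" tie label.  Problem sizes in the validation
suite: 4–10-atom random toys against a quaternion-grid + simplex-refined
oracle (agreement ≤ 1e-3 Å), 100-atom rigid copies (RMSD ≤ 1e-9 Å), and
60-atom hinge toys for classification.

## Reproducibility

Every generator is a pure function of (config, seed); random streams are
derived per operation from (seed, operation name) so adding a generator
never perturbs another's draws.  Pipeline runs record input digests,
parameters, seed and all output files in a manifest; identical
(inputs, config, seed) give identical outputs.

## Known limitations

- The HDX engine starts from centroid tables: spectral deconvolution,
  isotope-envelope fitting and peptide disambiguation are out of scope.
- Per-replicate or per-column back-exchange differences are not modelled;
  one `max_D` per peptide is shared across states and replicates.
- Cα-only superposition with residue-number pairing cannot align
  structures with renumbered or heavily mutated chains.
- The phosphosite parser treats each curated row as a site; isoform
  deduplication is reported, not applied.
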