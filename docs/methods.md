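# Methods

## The model

hNEIL1 is a broad-specificity DNA glycosylase of the Fpg/Nei family. It
interrogates a base flipped out of the duplex through a flexible,
GS-rich lesion-recognition loop (turning points Gly240 and Gly249)
carrying two probe residues, 242 (Lys in the genomically encoded enzyme,
Arg after RNA editing) and 244 (Tyr). Crystallography and MD identify
three metastable loop conformations:

* **apo / encounter** — the loop of the free enzyme, displaced from the
  base-binding position (probe distances > 9 Å; the loop sits rotated
  ~40° about the 240–249 hinge relative to the bound conformers);
* **242-in / activated** — the terminal nitrogen of residue 242 makes a
  short (~3.0 Å) tautomerization-dependent hydrogen bond to a
  heterocyclic nitrogen of the flipped base; catalytically competent;
* **244-in / quarantine** — residues 242 and 244 swap positions
  (DFG-flip-like) and Tyr244 stacks on the base, burying it in a
  hydrophobic enclosure; catalytically inactive.

Because only the activated fraction of the pre-equilibrated
enzyme–substrate complex turns over, the observed single-turnover rate
follows an auto-inhibition law

    k̃_cat = k_cat / (1 + exp(ΔG / RT)),     ΔG = ΔG_conf + ΔG_chem,

where ΔG is the free energy of the activated state relative to the
quarantine state (positive ⇒ quarantine dominates). ΔG_conf is the
loop-conformation ("structural check") term — stacking and the
desolvation penalty of burying the base — and ΔG_chem the
tautomerization ("chemical check") term. The package implements the
equality form of this law; the underlying approximation is that the
conformational equilibrium is fast relative to chemistry and the binding
step is pre-equilibrated, so no K_M machinery is modeled. ΔG_conf and
ΔG_chem are *inputs* here (upstream they come from enhanced-sampling and
QM/MM calculations, which are out of scope); the package's job is
everything downstream of them, plus the estimation of ΔG from
conformational ensembles.

Inverting the two-state Boltzmann fraction gives the population
estimator used on ensembles:

    ΔG = RT ln(p_quarantine / p_activated),
    SE(ΔG) = RT √(1/n_A + 1/n_Q)   (binomial propagation of the ln-ratio).

Constants: R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹; default T = 298.15 K
(assays are reported at bench-adjacent temperatures and the source
free-energy calculations quote RT without a stated T; 298.15 K is the
conventional choice and every API accepts an explicit T). Units are
fixed package-wide: kcal/mol, minutes, kelvin, ångström.

## Descriptors

Snapshots are reduced to two distances chosen to separate the three
conformers:

* `d242`: minimum distance from the terminal side-chain nitrogen(s) of
  residue 242 (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2; other types fall
  back to any side-chain N, then to all side-chain heavy atoms) to any
  heavy atom of the base moiety (sugar and phosphate excluded).
* `d244`: distance between the residue-244 aromatic-ring centroid
  (Tyr/Phe CG–CZ six-ring; His/Trp rings supported) and the base
  heterocycle-ring centroid. Non-aromatic substitutions at 244 and
  lesions with rearranged rings (hydantoins) fall back to side-chain /
  all-heavy-atom centroids and are flagged.

Using (d242, d244) as the landscape axes is an operationalization: the
published population maps are drawn over "relative positions of
R242/Y244 and the flipped base" without numeric axes. Any pair of
coordinates that separates the three conformers would serve; these two
are directly measurable in every crystal structure.

The hydrogen-bond test for the 242–base contact is heavy-atom
distance-only (default cutoff 3.5 Å, inclusive, configurable): the
crystallographic models carry no hydrogens, so a donor-angle term would
be invented, not measured.

The loop rotation angle is defined by superposing the mobile structure
onto a reference over all shared Cα atoms outside residues 240–249,
then measuring the angle between the two Cα244 directions after
projecting out the Cα240→Cα249 hinge-axis component. This
plane-through-the-apex definition is one of several reasonable readings
of "the loop rotates ~40° using Gly240/Gly249 as turning points"; it is
symmetric in its arguments, confined to [0°, 180°], and reproduces a
constructed rigid rotation exactly. Either bound conformer may serve as
the reference.

Solvation: `count_shell_waters` counts water oxygens whose minimum
distance to any base heavy atom is ≤ 5 Å (default; the shell radius used
for the published solvation comparisons). `delta_n_water` histograms
per-snapshot water distances on caller-supplied bins and reports the
mean per-bin difference between the 242-in and 244-in ensembles — the
number of waters shed on entering the quarantine state.

Missing atoms (e.g. loop segments unbuildable in density) make the
affected descriptor *not available*, carried as an empty CSV cell with a
reason string; nothing is imputed.

## Structure handling

Parsing is delegated to gemmi (PDB and mmCIF). Author residue numbering
is authoritative — the literature's labels (Pro2, K/R242, Y244,
Gly240/249) are author-numbered — and is never remapped. Alternate
locations are resolved at parse time to the highest-occupancy conformer,
ties broken by altloc letter; hydrogens are dropped; residues named
HOH/WAT/H2O are segregated as solvent. Superposition is a least-squares
rigid fit (Kabsch, via scipy's rotation alignment); fewer than three
pairs or a collinear selection is a hard geometry error. A minimal PDB
writer (ATOM/HETATM, three-decimal coordinates) exists for fixtures;
three decimals bound round-trip coordinate error at 5×10⁻⁴ Å, which
propagates to ≲0.002° in the rotation angle.

## Classification and zones

State assignment is nearest-centroid in (d242, d244) with Euclidean
distance (the axes share units; optional per-axis scaling exists),
deterministic tie-break apo < in242 < in244. The shipped default
centroids — apo (12, 10), in242 (3, 8), in244 (8, 3.5) Å — are
operational values consistent with the crystallographic conformers; no
numerical centroids are published, so these ship in an overridable YAML
config and the classifier can alternatively learn per-state means from
labelled data. Zone detection histograms the ensemble on a 0.5 Å grid
and keeps 4-connected components of cells with ≥ 20% of the modal
density (both configurable; no landscape parameters are published, and
these defaults cleanly resolve components separated by a few ångström at
sub-ångström spread).

## Kinetics

Single-turnover time-courses follow one-phase association,
`fraction_product(t) = A(1 − exp(−k_obs t))`, fit by bounded
trust-region least squares (scipy `curve_fit`) with multi-start
initialization: k_obs from the reciprocal half-rise time, 1/t_max and
10/t_max; A from max(y); best start by residual sum of squares. Bounds
A ∈ [0, 1.2] (tolerates noise overshoot, rejects degenerate amplitudes)
and k_obs ≥ 0. Standard errors come from the local curvature
(covariance). All-zero data short-circuits to the exact (0, 0) fit.
Replicates are pooled by stacking (matching mean ± s.e.m., n = 3
reporting); per-replicate fits remain available. Non-convergence after
all starts yields a flagged result, not an exception.

Two default grids: the assay's 13-point schedule (0.083–180 min) and a
log-spaced 72 h grid for very slow substrates (a mismatched normal dT,
k_obs ~ 10⁻⁴ min⁻¹, shows no curvature within 180 min — the tests
demonstrate the short grid's failure and the long grid's recovery).

`kobs_ratio_test` compares mean k_obs between two fit sets with a
log-scale delta-method interval using a Student-t quantile at
n_a + n_b − 2 degrees of freedom, appropriate for the three-replicate
regime (a normal quantile under-covers at n = 3).

## Synthetic data

The generators define the study conditions for every test:

* **Ensembles**: three-component Gaussian mixture over (d242, d244);
  component weights are Boltzmann factors exp(−G_s/RT) of supplied
  per-state free energies (or explicit weights); default per-axis SD
  0.5 Å — tight enough that the components are well separated at the
  default centroid spacing, wide enough that bins are populated. Truth
  labels are retained.
* **Kinetics**: per-(variant, substrate) rows with k_cat, ΔG_conf,
  ΔG_chem; true rate k_cat·p_A(ΔG); amplitude 0.9, noise SD 0.02 and
  3 replicates by default (gel densitometry at a few percent error,
  triplicate assays); truth sidecar JSON.
* **Toy structures**: idealized conformer fixtures (planar hexagonal
  rings of radius 1.39 Å, straight-line side-chain fill-in, a Gly-rich
  core Cα scaffold identical across states). Descriptor targets are
  placed *exactly*: 242-in d242 = 3.0 Å; 244-in d244 = 3.6 Å; apo both
  probes ≥ 9 Å with the loop Cα trace rotated exactly 40° about the
  hinge. These are descriptor fixtures, not chemically valid models —
  bond lengths, base pairing and backbone continuity are not honoured.
* **Water shells**: Poisson(λ) oxygens placed uniformly (rejection
  sampling) at base distance within (r_min, r_max], plus a fixed
  far-field set strictly outside; the generator's bookkeeping count is
  the oracle for the shell counter.

All generators are deterministic under a fixed seed; multi-part outputs
derive substreams by numpy `SeedSequence` spawning.

What the synthetic data does *not* emulate: real MD ensembles are
autocorrelated, non-Gaussian and may populate transition regions
(classification error near basin boundaries is therefore
underestimated); real gel noise is heteroscedastic and amplitudes drift;
real structures have occupancy, disorder and missing loops beyond the
altloc/absent-atom cases exercised. Passing tests demonstrate
correctness of the estimators under their stated models, not robustness
to all real-data pathologies.

## Problem sizes

The test suite and the acceptance script use: 10,000-snapshot ensembles
(20 seeds × 5 free-energy levels) for recovery statistics;
3,000-snapshot landscapes for zone detection; 200 seeded repeats of
3-replicate fits for kinetics error; 200 draws for Poisson-shell means.
These sizes put Monte-Carlo error well below the tolerances being
checked while keeping a full run in seconds.

## Known limitations

* ΔG_conf/ΔG_chem cannot be computed here; they are inputs.
* Validation of the structural measurements against deposited
  crystallographic coordinates requires the PDB entries on disk (the
  relevant test documents the expected paths); toy conformers validate
  the measurement code paths exactly but are constructions, not
  experiments.
* The (d242, d244) axes, the default centroids and the zone-detection
  thresholds are operational choices, flagged as such above.
* No Markov-state or kinetic-network modelling: populations are treated
  as equilibrium samples.
* π-stacking energetics, electrostatics and solvent-accessible surface
  areas are out of scope; the descriptors are purely geometric.
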