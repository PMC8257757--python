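# neiltriage

Analysis toolkit for the **triage mechanism** of hNEIL1, a
broad-specificity human DNA glycosylase that initiates base excision
repair. hNEIL1 captures a flipped-out base in one of two competing
modes: an **activated** (*242-in*) state in which the terminal nitrogen
of residue 242 hydrogen-bonds the base (~3.0 Å) and catalysis can
proceed, and a **quarantine** (*244-in*) state in which Tyr244 stacks on
the base and blocks excision. The free enzyme prefers a third, *apo*
loop conformation rotated ~40° away from the base-binding position.
Because only the activated fraction of the enzyme–substrate complex
turns over, the apparent single-turnover rate constant obeys an
auto-inhibition law

```
k̃_cat = k_cat / (1 + exp(ΔG / RT)),    ΔG = ΔG_conf + ΔG_chem
```

with ΔG the activated-minus-quarantine free energy (positive when
quarantine dominates), split into a loop-conformation ("structural
check") term and a tautomerization ("chemical check") term. This
competition lets one enzyme excise chemically diverse lesions while
suppressing gratuitous cleavage of normal bases.

The package is for structural biologists and enzymologists who want to

* extract the loop/lesion geometric descriptors (d242, d244, H-bond
  flag, hinge rotation angle, solvation-shell water counts) from
  PDB/mmCIF structures or MD-style snapshot tables,
* classify snapshots into the apo / 242-in / 244-in states and convert
  state populations into ΔG with propagated errors,
* push ΔG through the rate law to apparent rate constants and
  substrate-discrimination ratios,
* simulate and fit single-turnover cleavage time-courses
  (`fraction_product = A(1 − exp(−k_obs t))`),
* generate fully synthetic test data (labelled Boltzmann ensembles,
  noisy kinetics with truth sidecars, toy conformer structures, Poisson
  water shells) so the entire pipeline runs without downloads.

## Worked example

```python
import neiltriage as nt
from neiltriage import synthdata, states, kinetics, thermo

# 1. a labelled conformational ensemble with a known free energy
spec = synthdata.EnsembleSpec(
    n=10_000, free_energies={"in242": 1.0, "in244": 0.0}, seed=1
)
ensemble = synthdata.gen_conformational_ensemble(spec)

# 2. classify and recover the free energy from state populations
summary = states.state_populations(ensemble)
print(f"activated fraction {summary.fractions['in242']:.4f}")
print(f"dG = {summary.dG:.3f} ± {summary.dG_se:.3f} kcal/mol")

# 3. the same free energy through the rate law
m = thermo.TwoStateModel(k_cat=1.5, dG_conf=1.0, dG_chem=0.0)
print(f"apparent k_cat = {thermo.apparent_kcat(m):.4f} min^-1")

# 4. simulate a single-turnover assay at that rate and refit it
tc = kinetics.simulate_timecourse(A=0.9, k_obs=thermo.apparent_kcat(m))
fit = kinetics.fit_timecourse(tc)
print(f"fitted k_obs = {fit.k_obs:.4f} min^-1 (A = {fit.A:.3f})")
```

Output:

```
activated fraction 0.1582
dG = 0.990 ± 0.016 kcal/mol
apparent k_cat = 0.2341 min^-1
fitted k_obs = 0.2341 min^-1 (A = 0.900)
```

An ensemble generated with ΔG = 1 kcal/mol populates the activated state
at 1/(1 + e^{ΔG/RT}) ≈ 0.156; the nearest-centroid populations give back
ΔG within one standard error; and a 13-point time-course simulated at
the apparent rate refits to the same k_obs.

The same flow is available from the shell:

```bash
neiltriage simulate --what structures --out out/
neiltriage analyze-structure out/toy_*.pdb --reference out/toy_in242.pdb --out out/
neiltriage simulate --what kinetics --dg 1.0 --out out/
neiltriage fit-kinetics out/timecourses.csv --compare K242:DHU R242:DHU --out out/
neiltriage triage-report params.csv --out out/
```

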