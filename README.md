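# sahens

Integrative ensemble modelling of single-alpha-helix (SAH) protein
regions from NMR chemical shifts and small-angle X-ray scattering
(SAXS).

SAH domains are long, stable, monomeric helices whose solution behaviour
sits between a rigid rod and a disordered chain. Neither observable
alone resolves them: chemical shifts report local (per-residue) helicity
but not the overall shape; a SAXS curve reports the global shape but not
where the helix frays. `sahens` implements the joint route: generate a
large pool of helix-biased all-atom conformers, select a sub-ensemble
whose *ensemble-averaged* predictions agree simultaneously with the
Cα/Cβ shifts and the scattering curve, and characterize the result —
per-residue secondary-structure probabilities, salt bridges, cation-π
and aromatic edge-to-face contacts, and conformational PCA.

The package is built around a synthetic-data mode that emulates a
74-residue low-complexity charged SAH construct (an 8-residue
expression-tag remnant plus the native segment), so the entire pipeline
is exercised and validated without downloading deposited data; the same
readers accept real inputs (multi-model PDB, shift TSV or an NMR-STAR
chemical-shift loop, 3-column SAXS `.dat`).

## The model in brief

- Conformers: per-residue (φ, ψ) from a helical basin with probability
  `p_i` (the helicity profile) or a coil mixture otherwise; ideal
  covalent geometry; rotamer-sampled side chains; hard-sphere clash
  relief.
- Forward models: two-state shifts δ = δ_coil + h_i·Δδ_helix with h_i
  the per-conformer DSSP 'H' indicator, and Debye scattering
  I(s) = Σ f_i f_j sinc(s·r_ij).
- Selection: minimize O = RMSD/RMSD₀ + χ²/χ²₀ by forward greedy growth
  with exchange refinement; repeated random draws, union, side-chain
  resampled secondary pool, final 60-conformer ensemble.
- SAXS shape analysis: Guinier (s·Rg < 1.2), p(r)/Dmax, dimensionless
  Kratky (sRg)²·I/I(0), and the mass-fractal dimension Dm from the
  mid-angle log-log slope (rod ≈ 1, swollen chain 1.7–1.8, random walk
  2, globule 3–4; Flory exponent ν = 1/Dm).

See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

```python
from sahens import SyntheticScenario, make_truth, observe
from sahens.experiments import recovery_experiment

report = recovery_experiment(seed=0, n_replicates=10)
print(report)
```

Under the default scaled-down study conditions (decoy pool 2000, draws
of 500, five repeats, final ensemble 60) this prints, after a few
minutes on one CPU:

```
RecoveryReport(chi2=0.790, secondary_correlation=0.988,
               mean_rg_selected=3.000, mean_rg_truth=2.973,
               helicity_r=0.979, n_selected=60, n_union=76,
               n_secondary=760, joint_wins=10, n_replicates=10)
```

Reading: the 60 conformers selected jointly against the synthetic
shifts and SAXS curve fit the scattering data within noise (reduced
χ² ≈ 0.8), reproduce the secondary-shift pattern (Pearson r ≈ 0.99),
recover the ground-truth radius of gyration within 1%, and recover the
per-residue helicity profile (r ≈ 0.98); selecting on SAXS alone
degrades the shift agreement in 10 of 10 noise replicates, which is why
the two data types are used together.

The numbered drivers under `analysis/` run the same study step by step
and write tables under `results/`: `01_simulate_observables.py`
(ground truth + noisy observables), `02_select_ensemble.py` (the
selection pipeline and per-stage score report),
`03_saxs_characterization.py` (Guinier/p(r)/Kratky/Dm and the shape
ladder), `04_structure_analysis.py` (helicity segments and interaction
matrices), `05_recovery_validation.py` (the recovery report above).

Sequence-level bookkeeping is also covered: the 74-residue construct's
average mass evaluates to 9727.78 Da, and mean-residue-weight /
mean-residue-ellipticity arithmetic reproduces published CD-table
values exactly.

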