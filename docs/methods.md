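# Methods

`sahens` models a single-alpha-helix (SAH) protein region as an ensemble
of all-atom conformers selected to agree simultaneously with NMR
chemical shifts (local structure) and a small-angle X-ray scattering
(SAXS) curve (global shape). This note documents the models, the
numerical choices, and what the synthetic experiments do and do not
demonstrate.

## Conformer generation

Backbone torsions are sampled independently per residue: with
probability `p_i` — the per-residue **helicity profile** — (φ, ψ) is
drawn from a tight alpha-helical basin (Gaussian around (−63°, −42°),
σ = 7°), otherwise from a residue-independent mixture of coil basins
(β 32%, polyproline-II 35%, α_R 20%, α_L 13%). The α_R component gives
the coil distribution a nonzero intrinsic helical-basin mass, as real
coil libraries have. ω is trans (180° ± 5°); cis peptides can be
switched on at a configurable rate and are off by default. The mixture
is deliberately residue-independent: the analyses downstream depend on
controllable helicity, not on neighbor-dependent coil fine structure,
which we do not claim to reproduce.

Chains are grown with ideal covalent geometry (NeRF internal
coordinates; N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, standard angles),
the carbonyl O in the peptide plane and the amide H placed geometrically
(N–H 0.98 Å opposite the C(i−1)/CA bisector; absent for Pro and residue
1). Side-chain heavy atoms come from ideal residue templates (Chemical
Component Dictionary geometry) expressed in the local N/CA/C frame and
rotated to the sampled χ angles; χ priors are three-well rotamer
distributions (−60°/180°/+60°, weights 0.50/0.35/0.15, σ = 10°) with
ring-flip wells for aromatics and uniform sampling for terminal planar
groups.

**Clash relief.** A clash is a heavy-atom pair closer than 0.2 nm in
different residues (peptide-bonded backbone neighbours exempt). The
0.2 nm cutoff is permissive compared with van der Waals contact — it
rejects genuine overlaps while tolerating the tight packing of an ideal
helix. Side-chain clashes are relieved by greedy rotamer search (up to
12 proposals per residue against the current structure); clashes between
χ-invariant atoms (backbone, CB, Gly/Ala/Pro side chains) indicate a
backbone self-intersection and are relieved by pivot moves — redrawing
(φ, ψ) of a residue on the arc between the clashing positions — with a
helical-bias decay on repeated failure, so conflicts the helical basin
cannot resolve (e.g. a proline ring against the preceding turn's
carbonyl) relax into a local coil kink. Conformers still clashing after
a 50-round budget are returned flagged, never dropped silently.

Pools are `n_seeds × variants_per_seed` conformers; variants are
clash-relaxed copies with torsions jittered by at most 5°, standing in
for short vacuum-MD diversification of each generated structure
(30,000 = 5,000 × 6 at full scale). The side-chain resampler freezes the
backbone heavy atoms bitwise and redraws all χ angles with hard-sphere
rejection, a surrogate for backbone-restrained explicit-solvent MD; by
default it returns 41 snapshots per parent, the count obtained by
sampling a 20-ns trajectory every 500 ps inclusive. Snapshots that
cannot be repacked fall back toward the parent's rotamers, so the yield
is complete; contacts already present in a (flagged) parent are treated
as its baseline.

## Forward models

**Chemical shifts.** A two-state model: δ = δ_coil(residue, nucleus) +
h_i·Δδ_helix(nucleus), with h_i the per-conformer DSSP 'H' indicator and
ensemble averaging giving δ_coil + f_H·Δδ_helix. The coil reference is a
static embedded table on the usual aqueous random-coil scale; the helix
offsets default to +3.1 (Cα), −0.5 (Cβ), −0.35 (Hα) ppm. These offsets
are defaults of the model, chosen in the range commonly reported for
helix formation; they are not fitted. The model ignores neighbor
corrections, ring currents and electrostatics — adequate here because
both the synthetic observations and the selection objective use the same
helicity-sensitive signal, which is exactly the property the selection
is meant to recover.

**SAXS.** The Debye equation over point scatterers,
I(s) = Σ_ij f_i f_j sin(s·r_ij)/(s·r_ij), with per-residue Cα scatterers
(uniform f) as the default for large pools and all-heavy-atom mode
(element-constant f = electron count) for final reporting. No hydration
shell or excluded-volume term is included; for selection only the curve
*shape* matters, and model and data are always related through a fitted
scale. For large point sets the curve can be evaluated from a binned
pair-distance histogram, exact to well below fit tolerances at the
angles used.

**Primary SAXS analysis.**

- Guinier: iterative linear fit of ln I vs s², restricted to
  s·Rg < 1.2, starting from the 10 lowest-angle points and re-applying
  the window until it stabilizes (≤ 20 iterations). Note the truncation
  bias: for elongated particles the quadratic expansion already deviates
  within the standard window, so the fitted Rg sits ~2–3% below the
  coordinate Rg; with a conservative window (s·Rg < 0.8) agreement is
  within 2%.
- p(r): weighted histogram of all pairwise distances (0.05 nm bins);
  Dmax is the largest pair distance; ensembles average member
  histograms, and bin centers may overhang Dmax by half a bin.
- Dimensionless Kratky: (sRg)²·I(s)/I(0) vs sRg — the standard
  definition. A globule peaks near (√3, 3/e) and decays; an extended
  chain keeps rising.
- Mass-fractal dimension: Dm = −d log I / d log s by linear regression
  over s = 0.55–2.0 nm⁻¹ (configurable); Flory exponent ν = 1/Dm.
  Anchors: a thin rod gives Dm ≈ 1, ensemble-averaged self-crossing
  random walks Dm ≈ 2 (the finite-window estimate sits slightly below 2
  because the asymptotic s⁻² regime is approached from above), swollen
  chains 1.7–1.8, globules 3–4.
- χ²: reduced chi-square with the closed-form least-squares scale
  (optional additive background, off by default — background fitting is
  exposed but not part of the default objective).

## Ensemble selection

The objective is O = w_s·RMSD/RMSD₀ + w_x·χ²/χ²₀ with the normalization
constants taken from the full pool, so the default weights 1:1 are
scale-free. Sub-ensembles grow by forward greedy search with the
ensemble-averaged prediction recomputed at every size (ties break to the
lower index; ties in the objective count as acceptable growth so a pool
of identical conformers fills the target with the first indices), stop
at the target size or after 10 additions without improvement, and are
then refined by deterministic exchange sweeps (replace one member by one
non-member whenever that lowers the objective, ≤ 5 sweeps). On small
instances where exhaustive enumeration is feasible the refined greedy
objective is within 20% of the optimum; the exchange step is what closes
most of plain forward-greedy's gap.

The repeated protocol draws `draw_size` members without replacement
(draws independent across repeats, as the original protocol leaves the
overlap between repeats unspecified), selects greedily, and unions the
selections by conformer identity tag. Each union member is side-chain
resampled into the secondary pool (cis-containing members excluded), and
the final ensemble (default 60) is selected from it with the same
objective. The RMSD is identical for primary and secondary shifts (the
coil term cancels); the secondary-shift Pearson correlation is reported
as the more sensitive agreement measure.

## Structure analysis

Secondary structure is assigned per conformer by the Kabsch–Sander
hydrogen-bond criterion (E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
kcal/mol < −0.5; helices from two consecutive n-turns, strands from
bridge ladders, then turns and bends, priority H > E > G > I), and
ensemble state frequencies give per-residue probabilities. This
single-threshold per-conformer assignment plus frequency averaging
approximates a continuous-DSSP profile: the ensemble averaging, not the
per-conformer soft assignment, dominates the probability signal.
Helicity is reported both as P(H) alone and with G/I folded in; the
default "high-helicity segment" thresholds are 85% and 90%. A logo
matrix (per-residue state percentages) and a 100-row pseudo-alignment
(largest-remainder apportionment) are exported for external logo tools.

Interaction criteria (all geometric):

- Salt bridge: any side-chain O (Asp/Glu) to side-chain N (Arg/Lys)
  distance < 0.4 nm; orientation (acidic partner toward N- or
  C-terminus) and spacing class (i±3, i±4, other) annotated; all
  simultaneous partners recorded.
- Cation-π: five distances all < 0.6 nm — (1) ring plane to Arg Cζ /
  Lys Nζ, (2) ring plane to Arg Nε / Lys Cε, (3) Cδ1, (4) Cδ2 (Trp:
  Cη2) and (5) Cζ (Trp: Cε2) to the cation atom. The asymmetry in
  distance 2 (Arg Nε but Lys Cε) follows the published criterion as
  printed. Ring planes are least-squares planes; the Trp plane uses the
  six-membered ring.
- Edge-to-face: a phenyl carbon within 0.5 nm of the indole
  least-squares plane, with its in-plane projection inside the ring
  extent (largest in-plane atom radius + 0.05 nm). The lateral
  containment is our addition — a plane-distance criterion alone would
  count coplanar but laterally distant rings.

Conformational PCA operates on condensed Cα–Cα distance matrices
(superposition-free, so the result does not depend on how a bending,
extending chain is aligned); selected conformers are projected into the
pool's component space.

## Synthetic data: what it emulates

The scenario emulates a 74-residue low-complexity charged SAH construct:
an 8-residue disordered expression-tag remnant, a long shallow rise of
helicity on the N side, a high-probability core, and a steeper fall at
the C-terminus (the asymmetric taper). Observations are the two-state
shift prediction plus Gaussian noise (σ = 0.3 ppm for Cα/Cβ, 0.05 ppm
for Hα) and the Cα Debye curve on s = 0.1–3.0 nm⁻¹ (100 points) with
relative noise growing linearly from 2% to 15% — the generic error
growth of a background-subtracted solution scattering profile.

The ground-truth ensemble is conditioned on the extended regime
(terminal Cα separation ≥ 9 nm), giving a mean Rg near 3.0 nm: a tight,
extended, helical reference state, which is the physical situation the
joint selection is designed to resolve. The decoy pool spans compact to
extended shapes by construction — truth-profile draws (unconditioned),
uniformly scaled profiles, flat profiles biased toward the disordered
end, the reversed profile (same mean helicity, wrong local pattern —
look-alikes in global shape that only the shifts can reject), kinked
multi-block helices (compact), and rigid full-length helices — and its
Rg spread is several-fold wider than the truth's.

Not emulated: NMR peak overlap and assignment ambiguity, instrument
SAXS artifacts (smearing, buffer mismatch), neighbor-dependent coil
shifts, side-chain-specific shift effects, hydration-shell scattering,
and any thermodynamic weighting of conformers. Passing the recovery
experiment therefore shows that the selection machinery recovers local
and global structure from data with the assumed noise structure; it does
not validate the forward models against real measurements.

## Scaled-down study conditions

The recovery experiment runs the full pipeline at pool 2000 / draws of
500 / five repeats / final 60, with 10 side-chain snapshots per union
member, completing on one CPU in a few minutes; the full-scale settings
(30,000 / 5,000 / 5 / 60 and 41 snapshots) remain plain configuration.
Success criteria: SAXS χ² ≤ 1.5, secondary-shift correlation ≥ 0.9,
mean Rg within 5% of truth, helicity-profile Pearson r ≥ 0.8, and joint
selection beating SAXS-only selection on shift correlation in ≥ 8/10
noise replicates. All are met with margin under the default seeds.

## Known limitations

- Ideal covalent geometry throughout; no energetics, no solvent, no
  thermodynamic weights — ensembles are conformational hypotheses
  filtered by data, not Boltzmann samples.
- The two-state shift model cannot represent fractional helicity within
  a single conformer, only across the ensemble.
- The Debye model omits hydration-layer contrast; absolute intensities
  are arbitrary.
- The cation-π criterion is purely geometric; contacts it reports are
  candidates compatible with the coordinates, not energetically
  validated interactions.
- The 0.2 nm clash cutoff under-rejects relative to true van der Waals
  radii; generated conformers are "not absurd" rather than
  force-field-relaxed.
- CD helicity percentages are carried as supplied; the two-state
  MRE-based estimator is a labelled approximation and deliberately not
  validated against deconvolution results.
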