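# Methods

This note documents the models implemented in switchlab, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer should know about.

## Peptide tiling-array enrichment

Arrays tile client-protein sequences as 18-mers stepping by 3 residues
(`ArrayDesign`, giving ⌊(L−18)/3⌋+1 spots per sequence). Intensities are
normalized per replicate to that replicate's brightest spot, making
replicates comparable regardless of exposure; normalization is idempotent
and enrichment is invariant to uniform intensity rescaling. The top set is
the highest ceil(0.10·N) spots — ceiling, so small arrays never yield an
empty set — with ties at the cut broken by (intensity descending, spot id
ascending) for determinism.

Enrichment per amino acid is E(a) = log2(f_top(a)/f_all(a)) on residue
frequencies. Occurrences are counted unweighted (not intensity-weighted),
and peptides are pooled across the proteins on the array by default;
per-protein scoring is available via the table's protein_id column. An
amino acid absent from the top set would give E = −∞; it instead receives
a pseudo-count of 0.5 residues and a `depletion_floor` flag, keeping E
finite and monotone while marking that the value is a floor.

Statistics: with `per_replicate=True` (the default) the top set is
selected within each replicate, E is computed per replicate, and each
amino acid is tested with an unpaired two-sided t-test of its replicate E
values against 0. Per-replicate selection is what makes a replicate-based
test possible at all: a single mean-ranked top set produces identical E
values in every replicate and hence no variance. The pooled mode
(`per_replicate=False`) uses one mean-ranked top set and reports E without
p-values. Probe-vs-probe comparison runs the same unpaired test on
E_A − E_B per amino acid. p-values are reported unadjusted, matching the
p < 0.05 flagging convention of this assay's literature; a
Benjamini–Hochberg option exists but is off by default. If replicate E
values are exactly identical the t statistic is degenerate; the
implementation then reports p = 0 for a nonzero mean and p = 1 otherwise.

## Binding isotherms

The model is F(x) = r_free + (r_max − r_free)/(1 + 10^((logK_half − x)·n_H))
with x = log10(concentration/µM). K_half is documented throughout as an
apparent half-saturation constant, not a Kd: the receptor populates
monomer/dimer/oligomer states, so a titration scores superimposed
equilibria. MST data are fitted with the identical model after min–max
normalization of the response to [0, 1].

Fitting is trust-region least squares (`scipy.optimize.least_squares`,
ftol/xtol/gtol 1e−12) with a deterministic 5-point multistart: logK_half
spread across the sampled x range, n_H = 1, plateaus from the curve ends.
Default bounds are n_H ∈ [0.3, 5] and plateaus within the observed
response range ± 50% of its span — minimal constraints that prevent the
plateau/K trade-off from blowing up on weak binders. Parameters can be
pinned (`fixed={"r_max": ...}`), the protocol used for weak binders whose
upper plateau is unreached. Standard errors come from the Gauss–Newton
covariance; the SE of K_half uses the delta method on logK_half. A fitted
logK_half more than one decade outside the sampled range is flagged as
extrapolated rather than suppressed; flat data raise "no binding signal".

Recovery study (`recovery.py`): 16 log-spaced concentrations spanning each
assay's range, Gaussian response noise of sd 0.005 anisotropy units (0.02
for the normalized 0–1 MST scale), 100 noise realizations per ligand.
Under these conditions the median recovered K_half is within ~2% of truth
for every ligand in the measured panel (0.456–29.2 µM), and the nominal
95% SE interval covers the truth for 85–99% of realizations.

## NMR peak-list analyses

Peak matching is mutual-nearest-neighbour in tolerance-scaled shift space
(ΔH/tol_H, ΔC/tol_C), a match requiring scaled distance ≤ 1; defaults
tol_H = 0.03 ppm, tol_C = 0.15 ppm reflect methyl-TROSY linewidths.
Mutation-based assignment reports wild-type peaks with no mutant partner
(vanished) and mutant-only peaks (appeared); more than one vanished peak,
or a simultaneous vanish/appear pair (a large shift masquerading as a
disappearance), is flagged ambiguous with all candidates returned.

Combined CSP: Δν = √(ΔδH² + (α_C·ΔδC)²) with α_C = 0.25, the standard
down-weighting of the broader ¹³C methyl dispersion; α_C is configurable
since conventions vary. Categories use strict inequalities (Δν > 0.005
slight, > 0.010 moderate, > 0.020 significant), so a value exactly on a
boundary stays in the lower class. The category function is total and
monotone. Unassigned fingerprint spectra are handled by positional
matching with per-category counts instead of per-residue records.

PRE: per site, ratio = I_PRE/I₀ ∈ [0, 1] with erased peaks assigned 0 —
erasure is the strongest broadening, not missing data. The reciprocal
convention (I₀/I_PRE) exists behind a flag but is off by default because
it is unbounded on erased peaks. Ratios are multiplied by sasa/max(sasa)
over the probed residues, discounting broadening that mere surface
exposure to free spin label could explain; profiles sort ascending so the
most broadened site comes first. Both spectra must share an intensity
scale — the ranking is invariant to a common rescaling, not to
independent ones.

## Structures, SASA and restraints

PDB input goes through gemmi; only the first model is read, and alternate
locations collapse deterministically (highest occupancy, ties by altloc
letter). CA-only models are first-class: ideal-helix fixtures
(r = 2.3 Å, rise 1.5 Å/res, twist 100°/res — canonical α-helix constants)
have closed-form CA–CA distances used as oracles to 1e−9 Å.

SASA is an in-repo Shrake–Rupley: 960 golden-spiral points per atom on
the probe-expanded sphere (probe 1.4 Å), exposure fraction × 4π(r+probe)²,
van der Waals radii H 1.20 / C 1.70 / N 1.55 / O 1.52 / S 1.80 / P 1.80 /
Se 1.90 Å. At 960 points an isolated sphere is exact to <0.5%; a
random-direction Monte-Carlo estimate written independently in the tests
agrees within 2% on small clusters. Per-residue SASA sums all of a
residue's atoms (side chains included when present). PRE normalization
depends only on SASA *ratios* across the probed residues, which are far
less sensitive to radius-set choices than absolute Å² values.

Cross-link classification: a lysine pair is inter-molecular when its mean
abundance is exactly 0 in the monomer band and positive in ≥1 oligomer
band; "abundant" additionally requires ≥1% mean abundance in the
highest-order band. On the published six-pair quantification this yields
exactly five abundant inter-molecular links (the K53–K265 pair sits at
0.5%). Both thresholds are arguments. The classification is invariant to
row order and symmetric duplicates. The literature's residue-numbering
ambiguity for the dimer-interface link (120 vs 121) is not silently
resolved; the table's own numbering (121) is used, and callers can apply
an alias map before restraint mapping if they adopt the other convention.

Restraints: the minimum Cα–Cα distance over allowed chain assignments
(same-chain only, or also cross-chain with `inter_chain=True`) is
classified as satisfied (< 28 Å), marginal ([28, 33] Å — the closed
interval, attributable to local flexibility), or violated. Pairs touching
residues absent from the model are reported "unmappable" rather than
dropped, mirroring real models whose flexible regions are unresolved.
Interface residues are those with any heavy atom within 5 Å of the
partner chain (8 Å default for CA-only models, since side chains are
missing). Groove arithmetic: an extended n-mer spans (n−1)·3.4 Å; it fits
when that is ≤ 39 Å, so a 12-mer (37.4 Å) fits and a 13-mer (40.8 Å) does
not.

## Synthetic data: what it does and does not emulate

Arrays: spot log-intensity = Σ residue weights + Normal(0, noise_sd²),
i.e. multiplicative log-normal noise on a positive fluorescence-like
scale, with noise seeded per (spot, replicate) from a stable hash so that
subsetting proteins or replicates never reshuffles the remaining noise.
Defaults: five client sequences at realistic tiled-protein lengths
(530/248/110/130/335 aa), 3 replicates, noise_sd 0.2, preferences +0.5
for C/Y/W/R and −0.5 for D/E — the qualitative preference pattern this
sensor shows. The weight model is a stand-in for an unknown physical
binding preference, not a claim about the assay: it generates additive,
position-independent effects, no spot-position artefacts, no saturation,
no cross-talk between adjacent spots. Passing recovery tests therefore
shows the *statistics* are correct and calibrated (false-positive rate
≈ 5% under the null), not that real arrays are this well behaved.

Titrations come from the same equation the fitter uses, so recovery tests
measure noise-driven bias and variance, not model misspecification.
Peak-list generation displaces or removes designated peaks only —
no peak overlap, lineshape or baseline effects. Helix fixtures provide
exact geometric oracles, not realistic protein packing. Cross-link tables
place designated pairs at zero monomer-band abundance by construction.

## Pipeline and determinism

`run_pipeline` executes simulate → arrays → binding → nmr → restraints,
writing every table plus a manifest (package version, seed, SHA-256
parameter hash, stage timings) and a report. All randomness flows from the
config seed through per-entity stable hashes; a rerun with the same config
is byte-identical in every data table. Configuration is a single YAML
block with CLI overrides; unknown keys are rejected rather than ignored.
A stage failure aborts with the stage name and the underlying error.

Problem sizes used by the shipped drivers and tests — 100 fits per ligand
in the recovery panel, 200 simulated arrays for the null-calibration
check, ≤10-atom SASA oracle clusters, 40-residue helix fixtures — were
chosen so each analysis states its claim at comfortable statistical
resolution while any single driver or the full test suite completes in
well under a minute of compute.

## Known limitations

- The combined-CSP weight α_C and the CSP thresholds are conventions;
  per-residue Δν values from other software will differ if it combines
  dimensions differently (e.g. taking the larger shift).
- K_half estimates assume a single effective transition; strongly
  multiphasic titrations will fit poorly and should be caught by R² and
  the extrapolation flag, not trusted.
- SASA uses a fixed radius set and no implicit hydrogens beyond those in
  the file; absolute values differ between radius conventions by several
  percent, which is why downstream use is ratio- or rank-based.
- The t-tests at 3 replicates have low power for small effects; the
  false-positive calibration holds, but depletion of rare amino acids may
  go undetected on small arrays.
- AUC oligomer-distribution analysis, raw spectrum processing and
  homology threading are out of scope; structural models are inputs.
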