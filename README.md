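# switchlab

Quantitative analysis of how the ER stress sensor IRE1α recognizes unfolded
proteins through its core lumenal domain (cLD). The package implements, as
reusable and tested Python, the four analyses that together support the
direct-recognition model of the unfolded protein response: peptide
tiling-array enrichment statistics, apparent-affinity fitting of binding
titrations, methyl-NMR chemical-shift-perturbation (CSP) and paramagnetic
relaxation enhancement (PRE) mapping, and cross-linking mass-spectrometry
distance restraints on oligomer models. It is aimed at structural
biologists and biochemists who want to rerun, audit or adapt these
analyses; because no raw datasets are deposited for this system, every
input can be simulated with known ground truth by the built-in generators.

## The quantitative core

**Array enrichment.** Client proteins are tiled as 18-mer peptides stepping
by 3 residues. Spot intensities are normalized per replicate to the
brightest spot, the top 10% of binders is selected, and each amino acid
*a* is scored as

    E(a) = log2( f_top(a) / f_all(a) )

the log-ratio of its frequency among top-binder residues to its frequency
over the whole array. Replicate-wise E values support an unpaired
two-sided t-test against 0, and two probes (the sensor vs the Hsp70
chaperone BiP) are compared per amino acid on E_A − E_B.

**Binding isotherms.** Titrations (fluorescence anisotropy, or normalized
microscale-thermophoresis response) are fitted with the Hill-type
log-dose model

    F(x) = r_free + (r_max − r_free) / (1 + 10^((logK_half − x)·n_H))

where x = log10 of protein concentration (µM). K_half = 10^logK_half is an
*apparent* half-saturation constant — the receptor interconverts between
monomers, dimers and oligomers, so the titration superimposes several
equilibria and K_half is not a Kd.

**NMR mapping.** Between two assigned methyl-TROSY peak lists, the combined
CSP per site is Δν = √(ΔδH² + (0.25·ΔδC)²), classified as slight/
moderate/significant above 0.005/0.010/0.020 ppm (strict inequality).
PRE broadening is the intensity ratio I_PRE/I₀ (0 = erased), multiplied by
the residue's fractional solvent accessibility (Shrake–Rupley SASA,
computed in-repo) to discount nonspecific surface contacts.

**Cross-link restraints.** Lysine–lysine BS3 cross-links quantified per
SDS-PAGE band are inter-molecular when absent from the monomer band;
abundant ones (≥1% in the highest oligomer band) become Cα–Cα restraints:
satisfied below 28 Å, marginal up to 33 Å, violated beyond. An extended
peptide of n residues spans (n−1)·3.4 Å, compared against the 39 Å
MHC-like groove.

## Worked example

```
$ switchlab demo --seed 1 --outdir demo_run
$ python analysis/03_binding_affinities.py --seed 1
single titration: K_half = 26.5 +/- 2.5 uM (true 24), R^2 = 0.9968
     ligand  true_K_half_uM  median_fit_uM  q25_uM  q75_uM  bias_pct
       mpz1              24           24.3    22.3    25.5      1.21
       8ab1               5           4.95    4.68    5.24    -0.949
     mpz1_n              16           15.9    14.9    16.9    -0.821
  mpz1_n_2x           0.456           0.45   0.425   0.479     -1.33
        ch1            29.2             29    27.6    30.5    -0.568
   delta131            21.4           21.5    19.8    22.7     0.234
if2l_mpz1_n             5.4           5.37    5.07    5.69    -0.606
worst median bias across the panel: 1.3% (10% tolerance)
tandem repeat binds 35x tighter than the single minimal site (avidity)
```

Each row simulates 100 titrations at a measured apparent affinity
(full-length and minimal peptides, an unfolded IgG C_H1 domain by
thermophoresis, a destabilized nuclease, and an oligomerization-dead
interface mutant) and refits them: the median recovered K_half sits within
~1% of the generative truth, and the tandem-repeat ligand shows the
~35-fold avidity gain expected from two binding sites.

The other drivers follow the same pattern: `01_simulate_inputs.py` writes
every synthetic input under `results/inputs/`, `02_array_enrichment.py`
recovers the injected Cys/Tyr/Trp/Arg preference (and Asp/Glu depletion)
at p < 0.05, `04_nmr_mapping.py` assigns a methyl by its disappearance in
a mutant spectrum and classifies CSPs/PREs, and
`05_crosslink_restraints.py` reproduces the five-of-six abundant
inter-molecular cross-link selection and the groove-length arithmetic
(a 12-mer fits the 39 Å groove at 37.4 Å; a 13-mer does not at 40.8 Å).

## Layout

- `src/switchlab/` — library: `synth` (generators), `arrays`, `binding`,
  `recovery`, `nmr`, `structure`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers writing to `results/`
- `tests/` — pytest suite (unit, property and acceptance tests)
- `docs/methods.md` — models, assumptions, parameter choices, limitations
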