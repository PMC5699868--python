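#!/usr/bin/env python
"""Map peptide-binding effects on methyl spectra: assignment, CSP, PRE.

Assigns a methyl by its disappearance in the point-mutant spectrum,
classifies combined chemical-shift perturbations of the peptide-bound
spectrum against the slight/moderate/significant thresholds, and ranks
SASA-normalized PRE broadening from a spin-labelled ligand.  Writes
csp.tsv, csp_counts.json and pre.tsv.
"""

import argparse
import json
from pathlib import Path

import switchlab as sl
from switchlab.nmr import category_counts, csp_profile, csp_table, pre_profile, pre_table, read_sparky
from switchlab.structure import parse_structure, sasa
from switchlab.synth import gen_peaklists

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--inputs", type=Path, default=Path("results/inputs"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

ref = read_sparky(args.inputs / "peaks_ref.list")
bound = read_sparky(args.inputs / "peaks_bound.list")
mutant = read_sparky(args.inputs / "peaks_mutant.list")

assign = sl.assign_by_disappearance(ref, mutant)
print(f"mutation-based assignment: vanished peak(s) {assign['vanished']} "
      f"(ambiguous: {assign['ambiguous']})")

records = csp_profile(ref, bound)
csp_table(records).to_csv(args.out / "csp.tsv", sep="\t", index=False)
counts = category_counts(records)
(args.out / "csp_counts.json").write_text(json.dumps(counts, indent=1))
moved = [r.label for r in records if r.category != "none"]
print(f"CSP categories: {counts}; perturbed methyls: {moved}")

# PRE: spin label erases the closest methyl; normalize by residue SASA
dimer = parse_structure(args.inputs / "helix_dimer.pdb")
_, per_res = sasa(dimer)
chain_a = per_res[per_res.chain == "A"].set_index("resnum")["sasa_A2"]
sasa_map = {lab: float(chain_a.iloc[i % len(chain_a)]) for i, lab in enumerate(ref.labels())}
_, pre_spec = gen_peaklists(ref, vanished={"I105"}, seed=args.seed)
pre_records = pre_profile(ref, pre_spec, sasa_map)
pre_table(pre_records).to_csv(args.out / "pre.tsv", sep="\t", index=False)
print(f"strongest PRE broadening: {pre_records[0].label} "
      f"(normalized PRE {pre_records[0].normalized_pre:.3f}; erased peak ranks first)")
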