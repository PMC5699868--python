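#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under results/inputs/: client FASTA, tiling-array spot table,
anisotropy titration, methyl peak lists (reference / peptide-bound /
mutant), an ideal-helix dimer PDB, and a simulated cross-link table.
Everything is seeded; rerunning reproduces identical files.
"""

import argparse
from pathlib import Path

import numpy as np

import switchlab as sl
from switchlab.nmr import write_sparky
from switchlab.pipeline import DEMO_PREFERENCES, _demo_peaklist
from switchlab.structure import crosslink_table_to_csv, write_pdb
from switchlab.synth import (
    AAWeightModel,
    client_sequences,
    gen_array,
    gen_peaklists,
    gen_titration,
    gen_xlink_table,
    write_fasta,
    write_titration_csv,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/inputs"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

clients = client_sequences(seed=args.seed)
write_fasta(clients, args.out / "clients.fasta")
print(f"clients: {len(clients)} sequences, {sum(map(len, clients.values()))} aa total")

model = AAWeightModel.with_preferences(DEMO_PREFERENCES, noise_sd=0.2, seed=args.seed)
array = gen_array(clients, model, replicates=3)
array.to_csv(args.out / "array_spots.csv")
print(f"array: {array.spots.spot_id.nunique()} spots x 3 replicates "
      f"(favouring C/Y/W/R, disfavouring D/E)")

params = sl.BindingParams(0.05, 0.25, np.log10(24.0), 1.0)
x = np.linspace(np.log10(0.1), np.log10(500.0), 16)
write_titration_csv(gen_titration(params, x, 0.005, seed=args.seed),
                    args.out / "titration_mpz1.csv")
print("titration: 16 points, true K_half 24 uM, anisotropy noise sd 0.005")

base = _demo_peaklist()
shifted = {"I110": (0.015, 0.05), "I125": (0.004, 0.08), "I140": (0.025, 0.01)}
_, bound = gen_peaklists(base, shifted=shifted, seed=args.seed)
_, mutant = gen_peaklists(base, vanished={"I120"}, seed=args.seed)
write_sparky(base, args.out / "peaks_ref.list")
write_sparky(bound, args.out / "peaks_bound.list")
write_sparky(mutant, args.out / "peaks_mutant.list")
print(f"peak lists: {len(base)} methyls; shifted {sorted(shifted)}; I120 removed in mutant")

a = sl.gen_helix(sl.HelixSpec(n_res=40), chain="A")
b = sl.gen_helix(sl.HelixSpec(n_res=40), chain="B", offset=(9.0, 0.0, 0.0))
dimer = sl.StructureModel(
    chain=np.concatenate([a.chain, b.chain]),
    resnum=np.concatenate([a.resnum, b.resnum]),
    resname=np.concatenate([a.resname, b.resname]),
    atom_name=np.concatenate([a.atom_name, b.atom_name]),
    element=np.concatenate([a.element, b.element]),
    coords=np.vstack([a.coords, b.coords]),
)
write_pdb(dimer, args.out / "helix_dimer.pdb")
print("structure: two 40-residue ideal helices 9 A apart (chains A/B)")

pairs = [(5, 35), (12, 28), (20, 20)]
xlinks = gen_xlink_table(pairs, inter_set={(5, 35), (12, 28)}, seed=args.seed)
crosslink_table_to_csv(xlinks, args.out / "xlinks_synthetic.csv")
print(f"cross-links: {len(pairs)} pairs, 2 designated inter-molecular")
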