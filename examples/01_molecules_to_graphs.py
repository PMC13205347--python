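"""Parse molecules into attributed graphs and screen them for the dataset.

Builds heavy-atom graphs from a few SMILES strings, checks them against
the corpus constraints (<= 16 heavy atoms, only C/N/O) and prints a
structural similarity matrix used for hard-negative mining.
"""

import numpy as np

from nmrmatch import smiles_to_graph, structural_similarity, validate_molecule

candidates = {
    "ethanol": "CCO",
    "benzene": "c1ccccc1",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "octadecane": "C" * 18,          # too large for the corpus
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
}

graphs = {}
for name, smi in candidates.items():
    g = smiles_to_graph(smi)
    ok, reason = validate_molecule(g)
    status = "accepted" if ok else f"rejected ({reason})"
    print(f"{name:12s} {g.heavy_atom_count:2d} heavy atoms, "
          f"{len(g.edges):2d} directed edges -> {status}")
    if ok:
        graphs[name] = g

print("\nTanimoto similarity (Morgan radius 2, 1024 bits):")
names = list(graphs)
for a in names:
    row = " ".join(f"{structural_similarity(graphs[a], graphs[b]):.2f}"
                   for b in names)
    print(f"{a:12s} {row}")
print("\nValues near 1 mean near-identical substructure content; the "
      "hard-negative (Test_diff) builder pairs molecules below 0.2.")
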