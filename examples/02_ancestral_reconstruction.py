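"""Marginal ancestral reconstruction on a toy four-taxon alignment.

Reconstructs internal-node states for a short peptide alignment under the
JTT model with frequencies estimated from the alignment itself, and prints
the root's assigned residue and posterior per site.
"""

import numpy as np

import rifconv as rc
from rifconv.io import encode_sequence

tree = rc.read_tree("((A:0.12,B:0.07):0.05,(C:0.20,D:0.09):0.11);")
seqs = {"A": "KRSWQ", "B": "KNSWQ", "C": "QNSW-", "D": "KDSWA"}
aln = rc.Alignment("toy", list(seqs),
                   np.vstack([encode_sequence(s) for s in seqs.values()]))

model = rc.build_model(rc.estimate_f_gene(aln, pseudocount=1.0))
rec = rc.reconstruct(aln, tree, model)

print("leaf sequences:", ", ".join(f"{t}={s}" for t, s in seqs.items()))
print(f"\n{'site':>4} {'root state':>10} {'posterior':>10}")
for s in range(aln.length):
    a = rec.states[tree.root, s]
    print(f"{s + 1:>4} {rc.AMINO_ACIDS[a]:>10} "
          f"{rec.posteriors[tree.root, s, a]:>10.3f}")
print("\nInvariant columns (S, W) reconstruct with posterior ~1; variable "
      "columns\nspread posterior mass over the residues seen in the leaves.")
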