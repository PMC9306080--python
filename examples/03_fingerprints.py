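"""Substructure-count fingerprints over the 4860-pattern library.

Fingerprints a few small molecules and prints the number of non-zero
patterns and a couple of matched pattern strings.  The count vector is the
protein-space model's input representation; its binary view is the
indicator count > 0.
"""

from ahiot.fingerprints import compute_fingerprint, load_library

library = load_library()
print(f"library: {library.size} substructure patterns ({library.version})")

for smiles in ("CCO", "CC(=O)Nc1ccc(O)cc1", "c1cnc[nH]1"):
    fp = compute_fingerprint(smiles, library)
    nonzero = [(library.patterns[i], int(fp.counts[i]))
               for i in fp.counts.nonzero()[0][:4]]
    print(f"{smiles:<22s} non-zero patterns: {int((fp.counts > 0).sum()):>3d}  "
          f"first matches: {nonzero}")
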