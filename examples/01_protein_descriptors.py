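"""Build the three protein descriptor families and assemble a pair vector.

A target protein is described by a binary domain indicator, Chou's
type-I pseudo amino acid composition (20 residue frequencies plus
lambda=30 sequence-order correlation factors) and 400 bi-gram features
of its position-specific scoring matrix; the drug block is ingested
as-is and the four blocks concatenate into one pair vector.
"""

import numpy as np

from pudti import (
    assemble_dti_vector,
    build_domain_vector,
    compute_bigram_pssm,
    compute_paac,
)

rng = np.random.default_rng(0)
sequence = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))

domain_vec = build_domain_vector(["PF00001", "PF00042"],
                                 [f"PF{i:05d}" for i in range(1, 1332)])
paac = compute_paac(sequence, lam=30)
pssm = rng.integers(-5, 9, size=(120, 20)).astype(float)  # stand-in log-odds
bigram = compute_bigram_pssm(pssm)

drug = rng.normal(size=1444)  # stand-in for ingested PaDEL descriptors
pair_vector = assemble_dti_vector(drug, domain_vec, paac, bigram)

print(f"domain indicator : {domain_vec.shape[0]} entries, "
      f"{int(domain_vec.sum())} domains present")
print(f"PAAC             : {paac.shape[0]} entries, sum = {paac.sum():.6f} "
      "(composition + correlation blocks, normalized to 1)")
print(f"PSSM bi-gram     : {bigram.shape[0]} entries")
print(f"pair vector      : {pair_vector.shape[0]} entries "
      "(drug 1444 + domains 1331 + PAAC 50 + bi-gram 400)")
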