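"""Published reference values used by the regression and acceptance suites.

`BENCHMARK_ROWS` holds the component metrics (validity, uniqueness, novelty)
and the printed success rate for each published distribution-learning
benchmark row; the success-rate product identity is regression-tested over
all of them.

`CASE_STUDY_PAIRS` holds the printed case-study SMILES (generated molecule,
nearest test-set molecule) with internal whitespace already stripped, and
`CASE_STUDY_PROPERTIES` the printed per-row descriptor values
(tanimoto, qed, sascore, logp) for the generated molecule of each row.
"""

BENCHMARK_ROWS = [
    # (label, validity, uniqueness, novelty, printed success rate)
    ("moses/CharRNN", 0.975, 0.999, 0.842, 0.820),
    ("moses/VAE", 0.977, 0.998, 0.695, 0.678),
    ("moses/AAE", 0.937, 0.997, 0.793, 0.741),
    ("moses/LatentGAN", 0.897, 0.997, 0.949, 0.849),
    ("moses/JT-VAE", 1.0, 0.999, 0.914, 0.913),
    ("moses/MolGPT", 0.995, 1.0, 0.781, 0.777),
    ("moses/CON-GPT-unfrozen", 0.992, 1.0, 0.791, 0.785),
    ("moses/CON-GPT-frozen", 0.991, 1.0, 0.834, 0.826),
    ("guacamol/SMILES-LSTM", 0.959, 1.0, 0.912, 0.875),
    ("guacamol/VAE", 0.870, 0.999, 0.974, 0.847),
    ("guacamol/AAE", 0.822, 1.0, 0.998, 0.820),
    ("guacamol/MolGPT", 0.979, 0.998, 0.958, 0.936),
    ("guacamol/CON-GPT-unfrozen", 0.968, 0.999, 0.968, 0.936),
    ("guacamol/CON-GPT-frozen", 0.961, 0.999, 0.975, 0.936),
]

CASE_STUDY_PAIRS = [
    ("COc1ccc(NC(=O)N2CCN(C(=O)C3CCCCC3)CC2)cc1",
     "COc1ccc(NC(=O)N2CCN(C(=O)C3CCCC3)CC2)cc1"),
    ("Cc1nc2cc3c(cc2n1CC(=O)NC1CCCCC1)OCCO3",
     "Cc1nc2cc3c(cc2n1CC(=O)NC1CCCC1)OCCO3"),
    ("Cn1ccc(C(=O)Nc2cc(F)ccc2N2CCCC2)cc1=O",
     "Cn1ccc(C(=O)Nc2cc(F)ccc2N2CCCCC2)cc1=O"),
    ("Cc1cc(CN(C)C(=O)Nc2ccccc2N2CCCC2)no1",
     "Cc1cc(CN(C)C(=O)Nc2ccccc2N2CCCCC2)no1"),
    ("COc1ccccc1-c1noc(C(=O)N2CCCC2)c1N",
     "COc1ccccc1-c1noc(C(=O)N2CCCCC2)c1N"),
    ("CC(CC#N)N(C)C(=O)Nc1ccccc1N1CCCC1",
     "CC(CC#N)N(C)C(=O)Nc1ccccc1N1CCCCC1"),
]

CASE_STUDY_PROPERTIES = [
    # (tanimoto, qed, sascore, logp) as printed, one row per case-study pair
    (0.958, 0.916, 1.839, 2.952),
    (0.957, 0.940, 2.318, 2.565),
    (0.957, 0.941, 2.184, 2.377),
    (0.956, 0.950, 2.102, 3.247),
    (0.952, 0.935, 2.284, 2.168),
    (0.952, 0.925, 2.685, 3.053),
]

# Candidate fingerprints for the documented sweep behind the case-study
# Tanimoto value (the fingerprint behind the printed numbers is not stated).
FINGERPRINT_SWEEP = ("morgan-2-2048", "morgan-2-1024", "morgan-3-2048",
                     "morgan-1-2048", "rdkit", "maccs")
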