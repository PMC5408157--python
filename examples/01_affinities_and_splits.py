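"""Affinity handling: Ki -> pKi conversion, activity classes, train/test split.

Builds a tiny affinity table in memory, classifies each compound by the
hERG potency thresholds (potent Ki <= 50 nM, moderate 50 nM - 5 uM,
inactive >= 5 uM) and performs the reproducible 60/40 split used before
QSAR model building.
"""

from phore3d import MoleculeRecord, classify_activity, ki_to_pki, split_train_test

compounds = [
    ("astemizole-like", 3.3e-9),   # most potent end of the span
    ("moderate-blocker", 1.0e-6),
    ("weak-blocker", 5.4e-5),      # weakest end
]
for name, ki in compounds:
    print(f"{name:18s} Ki={ki * 1e9:10.1f} nM  pKi={ki_to_pki(ki):.4f}  class={classify_activity(ki)}")

records = [MoleculeRecord(id=f"m{i:03d}", ki=10 ** -(5 + (i % 45) / 10)) for i in range(421)]
train, test = split_train_test(records, train_fraction=0.6, seed=42)
print(f"\n421 compounds split 60/40 -> {len(train)} train / {len(test)} test")
print("The pKi values are the regression response; the potent subset seeds the pharmacophore.")
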