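"""Conformer ensembles and pharmacophore feature perception on real ligands.

Takes one member of the bundled benzylpiperidine family (the classic hERG
blocker motif), generates a pruned conformer ensemble (21 kJ/mol energy
window, 0.5 A redundancy cutoff) and perceives its pharmacophore feature
sites from the shipped SMARTS rule table.
"""

from collections import Counter

from phore3d import generate_ensemble, sites_for_ensemble
from phore3d.synthdata import real_family

record = real_family()[0]
ensemble = generate_ensemble(record, max_confs=30, seed=42)
print(f"{record.id}: Ki={record.ki * 1e9:.0f} nM, {len(ensemble)} conformers kept")
print(f"relative energies (kJ/mol): {[round(float(e), 1) for e in ensemble.rel_energies[:6]]}")

sites = sites_for_ensemble(record, ensemble)[0]
kinds = Counter(s.kind for s in sites)
print(f"feature sites of the lowest-energy conformer: {dict(sorted(kinds.items()))}")
print(
    "P = protonated piperidine nitrogen, R = the two aromatic rings, "
    "H = hydrophobic groups, D = donor N-H; this A/D/H/P/R inventory is what "
    "the common-hypothesis search consumes."
)
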