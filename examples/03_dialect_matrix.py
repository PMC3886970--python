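"""Asymmetric distances between three synthetic dialects.

Each dialect gets its own listener model trained on its own pronunciations;
the cell (i, j) is how much dialect j's speech under-activates meanings for
listener i relative to listener i's own baseline.  Rows are listeners, so
the matrix need not be symmetric, and the diagonal is exactly zero.
"""

from ndldist import dialect_matrix, generate_lexicon, perturb_speaker
from ndldist.synthetic import PerturbationModel

INVENTORY = list("ptkbdgmnslrieaou")

canonical = generate_lexicon(25, INVENTORY, seed=42)
dialects = {}
for name, rate in [("nord", 0.05), ("mitte", 0.15), ("sud", 0.3)]:
    model = PerturbationModel(substitution=rate, insertion=rate / 3, deletion=rate / 3,
                              inventory=INVENTORY, seed=42)
    dialects[name] = perturb_speaker(canonical, model, name)

m = dialect_matrix(dialects, n=3)
print("listener \\ speaker\t" + "\t".join(m.labels))
for lab, row in zip(m.labels, m.values):
    print(lab + "\t\t" + "\t".join(f"{v:.3f}" for v in row))
print()
print(f"{len(m.off_diagonal())} off-diagonal distances; asymmetry example:")
print(f"  d(nord hears sud) = {m.cell('nord', 'sud'):.3f}")
print(f"  d(sud hears nord) = {m.cell('sud', 'nord'):.3f}")
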