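"""Per-functional-class interaction profiles over a synthetic corpus.

Generates an annotated corpus (two complexes per protein class, with class
signatures patterned on published complexes: tyrosine stacking and arginine
salt bridges in synthetases and nucleotide-metabolic enzymes, neither
stacking, metals nor salt bridges in GTPases), fingerprints every complex
and aggregates per class.
"""

from alarmone.aggregation import aggregate_by_class
from alarmone.interactions import fingerprint_complex
from alarmone.synthetic import build_corpus

corpus = build_corpus(n_per_class=2, seed=42)
fingerprints = [fingerprint_complex(c.model, c.ligand) for c in corpus]
profile = aggregate_by_class(fingerprints, [c.annotation for c in corpus])

print("contacts per class and category:")
print(profile.by_category.astype(int).to_string())
print()
print("guanine-atom hydrogen bonds per class:")
panel = profile.guanine_hbonds.astype(int)
print(panel.loc[:, panel.sum() > 0].to_string())
print()
total = sum(fp.total_contacts for fp in fingerprints)
print(f"conservation: class-profile total {int(profile.total)} == "
      f"corpus contact total {total}")
print("Note the zero aromatic/metal/ionic rows for the GTPase class — the")
print("planted class signature survives the full detect-and-aggregate path.")
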