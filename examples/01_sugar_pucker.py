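"""Sugar pucker analysis of published (p)ppGpp conformers.

Feeds the bundled endocyclic-torsion table (two energy-minimized unbound
nucleotides and four receptor-bound conformers) to the pseudorotation
analysis and prints the phase angle P, the amplitude nu_max, the pucker
class and the syn/anti state of the glycosidic bond.
"""

from importlib import resources

import pandas as pd

from alarmone.conformation import analyze_torsion_table

with resources.files("alarmone.data").joinpath("reported_conformers.tsv").open() as fh:
    table = pd.read_csv(fh, sep="\t", comment="#")

result = analyze_torsion_table(table)
print(result[["id", "P", "nu_max", "pucker_class", "glycosidic_class"]]
      .to_string(index=False, float_format="%.2f"))
print()
print("P in [0,36) is C3'-endo (north), P in [144,180) C2'-endo and [180,216)")
print("C3'-exo (south); anti means chi mod 360 in [90,270).  The unbound")
print("conformers are C3'-exo while receptor-bound copies span C3'-endo to")
print("C2'-endo — the ribose ring is conformationally plastic.")
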