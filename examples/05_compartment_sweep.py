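"""Receptor/G-protein distribution across compartments vs gene dosage.

The anchor competition produces the protective asymmetry: lowering total
D1R to 20 % leaves the high-affinity AC5 compartment nearly full while the
NMDAR compartment empties, and conversely for Golf at 40 %.
"""
from msnsig.experiments import compartment_sweep

for ligand in ("D1R", "Golf"):
    rows = compartment_sweep(ligand, fractions=(0.2, 0.4, 0.7, 1.0))
    print(f"{ligand} dosage sweep (µM bound):")
    for r in rows:
        print(f"  {r['fraction']:4.0%}  AC5 {r['AC5_compartment']:6.3f}   "
              f"NMDAR {r['NMDAR_compartment']:6.3f}")
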