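"""Enumerate a two-level full-factorial media screen and lay it out on
96-well plates.

Eight growth factors at two levels each give 2^8 = 256 candidate media
formulations. Each plate carries 12 SCM and 12 CDBM negative-control
wells, 4 positive-control wells, and 17 treatments x 4 replicate wells;
well positions are shuffled by a seeded RNG.
"""

from morphoscreen import Factor, LayoutConfig, assign_plate_layout, enumerate_full_factorial

factors = [
    Factor("FGF", 0.0, 20.0),
    Factor("TGFb1", 0.0, 2.0),
    Factor("EGF", 0.0, 20.0),
    Factor("IGF", 0.0, 20.0),
    Factor("PDGF", 0.0, 10.0),
    Factor("LIF", 0.0, 10.0),
    Factor("SCF", 0.0, 20.0),
    Factor("ActivinA", 0.0, 10.0),
]

design = enumerate_full_factorial(factors)
print(f"{design.n_formulations} formulations from {len(factors)} factors")
print(design.concentrations().head())

layouts = assign_plate_layout(design, LayoutConfig(), seed=0)
print(f"\n{len(layouts)} plates; plate 1 role counts:")
print(layouts[0].table["role"].value_counts().to_string())
# 256 formulations need 16 plates at 17 treatments/plate; every plate
# carries its own controls so normalization and testing stay per-plate.
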