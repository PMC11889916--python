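"""Simulate a small screen with known planted effects.

The generator draws per-well cell counts from a negative binomial (mean
= baseline x proliferation multiplier m) and per-cell feature vectors
with correlated feature blocks plus a phenotype shift of magnitude delta
along a fixed per-condition direction. The returned ground truth makes
every downstream stage checkable.
"""

from morphoscreen import (
    Factor,
    SyntheticConfig,
    TreatmentEffect,
    assign_plate_layout,
    enumerate_full_factorial,
    simulate_screen,
)

design = enumerate_full_factorial([Factor(f"GF{i}", 0.0, 10.0) for i in range(4)])
layouts = assign_plate_layout(design, seed=0)

effects = {fid: TreatmentEffect() for fid in design.formulation_ids}
effects["T05"] = TreatmentEffect(m=2.0, delta=6.0)  # a strong planted hit

config = SyntheticConfig(seed=0, n_features=60, n_latent=6, effects=effects)
cells, truth = simulate_screen(config, layouts)

counts = cells.groupby(["Metadata_Plate", "Metadata_Well"]).size()
print(f"{len(cells)} cells over {len(counts)} wells "
      f"({counts.mean():.0f} cells/well on average)")
print(f"intended hits (m >= {config.hit_m_threshold}, "
      f"delta >= {config.hit_delta_threshold}): {truth.intended_hits}")
# T05's wells should hold about twice the baseline cell count and sit
# delta = 6 normalized units away from controls in feature space.
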