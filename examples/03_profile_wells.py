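"""From per-cell features to analysis-ready well profiles.

The fixed processing order is: aggregate cells to per-well medians,
MAD-normalize each feature to the plate's negative-control wells,
drop features correlated above |r| = 0.9, and fit a correlation-mode
PCA keeping the components that explain 90% of the variance.
"""

from morphoscreen import (
    Factor,
    SyntheticConfig,
    TreatmentEffect,
    aggregate_wells,
    assign_plate_layout,
    enumerate_full_factorial,
    fit_pca,
    mad_normalize,
    select_features,
    simulate_screen,
)

design = enumerate_full_factorial([Factor(f"GF{i}", 0.0, 10.0) for i in range(4)])
layouts = assign_plate_layout(design, seed=0)
effects = {fid: TreatmentEffect() for fid in design.formulation_ids}
config = SyntheticConfig(seed=1, n_features=80, n_latent=8, effects=effects)
cells, _ = simulate_screen(config, layouts)

profiles = aggregate_wells(cells, layouts)
print(f"{len(profiles)} well profiles, mean cell count "
      f"{profiles['CellCount'].mean():.0f}")

normalized, params = mad_normalize(profiles)  # pooled SCM + CDBM reference
print(f"normalized to {params.reference}; "
      f"{len(params.dropped_zero_mad)} zero-MAD features dropped")

selection = select_features(normalized, threshold=0.9)
print(f"feature selection kept {len(selection.kept)} of "
      f"{len(selection.kept) + len(selection.dropped)} features")

model, scores = fit_pca(normalized, selection.kept, variance_target=0.9)
print(f"PCA retains {model.n_retained} components "
      f"({model.explained_variance_ratio[:model.n_retained].sum():.1%} of variance)")
# Downstream statistics run on the retained PC scores; a control well
# sits near the origin because normalization centers on the controls.
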