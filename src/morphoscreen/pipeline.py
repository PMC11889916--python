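"""End-to-end pipeline: design -> simulate -> profile -> stats -> hits.

Orchestrates the stages in fixed order, writes every intermediate
artifact as CSV with stable column order, and records a JSON manifest
(seeds, parameters, per-stage row counts, file checksums) so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import (
    Factor,
    LayoutConfig,
    PlateLayout,
    assign_plate_layout,
    enumerate_full_factorial,
    is_valid_well,
    write_design_csv,
    write_platemap_csv,
)
from .hit_calling import (
    HitCriteria,
    cluster_potential_hits,
    identify_potential_hits,
    select_final_hits,
    select_representative_wells,
)
from .profiling import aggregate_wells, fit_pca, mad_normalize, select_features
from .stats import count_comparisons_frame, dunnett_many_to_one, mp_values_per_plate
from .synthetic import SyntheticConfig, TreatmentEffect, simulate_screen, write_cell_table

__all__ = [
    "RunConfig",
    "ScreenAnalysis",
    "analyze_screen",
    "run_pipeline",
    "validate_inputs",
    "ValidationReport",
    "demo_config",
]

log = logging.getLogger("morphoscreen")


@dataclass
class RunConfig:
    """Everything a full screen run needs; all seeds explicit."""

    factors: list[Factor]
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    criteria: HitCriteria = field(default_factory=HitCriteria)
    reference: tuple[str, ...] = ("neg_ctl_a", "neg_ctl_b")
    correlation_threshold: float = 0.9
    variance_target: float = 0.9
    epsilon: float = 1e-12
    n_permutations: int = 2000
    ridge_scale: float = 1e-6
    layout_seed: int = 0
    permutation_seed: int = 0
    cluster_k: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        factors = [Factor(**f) for f in raw.pop("factors")]
        layout = LayoutConfig(**raw.pop("layout", {}))
        syn = raw.pop("synthetic", {})
        effects = {
            name: TreatmentEffect(**e) for name, e in syn.pop("effects", {}).items()
        }
        synthetic = SyntheticConfig(effects=effects, **syn)
        crit = raw.pop("criteria", {})
        for key in ("require_higher_than", "require_distinct_from"):
            if key in crit:
                crit[key] = tuple(crit[key])
        criteria = HitCriteria(**crit)
        if "reference" in raw:
            raw["reference"] = tuple(raw["reference"])
        return cls(factors=factors, layout=layout, synthetic=synthetic,
                   criteria=criteria, **raw)


@dataclass
class ScreenAnalysis:
    """In-memory results of the analysis stages of one screen."""

    profiles: pd.DataFrame
    normalized: pd.DataFrame
    kept_features: list[str]
    model: object  # profiling.PCAModel
    scores: pd.DataFrame  # metadata + retained PCs
    counts: pd.DataFrame
    mp_values: pd.DataFrame
    treatments: pd.DataFrame
    clusters: pd.DataFrame
    linkage: np.ndarray
    final_hits: list[str]
    final_reasons: pd.DataFrame
    representative_wells: dict


def analyze_screen(
    cells: pd.DataFrame,
    layouts: list[PlateLayout],
    reference: tuple[str, ...] = ("neg_ctl_a", "neg_ctl_b"),
    correlation_threshold: float = 0.9,
    variance_target: float = 0.9,
    epsilon: float = 1e-12,
    criteria: HitCriteria = HitCriteria(),
    n_permutations: int = 2000,
    ridge_scale: float = 1e-6,
    seed: int = 0,
    cluster_k: int | None = None,
) -> ScreenAnalysis:
    """Run the analysis stages (aggregate -> normalize -> select -> PCA ->
    stats -> hit calling) on an existing per-cell table, in memory."""
    profiles = aggregate_wells(cells, layouts)
    normalized, _ = mad_normalize(profiles, reference=reference, epsilon=epsilon)
    selection = select_features(normalized, threshold=correlation_threshold)
    model, scores = fit_pca(normalized, selection.kept, variance_target=variance_target)
    pcs = [f"PC{i + 1}" for i in range(model.n_retained)]
    meta_cols = [c for c in scores.columns if not c.startswith("PC")]
    scores = scores[meta_cols + pcs]
    comparisons = dunnett_many_to_one(
        profiles, controls=criteria.require_higher_than, alpha=criteria.alpha,
        seed=seed,
    )
    counts_df = count_comparisons_frame(comparisons)
    mp_df = mp_values_per_plate(
        scores, controls=criteria.require_distinct_from,
        weights=model.retained_ratios, n_permutations=n_permutations,
        seed=seed, ridge_scale=ridge_scale,
    )
    treatments = identify_potential_hits(profiles, counts_df, mp_df, criteria)
    potential = sorted(treatments.loc[treatments["potential_hit"], "treatment"])
    if potential:
        clusters, z = cluster_potential_hits(
            normalized, potential, variance_target=criteria.variance_target,
            k=cluster_k,
        )
        report = select_final_hits(clusters, treatments, z, criteria)
        rep = (
            select_representative_wells(profiles, report.final_hits)
            if report.final_hits
            else {}
        )
        final_hits, reasons = report.final_hits, report.final_reasons
    else:
        clusters = pd.DataFrame(
            columns=["Metadata_Plate", "Metadata_Well", "Metadata_Condition", "cluster"]
        )
        z = np.empty((0, 4))
        final_hits, rep = [], {}
        reasons = pd.DataFrame(columns=["treatment", "cluster", "eligible", "reason"])
    return ScreenAnalysis(
        profiles=profiles,
        normalized=normalized,
        kept_features=selection.kept,
        model=model,
        scores=scores,
        counts=counts_df,
        mp_values=mp_df,
        treatments=treatments,
        clusters=clusters,
        linkage=z,
        final_hits=final_hits,
        final_reasons=reasons,
        representative_wells=rep,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, index=False, lineterminator="\n", **kw)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage, write artifacts + manifest to ``out_dir``.

    Returns the manifest dict. Identical config reproduces identical
    outputs byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seeds": {
            "layout": config.layout_seed,
            "simulation": config.synthetic.seed,
            "permutation": config.permutation_seed,
        },
        "parameters": {
            "correlation_threshold": config.correlation_threshold,
            "variance_target": config.variance_target,
            "epsilon": config.epsilon,
            "n_permutations": config.n_permutations,
            "ridge_scale": config.ridge_scale,
            "reference": list(config.reference),
            "criteria": asdict(config.criteria),
        },
        "stages": {},
        "files": {},
    }

    def stage(name: str, n_rows: int) -> None:
        log.info("[%s] %d rows", name, n_rows)
        manifest["stages"][name] = {"rows": int(n_rows)}

    try:
        design = enumerate_full_factorial(config.factors)
        write_design_csv(design, out / "design.csv")
        stage("design", design.n_formulations)

        layouts = assign_plate_layout(design, config.layout, seed=config.layout_seed)
        write_platemap_csv(layouts, out / "platemap.csv")
        stage("layout", sum(len(l.table) for l in layouts))

        cells, truth = simulate_screen(config.synthetic, layouts)
        write_cell_table(cells, out / "cells.csv", format="csv")
        stage("simulate", len(cells))

        analysis = analyze_screen(
            cells, layouts,
            reference=config.reference,
            correlation_threshold=config.correlation_threshold,
            variance_target=config.variance_target,
            epsilon=config.epsilon,
            criteria=config.criteria,
            n_permutations=config.n_permutations,
            ridge_scale=config.ridge_scale,
            seed=config.permutation_seed,
            cluster_k=config.cluster_k,
        )
        _write_csv(analysis.profiles, out / "profiles.csv")
        stage("aggregate", len(analysis.profiles))
        stage("normalize", len(analysis.normalized))
        stage("select_features", len(analysis.kept_features))
        _write_csv(analysis.scores, out / "scores.csv")
        stage("pca", analysis.model.n_retained)
        _write_csv(analysis.counts, out / "counts.csv")
        _write_csv(analysis.mp_values, out / "mp_values.csv")
        stage("stats", len(analysis.counts) + len(analysis.mp_values))
        _write_csv(analysis.clusters, out / "clusters.csv")
        linkage_df = pd.DataFrame(
            analysis.linkage, columns=["left", "right", "height", "size"]
        )
        _write_csv(linkage_df, out / "linkage.csv")
        treatments = analysis.treatments
        final_hits = analysis.final_hits
        rep = analysis.representative_wells
        reasons = (
            analysis.final_reasons.set_index("treatment")
            if len(analysis.final_reasons)
            else pd.DataFrame(columns=["cluster", "eligible", "reason"])
        )
        hits_rows = treatments.copy()
        hits_rows["cluster"] = [
            int(reasons.loc[t, "cluster"]) if t in reasons.index else -1
            for t in hits_rows["treatment"]
        ]
        hits_rows["final_hit"] = hits_rows["treatment"].isin(final_hits)
        hits_rows["reason"] = [
            reasons.loc[t, "reason"] if t in reasons.index else hits_rows.loc[i, "failed_criteria"]
            for i, t in hits_rows["treatment"].items()
        ]
        hits_rows["representative_well"] = [
            "/".join(rep[t]) if t in rep else "" for t in hits_rows["treatment"]
        ]
        _write_csv(hits_rows, out / "hits.csv")
        stage("hit_calling", len(hits_rows))
        manifest["ground_truth_hits"] = list(truth.intended_hits)
        manifest["final_hits"] = list(final_hits)
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    for f in sorted(out.glob("*.csv")):
        manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


@dataclass
class ValidationReport:
    findings: list[dict] = field(default_factory=list)

    def add(self, severity: str, message: str) -> None:
        self.findings.append({"severity": severity, "message": message})

    @property
    def fatal(self) -> bool:
        return any(f["severity"] == "fatal" for f in self.findings)

    @property
    def empty(self) -> bool:
        return not self.findings


def validate_inputs(cells: pd.DataFrame, layouts: list[PlateLayout]) -> ValidationReport:
    """Check a per-cell table against its plate map before any analysis."""
    rep = ValidationReport()
    feats = [c for c in cells.columns if not c.startswith("Metadata_")]
    for col in ("Metadata_Plate", "Metadata_Well", "Metadata_Field", "Metadata_CellID"):
        if col not in cells.columns:
            rep.add("fatal", f"missing required column {col}")
    if rep.fatal:
        return rep
    bad_wells = sorted({w for w in cells["Metadata_Well"].unique() if not is_valid_well(str(w))})
    for w in bad_wells:
        rep.add("fatal", f"well outside A1-H12: {w!r}")
    assigned = {
        (lay.plate_id, r["well"])
        for lay in layouts
        for _, r in lay.table.iterrows()
        if r["role"] != "empty"
    }
    unknown = sorted(
        set(zip(cells["Metadata_Plate"], cells["Metadata_Well"])) - assigned
    )
    for plate, well in unknown[:20]:
        if is_valid_well(str(well)):
            rep.add("fatal", f"cells in unassigned well {plate}/{well}")
    vals = cells[feats].to_numpy()
    if not np.isfinite(vals).all():
        rows, cols = np.nonzero(~np.isfinite(vals))
        for r, c in list(zip(rows, cols))[:20]:
            rep.add("fatal", f"non-finite value in feature {feats[c]} at row {r}")
    dup = cells.duplicated(
        subset=["Metadata_Plate", "Metadata_Well", "Metadata_Field", "Metadata_CellID"]
    )
    if dup.any():
        rep.add("fatal", f"{int(dup.sum())} duplicate (plate, well, field, cell) ids")
    empty_wells = [
        (lay.plate_id, r["well"])
        for lay in layouts
        for _, r in lay.table.iterrows()
        if r["role"] != "empty"
    ]
    with_cells = set(zip(cells["Metadata_Plate"], cells["Metadata_Well"]))
    n_empty = sum(1 for k in empty_wells if k not in with_cells)
    if n_empty:
        rep.add("warning", f"{n_empty} assigned wells contain no cells")
    return rep


def demo_config(seed: int = 0) -> RunConfig:
    """Small bundled demo: 5 factors (32 formulations, 2 plates) with a
    few planted proliferative + phenotypic hits."""
    factors = [
        Factor("FGF", 0.0, 20.0),
        Factor("TGFb1", 0.0, 2.0),
        Factor("EGF", 0.0, 20.0),
        Factor("PDGF", 0.0, 10.0),
        Factor("LIF", 0.0, 10.0),
    ]
    effects = {f"T{i:02d}": TreatmentEffect() for i in range(1, 33)}
    for fid, m, d in [("T07", 2.0, 6.0), ("T18", 1.9, 6.0), ("T29", 2.2, 7.0)]:
        effects[fid] = TreatmentEffect(m=m, delta=d)
    return RunConfig(
        factors=factors,
        synthetic=SyntheticConfig(seed=seed, n_features=60, n_latent=6,
                                  baseline_cells_per_well=60.0, effects=effects),
        layout_seed=seed,
        permutation_seed=seed,
    )
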