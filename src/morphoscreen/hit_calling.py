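"""Two-stage hit identification for a media screen.

Stage 1 ("potential hits"): a treatment passes when its replicate cell
counts have CV below a threshold, its proliferation is significantly
higher than every required negative control (Dunnett-adjusted), and its
morphological profile is significantly distinct from every required
control (mp-value below alpha).

Stage 2 ("final hits"): PCA is refit on the potential-hit replicate
wells, Ward's hierarchical clustering groups them in retained-PC space,
and per cluster the treatment with all replicates in that cluster
(replicate coherence) and the highest mean count, with CV still under the
threshold, becomes the final hit. A representative well per hit is the
replicate closest to the replicate-mean profile in standardized
cell-shape feature space.
"""

from __future__ import annotations

import fnmatch
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .profiling import fit_pca, feature_columns
from .stats import CountComparison, replicate_cv

__all__ = [
    "HitCriteria",
    "HitReport",
    "identify_potential_hits",
    "select_similarity_hits",
    "cluster_potential_hits",
    "select_final_hits",
    "select_representative_wells",
]


@dataclass(frozen=True)
class HitCriteria:
    cv_threshold: float = 0.2
    alpha: float = 0.05
    variance_target: float = 0.9
    require_higher_than: tuple[str, ...] = ("neg_ctl_a", "neg_ctl_b")
    require_distinct_from: tuple[str, ...] = ("neg_ctl_a", "neg_ctl_b")

    def __post_init__(self) -> None:
        if not 0 < self.cv_threshold:
            raise ValueError("cv_threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.variance_target <= 1:
            raise ValueError("variance_target must be in (0, 1]")


def identify_potential_hits(
    profiles: pd.DataFrame,
    count_comparisons: list[CountComparison] | pd.DataFrame,
    mp_values: pd.DataFrame,
    criteria: HitCriteria = HitCriteria(),
) -> pd.DataFrame:
    """Flag treatments passing all stage-1 criteria.

    Returns one row per treatment with its CV, per-criterion outcomes,
    the ``potential_hit`` flag, and the names of failed criteria.
    """
    if isinstance(count_comparisons, list):
        from .stats import count_comparisons_frame

        count_comparisons = count_comparisons_frame(count_comparisons)
    treatments = (
        profiles[profiles["Metadata_Role"] == "treatment"]
        .groupby("Metadata_Condition", sort=True)
    )
    rows = []
    for t, grp in treatments:
        counts = grp["CellCount"].to_numpy(dtype=float)
        cv = replicate_cv(counts) if counts.mean() > 0 and counts.size >= 2 else np.inf
        failed: list[str] = []
        if not cv < criteria.cv_threshold:
            failed.append("CV")
        for ctl in criteria.require_higher_than:
            sub = count_comparisons[
                (count_comparisons["treatment"] == t)
                & (count_comparisons["control"] == ctl)
            ]
            if sub.empty:
                raise KeyError(f"no count comparison for {t!r} vs {ctl!r}")
            r = sub.iloc[0]
            if not (bool(r["significant"]) and r["direction"] == "higher"):
                failed.append(f"count_vs_{ctl}")
        for ctl in criteria.require_distinct_from:
            sub = mp_values[
                (mp_values["treatment"] == t) & (mp_values["control"] == ctl)
            ]
            if sub.empty:
                raise KeyError(f"no mp-value for {t!r} vs {ctl!r}")
            if not float(sub.iloc[0]["mp_value"]) < criteria.alpha:
                failed.append(f"mp_vs_{ctl}")
        rows.append(
            {
                "treatment": t,
                "plate": grp["Metadata_Plate"].iloc[0],
                "mean_count": float(counts.mean()),
                "cv": float(cv),
                "potential_hit": not failed,
                "failed_criteria": ";".join(failed),
            }
        )
    return pd.DataFrame(rows)


def select_similarity_hits(
    count_comparisons: pd.DataFrame,
    mp_values: pd.DataFrame,
    control: str = "neg_ctl_a",
    alpha: float = 0.05,
) -> list[str]:
    """Treatments *indistinguishable* from a named control.

    The inverse selection mode: a treatment qualifies when both its count
    comparison and its mp-value against ``control`` are non-significant —
    media that reproduce the control's growth and morphology (e.g. a
    serum-free formulation behaving like serum-containing medium)."""
    counts_ns = set(
        count_comparisons.loc[
            (count_comparisons["control"] == control)
            & ~count_comparisons["significant"].astype(bool),
            "treatment",
        ]
    )
    mp_ns = set(
        mp_values.loc[
            (mp_values["control"] == control) & (mp_values["mp_value"] >= alpha),
            "treatment",
        ]
    )
    return sorted(counts_ns & mp_ns)


def _choose_k(heights: np.ndarray, k_max: int) -> int:
    """Largest relative gap in merge heights over k in [2, k_max]."""
    n_merges = heights.size
    if n_merges == 0 or heights[-1] <= 0:
        return 1
    best_k, best_gap = 2, -np.inf
    for k in range(2, k_max + 1):
        if k > n_merges:
            break
        lo = heights[n_merges - k]  # last merge surviving a k-cluster cut
        hi = heights[n_merges - k + 1] if k > 1 else np.inf
        gap = (hi - lo) / max(lo, 1e-12)
        if gap > best_gap:
            best_k, best_gap = k, gap
    return best_k


def cluster_potential_hits(
    profiles: pd.DataFrame,
    potential_hits: list[str],
    variance_target: float = 0.9,
    k: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Ward clustering of potential-hit replicate wells in refit PC space.

    PCA is refit on the potential-hit wells only; Ward linkage runs on
    Euclidean distance over the retained components. If ``k`` is not
    given it is chosen by the largest relative gap in merge heights over
    k in [2, min(15, #potential hits)]. Returns (assignments frame with a
    ``cluster`` column, linkage matrix). Cluster labels are canonicalized
    by first appearance in (plate, well) sorted order.
    """
    wells = profiles[profiles["Metadata_Condition"].isin(potential_hits)].copy()
    wells = wells.sort_values(["Metadata_Plate", "Metadata_Well"]).reset_index(drop=True)
    if len(potential_hits) < 2:
        warnings.warn("fewer than 2 potential hits: trivial single cluster")
        wells["cluster"] = 1
        return wells[
            ["Metadata_Plate", "Metadata_Well", "Metadata_Condition", "cluster"]
        ], np.empty((0, 4))
    feats = feature_columns(wells)
    if np.allclose(wells[feats].std(ddof=0), 0.0):
        # all wells identical: degenerate heights, single cluster
        wells["cluster"] = 1
        return wells[
            ["Metadata_Plate", "Metadata_Well", "Metadata_Condition", "cluster"]
        ], np.empty((0, 4))
    model, scores = fit_pca(wells, variance_target=variance_target)
    pcs = [f"PC{i + 1}" for i in range(model.n_retained)]
    x = scores[pcs].to_numpy()
    z = linkage(x, method="ward")
    heights = z[:, 2]
    if k is None:
        if np.allclose(heights, 0):
            k = 1
        else:
            k = _choose_k(heights, min(15, len(potential_hits)))
    labels = fcluster(z, t=k, criterion="maxclust")
    # canonical labels: order of first appearance in sorted well order
    seen: dict[int, int] = {}
    canon = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen) + 1
        canon[i] = seen[lab]
    out = wells[["Metadata_Plate", "Metadata_Well", "Metadata_Condition"]].copy()
    out["cluster"] = canon
    return out, z


@dataclass
class HitReport:
    treatments: pd.DataFrame  # stage-1 table incl. potential_hit
    clusters: pd.DataFrame  # well-level cluster assignments
    linkage: np.ndarray
    final_hits: list[str]
    final_reasons: pd.DataFrame  # treatment, cluster, eligible, reason
    representative_wells: dict[str, tuple[str, str]] = field(default_factory=dict)

    def validate(self) -> None:
        forced = set(
            self.final_reasons.loc[
                self.final_reasons["reason"] == "forced", "treatment"
            ]
        ) if len(self.final_reasons) else set()
        selected = set(self.final_hits) - forced
        potential = set(self.treatments.loc[self.treatments["potential_hit"], "treatment"])
        if not selected <= potential:
            raise ValueError("final hits must be a subset of potential hits")
        for t in selected:
            labs = self.clusters.loc[self.clusters["Metadata_Condition"] == t, "cluster"]
            if labs.nunique() != 1:
                raise ValueError(f"final hit {t!r} replicates span clusters")


def select_final_hits(
    clusters: pd.DataFrame,
    treatments: pd.DataFrame,
    linkage_matrix: np.ndarray,
    criteria: HitCriteria = HitCriteria(),
    force_report: tuple[str, ...] = (),
) -> HitReport:
    """Per cluster, pick the coherent treatment (all replicates in that
    cluster, CV under threshold) with the highest mean count.

    ``force_report`` treatments are appended to the final list regardless
    of selection (e.g. an all-factors-high condition kept for
    interpretation); their statistics are reported unchanged."""
    info = treatments.set_index("treatment")
    coherence = clusters.groupby("Metadata_Condition")["cluster"].agg(["nunique", "first"])
    final: list[str] = []
    reasons = []
    for t in coherence.index:
        coherent = coherence.loc[t, "nunique"] == 1
        cv_ok = info.loc[t, "cv"] < criteria.cv_threshold
        if not coherent:
            reasons.append((t, -1, False, "replicates not coherent"))
        elif not cv_ok:
            reasons.append((t, int(coherence.loc[t, "first"]), False, "CV"))
        else:
            reasons.append((t, int(coherence.loc[t, "first"]), True, ""))
    elig = pd.DataFrame(reasons, columns=["treatment", "cluster", "eligible", "reason"])
    for c, grp in elig[elig["eligible"]].groupby("cluster"):
        cands = grp["treatment"]
        means = info.loc[cands, "mean_count"]
        winner = means.sort_index().idxmax()  # ties: first in name order
        final.append(winner)
        elig.loc[elig["treatment"].isin(cands) & (elig["treatment"] != winner), "reason"] = (
            "lower count than cluster winner"
        )
    final = sorted(set(final))
    forced = [t for t in force_report if t in info.index and t not in final]
    report = HitReport(
        treatments=treatments,
        clusters=clusters,
        linkage=linkage_matrix,
        final_hits=final,
        final_reasons=elig,
    )
    report.validate()
    for t in forced:  # appended after validation: bypass selection, not stats
        report.final_hits.append(t)
        report.final_reasons.loc[len(report.final_reasons)] = (t, -1, False, "forced")
    return report


def select_representative_wells(
    profiles: pd.DataFrame,
    hits: list[str],
    shape_pattern: str = "*_AreaShape_*",
) -> dict[str, tuple[str, str]]:
    """Per hit, the replicate well whose cell-shape profile is closest to
    the mean of the hit's replicate well-median profiles.

    Shape features (default ``*_AreaShape_*``) are standardized over the
    hit's candidate wells; the well minimizing Euclidean distance to the
    candidate mean wins; ties break on (plate, well) name order.
    """
    feats = feature_columns(profiles)
    shape = [f for f in feats if fnmatch.fnmatch(f, shape_pattern)]
    if not shape:
        raise ValueError(f"no features match shape pattern {shape_pattern!r}")
    out: dict[str, tuple[str, str]] = {}
    for t in hits:
        wells = profiles[
            (profiles["Metadata_Condition"] == t) & (profiles["CellCount"] > 0)
        ].sort_values(["Metadata_Plate", "Metadata_Well"])
        if wells.empty:
            raise ValueError(f"hit {t!r} has no wells with a profile")
        x = wells[shape].to_numpy(dtype=float)
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        zs = (x - mu) / sd
        dist = np.linalg.norm(zs - zs.mean(axis=0), axis=1)
        i = int(np.argmin(dist))  # argmin takes the first minimum: name order
        out[t] = (
            str(wells.iloc[i]["Metadata_Plate"]),
            str(wells.iloc[i]["Metadata_Well"]),
        )
    return out
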