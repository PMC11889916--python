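"""Per-cell tables -> analysis-ready well profiles.

Fixed pipeline order: aggregate single cells to per-well median profiles,
normalize each feature to on-plate negative controls by median absolute
deviation (MAD), drop features correlated above a threshold, then fit a
correlation-mode PCA and keep the components explaining a target share of
the variance (default 90%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .design import PlateLayout

__all__ = [
    "aggregate_wells",
    "mad_normalize",
    "select_features",
    "fit_pca",
    "NormalizationParams",
    "FeatureSelectionResult",
    "PCAModel",
    "feature_columns",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = (
    "Metadata_Plate",
    "Metadata_Well",
    "Metadata_Condition",
    "Metadata_Role",
    "Metadata_Replicate",
    "CellCount",
)


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Columns that hold features (everything that is not metadata)."""
    return [
        c
        for c in df.columns
        if c not in METADATA_COLUMNS and not c.startswith("Metadata_") and c != "CellCount"
    ]


def aggregate_wells(cells: pd.DataFrame, layouts: list[PlateLayout]) -> pd.DataFrame:
    """Aggregate a single-cell table into per-well median profiles.

    One row per assigned (plate, well) of the layouts: each feature is the
    median over that well's cells (pandas/numpy convention: even counts
    average the two central order statistics), ``CellCount`` the number of
    cells. Assigned wells with no cells are emitted with count 0 and NaN
    features. Cells in wells absent from the layouts are an error.
    """
    laymap = {}
    for lay in layouts:
        for _, r in lay.table.iterrows():
            if r["role"] != "empty":
                laymap[(lay.plate_id, r["well"])] = (
                    r["condition"],
                    r["role"],
                    int(r["replicate"]),
                )
    feats = [c for c in cells.columns if not c.startswith("Metadata_")]
    keys = list(zip(cells["Metadata_Plate"], cells["Metadata_Well"]))
    unknown = sorted({k for k in keys if k not in laymap})
    if unknown:
        raise ValueError(
            f"cells map to wells absent from the plate layout: {unknown[:5]}"
            + ("..." if len(unknown) > 5 else "")
        )
    grouped = cells.groupby(["Metadata_Plate", "Metadata_Well"], sort=True)
    medians = grouped[feats].median()
    counts = grouped.size()
    rows = []
    for (plate, well), (cond, role, rep) in sorted(laymap.items()):
        key = (plate, well)
        if key in medians.index:
            vals = medians.loc[key]
            n = int(counts.loc[key])
        else:
            vals = pd.Series(np.nan, index=feats)
            n = 0
        rows.append(
            {
                "Metadata_Plate": plate,
                "Metadata_Well": well,
                "Metadata_Condition": cond,
                "Metadata_Role": role,
                "Metadata_Replicate": rep,
                "CellCount": n,
                **vals.to_dict(),
            }
        )
    return pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + feats)


@dataclass
class NormalizationParams:
    """Per-plate centers/scales from reference wells, and dropped features."""

    reference: tuple[str, ...]
    epsilon: float
    centers: dict[str, pd.Series] = field(default_factory=dict)  # plate -> per-feature median
    scales: dict[str, pd.Series] = field(default_factory=dict)  # plate -> per-feature MAD
    dropped_zero_mad: list[str] = field(default_factory=list)


def mad_normalize(
    profiles: pd.DataFrame,
    reference: tuple[str, ...] = ("neg_ctl_a", "neg_ctl_b"),
    epsilon: float = 1e-12,
) -> tuple[pd.DataFrame, NormalizationParams]:
    """Normalize well profiles to on-plate reference wells by MAD.

    Per plate and feature: center = median over reference wells, scale =
    raw median absolute deviation about that center (no Gaussian
    consistency constant); x' = (x - center) / (scale + epsilon).
    Features whose reference MAD is 0 on any plate are dropped and
    recorded. Reference wells are selected by ``Metadata_Condition``;
    wells with zero cells never contribute to the statistics.
    """
    feats = feature_columns(profiles)
    params = NormalizationParams(reference=tuple(reference), epsilon=epsilon)
    zero_mad: set[str] = set()
    pieces = []
    for plate, grp in profiles.groupby("Metadata_Plate", sort=True):
        ref = grp[grp["Metadata_Condition"].isin(reference) & (grp["CellCount"] > 0)]
        if len(ref) < 2:
            raise ValueError(
                f"plate {plate}: fewer than 2 reference wells with cells"
            )
        center = ref[feats].median()
        scale = (ref[feats] - center).abs().median()
        params.centers[plate] = center
        params.scales[plate] = scale
        zero_mad.update(scale.index[scale == 0])
        norm = grp.copy()
        norm[feats] = (grp[feats] - center) / (scale + epsilon)
        pieces.append(norm)
    params.dropped_zero_mad = sorted(zero_mad)
    out = pd.concat(pieces).loc[profiles.index]
    out = out.drop(columns=params.dropped_zero_mad)
    return out, params


@dataclass
class FeatureSelectionResult:
    kept: list[str]
    dropped: list[dict]  # feature, partner, correlation, reason
    threshold: float

    @property
    def dropped_names(self) -> list[str]:
        return [d["feature"] for d in self.dropped]


def select_features(
    profiles: pd.DataFrame, threshold: float = 0.9
) -> FeatureSelectionResult:
    """Greedy correlation filter: drop features until no pair of kept
    features has |Pearson r| > ``threshold``.

    Zero-variance features are dropped first. Then, repeatedly, the pair
    with the largest |r| above the threshold is resolved by dropping its
    member with the larger mean |r| against all remaining features (exact
    ties keep the lexicographically smaller name). Deterministic.
    """
    feats = sorted(feature_columns(profiles))
    if len(feats) < 2:
        raise ValueError("need at least 2 features")
    data = profiles[feats]
    data = data.dropna(axis=0, how="any")
    if len(data) < 2:
        raise ValueError("need at least 2 complete wells")
    dropped: list[dict] = []
    const = [f for f in feats if data[f].std(ddof=0) == 0]
    for f in const:
        dropped.append({"feature": f, "partner": None, "correlation": np.nan, "reason": "zero variance"})
    keep = [f for f in feats if f not in const]
    corr = np.abs(np.corrcoef(data[keep].to_numpy(), rowvar=False))
    np.fill_diagonal(corr, 0.0)
    names = list(keep)
    while corr.size and corr.max() > threshold:
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        i, j = sorted((i, j))
        mean_i = corr[i].sum() / (corr.shape[0] - 1)
        mean_j = corr[j].sum() / (corr.shape[0] - 1)
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:  # exact tie: keep the lexicographically smaller name
            drop = j if names[i] < names[j] else i
        partner = j if drop == i else i
        dropped.append(
            {
                "feature": names[drop],
                "partner": names[partner],
                "correlation": float(corr[i, j]),
                "reason": "correlated",
            }
        )
        corr = np.delete(np.delete(corr, drop, axis=0), drop, axis=1)
        del names[drop]
    return FeatureSelectionResult(kept=names, dropped=dropped, threshold=threshold)


@dataclass
class PCAModel:
    """Correlation-mode PCA: features standardized to unit variance before
    the decomposition; components ordered by decreasing explained
    variance; ``n_retained`` is the smallest m whose cumulative
    explained-variance ratio reaches ``variance_target``."""

    feature_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray  # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    variance_target: float
    n_retained: int

    def transform(self, profiles: pd.DataFrame) -> pd.DataFrame:
        x = (profiles[self.feature_names].to_numpy() - self.means) / self.scales
        scores = x @ self.loadings.T
        meta = [c for c in METADATA_COLUMNS if c in profiles.columns]
        pc_frame = pd.DataFrame(
            scores,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
            index=profiles.index,
        )
        return pd.concat([profiles[meta], pc_frame], axis=1)

    @property
    def retained_ratios(self) -> np.ndarray:
        return self.explained_variance_ratio[: self.n_retained]


def fit_pca(
    profiles: pd.DataFrame,
    features: list[str] | None = None,
    variance_target: float = 0.9,
) -> tuple[PCAModel, pd.DataFrame]:
    """Fit correlation-mode PCA on well profiles and score every well.

    Returns the model and a scores frame (metadata + PC1..PCm for all
    components); slice to ``model.n_retained`` columns for downstream
    testing. Wells with missing profiles (zero cells) are excluded.
    """
    if features is None:
        features = feature_columns(profiles)
    complete = profiles.dropna(subset=features)
    if len(complete) < 2:
        raise ValueError("need at least 2 complete wells")
    x = complete[features].to_numpy(dtype=float)
    scales = x.std(axis=0, ddof=1)
    nonconst = scales > 0
    if nonconst.sum() < 2:
        raise ValueError("fewer than 2 non-constant features")
    features = [f for f, ok in zip(features, nonconst) if ok]
    x = x[:, nonconst]
    means = x.mean(axis=0)
    scales = scales[nonconst]
    xs = (x - means) / scales
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(xs)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    n_retained = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_retained = min(n_retained, len(ratios))
    model = PCAModel(
        feature_names=features,
        means=means,
        scales=scales,
        loadings=pca.components_,
        explained_variance_ratio=ratios,
        variance_target=variance_target,
        n_retained=n_retained,
    )
    meta = [c for c in METADATA_COLUMNS if c in complete.columns]
    pc_frame = pd.DataFrame(
        scores,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        index=complete.index,
    )
    return model, pd.concat([complete[meta], pc_frame], axis=1)
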