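"""Screen statistics: replicate CV, Mahalanobis distance between groups,
the mp-value permutation test, and Dunnett many-to-one count comparisons.

The mp-value (multidimensional perturbation value) asks whether two groups
of wells occupy different regions of principal-component space. Retained
PC scores are weighted by their explained-variance ratios (down-weighting
minor components), the Mahalanobis distance between the two group
centroids is computed under the covariance of the pooled scores, and its
significance is assessed by permuting group labels — exhaustively when the
number of distinct splits is small enough, otherwise by seeded sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps

__all__ = [
    "replicate_cv",
    "mahalanobis_between_groups",
    "mp_value",
    "mp_value_refit_pca",
    "mp_values_per_plate",
    "dunnett_many_to_one",
    "MpValueResult",
    "CountComparison",
]


def replicate_cv(counts) -> float:
    """Coefficient of variation of replicate counts: sample sd (n-1
    denominator) over mean. Requires >= 2 values and a positive mean."""
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least 2 replicate values")
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("mean count must be positive")
    return float(x.std(ddof=1) / mean)


def _pooled_cov(x: np.ndarray, ridge: float) -> np.ndarray:
    s = np.atleast_2d(np.cov(x, rowvar=False, ddof=1))
    return s + ridge * np.eye(s.shape[0])


def mahalanobis_between_groups(
    scores_a: np.ndarray, scores_b: np.ndarray, ridge: float = 0.0
) -> float:
    """Mahalanobis distance between two group centroids under the
    covariance of the pooled (combined) scores, with ``ridge`` added to
    the covariance diagonal.

    Symmetric in (a, b); with ridge = 0 and a nonsingular covariance it is
    invariant under any shared invertible affine map, and in one dimension
    it reduces to |mean_a - mean_b| / pooled sd. A singular covariance at
    ridge = 0 falls back to the Moore-Penrose pseudoinverse.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.ndim == 1:  # 1-D input: observations of a single component
        a = a.reshape(-1, 1)
    if b.ndim == 1:
        b = b.reshape(-1, 1)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    d = a.mean(axis=0) - b.mean(axis=0)
    s = _pooled_cov(np.vstack([a, b]), ridge)
    try:
        c, low = linalg.cho_factor(s)
        q = float(d @ linalg.cho_solve((c, low), d))
    except linalg.LinAlgError:
        q = float(d @ linalg.pinvh(s) @ d)
    return float(np.sqrt(max(q, 0.0)))


@dataclass(frozen=True)
class MpValueResult:
    treatment: str
    control: str
    n_treatment: int
    n_control: int
    n_components: int
    distance: float
    n_permutations: int
    mp_value: float
    exhaustive: bool
    seed: int | None


@lru_cache(maxsize=32)
def _comb_indices(n: int, n_a: int) -> np.ndarray:
    """All C(n, n_a) group-A index sets; the identity split comes first."""
    out = np.array(list(combinations(range(n), n_a)), dtype=np.intp)
    out.setflags(write=False)
    return out


def _split_distances(
    x: np.ndarray, idx_a: np.ndarray, ridge: float
) -> np.ndarray:
    """Squared centroid Mahalanobis distances for many group-A index sets.

    The pooled covariance is label-invariant, so it is factored once and
    only the mean difference varies per split. ``idx_a`` is (n_splits,
    n_a) row indices of group A."""
    n, p = x.shape
    n_a = idx_a.shape[1]
    n_b = n - n_a
    s = _pooled_cov(x, ridge)
    total = x.sum(axis=0)
    sums_a = x[idx_a].sum(axis=1)  # (n_splits, p)
    d = sums_a / n_a - (total - sums_a) / n_b
    try:
        c, low = linalg.cho_factor(s)
        sol = linalg.cho_solve((c, low), d.T)
    except linalg.LinAlgError:
        sol = linalg.pinvh(s) @ d.T
    return np.maximum(np.einsum("ij,ji->i", d, sol), 0.0)


def mp_value_from_scores(
    scores_t: np.ndarray,
    scores_c: np.ndarray,
    weights: np.ndarray | None = None,
    n_permutations: int = 1000,
    seed: int | None = 0,
    ridge_scale: float = 1e-6,
) -> tuple[float, float, int, bool]:
    """Core mp-value computation on raw score arrays.

    Returns (mp_value, observed distance, permutations used, exhaustive?).
    ``weights`` (explained-variance ratios) multiply each component's
    scores before any distance is computed. ``ridge_scale`` scales the
    mean covariance diagonal to regularize near-singular covariances
    (small groups, many components).
    """
    a = np.atleast_2d(np.asarray(scores_t, dtype=float))
    b = np.atleast_2d(np.asarray(scores_c, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("both groups need at least 2 wells")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        a = a * w
        b = b * w
    x = np.vstack([a, b])
    n, n_a = x.shape[0], a.shape[0]
    ridge = ridge_scale * float(np.mean(np.diag(np.atleast_2d(np.cov(x, rowvar=False, ddof=1)))))
    tol = 1e-9  # absolute tie tolerance on squared distances
    n_exhaustive = comb(n, n_a)
    if n_exhaustive <= n_permutations:
        idx_a = _comb_indices(n, n_a)
        d2 = _split_distances(x, idx_a, ridge)
        observed2 = d2[0]  # identity split enumerates first
        count = int(np.sum(d2 >= observed2 - tol))
        n_perm = n_exhaustive
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((n_permutations, n)), axis=1)[:, :n_a]
        observed2 = _split_distances(x, np.arange(n_a, dtype=np.intp)[None, :], ridge)[0]
        d2 = _split_distances(x, idx.astype(np.intp), ridge)
        count = int(np.sum(d2 >= observed2 - tol))
        n_perm = n_permutations
        exhaustive = False
    mp = (1 + count) / (n_perm + 1)
    return float(mp), float(np.sqrt(observed2)), n_perm, exhaustive


def mp_value(
    scores: pd.DataFrame,
    treatment: str,
    control: str,
    weights: np.ndarray | None = None,
    n_components: int | None = None,
    n_permutations: int = 1000,
    seed: int | None = 0,
    ridge_scale: float = 1e-6,
    label_col: str = "Metadata_Condition",
) -> MpValueResult:
    """mp-value of ``treatment`` vs ``control`` from a well-scores frame.

    ``scores`` holds metadata plus PC columns (PC1, PC2, ...);
    ``n_components`` restricts to the leading components (default: all PC
    columns present); ``weights`` are the matching explained-variance
    ratios. Deterministic given ``seed``.
    """
    pcs = [c for c in scores.columns if c.startswith("PC")]
    if n_components is not None:
        pcs = pcs[:n_components]
    for grp in (treatment, control):
        if not (scores[label_col] == grp).any():
            raise KeyError(f"group {grp!r} absent from scores")
    a = scores.loc[scores[label_col] == treatment, pcs].to_numpy()
    b = scores.loc[scores[label_col] == control, pcs].to_numpy()
    if weights is not None:
        weights = np.asarray(weights, dtype=float)[: len(pcs)]
    mp, dist, n_perm, exhaustive = mp_value_from_scores(
        a, b, weights, n_permutations, seed, ridge_scale
    )
    return MpValueResult(
        treatment=treatment,
        control=control,
        n_treatment=a.shape[0],
        n_control=b.shape[0],
        n_components=len(pcs),
        distance=dist,
        n_permutations=n_perm,
        mp_value=mp,
        exhaustive=exhaustive,
        seed=seed,
    )


def mp_values_per_plate(
    scores: pd.DataFrame,
    controls: tuple[str, ...] = ("neg_ctl_a", "neg_ctl_b"),
    weights: np.ndarray | None = None,
    n_components: int | None = None,
    n_permutations: int = 2000,
    seed: int | None = 0,
    ridge_scale: float = 1e-6,
    treatment_role: str = "treatment",
) -> pd.DataFrame:
    """mp-value of every treatment vs every control on its own plate."""
    rows = []
    for plate, grp in scores.groupby("Metadata_Plate", sort=True):
        treatments = sorted(
            grp.loc[grp["Metadata_Role"] == treatment_role, "Metadata_Condition"].unique()
        )
        for t in treatments:
            for ctl in controls:
                res = mp_value(
                    grp, t, ctl,
                    weights=weights,
                    n_components=n_components,
                    n_permutations=n_permutations,
                    seed=seed,
                    ridge_scale=ridge_scale,
                )
                rows.append(
                    {
                        "plate": plate,
                        "treatment": t,
                        "control": ctl,
                        "n_components": res.n_components,
                        "distance": res.distance,
                        "n_permutations": res.n_permutations,
                        "mp_value": res.mp_value,
                        "seed": seed if seed is not None else -1,
                    }
                )
    return pd.DataFrame(rows)


def mp_value_refit_pca(
    normalized_profiles: pd.DataFrame,
    treatment: str,
    control: str,
    variance_target: float = 0.9,
    n_permutations: int = 2000,
    seed: int | None = 0,
    ridge_scale: float = 1e-6,
) -> MpValueResult:
    """mp-value with a per-comparison PCA refit.

    Instead of scoring wells with the plate-level PCA model, PCA is refit
    on just the two groups' normalized profiles, the components reaching
    ``variance_target`` are retained, and the mp-value is computed on
    those variance-ratio-weighted scores."""
    from .profiling import fit_pca

    pair = normalized_profiles[
        normalized_profiles["Metadata_Condition"].isin((treatment, control))
    ]
    for grp in (treatment, control):
        if not (pair["Metadata_Condition"] == grp).any():
            raise KeyError(f"group {grp!r} absent from profiles")
    model, scores = fit_pca(pair, variance_target=variance_target)
    pcs = [f"PC{i + 1}" for i in range(model.n_retained)]
    a = scores.loc[scores["Metadata_Condition"] == treatment, pcs].to_numpy()
    b = scores.loc[scores["Metadata_Condition"] == control, pcs].to_numpy()
    mp, dist, n_perm, exhaustive = mp_value_from_scores(
        a, b, model.retained_ratios, n_permutations, seed, ridge_scale
    )
    return MpValueResult(
        treatment=treatment,
        control=control,
        n_treatment=a.shape[0],
        n_control=b.shape[0],
        n_components=model.n_retained,
        distance=dist,
        n_permutations=n_perm,
        mp_value=mp,
        exhaustive=exhaustive,
        seed=seed,
    )


@dataclass(frozen=True)
class CountComparison:
    plate: str
    treatment: str
    control: str
    mean_treatment: float
    mean_control: float
    p_adjusted: float
    direction: str  # "higher" | "lower"
    significant: bool


def dunnett_many_to_one(
    counts: pd.DataFrame,
    controls: tuple[str, ...] = ("neg_ctl_a", "neg_ctl_b"),
    alpha: float = 0.05,
    seed: int | None = 0,
    condition_col: str = "Metadata_Condition",
    plate_col: str = "Metadata_Plate",
    count_col: str = "CellCount",
    treatment_role: str | None = "treatment",
    role_col: str = "Metadata_Role",
) -> list[CountComparison]:
    """Two-sided Dunnett many-to-one comparisons of per-well counts.

    Per plate and per named control, all treatments are compared to that
    control as one family, controlling family-wise error. A comparison is
    ``significant`` with ``direction='higher'`` when the adjusted p-value
    is below ``alpha`` and the treatment mean exceeds the control mean.
    """
    results: list[CountComparison] = []
    for plate, grp in counts.groupby(plate_col, sort=True):
        if treatment_role is not None and role_col in grp.columns:
            treatments = sorted(
                grp.loc[grp[role_col] == treatment_role, condition_col].unique()
            )
        else:
            treatments = sorted(
                c for c in grp[condition_col].unique() if c not in controls
            )
        samples = [
            grp.loc[grp[condition_col] == t, count_col].to_numpy(dtype=float)
            for t in treatments
        ]
        for s, t in zip(samples, treatments):
            if s.size < 2:
                raise ValueError(f"condition {t!r} on plate {plate}: < 2 replicates")
        for ctl in controls:
            ctl_counts = grp.loc[grp[condition_col] == ctl, count_col].to_numpy(dtype=float)
            if ctl_counts.size == 0:
                raise KeyError(f"control {ctl!r} absent from plate {plate}")
            res = sps.dunnett(
                *samples, control=ctl_counts, alternative="two-sided",
                rng=np.random.default_rng(seed),
            )
            for t, s, p in zip(treatments, samples, res.pvalue):
                mt, mc = float(s.mean()), float(ctl_counts.mean())
                results.append(
                    CountComparison(
                        plate=str(plate),
                        treatment=t,
                        control=ctl,
                        mean_treatment=mt,
                        mean_control=mc,
                        p_adjusted=float(min(max(p, 0.0), 1.0)),
                        direction="higher" if mt > mc else "lower",
                        significant=bool(p < alpha),
                    )
                )
    return results


def count_comparisons_frame(results: list[CountComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plate": r.plate,
                "treatment": r.treatment,
                "control": r.control,
                "mean_t": r.mean_treatment,
                "mean_c": r.mean_control,
                "p_adj": r.p_adjusted,
                "direction": r.direction,
                "significant": r.significant,
            }
            for r in results
        ]
    )
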