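"""Synthetic screen generator with planted ground truth.

Emulates the statistical structure of a per-cell morphological feature
table from a plate-based screen: per-well cell counts follow a negative
binomial whose mean is a baseline times a treatment-specific proliferation
multiplier m_t, and each cell's feature vector is

    x = Lambda z + mu_base + delta_t * u_t + well effect + plate effect + noise

where z is a standard latent vector inducing correlated feature blocks,
u_t a fixed unit direction per condition, and delta_t the planted
phenotype shift. Known (m_t, delta_t, u_t) per condition make every
downstream pipeline stage testable without imaging data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import PlateLayout

__all__ = [
    "TreatmentEffect",
    "SyntheticConfig",
    "GroundTruth",
    "simulate_screen",
    "write_cell_table",
    "read_cell_table",
    "feature_names",
    "META_COLUMNS",
]

META_COLUMNS = ("Metadata_Plate", "Metadata_Well", "Metadata_Field", "Metadata_CellID")

_COMPARTMENTS = ("Cell", "Nuclei", "Cytoplasm")
_CATEGORIES = ("AreaShape", "Intensity", "Texture", "Granularity", "RadialDistribution")


def feature_names(n_features: int) -> list[str]:
    """CellProfiler-style Compartment_Category_Name feature names."""
    names = []
    i = 0
    while len(names) < n_features:
        comp = _COMPARTMENTS[i % len(_COMPARTMENTS)]
        cat = _CATEGORIES[(i // len(_COMPARTMENTS)) % len(_CATEGORIES)]
        names.append(f"{comp}_{cat}_F{i:03d}")
        i += 1
    return names


@dataclass(frozen=True)
class TreatmentEffect:
    """Planted effect of one condition: proliferation multiplier m (>=0)
    on the mean well cell count, and phenotype shift magnitude delta (>=0)
    along that condition's fixed unit direction."""

    m: float = 1.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.m < 0 or self.delta < 0:
            raise ValueError("effect magnitudes must be nonnegative")


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_features: int = 200
    n_latent: int = 10
    baseline_cells_per_well: float = 120.0  # ~48 h growth from 1563 cells/cm^2
    count_dispersion: float = 200.0  # NB size parameter; var = mu + mu^2/size
    fields_per_well: int = 36  # 6x6 montage
    cell_noise_sd: float = 1.0
    well_noise_sd: float = 0.3  # latent-space well-to-well variation
    well_feature_noise_sd: float = 0.1  # independent per-feature well noise
    plate_effect_sd: float = 0.25
    effects: dict[str, TreatmentEffect] = field(default_factory=dict)
    # thresholds above which a planted condition counts as an intended hit
    hit_m_threshold: float = 1.5
    hit_delta_threshold: float = 3.0

    def __post_init__(self) -> None:
        if self.n_latent > self.n_features:
            raise ValueError("n_latent must not exceed n_features")
        if self.count_dispersion <= 0:
            raise ValueError("count_dispersion must be positive")
        for name, eff in self.effects.items():
            if not isinstance(eff, TreatmentEffect):
                raise TypeError(f"effect for {name!r} is not a TreatmentEffect")

    def with_effects(self, effects: dict[str, TreatmentEffect]) -> "SyntheticConfig":
        return replace(self, effects={**self.effects, **effects})


#: baseline control behaviour: SCM is the reference (m=1, delta=0); the
#: basal medium grows cells poorly and looks different; the FGF-spiked
#: positive control boosts growth and shifts morphology.
DEFAULT_CONTROL_EFFECTS: dict[str, TreatmentEffect] = {
    "neg_ctl_a": TreatmentEffect(m=1.0, delta=0.0),
    "neg_ctl_b": TreatmentEffect(m=0.6, delta=2.0),
    "pos_ctl": TreatmentEffect(m=1.5, delta=2.5),
}


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for one simulated screen."""

    effects: dict[str, TreatmentEffect]
    directions: dict[str, np.ndarray]  # unit shift direction per condition
    intended_hits: tuple[str, ...]


def _condition_rng(seed: int, condition: str) -> np.random.Generator:
    # stable per-condition stream, independent of iteration order
    return np.random.default_rng([seed, zlib.crc32(condition.encode())])


def _unit_direction(seed: int, condition: str, n_features: int) -> np.ndarray:
    v = _condition_rng(seed, condition).standard_normal(n_features)
    return v / np.linalg.norm(v)


def _loading_matrix(rng: np.random.Generator, n_features: int, n_latent: int) -> np.ndarray:
    """Block loadings: each feature loads on one latent factor with a
    random magnitude, giving within-block correlations well above
    between-block ones."""
    lam = np.zeros((n_features, n_latent))
    block = np.arange(n_features) % n_latent
    mag = rng.uniform(0.8, 1.5, size=n_features)
    sign = rng.choice([-1.0, 1.0], size=n_features)
    lam[np.arange(n_features), block] = mag * sign
    return lam


def resolve_effects(
    conditions: list[str], config: SyntheticConfig
) -> dict[str, TreatmentEffect]:
    effects = dict(DEFAULT_CONTROL_EFFECTS)
    effects.update(config.effects)
    missing = [c for c in conditions if c not in effects]
    if missing:
        raise KeyError(
            f"conditions without an effect-table entry: {sorted(missing)[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    return {c: effects[c] for c in conditions}


def simulate_screen(
    config: SyntheticConfig, layouts: list[PlateLayout]
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate per-cell features for every non-empty well of ``layouts``.

    Returns the long single-cell table (metadata + feature columns) and
    the planted :class:`GroundTruth`. Identical config (incl. seed) and
    layouts give an identical table.
    """
    feats = feature_names(config.n_features)
    conditions = sorted(
        {
            c
            for lay in layouts
            for c in lay.table.loc[lay.table["role"] != "empty", "condition"]
        }
    )
    effects = resolve_effects(conditions, config)
    rng = np.random.default_rng(config.seed)
    lam = _loading_matrix(rng, config.n_features, config.n_latent)
    mu_base = rng.normal(0.0, 1.0, size=config.n_features)
    directions = {
        c: _unit_direction(config.seed, c, config.n_features) for c in conditions
    }

    frames = []
    for lay in layouts:
        plate_eff = rng.normal(0.0, config.plate_effect_sd, size=config.n_features)
        wells = lay.table[lay.table["role"] != "empty"]
        mus = np.array(
            [config.baseline_cells_per_well * effects[c].m for c in wells["condition"]]
        )
        size = config.count_dispersion
        counts = rng.negative_binomial(size, size / (size + mus))
        total = int(counts.sum())
        z = rng.standard_normal((total, config.n_latent))
        eps = rng.normal(0.0, config.cell_noise_sd, size=(total, config.n_features))
        x = z @ lam.T
        x += eps
        x += mu_base + plate_eff
        # per-well shift: condition effect + well-level random offset; the
        # well offset acts through the latent loadings (plus a small
        # independent term) so well profiles inherit the block structure
        well_latent = rng.normal(
            0.0, config.well_noise_sd, size=(len(wells), config.n_latent)
        )
        well_offsets = well_latent @ lam.T + rng.normal(
            0.0, config.well_feature_noise_sd, size=(len(wells), config.n_features)
        )
        shift = np.empty((len(wells), config.n_features))
        for i, cond in enumerate(wells["condition"].to_numpy()):
            eff = effects[cond]
            shift[i] = eff.delta * directions[cond] + well_offsets[i]
        x += np.repeat(shift, counts, axis=0)
        fields = rng.integers(1, config.fields_per_well + 1, size=total)
        meta = pd.DataFrame(
            {
                "Metadata_Plate": lay.plate_id,
                "Metadata_Well": np.repeat(wells["well"].to_numpy(), counts),
                "Metadata_Field": fields,
                "Metadata_CellID": np.concatenate(
                    [np.arange(1, c + 1) for c in counts]
                )
                if total
                else np.array([], dtype=int),
            }
        )
        frames.append(pd.concat([meta, pd.DataFrame(x, columns=feats)], axis=1))
    table = pd.concat(frames, ignore_index=True)
    hits = tuple(
        c
        for c in conditions
        if effects[c].m >= config.hit_m_threshold
        and effects[c].delta >= config.hit_delta_threshold
    )
    truth = GroundTruth(effects=effects, directions=directions, intended_hits=hits)
    return table, truth


def planted_screen_effects(
    formulation_ids,
    n_hits: int = 8,
    seed: int = 0,
    m_range: tuple[float, float] = (1.8, 2.5),
    delta_range: tuple[float, float] = (5.0, 8.0),
) -> dict[str, TreatmentEffect]:
    """Effect table with ``n_hits`` strong planted hits among nulls.

    Hit formulations are drawn by a seeded RNG; each gets a proliferation
    multiplier and phenotype shift sampled uniformly from the given
    ranges (each hit's shift direction is distinct by construction of
    :func:`simulate_screen`). All other formulations are null (m=1,
    delta=0)."""
    ids = list(formulation_ids)
    rng = np.random.default_rng(seed)
    hit_ids = rng.choice(len(ids), size=n_hits, replace=False)
    effects = {fid: TreatmentEffect() for fid in ids}
    for i in hit_ids:
        effects[ids[i]] = TreatmentEffect(
            m=float(rng.uniform(*m_range)), delta=float(rng.uniform(*delta_range))
        )
    return effects


def write_cell_table(table: pd.DataFrame, path, format: str = "csv") -> None:
    """Write a per-cell table as CSV (text) or Parquet (columnar binary)."""
    if format == "csv":
        table.to_csv(path, index=False)
    elif format == "parquet":
        table.to_parquet(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_cell_table(path, format: str | None = None) -> pd.DataFrame:
    if format is None:
        format = "parquet" if str(path).endswith(".parquet") else "csv"
    if format == "csv":
        return pd.read_csv(path)
    if format == "parquet":
        return pd.read_parquet(path)
    raise ValueError(f"unknown format {format!r}")
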