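"""Full-factorial screen designs and semi-random 96-well plate layouts.

A media-optimization screen tests every combination of k two-level factors
(growth factors at a low and a high concentration, the low level often 0 =
absent), giving 2^k formulations. Formulations are distributed over 96-well
plates that each carry their own negative controls (serum-containing medium,
SCM, and chemically defined basal medium, CDBM), a positive control, and a
fixed number of replicate wells per treatment, with well positions shuffled
by a seeded RNG ("semi-random" layout).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "DesignMatrix",
    "LayoutConfig",
    "PlateLayout",
    "enumerate_full_factorial",
    "assign_plate_layout",
    "write_design_csv",
    "read_design_csv",
    "write_platemap_csv",
    "read_platemap_csv",
    "PLATE_ROWS",
    "PLATE_COLS",
    "all_wells",
    "CONTROL_ROLES",
]

PLATE_ROWS = "ABCDEFGH"
PLATE_COLS = tuple(range(1, 13))

#: roles a well can take besides carrying a treatment formulation
CONTROL_ROLES = ("neg_ctl_a", "neg_ctl_b", "pos_ctl")


def all_wells() -> list[str]:
    """96 well names in row-major A1..H12 order."""
    return [f"{r}{c}" for r in PLATE_ROWS for c in PLATE_COLS]


def is_valid_well(well: str) -> bool:
    if len(well) < 2 or well[0] not in PLATE_ROWS:
        return False
    try:
        col = int(well[1:])
    except ValueError:
        return False
    return 1 <= col <= 12


@dataclass(frozen=True)
class Factor:
    """A two-level screen factor (e.g. one growth factor).

    ``low`` and ``high`` are concentrations in ``unit``; ``low`` may be 0,
    meaning the factor is absent at its low level.
    """

    name: str
    low: float
    high: float
    unit: str = "ng/mL"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("factor name must be non-empty")
        if self.low == self.high:
            raise ValueError(
                f"factor {self.name!r}: low and high levels must differ"
            )


@dataclass(frozen=True)
class DesignMatrix:
    """Enumerated factor-level combinations of a full-factorial screen.

    ``levels`` is a (2^k, k) 0/1 array (0 = low, 1 = high), one row per
    formulation, in lexicographic order with the first factor varying
    slowest. ``formulation_ids`` are stable string ids ("T001", ...).
    """

    factors: tuple[Factor, ...]
    levels: np.ndarray
    formulation_ids: tuple[str, ...]

    @property
    def n_formulations(self) -> int:
        return self.levels.shape[0]

    def concentrations(self) -> pd.DataFrame:
        """One row per formulation, one column per factor, holding the
        concentration at the assigned level."""
        data = {
            f.name: np.where(self.levels[:, j] == 1, f.high, f.low)
            for j, f in enumerate(self.factors)
        }
        return pd.DataFrame(data, index=pd.Index(self.formulation_ids, name="formulation_id"))

    def validate(self) -> None:
        k = len(self.factors)
        n = self.levels.shape[0]
        if n != 2**k:
            raise ValueError(f"expected {2**k} rows for {k} factors, got {n}")
        if len({tuple(r) for r in self.levels}) != n:
            raise ValueError("design rows are not unique")
        high_counts = self.levels.sum(axis=0)
        if not np.all(high_counts == n // 2):
            raise ValueError("design is not balanced")


def enumerate_full_factorial(factors: list[Factor]) -> DesignMatrix:
    """Enumerate all 2^k level combinations of k two-level factors.

    Rows come out in deterministic lexicographic order (low before high,
    first factor slowest), each factor at its high level in exactly
    2^(k-1) rows.
    """
    k = len(factors)
    if not 1 <= k <= 16:
        raise ValueError(f"number of factors must be in [1, 16], got {k}")
    names = [f.name for f in factors]
    if len(set(names)) != k:
        raise ValueError("duplicate factor names")
    levels = np.array(list(itertools.product((0, 1), repeat=k)), dtype=np.int8)
    width = len(str(levels.shape[0]))
    ids = tuple(f"T{i + 1:0{width}d}" for i in range(levels.shape[0]))
    dm = DesignMatrix(factors=tuple(factors), levels=levels, formulation_ids=ids)
    dm.validate()
    return dm


@dataclass(frozen=True)
class LayoutConfig:
    """Per-plate well budget: control counts, replicates per treatment."""

    n_neg_ctl_a: int = 12
    n_neg_ctl_b: int = 12
    n_pos_ctl: int = 4
    replicates: int = 4
    treatments_per_plate: int | None = None  # default: floor(free wells / replicates)
    edge_exclusion: bool = False  # ban treatments from the outer well ring

    @property
    def control_wells(self) -> int:
        return self.n_neg_ctl_a + self.n_neg_ctl_b + self.n_pos_ctl

    def resolved_treatments_per_plate(self) -> int:
        free = 96 - self.control_wells
        if free <= 0:
            raise ValueError("control wells exceed plate capacity")
        tpp = self.treatments_per_plate
        if tpp is None:
            tpp = free // self.replicates
            if self.edge_exclusion:  # treatments confined to the 60 inner wells
                tpp = min(tpp, 60 // self.replicates)
        if tpp < 1:
            raise ValueError("no room for any treatment on a plate")
        if tpp * self.replicates + self.control_wells > 96:
            raise ValueError(
                f"infeasible well budget: {tpp} treatments x {self.replicates} "
                f"replicates + {self.control_wells} control wells > 96"
            )
        return tpp


@dataclass
class PlateLayout:
    """Assignment of the 96 wells of one plate to conditions.

    ``table`` has one row per well with columns ``well``, ``role``
    (neg_ctl_a / neg_ctl_b / pos_ctl / treatment / empty), ``condition``
    (the formulation id for treatments, the role name for controls, '' for
    empty wells) and ``replicate`` (1-based within condition, 0 for empty).
    """

    plate_id: str
    table: pd.DataFrame = field(repr=False)

    def condition_wells(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for cond, grp in self.table[self.table["role"] != "empty"].groupby("condition"):
            out[cond] = sorted(grp["well"].tolist())
        return out

    def validate(self, config: LayoutConfig | None = None) -> None:
        t = self.table
        if sorted(t["well"]) != sorted(all_wells()):
            raise ValueError(f"plate {self.plate_id}: wells are not exactly A1..H12")
        if t["well"].duplicated().any():
            raise ValueError(f"plate {self.plate_id}: duplicated wells")
        if config is not None:
            counts = t["role"].value_counts()
            expect = {
                "neg_ctl_a": config.n_neg_ctl_a,
                "neg_ctl_b": config.n_neg_ctl_b,
                "pos_ctl": config.n_pos_ctl,
            }
            for role, n in expect.items():
                if counts.get(role, 0) != n:
                    raise ValueError(
                        f"plate {self.plate_id}: {counts.get(role, 0)} {role} wells, expected {n}"
                    )
            reps = t[t["role"] == "treatment"].groupby("condition").size()
            if not (reps == config.replicates).all():
                raise ValueError(
                    f"plate {self.plate_id}: treatments without exactly "
                    f"{config.replicates} replicate wells"
                )


def _inner_wells() -> set[str]:
    return {f"{r}{c}" for r in PLATE_ROWS[1:-1] for c in range(2, 12)}


def assign_plate_layout(
    design: DesignMatrix,
    config: LayoutConfig = LayoutConfig(),
    seed: int = 0,
    max_plates: int | None = None,
) -> list[PlateLayout]:
    """Distribute a design over 96-well plates with seeded well shuffling.

    Every formulation lands on exactly one plate with exactly
    ``config.replicates`` wells; each plate carries its own controls; the
    last plate may be partially filled (unused wells marked ``empty``).
    Identical ``seed`` yields identical layouts.
    """
    tpp = config.resolved_treatments_per_plate()
    n_t = design.n_formulations
    n_plates = math.ceil(n_t / tpp)
    if max_plates is not None and n_plates > max_plates:
        raise ValueError(
            f"design needs {n_plates} plates but only {max_plates} allowed"
        )
    rng = np.random.default_rng(seed)
    plate_width = len(str(n_plates))
    layouts: list[PlateLayout] = []
    for p in range(n_plates):
        chunk = design.formulation_ids[p * tpp : (p + 1) * tpp]
        entries: list[tuple[str, str, int]] = []  # (role, condition, replicate)
        for role, n in (
            ("neg_ctl_a", config.n_neg_ctl_a),
            ("neg_ctl_b", config.n_neg_ctl_b),
            ("pos_ctl", config.n_pos_ctl),
        ):
            entries += [(role, role, i + 1) for i in range(n)]
        treat_entries = [
            ("treatment", fid, i + 1) for fid in chunk for i in range(config.replicates)
        ]
        wells = all_wells()
        if config.edge_exclusion:
            inner = sorted(_inner_wells())
            if len(treat_entries) > len(inner):
                raise ValueError(
                    "edge_exclusion: more treatment wells than inner wells"
                )
            inner_perm = [inner[i] for i in rng.permutation(len(inner))]
            treat_wells = inner_perm[: len(treat_entries)]
            rest = [w for w in wells if w not in set(treat_wells)]
            rest_perm = [rest[i] for i in rng.permutation(len(rest))]
            assignment = dict(zip(treat_wells, treat_entries))
            for w, e in zip(rest_perm, entries):
                assignment[w] = e
        else:
            combined = entries + treat_entries
            perm = [wells[i] for i in rng.permutation(96)]
            assignment = dict(zip(perm, combined))
        rows = []
        for w in wells:
            role, cond, rep = assignment.get(w, ("empty", "", 0))
            rows.append((w, role, cond, rep))
        table = pd.DataFrame(rows, columns=["well", "role", "condition", "replicate"])
        layout = PlateLayout(plate_id=f"P{p + 1:0{plate_width}d}", table=table)
        layout.validate()
        layouts.append(layout)
    return layouts


def write_design_csv(design: DesignMatrix, path) -> None:
    design.concentrations().to_csv(path)


def read_design_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="formulation_id")


def write_platemap_csv(layouts: list[PlateLayout], path) -> None:
    frames = []
    for lay in layouts:
        t = lay.table.copy()
        t.insert(0, "plate_id", lay.plate_id)
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    out = out.rename(columns={"condition": "formulation_id"})
    out.to_csv(path, index=False)


def read_platemap_csv(path) -> list[PlateLayout]:
    df = pd.read_csv(path, keep_default_na=False, dtype={"formulation_id": str})
    df["replicate"] = df["replicate"].astype(int)
    layouts = []
    for pid, grp in df.groupby("plate_id", sort=True):
        t = grp.rename(columns={"formulation_id": "condition"})[
            ["well", "role", "condition", "replicate"]
        ].reset_index(drop=True)
        lay = PlateLayout(plate_id=str(pid), table=t)
        lay.validate()
        layouts.append(lay)
    return layouts
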