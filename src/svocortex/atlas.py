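"""Destrieux-style cortical parcellation: atlas, lobes and thickness tables.

The cortex is represented as 74 named parcels per hemisphere, grouped into
four lobes (frontal 27, parietal 17, temporal 18, occipital 12). Thickness
data arrive as a wide subject x parcel table with one column per
(hemisphere, parcel), named ``lh_<parcel>`` / ``rh_<parcel>``; the
per-hemisphere average thickness used as a model covariate is computed here.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LOBES",
    "LOBE_COUNTS",
    "HEMISPHERES",
    "ParcelAtlas",
    "ThicknessMatrix",
    "AtlasValidationError",
    "ThicknessInputError",
    "load_atlas",
    "read_thickness",
    "thickness_from_frame",
    "write_thickness",
    "select_lobe",
    "read_demographics",
]

LOBES = ("frontal", "parietal", "temporal", "occipital")
LOBE_COUNTS = {"frontal": 27, "parietal": 17, "temporal": 18, "occipital": 12}
HEMISPHERES = ("left", "right")
_HEMI_PREFIX = {"left": "lh", "right": "rh"}


class AtlasValidationError(ValueError):
    """Raised when an atlas table violates the 74-parcel taxonomy."""


class ThicknessInputError(ValueError):
    """Raised for malformed thickness tables; message lists the offenders."""


def snake_name(name: str) -> str:
    """Canonical column-safe parcel name (lowercase, underscores)."""
    return re.sub(r"[^a-z0-9]+", "_", name.lower()).strip("_")


@dataclass(frozen=True)
class ParcelAtlas:
    """74 named parcels with integer IDs 1..74 and a lobe assignment each."""

    table: pd.DataFrame = field(repr=False)  # columns: id, name, lobe, snake

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def hemispheres(self) -> tuple[str, str]:
        return HEMISPHERES

    def lobe_ids(self, lobe: str) -> list[int]:
        if lobe not in LOBES:
            raise AtlasValidationError(f"unknown lobe {lobe!r}; expected one of {LOBES}")
        sub = self.table[self.table["lobe"] == lobe]
        return sub["id"].tolist()

    def columns(self, hemisphere: str, lobe: str | None = None) -> list[str]:
        """Thickness column names for a hemisphere, ordered by parcel id."""
        if hemisphere not in HEMISPHERES:
            raise AtlasValidationError(f"unknown hemisphere {hemisphere!r}")
        prefix = _HEMI_PREFIX[hemisphere]
        sub = self.table if lobe is None else self.table[self.table["lobe"] == lobe]
        if lobe is not None and lobe not in LOBES:
            raise AtlasValidationError(f"unknown lobe {lobe!r}; expected one of {LOBES}")
        return [f"{prefix}_{s}" for s in sub.sort_values("id")["snake"]]

    def all_columns(self) -> list[str]:
        return self.columns("left") + self.columns("right")

    def name_of(self, parcel_id: int) -> str:
        row = self.table[self.table["id"] == parcel_id]
        if row.empty:
            raise AtlasValidationError(f"no parcel with id {parcel_id}")
        return row["name"].iloc[0]

    def lobe_of(self, parcel_id: int) -> str:
        row = self.table[self.table["id"] == parcel_id]
        if row.empty:
            raise AtlasValidationError(f"no parcel with id {parcel_id}")
        return row["lobe"].iloc[0]


def _validate_atlas(df: pd.DataFrame) -> pd.DataFrame:
    required = {"id", "name", "lobe"}
    missing = required - set(df.columns)
    if missing:
        raise AtlasValidationError(f"atlas table missing columns {sorted(missing)}")
    df = df.copy()
    df["id"] = df["id"].astype(int)
    if len(df) != 74:
        raise AtlasValidationError(f"expected 74 parcels, got {len(df)}")
    if sorted(df["id"]) != list(range(1, 75)):
        raise AtlasValidationError("parcel ids must be unique and contiguous 1..74")
    if df["name"].duplicated().any():
        dups = df.loc[df["name"].duplicated(), "name"].tolist()
        raise AtlasValidationError(f"duplicate parcel names: {dups}")
    bad = set(df["lobe"]) - set(LOBES)
    if bad:
        raise AtlasValidationError(f"unknown lobe labels: {sorted(bad)}")
    counts = df["lobe"].value_counts().to_dict()
    if counts != LOBE_COUNTS:
        raise AtlasValidationError(
            f"lobe counts {counts} do not match required {LOBE_COUNTS}"
        )
    df["snake"] = df["name"].map(snake_name)
    if df["snake"].duplicated().any():
        raise AtlasValidationError("parcel names collide after canonicalisation")
    return df.sort_values("id").reset_index(drop=True)


def load_atlas(path=None) -> ParcelAtlas:
    """Load a parcel atlas table (id, name, lobe); default is the packaged one."""
    if path is None:
        ref = importlib.resources.files("svocortex.data") / "destrieux_lobes.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return ParcelAtlas(table=_validate_atlas(df))


@dataclass(frozen=True)
class ThicknessMatrix:
    """Subject x (hemisphere, parcel) cortical thickness in mm.

    ``hemi_average`` carries each subject's whole-hemisphere average
    thickness (unweighted mean of the 74 parcels by default); it is kept on
    lobe subsets because it stays the whole-hemisphere covariate in the
    regression models.
    """

    values: pd.DataFrame = field(repr=False)  # index: subject, columns: lh_*/rh_*
    hemi_average: pd.DataFrame = field(repr=False)  # columns: left, right

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def subset(self, columns: list[str]) -> "ThicknessMatrix":
        missing = [c for c in columns if c not in self.values.columns]
        if missing:
            raise ThicknessInputError(f"columns not present: {missing}")
        return ThicknessMatrix(values=self.values[columns], hemi_average=self.hemi_average)

    def reindex(self, subjects) -> "ThicknessMatrix":
        missing = [s for s in subjects if s not in self.values.index]
        if missing:
            raise ThicknessInputError(f"subjects not present: {missing}")
        return ThicknessMatrix(
            values=self.values.loc[subjects], hemi_average=self.hemi_average.loc[subjects]
        )


def thickness_from_frame(
    df: pd.DataFrame,
    atlas: ParcelAtlas,
    weights: pd.Series | None = None,
) -> ThicknessMatrix:
    """Build a validated :class:`ThicknessMatrix` from a wide DataFrame.

    ``df`` must be indexed by subject with one column per atlas parcel and
    hemisphere. ``weights``, if given, maps column name -> per-parcel weight
    (e.g. surface area) for an area-weighted hemisphere average; default is
    the unweighted mean.
    """
    expected = atlas.all_columns()
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ThicknessInputError(f"thickness table missing columns: {missing}")
    vals = df[expected].apply(pd.to_numeric, errors="coerce")
    bad_cells = []
    arr = vals.to_numpy(dtype=float)
    bad_mask = ~np.isfinite(arr) | (arr <= 0)
    if bad_mask.any():
        for i, j in zip(*np.nonzero(bad_mask)):
            bad_cells.append(f"subject {vals.index[i]!r}, column {vals.columns[j]}")
        raise ThicknessInputError(
            "non-numeric, non-finite or non-positive thickness at: "
            + "; ".join(bad_cells[:20])
            + ("; ..." if len(bad_cells) > 20 else "")
        )
    hemi = {}
    for h in HEMISPHERES:
        cols = atlas.columns(h)
        if weights is None:
            hemi[h] = vals[cols].mean(axis=1)
        else:
            w = np.array([weights[c] for c in cols], dtype=float)
            hemi[h] = vals[cols].to_numpy() @ (w / w.sum())
    hemi_average = pd.DataFrame(hemi, index=vals.index)
    return ThicknessMatrix(values=vals, hemi_average=hemi_average)


def read_thickness(
    path,
    atlas: ParcelAtlas,
    name_map: dict[str, str] | None = None,
    weights: pd.Series | None = None,
) -> ThicknessMatrix:
    """Read a wide thickness table (one row per subject).

    ``name_map`` renames external column dialects (e.g. surface-software
    exports) onto the ``lh_<parcel>`` / ``rh_<parcel>`` convention before
    validation.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    # round_trip parsing keeps write -> read cycles bit-identical
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if "participant_id" not in df.columns:
        raise ThicknessInputError(f"{path}: thickness table needs a participant_id column")
    df = df.set_index("participant_id")
    if name_map:
        df = df.rename(columns=name_map)
    return thickness_from_frame(df, atlas, weights=weights)


def write_thickness(matrix: ThicknessMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "participant_id"
    out.to_csv(path)


def select_lobe(
    matrix: ThicknessMatrix,
    atlas: ParcelAtlas,
    lobe: str,
    hemisphere: str,
) -> ThicknessMatrix:
    """Restrict a thickness matrix to one lobe of one hemisphere.

    The whole-hemisphere average covariate is retained unchanged.
    """
    return matrix.subset(atlas.columns(hemisphere, lobe))


def read_demographics(
    path,
    impute: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Read demographics (participant_id, age in years, gender coded female=1).

    Gender accepts 0/1 or f/female/m/male labels. Missing age or gender is an
    error unless ``impute`` is set, in which case missing ages take the sample
    mean and missing genders are assigned at random (seeded).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"participant_id", "age", "gender"}
    missing = required - set(df.columns)
    if missing:
        raise ThicknessInputError(f"{path}: demographics missing columns {sorted(missing)}")
    df = df.copy()
    gender_map = {"f": 1, "female": 1, "1": 1, "m": 0, "male": 0, "0": 0}
    df["gender"] = (
        df["gender"].astype(str).str.strip().str.lower().map(gender_map)
    )
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    has_missing = df["age"].isna() | df["gender"].isna()
    if has_missing.any():
        if not impute:
            offenders = df.loc[has_missing, "participant_id"].tolist()
            raise ThicknessInputError(
                f"missing age/gender for participants {offenders}; "
                "pass impute=True to mean-impute age and randomly assign gender"
            )
        rng = np.random.default_rng(seed)
        df.loc[df["age"].isna(), "age"] = df["age"].mean()
        n_miss = int(df["gender"].isna().sum())
        df.loc[df["gender"].isna(), "gender"] = rng.integers(0, 2, size=n_miss)
    df["gender"] = df["gender"].astype(int)
    return df[["participant_id", "age", "gender"]]
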