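"""Domain types and tabular IO for the mixed-species-group (MSG) pipeline.

The unit of observation is a *sighting* (one species detected at one place on
one day) and the unit of analysis is an *animal group* (sightings chained
within 50 m of one another).  A group is a mixed-species group (MSG) when it
contains two or more distinct species.  All tables are plain RFC-4180 CSV with
mandatory headers; species identifiers are case-insensitive slugs.
"""

from __future__ import annotations


import datetime as _dt
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HABITATS",
    "SCENARIO_NAMES",
    "Sighting",
    "AnimalGroup",
    "OccurrenceMatrix",
    "Scenario",
    "SchemaError",
    "ValidationError",
    "species_reference_table",
    "species_attributes",
    "default_species_pool",
    "read_sightings",
    "write_sightings",
    "read_groups",
    "write_groups",
    "read_attributes",
    "write_attributes",
    "summarize_species",
    "scenario_groups",
    "filter_common_species",
    "load_deposited",
]

#: Closed habitat vocabulary, coarsest-to-densest vegetation; also the fixed
#: tie-break order for modal-habitat assignment.
HABITATS: tuple[str, ...] = ("grassland", "open_bushland", "bushland", "riverine")

SCENARIO_NAMES: tuple[str, ...] = (
    "inside_lhr",
    "outside_lhr",
    "ndvi_small",
    "ndvi_medium",
    "ndvi_large",
)

NDVI_CLASSES: tuple[str, ...] = ("small", "medium", "large")
ZONES: tuple[str, ...] = ("core", "edge")


class SchemaError(ValueError):
    """A required column is missing or a table has the wrong shape."""


class ValidationError(ValueError):
    """A row violates a domain invariant (bad habitat label, count < 1, ...)."""


_SLUG_RE = re.compile(r"[^a-z0-9]+")


def slugify(name: str) -> str:
    """Normalise a species name to a case-insensitive underscore slug."""
    return _SLUG_RE.sub("_", str(name).strip().lower()).strip("_")


# ---------------------------------------------------------------------------
# Reference table: per-species sighting counts, lion prey preference
# (Jacobs' index, in [-1, 1]) and proportion of monocots in the diet.
# 18 species; the 15 that occur in every scenario network exclude buffalo,
# gerenuk and olive baboon.  The six focal species used for aggregated
# network measures are flagged.
# ---------------------------------------------------------------------------
_SPECIES_REFERENCE: tuple[tuple[str, int, float, float, bool], ...] = (
    ("elephant", 14, -0.87, 0.23, False),
    ("giraffe", 128, 0.24, 0.05, True),
    ("buffalo", 1, 0.32, 0.78, False),
    ("eland", 34, 0.18, 0.50, False),
    ("zebra", 498, 0.16, 0.92, True),
    ("wildebeest", 118, 0.27, 0.81, True),
    ("waterbuck", 20, 0.18, 0.84, False),
    ("warthog", 15, 0.11, 0.91, False),
    ("lesser_kudu", 16, -0.20, 0.34, False),
    ("grants_gazelle", 96, -0.56, 0.65, True),
    ("impala", 137, -0.73, 0.40, True),
    ("gerenuk", 2, -0.73, 0.00, False),
    ("thomsons_gazelle", 85, -0.62, 0.75, True),
    ("olive_baboon", 2, -0.89, 0.20, False),
    ("steenbok", 6, -0.86, 0.34, False),
    ("black_backed_jackal", 9, -1.00, 0.06, False),
    ("kirks_dikdik", 57, -0.88, 0.17, False),
    ("vervet_monkey", 16, -1.00, 0.07, False),
)

#: Species excluded from cross-scenario network comparison (absent from at
#: least one scenario in the field data).
RARE_SPECIES: tuple[str, ...] = ("buffalo", "gerenuk", "olive_baboon")

FOCAL_SPECIES: tuple[str, ...] = (
    "giraffe",
    "zebra",
    "wildebeest",
    "grants_gazelle",
    "impala",
    "thomsons_gazelle",
)


def species_reference_table() -> pd.DataFrame:
    """Per-species reference data: sighting counts and trait attributes.

    Returns a DataFrame indexed by species slug with columns ``sightings``
    (number of occurrences in the field survey), ``jacobs_index`` (lion prey
    preference, [-1, 1]), ``monocot_prop`` (diet proportion of monocots,
    [0, 1]) and ``focal`` (bool).
    """
    df = pd.DataFrame(
        _SPECIES_REFERENCE,
        columns=["species", "sightings", "jacobs_index", "monocot_prop", "focal"],
    )
    return df.set_index("species")


def species_attributes() -> pd.DataFrame:
    """Attribute table (jacobs_index, monocot_prop) for all reference species."""
    return species_reference_table()[["jacobs_index", "monocot_prop"]].copy()


def default_species_pool() -> pd.DataFrame:
    """The 15-species pool used for network analyses, with relative abundances
    proportional to the reference sighting counts."""
    ref = species_reference_table().drop(index=list(RARE_SPECIES))
    out = ref[["sightings", "jacobs_index", "monocot_prop", "focal"]].copy()
    out["rel_abundance"] = out["sightings"] / out["sightings"].sum()
    return out


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sighting:
    """A single-species detection: where, when, how many, in what habitat."""

    species: str
    x: float
    y: float
    date: _dt.date
    count: int
    habitat: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", slugify(self.species))
        if self.count < 1:
            raise ValidationError(f"count must be >= 1, got {self.count}")
        if self.habitat not in HABITATS:
            raise ValidationError(
                f"unknown habitat {self.habitat!r}; expected one of {HABITATS}"
            )
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError("coordinates must be finite")


@dataclass
class AnimalGroup:
    """A set of co-occurring species with its scenario covariates.

    ``members`` maps species slug -> individual count.  ``is_msg`` is a
    derived property: true iff the group holds >= 2 distinct species.
    ``ndvi_class``, ``in_lhr`` and ``zone`` stay ``None`` until the
    corresponding classification step has run.
    """

    group_id: str
    members: dict[str, int]
    habitat: str
    ndvi_value: float | None = None
    ndvi_class: str | None = None
    in_lhr: bool | None = None
    zone: str | None = None
    x: float | None = None
    y: float | None = None
    date: _dt.date | None = None

    def __post_init__(self) -> None:
        self.members = {slugify(s): int(c) for s, c in self.members.items()}
        if not self.members:
            raise ValidationError(f"group {self.group_id}: needs >= 1 member")
        for s, c in self.members.items():
            if c < 1:
                raise ValidationError(f"group {self.group_id}: count < 1 for {s}")
        if self.habitat not in HABITATS:
            raise ValidationError(
                f"group {self.group_id}: unknown habitat {self.habitat!r}"
            )
        if self.ndvi_value is not None and not -1.0 <= self.ndvi_value <= 1.0:
            raise ValidationError(
                f"group {self.group_id}: ndvi_value {self.ndvi_value} outside [-1, 1]"
            )
        if self.ndvi_class is not None and self.ndvi_class not in NDVI_CLASSES:
            raise ValidationError(f"group {self.group_id}: bad ndvi_class")
        if self.zone is not None and self.zone not in ZONES:
            raise ValidationError(f"group {self.group_id}: bad zone")

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.members)

    @property
    def is_msg(self) -> bool:
        return len(self.members) >= 2

    @property
    def size(self) -> int:
        return sum(self.members.values())


@dataclass(frozen=True)
class Scenario:
    """A named group-level filter; five scenarios in two mutually exclusive
    families (inside/outside the lion home range; NDVI tertile)."""

    name: str
    predicate: Callable[[AnimalGroup], bool]

    def select(self, groups: Iterable[AnimalGroup]) -> list[AnimalGroup]:
        return [g for g in groups if self.predicate(g)]


SCENARIOS: dict[str, Scenario] = {
    "inside_lhr": Scenario("inside_lhr", lambda g: g.in_lhr is True),
    "outside_lhr": Scenario("outside_lhr", lambda g: g.in_lhr is False),
    "ndvi_small": Scenario("ndvi_small", lambda g: g.ndvi_class == "small"),
    "ndvi_medium": Scenario("ndvi_medium", lambda g: g.ndvi_class == "medium"),
    "ndvi_large": Scenario("ndvi_large", lambda g: g.ndvi_class == "large"),
}


def scenario_groups(groups: Sequence[AnimalGroup]) -> dict[str, list[AnimalGroup]]:
    """Split groups into the five scenario subsets (LHR pair, NDVI triple)."""
    missing = [g.group_id for g in groups if g.in_lhr is None or g.ndvi_class is None]
    if missing:
        raise ValidationError(
            f"groups not fully classified (in_lhr/ndvi_class unset): {missing[:5]}..."
            if len(missing) > 5
            else f"groups not fully classified: {missing}"
        )
    return {name: sc.select(groups) for name, sc in SCENARIOS.items()}


class OccurrenceMatrix:
    """Binary groups x species matrix, the randomisation substrate.

    Cell (i, j) is 1 iff species j was present in group i.  Row strata carry
    the group habitat labels so the habitat-constrained null can additionally
    preserve per-habitat species totals.  Rows that contain none of the
    requested species are dropped (they carry no information for any
    pairwise statistic and would violate the row-sum >= 1 invariant).
    """

    def __init__(
        self,
        data: np.ndarray,
        row_ids: Sequence[str],
        species: Sequence[str],
        row_stratum: Sequence[str],
    ) -> None:
        data = np.asarray(data, dtype=np.int8)
        if data.ndim != 2:
            raise ValidationError("occurrence matrix must be 2-D")
        if not np.isin(data, (0, 1)).all():
            raise ValidationError("occurrence matrix cells must be 0/1")
        if data.shape != (len(row_ids), len(species)):
            raise ValidationError("matrix shape does not match row/column labels")
        if len(row_stratum) != len(row_ids):
            raise ValidationError("row_stratum length mismatch")
        if data.shape[0] and (data.sum(axis=1) < 1).any():
            raise ValidationError("every row must contain at least one species")
        self.data = data
        self.row_ids = list(row_ids)
        self.species = [slugify(s) for s in species]
        self.row_stratum = np.asarray(row_stratum, dtype=object)

    @classmethod
    def from_groups(
        cls, groups: Sequence[AnimalGroup], species: Sequence[str] | None = None
    ) -> "OccurrenceMatrix":
        if species is None:
            species = sorted({s for g in groups for s in g.species})
        species = [slugify(s) for s in species]
        idx = {s: j for j, s in enumerate(species)}
        rows, ids, strata = [], [], []
        for g in groups:
            row = np.zeros(len(species), dtype=np.int8)
            for s in g.species:
                j = idx.get(s)
                if j is not None:
                    row[j] = 1
            if row.any():
                rows.append(row)
                ids.append(g.group_id)
                strata.append(g.habitat)
        data = np.vstack(rows) if rows else np.zeros((0, len(species)), dtype=np.int8)
        return cls(data, ids, species, strata)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row_sums(self) -> np.ndarray:
        return self.data.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        """N_j: number of groups in which each species occurs."""
        return self.data.sum(axis=0)

    def stratum_col_sums(self) -> dict[str, np.ndarray]:
        """Per-habitat species totals (the quantity the stratified null fixes)."""
        return {
            h: self.data[self.row_stratum == h].sum(axis=0)
            for h in dict.fromkeys(self.row_stratum)
        }

    def cooccurrence(self, a: str, b: str) -> int:
        """N_ab: number of groups holding both species."""
        ia, ib = self.species.index(slugify(a)), self.species.index(slugify(b))
        return int((self.data[:, ia] & self.data[:, ib]).sum())

    def copy(self) -> "OccurrenceMatrix":
        return OccurrenceMatrix(
            self.data.copy(), list(self.row_ids), list(self.species), self.row_stratum.copy()
        )


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------

_SIGHTING_COLS = ["species", "x", "y", "date", "count", "habitat"]
_GROUP_COLS = ["group_id", "species_list", "habitat", "ndvi_value", "in_lhr", "zone"]
_ATTR_COLS = ["species", "jacobs_index", "monocot_prop"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def read_sightings(path: str | Path) -> list[Sighting]:
    """Read a sightings CSV (species,x,y,date,count,habitat)."""
    df = pd.read_csv(path)
    _require_columns(df, _SIGHTING_COLS, "sightings table")
    out: list[Sighting] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                Sighting(
                    species=row.species,
                    x=float(row.x),
                    y=float(row.y),
                    date=_dt.date.fromisoformat(str(row.date)),
                    count=int(row.count),
                    habitat=str(row.habitat),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"sightings row {i}: {exc}") from exc
    return out


def write_sightings(sightings: Iterable[Sighting], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (s.species, s.x, s.y, s.date.isoformat(), s.count, s.habitat)
            for s in sightings
        ],
        columns=_SIGHTING_COLS,
    )
    df.to_csv(path, index=False)


def _members_to_str(members: Mapping[str, int]) -> str:
    return ";".join(f"{s}:{c}" for s, c in sorted(members.items()))


def _members_from_str(text: str) -> dict[str, int]:
    members: dict[str, int] = {}
    for tok in str(text).split(";"):
        tok = tok.strip()
        if not tok:
            continue
        if ":" in tok:
            name, _, cnt = tok.rpartition(":")
            members[slugify(name)] = int(cnt)
        else:  # bare species name, count defaults to 1
            members[slugify(tok)] = members.get(slugify(tok), 0) + 1
    return members


def write_groups(groups: Iterable[AnimalGroup], path: str | Path) -> None:
    rows = []
    for g in groups:
        rows.append(
            {
                "group_id": g.group_id,
                "species_list": _members_to_str(g.members),
                "habitat": g.habitat,
                "ndvi_value": g.ndvi_value,
                "in_lhr": g.in_lhr,
                "zone": g.zone,
                "ndvi_class": g.ndvi_class,
                "x": g.x,
                "y": g.y,
                "date": g.date.isoformat() if g.date else None,
                "is_msg": g.is_msg,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def _opt(value, cast):
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return cast(value)


def read_groups(path: str | Path) -> list[AnimalGroup]:
    """Read a groups CSV (group_id,species_list,habitat,ndvi_value,in_lhr,zone)."""
    df = pd.read_csv(path)
    _require_columns(df, _GROUP_COLS, "groups table")
    out: list[AnimalGroup] = []
    for i, row in df.iterrows():
        try:
            g = AnimalGroup(
                group_id=str(row["group_id"]),
                members=_members_from_str(row["species_list"]),
                habitat=str(row["habitat"]),
                ndvi_value=_opt(row["ndvi_value"], float),
                ndvi_class=_opt(row.get("ndvi_class"), str),
                in_lhr=_opt(row["in_lhr"], lambda v: str(v).lower() in ("true", "1")),
                zone=_opt(row["zone"], str),
                x=_opt(row.get("x"), float),
                y=_opt(row.get("y"), float),
                date=_opt(row.get("date"), lambda v: _dt.date.fromisoformat(str(v))),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"groups row {i}: {exc}") from exc
        if "is_msg" in df.columns and not pd.isna(row["is_msg"]):
            flagged = str(row["is_msg"]).lower() in ("true", "1")
            if flagged != g.is_msg:
                raise ValidationError(
                    f"groups row {i}: is_msg flag inconsistent with member count"
                )
        out.append(g)
    return out


def read_attributes(path: str | Path) -> pd.DataFrame:
    """Read a species attribute CSV into a species-indexed DataFrame."""
    df = pd.read_csv(path)
    _require_columns(df, _ATTR_COLS, "attributes table")
    df["species"] = df["species"].map(slugify)
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValidationError(f"duplicate species in attribute table: {dups}")
    df = df.set_index("species")
    if not df["jacobs_index"].between(-1, 1).all():
        raise ValidationError("jacobs_index outside [-1, 1]")
    if not df["monocot_prop"].between(0, 1).all():
        raise ValidationError("monocot_prop outside [0, 1]")
    return df[["jacobs_index", "monocot_prop"]]


def write_attributes(attrs: pd.DataFrame, path: str | Path) -> None:
    attrs.reset_index().rename(columns={"index": "species"}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def summarize_species(groups: Sequence[AnimalGroup]) -> pd.DataFrame:
    """Occurrence counts N_j: number of groups containing each species."""
    if not groups:
        raise ValidationError("summarize_species: empty group list")
    counts: dict[str, int] = {}
    for g in groups:
        for s in g.species:
            counts[s] = counts.get(s, 0) + 1
    df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["species", "n_occurrences"],
    )
    return df


def filter_common_species(
    by_scenario: Mapping[str, Sequence[AnimalGroup]]
) -> list[str]:
    """Species occurring (N_j >= 1) in every scenario; networks rebuilt on this
    set share one node set.  Raises if the intersection is empty."""
    common: set[str] | None = None
    for name, groups in by_scenario.items():
        present = {s for g in groups for s in g.species}
        common = present if common is None else common & present
    if not common:
        raise ValidationError(
            "no species occurs in every scenario; networks cannot be compared"
        )
    return sorted(common)


def load_deposited(directory: str | Path) -> dict[str, object]:
    """Load the deposited field dataset from a local directory.

    The survey data are archived in the Goettingen Research Online repository
    and are not bundled here; download them and point ``directory`` at a
    folder holding ``sightings.csv``/``groups.csv`` (and optionally
    ``attributes.csv``) in the formats this module writes.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(
            f"deposited-data directory {directory} not found: the field dataset "
            "is not bundled with this package; download it from the public "
            "repository (doi:10.25625/KRTSLI) and convert it to the CSV layout "
            "described in the msgnet.data docstrings"
        )
    out: dict[str, object] = {}
    if (directory / "sightings.csv").exists():
        out["sightings"] = read_sightings(directory / "sightings.csv")
    if (directory / "groups.csv").exists():
        out["groups"] = read_groups(directory / "groups.csv")
    if not out:
        raise FileNotFoundError(
            f"{directory} holds neither sightings.csv nor groups.csv"
        )
    attrs = directory / "attributes.csv"
    out["attributes"] = read_attributes(attrs) if attrs.exists() else species_attributes()
    return out
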