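"""Accident-record data model, categorical factor codings, I/O and stratification.

The central container is :class:`AccidentTable`: one row per recorded accident,
carrying WGS84 point coordinates, two severity outcomes (fatalities, injuries)
and a set of integer-coded categorical factors (cause of the accident, road
characteristics, environment, responsible party, ...).  Every detector in
:mod:`geodetect.detectors` consumes either the table directly or a
:class:`Stratification` derived from one of its factors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: Sentinel category code for a missing factor value.  Records carrying the
#: sentinel for a factor are dropped from any stratification on that factor.
MISSING: int = -1

_META_COLUMNS = ("record_id", "lon", "lat", "year", "fatalities", "injuries")


class SchemaError(ValueError):
    """A required column is absent or of the wrong kind."""


class ValidationError(ValueError):
    """Row-level content violates an invariant; carries offending row ids."""

    def __init__(self, message: str, rows: Sequence[int] = ()):
        super().__init__(message)
        self.rows = list(rows)


@dataclass(frozen=True)
class FactorCoding:
    """Declared category set of one categorical factor.

    Parameters
    ----------
    name : str
        Factor identifier, e.g. ``"primary_cause"``.
    categories : sequence of (int, str)
        Ordered ``(code, label)`` pairs; codes must be unique and at least
        two categories must be declared.
    """

    name: str
    categories: tuple[tuple[int, str], ...]

    def __post_init__(self):
        cats = tuple((int(c), str(l)) for c, l in self.categories)
        object.__setattr__(self, "categories", cats)
        codes = [c for c, _ in cats]
        if len(codes) < 2:
            raise ValueError(f"factor {self.name!r} needs >= 2 categories")
        if len(set(codes)) != len(codes):
            raise ValueError(f"factor {self.name!r} has duplicate codes")

    @property
    def codes(self) -> frozenset[int]:
        return frozenset(c for c, _ in self.categories)

    def label(self, code: int) -> str:
        for c, l in self.categories:
            if c == code:
                return l
        raise KeyError(code)


@dataclass(frozen=True)
class AccidentRecord:
    """A single accident record (row view of an :class:`AccidentTable`)."""

    record_id: str
    lon: float
    lat: float
    year: int
    fatalities: float
    injuries: float
    factors: Mapping[str, int]


def default_coding() -> dict[str, FactorCoding]:
    """The packaged 17-factor coding scheme (zones, time, road, management,
    environment and violation factors with their integer category codes)."""
    text = resources.files("geodetect.data").joinpath("factor_codings.json").read_text()
    raw = json.loads(text)
    return {
        name: FactorCoding(name, tuple((int(c), l) for c, l in entries))
        for name, entries in raw.items()
    }


class AccidentTable:
    """Validated table of accident records plus the coding of its factors.

    Internally a :class:`pandas.DataFrame` with the metadata columns
    ``record_id, lon, lat, year, fatalities, injuries`` followed by one
    integer column per coded factor.
    """

    def __init__(self, frame: pd.DataFrame, coding: Mapping[str, FactorCoding]):
        self.coding = dict(coding)
        self.frame = self._validate(frame.reset_index(drop=True))

    # -- validation ------------------------------------------------------
    def _validate(self, df: pd.DataFrame) -> pd.DataFrame:
        for col in _META_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        for name in self.coding:
            if name not in df.columns:
                raise SchemaError(f"missing factor column {name!r}")
        if len(df) == 0:
            raise ValidationError("table must contain at least one record")
        for col in ("fatalities", "injuries"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[~np.isfinite(vals) | (vals < 0)].tolist()
            if bad:
                raise ValidationError(f"negative or non-numeric {col}", rows=bad)
            df[col] = vals.astype(float)
        bad = df.index[(df["lon"].abs() > 180) | (df["lat"].abs() > 90)].tolist()
        if bad:
            raise ValidationError("coordinates outside WGS84 bounds", rows=bad)
        for name, coding in self.coding.items():
            codes = pd.to_numeric(df[name], errors="coerce")
            ok = codes.isin(list(coding.codes) + [MISSING])
            bad = df.index[~ok].tolist()
            if bad:
                raise ValidationError(
                    f"undeclared category code for factor {name!r} "
                    f"(rows {bad[:10]}{'...' if len(bad) > 10 else ''})",
                    rows=bad,
                )
            df[name] = codes.astype(int)
        df["year"] = pd.to_numeric(df["year"]).astype(int)
        df["record_id"] = df["record_id"].astype(str)
        return df

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def factor_names(self) -> list[str]:
        return list(self.coding)

    def outcome(self, name: str) -> np.ndarray:
        if name not in ("fatalities", "injuries"):
            raise KeyError(f"unknown outcome {name!r}")
        return self.frame[name].to_numpy(dtype=float)

    def coords(self) -> np.ndarray:
        """(n, 2) array of (lon, lat) in decimal degrees."""
        return self.frame[["lon", "lat"]].to_numpy(dtype=float)

    def record(self, i: int) -> AccidentRecord:
        row = self.frame.iloc[i]
        return AccidentRecord(
            record_id=row["record_id"],
            lon=float(row["lon"]),
            lat=float(row["lat"]),
            year=int(row["year"]),
            fatalities=float(row["fatalities"]),
            injuries=float(row["injuries"]),
            factors={name: int(row[name]) for name in self.coding},
        )

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other) -> bool:
        if not isinstance(other, AccidentTable):
            return NotImplemented
        if set(self.coding) != set(other.coding):
            return False
        cols = list(_META_COLUMNS) + self.factor_names
        try:
            pd.testing.assert_frame_equal(
                self.frame[cols], other.frame[cols], check_dtype=False
            )
        except AssertionError:
            return False
        return True

    def subset(self, mask: np.ndarray) -> "AccidentTable":
        return AccidentTable(self.frame[mask], self.coding)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_accident_csv(path, coding: Mapping[str, FactorCoding]) -> AccidentTable:
    """Read and validate an accident-record CSV.

    The header must name the metadata columns and every factor declared in
    ``coding``; rows violating the coding raise :class:`ValidationError`
    with the offending row indices.
    """
    df = pd.read_csv(path)
    return AccidentTable(df, coding)


def write_accident_csv(table: AccidentTable, path) -> str:
    """Write a table to CSV (UTF-8, comma separated, header row) such that
    :func:`read_accident_csv` returns an identical table."""
    cols = list(_META_COLUMNS) + table.factor_names
    table.frame[cols].to_csv(path, index=False)
    return str(path)


def to_geojson(table: AccidentTable, path=None) -> dict:
    """Export records as a GeoJSON FeatureCollection of points; outcomes and
    factor codes ride along as feature properties."""
    features = []
    for _, row in table.frame.iterrows():
        props = {
            "record_id": row["record_id"],
            "year": int(row["year"]),
            "fatalities": float(row["fatalities"]),
            "injuries": float(row["injuries"]),
        }
        props.update({name: int(row[name]) for name in table.coding})
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(row["lon"]), float(row["lat"])],
                },
                "properties": props,
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(collection, fh)
    return collection


# ---------------------------------------------------------------------------
# Group splitting
# ---------------------------------------------------------------------------

class GroupSplit(NamedTuple):
    group1: AccidentTable | None   #: fatal accidents, analysed on fatalities
    group2: AccidentTable | None   #: injury-only accidents, analysed on injuries
    n_excluded: int                #: records with neither fatalities nor injuries


def split_groups(table: AccidentTable) -> GroupSplit:
    """Split into the fatal group and the injuries-only group.

    Group 1 holds accidents with casualties (fatalities > 0) and is analysed
    on the fatalities outcome; group 2 holds accidents with injuries but no
    fatalities, analysed on injuries.  Records with neither are excluded and
    counted.  Empty groups are allowed and returned as ``None``.
    """
    fat = table.frame["fatalities"].to_numpy(dtype=float)
    inj = table.frame["injuries"].to_numpy(dtype=float)
    m1 = fat > 0
    m2 = (fat == 0) & (inj > 0)
    excluded = int((~m1 & ~m2).sum())
    g1 = table.subset(m1) if m1.any() else None
    g2 = table.subset(m2) if m2.any() else None
    return GroupSplit(g1, g2, excluded)


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stratification:
    """Assignment of records to named strata.

    ``index`` holds the positional row indices of the records covered (records
    with a missing factor code are excluded), ``labels`` the stratum label per
    covered record.  A stratification is a partition of its covered records:
    every covered record maps to exactly one stratum and empty strata are
    never retained.
    """

    source: tuple[str, ...]
    index: np.ndarray
    labels: np.ndarray
    strata: tuple[tuple[str, int], ...] = field(init=False)

    def __post_init__(self):
        idx = np.asarray(self.index, dtype=np.intp)
        lab = np.asarray(self.labels, dtype=object)
        if idx.shape != lab.shape:
            raise ValueError("index and labels must align")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("a record may belong to exactly one stratum")
        object.__setattr__(self, "index", idx)
        object.__setattr__(self, "labels", lab)
        uniq, counts = np.unique(lab.astype(str), return_counts=True)
        object.__setattr__(
            self, "strata", tuple(zip(uniq.tolist(), counts.astype(int).tolist()))
        )

    @property
    def n(self) -> int:
        return len(self.index)

    @property
    def n_strata(self) -> int:
        return len(self.strata)


def stratify(table: AccidentTable, factor: str) -> Stratification:
    """Partition the table's records by one factor's observed categories.

    ``"year"`` is accepted alongside the declared factors so that the year of
    occurrence can enter the detectors like any coded factor.  Records with
    the :data:`MISSING` sentinel are excluded from the partition.
    """
    if factor == "year":
        codes = table.frame["year"].to_numpy(dtype=int)
    elif factor in table.coding:
        codes = table.frame[factor].to_numpy(dtype=int)
    else:
        raise KeyError(f"unknown factor {factor!r}")
    keep = codes != MISSING
    idx = np.flatnonzero(keep)
    labels = np.array([f"{factor}={c}" for c in codes[keep]], dtype=object)
    return Stratification(source=(factor,), index=idx, labels=labels)


def stratification_from_labels(labels: Iterable, source: str = "custom") -> Stratification:
    """Build a stratification directly from an array of per-record labels."""
    lab = np.asarray(list(labels), dtype=object)
    return Stratification(source=(source,), index=np.arange(len(lab)), labels=lab)
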