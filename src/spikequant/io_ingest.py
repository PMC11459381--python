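"""Input parsing, validation, and table serialization.

All tables enter and leave the pipeline through this module. Canonical
internal units are liters for volume and copies/L (or cells/L) for
abundances; anything arriving in mL or cells/mL is converted here so the
rest of the pipeline never sees mixed units.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

AVOGADRO = 6.02214076e23
#: mean molar mass of one double-stranded base pair, g/mol (configurable).
BP_MOLAR_MASS_G_PER_MOL = 650.0

_VOLUME_TO_L = {"L": 1.0, "l": 1.0, "mL": 1e-3, "ml": 1e-3}
_FCM_TO_PER_L = {
    "cells_per_L": 1.0,
    "cells_per_mL": 1e3,
    "cells_per_ml": 1e3,
    "cells_per_uL": 1e6,
    "cells_per_ul": 1e6,
}


class InputError(ValueError):
    """Raised for any malformed or invariant-violating input."""


def _require_tz(ts: pd.Timestamp, context: str) -> pd.Timestamp:
    if ts.tzinfo is None:
        raise InputError(f"naive timestamp {ts!r} in {context}; supply a zone "
                         f"(ISO 8601 with offset) or configure default_tz")
    return ts.tz_convert("UTC")


@dataclass(frozen=True)
class SampleRecord:
    """One technical-replicate filter: identity, volume, position, time."""

    sample_id: str
    site_id: str
    replicate: int
    volume_L: float
    lat: float
    lon: float
    timestamp: pd.Timestamp

    def __post_init__(self) -> None:
        if self.volume_L <= 0:
            raise InputError(f"sample {self.sample_id}: volume must be > 0 L, "
                             f"got {self.volume_L}")
        if not -90.0 <= self.lat <= 90.0:
            raise InputError(f"sample {self.sample_id}: latitude out of range "
                             f"({self.lat})")
        if not -180.0 <= self.lon < 180.0:
            raise InputError(f"sample {self.sample_id}: longitude out of range "
                             f"({self.lon})")
        object.__setattr__(self, "timestamp",
                           _require_tz(pd.Timestamp(self.timestamp),
                                       f"sample {self.sample_id}"))


@dataclass
class CountTable:
    """Integer read counts, ASV rows by sample columns."""

    asv_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_asvs, n_samples), int64

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.asv_ids), len(self.sample_ids)):
            raise InputError("count matrix shape does not match id lists")
        for label, ids in (("ASV", self.asv_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise InputError(f"duplicate {label} id: {i!r}")
                seen.add(i)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                bad = np.argwhere(self.counts != np.floor(self.counts))[0]
                raise InputError(
                    f"non-integer count at ASV {self.asv_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise InputError(f"negative count at ASV {self.asv_ids[bad[0]]!r}, "
                             f"sample {self.sample_ids[bad[1]]!r}")
        self._asv_index = {a: i for i, a in enumerate(self.asv_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    def reads(self, asv_id: str, sample_id: str) -> int:
        """Reads for one (ASV, sample); absent ASV counts as 0."""
        i = self._asv_index.get(asv_id)
        if i is None:
            return 0
        return int(self.counts[i, self._sample_index[sample_id]])

    def sample_column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self._sample_index[sample_id]]

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.asv_ids,
                            columns=self.sample_ids)


def read_count_table(path: str | Path, dialect: str = "tsv") -> CountTable:
    """Read an ASV x sample count table (first column ``asv_id``)."""
    path = Path(path)
    sep = {"tsv": "\t", "csv": ","}[dialect]
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(header) < 2:
        raise InputError(f"{path}: no sample columns")
    samples = header[1:]
    dup = {s for s in samples if samples.count(s) > 1}
    if dup:
        raise InputError(f"{path}: duplicated sample column name(s): "
                         f"{sorted(dup)}")
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise InputError(f"{path}: no ASV rows")
    asv_ids = df.iloc[:, 0].tolist()
    mat = np.empty((len(asv_ids), len(samples)), dtype=np.int64)
    for j, col in enumerate(df.columns[1:]):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna())[0])
            raise InputError(f"{path}: non-numeric count at ASV "
                             f"{asv_ids[row]!r}, sample {samples[j]!r}")
        if (vals < 0).any():
            row = int(np.flatnonzero(vals < 0)[0])
            raise InputError(f"{path}: negative count at ASV "
                             f"{asv_ids[row]!r}, sample {samples[j]!r}")
        if not np.all(vals.to_numpy() == np.floor(vals.to_numpy())):
            row = int(np.flatnonzero(vals != np.floor(vals))[0])
            raise InputError(f"{path}: non-integer count at ASV "
                             f"{asv_ids[row]!r}, sample {samples[j]!r}")
        mat[:, j] = vals.astype(np.int64).to_numpy()
    return CountTable(asv_ids=asv_ids, sample_ids=samples, counts=mat)


_META_COLUMNS = ["sample_id", "site_id", "replicate", "volume", "volume_unit",
                 "lat", "lon", "datetime"]


def read_metadata(path: str | Path,
                  default_tz: str | None = None) -> list[SampleRecord]:
    """Read the sample metadata CSV; volumes normalized to liters."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing metadata column(s): {missing}")
    records: list[SampleRecord] = []
    seen_keys: set[tuple[str, int]] = set()
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # header is line 1
        unit = row["volume_unit"]
        if unit not in _VOLUME_TO_L:
            raise InputError(f"{path} row {rowno}: unknown volume unit "
                             f"{unit!r} (expected mL or L)")
        try:
            ts = pd.Timestamp(row["datetime"])
        except (ValueError, TypeError) as exc:
            raise InputError(f"{path} row {rowno}: unparsable timestamp "
                             f"{row['datetime']!r}") from exc
        if ts.tzinfo is None:
            if default_tz is None:
                raise InputError(f"{path} row {rowno}: naive timestamp "
                                 f"{row['datetime']!r} and no default_tz")
            ts = ts.tz_localize(default_tz)
        rec = SampleRecord(
            sample_id=row["sample_id"], site_id=row["site_id"],
            replicate=int(row["replicate"]),
            volume_L=float(row["volume"]) * _VOLUME_TO_L[unit],
            lat=float(row["lat"]), lon=float(row["lon"]), timestamp=ts)
        key = (rec.site_id, rec.replicate)
        if key in seen_keys:
            raise InputError(f"{path} row {rowno}: duplicate "
                             f"(site_id, replicate) = {key}")
        seen_keys.add(key)
        records.append(rec)
    return records


def standard_copy_load(mass_ng: float, genome_size_bp: float,
                       copies_per_genome: float,
                       bp_molar_mass: float = BP_MOLAR_MASS_G_PER_MOL) -> float:
    """16S copies delivered by ``mass_ng`` of genomic DNA.

    mass [g] / (genome_size * bp_molar_mass / N_A) [g/genome] gives genomes,
    times operons per genome gives copies.
    """
    for name, v in (("mass_ng", mass_ng), ("genome_size_bp", genome_size_bp),
                    ("copies_per_genome", copies_per_genome),
                    ("bp_molar_mass", bp_molar_mass)):
        if not (v > 0 and math.isfinite(v)):
            raise InputError(f"standard_copy_load: {name} must be positive, "
                             f"got {v}")
    genomes = mass_ng * 1e-9 * AVOGADRO / (genome_size_bp * bp_molar_mass)
    return genomes * copies_per_genome


@dataclass(frozen=True)
class StandardSpec:
    """One spiked genomic standard and its derived 16S copy load."""

    name: str
    mass_ng: float
    genome_size_bp: float
    copies_per_genome: float
    asv_ids: frozenset[str]
    copies_added: float = None  # type: ignore[assignment]  # derived below

    def __post_init__(self) -> None:
        if self.mass_ng <= 0 or self.genome_size_bp <= 0:
            raise InputError(f"standard {self.name}: mass and genome size "
                             f"must be positive")
        if self.copies_per_genome < 1:
            raise InputError(f"standard {self.name}: copies_per_genome must "
                             f"be >= 1")
        object.__setattr__(self, "asv_ids", frozenset(self.asv_ids))
        if self.copies_added is None:
            object.__setattr__(
                self, "copies_added",
                standard_copy_load(self.mass_ng, self.genome_size_bp,
                                   self.copies_per_genome))
        if not self.copies_added > 0:
            raise InputError(f"standard {self.name}: copies_added must be "
                             f"positive")


def validate_standards(standards: Sequence[StandardSpec]) -> None:
    """Check cross-standard invariants (disjoint ASV id sets)."""
    seen: dict[str, str] = {}
    for std in standards:
        for asv in std.asv_ids:
            if asv in seen:
                raise InputError(
                    f"ASV {asv!r} assigned to both standard "
                    f"{seen[asv]!r} and {std.name!r}")
            seen[asv] = std.name


def read_standards(path: str | Path) -> list[StandardSpec]:
    """Read the standards YAML/JSON list."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise InputError(f"{path}: expected a non-empty list of standards")
    standards = [
        StandardSpec(name=d["name"], mass_ng=float(d["mass_ng"]),
                     genome_size_bp=float(d["genome_size_bp"]),
                     copies_per_genome=float(d["copies_per_genome"]),
                     asv_ids=frozenset(d["asv_ids"]))
        for d in raw
    ]
    validate_standards(standards)
    return standards


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read ``asv_id<TAB>taxonomy_string`` (optional header row)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"{path}: expected 2 tab-separated columns, "
                                 f"got {line!r}")
            if parts[0] == "asv_id":
                continue
            if parts[0] in out:
                raise InputError(f"{path}: duplicate ASV id {parts[0]!r}")
            out[parts[0]] = parts[1]
    return out


def read_copy_map(path: str | Path) -> dict[str, float]:
    """Read taxon -> 16S copies-per-cell YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise InputError(f"{path}: expected a mapping taxon -> copies per cell")
    out = {}
    for taxon, v in raw.items():
        v = float(v)
        if v < 1:
            raise InputError(f"{path}: copy number for {taxon!r} must be >= 1")
        out[str(taxon)] = v
    return out


@dataclass
class FcmObservation:
    """One flow-cytometry sampling event for one population."""

    event_id: str
    timestamp: pd.Timestamp
    lat: float
    lon: float
    population: str
    replicate_counts: list[float]  # cells per liter

    def __post_init__(self) -> None:
        if not self.replicate_counts:
            raise InputError(f"FCM event {self.event_id}: empty replicates")
        if any(c < 0 for c in self.replicate_counts):
            raise InputError(f"FCM event {self.event_id}: negative count")
        self.timestamp = _require_tz(pd.Timestamp(self.timestamp),
                                     f"FCM event {self.event_id}")

    @property
    def mean_count(self) -> float:
        return float(np.mean(self.replicate_counts))

    @property
    def range(self) -> tuple[float, float]:
        return (float(min(self.replicate_counts)),
                float(max(self.replicate_counts)))


def read_fcm(path: str | Path,
             default_tz: str | None = None) -> list[FcmObservation]:
    """Read the long-format FCM CSV; abundances converted to cells/L."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = ["event_id", "datetime", "lat", "lon", "population",
                "replicate", "abundance", "abundance_unit"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing FCM column(s): {missing}")
    obs: list[FcmObservation] = []
    for (event_id, pop), grp in df.groupby(["event_id", "population"],
                                           sort=True):
        grp = grp.sort_values("replicate", key=lambda s: s.astype(int))
        counts = []
        for _, row in grp.iterrows():
            unit = row["abundance_unit"]
            if unit not in _FCM_TO_PER_L:
                raise InputError(f"{path}: unknown FCM abundance unit "
                                 f"{unit!r}")
            counts.append(float(row["abundance"]) * _FCM_TO_PER_L[unit])
        first = grp.iloc[0]
        ts = pd.Timestamp(first["datetime"])
        if ts.tzinfo is None:
            if default_tz is None:
                raise InputError(f"{path}: naive timestamp for event "
                                 f"{event_id!r} and no default_tz")
            ts = ts.tz_localize(default_tz)
        obs.append(FcmObservation(
            event_id=str(event_id), timestamp=ts, lat=float(first["lat"]),
            lon=float(first["lon"]), population=str(pop),
            replicate_counts=counts))
    return obs


# ---------------------------------------------------------------------------
# abundance-matrix serialization

_FLOAT_FMT = "%.12g"


def _slot_col(rep: int, std: str) -> str:
    return f"r{rep}:{std}"


def write_abundance_table(matrix, path: str | Path) -> None:
    """Write an AbundanceMatrix as TSV, one row per (site, ASV).

    Columns: site identity and position, mean/min/max/n, then one column per
    (replicate, standard) slot in the matrix's stable slot order (``NA`` where
    an estimate was dropped). Values round-trip at 12 significant digits.
    """
    path = Path(path)
    slot_cols = [_slot_col(r, s) for r, s in matrix.slot_order]
    header = ["site_id", "asv_id", "site_lat", "site_lon", "site_time",
              "mean", "min", "max", "n_estimates"] + slot_cols
    lines = ["\t".join(header)]
    for es in matrix.sets.values():
        info = matrix.site_info.get(es.site_id)
        lat, lon, time = ("NA", "NA", "NA")
        if info is not None:
            lat = _FLOAT_FMT % info[0]
            lon = _FLOAT_FMT % info[1]
            time = pd.Timestamp(info[2]).isoformat()
        by_slot = {(r, s): v for r, s, v in es.estimates}
        row = [es.site_id, es.asv_id, lat, lon, time,
               _FLOAT_FMT % es.mean, _FLOAT_FMT % es.min,
               _FLOAT_FMT % es.max, str(es.n)]
        for key in matrix.slot_order:
            v = by_slot.get(key)
            row.append("NA" if v is None else _FLOAT_FMT % v)
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_abundance_table(path: str | Path):
    """Re-read a table written by :func:`write_abundance_table`."""
    from .quantify import AbundanceMatrix, EstimateSet  # lazy: avoid cycle

    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        fixed = ["site_id", "asv_id", "site_lat", "site_lon", "site_time",
                 "mean", "min", "max", "n_estimates"]
        if header[:len(fixed)] != fixed:
            raise InputError(f"{path}: not an abundance table")
        slot_order = []
        for col in header[len(fixed):]:
            rep_s, std = col.split(":", 1)
            slot_order.append((int(rep_s[1:]), std))
        sets: dict[tuple[str, str], EstimateSet] = {}
        site_info: dict[str, tuple[float, float, pd.Timestamp]] = {}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            site, asv = parts[0], parts[1]
            if parts[2] != "NA":
                site_info[site] = (float(parts[2]), float(parts[3]),
                                   pd.Timestamp(parts[4]))
            ests = []
            for key, raw in zip(slot_order, parts[len(fixed):]):
                if raw != "NA":
                    ests.append((key[0], key[1], float(raw)))
            sets[(site, asv)] = EstimateSet.from_estimates(site, asv, ests)
    return AbundanceMatrix(sets=sets, slot_order=slot_order,
                           site_info=site_info)
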