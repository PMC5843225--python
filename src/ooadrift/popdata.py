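"""Domain types and tabular I/O for the population-genetic analysis.

The central container is :class:`PopulationTable`: one row per population,
carrying its cumulative Out-of-Africa migratory distance (km) and the allele
proportion of each SNP marker.  A bundled fixture transcribes the nine
SIRPB1-region markers for the 43 populations printed in the source allele
frequency table; it is the input for every desk-scale reproduction in this
package.

Frequencies may be printed with decimal commas ("0,75"); readers accept both
"," and "." decimals.  Missing values are encoded with the explicit token
``NA`` and are dropped per-model (complete-case) downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeoPoint",
    "PopulationRecord",
    "PopulationTable",
    "DriftDistanceMatrix",
    "GenotypeTable",
    "CtRecord",
    "read_population_table",
    "write_population_table",
    "read_drift_matrix",
    "write_drift_matrix",
    "read_genotype_table",
    "read_ct_records",
    "table1_fixture",
    "TABLE1_MARKERS",
]

#: Marker order of the bundled allele-frequency fixture.
TABLE1_MARKERS = (
    "rs2263664", "rs2253698", "rs2746603", "rs6074896", "rs2209313",
    "rs1535882", "rs11696842", "rs6105421", "rs4814391",
)

_NA_TOKENS = {"NA", "na", "NaN", "nan", ""}


@dataclass(frozen=True)
class GeoPoint:
    """A geographic coordinate in decimal degrees.

    lat must lie in [-90, 90], lon in (-180, 180].
    """

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 < self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside (-180, 180]")


@dataclass(frozen=True)
class PopulationRecord:
    """One population: name, migratory distance (km), marker allele proportions."""

    name: str
    distance_km: float
    freqs: Mapping[str, float]
    coords: GeoPoint | None = None

    def __post_init__(self) -> None:
        if self.distance_km < 0:
            raise ValueError(f"{self.name}: negative migratory distance")
        for marker, p in self.freqs.items():
            if not math.isnan(p) and not (0.0 <= p <= 1.0):
                raise ValueError(
                    f"{self.name}/{marker}: allele proportion {p} outside [0, 1]"
                )


@dataclass(frozen=True)
class PopulationTable:
    """Ordered collection of :class:`PopulationRecord` over a shared marker list."""

    records: tuple[PopulationRecord, ...]
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        for r in self.records:
            missing = set(self.markers) - set(r.freqs)
            if missing:
                raise ValueError(f"{r.name}: no value for markers {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.records)

    @property
    def distances_km(self) -> np.ndarray:
        return np.array([r.distance_km for r in self.records], dtype=float)

    def frequencies(self, marker: str) -> np.ndarray:
        """Allele proportions for one marker (NaN where missing)."""
        if marker not in self.markers:
            raise KeyError(f"unknown marker {marker!r}")
        return np.array([r.freqs[marker] for r in self.records], dtype=float)

    def record(self, name: str) -> PopulationRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def complemented(self, markers: Iterable[str]) -> "PopulationTable":
        """Return a table with p -> 1 - p for the given markers.

        Allele proportions are orientation conventions: a table may count
        either allele of a biallelic SNP.  Complementing re-expresses a
        marker in the opposite allele; on the arcsine-sqrt scale this is the
        exact reflection arcsin(sqrt(1-p)) = pi/2 - arcsin(sqrt(p)), so a
        regression slope flips sign with unchanged magnitude.
        """
        flip = set(markers)
        unknown = flip - set(self.markers)
        if unknown:
            raise KeyError(f"unknown markers {sorted(unknown)}")
        new_records = tuple(
            replace(
                r,
                freqs={
                    m: (1.0 - p if m in flip and not math.isnan(p) else p)
                    for m, p in r.freqs.items()
                },
            )
            for r in self.records
        )
        return PopulationTable(records=new_records, markers=self.markers)

    def to_dataframe(self) -> pd.DataFrame:
        data: dict[str, list] = {
            "population": list(self.names),
            "distance_km": [r.distance_km for r in self.records],
        }
        if any(r.coords is not None for r in self.records):
            data["lat"] = [r.coords.lat if r.coords else np.nan for r in self.records]
            data["lon"] = [r.coords.lon if r.coords else np.nan for r in self.records]
        for m in self.markers:
            data[m] = [r.freqs[m] for r in self.records]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class DriftDistanceMatrix:
    """Symmetric microsatellite-based genetic distance matrix D^2 (zero diagonal)."""

    labels: tuple[str, ...]
    D2: np.ndarray

    def __post_init__(self) -> None:
        D2 = np.asarray(self.D2, dtype=float)
        object.__setattr__(self, "D2", D2)
        n = len(self.labels)
        if D2.shape != (n, n):
            raise ValueError(f"matrix shape {D2.shape} does not match {n} labels")
        if np.any(D2 < 0):
            raise ValueError("negative genetic distances")
        if np.max(np.abs(D2 - D2.T)) > 1e-9:
            raise ValueError("genetic distance matrix is asymmetric beyond 1e-9")
        if np.any(np.diag(D2) != 0.0):
            raise ValueError("genetic distance matrix has nonzero diagonal")

    def reorder(self, labels: Sequence[str]) -> "DriftDistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DriftDistanceMatrix(tuple(labels), self.D2[np.ix_(idx, idx)])


@dataclass(frozen=True)
class GenotypeTable:
    """Unphased two-locus genotypes: a CNV locus (Sin/Dup) and a SNP locus (C/T).

    Each subject is a pair of unordered allele pairs, e.g.
    ``(("Sin", "Dup"), ("C", "T"))`` for the double heterozygote.
    """

    subjects: tuple[tuple[tuple[str, str], tuple[str, str]], ...]
    alleles_a: tuple[str, str] = ("Sin", "Dup")
    alleles_b: tuple[str, str] = ("C", "T")

    def __post_init__(self) -> None:
        if len(self.subjects) < 1:
            raise ValueError("genotype table needs at least one subject")
        sa, sb = set(self.alleles_a), set(self.alleles_b)
        for i, (ga, gb) in enumerate(self.subjects):
            if not set(ga) <= sa:
                raise ValueError(f"subject {i}: locus-A alleles {ga} not in {sorted(sa)}")
            if not set(gb) <= sb:
                raise ValueError(f"subject {i}: locus-B alleles {gb} not in {sorted(sb)}")

    def __len__(self) -> int:
        return len(self.subjects)

    def genotype_counts(self) -> np.ndarray:
        """3x3 count table indexed by copies of alleles_a[1] and alleles_b[1]."""
        counts = np.zeros((3, 3), dtype=int)
        for ga, gb in self.subjects:
            i = sum(a == self.alleles_a[1] for a in ga)
            j = sum(b == self.alleles_b[1] for b in gb)
            counts[i, j] += 1
        return counts


@dataclass(frozen=True)
class CtRecord:
    """qPCR threshold cycles of one amplicon, per allele, over replicates."""

    sample: str
    role: str  # "control" | "sensor"
    ct_c: tuple[float, ...]
    ct_t: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.role not in ("control", "sensor"):
            raise ValueError(f"amplicon role {self.role!r} not control/sensor")
        if len(self.ct_c) < 1 or len(self.ct_t) < 1:
            raise ValueError("need at least one Ct replicate per allele")
        if any(c <= 0 for c in self.ct_c + self.ct_t):
            raise ValueError("Ct values must be positive")


def _parse_number(token: str, row: str, column: str) -> float:
    token = token.strip()
    if token in _NA_TOKENS:
        return math.nan
    try:
        return float(token.replace(",", "."))
    except ValueError as exc:
        raise ValueError(f"malformed number {token!r} at row {row!r}, column {column!r}") from exc


def read_population_table(path) -> PopulationTable:
    """Read a population table from TSV.

    Expected header: ``population  distance_km  <marker1> ...`` with optional
    ``lat``/``lon`` columns.  Decimal commas are accepted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"population", "distance_km"}
    if not required <= set(df.columns):
        raise ValueError(f"missing required columns {sorted(required - set(df.columns))}")
    if len(df) == 0:
        raise ValueError("no records")
    has_coords = {"lat", "lon"} <= set(df.columns)
    markers = tuple(c for c in df.columns if c not in ("population", "distance_km", "lat", "lon"))
    records = []
    for _, row in df.iterrows():
        name = row["population"]
        dist = _parse_number(row["distance_km"], name, "distance_km")
        freqs = {m: _parse_number(row[m], name, m) for m in markers}
        coords = None
        if has_coords:
            lat = _parse_number(row["lat"], name, "lat")
            lon = _parse_number(row["lon"], name, "lon")
            if not (math.isnan(lat) or math.isnan(lon)):
                coords = GeoPoint(lat, lon)
        records.append(PopulationRecord(name, dist, freqs, coords))
    return PopulationTable(tuple(records), markers)


def write_population_table(table: PopulationTable, path) -> None:
    """Write a population table to TSV ("." decimals, NA for missing)."""
    df = table.to_dataframe()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_drift_matrix(path) -> DriftDistanceMatrix:
    """Read a square labelled genetic-distance matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("row labels do not match column labels")
    return DriftDistanceMatrix(tuple(str(l) for l in df.index), df.to_numpy(dtype=float))


def write_drift_matrix(mat: DriftDistanceMatrix, path) -> None:
    pd.DataFrame(mat.D2, index=list(mat.labels), columns=list(mat.labels)).to_csv(path, sep="\t")


def _parse_genotype(token: str) -> tuple[str, str]:
    parts = token.strip().split("/")
    if len(parts) != 2:
        raise ValueError(f"genotype {token!r} is not of the form allele/allele")
    return (parts[0], parts[1])


def read_genotype_table(path) -> GenotypeTable:
    """Read two-locus genotypes from TSV with header ``subject  locusA  locusB``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    subjects = tuple(
        (_parse_genotype(row["locusA"]), _parse_genotype(row["locusB"]))
        for _, row in df.iterrows()
    )
    return GenotypeTable(subjects)


def read_ct_records(path) -> list[CtRecord]:
    """Read replicate Ct values from TSV.

    Header: ``sample  role  allele  ct`` with one row per replicate
    measurement; allele is C or T.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "role": str, "allele": str, "ct": float})
    records = []
    for (sample, role), grp in df.groupby(["sample", "role"], sort=False):
        ct_c = tuple(grp.loc[grp["allele"] == "C", "ct"])
        ct_t = tuple(grp.loc[grp["allele"] == "T", "ct"])
        records.append(CtRecord(sample, role, ct_c, ct_t))
    return records


def table1_fixture() -> PopulationTable:
    """The bundled allele-frequency table: 43 populations, 9 SIRPB1-region SNPs.

    Frequencies are stored exactly as printed (two decimals); the counted
    allele per marker is the printing convention of the source table, see
    :meth:`PopulationTable.complemented` for re-orientation.
    """
    ref = resources.files("ooadrift.data").joinpath("table1.tsv")
    with resources.as_file(ref) as path:
        table = read_population_table(path)
    assert table.markers == TABLE1_MARKERS
    return table
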