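"""Readers and writers for the tabular and raster formats used by the pipeline.

Genotypes travel as Genepop files, counts/life tables/biomass/occurrences as
headed CSV, and environmental rasters as year-stamped ESRI ASCII grids.
All pairs round-trip losslessly on valid input.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("codmix")

MISSING = np.nan


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Individuals x biallelic loci, calls coded as reference-allele dosage.

    ``calls[i, j]`` is 0, 1 or 2 (count of the reference allele) or NaN for
    missing. ``group_labels`` is present for baseline samples and ``None``
    for mixed-stock samples.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    group_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.individual_ids), len(self.locus_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.locus_ids)} loci"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicated individual id")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicated locus id")
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid call {self.calls[tuple(bad)]} for individual "
                f"{self.individual_ids[bad[0]]} at locus {self.locus_ids[bad[1]]}"
            )
        if self.group_labels is not None and len(self.group_labels) != len(
            self.individual_ids
        ):
            raise ValueError("group_labels must cover all individuals")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        idx = [self.locus_ids.index(l) for l in loci]
        return GenotypeTable(
            individual_ids=list(self.individual_ids),
            locus_ids=list(loci),
            calls=self.calls[:, idx].copy(),
            group_labels=None if self.group_labels is None else list(self.group_labels),
        )


@dataclass
class CatchCountTable:
    """Assigned-individual counts per (year, stratum) for K populations."""

    times: np.ndarray  # decimal years, one per record
    strata: list[str]
    populations: list[str]  # K labels
    counts: np.ndarray  # (n_records, K) non-negative ints

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.times), len(self.populations)):
            raise ValueError("counts shape mismatch")
        if len(self.strata) != len(self.times):
            raise ValueError("strata length mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative count")

    @property
    def totals(self) -> np.ndarray:
        """N_i per record."""
        return self.counts.sum(axis=1)

    def aggregate_by_time(self) -> "CatchCountTable":
        """Pool all strata, returning one record per unique time."""
        times = np.unique(self.times)
        counts = np.vstack(
            [self.counts[self.times == t].sum(axis=0) for t in times]
        )
        return CatchCountTable(
            times=times,
            strata=["pooled"] * len(times),
            populations=list(self.populations),
            counts=counts,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.populations)
        df.insert(0, "stratum", self.strata)
        df.insert(0, "year", self.times)
        return df


@dataclass
class LifeTable:
    """Age-structured schedules driving per-recruit computations."""

    ages: np.ndarray  # consecutive integers
    M: np.ndarray  # natural mortality per year
    s: np.ndarray  # relative fishing pattern (dimensionless)
    w: np.ndarray  # weight-at-age, kg
    m: np.ndarray  # maturity-at-age in [0, 1]

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        for name in ("M", "s", "w", "m"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.ages)
        if not all(len(getattr(self, k)) == n for k in ("M", "s", "w", "m")):
            raise ValueError("all schedules must match the number of ages")
        if not np.array_equal(self.ages, np.arange(self.ages[0], self.ages[0] + n)):
            raise ValueError("ages must be consecutive integers")
        if (self.M < 0).any():
            raise ValueError("natural mortality must be >= 0")
        if (self.w <= 0).any():
            raise ValueError("weight-at-age must be > 0")
        if ((self.m < 0) | (self.m > 1)).any():
            raise ValueError("maturity-at-age must lie in [0, 1]")

    @property
    def n_ages(self) -> int:
        return len(self.ages)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "M": self.M, "s": self.s, "w": self.w, "m": self.m}
        )


@dataclass
class GridSeries:
    """Yearly scalar fields on a shared land/sea mask (sea=True)."""

    years: list[int]
    mask: np.ndarray  # bool, True on sea
    cell_size_km: float
    layers: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        for year, layer in self.layers.items():
            layer = np.asarray(layer, dtype=float)
            if layer.shape != self.mask.shape:
                raise ValueError(f"layer {year} shape does not match mask")
            self.layers[year] = layer
        missing = set(self.years) - set(self.layers)
        if missing:
            raise ValueError(f"missing layers for years {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def sea_values(self, year: int) -> np.ndarray:
        return self.layers[year][self.mask]

    def map_layers(self, fn) -> "GridSeries":
        """Apply ``fn`` to each layer's sea cells, keeping land as NaN."""
        out: dict[int, np.ndarray] = {}
        for year in self.years:
            layer = np.full(self.shape, np.nan)
            layer[self.mask] = fn(self.layers[year][self.mask])
            out[year] = layer
        return GridSeries(
            years=list(self.years),
            mask=self.mask.copy(),
            cell_size_km=self.cell_size_km,
            layers=out,
        )


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------


def _split_genepop_alleles(code: str, locus: str) -> tuple[int, int]:
    if len(code) == 4:
        a, b = int(code[:2]), int(code[2:])
    elif len(code) == 6:
        a, b = int(code[:3]), int(code[3:])
    else:
        raise FormatError(f"malformed genotype code '{code}' at locus {locus}")
    return a, b


def read_genepop(path: str | Path) -> GenotypeTable:
    """Parse a Genepop 4.x file of biallelic loci into a GenotypeTable.

    POP blocks become group labels (named after the last individual id of
    the block, the usual Genepop convention, unless ids carry an explicit
    ``label_xxx`` prefix in which case the prefix wins). Allele 1 is the
    reference allele; ``0`` codes missing. More than two distinct alleles
    at a locus is a format error naming the locus.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError("empty genepop file")
    # first line is a title comment
    body = [ln.strip() for ln in lines[1:]]
    locus_ids: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        chunk = body[i].strip()
        if chunk:
            # loci may be comma-separated on one line or one per line
            locus_ids.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if i == len(body):
        raise FormatError("no POP block found")
    individual_ids: list[str] = []
    group_labels: list[str] = []
    rows: list[list[float]] = []
    blocks: list[list[int]] = []  # row indices per pop block
    current: list[int] = []
    alleles_seen: list[set[int]] = [set() for _ in locus_ids]
    while i < len(body):
        line = body[i].strip()
        i += 1
        if not line:
            continue
        if line.lower() == "pop":
            if current:
                blocks.append(current)
            current = []
            continue
        if "," not in line:
            raise FormatError(f"malformed individual line: '{line}'")
        ind_id, geno = line.split(",", 1)
        ind_id = ind_id.strip()
        codes = geno.split()
        if len(codes) != len(locus_ids):
            raise FormatError(
                f"individual {ind_id} has {len(codes)} genotypes, "
                f"expected {len(locus_ids)}"
            )
        row: list[float] = []
        for j, code in enumerate(codes):
            a, b = _split_genepop_alleles(code, locus_ids[j])
            if a == 0 or b == 0:
                row.append(MISSING)
                continue
            for allele in (a, b):
                alleles_seen[j].add(allele)
                if allele not in (1, 2):
                    raise FormatError(
                        f"allele code {allele} at biallelic locus {locus_ids[j]}"
                    )
            row.append(float((a == 1) + (b == 1)))
        if ind_id in individual_ids:
            raise FormatError(f"duplicated individual id '{ind_id}'")
        individual_ids.append(ind_id)
        current.append(len(rows))
        rows.append(row)
    if current:
        blocks.append(current)
    for j, seen in enumerate(alleles_seen):
        if len(seen) > 2:
            raise FormatError(f">2 alleles at locus {locus_ids[j]}")
    group_labels = [""] * len(individual_ids)
    for block in blocks:
        last_id = individual_ids[block[-1]]
        label = last_id.split("_")[0] if "_" in last_id else last_id
        for r in block:
            group_labels[r] = label
    return GenotypeTable(
        individual_ids=individual_ids,
        locus_ids=locus_ids,
        calls=np.array(rows, dtype=float),
        group_labels=group_labels,
    )


def write_genepop(table: GenotypeTable, path: str | Path, title: str = "codmix") -> None:
    """Write a GenotypeTable as a Genepop file with 2-digit allele codes.

    Reference-allele dosage d becomes d copies of allele 01 and 2-d copies
    of allele 02; missing becomes 0000. Individuals are grouped into POP
    blocks by group label (a single block when labels are absent) and ids
    are prefixed with ``<label>_`` so labels survive the round trip.
    """
    labels = table.group_labels or ["mixed"] * table.n_individuals
    out = [title]
    out.extend(table.locus_ids)
    order: dict[str, list[int]] = {}
    for idx, lab in enumerate(labels):
        order.setdefault(lab, []).append(idx)
    for lab, idxs in order.items():
        out.append("pop")
        for idx in idxs:
            codes = []
            for call in table.calls[idx]:
                if np.isnan(call):
                    codes.append("0000")
                else:
                    d = int(call)
                    codes.append({0: "0202", 1: "0102", 2: "0101"}[d])
            ind = table.individual_ids[idx]
            name = ind if ind.startswith(f"{lab}_") else f"{lab}_{ind}"
            out.append(f"{name} ,  " + " ".join(codes))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "catch_counts": None,  # year, stratum, then one column per population
    "life_table": ["age", "M", "s", "w", "m"],
    "biomass_series": ["year", "biomass"],
    "occurrences": None,  # year, presence (+cell/lon-lat, predictors, label)
}


def read_table(path: str | Path, schema: str):
    """Read a delimited table under one of the documented schemas.

    Returns a :class:`CatchCountTable`, :class:`LifeTable`,
    ``pandas.Series`` (year-indexed biomass) or occurrence
    ``pandas.DataFrame`` depending on ``schema``.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema '{schema}'")
    df = pd.read_csv(path, sep=None, engine="python")
    if schema == "catch_counts":
        required = {"year", "stratum"}
        if not required <= set(df.columns):
            raise FormatError(f"catch_counts requires columns {sorted(required)}")
        pops = [c for c in df.columns if c not in ("year", "stratum")]
        if not pops:
            raise FormatError("catch_counts requires at least one population column")
        counts = df[pops].to_numpy()
        if not np.issubdtype(counts.dtype, np.number):
            raise FormatError("non-numeric count cell")
        if not np.allclose(counts, np.round(counts)):
            raise FormatError("counts must be integers")
        return CatchCountTable(
            times=df["year"].to_numpy(dtype=float),
            strata=[str(s) for s in df["stratum"]],
            populations=pops,
            counts=counts.astype(int),
        )
    if schema == "life_table":
        cols = _SCHEMAS["life_table"]
        missing = set(cols) - set(df.columns)
        if missing:
            raise FormatError(f"life_table missing columns {sorted(missing)}")
        for c in cols:
            if not np.issubdtype(df[c].dtype, np.number):
                raise FormatError(f"non-numeric cell in column '{c}'")
        if ((df["m"] < 0) | (df["m"] > 1)).any():
            raise FormatError("maturity outside [0, 1]")
        return LifeTable(
            ages=df["age"].to_numpy(),
            M=df["M"].to_numpy(),
            s=df["s"].to_numpy(),
            w=df["w"].to_numpy(),
            m=df["m"].to_numpy(),
        )
    if schema == "biomass_series":
        missing = {"year", "biomass"} - set(df.columns)
        if missing:
            raise FormatError(f"biomass_series missing columns {sorted(missing)}")
        if not np.issubdtype(df["biomass"].dtype, np.number):
            raise FormatError("non-numeric biomass cell")
        return pd.Series(
            df["biomass"].to_numpy(dtype=float),
            index=df["year"].to_numpy(dtype=float),
            name="biomass",
        )
    # occurrences
    missing = {"year", "presence"} - set(df.columns)
    if missing:
        raise FormatError(f"occurrences missing columns {sorted(missing)}")
    if not set(df["presence"].unique()) <= {0, 1}:
        raise FormatError("presence must be binary")
    return df


def write_table(obj, path: str | Path, schema: str) -> None:
    """Inverse of :func:`read_table` for the typed schemas."""
    if schema == "catch_counts":
        obj.to_frame().to_csv(path, index=False)
    elif schema == "life_table":
        obj.to_frame().to_csv(path, index=False)
    elif schema == "biomass_series":
        pd.DataFrame({"year": obj.index, "biomass": obj.to_numpy()}).to_csv(
            path, index=False
        )
    elif schema == "occurrences":
        obj.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown schema '{schema}'")


# ---------------------------------------------------------------------------
# ESRI ASCII grids
# ---------------------------------------------------------------------------

_YEAR_RE = re.compile(r"(\d{4})")


def _read_asc(path: Path) -> tuple[dict, np.ndarray]:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in (
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "cellsize",
                "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
    data = np.array(rows, dtype=float)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise FormatError(
            f"{path.name}: data shape {data.shape} disagrees with header"
        )
    return header, data


def read_grid_series(path: str | Path) -> GridSeries:
    """Read year-stamped ESRI ASCII grids (one file per year, or one file).

    NODATA cells become the land mask; the year is parsed from each file
    name. All headers must agree across years.
    """
    p = Path(path)
    files = sorted(p.glob("*.asc")) if p.is_dir() else [p]
    if not files:
        raise FormatError(f"no .asc files under {p}")
    ref_header = None
    years: list[int] = []
    layers: dict[int, np.ndarray] = {}
    mask = None
    for f in files:
        m = _YEAR_RE.search(f.stem)
        if not m:
            raise FormatError(f"cannot parse year from file name '{f.name}'")
        year = int(m.group(1))
        header, data = _read_asc(f)
        if ref_header is None:
            ref_header = header
        elif any(header.get(k) != ref_header.get(k) for k in ref_header):
            raise FormatError(f"inconsistent grid header in {f.name}")
        nodata = header.get("nodata_value", -9999.0)
        sea = data != nodata
        if mask is None:
            mask = sea
        else:
            mask = mask & sea
        layer = np.where(sea, data, np.nan)
        years.append(year)
        layers[year] = layer
    cell_km = ref_header.get("cellsize", 1.0)
    return GridSeries(years=years, mask=mask, cell_size_km=cell_km, layers=layers)


def write_grid_series(series: GridSeries, directory: str | Path, nodata: float = -9999.0) -> None:
    """Write one ``<year>.asc`` ESRI ASCII grid per year."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    nrows, ncols = series.shape
    header = (
        f"ncols {ncols}\nnrows {nrows}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize {series.cell_size_km}\nNODATA_value {nodata}\n"
    )
    for year in series.years:
        layer = series.layers[year]
        out = np.where(series.mask & ~np.isnan(layer), layer, nodata)
        body = "\n".join(" ".join(f"{v:.10g}" for v in row) for row in out)
        (d / f"{year}.asc").write_text(header + body + "\n")
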