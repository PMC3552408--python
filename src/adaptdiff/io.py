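"""Readers and writers for the formats the pipeline touches.

Genotypes travel either as GenePop files (the de-facto standard for
microsatellite data; 2- and 3-digit allele encodings both accepted, 00/000
missing) or as plain CSV.  Distance matrices are square labelled CSV or
PHYLIP square format.  Trait, environment and pot-level fitness tables are
CSV with a header row.  Geographic distances are great-circle (haversine)
on the WGS84 sphere, in km.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DistanceMatrix,
    GenotypeTable,
    PairExperiment,
    SiteEnvironment,
    TraitTable,
    ValidationError,
    POT_COLUMNS,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_traits",
    "write_traits",
    "read_environment",
    "write_environment",
    "read_pair_experiments",
    "write_pair_experiments",
    "geographic_distances",
    "haversine_km",
]

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


class ParseError(ValueError):
    """A file does not parse under the named dialect."""


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _split_genepop_allele(token: str, line_no: int) -> tuple[int, int]:
    token = token.strip()
    if len(token) == 4:
        a, b = int(token[:2]), int(token[2:])
    elif len(token) == 6:
        a, b = int(token[:3]), int(token[3:])
    else:
        raise ParseError(f"line {line_no}: allele token {token!r} is not 4 or 6 digits")
    return a, b


def _read_genepop(path: Path) -> GenotypeTable:
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: too short for a GenePop file")
    # line 1 is a free title; locus names follow, one per line or comma-separated
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        part = lines[i].strip()
        if part:
            loci.extend(x.strip() for x in part.split(",") if x.strip())
        i += 1
    if not loci:
        raise ParseError(f"{path}: no locus names before first 'pop'")
    individuals: list[str] = []
    populations: list[str] = []
    alleles: list[list[tuple[int, int]]] = []
    pop_label = None
    pop_count = 0
    for line_no, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_count += 1
            pop_label = None
            continue
        if pop_count == 0:
            raise ParseError(f"line {line_no}: individual before first 'pop'")
        if "," not in line:
            raise ParseError(f"line {line_no}: expected 'id , alleles'")
        ident, geno = line.split(",", 1)
        ident = ident.strip()
        # our writer encodes the population label as 'pop:individual'
        if ":" in ident:
            pop_name, ident = ident.split(":", 1)
        else:
            pop_name = f"pop_{pop_count}"
        if pop_label is None:
            pop_label = pop_name
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise ParseError(
                f"line {line_no}: {len(tokens)} genotype fields for {len(loci)} loci"
            )
        row = [_split_genepop_allele(t, line_no) for t in tokens]
        individuals.append(ident)
        populations.append(pop_label)
        alleles.append(row)
    if not individuals:
        raise ParseError(f"{path}: no individuals")
    return GenotypeTable(
        individuals=individuals,
        populations=np.array(populations, dtype=object),
        loci=loci,
        alleles=np.array(alleles, dtype=np.int64),
    )


def _read_genotype_csv(path: Path) -> GenotypeTable:
    df = pd.read_csv(path, dtype=str).fillna("")
    for col in ("individual_id", "population"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    loci = [c for c in df.columns if c not in ("individual_id", "population")]
    if not loci:
        raise ParseError(f"{path}: no locus columns")
    n = len(df)
    alleles = np.zeros((n, len(loci), 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        for i, cell in enumerate(df[locus]):
            cell = cell.strip()
            if cell in ("", "0/0", "./."):
                continue
            if "/" not in cell:
                raise ParseError(f"{path}: row {i + 2}, locus {locus!r}: expected 'a/b'")
            a, b = cell.split("/", 1)
            alleles[i, j] = (int(a), int(b))
    return GenotypeTable(
        individuals=list(df["individual_id"]),
        populations=df["population"].to_numpy(dtype=object),
        loci=loci,
        alleles=alleles,
    )


def read_genotypes(path: str | Path, dialect: str = "genepop") -> GenotypeTable:
    """Read a genotype table (``dialect`` 'genepop' or 'csv')."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "genepop":
        return _read_genepop(path)
    if dialect == "csv":
        return _read_genotype_csv(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def write_genotypes(table: GenotypeTable, path: str | Path, dialect: str = "genepop") -> None:
    path = Path(path)
    if dialect == "genepop":
        digits = 3 if table.alleles.max(initial=0) > 99 else 2
        out = ["adaptdiff genotype export"]
        out.extend(table.loci)
        for pop in table.population_labels:
            out.append("pop")
            for i in table.population_indices(pop):
                cells = " ".join(
                    f"{a:0{digits}d}{b:0{digits}d}" for a, b in table.alleles[i]
                )
                out.append(f"{pop}:{table.individuals[i]} , {cells}")
        path.write_text("\n".join(out) + "\n")
    elif dialect == "csv":
        cols = {"individual_id": table.individuals, "population": list(table.populations)}
        for j, locus in enumerate(table.loci):
            cells = []
            for a, b in table.alleles[:, j]:
                cells.append("" if a == 0 else f"{a}/{b}")
            cols[locus] = cells
        pd.DataFrame(cols).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


def read_distance_matrix(path: str | Path, kind: str = "custom", fmt: str | None = None) -> DistanceMatrix:
    """Read a square labelled CSV or PHYLIP square distance matrix.

    The format is auto-detected (PHYLIP files start with the site count)
    unless ``fmt`` names one explicitly.  Asymmetry beyond 1e-9 and nonzero
    diagonals are rejected.
    """
    path = Path(path)
    if fmt is None:
        first = path.read_text().splitlines()[0].strip()
        fmt = "phylip" if first.isdigit() else "csv"
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        labels = [str(x) for x in df.index]
        if [str(c) for c in df.columns] != labels:
            raise ValidationError(f"{path}: row and column labels differ (non-square?)")
        values = df.to_numpy(dtype=float)
    elif fmt == "phylip":
        lines = [l for l in path.read_text().splitlines() if l.strip()]
        n = int(lines[0])
        if len(lines) != n + 1:
            raise ValidationError(f"{path}: expected {n} rows, found {len(lines) - 1}")
        labels, rows = [], []
        for line in lines[1:]:
            parts = line.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        values = np.array(rows, dtype=float)
        if values.shape != (n, n):
            raise ValidationError(f"{path}: non-square PHYLIP matrix")
    else:
        raise ValueError(f"unknown distance-matrix format {fmt!r}")
    return DistanceMatrix(labels, values, kind=kind)


def write_distance_matrix(m: DistanceMatrix, path: str | Path, fmt: str = "csv") -> None:
    path = Path(path)
    if fmt == "csv":
        m.to_frame().to_csv(path, float_format="%.17g")
    elif fmt == "phylip":
        lines = [str(m.n)]
        for label, row in zip(m.labels, m.values):
            lines.append(label + "  " + " ".join(f"{x:.17g}" for x in row))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown distance-matrix format {fmt!r}")


# ---------------------------------------------------------------------------
# traits / environment / fitness tables
# ---------------------------------------------------------------------------


def read_traits(path: str | Path) -> TraitTable:
    df = pd.read_csv(path)
    return TraitTable(df)


def write_traits(table: TraitTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def read_environment(path: str | Path) -> list[SiteEnvironment]:
    df = pd.read_csv(path)
    meta = ("site", "latitude", "longitude", "elevation")
    for col in meta:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    var_cols = [c for c in df.columns if c not in meta]
    sites = []
    for _, row in df.iterrows():
        sites.append(
            SiteEnvironment(
                site=str(row["site"]),
                variables={c: float(row[c]) for c in var_cols},
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                elevation=float(row["elevation"]),
            )
        )
    return sites


def write_environment(sites: list[SiteEnvironment], path: str | Path) -> None:
    rows = []
    for s in sites:
        row = {"site": s.site, "latitude": s.latitude, "longitude": s.longitude,
               "elevation": s.elevation}
        row.update(s.variables)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pair_experiments(pots_path: str | Path, pairs_path: str | Path) -> list[PairExperiment]:
    """Assemble PairExperiments from a pot-level CSV and a pair-metadata CSV.

    ``pots_path`` columns: pair_id plus the pot columns; ``pairs_path``
    columns: pair_id, local_pop, foreign_pop, distance_km, local_N, foreign_N.
    """
    pots = pd.read_csv(pots_path)
    meta = pd.read_csv(pairs_path)
    out = []
    for _, m in meta.iterrows():
        sub = pots.loc[pots["pair_id"] == m["pair_id"], list(POT_COLUMNS)].reset_index(drop=True)
        if sub.empty:
            raise ValidationError(f"no pots for pair {m['pair_id']!r}")
        out.append(
            PairExperiment(
                pair_id=str(m["pair_id"]),
                local_pop=str(m["local_pop"]),
                foreign_pop=str(m["foreign_pop"]),
                distance_km=float(m["distance_km"]),
                local_N=int(m["local_N"]),
                foreign_N=int(m["foreign_N"]),
                pots=sub,
            )
        )
    return out


def write_pair_experiments(pairs: list[PairExperiment], pots_path: str | Path,
                           pairs_path: str | Path) -> None:
    pot_frames = []
    meta_rows = []
    for p in pairs:
        sub = p.pots.copy()
        sub.insert(0, "pair_id", p.pair_id)
        pot_frames.append(sub)
        meta_rows.append(
            {"pair_id": p.pair_id, "local_pop": p.local_pop, "foreign_pop": p.foreign_pop,
             "distance_km": p.distance_km, "local_N": p.local_N, "foreign_N": p.foreign_N}
        )
    pd.concat(pot_frames, ignore_index=True).to_csv(pots_path, index=False)
    pd.DataFrame(meta_rows).to_csv(pairs_path, index=False)


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two WGS84 points (haversine)."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def geographic_distances(sites: list[SiteEnvironment]) -> DistanceMatrix:
    """Pairwise great-circle distances (km) between sites."""
    n = len(sites)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(sites[i].latitude, sites[i].longitude,
                             sites[j].latitude, sites[j].longitude)
            values[i, j] = values[j, i] = d
    return DistanceMatrix([s.site for s in sites], values, kind="geographic")
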