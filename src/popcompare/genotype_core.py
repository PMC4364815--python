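"""Domain types and text-format I/O for multilocus codominant diploid genotypes.

The universal input of the pipeline is a :class:`GenotypeDataset`: individuals
typed at a shared panel of microsatellite loci, each genotype an unordered pair
of allele codes (fragment lengths or repeat counts), with per-site metadata
(planar UTM coordinates, watershed group label, climate scalars).

Conventions
-----------
* Allele codes are positive integers; ``0`` is the missing sentinel
  (:data:`MISSING`).  A genotype is missing only as a whole pair —
  half-missing calls are rejected at parse time.
* Missingness is per locus per individual; individuals are never dropped
  globally.  All per-locus statistics exclude untyped individuals locus-wise.
* Population order everywhere follows input order; matrices downstream carry
  explicit labels so order is checkable.
* Coordinates are planar meters in a single UTM zone; no geodesic correction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "ALL",
    "AlleleCall",
    "Individual",
    "PopulationSite",
    "GenotypeDataset",
    "GenotypeParseError",
    "read_genepop",
    "write_genepop",
    "read_structure_table",
    "write_structure_table",
    "read_site_metadata",
    "write_site_metadata",
    "allele_counts",
]

#: Sentinel allele value for a missing call.
MISSING = 0

#: Sentinel population selector meaning "pool all populations".
ALL = "ALL"


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates its dialect."""


@dataclass(frozen=True)
class AlleleCall:
    """A single allele observation (microsatellite fragment length or repeat count)."""

    value: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"allele value must be non-negative, got {self.value}")

    @property
    def is_missing(self) -> bool:
        return self.value == MISSING


@dataclass(frozen=True)
class Individual:
    """One sampled diploid individual with its per-locus genotype pairs."""

    id: str
    population_id: str
    genotypes: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for a, b in self.genotypes:
            if (a == MISSING) != (b == MISSING):
                raise ValueError(
                    f"individual {self.id!r}: half-missing genotype ({a},{b}); "
                    "a pair is missing only as a whole"
                )
            if a < 0 or b < 0:
                raise ValueError(f"individual {self.id!r}: negative allele code")


@dataclass(frozen=True)
class PopulationSite:
    """A sampling site: planar UTM coordinates, watershed group, climate scalars."""

    id: str
    easting: float = float("nan")
    northing: float = float("nan")
    group_id: str = ""
    climate: Mapping[str, float] = field(default_factory=dict)

    def require_coordinates(self) -> None:
        if not (np.isfinite(self.easting) and np.isfinite(self.northing)):
            raise ValueError(f"site {self.id!r} lacks finite coordinates")


class GenotypeDataset:
    """Individuals x loci diploid allele calls plus site metadata.

    Internally the calls are held as an integer array of shape
    ``(n_individuals, n_loci, 2)`` with :data:`MISSING` (0) for untyped pairs;
    the :attr:`individuals` property exposes the record view.
    """

    def __init__(
        self,
        loci: Sequence[str],
        alleles: np.ndarray,
        individual_ids: Sequence[str],
        individual_pops: Sequence[str],
        sites: Sequence[PopulationSite] | None = None,
    ) -> None:
        alleles = np.asarray(alleles, dtype=np.int64)
        if alleles.ndim != 3 or alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_individuals, n_loci, 2)")
        n, L, _ = alleles.shape
        if L != len(loci):
            raise ValueError(f"{len(loci)} locus names but {L} allele columns")
        if len(individual_ids) != n or len(individual_pops) != n:
            raise ValueError("individual id/population lists must match allele rows")
        if (alleles < 0).any():
            raise ValueError("negative allele codes")
        half = (alleles[:, :, 0] == MISSING) != (alleles[:, :, 1] == MISSING)
        if half.any():
            i, j = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing genotype for individual {individual_ids[i]!r} "
                f"at locus {loci[j]!r}"
            )
        self.loci: list[str] = list(loci)
        self.alleles = alleles
        self.individual_ids: list[str] = [str(x) for x in individual_ids]
        self.individual_pops: list[str] = [str(x) for x in individual_pops]

        pop_order: list[str] = []
        for p in self.individual_pops:
            if p not in pop_order:
                pop_order.append(p)
        if sites is None:
            sites = [PopulationSite(id=p) for p in pop_order]
        site_ids = [s.id for s in sites]
        if len(set(site_ids)) != len(site_ids):
            raise ValueError("duplicate site ids")
        missing_sites = [p for p in pop_order if p not in site_ids]
        if missing_sites:
            raise ValueError(
                f"individuals reference populations with no site metadata: {missing_sites}"
            )
        self.sites: list[PopulationSite] = list(sites)
        # population order follows the site list, restricted to sampled pops
        self.populations: list[str] = [s.id for s in self.sites if s.id in pop_order]
        self._pop_index = {p: k for k, p in enumerate(self.populations)}
        self.pop_codes = np.array(
            [self._pop_index[p] for p in self.individual_pops], dtype=np.int64
        )

    # -- record views -----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def individuals(self) -> list[Individual]:
        return [
            Individual(
                id=self.individual_ids[i],
                population_id=self.individual_pops[i],
                genotypes=tuple(
                    (int(a), int(b)) for a, b in self.alleles[i]
                ),
            )
            for i in range(self.n_individuals)
        ]

    def site(self, population_id: str) -> PopulationSite:
        for s in self.sites:
            if s.id == population_id:
                return s
        raise KeyError(population_id)

    def sample_sizes(self) -> dict[str, int]:
        """Individuals sampled per population, in population order."""
        return {
            p: int((self.pop_codes == self._pop_index[p]).sum())
            for p in self.populations
        }

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def pop_mask(self, population: str) -> np.ndarray:
        if population not in self._pop_index:
            raise KeyError(f"unknown population {population!r}")
        return self.pop_codes == self._pop_index[population]

    def with_sites(self, sites: Sequence[PopulationSite]) -> "GenotypeDataset":
        """Attach (replace) site metadata; every sampled population must be covered."""
        return GenotypeDataset(
            self.loci, self.alleles, self.individual_ids, self.individual_pops, sites
        )

    def subset_populations(self, keep: Sequence[str]) -> "GenotypeDataset":
        keep_set = set(keep)
        mask = np.array([p in keep_set for p in self.individual_pops])
        return GenotypeDataset(
            self.loci,
            self.alleles[mask],
            [i for i, m in zip(self.individual_ids, mask) if m],
            [p for p, m in zip(self.individual_pops, mask) if m],
            [s for s in self.sites if s.id in keep_set],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        # genotype pairs are unordered: compare sorted pairs
        return (
            self.loci == other.loci
            and self.individual_ids == other.individual_ids
            and self.individual_pops == other.individual_pops
            and np.array_equal(np.sort(self.alleles, 2), np.sort(other.alleles, 2))
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeDataset({self.n_individuals} individuals, "
            f"{self.n_loci} loci, {len(self.populations)} populations)"
        )


def _from_individuals(
    loci: Sequence[str],
    individuals: Iterable[Individual],
    sites: Sequence[PopulationSite] | None = None,
) -> GenotypeDataset:
    inds = list(individuals)
    for ind in inds:
        if len(ind.genotypes) != len(loci):
            raise GenotypeParseError(
                f"individual {ind.id!r} has {len(ind.genotypes)} genotypes "
                f"for {len(loci)} loci"
            )
    arr = np.array(
        [[[a, b] for a, b in ind.genotypes] for ind in inds], dtype=np.int64
    ).reshape(len(inds), len(loci), 2)
    return GenotypeDataset(
        loci, arr, [i.id for i in inds], [i.population_id for i in inds], sites
    )


# ---------------------------------------------------------------------------
# Genepop dialect
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(path: str | Path) -> GenotypeDataset:
    """Parse a Genepop file (2- or 3-digit allele encoding; 00/000 = missing).

    Layout: title line; locus names, one per line or comma-separated; blocks
    introduced by a line reading ``POP``.  Each individual line is
    ``label , tok tok ...`` with one fixed-width token per locus.  Populations
    are labelled by the longest common ``_``-prefix of their members' labels
    when one exists, else ``pop1`` .. ``popK`` in file order.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    body = lines[1:]  # title line discarded
    loci: list[str] = []
    i = 0
    while i < len(body) and not _POP_RE.match(body[i]):
        chunk = body[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if not loci:
        raise GenotypeParseError(f"{path}: no locus names before first POP")
    if i >= len(body):
        raise GenotypeParseError(f"{path}: no POP block")

    blocks: list[list[tuple[str, list[str]]]] = []
    current: list[tuple[str, list[str]]] | None = None
    for lineno, raw in enumerate(body[i:], start=i + 2):
        if _POP_RE.match(raw):
            current = []
            blocks.append(current)
            continue
        if not raw.strip():
            continue
        if current is None:
            raise GenotypeParseError(f"{path}:{lineno}: data before POP")
        if "," in raw:
            label, _, rest = raw.partition(",")
        else:  # tolerated: whitespace-separated label
            label, _, rest = raw.strip().partition(" ")
        toks = rest.split()
        if len(toks) != len(loci):
            raise GenotypeParseError(
                f"{path}:{lineno}: {len(toks)} genotype tokens for {len(loci)} loci"
            )
        current.append((label.strip(), toks))

    # detect digit width from token lengths
    widths = {len(t) for block in blocks for _, toks in block for t in toks}
    if widths <= {4}:
        digits = 2
    elif widths <= {6}:
        digits = 3
    elif widths <= {4, 6}:
        raise GenotypeParseError(f"{path}: mixed 2- and 3-digit allele encoding")
    else:
        bad = sorted(widths - {4, 6})
        raise GenotypeParseError(
            f"{path}: genotype token of length {bad[0]} is neither 4 (2-digit) "
            "nor 6 (3-digit)"
        )

    individuals: list[Individual] = []
    for bi, block in enumerate(blocks):
        labels = [lab for lab, _ in block]
        pop_id = _common_pop_label(labels) or f"pop{bi + 1}"
        for lab, toks in block:
            pairs = []
            for t in toks:
                if len(t) != 2 * digits or not t.isdigit():
                    raise GenotypeParseError(
                        f"{path}: malformed genotype token {t!r} under "
                        f"{digits}-digit encoding (individual {lab!r})"
                    )
                pairs.append((int(t[:digits]), int(t[digits:])))
            individuals.append(
                Individual(id=lab or f"{pop_id}_{len(individuals)}",
                           population_id=pop_id, genotypes=tuple(pairs))
            )
    try:
        return _from_individuals(loci, individuals)
    except ValueError as exc:  # half-missing etc.
        raise GenotypeParseError(f"{path}: {exc}") from exc


def _common_pop_label(labels: list[str]) -> str | None:
    prefixes = {lab.rsplit("_", 1)[0] for lab in labels if "_" in lab}
    if len(prefixes) == 1 and len(labels) > 0:
        p = prefixes.pop()
        if p and all(lab.startswith(p + "_") for lab in labels):
            return p
    return None


def write_genepop(ds: GenotypeDataset, path: str | Path, digits: int = 3,
                  title: str = "popcompare export") -> None:
    """Write a Genepop file; individuals are labelled ``{population}_{k}``."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    amax = int(ds.alleles.max(initial=0))
    if amax >= 10 ** digits:
        raise ValueError(
            f"allele code {amax} does not fit {digits}-digit Genepop encoding"
        )
    out = [title]
    out.extend(ds.loci)
    for pop in ds.populations:
        out.append("POP")
        mask = ds.pop_mask(pop)
        for k, i in enumerate(np.flatnonzero(mask), start=1):
            toks = [
                f"{a:0{digits}d}{b:0{digits}d}" for a, b in ds.alleles[i]
            ]
            out.append(f"{pop}_{k} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# STRUCTURE-format matrix
# ---------------------------------------------------------------------------

_STRUCT_MISSING = -9


def read_structure_table(
    path: str | Path, one_row_per_individual: bool = True
) -> GenotypeDataset:
    """Parse a STRUCTURE-format genotype matrix (whitespace-delimited, -9 = missing).

    Each data row carries ``label pop a a ...``: with ``one_row_per_individual``
    two adjacent columns per locus, otherwise two rows per individual with one
    column per locus.  An optional first line holding only the locus names
    (two fewer fields than data rows) is honoured; otherwise loci are named
    ``L1`` .. ``Ln``.
    """
    rows = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not rows:
        raise GenotypeParseError(f"{path}: empty file")

    def _all_names(row: list[str]) -> bool:
        return not any(tok.lstrip("-").isdigit() for tok in row)

    header: list[str] | None = None
    data = rows
    # a leading row of pure locus names (no numeric fields) is a header
    if len(rows) > 1 and _all_names(rows[0]) and len(rows[0]) != len(rows[1]):
        header, data = rows[0], rows[1:]
    widths = {len(r) for r in data}
    if len(widths) != 1:
        raise GenotypeParseError(f"{path}: ragged rows (widths {sorted(widths)})")
    ncol = widths.pop()
    if ncol < 3:
        raise GenotypeParseError(
            f"{path}: rows have {ncol} fields; need label, population column and "
            "at least one locus — a file without a population column requires an "
            "explicit site map, which this reader does not take"
        )
    n_loc_cols = ncol - 2

    if one_row_per_individual:
        if n_loc_cols % 2:
            raise GenotypeParseError(
                f"{path}: odd number of allele columns ({n_loc_cols}) in "
                "one-row-per-individual layout"
            )
        n_loci = n_loc_cols // 2
        loci = header if header else [f"L{j + 1}" for j in range(n_loci)]
        if len(loci) == n_loc_cols:  # header listed each allele column
            loci = loci[0::2]
        if len(loci) != n_loci:
            raise GenotypeParseError(f"{path}: header names {len(loci)} loci, data has {n_loci}")
        individuals = []
        for r in data:
            lab, pop, vals = r[0], r[1], [_struct_int(x, path) for x in r[2:]]
            pairs = tuple(
                _struct_pair(vals[2 * j], vals[2 * j + 1], lab)
                for j in range(n_loci)
            )
            individuals.append(Individual(id=lab, population_id=pop, genotypes=pairs))
    else:
        n_loci = n_loc_cols
        loci = header if header else [f"L{j + 1}" for j in range(n_loci)]
        if len(data) % 2:
            raise GenotypeParseError(f"{path}: odd row count in two-row layout")
        individuals = []
        for r1, r2 in zip(data[0::2], data[1::2]):
            if r1[0] != r2[0]:
                raise GenotypeParseError(
                    f"{path}: row pair labels differ ({r1[0]!r} vs {r2[0]!r})"
                )
            if r1[1] != r2[1]:
                raise GenotypeParseError(
                    f"{path}: row pair populations differ for {r1[0]!r}"
                )
            v1 = [_struct_int(x, path) for x in r1[2:]]
            v2 = [_struct_int(x, path) for x in r2[2:]]
            pairs = tuple(_struct_pair(a, b, r1[0]) for a, b in zip(v1, v2))
            individuals.append(
                Individual(id=r1[0], population_id=r1[1], genotypes=pairs)
            )
    try:
        return _from_individuals(loci, individuals)
    except ValueError as exc:
        raise GenotypeParseError(f"{path}: {exc}") from exc


def _struct_int(tok: str, path: str | Path) -> int:
    try:
        return int(tok)
    except ValueError:
        raise GenotypeParseError(f"{path}: non-integer allele field {tok!r}") from None


def _struct_pair(a: int, b: int, label: str) -> tuple[int, int]:
    a = MISSING if a == _STRUCT_MISSING else a
    b = MISSING if b == _STRUCT_MISSING else b
    if (a == MISSING) != (b == MISSING):
        raise GenotypeParseError(
            f"half-missing genotype for individual {label!r}"
        )
    if a < 0 or b < 0:
        raise GenotypeParseError(
            f"negative allele code for individual {label!r} (only -9 is missing)"
        )
    return a, b


def write_structure_table(
    ds: GenotypeDataset, path: str | Path, one_row_per_individual: bool = True
) -> None:
    """Write the dataset as a STRUCTURE-format matrix with a locus-name header."""
    lines = [" ".join(ds.loci)]

    def enc(v: int) -> str:
        return str(_STRUCT_MISSING if v == MISSING else v)

    for i in range(ds.n_individuals):
        lab, pop = ds.individual_ids[i], ds.individual_pops[i]
        g = ds.alleles[i]
        if one_row_per_individual:
            flat = " ".join(f"{enc(a)} {enc(b)}" for a, b in g)
            lines.append(f"{lab} {pop} {flat}")
        else:
            lines.append(f"{lab} {pop} " + " ".join(enc(a) for a, _ in g))
            lines.append(f"{lab} {pop} " + " ".join(enc(b) for _, b in g))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Site metadata
# ---------------------------------------------------------------------------

_META_CORE = ("id", "easting", "northing", "group")


def read_site_metadata(path: str | Path) -> list[PopulationSite]:
    """Read a delimited site table: id, easting, northing, group, climate columns.

    The delimiter (comma or tab) is sniffed; any column beyond the four core
    ones is stored as a climate scalar under its header name.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={"id": str, "group": str})
    missing = [c for c in _META_CORE if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"{path}: duplicate site id {dup!r}")
    for col in ("easting", "northing"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), "id"].iloc[0]
            raise ValueError(f"{path}: non-numeric {col} for site {bad!r}")
        df[col] = vals
    climate_cols = [c for c in df.columns if c not in _META_CORE]
    sites = []
    for _, row in df.iterrows():
        sites.append(
            PopulationSite(
                id=str(row["id"]),
                easting=float(row["easting"]),
                northing=float(row["northing"]),
                group_id="" if pd.isna(row["group"]) else str(row["group"]),
                climate={c: float(row[c]) for c in climate_cols},
            )
        )
    return sites


def write_site_metadata(sites: Sequence[PopulationSite], path: str | Path) -> None:
    climate_cols: list[str] = []
    for s in sites:
        for c in s.climate:
            if c not in climate_cols:
                climate_cols.append(c)
    rows = [
        {
            "id": s.id,
            "easting": s.easting,
            "northing": s.northing,
            "group": s.group_id,
            **{c: s.climate.get(c, float("nan")) for c in climate_cols},
        }
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Shared counting kernel
# ---------------------------------------------------------------------------

def allele_counts(
    ds: GenotypeDataset, locus: str, population: str = ALL
) -> dict[int, int]:
    """Gene counts per allele at ``locus``, over one population or pooled (:data:`ALL`).

    Counts cover non-missing calls only; the total is twice the number of
    typed individuals.
    """
    j = ds.locus_index(locus)
    if population == ALL:
        calls = ds.alleles[:, j, :]
    else:
        calls = ds.alleles[ds.pop_mask(population), j, :]
    flat = calls.reshape(-1)
    flat = flat[flat != MISSING]
    vals, cnt = np.unique(flat, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, cnt)}
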