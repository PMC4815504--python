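"""Core data types and file formats for RAD marker catalogues.

A RAD *marker* is a cluster of similar sequences flanking a restriction
site, treated as a homologous locus; its sequence variants are *alleles*.
The central container, :class:`MarkerCatalogue`, is a marker x individual
table of diploid genotype calls (unordered allele pairs, or missing) and
integer read depths.  Individuals carry population, phenotypic sex and a
sex-chromosome karyotype (``unknown`` until inferred or planted by the
simulator).

File formats
------------
Catalogue TSV
    One row per marker.  First column ``marker_id``; one column per
    individual with cells ``alleleA/alleleB:depth``, or ``./.:depth`` for
    a cell with no genotype call.  Header row holds the sample ids.
Metadata TSV
    Columns ``id``, ``population``, ``phenotype`` and optionally
    ``karyotype``.
Genepop
    Standard Genepop dialect with 3-digit allele coding: a title line,
    one marker name per line, a capitalised ``Pop`` separator before each
    population, then ``<id> , 001002 ...`` genotype rows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PHENOTYPES = ("male", "female", "hermaphrodite")
KARYOTYPES = ("ZZ", "ZW", "WW", "unknown")

#: genotype cell for "no call" in the catalogue TSV
MISSING_CELL = "./."


class FormatError(ValueError):
    """A catalogue or Genepop file violates the expected layout."""


class MetadataError(ValueError):
    """Sample metadata is missing, duplicated or inconsistent."""


class ValidationError(ValueError):
    """Catalogue contents violate a structural invariant."""


@dataclass(frozen=True)
class Individual:
    """A sampled animal: population of origin, phenotypic sex, karyotype."""

    id: str
    population: str
    phenotype: str
    karyotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValidationError(
                f"individual {self.id!r}: phenotype {self.phenotype!r} "
                f"not one of {PHENOTYPES}"
            )
        if self.karyotype not in KARYOTYPES:
            raise ValidationError(
                f"individual {self.id!r}: karyotype {self.karyotype!r} "
                f"not one of {KARYOTYPES}"
            )


@dataclass
class MarkerCatalogue:
    """Marker x individual genotype calls and read depths.

    ``genotype`` is an object array of shape (n_markers, n_individuals)
    whose entries are either ``None`` (no call) or a sorted 2-tuple of
    allele labels; a hemizygous call shows a single allele twice.
    ``depth`` is an integer array of the same shape.  Depth may be
    positive at a cell with a missing genotype (a failed call); how
    "absence" is defined for presence-absence logic is the business of
    the sex-linkage module, not of this container.
    """

    marker_ids: list[str]
    individuals: list[Individual]
    genotype: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype, dtype=object)
        self.depth = np.asarray(self.depth)
        shape = (len(self.marker_ids), len(self.individuals))
        if self.genotype.shape != shape or self.depth.shape != shape:
            raise ValidationError(
                f"genotype/depth shape {self.genotype.shape}/{self.depth.shape} "
                f"does not match {shape} (markers x individuals)"
            )
        if not np.issubdtype(self.depth.dtype, np.integer):
            if np.any(self.depth != np.floor(self.depth)):
                raise ValidationError("depths must be integers")
            self.depth = self.depth.astype(np.int64)
        if np.any(self.depth < 0):
            raise ValidationError("negative read depth")
        ids = [i.id for i in self.individuals]
        if len(set(ids)) != len(ids):
            raise MetadataError("duplicate individual ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValidationError("duplicate marker ids")
        # a population mixes females with hermaphrodites only by mistake
        for pop in {i.population for i in self.individuals}:
            phenos = {i.phenotype for i in self.individuals if i.population == pop}
            if {"female", "hermaphrodite"} <= phenos:
                raise MetadataError(
                    f"population {pop!r} contains both females and hermaphrodites"
                )

    # -- indexing helpers -------------------------------------------------

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def individual_ids(self) -> list[str]:
        return [i.id for i in self.individuals]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._midx[marker_id]
        except AttributeError:
            self._midx = {m: k for k, m in enumerate(self.marker_ids)}
            return self._midx[marker_id]

    def individual_index(self, ind_id: str) -> int:
        try:
            return self._iidx[ind_id]
        except AttributeError:
            self._iidx = {i.id: k for k, i in enumerate(self.individuals)}
            return self._iidx[ind_id]

    def populations(self) -> list[str]:
        seen: list[str] = []
        for ind in self.individuals:
            if ind.population not in seen:
                seen.append(ind.population)
        return seen

    def individuals_in(self, population: str) -> list[Individual]:
        return [i for i in self.individuals if i.population == population]

    @property
    def called(self) -> np.ndarray:
        """Boolean mask: genotype call present."""
        return np.not_equal(self.genotype, None)

    def alleles_at(self, marker_id: str, columns: Sequence[int] | None = None) -> list[str]:
        """Sorted distinct allele labels observed at a marker."""
        row = self.genotype[self.marker_index(marker_id)]
        if columns is not None:
            row = row[list(columns)]
        out: set[str] = set()
        for g in row:
            if g is not None:
                out.update(g)
        return sorted(out)

    # -- subsetting -------------------------------------------------------

    def subset_markers(self, marker_ids: Iterable[str]) -> "MarkerCatalogue":
        idx = [self.marker_index(m) for m in marker_ids]
        return MarkerCatalogue(
            [self.marker_ids[k] for k in idx],
            list(self.individuals),
            self.genotype[idx, :],
            self.depth[idx, :],
        )

    def subset_individuals(self, ind_ids: Iterable[str]) -> "MarkerCatalogue":
        idx = [self.individual_index(i) for i in ind_ids]
        return MarkerCatalogue(
            list(self.marker_ids),
            [self.individuals[k] for k in idx],
            self.genotype[:, idx],
            self.depth[:, idx],
        )

    def with_karyotypes(self, karyotypes: dict[str, str]) -> "MarkerCatalogue":
        """Return a copy with karyotypes set on the named individuals."""
        inds = [
            replace(i, karyotype=karyotypes.get(i.id, i.karyotype))
            for i in self.individuals
        ]
        return MarkerCatalogue(
            list(self.marker_ids), inds, self.genotype.copy(), self.depth.copy()
        )

    def validate_call_threshold(self, call_threshold: int) -> None:
        """Check: genotype non-missing implies depth >= call threshold."""
        bad = self.called & (self.depth < call_threshold)
        if np.any(bad):
            m, i = np.argwhere(bad)[0]
            raise ValidationError(
                f"marker {self.marker_ids[m]} / individual "
                f"{self.individuals[i].id}: genotype called at depth "
                f"{self.depth[m, i]} < {call_threshold}"
            )


@dataclass
class NormalizedCoverage:
    """Per-individual depth divided by that individual's reference median.

    The reference set is, by default, exactly the markers genotyped in
    every individual — a large sample of putatively autosomal, diploid
    markers, so autosomal cells sit near 1.0 and hemizygous cells near
    0.5 regardless of library size.
    """

    marker_ids: list[str]
    individual_ids: list[str]
    values: np.ndarray
    reference_marker_ids: list[str]
    reference_medians: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.marker_ids), len(self.individual_ids)):
            raise ValidationError("normalized coverage shape mismatch")
        if np.any(self.values < 0):
            raise ValidationError("negative normalized coverage")

    def value(self, marker_id: str, ind_id: str) -> float:
        return float(
            self.values[
                self.marker_ids.index(marker_id), self.individual_ids.index(ind_id)
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.marker_ids, columns=self.individual_ids
        )


# ---------------------------------------------------------------------------
# Metadata I/O


def read_metadata(path: str | Path) -> list[Individual]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "population", "phenotype"}
    if not required <= set(df.columns):
        raise FormatError(
            f"metadata {path}: missing column(s) {sorted(required - set(df.columns))}"
        )
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise MetadataError(f"metadata {path}: duplicate individual id {dup!r}")
    out = []
    for row in df.itertuples(index=False):
        kt = getattr(row, "karyotype", "unknown")
        if not isinstance(kt, str) or kt == "":
            kt = "unknown"
        out.append(Individual(row.id, row.population, row.phenotype, kt))
    return out


def write_metadata(individuals: Sequence[Individual], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [i.id for i in individuals],
            "population": [i.population for i in individuals],
            "phenotype": [i.phenotype for i in individuals],
            "karyotype": [i.karyotype for i in individuals],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Catalogue I/O

_CELL_RE = re.compile(r"^(.+?)/(.+?):(\d+)$|^\./\.:(\d+)$")


def _parse_cell(cell: str, where: str) -> tuple[tuple[str, str] | None, int]:
    if ":" not in cell:
        raise FormatError(f"{where}: malformed cell {cell!r} (no ':depth' part)")
    geno_s, _, depth_s = cell.rpartition(":")
    try:
        depth = int(depth_s)
    except ValueError:
        raise FormatError(f"{where}: non-integer depth in cell {cell!r}") from None
    if depth < 0:
        raise ValidationError(f"{where}: negative depth in cell {cell!r}")
    if geno_s == MISSING_CELL:
        return None, depth
    parts = geno_s.split("/")
    if len(parts) != 2 or not all(parts):
        raise FormatError(f"{where}: malformed genotype in cell {cell!r}")
    a, b = sorted(parts)
    return (a, b), depth


def read_catalogue(path: str | Path, metadata_path: str | Path) -> MarkerCatalogue:
    """Read a catalogue TSV plus its sample metadata.

    Every sample column in the catalogue must have a metadata row; extra
    metadata rows are ignored.  Missing genotypes are preserved as
    missing and depths parsed as integers.
    """
    path = Path(path)
    individuals_all = {i.id: i for i in read_metadata(metadata_path)}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if not cols or cols[0] != "marker_id":
            raise FormatError(
                f"{path}, line 1: header must start with 'marker_id', got {cols[:1]}"
            )
        sample_ids = cols[1:]
        if len(set(sample_ids)) != len(sample_ids):
            raise FormatError(f"{path}, line 1: duplicate sample columns")
        missing_meta = [s for s in sample_ids if s not in individuals_all]
        if missing_meta:
            raise MetadataError(
                f"samples {missing_meta} in catalogue but not in metadata"
            )
        individuals = [individuals_all[s] for s in sample_ids]

        marker_ids: list[str] = []
        geno_rows: list[list[tuple[str, str] | None]] = []
        depth_rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise FormatError(
                    f"{path}, line {lineno}: expected {len(cols)} columns, "
                    f"got {len(fields)}"
                )
            marker_ids.append(fields[0])
            g_row, d_row = [], []
            for s, cell in zip(sample_ids, fields[1:]):
                g, d = _parse_cell(cell, f"{path}, line {lineno}, sample {s}")
                g_row.append(g)
                d_row.append(d)
            geno_rows.append(g_row)
            depth_rows.append(d_row)

    geno = np.empty((len(marker_ids), len(individuals)), dtype=object)
    for k, row in enumerate(geno_rows):
        for j, g in enumerate(row):
            geno[k, j] = g
    depth = np.array(depth_rows, dtype=np.int64).reshape(len(marker_ids), len(individuals))
    return MarkerCatalogue(marker_ids, individuals, geno, depth)


def write_catalogue(cat: MarkerCatalogue, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("marker_id\t" + "\t".join(cat.individual_ids) + "\n")
        for k, m in enumerate(cat.marker_ids):
            cells = []
            for j in range(cat.n_individuals):
                g = cat.genotype[k, j]
                gs = MISSING_CELL if g is None else f"{g[0]}/{g[1]}"
                cells.append(f"{gs}:{cat.depth[k, j]}")
            fh.write(m + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Genepop export


def complete_markers(cat: MarkerCatalogue) -> list[str]:
    """Markers with a genotype call in every individual of the catalogue."""
    mask = cat.called.all(axis=1)
    return [m for m, ok in zip(cat.marker_ids, mask) if ok]


def write_genepop(
    cat: MarkerCatalogue,
    markers: Sequence[str] | None,
    out: str | Path,
    title: str = "zwrad export",
) -> list[str]:
    """Write a Genepop file (3-digit allele coding) for the given markers.

    ``markers=None`` selects exactly the markers genotyped in every
    individual; passing a marker with a missing genotype among the
    included individuals is a precondition error.  Returns the marker
    list actually written.
    """
    if markers is None:
        markers = complete_markers(cat)
    markers = list(markers)
    called = cat.called
    for m in markers:
        k = cat.marker_index(m)
        if not called[k].all():
            j = int(np.flatnonzero(~called[k])[0])
            raise ValidationError(
                f"marker {m} has no genotype call for individual "
                f"{cat.individuals[j].id}; Genepop export requires markers "
                "found in all individuals"
            )

    codes: dict[str, dict[str, int]] = {}
    for m in markers:
        alleles = cat.alleles_at(m)
        if len(alleles) > 99:
            raise ValidationError(
                f"marker {m} has {len(alleles)} alleles; 3-digit Genepop "
                "coding supports at most 99"
            )
        codes[m] = {a: i + 1 for i, a in enumerate(alleles)}

    with open(out, "wt", encoding="utf-8") as fh:
        fh.write(title + "\n")
        for m in markers:
            fh.write(m + "\n")
        for pop in cat.populations():
            fh.write("Pop\n")
            for ind in cat.individuals_in(pop):
                j = cat.individual_index(ind.id)
                entries = []
                for m in markers:
                    g = cat.genotype[cat.marker_index(m), j]
                    if g is None:  # unreachable for validated marker sets
                        entries.append("000000")
                    else:
                        c = codes[m]
                        entries.append(f"{c[g[0]]:03d}{c[g[1]]:03d}")
                fh.write(f"{ind.id} , " + " ".join(entries) + "\n")
    return markers
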