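"""Catalogue-level coverage filters and per-individual normalization.

Pre-processing mirrors a standard high-coverage RAD workflow: keep
markers with deep support in enough individuals, drop suspiciously deep
(likely repetitive) markers, then express each cell's depth relative to
the individual's library size.  The normalizer divides every depth by
the median depth, in that individual, of a reference set of markers —
by default exactly the markers genotyped in *all* individuals, a large
sample of putatively autosomal diploid loci.  Autosomal cells then sit
near 1.0 and hemizygous cells near 0.5, which is the quantitative
signal used to detect sex-chromosome-specific markers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .catalogue import MarkerCatalogue, NormalizedCoverage, ValidationError

AUTO = "AUTO"


@dataclass
class FilterReport:
    n_input_markers: int = 0
    n_after_high_coverage_filter: int = 0
    n_after_repeat_filter: int = 0
    reference_set_size: int = 0
    per_individual_reference_median: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def filter_high_coverage(
    cat: MarkerCatalogue,
    min_depth: int = 20,
    min_individuals: int = 6,
    report: FilterReport | None = None,
) -> MarkerCatalogue:
    """Keep markers with depth strictly greater than ``min_depth`` reads
    in at least ``min_individuals`` individuals.

    The defaults retain "high coverage" markers (>20 reads) found in six
    or more individuals — six being the smallest sex-by-population
    sample a marker class could be restricted to.
    """
    if min_depth < 0 or min_individuals < 1:
        raise ValidationError("min_depth must be >= 0 and min_individuals >= 1")
    if report is not None:
        report.n_input_markers = cat.n_markers
    if cat.n_markers == 0:
        warnings.warn("filter_high_coverage: empty catalogue", stacklevel=2)
        if report is not None:
            report.n_after_high_coverage_filter = 0
        return cat
    keep = (cat.depth > min_depth).sum(axis=1) >= min_individuals
    out = cat.subset_markers([m for m, k in zip(cat.marker_ids, keep) if k])
    if report is not None:
        report.n_after_high_coverage_filter = out.n_markers
    return out


def remove_repetitive(
    cat: MarkerCatalogue, n_sd: float = 2.0, report: FilterReport | None = None
) -> MarkerCatalogue:
    """Drop markers whose mean depth exceeds the grand mean by ``n_sd``
    standard deviations (single pass) — putative repetitive elements.

    Each marker's mean depth is taken over its genotyped (non-missing)
    cells; markers with no calls fall back to the mean over all cells.
    """
    if cat.n_markers < 2:
        raise ValidationError("remove_repetitive requires at least 2 markers")
    called = cat.called
    depth = cat.depth.astype(float)
    sums = np.where(called, depth, 0.0).sum(axis=1)
    counts = called.sum(axis=1)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), depth.mean(axis=1))
    cutoff = means.mean() + n_sd * means.std(ddof=0)
    keep = means <= cutoff
    out = cat.subset_markers([m for m, k in zip(cat.marker_ids, keep) if k])
    if report is not None:
        report.n_after_repeat_filter = out.n_markers
    return out


def _median(values: np.ndarray) -> float:
    # plain midpoint-of-central-values median
    return float(np.median(values))


def normalize_depths(
    cat: MarkerCatalogue,
    reference: Sequence[str] | str = AUTO,
    report: FilterReport | None = None,
) -> NormalizedCoverage:
    """Divide each individual's depths by its reference-set median depth.

    ``reference=AUTO`` selects the markers genotyped in every
    individual.  Errors if that set is empty (pass an explicit
    reference instead) or if any individual's reference median is zero.
    """
    if isinstance(reference, str):
        if reference != AUTO:
            raise ValidationError(f"unknown reference spec {reference!r}")
        mask = cat.called.all(axis=1)
        ref_ids = [m for m, ok in zip(cat.marker_ids, mask) if ok]
        if not ref_ids:
            raise ValidationError(
                "AUTO reference is empty: no marker is genotyped in all "
                "individuals; pass an explicit reference marker list"
            )
    else:
        ref_ids = list(reference)
        if not ref_ids:
            raise ValidationError("reference marker set must be non-empty")
    ref_rows = [cat.marker_index(m) for m in ref_ids]
    medians = np.array(
        [_median(cat.depth[ref_rows, j]) for j in range(cat.n_individuals)]
    )
    for j, med in enumerate(medians):
        if med <= 0:
            raise ValidationError(
                f"individual {cat.individuals[j].id} has reference median 0; "
                "cannot normalize"
            )
    values = cat.depth / medians[np.newaxis, :]
    if report is not None:
        report.reference_set_size = len(ref_ids)
        report.per_individual_reference_median = {
            ind.id: float(m) for ind, m in zip(cat.individuals, medians)
        }
    return NormalizedCoverage(
        list(cat.marker_ids),
        cat.individual_ids,
        values,
        ref_ids,
        {ind.id: float(m) for ind, m in zip(cat.individuals, medians)},
    )


def preprocess(
    cat: MarkerCatalogue,
    min_depth: int = 20,
    min_individuals: int = 6,
    n_sd: float = 2.0,
    reference: Sequence[str] | str = AUTO,
) -> tuple[MarkerCatalogue, NormalizedCoverage, FilterReport]:
    """High-coverage filter, repeat removal, then normalization."""
    report = FilterReport()
    cat = filter_high_coverage(cat, min_depth, min_individuals, report)
    cat = remove_repetitive(cat, n_sd, report)
    cov = normalize_depths(cat, reference, report)
    return cat, cov, report
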