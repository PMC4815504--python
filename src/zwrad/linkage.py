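"""Genotypic linkage disequilibrium tests between marker pairs.

The test treats each locus's diploid genotypes as unordered categories,
builds the genotype x genotype contingency table over individuals
scored at both loci, and computes the log-likelihood-ratio (G)
statistic.  Significance comes from a permutation null: genotypes at
one locus are shuffled across individuals, which preserves both
single-locus genotype distributions while breaking their association.
Because the test operates on genotypes rather than haplotypes it needs
no phasing and is sensitive to the identity disequilibrium (correlated
homozygosity across loci) that partial selfing generates genome-wide.

p-values use the add-one permutation estimate ``(1 + #{G* >= G}) /
(n_perm + 1)`` and are a function of the contingency table alone, so
they are invariant under reordering of individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .catalogue import MarkerCatalogue, ValidationError


@dataclass(frozen=True)
class LDResult:
    """One tested (unordered, canonicalized a < b) marker pair."""

    marker_a: str
    marker_b: str
    p_value: float
    n_individuals: int
    significant: bool

    def __post_init__(self) -> None:
        if self.marker_a >= self.marker_b:
            raise ValidationError("pair must be canonicalized with marker_a < marker_b")
        if not 0 < self.p_value <= 1:
            raise ValidationError("p_value must lie in (0, 1]")


def g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio statistic of independence for a contingency
    table: ``G = 2 * sum O * ln(O / E)`` with expected counts from the
    margins; empty cells contribute zero."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return float(2.0 * terms.sum())


def _encode(column: Sequence[tuple[str, str] | None]) -> tuple[np.ndarray, int]:
    """Integer-code genotype categories, sorted so that the coding (and
    hence the permutation stream) is independent of individual order."""
    cats = {g: i for i, g in enumerate(sorted(set(column)))}
    codes = [cats[g] for g in column]
    return np.asarray(codes, dtype=np.int64), len(cats)


def genotypic_ld_test(
    g1: Sequence[tuple[str, str] | None],
    g2: Sequence[tuple[str, str] | None],
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> float | None:
    """Permutation p-value for genotypic association between two loci.

    Individuals missing at either locus are dropped.  Returns ``None``
    (not testable) when either locus is monomorphic among the retained
    individuals, mirroring how monomorphic loci are excluded from LD
    screens.
    """
    rng = np.random.default_rng() if rng is None else rng
    pairs = [(a, b) for a, b in zip(g1, g2) if a is not None and b is not None]
    if not pairs:
        return None
    c1, k1 = _encode([p[0] for p in pairs])
    c2, k2 = _encode([p[1] for p in pairs])
    if k1 < 2 or k2 < 2:
        return None

    # work from the table's canonical vectors so the p-value depends on
    # the table only, not on how individuals happened to be ordered
    table = np.bincount(c1 * k2 + c2, minlength=k1 * k2).reshape(k1, k2)
    g_obs = g_statistic(table)
    rows = np.repeat(np.arange(k1), table.sum(axis=1))
    cols = np.concatenate([np.repeat(np.arange(k2), table[i]) for i in range(k1)])

    # all permutations at once: one flat bincount over offset linear indices
    perm_mat = rng.permuted(np.tile(cols, (n_perm, 1)), axis=1)
    lin = rows[np.newaxis, :] * k2 + perm_mat
    lin += np.arange(n_perm)[:, np.newaxis] * (k1 * k2)
    tables = (
        np.bincount(lin.ravel(), minlength=n_perm * k1 * k2)
        .reshape(n_perm, k1, k2)
        .astype(float)
    )
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / len(pairs)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(tables > 0, tables * np.log(tables / expected), 0.0)
    g_perm = 2.0 * terms.sum(axis=(1, 2))
    n_ge = int((g_perm >= g_obs - 1e-9).sum())
    return (1 + n_ge) / (n_perm + 1)


def ld_screen(
    cat: MarkerCatalogue,
    population: str,
    alpha: float = 0.05,
    n_perm: int = 10000,
    rng: np.random.Generator | int | None = None,
    markers: Sequence[str] | None = None,
) -> list[LDResult]:
    """Test all unordered marker pairs for genotypic LD in one population.

    Only markers genotyped in every individual of the population and
    polymorphic within it enter the screen (the same restriction used
    when exporting population genotype files).  Returns one result per
    testable pair, flagged significant at raw ``alpha``.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    sub = cat.subset_individuals([i.id for i in cat.individuals_in(population)])
    if markers is None:
        markers = sub.marker_ids
    complete = []
    for m in markers:
        k = sub.marker_index(m)
        row = sub.genotype[k]
        if all(g is not None for g in row) and len({g for g in row}) >= 2:
            complete.append(m)
    if len(complete) < 2:
        warnings.warn(
            f"ld_screen: fewer than 2 polymorphic complete markers in "
            f"{population}; nothing to test",
            stacklevel=2,
        )
        return []
    columns = {m: list(sub.genotype[sub.marker_index(m)]) for m in complete}
    results: list[LDResult] = []
    for a, b in combinations(sorted(complete), 2):
        p = genotypic_ld_test(columns[a], columns[b], n_perm, rng)
        if p is None:
            continue
        n = sum(
            1 for x, y in zip(columns[a], columns[b]) if x is not None and y is not None
        )
        results.append(LDResult(a, b, p, n, p <= alpha))
    return results


def summarize_sexlinked_pairs(
    results: Sequence[LDResult], sexlinked_ids: set[str] | Sequence[str]
) -> dict:
    """Among significant pairs, count those touching a sex-linked marker.

    Returns the number of significant pairs, the number involving at
    least one known completely sex-linked marker, their proportion, and
    the distinct non-sex-linked partner markers (candidates for being
    physically linked to the sex-determining region).
    """
    sexlinked = set(sexlinked_ids)
    sig = [r for r in results if r.significant]
    sl_pairs = [r for r in sig if r.marker_a in sexlinked or r.marker_b in sexlinked]
    partners = sorted(
        {
            m
            for r in sl_pairs
            for m in (r.marker_a, r.marker_b)
            if m not in sexlinked
        }
    )
    return {
        "n_pairs_sig": len(sig),
        "n_sexlinked_pairs_sig": len(sl_pairs),
        "proportion": (len(sl_pairs) / len(sig)) if sig else 0.0,
        "partner_markers": partners,
    }
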