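"""Population differentiation and polymorphism summaries.

F_ST uses the Weir & Cockerham (1984) theta estimator for diploid
genotypes: per locus and allele, the variance in allele frequencies is
partitioned into among-population (a), among-individual-within-
population (b) and within-individual (c) components, and the
multilocus estimate is the ratio of sums ``sum(a) / sum(a + b + c)``
over loci and alleles.  Negative estimates are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalogue import MarkerCatalogue, ValidationError


@dataclass
class FstResult:
    per_locus_components: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    multilocus_fst: float = float("nan")
    n_loci: int = 0


def _wc_components(
    genotypes_by_pop: list[list[tuple[str, str]]]
) -> tuple[float, float, float] | None:
    """Weir-Cockerham a, b, c summed over alleles at one locus.

    ``genotypes_by_pop`` holds the non-missing diploid genotypes of each
    population.  Returns None when fewer than two populations have data
    or the locus is monomorphic overall (components conventionally all
    zero — handled by the caller).
    """
    pops = [p for p in genotypes_by_pop if p]
    r = len(pops)
    if r < 2:
        return None
    alleles = sorted({a for p in pops for g in p for a in g})
    if len(alleles) < 2:
        return (0.0, 0.0, 0.0)
    n = np.array([len(p) for p in pops], dtype=float)
    n_bar = n.mean()
    n_c = (r * n_bar - (n**2).sum() / (r * n_bar)) / (r - 1)
    if n_bar <= 1 or n_c <= 0:
        return None
    a_tot = b_tot = c_tot = 0.0
    for allele in alleles:
        p_i = np.array(
            [sum(g.count(allele) for g in p) / (2 * len(p)) for p in pops]
        )
        h_i = np.array(
            [sum(1 for g in p if (allele in g) and g[0] != g[1]) / len(p) for p in pops]
        )
        p_bar = (n * p_i).sum() / (r * n_bar)
        s2 = (n * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n * h_i).sum() / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - s2 * (r - 1) / r
            - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2.0
        a_tot, b_tot, c_tot = a_tot + a, b_tot + b, c_tot + c
    return (a_tot, b_tot, c_tot)


def fst_weir_cockerham(
    cat: MarkerCatalogue,
    pops: tuple[str, str] | None = None,
    loci: list[str] | None = None,
) -> FstResult:
    """Multilocus Weir-Cockerham F_ST between two populations.

    ``loci=None`` selects markers genotyped in *all* individuals of at
    least one of the two populations (sex-chromosome-specific markers,
    absent in one sex, are thereby excluded) and genotyped in at least
    two individuals of each population.  Loci monomorphic across both
    populations contribute zero to every component sum.
    """
    if pops is None:
        ps = cat.populations()
        if len(ps) != 2:
            raise ValidationError("specify pops: catalogue does not hold exactly 2")
        pops = (ps[0], ps[1])
    idx = {
        p: [cat.individual_index(i.id) for i in cat.individuals_in(p)] for p in pops
    }
    for p in pops:
        if not idx[p]:
            raise ValidationError(f"population {p!r} has no individuals")
    called = cat.called
    if loci is None:
        loci = []
        for k, m in enumerate(cat.marker_ids):
            complete_in_one = any(called[k, idx[p]].all() for p in pops)
            enough_both = all(called[k, idx[p]].sum() >= 2 for p in pops)
            if complete_in_one and enough_both:
                loci.append(m)
    if not loci:
        raise ValidationError("no usable loci for F_ST")

    result = FstResult()
    sum_a = sum_abc = 0.0
    for m in loci:
        k = cat.marker_index(m)
        by_pop = [
            [cat.genotype[k, j] for j in idx[p] if called[k, j]] for p in pops
        ]
        comp = _wc_components(by_pop)
        if comp is None:
            continue
        result.per_locus_components[m] = comp
        a, b, c = comp
        sum_a += a
        sum_abc += a + b + c
    result.n_loci = len(result.per_locus_components)
    if sum_abc != 0:
        result.multilocus_fst = sum_a / sum_abc
    return result


def polymorphism_summary(
    cat: MarkerCatalogue, population: str, require_complete: bool = True
) -> dict:
    """Proportion of markers with >= 2 alleles within one population.

    With ``require_complete`` (the default) the denominator is the set
    of markers genotyped in every individual of the population — the
    same restriction used for population genotype exports; otherwise
    any marker with at least one call counts.
    """
    idx = [cat.individual_index(i.id) for i in cat.individuals_in(population)]
    if not idx:
        raise ValidationError(f"population {population!r} has no individuals")
    called = cat.called
    n_markers = 0
    n_poly = 0
    for k in range(cat.n_markers):
        calls = called[k, idx]
        if require_complete and not calls.all():
            continue
        if not calls.any():
            continue
        n_markers += 1
        alleles = {a for j in idx if called[k, j] for a in cat.genotype[k, j]}
        if len(alleles) >= 2:
            n_poly += 1
    return {
        "population": population,
        "n_markers": n_markers,
        "n_polymorphic": n_poly,
        "proportion": (n_poly / n_markers) if n_markers else 0.0,
    }
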