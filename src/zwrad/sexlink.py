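"""Sex-linked marker discovery under an explicit heterogametic model.

The inference combines three lines of evidence against the predictions
of a chromosomal sex-determination model in which one sex (females, or
hermaphrodites, in a ZW system; males in an XY system) is heterogametic:

presence-absence
    A chromosome-specific marker is present in every carrier of that
    chromosome and absent in every non-carrier (a W-specific marker is
    found in all ZW/WW individuals and in no ZZ male; a Z-specific
    marker is absent only from WW monogenic hermaphrodites).
normalized coverage
    Carriers with one copy of the chromosome show ~0.5 normalized
    coverage (hemizygous); carriers with two copies show ~1.0.
SNP segregation
    A marker present on both sex chromosomes with chromosome-diagnostic
    alleles is heterozygous in every heterogametic individual, carrying
    a W-linked allele never seen in ZZ males, while males (and WW
    monogenics) are homozygous.

In an androdioecious population the order of operations matters:
W-specific markers are found first from the hermaphrodite/male
contrast, their coverage splits hermaphrodites into monogenic (WW,
coverage ~1) and amphigenic (ZW, ~0.5) classes, and only then can
Z-specific markers be recognised (present in males and amphigenics,
absent in monogenics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .catalogue import Individual, MarkerCatalogue, NormalizedCoverage, ValidationError

FEMALE_ZW = "female_ZW"
MALE_XY = "male_XY"

CATEGORIES = ("W_specific", "Z_specific", "sexlinked_alleles", "ld_linked", "unclassified")

#: Expected segregation of completely sex-linked markers by karyotype,
#: for the female-heterogametic model: (presence, coverage, zygosity).
ZW_CLASS_EXPECTATIONS: dict[tuple[str, str], tuple[str, float | None, str]] = {
    ("W_specific", "ZW"): ("present", 0.5, "hemizygous"),
    ("W_specific", "ZZ"): ("absent", None, "none"),
    ("W_specific", "WW"): ("present", 1.0, "homozygous_or_het"),
    ("Z_specific", "ZW"): ("present", 0.5, "hemizygous"),
    ("Z_specific", "ZZ"): ("present", 1.0, "homozygous_or_het"),
    ("Z_specific", "WW"): ("absent", None, "none"),
    ("sexlinked_alleles", "ZW"): ("present", 1.0, "het_with_specific_allele"),
    ("sexlinked_alleles", "ZZ"): ("present", 1.0, "homozygous"),
    ("sexlinked_alleles", "WW"): ("present", 1.0, "homozygous"),
}


@dataclass(frozen=True)
class SegregationModel:
    """A heterogametic-sex hypothesis with its expected patterns.

    Under ``male_XY`` the table is the mirror image of the ZW one: the
    sexes swap roles and W/Z become Y/X.  Windows define "coverage
    consistent with" one copy (hemizygous) or two (homozygous) of a
    chromosome, relative to the autosomal reference.
    """

    heterogametic_sex: str = FEMALE_ZW
    hemizygous_window: tuple[float, float] = (0.25, 0.75)
    homozygous_window: tuple[float, float] = (0.75, 1.5)
    class_expectations: Mapping[tuple[str, str], tuple[str, float | None, str]] = field(
        default_factory=lambda: dict(ZW_CLASS_EXPECTATIONS)
    )

    def __post_init__(self) -> None:
        if self.heterogametic_sex not in (FEMALE_ZW, MALE_XY):
            raise ValidationError(
                f"heterogametic_sex must be {FEMALE_ZW!r} or {MALE_XY!r}"
            )

    @property
    def heterogametic_phenotypes(self) -> tuple[str, ...]:
        if self.heterogametic_sex == FEMALE_ZW:
            return ("female", "hermaphrodite")
        return ("male",)


ZW_MODEL = SegregationModel(FEMALE_ZW)
XY_MODEL = SegregationModel(MALE_XY)


@dataclass
class SexLinkageCall:
    """Per-marker classification with its supporting evidence flags."""

    marker_id: str
    category: str
    evidence: dict[str, bool] = field(default_factory=dict)
    phased_alleles: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if self.category != "unclassified" and not all(self.evidence.values()):
            raise ValidationError(
                f"marker {self.marker_id}: category {self.category} assigned "
                "with failing evidence"
            )
        if self.phased_alleles is not None and self.category != "sexlinked_alleles":
            raise ValidationError("phased alleles only apply to sexlinked_alleles calls")


def _resolve(cat: MarkerCatalogue, group: Iterable[Individual | str]) -> list[Individual]:
    out = []
    for x in group:
        if isinstance(x, Individual):
            out.append(x)
        else:
            out.append(cat.individuals[cat.individual_index(x)])
    return out


# ---------------------------------------------------------------------------
# Chromosome-specific markers (presence-absence + coverage + zygosity)


def find_chromosome_specific(
    cat: MarkerCatalogue,
    cov: NormalizedCoverage,
    carriers: Sequence[Individual | str],
    non_carriers: Sequence[Individual | str],
    target_chromosome: str = "W",
    model: SegregationModel = ZW_MODEL,
    absent_max_depth: int = 5,
    expected_copies: Mapping[str, int] | None = None,
    coverage_check: str = "group_mean",
) -> list[SexLinkageCall]:
    """Markers present in all carriers and absent in all non-carriers.

    Presence means a genotype call; absence means no call *and* depth
    below ``absent_max_depth`` (a guard band so that trace read counts
    do not pass as presence — depths between the guard and the call
    threshold are indeterminate and disqualify the marker).

    ``coverage_ok`` judges the marker's normalized coverage against the
    window for each expected copy number: the hemizygous window for
    single-copy carriers, the homozygous window for two-copy carriers
    (e.g. WW monogenics at a W-specific marker).  With the default
    ``coverage_check="group_mean"`` the *mean* coverage over the
    carriers of each copy class must fall in that class's window —
    the marker-level reading of "coverage consistent with being
    hemizygous"; ``"per_carrier"`` instead requires every individual
    cell inside its window.  Carriers of unknown karyotype are always
    checked per-cell against the union of the two windows.
    ``zygosity_ok`` requires a single allele wherever one copy is
    expected.  The returned category is the chromosome-specific class
    only when all evidence holds; otherwise the call is reported
    unclassified with its flags.

    ``expected_copies`` may pre-assign copy numbers per carrier id;
    otherwise they derive from the carrier's karyotype when known.
    """
    if coverage_check not in ("group_mean", "per_carrier"):
        raise ValidationError(f"unknown coverage_check {coverage_check!r}")
    carriers = _resolve(cat, carriers)
    non_carriers = _resolve(cat, non_carriers)
    if not carriers or not non_carriers:
        raise ValidationError("carrier and non-carrier groups must be non-empty")
    overlap = {i.id for i in carriers} & {i.id for i in non_carriers}
    if overlap:
        raise ValidationError(f"carriers and non-carriers overlap: {sorted(overlap)}")

    def copies_of(ind: Individual) -> int | None:
        if expected_copies is not None and ind.id in expected_copies:
            return expected_copies[ind.id]
        if ind.karyotype in ("ZZ", "ZW", "WW"):
            return ind.karyotype.count(target_chromosome)
        return None  # unknown karyotype: accept either window

    c_idx = [cat.individual_index(i.id) for i in carriers]
    n_idx = [cat.individual_index(i.id) for i in non_carriers]
    called = cat.called
    lo_h, hi_h = model.hemizygous_window
    lo_d, hi_d = model.homozygous_window

    calls: list[SexLinkageCall] = []
    for k, m in enumerate(cat.marker_ids):
        if not called[k, c_idx].all():
            continue
        absent = all(
            (not called[k, j]) and cat.depth[k, j] < absent_max_depth for j in n_idx
        )
        if not absent:
            continue
        coverage_ok = True
        zygosity_ok = True
        by_class: dict[int, list[float]] = {1: [], 2: []}
        cov_row = cov.marker_ids.index(m)
        for ind, j in zip(carriers, c_idx):
            v = float(cov.values[cov_row, cov.individual_ids.index(ind.id)])
            exp = copies_of(ind)
            if exp == 1:
                if coverage_check == "per_carrier":
                    coverage_ok &= lo_h <= v <= hi_h
                else:
                    by_class[1].append(v)
                a, b = cat.genotype[k, j]
                zygosity_ok &= a == b
            elif exp == 2:
                if coverage_check == "per_carrier":
                    coverage_ok &= lo_d < v <= hi_d
                else:
                    by_class[2].append(v)
            else:
                # unknown karyotype: either copy number is plausible
                coverage_ok &= lo_h <= v <= hi_d
        if by_class[1]:
            mean1 = float(np.mean(by_class[1]))
            coverage_ok &= lo_h <= mean1 <= hi_h
        if by_class[2]:
            mean2 = float(np.mean(by_class[2]))
            coverage_ok &= lo_d < mean2 <= hi_d
        evidence = {
            "presence_pattern_ok": True,
            "coverage_ok": bool(coverage_ok),
            "zygosity_ok": bool(zygosity_ok),
        }
        category = (
            f"{target_chromosome}_specific"
            if coverage_ok and zygosity_ok
            else "unclassified"
        )
        calls.append(SexLinkageCall(m, category, evidence))
    return calls


# ---------------------------------------------------------------------------
# Completely sex-linked alleles (SNP segregation)


def find_sexlinked_alleles(
    cat: MarkerCatalogue,
    groups: Mapping[str, Sequence[Individual | str]],
    model: SegregationModel = ZW_MODEL,
) -> list[SexLinkageCall]:
    """Markers whose alleles segregate with the sex chromosomes.

    ``groups`` maps karyotype labels to individuals: ``"ZW"`` (the
    heterogametic class) and ``"ZZ"`` (homogametic) are required,
    ``"WW"`` (monogenic hermaphrodites) optional.  Under the mirror
    ``male_XY`` model pass the heterogametic males as ``"ZW"`` and the
    homogametic females as ``"ZZ"``; the letters name roles, not
    chromosomes.

    A marker qualifies iff it is genotyped in every grouped individual
    and there is an allele *w* such that every ZW individual is
    heterozygous ``{w, z}`` with its other allele *z* observed among
    the ZZ group, *w* never occurs in ZZ, every ZZ individual is
    homozygous — and, if WW individuals are given, each is homozygous
    for *w*.  The phased W and Z alleles are recorded on the call.
    """
    for key in ("ZW", "ZZ"):
        if key not in groups or not len(groups[key]):
            raise ValidationError(f"group {key!r} is required and must be non-empty")
    unknown = set(groups) - {"ZW", "ZZ", "WW"}
    if unknown:
        raise ValidationError(f"unknown group labels: {sorted(unknown)}")
    het = _resolve(cat, groups["ZW"])
    hom = _resolve(cat, groups["ZZ"])
    ww = _resolve(cat, groups["WW"]) if "WW" in groups else []

    het_idx = [cat.individual_index(i.id) for i in het]
    hom_idx = [cat.individual_index(i.id) for i in hom]
    ww_idx = [cat.individual_index(i.id) for i in ww]
    all_idx = het_idx + hom_idx + ww_idx
    called = cat.called

    calls: list[SexLinkageCall] = []
    for k, m in enumerate(cat.marker_ids):
        if not called[k, all_idx].all():
            continue
        g_het = [cat.genotype[k, j] for j in het_idx]
        g_hom = [cat.genotype[k, j] for j in hom_idx]
        g_ww = [cat.genotype[k, j] for j in ww_idx]

        if any(a == b for a, b in g_het):
            continue
        if any(a != b for a, b in g_hom):
            continue
        hom_alleles = {a for a, _ in g_hom}
        w_cands = set.intersection(*(set(g) for g in g_het)) - hom_alleles
        if len(w_cands) != 1:
            continue
        w = next(iter(w_cands))
        if any((set(g) - {w}) - hom_alleles for g in g_het):
            continue
        if g_ww:
            if any(a != b for a, b in g_ww) or any(g[0] != w for g in g_ww):
                continue
        z_counts: dict[str, int] = {}
        for a, _ in g_hom:
            z_counts[a] = z_counts.get(a, 0) + 1
        z = max(sorted(z_counts), key=z_counts.get)
        calls.append(
            SexLinkageCall(
                m,
                "sexlinked_alleles",
                {"presence_pattern_ok": True, "coverage_ok": True, "zygosity_ok": True},
                {"w_allele": w, "z_allele": z},
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Hermaphrodite karyotype classification


def classify_hermaphrodites(
    cov: NormalizedCoverage,
    w_specific_markers: Sequence[str],
    hermaphrodites: Sequence[str],
    threshold_lo: float = 0.70,
    threshold_hi: float = 0.80,
) -> dict[str, str]:
    """Split hermaphrodites into monogenic (WW) and amphigenic (ZW).

    Mean normalized coverage across the W-specific markers is ~1 for a
    WW individual (two W copies) and ~0.5 for a ZW one (hemizygous).
    Individuals at or above ``threshold_hi`` are called monogenic_WW,
    at or below ``threshold_lo`` amphigenic_ZW, and anything in the
    dead zone between is left ambiguous.
    """
    if not w_specific_markers:
        raise ValidationError("classify_hermaphrodites needs >= 1 W-specific marker")
    if threshold_lo > threshold_hi:
        raise ValidationError("threshold_lo must not exceed threshold_hi")
    rows = [cov.marker_ids.index(m) for m in w_specific_markers]
    out: dict[str, str] = {}
    for ind in hermaphrodites:
        j = cov.individual_ids.index(ind)
        mean = float(np.mean(cov.values[rows, j]))
        if mean >= threshold_hi:
            out[ind] = "monogenic_WW"
        elif mean <= threshold_lo:
            out[ind] = "amphigenic_ZW"
        else:
            out[ind] = "ambiguous"
    return out


# ---------------------------------------------------------------------------
# Full discovery under one heterogametic hypothesis


@dataclass
class PopulationDiscovery:
    population: str
    w_specific: list[SexLinkageCall] = field(default_factory=list)
    z_specific: list[SexLinkageCall] = field(default_factory=list)
    sexlinked_alleles: list[SexLinkageCall] = field(default_factory=list)
    hermaphrodite_karyotypes: dict[str, str] = field(default_factory=dict)

    def ids(self, which: str) -> list[str]:
        calls: list[SexLinkageCall] = getattr(self, which)
        return [c.marker_id for c in calls if c.category != "unclassified"]


@dataclass
class ModelSummary:
    model: str
    populations: dict[str, PopulationDiscovery]
    n_W_specific: int
    n_Z_specific: int
    n_sexlinked_alleles: int
    n_total: int

    def sexlinked_ids(self, population: str | None = None) -> set[str]:
        """All completely sex-linked marker ids (optionally one population)."""
        pops = (
            [self.populations[population]]
            if population is not None
            else list(self.populations.values())
        )
        out: set[str] = set()
        for d in pops:
            out |= set(d.ids("w_specific"))
            out |= set(d.ids("z_specific"))
            out |= set(d.ids("sexlinked_alleles"))
        return out


def evaluate_model(
    cat: MarkerCatalogue,
    cov: NormalizedCoverage,
    model: SegregationModel = ZW_MODEL,
    absent_max_depth: int = 5,
    threshold_lo: float = 0.70,
    threshold_hi: float = 0.80,
) -> ModelSummary:
    """Run the full discovery under one heterogametic hypothesis.

    Per population: chromosome-specific discovery from the
    heterogametic-carrier vs homogametic contrast, hermaphrodite
    karyotype classification where applicable, then the Z-specific
    search (androdioecious only — it needs identified monogenics) and
    the sex-linked-allele screen.  Returns per-population calls plus
    marker counts (unique across populations); under ``male_XY`` the
    "W"/"Z" slots hold the Y- and X-analogous classes.
    """
    per_pop: dict[str, PopulationDiscovery] = {}
    for pop in cat.populations():
        inds = cat.individuals_in(pop)
        males = [i for i in inds if i.phenotype == "male"]
        females = [i for i in inds if i.phenotype == "female"]
        herms = [i for i in inds if i.phenotype == "hermaphrodite"]
        disc = PopulationDiscovery(pop)
        zw = model.heterogametic_sex == FEMALE_ZW

        if females and males:  # dioecious
            het, hom = (females, males) if zw else (males, females)
            disc.w_specific = find_chromosome_specific(
                cat, cov, het, hom, "W", model, absent_max_depth,
                expected_copies={i.id: 1 for i in het},
            )
            disc.sexlinked_alleles = find_sexlinked_alleles(
                cat, {"ZW": het, "ZZ": hom}, model
            )
            # Z-specific markers are unidentifiable here: both sexes carry Z
        elif herms and males:  # androdioecious
            if zw:
                disc.w_specific = find_chromosome_specific(
                    cat, cov, herms, males, "W", model, absent_max_depth
                )
                w_ids = disc.ids("w_specific")
                if w_ids:
                    disc.hermaphrodite_karyotypes = classify_hermaphrodites(
                        cov, w_ids, [i.id for i in herms], threshold_lo, threshold_hi
                    )
                    mono = [
                        i for i in herms
                        if disc.hermaphrodite_karyotypes[i.id] == "monogenic_WW"
                    ]
                    amph = [
                        i for i in herms
                        if disc.hermaphrodite_karyotypes[i.id] == "amphigenic_ZW"
                    ]
                    if mono and amph:
                        copies = {i.id: 1 for i in amph} | {i.id: 2 for i in males}
                        disc.z_specific = find_chromosome_specific(
                            cat, cov, males + amph, mono, "Z", model,
                            absent_max_depth, expected_copies=copies,
                        )
                        disc.sexlinked_alleles = find_sexlinked_alleles(
                            cat, {"ZW": amph, "ZZ": males, "WW": mono}, model
                        )
            else:
                # mirror: heterogametic males vs homogametic hermaphrodites
                disc.w_specific = find_chromosome_specific(
                    cat, cov, males, herms, "W", model, absent_max_depth,
                    expected_copies={i.id: 1 for i in males},
                )
                disc.sexlinked_alleles = find_sexlinked_alleles(
                    cat, {"ZW": males, "ZZ": herms}, model
                )
        per_pop[pop] = disc

    w_ids = {m for d in per_pop.values() for m in d.ids("w_specific")}
    z_ids = {m for d in per_pop.values() for m in d.ids("z_specific")}
    s_ids = {m for d in per_pop.values() for m in d.ids("sexlinked_alleles")}
    return ModelSummary(
        model=model.heterogametic_sex,
        populations=per_pop,
        n_W_specific=len(w_ids),
        n_Z_specific=len(z_ids),
        n_sexlinked_alleles=len(s_ids),
        n_total=len(w_ids | z_ids | s_ids),
    )
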