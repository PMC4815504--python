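"""Forward simulation of ZW populations and RAD-seq read depths.

This module is the test harness for the whole inference pipeline: it
plants a known marker architecture (autosomal, W-specific, Z-specific,
shared sex-linked, LD-flanking) in dioecious and androdioecious
populations with ZW inheritance, generates negative-binomial read
depths proportional to copy number, calls genotypes at a read-depth
threshold, and returns both the resulting :class:`MarkerCatalogue` and
the planted truth (:class:`SimTruth`) for recovery testing.

Genetic model
-------------
Sex (and hermaphroditism in androdioecious populations) is determined
by a dominant W: any individual carrying at least one W is female (in a
dioecious population) or hermaphrodite (in an androdioecious one);
ZZ individuals are male.  Self-fertilisation of an amphigenic (ZW)
hermaphrodite therefore yields WW:ZW:ZZ offspring in 1:2:1, i.e. three
hermaphrodites for every male, while monogenic (WW) hermaphrodites
self to produce only WW hermaphrodites.

Marker architecture
-------------------
* ``autosomal`` — two copies in everyone; per-population allele
  frequencies; optional restriction-site null alleles that silently
  remove a copy.
* ``W_specific`` / ``Z_specific`` — carried only on the named sex
  chromosome, so copy number equals the count of that chromosome in
  the karyotype (hemizygous in ZW, absent in the other homogametic
  class).
* ``shared_sexlinked`` — present on both W and Z with chromosome-
  diagnostic alleles, phased with the sex chromosomes (ZW het, ZZ and
  WW homozygous).  ``n_null_shared`` of these additionally segregate a
  null allele on the Z background, which defeats the strict complete-
  linkage criteria downstream — a known limitation the simulator
  reproduces on purpose.
* ``ld_flanking`` — present on both sex chromosomes; the W haplotype
  carries a designated allele while the Z background is polymorphic,
  and the locus recombines with the sex-determining block at fraction
  ``r`` per meiosis.  At ``r=0`` the W-linked allele is in complete
  gametic association with the sex-determining locus in the founding
  generation.

Read depths are drawn from a negative binomial with mean
``copies/2 * lambda_i`` (per-individual library size ``lambda_i``) and
gamma dispersion ``k``; a genotype is called iff depth reaches the
call threshold, so hemizygous markers average half the normalized
coverage of autosomal ones — the signal the inference exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalogue import Individual, MarkerCatalogue

SELF = "SELF"
_ABSENT = -1

MARKER_CATEGORIES = (
    "autosomal",
    "W_specific",
    "Z_specific",
    "shared_sexlinked",
    "ld_flanking",
)


class ModelError(ValueError):
    """A genetically impossible operation (e.g. a selfing ZZ male)."""


class ConfigError(ValueError):
    """An invalid simulation configuration."""


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class DepthModel:
    """Read-depth generative model.

    lambda_range
        Bounds (reads) for the per-individual mean depth at a diploid
        marker; each individual's ``lambda_i`` is drawn uniformly from
        this interval.  The default (200, 450) brackets typical
        high-coverage RAD libraries with autosomal medians around 300x.
    dispersion
        Gamma shape of the negative binomial (larger = closer to
        Poisson).  The default of 200 gives a coefficient of variation
        of ~9% at 300x — normalized coverage clusters tightly around
        1.0 (diploid) and 0.5 (hemizygous), the regime in which
        coverage-based karyotype inference is designed to operate.
    call_threshold
        Minimum identical-read count to call an allele; 15 by default.
    """

    lambda_range: tuple[float, float] = (200.0, 450.0)
    dispersion: float = 200.0
    call_threshold: int = 15

    def validate(self) -> None:
        lo, hi = self.lambda_range
        if not (0 < lo <= hi):
            raise ConfigError(f"lambda_range bounds must be positive, got {self.lambda_range}")
        if self.dispersion <= 0:
            raise ConfigError(f"dispersion must be > 0, got {self.dispersion}")
        if self.call_threshold < 1:
            raise ConfigError("call_threshold must be >= 1")


@dataclass
class PopSpec:
    """One simulated population.

    ``n_by_phenotype`` gives the sampled composition, e.g.
    ``{"female": 12, "male": 14}`` for a dioecious outcrosser or
    ``{"hermaphrodite": 15, "male": 6}`` for an androdioecious selfer.
    ``n_founders=None`` means an effectively infinite founding pool
    (independent Hardy-Weinberg draws); a finite pool adds drift, which
    together with selfing is what elevates genome-wide genotypic LD.
    ``n_monogenic`` optionally fixes the number of WW hermaphrodites in
    the sample (androdioecious only).
    """

    name: str
    sexual_system: str
    n_by_phenotype: dict[str, int]
    selfing_generations: int = 0
    fraction_monogenic_founders: float = 0.0
    n_founders: int | None = None
    n_monogenic: int | None = None

    def validate(self) -> None:
        if self.sexual_system not in ("dioecious", "androdioecious"):
            raise ConfigError(f"unknown sexual_system {self.sexual_system!r}")
        for ph, n in self.n_by_phenotype.items():
            if n <= 0:
                raise ConfigError(
                    f"population {self.name}: phenotype {ph!r} requested with "
                    f"count {n}; every listed phenotype needs at least one individual"
                )
        need = {"dioecious": {"female", "male"}, "androdioecious": {"hermaphrodite"}}
        missing = need[self.sexual_system] - set(self.n_by_phenotype)
        if missing:
            raise ConfigError(
                f"population {self.name} ({self.sexual_system}) requires "
                f"phenotype counts for {sorted(missing)}"
            )
        if self.sexual_system == "dioecious" and "hermaphrodite" in self.n_by_phenotype:
            raise ConfigError(f"population {self.name}: dioecious populations have no hermaphrodites")
        if self.sexual_system == "androdioecious" and "female" in self.n_by_phenotype:
            raise ConfigError(f"population {self.name}: androdioecious populations have no females")
        if not 0 <= self.fraction_monogenic_founders <= 1:
            raise ConfigError("fraction_monogenic_founders must lie in [0, 1]")
        if self.selfing_generations < 0:
            raise ConfigError("selfing_generations must be >= 0")
        if self.n_monogenic is not None:
            n_h = self.n_by_phenotype.get("hermaphrodite", 0)
            if not 0 <= self.n_monogenic <= n_h:
                raise ConfigError("n_monogenic must be between 0 and the hermaphrodite count")


@dataclass
class Architecture:
    """Planted marker counts per category."""

    n_autosomal: int = 3767
    n_w_specific: int = 18
    n_z_specific: int = 11
    n_shared_sexlinked: int = 21
    n_null_shared: int = 2
    n_ld_flanking: int = 3

    def validate(self) -> None:
        for f_ in (
            self.n_autosomal,
            self.n_w_specific,
            self.n_z_specific,
            self.n_shared_sexlinked,
            self.n_null_shared,
            self.n_ld_flanking,
        ):
            if f_ < 0:
                raise ConfigError("marker counts must be >= 0")

    @property
    def n_total(self) -> int:
        return (
            self.n_autosomal
            + self.n_w_specific
            + self.n_z_specific
            + self.n_shared_sexlinked
            + self.n_null_shared
            + self.n_ld_flanking
        )


def _default_pops() -> list[PopSpec]:
    return [
        PopSpec("ESP", "dioecious", {"female": 12, "male": 14}),
        PopSpec(
            "KOE",
            "androdioecious",
            {"hermaphrodite": 15, "male": 6},
            selfing_generations=3,
            fraction_monogenic_founders=0.2,
            n_founders=20,
            n_monogenic=4,
        ),
    ]


@dataclass
class SimConfig:
    """Full simulation configuration; defaults mirror the study design:

    a dioecious outcrossing population of 12 females + 14 males and an
    androdioecious selfing population of 15 hermaphrodites (4 of them
    monogenic) + 6 males, sharing a catalogue of 3822 markers.
    """

    seed: int = 0
    pop_specs: list[PopSpec] = field(default_factory=_default_pops)
    architecture: Architecture = field(default_factory=Architecture)
    r: float = 0.05
    depth_model: DepthModel = field(default_factory=DepthModel)
    null_allele_rate: float = 0.01
    polymorphic_fraction: float = 0.3

    def validate(self) -> None:
        if not self.pop_specs:
            raise ConfigError("at least one population required")
        names = [p.name for p in self.pop_specs]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate population names")
        for p in self.pop_specs:
            p.validate()
        self.architecture.validate()
        self.depth_model.validate()
        if not 0 <= self.r <= 0.5:
            raise ConfigError("recombination fraction r must lie in [0, 0.5]")
        if not 0 <= self.null_allele_rate <= 1:
            raise ConfigError("null_allele_rate must lie in [0, 1]")
        if not 0 <= self.polymorphic_fraction <= 1:
            raise ConfigError("polymorphic_fraction must lie in [0, 1]")


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain dict (YAML/JSON payload)."""
    d = dict(d)
    pops = [PopSpec(**p) for p in d.pop("pop_specs", [])] or _default_pops()
    for p in pops:
        if isinstance(p.n_by_phenotype, dict):
            p.n_by_phenotype = {k: int(v) for k, v in p.n_by_phenotype.items()}
    arch = Architecture(**d.pop("architecture", {}))
    dm = d.pop("depth_model", {})
    if "lambda_range" in dm:
        dm["lambda_range"] = tuple(dm["lambda_range"])
    depth = DepthModel(**dm)
    return SimConfig(pop_specs=pops, architecture=arch, depth_model=depth, **d)


# ---------------------------------------------------------------------------
# Planted truth


@dataclass
class SimTruth:
    """Planted category per marker and karyotype per individual."""

    marker_category: dict[str, str]
    individual_karyotype: dict[str, str]
    w_allele: dict[str, str] = field(default_factory=dict)
    z_allele: dict[str, str] = field(default_factory=dict)
    null_z_markers: set[str] = field(default_factory=set)

    def markers(self, category: str) -> list[str]:
        return [m for m, c in self.marker_category.items() if c == category]


def write_truth(truth: SimTruth, path: str | Path) -> None:
    rows = []
    for m, c in truth.marker_category.items():
        rows.append(
            {
                "kind": "marker",
                "id": m,
                "value": c,
                "w_allele": truth.w_allele.get(m, ""),
                "z_allele": truth.z_allele.get(m, ""),
                "null_z": int(m in truth.null_z_markers),
            }
        )
    for i, k in truth.individual_karyotype.items():
        rows.append(
            {"kind": "individual", "id": i, "value": k, "w_allele": "", "z_allele": "", "null_z": 0}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> SimTruth:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "value": str}, keep_default_na=False)
    mk = df[df["kind"] == "marker"]
    ind = df[df["kind"] == "individual"]
    return SimTruth(
        marker_category=dict(zip(mk["id"], mk["value"])),
        individual_karyotype=dict(zip(ind["id"], ind["value"])),
        w_allele={m: a for m, a in zip(mk["id"], mk["w_allele"].astype(str)) if a},
        z_allele={m: a for m, a in zip(mk["id"], mk["z_allele"].astype(str)) if a},
        null_z_markers=set(mk.loc[mk["null_z"].astype(int) == 1, "id"]),
    )


# ---------------------------------------------------------------------------
# Karyotype inheritance


def _gamete_chrom(karyotype: str, rng: np.random.Generator) -> str:
    return karyotype[rng.integers(2)]


def _karyotype_label(chrom_a: str, chrom_b: str) -> str:
    pair = "".join(sorted((chrom_a, chrom_b)))  # 'WW', 'WZ', 'ZZ'
    return "ZW" if pair == "WZ" else pair


def phenotype_of(karyotype: str, sexual_system: str) -> str:
    """Phenotype is a deterministic function of karyotype (W dominant)."""
    if "W" in karyotype:
        return "female" if sexual_system == "dioecious" else "hermaphrodite"
    return "male"


def inherit_karyotype(
    parent1: str, parent2: str | None = SELF, rng: np.random.Generator | None = None
) -> str:
    """Draw an offspring karyotype from two parents (or a selfing one).

    Each parent contributes one uniformly random sex chromosome.  Use
    ``parent2=SELF`` for self-fertilisation; only W-bearing karyotypes
    (hermaphrodites) can self.
    """
    rng = np.random.default_rng() if rng is None else rng
    for p in (parent1,) + (() if parent2 in (SELF, None) else (parent2,)):
        if p not in ("ZZ", "ZW", "WW"):
            raise ModelError(f"invalid karyotype {p!r}")
    if parent2 in (SELF, None):
        if parent1 == "ZZ":
            raise ModelError("a ZZ male cannot self-fertilise")
        parent2 = parent1
    return _karyotype_label(_gamete_chrom(parent1, rng), _gamete_chrom(parent2, rng))


# ---------------------------------------------------------------------------
# Copy number and depth


def assign_marker_copies(
    karyotype: str, marker_category: str, null_allele_state: tuple[bool, bool] = (False, False)
) -> int:
    """Number of genomic copies of a marker in a given karyotype.

    W-specific markers have one copy per W chromosome, Z-specific one
    per Z; autosomal, shared sex-linked and LD-flanking markers are
    diploid.  ``null_allele_state`` flags chromosome lineages whose
    restriction site is lost, each removing one copy.
    """
    if karyotype not in ("ZZ", "ZW", "WW"):
        raise ModelError(f"invalid karyotype {karyotype!r}")
    if marker_category not in MARKER_CATEGORIES:
        raise ModelError(f"unknown marker category {marker_category!r}")
    if marker_category == "W_specific":
        copies = karyotype.count("W")
    elif marker_category == "Z_specific":
        copies = karyotype.count("Z")
    else:
        copies = 2
    copies -= sum(bool(x) for x in null_allele_state[:copies])
    return max(copies, 0)


def draw_depth(
    copies: int, lambda_i: float, dispersion: float, rng: np.random.Generator
) -> int:
    """One negative-binomial read depth with mean ``copies/2 * lambda_i``."""
    if lambda_i <= 0:
        raise ConfigError("lambda_i must be > 0")
    if dispersion <= 0:
        raise ConfigError("dispersion must be > 0")
    if copies == 0:
        return 0
    mean = copies / 2.0 * lambda_i
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _draw_depth_vector(
    copies: np.ndarray, lambda_i: float, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    depth = np.zeros(copies.shape, dtype=np.int64)
    pos = copies > 0
    if np.any(pos):
        mean = copies[pos] / 2.0 * lambda_i
        p = dispersion / (dispersion + mean)
        depth[pos] = rng.negative_binomial(dispersion, p)
    return depth


def random_genome(length: int, gc: float, rng: np.random.Generator) -> str:
    """An i.i.d. nucleotide sequence with the given GC content."""
    if not 0 < gc < 1:
        raise ConfigError("gc must lie strictly between 0 and 1")
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(bases, size=length, p=p).tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Genomes and meiosis

# Internal marker layout: [autosomal | W_specific | Z_specific | shared |
# null_shared | ld_flanking].  The sex block (everything after the
# autosomal block) stores one allele per sex-chromosome slot, aligned
# with the individual's (chrom, chrom) pair; _ABSENT encodes a missing
# restriction site (true absence or a null allele).


class _Layout:
    def __init__(self, arch: Architecture):
        self.n_auto = arch.n_autosomal
        nW, nZ = arch.n_w_specific, arch.n_z_specific
        nS, nN, nF = arch.n_shared_sexlinked, arch.n_null_shared, arch.n_ld_flanking
        self.n_sexblock = nW + nZ + nS + nN + nF
        self.w_slice = slice(0, nW)
        self.z_slice = slice(nW, nW + nZ)
        self.shared_slice = slice(nW + nZ, nW + nZ + nS + nN)  # nulls included
        self.nullshared_slice = slice(nW + nZ + nS, nW + nZ + nS + nN)
        self.flank_slice = slice(nW + nZ + nS + nN, self.n_sexblock)
        self.n_flank = nF
        self.categories = (
            ["autosomal"] * self.n_auto
            + ["W_specific"] * nW
            + ["Z_specific"] * nZ
            + ["shared_sexlinked"] * (nS + nN)
            + ["ld_flanking"] * nF
        )
        self.null_flags = (
            [False] * (self.n_auto + nW + nZ + nS) + [True] * nN + [False] * nF
        )


class _Genome:
    __slots__ = ("chroms", "auto", "sexblock")

    def __init__(self, chroms: tuple[str, str], auto: np.ndarray, sexblock: np.ndarray):
        self.chroms = chroms  # aligned with auto/sexblock columns
        self.auto = auto  # (n_auto, 2) allele indices, _ABSENT = lost site
        self.sexblock = sexblock  # (n_sexblock, 2)

    @property
    def karyotype(self) -> str:
        return _karyotype_label(*self.chroms)


class _PopFreqs:
    """Per-population founder allele frequencies."""

    def __init__(self, layout: _Layout, cfg: SimConfig, rng: np.random.Generator):
        n_auto = layout.n_auto
        self.poly = rng.random(n_auto) < cfg.polymorphic_fraction
        maf = rng.uniform(0.1, 0.5, size=n_auto)
        which = rng.integers(2, size=n_auto)  # which allele is minor
        self.freq0 = np.where(self.poly, np.where(which == 0, maf, 1 - maf), 1.0)
        fixed_allele = rng.integers(2, size=n_auto)
        self.freq0[~self.poly] = (fixed_allele[~self.poly] == 0).astype(float)
        # Z-background allele-0 frequency at LD-flanking loci; kept at
        # intermediate frequency so the flanking polymorphism is
        # informative about the sex-linked block it rides with
        self.flank_freq0 = rng.uniform(0.3, 0.7, size=layout.n_flank)


def _founder_hap_auto(freqs: _PopFreqs, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    hap = (rng.random(freqs.freq0.shape) >= freqs.freq0).astype(np.int8)  # 0 or 1
    nulls = rng.random(hap.shape) < cfg.null_allele_rate
    hap[nulls] = _ABSENT
    return hap


def _founder_sex_hap(
    chrom: str, layout: _Layout, freqs: _PopFreqs, rng: np.random.Generator
) -> np.ndarray:
    hap = np.full(layout.n_sexblock, _ABSENT, dtype=np.int8)
    if chrom == "W":
        hap[layout.w_slice] = 0
        hap[layout.shared_slice] = 0  # the W-diagnostic allele
        hap[layout.flank_slice] = 0  # W-haplotype-private flanking variant
    else:
        hap[layout.z_slice] = 0
        hap[layout.shared_slice] = 1  # the Z-diagnostic allele
        null = rng.random(layout.nullshared_slice.stop - layout.nullshared_slice.start) < 0.5
        sub = hap[layout.nullshared_slice]
        sub[null] = _ABSENT
        hap[layout.nullshared_slice] = sub
        # Z background polymorphic for two non-W alleles: the flanking
        # marker tracks the sex-linked block without being completely
        # sex linked (within-Z polymorphism defeats the strict criteria)
        draws = rng.random(layout.n_flank) >= freqs.flank_freq0
        hap[layout.flank_slice] = draws.astype(np.int8) + 1
    return hap


def _founder(
    karyotype: str, layout: _Layout, freqs: _PopFreqs, cfg: SimConfig, rng: np.random.Generator
) -> _Genome:
    chroms = (karyotype[0], karyotype[1])
    auto = np.stack(
        [_founder_hap_auto(freqs, cfg, rng), _founder_hap_auto(freqs, cfg, rng)], axis=1
    )
    sexblock = np.stack(
        [
            _founder_sex_hap(chroms[0], layout, freqs, rng),
            _founder_sex_hap(chroms[1], layout, freqs, rng),
        ],
        axis=1,
    )
    return _Genome(chroms, auto, sexblock)


def _gamete(
    g: _Genome, layout: _Layout, r: float, rng: np.random.Generator
) -> tuple[str, np.ndarray, np.ndarray]:
    k = int(rng.integers(2))
    chrom = g.chroms[k]
    pick = rng.integers(2, size=layout.n_auto)
    auto = g.auto[np.arange(layout.n_auto), pick]
    sex = g.sexblock[:, k].copy()
    if layout.n_flank and r > 0:
        rec = rng.random(layout.n_flank) < r
        if rec.any():
            other = g.sexblock[layout.flank_slice, 1 - k]
            seg = sex[layout.flank_slice]
            seg[rec] = other[rec]
            sex[layout.flank_slice] = seg
    return chrom, auto, sex


def _cross(
    p1: _Genome, p2: _Genome, layout: _Layout, r: float, rng: np.random.Generator
) -> _Genome:
    c1, a1, s1 = _gamete(p1, layout, r, rng)
    c2, a2, s2 = _gamete(p2, layout, r, rng)
    return _Genome((c1, c2), np.stack([a1, a2], axis=1), np.stack([s1, s2], axis=1))


# ---------------------------------------------------------------------------
# Population simulation

_MAX_DRAWS = 400  # rejection-sampling attempts per requested individual


def _simulate_pop(
    spec: PopSpec, layout: _Layout, cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[tuple[str, _Genome]], _PopFreqs]:
    """Simulate one population and sample the requested composition.

    Returns (phenotype, genome) pairs in sampling order.
    ``selfing_generations`` counts the rounds of reproduction (selfing
    in androdioecious populations, random male x female mating in
    dioecious ones) separating the sample from the founders: 0 samples
    the founding generation itself, 1 samples their immediate
    offspring, and so on.  With ``n_founders=None`` each sampled
    individual descends from fresh, independent founders; a finite
    pool evolves between generations and adds genetic drift.
    """
    freqs = _PopFreqs(layout, cfg, rng)
    system = spec.sexual_system
    g = spec.selfing_generations

    def founder(karyotype: str) -> _Genome:
        return _founder(karyotype, layout, freqs, cfg, rng)

    def founder_pool(n: int) -> list[_Genome]:
        pool: list[_Genome] = []
        if system == "dioecious":
            n_f = max(n // 2, 1)
            pool += [founder("ZW") for _ in range(n_f)]
            pool += [founder("ZZ") for _ in range(n - n_f)]
        else:
            n_ww = int(round(spec.fraction_monogenic_founders * n))
            pool += [founder("WW") for _ in range(n_ww)]
            pool += [founder("ZW") for _ in range(n - n_ww)]
        return pool

    def next_generation(pool: list[_Genome]) -> list[_Genome]:
        if system == "dioecious":
            females = [x for x in pool if "W" in x.karyotype]
            males = [x for x in pool if x.karyotype == "ZZ"]
            if not females or not males:
                raise ModelError("population lost one sex during simulation")
            return [
                _cross(
                    females[rng.integers(len(females))],
                    males[rng.integers(len(males))],
                    layout,
                    cfg.r,
                    rng,
                )
                for _ in range(len(pool))
            ]
        herms = [x for x in pool if "W" in x.karyotype]
        if not herms:
            raise ModelError("population lost all hermaphrodites during selfing")
        return [
            _cross(h, h, layout, cfg.r, rng)
            for h in (herms[rng.integers(len(herms))] for _ in range(len(pool)))
        ]

    def pool_ok(pool: list[_Genome]) -> bool:
        kts = {x.karyotype for x in pool}
        if system == "dioecious":
            return "ZZ" in kts and ("ZW" in kts or "WW" in kts)
        # keep at least one amphigenic so males / ZW offspring stay drawable
        need_zw = spec.n_by_phenotype.get("male", 0) > 0 or (
            spec.n_monogenic is not None
            and spec.n_monogenic < spec.n_by_phenotype.get("hermaphrodite", 0)
        )
        return ("ZW" in kts) if need_zw else bool(kts & {"ZW", "WW"})

    # --- evolve the founding pool ---------------------------------------
    pool: list[_Genome] | None
    if spec.n_founders is None:
        if g > 1 and system == "dioecious":
            raise ConfigError(
                "dioecious populations with selfing_generations > 1 require a "
                "finite n_founders"
            )
        pool = None
    elif g >= 1:
        pool = founder_pool(spec.n_founders)
        for _ in range(g - 1):
            for _attempt in range(50):
                new = next_generation(pool)
                if pool_ok(new):
                    pool = new
                    break
            else:
                raise ModelError(
                    f"population {spec.name}: could not maintain required "
                    "karyotypes through the generations"
                )
    else:
        pool = None

    def draw_offspring() -> _Genome:
        if system == "dioecious":
            if pool is None:
                return _cross(founder("ZW"), founder("ZZ"), layout, cfg.r, rng)
            females = [x for x in pool if "W" in x.karyotype]
            males = [x for x in pool if x.karyotype == "ZZ"]
            return _cross(
                females[rng.integers(len(females))],
                males[rng.integers(len(males))],
                layout,
                cfg.r,
                rng,
            )
        if pool is None:
            # a fresh selfing lineage: single-seed descent for g-1
            # generations, then one final selfing produces the sample
            lineage = founder("WW" if rng.random() < spec.fraction_monogenic_founders else "ZW")
            for _ in range(g - 1):
                for _attempt in range(_MAX_DRAWS):
                    child = _cross(lineage, lineage, layout, cfg.r, rng)
                    if "W" in child.karyotype:  # only hermaphrodites can continue
                        lineage = child
                        break
                else:  # pragma: no cover - needs absurd luck
                    raise ModelError("selfing lineage produced only males")
            return _cross(lineage, lineage, layout, cfg.r, rng)
        herms = [x for x in pool if "W" in x.karyotype]
        h = herms[rng.integers(len(herms))]
        return _cross(h, h, layout, cfg.r, rng)

    # --- rejection-sample the requested composition ---------------------
    quotas: dict[str, int] = {}
    if system == "androdioecious" and spec.n_monogenic is not None:
        n_h = spec.n_by_phenotype.get("hermaphrodite", 0)
        quotas["WW"] = spec.n_monogenic
        quotas["ZW"] = n_h - spec.n_monogenic
        if "male" in spec.n_by_phenotype:
            quotas["ZZ"] = spec.n_by_phenotype["male"]
    else:
        for ph, n in spec.n_by_phenotype.items():
            quotas[ph] = n

    by_karyotype = "WW" in quotas or "ZW" in quotas or "ZZ" in quotas
    total = sum(quotas.values())

    if g == 0:
        # the sample *is* the founding generation
        def founder_karyotype(key: str) -> str:
            if by_karyotype:
                return key
            if key == "male":
                return "ZZ"
            if key == "female":
                return "ZW"
            return "WW" if rng.random() < spec.fraction_monogenic_founders else "ZW"

        sample = [
            (phenotype_of(kt, system), founder(kt))
            for key, nq in quotas.items()
            for kt in (founder_karyotype(key) for _ in range(nq))
        ]
        rng.shuffle(sample)
        return sample, freqs

    got: dict[str, list[_Genome]] = {k: [] for k in quotas}
    attempts = 0
    while not all(len(got[k]) >= quotas[k] for k in quotas):
        if attempts >= _MAX_DRAWS * total:
            short = {k: quotas[k] - len(got[k]) for k in quotas if len(got[k]) < quotas[k]}
            raise ModelError(
                f"population {spec.name}: could not sample requested composition "
                f"(short by {short})"
            )
        attempts += 1
        child = draw_offspring()
        key = child.karyotype if by_karyotype else phenotype_of(child.karyotype, system)
        if key in quotas and len(got[key]) < quotas[key]:
            got[key].append(child)

    sample: list[tuple[str, _Genome]] = []
    for key in quotas:
        for child in got[key]:
            sample.append((phenotype_of(child.karyotype, system), child))
    rng.shuffle(sample)  # sampling order must not encode karyotype
    return sample, freqs


def simulate_population(cfg: SimConfig) -> tuple[MarkerCatalogue, SimTruth]:
    """Run the forward simulation and emit a catalogue plus its truth.

    Deterministic given ``cfg.seed``.  Genotypes are called iff depth
    reaches ``cfg.depth_model.call_threshold``; a hemizygous call is
    reported as a homozygous-looking single allele (read counts cannot
    distinguish one copy from two identical ones — only coverage can).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    layout = _Layout(cfg.architecture)
    n_total = cfg.architecture.n_total

    # output marker order is shuffled so position carries no category signal
    perm = rng.permutation(n_total)
    marker_ids = [f"m{k + 1}" for k in range(n_total)]
    out_row = np.empty(n_total, dtype=np.int64)
    out_row[perm] = np.arange(n_total)  # internal index -> output row

    # catalogue individuals carry karyotype "unknown": resolving it is the
    # inference pipeline's job; the planted karyotype lives in SimTruth
    individuals: list[Individual] = []
    true_karyotype: dict[str, str] = {}
    genomes: list[_Genome] = []
    for spec in cfg.pop_specs:
        sample, _freqs = _simulate_pop(spec, layout, cfg, rng)
        counters: dict[str, int] = {}
        prefix = {"female": "F", "male": "M", "hermaphrodite": "H"}
        for phenotype, genome in sample:
            counters[phenotype] = counters.get(phenotype, 0) + 1
            ind_id = f"{spec.name}_{prefix[phenotype]}{counters[phenotype]:02d}"
            individuals.append(Individual(ind_id, spec.name, phenotype, "unknown"))
            true_karyotype[ind_id] = genome.karyotype
            genomes.append(genome)

    dm = cfg.depth_model
    n_ind = len(individuals)
    depth = np.zeros((n_total, n_ind), dtype=np.int64)
    geno = np.empty((n_total, n_ind), dtype=object)
    geno[:] = None
    lambdas = rng.uniform(dm.lambda_range[0], dm.lambda_range[1], size=n_ind)

    for j, genome in enumerate(genomes):
        haps = np.concatenate([genome.auto, genome.sexblock], axis=0)  # internal order
        copies = (haps != _ABSENT).sum(axis=1)
        d_int = _draw_depth_vector(copies, lambdas[j], dm.dispersion, rng)
        called = (d_int >= dm.call_threshold) & (copies > 0)
        depth[out_row, j] = d_int
        for k in np.nonzero(called)[0]:
            present = haps[k][haps[k] != _ABSENT]
            if present.size == 1:
                a = str(present[0] + 1)
                geno[out_row[k], j] = (a, a)
            else:
                a, b = sorted(str(x + 1) for x in present)
                geno[out_row[k], j] = (a, b)

    cat = MarkerCatalogue(marker_ids, individuals, geno, depth)

    marker_category = {
        marker_ids[out_row[k]]: layout.categories[k] for k in range(n_total)
    }
    w_allele: dict[str, str] = {}
    z_allele: dict[str, str] = {}
    null_z: set[str] = set()
    for k in range(n_total):
        m = marker_ids[out_row[k]]
        if layout.categories[k] == "shared_sexlinked":
            w_allele[m], z_allele[m] = "1", "2"
            if layout.null_flags[k]:
                null_z.add(m)
    truth = SimTruth(
        marker_category=marker_category,
        individual_karyotype=true_karyotype,
        w_allele=w_allele,
        z_allele=z_allele,
        null_z_markers=null_z,
    )
    return cat, truth
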