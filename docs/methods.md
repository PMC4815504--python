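# Methods

## The genetic model

Sex determination is chromosomal with a dominant W.  Karyotypes are ZZ
(male), ZW (female in a dioecious population; amphigenic hermaphrodite
in an androdioecious one) and WW (monogenic hermaphrodite).  Gametes
carry one uniformly chosen sex chromosome per parent; selfing is
possible only for W-bearers.  Phenotype is a deterministic function of
karyotype, so selfing a ZW hermaphrodite yields hermaphrodites and
males 3:1 and a WW hermaphrodite breeds true — the two facts the
whole inference leans on.

The male-heterogametic (XY) hypothesis is the exact mirror: swap the
sexes' roles and rename W→Y, Z→X.  `evaluate_model` runs the identical
discovery machinery under either hypothesis, which is how the
heterogametic sex is decided empirically: on female-heterogametic data
the XY run returns nothing.

## Marker classes and their signatures

Markers are classified from three independent signals, all computed on
a catalogue of genotype calls (unordered allele pairs) and integer read
depths:

* **presence–absence** — a chromosome-specific marker is *called* in
  every carrier of that chromosome and *absent* in every non-carrier.
  "Present" means a genotype call (which requires depth ≥ the call
  threshold, default 15 reads).  "Absent" means no call *and* depth
  below a guard band (default 5 reads), so trace read counts neither
  qualify as presence nor as clean absence; cells between the guard
  band and the call threshold disqualify the marker.  The guard band is
  a conservative choice the source data do not constrain.
* **normalized coverage** — depth divided, per individual, by the
  median depth over the reference set (by default exactly the markers
  called in all individuals; with hundreds of autosomal markers this
  estimates library size robustly).  Expected values: 1.0 for two
  copies, 0.5 for one.  The windows are [0.25, 0.75] for hemizygous and
  (0.75, 1.5] for diploid — generous bands around the theoretical
  values, configurable on `SegregationModel`.  Coverage evidence is
  judged on the *mean* over the carriers of each expected copy class
  (the marker-level reading of "coverage consistent with hemizygosity");
  carriers of unknown karyotype are checked cell-wise against the union
  of the windows.  A strict per-cell mode (`coverage_check=
  "per_carrier"`) exists but at realistic depth noise it rejects true
  markers at a rate proportional to carriers × markers, which is why it
  is not the default.
* **SNP segregation** — a marker on both sex chromosomes with
  chromosome-diagnostic alleles is heterozygous in every ZW individual,
  carrying a W allele never seen in ZZ males (and fixed homozygous in
  WW monogenics), while every ZZ male is homozygous for a Z allele.
  The discovered W/Z phase is recorded per marker.

Inference order matters in androdioecious populations: W-specific
markers first (hermaphrodites vs males), then hermaphrodite
classification by mean coverage at those markers (≥ 0.80 → WW,
≤ 0.70 → ZW, between → ambiguous; a deterministic dead-zone rule around
the 0.75 midpoint chosen over clustering for robustness at n = 15),
and only then Z-specific discovery, which needs identified monogenics
as the "absent" class.

A deliberate, reproduced limitation: a completely sex-linked marker
with a null allele segregating on the Z background (a lost restriction
site) makes some ZW individuals look homozygous and some ZZ males look
absent, so it fails the strict criteria and is left unclassified.  The
simulator plants such markers so tests can pin this behaviour down.

## Linkage disequilibrium

Genotypic LD between two markers is tested on the genotype × genotype
contingency table over individuals called at both (pairwise deletion),
with the log-likelihood-ratio statistic G = 2·Σ O·ln(O/E) and a
permutation null (default 10 000 permutations; p = (1 + #{G* ≥ G}) /
(n_perm + 1)).  The test is phase-free and picks up both gametic
association and the correlated homozygosity (identity disequilibrium)
that partial selfing generates genome-wide.  Monomorphic loci are not
testable and are excluded from denominators.  Permutations are drawn
from the table's canonical vectors, so p-values depend only on the
table (invariant to individual order) and are reproducible given the
generator.  Significance is raw p ≤ α (default 0.05), as in classical
pairwise LD screens; a multiple-testing correction is deliberately not
applied by default because the reported quantity is the *proportion* of
nominally significant pairs, compared between populations.

## Population summaries

F_ST is Weir & Cockerham's (1984) θ for diploid genotypes: variance
components a (among populations), b (among individuals within) and c
(within individuals) per locus and allele, combined as ratio of sums
Σa / Σ(a+b+c).  Negative estimates are reported as-is.  Default locus
selection mirrors the population-genotype-export convention: markers
called in all individuals of at least one population (which excludes
sex-chromosome-specific markers) and in ≥ 2 individuals of the other.
Polymorphism is the proportion of markers (among those called in every
individual of a population) with ≥ 2 alleles observed in it.

## Region-size arithmetic

Under an i.i.d. base model with GC content g, an unambiguous motif with
n_GC strong and n_AT weak bases occurs with per-position probability
p = (g/2)^n_GC · ((1−g)/2)^n_AT; expected spacing is 1/p bp.  For SbfI
(CCTGCAGG, its own reverse complement — one strand suffices) at
g = 0.47 this is ≈ 84.5 kb, rounded to the nearest 100 kb before the
extent multiplication (the exact value is also reported).  Each site
contributes two flanking RAD markers, so n_sites = round(n_markers/2)
with ties-to-even; extent = n_sites × rounded spacing.  GC heterogeneity
along the genome is out of scope.

## The simulator

`simulate_population` is the test harness: it emulates a RAD catalogue
of the study design — a dioecious outcrosser (12 females + 14 males)
and an androdioecious selfer (15 hermaphrodites, 4 of them monogenic,
+ 6 males), 3822 markers by default — with planted truth for recovery
testing.

* **Architecture** (defaults): 3767 autosomal, 18 W-specific, 11
  Z-specific, 21 shared sex-linked, 2 shared with a Z-lineage null
  allele (founder null frequency 0.5 on Z), 3 LD-flanking markers.
  Output marker order is shuffled so position carries no signal.
* **Alleles**: autosomal markers have up to two alleles; a fraction
  (default 0.3) is polymorphic per population with minor allele
  frequency U(0.1, 0.5), frequencies drawn independently per population
  (which yields strong between-population differentiation).  Shared
  sex-linked markers carry a W-diagnostic and a Z-diagnostic allele
  phased with the chromosomes.  LD-flanking markers carry a
  W-haplotype-private allele while the Z background segregates two
  other alleles at intermediate frequency (U(0.3, 0.7)) — associated
  with the sex-linked block but, in an outcrossing population, short of
  complete sex linkage; they recombine with the block at fraction r
  (default 0.05) per meiosis.  Restriction-site null alleles hit
  autosomal haplotypes at rate 0.01.
* **Populations**: `selfing_generations` counts reproduction rounds
  between founders and the sample (0 = the founding generation itself).
  With `n_founders=None` every sampled individual descends from fresh
  founders (exact Hardy–Weinberg, no LD); a finite pool (default 20 for
  the selfer) evolves by selfing (androdioecious) or random male ×
  female mating (dioecious), adding drift.  Genome-wide genotypic LD in
  the selfing population arises from drift × selfing jointly — fixed-
  generation selfing of independent founders alone produces none, which
  is why the founder pool is finite.  Generations that would lose a
  karyotype required downstream are redrawn (a mild conditioning,
  logged here for honesty); the sampled composition is rejection-
  sampled to the requested phenotype (and optionally monogenic) counts.
* **Depths**: per-individual library size λ_i ~ U(200, 450) reads;
  depth ~ NegBin(mean = copies/2 · λ_i, dispersion k = 200, i.e. CV
  ≈ 9% at 300×).  The dispersion default is deliberately low —
  normalized coverage must separate 0.5 from 1.0 per individual for
  coverage-based karyotyping to work at all, matching the tight
  clusters this method presumes; heavier overdispersion (k ≈ 10–50)
  is available for stress-testing and degrades recovery, which is the
  expected behaviour, not a bug.  Genotypes are called iff depth ≥ 15;
  a hemizygous call reports a single allele (read counts cannot
  distinguish one copy from two identical ones).

What the simulator does **not** emulate: sequencing error and barcode
artefacts, assembly (markers are given, not built from reads), PCR
duplicates, mutation during the simulated generations, overlapping
generations, migration, and GC-dependent restriction-site density.
Passing recovery tests therefore demonstrates the inference logic is
correct under the stated generative model, not that the thresholds are
optimal for any particular real library.

A consequence of taking the population genetics seriously: in the
selfing population, drift can fix the Z-side polymorphism of a planted
null-carrying or LD-flanking marker, after which that marker genuinely
segregates as completely sex-linked there and is (correctly) reported
as such.  Recovery tests therefore assert exact recovery in the
outcrossing population and treat such markers as legitimately
population-dependent, never as false positives; planted autosomal
markers must never be called anywhere.

## Numerical and interface choices

* Medians are plain midpoint-of-central-values medians.
* The repeat filter (drop markers whose mean called-cell depth exceeds
  the grand mean of marker means + 2 SD) is applied once at catalogue
  level, not iterated; with ≤ 2 markers it can never remove anything
  (the cutoff is ≥ the maximum by construction).
* The high-coverage filter is strict: depth > 20 in ≥ 6 individuals,
  with per-individual depths (not sums).
* Genepop export uses 3-digit allele coding (≥ 10 alleles possible),
  capitalised `Pop` separators and `id , ` rows; only markers called in
  every included individual may be exported, and missingness in the
  catalogue TSV is explicit (`./.:depth`) rather than encoded as a null
  allele.
* All randomness flows from one `numpy` Generator per entry point; the
  pipeline writes no timestamps, so a (config, seed) pair reproduces
  its output bundle byte for byte.
* Test and acceptance problem sizes are scaled-down versions of the
  default architecture (hundreds rather than thousands of autosomal
  markers, hundreds of permutations rather than ten thousand), sizes at
  which every recovery property is already sharply testable.
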