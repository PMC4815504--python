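# zwrad

ZW sex-linkage inference from RAD-seq marker catalogues, with a forward
simulator of dioecious and androdioecious populations.

## The problem

In many crustaceans, sex (or hermaphroditism) is determined by a dominant
W chromosome: W-bearing individuals are female — or self-fertile
hermaphrodites in androdioecious populations — and ZZ individuals are
male.  Selfing an amphigenic (ZW) hermaphrodite yields WW : ZW : ZZ
offspring in 1:2:1, i.e. three hermaphrodites per male, while monogenic
(WW) hermaphrodites breed true.  Without a reference genome, sex-linked
regions can still be mapped from a RAD-seq marker catalogue: a
marker × individual table of genotype calls and read depths.

`zwrad` classifies markers against the predictions of an explicit
heterogametic model:

| class | presence | normalized coverage | zygosity |
|---|---|---|---|
| W-specific | all W-carriers, no ZZ male | 0.5 in ZW, 1.0 in WW | single allele where hemizygous |
| Z-specific | all Z-carriers, no WW monogenic | 0.5 in ZW, 1.0 in ZZ | single allele where hemizygous |
| sex-linked alleles | everyone | ~1.0 | ZW heterozygous with a W-private allele; ZZ (and WW) homozygous |

Coverage is normalized per individual by the median depth of the markers
found in *all* individuals (a large autosomal reference), so hemizygous
markers sit near 0.5 and diploid markers near 1.0.  The same coverage
signal splits hermaphrodites into monogenic (WW, ≈1.0 at W-specific
markers) and amphigenic (ZW, ≈0.5) classes — which in turn unlocks
Z-specific discovery in androdioecious populations.  A genotypic LD
screen (G statistic on the genotype × genotype table, permutation null)
finds markers riding with the sex-linked block, and selfing-elevated
genome-wide LD.  Region sizes follow from restriction-site density: an
8-bp motif such as SbfI's CCTGCAGG occurs every
`1 / [(gc/2)^6 ((1-gc)/2)^2]` bp in an i.i.d. genome, ≈100 kb at
GC = 0.47, with two RAD markers per site.

Because real catalogues of this kind are rarely redistributable, the
package ships a forward simulator (`zwrad.simulate`) that plants a known
marker architecture — autosomal, W-specific, Z-specific, shared
sex-linked (optionally with Z-lineage null alleles) and LD-flanking
markers — in dioecious outcrossing and androdioecious selfing
populations, with negative-binomial read depths proportional to copy
number.  Every inference stage is tested by recovery against the
planted truth.

## Worked example

Simulate both study populations (a dioecious outcrosser of 12 females +
14 males; an androdioecious selfer of 15 hermaphrodites + 6 males) with
18 W-specific, 11 Z-specific, 21 shared sex-linked, 2 null-carrying and
3 LD-flanking markers planted among 300 autosomal ones, then run the
whole pipeline:

```bash
cat > run.yaml <<'YAML'
seed: 11
simulate:
  architecture: {n_autosomal: 300, n_w_specific: 18, n_z_specific: 11,
                 n_shared_sexlinked: 21, n_null_shared: 2, n_ld_flanking: 3}
ld: {enabled: true, n_perm: 500, max_markers: 40}
YAML
zwrad run-all --config run.yaml --out out/
```

prints (from `out/summary.txt`):

```
zwrad pipeline summary (seed=11)

markers: 355 input, 355 after filtering, 310 in the normalization reference
ZW model: 18 W-specific, 11 Z-specific, 24 with sex-linked alleles (53 total)
XY model: 0 W-specific, 0 Z-specific, 0 with sex-linked alleles (0 total)
LD ESP: 235/780 pairs significant; 231 involve a sex-linked marker
LD KOE: 575/780 pairs significant; 539 involve a sex-linked marker
polymorphism ESP: 108/334 (32.3%)
polymorphism KOE: 86/313 (27.5%)
F_ST = 0.779 over 337 loci
expected CCTGCAGG spacing: 84.5 kb (rounded 100 kb)
sex-linked extent ESP: 2000 kb
sex-linked extent KOE: 2600 kb
```

Reading this: all 18 planted W-specific and 11 Z-specific markers are
recovered, and only under the female-heterogametic (ZW) hypothesis —
the male-XY mirror finds nothing, which is how the heterogametic sex is
diagnosed.  The 24 markers with sex-linked alleles are the 21 planted
clean ones plus 3 whose within-Z polymorphism (a null allele or a
flanking variant) drifted away in the selfing population, making them
completely sex-linked there.  The LD screen (which keeps all sex-linked
markers plus autosomal fill-in, 40 markers total here) shows the
selfing population's elevated genome-wide LD, and the region-size
arithmetic converts sex-linked marker counts into physical extents via
the 100 kb SbfI spacing.

Other subcommands: `simulate`, `filter`, `discover`, `ld`, `popgen`,
`regionsize`, `genepop` (3-digit Genepop export of markers found in all
individuals).  The same functionality is importable (`zwrad.preprocess`,
`zwrad.evaluate_model`, `zwrad.ld_screen`, ...).

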