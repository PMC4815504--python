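"""Sex-linked marker discovery and hermaphrodite classification."""

import numpy as np
import pytest

import zwrad as z
from conftest import small_paper_shaped_config


def _esp_groups(cat):
    inds = cat.individuals_in("ESP")
    return (
        [i for i in inds if i.phenotype == "female"],
        [i for i in inds if i.phenotype == "male"],
    )


def test_w_specific_recovery_in_dioecious_population(paper_run):
    """Exactly the planted W-specific markers pass the female-present /
    male-absent filter with hemizygous coverage and a single allele."""
    cat_f, cov, _, _, truth = paper_run
    females, males = _esp_groups(cat_f)
    calls = z.find_chromosome_specific(
        cat_f, cov, females, males, "W",
        expected_copies={i.id: 1 for i in females},
    )
    found = {c.marker_id for c in calls if c.category == "W_specific"}
    assert found == set(truth.markers("W_specific"))


def test_marker_present_everywhere_is_excluded(paper_run):
    cat_f, cov, _, _, truth = paper_run
    females, males = _esp_groups(cat_f)
    calls = z.find_chromosome_specific(cat_f, cov, females, males, "W")
    reported = {c.marker_id for c in calls}
    shared = set(truth.markers("shared_sexlinked"))
    assert not reported & shared  # present in males too -> fails absence


def test_overlapping_groups_rejected(paper_run):
    cat_f, cov, _, _, _ = paper_run
    females, males = _esp_groups(cat_f)
    with pytest.raises(z.ValidationError, match="overlap"):
        z.find_chromosome_specific(cat_f, cov, females, males + females[:1], "W")


def test_z_specific_recovery_requires_monogenics(paper_run):
    """The Z-specific class (present in males and amphigenics, absent in
    monogenics) is recovered exactly in the androdioecious population."""
    cat_f, _, _, disc, truth = paper_run
    koe = disc.populations["KOE"]
    assert set(koe.ids("z_specific")) == set(truth.markers("Z_specific"))
    # and is invisible in the dioecious population, where every
    # individual carries at least one Z
    esp = disc.populations["ESP"]
    assert esp.ids("z_specific") == []


def test_sexlinked_alleles_recovered_with_correct_phase(paper_run):
    cat_f, cov, _, disc, truth = paper_run
    esp = disc.populations["ESP"]
    clean_shared = set(truth.markers("shared_sexlinked")) - truth.null_z_markers
    calls = {
        c.marker_id: c
        for c in esp.sexlinked_alleles
        if c.category == "sexlinked_alleles"
    }
    assert set(calls) == clean_shared
    for m, call in calls.items():
        assert call.phased_alleles == {
            "w_allele": truth.w_allele[m],
            "z_allele": truth.z_allele[m],
        }


def test_monomorphic_marker_cannot_have_sexlinked_alleles():
    inds = [z.Individual("f1", "P", "female"), z.Individual("m1", "P", "male")]
    geno = np.empty((1, 2), dtype=object)
    geno[0] = [("a", "a"), ("a", "a")]
    cat = z.MarkerCatalogue(["m1"], inds, geno, np.full((1, 2), 100))
    calls = z.find_sexlinked_alleles(cat, {"ZW": [inds[0]], "ZZ": [inds[1]]})
    assert calls == []


def test_heterozygous_males_qualify_only_under_xy():
    """A marker heterozygous in all males with a male-private allele is
    the mirror image: found when males are treated as heterogametic."""
    inds = [z.Individual("f1", "P", "female"), z.Individual("f2", "P", "female"),
            z.Individual("m1", "P", "male"), z.Individual("m2", "P", "male")]
    geno = np.empty((1, 4), dtype=object)
    geno[0] = [("z", "z"), ("z", "z"), ("w", "z"), ("w", "z")]
    cat = z.MarkerCatalogue(["m1"], inds, geno, np.full((1, 4), 100))
    females, males = inds[:2], inds[2:]
    assert z.find_sexlinked_alleles(cat, {"ZW": females, "ZZ": males}) == []
    mirror = z.find_sexlinked_alleles(cat, {"ZW": males, "ZZ": females})
    assert [c.marker_id for c in mirror] == ["m1"]


def test_null_allele_shared_marker_not_classified(paper_run):
    """A completely sex-linked marker with a null allele segregating on
    the Z background defeats the strict criteria: hermaphrodite-line
    carriers of the null look homozygous, so the marker stays
    unclassified in the dioecious population."""
    cat_f, _, _, disc, truth = paper_run
    assert truth.null_z_markers  # the architecture plants them
    esp_found = set(disc.populations["ESP"].ids("sexlinked_alleles"))
    esp_found |= set(disc.populations["ESP"].ids("w_specific"))
    assert not esp_found & truth.null_z_markers


# ---------------------------------------------------------------------------
# Hermaphrodite classification


def _cov_from_values(values, ind_ids):
    values = np.asarray(values, dtype=float)
    markers = [f"w{k}" for k in range(values.shape[0])]
    return z.NormalizedCoverage(markers, list(ind_ids), values, markers)


@pytest.mark.parametrize(
    "mean_cov, expected",
    [(1.0, "monogenic_WW"), (0.5, "amphigenic_ZW"), (0.75, "ambiguous")],
)
def test_hermaphrodite_thresholds(mean_cov, expected):
    cov = _cov_from_values([[mean_cov], [mean_cov]], ["h1"])
    out = z.classify_hermaphrodites(cov, ["w0", "w1"], ["h1"])
    assert out["h1"] == expected


def test_classification_needs_markers():
    cov = _cov_from_values([[1.0]], ["h1"])
    with pytest.raises(z.ValidationError):
        z.classify_hermaphrodites(cov, [], ["h1"])


def test_all_simulated_hermaphrodites_classified_correctly(paper_run):
    cat_f, _, _, disc, truth = paper_run
    kts = disc.populations["KOE"].hermaphrodite_karyotypes
    assert len(kts) == 15
    mapping = {"monogenic_WW": "WW", "amphigenic_ZW": "ZW"}
    assert all(v != "ambiguous" for v in kts.values())
    assert all(mapping[v] == truth.individual_karyotype[k] for k, v in kts.items())
    assert sum(v == "monogenic_WW" for v in kts.values()) == 4


# ---------------------------------------------------------------------------
# Model-level properties


def test_no_marker_lands_in_two_categories(paper_run):
    _, _, _, disc, _ = paper_run
    for d in disc.populations.values():
        w = set(d.ids("w_specific"))
        zs = set(d.ids("z_specific"))
        sl = set(d.ids("sexlinked_alleles"))
        assert not (w & zs) and not (w & sl) and not (zs & sl)


def test_xy_evaluation_of_zw_data_finds_nothing(paper_run):
    cat_f, cov, _, _, _ = paper_run
    xy = z.evaluate_model(cat_f, cov, z.XY_MODEL)
    assert (xy.n_W_specific, xy.n_Z_specific, xy.n_sexlinked_alleles) == (0, 0, 0)


def test_sex_relabelling_symmetry():
    """Swapping the male/female labels and evaluating under the male-XY
    mirror reproduces the female-ZW results marker for marker."""
    cfg = small_paper_shaped_config(seed=4)
    cfg.pop_specs = [cfg.pop_specs[0]]  # dioecious population only
    cat, _ = z.simulate_population(cfg)
    cat_f, cov, _ = z.preprocess(cat)
    zw = z.evaluate_model(cat_f, cov, z.ZW_MODEL)

    swap = {"female": "male", "male": "female"}
    flipped = z.MarkerCatalogue(
        list(cat_f.marker_ids),
        [
            z.Individual(i.id, i.population, swap[i.phenotype], i.karyotype)
            for i in cat_f.individuals
        ],
        cat_f.genotype.copy(),
        cat_f.depth.copy(),
    )
    cov_flipped = z.NormalizedCoverage(
        list(cov.marker_ids), list(cov.individual_ids), cov.values.copy(),
        list(cov.reference_marker_ids),
    )
    xy = z.evaluate_model(flipped, cov_flipped, z.XY_MODEL)
    for pop in zw.populations:
        for kind in ("w_specific", "z_specific", "sexlinked_alleles"):
            assert sorted(zw.populations[pop].ids(kind)) == sorted(
                xy.populations[pop].ids(kind)
            )


def test_autosomal_only_catalogue_yields_zero_everywhere():
    pop_e = z.PopSpec("ESP", "dioecious", {"female": 6, "male": 6})
    pop_k = z.PopSpec(
        "KOE", "androdioecious", {"hermaphrodite": 8, "male": 4},
        selfing_generations=2, n_founders=12, fraction_monogenic_founders=0.25,
        n_monogenic=3,
    )
    cfg = z.SimConfig(
        seed=9, pop_specs=[pop_e, pop_k], architecture=z.Architecture(80, 0, 0, 0, 0, 0)
    )
    cat, _ = z.simulate_population(cfg)
    cov = z.normalize_depths(cat)
    for model in (z.ZW_MODEL, z.XY_MODEL):
        s = z.evaluate_model(cat, cov, model)
        assert s.n_total == 0
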