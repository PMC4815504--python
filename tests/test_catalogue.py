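"""Catalogue data model, TSV round trips and Genepop export."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import zwrad as z
from conftest import toy_catalogue


def test_toy_catalogue_shape_and_missingness():
    cat = toy_catalogue()
    assert (cat.n_markers, cat.n_individuals) == (2, 3)
    assert int((~cat.called).sum()) == 1
    assert cat.genotype[1, 1] is None and cat.depth[1, 1] == 8


def test_read_write_roundtrip_is_identity(tmp_path):
    cat = toy_catalogue()
    z.write_catalogue(cat, tmp_path / "cat.tsv")
    z.write_metadata(cat.individuals, tmp_path / "meta.tsv")
    back = z.read_catalogue(tmp_path / "cat.tsv", tmp_path / "meta.tsv")
    assert back.marker_ids == cat.marker_ids
    assert back.individuals == cat.individuals
    assert np.array_equal(back.depth, cat.depth)
    assert all(
        back.genotype[k, j] == cat.genotype[k, j]
        for k in range(2)
        for j in range(3)
    )


def test_malformed_header_names_line(tmp_path):
    meta = tmp_path / "meta.tsv"
    z.write_metadata(toy_catalogue().individuals, meta)
    bad = tmp_path / "bad.tsv"
    bad.write_text("locus\tESP_F01\nm1\ta/a:30\n")
    with pytest.raises(z.FormatError, match="line 1"):
        z.read_catalogue(bad, meta)


def test_sample_missing_from_metadata(tmp_path):
    cat = toy_catalogue()
    z.write_catalogue(cat, tmp_path / "cat.tsv")
    z.write_metadata(cat.individuals[:2], tmp_path / "meta.tsv")
    with pytest.raises(z.MetadataError, match="ESP_M02"):
        z.read_catalogue(tmp_path / "cat.tsv", tmp_path / "meta.tsv")


@pytest.mark.parametrize(
    "cell, exc",
    [
        ("a/a:-3", z.ValidationError),
        ("a:30", z.FormatError),
        ("a/a:x", z.FormatError),
    ],
)
def test_bad_cells_rejected(tmp_path, cell, exc):
    meta = tmp_path / "meta.tsv"
    z.write_metadata([z.Individual("i1", "P", "male")], meta)
    bad = tmp_path / "bad.tsv"
    bad.write_text(f"marker_id\ti1\nm1\t{cell}\n")
    with pytest.raises(exc):
        z.read_catalogue(bad, meta)


def test_females_and_hermaphrodites_cannot_share_a_population():
    inds = [
        z.Individual("a", "P", "female"),
        z.Individual("b", "P", "hermaphrodite"),
    ]
    geno = np.empty((1, 2), dtype=object)
    geno[0] = [("x", "x"), ("x", "x")]
    with pytest.raises(z.MetadataError):
        z.MarkerCatalogue(["m1"], inds, geno, np.array([[20, 20]]))


# ---------------------------------------------------------------------------
# Genepop


def _genepop_catalogue():
    inds = [
        z.Individual("A1", "P1", "female"),
        z.Individual("A2", "P1", "male"),
        z.Individual("B1", "P2", "hermaphrodite"),
    ]
    geno = np.empty((2, 3), dtype=object)
    geno[0] = [("a1", "a2"), ("a1", "a1"), ("a2", "a2")]
    geno[1] = [("t", "t"), ("g", "t"), ("g", "g")]
    depth = np.full((2, 3), 100)
    return z.MarkerCatalogue(["m1", "m2"], inds, geno, depth)


def test_genepop_dialect(tmp_path):
    out = tmp_path / "out.gen"
    z.write_genepop(_genepop_catalogue(), ["m1", "m2"], out, title="toy")
    lines = out.read_text().splitlines()
    assert lines[0] == "toy"
    assert lines[1:3] == ["m1", "m2"]
    assert lines.count("Pop") == 2  # capitalised separator per population
    het_line = next(l for l in lines if l.startswith("A1"))
    assert het_line.startswith("A1 , ")  # comma after the id
    assert het_line.split()[2] == "001002"  # heterozygote coding


def test_genepop_missing_genotype_is_precondition_error(tmp_path):
    cat = toy_catalogue()
    with pytest.raises(z.ValidationError, match="m2"):
        z.write_genepop(cat, ["m2"], tmp_path / "x.gen")


def test_genepop_too_many_alleles(tmp_path):
    inds = [z.Individual(f"i{k}", "P", "male") for k in range(120)]
    geno = np.empty((1, 120), dtype=object)
    geno[0] = [(f"a{k}", f"a{k}") for k in range(120)]
    cat = z.MarkerCatalogue(["m1"], inds, geno, np.full((1, 120), 50))
    with pytest.raises(z.ValidationError, match="99"):
        z.write_genepop(cat, ["m1"], tmp_path / "x.gen")


def test_genepop_auto_selection_excludes_exactly_incomplete_markers(tmp_path):
    cat = toy_catalogue()
    written = z.write_genepop(cat, None, tmp_path / "x.gen")
    assert written == ["m1"]  # m2 has a missing genotype


def _parse_genepop(path):
    """Independent minimal Genepop reader used as the round-trip oracle."""
    lines = path.read_text().splitlines()
    markers = []
    i = 1
    while lines[i] != "Pop":
        markers.append(lines[i])
        i += 1
    genotypes = {}  # (individual, marker) -> (code, code)
    while i < len(lines):
        assert lines[i] == "Pop"
        i += 1
        while i < len(lines) and lines[i] != "Pop":
            ind, _, rest = lines[i].partition(" , ")
            fields = rest.split()
            assert len(fields) == len(markers)
            for m, f in zip(markers, fields):
                genotypes[(ind, m)] = tuple(sorted((int(f[:3]), int(f[3:]))))
            i += 1
    return markers, genotypes


def test_genepop_roundtrip_against_independent_parser(tmp_path):
    pop = z.PopSpec(
        "KOE", "androdioecious", {"hermaphrodite": 15, "male": 6},
        selfing_generations=3, fraction_monogenic_founders=0.2,
        n_founders=20, n_monogenic=4,
    )
    arch = z.Architecture(40, 0, 0, 5, 0, 0)
    cat, _ = z.simulate_population(
        z.SimConfig(seed=7, pop_specs=[pop], architecture=arch)
    )
    out = tmp_path / "koe.gen"
    written = z.write_genepop(cat, None, out)
    markers, parsed = _parse_genepop(out)
    assert markers == written
    for m in written:
        k = cat.marker_index(m)
        alleles = cat.alleles_at(m)
        code = {a: i + 1 for i, a in enumerate(alleles)}
        for ind in cat.individuals:
            g = cat.genotype[k, cat.individual_index(ind.id)]
            expect = tuple(sorted((code[g[0]], code[g[1]])))
            assert parsed[(ind.id, m)] == expect


def test_default_simulation_parses_cleanly(tmp_path):
    """The full-scale default simulation (3822 markers x 47 individuals)
    survives a disk round trip with zero validation errors."""
    cat, truth = z.simulate_population(z.SimConfig(seed=1))
    assert (cat.n_markers, cat.n_individuals) == (3822, 47)
    cat.validate_call_threshold(15)
    z.write_catalogue(cat, tmp_path / "cat.tsv")
    z.write_metadata(cat.individuals, tmp_path / "meta.tsv")
    back = z.read_catalogue(tmp_path / "cat.tsv", tmp_path / "meta.tsv")
    assert back.marker_ids == cat.marker_ids
    assert np.array_equal(back.depth, cat.depth)
    assert len(truth.marker_category) == 3822
    assert len(truth.individual_karyotype) == 47


@st.composite
def catalogues(draw):
    n_m = draw(st.integers(1, 4))
    n_i = draw(st.integers(1, 4))
    inds = [z.Individual(f"i{k}", "P", "male") for k in range(n_i)]
    geno = np.empty((n_m, n_i), dtype=object)
    depth = np.zeros((n_m, n_i), dtype=np.int64)
    alleles = st.text(alphabet="acgt", min_size=1, max_size=3)
    for k in range(n_m):
        for j in range(n_i):
            if draw(st.booleans()):
                pair = tuple(sorted((draw(alleles), draw(alleles))))
                geno[k, j] = pair
                depth[k, j] = draw(st.integers(15, 1000))
            else:
                geno[k, j] = None
                depth[k, j] = draw(st.integers(0, 14))
    return z.MarkerCatalogue([f"m{k}" for k in range(n_m)], inds, geno, depth)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(catalogues())
def test_roundtrip_property(tmp_path_factory, cat):
    tmp = tmp_path_factory.mktemp("rt")
    z.write_catalogue(cat, tmp / "c.tsv")
    z.write_metadata(cat.individuals, tmp / "m.tsv")
    back = z.read_catalogue(tmp / "c.tsv", tmp / "m.tsv")
    assert np.array_equal(back.depth, cat.depth)
    assert all(
        back.genotype[k, j] == cat.genotype[k, j]
        for k in range(cat.n_markers)
        for j in range(cat.n_individuals)
    )
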