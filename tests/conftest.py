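import numpy as np
import pytest

import zwrad as z


def toy_catalogue():
    """2 markers x 3 individuals with exactly one missing genotype cell."""
    inds = [
        z.Individual("ESP_F01", "ESP", "female"),
        z.Individual("ESP_M01", "ESP", "male"),
        z.Individual("ESP_M02", "ESP", "male"),
    ]
    geno = np.empty((2, 3), dtype=object)
    geno[0] = [("a1", "a2"), ("a1", "a1"), ("a2", "a2")]
    geno[1] = [("c", "c"), None, ("c", "t")]
    depth = np.array([[300, 310, 290], [150, 8, 305]])
    return z.MarkerCatalogue(["m1", "m2"], inds, geno, depth)


def small_paper_shaped_config(seed, **overrides):
    """Both study populations with the full marker architecture, scaled
    down to 300 autosomal markers for fast tests."""
    arch = z.Architecture(
        n_autosomal=300,
        n_w_specific=18,
        n_z_specific=11,
        n_shared_sexlinked=21,
        n_null_shared=2,
        n_ld_flanking=3,
    )
    return z.SimConfig(seed=seed, architecture=arch, **overrides)


@pytest.fixture(scope="session")
def paper_sim():
    """One scaled paper-shaped simulation shared across read-only tests."""
    cat, truth = z.simulate_population(small_paper_shaped_config(seed=1))
    return cat, truth


@pytest.fixture(scope="session")
def paper_run(paper_sim):
    """Filter + normalize + ZW discovery on the shared simulation."""
    cat, truth = paper_sim
    cat_f, cov, report = z.preprocess(cat)
    disc = z.evaluate_model(cat_f, cov, z.ZW_MODEL)
    return cat_f, cov, report, disc, truth


def matched_pair_catalogues(seed, n_markers=200, generations=6, n_founders=15):
    """A selfing and an outcrossing population simulated from identical
    ancestral allele frequencies (same seed drives the frequency draws),
    differing only in mating system."""
    arch = z.Architecture(n_markers, 0, 0, 0, 0, 0)
    out_pop = z.PopSpec(
        "P", "dioecious", {"female": 10, "male": 10},
        selfing_generations=generations, n_founders=n_founders,
    )
    self_pop = z.PopSpec(
        "P", "androdioecious", {"hermaphrodite": 15, "male": 5},
        selfing_generations=generations, fraction_monogenic_founders=0.2,
        n_founders=n_founders,
    )
    cat_out, _ = z.simulate_population(
        z.SimConfig(seed=seed, pop_specs=[out_pop], architecture=arch,
                    polymorphic_fraction=0.8)
    )
    cat_self, _ = z.simulate_population(
        z.SimConfig(seed=seed, pop_specs=[self_pop], architecture=arch,
                    polymorphic_fraction=0.8)
    )
    return cat_out, cat_self
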