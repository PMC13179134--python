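"""Synthetic-section generator: determinism, placement laws, field model."""

import numpy as np
import pytest
from scipy import stats as sps

from marrowmap import (SimulationConfig, compute_cxcl12_field,
                       generate_section, place_cells, simulate_lda)
from marrowmap.containers import Primitive, StructureSet
from marrowmap.distances import assign_region, region_proportions
from marrowmap.errors import (ContractError, DegenerateWeightsError,
                              ValidationError)
from .conftest import spawn_seeds


def test_generator_is_deterministic(small_config):
    g1, v1, s1 = generate_section(small_config)
    g2, v2, s2 = generate_section(small_config)
    assert np.array_equal(g1.marrow_mask, g2.marrow_mask)
    for a, b in zip(v1.primitives + s1.primitives,
                    v2.primitives + s2.primitives):
        assert np.array_equal(a.coordinates, b.coordinates)
    f1 = compute_cxcl12_field(g1, s1, small_config)
    f2 = compute_cxcl12_field(g2, s2, small_config)
    assert np.array_equal(f1.values, f2.values)
    c1 = place_cells(g1, f1, 50, 2.0, seed=5)
    c2 = place_cells(g2, f2, 50, 2.0, seed=5)
    assert np.array_equal(c1.coords, c2.coords)


def test_no_vessels_gives_empty_set_and_valid_geometry(small_config):
    cfg = small_config.replace(n_vessels=0)
    geometry, vessels, stromal = generate_section(cfg)
    assert len(vessels) == 0
    assert geometry.marrow_mask.any()
    assert len(stromal) == cfg.n_stromal


def test_structures_inside_bounding_box(small_section):
    geometry, vessels, stromal = small_section
    for prim in vessels.primitives + stromal.primitives:
        c = np.atleast_2d(prim.coordinates)
        assert np.all(c[:, 0] >= 0) and np.all(c[:, 0] <= geometry.length_um)
        assert np.all(c[:, 1] >= 0) and np.all(c[:, 1] <= geometry.width_um)


def test_unenriched_stroma_follows_area_fractions(small_config):
    """With enrichment 1 the stromal placement is uniform: pooled counts
    over many seeds pass a binomial test against the PM+DM area share."""
    cfg = small_config.replace(stromal_pm_dm_enrichment=1.0, n_stromal=20)
    geometry, _, _ = generate_section(cfg)
    area = geometry.region_area_fractions()
    p_meta = area["PM"] + area["DM"]
    in_meta = total = 0
    for seed in spawn_seeds(101, 300):
        _, _, stromal = generate_section(cfg.replace(seed=seed))
        labels = geometry.region_of(stromal.centers()[:, 0])
        in_meta += int(np.sum(labels != "CM"))
        total += len(labels)
    p = sps.binomtest(in_meta, total, p_meta).pvalue
    assert p > 1e-3


def test_enriched_stroma_concentrates_in_metaphyses(small_config):
    cfg = small_config.replace(stromal_pm_dm_enrichment=8.0, n_stromal=200)
    geometry, _, stromal = generate_section(cfg)
    labels = geometry.region_of(stromal.centers()[:, 0])
    area = geometry.region_area_fractions()
    frac_meta = np.mean(labels != "CM")
    assert frac_meta > area["PM"] + area["DM"]


# ----------------------------- chemokine field -----------------------------

def test_field_constant_without_sources(small_config):
    cfg = small_config.replace(n_stromal=0, dpp4_activity=0.0,
                               baseline_c0=0.7)
    geometry, _, stromal = generate_section(cfg)
    field = compute_cxcl12_field(geometry, stromal, cfg)
    assert np.allclose(field.values, 0.7)


def test_field_single_source_matches_exponential_kernel(small_config):
    cfg = small_config.replace(dpp4_activity=0.0, baseline_c0=0.0,
                               source_amplitude=2.0, decay_length_um=40.0)
    geometry, _, _ = generate_section(cfg)
    src = np.array([300.0, 150.0])
    stromal = StructureSet(
        primitives=[Primitive(kind="point", coordinates=src)],
        label="stromal", marks={"gpc3_level": np.array([1.0])})
    field = compute_cxcl12_field(geometry, stromal, cfg)
    xg, yg = geometry.pixel_centers()
    d = np.hypot(xg - src[0], yg - src[1])
    expected = 2.0 * np.exp(-d / 40.0)
    assert np.allclose(field.values, expected, atol=1e-12)


def test_full_degradation_without_protection_zeroes_field(small_config):
    cfg = small_config.replace(dpp4_activity=1.0, gpc3_strength=0.0)
    geometry, _, stromal = generate_section(cfg)
    field = compute_cxcl12_field(geometry, stromal, cfg)
    assert np.allclose(field.values, 0.0)


def test_field_requires_gpc3_mark(small_config):
    geometry, _, stromal = generate_section(small_config)
    bare = StructureSet(primitives=stromal.primitives, label="stromal")
    with pytest.raises(ContractError):
        compute_cxcl12_field(geometry, bare, small_config)


def test_protease_depresses_central_marrow(small_config):
    """With metaphysis-enriched GPC3 hotspots, DPP4 activity lowers the
    CM mean; switching the protease off raises it (all else fixed)."""
    from marrowmap.stats import regional_field_summary
    geometry, _, stromal = generate_section(small_config)
    with_k = compute_cxcl12_field(geometry, stromal, small_config)
    without = compute_cxcl12_field(geometry, stromal,
                                   small_config.replace(dpp4_activity=0.0))
    s_with = regional_field_summary(with_k, geometry)
    s_without = regional_field_summary(without, geometry)
    assert s_with.compartment_means["PM"] > s_with.compartment_means["CM"]
    assert s_without.compartment_means["CM"] > \
        s_with.compartment_means["CM"]
    assert s_with.ratio > s_without.ratio > 0


# ------------------------------- cell placement ----------------------------

def test_uniform_placement_calibrated(small_config, small_field):
    """beta = 0: regional counts pass a multinomial chi-square GOF against
    marrow-area fractions in >= 95% of seeds at alpha = 0.01."""
    geometry, _, _ = generate_section(small_config)
    area = geometry.region_area_fractions()
    regions = ("PM", "CM", "DM")
    expected = np.array([1000 * area[r] for r in regions])
    not_rejected = 0
    seeds = spawn_seeds(77, 200)
    for seed in seeds:
        cells = place_cells(geometry, small_field, 1000, 0.0, seed)
        labels = assign_region(cells, geometry).labels
        observed = np.array([np.sum(labels == r) for r in regions])
        if sps.chisquare(observed, expected).pvalue > 0.01:
            not_rejected += 1
    assert not_rejected >= 0.95 * len(seeds)


def test_attraction_concentrates_cells_in_metaphyses(small_config,
                                                     small_field):
    geometry, _, _ = generate_section(small_config)
    for seed in spawn_seeds(3, 50):
        uni = place_cells(geometry, small_field, 400, 0.0, seed)
        att = place_cells(geometry, small_field, 400, 8.0, seed)

        def meta_fraction(cells):
            p = region_proportions(assign_region(cells, geometry))
            return p["PM"] + p["DM"]

        assert meta_fraction(att) > meta_fraction(uni)


def test_cells_inside_marrow_and_counts(small_config, small_field):
    geometry, _, _ = generate_section(small_config)
    cells = place_cells(geometry, small_field, 1, 0.0, seed=1)
    assert len(cells) == 1
    many = place_cells(geometry, small_field, 500, 3.0, seed=1)
    res = geometry.resolution_um
    cols = (many.x_um / res).astype(int)
    rows = (many.y_um / res).astype(int)
    assert geometry.marrow_mask[rows, cols].all()


def test_zero_field_with_attraction_is_degenerate(small_config):
    from marrowmap.containers import ChemokineField
    geometry, _, _ = generate_section(small_config)
    zero = ChemokineField(values=np.zeros(geometry.shape),
                          resolution_um=geometry.resolution_um)
    with pytest.raises(DegenerateWeightsError):
        place_cells(geometry, zero, 10, 2.0, seed=0)
    # beta = 0 ignores the field entirely
    assert len(place_cells(geometry, zero, 10, 0.0, seed=0)) == 10


# ------------------------------- LDA simulation ----------------------------

def test_simulate_lda_closed_form_rate():
    """f = 1/100 at dose 100: response probability 1-(0.99)^100 = 0.634."""
    data = simulate_lda(0.01, [100], [10_000], seed=8)
    rate = data.table["n_responding"].iloc[0] / 10_000
    assert rate == pytest.approx(1 - 0.99 ** 100, abs=0.02)


def test_simulate_lda_certain_response_and_determinism():
    d1 = simulate_lda(1.0, [1, 10], [20, 20], seed=3)
    assert (d1.table["n_responding"] == d1.table["n_tested"]).all()
    d2 = simulate_lda(0.05, [10, 100], [15, 15], seed=11)
    d3 = simulate_lda(0.05, [10, 100], [15, 15], seed=11)
    assert d2.table.equals(d3.table)


@pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
def test_simulate_lda_frequency_validation(bad):
    with pytest.raises(ValidationError):
        simulate_lda(bad, [10], [5], seed=0)
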