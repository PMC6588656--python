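"""Shared fixtures: small deterministic populations built once per session."""

import pytest

from traingp import kinship, phenoblue, simdata

TREND_SEED = 11


@pytest.fixture(scope="session")
def tiny_map():
    return simdata.GeneticMap.uniform(2, 25, 100.0)


@pytest.fixture(scope="session")
def small_bundle(tiny_map):
    """8 crosses x 12 lines: design, dosages, GRM, blues — cheap utility data."""
    design = simdata.design_crosses(
        8,
        (simdata.UsageBucket(2, 3, None), simdata.UsageBucket(2, 2, 2), simdata.UsageBucket(4, 1, 1)),
        n_bi=7,
        n_tri=1,
        lines_per_cross=12,
        seed=4,
    )
    pop = simdata.generate_population(design, tiny_map, seed=4)
    filt, _, _ = kinship.filter_segregating(pop)
    grm = kinship.stabilize(kinship.compute_grm(filt))
    model = simdata.TraitModel.random(
        tiny_map.n_markers, 30, seed=4, h2_plot=0.4, spatial_weight=0.0, nugget_weight=1.0
    )
    gv = simdata.simulate_trait(pop, model, seed=4)
    alloc = simdata.AllocationSpec.balanced(design, n_cols=12)
    plots = simdata.simulate_trials(simdata.allocate_trials(design, alloc, seed=4), gv, model, seed=4)
    plots["adjusted"] = plots["yield"]
    blues = phenoblue.estimate_blues(plots).set_index("line")["blue"]
    return {
        "design": design,
        "map": tiny_map,
        "dosages": pop,
        "grm": grm,
        "gvalues": gv,
        "plots": plots,
        "blues": blues,
        "cross_of": design.cross_of(),
    }


def _build_population(
    seed,
    n_parents,
    buckets,
    n_bi,
    n_tri,
    lines_per_cross,
    n_chrom,
    markers_per_chrom,
    n_qtl,
    line_h2,
):
    """Simulate genotype + phenotype data down to BLUEs and a GRM.

    Nugget-only noise, balanced allocation across the four trials; the
    spatial stage is exercised by its own tests.
    """
    design = simdata.design_crosses(
        n_parents,
        tuple(simdata.UsageBucket(*b) for b in buckets),
        n_bi=n_bi,
        n_tri=n_tri,
        lines_per_cross=lines_per_cross,
        seed=seed,
    )
    gmap = simdata.GeneticMap.uniform(n_chrom, markers_per_chrom, 150.0)
    pop = simdata.generate_population(design, gmap, seed=seed)
    h2p = simdata.TraitModel.plot_h2_for_line_h2(line_h2, 4)
    model = simdata.TraitModel.random(
        gmap.n_markers, n_qtl, seed=seed, h2_plot=h2p, spatial_weight=0.0, nugget_weight=1.0
    )
    gv = simdata.simulate_trait(pop, model, seed=seed)
    alloc = simdata.AllocationSpec.balanced(design, n_cols=30)
    plots = simdata.simulate_trials(
        simdata.allocate_trials(design, alloc, seed=seed), gv, model, seed=seed
    )
    plots["adjusted"] = plots["yield"]
    blues = phenoblue.estimate_blues(plots).set_index("line")["blue"]
    filt, _, _ = kinship.filter_segregating(pop)
    grm = kinship.stabilize(kinship.compute_grm(filt))
    return {
        "design": design,
        "map": gmap,
        "dosages": pop,
        "model": model,
        "gvalues": gv,
        "plots": plots,
        "blues": blues,
        "grm": grm,
        "cross_of": design.cross_of(),
    }


@pytest.fixture(scope="session")
def trend_bundle():
    """15 crosses x 60 lines with hub parents: the trend-experiment population."""
    return _build_population(
        seed=TREND_SEED,
        n_parents=12,
        buckets=[[2, 4, None], [3, 2, 3], [7, 1, 1]],
        n_bi=13,
        n_tri=2,
        lines_per_cross=60,
        n_chrom=8,
        markers_per_chrom=100,
        n_qtl=300,
        line_h2=0.65,
    )


@pytest.fixture(scope="session")
def hub_validation_crosses(trend_bundle):
    """One validation cross per hub parent, distinct."""
    design = trend_bundle["design"]
    usage = design.parent_usage()
    hubs = sorted(usage, key=usage.get, reverse=True)[:2]
    vcs, seen = [], set()
    for hub in hubs:
        for c in design.crosses:
            if hub in c.parents and c.cross_id not in seen:
                vcs.append(c.cross_id)
                seen.add(c.cross_id)
                break
    return vcs
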