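"""Breeding-structure, transmission and phenotype-law tests for the simulator."""

import math

import numpy as np
import pytest
from scipy import stats

import ammscreen as amm
from ammscreen.types import HET, REF, VAR

from oracles import g3_var_count_moments


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_g1_founders": 0},
        {"n_mutations_per_founder": 0},
        {"g2_per_g1": 0},
        {"g3_per_g2": -1},
    ],
)
def test_nonpositive_counts_rejected(kwargs):
    args = dict(n_g1_founders=1, n_mutations_per_founder=5, g2_per_g1=2, g3_per_g2=2, seed=0)
    args.update(kwargs)
    with pytest.raises(ValueError):
        amm.simulate_pedigree(**args)


def test_breeding_structure_links():
    members, muts, geno = amm.simulate_pedigree(2, 10, 4, 3, seed=3)
    by_id = {m.mouse_id: m for m in members}
    for m in members:
        if m.generation == "G3":
            assert by_id[m.dam_id].generation == "G2"
            assert by_id[m.sire_id].generation == "G1"
            assert by_id[m.dam_id].pedigree_id == m.pedigree_id
        if m.generation == "G2":
            assert by_id[m.sire_id].generation == "G1"
    screened = [m.mouse_id for m in members if m.sex == "F" and m.generation in ("G2", "G3")]
    assert sorted(geno.index) == sorted(screened)
    assert len(muts) == 20 and len({m.id for m in muts}) == 20


def test_g2_females_never_homozygous_mutant():
    members, _, geno = amm.simulate_pedigree(1, 30, 8, 4, seed=5)
    g2 = [m.mouse_id for m in members if m.generation == "G2"]
    assert set(np.unique(geno.loc[g2].to_numpy())) <= {REF, HET}


def test_mendelian_consistency_no_var_under_ref_dam():
    members, muts, geno = amm.simulate_pedigree(1, 42, 10, 9, seed=11)
    by_id = {m.mouse_id: m for m in members}
    for mid in geno.index:
        m = by_id[mid]
        if m.generation != "G3":
            continue
        dam_calls = geno.loc[m.dam_id]
        child = geno.loc[mid]
        assert not ((child == VAR) & (dam_calls == REF)).any()


def test_g3_class_frequencies_match_cross_enumeration():
    """VAR cells follow the dam-mixture law (mean n/8, overdispersed); HET
    cells are exactly Binomial(n, 1/2). Checked at 99% bounds."""
    n_dams, g3, n_loci = 6, 8, 42
    var_count = het_count = n_cells = 0
    seeds = (7, 8, 9)
    for seed in seeds:
        members, muts, geno = amm.simulate_pedigree(1, n_loci, n_dams, g3, seed=seed)
        g3_ids = [m.mouse_id for m in members if m.generation == "G3"]
        calls = geno.loc[g3_ids]
        n_cells += len(g3_ids) * n_loci
        var_count += int((calls == VAR).to_numpy().sum())
        het_count += int((calls == HET).to_numpy().sum())
    mean, var = g3_var_count_moments(n_dams, g3, n_loci)
    mean, var = mean * len(seeds), var * len(seeds)
    assert abs(var_count - mean) <= 2.576 * math.sqrt(var)
    assert abs(het_count - n_cells / 2) <= 2.576 * math.sqrt(n_cells * 0.25)


def test_default_design_reproduces_screen_totals():
    design = amm.DEFAULT_SCREEN_DESIGN
    loads = [p.n_mutations for p in design.pedigrees]
    assert sum(loads) == 594
    assert round(sum(loads) / len(loads), 1) == 42.4
    screened = sum(p.n_g2 * (1 + p.g3_per_g2) for p in design.pedigrees)
    assert screened == 844
    small = [p for p in design.pedigrees if p.n_g2 * p.g3_per_g2 <= 14]
    assert len(small) == 10


def test_simulation_is_deterministic_under_seed():
    a1 = amm.simulate_pedigree(1, 12, 3, 3, seed=99)
    a2 = amm.simulate_pedigree(1, 12, 3, 3, seed=99)
    assert a1[2].equals(a2[2])
    assert [m.mouse_id for m in a1[0]] == [m.mouse_id for m in a2[0]]


def test_censoring_rule_and_week_grid(null_screen):
    for p in null_screen.phenotypes:
        assert 1.0 <= p.onset_week <= 40.0
        assert p.onset_week == math.ceil(p.onset_week)
        if not p.event:
            assert p.onset_week == 40.0


def test_baseline_incidence_near_configured(null_screen):
    events = sum(p.event for p in null_screen.phenotypes)
    n = len(null_screen.phenotypes)
    assert abs(events / n - 0.80) <= 2.576 * math.sqrt(0.8 * 0.2 / n)


def test_zero_multiplier_recessive_suppressor_makes_var_immune(suppressor_screen):
    screen, effect = suppressor_screen
    calls = screen.genotypes[effect.mutation_id]
    phen = {p.mouse_id: p for p in screen.phenotypes}
    var_mice = [phen[m] for m in calls.index[calls == VAR]]
    assert len(var_mice) >= 2
    assert all(not p.event for p in var_mice)


def test_dominant_accelerator_shifts_median_to_analytic_value(baseline_law):
    """Carrier onset median should sit at the closed-form Weibull median
    under a 4x hazard; REF mice keep the baseline median."""
    design = amm.ScreenDesign(pedigrees=(amm.PedigreeDesign(6, 30, 10),))
    probe = amm.simulate_screen(design, seed=21, phenotypes=False)
    eff = amm.EffectSpec(probe.mutations[0].id, "dominant", "accelerate", 4.0)
    screen = amm.simulate_screen(design, seed=21, effects=[eff])
    calls = screen.genotypes[eff.mutation_id]
    phen = screen.phenotype_frame()
    carriers = phen.loc[[m for m in calls.index if calls[m] in (HET, VAR)], "onset_week"]
    refs = phen.loc[[m for m in calls.index if calls[m] == REF], "onset_week"]
    med_expect = baseline_law.median(4.0)
    assert abs(np.median(carriers) - math.ceil(med_expect)) <= 1.0
    assert np.median(carriers) < np.median(refs)


def test_no_effect_onsets_exchangeable_across_genotypes(null_screen):
    calls = null_screen.genotypes[null_screen.mutations[0].id]
    phen = null_screen.phenotype_frame()
    groups = [
        phen.loc[[m for m in calls.index if calls[m] == z], "onset_week"].to_numpy()
        for z in (REF, HET, VAR)
    ]
    assert stats.ks_2samp(groups[0], np.concatenate(groups[1:])).pvalue > 0.01


def test_effect_referencing_unknown_mutation_raises(null_screen):
    eff = amm.EffectSpec("nope", "recessive", "suppress", 0.5)
    with pytest.raises(ValueError, match="unknown mutation"):
        amm.simulate_phenotypes(
            null_screen.members, null_screen.genotypes, [eff], seed=1
        )


@pytest.mark.parametrize(
    "model,direction,mult",
    [
        ("recessive", "accelerate", 0.5),  # accelerate needs mult > 1
        ("dominant", "suppress", 2.0),     # suppress needs mult < 1
        ("recessive", "suppress", -0.1),   # negative multiplier
        ("sideways", "suppress", 0.5),     # unknown model
    ],
)
def test_effect_spec_validation(model, direction, mult):
    with pytest.raises(ValueError):
        amm.EffectSpec("m1", model, direction, mult)


def test_missing_rate_masks_cells_without_touching_truth():
    design = amm.ScreenDesign(
        pedigrees=(amm.PedigreeDesign(20, 6, 5),), missing_rate=0.1
    )
    screen = amm.simulate_screen(design, seed=2)
    frac = (screen.genotypes == "MISSING").to_numpy().mean()
    assert 0.05 < frac < 0.15
    # phenotypes still generated for every screened female
    assert len(screen.phenotypes) == len(screen.genotypes)
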