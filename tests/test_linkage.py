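"""Kaplan-Meier, logrank and Weibull-LRT behavior, plus scan-level checks."""

import math

import numpy as np
import pytest
from scipy import stats

import ammscreen as amm
from ammscreen.linkage import best_result, lrt_association, results_table
from ammscreen.types import PhenotypeRecord


# ---------------------------------------------------------------------------
# encoding


@pytest.mark.parametrize(
    "model,expected",
    [
        ("recessive", [0.0, 0.0, 1.0]),
        ("additive", [0.0, 0.5, 1.0]),
        ("dominant", [0.0, 1.0, 1.0]),
    ],
)
def test_encode_definitions(model, expected):
    assert list(amm.encode(model, ["REF", "HET", "VAR"])) == expected


def test_encode_missing_becomes_nan_and_bad_token_raises():
    out = amm.encode("additive", ["REF", "MISSING", "VAR"])
    assert math.isnan(out[1])
    with pytest.raises(ValueError, match="unknown genotype call"):
        amm.encode("additive", ["REF", "het"])
    with pytest.raises(ValueError, match="unknown model"):
        amm.encode("codominant", ["REF"])


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_hand_product_limit(make_records):
    curve = amm.km_estimate(make_records([10, 20, 40], [1, 1, 0]))
    assert list(curve.times) == [10.0, 20.0]
    assert np.allclose(curve.survival, [2 / 3, 1 / 3])
    assert curve.survival_at(40.0) == pytest.approx(1 / 3)


def test_km_all_censored_is_flat_one(make_records):
    curve = amm.km_estimate(make_records([40, 40, 40], [0, 0, 0]))
    assert curve.times.size == 0
    assert curve.survival_at(40.0) == 1.0
    assert math.isinf(curve.median())


def test_km_empty_input_raises():
    with pytest.raises(ValueError):
        amm.km_estimate([])


def test_km_equals_empirical_survival_without_censoring(make_records, rng):
    weeks = rng.integers(1, 40, size=60)
    curve = amm.km_estimate(make_records(weeks, np.ones(60)))
    for t in (5, 15, 30):
        assert curve.survival_at(t) == pytest.approx(np.mean(weeks > t))
    assert np.all(np.diff(curve.survival) <= 1e-12)


def test_km_survival_at_horizon_tracks_simulated_incidence(baseline_law, rng, make_records):
    t = baseline_law.sample(rng, np.ones(200))
    ev = t <= 40
    weeks = np.where(ev, np.ceil(t), 40.0)
    curve = amm.km_estimate(make_records(weeks, ev))
    assert abs(curve.survival_at(40.0) - 0.20) <= 2.576 * math.sqrt(0.8 * 0.2 / 200)


# ---------------------------------------------------------------------------
# logrank


def test_logrank_identical_groups_is_null(make_records):
    recs = make_records([5, 9, 13, 40, 40], [1, 1, 1, 0, 0])
    chi2, p = amm.logrank_test(recs, list(recs))
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_empty_group_raises(make_records):
    with pytest.raises(ValueError):
        amm.logrank_test(make_records([5], [1]), [])


def test_logrank_matches_lifelines(make_records, rng):
    """Cross-check statistic and asymptotic p against lifelines."""
    from lifelines.statistics import logrank_test as ll_logrank

    t = np.concatenate([rng.integers(1, 41, 25), rng.integers(5, 41, 25)]).astype(float)
    e = rng.random(50) < 0.8
    chi2, p = amm.logrank_test(
        make_records(np.where(e[:25], t[:25], 40.0), e[:25]),
        make_records(np.where(e[25:], t[25:], 40.0), e[25:]),
    )
    res = ll_logrank(
        np.where(e[:25], t[:25], 40.0), np.where(e[25:], t[25:], 40.0),
        event_observed_A=e[:25], event_observed_B=e[25:],
    )
    assert chi2 == pytest.approx(res.test_statistic, rel=1e-9)
    assert p == pytest.approx(res.p_value, rel=1e-9)


def test_logrank_type_one_error_close_to_nominal(baseline_law):
    """1000 null comparisons of two 30-mouse groups: rejection rate at
    alpha = 0.05 should sit within 0.05 +/- 0.02."""
    rng = np.random.default_rng(123)
    rejections = 0
    n_rep = 1000
    for _ in range(n_rep):
        t = baseline_law.sample(rng, np.ones(60))
        ev = t <= 40
        weeks = np.where(ev, np.ceil(t), 40.0)
        recs = [
            PhenotypeRecord(f"m{i}", float(weeks[i]), bool(ev[i])) for i in range(60)
        ]
        _, p = amm.logrank_test(recs[:30], recs[30:])
        rejections += p < 0.05
    assert 0.03 <= rejections / n_rep <= 0.07


# ---------------------------------------------------------------------------
# Weibull LRT


def _sim_records(law, rng, hr):
    t = law.sample(rng, hr)
    ev = t <= 40
    weeks = np.where(ev, np.ceil(t), 40.0)
    return [PhenotypeRecord(f"m{i}", float(weeks[i]), bool(ev[i])) for i in range(len(hr))]


def test_lrt_invariant_to_affine_dose_relabeling(baseline_law, rng):
    recs = _sim_records(baseline_law, rng, np.ones(50))
    dose = (rng.random(50) < 0.3).astype(float)
    r1 = lrt_association(recs, dose)
    r2 = lrt_association(recs, 2.0 * dose + 3.0)
    assert r1.stat == pytest.approx(r2.stat, abs=1e-6)
    assert r2.beta == pytest.approx(r1.beta / 2.0, abs=1e-6)


def test_lrt_constant_dose_not_testable(baseline_law, rng):
    recs = _sim_records(baseline_law, rng, np.ones(10))
    res = lrt_association(recs, np.zeros(10))
    assert res.flag == "not_testable"
    assert math.isnan(res.p)


def test_lrt_requires_minimum_cohort(make_records):
    with pytest.raises(ValueError, match="at least 4"):
        lrt_association(make_records([5, 9, 40], [1, 1, 0]), [0.0, 1.0, 0.0])


def test_lrt_missing_doses_dropped(baseline_law, rng):
    recs = _sim_records(baseline_law, rng, np.ones(40))
    dose = (rng.random(40) < 0.4).astype(float)
    dose_nan = dose.copy()
    dose_nan[:5] = np.nan
    r_full = lrt_association(recs[5:], dose[5:])
    r_nan = lrt_association(recs, dose_nan)
    assert r_nan.stat == pytest.approx(r_full.stat, abs=1e-9)


def test_lrt_loglik_matches_lifelines_weibull_aft(baseline_law, rng):
    """The maximized log-likelihood should agree with lifelines'
    WeibullAFTFitter (same model, different parameterization and optimizer)."""
    import pandas as pd
    from lifelines import WeibullAFTFitter

    recs = _sim_records(baseline_law, rng, np.ones(80))
    dose = (rng.random(80) < 0.4).astype(float)
    res = lrt_association(recs, dose)
    df = pd.DataFrame(
        {
            "t": [r.onset_week for r in recs],
            "e": [r.event for r in recs],
            "dose": dose,
        }
    )
    aft = WeibullAFTFitter().fit(df, "t", "e", formula="dose")
    assert res.loglik_alt == pytest.approx(aft.log_likelihood_, abs=1e-4)


def test_lrt_null_p_uniform_under_shuffled_dose(baseline_law):
    """Shuffling dose breaks any association: raw p values over replicates
    should be uniform (KS test, alpha = 0.01)."""
    rng = np.random.default_rng(7)
    recs = _sim_records(baseline_law, rng, np.ones(120))
    dose = np.zeros(120)
    dose[:15] = 1.0
    pvals = []
    for _ in range(200):
        pvals.append(lrt_association(recs, rng.permutation(dose)).p)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_lrt_with_dam_cluster_close_to_fixed_when_no_frailty(baseline_law, rng):
    recs = _sim_records(baseline_law, rng, np.ones(60))
    dose = (rng.random(60) < 0.3).astype(float)
    clusters = [f"d{i // 6}" for i in range(60)]
    fixed = lrt_association(recs, dose)
    mixed = lrt_association(recs, dose, cluster=clusters)
    assert mixed.flag in ("ok", "non_converged")
    assert abs(mixed.stat - fixed.stat) < 0.5


def test_interval_censored_mode_agrees_roughly_with_exact(baseline_law, rng):
    recs = _sim_records(baseline_law, rng, np.ones(60))
    dose = (rng.random(60) < 0.3).astype(float)
    exact = lrt_association(recs, dose)
    interval = lrt_association(recs, dose, interval=True)
    assert interval.flag in ("ok", "non_converged")
    assert abs(interval.stat - exact.stat) < 1.0


# ---------------------------------------------------------------------------
# scan


def test_scan_is_deterministic(null_screen):
    r1, m1 = amm.scan(null_screen)
    r2, m2 = amm.scan(null_screen)
    assert results_table(r1).equals(results_table(r2))
    assert m1.equals(m2)


def test_scan_bonferroni_uses_mutations_times_models(null_screen):
    results, _ = amm.scan(null_screen)
    m = len(null_screen.mutations) * 3
    assert len(results) == m
    for r in results:
        if math.isnan(r.p_raw) or r.p_bonferroni < 0.25:
            continue  # refined tests replace the raw chi-square p
        assert r.p_bonferroni == pytest.approx(min(1.0, r.p_raw * m))


def test_scan_counts_are_screen_consistent(null_screen):
    results, _ = amm.scan(null_screen)
    n = len(null_screen.phenotypes)
    for r in results:
        assert r.n_ref + r.n_het + r.n_var <= n


def test_scan_recovers_planted_suppressor_as_minimum_p(suppressor_screen):
    screen, effect = suppressor_screen
    results, manhattan = amm.scan(screen)
    ok = [r for r in results if not math.isnan(r.p_bonferroni)]
    top = min(ok, key=lambda r: r.p_bonferroni)
    assert top.mutation_id == effect.mutation_id
    assert top.direction == "suppress"
    row = manhattan.loc[manhattan["neg_log10_p"].idxmax()]
    assert row["mutation_id"] == effect.mutation_id


def test_manhattan_table_one_row_per_mutation(null_screen):
    _, manhattan = amm.scan(null_screen)
    assert len(manhattan) == len(null_screen.mutations)
    assert (manhattan["neg_log10_p"].dropna() >= 0).all()


def test_exclude_nothing_matches_plain_scan(manual_screen_builder, baseline_law):
    """Excluding a zygosity class with no members must reproduce the plain
    scan result for the target mutation exactly."""
    rng = np.random.default_rng(42)
    n = 60
    t = baseline_law.sample(rng, np.ones(n))
    ev = t <= 40
    weeks = np.where(ev, np.ceil(t), 40.0)
    calls_a = ["REF"] * 20 + ["HET"] * 28 + ["VAR"] * 12
    calls_b = ["REF"] * 30 + ["HET"] * 30  # no VAR anywhere at this locus
    screen = manual_screen_builder({"mA": calls_a, "mB": calls_b}, weeks, ev)
    results, _ = amm.scan(screen)
    best = best_result([r for r in results if r.mutation_id == "mA"])
    res = amm.exclude_and_rescan(screen, "mB", "VAR", "mA")
    assert res.model == best.model
    assert res.lrt_stat == pytest.approx(best.lrt_stat, abs=1e-9)
    assert res.p_raw == pytest.approx(best.p_raw, rel=1e-6)
    assert (res.n_ref, res.n_het, res.n_var) == (best.n_ref, best.n_het, best.n_var)


def test_exclude_and_rescan_two_locus_directions(screen_design_100):
    """With one planted accelerator and one suppressor, conditioning away
    either one's homozygotes must preserve the other's direction call."""
    probe = amm.simulate_screen(screen_design_100, seed=902, phenotypes=False)
    acc = amm.EffectSpec(probe.mutations[0].id, "recessive", "accelerate", 8.0)
    sup = amm.EffectSpec(probe.mutations[1].id, "recessive", "suppress", 0.0)
    screen = amm.simulate_screen(screen_design_100, seed=902, effects=[acc, sup])
    r_acc = amm.exclude_and_rescan(screen, sup.mutation_id, "VAR", acc.mutation_id)
    r_sup = amm.exclude_and_rescan(screen, acc.mutation_id, "VAR", sup.mutation_id)
    assert r_acc.direction == "accelerate"
    assert r_sup.direction == "suppress"


def test_exclude_all_mice_raises(manual_screen_builder):
    screen = manual_screen_builder(
        {"mA": ["REF", "HET", "VAR", "REF"], "mB": ["HET"] * 4},
        [10, 20, 30, 40],
        [1, 1, 1, 0],
    )
    with pytest.raises(ValueError, match="every screened mouse"):
        amm.exclude_and_rescan(screen, "mB", "HET", "mA")
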