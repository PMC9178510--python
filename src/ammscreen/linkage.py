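"""Single-locus linkage of zygosity to censored onset age.

For every mutation and each inheritance model (recessive, additive,
dominant), genotype calls are encoded as a dose covariate and tested against
weekly onset ages right-censored at 40 weeks. The test is a likelihood-ratio
test from a Weibull proportional-hazards regression (a log-linear model of
the hazard), optionally with a shared dam-level normal random intercept
(frailty) in both null and alternative fits. Kaplan-Meier estimation and the
Mantel-Cox logrank test support curve display and pairwise comparisons.

The Weibull likelihood is maximized over (log shape, dose coefficient) after
profiling out the rate parameter, which has a closed-form optimum given the
others; this keeps a full screen scan (mutations x 3 models) cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .simulate import AUTOSOME_LENGTHS_BP
from .types import (
    HET,
    HET_DOSE,
    MISSING,
    MODELS,
    REF,
    VAR,
    PhenotypeRecord,
    Screen,
)

# ---------------------------------------------------------------------------
# Genotype encoding


def encode(model: str, calls: Sequence[str]) -> np.ndarray:
    """Map zygosity calls to the model's dose: REF 0, VAR 1, HET 0 / 0.5 / 1
    under recessive / additive / dominant. MISSING becomes NaN and is dropped
    (with its phenotype row) by callers."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    het = HET_DOSE[model]
    out = np.empty(len(calls), dtype=float)
    for i, c in enumerate(calls):
        if c == REF:
            out[i] = 0.0
        elif c == HET:
            out[i] = het
        elif c == VAR:
            out[i] = 1.0
        elif c == MISSING:
            out[i] = np.nan
        else:
            raise ValueError(f"unknown genotype call {c!r}")
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate over the distinct event weeks."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function value of the KM estimate at time ``t``."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median(self) -> float:
        """Smallest time with survival <= 0.5, inf if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return math.inf if below.size == 0 else float(self.times[below[0]])


def km_estimate(records: Sequence[PhenotypeRecord]) -> SurvivalCurve:
    """Kaplan-Meier estimate of onset-free survival from weekly records."""
    if len(records) == 0:
        raise ValueError("km_estimate requires at least one record")
    from lifelines import KaplanMeierFitter

    time = np.array([r.onset_week for r in records], dtype=float)
    event = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = np.array([float(kmf.predict(t)) for t in times])
    return SurvivalCurve(
        times=times,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        events=ev["observed"].to_numpy(dtype=int),
        n=len(records),
    )


# ---------------------------------------------------------------------------
# Logrank (Mantel-Cox)


def _logrank_chi2(time: np.ndarray, event: np.ndarray, in_a: np.ndarray) -> float:
    """Mantel-Cox chi-square with the standard tied-data hypergeometric
    variance. ``in_a`` is a boolean (or column-stacked) group-A indicator."""
    et = np.unique(time[event])
    if et.size == 0:
        return 0.0 if in_a.ndim == 1 else np.zeros(in_a.shape[1])  # type: ignore[return-value]
    at_risk = (time[None, :] >= et[:, None]).astype(float)
    ev_at = ((time[None, :] == et[:, None]) & event[None, :]).astype(float)
    n_j = at_risk.sum(axis=1)
    d_j = ev_at.sum(axis=1)
    g = in_a.astype(float)
    n1 = at_risk @ g
    d1 = ev_at @ g
    if g.ndim == 1:
        n1 = n1[:, None]
        d1 = d1[:, None]
    frac = n1 / n_j[:, None]
    o_minus_e = (d1 - d_j[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_j = (
            d_j[:, None]
            * frac
            * (1.0 - frac)
            * ((n_j - d_j) / np.maximum(n_j - 1.0, 1.0))[:, None]
        )
    v = var_j.sum(axis=0)
    chi2 = np.where(v > 0, o_minus_e**2 / np.maximum(v, 1e-300), 0.0)
    return float(chi2[0]) if in_a.ndim == 1 else chi2  # type: ignore[return-value]


def logrank_test(
    records_a: Sequence[PhenotypeRecord],
    records_b: Sequence[PhenotypeRecord],
    p_method: str = "asymptotic",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel-Cox comparison of two onset curves; returns (chi2, p).

    ``p_method="asymptotic"`` uses the chi-square(1) reference;
    ``"permutation"`` uses a group-label permutation null of the same
    statistic, which is preferred for very small groups where the asymptotic
    reference is unreliable.
    """
    if len(records_a) == 0 or len(records_b) == 0:
        raise ValueError("both groups must be non-empty")
    time = np.array([r.onset_week for r in list(records_a) + list(records_b)], dtype=float)
    event = np.array([r.event for r in list(records_a) + list(records_b)], dtype=bool)
    in_a = np.zeros(time.size, dtype=bool)
    in_a[: len(records_a)] = True
    chi2 = _logrank_chi2(time, event, in_a)
    if p_method == "asymptotic":
        p = float(stats.chi2.sf(chi2, 1))
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        perms = np.stack(
            [rng.permutation(in_a) for _ in range(n_permutations)], axis=1
        )
        null = _logrank_chi2(time, event, perms)
        p = (1.0 + np.sum(null >= chi2 - 1e-12)) / (1.0 + n_permutations)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return chi2, p


# ---------------------------------------------------------------------------
# Weibull proportional-hazards likelihood-ratio test

_A_BOUNDS = (-4.0, 3.5)   # log shape
_B_BOUNDS = (-30.0, 30.0)  # dose coefficient


def _profile_negll(theta, logt, d, x, D, Ld, Xd, with_beta):
    """Negative profile log-likelihood (rate profiled out) and gradient."""
    a = theta[0]
    beta = theta[1] if with_beta else 0.0
    k = math.exp(a)
    w = np.exp(k * logt)
    e = np.exp(beta * x) if with_beta else 1.0
    ew = e * w
    s = ew.sum()
    ll = D * (math.log(D) - 1.0 + a) + (k - 1.0) * Ld + beta * Xd - D * math.log(s)
    ga = D + k * Ld - D * k * float((ew * logt).sum()) / s
    if with_beta:
        gb = Xd - D * float((x * ew).sum()) / s
        return -ll, np.array([-ga, -gb])
    return -ll, np.array([-ga])


def _profile_ll_grad_hess(a, beta, logt, x, D, Ld, Xd, with_beta):
    """Profile log-likelihood with analytic gradient and Hessian."""
    k = math.exp(a)
    ew = np.exp(k * logt + beta * x) if with_beta else np.exp(k * logt)
    s = float(ew.sum())
    t1 = float((ew * logt).sum())
    t2 = float((ew * logt * logt).sum())
    ll = D * (math.log(D) - 1.0 + a) + (k - 1.0) * Ld + beta * Xd - D * math.log(s)
    ga = D + k * Ld - D * k * t1 / s
    haa = k * Ld - D * ((k * t1 + k * k * t2) / s - (k * t1 / s) ** 2)
    if not with_beta:
        return ll, np.array([ga]), np.array([[haa]])
    x1 = float((x * ew).sum())
    x2 = float((x * x * ew).sum())
    xt = float((x * ew * logt).sum())
    gb = Xd - D * x1 / s
    hab = -D * k * (xt / s - t1 * x1 / (s * s))
    hbb = -D * (x2 / s - (x1 / s) ** 2)
    return ll, np.array([ga, gb]), np.array([[haa, hab], [hab, hbb]])


def _newton_fit(logt, d, x, with_beta, start):
    """Damped Newton ascent of the profile log-likelihood; falls back to
    L-BFGS-B when curvature is unusable. Returns (loglik, params, ok)."""
    D = float(d.sum())
    Ld = float(logt[d].sum())
    Xd = float(x[d].sum()) if with_beta else 0.0
    theta = np.asarray(start, dtype=float)
    ll, g, h = _profile_ll_grad_hess(
        theta[0], theta[1] if with_beta else 0.0, logt, x, D, Ld, Xd, with_beta
    )
    for _ in range(60):
        if float(np.abs(g).max()) < 1e-9 * max(D, 1.0):
            return ll, theta, True
        try:
            step = np.linalg.solve(-h, g)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        # keep steps sane; large beta steps occur under separation
        nrm = float(np.abs(step).max())
        if nrm > 4.0:
            step *= 4.0 / nrm
        lam = 1.0
        for _bt in range(30):
            cand = theta + lam * step
            if abs(cand[0]) > 6.0 or (with_beta and abs(cand[1]) > _B_BOUNDS[1]):
                lam *= 0.5
                continue
            ll_new, g_new, h_new = _profile_ll_grad_hess(
                cand[0], cand[1] if with_beta else 0.0, logt, x, D, Ld, Xd, with_beta
            )
            if ll_new >= ll - 1e-12:
                theta, ll, g, h = cand, ll_new, g_new, h_new
                break
            lam *= 0.5
        else:
            # no uphill step found: either converged on a flat ridge or stuck
            return ll, theta, float(np.abs(g).max()) < 1e-5 * max(D, 1.0)
    res = _fit_weibull(logt, d, x, with_beta, theta)
    return -res.fun, res.x, bool(res.success)


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of a dose covariate in the onset model."""

    stat: float
    p: float
    beta: float
    loglik_null: float
    loglik_alt: float
    flag: str = "ok"  # ok | not_testable | no_events | non_converged

    @property
    def testable(self) -> bool:
        return self.flag in ("ok", "non_converged")


def _fit_weibull(logt, d, x, with_beta, start):
    D = float(d.sum())
    Ld = float(logt[d].sum())
    Xd = float(x[d].sum()) if with_beta else 0.0
    bounds = [_A_BOUNDS] + ([_B_BOUNDS] if with_beta else [])
    res = optimize.minimize(
        _profile_negll,
        np.asarray(start, dtype=float),
        args=(logt, d, x, D, Ld, Xd, with_beta),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
    )
    return res


def lrt_association(
    phenotypes: Sequence[PhenotypeRecord],
    dose: Sequence[float],
    cluster: Optional[Sequence[str]] = None,
    interval: bool = False,
) -> LRTResult:
    """LRT for association between a numeric dose and censored onset age.

    Twice the log-likelihood difference between Weibull proportional-hazards
    fits with and without the dose covariate, referred to chi-square(1). With
    ``cluster`` ids (dams), a shared normal random intercept on the log
    hazard is included in both fits. ``interval=True`` treats an onset at
    week w as occurring in (w-1, w] rather than exactly at w.
    """
    time = np.array([r.onset_week for r in phenotypes], dtype=float)
    event = np.array([r.event for r in phenotypes], dtype=bool)
    x = np.asarray(dose, dtype=float)
    if x.shape[0] != time.shape[0]:
        raise ValueError("dose and phenotypes must be the same length")
    keep = ~np.isnan(x)
    time, event, x = time[keep], event[keep], x[keep]
    clus = None
    if cluster is not None:
        clus = np.asarray([c for c, k in zip(cluster, keep) if k])
    if time.size < 4:
        raise ValueError("need at least 4 usable mice")
    if np.unique(x).size < 2:
        return LRTResult(math.nan, math.nan, math.nan, math.nan, math.nan, "not_testable")
    if not event.any():
        return LRTResult(math.nan, math.nan, math.nan, math.nan, math.nan, "no_events")

    if clus is not None:
        return _lrt_frailty(time, event, x, clus, interval=interval)
    if interval:
        return _lrt_interval(time, event, x)

    logt = np.log(time)
    ll0, th0, ok0 = _newton_fit(logt, event, x, with_beta=False, start=[0.0])
    ll1, th1, ok1 = _newton_fit(logt, event, x, with_beta=True, start=[th0[0], 0.0])
    stat = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(stat, 1))
    flag = "ok" if (ok0 and ok1) else "non_converged"
    return LRTResult(stat, p, float(th1[1]), ll0, ll1, flag)


def _full_negll(params, time, event, x, interval):
    """Unprofiled negative log-likelihood over (log shape, log rate, beta)."""
    a, lnu, beta = params
    k = math.exp(a)
    nu = math.exp(lnu)
    eta = nu * np.exp(beta * x)
    if interval:
        h_hi = eta * time**k
        h_lo = eta * np.maximum(time - 1.0, 0.0) ** k
        ll_ev = -h_lo + np.log(-np.expm1(-(np.maximum(h_hi - h_lo, 1e-300))))
        ll = float(ll_ev[event].sum()) - float(h_hi[~event].sum())
    else:
        h = eta * time**k
        ll_ev = math.log(k) + lnu + beta * x + (k - 1.0) * np.log(time)
        ll = float(ll_ev[event].sum()) - float(h.sum())
    return -ll


def _lrt_interval(time, event, x):
    def fit(with_beta):
        def obj(p):
            params = (p[0], p[1], p[2] if with_beta else 0.0)
            return _full_negll(params, time, event, x, interval=True)

        start = [0.5, -6.0] + ([0.0] if with_beta else [])
        res = optimize.minimize(obj, start, method="Nelder-Mead",
                                options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000})
        return res

    r0 = fit(False)
    r1 = fit(True)
    stat = max(0.0, 2.0 * (r0.fun - r1.fun))
    p = float(stats.chi2.sf(stat, 1))
    flag = "ok" if (r0.success and r1.success) else "non_converged"
    return LRTResult(stat, p, float(r1.x[2]), -r0.fun, -r1.fun, flag)


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(15)


def _frailty_negll(params, time, event, x, cidx, n_clusters, with_beta):
    a, lnu = params[0], params[1]
    beta = params[2] if with_beta else 0.0
    lsig = params[-1]
    k = math.exp(a)
    sig = math.exp(lsig)
    b_q = math.sqrt(2.0) * sig * _GH_NODES  # (Q,)
    base_ev = a + lnu + beta * x + (k - 1.0) * np.log(time)
    haz = np.exp(lnu + beta * x) * time**k
    # per-cluster event-part and hazard-part sums
    ev_sum = np.bincount(cidx, weights=np.where(event, base_ev, 0.0), minlength=n_clusters)
    n_ev = np.bincount(cidx, weights=event.astype(float), minlength=n_clusters)
    h_sum = np.bincount(cidx, weights=haz, minlength=n_clusters)
    # ll_j(q) = ev_sum_j + n_ev_j * b_q - h_sum_j * exp(b_q)
    mat = ev_sum[:, None] + n_ev[:, None] * b_q[None, :] - h_sum[:, None] * np.exp(b_q)[None, :]
    logw = np.log(_GH_WEIGHTS / math.sqrt(math.pi))
    return -float(logsumexp(mat + logw[None, :], axis=1).sum())


def _lrt_frailty(time, event, x, cluster, interval=False):
    if interval:
        raise NotImplementedError("interval censoring with frailty is not supported")
    uniq = {c: i for i, c in enumerate(dict.fromkeys(cluster))}
    cidx = np.array([uniq[c] for c in cluster])
    n_clusters = len(uniq)

    def fit(with_beta):
        start = [0.5, -6.0] + ([0.0] if with_beta else []) + [math.log(0.3)]
        res = optimize.minimize(
            _frailty_negll,
            start,
            args=(time, event, x, cidx, n_clusters, with_beta),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 6000},
        )
        return res

    r0 = fit(False)
    r1 = fit(True)
    stat = max(0.0, 2.0 * (r0.fun - r1.fun))
    p = float(stats.chi2.sf(stat, 1))
    flag = "ok" if (r0.success and r1.success) else "non_converged"
    return LRTResult(stat, p, float(r1.x[2]), -r0.fun, -r1.fun, flag)


# ---------------------------------------------------------------------------
# Screen-wide scan


@dataclass(frozen=True)
class LinkageResult:
    """One mutation x inheritance-model association test."""

    mutation_id: str
    pedigree_id: str
    model: str
    n_ref: int
    n_het: int
    n_var: int
    lrt_stat: float
    p_raw: float
    p_bonferroni: float
    direction: str  # accelerate | suppress | none
    beta: float
    flag: str  # ok | not_testable | no_events | non_converged | direction_discordant


_MODEL_RANK = {"recessive": 0, "additive": 1, "dominant": 2}


def best_result(results: Iterable[LinkageResult]) -> Optional[LinkageResult]:
    """Minimum-p result among testable ones; ties broken recessive >
    additive > dominant."""
    ok = [r for r in results if r.flag in ("ok", "direction_discordant")]
    if not ok:
        return None
    return min(ok, key=lambda r: (r.p_bonferroni, _MODEL_RANK[r.model]))


def _km_direction(
    phen: list[PhenotypeRecord], calls: pd.Series, model: str
) -> Optional[str]:
    """Direction suggested by KM curves: affected class (per model) vs REF."""
    affected_classes = {"recessive": (VAR,), "additive": (VAR,), "dominant": (HET, VAR)}[model]
    by_id = {p.mouse_id: p for p in phen}
    aff = [by_id[m] for m in calls.index if calls[m] in affected_classes and m in by_id]
    ref = [by_id[m] for m in calls.index if calls[m] == REF and m in by_id]
    if not aff or not ref:
        return None
    km_a, km_r = km_estimate(aff), km_estimate(ref)
    med_a, med_r = km_a.median(), km_r.median()
    if med_a == med_r:
        sa, sr = km_a.survival_at(40.0), km_r.survival_at(40.0)
        if sa == sr:
            return None
        return "accelerate" if sa < sr else "suppress"
    return "accelerate" if med_a < med_r else "suppress"


def _calibration_factors(
    time: np.ndarray,
    event: np.ndarray,
    doses_by_model: dict[str, list[np.ndarray]],
    n_perm: int,
    seed: int,
) -> dict[str, float]:
    """Bartlett-type calibration of the LRT per inheritance model.

    Under the null, E[LRT] should equal 1 (chi-square, 1 df); with small
    dose groups the statistic runs slightly hot and its far tail with it.
    The factor is the mean LRT over dose-permutation replicates pooled
    across the pedigree's complete-genotype loci — permutation is the exact
    null for independence of dose and onset, and the mean needs far fewer
    draws than a tail estimate would. Dividing each statistic by its
    model's factor restores the chi-square reference to first order.
    """
    rng = np.random.default_rng(seed)
    logt = np.log(time)
    ll0, th0, _ = _newton_fit(logt, event, np.zeros_like(time), False, [0.0])
    factors = {}
    for model, doses in doses_by_model.items():
        stats_ = []
        for dose in doses:
            if np.isnan(dose).any() or np.unique(dose).size < 2:
                continue
            for _b in range(n_perm):
                xp = rng.permutation(dose)
                ll1, _th, ok = _newton_fit(logt, event, xp, True, [th0[0], 0.0])
                if ok:
                    stats_.append(max(0.0, 2.0 * (ll1 - ll0)))
        factors[model] = float(np.mean(stats_)) if len(stats_) >= 50 else 1.0
    return factors


def _score_permutation_p(
    time: np.ndarray,
    event: np.ndarray,
    dose: np.ndarray,
    seed: int,
    n_perm_screen: int = 4000,
    n_perm_full: int = 200_000,
    escalate_below: float = 0.02,
) -> float:
    """Exact dose-permutation p of the model's score statistic at one locus.

    The score for the dose coefficient, evaluated at the null (no-dose)
    Weibull MLE, is linear in the dose vector: U = sum_i x_i c_i with
    c_i = d_i - D w_i / S, so permutation replicates are a single matrix
    product and an essentially exact permutation null is affordable. The
    chi-square reference for the LRT is reliable in the bulk but runs hot in
    the far tail at screen-sized pedigrees; borderline tests are therefore
    decided by this exact test of the asymptotically equivalent score
    statistic. A first batch of ``n_perm_screen`` shuffles is escalated to
    ``n_perm_full`` when the estimate falls below ``escalate_below``.
    """
    keep = ~np.isnan(dose)
    time, event, x = time[keep], event[keep], dose[keep]
    logt = np.log(time)
    _ll0, th0, _ok = _newton_fit(logt, event, np.zeros_like(time), False, [0.0])
    k = math.exp(th0[0])
    w = np.exp(k * logt)
    d_total = float(event.sum())
    c = event.astype(float) - d_total * w / float(w.sum())
    u_obs = float(x @ c) ** 2
    rng = np.random.default_rng(seed)

    def batch(n: int) -> int:
        exceed = 0
        chunk = 50_000
        for start in range(0, n, chunk):
            b = min(chunk, n - start)
            perm = rng.permuted(np.broadcast_to(c, (b, c.size)).copy(), axis=1)
            u = (perm @ x) ** 2
            exceed += int(np.sum(u >= u_obs - 1e-12))
        return exceed

    exceed = batch(n_perm_screen)
    p = (1.0 + exceed) / (1.0 + n_perm_screen)
    if p < escalate_below:
        exceed += batch(n_perm_full - n_perm_screen)
        p = (1.0 + exceed) / (1.0 + n_perm_full)
    return p


def scan(
    screen: Screen,
    models: Sequence[str] = MODELS,
    mixed: bool = False,
    pedigree_id: Optional[str] = None,
    calibrate: bool = True,
    calibration_permutations: int = 16,
    calibration_seed: int = 0,
    refine_permutations: int = 200_000,
    refine_threshold: float = 0.25,
) -> tuple[list[LinkageResult], pd.DataFrame]:
    """Scan every mutation under every inheritance model, per pedigree.

    Bonferroni multiplicity is (mutations in the pedigree) x (number of
    models), applied within each pedigree (each pedigree is an independent
    scan). With ``calibrate`` (default, fixed-effect fits only) each model's
    LRT statistics are divided by a permutation-estimated Bartlett factor
    before the chi-square p is taken; tests whose corrected Bonferroni p
    falls below ``refine_threshold`` are then decided by an exact
    dose-permutation test of the score statistic with up to
    ``refine_permutations`` shuffles. The scan stays deterministic because
    every permutation stream is seeded from ``calibration_seed``. Direction is
    the sign of the fitted dose coefficient; for results passing the
    Bonferroni 0.05 threshold it is cross-checked against the Kaplan-Meier
    median order and flagged when discordant. Returns the result list and a
    Manhattan table with the best model per mutation.
    """
    for m in models:
        if m not in MODELS:
            raise ValueError(f"unknown model {m!r}")
    phen_by_id = {p.mouse_id: p for p in screen.phenotypes}
    pids = [pedigree_id] if pedigree_id is not None else screen.pedigree_ids
    results: list[LinkageResult] = []
    for pid in pids:
        muts = screen.mutations_of(pid)
        if not muts:
            continue
        mice = [m for m in screen.screened_females(pid) if m in phen_by_id]
        if not mice:
            raise ValueError(f"pedigree {pid}: no screened mice with phenotypes")
        phen = [phen_by_id[m] for m in mice]
        time = np.array([p.onset_week for p in phen], dtype=float)
        event = np.array([p.event for p in phen], dtype=bool)
        m_tests = len(muts) * len(models)
        call_cols = {mut.id: screen.genotypes.loc[mice, mut.id] for mut in muts}
        doses = {
            (mut.id, model): encode(model, call_cols[mut.id].to_list())
            for mut in muts
            for model in models
        }
        factors = {model: 1.0 for model in models}
        if calibrate and not mixed:
            by_model = {
                model: [doses[(mut.id, model)] for mut in muts] for model in models
            }
            factors = _calibration_factors(
                time, event, by_model, calibration_permutations, calibration_seed
            )
        cluster = [screen.member(m).dam_id or "none" for m in mice] if mixed else None
        for mut_i, mut in enumerate(muts):
            calls = call_cols[mut.id]
            n_ref = int((calls == REF).sum())
            n_het = int((calls == HET).sum())
            n_var = int((calls == VAR).sum())
            for model_i, model in enumerate(models):
                raw = lrt_association(phen, doses[(mut.id, model)], cluster=cluster)
                res = raw
                fac = factors[model]
                if not math.isnan(raw.stat) and fac != 1.0:
                    stat = raw.stat / fac
                    res = LRTResult(
                        stat, float(stats.chi2.sf(stat, 1)), raw.beta,
                        raw.loglik_null, raw.loglik_alt, raw.flag,
                    )
                if not math.isnan(res.p):
                    p_bonf = min(1.0, res.p * m_tests)
                else:
                    p_bonf = math.nan
                if (
                    calibrate
                    and not mixed
                    and raw.flag == "ok"
                    and not math.isnan(p_bonf)
                    and p_bonf < refine_threshold
                ):
                    loc_seed = (
                        calibration_seed * 1_000_003 + mut_i * len(models) + model_i + 1
                    ) % (2**31 - 1)
                    p_exact = _score_permutation_p(
                        time, event, doses[(mut.id, model)], loc_seed,
                        n_perm_full=refine_permutations,
                    )
                    res = LRTResult(
                        res.stat, p_exact, raw.beta,
                        raw.loglik_null, raw.loglik_alt, raw.flag,
                    )
                    p_bonf = min(1.0, p_exact * m_tests)
                if res.flag in ("ok", "non_converged") and not math.isnan(res.beta):
                    direction = (
                        "accelerate" if res.beta > 0 else "suppress" if res.beta < 0 else "none"
                    )
                else:
                    direction = "none"
                flag = res.flag
                if flag == "ok" and not math.isnan(p_bonf) and p_bonf < 0.05:
                    km_dir = _km_direction(phen, calls, model)
                    if km_dir is not None and km_dir != direction:
                        flag = "direction_discordant"
                results.append(
                    LinkageResult(
                        mutation_id=mut.id,
                        pedigree_id=pid,
                        model=model,
                        n_ref=n_ref,
                        n_het=n_het,
                        n_var=n_var,
                        lrt_stat=res.stat,
                        p_raw=res.p,
                        p_bonferroni=p_bonf,
                        direction=direction,
                        beta=res.beta,
                        flag=flag,
                    )
                )
    return results, manhattan_table(results, screen)


def manhattan_table(results: Sequence[LinkageResult], screen: Screen) -> pd.DataFrame:
    """Per-mutation best raw p across models, with cumulative genome x-axis."""
    offsets = {}
    cum = 0
    for c, length in AUTOSOME_LENGTHS_BP.items():
        offsets[c] = cum
        cum += length
    by_mut: dict[str, list[LinkageResult]] = {}
    for r in results:
        by_mut.setdefault(r.mutation_id, []).append(r)
    rows = []
    for mut_id, rs in by_mut.items():
        best = best_result(rs)
        mut = screen.mutation(mut_id)
        if best is None:
            rows.append((mut_id, mut.pedigree_id, mut.chrom, mut.pos,
                         offsets[mut.chrom] + mut.pos, None, math.nan, math.nan))
        else:
            rows.append(
                (
                    mut_id,
                    mut.pedigree_id,
                    mut.chrom,
                    mut.pos,
                    offsets[mut.chrom] + mut.pos,
                    best.model,
                    best.p_raw,
                    -math.log10(best.p_raw) if best.p_raw > 0 else math.inf,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "mutation_id", "pedigree_id", "chrom", "pos", "genome_pos",
            "best_model", "p_raw", "neg_log10_p",
        ],
    )


def exclude_and_rescan(
    screen: Screen,
    exclude_mutation: str,
    exclude_zygosity: str,
    target_mutation: str,
    model: Optional[str] = None,
    models: Sequence[str] = MODELS,
    calibrate: bool = True,
    calibration_permutations: int = 16,
    calibration_seed: int = 0,
) -> LinkageResult:
    """Re-test one mutation after removing mice of a given zygosity at
    another locus (conditional analysis of co-segregating modifiers).

    Returns the target's best-model result (or the requested ``model``) on
    the retained cohort, with that cohort's genotype-class counts.
    """
    if exclude_zygosity not in (REF, HET, VAR):
        raise ValueError(f"exclude_zygosity must be REF/HET/VAR, got {exclude_zygosity!r}")
    mut = screen.mutation(target_mutation)
    pid = mut.pedigree_id
    excl_calls = screen.genotypes[exclude_mutation]
    drop = set(excl_calls.index[excl_calls == exclude_zygosity])
    phen_by_id = {p.mouse_id: p for p in screen.phenotypes}
    mice = [m for m in screen.screened_females(pid) if m in phen_by_id and m not in drop]
    if not mice:
        raise ValueError("exclusion predicate removes every screened mouse")
    phen = [phen_by_id[m] for m in mice]
    calls = screen.genotypes.loc[mice, target_mutation]
    n_ref = int((calls == REF).sum())
    n_het = int((calls == HET).sum())
    n_var = int((calls == VAR).sum())
    ped_muts = screen.mutations_of(pid)
    m_tests = len(ped_muts) * len(models)
    use_models = [model] if model is not None else list(models)
    factors = {mdl: 1.0 for mdl in use_models}
    if calibrate:
        time = np.array([p.onset_week for p in phen], dtype=float)
        event = np.array([p.event for p in phen], dtype=bool)
        by_model = {
            mdl: [
                encode(mdl, screen.genotypes.loc[mice, m.id].to_list()) for m in ped_muts
            ]
            for mdl in use_models
        }
        factors = _calibration_factors(
            time, event, by_model, calibration_permutations, calibration_seed
        )
    time = np.array([p.onset_week for p in phen], dtype=float)
    event = np.array([p.event for p in phen], dtype=bool)
    mut_i = next(i for i, m in enumerate(ped_muts) if m.id == target_mutation)
    per_model = []
    for mdl in use_models:
        dose = encode(mdl, calls.to_list())
        raw = lrt_association(phen, dose)
        res = raw
        fac = factors[mdl]
        if not math.isnan(raw.stat) and fac != 1.0:
            stat = raw.stat / fac
            res = LRTResult(
                stat, float(stats.chi2.sf(stat, 1)), raw.beta,
                raw.loglik_null, raw.loglik_alt, raw.flag,
            )
        p_bonf = min(1.0, res.p * m_tests) if not math.isnan(res.p) else math.nan
        if (
            calibrate
            and raw.flag == "ok"
            and not math.isnan(p_bonf)
            and p_bonf < 0.25
        ):
            model_i = list(models).index(mdl)
            loc_seed = (
                calibration_seed * 1_000_003 + mut_i * len(models) + model_i + 1
            ) % (2**31 - 1)
            p_exact = _score_permutation_p(time, event, dose, loc_seed)
            res = LRTResult(
                res.stat, p_exact, raw.beta,
                raw.loglik_null, raw.loglik_alt, raw.flag,
            )
            p_bonf = min(1.0, p_exact * m_tests)
        direction = "none"
        if res.flag in ("ok", "non_converged") and not math.isnan(res.beta) and res.beta != 0:
            direction = "accelerate" if res.beta > 0 else "suppress"
        per_model.append(
            LinkageResult(
                target_mutation, pid, mdl, n_ref, n_het, n_var,
                res.stat, res.p, p_bonf, direction, res.beta, res.flag,
            )
        )
    best = best_result(per_model)
    return best if best is not None else per_model[0]


def results_table(results: Sequence[LinkageResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mutation_id": r.mutation_id,
                "pedigree_id": r.pedigree_id,
                "model": r.model,
                "n_ref": r.n_ref,
                "n_het": r.n_het,
                "n_var": r.n_var,
                "lrt_stat": r.lrt_stat,
                "p_raw": r.p_raw,
                "p_bonferroni": r.p_bonferroni,
                "direction": r.direction,
                "beta": r.beta,
                "flag": r.flag,
            }
            for r in results
        ]
    )
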