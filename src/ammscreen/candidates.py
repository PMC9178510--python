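"""Candidate calling: count thresholds plus Bonferroni significance.

A mutation becomes a candidate modifier only when (1) its pedigree holds at
least ``min_g3_per_pedigree`` G3 females, (2) at least ``min_hom_var_screened``
homozygous-mutant mice were phenotyped, (3) at least ``min_hom_ref_screened``
homozygous-reference mice were phenotyped, and (4) the best inheritance
model's Bonferroni-corrected P falls below ``alpha``. Surviving calls are
classified as accelerating or delaying onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .linkage import LinkageResult, SurvivalCurve, best_result
from .types import Screen


@dataclass(frozen=True)
class CandidateCriteria:
    min_g3_per_pedigree: int = 20
    min_hom_var_screened: int = 2
    min_hom_ref_screened: int = 2
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if min(self.min_g3_per_pedigree, self.min_hom_var_screened, self.min_hom_ref_screened) < 1:
            raise ValueError("count thresholds must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class PedigreeStats:
    pedigree_id: str
    n_g3_females: int
    n_screened: int


def pedigree_stats(screen: Screen) -> dict[str, PedigreeStats]:
    phen_ids = {p.mouse_id for p in screen.phenotypes}
    out = {}
    for pid in screen.pedigree_ids:
        screened = [m for m in screen.screened_females(pid) if m in phen_ids]
        out[pid] = PedigreeStats(pid, screen.g3_female_count(pid), len(screened))
    return out


@dataclass(frozen=True)
class CandidateCall:
    mutation_id: str
    gene: str
    pedigree_id: str
    best_model: str
    p_bonferroni: float
    direction: str  # accelerate | delay
    criteria_trace: Mapping[str, bool]


def apply_criteria(
    results: Sequence[LinkageResult],
    stats: Mapping[str, PedigreeStats],
    criteria: CandidateCriteria = CandidateCriteria(),
    genes: Optional[Mapping[str, str]] = None,
) -> list[CandidateCall]:
    """Evaluate the four criteria for every mutation in a scan's results.

    ``genes`` maps mutation id to gene symbol (empty symbol if omitted).
    Non-converged or untestable results are excluded from best-model choice;
    if the models passing ``alpha`` disagree on direction, the mutation is
    not called.
    """
    by_mut: dict[str, list[LinkageResult]] = {}
    for r in results:
        if r.pedigree_id not in stats:
            raise ValueError(f"no pedigree stats for {r.pedigree_id!r}")
        st = stats[r.pedigree_id]
        if r.n_ref + r.n_het + r.n_var > st.n_screened:
            raise ValueError(
                f"{r.mutation_id}: zygosity counts exceed screened mice "
                f"({r.n_ref + r.n_het + r.n_var} > {st.n_screened})"
            )
        by_mut.setdefault(r.mutation_id, []).append(r)

    calls = []
    for mut_id, rs in by_mut.items():
        ok = [r for r in rs if r.flag == "ok"]
        best = best_result(ok)
        if best is None:
            continue
        st = stats[best.pedigree_id]
        passing = [
            r for r in ok if not math.isnan(r.p_bonferroni) and r.p_bonferroni < criteria.alpha
        ]
        concordant = len({r.direction for r in passing}) <= 1
        trace = {
            "min_g3_per_pedigree": st.n_g3_females >= criteria.min_g3_per_pedigree,
            "min_hom_var_screened": best.n_var >= criteria.min_hom_var_screened,
            "min_hom_ref_screened": best.n_ref >= criteria.min_hom_ref_screened,
            "alpha": (
                not math.isnan(best.p_bonferroni) and best.p_bonferroni < criteria.alpha
            ),
        }
        if all(trace.values()) and concordant and best.direction != "none":
            calls.append(
                CandidateCall(
                    mutation_id=mut_id,
                    gene=(genes or {}).get(mut_id, ""),
                    pedigree_id=best.pedigree_id,
                    best_model=best.model,
                    p_bonferroni=best.p_bonferroni,
                    direction="accelerate" if best.direction == "accelerate" else "delay",
                    criteria_trace=trace,
                )
            )
    return calls


def classify_direction(
    curves_by_genotype: Mapping[str, SurvivalCurve], effect_sign: float
) -> Optional[str]:
    """Classify a modifier as accelerating or delaying onset.

    ``curves_by_genotype`` maps zygosity class to its KM curve; the affected
    class is taken as VAR when present, else HET. Accelerate requires the
    affected class to sit below the REF curve (earlier onset) with a positive
    hazard effect; delay is the symmetric case. Discordant or identical
    curves return None (flagged for manual review).
    """
    if len(curves_by_genotype) < 2:
        raise ValueError("need at least two genotype classes")
    ref = curves_by_genotype.get("REF")
    aff = curves_by_genotype.get("VAR", curves_by_genotype.get("HET"))
    if ref is None or aff is None or aff is ref:
        raise ValueError("need a REF curve and an affected-class curve")
    med_a, med_r = aff.median(), ref.median()
    if med_a == med_r:
        sa, sr = aff.survival_at(40.0), ref.survival_at(40.0)
        if sa == sr:
            return None
        km_earlier = sa < sr
    else:
        km_earlier = med_a < med_r
    if km_earlier and effect_sign > 0:
        return "accelerate"
    if not km_earlier and effect_sign < 0:
        return "delay"
    return None


_CALLS_COLUMNS = [
    "gene", "mutation_id", "pedigree_id", "model", "p_bonferroni", "direction",
    "pass_min_g3_per_pedigree", "pass_min_hom_var_screened",
    "pass_min_hom_ref_screened", "pass_alpha",
]


def calls_table(calls: Sequence[CandidateCall]) -> pd.DataFrame:
    if not calls:
        return pd.DataFrame(columns=_CALLS_COLUMNS)
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "mutation_id": c.mutation_id,
                "pedigree_id": c.pedigree_id,
                "model": c.best_model,
                "p_bonferroni": c.p_bonferroni,
                "direction": c.direction,
                **{f"pass_{k}": v for k, v in c.criteria_trace.items()},
            }
            for c in calls
        ]
    )
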