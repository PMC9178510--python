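"""Synthetic modifier screens: breeding structure, genotypes, onset phenotypes.

Emulates the screen design: mutagenized G0 males sire G1 founder males, each
heterozygous for his own set of induced coding/splice mutations; G1 x
wild-type crosses give G2 females (HET or REF at every locus); each G2 female
is backcrossed to the G1 sire, so G3 daughters can be homozygous mutant (VAR)
only at loci where the dam is HET. G2 and G3 females are genotyped and
followed weekly for disease onset through a 40-week horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import WeibullOnset
from .types import (
    HET,
    HET_DOSE,
    MISSING,
    REF,
    VAR,
    EffectSpec,
    Mutation,
    PedigreeMember,
    PhenotypeRecord,
    Screen,
)

# Approximate mouse autosome lengths (bp), used to place mutations.
AUTOSOME_LENGTHS_BP = {
    "1": 195_000_000, "2": 182_000_000, "3": 160_000_000, "4": 157_000_000,
    "5": 152_000_000, "6": 150_000_000, "7": 145_000_000, "8": 129_000_000,
    "9": 125_000_000, "10": 131_000_000, "11": 122_000_000, "12": 120_000_000,
    "13": 120_000_000, "14": 125_000_000, "15": 104_000_000, "16": 98_000_000,
    "17": 95_000_000, "18": 91_000_000, "19": 61_000_000,
}

# Marginal frequencies of predicted damage classes among induced coding
# changes (mostly missense, a minority of nulls from nonsense/splice hits).
_DAMAGE_PROBS = {
    "probably_damaging": 0.30,
    "possibly_damaging": 0.25,
    "benign": 0.35,
    "probably_null": 0.10,
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PedigreeDesign:
    """Per-pedigree sizing: mutation load and female counts."""

    n_mutations: int
    n_g2: int
    g3_per_g2: int


@dataclass(frozen=True)
class ScreenDesign:
    """Sizing of a whole screen plus baseline phenotype parameters."""

    pedigrees: tuple[PedigreeDesign, ...]
    baseline_incidence: float = 0.80
    baseline_median_onset: float = 22.0
    frailty_sd: float = 0.0
    missing_rate: float = 0.0


# Screen-scale defaults: 14 pedigrees carrying 594 mutations in total
# (six of 43 and eight of 42, mean 42.4 per pedigree) and 844 screened
# G2+G3 females, ten pedigrees having <= 14 G3 females each.
DEFAULT_SCREEN_DESIGN = ScreenDesign(
    pedigrees=(
        PedigreeDesign(43, 26, 5),
        PedigreeDesign(43, 26, 5),
        PedigreeDesign(43, 23, 6),
        PedigreeDesign(43, 23, 6),
        PedigreeDesign(43, 7, 2),
        PedigreeDesign(43, 7, 2),
        PedigreeDesign(42, 7, 2),
        PedigreeDesign(42, 7, 2),
        PedigreeDesign(42, 7, 2),
        PedigreeDesign(42, 7, 2),
        PedigreeDesign(42, 7, 2),
        PedigreeDesign(42, 7, 2),
        PedigreeDesign(42, 7, 2),
        PedigreeDesign(42, 7, 2),
    ),
)


def _draw_mutations(
    rng: np.random.Generator, n: int, pedigree_id: str, start_index: int
) -> list[Mutation]:
    chroms = list(AUTOSOME_LENGTHS_BP)
    lengths = np.array([AUTOSOME_LENGTHS_BP[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    classes = list(_DAMAGE_PROBS)
    class_p = np.array([_DAMAGE_PROBS[c] for c in classes])
    out = []
    for i in range(n):
        k = start_index + i
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        pos = int(rng.integers(1, AUTOSOME_LENGTHS_BP[chrom] + 1))
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice(_BASES[_BASES != ref]))
        out.append(
            Mutation(
                id=f"{pedigree_id}M{k:03d}",
                chrom=chrom,
                pos=pos,
                gene=f"{pedigree_id.lower()}g{k:03d}",
                ref_allele=ref,
                alt_allele=alt,
                damage_class=classes[int(rng.choice(len(classes), p=class_p))],
                pedigree_id=pedigree_id,
            )
        )
    return out


def _offspring_calls(
    rng: np.random.Generator, dam_alt: np.ndarray, sire_het: bool = True
) -> np.ndarray:
    """Allele counts for one offspring given the dam's alt-allele dose vector
    (0 for REF, 1 for HET) and a HET sire."""
    n = dam_alt.shape[0]
    from_dam = (rng.random(n) < 0.5) & (dam_alt == 1)
    from_sire = rng.random(n) < 0.5 if sire_het else np.zeros(n, bool)
    return from_dam.astype(int) + from_sire.astype(int)


_CALL_BY_COUNT = np.array([REF, HET, VAR])


def simulate_pedigree(
    n_g1_founders: int,
    n_mutations_per_founder: int,
    g2_per_g1: int,
    g3_per_g2: int,
    seed: int,
) -> tuple[list[PedigreeMember], list[Mutation], pd.DataFrame]:
    """Simulate breeding and Mendelian transmission for one or more pedigrees.

    Returns pedigree members (including G0 sires and WT dams), the mutation
    table, and the genotype matrix over screened (G2+G3 female) mice. Every
    G1 founder is heterozygous for all of his mutations; each pedigree's loci
    are MISSING in mice of other pedigrees (they are never genotyped there).
    """
    for name, v in (
        ("n_g1_founders", n_g1_founders),
        ("n_mutations_per_founder", n_mutations_per_founder),
        ("g2_per_g1", g2_per_g1),
        ("g3_per_g2", g3_per_g2),
    ):
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    design = ScreenDesign(
        pedigrees=tuple(
            PedigreeDesign(n_mutations_per_founder, g2_per_g1, g3_per_g2)
            for _ in range(n_g1_founders)
        )
    )
    screen = simulate_screen(design, seed=seed, phenotypes=False)
    return screen.members, screen.mutations, screen.genotypes


def simulate_screen(
    design: ScreenDesign, seed: int, phenotypes: bool = True,
    effects: list[EffectSpec] | None = None,
) -> Screen:
    """Simulate a full screen per ``design``; optionally attach phenotypes."""
    rng = np.random.default_rng(seed)
    members: list[PedigreeMember] = []
    mutations: list[Mutation] = []
    geno_blocks: dict[str, dict[str, np.ndarray]] = {}
    screened_ids: list[str] = []

    for p_i, ped in enumerate(design.pedigrees, start=1):
        pid = f"P{p_i:02d}"
        if ped.n_mutations < 1 or ped.n_g2 < 1 or ped.g3_per_g2 < 1:
            raise ValueError(f"pedigree {pid}: all counts must be >= 1")
        muts = _draw_mutations(rng, ped.n_mutations, pid, start_index=1)
        mutations.extend(muts)
        mut_ids = [m.id for m in muts]

        g0 = PedigreeMember(f"{pid}_G0", pid, "G0", "M")
        g0_dam = PedigreeMember(f"{pid}_W0F", pid, "WT", "F")
        g1 = PedigreeMember(f"{pid}_G1", pid, "G1", "M", dam_id=g0_dam.mouse_id, sire_id=g0.mouse_id)
        wt_dam = PedigreeMember(f"{pid}_W1F", pid, "WT", "F")
        members += [g0, g0_dam, g1, wt_dam]

        ped_mouse_ids: list[str] = []
        ped_counts: list[np.ndarray] = []
        for d_i in range(1, ped.n_g2 + 1):
            g2_id = f"{pid}_G2_{d_i:03d}"
            members.append(
                PedigreeMember(g2_id, pid, "G2", "F", dam_id=wt_dam.mouse_id, sire_id=g1.mouse_id)
            )
            # G2 dam inherits each mutation from the HET sire w.p. 1/2.
            dam_alt = (rng.random(ped.n_mutations) < 0.5).astype(int)
            ped_mouse_ids.append(g2_id)
            ped_counts.append(dam_alt)
            screened_ids.append(g2_id)
            for o_i in range(1, ped.g3_per_g2 + 1):
                g3_id = f"{pid}_G3_{d_i:03d}_{o_i:02d}"
                members.append(
                    PedigreeMember(g3_id, pid, "G3", "F", dam_id=g2_id, sire_id=g1.mouse_id)
                )
                ped_mouse_ids.append(g3_id)
                ped_counts.append(_offspring_calls(rng, dam_alt))
                screened_ids.append(g3_id)
        geno_blocks[pid] = {  # type: ignore[dict-item]
            "mut_ids": mut_ids,
            "mouse_ids": ped_mouse_ids,
            "counts": np.vstack(ped_counts),
        }

    all_mut_ids = [m.id for m in mutations]
    col_of = {mid: j for j, mid in enumerate(all_mut_ids)}
    row_of = {mid: i for i, mid in enumerate(screened_ids)}
    cells = np.full((len(screened_ids), len(all_mut_ids)), MISSING, dtype=object)
    for block in geno_blocks.values():
        rows = [row_of[m] for m in block["mouse_ids"]]
        cols = [col_of[m] for m in block["mut_ids"]]
        cells[np.ix_(rows, cols)] = _CALL_BY_COUNT[block["counts"]]
    geno = pd.DataFrame(cells, index=screened_ids, columns=all_mut_ids)
    geno.index.name = "mouse_id"

    if design.missing_rate > 0:
        observed = geno.copy()
        mask = rng.random(geno.shape) < design.missing_rate
        observed.values[mask] = MISSING
    else:
        observed = geno

    screen = Screen(
        members=members,
        mutations=mutations,
        genotypes=observed,
        params={
            "seed": seed,
            "design": design_to_dict(design),
        },
    )
    # True (pre-missingness) genotypes drive phenotype simulation.
    if phenotypes:
        screen.phenotypes = simulate_phenotypes(
            members,
            geno,
            effects or [],
            baseline_incidence=design.baseline_incidence,
            baseline_median_onset=design.baseline_median_onset,
            seed=int(rng.integers(0, 2**31 - 1)),
            frailty_sd=design.frailty_sd,
        )
        if effects:
            screen.params["effects"] = [
                {
                    "mutation_id": e.mutation_id,
                    "model": e.model,
                    "direction": e.direction,
                    "hazard_multiplier": e.hazard_multiplier,
                }
                for e in effects
            ]
    return screen


def effect_dose(calls: pd.Series, model: str) -> pd.Series:
    """Dose in [0, 1] per mouse for an effect's inheritance model."""
    het = HET_DOSE[model]
    mapping = {REF: 0.0, HET: het, VAR: 1.0, MISSING: 0.0}
    return calls.map(mapping)


def simulate_phenotypes(
    members: list[PedigreeMember],
    genotypes: pd.DataFrame,
    effects: list[EffectSpec],
    baseline_incidence: float = 0.80,
    baseline_median_onset: float = 22.0,
    seed: int = 0,
    frailty_sd: float = 0.0,
) -> list[PhenotypeRecord]:
    """Draw censored weekly onset ages for every screened (G2/G3 female) mouse.

    The per-mouse hazard is the baseline Weibull hazard times the product of
    each effect's ``hazard_multiplier ** dose``; with ``frailty_sd > 0`` a
    shared log-normal dam-level frailty multiplies the hazard of all
    daughters of a dam. Latent times beyond the horizon are censored; onset
    is rounded up to the next whole week (weekly testing).
    """
    if not 0 < baseline_incidence < 1:
        raise ValueError("baseline_incidence must be in (0, 1)")
    known = set(genotypes.columns)
    for e in effects:
        if e.mutation_id not in known:
            raise ValueError(f"effect references unknown mutation id {e.mutation_id!r}")

    law = WeibullOnset.from_screen_design(baseline_incidence, baseline_median_onset)
    rng = np.random.default_rng(seed)
    by_id = {m.mouse_id: m for m in members}
    mice = [
        mid
        for mid in genotypes.index
        if by_id[mid].sex == "F" and by_id[mid].generation in ("G2", "G3")
    ]

    hr = np.ones(len(mice))
    for e in effects:
        dose = effect_dose(genotypes.loc[mice, e.mutation_id], e.model).to_numpy()
        with np.errstate(divide="ignore"):
            hr *= np.where(
                (e.hazard_multiplier == 0) & (dose > 0),
                0.0,
                np.power(max(e.hazard_multiplier, 1e-300), dose),
            )
    if frailty_sd > 0:
        dams = [by_id[mid].dam_id for mid in mice]
        uniq = {d: i for i, d in enumerate(dict.fromkeys(dams))}
        z = rng.normal(0.0, frailty_sd, size=len(uniq))
        hr = hr * np.exp(z[[uniq[d] for d in dams]])

    t = law.sample(rng, hr)
    records = []
    for mid, ti in zip(mice, t):
        if ti <= law.horizon:
            week = float(math.ceil(ti - 1e-12))
            records.append(PhenotypeRecord(mid, max(week, 1.0), True))
        else:
            records.append(PhenotypeRecord(mid, law.horizon, False))
    return records


def design_to_dict(design: ScreenDesign) -> dict:
    return {
        "pedigrees": [
            {"n_mutations": p.n_mutations, "n_g2": p.n_g2, "g3_per_g2": p.g3_per_g2}
            for p in design.pedigrees
        ],
        "baseline_incidence": design.baseline_incidence,
        "baseline_median_onset": design.baseline_median_onset,
        "frailty_sd": design.frailty_sd,
        "missing_rate": design.missing_rate,
    }


def design_from_dict(d: dict) -> ScreenDesign:
    allowed = {
        "pedigrees",
        "baseline_incidence",
        "baseline_median_onset",
        "frailty_sd",
        "missing_rate",
    }
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown design keys: {sorted(unknown)}")
    peds = tuple(
        PedigreeDesign(p["n_mutations"], p["n_g2"], p["g3_per_g2"]) for p in d["pedigrees"]
    )
    return ScreenDesign(
        pedigrees=peds,
        baseline_incidence=d.get("baseline_incidence", 0.80),
        baseline_median_onset=d.get("baseline_median_onset", 22.0),
        frailty_sd=d.get("frailty_sd", 0.0),
        missing_rate=d.get("missing_rate", 0.0),
    )
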