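"""Screen tables on disk, configuration, validation and the pipeline driver.

On-disk layout of a screen directory (all UTF-8 plain text, ``NA`` for
missing cells, no quoting of ids):

* ``mutations.tsv``  — ``#id chrom pos ref alt gene damage_class [pedigree_id]``
* ``genotypes.tsv``  — first column ``mouse_id``, one column per mutation id
* ``phenotypes.csv`` — ``mouse_id,onset_week,event`` with event in {1,0}
* ``pedigree.tsv``   — ``mouse_id pedigree_id generation sex dam_id sire_id``
* ``manifest.json``  — seed and simulation parameters
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import candidates as cand
from . import linkage, saturation
from .simulate import ScreenDesign, design_from_dict, design_to_dict, simulate_screen
from .types import (
    MISSING,
    MODELS,
    ZYGOSITIES,
    EffectSpec,
    Mutation,
    PedigreeMember,
    PhenotypeRecord,
    Screen,
)


class ScreenValidationError(ValueError):
    """A screen table violates the format or cross-table consistency rules."""


def write_screen(dir_path: str | Path, screen: Screen) -> Path:
    """Write all screen tables plus a manifest; returns the directory."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    try:
        mut_rows = []
        for m in screen.mutations:
            mut_rows.append(
                {
                    "#id": m.id,
                    "chrom": m.chrom,
                    "pos": m.pos,
                    "ref": m.ref_allele,
                    "alt": m.alt_allele,
                    "gene": m.gene,
                    "damage_class": m.damage_class,
                    "pedigree_id": m.pedigree_id or "NA",
                }
            )
        pd.DataFrame(mut_rows).to_csv(d / "mutations.tsv", sep="\t", index=False)

        geno = screen.genotypes.replace(MISSING, "NA")
        geno.to_csv(d / "genotypes.tsv", sep="\t", index=True, index_label="mouse_id")

        pd.DataFrame(
            {
                "mouse_id": [p.mouse_id for p in screen.phenotypes],
                "onset_week": [p.onset_week for p in screen.phenotypes],
                "event": [int(p.event) for p in screen.phenotypes],
            }
        ).to_csv(d / "phenotypes.csv", index=False)

        pd.DataFrame(
            [
                {
                    "mouse_id": m.mouse_id,
                    "pedigree_id": m.pedigree_id,
                    "generation": m.generation,
                    "sex": m.sex,
                    "dam_id": m.dam_id or "NA",
                    "sire_id": m.sire_id or "NA",
                }
                for m in screen.members
            ]
        ).to_csv(d / "pedigree.tsv", sep="\t", index=False)

        (d / "manifest.json").write_text(
            json.dumps(screen.params, indent=2, sort_keys=True) + "\n"
        )
    except OSError as e:
        raise OSError(f"failed writing screen to {d}: {e}") from e
    return d


def _require(path: Path) -> Path:
    if not path.exists():
        raise ScreenValidationError(f"missing file: {path}")
    return path


def read_screen(dir_path: str | Path) -> Screen:
    """Load and cross-validate a screen directory; raises
    ScreenValidationError naming the offending file/row on any violation."""
    d = Path(dir_path)
    mut_df = pd.read_csv(
        _require(d / "mutations.tsv"), sep="\t", dtype=str, keep_default_na=False
    )
    geno = pd.read_csv(
        _require(d / "genotypes.tsv"), sep="\t", dtype=str, index_col="mouse_id",
        keep_default_na=False,
    )
    phen_df = pd.read_csv(_require(d / "phenotypes.csv"), dtype={"mouse_id": str})
    ped_df = pd.read_csv(
        _require(d / "pedigree.tsv"), sep="\t", dtype=str, keep_default_na=False
    )
    manifest = {}
    if (d / "manifest.json").exists():
        manifest = json.loads((d / "manifest.json").read_text())

    members = []
    for i, row in ped_df.iterrows():
        try:
            members.append(
                PedigreeMember(
                    mouse_id=row["mouse_id"],
                    pedigree_id=row["pedigree_id"],
                    generation=row["generation"],
                    sex=row["sex"],
                    dam_id=None if row["dam_id"] == "NA" else row["dam_id"],
                    sire_id=None if row["sire_id"] == "NA" else row["sire_id"],
                )
            )
        except (ValueError, KeyError) as e:
            raise ScreenValidationError(f"pedigree.tsv row {i + 2}: {e}") from e
    by_id = {m.mouse_id: m for m in members}

    mutations = []
    id_col = "#id" if "#id" in mut_df.columns else "id"
    for i, row in mut_df.iterrows():
        try:
            ped = row.get("pedigree_id")
            mutations.append(
                Mutation(
                    id=row[id_col],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    gene=row["gene"],
                    ref_allele=row["ref"],
                    alt_allele=row["alt"],
                    damage_class=row["damage_class"],
                    pedigree_id=None if ped in (None, "NA") or pd.isna(ped) else ped,
                )
            )
        except (ValueError, KeyError) as e:
            raise ScreenValidationError(f"mutations.tsv row {i + 2}: {e}") from e
    mut_ids = {m.id for m in mutations}

    geno = geno.replace("NA", MISSING)
    for col in geno.columns:
        if col not in mut_ids:
            raise ScreenValidationError(f"genotypes.tsv: unknown mutation column {col!r}")
    bad = ~geno.isin(ZYGOSITIES)
    if bad.to_numpy().any():
        r, c = map(int, next(zip(*bad.to_numpy().nonzero())))
        raise ScreenValidationError(
            f"genotypes.tsv: malformed cell at mouse {geno.index[r]!r}, "
            f"column {geno.columns[c]!r}: {geno.iat[r, c]!r}"
        )
    for mid in geno.index:
        if mid not in by_id:
            raise ScreenValidationError(f"genotypes.tsv: mouse {mid!r} has no pedigree row")

    phenotypes = []
    for i, row in phen_df.iterrows():
        mid = row["mouse_id"]
        if mid not in by_id:
            raise ScreenValidationError(f"phenotypes.csv row {i + 2}: unknown mouse {mid!r}")
        member = by_id[mid]
        if member.sex != "F" or member.generation not in ("G2", "G3"):
            raise ScreenValidationError(
                f"phenotypes.csv row {i + 2}: mouse {mid!r} is {member.sex} {member.generation}; "
                "screening is restricted to female G2/G3 mice"
            )
        try:
            phenotypes.append(
                PhenotypeRecord(mid, float(row["onset_week"]), bool(int(row["event"])))
            )
        except ValueError as e:
            raise ScreenValidationError(f"phenotypes.csv row {i + 2}: {e}") from e

    return Screen(
        members=members,
        mutations=mutations,
        genotypes=geno,
        phenotypes=phenotypes,
        params=manifest,
    )


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class ScreenConfig:
    """Resolved run configuration (simulation + analysis + calling)."""

    seed: int = 0
    design: ScreenDesign = field(default_factory=lambda: ScreenDesign(pedigrees=()))
    effects: tuple[dict, ...] = ()
    models: tuple[str, ...] = MODELS
    mixed: bool = False
    criteria: cand.CandidateCriteria = field(default_factory=cand.CandidateCriteria)
    total_autosomal_genes: int = 20_000
    plots: bool = False

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "simulate": {**design_to_dict(self.design), "effects": list(self.effects)},
            "analysis": {"models": list(self.models), "mixed": self.mixed},
            "criteria": {
                "min_g3_per_pedigree": self.criteria.min_g3_per_pedigree,
                "min_hom_var_screened": self.criteria.min_hom_var_screened,
                "min_hom_ref_screened": self.criteria.min_hom_ref_screened,
                "alpha": self.criteria.alpha,
            },
            "saturation": {"total_autosomal_genes": self.total_autosomal_genes},
            "plots": self.plots,
        }


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ScreenValidationError(f"unknown keys in {where}: {sorted(unknown)}")


def config_from_dict(raw: dict) -> ScreenConfig:
    _check_keys(raw, {"seed", "simulate", "analysis", "criteria", "saturation", "plots"}, "config")
    sim = dict(raw.get("simulate", {}))
    effects = tuple(sim.pop("effects", []))
    for e in effects:
        _check_keys(
            dict(e),
            {"mutation", "pedigree", "index", "model", "direction", "hazard_multiplier"},
            "effects entry",
        )
    design = design_from_dict(sim) if sim.get("pedigrees") else ScreenDesign(pedigrees=())
    analysis = raw.get("analysis", {})
    _check_keys(analysis, {"models", "mixed"}, "analysis")
    crit = raw.get("criteria", {})
    _check_keys(
        crit,
        {"min_g3_per_pedigree", "min_hom_var_screened", "min_hom_ref_screened", "alpha"},
        "criteria",
    )
    sat = raw.get("saturation", {})
    _check_keys(sat, {"total_autosomal_genes"}, "saturation")
    return ScreenConfig(
        seed=int(raw.get("seed", 0)),
        design=design,
        effects=effects,
        models=tuple(analysis.get("models", MODELS)),
        mixed=bool(analysis.get("mixed", False)),
        criteria=cand.CandidateCriteria(
            min_g3_per_pedigree=int(crit.get("min_g3_per_pedigree", 20)),
            min_hom_var_screened=int(crit.get("min_hom_var_screened", 2)),
            min_hom_ref_screened=int(crit.get("min_hom_ref_screened", 2)),
            alpha=float(crit.get("alpha", 0.05)),
        ),
        total_autosomal_genes=int(sat.get("total_autosomal_genes", 20_000)),
        plots=bool(raw.get("plots", False)),
    )


def load_config(path: str | Path) -> ScreenConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ScreenValidationError(f"config {path} is not a mapping")
    return config_from_dict(raw)


def resolve_effects(config: ScreenConfig, screen: Screen) -> list[EffectSpec]:
    """Turn config effect entries into EffectSpec, resolving pedigree/index
    references (1-based pedigree number, 0-based mutation index) to ids."""
    specs = []
    for e in config.effects:
        if "mutation" in e:
            mut_id = e["mutation"]
        else:
            pid = f"P{int(e['pedigree']):02d}"
            muts = screen.mutations_of(pid)
            mut_id = muts[int(e["index"])].id
        specs.append(
            EffectSpec(
                mutation_id=mut_id,
                model=e["model"],
                direction=e["direction"],
                hazard_multiplier=float(e["hazard_multiplier"]),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(
    config: ScreenConfig,
    out_dir: str | Path,
    screen: Optional[Screen] = None,
    seed: Optional[int] = None,
) -> dict:
    """simulate (unless a screen is given) -> scan -> call -> saturation.

    Writes the screen tables, results/candidates TSVs, a saturation JSON, the
    resolved config and a deterministic ``summary.json`` (no timestamps) to
    ``out_dir``; returns the summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []
    use_seed = config.seed if seed is None else seed

    if screen is None:
        if not config.design.pedigrees:
            raise ScreenValidationError("config has no pedigrees to simulate")
        probe = simulate_screen(config.design, seed=use_seed, phenotypes=False)
        effects = resolve_effects(config, probe)
        screen = simulate_screen(config.design, seed=use_seed, effects=effects)
        log_lines.append(f"simulate: seed={use_seed} pedigrees={len(config.design.pedigrees)}")
    else:
        effects = resolve_effects(config, screen)
    write_screen(out / "screen", screen)

    results, manhattan = linkage.scan(screen, models=config.models, mixed=config.mixed)
    n_flagged = sum(1 for r in results if r.flag not in ("ok",))
    for pid in screen.pedigree_ids:
        n_ped = sum(1 for r in results if r.pedigree_id == pid)
        log_lines.append(f"scan: pedigree={pid} tests={n_ped}")
    if n_flagged:
        log_lines.append(f"scan: flagged_tests={n_flagged}")
    linkage.results_table(results).to_csv(out / "results.tsv", sep="\t", index=False)
    manhattan.to_csv(out / "manhattan.tsv", sep="\t", index=False)

    stats = cand.pedigree_stats(screen)
    genes = {m.id: m.gene for m in screen.mutations}
    calls = cand.apply_criteria(results, stats, config.criteria, genes=genes)
    cand.calls_table(calls).to_csv(out / "candidates.tsv", sep="\t", index=False)
    log_lines.append(f"call: candidates={len(calls)}")

    sat_in = saturation.tally_saturation(screen, config.total_autosomal_genes)
    sat = saturation.genome_saturation(sat_in)
    n_acc = sum(1 for c in calls if c.direction == "accelerate")
    n_del = sum(1 for c in calls if c.direction == "delay")
    sat_report = {
        "saturation": sat,
        "genes_dn_hom_x2": sat_in.genes_dn_hom_x2,
        "total_autosomal_genes": sat_in.total_autosomal_genes,
        "footprint_exacerbate": (
            saturation.genomic_footprint(n_acc, sat).footprint_rounded if sat > 0 else None
        ),
        "footprint_suppress": (
            saturation.genomic_footprint(n_del, sat).footprint_rounded if sat > 0 else None
        ),
    }
    (out / "saturation.json").write_text(json.dumps(sat_report, indent=2) + "\n")

    planted = {e.mutation_id: e for e in effects}
    called = {c.mutation_id for c in calls}
    recovery = {
        "planted": sorted(planted),
        "recovered": sorted(called & set(planted)),
        "missed": sorted(set(planted) - called),
        "false_calls": sorted(called - set(planted)),
    }

    summary = {
        "seed": use_seed,
        "n_pedigrees": len(screen.pedigree_ids),
        "n_mutations": len(screen.mutations),
        "n_screened_females": len(screen.phenotypes),
        "n_tests": len(results),
        "n_flagged_tests": n_flagged,
        "candidates": [
            {
                "mutation_id": c.mutation_id,
                "gene": c.gene,
                "pedigree_id": c.pedigree_id,
                "model": c.best_model,
                "p_bonferroni": c.p_bonferroni,
                "direction": c.direction,
            }
            for c in calls
        ],
        "saturation": sat_report,
        "recovery": recovery,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")

    if config.plots:
        from . import plots

        plots.manhattan_plot(manhattan, screen, out / "manhattan.svg")
        for c in calls:
            plots.km_by_genotype(screen, c.mutation_id, out / f"km_{c.mutation_id}.svg")
    return summary
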