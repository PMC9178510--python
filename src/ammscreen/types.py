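"""Core record types for an ENU modifier screen.

A screen consists of one or more pedigrees descended from mutagenized (G0)
males. Each pedigree carries the coding/splice mutations found by exome
sequencing of its G1 founder male; G2 daughters (G1 x wild-type) and G3
granddaughters (G2 backcrossed to the G1 sire) are genotyped at those sites
and followed weekly for disease onset up to a fixed horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

# Zygosity call tokens (``NA`` on disk for MISSING).
REF = "REF"
HET = "HET"
VAR = "VAR"
MISSING = "MISSING"
ZYGOSITIES = (REF, HET, VAR, MISSING)

# Inheritance models and the dose each assigns to a HET call.
MODELS = ("recessive", "additive", "dominant")
HET_DOSE = {"recessive": 0.0, "additive": 0.5, "dominant": 1.0}

DAMAGE_CLASSES = (
    "probably_damaging",
    "possibly_damaging",
    "benign",
    "probably_null",
)
# Classes counted as "damaging and/or null" for saturation purposes.
DAMAGING_CLASSES = frozenset({"probably_damaging", "probably_null"})

GENERATIONS = ("G0", "G1", "G2", "G3", "WT")
SEXES = ("F", "M")

AUTOSOMES = tuple(str(c) for c in range(1, 20))

# Monitoring horizon: mice event-free at this week are right-censored.
HORIZON_WEEKS = 40.0


@dataclass(frozen=True)
class Mutation:
    """One ENU-induced coding/splice variant segregating in a pedigree."""

    id: str
    chrom: str
    pos: int
    gene: str
    ref_allele: str
    alt_allele: str
    damage_class: str
    pedigree_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.chrom not in AUTOSOMES:
            raise ValueError(f"chrom must be an autosome 1-19, got {self.chrom!r}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele and alt_allele must differ")
        if self.damage_class not in DAMAGE_CLASSES:
            raise ValueError(f"unknown damage_class {self.damage_class!r}")


@dataclass(frozen=True)
class PedigreeMember:
    """A mouse in the breeding scheme, with parent links."""

    mouse_id: str
    pedigree_id: str
    generation: str
    sex: str
    dam_id: Optional[str] = None
    sire_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.generation not in GENERATIONS:
            raise ValueError(f"unknown generation {self.generation!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be F or M, got {self.sex!r}")


@dataclass(frozen=True)
class PhenotypeRecord:
    """Weekly-monitored onset: event week, or censored at the horizon."""

    mouse_id: str
    onset_week: float
    event: bool

    def __post_init__(self) -> None:
        if not (0 < self.onset_week <= HORIZON_WEEKS):
            raise ValueError(
                f"onset_week must be in (0, {HORIZON_WEEKS:g}], got {self.onset_week}"
            )
        if not self.event and self.onset_week != HORIZON_WEEKS:
            raise ValueError("censored records must have onset_week at the horizon")


@dataclass(frozen=True)
class EffectSpec:
    """A planted modifier: inheritance model, direction, hazard multiplier.

    The multiplier scales the baseline onset hazard for a fully expressing
    genotype (dose 1); dose follows the inheritance model. A multiplier of 0
    makes fully expressing mice immune (never develop disease).
    """

    mutation_id: str
    model: str
    direction: str
    hazard_multiplier: float

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.direction not in ("accelerate", "suppress"):
            raise ValueError(f"direction must be accelerate/suppress, got {self.direction!r}")
        if self.hazard_multiplier < 0:
            raise ValueError("hazard_multiplier must be >= 0")
        if self.direction == "accelerate" and not self.hazard_multiplier > 1:
            raise ValueError("accelerate requires hazard_multiplier > 1")
        if self.direction == "suppress" and not self.hazard_multiplier < 1:
            raise ValueError("suppress requires hazard_multiplier < 1")


@dataclass
class Screen:
    """In-memory bundle of one simulated or loaded screen.

    genotypes: DataFrame indexed by mouse_id, one column per mutation id,
    string cells in {REF, HET, VAR, MISSING}. Only screened (G2+G3 female)
    mice appear as rows; in multi-pedigree screens a mouse is MISSING at
    every locus belonging to another pedigree.
    """

    members: list[PedigreeMember]
    mutations: list[Mutation]
    genotypes: pd.DataFrame
    phenotypes: list[PhenotypeRecord] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def member(self, mouse_id: str) -> PedigreeMember:
        return self._member_index()[mouse_id]

    def _member_index(self) -> dict[str, PedigreeMember]:
        idx = getattr(self, "_midx", None)
        if idx is None or len(idx) != len(self.members):
            idx = {m.mouse_id: m for m in self.members}
            object.__setattr__(self, "_midx", idx)
        return idx

    @property
    def pedigree_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.members:
            seen.setdefault(m.pedigree_id, None)
        return list(seen)

    def mutation(self, mutation_id: str) -> Mutation:
        for mut in self.mutations:
            if mut.id == mutation_id:
                return mut
        raise KeyError(mutation_id)

    def mutations_of(self, pedigree_id: str) -> list[Mutation]:
        return [m for m in self.mutations if m.pedigree_id == pedigree_id]

    def screened_females(self, pedigree_id: Optional[str] = None) -> list[str]:
        """Mouse ids of phenotype-eligible mice (female G2/G3), in member order."""
        out = []
        for m in self.members:
            if m.sex != "F" or m.generation not in ("G2", "G3"):
                continue
            if pedigree_id is not None and m.pedigree_id != pedigree_id:
                continue
            out.append(m.mouse_id)
        return out

    def g3_female_count(self, pedigree_id: str) -> int:
        return sum(
            1
            for m in self.members
            if m.pedigree_id == pedigree_id and m.generation == "G3" and m.sex == "F"
        )

    def phenotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mouse_id": [p.mouse_id for p in self.phenotypes],
                "onset_week": [p.onset_week for p in self.phenotypes],
                "event": [p.event for p in self.phenotypes],
            }
        ).set_index("mouse_id")
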