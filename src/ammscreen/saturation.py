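"""Genome saturation and genomic-footprint extrapolation.

Saturation is the fraction of annotated autosomal protein-coding genes that
the screen tested adequately: genes carrying a damaging or null allele
phenotyped at least twice in the homozygous state. The genomic footprint of
a modifier class (suppressing or exacerbating) extrapolates the observed hit
count to the whole genome as hits / saturation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .types import DAMAGING_CLASSES, VAR, Screen


@dataclass(frozen=True)
class SaturationInput:
    genes_dn_hom_x2: int
    total_autosomal_genes: int

    def __post_init__(self) -> None:
        if not 0 <= self.genes_dn_hom_x2 <= self.total_autosomal_genes:
            raise ValueError("genes_dn_hom_x2 must be in [0, total_autosomal_genes]")


@dataclass(frozen=True)
class FootprintEstimate:
    n_hits: int
    saturation: float
    footprint: float
    footprint_rounded: int


def genome_saturation(inp: SaturationInput) -> float:
    """Fraction of autosomal protein-coding genes adequately screened."""
    if inp.total_autosomal_genes <= 0:
        raise ValueError("total_autosomal_genes must be positive")
    return inp.genes_dn_hom_x2 / inp.total_autosomal_genes


def _round_to_hundred(x: float) -> int:
    """Round half away from zero to the nearest 100."""
    return int(math.floor(x / 100.0 + 0.5) * 100)


def genomic_footprint(n_hits: int, saturation: float) -> FootprintEstimate:
    """Extrapolate observed modifier hits to the genome-wide gene count."""
    if saturation <= 0:
        raise ValueError("saturation must be > 0")
    if n_hits < 0:
        raise ValueError("n_hits must be >= 0")
    fp = n_hits / saturation
    return FootprintEstimate(
        n_hits=n_hits,
        saturation=saturation,
        footprint=fp,
        footprint_rounded=_round_to_hundred(fp),
    )


def tally_saturation(
    screen: Screen,
    total_autosomal_genes: int = 20_000,
    min_hom_screened: int = 2,
) -> SaturationInput:
    """Count genes with damaging/null alleles screened >= ``min_hom_screened``
    times in the homozygous state among phenotyped mice."""
    phen_ids = [p.mouse_id for p in screen.phenotypes]
    geno = screen.genotypes.loc[[m for m in phen_ids if m in screen.genotypes.index]]
    genes = set()
    for mut in screen.mutations:
        if mut.damage_class not in DAMAGING_CLASSES:
            continue
        if int((geno[mut.id] == VAR).sum()) >= min_hom_screened:
            genes.add(mut.gene)
    return SaturationInput(
        genes_dn_hom_x2=len(genes), total_autosomal_genes=total_autosomal_genes
    )
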