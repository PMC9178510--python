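import numpy as np
import pytest

import ammscreen as amm
from ammscreen.types import PhenotypeRecord


@pytest.fixture(scope="session")
def screen_design_100():
    """One pedigree, 42 mutations, 10 G2 dams x 9 G3 daughters = 100 females."""
    return amm.ScreenDesign(pedigrees=(amm.PedigreeDesign(42, 10, 9),))


@pytest.fixture(scope="session")
def null_screen(screen_design_100):
    """A no-effect screen used by several read-only tests."""
    return amm.simulate_screen(screen_design_100, seed=20260919 % (2**31 - 1))


@pytest.fixture(scope="session")
def suppressor_screen(screen_design_100):
    """Screen with a fully penetrant recessive suppressor at the first locus."""
    probe = amm.simulate_screen(screen_design_100, seed=4711, phenotypes=False)
    effect = amm.EffectSpec(probe.mutations[0].id, "recessive", "suppress", 0.0)
    screen = amm.simulate_screen(screen_design_100, seed=4711, effects=[effect])
    return screen, effect


def records(times, events):
    return [
        PhenotypeRecord(f"m{i}", float(t), bool(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


@pytest.fixture
def make_records():
    return records


@pytest.fixture(scope="session")
def baseline_law():
    return amm.WeibullOnset.from_screen_design(0.80, 22.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def build_manual_screen(calls_by_mutation, weeks, events, pedigree_id="P01"):
    """Screen with hand-specified G3 genotype columns and phenotypes.

    ``calls_by_mutation`` maps mutation id to a list of zygosity calls, one
    per mouse; all mice are G3 daughters of a single G2 dam and G1 sire.
    """
    import pandas as pd

    from ammscreen.types import Mutation, PedigreeMember, Screen

    n = len(weeks)
    members = [
        PedigreeMember(f"{pedigree_id}_G0", pedigree_id, "G0", "M"),
        PedigreeMember(f"{pedigree_id}_W0F", pedigree_id, "WT", "F"),
        PedigreeMember(
            f"{pedigree_id}_G1", pedigree_id, "G1", "M",
            dam_id=f"{pedigree_id}_W0F", sire_id=f"{pedigree_id}_G0",
        ),
        PedigreeMember(
            f"{pedigree_id}_G2_001", pedigree_id, "G2", "F",
            dam_id=f"{pedigree_id}_W0F", sire_id=f"{pedigree_id}_G1",
        ),
    ]
    mice = [f"{pedigree_id}_G3_{i:03d}" for i in range(n)]
    members += [
        PedigreeMember(
            m, pedigree_id, "G3", "F",
            dam_id=f"{pedigree_id}_G2_001", sire_id=f"{pedigree_id}_G1",
        )
        for m in mice
    ]
    mutations = [
        Mutation(mid, "1", 1000 + j, f"gene{j}", "A", "G", "probably_damaging", pedigree_id)
        for j, mid in enumerate(calls_by_mutation)
    ]
    geno = pd.DataFrame(calls_by_mutation, index=mice)
    geno.index.name = "mouse_id"
    phenos = [
        PhenotypeRecord(m, float(w), bool(e)) for m, w, e in zip(mice, weeks, events)
    ]
    return Screen(members=members, mutations=mutations, genotypes=geno, phenotypes=phenos)


@pytest.fixture
def manual_screen_builder():
    return build_manual_screen
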