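"""Manhattan and genotype-stratified Kaplan-Meier plots."""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import linkage
from .simulate import AUTOSOME_LENGTHS_BP
from .types import HET, REF, VAR, Screen


def manhattan_plot(manhattan, screen: Screen, out_path: str | Path) -> Path:
    """-log10 raw P versus cumulative genome position, one point per
    mutation, with horizontal lines at P=0.05 with (red) and without (pink)
    Bonferroni correction."""
    fig, ax = plt.subplots(figsize=(9, 3.2))
    for pid, grp in manhattan.groupby("pedigree_id"):
        ax.scatter(grp["genome_pos"], grp["neg_log10_p"], s=12, label=pid)
    n_tests = max(len(manhattan) * 3, 1)
    ax.axhline(-math.log10(0.05), color="pink", lw=1)
    ax.axhline(-math.log10(0.05 / n_tests), color="red", lw=1)
    # chromosome boundaries on the x axis
    cum = 0
    ticks, labels = [], []
    for c, length in AUTOSOME_LENGTHS_BP.items():
        ticks.append(cum + length / 2)
        labels.append(c)
        cum += length
        ax.axvline(cum, color="0.9", lw=0.5, zorder=0)
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} P$")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return Path(out_path)


def km_by_genotype(screen: Screen, mutation_id: str, out_path: str | Path) -> Path:
    """Onset curves stratified by zygosity at one locus, logrank P annotated."""
    phen = {p.mouse_id: p for p in screen.phenotypes}
    calls = screen.genotypes[mutation_id]
    groups = {}
    for z in (REF, HET, VAR):
        recs = [phen[m] for m in calls.index[calls == z] if m in phen]
        if recs:
            groups[z] = recs
    fig, ax = plt.subplots(figsize=(4, 3.2))
    for z, recs in groups.items():
        curve = linkage.km_estimate(recs)
        xs = [0.0]
        ys = [1.0]
        for t, s in zip(curve.times, curve.survival):
            xs += [t, t]
            ys += [ys[-1], s]
        xs.append(40.0)
        ys.append(ys[-1])
        ax.plot(xs, ys, drawstyle="default", label=f"{z} (n={curve.n})")
    if REF in groups and (VAR in groups or HET in groups):
        other = groups.get(VAR, groups.get(HET))
        _, p = linkage.logrank_test(groups[REF], other)
        ax.set_title(f"{mutation_id}  logrank P={p:.3g}", fontsize=9)
    ax.set_xlabel("age (weeks)")
    ax.set_ylabel("onset-free fraction")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return Path(out_path)
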