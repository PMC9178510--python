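# ammscreen

Single-locus linkage analysis of censored disease-onset traits in
ENU-mutagenized mouse pedigrees — a simulation-backed reimplementation of the
"automated meiotic mapping" style of forward-genetics modifier screen used to
find mutations that accelerate or suppress autoimmune (type 1) diabetes in
NOD mice.

## The problem

A mutagenized (G0) male founds a pedigree: his G1 son carries a private set
of ~40–45 induced coding/splice mutations (heterozygous); G1 × wild-type
crosses give G2 daughters; backcrossing each G2 to the G1 sire gives G3
daughters in which every mutation can become homozygous. G2+G3 females are
genotyped at all of the pedigree's mutation sites and monitored weekly for
glycosuria through 40 weeks of age; mice still disease-free at week 40 are
right-censored. The analysis asks, for every mutation: *is zygosity at this
locus associated with the age of disease onset?*

## The method

For each mutation and each inheritance model, genotypes are encoded as a
dose *x* ∈ {0, h, 1} for REF/HET/VAR with h = 0 (recessive), ½ (additive),
1 (dominant). Onset ages follow a Weibull proportional-hazards regression

&nbsp;&nbsp;&nbsp;&nbsp;h(t | x) = h₀(t) · e^{βx},&nbsp;&nbsp;
h₀(t) = (k/λ)(t/λ)^{k−1},

with right-censoring at 40 weeks. The test is the likelihood-ratio statistic
W = 2[ℓ(β̂) − ℓ(0)] referred to χ²₁, with two safeguards for screen-sized
pedigrees: each model's statistics are rescaled by a permutation-estimated
Bartlett factor, and any test approaching Bonferroni significance is decided
by an exact dose-permutation test of the model's score statistic (the score
at the null fit is linear in dose, so hundreds of thousands of permutations
are cheap). Bonferroni multiplicity is (mutations in the pedigree) × 3
models, per pedigree. An optional dam-level random intercept (shared
frailty, Gauss–Hermite integrated) handles litter clustering. Candidates
must (1) come from a pedigree with ≥ 20 G3 females, (2) have ≥ 2 homozygous
mutants and (3) ≥ 2 homozygous reference mice phenotyped, and (4) reach
Bonferroni-corrected P < 0.05; surviving calls are classified as
accelerating or delaying onset. Genome saturation (fraction of autosomal
protein-coding genes with damaging/null alleles screened ≥ 2× homozygous)
extrapolates hit counts to a per-direction genomic footprint = hits /
saturation.

Because no real screen data are distributed, the package includes a
first-class pedigree/phenotype simulator reproducing the breeding scheme,
Mendelian transmission, the screen's mutation load (594 mutations over 14
pedigrees, 844 phenotyped females by default) and a Weibull onset law
parameterized by cumulative incidence at 40 weeks (80% in females) and
median onset among affected mice.

## Worked example

```python
import ammscreen as amm
from ammscreen.candidates import apply_criteria, pedigree_stats

design = amm.ScreenDesign(pedigrees=(amm.PedigreeDesign(42, 10, 9),))  # 100 females
probe = amm.simulate_screen(design, seed=11, phenotypes=False)
effect = amm.EffectSpec(probe.mutations[0].id, "recessive", "suppress", 0.0)
screen = amm.simulate_screen(design, seed=11, effects=[effect])

results, manhattan = amm.scan(screen)
calls = apply_criteria(results, pedigree_stats(screen))
for c in calls:
    print(c.mutation_id, c.best_model, c.direction, f"p_bonf={c.p_bonferroni:.2e}")

sat = amm.genome_saturation(amm.tally_saturation(screen))
print(f"saturation={sat:.4f}")
print("footprint(7 exacerbating) =", amm.genomic_footprint(7, 0.0035).footprint_rounded)
print("footprint(5 suppressing)  =", amm.genomic_footprint(5, 0.0035).footprint_rounded)
```

prints

```
P01M001 recessive delay p_bonf=6.30e-04
saturation=0.0011
footprint(7 exacerbating) = 2000
footprint(5 suppressing)  = 1400
```

The planted fully penetrant recessive suppressor (hazard multiplier 0: the
~12 homozygous mutant females never develop disease while ~80% of the others
do) is recovered as the pedigree's only candidate, with direction `delay`.
A single 42-mutation pedigree saturates only ~0.1% of the genome; the two
footprint lines show the extrapolation at the screen-level saturation of
0.35%: 7 exacerbating hits imply ≈ 2000 genes whose loss of function could
accelerate disease, 5 suppressing hits ≈ 1400 genes that could delay it.

The same pipeline is scriptable from the shell:

```sh
amm report --config screen.yaml --seed 11 --out out/
```

writes the screen tables, per-test results, candidate calls, saturation
report and a machine-readable `summary.json`.

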