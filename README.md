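# hicsqueeze

Analysis of how constricted cell migration remodels 3D genome
organization, integrating Hi-C contact maps with RNA-seq differential
expression — together with a planted-truth simulator that makes every
stage of the analysis testable without sequencing data.

## The scientific problem

When a cell migrates through a pore smaller than its nucleus, the nucleus
must deform. The question this pipeline addresses: which layers of
chromatin architecture survive that deformation, and which are disrupted?
The analysis compares two migration conditions — through constricting
pores ("constricted", 5-µm analog) and through permissive pores
("baseline", 14-µm analog) — at four levels:

1. **Distance decay** — the contact probability P(s) as a function of
   genomic separation s, compared between conditions by a contact-weighted
   Kolmogorov–Smirnov test.
2. **A/B compartments** — per-chromosome PC1 of the Pearson correlation
   matrix of the observed/expected contact map; sign oriented by
   expressed-gene density (A = active). A 100-kb bin *switches*
   compartment when its PC1 sign flips between conditions **and** its
   interaction-pattern correlation falls below R = 0.6. Compartment bias
   of switching is assessed by logistic regression plus a 10,000-rep bin
   bootstrap.
3. **TADs** — called at 50 kb from a w = 5 diamond statistic with
   rank-sum-confirmed boundaries (BH < 0.05); a domain is *conserved*
   when a domain in the other condition reciprocally overlaps it by
   ≥ 80%. Conservation is modeled against log10 domain size (logistic
   regression) and compartment content (ANOVA with Tukey adjustment).
4. **Individual contacts** — counted in 100-kb windows tiled every 40 kb;
   significant contacts (> 100 kb apart) are Poisson upper-tail calls
   against a distance × coverage background (FDR < 0.05); differential
   contacts between depth-matched conditions are conditional binomial
   calls (FDR < 0.1). Decreased contacts are stratified by range
   (< / ≥ 1 Mb) and compartment, with B-compartment enrichment tested by
   bootstrap resampling from the significant-contact pool (99% CI).

Expression integration classifies differentially expressed genes into
three sets by significance pattern across the contrasts
(constricted-vs-control, baseline-vs-control, constricted-vs-baseline):
shared migration response, constriction-amplified, and
constriction-specific, with per-set fold-change R².

Because no public sequencing data accompanies the analysis, the
`synth` module generates binned contact maps with power-law decay
(exponent α), checkerboard compartment enrichment (κ), within-TAD
enrichment (τ), log-normal per-bin coverage bias, Poisson counts, and the
condition-specific perturbations under study: compartment flips and
boundary deletions concentrated in compartment B, and a multiplicative
short-range B–B depletion (δ) in the constricted condition. All planted
parameters are serialized, so recovery is checkable end to end.

## Worked example

```bash
hicsqueeze all --seed 1 --out runs/demo
```

runs simulate → balance → compartments → TADs → contacts → integrate and
writes TSV/BED/BEDPE outputs plus `summary.json`. With the default
configuration and seed 1 the log reports:

```
compartments: {'stable-A': 296, 'stable-B': 274, 'switch B>A': 27, 'switch A>B': 3}
TADs: 115 baseline, 97 constricted, 87.6% conserved
contacts: 7662 significant, 367 decreased, 179 increased
gene sets: {'set1': 420, 'set2': 1443, 'set3': 199}
```

and `summary.json` contains, among others: compartment stability 99.0%
(A) vs 91.0% (B) of unmasked bins — switching is B-biased (log odds 2.27,
p = 2.1e-4); short-range differential contacts are loss-dominated (342
decreased vs 145 increased, p = 6.6e-19) while long-range ones are not
(p = 0.30); the bootstrap flags B-compartment enrichment of decreased
contacts in every distance bin below 1 Mb and none above it; and the
three gene sets are recovered at their planted sizes. Each number is the
pipeline detecting a planted perturbation: flips and deletions aimed at
compartment B and a δ = 0.6 depletion of short-range B–B contacts.

The same machinery is importable directly — see `examples/` for one
short script per capability (simulation and balancing, compartment
switching, TAD conservation, differential contacts, gene sets):

```bash
python examples/04_differential_contacts.py
```

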