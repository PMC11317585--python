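# silentwing

Evolutionary dynamics and population genomics of competing male-silencing
mutations in Hawaiian field crickets (*Teleogryllus oceanicus*).

Under extreme selection from an acoustically orienting parasitoid fly,
several independent wing mutations that silence male song — X-linked
flatwing (Fw), autosomal curly-wing (Cw) — segregate in the same wild
populations. Either mutation alone protects a male, so expressing both
confers no extra benefit: the loci interact through **fitness epistasis**,
and each mutation shields the other's wild-type allele from selection
(**selective interference**). This package provides the two computational
halves needed to study that system:

1. **`silentwing.simcore`** — a forward-time Wright–Fisher simulator of two
   unlinked, male-beneficial mutations *m1* (autosomal, dominance *h₁*) and
   *m2* (X-linked or autosomal). Male relative fitness with expression
   levels *d₁*, *d₂* ∈ {0, h, 1} and selection coefficient *s* is

   | mode        | fitness of a male expressing both                |
   |-------------|--------------------------------------------------|
   | additive    | 1 + s·d₁ + s·d₂                                  |
   | nonadditive | 1 + s·max(d₁, d₂)                                |
   | negative    | 1 + s·max(d₁, d₂) − c (additive pleiotropic cost)|

   With s = 0.3 and c = 0.1, a doubly expressing male has fitness 1.6, 1.3
   or 1.2 in the three modes. Females always have fitness 1.

2. **`silentwing.synthpop` / `assoc` / `popscan`** — a synthetic genotype
   generator emulating the empirical architecture (a large segregating
   inversion whose arrangements are divergent non-recombining haplotype
   pools, a linked causal locus with incomplete penetrance, and
   population-specific gametic phase), plus the analysis stack: per-SNP
   linear-model association with likelihood-ratio tests and Bonferroni
   adjustment, windowed Weir–Cockerham F_ST (Σa/Σ(a+b+c)), region PCA with
   deterministic 3-means karyotype inference, heterozygosity and LD r²
   inversion diagnostics, and Wilcoxon rank-sum karyotype–phenotype tests.

## Worked example

Simulate the epistasis experiment at reduced scale (200 replicates per
scenario, N = 500, s = 0.3, h₁ = 0.75, X-linked m2):

```python
import numpy as np
from silentwing import simcore

scenarios = simcore.epistasis_scenarios(h1=0.75, generations=100)
table = simcore.run_experiment(scenarios, replicates=200, base_seed=1,
                               checkpoints=(100,))
summary = simcore.summarize_experiment(table)
print(summary.query("mutation == 'm1'")[["scenario", "median", "prop_lost"]])
```

```
      scenario  median  prop_lost
0     additive  0.8095      0.315
2  nonadditive  0.6085      0.345
4     negative  0.3545      0.420
6    single_m1  0.8345      0.325
8    single_m2  0.0000      1.000
```

The autosomal mutation's median frequency after 100 generations collapses
from ≈0.81–0.83 (additive benefits, or no competing mutation) to ≈0.61 when
coexpression adds nothing, and to ≈0.35 when coexpression additionally
carries a pleiotropic cost: co-occurring adaptations impede each other's
spread exactly when their benefits do not add.

The genomics half, from the shell:

```sh
silentwing make-synth --seed 1 --out-prefix syn
silentwing inversion-scan --vcf syn.vcf --meta syn.meta.tsv \
    --region chr2:7500000-80000000 --out report.json
silentwing assoc-scan --vcf syn.vcf --meta syn.meta.tsv \
    --phenotype Cw --out assoc.csv
```

`report.json` for the default architecture reports three PC1 clusters
(separation 0.97), a heterokaryotype/homokaryotype heterozygosity ratio of
1.9, a within-inversion LD excess of ≈10× over the flanking background and
a positive inversion call; the association scan ranks the true causal SNP
(65 Mb) first even though the two simulated populations carry the causal
allele on opposite arrangements.

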