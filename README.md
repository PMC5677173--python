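# invscan

Chromosomal inversions suppress recombination in heterozygotes and can
carry suites of linked alleles; whether and how they reshape gene
expression is a central question in inversion biology. `invscan` is a
reusable pipeline for testing the effect of inversion polymorphisms
(e.g., the cosmopolitan *D. melanogaster* inversions In(2L)t and
In(3R)Mo) on genome-wide transcript abundance in panels of inbred,
genotyped lines — and for dissecting *why* loci respond: linked SNP
variation (cis), regulators in LD with the inversion (trans), direct
breakpoint disruption, or plain co-expression structure.

It is written for population geneticists and quantitative-expression
people who have an expression matrix, line karyotypes, SNP calls and a
gene annotation as flat files, and want the full analysis — plus a
ground-truthed synthetic-data generator to validate the machinery.

## The statistics at the core

* **Per-probe nested ANOVA**, Y = mu + Sex + InvA + InvB + Line(karyotype) + eps,
  with sequential (Type-I) sums of squares because inversion contrasts
  are aliased with line contrasts; significance by permuting line-level
  karyotype labels (counts preserved) and recomputing F, B times;
  Storey q-values on the permutation P-values; effect sizes as per-term
  η² and Cohen's d over line means (d = (m_inv − m_std)/rms(SDs)).
  Loci with q < 0.05 are the IAL (inversion-affected loci).
* **SNP–inversion LD**: r² = D²/(p_S(1−p_S)p_I(1−p_I)) over the N lines
  non-missing at both, significance as χ² = N·r² against a per-arm
  Bonferroni critical value, after N ≥ 60 and 10%-MAF filters.
* **Hypergeometric enrichment** of IAL among genes in LD with the
  inversion and among targets of TFs carrying significant SNPs
  (E = nK/N, exact tails, 0.025 per tail).
* **Physical clustering** via the CV of intergenic gaps against a
  draw-k-genes null, and **breakpoint interruption/proximity** reports.
* **Co-expression controls**: mean pairwise adjusted r² (IAL×IAL vs
  background) and module-occupancy counts against a label-shuffle null.

See `docs/methods.md` for the full model, estimator choices and
limitations.

## Worked example

Simulate a study with 25 loci planted inside In(3R)Mo's breakpoint span
and 10 trans loci on another arm (effect size d = 2), then run the scan:

```python
import invscan as iv

base = iv.SimulationConfig(genes_per_arm=200, snps_per_arm=1000,
                           n_geno_inverted={"In(2L)t": 60, "In(3R)Mo": 50},
                           seed=42)
genome = iv.make_genome(base)
inside = [g.gene_id for g in genome.genes
          if g.arm == "3R" and 17_232_639 <= g.start <= 24_857_019][:25]
trans = [g.gene_id for g in genome.genes if g.arm == "2R"][:10]
cfg = iv.SimulationConfig(**{**base.__dict__,
    "planted_effects": [(g, "In(3R)Mo", 2.0) for g in inside + trans]})

bundle = iv.generate_bundle(cfg)
scan = iv.anova_scan(bundle.expression, bundle.design, B=2000, seed=7)
print({k: len(v) for k, v in scan["ial"].items()})
```

    {'In(2L)t': 0, 'In(3R)Mo': 29}

29 of the 35 planted loci are recovered (the 2-line In(2L)t arm has, as
expected, no calls). Chasing the mechanism:

```python
tab = iv.ld_scan_arm(bundle.snps.on_arm("3R"),
                     bundle.design.karyotypes["In(3R)Mo"])
sig = tab[tab["significant"]]
ial_genes = bundle.expression.genes_for(scan["ial"]["In(3R)Mo"])
hits = iv.genes_in_ld(sig, bundle.genome.genes, flank=5000)
rec = iv.ial_ld_enrichment({g.gene_id for g in bundle.genome.genes},
                           ial_genes, hits)
occ = iv.occupancy_null(bundle.truth.modules, ial_genes,
                        n_perm=20000, seed=3)
```

which prints, per the run above:

    3R: 164 of 1000 SNPs in significant LD (chi2 > 16.45)
    enrichment: N=1000 K=7 n=29 x=4 E=0.20 P(X>=x)=1.89e-05
    module occupancy: 16 observed, null 95% CI (13, 18) -> within CI

So IAL are massively overrepresented among genes in LD with the
inversion (4 observed vs 0.2 expected), and they are spread across
expression modules rather than riding one co-expressed block — the
planted cis-plus-trans architecture, read back correctly. The location
table (`invscan.structure.location_table`) splits the 29 IAL into 19
within the breakpoints and 10 on the unlinked arm.

The same pipeline runs from flat files via the CLI:

```sh
invscan simulate --out bundle/ --seed 42
invscan run-all --config manifest.yaml   # anova -> LD -> enrichment ->
                                         # structure -> co-expression
```

Each output TSV carries a header line naming the stage, parameters and
seed; reruns with the same manifest are byte-identical.

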