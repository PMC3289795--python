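# grsnbc

Genetic risk scores (GRS), Naive Bayes classifiers (NBC) for SNP profiles,
and the exact equivalence of their classification rules — plus a
case–control genotype simulator and nested-model AUC evaluation.

A binary trait is predicted from unphased biallelic genotypes in three
classic GRS flavours (risk-allele counting, additive log-odds-ratio
weights, genotypic log-odds-ratio weights) and by the NBC posterior
probability. When the genotypic GRS weights and the NBC conditionals are
estimated from the same (smoothed) case/control count tables, the NBC
trait log-odds is exactly affine in the raw GRS, so the two classifiers
rank subjects identically, share every ROC point, and their decision
thresholds interconvert in closed form. The package verifies this
numerically and reproduces the nested-model AUC experiment (rank SNPs on a
discovery set, grow models SNP by SNP, measure replication AUC, average
over replicates) at genome scale via a count-mode generator.

## Layout

| module               | contents |
|----------------------|----------|
| `grsnbc.data`        | genotype matrix / phenotype / 2×3 count-table types, genotype TSV dialect, VCF ingestion |
| `grsnbc.assoc`       | per-SNP additive and genotypic logistic fits, risk-allele rule, association-evidence ranking |
| `grsnbc.grs`         | the three weighting schemes, score computation, logistic calibration, threshold-shift algebra |
| `grsnbc.nbc`         | NBC fitting, log-space posterior/log-odds scoring, loss-ratio classification |
| `grsnbc.equivalence` | NBC↔GRS threshold mapping and the numerical equivalence report |
| `grsnbc.simulate`    | HWE controls, OR-tilted cases (additive/recessive/dominant), subject- and count-mode generation |
| `grsnbc.evaluate`    | Mann–Whitney AUC, nested-model curves, the discovery/replication experiment |

## CLI

```sh
# simulate a design described in YAML (fields mirror SimulationDesign)
grsnbc simulate design.yaml -o simdir --split both
grsnbc simulate design.yaml -o simdir --counts-only     # genome-scale tables

# genetic risk scores
grsnbc grs build simdir/discovery_r0.tsv --case case3 -o weights.tsv
grsnbc grs score simdir/replication_r0.tsv weights.tsv -o scores.tsv
grsnbc grs calibrate simdir/discovery_r0.tsv weights.tsv -o calibrated.tsv

# Naive Bayes
grsnbc nbc fit simdir/discovery_r0.tsv -o nbc.tsv
grsnbc nbc score simdir/replication_r0.tsv nbc.tsv -o posteriors.tsv

# equivalence report and the nested-model experiment
grsnbc equiv verify simdir/discovery_r0.tsv -o report.tsv
grsnbc experiment run design.yaml -o expdir --plot curves.png
```

A minimal `design.yaml`:

```yaml
n_cases: 3000
n_controls: 3000
or_grid: [1.2, 1.3, 1.4, 1.5, 1.6]
maf_grid: [0.1, 0.2, 0.3, 0.4, 0.5]
modes: [additive, recessive, dominant]
n_null: 500000
null_maf_range: [0.05, 0.5]
n_replicates: 5
seed: 1
```

## Genotype TSV dialect

```text
subject_id<TAB>phenotype<TAB>rs1:A/G<TAB>rs2:C/T
s1<TAB>1<TAB>AA<TAB>CT
s2<TAB>0<TAB>GA<TAB>..
```

Phenotype is 0/1 (1 = trait). Alleles are declared per SNP in
lexicographic order (A < C < G < T); genotype cells are two-character
allele strings in either order (`GA` ≡ `AG`), `..` for missing. VCF input
(biallelic SNPs, GT only) is re-ordered into the same convention.
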