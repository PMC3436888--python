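# genorep

Genotype reproducibility analysis for replicate SNP-array studies: pairwise
genotype concordance between technical replicates, replicate-based array QC,
and a Monte-Carlo simulator of the spurious case-control odds ratio caused
by genotyping error alone.

## The problem

High-density SNP arrays are reliable but not perfect, and genome-wide
association studies (GWAS) routinely report odds ratios of 1.1–1.5 — small
enough that a sub-percent genotyping error rate can matter. Two questions
follow for anyone running or auditing a genotyping effort:

1. **How reproducible are the calls?** When the same DNA is assayed several
   times — in one laboratory, in different laboratories on the same
   platform, or on different platforms — what fraction of SNPs agree?
2. **How much association signal can discordance fake?** If cases and
   controls truly have identical allele frequencies, how large an odds
   ratio can genotype noise alone produce?

`genorep` answers both on a replicate study design: six subjects (A–F),
four technical replicates each, five genotyping experiments (three on an
Affymetrix-6.0-like platform "Affy6", two on an Illumina-1M-like platform
"Illu1M"). A synthetic-data generator reproduces this design so every stage
is testable without array data; all statistics equally apply to real call
matrices read from TSV or PLINK-style `.ped`/`.map` text.

## Core statistics

**Concordance.** For samples *i*, *j* with calls G<sub>i</sub><sup>k</sup>,
G<sub>j</sub><sup>k</sup> on N SNPs, concordance is
(1/N′) Σ<sub>k</sub> 1[G<sub>i</sub><sup>k</sup> = G<sub>j</sub><sup>k</sup>].
In `co_called` mode (default) the denominator N′ counts only SNPs called in
both samples; `strict` mode uses all N SNPs. Pairs aggregate into three
levels: `intra` (same subject and experiment), `inter_lab` (same platform,
different experiments), `inter_platform` (different platforms, after SNP
intersection and allele/strand harmonization).

**Replicate QC.** Per array: call rate and heterozygote rate (HET/called).
Within each replicate group a sample is flagged `het_outlier` when its het
rate deviates from the group median by more than max(0.02, 5·MAD), and
`low_call_rate` below a 0.95 call rate; all thresholds are configurable and
echoed into the report.

**Odds-ratio inflation.** Case (n=2,000) and control (n=3,000) populations
are built with deterministic Hardy–Weinberg counts at the same minor allele
frequency p, so the allelic odds ratio
OR = (a·d)/(b·c) on the 2×2 allele table is exactly 1. Genotype noise at
concordance c (each individual keeps its genotype with probability c, else
moves uniformly to another class) is applied independently to both
populations, the OR recorded, and the process repeated 50,000 times per
(p, c) grid cell; the surface of 95th-percentile ("top 5%") ORs over
p ∈ {0.01…0.40} × c ∈ {0.940…1.000} quantifies the spurious effect size
genotyping error can mimic — largest at low MAF and low concordance.

## Worked example

```python
import genorep as g

panel, truth = g.generate_truth(6, 20_000, 0.05, 0.5, seed=1)
design = g.table1_design()           # 6 subjects x 4 replicates x E1..E5
model = g.ErrorModel({"E1": 0.004, "E2": 0.003, "E3": 0.002,
                      "E4": 0.001, "E5": 0.001}, nocall_rate=0.005)
calls = g.simulate_replicate_study(truth, design, model, seed=2)
calls = g.inject_low_quality(calls, "F1_E1", het_inflation=0.10,
                             callrate_drop=0.0, seed=3)

_, intra = g.reproducibility_summary(calls, design, "intra")
print(intra[intra.subject == "ALL"])
```

```
level subject group     mean       sd  n_pairs
intra     ALL    E1 0.986684 0.017709       36
intra     ALL    E2 0.993881 0.000514       36
intra     ALL    E3 0.995881 0.000479       36
intra     ALL    E4 0.997985 0.000281       36
intra     ALL    E5 0.997900 0.000388       36
intra     ALL   ALL 0.994466 0.008887      180
```

Per-experiment mean concordance tracks each experiment's error rate (a
per-call error e gives replicate agreement 1 − 2e + 1.5e²); E1's mean is
depressed and its SD inflated by the injected bad array, which the QC stage
pinpoints:

```python
report = g.flag_outlier_replicates(g.per_sample_stats(calls), design)
print(report.flags)
```

```
sample_id        rule    value  reference  threshold
    F1_E1 het_outlier 0.424332    0.36138       0.02
```

The simulator, on a reduced grid:

```python
cfg = g.SimConfig(reps=5000, maf_grid=(0.05, 0.10, 0.20),
                  concordance_grid=(0.94, 0.97, 1.00), seed=1)
print(g.percentile_surface(cfg).values.round(3))
```

```
[[1.111 1.099 1.   ]
 [1.076 1.06  1.   ]
 [1.047 1.035 1.   ]]
```

Rows are MAFs, columns concordances: at MAF 0.05 and concordance 0.94,
5% of null simulations exceed OR 1.11 from noise alone; at perfect
concordance every simulated OR is exactly 1.

The same pipeline is scriptable: `genorep simulate-study`, `genorep qc`,
`genorep concordance`, `genorep summarize`, `genorep error-sim`, and
`genorep run --config config.yaml` (full pipeline with a reproducibility
manifest).

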