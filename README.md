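# wmsnorm

Filtration and normalization of read counts for whole-metagenome
shotgun (WMS) sequencing.

Estimating bacterial abundances by mapping shotgun reads against
complete reference genomes is distorted by three systematic effects:

1. **Genomic-island false positives.** Reads that map to a reference
   only inside a horizontally transferred island really come from the
   island's donor; a hit supported by a few tight read clusters is a
   false positive and must be filtered before quantification.
2. **GC bias.** PCR and instrument chemistry make coverage depend on
   both the GC content of the read and the GC content of the genome it
   maps to; GC-poor genomes end up overrepresented.
3. **Reference length.** Longer genomes collect proportionally more
   reads, exactly as gene length inflates RNA-seq counts.

`wmsnorm` addresses the three in order and, when the host read count
is known, converts the corrected counts into absolute bacterial load
per host cell. It is aimed at labs quantifying well-characterized
communities against complete references — medical microbiome
diagnostics being the canonical case.

## Methods at a glance

**Island filtration.** For each reference with N mapped reads on a
genome of length G, the spacings Δ between consecutive read starts are
tested with a one-sample t-test against the uniform null mean
Δ̄₀ = G/N (one-sided, alternative Δ̄ < G/N). A complementary check
estimates the genome size from the read-start range under a uniform
model (R(N+1)/(N−1), with a Beta(N−1, 2) upper confidence bound):
hits whose size upper bound is below 10% of the true genome size are
filtered, between 10 and 50% they are flagged *uncertain* for manual
review with their t statistics and spacing histograms.

**GC normalization.** Normalized coverage per integer GC point i is

    NormCov_i = (Rst_i / W_i) / (Rst_Total / W_Total)

with Rst_i the read starts in 100 bp windows of GC% i and W_i the
count of such windows; in an m-genome pool the expected density is the
equal share Rst_Total/m over the genome's own windows. The bias
surface over read GC (GC_R) and genome GC (GC_G) is fitted by
nonlinear least squares to

    NormCov(GC_R, GC_G) = θ₁·exp(−½((GC_R−θ₂)/θ₃)²) + θ₄
                          + θ₅GC_R + θ₆GC_R² + θ₇GC_R³ + θ₈·ln(GC_G)

— a Gaussian bell for the central GC preference, a cubic for its
distortions, and a falling log term for the genome-wide GC effect.
Predictions are floored at 0.01; each read is weighted by the
reciprocal of its predicted coverage. The bias is platform-specific:
fit the model once per sequencing setup from individually sequenced
genomes spanning a wide GC range, then ship the eight coefficients as
JSON.

**Reporting.** Species abundances are reported as raw counts,
GC-weighted counts, and GC-weighted counts per Mb of reference;
multireads are kept only if resolvable to a single species (hits to
multiple strains of one species collapse to a representative strain,
hits to several species are discarded). With C_H host (human) reads,
the absolute abundance per host cell is

    A = 6191.39 · C_GCperMbR / C_H

where 6191.39 Mb is the diploid human genome length.

## Worked example

The built-in simulator plays the role of the sequencer: it draws read
starts window-by-window under a planted bell-shaped bias surface, so
the truth is known exactly. Calibrate on an equal-DNA pool of seven
genomes spanning GC 32.8–70.8%, then quantify an eight-genome pool
mixed in unequal, known proportions:

```python
from wmsnorm import (SimulationSpec, make_pool, run_pipeline, PipelineConfig, rmse,
                     load_references, load_alignments, gc_count_table, fit_gc_model)
from wmsnorm.gc_model import curves_from_counts
from wmsnorm.synthetic import gc_ladder_spec, planted_bias_model

bias = planted_bias_model()                      # acts as the sequencer

# 1. calibration: equal DNA of 7 genomes, GC 32.8-70.8%
cal = make_pool(gc_ladder_spec(total_reads=70_000, bias=bias, seed=11), "ex/cal")
genomes = load_references(cal["fasta"])
reads = load_alignments(cal["sam"], genomes=genomes)
curves = curves_from_counts(gc_count_table(reads, genomes), genomes, pooled=True)
model = fit_gc_model(curves)
model.to_json("ex/model.json")
print(f"residual SE {model.residual_se:.4f} on {model.dof} degrees of freedom")

# 2. validation: 8 genomes, unequal known proportions, same bias
props = [0.20, 0.17, 0.14, 0.12, 0.11, 0.10, 0.09, 0.07]
val = make_pool(SimulationSpec(
    genomes=[(400_000, gc) for gc in (33, 38, 44, 50, 56, 62, 67, 71)],
    pool_proportions=props, total_reads=80_000, bias=bias, seed=17), "ex/val")
truth = {f"genome{i:02d}_sp": 100 * p for i, p in enumerate(props)}
for label, m in (("raw", None), ("normalized", "ex/model.json")):
    s = run_pipeline(PipelineConfig(alignments=str(val["sam"]), references=str(val["fasta"]),
                                    taxonomy=str(val["taxonomy"]), model=m,
                                    out_dir=f"ex/{label}", log_level="WARNING"))
    est = {k: v["relative_percent"] for k, v in s["per_species"].items()}
    err = rmse([est[k] for k in sorted(est)], [truth[k] for k in sorted(est)])
    print(f"{label:>10} RMSE {err:.2f}%")
```

prints

```
residual SE 0.1238 on 192 degrees of freedom
       raw RMSE 3.71%
normalized RMSE 0.37%
```

Raw counts overestimate the GC-poor genomes and underestimate the
GC-rich ones by several percentage points; GC + length normalization
brings every species within a fraction of a point of its true DNA
proportion — a ten-fold RMSE reduction here. The pipeline report
(`ex/normalized/report.tsv`) also lists filtered and uncertain hits
with their t-test statistics, spacing histograms, and a read ledger
reconciling every input read.

## Command line

The same steps are available as subcommands of a single entry point:

```sh
wmsnorm simulate  --spec spec.yaml --out-dir sim/           # synthetic pool
wmsnorm gc-curves --alignments s.sam --references r.fasta --out curves.tsv
wmsnorm fit       --curves curves.tsv --out model.json
wmsnorm predict   --model model.json --read-gc 50 --genome-gc 67
wmsnorm filter    --alignments s.sam --references r.fasta --out hits.tsv
wmsnorm quantify  --alignments s.sam --references r.fasta \
                  --taxonomy tax.tsv --model model.json --out-dir out/
wmsnorm run       --config pipeline.yaml                    # all of the above
```

## Scope

`wmsnorm` consumes alignments (SAM/BAM); read trimming, host-read
removal and the alignment itself belong to upstream tools. Replication
-fork genome equivalents, CFU calibration and functional annotation of
unassigned reads are out of scope. See `docs/methods.md` for modelling
details, parameter defaults, and limitations.
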