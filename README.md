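# mzdecay

Maternal and zygotic mRNA decay analysis for paired embryo /
unfertilized-egg expression time courses.

## The problem

During the first hours of fly development the embryo is transcriptionally
silent, so early changes in transcript abundance directly reflect mRNA
*degradation*. Two machineries remove maternally deposited transcripts: a
**maternal** decay activity (deposited in the egg, triggered by egg
activation — the only activity present in unfertilized eggs) and a
**zygotic** activity that requires embryonic transcription. Comparing a
time course from embryos (E1–E3) with a matched time course from
unfertilized eggs (U1–U3) teases the two apart. For each transcript with
maternal provision X_M,

    embryos:            X(t) = X_M + ΔX_T(t) − ΔX_MD(t) − ΔX_ZD(t)
    unfertilized eggs:  X(t) = X_M − ΔX_MD(t)
    early eggs (U1):    X(U1) = X_M

where ΔX_T is zygotic transcription and ΔX_MD / ΔX_ZD are the maternal
and zygotic decay contributions. `mzdecay` implements this framework
end-to-end for log2 expression matrices:

* **simulate** — a ground-truth generator for paired U/E time courses
  (six conditions × n replicates, Gaussian log2 replicate noise) with
  per-gene decay rates, transcription gains and stability-class labels;
* **profiles** — replicate medians/SEMs, detection calls, one-sided
  Welch tests with Benjamini–Hochberg FDR, and sample QC clustering
  (complete linkage, 1 − Pearson r distance on median-centered profiles);
* **kinetics** — net decay (late − U1, log2), early/late partition,
  maternal (U3−U1) vs zygotic (E3−U3) components, and exponential
  half-lives between t2 and t3: k = (log2 X(t2) − log2 X(t3))·ln2/Δt,
  t½ = ln2/k, with Δt = 60 min;
* **classify** — nine stability classes: I (stable), II (maternal decay
  only), III (maternal decay + transcription), IV (zygotic decay only),
  V (mixed decay), purely zygotic, stable + transcription,
  non-classified (complex patterns), not expressed;
* **enrichment** — Fisher's exact test on 2×2 gene-set overlaps with
  odds ratios and BH FDR, plus candidate-regulator screens (RBPs with
  t½ < 150 min and ≥ 5 quantified peptides; miRNAs with > 100 early
  reads and a strict later drop);
* **motifs** — SYLAMER-style k-mer enrichment landscapes over 3' UTRs
  ranked by net decay: hypergeometric upper-tail −log10 p per word over
  40 cumulative bins, top-motif extraction and miRNA seed matching.

## Worked example

```python
from mzdecay import (SimConfig, simulate_dataset, classify_dataset,
                     ClassifyConfig, summarize_replicates, compute_kinetics)

cfg = SimConfig(n_genes_per_class=50, noise_sd=0.2, seed=1)
matrix, truth = simulate_dataset(cfg)
calls, summary = classify_dataset(matrix, ClassifyConfig(detection_threshold=5.0))
print(summary.to_string(index=False))
```

```
         class_label  count  pct_of_preloaded
                   I     50              14.3
                  II     50              14.3
                 III     50              14.3
                  IV     49              14.0
                   V     51              14.6
      PURELY_ZYGOTIC     50               NaN
STABLE_TRANSCRIPTION     50              14.3
      NOT_CLASSIFIED     50              14.3
       NOT_EXPRESSED     50               NaN
                II-V    200              57.1
```

Percentages are relative to the preloaded (maternally provided) total;
purely zygotic and non-expressed genes fall outside it. One noisy class
IV gene was called elsewhere here — at these settings overall recovery
of the true labels is ≥ 99%. Decay kinetics follow the class routing
(classes II/III read off the egg series, IV/V off the embryo series):

```python
prof = summarize_replicates(matrix, detection_threshold=5.0)
kin = compute_kinetics(prof, calls["class_label"])
print(kin.loc[calls["class_label"].isin(["II","III","IV","V"]),
              ["series_used","net_decay","early_decay","late_decay","half_life_min"]]
      .head(3).round(2).to_string())
```

```
         series_used  net_decay  early_decay  late_decay  half_life_min
gene_id
sim00050           U      -2.24        -1.30       -0.94          64.01
sim00051           U      -1.94        -1.11       -0.82          72.88
sim00052           U      -2.69        -1.34       -1.35          44.40
```

A net decay of −1 means 50% of the signal is gone (2^−1 remaining);
−2.24 leaves about 21%. Half-lives come from the t2→t3 drop; a gene
whose signal halves every hour has t½ = 60 min.

The same pipeline is available from the shell:

```
mzdecay simulate --out sim/ --seed 1
mzdecay run --matrix sim/expression.tsv --design sim/design.tsv \
            --out results/ --detection-threshold 5.0
```

`run` writes profile, calls, summary, kinetics (and optionally
enrichment and motif-landscape) TSVs plus a JSON manifest with input
checksums; reruns are byte-identical.

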