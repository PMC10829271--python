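# demux2kit

Sample demultiplexing for tag-based multiplexed scRNA-seq, built on a
mechanistic model of tag cross-contamination.

In a multiplexed single-cell experiment, each sample is labeled with a
sample-specific oligonucleotide tag (an LMO/CMO lipid-anchored barcode, a
hashtag antibody, or a chemical label) before pooling. After pooling, free
tags bind cell surfaces and co-encapsulate in droplets, so every cell
carries off-target tag counts in addition to its true label. Demultiplexing
— assigning each droplet back to its sample of origin, and flagging
multiplets and unlabeled cells — therefore has to separate signal from a
contamination background whose size varies cell by cell.

`demux2kit` models that background explicitly. For each tag the package fits
two negative-binomial generalized linear models in two feature spaces and
resolves each cell's identity with expectation–maximization:

- **Negative cells** (not labeled with the tag): the observed count *X* is
  pure contamination. Cell-bound contamination scales with cell surface
  area, for which the total tag count *N*<sub>total</sub> is a proxy, and
  ambient (droplet-captured) contamination is constant in expectation, so

  ln μ<sup>neg</sup> = β₁<sup>neg</sup> ln *N*<sub>total</sub> + β₀<sup>neg</sup>,  *X* ~ NB(μ<sup>neg</sup>, θ<sup>neg</sup>).

- **Positive cells** (labeled with the tag): the *contamination remainder*
  *N*<sub>total</sub> − *X* — the pooled counts of all other tags, which
  behave like a single contaminating meta-tag — follows the same law,

  ln μ<sup>pos</sup> = β₁<sup>pos</sup> ln *N*<sub>total</sub> + β₀<sup>pos</sup>,  *N*<sub>total</sub> − *X* ~ NB(μ<sup>pos</sup>, θ<sup>pos</sup>).

EM alternates fitting the two regressions on the current assignment with
recomputing posteriors p(Z=1 | X) from the two densities and class priors,
starting from a cosine-similarity cutoff between each cell's count vector
and the tag's canonical axis. A cell is called a **singlet** of tag T if
only T's posterior exceeds the probability cutoff, a **multiplet** if two
or more do, and **negative** otherwise.

The package also provides:

- a three-step generative simulator (staining → cell-bound contamination →
  ambient contamination) with doublet formation, optional zero-inflation
  (drop probability exp(−λx²)), and read/cell down-sampling;
- randomized quantile residuals (RQRs) for goodness-of-fit diagnostics —
  standard normal under a correctly specified count model;
- UMI tabulation from raw paired tag-library FASTQ files with barcode
  mismatch correction;
- per-tag precision/recall/F benchmarking against ground-truth labels.

## Worked example

Simulate a 10-sample pooled experiment at moderate contamination
(~7.9k droplets, 10% doublets, zero-inflation λ = 2), classify it, and
score the calls against the simulator's ground truth:

```sh
demux2kit pipeline --seed 4 -o runs/demo
```

```
macro F-score: 0.9997
```

`runs/demo/` then contains the count matrix (`tag_counts.csv`), per-cell
calls and posteriors (`classification.tsv`), mid-quantile residuals
(`rqr.tsv`), the per-tag score table (`metrics.tsv`), a confusion summary,
and the resolved configuration needed to regenerate the run bitwise. The
call table distribution for this run:

```
tag09        2639
tag02        1055
tag01         962
multiplet     652
...
```

and `metrics.tsv` reports per-tag precision/recall/F (macro precision
0.9994, recall 1.0, F 0.9997 here) — the macro F-score is the mean per-tag
harmonic mean of precision and recall over singlet calls. The same stages
are available individually (`simulate`, `demux`, `diagnose`, `evaluate`,
`count`) and as library functions (`demux2kit.simulate_tags`,
`demux2kit.demultiplex`, `demux2kit.evaluate`, ...).

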