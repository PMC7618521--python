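# betrescue

Analysis toolkit for studying **compensatory transcriptional rescue after BET
inhibition** in AML-like systems, and for planning sequential BET→p300
inhibitor treatment. It is aimed at computational biologists who have count
and signal tables in hand (nascent-transcription counts, ChIP region signal,
viability dose matrices, longitudinal expression) and want the downstream
statistics as a reusable, tested pipeline — plus synthetic generators that
plant known ground truth so every stage can be validated without any external
download.

## What it computes

**Temporal rescue classification.** From metabolic-labeling (SLAM-type)
counts at 0/4/24 h, each gene's nascent transcription is tested at 4 h and
24 h against baseline with a negative-binomial Wald test (median-of-ratios
size factors from total counts; gene-wise method-of-moments dispersions
moderated toward a log-linear mean-dispersion trend; BH correction). Genes
are then classified:

* **rescued** — significant early drop (FDR ≤ α, lfc₄ ≤ −t_down) followed by
  recovery (lfc₂₄ ≥ −t_recover **or** rebound lfc₂₄ − lfc₄ ≥ δ_min);
* **redundant** — significant, sustained decrease at both timepoints;
* **induced** — significantly above baseline at 24 h;
* **unchanged** — everything else.

The new-RNA fraction per gene is available from the conversion-count mixture
model: reads are labeled with probability `f·q_new + (1−f)·q_old`, where
`q = 1−(1−rate)^n_T`, and the maximum-likelihood `f` has the closed form
`(labeled/total − q_old)/(q_new − q_old)` clamped to [0, 1].

**Chromatin compensation.** Regions are annotated to the nearest TSS
(midpoint distance), differential binding is log2((mean_B+pc)/(mean_A+pc)) of
depth-scaled signal, and the reciprocal **compensation score** is
`log2fc(gained factor) − log2fc(lost factor)` — large and positive where p300
rises as BRD4 is excluded. Top-fraction gained sites (default 5%) can be
tested for cross-model concordance with a permutation test, and averaged
metagene profiles summarize binding shape around region sets.

**ZIP drug synergy.** Dose matrices (4 dosages + vehicle per drug) are scored
against the zero-interaction-potency reference: Bliss independence evaluated
through 4PL monotherapy fits, with observed combination responses taken from
potency-shifted 4PL re-fits along each row and column. The summary delta is
in percentage points; scores above +10 are called synergistic and below −10
antagonistic. The three scheduling modes (BETi-first, concomitant,
p300i-first) are scored identically and compared side by side.

**Resistance-module archetyping.** Expression over the four resistance stages
(DMSO, BETi_72h, IC50_r, IC90_r) is clustered (Ward, z-scored profiles) and
genes are assigned to named archetypes by template correlation — evolution
(0,1,2,3), degression (3,2,1,0), stress (0,1,0,0), inflammation (0,0,1,0),
interferon (0,1,1,−1) — with genes below r = 0.5 labeled flat. Gene-set
fold-change comparisons (e.g. "rescued genes are less down-regulated") use
one-sided Mann–Whitney tests with BH correction.

## Worked example

```python
from betrescue.synthio import SimConfig, simulate_timecourse_counts
from betrescue.quantify import normalize_counts, differential_test
from betrescue.rescue import classify_rescue

counts, truth = simulate_timecourse_counts(SimConfig(seed=1))
sf = normalize_counts(counts.total_counts)      # depth from totals
g0 = counts.samples_at(0.0)
d4 = differential_test(counts.labeled_counts, sf, g0, counts.samples_at(4.0))
d24 = differential_test(counts.labeled_counts, sf, g0, counts.samples_at(24.0))
cls = classify_rescue(d4, d24)
print(cls["class"].value_counts().to_dict())
merged = cls.join(truth["true_class"])
tp = ((merged["class"] == "rescued") & (merged["true_class"] == "rescued")).sum()
print("sensitivity:", round(tp / (merged["true_class"] == "rescued").sum(), 3))
```

prints

```
{'unchanged': 3346, 'redundant': 933, 'rescued': 474, 'induced': 247}
sensitivity: 0.91
```

i.e. of 5000 simulated genes (10% planted rescued with a −2 log2 drop at 4 h
recovering by 24 h), 474 are called rescued and 91% of the truly rescued
genes are found. The same flow runs from the shell:

```bash
betrescue run --outdir run1 --seed 1      # all stages; writes manifest.json
betrescue show-classification run1/classification.tsv
```

## Layout

| module | contents |
| --- | --- |
| `betrescue.synthio` | all synthetic generators with planted truth |
| `betrescue.quantify` | size factors, new-fraction estimator, NB Wald test |
| `betrescue.rescue` | rescue classification, binding–transcription correlation |
| `betrescue.chromatin` | annotation, differential binding, compensation, concordance, metagene |
| `betrescue.synergy` | Hill fits, ZIP delta surfaces, mode comparison |
| `betrescue.trajectory` | variable genes, clustering, archetypes, gene-set deltas |
| `betrescue.io` / `pipeline` / `cli` | TSV/MTX/BED readers, staged runs, manifest, CLI |

See `docs/methods.md` for the models, default parameters, and the limits of
what the synthetic validation shows.
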