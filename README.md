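# sonoagree

Inter-rater agreement analysis for multi-annotator anatomical-structure
annotations on ultrasound scans.

In ultrasound-guided regional anaesthesia (UGRA), accurate identification of
sono-anatomical structures — nerves, arteries, muscles, fascial planes — is
critical, and AI devices now overlay structure highlights on live B-mode
images. Evaluating such a device against a *single* expert "ground truth"
ignores the fact that experts themselves disagree. `sonoagree` implements an
evaluation framework built around that observation: a panel of expert
annotators (plus one AI annotator) each outline the same structures on the
same scans, and the package quantifies **human–human (H-H)** inter-observer
variability side by side with **AI–human (H-AI)** agreement, so the AI can be
judged against the *spread* of expert opinion rather than a fixed reference.

It is intended for researchers running expert-panel annotation studies of
medical image segmentation or AI overlay devices, and for anyone needing a
tested implementation of the underlying agreement metrics.

## What it computes

**Dice overlap** for structures annotated as enclosed regions (arteries,
muscles, nerves). Outlines are rasterized onto the scan's pixel grid and

```
Dice(A, B) = 2 |A ∩ B| / (|A| + |B|)        1 = identical, 0 = disjoint
```

**Normalized Hausdorff distance** for structures annotated as open lines
(fascial/serosal planes). Polylines are densely resampled and

```
h(A→B) = max_{a∈A} min_{b∈B} ‖a − b‖
H(A, B) = max(h(A→B), h(B→A)) / max(W, H)   0 = identical, clamped at 1
```

Around the metrics, the package provides:

* a validated **study data model** (YAML manifest + GeoJSON annotations,
  pixel coordinates) for panels of annotators, scans and structures,
  including structure *grouping* (e.g. C5+C6 nerve roots analysed as one
  unit, matching how the AI predicts them);
* **curation rules**: a scan left entirely unannotated by an annotator is
  treated as accidentally skipped and excluded; an individually missing
  structure is kept as an explicit "not visible"; wrong-geometry-kind
  annotations are flagged and excluded — with a full audit of the counts;
* **pairwise scoring and pooled summaries**: every human pair and every
  (AI, human) pair per scan and structure, pooled into
  min/mean/median/max/sd tables per structure or structure class, and an
  H-H vs H-AI comparison table;
* **consensus vote maps**: per-pixel counts of how many annotators included
  the pixel, exportable as colour-ramped PNG overlays with the AI mask
  superimposed;
* **qualitative assessment aggregation**: expert TP/TN/FP/FN accuracy rates,
  adverse-event risk-modification tallies and 0–10 subjective scores, with a
  bundled reference table of published assessment counts;
* a **synthetic study generator**: parametric ground-truth scenes and noisy
  annotator panels (translation/scale/boundary noise, omissions, wrong-kind
  errors, whole-scan skips) with per-class difficulty, so the entire
  pipeline is testable without any raw study data.

## Worked example

Simulate a small panel (6 experts + AI, 2 scans per region), curate it, and
summarize agreement by structure class:

```python
from sonoagree import simulate, curation, agreement

man, anns = simulate.simulate_study(
    simulate.StudyConfig(n_humans=6, scans_per_region=2, seed=11))
curated, report = curation.curate(anns, man)
print(report.to_text())

scores = agreement.pairwise_scores(curated, man)
rows = agreement.summarize(scores, man, by="class")
print(agreement.format_summary(rows))
```

```
Potential annotations (annotators x structures): 240
After grouping:                                  216
Removed - whole-image skips:                     1
Removed - wrong geometry kind:                   4
Total removed:                                   5
Collected and analysed:                          211

        scope scope_kind mode    metric  n_pairs  n_both_empty  min mean median  max   sd
       artery      class  HAI      dice       24             0 0.00 0.86   0.89 0.96 0.19
       artery      class   HH      dice       60             0 0.00 0.82   0.90 0.95 0.25
       muscle      class  HAI      dice       58             0 0.00 0.74   0.78 0.93 0.19
       muscle      class   HH      dice      140             0 0.00 0.75   0.84 0.92 0.26
        nerve      class  HAI      dice       82             0 0.00 0.60   0.65 0.82 0.20
        nerve      class   HH      dice      200             0 0.00 0.55   0.62 0.84 0.23
fascia_serosa      class  HAI hausdorff       47             0 0.01 0.09   0.02 1.00 0.24
fascia_serosa      class   HH hausdorff      114             1 0.01 0.13   0.02 1.00 0.29
```

The audit block is the annotation accounting: 6 annotators × 40 structure
instances = 240 potential annotations, 216 after grouping, of which 5 were
excluded (one whole-scan skip of a 3-structure region, plus 4 wrong-kind
annotations), leaving 211 analysed. In the summary, each row pools all raw
pairwise values for a class: arteries agree best (mean Dice 0.82–0.86),
nerves worst (0.55–0.60) — the class difficulty ordering the simulator's
noise model is built to produce — and line structures show small normalized
Hausdorff scores (lower = better). Minima of 0.00 appear wherever one
annotator marked a structure "not visible" that another outlined.

The same pipeline is available from the shell:

```
sonoagree simulate --seed 11 --humans 6 --scans-per-region 2 --out study/
sonoagree audit --study study/
sonoagree run --study study/ --out results/
sonoagree consensus --study study/ --scan acb_01 --structure sartorius \
    --with-ai --out sartorius.png
```

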