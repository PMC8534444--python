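# lesioneval

Low-bias evaluation toolkit for video-based computer-aided detection (CADe)
of colorectal lesions. The package implements the evaluation side of such a
system — not the detector itself — as a reusable, tested pipeline:

- **geometry** — axis-aligned bounding boxes (half-open pixel intervals) and
  intersection-over-union, with per-ground-truth best matching.
- **frame_dataset** — a versioned JSON annotation schema, fixed-interval
  frame sampling from annotated streams (default 5 s), and the six-rule
  frame-exclusion step with a conserved per-reason tally.
- **image_metrics** — image-level confusion semantics (an image is TP when
  both ground-truth and predicted boxes are present, regardless of overlap),
  the five diagnostic metrics with exact two-sided Clopper–Pearson 95% CIs,
  ROC over the 0.01–0.99 threshold grid with trapezoidal AUC and
  Youden-optimal cutoffs, the IoU ≥ 0.5 localization ratio among TP frames,
  and an imaging-mode-stratified report.
- **temporal_filter** — the causal m-of-n display persistence rule (default
  3-of-5 sequential frames) plus a brute-force equivalence oracle.
- **lesion_latency** — per-lesion latency from first appearance to first
  displayed detection, a 5 s failure timeout, and detection-rate/median
  summaries.
- **synthetic_data** — seeded generators for annotated image corpora and
  per-lesion detection clips with controllable prevalence, score
  distributions, false-positive rate, and box jitter, calibrated by default
  so a 0.27 threshold operates near 95%/95% sensitivity/specificity.
- **cli/reporting** — a `lesioneval` command-line interface and composed
  pipelines writing CSV/JSON reports.

## CLI

Subcommands: `simulate`, `sample`, `exclude`, `evaluate-images`, `filter`,
`evaluate-latency`, `run-image-pipeline`, `run-latency-pipeline`.

```sh
# simulate an annotated corpus, evaluate it, and render the stratified report
lesioneval simulate --n-images 6531 --seed 17 --out ann.json
lesioneval evaluate-images --input ann.json --grid 0.01:0.99:0.01 --out report/

# persistence-filter a detection stream
lesioneval filter --input stream.csv --window 5 --min-hits 3 --out display.csv

# lesion-based latency analysis over clip CSVs
lesioneval evaluate-latency --clips clips/ --events events.csv \
    --fps 30 --timeout 5 --out latency/
```

Annotation files are single JSON documents with a mandatory
`schema_version`; boxes serialize as `[x_min, y_min, x_max, y_max]`.
Detection-stream CSVs carry `frame_index, timestamp, hit, score`; the events
CSV carries `lesion_id, case_id, paris_class, size_mm, appearance_frame,
clip_file`.

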