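# gazeseq

Spatio-sequential analysis of gaze during facial expression recognition.

When observers categorize facial expressions, their fixations are not
spread uniformly over the face: gaze tends to concentrate on the central
facial region and to move between regions in a structured, history-
dependent way. `gazeseq` implements a complete analysis pipeline for
quantifying that organization from AOI-labeled fixation sequences, plus
a synthetic scanpath simulator so every stage can be exercised and
validated without access to raw recordings.

Fixations on a face are mapped to three stacked zones — Upper (UFZ),
Central (CFZ) and Lower (LFZ) Facial Zone — and analyzed with:

- **Markov transition models.** First order,
  P(X_t = j | X_{t-1} = i), and second order,
  P(X_t = k | X_{t-2} = i, X_{t-1} = j), estimated by maximum likelihood
  within each participant × item × event sequence.
- **Normalized transition entropy.** Per context,
  H_norm = −Σ p log₂ p / log₂ 3 ∈ [0, 1]; globally, the
  occupancy-weighted mean (the plug-in conditional entropy). Model
  orders are compared on per-participant entropies with a Wilcoxon
  signed-rank test and a participant-level bootstrap of the median
  H₁ − H₂ difference.
- **Cross-event repositioning.** Euclidean distance
  d = √((x₂−x₁)² + (y₂−y₁)²) from the last fixation of the event
  preceding a face (context image, or the previous trial's response
  screen) to the first fixation on the face, compared across landing
  zones with Kruskal–Wallis (ε² = H/(n−1)) and pairwise Holm-corrected
  rank-sum tests (r = |Z|/√n).
- **Gaze stability.** Stability = TotalDuration / PathLength per
  participant × zone (ms/px), with
  PathLength = Σᵢ √((xᵢ₊₁−xᵢ)² + (yᵢ₊₁−yᵢ)²) over consecutive
  same-zone fixation pairs, analyzed with linear mixed models
  (`stability ~ AOI + (1|participant)` and the AOI × EventType
  variant).
- **Concordance.** Kendall's W = 12S / (m²(n³−n)) over participants'
  rankings of spatial units by dwell.
- **Visualization.** Temporally ordered path plots and fixation density
  heatmaps per item.

The simulator (`gazeseq.simulate`) generates full trial structures
(context image / target face / response screen, in either procedural
order) with target-face scanpaths drawn from bundled first- or
second-order *fixture* transition matrices that encode the published
aggregate transition structure (e.g. P(CFZ→CFZ) = 0.920,
P(UFZ→CFZ) = 0.694), log-normal fixation durations and in-zone
coordinate jitter.

## Worked example

```python
import gazeseq as gz

cfg = gz.SynthConfig(n_participants=14, n_items=24, seed=2027)
records = gz.clean_fixations(gz.generate_fixations(cfg))
seqs = gz.target_sequences(records, cfg.layout)

model = gz.estimate_transitions(seqs, order=1)
summary = gz.global_entropy(model)
print(f"P(C->C) = {model.prob('CFZ', 'CFZ'):.3f}")
print(f"global entropy = {summary.global_h_bits:.3f} bits "
      f"(normalized {summary.global_h_norm:.3f})")
```

prints

```
P(C->C) = 0.921
global entropy = 0.548 bits (normalized 0.346)
```

i.e. in this simulated cohort a fixation already in the central zone
stays there with probability 0.921, and the next zone carries on
average 0.548 bits of uncertainty — 35% of the 1.585-bit maximum for
three destinations, so transitions are far from uniform.

The full analysis is organized as numbered drivers under `analysis/`
(simulate → ingest → Markov/entropy → repositioning/stability →
concordance/mixed models → figures); each prints its findings and
writes tables under `results/`.

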