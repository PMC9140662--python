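# capsleep

Automatic **cyclic alternating pattern (CAP)** analysis of single-channel
sleep EEG. CAP is the periodic NREM-sleep phenomenon in which transient
electrocortical activations (**A phases**, 2–60 s, subtypes A1/A2/A3)
alternate with background activity (**B phases**); the fraction of NREM
time spent in CAP — the **CAP rate** — is the most widely used
microstructural marker of sleep instability. Scoring it manually over a
full night is impractical, so this package implements an automatic stack
for sleep researchers and biomedical-signal engineers:

1. **Preprocessing** — decimation to 100 Hz (Chebyshev-I anti-aliasing,
   order 8, 0.05 dB ripple, cutoff 0.8/r), standardization, segmentation
   into 1 s epochs, overlapping windows `W = 2·O + 1` for convolutional
   models, and time-step sequences for recurrent models.
2. **Feature creation** — 20 per-epoch features: symbolic-dynamics counts
   `A1..A9` over amplitude thresholds `{−5σ, −4σ, −3σ, −2σ, −σ, 2σ, 3σ, 4σ}`,
   the amplitude-variation metric `A(E) = max(E) + max(E−2) − max(E−1)`,
   Welch band powers `PSD_D, PSD_T, PSD_A, PSD_S, PSD_B` (Hann window,
   M = 50, 50 % overlap), and the ratios `APSD_x = max(E) / PSD_x`.
3. **mRMR feature ranking** — greedy maximization of
   `μ(D, R) = max(D − R)` with mutual-information relevance
   `D = θ(ψ, ρ)` and mean pairwise redundancy `R`, plus the 20 nested
   candidate feature sets.
4. **Classifiers** — per-second binary A/not-A and NREM/not-NREM decisions
   from three families: an FFNN (tanh hidden layer, soft-max output), a
   1D-CNN built from *GofLayer* groups (conv kernel 2 / stride 1 + ReLU,
   max-pool 2/2, 10 % dropout), and (B)LSTM stacks — trained with Adam
   (lr 0.001), class-weighted cross-entropy for the A/not-A imbalance, and
   early stopping on validation AUC (< 0.01 gain over 5 epochs, max 50).
5. **HOSA** — the heuristic oriented search algorithm: level-by-level
   enumeration of architectures (levels = GofLayer groups or recurrent
   depth), stopping once a deeper level improves the best AUC by ≤ 0.01.
6. **CAP scoring** — isolated-epoch correction (`101→111`, `010→000`),
   NREM masking, and an FSM applying the scoring rules: valid phases last
   2–60 s, a cycle is an A phase plus its following all-NREM B phase, a
   sequence needs ≥ 2 consecutive cycles, and
   `CAP rate = CAP epochs / NREM epochs`.

A seeded synthetic-EEG generator (AR(2) 1/f-like background,
stage-dependent spectra, band-limited A-phase bursts with subtype-specific
content) provides full ground-truth cohorts, so everything runs end-to-end
without patient data. Real recordings are read from EDF
(`C3–A2` / `C4–A1` monopolar derivations) with annotations in a simple TSV
(`onset_s  duration_s  label`).

## Worked example

```bash
python examples/03_train_ffnn_pipeline.py
```

trains the feature-based FFNN preset on a 5-subject × 10-minute synthetic
cohort (subject-disjoint split) and prints:

```
A phase: AUC 0.974, Acc 0.943, Sen 0.889
NREM   : AUC 0.974, Acc 0.900
...
per-subject CAP rate (predicted vs truth, % error):
  subject 0 (train): 0.708 vs 0.685 (3.4%)
  subject 1 (train): 0.587 vs 0.576 (1.9%)
  subject 2 (eval): 0.614 vs 0.456 (34.7%)
  subject 3 (eval): 0.349 vs 0.347 (0.7%)
  subject 4 (train): 0.564 vs 0.593 (5.0%)
median CAP-rate percentage error: 3.4%
```

The AUCs say both per-second classifiers separate their classes well; the
last lines compare each subject's estimated CAP rate (CAP seconds / NREM
seconds) with the generator's ground truth — the quantity a clinician
would compare against age norms to judge sleep quality. The other examples
cover simulation + FSM scoring, feature creation + mRMR, and a HOSA search.

A thin CLI mirrors the stages:

```bash
capsleep simulate --out cohort/ --seed 1 --subjects 5
capsleep features --edf cohort/subject00.edf --out feat.csv
capsleep run --preset ffnn --seed 1 --out report.json
capsleep search --family cnn --toy --seed 1 --out trace.json
```

## Layout

```
src/capsleep/      synthetic, io_formats, preprocess, features, mrmr,
                   nn, classifiers, hosa, cap_scoring, evaluate,
                   pipeline, cli
examples/          one narrative script per capability
docs/methods.md    model, assumptions, parameter choices, limitations
tests/             pytest suite (unit, property, acceptance)
```
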