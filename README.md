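# pcgscreen

Heart-failure screening from phonocardiograms (PCG, heart-sound
recordings).  The pipeline classifies fixed-length heart-sound frames into
three groups — **normal**, **HFpEF** (heart failure with preserved
ejection fraction) and **HFrEF** (reduced ejection fraction) — and is
aimed at researchers in cardiac acoustics who want a fully reproducible,
end-to-end testbed for period-synchronous deep-learning screening.

The chain:

1. **Resample** recordings to a 600 Hz working rate (Nyquist-safe for the
   S2 band, 20–250 Hz).
2. **Segment**: localize first-heart-sound (S1) onsets with a
   logistic-regression hidden semi-Markov model — four states
   S1 → systole → S2 → diastole with explicit duration priors, decoded by
   a duration-dependent Viterbi pass.
3. **Frame**: cut a window of fixed length (1.6 s ⇒ 960 samples; 0.8 s
   optional) at every S1 onset, so consecutive frames overlap whenever the
   window exceeds one cardiac cycle, and min-max normalize each frame:
   `X = (x − x_min)/(x_max − x_min)`.
4. **Classify** with a gated recurrent unit network (2 layers × 64 units,
   3-unit softmax head) trained with Adam (lr 0.001), softmax
   cross-entropy + L2 (λ = 1e-4), batch 64, 50 epochs.  LSTM, FCN and a
   Tamhane-T2-screened RBF-SVM are included as baselines.
5. **Evaluate** by tenfold cross-validation (90/10 frame split, 20% of
   training held out for validation) with pooled confusion matrix and
   per-class precision/recall.

The GRU cell follows the update-gate convention
`h_t = z ⊙ h_{t−1} + (1 − z) ⊙ h̃_t` and the LSTM squashes its cell
candidate with a sigmoid — see `docs/methods.md` for why these
non-standard forms are kept verbatim.

Real HF-labelled PCG data is not publicly available, so the package ships
a synthetic generator (`pcgscreen.synth`) producing labelled recordings —
Gaussian-windowed S1/S2 chirps in jittered 0.6–0.8 s cycles, three
class-conditional acoustic profiles, additive noise — with ground-truth
onsets and state paths for every sample.

## Worked example

```python
from pcgscreen.io import PipelineConfig
from pcgscreen.pipeline import run_end_to_end

cfg = PipelineConfig(seed=1, epochs=50, chunk_size=10,
                     recordings_per_class=11, n_cycles=20)
report = run_end_to_end(cfg)
print(report.manifest["n_frames"], report.manifest["class_counts"])
print(f"{report.mean_accuracy:.4f} +/- {report.sd_accuracy:.4f}")
print(report.confusion)
```

prints (about six minutes on one CPU):

```
593 {'normal': 198, 'HFpEF': 198, 'HFrEF': 197}
0.9747 +/- 0.0183
[[192   5   1]
 [  3 195   0]
 [  2   4 191]]
```

i.e. 33 synthetic recordings yield 593 overlapping 1.6 s frames; the GRU
reaches 97.5% ± 1.8% mean tenfold accuracy, and the pooled confusion
matrix (rows = true normal/HFpEF/HFrEF, columns = predicted) shows the
few cross-class confusions.  `chunk_size=10` feeds each 960-sample frame
as 96 steps × 10 samples (the fast input embedding; `chunk_size=1` is the
one-sample-per-step default).

The same stages are scriptable from the shell:

```bash
pcgscreen synth --classes normal:5,HFpEF:5,HFrEF:5 --seed 7 --out data/
pcgscreen segment --in data/normal-000.wav --out onsets.csv
pcgscreen frame --in data/ --len 1.6 --out frames.npz
pcgscreen evaluate --model gru --frames frames.npz --folds 10 --epochs 50 \
    --chunk 10 --seed 1 --out report/
```

Every command writes a `manifest.json` (resolved config, seeds, content
digests) sufficient to re-run it.

## Layout

```
src/pcgscreen/
  synth.py          synthetic PCG generator (labelled, seeded)
  io.py             WAV + onset-sidecar + config + report I/O
  preprocess.py     resampling, min-max frame normalization
  segmentation.py   envelope features, LR emissions, HSMM Viterbi
  framing.py        period-synchronous framing, dataset assembly
  models.py         GRU / LSTM / FCN + training loop (numpy autograd)
  features_svm.py   feature bank, Tamhane T2 screening, RBF SVM
  evaluation.py     tenfold CV, metrics, sweeps, frame-length comparison
  pipeline.py       end-to-end runner with per-stage seed derivation
  cli.py            `pcgscreen` command-line entry point
docs/methods.md     model details, parameter rationale, limitations
```
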