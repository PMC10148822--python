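# drgquant

Quantification pipeline for sensory-neuron joint-pain studies: stimulus-
locked calcium response calling in dorsal root ganglion (DRG) imaging,
marker co-expression analysis (RNAscope-style per-cell calls and
single-cell count matrices), and behavioral/molecular endpoint
derivations — plus seeded synthetic-data generators so the whole chain
runs and is testable offline with full ground truth.

It is aimed at labs quantifying in vivo DRG GCaMP recordings (which
neurons respond to a mechanical stimulus at the knee, how big the
responses are, how responder size distributions shift) together with the
molecular side of the same question (which neurons co-express a
nociceptor marker such as *Scn10a*/Na_V1.8 with *Piezo2* and *Ntrk1*).

## The core quantities

* **ΔF/F₀ responder calling.** For each neuron, F₀ is the mean
  fluorescence over a 30-frame force-free baseline and
  ΔF/F₀(t) = (F(t) − F₀)/F₀. A neuron responds to a stimulus when its
  peak ΔF/F₀ during the 10-frame application window strictly exceeds
  4 × SD of baseline ΔF/F₀. On pure Gaussian noise with known σ this
  rule false-positives at 1 − Φ(4)¹⁰ ≈ 3.17 × 10⁻⁴ per window.
* **Peak AUC** of each response: trapezoidal integral (ΔF/F₀ · s) over
  the contiguous positive-ΔF/F₀ run containing the peak.
* **Percent responders** = 100 × responses / total neurons imaged, with
  totals optionally extrapolated from a counted sub-region of average
  density; responder soma areas as relative-frequency histograms.
* **Marker combinations.** k probes partition counted neurons into the
  2^k positivity lattice; percents are aggregated section → animal →
  mean ± SEM, and subset diameter distributions are compared by the
  two-sample Kolmogorov–Smirnov test.
* **Count-matrix co-expression.** Cells pass QC when n_features > 200
  and percent_mito < 15 (both strict); normalized expression is
  ln(1 + 10⁴ · count/total); a cell expresses a gene when that value
  is > 0.1, and co-expression fractions can be conditioned on a marker
  gene (e.g. Piezo2⁺Ntrk1⁺ among Scn10a⁺ cells).
* **Endpoints.** Swelling difference scores (post − baseline),
  trapezoidal time-course AUC, log₁₀ withdrawal thresholds, and
  comparative-CT fold changes 2^(−ΔΔCT).

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from drgquant import ImagingProtocol
from drgquant.imaging import analyze_session, summarize_session
from drgquant.synth import SimConfig, generate_imaging_dataset

protocol = ImagingProtocol()          # 0.7 Hz, 30 baseline + 2x(10/10/10)
cfg = SimConfig(n_neurons=300, responder_probability=0.1, seed=42)
session, truths = generate_imaging_dataset(cfg, protocol)

calls = analyze_session(session, k=4.0, baseline_mode="global")
summary = summarize_session(calls)
print(summary.per_stimulus.to_string(index=False))
```

prints

```
stimulus  n_responders  total_neurons  percent_responders  mean_peak_auc
     30g            28            300            9.333333      17.306706
    100g            28            300            9.333333      11.872036
```

28 of 300 simulated neurons were called responders to the 30 g knee
stimulus (9.3%), with a mean peak AUC of 17.3 ΔF/F₀·s over responders.
The generator's ground truth for this seed is 28 true responders at 30 g
and 26 at 100 g — the two extra 100 g calls are false positives from
estimating the baseline SD on 30 noisy frames, the expected behavior of
the 4σ rule at this noise level (the suite quantifies it exactly).

The same flow works from the shell:

```bash
drgquant simulate imaging --seed 42 --out scratch/sim
drgquant respond --traces scratch/sim/traces.csv --out scratch/resp
drgquant simulate counts --seed 1 --out scratch/mtx
drgquant coexpress counts --dir scratch/mtx --genes Piezo2,Ntrk1 \
    --condition-on Scn10a --out scratch/coexpr.json
```

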