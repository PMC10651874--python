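# selfsound

Spike-train analysis of **sensory attenuation of self-generated sounds** in
extracellular recordings from auditory cortex, for experiments in which a
head-fixed mouse presses a lever that triggers a sound while the identical
sound also plays at random times. The package is aimed at systems
neuroscientists who have sorted spike times and a behavioral event log and
want the full analysis chain — event selection, evoked responses,
modulation-index statistics, waveform cell-typing, optogenetic response
mapping and hierarchical-bootstrap inference — as tested, reusable code.

## The core statistic

For each neuron, the evoked response to a stimulus class is the mean firing
rate 10–50 ms after sound onset minus the baseline rate 0–200 ms before
onset. Attenuation is summarised by the **modulation index**

```
MI = (R_self − R_random) / (R_self + R_random)
```

with MI = −1 for a neuron responding only to the random sound, 0 for equal
responses, +1 for responses only to the self-generated sound. An MI of
−0.25 corresponds to a 40 % smaller self-generated response
(`R_self/R_random = (1+MI)/(1−MI)`); −0.08 to ~15 % smaller.

Around this sit:

* **event selection** — sounds are analysed only if ≥ 1 s has passed since
  the previous sound (sensory adaptation), and random sounds only if the
  preceding sound was self-generated (behavioral state); early/late blocks
  of 300 self-generated sounds; lever presses preceded by ≥ 2 s of silence
  for the motor-preparatory analysis.
* **responsiveness** — a neuron is auditory responsive if either class's
  response amplitude is ≥ 2× the SD of its 5 ms-binned baseline rate.
* **cell typing** — a 2-D Gaussian mixture on spike half-width and
  trough-to-peak separation splits units into putative pyramidal neurons
  and interneurons, with a 0.95 posterior confidence gate.
* **opto mapping** — light-evoked rate changes in 5 ms bins are tested
  against a surrogate-PSTH null built from resampled baseline segments;
  short-latency excitation (first significant bin ending ≤ 10 ms terminal /
  ≤ 15 ms soma, ≥ 10 spikes) indicates monosynaptic input.
* **hierarchical bootstrap** — group contrasts resample animals, then
  neurons within animals, respecting the nesting of the data.
* **synthetic sessions** — an inhomogeneous-Poisson generator reproduces
  the statistical structure the analysis assumes (bout-structured pressing,
  evoked transients with configurable attenuation and adaptation,
  pre-press ramps, two waveform classes, deep-layer opto responses), so
  every stage has a ground-truth oracle.

## Worked example

```python
import selfsound as ss
from selfsound import io

# two synthetic cohorts: strong attenuation (a = 0.6) vs weak (a = 0.852)
wt = ss.generate_cohort(ss.SimConfig.high_snr(seed=11, attenuation=0.600), "WT")
df = ss.generate_cohort(ss.SimConfig.high_snr(seed=12, attenuation=0.852), "DF16A")

report = io.run_full_analysis({"WT": wt, "DF16A": df}, io.RunConfig(seed=0))
c = report["modulation"]["contrast"]
for g in ("WT", "DF16A"):
    print(f"{g}: MI = {c[g]['mean_mi']:+.3f} ± {c[g]['sem_mi']:.3f} (n={c[g]['n_neurons']})")
print("hierarchical bootstrap p =", c["p_hierarchical_bootstrap"])
```

prints

```
WT: MI = -0.250 ± 0.002 (n=180)
DF16A: MI = -0.076 ± 0.002 (n=180)
hierarchical bootstrap p = 0.0
```

i.e. the pipeline recovers the analytic MI of each configured attenuation
factor, `(a−1)/(a+1)` = −0.25 and −0.08, and the cohort difference is
detected at the bootstrap's resolution (p < 1/1000).

The same stages are available from the shell:

```bash
selfsound simulate --seed 1 --out cohort/
selfsound analyze --data cohort/ --out report.json
selfsound report --report report.json
```

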