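# fretpaint

Analysis pipeline for **FRET-PAINT** single-molecule experiments: transient
binding of a short acceptor-labeled probe (e.g. a Cy5-PNA imager strand
complementary to one GGGTTA telomeric repeat, a "G-Tract") to a
donor-labeled, surface-immobilized docking construct, read out as discrete
FRET bursts in donor/acceptor intensity time traces.  The science question
such experiments answer is *accessibility*: how often can the probe reach a
binding site, how long does it stay, and where along the overhang does it
bind — and how all of that changes with the number of repeats, i.e. with
G-quadruplex folding and higher-order compaction of the telomeric overhang.

The package is aimed at single-molecule biophysicists who have per-molecule
intensity traces (movie processing and spot extraction are out of scope)
and want reproducible binding statistics with honest uncertainties.

## What it computes

For each construct dataset (one G-Tract count, hundreds of traces):

1. **FRET traces** — E = I_A / (I_A + I_D) after background subtraction.
2. **Donor-only correction** — molecules with no binding events define the
   leakage peak e_do; the linear rescale E' = (E − e_do)/(1 − e_do) puts
   the donor-only population at 0 and preserves E' = 1.
3. **Step detection** — each trace is idealized as a piecewise-constant
   signal by chi-square-optimal step placement (exhaustive best single
   split per segment, O(L) via prefix sums, applied greedily), with either
   a counter-fit S-curve or a noise-scaled penalty with backward
   elimination as the stopping rule.
4. **Event calling** — maximal runs of step segments with E' > 0.13
   lasting ≥ 4 frames (τ ≥ 300 ms at 100 ms/frame, with
   τ = (n_frames − 1)·frame_time) become binding events; observation time
   per molecule runs to donor photobleaching or the end of the recording,
   and zero-event molecules keep contributing observation time.
5. **Dwell kinetics** — dwell histograms fit with
   y = y₀ + A₁ e^(−(x−x₀)/t₁) (+ A₂ e^(−(x−x₀)/t₂)); the nested models are
   compared with an F-test on residuals.
6. **Binding frequencies** — f_ave = N_B / T_tot per construct and per
   G-Tract, with uncertainties from a 20 000-set molecule-level bootstrap
   whose frequency distribution is fit with a Gaussian (f_peak, f_sigma).
7. **Topography** — events classified into five 0.2-wide FRET segments
   (binding position along the overhang); per-segment dwell and frequency
   statistics with one-way ANOVA and Welch pairwise t-tests.

A kinetic Monte-Carlo simulator (`fretpaint.synthetic_data`) generates
traces with known ground truth — alternating-renewal binding, two-component
exponential dwell mixture, position-dependent FRET, donor leakage, Gaussian
camera noise, frame integration, and single-step donor photobleaching — so
every stage above is validated by parameter recovery.

## Worked example

```python
import fretpaint as fp

sim = fp.SimulationConfig(n_gtracts=4, k_on=3.2e-3, seed=11)
dataset, _ = fp.simulate_dataset(sim, 500)
report = fp.analyze_dataset(dataset, fp.PipelineConfig(n_boot=20_000, seed=0))
```

prints (via the snippet in `scripts/acceptance.py`-style reporting):

```
construct        : 4G-Tract  (N_DNA=500)
events / time    : N_B=147  T_tot=54619 s
binding frequency: f_ave=2.691e-03 /s  f_peak=2.687e-03 /s  f_sigma=2.17e-04 /s
per G-Tract      : 6.728e-04 /s
donor-only peak  : e_do=0.1385
dwell components : t1=0.67 s  t2=4.62 s
model comparison : F=9.8  p=2.24e-04
```

Reading the output: 500 molecules were simulated with a true binding rate
of 3.2×10⁻³ s⁻¹, leakage baseline 0.1379, and dwell mixture 0.7 s / 5.0 s.
The pipeline recovers the leakage peak (0.1385), the fast and slow dwell
components (0.67 s, 4.62 s), and a bootstrap peak frequency in agreement
with the direct average (2.69×10⁻³ s⁻¹; the deficit against the true rate
is the τ ≥ 300 ms event rule discarding the shortest dwells).  The F-test
correctly rejects the single-exponential dwell model (p < 0.001).

The same chain is scriptable from the shell:

```
fretpaint simulate --config sim.json --n-molecules 500 --out data/
fretpaint analyze  --data data/ --config pipe.json --out results/
fretpaint report   --runs results/ --out summary.csv
```

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

simulates six constructs (4–24 G-Tracts) whose per-repeat accessibility
decreases with length (a compaction scenario), runs the full pipeline on
each, and prints the construct-level frequency table (N_DNA, N_B, T_tot,
f_ave, f_peak, per-G-Tract frequency).

See `docs/methods.md` for the underlying models, parameter defaults, and
known limitations.
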