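# scon — simulated connectivity analysis of gas-release event streams

Overwintering sprat (*Sprattus sprattus*, a physostome) vent swim-bladder
gas through an anal duct; on an upward-facing echosounder each release
appears as an ascending bubble trace, and the releases double as a proxy
for sound production ("chirps"). If fish stimulate each other — e.g. if
release-associated sound is communicative — release times should cluster
in time beyond what a random (Poisson) process produces. `scon`
implements the full analysis chain for testing that hypothesis on a
stream of timestamped bubble detections, for fish bioacousticians and
anyone needing a small-sample randomness test for temporal point
processes.

## The statistic and the test

Bubbles within a 10-s period are pooled into single *release events*
T₁ ≤ … ≤ Tₙ (one fish can emit several bursts; pooling is deliberately
conservative). Within an analysis window of length *W*, the
**connectivity** of event *i* is the number of later events in
(Tᵢ, Tᵢ + Δ] with Δ = 30 s; the test statistic is the window-average
connectivity c̄ = (1/n) Σᵢ cᵢ — equivalently, the number of event pairs
closer than Δ, divided by n. The **S-CON test** simulates the null of
completely random timing by B = 1000 placements of n integers uniform on
[1, W], takes the 95th percentile of the simulated c̄ as the critical
value, and rejects when the observed c̄ is strictly larger. Because the
statistic is pairwise, windows with as few as two events are testable.
A sweep over window lengths (1, 5, 30 min; 1, 2, 4, 6 h) and
connectivity intervals (25/30/35 s) tabulates the percentage of windows
flagged non-random.

As a control against the alternative that clustering merely tracks
fluctuating fish abundance, 30-min event counts are regressed on the
summed surface-integrated backscattering coefficient S_A (an
echo-integration biomass proxy), both log-transformed, by generalized
least squares with AR(1) errors, reporting the slope F test and the
variance explained.

Because field recordings are not redistributable, the package ships
generators with the structure the analysis assumes: a nocturnal diel
intensity (dusk pulse, pre-dawn peak), a subcritical self-exciting
(Hawkes-type branching) process for mutual stimulation, within-burst
bubble expansion, and an S_A series with a tunable coupling strength.

## Worked example

```python
import numpy as np
from scon import PoolingConfig, SconConfig, AnalysisWindow, pool_bubbles, scon_test

bubbles = np.array([100, 103, 109, 125, 126, 131, 145, 1500])
events, n_pooled = pool_bubbles(bubbles, PoolingConfig(pool_interval_s=10))
window = AnalysisWindow(start=0, length_s=1800, offsets=events)
result = scon_test(window, SconConfig(seed=42))
print(events, result.observed_avg, result.critical_value, result.reject)
```

prints

```
[ 100  125  145 1500] 0.5 0.25 True
```

Eight bubbles pool into four events (three bursts within 45 s plus a
straggler). Two of the six event pairs are closer than 30 s, so the
observed average connectivity is 2/4 = 0.5, while 95% of 1000 random
placements of 4 points in [1, 1800] give 0.25 or less — the null of
random timing is rejected for this window. The scripts in `examples/`
walk through each capability (pooling + single-window test, diel
simulation, the rejection-rate sweep, the abundance control) and print
annotated output.

There is also a thin CLI:

```bash
scon simulate --model clustered --days 6 --seed 11 --out events.csv
scon sweep --events events.csv --windows 1min,5min,30min,1h,2h,4h,6h --conn 25,30,35 --seed 5 --out sweep.csv
scon run --config config.yaml    # full pipeline with provenance copy
```

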