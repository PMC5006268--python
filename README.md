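# maturesim

Stochastic spiking-network simulation of maturing cultured neuronal
networks, with adaptive burst analysis and brute-force parameter
calibration.

The package models each developmental stage of a cultured network as a
random directed excitatory/inhibitory graph (no autapses, triangular
parameter draws up to configurable upper bounds) whose units spike on a
5-ms grid: the momentary rate of a unit is its basic activity plus the
weighted input from units that spiked in the previous slice (clamped at
zero), the per-slice spike probability is `exp(-λΔt)·λΔt`, and a
multiplicative history factor transiently facilitates firing right
after a spike. Spike trains are analyzed with an adaptive ISI-threshold
burst detector (cumulative moving average of the ISI histogram scaled
by the sample skewness), summarized as quartiles of four features
(spike rate, burst rate, burst duration, spikes per burst), and
compared against an embedded experimental reference table. Parameter
upper bounds are fitted by exhaustive grid search against the reference
spike/burst rates.

## CLI

```sh
# simulate a network defined in a YAML/JSON config into a spike CSV
maturesim simulate --config config.yaml --seed 1 --out spikes.csv

# burst-analyze a spike CSV into a per-unit feature TSV
maturesim analyze --input spikes.csv --out features.tsv

# brute-force the parameter bounds for one maturation stage
maturesim search --vmtp 5 --runs 1 --seed 1 --n-neurons 200 \
    --duration 60 --out search_out/

# run the full six-stage maturation experiment
maturesim maturation --seed 1 --out maturation_out/

# generate planted-burst fixture trains with ground truth
maturesim fixtures --seed 1 --n-bursts 20 --out fixture.csv

# compare per-unit feature tables against the embedded reference
maturesim report --features 1 features.tsv --out comparison.tsv
```

Spike-train CSVs have a `unit_id,spike_time_s` header, times in seconds
with six decimals, rows sorted by unit then time, and a JSON sidecar
(`<name>.csv.meta.json`) holding duration/unit count so silent units
survive round trips.

## Layout

| module | role |
| --- | --- |
| `maturesim.network` | random E/I network construction |
| `maturesim.simulator` | discrete-time spiking dynamics (+ `_kernel`) |
| `maturesim.bursts` | adaptive ISI-threshold burst detection, features |
| `maturesim.stats` | quartiles, channel/well filters, reference comparison |
| `maturesim.reference` | embedded reference quartiles and bounds |
| `maturesim.search` | brute-force bound search, convention calibration |
| `maturesim.pipeline` | six-stage maturation experiment orchestration |
| `maturesim.fixtures` | planted-burst synthetic trains with ground truth |
| `maturesim.io` | spike CSV / feature TSV / config I/O |
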