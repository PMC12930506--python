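# mimicomm

Simulation and spatial analysis of RNA-based communication between
**cell mimics** — porous polymer microcompartments (60–80 µm) whose
condensed clay–DNA "nucleus" immobilises template DNA while remaining open
to a shared cell-free transcription–translation (TXTL) medium.

In these experiments two populations of *sender* mimics release small
regulatory RNAs that diffuse through a sandwiched TXTL droplet: a **STAR**
(Small Transcription Activating RNA, which prevents terminator formation)
and a **trigger** RNA (which opens a toehold switch sequestering the RBS).
*Receiver* mimics carry a TetR–sfGFP reporter behind both switches, so the
reporter is an **AND gate**: efficient expression requires both RNAs, with
terminator read-through leaking far more than the toehold. Because RNA is
short-lived in TXTL (τ ≈ 17 min), each signal only acts within a
characteristic range λ = √(Dτ) of a few hundred micrometres, and receiver
activation depends on the *local* composition of its neighbourhood rather
than on bulk concentrations.

`mimicomm` provides, as importable modules behind one consistent
mimic-record table schema:

| module | contents |
| --- | --- |
| `signal_model` | leaky dual-Hill AND gate `h(S,T) = h_S(S)·h_T(T)`, bulk TXTL kinetics with resource decay, 2-D diffusion–decay point-source fields `c(r) = (Q/2πD)·K₀(r/λ)` and their transient counterparts |
| `community` | synthetic-data generator: non-overlapping random / central-patch layouts, per-receiver reporter time courses driven by the transient fields, multi-channel synthetic microscopy rendering with ground truth |
| `imaging` | circular-Hough segmentation of the bright-field channel, rolling-ball background correction, membrane-dye threshold classification, sfGFP extraction |
| `spatial` | local densities n/A, radius-scanned density–fluorescence Pearson correlations, fold changes vs sender-free controls, 2-D LOESS response surfaces, positional-bias nulls |
| `kinetics` | per-frame correlation time courses, activation-onset estimation, radial kymographs |
| `calibration` / `workbench` | DNA-loading calibration (OLS), effective bulk concentrations, YAML configs, benchmark orchestration, CLI |

## Worked example

```python
import mimicomm as mc

# Bulk AND gate: both activator templates vs trigger alone
t, both = mc.simulate_bulk({"STAR": 10, "trigger": 10, "reporter": 2})
_, trig = mc.simulate_bulk({"STAR": 0, "trigger": 10, "reporter": 2})
print(f"bulk fold both/trigger-only at 5 h: {both[-1] / trig[-1]:.2f}")

# The shipped 29-sample end point benchmark (seeded, counts ~30-500)
samples, controls = mc.benchmark_samples("benchmark_endpoint")
scan = mc.radius_scan(samples)
print(f"optimal neighbourhood radius: {scan.joint_argmax_um:.0f} um")
i = list(scan.radii).index(scan.joint_argmax_um)
print(f"mean r at optimum: STAR {scan.mean_r['star_sender'][i]:.2f}, "
      f"trigger {scan.mean_r['trigger_sender'][i]:.2f}")
```

prints

```
bulk fold both/trigger-only at 5 h: 3.42
optimal neighbourhood radius: 500 um
mean r at optimum: STAR 0.19, trigger 0.34
```

The bulk fold is the ON/leak separation of the gate against its worst leak
channel (trigger-only read-through). The radius scan correlates each
receiver's end-point sfGFP with the local density (count/area, mm⁻²) of
each population within a radius, per sample, and averages r across
samples: the correlation peaks at an intermediate neighbourhood scale of a
few hundred micrometres — a direct spatial signature of the finite RNA
signaling range. Pooling all 2 946 receivers and normalising by sender-free
controls, the top-decile activated receivers reach a median 42-fold
activation and sit in neighbourhoods with median sender densities of
7.1 mm⁻² (STAR) and 6.2 mm⁻² (trigger).

The same analyses run from the shell:

```bash
mimicomm run --config benchmark_endpoint --out results/endpoint
mimicomm generate --config benchmark_central --out results/central
```

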