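# guvscan

Modelling and analysis for microwave scanning of giant unilamellar vesicle
(GUV) membranes with a split-ring resonator (SRR).

## The measurement

A planar microstrip line is coupled to a split-ring resonator whose 500 nm ×
100 µm split gap sits at the floor of a 25 µm × 18.8 µm microfluidic channel.
At the ring's odd modes (2.7 and 7.9 GHz after calibration) the split gap
carries a concentrated in-plane microwave field. GUVs slightly larger than
the channel flatten against the electrode surface and are dragged over the
gap by the flow; each flattened membrane section perturbs the gap load and
produces a 0.6–0.9 s plateau in the transmission magnitude |S21|. The scan
statistic per section is

    Δ|S21| = | mean(|S21|, no GUV) − mean(|S21|, section) |

Sphingomyelin-rich (liquid-ordered, raft-like) and POPC-rich
(liquid-disordered) membrane sections produce distinct Δ|S21| levels, so a
two-domain GUV shows two consecutive plateaus — the raft-like domain always
leads in the channel. Because the gap field is almost entirely parallel to
the membrane plane, inverting Δ|S21| through a calibrated circuit model and
a field sensitivity kernel yields the *in-plane* complex membrane
permittivity ε<sub>∥</sub> = ε′ − jε″, a quantity other techniques (which
probe ε<sub>⊥</sub>) do not reach.

The package implements that whole chain:

| module | contents |
| --- | --- |
| `guvscan.circuit` | ABCD equivalent circuit of the coupled SRR; odd-mode calibration; ΔS21 under gap-load changes |
| `guvscan.field` | 2-D quasi-static finite-volume solver of the slot cross-section over a layered stack; capacitance, sensitivity kernels, field profiles, elevation attenuation |
| `guvscan.extraction` | gain anchoring and two-parameter inversion ΔS21 → ε′ − jε″ (with optional hydration-film elevation) |
| `guvscan.traces` | change-point segmentation of scan traces, per-section Δ|S21|, SM/POPC classification, cohort statistics |
| `guvscan.synth` | synthetic traces/cohorts/anomalies with the published statistical structure; GUV size-regime and flattening estimators |
| `guvscan.io`, `guvscan.cli` | Touchstone `.s2p` and CSV formats; the `guvscan` command-line tool |

No instrument data files are required: the reference table of published
values ships with the package
(`guvscan/data/reference_values.json`) and every input can be generated
synthetically.

## Worked example

Generate a two-domain GUV trace planted with the first published 2.7 GHz
two-domain measurement, segment it, classify the sections, and invert the
second section's Δ|S21| into a membrane permittivity:

```python
from guvscan import synth, traces, extraction

bundle = synth.presets()
p1, p2 = bundle.two_domain_presets(0)            # Section I / II presets
trace = synth.gen_two_domain(p1, p2, seed=1)

result = traces.segment(trace)
traces.classify_sections(trace, result)
for seg, label in zip(result.sections(), result.classifications):
    print(f"{seg.kind:9s} {seg.start_s:5.2f}-{seg.end_s:5.2f} s  "
          f"delta|S21| = {seg.delta_magnitude*1e4:.2f}e-4  -> {label}")

cfg = extraction.ExtractionConfig(frequency_hz=2.7e9, membrane_thickness=4e-9)
gain = extraction.calibrate_gain(
    extraction.ComplexPermittivity(73.64, 6.13),      # POPC anchor at 2.7 GHz
    bundle.delta_stats("POPC", 2.7e9)[0], cfg)
cfg = cfg.replace(instrument_gain=gain, magnitude_only=True)
r = extraction.invert(result.sections()[1].delta_magnitude, cfg)
print(f"section II membrane permittivity: "
      f"{r.permittivity.eps_real:.2f} - j{r.permittivity.eps_imag:.2f}")
```

prints

```
plateau    0.48- 1.24 s  delta|S21| = 10.62e-4  -> SM-rich
plateau    1.24- 2.12 s  delta|S21| = 4.55e-4  -> POPC-rich
section II membrane permittivity: 73.28 - j5.69
```

The two plateaus recover the planted section values (10.64 and 4.55, in
units of 10⁻⁴), the leading section reads SM-rich, and the POPC-rich
section's permittivity comes out near the published POPC values at 2.7 GHz —
ε′ ≈ 73 with a few units of dielectric loss.

The same operations are available from the shell:

```sh
guvscan gen two-domain --seed 1 --out trace.csv
guvscan segment --trace trace.csv --frequency 2.7e9 --out segments.json
guvscan simulate --fmin 1e9 --fmax 10e9 --npoints 2001 --out spectrum.s2p
```

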