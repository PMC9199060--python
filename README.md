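# fusbeam

Therapy planning, mock low-intensity focused-ultrasound (FUS) treatment, and
real-time-style beam monitoring with a single linear imaging array — exercised
end to end on a bundled linear-acoustics RF simulator instead of hardware.

The package covers the full loop:

1. **Planning** (`fusbeam.planning`) — a user ROI polygon on a B-mode image is
   converted into an ordered focal-point grid. The lateral step is the focal
   zone's −3 dB beamwidth (`0.886·λ·f#`), the axial step half its depth of
   field (`0.5·7.1·λ·f#²`), with alternate rows offset by half a lateral step;
   candidates outside the ROI are discarded.
2. **Simulation** (`fusbeam.field_sim`) — channel RF from point-scatterer
   phantoms (speckle, point targets, two-echogenicity regions, a
   microbubble-balloon analog) for focused and steered plane-wave transmits,
   plus ground-truth incident intensity fields and beam metrics.
3. **Beamforming** (`fusbeam.beamform`) — delay-and-sum with dynamic receive
   focusing, a constant-f# (f#=1) dynamic receive aperture, Hanning
   apodization and generalized-coherence-factor (GCF, M=2) weighting for the
   beam-visualization path; coherent plane-wave compounding (11 angles,
   ±18°) for B-mode.
4. **Intensity reconstruction** (`fusbeam.visualize`) — echogenicity
   normalization of the RF image by a smoothed (5.5λ × 7λ) B-mode with a
   −60 dB noise floor, a sliding pulse intensity integral along depth, dB
   overlays on co-registered B-mode, and session-level field averaging.
5. **Sequencing** (`fusbeam.sequence`) — the interleaved schedule: 50 ms
   treatment windows (160-cycle, 5 MHz bursts at 3 kHz PRF; schedule-only,
   no bioeffect model) alternating with 2 s imaging windows (2-cycle focused
   visualization pulse + plane-wave B-mode) over every grid point, with
   pause/replan support.

## CLI

A `fusbeam` entry point exposes the pipeline; every subcommand takes a YAML
config with SI units spelled out in the key names (`pitch_m`, `prf_hz`…) and
rejects unknown keys. See `examples/config.yaml`.

```bash
fusbeam plan --roi examples/roi.json --config examples/config.yaml --outdir out/
fusbeam simulate --config examples/config.yaml --phantom phantom.txt --seed 1 --outdir out/
fusbeam run-mock --config examples/config.yaml --roi examples/roi.json \
    --phantom phantom.txt --seed 1 --outdir out/
fusbeam compare-excitations --config examples/config.yaml --focus-z-m 0.03
```

`run-mock` writes the plan table, an event log, per-point and averaged
intensity fields (HDF5), and PNG overlays of the reconstructed beam on the
B-mode. ROI files are JSON or two-column CSV, in meters or millimeters
(declared in the file). Phantoms are plain-text `x z amplitude` tables.

## Conventions

x lateral (m, positive right), z axial (m, positive away from the array),
array on z = 0 centered at x = 0; image arrays are indexed `[z, x]`;
default image sampling is `c/(2·fs)` axially and one element pitch
laterally. All randomness flows through explicit seeds; equal seeds give
bit-identical outputs (HDF5 written with `track_times=False`).
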