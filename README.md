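# zfbehave

Quantitative phenotyping of zebrafish locomotion as a tested, reusable
pipeline:

- **`zfbehave.tail_kinematics`** — scoring of high-speed (1000 fps) tracked
  tail traces: moving-average smoothing (15 frames x 3 points), deflection /
  curvature / tip-trajectory series, bout and half-beat segmentation at
  deflection zero-crossings, swim/escape (35 deg) and slow/fast (60 Hz)
  classification, per-bout summaries split by speed class.
- **`zfbehave.track_metrics`** — free-swim and tap-evoked escape endpoints
  from 25 fps centroid tracks: central-difference kinematics, hysteresis
  movement detection, 10 min free-swim bins, 280 ms escape windows in seven
  40 ms bins, five-tap averaging with response-rate reporting.
- **`zfbehave.coiling`** — embryonic coiling from per-ROI frame differencing
  (50 fps): robust median/MAD peak detection, coil frequency / duration /
  intensity / intercoil summaries.
- **`zfbehave.assays`** — swim-tunnel Umax scoring (4.5 cm/s steps of 60 s,
  last completed step before failure, body-length normalisation),
  delta-delta-Ct relative expression against two housekeeping genes
  (*rpl13*, *elfa*), and Western-blot densitometry with lane-background
  subtraction.
- **`zfbehave.group_stats`** — the two-group ladder (Shapiro-Wilk gate,
  Levene's test, pooled/Welch t or Mann-Whitney U, two-tailed alpha 0.05)
  and direction-coded significance matrices.
- **`zfbehave.mutant_models`** — transcript-variant annotation: apply
  substitutions/deletions in 1-based transcript coordinates, translate to
  the first stop, and compare truncated proteins (identical prefix,
  frameshifted tail, domain coverage).
- **`zfbehave.synth`** — synthetic-data generators for every stage with
  exact recorded ground truth, so the whole package is testable without any
  recordings or downloads.

## Command line

All subcommands share a YAML config (`--config`) whose defaults are the
published protocol constants; flags override file values. Inputs and
outputs are plain CSV (RFC 4180, header row), FASTA, or multi-page TIFF.

```bash
zfbehave simulate --kind tail --duration 2 --out-prefix out/run
zfbehave tail out/run_tail.csv --out-prefix out/scored        # half-beat + bout CSVs
zfbehave track out/run_track.csv --taps-csv out/run_taps.csv --out-prefix out/scored
zfbehave coil out/run_coil.csv --out-prefix out/coil          # or a TIFF stack + --rois-csv
zfbehave umax trials.csv --out umax.csv
zfbehave qpcr ct.csv --calibrator wt0 --calibrator wt1 --out rq.csv
zfbehave blot lanes.csv --out blot.csv
zfbehave compare endpoints.csv --group-a mutant --group-b wildtype --out-prefix cmp
zfbehave mutant transcript.fa variants.csv --cds-start 204 --out effects.csv
```

Column orders are fixed and deterministic; re-running any subcommand with
the same config and seed reproduces byte-identical CSVs.

Tail CSVs are accepted in long format (`frame,time_s,point_index,x,y`) or a
wide 40-column dialect (`x0..x19,y0..y19`, `--format wide`). Track CSVs use
`frame,time_s,x_mm,y_mm`; coil CSVs `frame,time_s,embryo_id,motion_energy`;
ROI tables `embryo_id,x,y,w,h` (0-based, half-open).

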