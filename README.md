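# ojiptools

JIP-test analysis of fast chlorophyll-*a* fluorescence (OJIP) transients for
drought-physiology experiments, plus the comparative statistics that usually
accompany it and a seeded synthetic-data generator so the whole pipeline can
be exercised without instrument data.

What it does:

- **Transient I/O** (`ojiptools.io`) — read/write OJIP traces in long or wide
  CSV dialects and tidy trait tables (`variety,treatment,replicate,trait,value`),
  with strict validation (monotone µs time axis covering ~10 µs–1 s, positive
  fluorescence).
- **JIP test** (`ojiptools.jip`) — landmark extraction (F0 at a configurable
  origin, F_L at 150 µs, F_K at 300 µs, F_J at 2 ms, F_I at 30 ms, Fm as the
  trace maximum; log-time linear interpolation) and the full algebraic
  parameter set: V_L/V_K/V_J/V_I, M0, quantum yields (φPo, ψEo, φEo, δRo,
  φRo), specific fluxes per reaction center (ABS/RC, TR0/RC, ET0/RC, DI0/RC,
  RE0/RC), cross-section fluxes (ABS/CSm ≈ Fm, …, RC/CSm) and the
  performance indices PI_abs and PI_total.
- **Band analysis** (`ojiptools.bands`) — double-normalized W_OJ / W_OK / W_OI
  curves, treatment-minus-control ΔW bands (K- and L-band diagnostics), the
  W_OI ≥ 1 tail amplitude, and the OEC-center and Q_A-reducing-center
  fractions versus control.
- **Physiology** (`ojiptools.physiology`) — Lichtenthaler chlorophyll /
  carotenoid contents from 665/649/470 nm absorbances, WUE = Pn/Tr, percent
  change versus a reference.
- **Statistics** (`ojiptools.stats`) — range variability V = (max−min)/max
  and ΔV between varieties, one-way ANOVA with Fisher-LSD compact letter
  display, balanced two-way ANOVA star tables, relative-to-control trait
  profiles, and pairwise Pearson correlation matrices starred at
  0.001/0.01/0.05/0.10.
- **Simulation** (`ojiptools.simulate`) — transients built by monotone PCHIP
  interpolation of relative fluorescence in log time through the step
  anchors, factorial experiments with injectable treatment effects
  (anchor shifts, φPo scaling, trait factors) and fully seeded noise,
  including a bundled two-variety drought scenario.

## Command line

```sh
ojip simulate --seed 1 --out run1                 # write synthetic inputs
ojip analyze  --seed 1 --out run1 \
     --transients run1/transients.csv \
     --physiology run1/physiology.csv [--plots]   # run every analysis stage
ojip report   --out run1                          # summarize to Markdown
```

`analyze` writes, in order: `landmarks.csv`, `jip_parameters.csv`,
`band_curves.csv` (mean W and ΔW per phase), `oec_qa_rc.csv`,
`relative_profiles.csv`, `traits_combined.csv`, `anova_letters.csv`,
`two_way_stars.csv`, `variability.csv`, `correlations.csv`, plus `run.log`
with per-stage row counts. With `--plots` it also renders OJIP curves, ΔW
bands, a relative-profile radar and a correlation heatmap.

### Configuration

`--config` takes a YAML file; every key is optional:

```yaml
seed: 1
t0_us: 20            # origin time for F0 (µs)
control: "0h"        # reference treatment label
treatments: ["0h", "4h", "8h", "24h"]   # display/order; not lexical
variety_pair: ["NH5", "FH18"]           # pair used for delta-V
alpha: 0.05
correlation_pooling: pooled   # or per_variety
qa_rc_mode: quotient          # or product (operator in the QA-RC formula)
n_reps: 3
noise_cv: 0.01        # fluorescence noise in simulate
trait_noise_cv: 0.04  # physiology trait noise in simulate
transients_csv: null  # default inputs for analyze
physiology_csv: null
```

## Data dialects

- `long_csv` transients: `variety,treatment,replicate,time_us,fluorescence`.
- `wide_csv` transients: `time_us` first, then one `variety|treatment|replicate`
  column per trace.
- Trait tables: `variety,treatment,replicate,trait,value`.

Time is microseconds everywhere; fluorescence stays in instrument units
(every derived JIP quantity is a ratio).
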