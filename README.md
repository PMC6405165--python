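# fishscreen

Semi-automated analysis of 96-well time-lapse screens of fish embryos
(medaka, zebrafish): ratiometric fluorescent-protein intensity
quantification, anaesthesia movement scoring, randomized plate design,
cross-species intensity comparison and codon-adaptation metrics — plus a
ground-truthed synthetic plate generator so the whole pipeline is testable
end to end without any microscope data.

It is written for labs that screen reporter constructs or anaesthetics by
plate imaging: embryos are injected at the one-cell stage, loaded into a
randomized 96-well plate and imaged automatically for ~40 h, and the
question is which fluorophore is brightest in vivo, or which anaesthetic
actually immobilizes the embryo.

## What it computes

**Ratiometric fluorescence.** Every well co-expresses a test fluorophore
and a reference (e.g. mCherry). Per well/timepoint/z-slice, the embryo is
segmented by Otsu's threshold in *both* channels, the masks are
intersected, and mean/median/sd/area are measured over masked pixels
(background excluded, not subtracted). The test trace is divided by the
well's reference value at the frame nearest 10 hpf,

    Î_w(t) = I_test,w(t) / I_ref,w(t₁₀),

which cancels the per-well injection volume. Negative wells (dead or
non-developing embryos) are dropped by checkpoint QC; plates are fused via
an internal-control condition; conditions are ranked by normalized
intensity. For cross-species comparison, window means (23–30 hpf) are
rescaled per colour class so each class normalizer matches its published
reference value (Venus → 1.2). Group differences use the two-sided
rank-sum test with the usual star thresholds.

**Movement index.** For brightfield time-lapses, the index of each
consecutive frame pair is mean_pixels[(frame_{n+1} − frame_n)²]; an
anaesthetized embryo sits at the camera-noise floor (2σ²), a moving one
far above it. Plates are stage-aligned by user-supplied offsets and
summarized per condition; startle-response counts get the same rank-sum
treatment.

**Codon metrics.** Relative adaptiveness w = f/max f within each
synonymous family (Sharp & Li, 0.5 pseudo-counts), CAI as the log-domain
geometric mean of w, and codon-usage-driven back-translation
(most-frequent or usage-weighted sampling).

**Synthetic plates.** `fishscreen.simulate` generates TIFF stacks with
known expression kinetics I(t) = v·b·(1−e^{−t/τ_mat})·e^{−t/τ_dec},
log-normal injection volumes shared across channels, embryo random walks,
dead wells, and a full ground-truth table. `fishscreen.protocols` bundles
the standard study set-ups.

## Worked example

Simulate the fluorophore panel (8 conditions × 8 wells, programmed
brightness ratios 0.25–4×, injection-volume CV 30%, noise 5% of signal)
and recover the ranking:

```python
from fishscreen.protocols import fluorophore_panel
from fishscreen import (simulate_plate, quantify_plate, aggregate_measurements,
                        build_traces, qc_filter, rank_conditions, QCParams)

config, layout, models = fluorophore_panel(seed=1)
series, truth = simulate_plate(config, layout, models, reference_channel="mCherry")
measurements = quantify_plate(series, "mCherry")          # per-slice stats
aggregated = aggregate_measurements(measurements)         # pooled over z
kept, dropped = qc_filter(aggregated, QCParams(), channel="mCherry")
traces, _ = build_traces(aggregated, layout, "mCherry", t_norm=10.0, wells=kept)
ranking = rank_conditions(traces, t=10.0)
print(f"kept {len(kept)}/64 wells")
print(ranking.to_string(index=False))
```

```
kept 64/64 wells
condition     mean       sd  n_wells
 mVenusNB 3.980984 0.012853        8
 mGFPmut2 2.790510 0.004883        8
  eGFPvar 1.992924 0.004652        8
    Venus 1.397057 0.001968        8
     eGFP 0.999948 0.002295        8
   Clover 0.701209 0.001839        8
      YFP 0.404226 0.001382        8
      CFP 0.254686 0.001489        8
```

The `mean` column is the normalized intensity at 10 hpf — the recovered
test/reference brightness ratio. The programmed ratios were 4.0, 2.8,
2.0, 1.4, 1.0, 0.7, 0.4 and 0.25: the ordering is recovered exactly and
every ratio is within 2% of truth, despite >2-fold injection-volume
differences between wells.

Codon metrics on a toy glycine usage table (GGC:GGA:GGG:GGT =
30:10:5:5):

```python
from fishscreen import cai, codon_average, relative_adaptiveness
from fishscreen.codon import ALL_CODONS, CodonUsageTable

entries = {c: 1.0 for c in ALL_CODONS}
entries.update({"GGC": 30.0, "GGA": 10.0, "GGG": 5.0, "GGT": 5.0})
table = CodonUsageTable(species="toy", entries=entries)
w = relative_adaptiveness(table)
print("w(GGA) =", w["GGA"])               # 0.3333333333333333
print("CAI('GGCGGA') =", cai("GGCGGA", w))  # 0.5773502691896257  (= sqrt(1/3))
print(codon_average("MG", table, mode="most_frequent"))  # ATGGGC
```

The same operations are available from the shell via the `fishscreen`
CLI (`layout`, `simulate`, `quantify`, `movement`, `fuse`, `rank`,
`crossspecies`, `cai`, `optimize`).

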