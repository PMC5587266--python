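# cryptofrog

An integrative species-delimitation toolkit for cryptic stream treefrogs,
built around the evidence used to split the Japanese stream treefrog
(*Buergeria japonica*, "JP" clade: Ryukyus + northwestern Taiwan) from its
cryptic sister species in eastern and southern Taiwan (*B. otai*, "OT"
clade). It is aimed at herpetologists and bioacousticians who want the
full analysis chain — call analysis, mitochondrial divergence,
morphometrics, and playback-response scoring — as reusable, tested code,
plus a synthetic-data generator that reproduces the statistical structure
of the study system so every stage can be exercised without field data.

## What it computes

**Bioacoustics** (`cryptofrog.acoustics`). Calls are segmented from the
amplitude envelope (moving RMS, 2 ms), pulses are detected as envelope
peaks, and calls are classified by the field rule: more than three pulses
after the first rising peak → *long call*, otherwise *short call*. Long
calls are typed from their amplitude profile (Type 1: a regular train of
similar-amplitude pulses, modal pulse count 16–17; Type 2: a dominant
onset peak, an accelerating weak-to-strong train, and a terminal peak —
the call type unique to the OT clade). Short calls yield five parameters:

* DT (call duration), RT (rise time to the highest envelope peak),
  FT (fall time), with DT = RT + FT;
* DF, the dominant frequency: the peak of the Welch power spectrum
  (1024-point FFT, Hann window);
* IQR, the spectral interquartile range |F(Q3) − F(Q1)| of in-call
  spectral energy.

Per-individual values average the first 10 analyzable calls; individuals
with fewer are excluded.

**Molecular divergence** (`cryptofrog.moldist`). Haplotype collapsing and
uncorrected p-distance with pairwise deletion,

    p = (# unambiguous differing sites) / (# sites unambiguous in both),

aggregated into within/between-group mean and maximum divergence tables
over unique haplotypes.

**Morphometrics** (`cryptofrog.morphometrics`). The 19 standard
measurements (SVL, HL, HW, …, T4L) are standardized as ratios to
snout-vent length; correlation-matrix PCA with Kaiser retention
(eigenvalue > 1) feeds an equal-priors linear discriminant whose
resubstitution accuracy measures cluster support; a diagnostic-ratio
calculator reproduces species-description percentages (half-up rounding).

**Statistics** (`cryptofrog.stats_core`). The ambient factor (PC1 of
temperature/humidity), a nested mixed model (region fixed, locality
random intercept nested in region, ambient covariate; REML, containment
denominator df = #localities − #regions), and Pearson chi-square with
adjusted standardized residuals (O − E)/√(E(1 − r/N)(1 − c/N)).

**Playback scoring** (`cryptofrog.playback`). Per-stimulus territorial
call counts, energy-allocation ratios, the highest-defense-opponent
(HDO), the strict >20-calls-per-window validity screen, and a one-way
chi-square of HDO choices against a uniform no-preference null.

**Synthetic data** (`cryptofrog.synth`). Call audio (carrier sinusoid,
raised-cosine pulse envelopes, additive noise at configurable SNR) drawn
from the published per-clade distributions (JP short calls DT
0.4180 ± 0.0725 s, DF 3341.5 ± 46.1 Hz; OT 0.1127 ± 0.0258 s,
3202.7 ± 36.2 Hz); cytochrome-*b*-like sequence sets hitting the
published six-lineage divergence matrix exactly (site-pattern
decomposition); morphometric tables with a clade head-size contrast; and
overdispersed playback trials with a planted conspecific preference.

## Worked example

```python
from cryptofrog import morphometrics, moldist, synth

# diagnostic ratios of the OT holotype measurement series
table = morphometrics.diagnostic_ratios(morphometrics.HOLOTYPE_MEASUREMENTS_MM)
print(table.loc[["HL/HW", "EL/HL", "TL/SVL", "FAL/HAL", "F1L/F3L"], "percent"])

# two-clade divergence from a synthetic six-lineage sequence set
seqs = synth.synth_sequences(synth.study_divergence_params(seed=1))
clades = [moldist.SequenceRecord(s.id, "JP" if s.group_label in
          ("Amami", "Okinawa", "Yaeyama", "NW-Taiwan") else "OT", s.bases)
          for s in seqs]
t = moldist.group_divergence(clades)
pair = frozenset({"JP", "OT"})
print(f"between-clade mean {t.between[pair]:.4f}, max {t.max_between[pair]:.4f}")
```

prints

```
ratio
HL/HW      103.0
EL/HL       39.4
TL/SVL      62.2
FAL/HAL     87.3
F1L/F3L     45.7
Name: percent, dtype: float64
between-clade mean 0.1607, max 0.1781
```

i.e. the holotype's head is marginally longer than wide (103.0%), its
tibia is 62.2% of snout-vent length, and the two clades differ by ~16%
mean mitochondrial p-distance — deep divergence for a pair of
morphologically similar frogs.

The full synthetic pipeline (audio → features → mixed model, sequences →
divergence table, morphometrics → discriminant sweep, playback →
preference test) runs from the shell:

```
cryptofrog run --seed 1 --out runs/demo
```

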