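# Methods

This note records the models, parameter choices, and numerical decisions
behind `cryptofrog`, in the spirit of a statistical methods appendix.

## Acoustic model and analysis chain

**Envelope.** The amplitude envelope is the moving RMS of the signal over
a 2 ms window. At the study's sampling rate (44.1 kHz) this spans ~88
samples — long enough to smooth a >3 kHz carrier (≥6 cycles), short
enough to resolve pulse trains far faster than any observed in this
system (fastest synthesized train: 40 pulses/s, 25 ms spacing).

**Segmentation.** Calls are maximal regions where the envelope exceeds a
noise floor of 5× the median envelope of the whole recording, with
sub-threshold gaps shorter than 50 ms merged (so a pulsed long call stays
one unit while calls in a bout split), regions shorter than 10 ms
dropped, and boundaries then extended outward by hysteresis down to 1.5×
the median envelope. The median-based floor presumes recordings are
mostly between-call background; the synthetic recordings are built with
0.8 s inter-call gaps so that holds. The hysteresis threshold sits ~6
noise-SDs above the background envelope, so extension stops reliably at
call edges; residual boundary clipping biases measured DT by about −2 to
−3% at 30 dB SNR (well inside the ±10% round-trip tolerance).

**Pulse detection.** Local envelope maxima above 0.1× the in-call peak,
with ≥5 ms separation and a prominence of ≥0.05× the peak (the prominence
guard rejects noise wiggles on slow envelope slopes). Validated against
the synthesizer: pulse counts of 12–18-pulse trains are recovered exactly
at SNR ≥ 20 dB, and are invariant under global amplitude scaling.

**Call typing.** The long/short rule counts pulses after the first rising
peak (the first detected pulse): ≥4 → long, ≤3 → short. The field rule
("more than three" long, "less than three" short) leaves exactly three
pulses unassigned; we classify that case short, and expose both the cut
(`long_min_pulses_after_first`) and whether the first pulse is excluded
(`count_excludes_first`) in `TypingConfig`. Long-call types are decided
by amplitude profile: Type 2 requires a dominant onset (first pulse ≥1.5×
the median mid-train amplitude) *and* a rising mid-train trend (Spearman
ρ > 0.5); Type 1 requires a flat train (amplitude CV < 0.25); anything
else is left unclassified. These three thresholds are heuristics
validated only against the synthesizer, not against field recordings.

**Short-call features.** DT is the segmented span; RT/FT split it at the
global envelope maximum, so DT = RT + FT holds to one sample by
construction. DF is the argmax of the Welch power spectrum (1024-point
Hann segments, 50% overlap; calls shorter than one segment are
zero-padded and flagged). Raven's exact power-spectrum averaging is not
documented publicly; Welch averaging is our declared choice. The spectral
IQR is |F(Q3) − F(Q1)| with F(q) the linear-interpolated frequency below
which fraction q of in-call spectral energy lies — the absolute value
resolves the sign convention of "Q1 minus Q3". Per-individual profiles
average exactly the first 10 analyzable short calls; individuals with
fewer than 10 are excluded rather than averaged over fewer calls.

## Statistics

**Ambient factor.** PC1 of the 2-variable correlation-matrix PCA of air
temperature and humidity, computed in closed form (eigenvalues 1 ± |r|),
sign-fixed so temperature loads positively. If one variable is constant
the other's z-scores are returned with a warning.

**Nested mixed model.** `response ~ region + ambient` with a random
intercept per locality, REML via statsmodels MixedLM. The region F-test
is a Wald test divided by its numerator df, referred to an F distribution
with *containment* denominator df (#localities − #regions): with 15
localities in 2 regions this yields df = 13, matching the reporting
pattern of SAS-style nested designs. Satterthwaite/Kenward–Roger df are
out of scope. When the locality variance estimate hits the boundary the
test agrees with the ordinary fixed-effects ANOVA F to ~1e-8 relative
error; under the null the empirical size at α = 0.05 is ~0.044 (500
simulations). Designs where each region has a single locality are
rejected (region and locality confounded).

**Contingency analysis.** Plain Pearson chi-square (no continuity
correction) with per-cell adjusted standardized residuals
(O − E)/√(E(1 − row/N)(1 − col/N)). No multiple-testing correction is
applied anywhere; per-feature tests are reported as-is.

## Molecular divergence

p-distance uses pairwise deletion: any site where either sequence is a
gap or an IUPAC ambiguity (non-ACGT) is dropped from both numerator and
denominator, the common convention of distance software. Group
divergences are computed over unique haplotypes, unweighted by haplotype
frequency — the within/between tables of this system are haplotype-based —
and the maximum between-group distance is reported alongside the mean
because it is invariant to that weighting choice. Alignment is out of
scope: inputs must be pre-aligned equal-length sequences (the system's
complete-cytb haplotypes already are); length mismatches raise an error
pointing to external aligners.

## The synthetic generators

The generators define the study conditions under which the pipeline is
tested; their defaults are the published values wherever values were
published.

**Call audio.** A carrier sinusoid amplitude-modulated by per-pulse
raised-cosine envelopes (long calls) or an asymmetric *triangular*
envelope (short calls). The triangle gives short calls a linear onset and
offset, so threshold segmentation clips only ~f·DT at threshold fraction
f; a raised-cosine short call would lose >20% of its measured duration to
its flat tails. Type 1 trains run at 20 pulses/s (Type 1B: 17/s — the
"slower Type 1" of the southern clade); Type 2 pulse rate rises linearly
to 2× its start (the published description is qualitative: "very rapid
pulses from weak to strong"), with mid-train amplitudes ramping 0.35→1.0,
an onset peak of gain 2.0, and a 1.2-amplitude terminal peak. White noise
is added at a default SNR of 30 dB (field recordings are noisy; no noise
figures were published). Pulse counts draw from {15, 16, 16, 17, 17, 18},
putting the mode at 16–17. Per-clade short-call parameters draw from the
published normal distributions, with the clade SD split into a locality
random effect (SD/2) and an individual effect (SD·√3/2) so the marginal
SD is preserved while giving the nested mixed model a true two-level
structure; rise time is drawn as a fraction of duration (so FT stays
positive even for the JP clade, where RT is 88% of DT on average).

**Sequences.** The six-lineage divergence matrix is realized *exactly*
(to ≤~1.4 substituted sites per pair, ~0.0014) rather than stochastically:
the within-adjusted between-group target matrix is decomposed into
non-negative integer counts over group partitions (≤4 blocks — one base
per block per site), via NNLS over all partition patterns followed by a
greedy ±1 integer repair. Each pattern occupies its own disjoint sites,
so recomputed distances equal the decomposition by construction. Each
member sequence adds private substitutions at further disjoint sites
(mean count = within-target·L/2, ±1 jitter when that keeps every member a
distinct haplotype), which realizes the within-group means and lets the
maximum between-clade distance exceed the mean, as observed. Infeasible
targets (site budget exceeded, between smaller than the within variation
it must contain, or a matrix outside the partition cone) are rejected
with a diagnostic.

**Morphometrics.** Trait means are the holotype's ratios to SVL; the JP
clade's seven head measurements are scaled by 0.95 (the OT clade has the
larger head), lineages jitter around clade means with 1% relative SD,
individuals vary with 3% CV per trait, and SVL draws near 26.5 mm. These
dispersions are our realistic choices — per-trait moments were not
published — so discriminant accuracies on synthetic data characterize the
pipeline, not the real specimens.

**Playback.** Counts are gamma-mixed Poisson (negative binomial; gamma
shape k = 1 models strong male-to-male variation in defensiveness). The
published response statistics are conditional on the strict >20-call
validity screen, so the generator's unconditional means were calibrated
once (fixed point on simulated conditional means, grid on k) to reproduce
the published conditional values: northern males ~51.1 calls toward
Type 1A at ~59% allocation with ~4/7 choosing correctly; southern males
~36.8 calls toward Type 2 at ~64% with ~10/13 correct. The acoustically
similar Type 1B draws most of the northern males' misdirected responses.

## Problem sizes and determinism

The test suite and acceptance script use: 15 individuals per clade
(pooled over three replicates in the acceptance script, reported n = 45)
with 10 short + 2 long calls each; 118 sequences of 1016 bp; 100
mixed-model and 100 preference-test replicates; 500 null-size
simulations. Every generator takes an explicit seed and is byte-
reproducible; the pipeline fans one master seed out to fixed per-stage
offsets and embeds the seed and a config hash in its report.

## Known limitations

* Segmentation assumes recordings are mostly background; continuous
  chorus recordings would inflate the median-envelope noise floor.
  Chorus overlap and reverberation are not modelled.
* The Type 1/Type 2 thresholds and the pulse-detection constants are
  validated against the synthesizer only; field recordings with gradual
  onset peaks or irregular trains may need retuned configs.
* Long-call durations/features are not analyzed (only typed), mirroring
  the source analysis.
* The sequence generator's exact site placement yields deterministic
  divergences; it does not emulate mutational processes (no
  transition/transversion bias, no rate heterogeneity), only the distance
  structure that the p-distance stage consumes.
* Playback trials are summarized at the count level; detecting
  territorial calls inside playback audio is upstream of this module.
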