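# Methods

`spnpipe` simulates and analyses the electrophysiological signature of
visual mirror-symmetry perception: the **Sustained Posterior Negativity
(SPN)**, a symmetry-minus-noise ERP difference over posterior electrodes,
together with the **topographic microstate** structure of the underlying
scalp fields.  Because no public recordings exist for this paradigm, the
package pairs every analysis stage with a seeded generator that plants the
corresponding ground truth, so the whole chain is testable end to end.

## Stimuli

Stimuli are fields of 60 achromatic (96 chromatic) Gaussian dots
(σ = 0.08°, truncated at 5σ) inside a 12°-diameter aperture on a mid-grey
background.  A fraction (0, 50 or 100%) of the dots is mirror-paired about
the vertical axis; the reflection is exact in floating point
((x, y) → (−x, y)), so mirror invariants can be asserted with zero
tolerance.  Luminance polarity / colour is assigned per arrangement:
anti-symmetric (mates opposite polarity), polarity-grouped anti-symmetric
(polarity split by the vertical midline), unsegregated (mates share
polarity, pairs balanced), segregated (signal dots one polarity, noise dots
the other; defined only at 50% symmetry), single-polarity, the matching
noise variants, and 2–4-colour patterns with colour-matched mates.

Placement choices the arrangement description leaves open are fixed as:
uniform sampling over the aperture disc, a minimum centre-to-centre spacing
of 0.5° and an exclusion strip of ±0.15° around the vertical axis, all
enforced by rejection sampling.  The spacing prevents dot overlap; the strip
prevents a dot from straddling the axis, which would make the
polarity-grouped split ambiguous.  Dots additionally keep 5σ (0.4°) clear of
the aperture rim so the rendered blob never crosses it.

One arithmetic corner is worth noting: a 60-dot pattern at 50% symmetry has
15 mirror pairs, so an *exactly* equal white/black pair split is impossible
for the unsegregated arrangement.  The generator treats the exact split as
the contract and raises by default; `balance="nearest"` (used by the
experiment-2 design) splits 8/7 instead.

Trial designs follow the two-interval forced-choice protocol: 100
presentations per condition in randomised order (300 trials in experiments
1 and 3, 600 in experiment 2), 500 ms stimulus, 500 ms ISI.  A Bernoulli
observer stands in for human responses.

## Synthetic EEG

The generator emulates a 64-channel extended 10-20 recording (online Cz
reference, 1 kHz, epochs −100…1000 ms).  Each trial is

```
trial = Σ_segments  a_k · template_k ⊗ envelope_k  +  SPN offset  +  noise
```

* **Templates** are average-referenced, unit-GFP maps built by mixing a few
  random dipolar patterns smoothed over the montage with an exponential
  distance kernel; candidates are redrawn until all pairwise spatial
  correlations satisfy |r| ≤ 0.7.
* **Envelopes** are boxcars with 10 ms raised-cosine ramps (no step
  discontinuities).  The default timeline tiles k = 4 maps over the
  200–600 ms analysis window; the last map is planted only in symmetry
  conditions, with the noise conditions extending the preceding map over
  its slot — a symmetry-specific late microstate.  For amplitude-recovery
  experiments the timeline is shared between conditions
  (`symmetry_only_map=None`), because a condition-specific topography is a
  genuine topographic difference that would otherwise contaminate the
  electrode-level difference wave.
* **SPN**: a sustained offset (default −1.5 μV) added at PO7/PO8 over
  200–600 ms in symmetry conditions only.
* **Noise**: Gaussian, white in time, spatially correlated across
  electrodes with an exponential covariance over unit-sphere chord
  distances (length scale 0.5).  The default single-trial amplitude is
  15 μV RMS per sample, chosen as typical of filtered single-trial
  posterior EEG — it leaves ≈0.5 μV residual noise in a 100-trial ERP,
  the order commonly reported for this kind of recording.
* **Between-participant variability**: a multiplicative log-normal gain
  (σ = 0.2, mean 1) on the whole signal, sized so that group effects at
  n = 24 are detectable but not trivial.
* **Artifacts**: a chosen fraction of epochs (default 6%, the rejection
  rate reported for this paradigm) receives a ~60 ms transient scaled so
  its peak sample exceeds the requested amplitude exactly; the mask of
  affected epochs is kept as ground truth.

What the generator does **not** emulate: 1/f spectral structure and
temporal autocorrelation of background EEG, ocular/muscle artifact
waveforms, electrode drift or impedance changes, and any cortical forward
model.  Passing recovery tests therefore demonstrates the correctness of
the analysis chain under a known signal-plus-noise model, not robustness to
every property of real recordings.

## Preprocessing

Zero-phase low-pass at 40 Hz realised as an order-8 Butterworth
(6 dB/octave per pole → 48 dB/octave one-pass asymptotic slope; the
forward–backward pass doubles the realised attenuation, accepted and
documented).  Baseline correction subtracts the per-epoch, per-electrode
mean over −100…0 ms.  Artifact rejection removes an epoch iff any sample
strictly exceeds ±100 μV ("exceeding" taken literally: a sample at exactly
100 μV is retained); it runs after filtering by default, with a flag to run
it first.  Epochs are averaged with equal weights per condition on the
online reference; ERPs are re-referenced to the common average only at the
measurement stage.  All analysis windows are closed intervals including
both endpoint samples.  The SPN is the mean of the symmetry-minus-noise
difference wave over {PO7, PO8} × [200, 600] ms, computed only from
common-average-referenced ERPs.

Filtering and baseline correction commute only for signals the filter
passes unchanged; the package asserts commutation to 1e-6 μV on band-limited
~1 μV inputs.  The recovered group-mean SPN is slightly shallower than the
planted offset (≈ −1.40 vs −1.5 μV) for two structural reasons: common-
average re-referencing returns 2/64 of the offset to all channels, and the
10 ms envelope ramps shave ~2.5% of the window mean.  Both are properties
of the measurement conventions, not estimation error.

## Topographic statistics

GFP is the spatial standard deviation of the average-referenced map
(population convention, divide by N — the field's standard; the sample
convention would change every number).  DISS between two maps is the RMS
difference of the average-referenced, GFP-normalised vectors and satisfies
DISS = √(2(1−r)) exactly.  Zero-GFP maps have no configuration and raise.

The paired TANOVA tests, at each timepoint, the DISS between the two
group-mean maps against a randomisation null obtained by swapping the two
condition maps independently within each participant (sign flips of the
paired difference maps, sampled `n_perm` = 1000 times by default; the
permutation count is a package default, not a published value).  P-values
use the add-one rule p = (1 + #{perm ≥ obs})/(n_perm + 1), so p ≥
1/(n_perm+1) and p = 0 is impossible.  Timepoints are tested independently;
the multiple-comparison control is the temporal-stability criterion:
significant windows are maximal runs of p < 0.05 lasting *strictly more*
than 30 ms (duration = offset − onset; a 30.0 ms run does not qualify).

## Microstate segmentation

Segmentation runs jointly on all conditions' grand-average maps inside
200–600 ms, concatenated into one clustering problem, so every condition
shares a single template set (the reported map sets are common to all
conditions of an experiment).  TAAHC starts with every timepoint map as its
own cluster and repeatedly *atomises* one cluster, reassigning each freed
map to the remaining cluster with the highest **signed** spatial
correlation (ERP polarity convention — flipping a map's sign changes its
assignment), then updating the receiving templates (normalised cluster
means).

The atomisation order is the one genuinely open design choice.  Dissolving
the cluster with the smallest raw GEV contribution fails in a configuration
this paradigm actually produces: when one template legitimately occupies
two slots (map C filling map D's slot in noise conditions), the duplicate
cluster out-contributes a small but distinct map, and the distinct map is
destroyed first.  The package therefore dissolves the cluster with the
smallest **GEV loss** — its contribution minus what the best remaining
cluster would absorb from its members — which retains the template set
explaining the greatest variance at each level.  No temporal smoothing or
minimum-segment merging is applied.

Model order is chosen from two criteria computed along the hierarchy:

* **CV criterion**: predictive residual variance σ̂² scaled by
  ((N−1)/(N−1−q))², N = number of electrodes; lower is better.
* **Krzanowski–Lai**: DIFF(q) = (q−1)^(2/m) W(q−1) − q^(2/m) W(q) on the
  within-cluster dispersion curve W, KL(q) = |DIFF(q)|/|DIFF(q+1)|; the
  maximum marks the elbow.  m is taken as the number of electrodes (the
  clustering-space dimension), and KL is defined only at interior q.

In practice the CV curve drops steeply until the true map count and is
then nearly flat: each extra cluster keeps absorbing noise at about the
rate the degrees-of-freedom penalty grows, so its argmin scatters over the
flat region while KL's argmax is sharp.  The joint rule therefore prefers
KL's argmax and flags a conflict whenever CV's argmin differs.

Back-fitting labels each timepoint of an individual ERP with the
best-correlating template and credits map m with the share
Σ_{t: label=m} (GFP(t)·r(t))² / Σ_t GFP(t)² of the windowed variance;
zero-GFP timepoints are skipped and counted.  Map timing reports the
maximal runs per map (onset, offset, total duration = Σ run spans) and
flags maps absent from a condition.

## Group statistics

Repeated-measures ANOVAs use the univariate approach with orthonormal
(Helmert) contrasts, supporting any number of fully-crossed within factors;
each effect's error term is its interaction with subjects, and the
Greenhouse–Geisser ε = tr(S)²/(q·tr(S²)) from the contrast-score covariance
rescales both degrees of freedom (original dfs are reported alongside, and
only GG — not Huynh–Feldt — is offered).  On two-level designs F equals
the squared paired t exactly.  Effect sizes are partial η² for ANOVAs and
Cohen's d with the paired-difference SD for t-tests.  Bonferroni adjustment
multiplies raw p by the number of comparisons, capped at 1.  P-values are
reported verbatim with no significance thresholds beyond α = 0.05 where a
binary decision is required.

## Problem sizes and numerical choices

Validation batteries run at scaled-down study sizes, chosen as the
package's own defaults for desk-scale reproduction: 250 Hz sampling instead
of 1 kHz and 30–50 trials per condition instead of 100, with participant
counts as stated per experiment (24 for SPN recovery, 12 for TANOVA
calibration/sensitivity, 8 for segmentation).  The planted effects are
unchanged, so recovered quantities estimate the same parameters with
somewhat wider Monte-Carlo error.  Tolerances: exact float equality for
mirror symmetry and seed determinism; 1e-10 for algebraic identities
(DISS/correlation); 1e-8 relative for F = t²; calibration bands of ±0.02
around the nominal 0.05 rate.  Ties in atomisation are broken by a seeded
1e-12 jitter so hierarchies are reproducible.

## Known limitations

* The epoch container is the package's documented HDF5 layout; EDF+ export
  is not provided.
* The TANOVA is paired-design only, with no cluster-mass correction (the
  duration criterion is the only temporal control, by design).
* Microstate analysis uses the signed (ERP) convention throughout;
  polarity-invariant resting-state segmentation is out of scope.
* The simulated observer models per-condition accuracy only — no reaction
  times, learning or lapses.
* Colour labels are symbolic; no colorimetry or isoluminance calibration is
  modelled.
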