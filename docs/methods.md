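# Methods

`auderp` re-implements, as tested and reusable code, a multidimensional
auditory ERP analysis for critically ill patients: two stimulus
paradigms probing self-processing (the subject's own name among other
first names) and semantic/lexical priming (word pairs), a preprocessing
chain for high-density scalp EEG, condition-averaged ERPs with global
field power, and spatio-temporal cluster permutation statistics.  No
patient data is available, so the package ships a synthetic-EEG
generator that emulates three study groups — healthy controls,
critically ill patients without delirium (DEL−) and with delirium
(DEL+) — with known ground truth, making every downstream stage
verifiable end to end.

## Stimulus paradigms

**Own-name (SON).** 12 sequences of 42 names: one subject's-own-name
token and six unfamiliar first names, each presented 6 times per
sequence in shuffled order (probability 1/7 ≈ 14.3 % per name).
Offset-to-onset ISI is uniform in 400–500 ms (1 ms steps), sequences
are separated by 4 s, and each sequence is spoken by one of three
voices drawn uniformly.  With ~1 s stimuli this yields ~60 s sequences
and a ~13 min session.  The shuffle additionally forbids immediate
repetition of the same name — standard oddball practice; the constraint
used in the original sequences is not documented, so this is a package
choice.

**Semantic/lexical priming (SLP).** 320 prime–target pairs in one
block: 80 semantically related (RW), 80 unrelated (UW) and 160
word–pseudoword (PW) pairs, with a fixed 400 ms within-pair ISI,
inter-pair ISIs uniform on {1500, 1600, …, 2000} ms and a 60 s pause at
half block.  Pair order is pseudo-random with at most three successive
pairs of the same category.  Because PW makes up half the pairs, a
uniform shuffle satisfies that constraint with probability ~e⁻²⁰, so
rejection sampling is infeasible; the order is instead built
sequentially — each position draws a category with probability
proportional to its remaining count, excluding any category already
repeated three times, restarting on dead ends.  This is not exactly
uniform over admissible sequences, but it is deterministic per seed,
fast, and unbiased in category placement to first order.  Words are
represented by integer ids; audio is out of scope.

## Synthetic EEG

The generator is additive: for each subject,

  data = 1/f background + 50 Hz line + blinks + event-locked components
         (+ rare high-amplitude "bad-trial" bursts).

*Components* are Gaussian-in-time deflections (peak latency, temporal
SD, signed amplitude) with Gaussian spatial falloff around a named
scalp focus on the unit sphere; each applies to a declared set of
condition labels and is scaled per trial by lognormal amplitude jitter
(σ = 0.2, ~±20 %).  Defaults: N100 (−4 µV, 100 ms, vertex) and P200
(+3 µV, 200 ms, vertex) on every auditory event in all three groups;
P300 own-name effect (+4 µV, 450 ms, centro-parietal) on SON events for
controls and DEL−; N400 (−3 µV, 450 ms) on UW and PW targets
(fronto-central) for controls and on PW targets only
(parieto-occipital) for DEL−; DEL+ carries neither higher-order
component.  The patient literature prints no effect amplitudes, so
these are stand-ins chosen for qualitative, not quantitative, fidelity:
~3 µV effects against 10 µV background noise give per-subject
single-sample z ≈ 2–3 after trial averaging, a realistic regime for
group-level ERP statistics.

*Noise.* Background is spectrally shaped white noise with power ∝ 1/f
(slope −1 in log-log, verified 1–20 Hz), SD 10 µV per sample; line
contamination is a 2 µV 50 Hz sinusoid; blinks are a ~300 ms biphasic
template with a dipolar periocular topography (positive above, negative
below the eye) at Poisson rate 0.2 Hz and ~80 µV amplitude; 2 % of
trials receive a broadband 150 µV burst on a random 15–40 % channel
subset.  What the generator does **not** emulate: dipolar forward-model
mixing, muscle/electrode artifacts, non-stationary noise, latency
jitter, between-subject topography variability.  Passing tests
therefore demonstrate correctness of the analysis chain under the
additive model, not robustness to every pathology of real ICU EEG.

*Montage.* A quasi-uniform 128-position Fibonacci-spiral cap (apex =
Cz, extending slightly below the equator for periocular coverage),
since the vendor geodesic geometry is proprietary and immaterial to the
method.  Simulated voltages are referenced ideally; the average
reference of the preprocessing chain removes any common term.

*Reduced generator.* For statistics-scale experiments the package draws
condition-average ERPs directly: the average of n independent Gaussian
1/f epochs is exactly one 1/f draw scaled 1/√n, and the per-trial
lognormal jitter enters the average through its sampled n-trial mean.
This is exact in distribution for the additive model without artifact
terms (which preprocessing removes), and avoids materialising
55 × 2 full-length recordings per replicate.

## Preprocessing

Zero-phase (forward–backward) 4th-order Butterworth band-pass
0.5–25 Hz, implemented as second-order sections — at a 0.5 Hz edge the
polynomial transfer-function form is numerically ill-conditioned — plus
a zero-phase 50 Hz IIR notch (Q = 30); 1 s reflection padding protects
the recording edges.  A virtual EOG channel (above-eye minus below-eye
channel) is appended and excluded from referencing and statistics.

**Blink suppression** is gated EOG regression: blink segments are
samples where |EOG| exceeds 3 scaled MADs (dilated ±100 ms); per-channel
regression coefficients are fitted on those segments and the scaled EOG
subtracted there only.  Restricting the subtraction to blink segments
is what keeps blink-free data untouched — a global regression would
inject the EOG's own noise everywhere.  The original analysis used ICA
for affected subjects; ICA is stochastic and heavier, and the simulated
blink subspace is a rank-one projection that regression removes by
construction, so regression is the default (an ICA hook can be added
without touching the chain).

**Average reference**: per-sample mean over scalp channels (reference
and EOG excluded) subtracted; the recording reference channel (Cz) is
then reconstructed by spherical-spline interpolation.  The spline is
Perrin-style: kernel g(cos θ) as a Legendre series truncated at 7 terms
with order m = 4 and ridge 1e-5 on the knot matrix (all configurable).
Leave-one-out error on smooth low-order fields is below 5 %; constants
are reproduced exactly, and with ridge 0 the spline passes through its
knots exactly.

**Epoching**: inclusive −200…+1000 ms windows (601 samples at 500 Hz;
t = 0 is an exact sample — whether the original used 600 or 601 samples
is not documented, the inclusive convention is this package's choice),
baseline correction by the −200…0 ms mean; events with partial windows
are dropped with a logged warning.

**Trial rejection/repair**: per-channel peak-to-peak threshold =
across-trial median + 6 scaled MADs (absolute 200 µV fallback where the
MAD degenerates); per trial, channels above threshold are repaired by
spherical-spline interpolation if they number at most 10 % of scalp
channels, otherwise the trial is rejected.  The two knobs (k = 6,
ρ = 0.1) realise "trial-wise assessment of individual sensor
thresholds" with documented, configurable defaults; the thresholds used
originally are not published.

## ERPs and global field power

Condition ERPs are arithmetic means over retained trials.  GFP is
computed per time sample as the root **summed** square of scalp-channel
voltages — the definition the analysis text states — with an `rms`
switch for the Lehmann–Skrandies root-mean-square variant; the two
differ by √N, so peak latencies and all shape-based comparisons are
identical.  Group GFP is the pointwise mean of individual GFP traces.
GFP is permutation- and sign-flip-invariant over channels and excludes
the virtual EOG.

## Cluster permutation statistics

Within-group, paired, one-sided contrasts: SON−OFN, RW−UW, RW−PW and
UW−PW (target words), oriented so positive t is the hypothesised
direction (own-name positivity; N400 negativity of unrelated/pseudoword
targets).  Per (channel, time) sample a paired t statistic is computed
on subject difference waves; samples with t above the cluster-forming
threshold (upper Student-t quantile at p = 0.05, with 0.1 as a second
reporting threshold) are clustered along consecutive time samples and
spatially adjacent channels; cluster mass is the summed t (size-based
mass available).  Channel adjacency is a great-circle distance rule —
arc < 0.35 rad, giving mean degree ~4.8 on the 128-channel montage —
scaled with montage density for reduced layouts.

The null exchanges each subject's difference wave with a random sign
flip (the standard paired-design exchangeability argument; the original
text names only "permutation tests"), and records the **maximum**
cluster mass per permutation, controlling family-wise error over
space × time.  Monte-Carlo p-values use (1 + #{null ≥ observed}) /
(n_perm + 1), counting the observed data as one permutation, so they
are valid and never below 1/(n_perm+1); 1000 permutations by default.
An exhaustive mode enumerates all 2ⁿ sign patterns (n ≤ 16) and
reports the exact p = #{null ≥ observed}/2ⁿ.  Results are annotated
at cluster p ≤ 0.05 and ≤ 0.1, and a cluster-level alpha of 0.01 is
carried as a configurable decision threshold: the source analysis
states an alpha of 0.01 while marking figures at 0.05/0.1, an ambiguity
this package resolves by reporting all three rather than hard-coding
one.

Implementation: supra-threshold samples are collapsed into per-channel
temporal runs; runs on adjacent channels with overlapping time
intervals are merged by union-find (equivalent to connected components
on the sample-level graph, verified against a brute-force BFS oracle
and against MNE's cluster test).  The permutation null is vectorised —
one sign-matrix product gives all permuted t maps, since sign flips
leave Σd² invariant — with a numba kernel for the run merging; the
numpy path is the reference implementation and the kernel is tested
against it.

## Validation experiments

The statistics are validated at a reduced spatial scale (32 channels,
full trial and subject counts, reduced generator; runtimes in minutes
on one CPU):

- **type-I error**: 200 noise-only cohorts (n = 14), fraction with any
  cluster p ≤ 0.05 — observed ~4 %, within [0.01, 0.10];
- **pattern recovery**: 50 replicate cohorts per group — controls show
  a significant, centro-parietally concentrated own-name cluster in
  well over 80 % of replicates; DEL− shows the lexical but not the
  semantic effect in a large majority; DEL+ shows no significant
  cluster in ~86–92 % of replicates.  Note the DEL+ rate is bounded
  near ~87 % in expectation: three exactly calibrated 5 %-level tests
  are run per cohort (the two priming contrasts correlated ~0.58
  through the shared RW condition), so "all clean" cannot sit much
  above (1−α)-style products; this is a property of the design, not a
  miscalibration.

## Degenerate inputs and numerical choices

Zero-variance samples in t maps are set to t = 0 and logged; degenerate
(zero-MAD) rejection thresholds fall back to an absolute 200 µV;
zero-variance EOG raises; spline interpolation requires ≥ 4 good
channels; epoch windows are validated against
round((tmax−tmin)·srate)+1; the epoch file format carries a SHA-256
binding the array bytes to the critical sidecar fields, so label or
array tampering fails on read; EDF export quantises to 16 bits over the
per-channel observed range and is therefore lossy (the `.dat`/JSON
epoch format is bit-exact and is the canonical interchange format).
All randomness flows from explicit seeds through
`numpy.random.SeedSequence` spawning, giving subject-level independence
and bit-stable reruns.

## Known limitations

Synthetic data only — no claim about real patient EEG is made or
testable here; monophasic Gaussian components rather than realistic ERP
morphology; no forward-model channel correlations in the noise; ICA not
implemented (regression hook only); no between-group statistics (the
source design compares groups narratively); EDF export is continuous
recordings only.
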