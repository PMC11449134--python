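# Methods

`dmndyn` implements an analysis chain for stereo-EEG (sEEG) studies of
default-mode-network (DMN) dynamics during internally directed cognition —
mind wandering (MW) and the alternate-uses divergent-thinking task (AUT) —
together with behavioral creativity scoring and stimulation-effect tests.
Because clinical sEEG recordings cannot be redistributed, the package ships a
synthetic-data generator with machine-readable ground truth; every stage of
the pipeline is validated by recovering what the generator planted.

## Spectral pipeline

Signals (channels × time, µV) are processed in a fixed order: channel
exclusion → zero-phase notch filtering (60 Hz and harmonics; second-order IIR
notches, Q = 30, applied forward–backward) → Laplacian local-average
re-referencing along each depth probe → anti-aliased downsampling to 500 Hz →
trial epoching.

The Laplacian subtracts the mean of a contact's immediate neighbors on the
same probe; probe-end contacts use their single neighbor (bipolar), and
excluded contacts are bridged: a neighbor search skips rejected contacts up
to two index steps before falling back to a single neighbor, so channels
adjacent to rejected ones are preserved. Contacts with no usable neighbor are
excluded (reason `no-neighbor`). Bridging is a package choice — boundary
handling at rejected contacts has no canonical convention — and is recorded
in the output channel table.

Time–frequency decomposition uses complex Morlet wavelets with 7 cycles
(temporal SD `n_cycles/(2πf)`), 100 centre frequencies geometrically spaced
from 1 to 200 Hz, L2-normalized, convolved by FFT with reflection padding.
Band power is the **unweighted mean of the wavelet magnitude** across centre
frequencies inside the band — theta 4–8 Hz, gamma 30–70 Hz. Magnitude (not
squared magnitude) is the default, matching the convention of averaging the
modulus of the decomposition; a `squared=True` flag provides power proper.
Band averaging evaluates only the in-band members of the family, which is
numerically identical to decomposing all 100 and averaging the in-band rows.

Each trial is epoched once, spanning both task stages plus 2 s of padding
(half the support of the 4 Hz wavelet, so edge effects never reach the
baseline window or the first bin). Band power is normalized to percent
change against the **single pre-trial baseline**, −0.5 to −0.1 s before the
*stimulus* onset — both the stimulus and the response stage are referenced to
this same window. The first 15 s of each stage are then summarized by a
sliding 1 s window with 50 % overlap: 29 bins, centres every 0.5 s starting
at 0.5 s. Partial final windows are never emitted.

Trial-level outliers are removed before averaging, per electrode × band ×
task × stage cell: a trial is dropped if its trial-mean percent change
exceeds the cell mean + 3 SD (one-sided, above the mean only) or if any bin
exceeds 1000 % (the ceiling is applied per bin, the stricter reading). The
long power table holds the trial-averaged values: one row per subject,
electrode, task, stage, bin, band.

## Network assignment

Electrodes are labeled by the modal network among parcellation points within
a 5 mm Euclidean radius (MNI mm); no point in range → `unassigned`. Modal
ties break by smaller mean distance, then lexicographically, making the
assignment permutation-invariant. Electrodes with both DMN and
fronto-parietal (FPN) points within the radius sit on an interlacing border
and are excluded (`transition-zone`); the rule is specific to that network
pair. DMN electrodes split into a dorsomedial subsystem (ventromedial
prefrontal, anterior cingulate, superior frontal gyrus, posterior cingulate,
posterior parietal, parahippocampal gyrus) and a lateral-temporal subsystem
(middle temporal gyrus, superior/middle temporal sulci) by their anatomical
region string. Surface-based atlas lookup is out of scope; the point-cloud
match is an approximation and outputs say so.

## Inference

Band-power variation is modeled with linear mixed-effects models: the
experimental factors (network, task, stage, time bin, subsystem) are fixed
effects; subjects and electrodes-within-subjects are nested random
intercepts (statsmodels `MixedLM` with an electrode variance component).
Fits feeding likelihood-ratio tests use maximum likelihood, never REML —
REML likelihoods are not comparable across fixed-effect structures. A
singular or non-converged nested fit falls back to subject-only intercepts
(then to a different optimizer), and the fallback is recorded.

Fixed effects are assessed by sequential model comparison: terms are added
one at a time (task → stage → task:stage → bin → bin interactions →
subsystem …) and each step is a chi-square difference test with degrees of
freedom equal to the added fixed-parameter count, clipped at zero. Time bin
enters as a categorical factor by default (a continuous-slope option
exists); both choices are declared in the report header. Post hoc cell
contrasts use the z approximation (estimate/SE against the standard normal),
two-sided, Bonferroni-corrected within the declared family. A simplified
cross-check averages across electrodes per subject and runs a
within-subject factorial ANOVA; when every subject shows zero variance
across cells the ANOVA is degenerate (all sums of squares zero) and F = 0,
p = 1 is reported explicitly.

Calibration properties verified by simulation: the LRT's type-I error and
the paired Wilcoxon's type-I error both sit at the nominal 5 % (±2 points,
500 null replicates; the exact signed-rank test at n = 9 is slightly
conservative by discreteness).

## Similarity clustering

Ten variables are tracked: {theta, gamma} × {MW, AUT} × {dorsomedial,
lateral} plus overall theta and overall gamma (means over the four variables
of each band — the "mean of variables" reading; recomputing from all
electrodes is the alternative and is noted in the report). Observations are
the electrode-averaged 29-bin time courses of both stages, concatenated
across subjects with electrodes in both subsystems (10 such subjects → 580
observations per variable; others are dropped with a log entry). Distance is
1 − Pearson correlation; agglomeration is complete linkage; reliability is
the plain bootstrap probability — the fraction of row-resampled replicate
trees containing a cluster with identical leaf membership. The
approximately-unbiased (multiscale-bootstrap) correction is deliberately not
implemented: the quantity reported here is the bootstrap probability itself.
Trees serialize to Newick with BP as internal node labels.

## Behavioral scoring

Responses are lowercased, stripped of punctuation/numbers and stop words
(bundled English list plus "use", "things", "stuff" — a compact stand-in for
a full NLP stop list); phrases indicating absence of thought ("nothing comes
to mind", …) are excluded, as are responses empty after cleaning.

* **Originality** is the semantic distance between cue and response: token
  vectors are composed multiplicatively (elementwise product — order-
  invariant), scored 1 − cosine ∈ [0, 2], and averaged across the configured
  embedding backends. OOV tokens are skipped; all-OOV responses are excluded.
* **Variability** is the total cosine distance: the sum over all unordered
  pairs of a subject's response vectors for one item, using sentence vectors
  (token means) — cue identity plays no role. One response → 0 by convention.
* **Flexibility** embeds all subjects' responses to an item into 2-D with
  t-SNE (perplexity 5, learning rate 1 — configurable — fixed seed), clusters
  the plane with affinity propagation, and counts the distinct clusters a
  subject's responses occupy. Responses are pooled across stimulation
  conditions before clustering. Non-convergence degrades to a single cluster
  with a warning.

Scores are backend-relative: absolute values depend on the embedding space,
so reports name the backend, and no pretrained space is bundled (a
deterministic hashed random-projection backend serves tests; a text-format
word-vector loader accepts pretrained files).

Stimulation effects are tested per metric with paired Wilcoxon signed-rank
tests on subject-level means (stim vs no-stim, plus block contrasts 1 vs 2,
2 vs 3, 1 vs 3, plus a leave-one-subject-out sensitivity rerun). Zero
differences are dropped (the classical convention); p is exact for n ≤ 25
without rank ties, else a tie-corrected normal approximation. Attention-task
performance is summarized as hit rates for target-only and target+mask
trials and the false-alarm rate on mask-only trials.

## Synthetic data: what it emulates, and what it does not

Each simulated session has three blocks of 4 MW + 4 AUT + 8 ATT trials,
MW/AUT trials with a 20 s stimulus stage and a response stage (60 s by
default), 2 s inter-trial intervals, and stimulation flagged throughout
block 2 (130 Hz, 4 mA, 180 µs, 3 s on/off — metadata only; the signal
generator never injects stimulation artifacts, and behavioral consequences
are planted directly in the response corpus).

Per electrode the signal is 1/f^α background noise plus one carrier per
band. A carrier is a **constant-envelope oscillation whose instantaneous
frequency sweeps the band slowly** (0.05–0.2 Hz modulation), divided by the
wavelet family's band-averaged tone response at the instantaneous frequency
so the measured band magnitude is flat across the sweep, and multiplied by
the planted gain trajectory `1 + pct/100` (linear interpolation through the
29 bin centres, flat beyond; gain 1 outside MW/AUT stages). Within a probe a
band's channels share one sweep with independent phase offsets, so Laplacian
mixtures of probe channels remain constant-envelope and the planted percent
change survives re-referencing exactly. Background noise is spectrally
removed inside the analysis bands plus a 3-spectral-SD wavelet-tail margin,
making the carrier the only in-band content.

Two of these choices trade realism for an analytic expectation, and the
trade is deliberate. A stochastic narrowband-noise carrier — the more
LFP-like alternative — makes the 0.4 s pre-trial baseline an average of
roughly one to two independent Rayleigh-distributed samples in theta; the
per-trial ratio estimator then inherits an inverse-moment (Jensen) bias of
order +10 %, shifting even null conditions away from zero. With the
constant-envelope compensated carrier the planted trajectory *is* the
pipeline's expectation: a +30 % gamma / −20 % theta plant is recovered
within a fraction of a point in the cell mean, and all null cells sit at
0 ± a few points. Consequences for interpretation: passing recovery tests
demonstrates the pipeline's correctness (filters, referencing, windowing,
normalization, bookkeeping), not its robustness to the amplitude
fluctuations, nonstationarity, artifacts, or epileptiform activity of real
LFP — the generator does not emulate those (declared non-goals). The gamma
sweep is additionally capped at 58 Hz so the 60 Hz notch never touches the
carrier.

The behavioral generator plants cue→response cosine distances exactly: each
response's token vector is constructed at a drawn distance d ~
N(base, sd) (clipped to [0, 2]) from its cue vector, shifted by the planted
stimulation effect in block-2 trials of the affected task. Absence-of-thought
filler rows exercise the exclusion path. ATT outcomes are Bernoulli draws at
the planted hit/false-alarm rates (defaults 0.70 / 0.43 / 0.20), with
latencies uniform on (0.2, 1.5) s (only a 2 s maximum is prescribed by the
task). The generator assumes stationarity of the baseline-period signal; one
flat low-amplitude reference channel per probe exercises the referencing
interface.

All randomness flows from a single seed (per-subject streams derived via
`SeedSequence`), so identical configurations are byte-identical on rerun.

## Problem sizes used in tests and the acceptance script

Planted-effect recovery runs 1 subject × 6 electrodes × 40 trials per task
at 500 Hz with 16 s stages (the 15 s analysis span plus margin). Structure
recovery runs 10 subjects × 4 electrodes × 4 trials per task, with
task-specific theta and subsystem-specific gamma trajectories, and B = 1000
bootstrap replicates. Calibration uses 500 null replicates of a reduced
nested design (6 subjects × 2 electrodes × 8 observations). The stimulation
pattern uses 9 subjects, a −0.03 originality decrement in block 2 (AUT
only), and is judged on the majority pattern across replicates. These sizes
are the package's chosen defaults for its own verification runs.

## Known limitations

* The generator's carriers are coherent within a probe (shared sweep);
  cross-channel coherence is therefore unrealistically high.
* Percent-change bias of short noisy baselines is a property of the
  *method*; the generator is designed so it vanishes, which means the
  pipeline's sensitivity to it on real data is not measured here.
* The point-cloud network assignment approximates surface-based atlas
  lookup; coordinates must already share the parcellation's space.
* Degrees-of-freedom corrections (Satterthwaite/Kenward–Roger) are not
  implemented; post hoc inference uses the z approximation.
* Originality/variability/flexibility values are embedding-backend-relative;
  only within-backend contrasts are meaningful.
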