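# Methods

## Data model

A recording is a pair of timed record streams: sensor activations
(`sensor_id`, start, end) and activity annotations (label, start, end),
both at second resolution with timezone-naive local timestamps. The
timeline from `t0` to `t1` is discretized into half-open slices
`[t, t+Δt)` with 0-based indices; a trailing partial slice is dropped, so
`T = floor((t1−t0)/Δt)`. A slice's sensor bit is set iff an activation
overlaps the slice by at least one second. The slice's label is the
annotation with the greatest temporal overlap, ties broken by the earlier
interval start; slices touched by no annotation get the explicit idle
class, which is always `class_names[0]`, participates in training and is
scored like any other class. Labels are 1-based (`y ∈ {1..Q}`).

Days are cut midnight-to-midnight and treated as independent sequences
everywhere: the initial distribution applies at each day's first slice, no
transition is counted across a day boundary, and cross-validation folds
are whole days.

## Feature representations

Three binary encodings of the `T×N` slice matrix, used standalone or
concatenated column-wise (seven combinations): *raw* (the matrix as
observed), *change point* (1 where a sensor differs from the previous
slice; row 0 is compared against an implicit all-zero pre-stream state, so
a stream that starts active registers a change at t=0), and *last sensor*
(1 on the sensor(s) whose most recent state change is the latest at or
before the slice; all sensors changing in the same most-recent slice carry
1, because sub-slice ordering is unobservable at slice granularity;
all-zero before the first change).

## Estimation and decoding

Training data are fully labeled, so HMM parameters are smoothed relative
frequencies with pseudocount α (default 1, Laplace): π from state
occupancy over all slices, A from within-day consecutive pairs, Bernoulli
means μ from per-state feature averages (α in the numerator, 2α in the
denominator). With α=0, a class absent from the labels is an error; a
state with no outgoing transitions (possible only at day ends) falls back
to a uniform row.

All decoding is in log space. Probabilities are floored at ε = 10⁻¹² before
logs, so emission scores stay finite even for degenerate μ ∈ {0,1};
Viterbi ties break toward the lowest state index, making every decode
deterministic. There is no Baum–Welch and no forward–backward smoothing:
decoding is maximum-a-posteriori path search only.

## Emitters and the scaled-likelihood conversion

The hybrid recognizers draw emission scores from a classifier posterior
via `log p(y|x) − log p(y)`; the observation marginal p(x) is dropped as
state-constant. Priors are training-label frequencies, floored at ε and
renormalized so absent classes cannot produce infinities.

*MLP*: one hidden layer, width 2× the feature count by default, trained by
back-propagation on cross-entropy with a softmax output layer
(scikit-learn `MLPClassifier`), 500 epochs by default. Early stopping on a
held-out 10% is available but **off** by default: the monitored quantity
is held-out accuracy, which under this domain's imbalance saturates once
the dominant classes are learned — training then stops long before the
rare classes are fitted, and rare classes carry half the weight of every
macro metric (switching it off raised held-out macro F from ≈0.31 to
≈0.41 on a typical fold).

*SVM*: RBF kernel K(x,y) = exp(−|x−y|²/(2σ²)) with σ chosen by the median
heuristic on pairwise training distances (500-point seeded subsample) and
cost C = 1 unless configured. The multiclass problem is reduced to binary
subproblems: one-vs-rest by default (Q sigmoid outputs renormalized to sum
to 1), one-vs-one optionally (pairwise win probabilities averaged per
class, then renormalized). Each subproblem's decision values are mapped to
probabilities by a Platt sigmoid `p = 1/(1+exp(−(a·s+b)))` — the standard
two-parameter form, equivalent up to reparameterization to the
`1/(1+A·exp(−s+B))` form — fitted by L-BFGS on the regularized negative
log-likelihood with Platt's smoothed targets (N₊+1)/(N₊+2) and 1/(N₋+2).
Calibration scores are pooled from a 3-fold stratified cross-validation
over the training slices so the sigmoid is not fitted on optimistically
separable scores; when a side of a subproblem has fewer than 3 examples
the pool degrades to full-fit decision values rather than failing on rare
classes. A posterior row whose sigmoids are all numerically zero becomes
uniform, with a warning.

Any object with `posteriors(feat) -> PosteriorMatrix` and `class_names`
serves as an emitter, so external classifiers (decision trees, k-NN, …)
plug into the hybrid and the evaluation harness unchanged.

## Hybrid training

Default training is a single supervised pass: π/A from label frequencies,
one emitter fit on all training slices, priors from the labels. Because
the labels are complete, this pass is well-defined and deterministic given
the seed. An optional EM-like *realignment* loop is provided for the
iterative reading of the training procedure: decode the training days with
the current model, refit the emitter on the decoded labels, stop when the
decoded paths are unchanged (exact equality) or after `max_iterations`.
π/A stay at their label-frequency estimates during realignment unless
`reestimate_transitions` is set; a realignment that collapses the labels
to a single class aborts with a warning and keeps the pre-collapse model.
`emitter_subsample=k` fits the classifier on every k-th slice (dynamics
and priors always use all slices) — a standard thinning for
kernel-classifier scalability on long recordings.

## Evaluation

Macro precision and recall average per-class ratios over **all** Q
classes; the F-measure is the harmonic mean of these two aggregates, not
the mean of per-class F. Empty-denominator rule (stated prominently
because it changes averages): a class never predicted contributes 0 to the
precision average, a class never true contributes 0 to the recall average,
and the class still counts in Q. Leave-one-day-out reports the unweighted
mean ± sd over folds. The paired t-test is two-tailed on fold differences;
the Wilcoxon statistic is min(W₊, W₋) with zero differences dropped, exact
null distribution for n ≤ 25 and the normal approximation beyond.
Degenerate cases are flagged rather than silently propagated: identical
score vectors report p = 1, a constant nonzero difference reports a
divergent t as a strong rejection.

## Simulator

The generator emulates what matters statistically in a single-resident
deployment: a semi-Markov activity schedule (dwell ~ geometric with the
configured mean, matching first-order HMM assumptions; an optional
lognormal mode violates them deliberately), hour-of-day entry weights,
activity-conditional per-slice Bernoulli sensor firing, and independent
bit-flip noise (default 0.02 per slice-sensor, a realistic error rate for
reed/PIR hardware). Contiguous firing slices are merged into events and
non-idle label runs into annotations, so discretizing the generated
streams reproduces the truth grid bit-exactly — the round trip is tested.
Draw order is fixed (schedule, then firing, then noise) from a single
seeded generator, so fixtures regenerate exactly from (config, seed).

The packaged default home (`small_home`, also shipped as
`configs/small_home.yaml`) has 8 activities including idle, 12 sensors and
14 days at Δt = 60 s, sized like the smaller published deployments, and
produces their characteristic imbalance (sleeping ≈ 35–55%, several
activities < 1%). Breakfast and lunch intentionally share nearly the same
kitchen-sensor signature: per-slice classifiers confuse them, temporal
context disambiguates — the mechanism behind the hybrid's advantage.

What the simulator does **not** model: multi-resident interleaving, sensor
dropout/failure, long-range (non-Markov) routine structure, and
annotation noise. Passing tests therefore demonstrate correctness of the
method and the direction of the hybrid-vs-static comparison under the
stated generative assumptions, not performance figures transferable to any
real home.

## Problem sizes

The directional replication (hybrid ≥ static macro F for both emitter
kinds) runs 20 independently simulated homes of 5 days at Δt = 120 s with
default noise, leave-one-day-out throughout — about 100 folds per model.
The acceptance script runs the same comparison at 10 replicates, plus the
slice-count arithmetic of the published durations, a 200-instance
exhaustive-enumeration check of the decoder, and parameter recovery from
20,000 sampled slices (max-abs error on A and μ, threshold 0.02). These
sizes are the package's chosen desk-scale defaults; the simulator itself
defaults to the full 14-day, 60-second configuration.

## Known limitations

Posterior-based emitters are only as calibrated as their training folds;
with very few examples of a class, Platt calibration degrades to full-fit
scores and can be overconfident. The one-vs-one coupling is a simple
vote-weighted average, not Hastie–Tibshirani iterative coupling. The
sliding-window comparators from the broader literature (C4.5, Ripper,
k-NN) are not implemented; they can be plugged in through the emitter
protocol.
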