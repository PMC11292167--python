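# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Preprocessing

Raw sessions are multirate: triaxial acceleration at 32 Hz, blood volume
pulse at 64 Hz, electrodermal activity (EDA) and skin temperature at 4 Hz,
heart rate at 1 Hz, interbeat intervals as an event stream. All statuses are
decided at 1-second resolution on the EDA/TEMP clock and broadcast to the
other channels by time interval, using 0-based half-open second intervals
[s, s+1).

**Off-body rule.** A second is off-body iff any EDA sample in it is below
0.05 µS (lost skin contact), above the 100 µS sensor range, or any
temperature sample lies outside the physiological 30–40 °C band.
Flagged-missing (NaN) samples also mark their second off-body: a sample we
cannot trust cannot prove skin contact. On-body runs shorter than 5 minutes
are relabeled off-body ("at least 5 minutes" is inclusive: a 300 s run
survives); the operation is idempotent.

**Sleep/wake.** The arm angle atan(z̄/√(x̄²+ȳ²)), computed on 5-s epoch
medians of the acceleration axes, defines stillness: a maximal run of epochs
in which no successive-epoch change exceeds 5°, lasting at least 300 s, is
sleep; everything else on-body is wake. Two deliberate choices: (i) an epoch
containing any off-body second breaks a still run — off-body data are
untrustworthy, so sleep never bridges a gap; (ii) the pipeline order is
off-body → minimum-wear-run → sleep scoring. A zero-gravity-norm epoch gets
angle 0°.

**Segmentation.** Each maximal wake span of length L ≥ ω yields
⌊(L−ω)/Δω⌋+1 segments at offsets span_start + kΔω. Library defaults are
ω = 512 s, Δω = 128 s; tests and examples run ω = 64 s, Δω = 32 s so the
full stack exercises in seconds rather than minutes. Segments never straddle
non-wake seconds and inherit the session label.

**Standardization.** Per-channel mean and population SD (divide by n) are
fitted on designated data only — the target training split, or for
self-supervision its union with unlabeled data — and applied as
(x−mean)/max(SD, ε) with ε = 10⁻⁸ guarding constant channels (which are
flagged degenerate and map to zero).

## Handcrafted features

For classical baselines each raw segment yields one row of 35 named
features: per acceleration axis and magnitude — mean, SD, min, max, energy
and entropy; EDA tonic/phasic mean and SD plus a phasic peak count; HRV from
interbeat events inside the window — mean NN, SDNN, RMSSD, pNN50; and
temperature mean and SD. The definitions are frozen and self-contained:
energy is the mean squared amplitude; entropy is the Shannon entropy (nats)
of a 16-bin value histogram (0 for a constant signal); the tonic component
is a zero-phase second-order Butterworth low-pass at 0.05 Hz, phasic its
residual, with peaks counted above 0.01 µS prominence; pNN50 uses the
standard 50 ms threshold; SDNN/RMSSD use population statistics. Fewer than
two interbeat intervals in a window flag the HRV block missing. Missing
cells are mean-imputed from training rows only; a column entirely missing in
the fitting rows imputes 0 with a warning.

## Pretext tasks

**Masked prediction.** Per channel, a Boolean mask is built from alternating
runs with geometric lengths on support {1, 2, …} (success probability
1/mean): masked runs have mean l₀, unmasked runs mean l₁ = l₀(1−r)/r, and
the first run is masked with probability r, which makes the stationary
masked fraction exactly r. Defaults are r = 0.15 and l₀ = 3 s; l₀ is
specified in seconds and converted through each channel's rate, so a 3 s
run is 96 samples at 32 Hz but 192 at 64 Hz. Masked positions are set to
zero and the objective is the RMSE over masked positions only; an empty mask
makes the loss undefined and is rejected.

**Transformation prediction.** One of six kinds is drawn iid uniform per
channel and applied to the standardized signal (so noise scale is in SD
units): identity (bit-exact pass-through); Gaussian noise with σ = 0.1;
magnitude warping by a cubic-spline envelope with 4 interior knots of SD
0.2 around 1; permutation of 4 equal blocks; time warping by a cubic-spline
time remap (same knot parameters, increments clipped positive, resampled to
the original length); cropping of a contiguous 50% window stretched back by
linear interpolation. All transformations preserve length. The objective is
the channel-average categorical cross-entropy of per-channel 6-way logits;
an uninformed prediction scores exactly ln 6.

## The multirate transformer

Each channel has its own convolutional embedding: a same-padded 1D
convolution with kernel size equal to the channel's sampling rate, GELU,
1D BatchNorm, then max pooling with the rate as kernel and stride — one
token per second, N = ω tokens regardless of rate. Same padding is a
choice (the token-count arithmetic requires it); so is the learned
positional encoding added after channel concatenation and linear projection
to d_model, and mean pooling over tokens before the classification head
(in place of a CLS token). The encoder is a stack of post-norm transformer
layers (feed-forward width 2·d_model, GELU, dropout). Heads: a two-layer
MLP with softmax over {euthymia, acute}; per-channel token-wise linear
reconstruction to the native rate (ω·f_c outputs per channel); a linear
6-way-per-channel transformation head on the pooled representation.
Classification minimizes cross-entropy on the two-class softmax, which for
two classes is the binary cross-entropy on the positive-class probability.

Transfer: linear readout (LR) freezes the encoder — its parameters leave the
optimizer and its BatchNorm layers stay in eval mode, so encoder outputs are
bit-identical across target training (frozen BN statistics are a choice; the
alternative of updating them would silently change a "frozen" feature
extractor). Fine-tuning (FT) trains everything from the pretrained
initialization. The pretext head is discarded in both modes.

The network runs on a small reverse-mode autodiff engine written for this
package (numpy arrays, a topologically-sorted tape, custom
convolution/pooling/cross-entropy kernels). Every operation's gradient is
verified against central finite differences in the test suite. The default
tiny configuration (F = 4–8 filters, d_model = 32–64, 2 layers, 4 heads)
trains in seconds per epoch on one CPU; a published-scale configuration is a
matter of the same `ModelConfig` with larger numbers.

## Training and evaluation protocol

Unlabeled recordings split 85:15 into pretraining train/validation by whole
recordings (seeded shuffle; the assignment rule is a package choice). Target
recordings are split 70:15:15 along recording time; a segment survives only
if its whole [start, start+ω) span lies inside one split's window, which
drops border-straddling segments whenever Δω < ω. Classes are balanced by
sorting each class's recordings by segment count, pairing rank-to-rank
(which minimizes the total absolute count difference), and keeping each
pair's first n = min(pair) segments in temporal order.

Optimization uses AdamW (decoupled weight decay) with a reduce-on-plateau
schedule: 10 stale validation epochs multiply the learning rate by 0.3;
when a third reduction would be needed, training stops; the
best-validation checkpoint is returned. Pretext validation losses use a
fixed corruption seed so epochs are compared on identical masks/transform
draws. Library defaults follow the published protocol (batch 256, up to 300
epochs); tests run far smaller budgets.

Metrics: segment accuracy, and subject accuracy by majority vote over each
subject's segments. Ties (even segment counts) go to the class favored by
the subject's mean probability — the vote formula presumes a strict
majority, so the tie-break is a package decision. Subject-level
probabilities are the mean of the subject's segment probabilities;
AUROC/precision/recall/F1 are reported at both levels.

Model comparisons run three tests on paired correct-class probabilities:
a two-tailed paired t test at the segment level; a random-intercept linear
mixed model of the per-segment difference with subjects as the grouping
factor (the response is the difference, testing a zero fixed intercept);
and a two-tailed paired t test on per-subject correct-segment fractions.
Bonferroni correction defaults to 19 tests. A zero-variance difference
(identical or constant-offset models) is flagged degenerate rather than
fitted.

The ablation harness retrains the MP-pretrained, fine-tuned pipeline on a
reduced unlabeled collection — stratified downsampling (keeping at least one
recording per dataset; ratio 0 means the target training set alone) or
leave-one-dataset-out — always keeping the target training set in the
pretraining pool, with the same initialization seed as the reference run so
the measured Δ isolates the data effect. The package also bundles the
published ablation summary tables and the Pearson-correlation analysis over
them (downsampling ratio vs accuracy change, left-out dataset share vs
accuracy change).

## Synthetic cohorts

The generator emulates, per channel, baseline + circadian sinusoid + AR(1)
noise; acceleration as a gravity orientation that changes at posture events
(~every 30 s awake, frozen during sleep) plus white movement bursts; the
pulse signal as a respiration-modulated oscillation at the instantaneous
heart rate; interbeat intervals from the same rate trace. Nonwear bouts are
drawn per hour (or planted explicitly) and produce sub-threshold EDA,
ambient temperature and a flat device; sleep windows freeze the arm angle.
The class effect is parameterized; the default "acute" effect is a +1 µS
EDA shift, 50% extra movement amplitude, and +5 bpm heart rate — large by
design, so end-to-end recovery is a property of the pipeline rather than of
a marginal effect size.

What the generator deliberately does **not** emulate: stable inter-individual
baseline differences (off by default, available via `subject_jitter`).
Under a time-split protocol the same subjects appear in training and test,
so subject-identifiable baselines would let a classifier predict a
subject's constant label from identity rather than state; with them off,
labels are exchangeable under a null class effect and the end-to-end
chance-level calibration test is meaningful. It also does not model
medication effects, artifacts in the pulse waveform, or realistic EDA
response shapes. Passing tests therefore demonstrate that the pipeline's
plumbing, objectives and statistics behave as specified — not that the
classifier's clinical accuracy transfers to real cohorts.

## Test-scale choices and known limitations

End-to-end tests run ω = 64 s windows, 6–16 subjects with 0.6–1 h sessions,
and the tiny model. The chance-level calibration uses many subjects with
short sessions (16 × 0.6 h) so within-subject clustering stays small enough
for the binomial yardstick on segment accuracy to be adequate.

For the pretraining-vs-scratch comparison, the planted class effect is easy
enough that supervised training from scratch saturates quickly; a converged
linear probe shows pretrained and randomly initialized encoders both encode
the class perfectly at this scale, i.e. desk-scale masked-prediction
pretraining neither adds nor destroys class information — it mainly changes
optimization trajectories. The comparison is therefore run at a matched
supervised budget at which both runs converge (12 epochs on a quarter of the
labeled segments, pretraining seeing all of them, both runs sharing one
initialization seed), where fine-tuning matches from-scratch accuracy. A
genuine pretraining *advantage* is a property of hard tasks and large
unlabeled corpora, which desk-scale synthetic data cannot represent.

Other limitations: the autodiff engine is minimal by design (no GPU, no
operator fusion); the masked-run sampler truncates the final run at the
segment boundary, which biases run-length statistics only at the ~0.1%
level for realistic segment lengths; the mixed model is fitted by REML via
statsmodels and can warn on degenerate between-subject variance, which the
comparison reports rather than hides.
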