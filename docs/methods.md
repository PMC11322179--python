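# Methods

## Signal model and pipeline

The unit of processing is a length-N real frame x cut from one EEG channel.
Acquisition is linear: y = Φx with an M×N sensing matrix, M < N, shared by
every frame of an experiment (one fixed matrix per compression ratio
CR = M/N). Reconstruction is non-iterative: the measurement is
back-projected with the Moore–Penrose pseudo-inverse, x̃ = Φ†y — this is the
orthogonal projection of x onto the row space of Φ, so it already carries
all the information in y at the signal's native length — then standardized
per frame to r = (x̃ − μ)/σ (population standard deviation), and finally
decoded by the trained network, x̂ = H(r). Frames whose proxy is constant
(σ below 1e-8) cannot be standardized; they are skipped and counted.

The z-scoring subtracts the per-frame mean; only subtraction yields the
defining property of the transform (mean 0, standard deviation 1), so that
is what the implementation does and asserts.

## Sensing matrices

* `gaussian`: i.i.d. Normal(0, 1/M) entries, so expected squared column
  norms are 1, the normalization under which restricted-isometry statements
  are made.
* `sparse_binary` (default): 0/1 entries with exactly 4 ones per column at
  uniformly drawn distinct rows. Fixing the per-column count — rather than
  an overall density — guarantees every sample is sensed. The count 4 is
  configurable; hardware-oriented CS favours such matrices because each
  measurement is an integer sum.

The pseudo-inverse is computed by SVD with singular-value cutoff
`max(M, N) · eps` relative to the largest singular value, which remains
stable for occasionally rank-deficient sparse-binary draws. The four
Penrose identities are verified to 1e-8 relative in the tests.

## CS-ResNet architecture

Stem: 1→16 channels, kernel 3. Two residual blocks, each six dilated
conv + ELU layers with channels 32, 64, 128, 64, 32, 16 and kernels
7, 7, 5, 5, 3, 3; the block output is F(x) + x. Head: 16→1 channels,
kernel 3, linear. Output: dense N→N. All convolutions use dilation 2,
stride 1 and symmetric zero-padding p = d(h−1)/2, so every feature map
keeps length N; the effective window of a dilated kernel is
h′ = h + (h−1)(d−1), and the cumulative receptive field of the default
stack is 105 samples.

Design points that were genuinely open, and how they were fixed:

* Dilation of the stem and head convolutions: set to 2, uniformly with the
  residual layers, since all layers are described as dilated.
* No activation after the head convolution and a linear dense output:
  the task is regression to signed signal values.
* No nonlinearity after the skip addition; the residual sum is passed on
  as-is (with zeroed branch weights each block is therefore an exact
  identity, which the tests assert).
* ELU α = 1.
* Weight initialization: variance-scaling (fan-in) uniform,
  limit √(3/fan_in), drawn from a single seeded generator so a model is
  bit-reproducible from `init_seed`.
* The dense layer maps the length-N single-channel feature map to the
  length-N output; input and output lengths must both be N.

The network is implemented directly in NumPy: convolutions run as
im2col + BLAS matrix products, and the backward pass is hand-derived
(validated against finite differences in development). This keeps the
package free of deep-learning framework dependencies and deterministic on a
single thread.

## Training

Pairs (r, x) use the raw, un-normalized frame as the label. The loss is the
mean over frames of squared l2 error — N times the per-element MSE — and is
minimized with Adam (lr 0.001, batch 64, β = (0.9, 0.999), ε = 1e-8) on
shuffled mini-batches. The epoch budget, stopping rule and validation
handling are not fixed by the problem statement, so the package defaults
to: at most 100 epochs, a seeded 10% validation carve-out from the training
pairs, early stopping after 10 epochs without validation improvement, and
restoration of the best-validation weights. An optional flag standardizes
targets as well; it is off by default because the raw-label formulation is
the definitional one.

`CSResNetModel.fit()` wraps this loop in an estimator/results interface:
the returned results object carries the trained network, per-epoch losses,
`summary()`, `reconstruct()`/`reconstruct_measurements()`, per-frame PRD,
and plotting of the loss history and reconstructions.

## Classical baselines

OMP and CoSaMP operate on the dictionary Θ = ΦΨ with Ψ an orthonormal
DCT-II basis by default (identity basis available for exactly-sparse
synthetic tests). Default sparsity for non-sparse EEG frames is
K = round(0.1·N), configurable and echoed in outputs. Least-squares
sub-problems use `numpy.linalg.lstsq`; atom selection breaks exact ties
toward the lowest index, making runs deterministic. A brute-force l0 oracle
enumerates all supports up to size K when C(N, K) ≤ 10,000 and anchors the
optimality ordering tests (oracle ≤ OMP ≤ ‖y‖). `empirical_rip` measures
the worst isometry deviation over enumerated (or sampled) K-column
submatrices.

## Synthetic EEG generator

Each channel is a sum of one sinusoid per rhythm band — delta 0.5–4 Hz,
theta 4–8 Hz, alpha 8–13 Hz, beta 13–30 Hz — with frequency, amplitude and
phase drawn per channel under one seed, plus pink noise (white Gaussian
noise shaped by 1/√f in the rFFT domain, DC forced to 0, rescaled to unit
std) and an optional residual 50 Hz line component. Default amplitude
ranges are plausible awake scalp-EEG magnitudes in microvolts: delta 20–40,
theta 10–20, alpha 15–30, beta 5–10, pink noise scale 5, line amplitude 1
(acquisition chains notch-filter the mains, leaving a small residue).
The sampling rate must exceed twice the highest band edge.

The generator reproduces the statistical features that matter for
compression experiments — band-limited spectra, 1/f background, fixed frame
grid — and deliberately omits event-related potentials, artifacts,
inter-channel correlation and nonstationarity. Passing tests therefore
demonstrate the pipeline's correctness and the learnability of the
reconstruction map on band-limited signals, not clinical-grade performance
on real recordings.

Framing cuts each channel into consecutive non-overlapping length-N
windows from sample 0, discarding a trailing partial window (all frames
must share one N, hence one Φ). The train/test split pools all channels'
frames and partitions them at random (80/20 by default, seeded,
|train| = round(fraction·total)); subject- or channel-wise splitting is not
modeled.

## Evaluation protocol

PRD = 100·‖x̂ − x‖₂/‖x‖₂ with the l2 norm in both numerator and
denominator; it is scale-invariant and equals 100 for the zero
reconstruction. Sweep cells report the arithmetic mean and population
standard deviation of per-frame PRD over the test set, the frame count and
informational per-frame wall time (never asserted — timing is
hardware-dependent). A failing method marks its cell failed without
aborting the sweep. Reports round-trip through CSV + JSON sidecar.

## Problem sizes for routine verification

The full-scale protocol (N = 500, 1,200 frames, CRs 10–90%) is what the
method targets, but training at that scale is a multi-hour job. Routine
verification — the end-to-end tests and `scripts/acceptance.py` — uses one
fixed scaled protocol chosen once: the same generator, 250 Hz rate,
sparse-binary sensing and 80/20 split, with 0.512-s frames (N = 128), a
4-channel 96-s recording (750 frames), and at most 30 training epochs.
At this scale one training run takes a few minutes on one CPU. The
learning gates assert directions, not absolute errors: the trained network
beats pseudo-inverse back-projection at CR = 0.5, and its PRD at CR = 0.8
is below that at CR = 0.2. Absolute PRD values at this training budget are
optimization-limited (the network is still converging after 30 epochs), so
they overstate the error achievable with full-scale training.

## Numerical choices and degenerate inputs

* Population (divide-by-N) standard deviation throughout the z-scoring.
* σ floor 1e-8 marks a frame degenerate.
* Matrix factories reject M ≥ N (no compression); the matrix container
  tolerates square test-only operators (e.g. identity at CR = 1) used in
  the lossless-limit tests.
* Split sizes use round-half-up; both split sides are kept non-empty.
* OMP stops on K atoms or residual ≤ tol·‖y‖ (tol 1e-10); CoSaMP returns
  its best iterate by residual norm with a 50-iteration cap.
* Training aborts with a diagnostic exception on a non-finite loss.

## Known limitations

* Synthetic EEG only; GDF/EDF readers for competition datasets are out of
  scope, so benchmark error tables on those datasets are not reproduced
  here.
* One network per compression ratio; no joint multi-CR model, no
  multi-channel joint reconstruction, no quantization of measurements.
* l1/basis-pursuit and Bayesian recovery families are not benchmarked; the
  sweep accepts user-plugged reconstructors instead.
* Wall-clock numbers are informational; no timing claims are tested.
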