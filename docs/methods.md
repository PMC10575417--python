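# Methods

`uctnet` reproduces, end to end and from first principles, a learned
full-waveform-inversion surrogate for transcranial ultrasound computed
tomography: acoustic waves are propagated through a head phantom with an
embedded clot, the recorded wavefields are reduced to a single-frequency
source–receiver amplitude matrix, and a small fully convolutional network is
trained to map that matrix directly to the velocity image. This note records
the models, the numerical choices, and the places where the design was
genuinely open.

## Phantom model

The head is modelled as three nested homogeneous regions on a regular grid:
water outside (1480 m/s, 1000 kg/m³), an elliptical/ellipsoidal skull shell
(2618 m/s — the measured velocity of the cured-resin skull replica — and
1900 kg/m³), and soft tissue inside (1540 m/s, 1040 kg/m³). A clot is a
uniform disc (2D) or sphere (3D) at 1700 m/s placed uniformly at random
wherever it fits entirely inside the tissue; its radius is drawn uniformly
from a configured range (9–15 mm at head scale). Tissue and water velocities
and all densities are editorial: the reference experiments state only the
skull and clot velocities, so standard textbook values for water and brain
tissue are used and are overridable in `PhantomSpec`.

Cell membership is by cell center (no anti-aliasing): cell `i` sits at
`(i + 0.5) * spacing` mm and belongs to a shape iff its center is inside.
This makes phantom construction exactly reproducible integer geometry.
Sensors are snapped to cell centers on a ring (2D) or stacked rings at
10 mm layer pitch (3D) in the water gap just outside the skull.

What the generator does **not** emulate: anatomical brain substructure,
acoustic attenuation, elastic (shear) wave conversion in the skull, sensor
directivity and electronics noise. Passing tests therefore demonstrate that
the pipeline recovers inclusions under idealized lossless acoustics, not
performance on in vivo data.

## Forward solver

The variable-density acoustic wave equation
`rho div((1/rho) grad p) = (1/c^2) p_tt`
is integrated by an explicit leapfrog scheme (2nd-order time, 2nd- or
4th-order space) on a collocated grid. Buoyancy `1/rho` is averaged onto
cell faces (arithmetic mean of buoyancy = harmonic mean of density), which
keeps the discrete operator symmetric; source–receiver reciprocity of the
recorded traces is a test, not an assumption. A `constant_density` switch
drops the density terms and uses the plain Laplacian.

Numerical choices:

* **Time step.** `dt = safety * h / (c_max * sqrt(ndim))` with safety 0.6 by
  default (the 4th-order stencil tightens the bound by `sqrt(3/4)`).
* **Source.** Zero-phase Ricker pulse, peak-normalized, injected additively
  at the source cell scaled by `dt^2 c^2 / h^2` — a conventional monopole.
  Excitation frequency defaults to 700 kHz.
* **Boundaries.** An exponential (Cerjan-style) sponge taper of configurable
  width multiplies the two live time levels each step. Default 20 cells with
  strength 0.015; small grids use a thinner, stronger taper.
* **Record length.** `max(0.2 ms, 2.5x` the longest straight-ray traversal
  at the slowest velocity`)`. Each shot starts from a zero field, so
  consecutive excitations cannot contaminate each other — the 0.2 ms
  inter-record separation requirement is satisfied by construction.
* **Receivers.** Nearest-cell pressure every time step, no interpolation.

Verification: in a homogeneous 3D medium the monochromatic trace amplitude
must follow the analytic free-space Green's function `exp(ikR)/(4 pi R)`
(log-log slope −1 ± 0.05 vs range), arrival times must match `R/c` plus the
wavelet delay within two time steps, traces must be reciprocal under
source–receiver exchange to < 1 % relative L2 in heterogeneous media, and
trace misfit against a fine-grid reference must decrease monotonically under
grid refinement. Peak-amplitude (broadband) measures decay slightly faster
than 1/R because grid dispersion spreads the pulse; the monochromatic
amplitude is the quantity the Green's function fixes.

## Feature matrices

Each trace is Fourier transformed; the magnitude at the DFT bin nearest the
characteristic frequency (default: the excitation center frequency) forms
entry (source, receiver) of an N×N matrix, which is then divided by its own
maximum so that amplitudes are relative and the maximum is exactly 1. The
divisor is recorded. Per-sample normalization (rather than one global
divisor across the dataset) was chosen so that overall source strength —
which carries no anatomical information — can never leak into the input;
the recorded divisor keeps the alternative recoverable. Phase is discarded.
A single frequency is used by default; a list of frequencies can be stacked
as channels.

## Reconstruction network

Input layer (the N×N normalized matrix), four hidden convolution layers
(same-padded cross-correlation + leaky ReLU, slope 0.01), one non-overlapping
max-pool, a deterministic bilinear resize to the output (x, y) extent, and a
convolutional output head with one kernel per output z-slice (one kernel for
2D) and no activation. Training minimizes mean squared error on min–max
normalized velocity (bounds taken over the training labels and stored with
the model) using Adam (defaults 1e-3, betas 0.9/0.999), batch size 8, at
most 5000 epochs, early stopping after 500 epochs without validation
improvement, returning the weights of the best validation epoch — the
published protocol. Everything is seeded: builder, shuffling, and splits
(`0.6:0.2:0.2` with train = floor, validation = ceil of the remainder's
half; 700 → 420/140/140, 401 → 240/81/80).

Open-design choices:

* **Hidden widths/kernels** are not recoverable from the reference
  description beyond "start small, approach the output size"; defaults are
  (32, 9×9) → (64, 7×7) → pool 2×2 → (64, 5×5) → (32, 3×3) → resize →
  output 3×3, all configurable.
* **Resize position.** With many sensors the pooled grid is finer than the
  output and the resize is a mild downsample before the head. With few
  sensors (desk scale) the pooled grid is much coarser than the output; a
  resize placed last would leave only one linear layer at output resolution,
  which cannot render the sharp skull ring. `resize_after` therefore allows
  the resize to run earlier so later hidden layers operate at output
  resolution; the desk-scale preset resizes immediately after the pool.
* **Weight initialization.** The published protocol draws initial weights
  uniformly from (0, 1). That all-positive initialization is implemented and
  is the builder default, but it produces outputs ~1e10 above the target
  scale and does not recover within a desk-scale epoch budget, so the
  desk-scale preset uses the conventional symmetric fan-in-scaled
  alternative (`weight_init="scaled"`).
* **Early-stop monitor.** Validation MSE drives both patience and best-model
  selection (train-loss monitoring is the other defensible reading of the
  protocol; validation monitoring is standard practice and matches how both
  losses are reported).

The convolution/pool/loss semantics are exposed as simple reference
functions (`conv2d_ref`, `max_pool`, `mse_loss`) which the batched im2col
training path must match exactly (integer inputs) or to 1e-12 (floats) —
this equivalence is part of the test suite, alongside a finite-difference
gradient check of the backpropagation.

## Evaluation

Pearson correlation between the true and reconstructed velocity maps over
all cells is the headline score, aggregated as mean/best and in three
clot-diameter bins (the published statistics use diameter bins 16–20,
21–26, > 26 mm; on other diameter ranges the same three-bin structure spans
the observed diameters). Whole-image PC is partly carried by the static
skull/water background, so two supplementary metrics are reported: PC
restricted to the tissue interior, and a clot-localization error — the
distance from the true clot center to the centroid of tissue cells whose
predicted velocity deviates from tissue background by more than half the
clot contrast. Both extras are clearly labelled as additions. Diameters on
bin edges go to the lower bin; per-sample failures (e.g. degenerate
constant maps) are flagged and do not abort the batch.

## Desk-scale study conditions

The default end-to-end experiment (also what `scripts/acceptance.py` runs)
is a 1/5-scale 2D study chosen to finish in minutes on one CPU:

| quantity | value |
| --- | --- |
| grid | 48 × 48 at 1 mm |
| skull | outer semi-axes (18, 16) mm, shell 3 mm |
| clot | radius 2.0–3.5 mm, 1700 m/s |
| sensors | 16, ring, 2 mm outside the skull |
| excitation | 300 kHz Ricker (~5 cells per water wavelength) |
| record | 0.2 ms, dt ≈ 0.162 µs (CFL 0.6) |
| samples | 120, split 72/25/23 |
| training | batch 8, ≤ 1500 epochs, patience 500, Adam 3e-3, scaled init |

The 700 kHz head-scale excitation would be sampled at only ~2 cells per
wavelength on this grid, far below accepted finite-difference practice, so
the scaled study excites at 300 kHz and extracts features there; the
wavelet default everywhere else remains 700 kHz. The full-scale geometry
(480 × 440 × 200 half-mm cells, 512 sensors, 240 × 200 × 100 output with
100 output kernels) is accepted structurally by every API and covered by
shape-level tests, but is not simulated by default.

## Known limitations

* The all-positive published weight initialization is faithful but
  untrainable at desk scale (see above); conclusions about it at full scale
  cannot be drawn from this implementation.
* Whole-image PC saturates near 1 even for reconstructions that miss the
  clot entirely, because the static background dominates the image variance.
  The clot-region PC and centroid error are the discriminating metrics.
* At the desk scale the network converges to a near-perfect static
  background but recovers little of the clot itself within the 1500-epoch
  budget: a 2–3.5 mm clot modulates the normalized feature matrix by only
  ~0.2 %, and train-set clot-region PC stays as low as test-set clot-region
  PC — an optimization limit, not a generalization gap. Consequences: the
  whole-image PC *decreases* slightly with clot size (an unlearned larger
  clot leaves more unexplained variance), and the centroid detector (which
  requires the predicted deviation to exceed half the clot contrast) finds
  no clot. Wider networks, higher learning rates and multi-frequency feature
  channels were evaluated and do not change this within the epoch budget;
  the corresponding acceptance checks are expected to fail at this scale
  and are kept strict rather than weakened.
* The solver is acoustic and lossless: no attenuation, no shear conversion,
  no PML (a sponge taper is used), no adjoint/gradient machinery.
* 2D simulations carry the usual cylindrical-spreading physics (amplitude
  decay and wake differ from 3D); features are self-consistent within a
  study but not comparable across dimensionalities.
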