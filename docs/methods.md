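# Methods

This note documents the models and procedures implemented in `pseudoavg`:
what the simulator emulates, how frames are registered and averaged, how the
denoiser is trained and applied, how quality and artifact safety are scored,
and where genuinely open design choices were settled.

## Synthetic enface OCTA model

OCTA flow signal is quasi-binary — decorrelation saturates where blood flows
and stays near the noise floor elsewhere — so the ground-truth *perfusion
map* is kept bimodal: vessel pixels carry intensities ≥ 0.45, non-vessel
residue is suppressed below ~0.19, and the global **vessel threshold 0.35**
makes the truth mask `vessel_mask = perfusion ≥ 0.35` an unambiguous
flow/no-flow partition. Geometry per eye (all seeded, all pure functions of
their parameters):

* **Vessel trees** — 3–5 trunks started on the image border walk toward the
  FAZ with angle jitter (σ = 0.15 rad per 1.5 px step), branch with
  probability 0.035/step, and decay in width (×0.985/step, branch ×0.7),
  depositing soft-edged disks. This yields a connected arteriole/venule
  hierarchy at trivial cost.
* **Capillary mesh** — the zero-crossing band (|z| < 0.28 σ) of Gaussian-
  smoothed white noise (σ = 1.6 px) forms a closed cellular web resembling
  the parafoveal capillary network; total vessel coverage outside the FAZ
  lands in 20–30% of pixels (checked to stay within 15–45%).
* **FAZ** — a capillary-free disk (radius ~11–15 px at 256 px / 6 mm, i.e.
  0.26–0.35 mm) whose bounding ring is itself vessel-positive, so contour
  continuity is a measurable truth property.
* **Pathology knob** — `healthy` (no lesions), `npdr` (3–8 microaneurysm
  dots, 1–3 elliptical capillary-dropout regions), `pdr` (8–15 and 3–6, plus
  one 20–40° attenuated FAZ-contour arc). Lesion counts and positions are
  recorded in the truth record.

**Noise model** (`render_single_frame`):
`clip(perfusion · (1 + speckle) + background, 0, 1)`, with multiplicative
speckle `N(0, 0.25²)`, additive decorrelation background `N(0.10, 0.05²)`,
then a Poisson(1.0) number of corrupted rows — each either replaced by a
bright line (`N(0.7, 0.15²)`) or shifted horizontally by up to 6 px, equal
odds — and, with probability 0.2, a rectangular shadow patch attenuated
×0.5. The motion-line rate 1.0 was chosen so the fraction of scans carrying
at least one corrupted row (1 − e⁻¹ ≈ 63%) matches the roughly two-thirds share of
scans that show motion artifact in repeated-scan enface cohorts; the remaining defaults are the
package's own calibration of a plausible single-frame appearance
(background σ within 5% of nominal is a tested invariant). Corrupted rows
and the shadow box are returned as annotations.

Repeated stacks draw an independent rigid transform per frame (shifts
U(−8, 8) px, rotations U(−2°, 2°)), warp the phantom, then add independent
noise — so averaging has real registration work to do and true transforms
are available for parameter-recovery tests.

What the simulator does **not** emulate: 3-D retinal structure and slab
projection, optics (PSF), flow-velocity-dependent signal, pulsation, and
spatially correlated speckle. Passing tests therefore show the pipeline's
mechanics are correct under this noise family, not clinical performance.

## Registration and averaging

Rigid model (dx, dy, θ about the image centre), bilinear warps. Estimation
is two-stage: plain (unwhitened) cross-correlation for a subpixel
translation initialisation — phase whitening proved fragile on
speckle-dominated frames with motion lines — then Powell refinement of
(dx, dy, θ) maximising normalised cross-correlation over the valid overlap
of band-passed images (Gaussian 1.5 px minus 12 px). Because warping only
the moving frame smooths it asymmetrically, the fit is run in both
directions and the two estimates averaged, which cancels the first-order
interpolation bias; measured recovery error under default noise is ≤ 0.35 px
and ≤ 0.02° over 100 seeded pairs (the tested bounds are 0.5 px / 0.2°).

Averaging registers every frame to the **best-quality** frame — quality
being mean gradient magnitude over an Otsu-background standard deviation, an
objective stand-in for subjective best-frame selection — and takes the
per-pixel mean over frames whose warped support covers the pixel (the
reference covers everything, so the divisor is ≥ 1 and output shape equals
input shape). Frames that fail to register are excluded; if all fail, the
reference is returned flagged.

## Denoiser

A 5-resolution-level U-Net on 64×64 patches ("5-layer" read as five
encoder/decoder levels, the standard depth reading): per level two 3×3
convolutions + ReLU, 2×2 max-pool down, nearest-neighbour + 3×3 conv up,
skip concatenation, 1×1 head. The output activation is a hard clip to [0, 1]
with a straight-through gradient; a sigmoid head is available but saturates
under the L1 + plain-SGD combination (training stalls in a constant-output
basin). Implementation is pure numpy (channels-last im2col convolutions,
hand-written backward passes), bit-deterministic single-threaded, ~0.5 M
parameters at the desk-scale width 8 (`UNetSpec` defaults to width 16; the
study uses 8, which halves runtime with no measured loss on any cohort
metric at this scale).

**Training pairs.** `single_to_average`: the best frame of each training eye
paired with its registered 4-frame average; rows around residual motion
lines and all shadow boxes are masked **out of the loss only** (inputs stay
intact — the network must see artifacts to learn their removal, it just must
not be told to reproduce them). `peer_to_peer`: an aligned degraded frame
(speckle 0.45, background σ 0.08, forced shadow, and globally attenuated
×0.5 — the whole-scan analogue of a low-signal acquisition) paired with an
artifact-free frame of the same eye. These pairs teach that dim regions
still contain perfusion — the counter-measure to false-negative perfusion
and over-denoising — and, because their targets are artifact-free, they are
also the only supervision for motion-line removal. The study mixes peer
pairs at one per two single-to-average pairs per epoch; with the lighter
1:4 mix and box-shadows only, the trained model still dimmed shadowed
vasculature slightly (≈0.04 mean intensity), so the heavier, globally-dim
mix is the study default (the anti-over-denoising property — shadowed
true-vessel output at least as bright as the input — then holds on every
shadow scan in the test cohort).

**Loss and loop.** Masked L1 (mean absolute difference over valid pixels),
SGD with momentum 0.9, learning rate 0.05 (constant by default; an optional
per-epoch decay exists), batch 32, 20 epochs, one random dihedral
(flip/rot90) variant per pair per epoch (all eight variants per epoch is an
option). Rates above 0.1 collapse to the constant-output solution; 0.05 is
stable. Everything is seeded: identical pairs + config reproduce
bit-identical weights.

## Inference

Full scans are processed as overlapping 64×64 tiles (stride 32), edge tiles
snapped inside the frame so no padding content enters the network, and
predictions blended with a strictly positive cosine² window — overlap
blending is exact for an identity network (max stitching error ~3e-8,
tested) and seam-free for trained ones (tile-boundary differences stay below
the 99th percentile of ordinary local differences). Optionally the output is
moment-matched to its input (affine map equalising mean and std, then
clipped): brightness/contrast is a two-parameter notion, so moment matching
rather than histogram matching, applied per scan.

## Objective evaluation

All metrics score a scan against its phantom's truth:

* **CNR** — (vessel mean − background mean)/background σ on the true masks
  (background excludes a 2 px halo around vessels).
* **Background σ** — standard deviation over true background.
* **Motion index** — mean absolute difference between each annotated row and
  the average of its nearest unannotated neighbours; 0 without annotations.
* **FAZ contour continuity** — fraction of 36 ten-degree bins of the truth
  contour ring whose mean intensity exceeds τ (one clock hour = 3 bins).
* **False-negative perfusion** — any true-vessel connected component
  ≥ 20 px whose mean output intensity falls below τ = 0.15.
* **False-positive perfusion** — any bright component (≥ 0.35) of ≥ 20 px
  lying entirely in true background, excluding a 2 px vessel halo **and**
  annotated motion-line rows ±1: residual line artifact is scored by the
  motion index and must not be double-counted as fictional vasculature
  (clinical grading likewise treats residual line artifact and fictional
  vessels as separate metrics).
  τ = 0.15 and the 20 px minimum are package constants, exposed as
  arguments.
* **Wilcoxon signed-rank** — two-sided, zero differences dropped, average
  ranks on ties; the null distribution of T⁺ is enumerated exactly by
  dynamic programming for n ≤ 25 (matching full 2ⁿ sign enumeration,
  tested), normal approximation with tie correction above; fewer than five
  nonzero differences reports NA. Scan variants are ranked per eye with
  ties allowed (equal metric → equal rank) before pairwise testing.

Cohort reports give the percentage of scans improved per metric; the
motion-reduction denominator counts only scans with at least one annotated
motion row.

## Desk-scale study conditions

The standard study (also what `scripts/acceptance.py` runs): 16 training
eyes and 50 held-out test eyes at 256×256 px, pathology cycling
healthy/npdr/healthy/pdr (≈ 50% with retinopathy-like changes), 4-frame
stacks, 8 peer-to-peer eyes, stride-64 patch lattice (16 patches/eye),
20 epochs. These sizes are the package's chosen desk-scale conditions — a
single-CPU run finishes in about five minutes; training-eye count and image
size are scaled down from a clinical study while keeping the effective
patch-sample structure (the patch lattice, not the eye count, is the
training sample size).

## Numerical and degenerate-input choices

Constant images score quality 0 and are flagged unregistrable (callers fall
back to the identity transform). Zero-variance outputs in moment matching
get a pure mean shift. Max-pool gradient splits equally among exact ties.
CNR is undefined (raises) on zero background variance. All PNG I/O is
16-bit to keep training targets quantisation-free; dataset writes are
byte-reproducible.

## Known limitations

* SGD + masked L1 converges slowly near its floor; an identity-task run
  converges toward zero but does not reach arbitrarily small loss in a few
  epochs (the stitching guarantee is therefore validated with an exact
  identity-weight network, and training gains with the held-out
  masked-L1-vs-identity-baseline comparison).
* Rigid registration only; no affine/deformable motion, no axial (depth)
  registration — enface projections are taken as given.
* The peer-to-peer degraded/clean pairs are rendered, not selected from
  acquisition repeats, so their quality gap is larger and cleaner than a
  clinical picker would produce.
* Artifact detectors rely on simulator annotations (motion rows, truth
  masks); on real data those would have to come from human annotation or
  separate detectors.
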