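# Methods

## Problem and model

Optical-resolution photoacoustic microscopy (OR-PAM) derives its lateral
resolution from a tightly focused laser beam, which limits the depth of
field (DoF): structure away from the focal plane is laterally blurred and
dimmer.  Acquiring the same field of view at several optical focal depths
and fusing the stacks recovers an extended-DoF volume at no hardware cost.
`pamfuse` implements a spatial-domain volumetric fusion chain:

1. **Focus measure.**  Per voxel, the 3D modified Laplacian (ML) — the sum
   over the three axes of the absolute discrete second difference.  Taking
   absolute values before summing prevents curvature of opposite sign
   along orthogonal axes from cancelling.  The volume is tiled into
   non-overlapping cubic blocks of edge `2N+1` and each block's focus
   measure is the sum-modified Laplacian (SML), the ML sum over the block.
2. **Initial decision map (IDM).**  Block-wise comparison of the two
   inputs' SMLs: 1 where input 1 is sharper, 0 where input 2 is, 0.5 on an
   exact tie.  Ties are kept at 0.5 (the fusion then averages); there is
   no randomized tie-breaking anywhere.
3. **Consistency verification.**  A block labelled 1 whose six
   face-adjacent blocks are all labelled 0 is flipped, and vice versa —
   one simultaneous pass over the block grid.  This removes isolated
   misclassifications without moving genuine focus boundaries.
4. **Final decision map (FDM).**  The refined map is smoothed with a
   truncated, window-normalized 3D Gaussian, yielding per-voxel weights in
   [0, 1] that remove block seams.
5. **Fusion.**  `Pf = FDM·P1 + (1−FDM)·P2`, a voxel-wise convex
   combination.  More than two foci are handled by folding adjacent foci
   pairwise in focal-depth order.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| block half-width `N` | 3 (7³ blocks) | voxels | pools enough voxels to suppress noise in the SML comparison while keeping focus boundaries localized to ~14–21 µm at the 2–3 µm voxel pitch |
| ML boundary | replicate | — | zero padding would fabricate edges at the volume faces and inflate SML in boundary blocks |
| verification mode | `unanimous6` | — | the flip rule as stated (all six face neighbours disagree); a `majority6` variant (≥ 4 of 6) is available behind a flag |
| verification passes | 1 | — | a single refinement step; iterating to a fixed point is exposed as an option |
| smoothing σ | 2 | voxels | spans roughly a quarter block at N=3: softens seams without destroying the decision structure |
| smoothing window radius | ceil(3σ) = 6 | voxels | 3σ truncation bounds the dropped Gaussian mass; the normalization is recomputed over the surviving window at volume faces, so constants are preserved exactly |
| input normalization | off | — | amplitudes are assumed commensurate (same instrument, same gain); an opt-in flag divides each input by its own maximum |

Blocks with fewer than six face neighbours are never flipped in
`unanimous6` mode: the rule predicates on six disagreeing neighbours and
acting on partial evidence would erode genuine edges.  Tied (0.5) blocks
are neither flipped nor counted as agreeing neighbours.  Smoothing
operates on voxel indices, not physical µm; both inputs share the same
anisotropy, so the comparison is unaffected (an anisotropic σz option
exists but is off by default).

## Synthetic focal stacks

The simulator emulates a virtual OR-PAM on a 120×120×120 grid with
(2, 2, 3) µm voxels.  Absorbers are capsules (straight tubes for the
tilted-fiber phantom, branch segments for vessel trees) rasterized with a
≤ 1-voxel antialiased edge, distances computed in physical µm so the
anisotropic z pitch is honoured.

Optics: a Gaussian beam with NA 0.14 at λ = 532 nm, giving waist
w0 = λ/(π·NA) ≈ 1.21 µm and Rayleigh range zR = π·w0²/λ ≈ 8.64 µm.  Each
depth plane is convolved with an isotropic 2D Gaussian PSF of standard
deviation w(z)/2 where w(z) = w0·√(1+((z−zf)/zR)²); kernels are truncated
at 4σ and renormalized.  By default each plane is also scaled by the
fluence factor (w0/w(z))², so amplitude — like measured SNR in a real
stack — decays away from the focal plane.  A fixed axial Gaussian blur
(default σ = 2 z-voxels) stands in for the finite detection bandwidth.
Full acoustic propagation is deliberately not modelled: the fusion chain
detects lateral focus/defocus, which the optical beam alone governs.

Noise is i.i.d. zero-mean Gaussian added to the blurred volume with
σn = max(P)/10^(SNR/20) (peak-referenced dB, the common PAM convention).
One RNG seed per simulated volume is derived from
(master seed, focus index) and logged in the manifest.

The fiber diameter is the one geometric knob that sets the single-focus
DoF scale.  The reference protocol tunes it over 4–12 µm (1 µm steps,
first candidate whose mean single-focus DoF lands in 70–80 µm wins); at
the default grid this selects 9 µm.

What the simulator does *not* reproduce: speckle and band-limited
acoustic texture, focal shift in scattering media, registration error
between stacks, and — importantly for the noise results below — the
axial correlation that a 75 MHz/67 % bandwidth detection chain imposes on
real noise.  Passing tests therefore demonstrate the chain's behaviour
under ideal co-registration and voxel-scale white noise, not performance
on tissue data.

## Measurement definitions

**FWHM(z).**  Per depth plane, the lateral line profile through the
structure's centre, perpendicular to the fiber's lateral drift (the
fibers tilt in x–z, so profiles run along y at the trajectory's x
column).  The profile is restricted to ±12 voxels around the known
trajectory centre, half-maximum crossings are linearly interpolated, and
when several crossings exist the outermost ones around the global peak
define the width.  A plane is invalid when the peak falls below 5 % of
the volume maximum or lies more than 3 voxels off the trajectory centre
(the structure was not found).  The windowing and the centre gate were
chosen to keep the crossing search local to the structure under noise;
both are configuration.

**DoF.**  Length (µm) of the maximal contiguous depth interval containing
the focal plane where FWHM(z) ≤ 2·FWHM(zf), with sub-plane linear
interpolation at the interval edges; invalid planes terminate the
interval.  Under fluence weighting the 5 % validity floor, not the
doubling condition, typically terminates the single-focus interval — the
defocused fiber dims below measurability at roughly the same depth scale
(≈ 70 µm) as the paper-reported single-focus DoF values, so the two
mechanisms are not distinguished by this protocol.

**Focus-classification accuracy.**  The FDM thresholded at 0.5 versus
the nearest-focus ground-truth label.  Signal-bearing blocks are those
whose noiseless block signal energy (sum of squared amplitude of the
voxel-wise max over the clean inputs) is ≥ 1 % of the maximum block
energy; a "1 % of peak" restriction is only dimensionally meaningful
energy-to-energy.  A voxel-level variant restricts instead to voxels with
noiseless amplitude ≥ 1 % of peak.

## Reference results (two-focus fiber protocol, defaults)

Computed by `scripts/acceptance.py` and the test suite; problem size
120³, foci at z-planes 40 and 60 (60 µm apart), tuned diameter 9 µm:

- single-focus DoF 72.0 and 72.0 µm, fused 132.0 µm → ratio **1.83**
  (the headline extension factor; ≥ 1.7);
- fused FWHM exceeds the sharper input's by at most 0.19 µm at every
  valid plane (resolution preserved within one 2 µm pitch);
- noiseless focus classification: 94.6 % of voxels in signal-bearing
  blocks; 100 % of signal-bearing voxels once the one-block-wide zone
  around the focus-equidistance plane is excluded.  The shortfall in the
  unrestricted figure is purely geometric: a block-constant decision with
  a deliberately smoothed boundary cannot track the voxel-level truth
  boundary inside the straddling block layer.

## Known limitation: white-noise sensitivity of the SML comparison

The chain is *not* noise-insensitive under voxel-scale white noise at
peak-referenced 15 dB.  Measured at defaults (seed 1): classification
accuracy on signal-bearing blocks is 0.47 at 15 dB, 0.67 at 20 dB, 0.77
at 25 dB, 0.90 at 30 dB.  Two mechanisms drive this:

1. **Rectified-noise bias.**  ML takes absolute second differences, and
   for X ~ N(0, σ²) the increment E|a+X| − |a| shrinks as |a| grows.
   Added noise therefore inflates the SML of the *smoother* (defocused)
   volume more than the focused one's — a systematic bias against the
   correct decision — while block-level noise fluctuations
   (std ≈ 80–115 σn per block at N=3) exceed the clean SML differences of
   most signal blocks at σn = 0.178·peak.
2. **Fluence dimming.**  With (w0/w(z))² weighting, most of the fiber's
   depth extent carries < 10 % of peak amplitude, far below the 15 dB
   noise floor; no block statistic can recover focus ordering there.

Neither mechanism applies with the same force to band-limited noise
(correlated over several voxels, as a real detection chain produces) or
to thick, bright absorbers, which is the regime the original
demonstrations of this class of methods address.  The FWHM-based
measurements degrade for the same reason: at 15 dB the profile floor and
half-max search are noise-dominated outside a ±10-plane neighbourhood of
each focus.  The corresponding acceptance test is left failing by design
rather than weakened; it documents the measured behaviour above.
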