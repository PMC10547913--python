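# pamfuse

Volumetric multi-focus fusion for extended depth-of-field (DoF)
optical-resolution photoacoustic microscopy (OR-PAM).

OR-PAM's tightly focused excitation beam buys micrometre lateral
resolution at the price of a narrow DoF: only a thin slab around the
focal plane is sharp.  `pamfuse` fuses two or more co-registered
photoacoustic volumes acquired at different optical focal depths into a
single volume that is sharp across the union of their focal regions.  It
is aimed at microscopy groups who acquire multi-focus stacks (by moving
the probe or sample axially) and want a cost-free, software-only DoF
extension, plus a simulator to validate the chain without instrument
data.

## Method

For inputs P1, P2 on a common grid the chain is, per voxel (x, y, z):

```
ML(x,y,z) = |2P − P(x−1,·) − P(x+1,·)| + |2P − P(·,y−1,·) − P(·,y+1,·)|
          + |2P − P(·,·,z−1) − P(·,·,z+1)|          (3D modified Laplacian)

SML_i     = Σ_block_i ML                              (block focus measure)

IDM_i     = 1 if SML1_i > SML2_i, 0 if <, 0.5 on tie  (initial decision map)
```

The IDM is refined by consistency verification (a block flips when all
six face-adjacent blocks disagree), smoothed with a normalized truncated
3D Gaussian into the final decision map FDM ∈ [0, 1], and the fused
volume is the voxel-wise convex combination

```
Pf = FDM · P1 + (1 − FDM) · P2.
```

More than two foci are fused by folding adjacent foci pairwise.  The
bundled simulator renders tilted-fiber / vessel phantoms on a 120³ grid
(2×2×3 µm voxels), blurs each depth plane with the depth-dependent
Gaussian-beam PSF (NA 0.14, λ 532 nm: w0 ≈ 1.21 µm, zR ≈ 8.64 µm) and
adds peak-referenced Gaussian noise.  The evaluation suite measures
FWHM-vs-depth profiles, DoF by the FWHM-doubling criterion, depth-resolved
SNR, and the CE / SF / SSIM fusion-quality metrics on maximum amplitude
projections.  See `docs/methods.md` for definitions, defaults and known
limitations.

## Worked example

Simulate the two-focus tilted-fiber protocol (foci at z-planes 40 and 60,
i.e. 60 µm apart), fuse with defaults and evaluate, in one command:

```
$ pamfuse pipeline --phantom fiber --foci 40,60 --snr none --seed 1 --diameter 9
{
  "dof_um": {
    "focus1": 72.0,
    "focus2": 72.0,
    "fused": 132.0
  },
  "dof_ratio": 1.8333333333333333,
  "focus_classification_accuracy": 0.9458892128279883,
  "map_quality": {
    "ce": 0.011853259325664698,
    "sf": 0.02889482884331815,
    "ssim_total": 1.9435015243536666,
    "qcv": "not computed"
  }
}
```

Each single-focus stack resolves the fiber over a 72 µm depth interval
before its lateral FWHM doubles (or the signal dims below the validity
floor); the fused stack stays sharp over 132 µm — a 1.83× DoF extension —
while the decision map picks the truly in-focus input for 94.6 % of the
voxels in signal-bearing blocks.  The low cross entropy (CE), the spatial
frequency (SF) matching the sharper content, and the summed SSIM near its
maximum of 2 say the fused MAP image stays faithful to both sources.

The same steps are available as separate `pamfuse simulate`,
`pamfuse fuse` and `pamfuse evaluate` subcommands for use with on-disk
stacks (multi-page TIFF or raw float32 + JSON sidecar); every run writes
a JSON provenance sidecar with the effective configuration and seeds.

Library use mirrors the CLI:

```python
from pamfuse import fuse_pair, read_volume

p1 = read_volume("focus1.tif")
p2 = read_volume("focus2.tif")
result = fuse_pair(p1, p2)          # result.fused, result.fdm
```

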