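"""Voxel-wise weighted fusion of multi-focus photoacoustic volumes.

Fusing a pair runs the full chain — per-voxel modified Laplacian, block
SML, initial decision map, consistency verification, Gaussian smoothing —
and then blends the inputs voxel-wise under the final decision map:

    Pf(x,y,z) = FDM(x,y,z) * P1(x,y,z) + (1 - FDM(x,y,z)) * P2(x,y,z).

Because FDM lies in [0, 1] the fused value is a convex combination of the
inputs at every voxel.  Background blocks (both SMLs ~ 0) hit the tie
branch and are averaged, which also suppresses uncorrelated noise.

More than two foci are handled by iterative pairwise fusion: adjacent
foci (sorted by focal depth) are combined first and the result folded
into the next focus, repeated until all inputs are consumed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .decision_map import (
    DecisionMap,
    GaussianSmoother,
    build_idm,
    consistency_verification,
    gaussian_smooth,
)
from .focus_measure import volume_sml
from .volume_io import ValidationError, Volume


@dataclass(frozen=True)
class FusionParams:
    """Tunables of the fusion chain (defaults used throughout the package).

    block_n
        Block half-width N; blocks are cubes of edge ``2N+1`` (default 7³).
    ml_boundary
        Padding for the modified Laplacian at volume faces.
    mf_mode / mf_iterations
        Consistency-verification rule and number of passes.
    gf_sigma / gf_radius
        Decision-map smoothing, in voxels (radius ``None`` -> ceil(3σ)).
    normalize_inputs
        Divide each input by its own maximum before fusing (off by default;
        inputs are assumed commensurate).
    fdm_override
        ``"ones"`` / ``"zeros"`` bypass the chain and select one input
        outright — a diagnostic hook, not part of the method.
    """

    block_n: int = 3
    ml_boundary: str = "replicate"
    mf_mode: str = "unanimous6"
    mf_iterations: int = 1
    gf_sigma: float = 2.0
    gf_radius: int | None = None
    normalize_inputs: bool = False
    fdm_override: str | None = None


@dataclass(frozen=True)
class FusionResult:
    fused: Volume
    fdm: DecisionMap
    idm: DecisionMap | None
    refined_idm: DecisionMap | None
    provenance: dict


def _check_compatible(volumes: Sequence[Volume]) -> None:
    ref = volumes[0]
    for i, v in enumerate(volumes[1:], start=2):
        if v.shape != ref.shape:
            raise ValidationError(
                f"input {i} shape {v.shape} does not match input 1 shape {ref.shape}"
            )
        if not np.allclose(v.spacing, ref.spacing):
            raise ValidationError(
                f"input {i} spacing {v.spacing} does not match input 1 "
                f"spacing {ref.spacing}"
            )


def _maybe_normalize(v: Volume, enabled: bool) -> Volume:
    if not enabled:
        return v
    peak = float(np.max(np.abs(v.data)))
    return v if peak == 0 else v.with_data(v.data / peak)


def fuse_pair(
    p1: Volume, p2: Volume, params: FusionParams | None = None
) -> FusionResult:
    """Fuse two co-registered volumes acquired at different focal depths."""
    params = params or FusionParams()
    _check_compatible([p1, p2])
    p1 = _maybe_normalize(p1, params.normalize_inputs)
    p2 = _maybe_normalize(p2, params.normalize_inputs)

    if params.fdm_override is not None:
        if params.fdm_override not in ("ones", "zeros"):
            raise ValidationError(
                f"fdm_override must be 'ones' or 'zeros', got {params.fdm_override!r}"
            )
        w = 1.0 if params.fdm_override == "ones" else 0.0
        fdm = DecisionMap(data=np.full(p1.shape, w), stage="FDM")
        idm = refined = None
    else:
        grid1 = volume_sml(p1, n=params.block_n, boundary=params.ml_boundary)
        grid2 = volume_sml(p2, n=params.block_n, boundary=params.ml_boundary)
        idm = build_idm(grid1, grid2)
        refined = consistency_verification(
            idm, mode=params.mf_mode, iterations=params.mf_iterations
        )
        fdm = gaussian_smooth(
            refined,
            GaussianSmoother(sigma=params.gf_sigma, window_radius=params.gf_radius),
        )

    w = fdm.data
    fused = p1.with_data(w * p1.data + (1.0 - w) * p2.data)
    provenance = {"inputs": ["input_1", "input_2"], "params": asdict(params)}
    return FusionResult(
        fused=fused, fdm=fdm, idm=idm, refined_idm=refined, provenance=provenance
    )


def fuse_multi(
    volumes: Sequence[Volume], params: FusionParams | None = None
) -> FusionResult:
    """Fuse >= 2 volumes supplied in focal-depth order.

    Adjacent foci are combined pairwise left-to-right: the running fused
    volume is folded with the next focus until all inputs are consumed.
    Provenance records the fold order.
    """
    if len(volumes) < 2:
        raise ValidationError(f"fusion needs at least 2 volumes, got {len(volumes)}")
    _check_compatible(volumes)
    result = fuse_pair(volumes[0], volumes[1], params)
    order = [["input_1", "input_2"]]
    for i, v in enumerate(volumes[2:], start=3):
        result = fuse_pair(result.fused, v, params)
        order.append(["fused", f"input_{i}"])
    provenance = dict(result.provenance)
    provenance["inputs"] = [f"input_{i+1}" for i in range(len(volumes))]
    provenance["fold_order"] = order
    return FusionResult(
        fused=result.fused,
        fdm=result.fdm,
        idm=result.idm,
        refined_idm=result.refined_idm,
        provenance=provenance,
    )
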