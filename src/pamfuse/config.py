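"""Run configuration and provenance.

Every tunable of the simulate/fuse/evaluate chain lives in one
:class:`RunConfig` with documented defaults; a serialized config plus the
package version fully determines deterministic outputs.  Configs load
from YAML, CLI flags override file values, and each CLI run echoes the
effective config (with seeds and input digests) into a JSON provenance
sidecar so reports are self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__ as _version

PROVENANCE_SCHEMA = 1


@dataclass
class RunConfig:
    """All tunables with their defaults.

    Fusion: ``block_n`` (block half-width N, blocks of edge 2N+1),
    ``mf_mode``/``mf_iterations`` (consistency verification),
    ``gf_sigma``/``gf_radius`` (decision-map smoothing, voxels),
    ``ml_boundary`` (Laplacian padding), ``normalize_inputs``.

    Simulator: beam NA and wavelength (µm), fluence ``amplitude_weighting``,
    detector-bandwidth ``axial_sigma_voxels``, phantom ``fiber_diameter_um``,
    focal-plane indices ``foci``, noise ``snr_db`` (None = noiseless),
    grid ``shape``/``spacing``.

    Metrics: histogram ``metric_bins``, FWHM validity floor and profile
    window (see :func:`pamfuse.metrics.fwhm_profile`).
    """

    # fusion
    block_n: int = 3
    mf_mode: str = "unanimous6"
    mf_iterations: int = 1
    gf_sigma: float = 2.0
    gf_radius: int | None = None
    ml_boundary: str = "replicate"
    normalize_inputs: bool = False
    # simulator
    na: float = 0.14
    wavelength_um: float = 0.532
    amplitude_weighting: bool = True
    axial_sigma_voxels: float | None = 2.0
    fiber_diameter_um: float = 6.0
    phantom: str = "fiber"
    foci: tuple[int, ...] = (40, 60)
    snr_db: float | None = None
    shape: tuple[int, int, int] = (120, 120, 120)
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)
    # metrics
    metric_bins: int = 256
    fwhm_floor_frac: float = 0.05
    fwhm_window_halfwidth: int = 12
    fwhm_center_tol: int = 3
    # randomness
    seed: int = 0

    def fusion_params(self):
        from .fusion import FusionParams

        return FusionParams(
            block_n=self.block_n,
            ml_boundary=self.ml_boundary,
            mf_mode=self.mf_mode,
            mf_iterations=self.mf_iterations,
            gf_sigma=self.gf_sigma,
            gf_radius=self.gf_radius,
            normalize_inputs=self.normalize_inputs,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("foci", "shape", "spacing"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for key in ("foci", "shape", "spacing"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def file_digest(path) -> str:
    """SHA-256 of a file, for provenance records."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(
    path, config: RunConfig, command: str, inputs: dict | None = None,
    extra: dict | None = None,
) -> None:
    """Echo the effective config, seeds and input digests next to outputs."""
    record = {
        "schema": PROVENANCE_SCHEMA,
        "package": "pamfuse",
        "version": _version,
        "command": command,
        "config": config.to_dict(),
        "inputs": inputs or {},
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2))
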