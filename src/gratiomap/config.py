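"""Pipeline configuration: every module default in one serializable place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # cohort / simulation
    n_healthy: int = 6
    n_patients: int = 6
    grid_shape: tuple[int, int, int] = (48, 48, 24)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_count_per_patient: int = 3
    lesion_radius_range: tuple[float, float] = (2.0, 4.0)
    lesion_demyelination: tuple[float, float] = (0.2, 0.9)
    noise_sigma: float = 0.005
    nmvf_wm: float = 0.0
    seed: int = 0
    # echo train
    n_echoes: int = 48
    echo_spacing: float = 8.0
    refocusing_flip: float = 180.0
    # forward model slopes
    mt_forward_slope: float = 0.15
    mtsat_slope: float = 0.12
    # T2 fitting
    t2_min: float = 10.0
    t2_max: float = 2000.0
    n_t2: int = 40
    window_max: float = 40.0
    reg_factor: float = 1.02
    flip_correction: bool = True
    t1_assumed: float = 1000.0
    sparsity_weight: float = 0.2
    max_components: int = 6
    # MT maps
    ihmtr_dialect: str = "2m0"
    pd_mode: str = "csf100"
    # g-ratio
    kappa_my: float = 0.36
    kappa_nm: float = 0.86
    g_target: float = 0.7
    calibration_voi: str = "splenium"
    # statistics
    connectivity: int = 6
    per_lesion: bool = True
    # execution
    fit_mask: str = "brain"  # brain | wm (restrict the slow T2 fits)

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.lesion_radius_range = tuple(float(v) for v in self.lesion_radius_range)
        self.lesion_demyelination = tuple(float(v) for v in self.lesion_demyelination)
        if self.ihmtr_dialect not in ("2m0", "m0"):
            raise ValueError("ihmtr_dialect must be '2m0' or 'm0'")
        if self.pd_mode not in ("csf100", "wm69"):
            raise ValueError("pd_mode must be 'csf100' or 'wm69'")
        if not (0 < self.g_target < 1):
            raise ValueError("g_target must lie in (0, 1)")
        if self.connectivity != 6:
            raise ValueError("only 6-connectivity is supported")
        if self.fit_mask not in ("brain", "wm"):
            raise ValueError("fit_mask must be 'brain' or 'wm'")
        if self.reg_factor < 1.0:
            raise ValueError("reg_factor must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
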