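"""Myelin/axonal volume fractions and aggregate g-ratio mapping.

Every myelin-sensitive measure is first converted to a myelin volume
fraction (MVF):

* MWF via the four-compartment hydration model
  ``MVF = MWF * k_nm / (MWF * (k_nm - k_my) + k_my)`` with MR-visible
  volume ratios k_my = 0.36 (myelin) and k_nm = 0.86 (non-myelin),
* MT-based measures via a calibrated linear scaling ``MVF = alpha * x``,
* macromolecular tissue volume used directly as a surrogate.

The axonal volume fraction combines MVF with diffusion-model signal
fractions, ``AVF = (1 - MVF - NMVF) * (1 - v_iso) * v_ic`` (NMVF defaults
to zero), and the aggregate g-ratio is ``g = sqrt(AVF / (AVF + MVF))``.

Linear scalings are calibrated so that the cohort-mean splenium g-ratio of
healthy subjects hits a target value (default 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .volume import VolumeMap, check_same_grid

__all__ = [
    "HydrationModel",
    "CalibrationSpec",
    "NoddiFractions",
    "GRatioMaps",
    "mvf_from_mwf",
    "mwf_from_mvf",
    "mvf_from_mwf_values",
    "mwf_from_mvf_values",
    "mvf_linear",
    "mvf_from_mtv",
    "compute_avf",
    "compute_gratio",
    "calibrate_alpha",
    "run_gratio_pipeline",
    "GRATIO_METHODS",
]

GRATIO_METHODS = ("mwf_nnls", "mwf_spijn", "ihmtr", "mtsat", "mtv")


@dataclass(frozen=True)
class HydrationModel:
    """MR-visible water volume ratios of myelin and non-myelin tissue."""

    kappa_my: float = 0.36
    kappa_nm: float = 0.86

    def __post_init__(self) -> None:
        if not (0.0 < self.kappa_my < self.kappa_nm <= 1.0):
            raise ValueError("require 0 < kappa_my < kappa_nm <= 1")


@dataclass
class CalibrationSpec:
    """Linear-scaling calibration state for MT-based MVF channels."""

    alpha_mtsat: float | None = None
    alpha_ihmt: float | None = None
    g_target: float = 0.7
    calibration_voi: str = "splenium"

    def __post_init__(self) -> None:
        if not (0.0 < self.g_target < 1.0):
            raise ValueError("g_target must lie in (0, 1)")


@dataclass
class NoddiFractions:
    """Intracellular and isotropic diffusion signal fractions."""

    v_ic: np.ndarray
    v_iso: np.ndarray

    def __post_init__(self) -> None:
        self.v_ic = np.asarray(self.v_ic, float)
        self.v_iso = np.asarray(self.v_iso, float)
        for name, arr in (("v_ic", self.v_ic), ("v_iso", self.v_iso)):
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.v_ic.shape != self.v_iso.shape:
            raise ValueError("v_ic and v_iso must share a grid")


@dataclass
class GRatioMaps:
    """MVF/AVF/g triple for one subject and one myelin measure."""

    mvf: VolumeMap
    avf: VolumeMap
    g: VolumeMap
    method: str = ""
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# MVF models
# ---------------------------------------------------------------------------


def mvf_from_mwf_values(mwf: np.ndarray, model: HydrationModel = HydrationModel()) -> np.ndarray:
    """Hydration-model transform, array in -> array out."""
    mwf = np.asarray(mwf, float)
    return mwf * model.kappa_nm / (mwf * (model.kappa_nm - model.kappa_my) + model.kappa_my)


def mwf_from_mvf_values(mvf: np.ndarray, model: HydrationModel = HydrationModel()) -> np.ndarray:
    """Analytic inverse of :func:`mvf_from_mwf_values`."""
    mvf = np.asarray(mvf, float)
    return mvf * model.kappa_my / (model.kappa_nm - mvf * (model.kappa_nm - model.kappa_my))


def _check_fraction(values: np.ndarray, name: str) -> None:
    finite = values[np.isfinite(values)]
    if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
        raise ValueError(f"{name} values must lie in [0, 1]")


def mvf_from_mwf(mwf: VolumeMap, model: HydrationModel = HydrationModel()) -> VolumeMap:
    _check_fraction(mwf.values, "MWF")
    return mwf.like(mvf_from_mwf_values(mwf.values, model), role="MVF")


def mwf_from_mvf(mvf: VolumeMap, model: HydrationModel = HydrationModel()) -> VolumeMap:
    _check_fraction(mvf.values, "MVF")
    return mvf.like(mwf_from_mvf_values(mvf.values, model), role="MWF")


def mvf_linear(x: VolumeMap, alpha: float) -> tuple[VolumeMap, int]:
    """Calibrated linear MVF model; returns (map, clip count)."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    scaled = alpha * x.values
    clipped = np.clip(scaled, 0.0, 1.0)
    n_clipped = int(np.sum(np.isfinite(scaled) & (scaled != clipped)))
    return x.like(clipped, role="MVF"), n_clipped


def mvf_from_mtv(mtv: VolumeMap) -> VolumeMap:
    """MTV used directly as the myelin volume fraction (fresh copy)."""
    _check_fraction(mtv.values, "MTV")
    return mtv.copy(role="MVF")


# ---------------------------------------------------------------------------
# AVF and g
# ---------------------------------------------------------------------------


def compute_avf(mvf: VolumeMap, fractions: NoddiFractions,
                nmvf: VolumeMap | None = None) -> VolumeMap:
    """Axonal volume fraction from MVF and diffusion signal fractions.

    With a non-myelin macromolecular map the non-aqueous budget shrinks:
    ``AVF = (1 - MVF - NMVF) * (1 - v_iso) * v_ic``. Voxels where
    MVF + NMVF exceeds 1 are marked invalid.
    """
    _check_fraction(mvf.values, "MVF")
    nm = np.zeros_like(mvf.values) if nmvf is None else np.asarray(nmvf.values, float)
    _check_fraction(nm, "NMVF")
    budget = 1.0 - mvf.values - nm
    avf = budget * (1.0 - fractions.v_iso) * fractions.v_ic
    avf = np.where(budget < -1e-12, np.nan, avf)
    return mvf.like(avf, role="AVF")


def compute_gratio(mvf: VolumeMap, avf: VolumeMap) -> VolumeMap:
    """Aggregate g-ratio ``sqrt(AVF / (AVF + MVF))``; 0/0 voxels invalid."""
    check_same_grid(mvf, avf)
    m, a = mvf.values, avf.values
    if np.any(m[np.isfinite(m)] < -1e-12) or np.any(a[np.isfinite(a)] < -1e-12):
        raise ValueError("MVF and AVF must be nonnegative")
    denom = a + m
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.sqrt(a / denom)
    g = np.where(denom > 0, g, np.nan)
    return mvf.like(g, role="g")


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def _splenium_g_mean(alpha: float, xs: Sequence[np.ndarray],
                     vics: Sequence[np.ndarray], visos: Sequence[np.ndarray]) -> float:
    """Cohort mean over subjects of the splenium-mean voxelwise g at alpha."""
    means = []
    for x, vic, viso in zip(xs, vics, visos):
        mvf = np.clip(alpha * x, 0.0, 1.0)
        avf = (1.0 - mvf) * (1.0 - viso) * vic
        denom = avf + mvf
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.sqrt(avf / denom)
        g = g[np.isfinite(g)]
        if g.size:
            means.append(float(g.mean()))
    if not means:
        raise ValueError("no valid splenium voxels for calibration")
    return float(np.mean(means))


def calibrate_alpha(x_maps: Sequence[VolumeMap], fractions: Sequence[NoddiFractions],
                    splenium_masks: Sequence[np.ndarray], g_target: float = 0.7,
                    tol: float = 1e-8) -> float:
    """Solve for the linear scaling that puts the healthy-cohort splenium
    g-ratio at ``g_target``.

    The cohort objective (subject-mean of splenium-mean voxelwise g) is
    strictly decreasing in alpha, so the unique root is found by bisection
    on [0, alpha_max] where alpha_max drives the largest splenium value to
    MVF = 1.
    """
    if not (0.0 < g_target < 1.0):
        raise ValueError("g_target must lie in (0, 1)")
    if len(x_maps) == 0:
        raise ValueError("calibration requires at least one subject")
    xs, vics, visos = [], [], []
    xmax = 0.0
    for m, f, msk in zip(x_maps, fractions, splenium_masks):
        msk = np.asarray(msk, bool)
        if not msk.any():
            raise ValueError("calibration mask is empty for a subject")
        sel = msk & np.isfinite(m.values)
        x = m.values[sel]
        if x.size == 0:
            raise ValueError("no valid calibration voxels for a subject")
        xs.append(x)
        vics.append(f.v_ic[sel])
        visos.append(f.v_iso[sel])
        xmax = max(xmax, float(np.nanmax(x)))
    if xmax <= 0:
        raise ValueError("calibration values are all non-positive")
    alpha_max = 1.0 / xmax

    f_lo = _splenium_g_mean(0.0, xs, vics, visos)  # = 1 wherever AVF > 0
    f_hi = _splenium_g_mean(alpha_max, xs, vics, visos)
    if not (f_hi - 1e-12 <= g_target <= f_lo + 1e-12):
        raise ValueError(
            f"g_target={g_target} outside attainable range [{f_hi:.4f}, {f_lo:.4f}]")

    lo, hi = 0.0, alpha_max
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = _splenium_g_mean(mid, xs, vics, visos)
        if abs(f_mid - g_target) < tol:
            return mid
        if f_mid > g_target:  # g too high -> need more myelin -> larger alpha
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# per-subject dispatch
# ---------------------------------------------------------------------------

_METHOD_INPUT_ROLE = {
    "mwf_nnls": "MWF_NNLS",
    "mwf_spijn": "MWF_SPIJN",
    "ihmtr": "ihMTR",
    "mtsat": "MTsat",
    "mtv": "MTV",
}


def run_gratio_pipeline(maps: dict[str, VolumeMap], method: str,
                        fractions: NoddiFractions,
                        calibration: CalibrationSpec | None = None,
                        model: HydrationModel = HydrationModel(),
                        nmvf: VolumeMap | None = None) -> GRatioMaps:
    """Full MVF -> AVF -> g chain for one subject and one myelin measure.

    ``maps`` is a role-to-map dict; the required role depends on
    ``method``. MT-based methods require a calibrated alpha in
    ``calibration``.
    """
    if method not in GRATIO_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {GRATIO_METHODS}")
    role = _METHOD_INPUT_ROLE[method]
    if role not in maps:
        raise ValueError(f"method {method!r} requires a map with role {role!r}")
    x = maps[role]

    n_clipped = 0
    if method in ("mwf_nnls", "mwf_spijn"):
        mvf = mvf_from_mwf(x, model)
        alpha = None
    elif method == "mtv":
        mvf = mvf_from_mtv(x)
        alpha = None
    else:
        if calibration is None:
            raise ValueError(f"method {method!r} requires a calibration")
        alpha = calibration.alpha_ihmt if method == "ihmtr" else calibration.alpha_mtsat
        if alpha is None:
            raise ValueError(f"calibration is missing alpha for method {method!r}")
        mvf, n_clipped = mvf_linear(x, alpha)

    avf = compute_avf(mvf, fractions, nmvf)
    g = compute_gratio(mvf, avf)
    provenance = {
        "method": method,
        "kappa_my": model.kappa_my,
        "kappa_nm": model.kappa_nm,
        "alpha": alpha,
        "n_clipped": n_clipped,
        "nmvf": nmvf is not None,
    }
    return GRatioMaps(mvf=mvf, avf=avf, g=g, method=method, provenance=provenance)
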