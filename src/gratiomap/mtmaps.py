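"""Magnetization-transfer and proton-density derived maps.

* ihMTR from the four single/dual-offset MT-weighted images and a
  reference, ``(S+ + S- - S_dualA - S_dualB) / (2 M0)`` (a ``single-m0``
  dialect dividing by M0 only is also provided).
* MTsat, R1 and the apparent amplitude from the T1-/PD-/MT-weighted
  spoiled gradient-echo triple via the rational small-angle estimators.
* PD by reference-region scaling of the apparent amplitude (CSF = 100% or
  whole-brain WM = 69%), and MTV = 1 - PD/100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import VolumeMap

__all__ = [
    "MtQuadruple",
    "MtsatInputs",
    "PdCalibration",
    "compute_ihmtr",
    "fit_mtsat",
    "calibrate_pd",
    "compute_mtv",
]


@dataclass
class MtQuadruple:
    """Four MT-weighted volumes (two single-offset, two dual-offset) plus
    the unsaturated reference."""

    s_plus: np.ndarray
    s_minus: np.ndarray
    s_dual_a: np.ndarray
    s_dual_b: np.ndarray
    m0: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        vols = [np.asarray(v, float) for v in
                (self.s_plus, self.s_minus, self.s_dual_a, self.s_dual_b, self.m0)]
        self.s_plus, self.s_minus, self.s_dual_a, self.s_dual_b, self.m0 = vols
        shapes = {v.shape for v in vols}
        if len(shapes) != 1:
            raise ValueError("all five volumes must share a grid")
        for v in vols:
            if np.any(v < 0):
                raise ValueError("MT-weighted intensities must be nonnegative")


@dataclass
class MtsatInputs:
    """T1-, PD-, and MT-weighted spoiled gradient-echo volumes."""

    s_t1w: np.ndarray
    s_pdw: np.ndarray
    s_mtw: np.ndarray
    flip_angles: tuple[float, float, float]  # degrees (T1w, PDw, MTw)
    repetition_times: tuple[float, float, float]  # ms
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        vols = [np.asarray(v, float) for v in (self.s_t1w, self.s_pdw, self.s_mtw)]
        self.s_t1w, self.s_pdw, self.s_mtw = vols
        if len({v.shape for v in vols}) != 1:
            raise ValueError("all three volumes must share a grid")
        for v in vols:
            if np.any(v < 0):
                raise ValueError("signals must be nonnegative")
        for a in self.flip_angles:
            if not (0.0 < a < 90.0):
                raise ValueError("flip angles must lie in (0, 90) degrees")


@dataclass
class PdCalibration:
    """Reference-region PD calibration: CSF at 100% or whole-brain WM at 69%."""

    mode: str = "csf100"

    def __post_init__(self) -> None:
        if self.mode not in ("csf100", "wm69"):
            raise ValueError("mode must be 'csf100' or 'wm69'")

    @property
    def reference_mask_role(self) -> str:
        return "CSF" if self.mode == "csf100" else "WM"

    @property
    def reference_value(self) -> float:
        return 100.0 if self.mode == "csf100" else 69.0


# ---------------------------------------------------------------------------
# ihMTR
# ---------------------------------------------------------------------------


def compute_ihmtr(quad: MtQuadruple, dialect: str = "2m0") -> tuple[VolumeMap, dict]:
    """Inhomogeneous MT ratio from the single/dual-offset quadruple.

    ``dialect='2m0'`` (default): ``(S+ + S- - Sda - Sdb) / (2 M0)``;
    ``dialect='m0'`` divides the same difference by M0 only. Values are not
    clamped; negative voxels are counted in the QC dict. Voxels with a
    non-positive reference are invalid.
    """
    if dialect not in ("2m0", "m0"):
        raise ValueError("dialect must be '2m0' or 'm0'")
    num = quad.s_plus + quad.s_minus - quad.s_dual_a - quad.s_dual_b
    denom = (2.0 if dialect == "2m0" else 1.0) * quad.m0
    with np.errstate(divide="ignore", invalid="ignore"):
        ihmtr = num / denom
    ihmtr = np.where(quad.m0 > 0, ihmtr, np.nan)
    qc = {
        "dialect": dialect,
        "n_invalid": int(np.sum(~(quad.m0 > 0))),
        "n_negative": int(np.sum(ihmtr < 0)),
    }
    return VolumeMap(ihmtr, quad.affine, role="ihMTR"), qc


# ---------------------------------------------------------------------------
# MTsat / R1 / A_app
# ---------------------------------------------------------------------------


def fit_mtsat(inputs: MtsatInputs) -> tuple[VolumeMap, VolumeMap, VolumeMap]:
    """Rational small-angle estimation of MTsat, R1 and apparent amplitude.

    The dual-angle T1w/PDw pair determines R1 and A_app exactly under the
    rational signal model ``S = A a R1 TR / (a^2/2 + R1 TR)``; the MT-
    weighted volume then gives the per-excitation saturation
    ``delta = (A a_mt / S_mt - 1) R1 TR_mt - a_mt^2 / 2``, reported x100
    in percent. Voxels with vanishing denominators are invalid.

    Returns (MTsat [%], R1 [1/s], A_app [arb]) maps.
    """
    a1, a2, amt = np.deg2rad(np.asarray(inputs.flip_angles, float))
    tr1, tr2, trmt = inputs.repetition_times
    if inputs.flip_angles[0] == inputs.flip_angles[1]:
        raise ValueError("T1w and PDw flip angles must differ")
    s1, s2, smt = inputs.s_t1w, inputs.s_pdw, inputs.s_mtw

    # linear system in (P, rho) with P = A*rho:
    #   a_i TR_i P - S_i TR_i rho = S_i a_i^2 / 2
    det = a1 * tr1 * (-s2 * tr2) - (-s1 * tr1) * (a2 * tr2)
    rhs1 = s1 * a1 ** 2 / 2.0
    rhs2 = s2 * a2 ** 2 / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (rhs1 * (-s2 * tr2) - (-s1 * tr1) * rhs2) / det
        rho = (a1 * tr1 * rhs2 - a2 * tr2 * rhs1) / det  # 1/ms
        a_app = p / rho
        delta = (a_app * amt / smt - 1.0) * rho * trmt - amt ** 2 / 2.0
    bad = ~np.isfinite(a_app) | ~np.isfinite(rho) | (rho <= 0) | (smt <= 0) | (np.abs(det) < 1e-30)
    a_app = np.where(bad, np.nan, a_app)
    rho = np.where(bad, np.nan, rho)
    delta = np.where(bad, np.nan, delta)

    mtsat = VolumeMap(100.0 * delta, inputs.affine, role="MTsat", units="%")
    r1 = VolumeMap(rho * 1000.0, inputs.affine, role="R1", units="1/s")
    amp = VolumeMap(a_app, inputs.affine, role="A_app")
    return mtsat, r1, amp


# ---------------------------------------------------------------------------
# PD / MTV
# ---------------------------------------------------------------------------


def calibrate_pd(a_app: VolumeMap, cal: PdCalibration,
                 reference_mask: np.ndarray) -> tuple[VolumeMap, dict]:
    """Scale the apparent amplitude so the reference region hits its
    assumed PD (CSF 100% or WM 69%); clipped to [0, 110] with a QC count."""
    mask = np.asarray(reference_mask, bool)
    if not mask.any():
        raise ValueError("reference mask is empty")
    ref_vals = a_app.values[mask & np.isfinite(a_app.values)]
    if ref_vals.size == 0:
        raise ValueError("reference mask has no valid voxels")
    ref_mean = float(ref_vals.mean())
    if ref_mean <= 0:
        raise ValueError("reference-region mean amplitude must be positive")
    pd = a_app.values * (cal.reference_value / ref_mean)
    clipped = np.clip(pd, 0.0, 110.0)
    n_clipped = int(np.sum(np.isfinite(pd) & (pd != clipped)))
    qc = {"mode": cal.mode, "reference_mean": ref_mean, "n_clipped": n_clipped}
    return VolumeMap(clipped, a_app.affine, role="PD", units="%"), qc


def compute_mtv(pd: VolumeMap) -> VolumeMap:
    """Macromolecular tissue volume ``1 - PD/100``, clipped to [0, 1]."""
    finite = pd.values[np.isfinite(pd.values)]
    if finite.size and (finite.min() < -1e-9 or finite.max() > 200):
        raise ValueError("PD input must be in percent units")
    mtv = np.clip(1.0 - pd.values / 100.0, 0.0, 1.0)
    return pd.like(mtv, role="MTV")
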