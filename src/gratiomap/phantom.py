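"""Synthetic multi-modal brain phantom with ground-truth microstructure.

Generates healthy and lesioned subjects on a shared voxel grid and
forward-simulates every acquired contrast the pipeline consumes:

* a multi-echo spin-echo magnitude series (EPG decay of three water
  compartments: myelin water T2 = 20 ms, intra/extracellular T2 = 80 ms,
  CSF T2 = 2000 ms),
* a four-image MT-weighted set (single/dual saturation offsets) plus
  reference, constructed so the derived saturation ratio is exactly linear
  in the true myelin volume fraction,
* a T1-/PD-/MT-weighted spoiled gradient-echo triple following the
  small-angle rational signal equation, and
* noisy copies of the "diffusion-model" intracellular/isotropic fractions.

Noise is Rician (magnitude of a complex Gaussian perturbation). All
simulators are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epg import EPGParams, epg_decay_curve
from .relaxometry import EchoSeries
from .mtmaps import MtQuadruple, MtsatInputs
from .gratio import HydrationModel, NoddiFractions, mwf_from_mvf_values
from . import voistats

__all__ = [
    "CohortSpec",
    "PhantomTruth",
    "build_phantom",
    "simulate_echo_series",
    "simulate_mt_quadruple",
    "simulate_mtsat_inputs",
    "simulate_noddi_fractions",
    "simulate_subject",
]

# background/CSF/GM/WM/lesion integer labels
BACKGROUND, CSF, GM, WM, LESION = 0, 1, 2, 3, 4

# compartment T2 values (ms): canonical literature values placing myelin
# water inside and all other water outside the short-T2 window
T2_MYELIN = 20.0
T2_IE = 80.0
T2_CSF = 2000.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort."""

    n_healthy: int = 6
    n_patients: int = 6
    grid_shape: tuple[int, int, int] = (48, 48, 24)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_count_per_patient: int = 3
    lesion_radius_range: tuple[float, float] = (2.0, 4.0)  # mm
    lesion_demyelination: tuple[float, float] = (0.2, 0.9)  # residual-myelin factor range
    noise_sigma: float = 0.005  # relative to WM first-echo / reference signal
    nmvf_wm: float = 0.0  # non-myelin macromolecular fraction in WM
    nmvf_lesion: float = 0.05  # extra non-myelin macromolecules in lesion cores
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 1 or self.n_patients < 0:
            raise ValueError("cohort counts must be >= 1 healthy, >= 0 patients")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 8:
            raise ValueError("grid_shape must be a 3-tuple with all dims >= 8")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ValueError("lesion_radius_range must satisfy 0 < lo <= hi")
        lo, hi = self.lesion_demyelination
        if not (0 < lo <= hi <= 1):
            raise ValueError("lesion_demyelination factors must lie in (0, 1]")


@dataclass
class PhantomTruth:
    """Ground-truth microstructure of one synthetic subject."""

    tissue_labels: np.ndarray  # int 3D
    mvf_true: np.ndarray
    avf_true: np.ndarray
    nmvf_true: np.ndarray
    mwf_true: np.ndarray
    v_ic_true: np.ndarray
    v_iso_true: np.ndarray
    r1_true: np.ndarray  # 1/ms, used by the gradient-echo simulator
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0], a[1, 1], a[2, 2] = self.voxel_size_mm
        return a

    @property
    def brain_mask(self) -> np.ndarray:
        return self.tissue_labels != BACKGROUND

    @property
    def water_content(self) -> np.ndarray:
        """MR-visible water volume fraction per voxel (zero outside brain)."""
        w = 1.0 - self.mvf_true - self.nmvf_true
        return np.where(self.brain_mask, w, 0.0)


def _ellipsoid(shape: tuple[int, int, int], center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def _radius_field(shape: tuple[int, int, int], center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    return np.sqrt(sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi)))


def build_phantom(spec: CohortSpec, subject_kind: str = "healthy",
                  seed: int | None = None) -> tuple[PhantomTruth, voistats.VOISet]:
    """Generate one synthetic subject: truth maps plus region masks.

    Geometry: an ellipsoidal brain with a cortical GM shell, a central CSF
    ellipsoid, WM in between, and box-shaped WM sub-regions (CC with a
    splenium sub-mask, CR, IC). Patients additionally receive disjoint
    spherical lesions with sigmoid (1-voxel) edges inside WM, each with a
    per-lesion residual-myelin factor drawn from
    ``spec.lesion_demyelination``.
    """
    if subject_kind not in ("healthy", "patient"):
        raise ValueError("subject_kind must be 'healthy' or 'patient'")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    shape = tuple(spec.grid_shape)
    vox = np.asarray(spec.voxel_size_mm, float)
    center = (np.asarray(shape, float) - 1.0) / 2.0
    brain_semi = 0.45 * np.asarray(shape, float)
    csf_semi = 0.16 * np.asarray(shape, float)
    if np.any(brain_semi < 3) or np.any(csf_semi < 1.5):
        raise ValueError("grid too small: every region must span >= 3 voxels")

    r = _radius_field(shape, center, brain_semi)
    brain = r <= 1.0
    gm = (r > 0.8) & brain
    csf = _ellipsoid(shape, center, csf_semi)
    wm = brain & ~gm & ~csf

    labels = np.zeros(shape, dtype=np.int16)
    labels[csf] = CSF
    labels[gm] = GM
    labels[wm] = WM

    cx, cy, cz = center
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    # corpus callosum: slab just above the central CSF (extents scale with grid)
    cc_lo = cz + csf_semi[2] * 0.5
    cc_hi = cc_lo + max(2.0, 0.15 * shape[2])
    cr_hi = cc_hi + max(2.0, 0.20 * shape[2])
    cc = wm & (np.abs(jj - cy) <= max(2.0, 0.08 * shape[1])) & (kk >= cc_lo) & (kk <= cc_hi)
    splenium = cc & (ii >= cx + 0.30 * brain_semi[0])
    # corona radiata: superior WM slab above the CC
    cr = wm & (kk > cc_hi) & (kk <= cr_hi)
    # internal capsule: two parasagittal boxes lateral to the ventricle
    ic = wm & (np.abs(jj - cy) >= csf_semi[1] + 1) & (np.abs(jj - cy) <= csf_semi[1] + max(3.0, 0.12 * shape[1])) \
        & (np.abs(kk - cz) <= max(2.0, 0.12 * shape[2])) & (np.abs(ii - cx) <= max(3.0, 0.12 * shape[0]))
    for name, m in (("CC", cc), ("splenium", splenium), ("CR", cr), ("IC", ic)):
        if not m.any():
            raise ValueError(f"grid too small: {name} region is empty")

    # smooth ground-truth fields; per-subject jitter keeps subjects distinct
    wm_base = rng.normal(0.30, 0.01)
    gm_base = rng.normal(0.10, 0.005)
    ripple = 0.01 * np.sin(2 * np.pi * ii / shape[0]) * np.cos(2 * np.pi * jj / shape[1])
    mvf = np.zeros(shape)
    mvf[wm] = wm_base + ripple[wm]
    mvf[gm] = gm_base + 0.5 * ripple[gm]

    v_ic = np.zeros(shape)
    v_ic[wm] = rng.normal(0.55, 0.01) + ripple[wm]
    v_ic[gm] = 0.40
    v_iso = np.zeros(shape)
    v_iso[wm] = 0.05
    v_iso[gm] = 0.15
    v_iso[csf] = 0.98

    nmvf = np.zeros(shape)
    nmvf[wm | gm] = spec.nmvf_wm

    # lesions: disjoint spheres with 1-voxel sigmoid edges, WM only
    lesion_prob = np.zeros(shape)
    lesion_mask = np.zeros(shape, dtype=bool)
    if subject_kind == "patient" and spec.lesion_count_per_patient > 0:
        coords_mm = np.stack([ii * vox[0], jj * vox[1], kk * vox[2]], axis=-1)
        interior = wm & (r <= 0.72) & ~csf & ~cc  # keep lesions off region/boundary edges
        cand = np.argwhere(interior)
        if cand.size == 0:
            raise ValueError("grid too small to place lesions inside WM")
        placed: list[tuple[np.ndarray, float]] = []
        attempts = 0
        while len(placed) < spec.lesion_count_per_patient:
            attempts += 1
            if attempts > 2000:
                raise ValueError("grid too small for requested lesion count/radius")
            radius = rng.uniform(*spec.lesion_radius_range)
            ctr_idx = cand[rng.integers(len(cand))]
            ctr_mm = ctr_idx * vox
            if any(np.linalg.norm(ctr_mm - p) < radius + pr + 2.0 for p, pr in placed):
                continue
            d = np.linalg.norm(coords_mm - ctr_mm, axis=-1)
            core = d <= radius
            if not np.all(wm[core] | lesion_mask[core]):
                continue  # sphere leaks out of WM
            w = 1.0 / (1.0 + np.exp((d - radius) / 0.5))
            factor = rng.uniform(*spec.lesion_demyelination)
            mult = 1.0 - (1.0 - factor) * w
            mvf *= mult
            v_ic *= 1.0 - 0.8 * (1.0 - factor) * w  # axonal loss tracks demyelination
            # lesions accumulate non-myelin macromolecules (debris, gliosis),
            # which MTV-type measures cannot distinguish from myelin
            nmvf += spec.nmvf_lesion * (1.0 - factor) * w * wm
            lesion_prob = np.maximum(lesion_prob, w)
            lesion_mask |= core & wm
            placed.append((ctr_mm, radius))
        labels[lesion_mask] = LESION

    mvf = np.clip(mvf, 0.0, 1.0)
    v_ic = np.clip(v_ic, 0.0, 1.0)
    v_iso = np.clip(v_iso, 0.0, 1.0)
    avf = (1.0 - mvf - nmvf) * (1.0 - v_iso) * v_ic
    model = HydrationModel()
    mwf = mwf_from_mvf_values(mvf, model)

    # R1 rises linearly with macromolecular content (per-ms units)
    r1 = np.where(labels != BACKGROUND, (0.25 + 2.2 * (mvf + nmvf)) / 1000.0, 0.0)

    truth = PhantomTruth(
        tissue_labels=labels, mvf_true=mvf, avf_true=avf, nmvf_true=nmvf,
        mwf_true=mwf, v_ic_true=v_ic, v_iso_true=v_iso, r1_true=r1,
        voxel_size_mm=tuple(spec.voxel_size_mm),
    )

    masks = {
        "WM": (labels == WM),
        "GM": (labels == GM),
        "CSF": (labels == CSF),
        "CC": cc & (labels == WM),
        "CR": cr & (labels == WM),
        "IC": ic & (labels == WM),
        "splenium": splenium & (labels == WM),
        "lesion": lesion_mask,
    }
    vois = voistats.VOISet(masks=masks, lesion_probability=lesion_prob)
    vois.apply_lesion_exclusion()
    if lesion_mask.any():
        vois.masks["perilesion"] = voistats.make_perilesion(lesion_mask, vois.masks["WM"])
        vois.masks["lesion_shell"] = voistats.make_lesion_shell(lesion_mask)
    else:
        vois.masks["perilesion"] = np.zeros(shape, dtype=bool)
        vois.masks["lesion_shell"] = np.zeros(shape, dtype=bool)
    return truth, vois


# ---------------------------------------------------------------------------
# noise helper
# ---------------------------------------------------------------------------


def rician(clean: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the clean signal plus complex Gaussian noise."""
    if sigma == 0:
        return np.asarray(clean, float).copy()
    n1 = rng.normal(0.0, sigma, clean.shape)
    n2 = rng.normal(0.0, sigma, clean.shape)
    return np.hypot(clean + n1, n2)


def _noise_scale(reference: np.ndarray, mask: np.ndarray) -> float:
    vals = reference[mask]
    return float(vals.mean()) if vals.size else float(np.mean(reference))


# ---------------------------------------------------------------------------
# forward simulators
# ---------------------------------------------------------------------------


def simulate_echo_series(truth: PhantomTruth, n_echoes: int = 48, echo_spacing: float = 8.0,
                         refocusing_flip: float = 180.0, noise_sigma: float = 0.0,
                         seed: int = 0) -> EchoSeries:
    """Multi-echo magnitude series from the three-compartment T2 model.

    Compartment amplitudes are set so the short-T2 amplitude fraction
    equals ``mwf_true`` exactly; the total amplitude is the voxel water
    content. The noise sigma is relative to the WM-mean first-echo signal.
    """
    params = EPGParams(refocusing_flip=refocusing_flip, echo_spacing=echo_spacing,
                       n_echoes=n_echoes)
    curves = epg_decay_curve(np.array([T2_MYELIN, T2_IE, T2_CSF]), params)  # (n_echo, 3)

    w = truth.water_content
    f_my = truth.mwf_true
    f_csf = (1.0 - f_my) * truth.v_iso_true
    f_ie = np.clip(1.0 - f_my - f_csf, 0.0, 1.0)
    amps = np.stack([w * f_my, w * f_ie, w * f_csf], axis=-1)  # (...,3)
    clean = amps @ curves.T  # (x,y,z,echo)

    if noise_sigma > 0:
        wm = truth.tissue_labels == WM
        sigma_abs = noise_sigma * _noise_scale(clean[..., 0], wm)
        rng = np.random.default_rng(seed)
        data = rician(clean, sigma_abs, rng)
    else:
        data = clean
    return EchoSeries(data=data, echo_times=params.echo_times,
                      mask=truth.brain_mask, affine=truth.affine)


def simulate_mt_quadruple(truth: PhantomTruth, forward_slope: float = 0.15,
                          conventional_mt: float = 0.30, asymmetry: float = 0.01,
                          noise_sigma: float = 0.0, seed: int = 0) -> MtQuadruple:
    """Single/dual-offset MT-weighted quadruple plus reference.

    Constructed so the noiseless saturation ratio
    ``(s_plus + s_minus - s_dual_a - s_dual_b) / (2 m0)`` equals
    ``forward_slope * mvf_true`` exactly (assumed linear relation between
    the ratio and myelin volume). ``conventional_mt`` attenuates all four
    weighted images in proportion to total macromolecular content;
    ``asymmetry`` makes the positive/negative offsets slightly unequal.
    """
    if forward_slope <= 0:
        raise ValueError("forward_slope must be > 0")
    mac = truth.mvf_true + truth.nmvf_true
    m0 = truth.water_content
    att = conventional_mt * mac
    s_plus = m0 * (1.0 - att + asymmetry * mac)
    s_minus = m0 * (1.0 - att - asymmetry * mac)
    dual = m0 * (1.0 - att - forward_slope * truth.mvf_true)
    if np.any(dual < 0) or np.any(s_minus < 0):
        raise ValueError("forward_slope/conventional_mt produce negative intensities")

    if noise_sigma > 0:
        sigma_abs = noise_sigma * _noise_scale(m0, truth.brain_mask)
        rng = np.random.default_rng(seed)
        vols = [rician(v, sigma_abs, rng) for v in (s_plus, s_minus, dual, dual, m0)]
    else:
        vols = [s_plus, s_minus, dual.copy(), dual.copy(), m0]
    return MtQuadruple(s_plus=vols[0], s_minus=vols[1], s_dual_a=vols[2],
                       s_dual_b=vols[3], m0=vols[4], affine=truth.affine)


def simulate_mtsat_inputs(truth: PhantomTruth,
                          flip_angles: tuple[float, float, float] = (20.0, 6.0, 6.0),
                          repetition_times: tuple[float, float, float] = (18.0, 25.0, 25.0),
                          mtsat_slope: float = 0.12, noise_sigma: float = 0.0,
                          seed: int = 0) -> tuple[MtsatInputs, np.ndarray]:
    """T1w/PDw/MTw spoiled gradient-echo triple.

    Signals follow the small-angle rational equation
    ``S = A * a * R1 * TR / (a^2/2 + R1 * TR)`` with amplitude A equal to
    the voxel water content; the MT-weighted signal has the per-excitation
    saturation ``delta_true = mtsat_slope * mvf_true`` added to its
    denominator. Returns the inputs plus the ``delta_true`` map.
    """
    for a_deg in flip_angles:
        if a_deg >= 90.0:
            raise ValueError("flip angles must be < 90 deg (small-angle signal model)")
        if a_deg <= 0.0:
            raise ValueError("flip angles must be > 0")
    if flip_angles[0] == flip_angles[1] and repetition_times[0] == repetition_times[1]:
        raise ValueError("T1w and PDw acquisitions must differ")
    a = np.deg2rad(np.asarray(flip_angles, float))
    tr = np.asarray(repetition_times, float)
    amp = truth.water_content
    r1 = truth.r1_true  # 1/ms
    delta_true = mtsat_slope * truth.mvf_true

    def spgr(alpha: float, tr_ms: float, delta: np.ndarray | float = 0.0) -> np.ndarray:
        e = r1 * tr_ms
        with np.errstate(divide="ignore", invalid="ignore"):
            s = amp * alpha * e / (alpha ** 2 / 2.0 + delta + e)
        return np.where(e > 0, s, 0.0)

    s_t1w = spgr(a[0], tr[0])
    s_pdw = spgr(a[1], tr[1])
    s_mtw = spgr(a[2], tr[2], delta_true)

    if noise_sigma > 0:
        sigma_abs = noise_sigma * _noise_scale(s_pdw, truth.brain_mask)
        rng = np.random.default_rng(seed)
        s_t1w, s_pdw, s_mtw = (rician(v, sigma_abs, rng) for v in (s_t1w, s_pdw, s_mtw))
    inputs = MtsatInputs(s_t1w=s_t1w, s_pdw=s_pdw, s_mtw=s_mtw,
                         flip_angles=tuple(flip_angles),
                         repetition_times=tuple(repetition_times), affine=truth.affine)
    return inputs, delta_true


def simulate_noddi_fractions(truth: PhantomTruth, noise_sigma: float = 0.0,
                             seed: int = 0) -> NoddiFractions:
    """Ground-truth diffusion fractions plus clipped Gaussian noise."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    v_ic = truth.v_ic_true.copy()
    v_iso = truth.v_iso_true.copy()
    if noise_sigma > 0:
        v_ic = v_ic + rng.normal(0.0, noise_sigma, v_ic.shape)
        v_iso = v_iso + rng.normal(0.0, noise_sigma, v_iso.shape)
    return NoddiFractions(v_ic=np.clip(v_ic, 0.0, 1.0), v_iso=np.clip(v_iso, 0.0, 1.0))


# ---------------------------------------------------------------------------
# convenience: everything for one subject
# ---------------------------------------------------------------------------


def simulate_subject(spec: CohortSpec, subject_kind: str, seed: int,
                     n_echoes: int = 48, echo_spacing: float = 8.0,
                     refocusing_flip: float = 180.0,
                     mt_forward_slope: float = 0.15,
                     mtsat_slope: float = 0.12) -> dict:
    """Build one subject and simulate all contrasts with derived sub-seeds."""
    truth, vois = build_phantom(spec, subject_kind, seed)
    ss = np.random.SeedSequence(entropy=(seed, 0xC0FFEE)).spawn(4)
    seeds = [int(s.generate_state(1)[0]) for s in ss]
    series = simulate_echo_series(truth, n_echoes, echo_spacing, refocusing_flip,
                                  spec.noise_sigma, seeds[0])
    quad = simulate_mt_quadruple(truth, forward_slope=mt_forward_slope,
                                 noise_sigma=spec.noise_sigma, seed=seeds[1])
    mtsat_inputs, delta_true = simulate_mtsat_inputs(truth, mtsat_slope=mtsat_slope,
                                                     noise_sigma=spec.noise_sigma,
                                                     seed=seeds[2])
    fractions = simulate_noddi_fractions(truth, noise_sigma=spec.noise_sigma, seed=seeds[3])
    return {
        "truth": truth,
        "vois": vois,
        "echo_series": series,
        "mt_quadruple": quad,
        "mtsat_inputs": mtsat_inputs,
        "delta_true": delta_true,
        "noddi": fractions,
        "kind": subject_kind,
        "seed": seed,
    }
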