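"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementations they check: the decay oracle
sums explicit Bloch-rotated isochromats, the morphology oracle enumerates
face neighbors voxel by voxel, and the statistics oracles evaluate the
textbook closed forms with scipy distribution functions only.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import t as t_dist


def isochromat_decay_curve(t2: float, flip_deg: float, echo_spacing: float,
                           n_echoes: int, t1: float = 1000.0,
                           n_iso: int | None = None) -> np.ndarray:
    """Echo amplitudes by brute-force isochromat summation.

    Simulates a uniform grid of dephasing angles (ideal crusher), rotating
    each magnetization vector with explicit Bloch rotation matrices:
    90 deg excitation about y, refocusing pulses about x, relaxation per
    half period without longitudinal regrowth. A grid of more than
    4*n_echoes isochromats resolves every dephasing order exactly.
    """
    if n_iso is None:
        n_iso = 4 * n_echoes + 5
    phis = 2.0 * np.pi * np.arange(n_iso) / n_iso
    cos_p, sin_p = np.cos(phis), np.sin(phis)
    a = math.radians(flip_deg)
    rot_x = np.array([[1.0, 0.0, 0.0],
                      [0.0, math.cos(a), -math.sin(a)],
                      [0.0, math.sin(a), math.cos(a)]])
    e2 = math.exp(-echo_spacing / 2.0 / t2)
    e1 = math.exp(-echo_spacing / 2.0 / t1)

    m = np.zeros((n_iso, 3))
    m[:, 0] = 1.0  # after 90y excitation

    def precess_relax(m: np.ndarray) -> np.ndarray:
        x = m[:, 0] * cos_p - m[:, 1] * sin_p
        y = m[:, 0] * sin_p + m[:, 1] * cos_p
        m[:, 0] = x * e2
        m[:, 1] = y * e2
        m[:, 2] *= e1
        return m

    out = np.empty(n_echoes)
    for i in range(n_echoes):
        m = precess_relax(m)
        m = m @ rot_x.T
        m = precess_relax(m)
        out[i] = math.hypot(m[:, 0].mean(), m[:, 1].mean())
    return out


def brute_erode(mask: np.ndarray) -> np.ndarray:
    """One 6-neighbor erosion by explicit enumeration; boundary = outside."""
    mask = np.asarray(mask, bool)
    out = np.zeros_like(mask)
    nx, ny, nz = mask.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                keep = True
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    ii, jj, kk = i + di, j + dj, k + dk
                    if not (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz):
                        keep = False
                        break
                    if not mask[ii, jj, kk]:
                        keep = False
                        break
                out[i, j, k] = keep
    return out


def brute_dilate(mask: np.ndarray) -> np.ndarray:
    """One 6-neighbor dilation by explicit enumeration."""
    mask = np.asarray(mask, bool)
    out = mask.copy()
    nx, ny, nz = mask.shape
    for i, j, k in np.argwhere(mask):
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                           (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ii, jj, kk = i + di, j + dj, k + dk
            if 0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz:
                out[ii, jj, kk] = True
    return out


def closed_form_ttest(a, b):
    """Pooled-variance two-sample t, straight from the textbook formula."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * float(t_dist.sf(abs(t), na + nb - 2))
    return t, p


def closed_form_pearson(x, y):
    """Pearson R and two-sided p via the t transform, textbook form."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    r = float(np.sum((x - x.mean()) * (y - y.mean()))
              / math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * float(t_dist.sf(abs(t), n - 2))
    return r, p
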