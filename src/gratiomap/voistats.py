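"""VOI construction and cohort-level statistics.

Masks use 6-connectivity (face neighbors) for erosion, dilation and lesion
labeling; the volume boundary counts as outside the mask. Lesions are
probability > 0.5 regions; every non-lesion VOI excludes those voxels.
Group comparisons use the pooled-variance two-sample t-test and pairwise
Pearson correlations of subject-mean values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import t as t_dist

from .volume import VolumeMap

__all__ = [
    "VOISet",
    "CohortStats",
    "STRUCTURE_6",
    "threshold_masks",
    "erode_mask",
    "dilate_mask",
    "make_perilesion",
    "make_lesion_shell",
    "label_lesions",
    "extract_voi_means",
    "two_sample_ttest",
    "pearson_corr",
    "build_cohort_report",
]

#: 6-connectivity (face-neighbor) structuring element.
STRUCTURE_6 = ndimage.generate_binary_structure(3, 1)

NON_LESION_ROLES = ("WM", "GM", "CSF", "CC", "CR", "IC", "splenium")


@dataclass
class VOISet:
    """Labeled masks for one subject."""

    masks: dict[str, np.ndarray]
    lesion_probability: np.ndarray | None = None
    tissue_probabilities: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.masks = {k: np.asarray(v, bool) for k, v in self.masks.items()}
        shapes = {v.shape for v in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all masks must share a grid")

    def apply_lesion_exclusion(self, threshold: float = 0.5) -> None:
        """Remove lesion-probability > threshold voxels from non-lesion masks."""
        if self.lesion_probability is None:
            return
        excl = self.lesion_probability > threshold
        for role in self.masks:
            if role not in ("lesion", "lesion_shell"):
                self.masks[role] = self.masks[role] & ~excl

    def __getitem__(self, role: str) -> np.ndarray:
        return self.masks[role]


@dataclass
class CohortStats:
    """Cohort-level tables: VOI means, group tests, correlations."""

    voi_means: pd.DataFrame
    ttests: pd.DataFrame
    correlations: pd.DataFrame
    n_tests: int = 0


# ---------------------------------------------------------------------------
# mask construction
# ---------------------------------------------------------------------------


def threshold_masks(tissue_probabilities: dict[str, np.ndarray],
                    lesion_probability: np.ndarray | None = None,
                    lesion_threshold: float = 0.5,
                    tissue_threshold: float = 0.9) -> VOISet:
    """Strict-inequality thresholding of probability maps into a VOISet."""
    masks: dict[str, np.ndarray] = {}
    for role, prob in tissue_probabilities.items():
        prob = np.asarray(prob, float)
        if prob.min() < 0 or prob.max() > 1:
            raise ValueError(f"{role} probabilities must lie in [0, 1]")
        masks[role] = prob > tissue_threshold
    if lesion_probability is not None:
        lesion_probability = np.asarray(lesion_probability, float)
        if lesion_probability.min() < 0 or lesion_probability.max() > 1:
            raise ValueError("lesion probabilities must lie in [0, 1]")
        masks["lesion"] = lesion_probability > lesion_threshold
    vois = VOISet(masks=masks, lesion_probability=lesion_probability,
                  tissue_probabilities=dict(tissue_probabilities))
    vois.apply_lesion_exclusion(lesion_threshold)
    return vois


def erode_mask(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """6-neighbor erosion; the volume boundary counts as outside."""
    mask = np.asarray(mask, bool)
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0 or not mask.any():
        return mask.copy()
    return ndimage.binary_erosion(mask, structure=STRUCTURE_6,
                                  iterations=iterations, border_value=0)


def dilate_mask(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """6-neighbor dilation."""
    mask = np.asarray(mask, bool)
    if iterations == 0 or mask.all():
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=STRUCTURE_6, iterations=iterations)


def make_perilesion(lesion_mask: np.ndarray, wm_mask: np.ndarray,
                    width: int = 2) -> np.ndarray:
    """Shell of normal-appearing WM around lesions:
    ``(dilate(lesion, width) \\ lesion) & WM``."""
    lesion_mask = np.asarray(lesion_mask, bool)
    wm_mask = np.asarray(wm_mask, bool)
    if lesion_mask.shape != wm_mask.shape:
        raise ValueError("masks must share a grid")
    if not lesion_mask.any():
        return np.zeros_like(lesion_mask)
    return dilate_mask(lesion_mask, width) & ~lesion_mask & wm_mask


def make_lesion_shell(lesion_mask: np.ndarray) -> np.ndarray:
    """Outermost 1-voxel layer of the lesion: ``lesion \\ erode(lesion)``."""
    lesion_mask = np.asarray(lesion_mask, bool)
    return lesion_mask & ~erode_mask(lesion_mask, 1)


def label_lesions(lesion_mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Connected lesion components under 6-connectivity."""
    return ndimage.label(np.asarray(lesion_mask, bool), structure=STRUCTURE_6)


# ---------------------------------------------------------------------------
# VOI means
# ---------------------------------------------------------------------------


def extract_voi_means(maps: dict[str, VolumeMap], vois: VOISet,
                      per_lesion: bool = False) -> pd.DataFrame:
    """Tidy table of per-VOI means over valid voxels.

    Columns: voi, metric, mean, n_voxels. Empty VOIs (or VOIs with no valid
    voxels) yield NaN means with n_voxels = 0. With ``per_lesion``, one row
    per connected lesion component is appended (voi = ``lesion_001``, ...).
    """
    rows = []
    targets: list[tuple[str, np.ndarray]] = list(vois.masks.items())
    if per_lesion and "lesion" in vois.masks and vois.masks["lesion"].any():
        labels, n = label_lesions(vois.masks["lesion"])
        for li in range(1, n + 1):
            targets.append((f"lesion_{li:03d}", labels == li))
    for voi_name, mask in targets:
        for metric, vmap in maps.items():
            vals = vmap.values[mask]
            vals = vals[np.isfinite(vals)]
            rows.append({
                "voi": voi_name,
                "metric": metric,
                "mean": float(vals.mean()) if vals.size else float("nan"),
                "n_voxels": int(vals.size),
            })
    return pd.DataFrame(rows, columns=["voi", "metric", "mean", "n_voxels"])


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def two_sample_ttest(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float, bool]:
    """Pooled-variance two-sided two-sample t-test.

    Returns (t, p, degenerate). With zero pooled variance the statistic is
    +/-inf (p = 0) for unequal means, or t = 0, p = 1 for equal means; both
    cases set ``degenerate=True``.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    ma, mb = a.mean(), b.mean()
    df = na + nb - 2
    sp2 = (((a - ma) ** 2).sum() + ((b - mb) ** 2).sum()) / df
    if sp2 == 0.0:
        if ma == mb:
            return 0.0, 1.0, True
        return math.copysign(math.inf, ma - mb), 0.0, True
    t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return float(t), p, False


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Sample Pearson correlation with two-sided p from the t-transform.

    Returns (R, p, degenerate); zero variance in either input yields
    (nan, nan, True).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    xm = x - x.mean()
    ym = y - y.mean()
    sx = math.sqrt(float(xm @ xm))
    sy = math.sqrt(float(ym @ ym))
    if sx == 0.0 or sy == 0.0:
        return float("nan"), float("nan"), True
    r = float(xm @ ym) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0, False
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(t_dist.sf(abs(t), n - 2))
    return r, p, False


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

#: group comparisons: (name, group A selector, group B selector); selectors
#: are (group, voi) pairs applied to the subject-level means table.
DEFAULT_COMPARISONS = (
    ("healthy_wm_vs_nawm", ("healthy", "WM"), ("patient", "WM")),
    ("nawm_vs_lesion", ("patient", "WM"), ("patient", "lesion")),
    ("nawm_vs_perilesion", ("patient", "WM"), ("patient", "perilesion")),
)

CORRELATION_TISSUES = (
    ("healthy_wm", "healthy", "WM"),
    ("nawm", "patient", "WM"),
    ("lesion", "patient", "lesion"),
)


def build_cohort_report(subject_means: pd.DataFrame,
                        comparisons=DEFAULT_COMPARISONS,
                        metric_families: dict[str, list[str]] | None = None) -> CohortStats:
    """Assemble t-test and correlation tables from subject-level VOI means.

    ``subject_means`` needs columns subject, group, voi, metric, mean.
    For every metric, each configured comparison is tested (skipped with a
    log row when a group has < 2 subjects). Correlations are computed for
    all unordered metric pairs within each metric family (e.g. the five
    myelin measures, the five g-ratio variants), separately per tissue
    class. No multiple-testing correction is applied; ``n_tests`` records
    how many tests were run.
    """
    required = {"subject", "group", "voi", "metric", "mean"}
    if not required.issubset(subject_means.columns):
        raise ValueError(f"subject_means must have columns {sorted(required)}")

    metrics = sorted(subject_means["metric"].unique())
    if metric_families is None:
        metric_families = {"all": metrics}

    def values_for(group: str, voi: str, metric: str) -> pd.Series:
        sel = subject_means[(subject_means["group"] == group)
                            & (subject_means["voi"] == voi)
                            & (subject_means["metric"] == metric)]
        return sel.set_index("subject")["mean"].dropna()

    t_rows = []
    n_tests = 0
    for metric in metrics:
        for name, (ga, va), (gb, vb) in comparisons:
            a = values_for(ga, va, metric)
            b = values_for(gb, vb, metric)
            if a.size < 2 or b.size < 2:
                t_rows.append({"comparison": name, "metric": metric, "t": np.nan,
                               "p": np.nan, "n_a": int(a.size), "n_b": int(b.size),
                               "skipped": True, "degenerate": False})
                continue
            t, p, degen = two_sample_ttest(a.to_numpy(), b.to_numpy())
            n_tests += 1
            t_rows.append({"comparison": name, "metric": metric, "t": t, "p": p,
                           "n_a": int(a.size), "n_b": int(b.size),
                           "skipped": False, "degenerate": degen})
    ttests = pd.DataFrame(t_rows)

    c_rows = []
    for family, fam_metrics in metric_families.items():
        fam_metrics = [m for m in fam_metrics if m in metrics]
        for tissue, group, voi in CORRELATION_TISSUES:
            for m1, m2 in itertools.combinations(fam_metrics, 2):
                x = values_for(group, voi, m1)
                y = values_for(group, voi, m2)
                common = x.index.intersection(y.index)
                if common.size < 3:
                    c_rows.append({"family": family, "tissue": tissue, "metric_a": m1,
                                   "metric_b": m2, "r": np.nan, "p": np.nan,
                                   "n": int(common.size), "skipped": True})
                    continue
                r, p, degen = pearson_corr(x.loc[common].to_numpy(),
                                           y.loc[common].to_numpy())
                n_tests += 1
                c_rows.append({"family": family, "tissue": tissue, "metric_a": m1,
                               "metric_b": m2, "r": r, "p": p,
                               "n": int(common.size), "skipped": degen})
    correlations = pd.DataFrame(c_rows)

    return CohortStats(voi_means=subject_means.copy(), ttests=ttests,
                       correlations=correlations, n_tests=n_tests)
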