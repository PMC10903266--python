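"""Ground-truth validation utilities for synthetic benchmark scenes.

Helpers to score a segmentation or classification against the exact
ground truth carried by generated scenes: centroid-based detection
matching, clone-recovery checks, and the global-threshold baseline the
trainable classifier is compared against.
"""

from __future__ import annotations

import dataclasses
from typing import Dict

import numpy as np
from scipy.stats import norm as _norm

from .counting import CountingConfig
from .synthetic import GroundTruth, SceneSpec, ZYG_HOM
from .twinspot import HETEROZYGOUS, HOMOZYGOUS
from .volumes import LabelVolume

__all__ = [
    "DetectionScore",
    "match_centroids",
    "object_truth_map",
    "min_interclone_gap",
    "clone_gap_threshold",
    "best_global_threshold_accuracy",
    "sample_annotations",
]


@dataclasses.dataclass
class DetectionScore:
    """Centroid-in-label detection score.

    A predicted label containing at least one ground-truth center is a
    true positive (counted once); labels containing none are false
    positives; centers beyond the first inside a label, or falling on
    background, are misses.
    """

    n_true: int
    n_predicted: int
    true_positives: int

    @property
    def precision(self) -> float:
        return self.true_positives / self.n_predicted if self.n_predicted else 0.0

    @property
    def recall(self) -> float:
        return self.true_positives / self.n_true if self.n_true else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def _labels_at_centers(gt: GroundTruth, labels: LabelVolume, channel: str) -> np.ndarray:
    idx = gt.channel_indices(channel)
    centers = np.rint(gt.centers[idx]).astype(int)
    shape = labels.shape
    centers = np.clip(centers, 0, np.array(shape) - 1)
    return labels.data[centers[:, 0], centers[:, 1], centers[:, 2]]


def match_centroids(gt: GroundTruth, labels: LabelVolume, channel: str = "dapi") -> DetectionScore:
    """Score a segmentation by the labels found at ground-truth centers."""
    at = _labels_at_centers(gt, labels, channel)
    hits = np.bincount(at[at > 0], minlength=labels.max_label + 1)
    return DetectionScore(
        n_true=int(at.size),
        n_predicted=int(labels.max_label),
        true_positives=int((hits[1:] > 0).sum()),
    )


def object_truth_map(gt: GroundTruth, labels: LabelVolume, channel: str = "twin") -> Dict[int, int]:
    """Map uniquely matched segmented labels to their true class code
    (1 = heterozygous, 2 = homozygous).  Labels claimed by several centers
    or centers on background are dropped."""
    idx = gt.channel_indices(channel)
    at = _labels_at_centers(gt, labels, channel)
    counts = np.bincount(at[at > 0], minlength=labels.max_label + 1)
    unique = (at > 0) & (counts[at] == 1)
    codes = np.where(gt.zygosity[idx] == ZYG_HOM, HOMOZYGOUS, HETEROZYGOUS)
    return {int(l): int(c) for l, c in zip(at[unique], codes[unique])}


def min_interclone_gap(gt: GroundTruth, spec: SceneSpec) -> float:
    """Smallest nucleus surface separation between different marked clones
    (normalized metric, in-plane voxels); inf with fewer than two clones."""
    idx = np.nonzero(gt.clone_id > 0)[0]
    if idx.size < 2:
        return float("inf")
    base = np.asarray(spec.nucleus_radii, dtype=float)
    cn = gt.centers[idx] / base
    s = gt.radii[idx][:, 1] / base[1]
    cid = gt.clone_id[idx]
    d = np.linalg.norm(cn[:, None, :] - cn[None, :, :], axis=2)
    sep = (d - s[:, None] - s[None, :]) * base[1]
    different = cid[:, None] != cid[None, :]
    return float(sep[different].min()) if different.any() else float("inf")


def clone_gap_threshold(spec: SceneSpec, counting_config: CountingConfig | None = None,
                        dilation_voxels: int = 1) -> float:
    """Ground-truth gap above which clone fusion cannot occur.

    Watershed labels extend past the nucleus surface to where the blurred
    edge falls below the watershed mask cut, so clones stay separate only
    when nucleus gaps exceed the nominal ``2 * (dilation + 1)`` plus twice
    that point-spread halo.  The halo is the distance at which a blurred
    intensity step of the scene's nuclear amplitude decays to the mask
    cut."""
    counting_config = counting_config or CountingConfig()
    sigma_total = float(np.hypot(spec.psf_sigma, counting_config.gaussian_sigma))
    max_value = (1 << spec.bit_depth) - 1
    cut = max_value - counting_config.resolve_max_intensity(spec.bit_depth)
    amplitude = spec.intensity.base
    halo = sigma_total * float(_norm.isf(min(cut / amplitude, 0.5)))
    return 2.0 * (dilation_voxels + 1) + 2.0 * halo


def best_global_threshold_accuracy(values: np.ndarray, codes: np.ndarray) -> float:
    """Accuracy of the best single intensity threshold (bright = homozygous),
    maximized over all candidate cuts — the baseline that regional intensity
    variation defeats."""
    values = np.asarray(values, dtype=float)
    codes = np.asarray(codes)
    order = np.argsort(values)
    v, y = values[order], codes[order]
    candidates = np.concatenate([[v[0] - 1.0], (v[1:] + v[:-1]) / 2.0, [v[-1] + 1.0]])
    best = 0.0
    is_hom = y == HOMOZYGOUS
    for t in candidates:
        best = max(best, float(((v > t) == is_hom).mean()))
    return best


def sample_annotations(
    truth: Dict[int, int], n_per_class: int, rng: np.random.Generator
) -> Dict[int, int]:
    """Draw a balanced training annotation set from a truth map."""
    out: Dict[int, int] = {}
    for code in (HETEROZYGOUS, HOMOZYGOUS):
        ids = np.array(sorted(l for l, c in truth.items() if c == code))
        chosen = rng.choice(ids, size=min(n_per_class, ids.size), replace=False)
        out.update({int(l): code for l in chosen})
    return out
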