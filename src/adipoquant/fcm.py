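"""Fuzzy C-means clustering of the fat-side intensities, region merging,
and skin/abdominal-wall stripping.

After the wall contour has converged, the body splits into a subcutaneous
side (outside the contour, inside the body mask) and a visceral side
(inside the contour). Each side is clustered independently — 3 classes for
the SAT side and 5 for the more heterogeneous VAT side — and the fat-like
clusters are merged by intensity proximity to the brightest class plus
spatial adjacency. Skin and the abdominal muscle wall are then stripped
from the subcutaneous mask.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .contour import LevelSetField


@dataclass
class MembershipMatrix:
    """Result of an FCM run: per-voxel graded class memberships.

    ``memberships`` has shape (N voxels, C classes), rows summing to 1;
    ``centroids`` are the class intensity centres sorted ascending;
    ``objective`` is the (non-increasing) value sequence of the FCM cost.
    """

    memberships: np.ndarray
    centroids: np.ndarray
    fuzzifier_m: float
    n_iters: int
    objective: list[float]


@dataclass
class RegionPartition:
    """Hard class labels over a voxel mask, with adjacency and class stats."""

    labels: np.ndarray  # per-voxel class id, -1 outside the mask
    class_means: np.ndarray
    class_counts: np.ndarray
    adjacency: np.ndarray  # symmetric class-pair contact counts


def _init_centroids(values: np.ndarray, n_classes: int, seed=None) -> np.ndarray:
    """Deterministic initialization at evenly spaced quantiles; a seed, if
    given, adds a small reproducible jitter."""
    qs = (np.arange(n_classes) + 0.5) / n_classes
    centroids = np.quantile(values, qs)
    # collapse-proof: spread exactly coincident centroids
    for i in range(1, n_classes):
        if centroids[i] <= centroids[i - 1]:
            centroids[i] = centroids[i - 1] + 1e-9
    if seed is not None:
        rng = np.random.default_rng(seed)
        span = np.ptp(values) or 1.0
        centroids = centroids + rng.normal(0, 1e-3 * span, n_classes)
    return centroids


def fcm(
    intensities: np.ndarray,
    n_classes: int,
    fuzzifier_m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed=None,
) -> MembershipMatrix:
    """Fuzzy C-means on a 1-D list of voxel intensities.

    Standard alternation: memberships from inverse-distance ratios with
    exponent 2/(m-1), centroids as membership**m weighted means, iterated
    until the largest centroid movement falls below ``tol`` or ``max_iter``
    is reached. Initialization is deterministic (intensity quantiles), so
    runs are bit-reproducible; ``seed`` adds jitter only when given.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if fuzzifier_m <= 1:
        raise ValidationError("fuzzifier m must be > 1")
    if n_classes < 1:
        raise ValidationError("n_classes must be >= 1")
    if np.unique(x).size < n_classes:
        raise ValidationError(
            f"need at least {n_classes} distinct intensity values, "
            f"got {np.unique(x).size}"
        )
    centroids = _init_centroids(x, n_classes, seed=seed)
    exponent = 2.0 / (fuzzifier_m - 1.0)
    objective: list[float] = []
    u = np.full((x.size, n_classes), 1.0 / n_classes)
    n_done = 0
    for n_done in range(1, max_iter + 1):
        d = np.abs(x[:, None] - centroids[None, :])  # (N, C)
        zero = d < 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d ** (-exponent)
            u = inv / inv.sum(axis=1, keepdims=True)
        # voxels sitting exactly on a centroid get full membership there
        rows = zero.any(axis=1)
        if rows.any():
            u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
        um = u**fuzzifier_m
        objective.append(float((um * d**2).sum()))
        new_centroids = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = np.max(np.abs(new_centroids - centroids))
        centroids = new_centroids
        if shift < tol:
            break
    order = np.argsort(centroids)
    return MembershipMatrix(
        memberships=u[:, order],
        centroids=centroids[order],
        fuzzifier_m=fuzzifier_m,
        n_iters=n_done,
        objective=objective,
    )


def harden(
    membership: MembershipMatrix,
    mask: np.ndarray,
    pixels: np.ndarray,
) -> RegionPartition:
    """Maximum-membership defuzzification over the voxels of ``mask``.

    Ties are broken toward the class with the higher centroid. Returns a
    partition with per-class mean intensities, counts, and the symmetric
    class-adjacency (4-neighbour contact) matrix used for region merging.
    """
    mask = np.asarray(mask, dtype=bool)
    u = membership.memberships
    if u.shape[0] != int(mask.sum()):
        raise ValidationError("membership rows do not match the mask voxel count")
    c = u.shape[1]
    # argmax with ties toward higher centroid: scan classes from brightest
    rev = u[:, ::-1]
    hard = c - 1 - np.argmax(rev, axis=1)
    labels = np.full(mask.shape, -1, dtype=int)
    labels[mask] = hard
    vals = np.asarray(pixels, dtype=float)[mask]
    means = np.array(
        [vals[hard == k].mean() if (hard == k).any() else np.nan for k in range(c)]
    )
    counts = np.array([(hard == k).sum() for k in range(c)])
    adjacency = np.zeros((c, c), dtype=int)
    for axis in range(labels.ndim):
        a = labels
        b = np.roll(labels, -1, axis=axis)
        sl = [slice(None)] * labels.ndim
        sl[axis] = slice(0, -1)
        aa, bb = a[tuple(sl)], b[tuple(sl)]
        valid = (aa >= 0) & (bb >= 0) & (aa != bb)
        np.add.at(adjacency, (aa[valid], bb[valid]), 1)
    adjacency = adjacency + adjacency.T
    return RegionPartition(
        labels=labels, class_means=means, class_counts=counts, adjacency=adjacency
    )


def merge_regions(
    partition: RegionPartition, intensity_gap: float = 0.15
) -> np.ndarray:
    """Merge fat-like classes into one binary fat mask.

    The brightest class anchors the fat mask; every class whose mean
    intensity lies within ``intensity_gap`` of the anchor's mean AND whose
    region touches the anchor's region is merged in. Everything else
    (muscle, organs, partial-volume shells) is excluded.
    """
    means = partition.class_means
    valid = ~np.isnan(means)
    if not valid.any() or partition.class_counts[valid].sum() == 0:
        raise ValidationError("partition has no populated classes")
    anchor = int(np.nanargmax(means))
    if partition.class_counts[anchor] == 0:
        raise ValidationError("brightest class is empty")
    merged = {anchor}
    for k in range(len(means)):
        if k == anchor or np.isnan(means[k]):
            continue
        close = (means[anchor] - means[k]) <= intensity_gap
        if close and partition.adjacency[k, anchor] > 0:
            merged.add(k)
    out = np.isin(partition.labels, sorted(merged)) & (partition.labels >= 0)
    return out


def strip_skin_wall(
    sat_mask: np.ndarray,
    body_mask: np.ndarray,
    wall_contour: LevelSetField,
    skin_depth: float = 2.0,
    wall_depth: float = 1.0,
) -> np.ndarray:
    """Remove skin and abdominal-wall voxels from the subcutaneous fat mask.

    Strips a ``skin_depth``-thick band just inside the body outline and a
    ``wall_depth``-thick band around the converged wall contour (|phi| <
    wall_depth). Zero depths are the identity. If everything is removed a
    warning is issued and the empty mask returned.
    """
    sat_mask = np.asarray(sat_mask, dtype=bool)
    body_mask = np.asarray(body_mask, dtype=bool)
    if sat_mask.shape != body_mask.shape:
        raise ValidationError("mask shapes differ")
    if skin_depth < 0 or wall_depth < 0:
        raise ValidationError("strip depths must be >= 0")
    if not sat_mask.any():
        warnings.warn("strip_skin_wall called with an empty SAT mask", stacklevel=2)
        return sat_mask.copy()
    out = sat_mask.copy()
    if skin_depth > 0 and body_mask.any():
        # pixel centers sit ~0.5 px inside the continuous body outline
        depth_in = ndimage.distance_transform_edt(body_mask) - 0.5
        out &= ~(body_mask & (depth_in <= skin_depth))
    if wall_depth > 0:
        out &= ~(np.abs(wall_contour.phi) < wall_depth)
    if sat_mask.any() and not out.any():
        warnings.warn(
            "skin/wall stripping removed every SAT voxel; depths likely "
            "exceed the subcutaneous ring thickness",
            stacklevel=2,
        )
    return out
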