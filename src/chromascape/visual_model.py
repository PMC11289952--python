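"""Observer-dependent perceptual computation.

Implements the receptor-noise-limited (RNL) model of color and luminance
discrimination for a trichromatic observer with a double cone (modeled on
the triggerfish *Rhinecanthus aculeatus*): Weber fractions from receptor
noise and relative channel abundances, chromatic and achromatic
perceptual distances (dS, in just-noticeable-difference units),
acuity-dependent viewing-distance blur, RNL ranked filtering to remove
blur artifacts, and RNL clustering of an image into patch classes that
the observer can discriminate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import CHANNELS, ConeCatchImage

__all__ = [
    "VisualSystem",
    "ViewingGeometry",
    "ClusteredImage",
    "weber_fractions",
    "delta_s_chromatic",
    "delta_s_luminance",
    "saturation",
    "apply_acuity",
    "rnl_ranked_filter",
    "rnl_cluster",
]


def weber_fractions(abundances, noise: float) -> np.ndarray:
    """Per-channel Weber fractions from relative abundances and noise.

    The channel with the largest relative photoreceptor abundance has
    Weber fraction equal to the receptor noise; rarer channels are
    noisier in proportion to the square root of the abundance ratio:

        omega_i = noise * sqrt(eta_max / eta_i)

    For the triggerfish defaults (1:2:2:2 sw:mw:lw:dbl, noise 0.05) this
    gives 0.07:0.05:0.05:0.05 after rounding to two decimals.
    """
    eta = np.asarray(abundances, dtype=np.float64)
    if np.any(eta <= 0):
        raise ValueError("relative abundances must be strictly positive")
    if noise <= 0:
        raise ValueError("receptor noise must be strictly positive")
    return noise * np.sqrt(eta.max() / eta)


@dataclass(frozen=True)
class VisualSystem:
    """Observer description driving all perceptual computation.

    Defaults describe *R. aculeatus*: three single cones (sw, mw, lw)
    plus a double cone (dbl) used for luminance, relative abundances
    1:2:2:2, receptor noise 0.05 and spatial acuity 3 cycles/degree.
    """

    channel_names: tuple[str, ...] = CHANNELS
    relative_abundances: tuple[float, ...] = (1.0, 2.0, 2.0, 2.0)
    receptor_noise: float = 0.05
    acuity_cpd: float = 3.0
    chromatic_channels: tuple[int, int, int] = (0, 1, 2)
    luminance_channel: int = 3

    def __post_init__(self) -> None:
        if self.acuity_cpd <= 0:
            raise ValueError("acuity must be positive")
        # validate via weber_fractions (raises on bad abundances/noise)
        weber_fractions(self.relative_abundances, self.receptor_noise)

    @property
    def weber(self) -> np.ndarray:
        """Weber fraction per channel (same order as channel_names)."""
        return weber_fractions(self.relative_abundances, self.receptor_noise)

    @property
    def weber_chromatic(self) -> np.ndarray:
        return self.weber[list(self.chromatic_channels)]

    @property
    def weber_luminance(self) -> float:
        return float(self.weber[self.luminance_channel])


@dataclass(frozen=True)
class ViewingGeometry:
    """Viewing distance and image scale linking pixels to visual angle."""

    distance_cm: float
    px_per_mm: float

    def __post_init__(self) -> None:
        if self.distance_cm <= 0 or self.px_per_mm <= 0:
            raise ValueError("distance and scale must be positive")

    @property
    def degrees_per_px(self) -> float:
        mm_per_px = 1.0 / self.px_per_mm
        return math.degrees(math.atan(mm_per_px / (self.distance_cm * 10.0)))


# ---------------------------------------------------------------------------
# Perceptual distances
# ---------------------------------------------------------------------------


def _check_positive(q: np.ndarray, what: str) -> np.ndarray:
    q = np.asarray(q, dtype=np.float64)
    if np.any(q <= 0) or not np.all(np.isfinite(q)):
        raise ValueError(f"{what} must be strictly positive and finite")
    return q


def delta_s_chromatic(catch_a, catch_b, vs: VisualSystem) -> np.ndarray:
    """Chromatic RNL distance dS between two catches (JND units).

    Works on single 3-vectors or broadcastable arrays of shape (..., 3).
    Operates on log catch ratios, so a common scaling of all channels
    (an intensity change) contributes nothing: only hue/saturation
    differences register. Equivalent to the Mahalanobis distance between
    the log-catch contrast vectors under independent channel noise,
    restricted to the chromatic plane.
    """
    qa = _check_positive(catch_a, "catches")
    qb = _check_positive(catch_b, "catches")
    w1, w2, w3 = vs.weber_chromatic
    df = np.log(qa) - np.log(qb)
    d1, d2, d3 = df[..., 0], df[..., 1], df[..., 2]
    num = (
        w1**2 * (d2 - d3) ** 2
        + w2**2 * (d1 - d3) ** 2
        + w3**2 * (d1 - d2) ** 2
    )
    den = (w1 * w2) ** 2 + (w1 * w3) ** 2 + (w2 * w3) ** 2
    out = np.sqrt(num / den)
    return out if out.ndim else float(out)


def delta_s_luminance(catch_a, catch_b, vs: VisualSystem) -> np.ndarray:
    """Achromatic (double-cone) RNL contrast dL = |ln(qa/qb)| / omega."""
    qa = _check_positive(catch_a, "catches")
    qb = _check_positive(catch_b, "catches")
    out = np.abs(np.log(qa) - np.log(qb)) / vs.weber_luminance
    return out if out.ndim else float(out)


def combined_distance(catch_a4, catch_b4, vs: VisualSystem) -> np.ndarray:
    """Euclidean combination sqrt(dS^2 + dL^2) of 4-channel catches."""
    ds = delta_s_chromatic(catch_a4[..., :3], catch_b4[..., :3], vs)
    dl = delta_s_luminance(catch_a4[..., 3], catch_b4[..., 3], vs)
    return np.hypot(ds, dl)


def saturation(catch_chrom, vs: VisualSystem) -> np.ndarray:
    """Chromatic dS of a catch from the achromatic (equal-catch) locus."""
    q = np.asarray(catch_chrom, dtype=np.float64)
    grey = np.ones_like(q)
    return delta_s_chromatic(q, grey, vs)


# ---------------------------------------------------------------------------
# Acuity modeling
# ---------------------------------------------------------------------------


def acuity_sigma_px(vs: VisualSystem, geom: ViewingGeometry) -> float:
    """Gaussian blur sigma (pixels) for the observer at a viewing distance.

    The blur represents the observer's modulation transfer: sigma is set
    so that the transfer at the acuity limit (``acuity_cpd``, mapped
    through viewing distance and image scale to a pixel frequency) is
    10%. Detail finer than the minimum resolvable angle is attenuated.
    """
    f_cutoff = vs.acuity_cpd * geom.degrees_per_px  # cycles / px
    return math.sqrt(math.log(10.0)) / (math.sqrt(2.0) * math.pi * f_cutoff)


def apply_acuity(
    img: ConeCatchImage, vs: VisualSystem, geom: ViewingGeometry
) -> ConeCatchImage:
    """Low-pass the image to the observer's spatial resolution.

    Channel-wise linear Gaussian blur; output catches stay positive.
    Raises if the blur extent exceeds the image (the scene would be a
    single unresolvable point at that distance).
    """
    sigma = acuity_sigma_px(vs, geom)
    h, w = img.shape
    if 3.0 * sigma > min(h, w):
        raise ValueError(
            f"blur extent ({3 * sigma:.1f} px) exceeds image size {min(h, w)} px; "
            "scene unresolvable at this distance/scale"
        )
    out = np.empty_like(img.data)
    for c in range(img.data.shape[2]):
        out[..., c] = ndimage.gaussian_filter(img.data[..., c], sigma, mode="reflect")
    return img.with_data(out)


# ---------------------------------------------------------------------------
# RNL ranked filter
# ---------------------------------------------------------------------------


def _disk_offsets(radius: int) -> list[tuple[int, int]]:
    offs = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if (dy or dx) and dy * dy + dx * dx <= radius * radius:
                offs.append((dy, dx))
    return offs


def rnl_ranked_filter(
    img: ConeCatchImage,
    vs: VisualSystem,
    falloff: int = 3,
    radius: int = 5,
    repetition: int = 5,
) -> ConeCatchImage:
    """Edge-preserving smoothing in perceptual (RNL) space.

    For each pixel, neighbors within ``radius`` are ranked by combined
    RNL distance sqrt(dS^2 + dL^2) to the center; the pixel is replaced
    by the mean of cone catches weighted by (1 - rank/N) ** falloff
    (the center itself has rank 0, weight 1). Applied ``repetition``
    times. Perceptually similar neighbors dominate the average, so
    genuine edges survive while acuity-blur gradients are flattened.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if repetition < 0:
        raise ValueError("repetition must be >= 0")
    if repetition == 0:
        return img

    offsets = _disk_offsets(radius)
    n_weights = len(offsets) + 1  # + center
    h, w = img.shape
    data = img.data
    for _ in range(repetition):
        padded = np.pad(data, ((radius, radius), (radius, radius), (0, 0)), mode="reflect")
        shifted = np.empty((len(offsets), h, w, data.shape[2]))
        for k, (dy, dx) in enumerate(offsets):
            shifted[k] = padded[
                radius + dy : radius + dy + h, radius + dx : radius + dx + w
            ]
        dist = combined_distance(shifted, data[None], vs)  # (n_off, h, w)
        order = np.argsort(dist, axis=0, kind="stable")
        ranks = np.empty_like(order)
        np.put_along_axis(
            ranks, order, np.arange(1, len(offsets) + 1)[:, None, None] * np.ones_like(order[:1]), axis=0
        )
        weights = (1.0 - ranks / n_weights) ** falloff
        num = data + np.einsum("khw,khwc->hwc", weights, shifted)
        den = 1.0 + weights.sum(axis=0)
        data = num / den[..., None]
    return img.with_data(data)


# ---------------------------------------------------------------------------
# RNL clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusteredImage:
    """Result of RNL clustering: integer patch classes plus a class table.

    ``class_map`` holds 0-based class labels inside the mask and -1
    outside. ``class_table`` has one row per class: mean catches,
    luminance (mean double-cone catch), saturation, and relative
    abundance (fraction of mask pixels). Any two classes differ by at
    least the chromatic OR the achromatic discrimination threshold.
    """

    class_map: np.ndarray
    class_table: pd.DataFrame
    px_per_mm: float
    t_color: float = 2.0
    t_lum: float = 4.0

    @property
    def n_classes(self) -> int:
        return len(self.class_table)

    @property
    def mask(self) -> np.ndarray:
        return self.class_map >= 0


def clustered_from_class_map(
    class_map: np.ndarray,
    colors: np.ndarray,
    px_per_mm: float,
    vs: VisualSystem,
    t_color: float = 2.0,
    t_lum: float = 4.0,
) -> ClusteredImage:
    """Build a ClusteredImage from a known class map and class colors.

    Convenience for constructing ground-truth segmentations (labels >= 0
    inside the mask, -1 outside); ``colors`` holds one 4-channel catch
    per class.
    """
    class_map = np.asarray(class_map, dtype=np.int32)
    colors = np.asarray(colors, dtype=np.float64)
    mask = class_map >= 0
    labels = np.unique(class_map[mask])
    rows = []
    n_in = mask.sum()
    for rank, c in enumerate(labels):
        m = colors[c]
        rows.append(
            {
                "class": rank,
                "abundance": float((class_map == c).sum() / n_in),
                "q_sw": m[0],
                "q_mw": m[1],
                "q_lw": m[2],
                "q_dbl": m[3],
                "luminance": m[3],
                "saturation": float(saturation(m[:3], vs)),
            }
        )
    relabel = np.full(class_map.max() + 1, -1, dtype=np.int32)
    for rank, c in enumerate(labels):
        relabel[c] = rank
    out_map = np.where(mask, relabel[np.clip(class_map, 0, None)], -1)
    table = pd.DataFrame(rows).set_index("class")
    return ClusteredImage(out_map.astype(np.int32), table, px_per_mm, t_color, t_lum)


def _farthest_point_seeds(
    pix: np.ndarray, vs: VisualSystem, n_seeds: int
) -> np.ndarray:
    """Deterministic farthest-point seed selection in combined RNL space."""
    first = int(np.argmax(pix[:, 3]))  # brightest pixel; ties -> lowest index
    seeds = [first]
    min_d = combined_distance(pix, pix[first], vs)
    while len(seeds) < n_seeds:
        nxt = int(np.argmax(min_d))
        if min_d[nxt] <= 1e-12:
            break  # no perceptually distinct pixel left
        seeds.append(nxt)
        min_d = np.minimum(min_d, combined_distance(pix, pix[nxt], vs))
    return pix[seeds]


def _region_pair_distances(means: np.ndarray, vs: VisualSystem):
    ds = delta_s_chromatic(means[:, None, :3], means[None, :, :3], vs)
    dl = delta_s_luminance(means[:, None, 3], means[None, :, 3], vs)
    return ds, dl


def rnl_cluster(
    img: ConeCatchImage,
    mask: np.ndarray,
    vs: VisualSystem,
    t_color: float = 2.0,
    t_lum: float = 4.0,
    n_seeds: int = 10,
) -> ClusteredImage:
    """Segment an image into patch classes discriminable to the observer.

    Pixels are first assigned to perceptual prototypes (farthest-point
    seeds in RNL space) and split into spatially connected regions.
    Adjacent regions are then merged agglomeratively whenever their
    means fall below BOTH the chromatic threshold ``t_color`` and the
    achromatic threshold ``t_lum`` (a pair exceeding either threshold is
    discriminable and stays split), smallest combined distance first,
    means recomputed after each merge. A final global pass merges
    indiscriminable classes regardless of adjacency, so the class table
    satisfies the pairwise-discriminability invariant.
    """
    if t_color <= 0 or t_lum <= 0:
        raise ValueError("thresholds must be positive")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("mask shape must match image")
    if not mask.any():
        raise ValueError("empty mask")

    data = img.data
    pix = data[mask]
    seeds = _farthest_point_seeds(pix, vs, n_seeds)
    # nearest-seed assignment in combined RNL distance
    d = combined_distance(pix[:, None, :], seeds[None, :, :], vs)  # (n, k)
    assign = np.argmin(d, axis=1)
    assign_map = np.full(img.shape, -1, dtype=np.int32)
    assign_map[mask] = assign

    # connected components of the assignment map -> initial regions
    region_map = np.full(img.shape, -1, dtype=np.int32)
    next_id = 0
    for s in range(len(seeds)):
        lab, n = ndimage.label(assign_map == s, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        for i in range(1, n + 1):
            region_map[lab == i] = next_id
            next_id += 1
    n_regions = next_id

    sums = np.zeros((n_regions, 4))
    counts = np.zeros(n_regions)
    flat_r = region_map[mask]
    np.add.at(sums, flat_r, pix)
    np.add.at(counts, flat_r, 1)

    # adjacency edges (4-connectivity, inside mask)
    def _edges_from(map_: np.ndarray) -> set[tuple[int, int]]:
        e = set()
        a, b = map_[:, :-1], map_[:, 1:]
        sel = (a >= 0) & (b >= 0) & (a != b)
        for x, y in zip(a[sel].ravel(), b[sel].ravel()):
            e.add((min(x, y), max(x, y)))
        a, b = map_[:-1, :], map_[1:, :]
        sel = (a >= 0) & (b >= 0) & (a != b)
        for x, y in zip(a[sel].ravel(), b[sel].ravel()):
            e.add((min(x, y), max(x, y)))
        return e

    edges = _edges_from(region_map)
    parent = np.arange(n_regions)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def pair_dist(i: int, j: int):
        mi, mj = sums[i] / counts[i], sums[j] / counts[j]
        ds = delta_s_chromatic(mi[:3], mj[:3], vs)
        dl = delta_s_luminance(mi[3], mj[3], vs)
        return ds, dl

    # agglomerative merge of adjacent regions to a fixed point
    while True:
        best = None
        for i, j in sorted(edges):
            ri, rj = find(i), find(j)
            if ri == rj:
                continue
            ds, dl = pair_dist(ri, rj)
            if ds < t_color and dl < t_lum:
                key = (math.hypot(ds, dl), min(ri, rj), max(ri, rj))
                if best is None or key < best:
                    best = key
        if best is None:
            break
        _, ri, rj = best
        parent[rj] = ri
        sums[ri] += sums[rj]
        counts[ri] += counts[rj]

    roots = sorted({find(r) for r in range(n_regions) if counts[find(r)] > 0})
    # global pass: merge indiscriminable classes regardless of adjacency
    cls_parent = {r: r for r in roots}

    def cfind(r: int) -> int:
        while cls_parent[r] != r:
            cls_parent[r] = cls_parent[cls_parent[r]]
            r = cls_parent[r]
        return r

    while True:
        live = sorted({cfind(r) for r in roots})
        best = None
        for a_idx in range(len(live)):
            for b_idx in range(a_idx + 1, len(live)):
                i, j = live[a_idx], live[b_idx]
                ds, dl = pair_dist(i, j)
                if ds < t_color and dl < t_lum:
                    key = (math.hypot(ds, dl), i, j)
                    if best is None or key < best:
                        best = key
        if best is None:
            break
        _, i, j = best
        cls_parent[j] = i
        sums[i] += sums[j]
        counts[i] += counts[j]

    final_roots = sorted({cfind(r) for r in roots})
    means = np.array([sums[r] / counts[r] for r in final_roots])
    abundance = np.array([counts[r] for r in final_roots])
    abundance = abundance / abundance.sum()
    # stable labels: by decreasing abundance, ties by luminance then root id
    order = sorted(
        range(len(final_roots)),
        key=lambda k: (-abundance[k], -means[k, 3], final_roots[k]),
    )
    relabel = {final_roots[k]: rank for rank, k in enumerate(order)}

    class_map = np.full(img.shape, -1, dtype=np.int32)
    lut = np.full(n_regions, -1, dtype=np.int32)
    for r in range(n_regions):
        if counts[find(r)] > 0 or True:
            root = cfind(find(r)) if find(r) in cls_parent else find(r)
            lut[r] = relabel.get(root, -1)
    class_map[mask] = lut[flat_r]

    rows = []
    for rank, k in enumerate(order):
        m = means[k]
        rows.append(
            {
                "class": rank,
                "abundance": abundance[k],
                "q_sw": m[0],
                "q_mw": m[1],
                "q_lw": m[2],
                "q_dbl": m[3],
                "luminance": m[3],
                "saturation": float(saturation(m[:3], vs)),
            }
        )
    table = pd.DataFrame(rows).set_index("class")
    return ClusteredImage(class_map, table, img.px_per_mm, t_color, t_lum)
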