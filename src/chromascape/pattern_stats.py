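"""Spatiochromatic color-pattern statistics.

Four families, computed per image per viewing distance:

* CAA (color adjacency analysis): a transition matrix of synonymous /
  nonsynonymous class transitions along horizontal and vertical
  transects describes pattern geometry (patch size, evenness, aspect).
* VCA (visual contrast analysis): abundance-weighted pairwise contrasts
  between patch classes.
* BSA (boundary strength analysis): contrasts weighted by how much
  boundary two classes actually share (off-diagonal transition
  frequencies).
* LEIA (local edge intensity analysis): distributions of pixel-to-
  neighbor RNL contrasts in the unsegmented (filtered) image.

Statistics ending in ``.hrz`` / ``.vrt`` are the horizontal (across the
body axis) and vertical (along the body axis) variants. Degenerate
inputs (a single patch class, no boundaries, zero variance) yield NaN;
downstream filtering removes such images, which is itself part of the
analysis (uniform backgrounds carry no pattern information).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import ConeCatchImage
from .visual_model import (
    ClusteredImage,
    VisualSystem,
    delta_s_chromatic,
    delta_s_luminance,
)

__all__ = [
    "TransitionMatrix",
    "transition_matrix",
    "caa_stats",
    "vca_stats",
    "bsa_stats",
    "leia_stats",
    "compute_stat_record",
    "STAT_NAMES",
]


@dataclass
class TransitionMatrix:
    """Counts of adjacent class pairs along sampling transects.

    ``horizontal_counts[a, b]`` counts left->right sample pairs with
    classes (a, b); ``vertical_counts`` the top->bottom pairs.
    ``counts`` is their sum. Diagonal entries are synonymous
    transitions (same class), off-diagonal nonsynonymous.
    """

    horizontal_counts: np.ndarray
    vertical_counts: np.ndarray
    sample_spacing: int = 1

    @property
    def counts(self) -> np.ndarray:
        return self.horizontal_counts + self.vertical_counts

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def symmetric(self) -> np.ndarray:
        c = self.counts
        return c + c.T - np.diag(np.diag(c))

    def offdiag_pair_counts(self) -> dict[tuple[int, int], float]:
        """Unordered off-diagonal pair -> total transition count."""
        c = self.counts
        out = {}
        k = self.n_classes
        for a in range(k):
            for b in range(a + 1, k):
                n = c[a, b] + c[b, a]
                if n > 0:
                    out[(a, b)] = float(n)
        return out


def _directional_counts(cls: np.ndarray, k: int, axis: int, spacing: int) -> np.ndarray:
    """Count class pairs between samples ``spacing`` apart along ``axis``."""
    if axis == 0:
        a, b = cls[:-spacing:, :], cls[spacing:, :]
    else:
        a, b = cls[:, :-spacing], cls[:, spacing:]
    valid = (a >= 0) & (b >= 0)
    pairs = a[valid] * k + b[valid]
    return np.bincount(pairs, minlength=k * k).reshape(k, k).astype(np.float64)


def transition_matrix(clustered: ClusteredImage, spacing: int = 1) -> TransitionMatrix:
    """Tally synonymous and nonsynonymous class transitions.

    Every horizontal and every vertical transect is sampled at the given
    pixel spacing; pairs with either sample outside the mask are
    ignored.
    """
    cls = clustered.class_map
    k = clustered.n_classes
    h = _directional_counts(cls, k, axis=1, spacing=spacing)
    v = _directional_counts(cls, k, axis=0, spacing=spacing)
    return TransitionMatrix(h, v, spacing)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _shannon_evenness(freqs: np.ndarray) -> float:
    """H / ln(m) over the m provided categories; 1 if only one category."""
    f = np.asarray(freqs, dtype=np.float64)
    f = f / f.sum()
    if len(f) == 1:
        return 1.0
    nz = f[f > 0]
    h = -(nz * np.log(nz)).sum()
    return float(h / np.log(len(f)))


def _weighted_mean_sd(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    w = w / w.sum()
    m = float((w * x).sum())
    var = float((w * (x - m) ** 2).sum())
    return m, np.sqrt(max(var, 0.0))


def _cov(x: np.ndarray, w: np.ndarray) -> float:
    m, s = _weighted_mean_sd(x, w)
    return s / m if m != 0 else np.nan


def _excess_kurtosis(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 2:
        return np.nan
    m = x.mean()
    v = ((x - m) ** 2).mean()
    if v <= 0:
        return np.nan
    return float(((x - m) ** 4).mean() / v**2 - 3.0)


def _class_pair_contrasts(clustered: ClusteredImage, vs: VisualSystem):
    """Per unordered class pair: chromatic dS, achromatic dL, |dSat|."""
    t = clustered.class_table
    q = t[["q_sw", "q_mw", "q_lw", "q_dbl"]].to_numpy()
    sat = t["saturation"].to_numpy()
    k = len(t)
    iu = np.triu_indices(k, 1)
    ds = np.atleast_1d(delta_s_chromatic(q[iu[0], :3], q[iu[1], :3], vs))
    dl = np.atleast_1d(delta_s_luminance(q[iu[0], 3], q[iu[1], 3], vs))
    dsat = np.abs(sat[iu[0]] - sat[iu[1]])
    return iu, ds, dl, dsat


# ---------------------------------------------------------------------------
# CAA
# ---------------------------------------------------------------------------


def caa_stats(clustered: ClusteredImage, tm: TransitionMatrix) -> dict[str, float]:
    """Color adjacency statistics from the class map and transitions."""
    out: dict[str, float] = {}
    mask = clustered.mask

    # CAA.PT: mean 4-connected patch size over the mask, in mm^2
    sizes = []
    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for c in range(clustered.n_classes):
        lab, n = ndimage.label((clustered.class_map == c) & mask, structure=four)
        if n:
            sizes.extend(np.bincount(lab.ravel())[1:])
    mm2_per_px = 1.0 / clustered.px_per_mm**2
    out["CAA.PT"] = float(np.mean(sizes) * mm2_per_px) if sizes else np.nan

    # class-abundance evenness
    ab = clustered.class_table["abundance"].to_numpy()
    out["CAA.Qc"] = _shannon_evenness(ab)

    # transition evenness over unordered off-diagonal pair types
    def _qt(counts: np.ndarray) -> float:
        k = counts.shape[0]
        m = k * (k - 1) // 2
        if m == 0:
            return np.nan
        pair = counts + counts.T
        vals = pair[np.triu_indices(k, 1)]
        if vals.sum() == 0:
            return np.nan
        return _shannon_evenness(vals) if m > 1 else 1.0

    out["CAA.Qt"] = _qt(tm.counts)
    out["CAA.Qt.hrz"] = _qt(tm.horizontal_counts)
    out["CAA.Qt.vrt"] = _qt(tm.vertical_counts)

    # aspect ratio of nonsynonymous transition rates (hrz / vrt)
    def _nonsyn_rate(c: np.ndarray) -> float:
        tot = c.sum()
        if tot == 0:
            return np.nan
        return float((tot - np.trace(c)) / tot)

    rh, rv = _nonsyn_rate(tm.horizontal_counts), _nonsyn_rate(tm.vertical_counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["CAA.Asp"] = float(np.divide(rh, rv))
    return out


# ---------------------------------------------------------------------------
# VCA
# ---------------------------------------------------------------------------


def vca_stats(clustered: ClusteredImage, vs: VisualSystem) -> dict[str, float]:
    """Abundance-weighted visual contrast statistics between classes."""
    t = clustered.class_table
    ab = t["abundance"].to_numpy()
    sat = t["saturation"].to_numpy()
    lum = t["luminance"].to_numpy()
    out = {
        "VCA.MeanLum": float((ab * lum).sum()),
        "VCA.MeanSat": float((ab * sat).sum()),
    }
    if len(t) < 2:
        out.update({"VCA.ML": np.nan, "VCA.MSL": np.nan, "VCA.CVS": np.nan})
        return out
    iu, ds, dl, _ = _class_pair_contrasts(clustered, vs)
    w = ab[iu[0]] * ab[iu[1]]
    ml, msl = _weighted_mean_sd(dl, w)
    out["VCA.ML"] = ml
    out["VCA.MSL"] = msl
    out["VCA.CVS"] = _cov(sat, ab)
    return out


# ---------------------------------------------------------------------------
# BSA
# ---------------------------------------------------------------------------


def bsa_stats(
    clustered: ClusteredImage, tm: TransitionMatrix, vs: VisualSystem
) -> dict[str, float]:
    """Boundary-strength statistics: contrasts weighted by shared boundary."""
    names = ("BSA.BML", "BSA.BMS", "BSA.BCVL", "BSA.BCVSsat")
    pair_counts = tm.offdiag_pair_counts()
    if not pair_counts:
        return {n: np.nan for n in names}
    iu, ds, dl, dsat = _class_pair_contrasts(clustered, vs)
    pair_index = {(a, b): i for i, (a, b) in enumerate(zip(*iu))}
    w = np.array([pair_counts[p] for p in pair_counts])
    idx = np.array([pair_index[p] for p in pair_counts])
    bml, bsl = _weighted_mean_sd(dl[idx], w)
    bms, _ = _weighted_mean_sd(dsat[idx], w)
    return {
        "BSA.BML": bml,
        "BSA.BMS": bms,
        "BSA.BCVL": _cov(dl[idx], w),
        "BSA.BCVSsat": _cov(dsat[idx], w),
    }


# ---------------------------------------------------------------------------
# LEIA
# ---------------------------------------------------------------------------


def _neighbor_contrasts(
    img: ConeCatchImage, mask: np.ndarray, vs: VisualSystem, axis: int
) -> tuple[np.ndarray, np.ndarray]:
    """(dS, dL) between each in-mask pixel and its right/lower neighbor."""
    d = img.data
    if axis == 1:
        a, b = d[:, :-1], d[:, 1:]
        va, vb = mask[:, :-1], mask[:, 1:]
    else:
        a, b = d[:-1, :], d[1:, :]
        va, vb = mask[:-1, :], mask[1:, :]
    sel = va & vb
    ds = delta_s_chromatic(a[sel][:, :3], b[sel][:, :3], vs)
    dl = delta_s_luminance(a[sel][:, 3], b[sel][:, 3], vs)
    return np.atleast_1d(ds), np.atleast_1d(dl)


def leia_stats(
    filtered: ConeCatchImage, mask: np.ndarray, vs: VisualSystem
) -> dict[str, float]:
    """Local edge intensity statistics on the unsegmented image."""
    if not np.asarray(mask).any():
        raise ValueError("empty mask")
    ds_h, dl_h = _neighbor_contrasts(filtered, mask, vs, axis=1)
    ds_v, dl_v = _neighbor_contrasts(filtered, mask, vs, axis=0)
    out: dict[str, float] = {}
    for prefix, pooled, h, v in (
        ("Lum", np.concatenate([dl_h, dl_v]), dl_h, dl_v),
        ("Col", np.concatenate([ds_h, ds_v]), ds_h, ds_v),
    ):
        for suffix, vals in (("", pooled), (".hrz", h), (".vrt", v)):
            if len(vals) == 0:
                out[f"{prefix}.mean{suffix}"] = np.nan
                out[f"{prefix}.CoV{suffix}"] = np.nan
                out[f"{prefix}.kurtosis{suffix}"] = np.nan
                continue
            m = float(vals.mean())
            sd = float(vals.std())
            out[f"{prefix}.mean{suffix}"] = m
            out[f"{prefix}.CoV{suffix}"] = sd / m if m != 0 else np.nan
            out[f"{prefix}.kurtosis{suffix}"] = _excess_kurtosis(vals)
    return out


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

STAT_NAMES: tuple[str, ...] = (
    "CAA.PT",
    "CAA.Qc",
    "CAA.Qt",
    "CAA.Qt.hrz",
    "CAA.Qt.vrt",
    "CAA.Asp",
    "VCA.ML",
    "VCA.MSL",
    "VCA.CVS",
    "VCA.MeanLum",
    "VCA.MeanSat",
    "BSA.BML",
    "BSA.BMS",
    "BSA.BCVL",
    "BSA.BCVSsat",
    "Lum.mean",
    "Lum.CoV",
    "Lum.kurtosis",
    "Lum.mean.hrz",
    "Lum.CoV.hrz",
    "Lum.kurtosis.hrz",
    "Lum.mean.vrt",
    "Lum.CoV.vrt",
    "Lum.kurtosis.vrt",
    "Col.mean",
    "Col.CoV",
    "Col.kurtosis",
    "Col.mean.hrz",
    "Col.CoV.hrz",
    "Col.kurtosis.hrz",
    "Col.mean.vrt",
    "Col.CoV.vrt",
    "Col.kurtosis.vrt",
)


def compute_stat_record(
    clustered: ClusteredImage,
    filtered: ConeCatchImage,
    mask: np.ndarray,
    vs: VisualSystem,
    image_id: str = "",
    species: str = "",
    distance_cm: float = np.nan,
) -> dict:
    """One row of the statistic table: all registered statistics."""
    tm = transition_matrix(clustered)
    stats: dict[str, float] = {}
    stats.update(caa_stats(clustered, tm))
    stats.update(vca_stats(clustered, vs))
    stats.update(bsa_stats(clustered, tm, vs))
    stats.update(leia_stats(filtered, mask, vs))
    record = {"image_id": image_id, "species": species, "distance_cm": distance_cm}
    for name in STAT_NAMES:
        record[name] = stats[name]
    return record
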