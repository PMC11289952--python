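"""Synthetic cone-catch background scenes with known ground truth.

Real background habitats in this kind of study are calibrated underwater
photographs, which cannot be bundled; this module generates patch-mosaic
stand-ins with controllable patch size, chromatic and luminance contrast
and group-level effects, plus matching assay tables and a phylogeny, so
every downstream stage (vision modeling, pattern statistics, factor
reduction, group models) can be exercised end-to-end with a known answer.

Scenes are Voronoi mosaics: patch seeds are Poisson-sampled at a density
set by the requested mean patch diameter, each cell takes its class's
mean quantum catch, and pixels get multiplicative lognormal noise
(catches are positive and RNL distances are log-ratio based, so
lognormal noise is the natural perturbation).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .images import ConeCatchImage
from .visual_model import VisualSystem, delta_s_chromatic, delta_s_luminance

__all__ = [
    "SceneConfig",
    "GroupEffectConfig",
    "make_scene",
    "make_study",
    "simulate_tree",
]

DEFENSE_LEVELS = ("undefended", "toxic_moderate", "toxic_high")

# index intervals consistent with defense_scoring's classification rules
_LEVEL_INTERVALS = {
    "undefended": ((0.0, 0.0), (0.0, 0.0)),  # (unpalatability, toxicity)
    "toxic_moderate": ((0.30, 0.70), (0.10, 0.90)),
    "toxic_high": ((0.74, 1.00), (0.10, 0.90)),
}


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic background scene.

    ``chromatic_spread`` and ``luminance_spread`` are target mean
    pairwise RNL distances (dS units) between patch-class means;
    class colors are placed so the realized spread matches the request.
    """

    image_size: tuple[int, int] = (64, 64)
    px_per_mm: float = 4.0
    n_patch_classes: int = 3
    mean_patch_diameter_mm: float = 4.0
    base_catch: tuple[float, float, float, float] = (0.4, 0.5, 0.5, 0.5)
    chromatic_spread: float = 6.0
    luminance_spread: float = 6.0
    pixel_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patch_classes < 1:
            raise ValueError("need at least one patch class")
        if self.chromatic_spread < 0 or self.luminance_spread < 0:
            raise ValueError("spreads must be non-negative")
        if any(c <= 0 for c in self.base_catch):
            raise ValueError("base catches must be strictly positive")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel noise sd must be non-negative")


@dataclass(frozen=True)
class GroupEffectConfig:
    """Design of a full synthetic study: species, groups, replicates.

    Each defense level perturbs the shared scene parameters via
    multiplicative factors on chromatic spread, luminance spread and
    patch diameter — the knobs through which group differences propagate
    to the pattern statistics.
    """

    defense_levels: tuple[str, ...] = DEFENSE_LEVELS
    n_species_per_level: tuple[int, ...] = (5, 4, 3)
    n_images_per_species: int = 10
    chromatic_multipliers: tuple[float, ...] = (1.0, 1.5, 1.5)
    luminance_multipliers: tuple[float, ...] = (1.0, 1.5, 1.5)
    patch_size_multipliers: tuple[float, ...] = (1.0, 1.0, 1.0)
    scene: SceneConfig = field(default_factory=SceneConfig)
    tree_seed: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.defense_levels)
        if len(set(self.defense_levels)) != k:
            raise ValueError("defense level labels must be unique")
        for name in ("n_species_per_level", "chromatic_multipliers",
                     "luminance_multipliers", "patch_size_multipliers"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have one entry per level")
        if any(n < 1 for n in self.n_species_per_level) or self.n_images_per_species < 1:
            raise ValueError("counts must be >= 1")

    @property
    def n_species(self) -> int:
        return sum(self.n_species_per_level)


# ---------------------------------------------------------------------------
# class colors at a requested perceptual spread
# ---------------------------------------------------------------------------


def _class_colors(cfg: SceneConfig, vs: VisualSystem, rng: np.random.Generator) -> np.ndarray:
    """Place class mean catches at the requested mean pairwise spreads.

    Random log-catch directions are drawn, then rescaled so that the
    mean pairwise chromatic dS and achromatic dL across classes hit the
    requested spreads (exactly in the noiseless geometry).
    """
    k = cfg.n_patch_classes
    base = np.asarray(cfg.base_catch)
    if k == 1:
        return base[None, :].copy()
    # chromatic directions in log space, centered
    chrom = rng.normal(size=(k, 3))
    chrom -= chrom.mean(axis=0)
    lum = rng.normal(size=k)
    lum -= lum.mean()
    colors = base[None, :] * np.exp(
        np.concatenate([chrom, lum[:, None]], axis=1)
    )
    iu = np.triu_indices(k, 1)
    if cfg.chromatic_spread > 0:
        ds = delta_s_chromatic(colors[iu[0], :3], colors[iu[1], :3], vs)
        mean_ds = np.atleast_1d(ds).mean()
        if mean_ds > 0:
            chrom *= cfg.chromatic_spread / mean_ds
    else:
        chrom[:] = 0.0
    if cfg.luminance_spread > 0:
        dl = delta_s_luminance(colors[iu[0], 3], colors[iu[1], 3], vs)
        mean_dl = np.atleast_1d(dl).mean()
        if mean_dl > 0:
            lum *= cfg.luminance_spread / mean_dl
    else:
        lum[:] = 0.0
    return base[None, :] * np.exp(np.concatenate([chrom, lum[:, None]], axis=1))


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------


def make_scene(
    cfg: SceneConfig,
    vs: VisualSystem | None = None,
    image_id: str = "scene",
    return_truth: bool = False,
):
    """Generate one Voronoi-mosaic cone-catch scene plus background mask.

    Returns ``(image, mask)`` or, with ``return_truth``,
    ``(image, mask, class_map)`` where ``class_map`` is the exact
    ground-truth patch-class label per pixel.
    """
    vs = vs or VisualSystem()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    colors = _class_colors(cfg, vs, rng)

    d_px = cfg.mean_patch_diameter_mm * cfg.px_per_mm
    n_seeds = max(cfg.n_patch_classes, int(round(h * w / (d_px * d_px))))
    pts = rng.uniform([0, 0], [h, w], size=(n_seeds, 2))
    # every class appears at least once; remaining seeds drawn uniformly
    cls = np.concatenate(
        [
            np.arange(cfg.n_patch_classes),
            rng.integers(0, cfg.n_patch_classes, size=n_seeds - cfg.n_patch_classes),
        ]
    )
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy.ravel()[:, None] - pts[:, 0]) ** 2 + (xx.ravel()[:, None] - pts[:, 1]) ** 2
    class_map = cls[np.argmin(d2, axis=1)].reshape(h, w).astype(np.int32)

    data = colors[class_map]
    if cfg.pixel_noise_sd > 0:
        # lognormal multiplicative noise with sd ~ pixel_noise_sd in catch units
        rel = cfg.pixel_noise_sd / np.maximum(data, 1e-12)
        sigma = np.sqrt(np.log1p(rel**2))
        data = data * np.exp(rng.normal(size=data.shape) * sigma - sigma**2 / 2)
    img = ConeCatchImage(data, cfg.px_per_mm, image_id=image_id)

    mask = np.ones((h, w), dtype=bool)
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False  # >= 70% background
    if return_truth:
        return img, mask, class_map
    return img, mask


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def simulate_tree(taxa: list[str], seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree over the given taxa, scaled to unit height."""
    rng = np.random.default_rng(seed)
    n = len(taxa)
    if n < 2:
        raise ValueError("need at least two taxa")
    # Yule process: start with 2 lineages, split a random lineage at
    # exponential waiting times until n tips exist.
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node.edge.length = 0.0
    active = []
    for _ in range(2):
        child = tree.seed_node.new_child(edge_length=0.0)
        active.append(child)
    t = 0.0
    birth = 1.0
    while len(active) < n:
        t += rng.exponential(1.0 / (birth * len(active)))
        node = active[int(rng.integers(len(active)))]
        node.edge.length = t - _node_depth(node)
        active.remove(node)
        for _ in range(2):
            child = node.new_child(edge_length=0.0)
            active.append(child)
    t_end = t + rng.exponential(1.0 / (birth * len(active)))
    for node in active:
        node.edge.length = t_end - _node_depth(node)
    order = rng.permutation(n)
    for node, k in zip(active, order):
        node.taxon = ns.get_taxon(taxa[k])
    # scale to unit height
    scale = 1.0 / t_end
    for e in tree.preorder_edge_iter():
        if e.length:
            e.length *= scale
    return tree


def _node_depth(node) -> float:
    d = 0.0
    while node.parent_node is not None:
        d += node.edge.length or 0.0
        node = node.parent_node
    return d


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


def make_study(group_cfg: GroupEffectConfig, vs: VisualSystem | None = None) -> dict:
    """Generate a full synthetic study with known group structure.

    Returns a dict with ``images`` (list of (ConeCatchImage, mask)),
    ``image_table`` (image_id -> species), ``species_table`` (species,
    level), ``assay_table`` (per-extract indices consistent with each
    species' defense level), and ``tree`` (dendropy Tree over species).
    """
    vs = vs or VisualSystem()
    rng = np.random.default_rng(group_cfg.seed)
    species, levels = [], []
    for lvl, n_sp in zip(group_cfg.defense_levels, group_cfg.n_species_per_level):
        for i in range(n_sp):
            species.append(f"{lvl}_sp{i + 1}")
            levels.append(lvl)
    species_table = pd.DataFrame({"species": species, "defense_level": levels})

    # assay table: 1-3 whole-body extracts per species, indices drawn
    # uniformly within the level's class interval so classification
    # round-trips exactly
    assay_rows = []
    for sp, lvl in zip(species, levels):
        (u_lo, u_hi), (t_lo, t_hi) = _LEVEL_INTERVALS[lvl]
        n_ext = int(rng.integers(1, 4))
        for e in range(n_ext):
            assay_rows.append(
                {
                    "species": sp,
                    "extract_id": f"{sp}_e{e + 1}",
                    "extract_type": "whole_body",
                    "unpalatability_index": float(rng.uniform(u_lo, u_hi)),
                    "toxicity_index": float(rng.uniform(t_lo, t_hi)),
                }
            )
    assay_table = pd.DataFrame(assay_rows)

    level_idx = {lvl: i for i, lvl in enumerate(group_cfg.defense_levels)}
    images, image_rows = [], []
    base = group_cfg.scene
    for sp, lvl in zip(species, levels):
        li = level_idx[lvl]
        for j in range(group_cfg.n_images_per_species):
            scene_cfg = replace(
                base,
                chromatic_spread=base.chromatic_spread * group_cfg.chromatic_multipliers[li],
                luminance_spread=base.luminance_spread * group_cfg.luminance_multipliers[li],
                mean_patch_diameter_mm=base.mean_patch_diameter_mm
                * group_cfg.patch_size_multipliers[li],
                seed=int(rng.integers(2**31 - 1)),
            )
            image_id = f"{sp}_img{j + 1}"
            img, mask = make_scene(scene_cfg, vs, image_id=image_id)
            images.append((img, mask))
            image_rows.append({"image_id": image_id, "species": sp, "defense_level": lvl})

    tree = simulate_tree(species, seed=group_cfg.tree_seed)
    return {
        "images": images,
        "image_table": pd.DataFrame(image_rows),
        "species_table": species_table,
        "assay_table": assay_table,
        "tree": tree,
    }


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True)


def tree_from_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")
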