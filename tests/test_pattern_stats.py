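"""Pattern statistics against hand counts and brute-force oracles."""

import numpy as np
import pytest

from chromascape.images import ConeCatchImage
from chromascape.pattern_stats import (
    STAT_NAMES,
    bsa_stats,
    caa_stats,
    compute_stat_record,
    leia_stats,
    transition_matrix,
    vca_stats,
)
from chromascape.visual_model import (
    VisualSystem,
    clustered_from_class_map,
    delta_s_luminance,
)
from conftest import TWO_LUM_COLORS

DL = delta_s_luminance(TWO_LUM_COLORS[1, 3], TWO_LUM_COLORS[0, 3], VisualSystem())


def _class_maps():
    uniform = np.zeros((4, 4), dtype=int)
    checker = np.indices((4, 4)).sum(axis=0) % 2
    stripes = np.tile(np.arange(4) % 2, (4, 1))  # vertical stripes width 1
    return {"uniform": uniform, "checker": checker, "stripes": stripes}


@pytest.mark.parametrize(
    "name, syn, nonsyn, h_nonsyn, v_nonsyn",
    [
        ("uniform", 24, 0, 0, 0),
        ("checker", 0, 24, 12, 12),
        ("stripes", 12, 12, 12, 0),
    ],
)
def test_transition_matrix_hand_counts(vs, name, syn, nonsyn, h_nonsyn, v_nonsyn):
    cm = _class_maps()[name]
    cl = clustered_from_class_map(cm, TWO_LUM_COLORS, 1.0, vs)
    tm = transition_matrix(cl)
    c = tm.counts
    assert np.trace(c) == syn
    assert c.sum() - np.trace(c) == nonsyn
    h = tm.horizontal_counts
    v = tm.vertical_counts
    assert h.sum() - np.trace(h) == h_nonsyn
    assert v.sum() - np.trace(v) == v_nonsyn
    np.testing.assert_array_equal(c, h + v)


def test_caa_checkerboard(vs, checkerboard):
    tm = transition_matrix(checkerboard)
    caa = caa_stats(checkerboard, tm)
    assert caa["CAA.PT"] == pytest.approx(1.0)  # 16 components of 1 px at 1 px/mm
    assert caa["CAA.Qc"] == pytest.approx(1.0)  # equal abundances
    assert caa["CAA.Qt"] == 1.0  # single off-diagonal type
    assert caa["CAA.Asp"] == pytest.approx(1.0)


def test_caa_stripes_degenerate_aspect(vs):
    cl = clustered_from_class_map(_class_maps()["stripes"], TWO_LUM_COLORS, 1.0, vs)
    caa = caa_stats(cl, transition_matrix(cl))
    assert np.isinf(caa["CAA.Asp"])  # no vertical nonsynonymous transitions


def test_caa_uniform_degenerate(vs, uniform_clustered):
    caa = caa_stats(uniform_clustered, transition_matrix(uniform_clustered))
    assert caa["CAA.Qc"] == 1.0
    assert np.isnan(caa["CAA.Qt"])
    assert np.isnan(caa["CAA.Asp"])


def test_vca_single_class_nan(vs, uniform_clustered):
    out = vca_stats(uniform_clustered, vs)
    assert np.isnan(out["VCA.ML"]) and np.isnan(out["VCA.MSL"]) and np.isnan(out["VCA.CVS"])


def test_vca_two_equal_classes(vs, checkerboard):
    out = vca_stats(checkerboard, vs)
    assert out["VCA.ML"] == pytest.approx(DL)
    assert out["VCA.MSL"] == pytest.approx(0.0, abs=1e-12)


def test_bsa_checkerboard_single_boundary_type(vs, checkerboard):
    out = bsa_stats(checkerboard, transition_matrix(checkerboard), vs)
    assert out["BSA.BML"] == pytest.approx(DL)
    assert out["BSA.BCVL"] == pytest.approx(0.0, abs=1e-12)


def test_bsa_uniform_nan(vs, uniform_clustered):
    out = bsa_stats(uniform_clustered, transition_matrix(uniform_clustered), vs)
    assert all(np.isnan(v) for v in out.values())


def test_bsa_three_class_brute_force_oracle(vs):
    rng = np.random.default_rng(17)
    cm = rng.integers(0, 3, size=(8, 8))
    colors = np.array(
        [[0.4, 0.5, 0.6, 0.4], [0.6, 0.5, 0.4, 0.55], [0.5, 0.6, 0.45, 0.75]]
    )
    cl = clustered_from_class_map(cm, colors, 1.0, vs)
    tm = transition_matrix(cl)
    out = bsa_stats(cl, tm, vs)
    # brute force: enumerate adjacent pixel pairs, tally per unordered pair
    from chromascape.visual_model import delta_s_luminance as dsl

    weights = {}
    h, w = cm.shape
    for y in range(h):
        for x in range(w):
            for dy, dx in ((0, 1), (1, 0)):
                if y + dy < h and x + dx < w:
                    a, b = cm[y, x], cm[y + dy, x + dx]
                    if a != b:
                        key = (min(a, b), max(a, b))
                        weights[key] = weights.get(key, 0) + 1
    tot = sum(weights.values())
    expected = sum(
        n / tot * dsl(colors[a, 3], colors[b, 3], vs) for (a, b), n in weights.items()
    )
    assert out["BSA.BML"] == pytest.approx(expected, abs=1e-12)


def test_leia_uniform_zero(vs):
    img = ConeCatchImage(np.full((8, 8, 4), 0.5), 1.0)
    out = leia_stats(img, np.ones((8, 8), bool), vs)
    assert out["Lum.mean"] == 0.0 and out["Col.mean"] == 0.0
    assert np.isnan(out["Lum.kurtosis"])  # zero variance


def test_leia_step_edge_hand_count(vs):
    data = np.full((8, 8, 4), 0.5)
    data[:, 4:, 3] = 0.5 * np.exp(0.2)  # dL = 4 across the edge
    img = ConeCatchImage(data, 1.0)
    out = leia_stats(img, np.ones((8, 8), bool), vs)
    # 8 rows x 7 horizontal pairs, 8 of them cross the edge at exactly 4 dS
    assert out["Lum.mean.hrz"] == pytest.approx(4 * 8 / 56)
    assert out["Lum.mean.vrt"] == 0.0


def test_leia_hrz_vrt_pool(vs):
    rng = np.random.default_rng(2)
    img = ConeCatchImage(rng.uniform(0.3, 0.7, (10, 10, 4)), 1.0)
    mask = np.ones((10, 10), bool)
    out = leia_stats(img, mask, vs)
    n_h, n_v = 10 * 9, 9 * 10
    pooled_mean = (out["Lum.mean.hrz"] * n_h + out["Lum.mean.vrt"] * n_v) / (n_h + n_v)
    assert out["Lum.mean"] == pytest.approx(pooled_mean)


def test_statistics_invariant_to_translation_and_relabeling(vs):
    rng = np.random.default_rng(30)
    cm = rng.integers(0, 3, size=(10, 10))
    colors = np.array(
        [[0.4, 0.5, 0.6, 0.4], [0.6, 0.5, 0.4, 0.55], [0.5, 0.6, 0.45, 0.75]]
    )
    base = clustered_from_class_map(cm, colors, 1.0, vs)
    rolled = clustered_from_class_map(np.roll(np.roll(cm, 3, 0), 2, 1), colors, 1.0, vs)
    relabeled = clustered_from_class_map(2 - cm, colors[::-1], 1.0, vs)

    def all_stats(cl):
        tm = transition_matrix(cl)
        return {**caa_stats(cl, tm), **vca_stats(cl, vs), **bsa_stats(cl, tm, vs)}

    a = all_stats(base)
    c = all_stats(relabeled)
    for key in a:
        if np.isnan(a[key]):
            assert np.isnan(c[key])
        else:
            assert a[key] == pytest.approx(c[key], abs=1e-10), key
    # translation with wraparound preserves abundances (hence Qc) exactly
    assert all_stats(rolled)["CAA.Qc"] == pytest.approx(a["CAA.Qc"])


def test_stat_record_complete(vs, checkerboard):
    img = ConeCatchImage(np.full((4, 4, 4), 0.5), 1.0)
    rec = compute_stat_record(checkerboard, img, checkerboard.mask, vs, "img1", "sp1", 2.0)
    for name in STAT_NAMES:
        assert name in rec
    assert rec["image_id"] == "img1" and rec["distance_cm"] == 2.0
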