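"""Observer math: Weber fractions, RNL distances, acuity, filter, clustering."""

import numpy as np
import pytest

from chromascape.images import ConeCatchImage
from chromascape.scene_sim import SceneConfig, make_scene
from chromascape.visual_model import (
    ViewingGeometry,
    VisualSystem,
    acuity_sigma_px,
    apply_acuity,
    delta_s_chromatic,
    delta_s_luminance,
    rnl_cluster,
    rnl_ranked_filter,
    weber_fractions,
)


# ---------------------------------------------------------------------------
# Weber fractions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "abundances, noise, expected",
    [
        ((1, 2, 2, 2), 0.05, (0.0707106781, 0.05, 0.05, 0.05)),
        ((1, 1, 1, 1), 0.05, (0.05, 0.05, 0.05, 0.05)),
        ((1, 4), 0.1, (0.2, 0.1)),
    ],
)
def test_weber_fractions(abundances, noise, expected):
    np.testing.assert_allclose(weber_fractions(abundances, noise), expected, atol=1e-9)


def test_weber_fractions_triggerfish_rounding():
    w = weber_fractions((1, 2, 2, 2), 0.05)
    assert tuple(np.round(w, 2)) == (0.07, 0.05, 0.05, 0.05)


@pytest.mark.parametrize("bad", [((0, 1), 0.05), ((1, 1), 0.0), ((-1, 2), 0.05)])
def test_weber_fractions_rejects_nonpositive(bad):
    with pytest.raises(ValueError):
        weber_fractions(*bad)


# ---------------------------------------------------------------------------
# RNL distances
# ---------------------------------------------------------------------------


def test_delta_s_identity_and_scaling(vs):
    q = np.array([0.4, 0.5, 0.6])
    assert delta_s_chromatic(q, q, vs) == 0
    # common intensity scaling carries no chromatic signal
    assert delta_s_chromatic(q, 2 * q, vs) == pytest.approx(0, abs=1e-12)


def test_delta_s_symmetry(vs):
    rng = np.random.default_rng(0)
    a, b = rng.uniform(0.1, 1, 3), rng.uniform(0.1, 1, 3)
    assert delta_s_chromatic(a, b, vs) == pytest.approx(delta_s_chromatic(b, a, vs))


def _mahalanobis_oracle(qa, qb, weber):
    """Independent oracle: Mahalanobis distance of the log-catch contrast
    under covariance diag(weber^2), projected onto the chromatic plane
    (contrasts orthogonal to uniform intensity changes)."""
    df = np.log(qa) - np.log(qb)
    proj = np.eye(3) - np.ones((3, 3)) / 3
    cov = proj @ np.diag(weber**2) @ proj
    x = proj @ df
    return np.sqrt(x @ np.linalg.pinv(cov) @ x)


def test_delta_s_equals_mahalanobis_oracle(vs):
    rng = np.random.default_rng(123)
    w = vs.weber_chromatic
    for _ in range(200):
        qa, qb = rng.uniform(0.05, 2.0, 3), rng.uniform(0.05, 2.0, 3)
        assert delta_s_chromatic(qa, qb, vs) == pytest.approx(
            _mahalanobis_oracle(qa, qb, w), abs=1e-9
        )


def test_delta_s_triangle_inequality(vs):
    # dS is a Mahalanobis (pseudo)metric in log-catch space
    rng = np.random.default_rng(7)
    for _ in range(300):
        a, b, c = rng.uniform(0.05, 2.0, (3, 3))
        ab = delta_s_chromatic(a, b, vs)
        bc = delta_s_chromatic(b, c, vs)
        ac = delta_s_chromatic(a, c, vs)
        assert ac <= ab + bc + 1e-9


def test_delta_s_luminance_closed_form(vs):
    q = 0.5
    assert delta_s_luminance(q, q, vs) == 0
    assert delta_s_luminance(q * np.exp(0.05), q, vs) == pytest.approx(1.0)
    assert delta_s_luminance(q, q * np.exp(0.05), vs) == pytest.approx(1.0)
    for _ in range(50):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0.1, 1, 2)
        assert delta_s_luminance(a, b, vs) >= 0


@pytest.mark.parametrize("func", [delta_s_chromatic, delta_s_luminance])
def test_distances_reject_nonpositive(vs, func):
    good = np.array([0.5, 0.5, 0.5]) if func is delta_s_chromatic else 0.5
    bad = np.array([0.0, 0.5, 0.5]) if func is delta_s_chromatic else 0.0
    with pytest.raises(ValueError):
        func(good, bad, vs)


# ---------------------------------------------------------------------------
# acuity modeling
# ---------------------------------------------------------------------------


def _uniform_image(value=0.5, size=(32, 32), px_per_mm=4.0):
    return ConeCatchImage(np.full((*size, 4), value), px_per_mm)


def test_acuity_uniform_fixed_point(vs):
    img = _uniform_image()
    out = apply_acuity(img, vs, ViewingGeometry(30, 4.0))
    np.testing.assert_allclose(out.data, img.data, rtol=1e-12)


def _highfreq_power(data, f_cutoff):
    spec = np.abs(np.fft.rfft2(data[..., 0])) ** 2
    fy = np.fft.fftfreq(data.shape[0])[:, None]
    fx = np.fft.rfftfreq(data.shape[1])[None, :]
    return spec[np.hypot(fy, fx) > f_cutoff].sum()


def test_acuity_far_view_attenuates_more(vs):
    img, _ = make_scene(SceneConfig(image_size=(64, 64), seed=4))
    near = apply_acuity(img, vs, ViewingGeometry(2, 4.0))
    far = apply_acuity(img, vs, ViewingGeometry(30, 4.0))
    f_c = vs.acuity_cpd * ViewingGeometry(30, 4.0).degrees_per_px
    assert _highfreq_power(far.data, f_c) <= _highfreq_power(near.data, f_c)
    assert far.data.min() > 0 and near.data.min() > 0


def test_acuity_grating_attenuation(vs):
    # grating six times finer than the minimum resolvable angle at 30 cm
    geom = ViewingGeometry(30, 10.0)
    mra_deg = 1.0 / vs.acuity_cpd
    mra_px = mra_deg / geom.degrees_per_px
    period_px = mra_px / 6.0
    n = 128
    x = np.arange(n)
    grating = 0.5 + 0.2 * np.sin(2 * np.pi * x / period_px)
    data = np.repeat(grating[None, :, None], n, axis=0)
    img = ConeCatchImage(np.repeat(data, 4, axis=2), 10.0)
    out = apply_acuity(img, vs, geom)
    amp_in = img.data[..., 0].max() - img.data[..., 0].min()
    amp_out = out.data[..., 0].max() - out.data[..., 0].min()
    assert amp_out <= 0.1 * amp_in


def test_acuity_linearity(vs):
    rng = np.random.default_rng(3)
    geom = ViewingGeometry(30, 4.0)
    a = ConeCatchImage(rng.uniform(0.2, 1.0, (32, 32, 4)), 4.0)
    b = ConeCatchImage(rng.uniform(0.2, 1.0, (32, 32, 4)), 4.0)
    summed = ConeCatchImage(a.data + b.data, 4.0)
    lhs = apply_acuity(summed, vs, geom).data
    rhs = apply_acuity(a, vs, geom).data + apply_acuity(b, vs, geom).data
    np.testing.assert_allclose(lhs, rhs, rtol=1e-10)


def test_acuity_rejects_unresolvable_scene(vs):
    img = _uniform_image(size=(16, 16), px_per_mm=50.0)
    with pytest.raises(ValueError, match="unresolvable|blur extent"):
        apply_acuity(img, vs, ViewingGeometry(500, 50.0))


# ---------------------------------------------------------------------------
# RNL ranked filter
# ---------------------------------------------------------------------------


def test_ranked_filter_zero_repetition_is_identity(vs):
    img, _ = make_scene(SceneConfig(image_size=(32, 32), seed=9))
    out = rnl_ranked_filter(img, vs, repetition=0)
    np.testing.assert_array_equal(out.data, img.data)


def test_ranked_filter_uniform_invariant(vs):
    img = _uniform_image(size=(24, 24))
    out = rnl_ranked_filter(img, vs)
    np.testing.assert_allclose(out.data, img.data, rtol=1e-12)


def test_ranked_filter_denoises_step_edge(vs):
    # two vertical halves ~10 dS apart in luminance, 5% salt noise
    h = w = 40
    data = np.full((h, w, 4), 0.5)
    data[:, w // 2 :, :] *= np.exp(0.5)  # 10 dS in luminance
    rng = np.random.default_rng(11)
    salt = rng.random((h, w)) < 0.05
    data[salt] *= 1.6
    img = ConeCatchImage(data, 1.0)
    out = rnl_ranked_filter(img, vs)
    # threshold in log-luminance midway between the two levels
    recovered = np.log(out.data[..., 3]) > np.log(0.5) + 0.25
    truth = np.zeros((h, w), bool)
    truth[:, w // 2 :] = True
    assert (recovered == truth).mean() >= 0.99
    # per-row edge crossing stays at the true boundary on average
    crossings = recovered.argmax(axis=1)
    assert abs(crossings.mean() - w // 2) <= 1.0
    assert np.median(crossings) == w // 2


# ---------------------------------------------------------------------------
# RNL clustering
# ---------------------------------------------------------------------------


def test_cluster_uniform_single_class(vs):
    img = _uniform_image(size=(24, 24))
    mask = np.ones((24, 24), bool)
    out = rnl_cluster(img, mask, vs)
    assert out.n_classes == 1
    assert (out.class_map[mask] == 0).all()
    assert out.class_table["abundance"].sum() == pytest.approx(1.0)


def test_cluster_supra_threshold_recovers_truth(vs):
    cfg = SceneConfig(
        image_size=(48, 48), n_patch_classes=2, chromatic_spread=8,
        luminance_spread=8, pixel_noise_sd=0.0, seed=21,
    )
    img, mask, truth = make_scene(cfg, vs, return_truth=True)
    out = rnl_cluster(img, mask, vs)
    assert out.n_classes == 2
    match = max(
        (out.class_map[mask] == truth[mask]).mean(),
        (out.class_map[mask] == 1 - truth[mask]).mean(),
    )
    assert match == 1.0


def test_cluster_sub_threshold_merges_to_one(vs):
    cfg = SceneConfig(
        image_size=(48, 48), n_patch_classes=2, chromatic_spread=0.5,
        luminance_spread=0.5, pixel_noise_sd=0.0, seed=22,
    )
    img, mask, _ = make_scene(cfg, vs, return_truth=True)
    out = rnl_cluster(img, mask, vs)
    assert out.n_classes == 1


def test_cluster_count_monotone_in_thresholds(vs):
    cfg = SceneConfig(image_size=(48, 48), n_patch_classes=4, chromatic_spread=4,
                      luminance_spread=4, pixel_noise_sd=0.01, seed=23)
    img, mask = make_scene(cfg, vs)
    counts = [
        rnl_cluster(img, mask, vs, t_color=t, t_lum=2 * t).n_classes
        for t in (0.5, 1.0, 2.0, 4.0, 8.0)
    ]
    assert counts == sorted(counts, reverse=True)


def test_cluster_pairwise_discriminability_invariant(vs):
    cfg = SceneConfig(image_size=(48, 48), n_patch_classes=5, chromatic_spread=3,
                      luminance_spread=3, pixel_noise_sd=0.02, seed=24)
    img, mask = make_scene(cfg, vs)
    out = rnl_cluster(img, mask, vs)
    q = out.class_table[["q_sw", "q_mw", "q_lw", "q_dbl"]].to_numpy()
    for i in range(out.n_classes):
        for j in range(i + 1, out.n_classes):
            ds = delta_s_chromatic(q[i, :3], q[j, :3], vs)
            dl = delta_s_luminance(q[i, 3], q[j, 3], vs)
            assert ds >= out.t_color or dl >= out.t_lum


def test_cluster_rejects_empty_mask(vs):
    img = _uniform_image(size=(8, 8))
    with pytest.raises(ValueError, match="empty mask"):
        rnl_cluster(img, np.zeros((8, 8), bool), vs)
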