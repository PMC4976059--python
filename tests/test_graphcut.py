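import itertools

import numpy as np
import pytest

from pmctseq.core import CTVolume, SeedSet
from pmctseq.graphcut import GraphCutConfig, labeling_energy, segment


def brute_force_minimum(vol, nll_fg, nll_bg, seedset, cfg):
    """Exhaustive enumeration over all seed-consistent labelings."""
    shape = vol.shape
    fg = seedset.fg.ravel()
    bg = seedset.bg.ravel()
    free = np.where(~fg & ~bg)[0]
    assert len(free) <= 12, "oracle only tractable for small instances"
    best_energy = np.inf
    best_labels = None
    base = fg.astype(bool).copy()
    for bits in itertools.product([False, True], repeat=len(free)):
        lab = base.copy()
        lab[free] = bits
        e = labeling_energy(vol, nll_fg, nll_bg, lab.reshape(shape), cfg)
        if e < best_energy:
            best_energy = e
            best_labels = lab.reshape(shape)
    return best_energy, best_labels


def random_instance(rng, shape=(2, 2, 3)):
    n = int(np.prod(shape))
    nll_fg = rng.uniform(0, 5, shape)
    nll_bg = rng.uniform(0, 5, shape)
    img = rng.uniform(0, 20, shape)
    flat_idx = rng.permutation(n)
    fg = np.zeros(n, bool)
    bg = np.zeros(n, bool)
    fg[flat_idx[0]] = True
    bg[flat_idx[1]] = True
    cfg = GraphCutConfig(
        lambda_smooth=float(rng.uniform(0, 2)),
        sigma_hu=float(rng.uniform(0.5, 10)),
        neighborhood=int(rng.choice([6, 26])),
        keep_fg_connected=False,
    )
    vol = CTVolume(img, tuple(rng.uniform(0.5, 2.0, 3)))
    return vol, nll_fg, nll_bg, SeedSet(fg.reshape(shape), bg.reshape(shape)), cfg


@pytest.mark.parametrize("seed", range(100))
def test_cut_energy_equals_exhaustive_minimum(seed):
    """Global optimality on every instance small enough to enumerate."""
    rng = np.random.default_rng(seed)
    vol, nll_fg, nll_bg, seeds, cfg = random_instance(rng)
    seg = segment(vol, nll_fg, nll_bg, seeds, cfg, roi=None)
    best_energy, _ = brute_force_minimum(vol, nll_fg, nll_bg, seeds, cfg)
    assert seg.energy == best_energy


def test_printed_toy_instance_matches_enumeration():
    """3x3x1 instance with hand-set data terms and one seed per class."""
    shape = (3, 3, 1)
    nll_fg = np.array([[1.0, 4.0, 8.0], [2.0, 5.0, 7.0], [1.5, 6.0, 9.0]]).reshape(shape)
    nll_bg = np.array([[8.0, 5.0, 1.0], [7.0, 4.0, 2.0], [9.0, 3.0, 0.5]]).reshape(shape)
    img = np.array([[10.0, 12.0, 30.0], [11.0, 15.0, 31.0], [10.5, 20.0, 29.0]]).reshape(shape)
    fg = np.zeros(shape, bool)
    fg[0, 0, 0] = True
    bg = np.zeros(shape, bool)
    bg[2, 2, 0] = True
    vol = CTVolume(img, (1, 1, 1))
    cfg = GraphCutConfig(lambda_smooth=1.0, sigma_hu=5.0, keep_fg_connected=False)
    seeds = SeedSet(fg, bg)
    seg = segment(vol, nll_fg, nll_bg, seeds, cfg, roi=None)
    best_energy, best_labels = brute_force_minimum(vol, nll_fg, nll_bg, seeds, cfg)
    assert seg.energy == best_energy
    assert np.array_equal(seg.labels.astype(bool), best_labels)


def test_lambda_zero_is_bayes_classification():
    rng = np.random.default_rng(1)
    shape = (6, 6, 6)
    nll_fg = rng.uniform(0, 10, shape)
    nll_bg = rng.uniform(0, 10, shape)
    fg = np.zeros(shape, bool)
    fg[3, 3, 3] = True
    bg = np.zeros(shape, bool)
    bg[0, 0, 0] = True
    vol = CTVolume(rng.uniform(0, 50, shape), (1, 1, 1))
    cfg = GraphCutConfig(lambda_smooth=0.0, keep_fg_connected=False)
    seg = segment(vol, nll_fg, nll_bg, SeedSet(fg, bg), cfg, roi=None)
    expected = nll_fg < nll_bg
    expected[fg] = True
    expected[bg] = False
    assert np.array_equal(seg.labels.astype(bool), expected)


def test_large_lambda_tight_cut_around_seeds():
    """Uniform image: strong smoothing yields the minimal boundary around fg."""
    shape = (5, 5, 1)
    img = np.zeros(shape)
    nll_fg = np.full(shape, 1.0)
    nll_bg = np.full(shape, 1.0)  # data indifferent
    fg = np.zeros(shape, bool)
    fg[2, 2, 0] = True
    bg = np.ones(shape, bool)  # border ring as background seeds
    bg[1:4, 1:4, 0] = False
    cfg = GraphCutConfig(lambda_smooth=100.0, sigma_hu=1.0, keep_fg_connected=False)
    vol = CTVolume(img, (1, 1, 1))
    seg = segment(vol, nll_fg, nll_bg, SeedSet(fg, bg), cfg, roi=None)
    # the optimum keeps only the seed voxel: the tightest cut has 4 unit-weight
    # edges, any larger fg region needs a longer boundary
    expected_energy = labeling_energy(vol, nll_fg, nll_bg, fg, cfg)
    assert expected_energy == pytest.approx(25.0 * 1.0 + 4 * 100.0)
    assert seg.energy == pytest.approx(expected_energy)
    assert seg.labels.sum() == 1


def test_seed_compliance_always():
    rng = np.random.default_rng(2)
    for _ in range(10):
        shape = (4, 4, 4)
        nll_fg = rng.uniform(0, 700, shape)
        nll_bg = rng.uniform(0, 700, shape)
        flat = rng.permutation(64)
        fg = np.zeros(64, bool)
        bg = np.zeros(64, bool)
        fg[flat[:5]] = True
        bg[flat[5:12]] = True
        vol = CTVolume(rng.uniform(-100, 100, shape), (1, 1, 1))
        seg = segment(vol, nll_fg, nll_bg,
                      SeedSet(fg.reshape(shape), bg.reshape(shape)),
                      GraphCutConfig(), roi=None)
        lab = seg.labels.astype(bool)
        assert lab[fg.reshape(shape)].all()
        assert not lab[bg.reshape(shape)].any()


def test_boundary_length_nonincreasing_in_lambda():
    rng = np.random.default_rng(3)
    shape = (8, 8, 8)
    nll_fg = rng.uniform(0, 5, shape)
    nll_bg = rng.uniform(0, 5, shape)
    img = rng.uniform(0, 30, shape)
    fg = np.zeros(shape, bool)
    fg[4, 4, 4] = True
    bg = np.zeros(shape, bool)
    bg[0, 0, 0] = True
    vol = CTVolume(img, (1, 1, 1))

    def boundary_len(lab):
        b = 0
        for ax in range(3):
            b += int((np.diff(lab.astype(int), axis=ax) != 0).sum())
        return b

    prev = None
    for lam in (0.0, 0.5, 1.0, 2.0, 5.0, 20.0):
        cfg = GraphCutConfig(lambda_smooth=lam, sigma_hu=1e6, keep_fg_connected=False)
        seg = segment(vol, nll_fg, nll_bg, SeedSet(fg, bg), cfg, roi=None)
        blen = boundary_len(seg.labels)
        if prev is not None:
            assert blen <= prev
        prev = blen


def test_roi_conditioning_matches_full_solution(small_static_volume):
    """Auto-ROI and full-grid optimization agree on a real phantom instance."""
    spec, vol, gt = small_static_volume
    from pmctseq import fit_em, make_rough_delineation, neg_log_likelihood, seeds_from_rough

    rough = make_rough_delineation(gt, 1.0, 3, spec.spacing_mm)
    ss = seeds_from_rough(rough, 2.0, 4.0, 8.0, spec.spacing_mm)
    model = fit_em(vol, ss)
    nf, nb = neg_log_likelihood(vol, model)
    cfg = GraphCutConfig()
    seg_roi = segment(vol, nf, nb, ss, cfg, roi="auto")
    seg_full = segment(vol, nf, nb, ss, cfg, roi=None)
    assert np.array_equal(seg_roi.labels, seg_full.labels)
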