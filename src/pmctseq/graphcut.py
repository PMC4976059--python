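"""Seeded binary segmentation by exact min-cut on a voxel grid graph.

The labeling minimizes the classic seeded-segmentation energy

    E(L) = Σ_p D_p(L_p) + λ Σ_{(p,q) ∈ N} w_pq · [L_p ≠ L_q]

with data terms ``D_p`` the per-class negative log-likelihoods from the
appearance model, contrast-sensitive neighbor weights
``w_pq = exp(−(I_p−I_q)² / 2σ²) / dist_mm(p, q)`` over a 6- or
26-neighborhood, and seed voxels tied to their class by large terminal
capacities. The min-cut is computed exactly with
``scipy.sparse.csgraph.maximum_flow`` on integer-scaled capacities; the
labeling is read off as the set of nodes reachable from the source in the
residual graph, which makes zero-cost ties deterministic.

For large volumes the graph is restricted to a box around the seed regions
(everything a background-seed shell separates from the foreground would be
discarded by the connectedness filter anyway); voxels outside the box are
labeled by their data terms and contribute fixed-label boundary terms, so the
cut is the exact optimum conditional on those labels. Passing ``roi=None``
optimizes over the full grid, which is what the exhaustive-search tests use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .core import CTVolume, Measurement, QCFlag, SeedSet, check_same_grid
from .errors import GridMismatchError, PmctseqError

_OFFSETS_6 = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
_OFFSETS_26 = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) > (0, 0, 0)
]


@dataclass
class GraphCutConfig:
    """Tunables of the segmentation energy.

    ``sigma_hu="auto"`` sets the contrast scale to the mean absolute neighbor
    HU difference of the image. ``keep_fg_connected`` applies the
    post-processing step that keeps only components 26-connected to a
    foreground seed; disable it to obtain the raw energy-optimal labeling.
    """

    lambda_smooth: float = 1.0
    sigma_hu: float | str = "auto"
    neighborhood: int = 6
    hard_seed_cost: float = 1e9
    keep_fg_connected: bool = True

    def __post_init__(self) -> None:
        if self.lambda_smooth < 0:
            raise ValueError("lambda_smooth must be >= 0")
        if self.neighborhood not in (6, 26):
            raise ValueError("neighborhood must be 6 or 26")
        if self.sigma_hu != "auto" and float(self.sigma_hu) <= 0:
            raise ValueError('sigma_hu must be positive or "auto"')


@dataclass
class Segmentation:
    """Binary labeling (1 = ventricle) with the energy of the returned labels."""

    labels: np.ndarray
    energy: float
    converged: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)


def _neighbor_offsets(neighborhood: int):
    return _OFFSETS_6 if neighborhood == 6 else _OFFSETS_26


def _auto_sigma(img: np.ndarray, neighborhood: int) -> float:
    diffs = []
    for off in _neighbor_offsets(neighborhood):
        sl_a = tuple(slice(0, n - o) for n, o in zip(img.shape, np.abs(off)))
        sl_b = tuple(slice(o, n) for n, o in zip(img.shape, np.abs(off)))
        diffs.append(np.abs(img[sl_a] - img[sl_b]).ravel())
    mean_diff = float(np.concatenate(diffs).mean()) if diffs else 0.0
    return mean_diff if mean_diff > 0 else 1.0


def labeling_energy(
    vol: CTVolume,
    nll_fg: np.ndarray,
    nll_bg: np.ndarray,
    labels: np.ndarray,
    cfg: GraphCutConfig,
) -> float:
    """E(L) of an arbitrary labeling — also the exhaustive-search oracle's energy."""
    labels = np.asarray(labels, dtype=bool)
    energy = float(np.where(labels, nll_fg, nll_bg).sum())
    if cfg.lambda_smooth > 0:
        img = vol.voxels.astype(np.float64)
        sigma = _auto_sigma(img, cfg.neighborhood) if cfg.sigma_hu == "auto" else float(cfg.sigma_hu)
        spacing = np.asarray(vol.spacing_mm)
        for off in _neighbor_offsets(cfg.neighborhood):
            sl_a = tuple(slice(0, n - abs(o)) for n, o in zip(img.shape, off))
            sl_b = tuple(slice(abs(o), n) for n, o in zip(img.shape, off))
            w = np.exp(-((img[sl_a] - img[sl_b]) ** 2) / (2.0 * sigma**2))
            w /= float(np.linalg.norm(spacing * np.asarray(off)))
            energy += cfg.lambda_smooth * float(w[labels[sl_a] != labels[sl_b]].sum())
    return energy


def _solve_cut(
    img: np.ndarray,
    nll_fg: np.ndarray,
    nll_bg: np.ndarray,
    fg_seed: np.ndarray,
    bg_seed: np.ndarray,
    spacing,
    cfg: GraphCutConfig,
    sigma: float,
) -> np.ndarray:
    """Exact min-cut labeling on the full given (sub)grid."""
    shape = img.shape
    n = int(np.prod(shape))
    idx = np.arange(n, dtype=np.int64).reshape(shape)
    source, sink = n, n + 1
    spacing = np.asarray(spacing, dtype=float)

    # t-links: cap(source->p) = D_p(bg) (paid when p ends background),
    #          cap(p->sink)  = D_p(fg) (paid when p ends foreground).
    # Subtracting the per-voxel minimum shifts the energy by a constant and
    # leaves one t-link per voxel, which keeps the integer capacities small
    # (scipy's max-flow works on int32).
    cap_src = nll_bg.astype(np.float64).ravel().copy()
    cap_snk = nll_fg.astype(np.float64).ravel().copy()
    shift = np.minimum(cap_src, cap_snk)
    cap_src -= shift
    cap_snk -= shift

    rows_e = []
    cols_e = []
    caps_e = []
    if cfg.lambda_smooth > 0:
        for off in _neighbor_offsets(cfg.neighborhood):
            sl_a = tuple(slice(0, s - abs(o)) for s, o in zip(shape, off))
            sl_b = tuple(slice(abs(o), s) for s, o in zip(shape, off))
            w = np.exp(-((img[sl_a] - img[sl_b]) ** 2) / (2.0 * sigma**2))
            w = cfg.lambda_smooth * w / float(np.linalg.norm(spacing * np.asarray(off)))
            a = idx[sl_a].ravel()
            b = idx[sl_b].ravel()
            wf = w.ravel()
            rows_e.append(a)
            cols_e.append(b)
            caps_e.append(wf)
            rows_e.append(b)
            cols_e.append(a)
            caps_e.append(wf)

    finite_sum = float(cap_src.sum() + cap_snk.sum())
    if caps_e:
        finite_sum += float(sum(c.sum() for c in caps_e))
    if not np.isfinite(finite_sum):
        raise PmctseqError("non-finite capacities in graph construction")
    hard = min(cfg.hard_seed_cost, finite_sum + 1.0)
    cap_src[fg_seed.ravel()] = hard
    cap_snk[fg_seed.ravel()] = 0.0
    cap_snk[bg_seed.ravel()] = hard
    cap_src[bg_seed.ravel()] = 0.0

    # Any seed-consistent cut avoids hard edges, so max-flow = min-cut
    # < hard * scale; choosing scale this way keeps every capacity and the
    # flow value inside int32.
    scale = (2.0**31 - 64.0) / (hard + 1.0)

    rows = [np.full(n, source, dtype=np.int64), np.arange(n, dtype=np.int64)]
    cols = [np.arange(n, dtype=np.int64), np.full(n, sink, dtype=np.int64)]
    caps = [
        np.round(cap_src * scale).astype(np.int32),
        np.round(cap_snk * scale).astype(np.int32),
    ]
    for r, c, w in zip(rows_e, cols_e, caps_e):
        rows.append(r)
        cols.append(c)
        caps.append(np.round(w * scale).astype(np.int32))

    graph = csr_matrix(
        (np.concatenate(caps).astype(np.int32),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(n + 2, n + 2),
        dtype=np.int32,
    )
    result = maximum_flow(graph, source, sink)
    residual = graph - result.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reachable, _ = breadth_first_order(residual, source, directed=True, return_predecessors=True)
    labels = np.zeros(n, dtype=bool)
    reachable = reachable[reachable < n]
    labels[reachable] = True
    return labels.reshape(shape)


def segment(
    vol: CTVolume,
    nll_fg: np.ndarray,
    nll_bg: np.ndarray,
    seedset: SeedSet,
    cfg: GraphCutConfig | None = None,
    roi: str | None = "auto",
    roi_margin_vox: int = 4,
) -> Segmentation:
    """Segment the ventricles as the global minimizer of the seeded energy.

    With ``roi="auto"`` the cut is solved inside the bounding box of the seed
    masks expanded by ``roi_margin_vox`` voxels, conditioning on data-term
    labels outside; on grids the box covers entirely this equals the full
    optimization. Foreground seeds are always labeled 1 and background seeds
    0 in the output.
    """
    cfg = cfg or GraphCutConfig()
    check_same_grid(vol.shape, nll_fg.shape, "volume and fg NLL")
    check_same_grid(vol.shape, nll_bg.shape, "volume and bg NLL")
    check_same_grid(vol.shape, seedset.fg.shape, "volume and seeds")
    if not (np.isfinite(nll_fg).all() and np.isfinite(nll_bg).all()):
        raise PmctseqError("data terms must be finite")

    img = vol.voxels.astype(np.float64)
    sigma = _auto_sigma(img, cfg.neighborhood) if cfg.sigma_hu == "auto" else float(cfg.sigma_hu)

    if roi == "auto":
        both = seedset.fg | seedset.bg
        sl = ndimage.find_objects(both.astype(np.uint8))[0]
        sl = tuple(
            slice(max(0, s.start - roi_margin_vox), min(n, s.stop + roi_margin_vox))
            for s, n in zip(sl, vol.shape)
        )
    else:
        sl = tuple(slice(0, n) for n in vol.shape)

    outside = np.ones(vol.shape, dtype=bool)
    outside[sl] = False
    labels = np.zeros(vol.shape, dtype=bool)
    labels[outside] = (nll_fg < nll_bg)[outside]

    sub_nll_fg = nll_fg[sl].astype(np.float64).copy()
    sub_nll_bg = nll_bg[sl].astype(np.float64).copy()
    if outside.any() and cfg.lambda_smooth > 0:
        _condition_on_outside(img, labels, outside, sl, sub_nll_fg, sub_nll_bg, cfg, sigma)

    labels[sl] = _solve_cut(
        img[sl], sub_nll_fg, sub_nll_bg, seedset.fg[sl], seedset.bg[sl],
        vol.spacing_mm, cfg, sigma,
    )

    if cfg.keep_fg_connected and labels.any():
        comp, _ = ndimage.label(labels, structure=np.ones((3, 3, 3), dtype=bool))
        keep = np.unique(comp[seedset.fg & labels])
        labels = np.isin(comp, keep[keep > 0])

    labels |= seedset.fg
    labels &= ~seedset.bg
    energy = labeling_energy(vol, nll_fg, nll_bg, labels, cfg)
    return Segmentation(labels=labels.astype(np.uint8), energy=energy, converged=True)


def _condition_on_outside(img, labels, outside, sl, sub_nll_fg, sub_nll_bg, cfg, sigma):
    """Fold boundary n-links to fixed outside labels into the subgrid t-links."""
    shape = img.shape
    for off in _neighbor_offsets(cfg.neighborhood):
        for sign in (+1, -1):
            o = tuple(sign * c for c in off)
            dist = float(np.linalg.norm(np.asarray(o, dtype=float)))
            # neighbor q = p + o; valid range for p
            sl_p = []
            sl_q = []
            ok = True
            for d, oc in enumerate(o):
                lo, hi = sl[d].start, sl[d].stop
                p_lo, p_hi = max(lo, -oc), min(hi, shape[d] - oc)
                if p_lo >= p_hi:
                    ok = False
                    break
                sl_p.append(slice(p_lo, p_hi))
                sl_q.append(slice(p_lo + oc, p_hi + oc))
            if not ok:
                continue
            sl_p, sl_q = tuple(sl_p), tuple(sl_q)
            q_out = outside[sl_q]
            if not q_out.any():
                continue
            w = np.exp(-((img[sl_p] - img[sl_q]) ** 2) / (2.0 * sigma**2))
            w = cfg.lambda_smooth * w / dist
            w = np.where(q_out, w, 0.0)
            q_fg = q_out & labels[sl_q]
            # paying w when labels differ from the fixed neighbor label
            sub_p = tuple(slice(s.start - r.start, s.stop - r.start) for s, r in zip(sl_p, sl))
            sub_nll_bg[sub_p] += np.where(q_fg, w, 0.0)
            sub_nll_fg[sub_p] += np.where(q_out & ~labels[sl_q], w, 0.0)


# --------------------------------------------------------------------------
# series-level driver


@dataclass
class TimepointResult:
    """Segmentation + measurement + QC outcome for one acquisition."""

    time_h: float
    segmentation: Segmentation | None
    measurement: Measurement


def segment_series(
    series,
    ref_seeds: SeedSet,
    register_policy: str = "identity",
    cfg: GraphCutConfig | None = None,
    ref_index: int = 0,
    k_fg: int = 1,
    k_bg: int = 3,
    collapse_threshold_ml: float = 2.0,
    min_separation_hu: float = 5.0,
    ffd_grid_spacing_mm: float = 16.0,
) -> list[TimepointResult]:
    """Run the full per-time-point pipeline over an aligned series.

    For every acquisition the reference seeds are propagated (identity for
    series acquired without moving the subject, free-form deformation
    otherwise), a fresh appearance model is fitted by EM, and the graph cut
    is solved. Quality control marks a time point ``collapsed`` when the
    foreground seeds vanish after propagation, when the fitted CSF mean is
    closer than ``min_separation_hu`` to a background component (the
    ventricle has narrowed past the point where CSF is distinguishable), or
    when the measured volume falls below ``collapse_threshold_ml``.
    """
    from .appearance import fit_em, neg_log_likelihood
    from .measure import measure

    if register_policy not in ("identity", "ffd"):
        raise ValueError('register_policy must be "identity" or "ffd"')
    cfg = cfg or GraphCutConfig()
    ref_vol = series[ref_index]
    results: list[TimepointResult] = []
    for i, vol in enumerate(series):
        if register_policy == "ffd" and i != ref_index:
            from .register import propagate_seeds, register_ffd

            transform = register_ffd(vol, ref_vol, grid_spacing_mm=ffd_grid_spacing_mm)
            seeds_t = propagate_seeds(ref_seeds, transform)
        else:
            seeds_t = ref_seeds
        if seeds_t is None or not seeds_t.fg.any():
            results.append(TimepointResult(
                vol.time_h, None,
                Measurement(vol.time_h, 0.0, 0.0, 0, QCFlag.COLLAPSED),
            ))
            continue
        model = fit_em(vol, seeds_t, k_fg=k_fg, k_bg=k_bg)
        fg_mean = float(np.average(model.fg.means, weights=model.fg.weights))
        separation = float(np.min(np.abs(model.bg.means - fg_mean)))
        if separation < min_separation_hu:
            results.append(TimepointResult(
                vol.time_h, None,
                Measurement(vol.time_h, 0.0, 0.0, 0, QCFlag.COLLAPSED),
            ))
            continue
        nll_fg, nll_bg = neg_log_likelihood(vol, model)
        seg = segment(vol, nll_fg, nll_bg, seeds_t, cfg)
        m = measure(vol, seg, collapse_threshold_ml=collapse_threshold_ml)
        results.append(TimepointResult(vol.time_h, seg, m))
    return results
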