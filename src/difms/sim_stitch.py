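"""SIM stitching: window merging, replicate filtering, cross-sample alignment.

Direct-infusion FT-ICR spectra are acquired as overlapping SIM (selected
ion monitoring) m/z windows to extend dynamic range. This module merges the
windows of one measurement into a single peak list (trimming window edges
and de-duplicating the overlap zones), keeps only peaks reproduced across
technical replicates, and aligns the per-sample peak lists into a
samples × features intensity matrix by single-linkage clustering of m/z
values with a ppm gap threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectra_io import FeatureMatrix, PeakList

log = logging.getLogger(__name__)


@dataclass
class StitchConfig:
    edge_trim: float = 2.5        # Da removed from each window end
    replicate_ppm: float = 1.5    # tolerance for matching across tech reps
    min_reps: int = 2             # peak must appear in >= this many reps
    align_ppm: float = 1.5        # cross-sample clustering gap threshold
    min_sample_frac: float = 0.5  # presence fraction within >= 1 group

    def __post_init__(self):
        if self.edge_trim < 0 or self.replicate_ppm <= 0 or self.align_ppm <= 0:
            raise ValueError("tolerances must be positive")
        if self.min_reps < 1:
            raise ValueError("min_reps must be >= 1")
        if not 0 < self.min_sample_frac <= 1:
            raise ValueError("min_sample_frac must be in (0, 1]")


class CoverageGapError(ValueError):
    """Trimmed SIM windows leave a hole in m/z coverage."""

    def __init__(self, gap: tuple[float, float]):
        self.gap = gap
        super().__init__(f"coverage gap ({gap[0]:g}, {gap[1]:g}) Th after edge "
                         "trimming; reduce edge_trim or widen the overlaps")


def stitch_windows(peaklists: list[PeakList],
                   windows: list[tuple[float, float]],
                   cfg: StitchConfig | None = None) -> PeakList:
    """Merge the SIM windows of one sample × replicate into one peak list.

    ``windows`` gives the (low, high) m/z bounds parallel to ``peaklists``.
    Each window is trimmed by ``edge_trim`` at both ends; within a residual
    overlap the midpoint splits ownership (lower window keeps m/z strictly
    below it), and any same-peak duplicates straddling a junction within
    ``replicate_ppm`` are merged. Raises :class:`CoverageGapError` when the
    trimmed windows no longer tile the acquired range.
    """
    cfg = cfg or StitchConfig()
    if len(peaklists) != len(windows):
        raise ValueError("need one (low, high) window per peak list")
    if not peaklists:
        raise ValueError("no peak lists supplied")
    order = np.argsort([w[0] for w in windows])
    pls = [peaklists[i] for i in order]
    wins = [windows[i] for i in order]
    trimmed = []
    for lo, hi in wins:
        if hi <= lo:
            raise ValueError(f"invalid window ({lo}, {hi})")
        t_lo, t_hi = lo + cfg.edge_trim, hi - cfg.edge_trim
        if t_hi <= t_lo:
            raise ValueError(f"edge_trim {cfg.edge_trim} consumes window ({lo}, {hi})")
        trimmed.append((t_lo, t_hi))
    for (a_lo, a_hi), (b_lo, b_hi) in zip(trimmed, trimmed[1:]):
        if b_lo > a_hi:
            raise CoverageGapError((a_hi, b_lo))
    # ownership boundaries at overlap midpoints
    bounds = [(a_hi + b_lo) / 2 for (_, a_hi), (b_lo, _) in zip(trimmed, trimmed[1:])]
    mzs, intens, origin = [], [], []
    for i, (pl, (t_lo, t_hi)) in enumerate(zip(pls, trimmed)):
        lo_edge = bounds[i - 1] if i > 0 else t_lo
        hi_edge = bounds[i] if i < len(bounds) else t_hi
        keep = (pl.mz >= lo_edge) & (pl.mz < hi_edge) if i < len(bounds) else \
               (pl.mz >= lo_edge) & (pl.mz <= hi_edge)
        mzs.append(pl.mz[keep])
        intens.append(pl.intensity[keep])
        origin.append(np.full(int(keep.sum()), i))
    mz = np.concatenate(mzs)
    inten = np.concatenate(intens)
    origin = np.concatenate(origin)
    order = np.argsort(mz, kind="stable")
    mz, inten, origin = mz[order], inten[order], origin[order]
    # merge junction duplicates: adjacent peaks from different windows
    # within replicate_ppm are the same physical peak measured twice
    out_mz, out_int = [], []
    i = 0
    while i < mz.size:
        j = i + 1
        if (j < mz.size and origin[j] != origin[i]
                and 1e6 * (mz[j] - mz[i]) / mz[i] <= cfg.replicate_ppm):
            w = inten[i] + inten[j]
            merged_mz = (mz[i] * inten[i] + mz[j] * inten[j]) / w if w > 0 \
                else (mz[i] + mz[j]) / 2
            out_mz.append(merged_mz)
            out_int.append((inten[i] + inten[j]) / 2)
            i += 2
        else:
            out_mz.append(mz[i])
            out_int.append(inten[i])
            i += 1
    first = pls[0]
    return PeakList(first.sample_id, first.replicate_id, "stitched",
                    np.array(out_mz), np.array(out_int))


def _cluster_sorted(mz: np.ndarray, gap_ppm: float) -> np.ndarray:
    """Single-linkage 1-D clustering: break where the consecutive gap
    exceeds ``gap_ppm`` relative to the lower member. Returns cluster ids
    for the (sorted) input."""
    ids = np.zeros(mz.size, dtype=int)
    if mz.size == 0:
        return ids
    gaps = 1e6 * np.diff(mz) / mz[:-1]
    ids[1:] = np.cumsum(gaps > gap_ppm)
    return ids


def replicate_filter(replicates: list[PeakList],
                     cfg: StitchConfig | None = None) -> PeakList:
    """Keep peaks reproduced in at least ``min_reps`` technical replicates.

    Pooled peaks are clustered within ``replicate_ppm``; a retained peak's
    m/z is the intensity-weighted mean of its matches and its intensity the
    mean over the replicates in which it occurs.
    """
    cfg = cfg or StitchConfig()
    if len(replicates) < cfg.min_reps:
        raise ValueError(f"need >= min_reps={cfg.min_reps} replicate peak lists")
    mz = np.concatenate([pl.mz for pl in replicates])
    inten = np.concatenate([pl.intensity for pl in replicates])
    rep = np.concatenate([np.full(len(pl), r) for r, pl in enumerate(replicates)])
    order = np.argsort(mz, kind="stable")
    mz, inten, rep = mz[order], inten[order], rep[order]
    ids = _cluster_sorted(mz, cfg.replicate_ppm)
    out_mz, out_int = [], []
    for cid in range(ids.max() + 1 if ids.size else 0):
        sel = ids == cid
        reps_here = rep[sel]
        if np.unique(reps_here).size < cfg.min_reps:
            continue
        w = inten[sel]
        m = mz[sel]
        out_mz.append(float(np.average(m, weights=w)) if w.sum() > 0
                      else float(m.mean()))
        # mean intensity per replicate present, then across replicates
        per_rep = [float(w[reps_here == r].mean()) for r in np.unique(reps_here)]
        out_int.append(float(np.mean(per_rep)))
    first = replicates[0]
    return PeakList(first.sample_id, "filtered", first.window_id,
                    np.array(out_mz), np.array(out_int))


def align_features(sample_peaklists: list[PeakList],
                   cfg: StitchConfig | None = None,
                   groups: dict[str, str] | None = None) -> FeatureMatrix:
    """Cluster per-sample peaks into features and build the intensity matrix.

    Features are 1-D single-linkage clusters over the pooled sorted m/z
    values with a consecutive-gap threshold of ``align_ppm``. Each sample
    contributes at most one peak per feature (nearest to the cluster mean
    wins, with a warning). Features present in fewer than
    ``min_sample_frac`` of the samples of every group are dropped; absent
    cells are marked missing (NaN), never zero.
    """
    cfg = cfg or StitchConfig()
    if len(sample_peaklists) < 2:
        raise ValueError("alignment requires >= 2 samples")
    sample_ids = [pl.sample_id for pl in sample_peaklists]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id among peak lists")
    if groups is None:
        groups = {s: "all" for s in sample_ids}
    mz = np.concatenate([pl.mz for pl in sample_peaklists])
    inten = np.concatenate([pl.intensity for pl in sample_peaklists])
    samp = np.concatenate([np.full(len(pl), i) for i, pl in
                           enumerate(sample_peaklists)])
    order = np.argsort(mz, kind="stable")
    mz, inten, samp = mz[order], inten[order], samp[order]
    ids = _cluster_sorted(mz, cfg.align_ppm)
    n_clusters = int(ids.max()) + 1 if ids.size else 0
    n_samples = len(sample_ids)
    feature_mzs: list[float] = []
    columns: list[np.ndarray] = []
    group_labels = np.array([groups[s] for s in sample_ids])
    group_sizes = {g: int(np.sum(group_labels == g)) for g in set(group_labels)}
    for cid in range(n_clusters):
        sel = ids == cid
        c_mz, c_int, c_samp = mz[sel], inten[sel], samp[sel]
        center = float(c_mz.mean())
        col = np.full(n_samples, np.nan)
        kept_mz, kept_int, kept_samp = [], [], []
        for s in np.unique(c_samp):
            s_sel = c_samp == s
            if int(s_sel.sum()) > 1:
                log.warning("sample %s contributed %d peaks to one cluster at "
                            "m/z %.5f; keeping the nearest",
                            sample_ids[int(s)], int(s_sel.sum()), center)
                # nearest to cluster mean; ties go to the lower m/z
                cand = np.flatnonzero(s_sel)
                best = cand[np.lexsort((c_mz[cand],
                                        np.abs(c_mz[cand] - center)))][0]
            else:
                best = int(np.flatnonzero(s_sel)[0])
            col[int(s)] = c_int[best]
            kept_mz.append(c_mz[best])
        present = ~np.isnan(col)
        ok = False
        for g, size in group_sizes.items():
            in_group = present & (group_labels == g)
            if size and int(in_group.sum()) / size >= cfg.min_sample_frac:
                ok = True
                break
        if not ok:
            continue
        feature_mzs.append(float(np.mean(kept_mz)))
        columns.append(col)
    if not feature_mzs:
        return FeatureMatrix(sample_ids, np.empty(0),
                             np.empty((n_samples, 0)))
    feat = np.array(feature_mzs)
    values = np.column_stack(columns)
    order = np.argsort(feat, kind="stable")
    return FeatureMatrix(sample_ids, feat[order], values[:, order])
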