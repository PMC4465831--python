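"""Simplified DNA structural descriptors.

Groove widths from cross-strand phosphate distances, local axis bending from
base-pair-center chords, inter-base-pair property correlations, and
block-averaged standard errors for autocorrelated series.

The groove convention here is deliberately simple and is tagged as such: the
width at base-pair level i is the minimal cross-strand P–P distance within a
fixed register window (|offset| 2–5 for the minor groove, 5–9 for the major),
minus 5.8 Å for the phosphate van der Waals radii.  On an idealized B-form
duplex this lands at the familiar ~5.4–5.7 Å (minor) and ~11–12 Å (major)
scales.  It is *not* a curvilinear-axis helicoidal analysis, and absolute
values are not comparable to ones from such programs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .trajectory_core import DNA_BACKBONE_ATOMS, Ensemble, RegionSelection

__all__ = [
    "GrooveProfile",
    "BendProfile",
    "PropertyCorrelation",
    "groove_widths",
    "bend_profile",
    "property_correlation",
    "block_se",
]

PHOSPHATE_RADIUS_CORRECTION = 5.8  # Å, subtracted from P-P distances
MINOR_REGISTER = (2, 5)   # |cross-strand offset| window for the minor groove
MAJOR_REGISTER = (5, 9)
EDGE_LEVELS = 2           # first/last levels flagged undefined

CONVENTION_TAG = "min-cross-strand-P-P(register 2-5/5-9) - 5.8 Å"


@dataclass
class GrooveProfile:
    """Per-level minor/major groove widths: per-frame values and summaries.

    ``per_frame_minor``/``per_frame_major`` have shape (n_frames, n_levels);
    undefined levels (near the duplex ends or missing register partners) are
    NaN.  ``mean``/``se`` frames carry the ensemble average ± block-averaged
    standard error.
    """

    levels: np.ndarray
    per_frame_minor: np.ndarray
    per_frame_major: np.ndarray
    convention: str = CONVENTION_TAG

    def summary(self) -> pd.DataFrame:
        rows = []
        for kind, data in (("minor", self.per_frame_minor),
                           ("major", self.per_frame_major)):
            for li, level in enumerate(self.levels):
                col = data[:, li]
                if np.all(np.isnan(col)):
                    mean, se = np.nan, np.nan
                else:
                    mean = float(np.nanmean(col))
                    se = block_se(col[~np.isnan(col)]) if len(col) >= 16 else 0.0
                rows.append({"level": int(level), "groove": kind,
                             "mean": mean, "se": se})
        return pd.DataFrame(rows)


@dataclass
class BendProfile:
    """Per-level local axis bend angles (degrees, ≥ 0); NaN near the ends."""

    levels: np.ndarray
    per_frame: np.ndarray

    def summary(self) -> pd.DataFrame:
        rows = []
        for li, level in enumerate(self.levels):
            col = self.per_frame[:, li]
            if np.all(np.isnan(col)):
                mean, se = np.nan, np.nan
            else:
                mean = float(np.nanmean(col))
                se = block_se(col[~np.isnan(col)]) if len(col) >= 16 else 0.0
            rows.append({"level": int(level), "mean": mean, "se": se})
        return pd.DataFrame(rows)


@dataclass
class PropertyCorrelation:
    """Base-pair × base-pair Pearson correlation of a scalar property."""

    levels: np.ndarray
    matrix: np.ndarray


def _strand_phosphates(ensemble: Ensemble, duplex: RegionSelection):
    """Map (chain → {level → P atom index}) for the two duplex strands."""
    idx = duplex.resolve(ensemble)
    top = ensemble.topology
    strands: dict[str, dict[int, int]] = {}
    for i in idx:
        if top["name"][i] != "P":
            continue
        strands.setdefault(top["chain"][i], {})[int(top["resid"][i])] = i
    if len(strands) < 2:
        raise ValueError("duplex needs phosphate atoms on both strands")
    chains = sorted(strands)[:2]
    return strands[chains[0]], strands[chains[1]]


def groove_widths(ensemble: Ensemble,
                  duplex: RegionSelection) -> GrooveProfile:
    """Minor and major groove widths per base-pair level and frame.

    Width at level i = min over cross-strand P-P distances with register
    offsets in the groove's window, minus 5.8 Å.  Levels within 2 of the
    duplex ends are flagged undefined (NaN).
    """
    pI, pJ = _strand_phosphates(ensemble, duplex)
    levels = np.array(sorted(set(pI) & set(pJ)))
    if len(levels) < 2 * EDGE_LEVELS + 1:
        raise ValueError("duplex too short for groove analysis")
    nf = ensemble.n_frames
    minor = np.full((nf, len(levels)), np.nan)
    major = np.full((nf, len(levels)), np.nan)
    level_set = set(levels.tolist())

    # grooves are directional in an antiparallel duplex: detect on a central
    # level which signed register offset crosses the minor groove
    mid = int(levels[len(levels) // 2])
    sign = +1
    if mid - 3 in level_set and mid + 3 in level_set:
        x0 = ensemble.frames[0]
        if (np.linalg.norm(x0[pI[mid]] - x0[pJ[mid - 3]])
                < np.linalg.norm(x0[pI[mid]] - x0[pJ[mid + 3]])):
            sign = -1

    windows = (
        ([sign * o for o in range(MINOR_REGISTER[0], MINOR_REGISTER[1] + 1)],
         minor),
        ([-sign * o for o in range(MAJOR_REGISTER[0], MAJOR_REGISTER[1] + 1)],
         major),
    )
    lo_edge, hi_edge = levels[0] + EDGE_LEVELS, levels[-1] - EDGE_LEVELS
    for li, lev in enumerate(levels):
        if lev < lo_edge or lev > hi_edge:
            continue
        for offsets, store in windows:
            partners = [lev + o for o in offsets]
            if not all(p in level_set for p in partners):
                continue  # incomplete register window near a duplex end
            a = ensemble.frames[:, pI[lev]]
            dists = np.stack(
                [np.linalg.norm(a - ensemble.frames[:, pJ[p]], axis=1)
                 for p in partners]
            )
            store[:, li] = dists.min(axis=0) - PHOSPHATE_RADIUS_CORRECTION
    return GrooveProfile(levels, minor, major)


def _basepair_centers(ensemble: Ensemble, duplex: RegionSelection):
    """Base-pair center = mean of the level's base atoms (the pair's
    hydrogen-bonded core straddles the helical axis); falls back to all
    atoms if the level carries no base atoms."""
    idx = duplex.resolve(ensemble)
    top = ensemble.topology
    levels = sorted(set(int(top["resid"][i]) for i in idx))
    centers = np.empty((ensemble.n_frames, len(levels), 3))
    for li, lev in enumerate(levels):
        sel = [i for i in idx if top["resid"][i] == lev
               and top["name"][i] not in DNA_BACKBONE_ATOMS]
        if not sel:
            sel = [i for i in idx if top["resid"][i] == lev]
        centers[:, li] = ensemble.frames[:, sel].mean(axis=1)
    return np.array(levels), centers


def bend_profile(ensemble: Ensemble,
                 duplex: RegionSelection,
                 window: int = 2) -> BendProfile:
    """Local axis bend angle at each base-pair level.

    The local axis direction below/above level i is taken from the chords
    c_i − c_{i−window} and c_{i+window} − c_i of the base-pair centers; the
    bend is the angle between them.  Levels without a full window are NaN.
    """
    levels, centers = _basepair_centers(ensemble, duplex)
    n = len(levels)
    if n < 2 * window + 1:
        raise ValueError("duplex too short for bend analysis")
    bend = np.full((ensemble.n_frames, n), np.nan)
    for li in range(window, n - window):
        u = centers[:, li] - centers[:, li - window]
        v = centers[:, li + window] - centers[:, li]
        un = u / np.linalg.norm(u, axis=1, keepdims=True)
        vn = v / np.linalg.norm(v, axis=1, keepdims=True)
        cosang = np.clip((un * vn).sum(axis=1), -1.0, 1.0)
        bend[:, li] = np.degrees(np.arccos(cosang))
    return BendProfile(levels, bend)


def property_correlation(values: np.ndarray,
                         levels: Optional[np.ndarray] = None
                         ) -> PropertyCorrelation:
    """Pearson correlation across frames of a per-level scalar property.

    ``values`` is (n_frames, n_levels).  Zero-variance levels get diagonal 1
    and NaN off-diagonal entries.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 10:
        raise ValueError("need >= 10 frames for correlations")
    n_lev = values.shape[1]
    if levels is None:
        levels = np.arange(n_lev)
    var = np.nanvar(values, axis=0)
    good = var > 1e-14
    mat = np.full((n_lev, n_lev), np.nan)
    if good.any():
        sub = values[:, good]
        # rows with any NaN (undefined levels) are dropped pairwise-complete
        finite = np.all(np.isfinite(sub), axis=1)
        c = np.corrcoef(sub[finite].T)
        mat[np.ix_(good, good)] = c
    np.fill_diagonal(mat, 1.0)
    return PropertyCorrelation(np.asarray(levels), mat)


def block_se(series: np.ndarray) -> float:
    """Standard error of the mean by block averaging.

    Block sizes double from 1; for each size the SE estimate is
    std(block means)/sqrt(n_blocks).  The reported SE is the estimate at the
    largest block size that still leaves ≥ 8 blocks — the plateau of the
    block-size curve for series whose correlation time is resolved.
    For a constant series the SE is exactly 0.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 16:
        raise ValueError("block averaging needs >= 16 points")
    if np.ptp(x) == 0:
        return 0.0
    best = 0.0
    size = 1
    while len(x) // size >= 8:
        nb = len(x) // size
        means = x[: nb * size].reshape(nb, size).mean(axis=1)
        best = float(np.std(means, ddof=1) / np.sqrt(nb))
        size *= 2
    return best
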