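"""Docking-helix orientation in a DNA-based coordinate frame.

The frame is anchored on the binding site: v_x runs between the centers of
mass of the first and last base pairs of the site, v_t across the first base
pair between the two strands' backbone reference atoms (P, falling back to
C3'), v_z = v_x × v_t and v_y = v_x × v_z.  The *Rock* angle measures the
docking-helix axis around the DNA helical axis (projection onto the v_y/v_z
plane, signed from v_y); the *Tumble* angle measures it within the binding
groove (projection onto the v_x/v_z plane, signed from v_x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory_core import Ensemble, RegionSelection

__all__ = [
    "DnaFrame",
    "OrientationSample",
    "dna_frame",
    "helix_axis",
    "rock_tumble",
    "ellipse_area_ratio",
]


@dataclass(frozen=True)
class DnaFrame:
    """Orthonormalized DNA-based coordinate system (v_x, v_t, v_z, v_y)."""

    v_x: np.ndarray
    v_t: np.ndarray
    v_z: np.ndarray
    v_y: np.ndarray


@dataclass(frozen=True)
class OrientationSample:
    rock: float
    tumble: float
    frame_index: int


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("degenerate (zero-length) frame vector")
    return v / n


def _site_atoms(ensemble: Ensemble, site: RegionSelection) -> np.ndarray:
    """Resolve a binding-site selection to its nucleic-acid atoms only, so a
    residue range shared with protein numbering still defines a DNA site."""
    idx = site.resolve(ensemble)
    dna = ensemble.is_dna()
    idx = idx[dna[idx]]
    if len(idx) == 0:
        raise ValueError(f"site {site.name!r} contains no nucleic-acid atoms")
    return idx


def _basepair_atoms(ensemble: Ensemble, site: RegionSelection, level: int,
                    names: tuple[str, ...]):
    """Atom indices of one base-pair level on each strand, preferring the
    first name in ``names`` (P, fallback C3')."""
    idx = _site_atoms(ensemble, site)
    top = ensemble.topology
    chains = sorted(set(top["chain"][i] for i in idx))
    if len(chains) < 2:
        raise ValueError("site must span two strands")
    out = []
    for chain in chains[:2]:
        found = None
        for nm in names:
            for i in idx:
                if (top["chain"][i] == chain and top["resid"][i] == level
                        and top["name"][i] == nm):
                    found = i
                    break
            if found is not None:
                break
        if found is None:
            raise ValueError(
                f"no backbone atom {names} at level {level} on strand {chain}"
            )
        out.append(found)
    return out


def dna_frame(frame_xyz: np.ndarray, ensemble: Ensemble,
              site: RegionSelection) -> DnaFrame:
    """DNA-based coordinate system for one frame.

    v_x: first→last base-pair center of mass of the site (unweighted atom
    mean per level).  v_t: across the first base pair between the two
    strands' backbone reference atoms.  v_z = v_x × v_t; v_y = v_x × v_z.
    All vectors normalized.
    """
    idx = _site_atoms(ensemble, site)
    top = ensemble.topology
    levels = sorted(set(int(top["resid"][i]) for i in idx))
    if len(levels) < 2:
        raise ValueError("site needs at least 2 base-pair levels")
    first, last = levels[0], levels[-1]

    def _level_com(level):
        # base-pair center: the H-bonded base core straddles the helical
        # axis, so base atoms give the proper center; backbone atoms would
        # pull it toward the strands
        from .trajectory_core import DNA_BACKBONE_ATOMS

        sel = [i for i in idx if top["resid"][i] == level
               and top["name"][i] not in DNA_BACKBONE_ATOMS]
        if not sel:
            sel = [i for i in idx if top["resid"][i] == level]
        return frame_xyz[sel].mean(axis=0)

    v_x = _level_com(last) - _level_com(first)
    a, b = _basepair_atoms(ensemble, site, first, ("P", "C3'"))
    v_t = frame_xyz[b] - frame_xyz[a]
    v_x = _normalize(np.asarray(v_x))
    v_t = _normalize(np.asarray(v_t))
    cross = np.cross(v_x, v_t)
    if np.linalg.norm(cross) < 1e-8:
        raise ValueError("degenerate frame: v_x parallel to v_t")
    v_z = _normalize(cross)
    v_y = _normalize(np.cross(v_x, v_z))
    return DnaFrame(v_x, v_t, v_z, v_y)


def helix_axis(frame_xyz: np.ndarray, ensemble: Ensemble,
               helix: RegionSelection,
               backbone_names: tuple[str, ...] = ("CA",)) -> np.ndarray:
    """Axis of a protein helix: principal component of its backbone atom
    positions, signed to run N→C (increasing residue number)."""
    idx = helix.resolve(ensemble)
    top = ensemble.topology
    sel = [i for i in idx if top["name"][i] in backbone_names]
    if len(sel) < 4:
        raise ValueError("helix axis needs >= 4 backbone positions")
    order = np.argsort([top["resid"][i] for i in sel], kind="stable")
    pts = frame_xyz[np.array(sel)[order]]
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # sign: along the N→C displacement
    if axis @ (pts[-1] - pts[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _signed_plane_angle(axis: np.ndarray, ref: np.ndarray,
                        other: np.ndarray) -> float:
    """Signed angle (deg) of the projection of ``axis`` onto the (ref, other)
    plane, measured from ``ref`` toward ``other`` via atan2."""
    a_ref = float(axis @ ref)
    a_oth = float(axis @ other)
    if np.hypot(a_ref, a_oth) < 1e-9:
        raise FloatingPointError("projection onto the plane vanishes")
    return float(np.degrees(np.arctan2(a_oth, a_ref)))


def rock_tumble(ensemble: Ensemble, site: RegionSelection,
                helix: RegionSelection,
                backbone_names: tuple[str, ...] = ("CA",)
                ) -> list[OrientationSample]:
    """Per-frame Rock and Tumble angles of a docking helix.

    Rock: docking-helix axis projected onto the v_y/v_z plane, signed angle
    from v_y.  Tumble: projection onto the v_x/v_z plane, signed from v_x.
    An angle whose projection vanishes (axis parallel to the plane normal)
    is flagged undefined (NaN) with a warning.
    """
    out = []
    undefined = 0
    for f in range(ensemble.n_frames):
        xyz = ensemble.frames[f]
        frm = dna_frame(xyz, ensemble, site)
        axis = helix_axis(xyz, ensemble, helix, backbone_names)
        angles = []
        for ref, other in ((frm.v_y, frm.v_z), (frm.v_x, frm.v_z)):
            try:
                angles.append(_signed_plane_angle(axis, ref, other))
            except FloatingPointError:
                angles.append(float("nan"))
                undefined += 1
        out.append(OrientationSample(angles[0], angles[1], f))
    if undefined:
        warnings.warn(f"{undefined} angle(s) undefined: projection vanishes",
                      stacklevel=2)
    return out


def samples_to_frame(samples: list[OrientationSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {"frame": [s.frame_index for s in samples],
         "rock": [s.rock for s in samples],
         "tumble": [s.tumble for s in samples]}
    )


def _ellipse_area(samples: list[OrientationSample]) -> float:
    data = np.array([[s.rock, s.tumble] for s in samples])
    data = data[np.all(np.isfinite(data), axis=1)]
    if len(data) < 50:
        raise ValueError("need >= 50 orientation samples")
    cov = np.cov(data.T)
    evals = np.linalg.eigvalsh(cov)
    if np.min(evals) <= 1e-12:
        raise ValueError("rank-deficient orientation covariance")
    return float(np.sqrt(np.prod(evals)))


def ellipse_area_ratio(samplesA: list[OrientationSample],
                       samplesB: list[OrientationSample]) -> float:
    """Ratio of Rock/Tumble conformational areas between two sample sets.

    The sampled area is the confidence-ellipse area from a 2D PCA of the
    (rock, tumble) cloud, which for any fixed confidence level is
    proportional to sqrt(λ1·λ2) of the covariance matrix — so the confidence
    threshold cancels in the ratio.
    """
    return _ellipse_area(samplesA) / _ellipse_area(samplesB)
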