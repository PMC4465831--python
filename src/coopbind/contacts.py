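"""Protein-DNA contact maps, recurrence classification, and unbinding profiles.

A contact is a heavy-atom pair within 4.5 Å (tie included).  Contacts present
in more than half of the frames are *recurrent*; the rest are *non-stable*.
During forced unbinding the fraction of recurrent reference contacts that
survive, and the count of non-stable contacts, are tracked per separation bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajectory_core import DNA_BACKBONE_ATOMS, Ensemble, RegionSelection

__all__ = [
    "ContactTable",
    "contact_map",
    "classify_recurrence",
    "per_residue_profile",
    "unbinding_profile",
]

DEFAULT_CUTOFF = 4.5
DEFAULT_RECURRENCE = 0.5


@dataclass
class ContactTable:
    """All observed atom-pair contacts of an ensemble.

    ``pairs`` has one row per observed pair with atom/residue metadata,
    occupancy and (after :func:`classify_recurrence`) a recurrent /
    non-stable label; ``presence`` is the per-frame boolean mask,
    shape (n_pairs, n_frames).
    """

    pairs: pd.DataFrame
    presence: np.ndarray
    cutoff: float
    n_frames: int
    recurrence_threshold: Optional[float] = None

    def __post_init__(self):
        if len(self.pairs) != self.presence.shape[0]:
            raise ValueError("pairs/presence mismatch")
        occ = self.presence.sum(axis=1) / max(self.n_frames, 1)
        if "occupancy" in self.pairs and len(self.pairs):
            if not np.allclose(self.pairs["occupancy"].to_numpy(), occ):
                raise ValueError("occupancy inconsistent with presence mask")

    @property
    def recurrent(self) -> pd.DataFrame:
        self._need_labels()
        return self.pairs[self.pairs["label"] == "recurrent"]

    @property
    def non_stable(self) -> pd.DataFrame:
        self._need_labels()
        return self.pairs[self.pairs["label"] == "non-stable"]

    def _need_labels(self):
        if "label" not in self.pairs:
            raise ValueError("table is unlabeled; run classify_recurrence")

    def pair_keys(self) -> set[tuple[int, int]]:
        return set(zip(self.pairs["i"], self.pairs["j"]))

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


def _dna_class(atom_name: str) -> str:
    return "backbone" if atom_name in DNA_BACKBONE_ATOMS else "base"


def contact_map(ensemble: Ensemble, selA: RegionSelection,
                selB: RegionSelection, cutoff: float = DEFAULT_CUTOFF,
                heavy_only: bool = True) -> ContactTable:
    """All cross atom pairs (i ∈ selA, j ∈ selB) within ``cutoff`` in at
    least one frame, with per-frame presence and occupancy.

    selA is conventionally the protein side and selB the DNA side; DNA atoms
    are classified base vs backbone by atom name (sugar-phosphate names →
    backbone).  Distances are superposition-invariant, so the ensemble needs
    no prior fitting.
    """
    if ensemble.n_frames == 0:
        raise ValueError("empty ensemble")
    ia = selA.resolve(ensemble)
    ib = selB.resolve(ensemble)
    if heavy_only:
        heavy = ensemble.topology["is_heavy"].to_numpy()
        ia, ib = ia[heavy[ia]], ib[heavy[ib]]
    if np.intersect1d(ia, ib).size:
        raise ValueError("selections must be disjoint")

    nf = ensemble.n_frames
    seen: dict[tuple[int, int], int] = {}
    hits: list[tuple[int, int]] = []  # (pair_id, frame)
    for f in range(nf):
        xyz = ensemble.frames[f]
        ta = cKDTree(xyz[ia])
        tb = cKDTree(xyz[ib])
        # tie at the cutoff is a contact: d <= cutoff
        pairs = ta.query_ball_tree(tb, r=cutoff + 1e-12)
        for a_local, blist in enumerate(pairs):
            for b_local in blist:
                d = np.linalg.norm(xyz[ia[a_local]] - xyz[ib[b_local]])
                if d > cutoff + 1e-9:
                    continue
                key = (int(ia[a_local]), int(ib[b_local]))
                pid = seen.setdefault(key, len(seen))
                hits.append((pid, f))

    n_pairs = len(seen)
    presence = np.zeros((n_pairs, nf), dtype=bool)
    for pid, f in hits:
        presence[pid, f] = True
    keys = sorted(seen, key=seen.get)
    top = ensemble.topology
    rows = []
    for (i, j), mask in zip(keys, presence):
        rows.append(
            {
                "i": i, "j": j,
                "name_i": top["name"][i], "resid_i": int(top["resid"][i]),
                "resname_i": top["resname"][i], "chain_i": top["chain"][i],
                "name_j": top["name"][j], "resid_j": int(top["resid"][j]),
                "resname_j": top["resname"][j], "chain_j": top["chain"][j],
                "dna_class": _dna_class(top["name"][j]),
                "occupancy": mask.sum() / nf,
            }
        )
    pairs_df = pd.DataFrame(
        rows,
        columns=["i", "j", "name_i", "resid_i", "resname_i", "chain_i",
                 "name_j", "resid_j", "resname_j", "chain_j", "dna_class",
                 "occupancy"],
    )
    return ContactTable(pairs_df, presence, cutoff, nf)


def classify_recurrence(table: ContactTable,
                        threshold: float = DEFAULT_RECURRENCE) -> ContactTable:
    """Label pairs recurrent (occupancy strictly above threshold) or
    non-stable (at or below)."""
    pairs = table.pairs.copy()
    occ = pairs["occupancy"].to_numpy() if len(pairs) else np.array([])
    pairs["label"] = np.where(occ > threshold, "recurrent", "non-stable")
    return ContactTable(pairs, table.presence, table.cutoff, table.n_frames,
                        recurrence_threshold=threshold)


def per_residue_profile(table: ContactTable, which: str = "recurrent",
                        split: bool = True) -> pd.DataFrame:
    """Number of contacts per protein residue, optionally split into DNA-base
    vs DNA-backbone partners.

    Counting is per atom pair: a residue whose three atoms each touch the
    same DNA atom contributes three.  ``which`` is ``recurrent``,
    ``non-stable`` or ``all``.
    """
    if which == "all":
        sub = table.pairs
    else:
        table._need_labels()
        sub = table.pairs[table.pairs["label"] == which]
    if split:
        out = (
            sub.groupby(["resid_i", "dna_class"]).size().unstack(fill_value=0)
        )
        for col in ("base", "backbone"):
            if col not in out:
                out[col] = 0
        out = out[["base", "backbone"]]
        out["total"] = out.sum(axis=1)
    else:
        out = sub.groupby("resid_i").size().to_frame("total")
    out.index.name = "resid"
    return out.reset_index()


def unbinding_profile(
    labeled_ensembles: Sequence[tuple[float, Ensemble]],
    reference: ContactTable,
    selA: RegionSelection,
    selB: RegionSelection,
    cutoff: Optional[float] = None,
) -> pd.DataFrame:
    """Survival of reference contacts during forced separation.

    For each (d_min label, ensemble): a recurrent reference pair counts as
    intact if it sits within the cutoff in more than half of that window's
    frames; the fraction intact (relative to the full recurrent reference
    set) and the number of distinct non-reference-recurrent ("non-stable")
    contact pairs are reported per label.
    """
    reference._need_labels()
    rec = reference.recurrent
    if len(rec) == 0:
        raise ValueError("reference has no recurrent contacts")
    cutoff = cutoff if cutoff is not None else reference.cutoff
    rec_keys = set(zip(rec["i"], rec["j"]))
    rows = []
    for d_label, ens in labeled_ensembles:
        tab = contact_map(ens, selA, selB, cutoff)
        occ = dict(zip(zip(tab.pairs["i"], tab.pairs["j"]),
                       tab.pairs["occupancy"]))
        intact = sum(1 for key in rec_keys if occ.get(key, 0.0) > 0.5)
        nonstable = sum(1 for key in occ if key not in rec_keys)
        rows.append(
            {"d_min": d_label,
             "fraction_recurrent": intact / len(rec_keys),
             "n_non_stable": nonstable}
        )
    return pd.DataFrame(rows).sort_values("d_min").reset_index(drop=True)
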