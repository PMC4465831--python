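"""Structure/ensemble data model, standard-format I/O, superposition, selections.

The central container is :class:`Ensemble`: an ordered atom table (topology)
plus a stack of coordinate frames in Å.  Everything downstream — contact maps,
orientation angles, groove geometry, correlation networks, the minimal-distance
collective variable — consumes this one type.

File formats (PDB, multi-model PDB, DCD, XTC) are read through MDAnalysis; a
plain long-format CSV of per-frame coordinates is accepted as a text-only
fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomRecord",
    "Ensemble",
    "RegionSelection",
    "SELECTION_PRESETS",
    "guess_element",
    "read_structure",
    "read_ensemble",
    "write_pdb",
    "write_csv_frames",
    "superpose",
    "min_distance",
]

# Sugar/phosphate atom names of a nucleotide; everything else on a DNA residue
# is treated as part of the base.
DNA_BACKBONE_ATOMS = frozenset(
    {"P", "OP1", "OP2", "O1P", "O2P", "O5'", "C5'", "C4'", "O4'",
     "C3'", "O3'", "C2'", "O2'", "C1'"}
)

DNA_RESNAMES = frozenset(
    {"DA", "DT", "DG", "DC", "A", "T", "G", "C", "DA5", "DT5", "DG5", "DC5",
     "DA3", "DT3", "DG3", "DC3", "ADE", "THY", "GUA", "CYT"}
)

_TWO_LETTER_ELEMENTS = {"CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CA2"}


def guess_element(atom_name: str, residue_name: str = "") -> str:
    """Derive the element from a PDB-style atom name.

    The rule is the standard one for biomolecular atom names: strip digits and
    primes, take the leading alphabetic character.  ``CA`` in a protein residue
    is Cα carbon, not calcium; two-letter elements (Cl, Na, ...) are only
    recognised for monoatomic ion residues.
    """
    name = atom_name.strip()
    if residue_name.strip().upper() in {"CL", "NA", "MG", "ZN", "CA", "K"}:
        return residue_name.strip().capitalize()
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        raise ValueError(f"cannot derive element from atom name {atom_name!r}")
    return stripped[0].upper()


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology, with identity metadata and a single position."""

    atom_name: str
    residue_index: int
    residue_name: str
    chain_id: str
    coordinates: np.ndarray
    element: str = ""

    def __post_init__(self):
        if not self.element:
            object.__setattr__(
                self, "element", guess_element(self.atom_name, self.residue_name)
            )
        object.__setattr__(
            self, "coordinates", np.asarray(self.coordinates, dtype=float)
        )

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


class Ensemble:
    """Topology + ordered coordinate frames (n_frames × n_atoms × 3, Å).

    Parameters
    ----------
    topology : pandas.DataFrame
        One row per atom, columns ``name, resid, resname, chain, element,
        is_heavy``.  Atom order is meaningful and preserved by all I/O.
    frames : ndarray
        Coordinates, shape ``(n_frames, n_atoms, 3)``.
    frame_period : float
        Time between saved frames in ps (must be > 0).
    """

    TOPOLOGY_COLUMNS = ("name", "resid", "resname", "chain", "element", "is_heavy")

    def __init__(self, topology: pd.DataFrame, frames: np.ndarray,
                 frame_period: float = 1.0):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if frames.shape[1] != len(topology):
            raise ValueError(
                f"atom-count mismatch: topology has {len(topology)} atoms, "
                f"frames have {frames.shape[1]}"
            )
        if frame_period <= 0:
            raise ValueError("frame_period must be > 0")
        self.topology = topology.reset_index(drop=True)
        self.frames = frames
        self.frame_period = float(frame_period)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_records(cls, records: Sequence[AtomRecord],
                     frames: Optional[np.ndarray] = None,
                     frame_period: float = 1.0) -> "Ensemble":
        top = pd.DataFrame(
            {
                "name": [r.atom_name for r in records],
                "resid": [r.residue_index for r in records],
                "resname": [r.residue_name for r in records],
                "chain": [r.chain_id for r in records],
                "element": [r.element for r in records],
                "is_heavy": [r.is_heavy for r in records],
            }
        )
        if frames is None:
            frames = np.array([[r.coordinates for r in records]])
        return cls(top, frames, frame_period)

    # -- basic views ----------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def atom_records(self, frame: int = 0) -> list[AtomRecord]:
        t = self.topology
        xyz = self.frames[frame]
        return [
            AtomRecord(t["name"][i], int(t["resid"][i]), t["resname"][i],
                       t["chain"][i], xyz[i], t["element"][i])
            for i in range(self.n_atoms)
        ]

    def subsample(self, stride: int) -> "Ensemble":
        """Deterministic frame subsampling: frames 0, stride, 2·stride, ..."""
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return Ensemble(self.topology, self.frames[::stride],
                        self.frame_period * stride)

    def heavy_indices(self) -> np.ndarray:
        return np.flatnonzero(self.topology["is_heavy"].to_numpy())

    def is_dna(self) -> np.ndarray:
        """Boolean mask of atoms belonging to nucleic-acid residues."""
        return self.topology["resname"].str.upper().isin(DNA_RESNAMES).to_numpy()


# -- selections ---------------------------------------------------------------

#: Residue-range presets for the OCT4 POU domains (1-based, inclusive).  The
#: POU-specific domain includes the helical part of the linker; the homeodomain
#: tail is the disordered N-terminal arm that docks into the minor groove.
#: Docking-helix ranges are approximate recognition-helix spans and are meant
#: to be overridden per system.
SELECTION_PRESETS: dict[str, tuple[int, int]] = {
    "POU_S": (1, 88),
    "POU_HD": (95, 152),
    "POU_HD_tail": (95, 107),
    "POU_HD_globular": (108, 152),
    "docking_helix_POU_S": (40, 52),
    "docking_helix_POU_HD": (136, 150),
}


@dataclass
class RegionSelection:
    """A named region: residue range and/or chain and/or explicit atoms.

    ``residue_range`` is a 1-based inclusive ``(lo, hi)`` pair.  ``preset``
    looks the range up in :data:`SELECTION_PRESETS`.  ``atom_indices`` takes
    precedence over everything else.
    """

    name: str
    residue_range: Optional[tuple[int, int]] = None
    chain: Optional[str] = None
    atom_names: Optional[frozenset] = None
    atom_indices: Optional[np.ndarray] = None
    preset: Optional[str] = None
    heavy_only: bool = False

    def __post_init__(self):
        if self.preset is not None:
            if self.preset not in SELECTION_PRESETS:
                raise KeyError(f"unknown selection preset {self.preset!r}")
            self.residue_range = SELECTION_PRESETS[self.preset]
        if self.atom_names is not None:
            self.atom_names = frozenset(self.atom_names)

    def resolve(self, ensemble: Ensemble) -> np.ndarray:
        """Return sorted atom indices of this selection in ``ensemble``."""
        if self.atom_indices is not None:
            idx = np.asarray(self.atom_indices, dtype=int)
        else:
            top = ensemble.topology
            mask = np.ones(len(top), dtype=bool)
            if self.residue_range is not None:
                lo, hi = self.residue_range
                resid = top["resid"].to_numpy()
                mask &= (resid >= lo) & (resid <= hi)
            if self.chain is not None:
                mask &= (top["chain"] == self.chain).to_numpy()
            if self.atom_names is not None:
                mask &= top["name"].isin(self.atom_names).to_numpy()
            idx = np.flatnonzero(mask)
        if self.heavy_only:
            heavy = ensemble.topology["is_heavy"].to_numpy()
            idx = idx[heavy[idx]]
        if len(idx) == 0:
            raise ValueError(f"selection {self.name!r} resolves to no atoms")
        return np.sort(idx)


# -- I/O ----------------------------------------------------------------------

def _validate_pdb_text(path: Path) -> None:
    """Pre-scan a PDB file: raise a parse error naming the offending line."""
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    n_atoms = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            n_atoms += 1
            if len(line) < 54:
                raise ValueError(
                    f"{path}: line {lineno}: truncated ATOM/HETATM record"
                )
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}: malformed {what} coordinate "
                        f"field {line[lo:hi]!r}"
                    ) from None
    if n_atoms == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records found")


def _topology_from_universe(u) -> pd.DataFrame:
    atoms = u.atoms
    try:
        chains = atoms.chainIDs
    except Exception:  # pragma: no cover - topology without chain info
        chains = atoms.segids
    names = [n.strip() for n in atoms.names]
    resnames = [r.strip() for r in atoms.resnames]
    elements = [guess_element(n, rn) for n, rn in zip(names, resnames)]
    return pd.DataFrame(
        {
            "name": names,
            "resid": atoms.resids.astype(int),
            "resname": resnames,
            "chain": [c.strip() or "A" for c in chains],
            "element": elements,
            "is_heavy": [e != "H" for e in elements],
        }
    )


def read_structure(path: Union[str, Path], fmt: str = "pdb") -> Ensemble:
    """Read a single-frame structure (PDB).  Atom order, chains and residue
    numbering are preserved exactly as written."""
    import MDAnalysis as mda

    path = Path(path)
    if fmt.lower() != "pdb":
        raise ValueError(f"unsupported structure format {fmt!r}")
    _validate_pdb_text(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    top = _topology_from_universe(u)
    frame = u.atoms.positions.astype(float)
    return Ensemble(top, frame[None], frame_period=1.0)


def read_ensemble(topology_path: Union[str, Path],
                  traj_path: Optional[Union[str, Path]] = None,
                  fmt: str = "pdb",
                  stride: int = 1,
                  frame_period: float = 1.0) -> Ensemble:
    """Read a multi-frame ensemble.

    ``fmt`` is the trajectory format: ``pdb`` (multi-model), ``dcd``, ``xtc``
    or ``csv`` (long table with columns frame, atom, x, y, z).  For multi-model
    PDB, ``traj_path`` may be omitted.
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    fmt = fmt.lower()
    if fmt == "csv":
        top_ens = read_structure(topology_path)
        df = pd.read_csv(traj_path)
        need = {"frame", "atom", "x", "y", "z"}
        if not need.issubset(df.columns):
            raise ValueError(f"csv frames need columns {sorted(need)}")
        df = df.sort_values(["frame", "atom"])
        n_per = df.groupby("frame").size().unique()
        if len(n_per) != 1 or n_per[0] != top_ens.n_atoms:
            raise ValueError(
                f"atom-count mismatch: topology has {top_ens.n_atoms} atoms, "
                f"csv frames have {sorted(set(n_per))}"
            )
        n_frames = df["frame"].nunique()
        frames = df[["x", "y", "z"]].to_numpy().reshape(n_frames, -1, 3)
        ens = Ensemble(top_ens.topology, frames, frame_period)
        return ens.subsample(stride) if stride > 1 else ens

    _validate_pdb_text(topology_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if traj_path is None:
            u = mda.Universe(str(topology_path))
        else:
            u = mda.Universe(str(topology_path), str(traj_path))
    top = _topology_from_universe(u)
    frames = []
    for ts in u.trajectory:
        if ts.positions.shape[0] != len(top):
            raise ValueError(
                f"atom-count mismatch: expected {len(top)}, "
                f"got {ts.positions.shape[0]} in frame {ts.frame}"
            )
        frames.append(ts.positions.astype(float).copy())
    ens = Ensemble(top, np.array(frames), frame_period)
    return ens.subsample(stride) if stride > 1 else ens


def write_pdb(ensemble: Ensemble, path: Union[str, Path]) -> None:
    """Write the ensemble as a (multi-model) PDB file.

    A plain fixed-column writer is used so that round-trips preserve atom
    order, chain identity and coordinates to the format's 10^-3 Å precision.
    """
    path = Path(path)
    t = ensemble.topology
    with open(path, "w") as fh:
        for m in range(ensemble.n_frames):
            if ensemble.n_frames > 1:
                fh.write(f"MODEL     {m + 1:4d}\n")
            xyz = ensemble.frames[m]
            for i in range(ensemble.n_atoms):
                name = t["name"][i]
                # PDB atom-name column convention: 1-letter elements start in
                # column 14
                pname = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
                fh.write(
                    "ATOM  {serial:5d} {name} {resname:<4s}{chain:1s}{resid:4d}"
                    "    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
                    "          {elem:>2s}\n".format(
                        serial=(i + 1) % 100000,
                        name=pname,
                        resname=t["resname"][i][:4],
                        chain=(t["chain"][i] or "A")[:1],
                        resid=int(t["resid"][i]) % 10000,
                        x=xyz[i, 0], y=xyz[i, 1], z=xyz[i, 2],
                        occ=1.0, b=0.0,
                        elem=t["element"][i][:2],
                    )
                )
            fh.write("TER\n")
            if ensemble.n_frames > 1:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_csv_frames(ensemble: Ensemble, path: Union[str, Path]) -> None:
    """Write frames as a long CSV (frame, atom, x, y, z)."""
    n_f, n_a = ensemble.n_frames, ensemble.n_atoms
    frame_col = np.repeat(np.arange(n_f), n_a)
    atom_col = np.tile(np.arange(n_a), n_f)
    flat = ensemble.frames.reshape(-1, 3)
    pd.DataFrame(
        {"frame": frame_col, "atom": atom_col,
         "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]}
    ).to_csv(path, index=False)


# -- superposition and distances ---------------------------------------------

def _check_fittable(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise ValueError("superposition needs >= 3 fit atoms")
    centered = coords - coords.mean(axis=0)
    # collinear points span a rank-1 subspace
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("fit selection is collinear; rotation is underdetermined")


def superpose(ensemble: Ensemble,
              fit_selection: RegionSelection,
              reference: Union[int, Ensemble] = 0) -> Ensemble:
    """Least-squares rigid-body fit of every frame onto a reference.

    The optimal rotation is the Kabsch solution over ``fit_selection``; the
    whole frame is transformed.  ``reference`` is a frame index of the
    ensemble itself or an external single-frame :class:`Ensemble`.
    """
    idx = fit_selection.resolve(ensemble)
    if isinstance(reference, Ensemble):
        ref = reference.frames[0][fit_selection.resolve(reference)]
    else:
        ref = ensemble.frames[int(reference)][idx]
    _check_fittable(ref)
    ref_center = ref.mean(axis=0)
    ref_c = ref - ref_center
    out = np.empty_like(ensemble.frames)
    for f in range(ensemble.n_frames):
        mob = ensemble.frames[f][idx]
        _check_fittable(mob)
        mob_center = mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, mob - mob_center)
        out[f] = rot.apply(ensemble.frames[f] - mob_center) + ref_center
    return Ensemble(ensemble.topology, out, ensemble.frame_period)


def fit_rmsd(ensemble: Ensemble, fit_selection: RegionSelection,
             reference: int = 0) -> np.ndarray:
    """Per-frame RMSD over the fit selection against a reference frame."""
    idx = fit_selection.resolve(ensemble)
    ref = ensemble.frames[reference][idx]
    diff = ensemble.frames[:, idx] - ref
    return np.sqrt((diff ** 2).sum(axis=2).mean(axis=1))


def min_distance(frame: np.ndarray,
                 ensemble: Ensemble,
                 selA: RegionSelection,
                 selB: RegionSelection,
                 heavy_only: bool = True) -> tuple[float, tuple[int, int]]:
    """Minimal interatomic distance between two disjoint selections.

    This is the collective variable d_min used for the unbinding coordinate:
    the minimum over all cross pairs of (by default heavy) atoms.  Returns
    ``(d_min, (i, j))`` with the arg-min atom indices.
    """
    ia = selA.resolve(ensemble)
    ib = selB.resolve(ensemble)
    if heavy_only:
        heavy = ensemble.topology["is_heavy"].to_numpy()
        ia, ib = ia[heavy[ia]], ib[heavy[ib]]
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("empty selection after heavy-atom filter")
    if np.intersect1d(ia, ib).size:
        raise ValueError("selections must be disjoint")
    xyz = np.asarray(frame, dtype=float)
    tree = cKDTree(xyz[ib])
    d, j = tree.query(xyz[ia], k=1)
    a = int(np.argmin(d))
    return float(d[a]), (int(ia[a]), int(ib[j[a]]))


def min_distance_series(ensemble: Ensemble, selA: RegionSelection,
                        selB: RegionSelection,
                        heavy_only: bool = True) -> np.ndarray:
    """d_min of every frame, as a 1D array."""
    return np.array(
        [min_distance(ensemble.frames[f], ensemble, selA, selB, heavy_only)[0]
         for f in range(ensemble.n_frames)]
    )
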