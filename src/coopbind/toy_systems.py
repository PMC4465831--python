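"""Synthetic-data generators.

The analyses in this package were designed for microsecond-scale atomistic
ensembles of protein-DNA complexes.  This module generates small synthetic
stand-ins that reproduce the *statistical structure* those analyses consume —
not the chemistry:

* :func:`gen_ideal_bdna` — an idealized B-form duplex (regular helix, four
  coarse atoms per nucleotide) that anchors groove-geometry and DNA-frame
  calculations.
* :func:`gen_toy_complex_ensemble` — duplex plus coarse pseudo-protein
  domains, with designated atom-pair contacts toggled by Bernoulli
  persistence, correlated Gaussian node displacements, and isotropic
  positional noise.
* :func:`gen_bd_umbrella` — overdamped Brownian (Euler–Maruyama) sampling of
  a prescribed 1D reference free-energy curve under harmonic umbrella
  restraints, producing an :class:`~coopbind.umbrella_fe.UmbrellaDataset`.
* :func:`gen_unbinding_schedule` — ensembles labeled by separation d_min in
  which designated contacts are broken exactly on schedule.

All generators are seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trajectory_core import Ensemble
from .umbrella_fe import KB, Thermo, UmbrellaDataset, UmbrellaWindow

__all__ = [
    "ReferencePMF",
    "BDParams",
    "PseudoDomain",
    "DesignedContact",
    "CorrelatedNodes",
    "ToyComplexSpec",
    "double_well_pmf",
    "gen_ideal_bdna",
    "gen_toy_complex_ensemble",
    "gen_bd_umbrella",
    "gen_unbinding_schedule",
]

# canonical idealized B-DNA cylindrical coordinates (radius Å, azimuth deg
# from the base-pair dyad); coarse four-atom nucleotide
_NUC_GEOMETRY = {
    "P": (8.91, 71.0),
    "C3'": (7.70, 62.0),
    "C2'": (5.50, 75.0),
    "C1'": (5.90, 45.0),
    "base": (1.50, 90.0),
}

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_PURINES = {"A", "G"}


@dataclass
class ReferencePMF:
    """A 1D reference free-energy curve G_ref(x) with linear interpolation."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or len(self.grid) < 2:
            raise ValueError("grid must be 1D with >= 2 points")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        # piecewise-constant slope per interval
        self._slopes = np.diff(self.values) / np.diff(self.grid)

    def value(self, x) -> np.ndarray:
        return np.interp(x, self.grid, self.values)

    def gradient(self, x) -> np.ndarray:
        """dG/dx under the linear interpolation rule."""
        idx = np.clip(np.searchsorted(self.grid, x) - 1, 0,
                      len(self._slopes) - 1)
        return self._slopes[idx]

    @property
    def max_abs_gradient(self) -> float:
        return float(np.max(np.abs(self._slopes)))


def double_well_pmf(well_depth: float = 3.0, barrier_height: float = 1.0,
                    lo: float = 2.55, hi: float = 5.5,
                    n: int = 1000) -> ReferencePMF:
    """Reference unbinding landscape: a deep bound well at 3.05 Å, a barrier
    at 3.6 Å, and a nearly flat unbound plateau with a shallow secondary well
    at 4.6 Å, behind a soft repulsive wall at short separation.

    With the defaults the barrier measured from the bound-well bottom is
    well_depth + barrier_height = 4 kcal/mol.  The shape mimics the sharp
    bound→unbound transition near hydrogen-bond distances seen in
    protein-DNA dissociation profiles, with a genuinely double-welled G(x).
    """
    x = np.linspace(lo, hi, n)
    g = (barrier_height * np.exp(-0.5 * ((x - 3.60) / 0.18) ** 2)
         - well_depth * np.exp(-0.5 * ((x - 3.05) / 0.18) ** 2)
         - 0.3 * np.exp(-0.5 * ((x - 4.60) / 0.35) ** 2)
         + 50.0 * np.where(x < 2.75, (x - 2.75) ** 2, 0.0))
    return ReferencePMF(x, g - g.min())


@dataclass(frozen=True)
class BDParams:
    """Overdamped Langevin integration parameters."""

    temperature: float = 300.0
    diffusion: float = 0.1      # Å²/ps
    timestep: float = 0.01      # ps
    n_steps: int = 100_000
    save_stride: int = 10
    seed: int = 0

    def stability_check(self, pmf: ReferencePMF,
                        max_force_constant: float = 0.0) -> None:
        """Check the Euler–Maruyama step resolves the landscape.

        Two conditions: the deterministic drift per step stays well below kT
        length scales, max|G'|·Δt·D/kT < 0.1 on the grid; and the stiffest
        harmonic restraint is resolved, 2k·D·Δt/kT < 0.25 (beyond that the
        discrete stationary variance is visibly biased)."""
        kT = KB * self.temperature
        drift = pmf.max_abs_gradient * self.timestep * self.diffusion / kT
        if drift >= 0.1:
            raise ValueError(
                f"unstable integration: |G'|·Δt·D/kT = {drift:.3f} >= 0.1; "
                "use a smaller timestep"
            )
        stiff = 2 * max_force_constant * self.diffusion * self.timestep / kT
        if stiff >= 0.25:
            raise ValueError(
                f"restraint too stiff for the timestep: 2k·D·Δt/kT = "
                f"{stiff:.3f} >= 0.25; use a smaller timestep"
            )


def gen_bd_umbrella(pmf: ReferencePMF,
                    windows: Sequence[tuple[float, float]],
                    bd: BDParams,
                    equil_fraction: float = 6.0 / 22.5) -> UmbrellaDataset:
    """Brownian-dynamics umbrella sampling on a 1D reference curve.

    Each window (center d_c, force constant k) evolves x by Euler–Maruyama
    on G_ref(x) + k(x − d_c)² with reflecting boundaries at the grid edges.
    All windows are integrated in lock-step (vectorized); the trajectory is
    saved every ``save_stride`` steps.  The first ``equil_fraction`` of each
    saved series is marked as equilibration and excluded from analysis.
    """
    centers = np.array([c for c, _ in windows], dtype=float)
    ks = np.array([k for _, k in windows], dtype=float)
    bd.stability_check(pmf, max_force_constant=float(ks.max()))
    lo, hi = pmf.grid[0], pmf.grid[-1]
    if np.any(centers < lo) or np.any(centers > hi):
        raise ValueError("window centers must lie inside the PMF grid")

    kT = KB * bd.temperature
    dt, D = bd.timestep, bd.diffusion
    noise_scale = np.sqrt(2 * D * dt)
    mobility = D * dt / kT
    rng = np.random.default_rng(bd.seed)

    x = centers.copy()
    n_saved = bd.n_steps // bd.save_stride
    out = np.empty((len(centers), n_saved))
    chunk = 10_000
    saved = 0
    step = 0
    while step < bd.n_steps:
        n = min(chunk, bd.n_steps - step)
        xi = rng.standard_normal((n, len(centers)))
        for s in range(n):
            force = -pmf.gradient(x) - 2.0 * ks * (x - centers)
            x = x + mobility * force + noise_scale * xi[s]
            # reflecting boundaries
            x = np.where(x < lo, 2 * lo - x, x)
            x = np.where(x > hi, 2 * hi - x, x)
            x = np.clip(x, lo, hi)
            step += 1
            if step % bd.save_stride == 0:
                out[:, saved] = x
                saved += 1
    uw = [
        UmbrellaWindow(centers[i], ks[i], out[i], equil_fraction)
        for i in range(len(centers))
    ]
    return UmbrellaDataset(uw, Thermo(bd.temperature))


# -- toy protein-DNA complexes ------------------------------------------------

@dataclass(frozen=True)
class PseudoDomain:
    """A coarse pseudo-protein domain: residues along an ideal α-helical path.

    Each residue carries five pseudo-atoms (N, CA, CB, C, O).  The helix runs
    from ``origin`` along unit ``direction`` with 1.5 Å rise and 100°/residue
    twist at 2.3 Å radius — the standard α-helix parameters.
    """

    name: str
    chain: str
    n_residues: int
    start_resid: int
    origin: tuple[float, float, float]
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)


@dataclass(frozen=True)
class DesignedContact:
    """A designated protein-DNA atom pair with Bernoulli frame persistence.

    When "in contact" the protein atom is placed ``bound_distance`` Å from its
    DNA partner (below the 4.5 Å contact cutoff); otherwise at
    ``unbound_distance``.  ``break_at`` marks the separation d_min at which
    the contact is permanently lost in scheduled-unbinding constructions.
    """

    name: str
    protein_atom: tuple[str, int, str]   # (chain, resid, atom name)
    dna_atom: tuple[str, int, str]
    persistence: float = 1.0
    bound_distance: float = 3.5
    unbound_distance: float = 6.5
    break_at: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must be in [0, 1]")


@dataclass
class CorrelatedNodes:
    """Atoms given correlated scalar displacements along a common direction.

    Per frame a vector δ ~ N(0, Σ) is drawn and atom m displaced by
    δ_m·amplitude·direction, so the positional cross-correlation of atoms
    (m, n) converges to corr(Σ)_{mn}.
    """

    atoms: list[tuple[str, int, str]]
    covariance: np.ndarray
    amplitude: float = 1.0
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self):
        self.covariance = np.asarray(self.covariance, dtype=float)
        k = len(self.atoms)
        if self.covariance.shape != (k, k):
            raise ValueError("covariance shape must match number of atoms")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(self.covariance)) < -1e-10:
            raise ValueError("covariance must be positive semi-definite")


@dataclass
class ToyComplexSpec:
    """Full specification of a synthetic protein-DNA complex ensemble."""

    n_basepairs: int = 12
    rise: float = 3.38
    twist: float = 36.0
    sequence: Optional[str] = None
    domains: list[PseudoDomain] = field(default_factory=list)
    contacts: list[DesignedContact] = field(default_factory=list)
    correlated: Optional[CorrelatedNodes] = None
    noise_sigma: float = 0.1
    seed: int = 0


def _duplex_rows(spec: ToyComplexSpec):
    """Topology rows and coordinates of the ideal duplex (two strands I/J)."""
    n = spec.n_basepairs
    if n < 4:
        raise ValueError("need at least 4 base pairs")
    seq = spec.sequence or ("ATGC" * ((n + 3) // 4))[:n]
    seq = seq.upper()
    if len(seq) != n or any(b not in _COMPLEMENT for b in seq):
        raise ValueError("sequence must be ACGT of length n_basepairs")
    twist = np.deg2rad(spec.twist)
    rows, coords = [], []
    for strand, chain, sign in (("I", "I", +1), ("J", "J", -1)):
        for i in range(n):
            base = seq[i] if strand == "I" else _COMPLEMENT[seq[i]]
            resname = "D" + base
            theta = twist * i
            z = spec.rise * i
            for atom, (r, phi_deg) in _NUC_GEOMETRY.items():
                phi = np.deg2rad(phi_deg) * sign
                name = atom
                if atom == "base":
                    name = "N3" if base in _PURINES else "C4"
                rows.append((name, i + 1, resname, chain))
                coords.append(
                    (r * np.cos(theta + phi), r * np.sin(theta + phi), z)
                )
    return rows, np.array(coords)


def gen_ideal_bdna(spec: ToyComplexSpec) -> Ensemble:
    """Idealized B-form duplex, single frame.

    Two antiparallel strands (chains I and J) on a regular helix with the
    spec's rise and twist.  Residues are numbered by base-pair level (pairing
    register) on both strands.  Each nucleotide carries P, C3', C1' and a
    base proxy atom (N3 for purines, C4 for pyrimidines).  The helical axis
    is the lab z axis.
    """
    rows, coords = _duplex_rows(spec)
    top = _topology_frame(rows)
    return Ensemble(top, coords[None], frame_period=1.0)


def _topology_frame(rows) -> pd.DataFrame:
    from .trajectory_core import guess_element

    names = [r[0] for r in rows]
    elements = [guess_element(nm) for nm in names]
    return pd.DataFrame(
        {
            "name": names,
            "resid": [r[1] for r in rows],
            "resname": [r[2] for r in rows],
            "chain": [r[3] for r in rows],
            "element": elements,
            "is_heavy": [e != "H" for e in elements],
        }
    )


_RESIDUE_ATOMS = ("N", "CA", "CB", "C", "O")
# small in-plane offsets (Å) of the backbone pseudo-atoms around the CA path
_ATOM_OFFSETS = {
    "N": (-0.7, -0.5), "CA": (0.0, 0.0), "CB": (0.0, 1.5),
    "C": (0.7, -0.5), "O": (1.1, -1.4),
}


def _domain_rows(dom: PseudoDomain):
    rows, coords = [], []
    d = np.asarray(dom.direction, dtype=float)
    d /= np.linalg.norm(d)
    # orthonormal frame around the helix direction
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    origin = np.asarray(dom.origin, dtype=float)
    radius, rise, turn = 2.3, 1.5, np.deg2rad(100.0)
    for r in range(dom.n_residues):
        ca = (origin + d * rise * r
              + e1 * radius * np.cos(turn * r)
              + e2 * radius * np.sin(turn * r))
        radial = e1 * np.cos(turn * r) + e2 * np.sin(turn * r)
        for atom in _RESIDUE_ATOMS:
            off_par, off_rad = _ATOM_OFFSETS[atom]
            pos = ca + d * off_par + radial * off_rad
            rows.append((atom, dom.start_resid + r, "ALA" if atom != "CB"
                         else "ALA", dom.chain))
            coords.append(pos)
    # use a generic residue name carrying CB so both Cα and Cβ network nodes
    # exist; rename to LEU for clarity
    rows = [(nm, ri, "LEU", ch) for (nm, ri, _, ch) in rows]
    return rows, np.array(coords)


def _base_complex(spec: ToyComplexSpec):
    rows, coords = _duplex_rows(spec)
    for dom in spec.domains:
        drows, dcoords = _domain_rows(dom)
        rows.extend(drows)
        coords = np.vstack([coords, dcoords])
    top = _topology_frame(rows)
    index = {
        (top["chain"][i], int(top["resid"][i]), top["name"][i]): i
        for i in range(len(top))
    }
    return top, coords, index


def _locate(index: dict, key: tuple[str, int, str]) -> int:
    if key not in index:
        raise KeyError(f"no atom {key} in toy complex")
    return index[key]


def _duplex_atom_mask(top: pd.DataFrame) -> np.ndarray:
    return top["chain"].isin(["I", "J"]).to_numpy()


def _fibonacci_directions(n: int = 128) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z ** 2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _clearance_direction(base: np.ndarray, partner: int,
                         dna_mask: np.ndarray,
                         bound_distance: float,
                         unbound_distance: float) -> np.ndarray:
    """Placement direction for a designated contact atom: the unit vector
    from the DNA partner that keeps both the bound and the unbound placement
    maximally clear of every *other* DNA atom, so toggling the pair cleanly
    adds/removes exactly one contact."""
    others = base[dna_mask]
    others = others[np.linalg.norm(others - base[partner], axis=1) > 1e-9]
    dirs = _fibonacci_directions()
    best, best_score = dirs[0], -np.inf
    for d in dirs:
        pb = base[partner] + d * bound_distance
        pu = base[partner] + d * unbound_distance
        clear_b = np.min(np.linalg.norm(others - pb, axis=1))
        clear_u = np.min(np.linalg.norm(others - pu, axis=1))
        score = min(clear_b, clear_u)
        if score > best_score:
            best_score, best = score, d
    return best


def gen_toy_complex_ensemble(spec: ToyComplexSpec, n_frames: int) -> Ensemble:
    """Synthetic ensemble with controlled contact and correlation statistics.

    Per frame: designated contacts are toggled in/out of contact range by
    independent Bernoulli draws with their persistence probability;
    correlated-node atoms receive Gaussian displacements drawn from the
    spec covariance; every atom receives isotropic N(0, σ²) noise.
    """
    top, base, index = _base_complex(spec)
    rng = np.random.default_rng(spec.seed)
    frames = np.repeat(base[None], n_frames, axis=0)

    if spec.correlated is not None:
        corr = spec.correlated
        node_idx = [_locate(index, a) for a in corr.atoms]
        u = np.asarray(corr.direction, dtype=float)
        u /= np.linalg.norm(u)
        delta = rng.multivariate_normal(
            np.zeros(len(node_idx)), corr.covariance, size=n_frames,
            method="eigh",
        )
        for m, ai in enumerate(node_idx):
            frames[:, ai] += np.outer(delta[:, m] * corr.amplitude, u)

    dna_mask = _duplex_atom_mask(top)
    for c in spec.contacts:
        pi = _locate(index, c.protein_atom)
        di = _locate(index, c.dna_atom)
        present = rng.random(n_frames) < c.persistence
        udir = _clearance_direction(base, di, dna_mask,
                                    c.bound_distance, c.unbound_distance)
        dist = np.where(present, c.bound_distance, c.unbound_distance)
        frames[:, pi] = frames[:, di] + udir[None] * dist[:, None]

    if spec.noise_sigma > 0:
        frames += rng.normal(0.0, spec.noise_sigma, size=frames.shape)
    return Ensemble(top, frames, frame_period=1.0)


def gen_unbinding_schedule(
    spec: ToyComplexSpec,
    schedule: dict[float, frozenset | set],
    n_frames_per_label: int = 25,
) -> list[tuple[float, Ensemble]]:
    """Ensembles labeled by separation d_min with contacts broken on schedule.

    ``schedule`` maps each d_min label (increasing) to the set of contact
    names *surviving* at that separation.  Surviving contacts are held in
    contact deterministically (persistence 1); broken contacts are placed out
    of range.  Survivor sets must shrink monotonically — a contact cannot
    re-form at larger separation.
    """
    labels = sorted(schedule)
    if list(schedule) != labels:
        raise ValueError("schedule keys must be increasing")
    known = {c.name for c in spec.contacts}
    prev = None
    for d in labels:
        surv = set(schedule[d])
        if not surv <= known:
            raise ValueError(f"unknown contact names {surv - known}")
        if prev is not None and not surv <= prev:
            raise ValueError(
                f"schedule violates monotone separation at {d}: "
                f"{surv - prev} re-form"
            )
        prev = surv
    out = []
    for d in labels:
        surv = set(schedule[d])
        contacts = [
            DesignedContact(c.name, c.protein_atom, c.dna_atom,
                            persistence=1.0 if c.name in surv else 0.0,
                            bound_distance=c.bound_distance,
                            unbound_distance=c.unbound_distance)
            for c in spec.contacts
        ]
        sub = ToyComplexSpec(
            n_basepairs=spec.n_basepairs, rise=spec.rise, twist=spec.twist,
            sequence=spec.sequence, domains=spec.domains, contacts=contacts,
            correlated=spec.correlated, noise_sigma=spec.noise_sigma,
            seed=spec.seed + int(round(d * 1000)),
        )
        out.append((d, gen_toy_complex_ensemble(sub, n_frames_per_label)))
    return out
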