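"""C-alpha backbone reconstruction from internal-coordinate constraints.

A protein's C-alpha trace is fully described, up to a rigid motion and
chirality, by its virtual-bond internal coordinates: consecutive Ca-Ca
distances ``b_i`` (~3.8 A for trans peptides), planar pseudo-bond angles
``theta_i`` and pseudo-dihedrals ``tau_i``.  This module

1. extracts that geometry from a trace (:func:`extract_geometry`),
2. converts it into per-atom distance constraints
   (:func:`geometry_to_distances`): atom ``i >= 5`` must sit at prescribed
   distances from its four predecessors, the distances implied by four bond
   lengths, three bond angles and two dihedrals,
3. rebuilds the chain sequentially (:func:`rebuild_chain`): the first four
   atoms are placed by exact geometric construction (the first at random,
   the rest by the NeRF internal-to-Cartesian rules), and every later atom
   is found by minimizing a constraint energy over a 3-D box with the
   adaptive firefly optimizer (:func:`place_next_ca`),
4. optionally perturbs the constraints with proportional Gaussian noise
   (:func:`add_constraint_noise`) to probe robustness.

The constraint energy is the sum of squared deviations between the
candidate's distances to its four placed predecessors and their targets
(zero exactly at a solution); an absolute-deviation form is available via
``energy_form="abs"``.

The reconstruction is defined only up to a rigid motion, so comparisons to
the source trace go through optimal superposition (see
:mod:`adafa.metrics`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adaptive import AdaptiveConfig, run_adafa
from .core import FAConfig, SearchSpace

__all__ = [
    "CaTrace",
    "InternalGeometry",
    "DistanceConstraints",
    "extract_geometry",
    "build_from_geometry",
    "geometry_to_distances",
    "placement_energy",
    "add_distance_noise",
    "seed_first_four",
    "place_next_ca",
    "rebuild_chain",
    "add_constraint_noise",
    "synthetic_helix",
    "read_ca_trace",
    "write_ca_trace",
    "STANDARD_CA_BOND",
]

#: Standard virtual Ca-Ca bond length (A) used when seeding a chain.
STANDARD_CA_BOND = 3.8


@dataclass
class CaTrace:
    """Ordered C-alpha coordinates (Angstroms) with residue numbering."""

    residue_ids: list
    coords: np.ndarray          # (n, 3)
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.residue_ids) != self.coords.shape[0]:
            raise ValueError("one residue id per coordinate required")

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass
class InternalGeometry:
    """Virtual-bond geometry of a Ca chain of n residues.

    ``bond_lengths`` has n-1 entries (b_2..b_n, A), ``bond_angles`` n-2
    entries (theta_3..theta_n, degrees in (0, 180)), ``dihedrals`` n-3
    entries (tau_4..tau_n, signed degrees in (-180, 180]).
    """

    bond_lengths: np.ndarray
    bond_angles: np.ndarray
    dihedrals: np.ndarray

    def __post_init__(self) -> None:
        self.bond_lengths = np.asarray(self.bond_lengths, dtype=float)
        self.bond_angles = np.asarray(self.bond_angles, dtype=float)
        self.dihedrals = np.asarray(self.dihedrals, dtype=float)
        n = self.n_residues
        if self.bond_angles.shape[0] != max(n - 2, 0) or self.dihedrals.shape[0] != max(n - 3, 0):
            raise ValueError("inconsistent internal-coordinate counts")

    @property
    def n_residues(self) -> int:
        return self.bond_lengths.shape[0] + 1


@dataclass
class DistanceConstraints:
    """Per-atom targets d(i, i-1..i-4) for atoms i >= 5 (0-based rows).

    ``targets[m]`` holds the four distances of atom ``i = m + 4`` (0-based)
    to atoms ``i-1, i-2, i-3, i-4`` in that order.
    """

    targets: np.ndarray         # (n-4, 4)

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        if self.targets.ndim != 2 or self.targets.shape[1] != 4:
            raise ValueError("targets must be an (n-4, 4) array")
        if np.any(self.targets <= 0):
            raise ValueError("distance targets must be positive")


# --------------------------------------------------------------------------
# internal coordinates <-> Cartesian
# --------------------------------------------------------------------------

def extract_geometry(trace: CaTrace | np.ndarray) -> InternalGeometry:
    """Virtual bond lengths, planar angles and signed dihedrals of a trace."""
    X = np.asarray(getattr(trace, "coords", trace), dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("geometry extraction requires at least 4 residues")
    v = np.diff(X, axis=0)                       # bond vectors (n-1, 3)
    b = np.linalg.norm(v, axis=1)
    if np.any(b == 0):
        raise ValueError("coincident consecutive residues")
    # planar angles at residues 2..n-1 (0-based 1..n-2)
    u1, u2 = -v[:-1], v[1:]
    cosang = np.sum(u1 * u2, axis=1) / (np.linalg.norm(u1, axis=1) * np.linalg.norm(u2, axis=1))
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    # signed dihedrals over residue quadruples
    b1, b2, b3 = v[:-2], v[1:-1], v[2:]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1n = np.linalg.norm(n1, axis=1)
    n2n = np.linalg.norm(n2, axis=1)
    bad = np.where((n1n < 1e-10) | (n2n < 1e-10))[0]
    if bad.size:
        raise ValueError(f"dihedral undefined: collinear triple near residue {int(bad[0]) + 2}")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(m1 * n2, axis=1)
    tau = np.degrees(np.arctan2(y, x))
    return InternalGeometry(bond_lengths=b, bond_angles=theta, dihedrals=tau)


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of the atom bonded to ``c`` given frame atoms a-b-c."""
    theta = np.radians(angle_deg)
    tau = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        # a-b-c collinear: the torsion reference plane is arbitrary
        probe = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        n = np.cross(probe, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    # torsion sign convention matches extract_geometry's signed dihedral
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(tau),
        -bond * np.sin(theta) * np.sin(tau),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_from_geometry(geom: InternalGeometry, origin: np.ndarray | None = None) -> np.ndarray:
    """Exact internal-to-Cartesian conversion (reference placer).

    Deterministic canonical frame: atom 1 at ``origin`` (default 0), atom 2
    along +x, atom 3 in the xy-plane.  Used as the energy-zero oracle placer
    and for converting geometry to distance constraints.
    """
    n = geom.n_residues
    X = np.zeros((n, 3))
    if origin is not None:
        X[0] = origin
    b = geom.bond_lengths
    X[1] = X[0] + np.array([b[0], 0.0, 0.0])
    if n >= 3:
        th = np.radians(geom.bond_angles[0])
        X[2] = X[1] + b[1] * np.array([-np.cos(th), np.sin(th), 0.0])
    for i in range(3, n):
        X[i] = _place_atom(X[i - 3], X[i - 2], X[i - 1],
                           b[i - 1], geom.bond_angles[i - 2], geom.dihedrals[i - 3])
    return X


def geometry_to_distances(geom: InternalGeometry) -> DistanceConstraints:
    """Distance targets d(i, i-1..i-4) implied by the internal coordinates.

    For each atom the 5-atom fragment ending at it is built exactly from its
    four bond lengths, three bond angles and two dihedrals, and the four
    distances are measured on it.
    """
    n = geom.n_residues
    if n < 5:
        raise ValueError("distance constraints require at least 5 residues")
    X = build_from_geometry(geom)
    targets = np.empty((n - 4, 4))
    for i in range(4, n):
        targets[i - 4] = [np.linalg.norm(X[i] - X[i - 1 - j]) for j in range(4)]
    return DistanceConstraints(targets=targets)


# --------------------------------------------------------------------------
# constraint energy and sequential placement
# --------------------------------------------------------------------------

def placement_energy(candidate, prev4: np.ndarray, targets, form: str = "squared") -> float:
    """Constraint energy of a candidate position against its 4 predecessors.

    ``prev4`` rows are the previous atoms ordered i-1, i-2, i-3, i-4;
    squared form: ``sum_j (|candidate - prev4_j| - target_j)**2``.
    """
    c = np.asarray(candidate, dtype=float)
    d = np.linalg.norm(np.asarray(prev4, dtype=float) - c, axis=1)
    dev = d - np.asarray(targets, dtype=float)
    if form == "squared":
        return float(np.sum(dev * dev))
    if form == "abs":
        return float(np.sum(np.abs(dev)))
    raise ValueError("energy form must be 'squared' or 'abs'")


class _PlacementProblem:
    """3-D box-constrained minimization of the placement energy."""

    def __init__(self, prev4: np.ndarray, targets: np.ndarray, form: str):
        self.prev4 = np.asarray(prev4, dtype=float)
        self.targets = np.asarray(targets, dtype=float)
        self.form = form
        half = 2.0 * float(np.max(self.targets))
        center = self.prev4[0]
        self.space = SearchSpace(3, center - half, center + half)

    def evaluate(self, X, rng=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = np.linalg.norm(X[:, None, :] - self.prev4[None, :, :], axis=2)
        dev = d - self.targets[None, :]
        if self.form == "squared":
            return np.sum(dev * dev, axis=1)
        return np.sum(np.abs(dev), axis=1)


def _default_placer_configs(seed: int) -> tuple[FAConfig, AdaptiveConfig]:
    fa = FAConfig(pop_size=20, max_gen=150, seed=seed)
    ada = AdaptiveConfig(strategy="S1")
    return fa, ada


def place_next_ca(
    prev4: np.ndarray,
    targets,
    seed: int = 0,
    fa_cfg: FAConfig | None = None,
    ada_cfg: AdaptiveConfig | None = None,
    energy_form: str = "squared",
    n_restarts: int = 3,
    restart_tolerance: float = 1e-8,
) -> tuple[np.ndarray, float]:
    """Locate the next atom by AdaFa over a box around the last placed atom.

    The search cube has side 4x the largest target distance centered on atom
    i-1, so any feasible candidate lies inside.  The energy landscape has
    two basins (the mirror pair cut out by the three nearest spheres, split
    by the fourth distance), so up to ``n_restarts`` independent runs are
    taken and the lowest-energy candidate kept; restarts stop early once the
    residual drops below ``restart_tolerance``.  Returns the best position
    and its residual energy.
    """
    problem = _PlacementProblem(np.asarray(prev4, dtype=float),
                                np.asarray(targets, dtype=float), energy_form)
    if fa_cfg is None or ada_cfg is None:
        d_fa, d_ada = _default_placer_configs(seed)
        fa_cfg = fa_cfg or d_fa
        ada_cfg = ada_cfg or d_ada
    best_pos, best_e = None, np.inf
    for k in range(max(n_restarts, 1)):
        cfg_k = FAConfig(beta0=fa_cfg.beta0, gamma=fa_cfg.gamma, alpha0=fa_cfg.alpha0,
                         pop_size=fa_cfg.pop_size, max_gen=fa_cfg.max_gen,
                         seed=fa_cfg.seed + 7919 * k,
                         scale_by_range=fa_cfg.scale_by_range)
        res = run_adafa(problem, cfg_k, ada_cfg)
        if res.best_value < best_e:
            best_pos, best_e = res.best_position, float(res.best_value)
        if best_e <= restart_tolerance:
            break
    return best_pos, best_e


def seed_first_four(geom: InternalGeometry, rng: np.random.Generator) -> np.ndarray:
    """Exact placement of atoms 1-4: random origin, then b2; b3, theta3;
    b4, theta4, tau4."""
    if geom.n_residues < 4:
        raise ValueError("need at least 4 residues of geometry")
    origin = rng.random(3)
    head = InternalGeometry(
        bond_lengths=geom.bond_lengths[:3],
        bond_angles=geom.bond_angles[:2],
        dihedrals=geom.dihedrals[:1],
    )
    return build_from_geometry(head, origin=origin)


def add_distance_noise(
    constraints: DistanceConstraints, fraction: float, rng: np.random.Generator
) -> DistanceConstraints:
    """Proportional Gaussian noise on the derived distance targets instead
    of the internal coordinates (the alternative noise model)."""
    if fraction < 0:
        raise ValueError("noise fraction must be non-negative")
    t = constraints.targets
    noisy = t + fraction * np.abs(t) * rng.standard_normal(t.shape)
    return DistanceConstraints(targets=np.maximum(noisy, 1e-3))


def rebuild_chain(
    geom: InternalGeometry,
    seed: int = 0,
    energy_form: str = "squared",
    energy_tolerance: float = 1e-6,
    placer_pop: int = 12,
    placer_gen: int = 100,
    placer_restarts: int = 6,
    ada_cfg: AdaptiveConfig | None = None,
    constraints: DistanceConstraints | None = None,
) -> tuple[CaTrace, np.ndarray]:
    """Sequential AdaFa reconstruction of a full chain from its geometry.

    Atoms 1-4 are placed exactly; each later atom minimizes the 4-distance
    constraint energy.  ``constraints`` overrides the targets derived from
    ``geom`` (e.g. to inject distance-level noise).  Returns the rebuilt
    trace and the per-atom residual energies (zeros for the first four);
    an atom whose residual exceeds ``energy_tolerance`` leaves the build
    running but is reported through the energies array.
    """
    n = geom.n_residues
    if n < 5:
        raise ValueError("rebuild requires at least 5 residues")
    rng = np.random.default_rng(seed)
    if constraints is None:
        constraints = geometry_to_distances(geom)
    if constraints.targets.shape[0] != n - 4:
        raise ValueError("constraint rows must match the chain length")
    X = np.zeros((n, 3))
    X[:4] = seed_first_four(geom, rng)
    energies = np.zeros(n)
    if ada_cfg is None:
        ada_cfg = AdaptiveConfig(strategy="S1")
    for i in range(4, n):
        prev4 = X[i - 1::-1][:4]               # rows i-1, i-2, i-3, i-4
        fa_cfg = FAConfig(pop_size=placer_pop, max_gen=placer_gen,
                          seed=int(rng.integers(0, 2 ** 31 - 1)))
        pos, e = place_next_ca(prev4, constraints.targets[i - 4],
                               fa_cfg=fa_cfg, ada_cfg=ada_cfg,
                               energy_form=energy_form,
                               n_restarts=placer_restarts)
        X[i] = pos
        energies[i] = e
    trace = CaTrace(residue_ids=list(range(1, n + 1)), coords=X)
    return trace, energies


def add_constraint_noise(
    geom: InternalGeometry, fraction: float, rng: np.random.Generator
) -> InternalGeometry:
    """Perturb each internal coordinate with proportional Gaussian noise.

    Each value gets zero-mean Gaussian noise with standard deviation
    ``fraction * |value|`` (so ``fraction=0.1`` is 10% white noise).  Angles
    are re-wrapped into their valid ranges: bond angles reflected into
    (0, 180), dihedrals wrapped into (-180, 180].
    """
    if fraction < 0:
        raise ValueError("noise fraction must be non-negative")
    if fraction == 0:
        return InternalGeometry(geom.bond_lengths.copy(), geom.bond_angles.copy(),
                                geom.dihedrals.copy())

    def jitter(x):
        return x + fraction * np.abs(x) * rng.standard_normal(x.shape)

    b = np.maximum(jitter(geom.bond_lengths), 1e-3)
    theta = jitter(geom.bond_angles)
    theta = np.abs((theta + 360.0) % 360.0)
    theta = np.where(theta > 180.0, 360.0 - theta, theta)
    theta = np.clip(theta, 1e-3, 180.0 - 1e-3)
    tau = (jitter(geom.dihedrals) + 180.0) % 360.0 - 180.0
    tau = np.where(tau == -180.0, 180.0, tau)
    return InternalGeometry(bond_lengths=b, bond_angles=theta, dihedrals=tau)


def synthetic_helix(
    n: int, rise: float = 1.5, radius: float = 2.3, twist: float = 100.0
) -> CaTrace:
    """Ideal alpha-helical Ca spiral (synthetic stand-in for real chains).

    Defaults (1.5 A rise, 2.3 A radius, 100 deg/residue twist) give the
    canonical ~3.8 A consecutive Ca-Ca distance of an alpha helix.
    """
    if n < 5:
        raise ValueError("helix fixture needs at least 5 residues")
    k = np.arange(n)
    phi = np.radians(twist) * k
    coords = np.column_stack([radius * np.cos(phi), radius * np.sin(phi), rise * k])
    return CaTrace(residue_ids=list(range(1, n + 1)), coords=coords)


# --------------------------------------------------------------------------
# PDB I/O (C-alpha subset)
# --------------------------------------------------------------------------

def read_ca_trace(path, chain: str | None = None) -> CaTrace:
    """Read the C-alpha trace of one chain from a PDB file.

    Keeps CA atoms with blank or 'A' altloc from the first model; ``chain``
    defaults to the first chain present.  Residue numbering is preserved.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    chains = [ch.name for ch in model]
    if not chains:
        raise ValueError(f"no chains in {path}")
    name = chain if chain is not None else chains[0]
    if name not in chains:
        raise ValueError(f"chain {name!r} not found in {path} (has {chains})")
    ids, xyz = [], []
    for res in model[name]:
        for atom in res:
            if atom.name == "CA" and atom.altloc in ("", "A", "\x00"):
                ids.append(res.seqid.num)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                break
    if len(ids) < 1:
        raise ValueError(f"no CA atoms in chain {name!r} of {path}")
    return CaTrace(residue_ids=ids, coords=np.array(xyz), chain_id=name)


def write_ca_trace(trace: CaTrace, path) -> None:
    """Write a trace as minimal PDB ATOM records (CA of alanine residues)."""
    lines = []
    for k, (rid, (x, y, z)) in enumerate(zip(trace.residue_ids, trace.coords), start=1):
        lines.append(
            f"ATOM  {k:5d}  CA  ALA {trace.chain_id:1s}{int(rid):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
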