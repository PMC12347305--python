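"""Torsion-angle peptide model and deterministic Cartesian construction.

The peptide is represented in internal coordinates with rigid covalent
geometry: bond lengths and bond angles are fixed by the bundled topology
table and only torsion angles vary.  Atoms are placed sequentially by
natural-extension-of-reference-frame (NeRF) construction, so coordinates
are a pure, deterministic function of (sequence, torsions).

Conventions
-----------
* All angles are degrees in the half-open interval [-180, 180).
* Flattened variable order per residue: phi, psi, chi_1..chi_c, omega.
  omega_i is the dihedral about the peptide bond *following* residue i
  (CA_i - C_i - N_{i+1} - CA_{i+1}); the last residue's omega is retained
  in the vector for a uniform per-residue layout but moves no atom.
* Coordinate frame: residue 1's N at the origin, its CA on +x, its
  phi reference (a virtual predecessor carbonyl carbon) in the xy-plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, NumericError
from .io_formats import AminoAcidSequence, TopologyTable, load_topology

__all__ = [
    "wrap_angle",
    "count_variables",
    "TorsionState",
    "Atom",
    "AtomModel",
    "PeptideSystem",
    "build_coordinates",
    "measure_dihedral",
]

# branch dihedral C-N-CA-CB placing the first side-chain atom (deg);
# fixed improper giving an L-like handedness
_CB_BRANCH_DIHEDRAL = -122.6


def wrap_angle(x: float) -> float:
    """Wrap an angle in degrees into [-180, 180)."""
    if not math.isfinite(x):
        raise NumericError(f"cannot wrap non-finite angle {x!r}")
    return (x + 180.0) % 360.0 - 180.0


def wrap_angles(x: np.ndarray) -> np.ndarray:
    """Vectorized :func:`wrap_angle`."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise NumericError("cannot wrap non-finite angles")
    return (x + 180.0) % 360.0 - 180.0


def _as_sequence(sequence) -> AminoAcidSequence:
    if isinstance(sequence, AminoAcidSequence):
        return sequence
    return AminoAcidSequence("seq", str(sequence))


def count_variables(sequence, omega_free: bool = True,
                    topology: TopologyTable | None = None) -> int:
    """Number of free torsions: per residue 2 backbone (+1 if omega is free)
    plus the residue type's rotatable-chi count from the topology table."""
    seq = _as_sequence(sequence)
    topology = topology or load_topology()
    per_res = 3 if omega_free else 2
    return sum(per_res + topology.residue(ch).chi_count for ch in seq.residues)


@dataclass
class TorsionState:
    """Per-residue dihedral angles; the optimizer's solution vector.

    ``chis[i]`` has exactly the rotatable-chi count of residue i's type.
    All angles are wrapped into [-180, 180) on construction.
    """

    sequence: AminoAcidSequence
    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    chis: list[np.ndarray]
    omega_free: bool = True

    def __post_init__(self):
        self.sequence = _as_sequence(self.sequence)
        n = len(self.sequence)
        self.phi = wrap_angles(np.asarray(self.phi, dtype=float))
        self.psi = wrap_angles(np.asarray(self.psi, dtype=float))
        self.omega = wrap_angles(np.asarray(self.omega, dtype=float))
        for arr in (self.phi, self.psi, self.omega):
            if arr.shape != (n,):
                raise DomainError(
                    f"backbone angle arrays must have length {n}, got {arr.shape}"
                )
        if len(self.chis) != n:
            raise DomainError(f"chis must have one entry per residue ({n})")
        self.chis = [wrap_angles(np.asarray(c, dtype=float)) for c in self.chis]

    def validate_against(self, topology: TopologyTable) -> None:
        for i, ch in enumerate(self.sequence.residues):
            expected = topology.residue(ch).chi_count
            if len(self.chis[i]) != expected:
                raise DomainError(
                    f"residue {i + 1} ({ch}) expects {expected} chi angles, "
                    f"got {len(self.chis[i])}"
                )

    def flatten(self) -> np.ndarray:
        """Flattened view: per residue [phi, psi, chi_1..chi_c, omega?]."""
        out = []
        for i in range(len(self.sequence)):
            out.extend([self.phi[i], self.psi[i]])
            out.extend(self.chis[i])
            if self.omega_free:
                out.append(self.omega[i])
        return np.array(out, dtype=float)

    @classmethod
    def from_flat(cls, sequence, vector, omega_free: bool = True,
                  topology: TopologyTable | None = None) -> "TorsionState":
        seq = _as_sequence(sequence)
        topology = topology or load_topology()
        vector = np.asarray(vector, dtype=float)
        expected = count_variables(seq, omega_free, topology)
        if vector.shape != (expected,):
            raise DomainError(
                f"flattened vector for {seq.residues!r} must have length "
                f"{expected}, got {vector.shape}"
            )
        phi, psi, omega, chis = [], [], [], []
        pos = 0
        for ch in seq.residues:
            c = topology.residue(ch).chi_count
            phi.append(vector[pos]); psi.append(vector[pos + 1])
            chis.append(np.array(vector[pos + 2:pos + 2 + c]))
            pos += 2 + c
            if omega_free:
                omega.append(vector[pos]); pos += 1
            else:
                omega.append(180.0)
        return cls(seq, np.array(phi), np.array(psi),
                   np.array(omega), chis, omega_free=omega_free)

    @classmethod
    def extended(cls, sequence, omega_free: bool = True,
                 topology: TopologyTable | None = None) -> "TorsionState":
        """Fully extended conformation: every torsion at 180 degrees."""
        seq = _as_sequence(sequence)
        topology = topology or load_topology()
        n = len(seq)
        chis = [np.full(topology.residue(ch).chi_count, 180.0) for ch in seq.residues]
        full = np.full(n, 180.0)
        return cls(seq, full.copy(), full.copy(), full.copy(), chis,
                   omega_free=omega_free)


@dataclass(frozen=True)
class Atom:
    name: str
    residue_index: int  # 1-based
    atom_class: str
    charge: float
    xyz: tuple[float, float, float]
    res_name: str = "UNK"


@dataclass
class AtomModel:
    """Built Cartesian atoms plus the covalent bond graph (index pairs)."""

    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def ca_coordinates(self) -> np.ndarray:
        pts = [a.xyz for a in self.atoms if a.name == "CA"]
        return np.array(pts, dtype=float)


def _place(a, b, c, r, theta, phi):
    """NeRF placement of atom D bonded to C.

    theta is the bond angle B-C-D, phi the dihedral A-B-C-D (radians).
    """
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    nb = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx / nb, bcy / nb, bcz / nb
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    # n = unit(ab x bc), m = n x bc
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    st, ct = math.sin(theta), math.cos(theta)
    sp, cp = math.sin(phi), math.cos(phi)
    d0, d1, d2 = -r * ct, r * st * cp, r * st * sp
    return (c[0] + d0 * bcx + d1 * mx + d2 * nx,
            c[1] + d0 * bcy + d1 * my + d2 * ny,
            c[2] + d0 * bcz + d1 * mz + d2 * nz)


def measure_dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in [-180, 180)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return wrap_angle(math.degrees(math.atan2(y, x)))


class PeptideSystem:
    """Compiled internal-coordinate builder for one sequence.

    Compiling once per sequence precomputes the atom placement program,
    atom classes/charges and the covalent bond graph, so repeated builds
    during optimization are cheap.  Atom count and bond graph depend only
    on the sequence, never on torsion values.
    """

    def __init__(self, sequence, topology: TopologyTable | None = None,
                 omega_free: bool = True):
        self.sequence = _as_sequence(sequence)
        self.topology = topology or load_topology()
        self.omega_free = omega_free
        self.n_variables = count_variables(self.sequence, omega_free, self.topology)
        self._compile()

    # -- compilation -------------------------------------------------------
    def _compile(self):
        topo = self.topology
        seq = self.sequence.residues
        self.atom_names: list[str] = []
        self.atom_classes: list[str] = []
        self.atom_residue: list[int] = []  # 1-based
        self.res_names: list[str] = []
        self.bonds: list[tuple[int, int]] = []
        # placement program entries:
        #   (a, b, c, r, theta_rad, var_index or -1, offset_deg)
        self._program: list[tuple] = []
        self.var_kinds: list[str] = []

        # flattened-variable index bookkeeping
        var_index: dict[tuple[int, str], int] = {}
        pos = 0
        for i, ch in enumerate(seq):
            c = topo.residue(ch).chi_count
            var_index[(i, "phi")] = pos
            var_index[(i, "psi")] = pos + 1
            self.var_kinds.extend(["phi", "psi"])
            for j in range(c):
                var_index[(i, f"chi{j + 1}")] = pos + 2 + j
                self.var_kinds.append("chi")
            pos += 2 + c
            if self.omega_free:
                var_index[(i, "omega")] = pos
                self.var_kinds.append("omega")
                pos += 1
        assert pos == self.n_variables

        def vid(i, kind):
            return var_index.get((i, kind), -1)

        idx: dict[tuple[int, str], int] = {}

        def add(name, res_i, cls, a, b, c, r, theta, var, offset, bond_to):
            k = len(self.atom_names)
            self.atom_names.append(name)
            self.atom_classes.append(cls)
            self.atom_residue.append(res_i + 1)
            self.res_names.append(topo.residue(seq[res_i]).name)
            self._program.append((a, b, c, r, math.radians(theta), var,
                                  math.radians(offset)))
            if bond_to is not None:
                self.bonds.append((bond_to, k))
            idx[(res_i, name)] = k
            return k

        ang = topo.bond_angle
        bl = topo.bond_length
        for i, ch in enumerate(seq):
            res = topo.residue(ch)
            if i == 0:
                n_i = add("N", 0, "N", -1, -1, -1, 0, 0, -1, 0, None)
                ca_i = add("CA", 0, "CA", -1, -1, -1, 0, 0, -1, 0, n_i)
                # phi reference: virtual predecessor carbonyl C (index -2)
                c_i = add("C", 0, "C", -2, n_i, ca_i, bl("CA", "C"),
                          ang("N", "CA", "C"), vid(0, "phi"), 0.0, ca_i)
                h_i = add("H", 0, "H", c_i, ca_i, n_i, bl("N", "H"),
                          ang("CA", "N", "H"), -1, 180.0, n_i)
            else:
                p_n = idx[(i - 1, "N")]
                p_ca = idx[(i - 1, "CA")]
                p_c = idx[(i - 1, "C")]
                n_i = add("N", i, "N", p_n, p_ca, p_c, bl("C", "N"),
                          ang("CA", "C", "N"), vid(i - 1, "psi"), 0.0, p_c)
                omega_var = vid(i - 1, "omega")
                ca_i = add("CA", i, "CA", p_ca, p_c, n_i, bl("N", "CA"),
                           ang("C", "N", "CA"), omega_var,
                           0.0 if self.omega_free else 180.0, n_i)
                c_i = add("C", i, "C", p_c, n_i, ca_i, bl("CA", "C"),
                          ang("N", "CA", "C"), vid(i, "phi"), 0.0, ca_i)
                h_i = add("H", i, "H", p_ca, p_c, n_i, bl("N", "H"),
                          ang("C", "N", "H"), omega_var,
                          180.0, n_i)
            add("O", i, "O", n_i, ca_i, c_i, bl("C", "O"),
                ang("CA", "C", "O"), vid(i, "psi"), 180.0, c_i)
            # side chain: linear chain of united atoms off CA
            prev2, prev1, cur = c_i, n_i, ca_i
            for j, aname in enumerate(res.side_atoms):
                if j == 0:
                    k = add(aname, i, "CS", c_i, n_i, ca_i, bl("CA", "CS"),
                            ang("N", "CA", "CS"), -1, _CB_BRANCH_DIHEDRAL, ca_i)
                    prev2, prev1, cur = n_i, ca_i, k
                else:
                    theta = ang("CA", "CS", "CS") if j == 1 else ang("CS", "CS", "CS")
                    k = add(aname, i, "CS", prev2, prev1, cur, bl("CS", "CS"),
                            theta, vid(i, f"chi{j}"), 0.0, cur)
                    prev2, prev1, cur = prev1, cur, k
        self.n_atoms = len(self.atom_names)
        self._var_index = var_index

    # -- building ----------------------------------------------------------
    def build_coords(self, state) -> np.ndarray:
        """Cartesian coordinates (n_atoms, 3) for a torsion state or vector."""
        if isinstance(state, TorsionState):
            state.validate_against(self.topology)
            vec = state.flatten()
        else:
            vec = np.asarray(state, dtype=float)
        if vec.shape != (self.n_variables,):
            raise DomainError(
                f"state has {vec.shape} variables, system expects {self.n_variables}"
            )
        rad = np.radians(vec)
        coords: list[tuple] = []
        # virtual predecessor for residue 1's phi reference (index -2)
        theta_v = math.radians(self.topology.bond_angle("C", "N", "CA"))
        r_v = self.topology.bond_length("C", "N")
        virtual = (r_v * math.cos(theta_v), r_v * math.sin(theta_v), 0.0)
        bl_nca = self.topology.bond_length("N", "CA")
        for k, (a, b, c, r, theta, var, offset) in enumerate(self._program):
            if k == 0:
                coords.append((0.0, 0.0, 0.0))
                continue
            if k == 1:
                coords.append((bl_nca, 0.0, 0.0))
                continue
            pa = virtual if a == -2 else coords[a]
            phi = offset if var < 0 else rad[var] + offset
            coords.append(_place(pa, coords[b], coords[c], r, theta, phi))
        return np.array(coords, dtype=float)

    def to_atom_model(self, coords: np.ndarray, charges: dict | None = None) -> AtomModel:
        atoms = [
            Atom(name=self.atom_names[k], residue_index=self.atom_residue[k],
                 atom_class=self.atom_classes[k],
                 charge=0.0 if charges is None else charges.get(self.atom_classes[k], 0.0),
                 xyz=tuple(coords[k]), res_name=self.res_names[k])
            for k in range(self.n_atoms)
        ]
        return AtomModel(atoms=atoms, bonds=list(self.bonds))

    def build_model(self, state, charges: dict | None = None) -> AtomModel:
        return self.to_atom_model(self.build_coords(state), charges)

    # -- measurement -------------------------------------------------------
    def measure_backbone(self, coords: np.ndarray):
        """Measure (phi, psi, omega) from coordinates, same reference
        conventions as the builder.  The last residue's psi is recovered from
        the carbonyl O; its omega moves no atom and is returned as nan."""
        n = len(self.sequence)
        ix = self._atom_index()
        theta_v = math.radians(self.topology.bond_angle("C", "N", "CA"))
        r_v = self.topology.bond_length("C", "N")
        virtual = np.array([r_v * math.cos(theta_v), r_v * math.sin(theta_v), 0.0])
        phi = np.empty(n)
        psi = np.empty(n)
        omega = np.full(n, np.nan)
        for i in range(n):
            N, CA, C, O = (coords[ix[(i, nm)]] for nm in ("N", "CA", "C", "O"))
            prevC = virtual if i == 0 else coords[ix[(i - 1, "C")]]
            phi[i] = measure_dihedral(prevC, N, CA, C)
            if i + 1 < n:
                nextN = coords[ix[(i + 1, "N")]]
                nextCA = coords[ix[(i + 1, "CA")]]
                psi[i] = measure_dihedral(N, CA, C, nextN)
                omega[i] = measure_dihedral(CA, C, nextN, nextCA)
            else:
                psi[i] = wrap_angle(measure_dihedral(N, CA, C, O) - 180.0)
        return phi, psi, omega

    def _atom_index(self):
        return {(self.atom_residue[k] - 1, self.atom_names[k]): k
                for k in range(self.n_atoms)}


def build_coordinates(sequence, state: TorsionState,
                      topology: TopologyTable | None = None) -> AtomModel:
    """One-shot convenience: compile the sequence and build an atom model."""
    system = PeptideSystem(sequence, topology, omega_free=state.omega_free)
    return system.build_model(state)
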