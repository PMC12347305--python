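"""Empirical in-vacuo potential in torsion space — the optimizer's objective.

E_total = sum_{j>i} [ A_ij/r^12 - B_ij/r^6 ]          (12-6 dispersion/repulsion)
        + 332 * sum_{j>i} q_i q_j / (eps * r_ij)       (Coulomb, distance in A)
        + sum_{hb pairs} [ C_ij/r^12 - D_ij/r^10 ]     (12-10 hydrogen bond)
        + sum_n U_n (1 +/- cos(k_n * phi_n))           (torsion barriers)

With rigid covalent geometry the potential is a pure function of the
torsion vector.  By default a flagged donor-H/acceptor pair contributes the
12-10 term *instead of* its 12-6 term; an additive mode that sums both
unconditionally is available for fidelity with formulations that print it
that way.  Nonbonded pairs separated by one or two covalent bonds are
excluded; 1-4 pairs and beyond are included at full weight.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, NumericError
from .geometry import PeptideSystem, TorsionState
from .io_formats import EnergyParameterSet, load_parameter_set

__all__ = [
    "EnergyBreakdown",
    "nonbonded_pair_energy",
    "torsion_energy",
    "evaluate_energy",
    "EnergySystem",
]

_MIN_DISTANCE = 1e-6  # A; below this two atoms are treated as coincident


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term decomposition; ``total`` is the exact sum of the four parts."""

    lj: float
    electrostatic: float
    hbond: float
    torsion: float

    @property
    def total(self) -> float:
        return self.lj + self.electrostatic + self.hbond + self.torsion


def nonbonded_pair_energy(class_a: str, class_b: str, r: float,
                          params: EnergyParameterSet,
                          hbond_mode: str = "replace"):
    """(lj, electrostatic, hbond) energies of one atom pair at distance r.

    For a flagged donor-H/acceptor pair the 12-10 term applies; in the
    default ``replace`` mode it supersedes the pair's 12-6 term.
    """
    if r <= 0:
        raise DomainError(f"pair distance must be positive, got {r}")
    hb = params.hbond(class_a, class_b) or params.hbond(class_b, class_a)
    qq = params.charge(class_a) * params.charge(class_b)
    elec = params.coulomb_constant * qq / (params.dielectric * r)
    if hb is not None:
        c, d = hb
        hbond = c / r**12 - d / r**10
        if hbond_mode == "replace":
            return 0.0, elec, hbond
    else:
        hbond = 0.0
    a, b = params.pair(class_a, class_b)
    lj = a / r**12 - b / r**6
    return lj, elec, hbond


def torsion_energy(state: TorsionState, params: EnergyParameterSet) -> float:
    """Sum of U_n (1 +/- cos(k_n phi_n)) over every torsion in the state.

    chi torsions share one parameter entry (kind ``chi``); the last
    residue's omega is included — at its 180-degree rest value it
    contributes nothing under the bundled table.
    """
    total = 0.0
    for kind, angles in (("phi", state.phi), ("psi", state.psi),
                         ("omega", state.omega)):
        u, k, sign = params.torsion(kind)
        total += float(np.sum(u * (1.0 + sign * np.cos(np.radians(k * angles)))))
    u, k, sign = params.torsion("chi")
    for chis in state.chis:
        if len(chis):
            total += float(np.sum(u * (1.0 + sign * np.cos(np.radians(k * chis)))))
    return total


def _bond_separations(n_atoms: int, bonds, max_sep: int) -> set[tuple[int, int]]:
    """Pairs (i<j) within ``max_sep`` covalent bonds of each other."""
    adj = [[] for _ in range(n_atoms)]
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    close = set()
    for start in range(n_atoms):
        seen = {start: 0}
        q = deque([start])
        while q:
            u = q.popleft()
            if seen[u] == max_sep:
                continue
            for v in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + 1
                    q.append(v)
        for v, d in seen.items():
            if start < v and d >= 1:
                close.add((start, v))
    return close


class EnergySystem:
    """Precompiled evaluator binding a :class:`PeptideSystem` to parameters.

    Pair lists, parameters and torsion-kind tables are assembled once, so a
    single evaluation costs one coordinate build plus vectorized pair sums.
    """

    def __init__(self, system: PeptideSystem,
                 params: EnergyParameterSet | None = None,
                 hbond_mode: str = "replace", excluded_separations: int = 2):
        if hbond_mode not in ("replace", "additive"):
            raise DomainError(f"unknown hbond_mode {hbond_mode!r}")
        self.system = system
        self.params = params or load_parameter_set()
        self.hbond_mode = hbond_mode
        p = self.params
        n = system.n_atoms
        excluded = _bond_separations(n, system.bonds, excluded_separations)
        ii, jj, aa, bb, qq, cc, dd, hb = [], [], [], [], [], [], [], []
        for i in range(n):
            ci = system.atom_classes[i]
            for j in range(i + 1, n):
                if (i, j) in excluded:
                    continue
                cj = system.atom_classes[j]
                hbp = p.hbond(ci, cj) or p.hbond(cj, ci)
                a, b = p.pair(ci, cj)
                ii.append(i); jj.append(j)
                qq.append(p.charge(ci) * p.charge(cj))
                if hbp is not None:
                    hb.append(True)
                    cc.append(hbp[0]); dd.append(hbp[1])
                    if hbond_mode == "replace":
                        a, b = 0.0, 0.0
                else:
                    hb.append(False)
                    cc.append(0.0); dd.append(0.0)
                aa.append(a); bb.append(b)
        self._i = np.array(ii, dtype=int)
        self._j = np.array(jj, dtype=int)
        self._a = np.array(aa)
        self._b = np.array(bb)
        self._qq = np.array(qq) * p.coulomb_constant / p.dielectric
        self._c = np.array(cc)
        self._d = np.array(dd)
        self._hb = np.array(hb, dtype=bool)
        # torsion parameters per flattened variable
        u, k, s = zip(*(p.torsion(kind) for kind in system.var_kinds))
        self._t_u = np.array(u)
        self._t_k = np.array(k, dtype=float)
        self._t_s = np.array(s, dtype=float)

    def breakdown_from_coords(self, coords: np.ndarray,
                              vec: np.ndarray) -> EnergyBreakdown:
        diff = coords[self._i] - coords[self._j]
        r2 = np.einsum("ij,ij->i", diff, diff)
        rmin2 = r2.min() if len(r2) else 1.0
        if rmin2 < _MIN_DISTANCE**2:
            k = int(np.argmin(r2))
            i, j = self._i[k], self._j[k]
            raise NumericError(
                f"atoms {self.system.atom_names[i]}/{self.system.atom_residue[i]} and "
                f"{self.system.atom_names[j]}/{self.system.atom_residue[j]} overlap "
                f"(r = {np.sqrt(r2[k]):.2e} A)"
            )
        inv2 = 1.0 / r2
        inv6 = inv2 * inv2 * inv2
        inv10 = inv6 * inv2 * inv2
        inv12 = inv6 * inv6
        lj = float(np.sum(self._a * inv12 - self._b * inv6))
        elec = float(np.sum(self._qq * np.sqrt(inv2)))
        hbond = float(np.sum((self._c * inv12 - self._d * inv10)[self._hb]))
        tors = float(np.sum(self._t_u *
                            (1.0 + self._t_s * np.cos(np.radians(self._t_k * vec)))))
        return EnergyBreakdown(lj=lj, electrostatic=elec, hbond=hbond, torsion=tors)

    def breakdown(self, state) -> EnergyBreakdown:
        vec = state.flatten() if isinstance(state, TorsionState) else np.asarray(state, float)
        coords = self.system.build_coords(vec)
        return self.breakdown_from_coords(coords, vec)

    def __call__(self, vec: np.ndarray) -> float:
        """Total energy of a flattened torsion vector (the optimization objective)."""
        return self.breakdown(vec).total


def evaluate_energy(model, state: TorsionState,
                    params: EnergyParameterSet | None = None,
                    hbond_mode: str = "replace",
                    excluded_separations: int = 2) -> EnergyBreakdown:
    """Energy of an atom model + torsion state pair.

    The nonbonded sums run over the model's atoms (respecting the
    bond-separation exclusion rule on its bond graph); the torsion sum runs
    over the state.  Deterministic: identical inputs give identical output.
    """
    params = params or load_parameter_set()
    excluded = _bond_separations(len(model.atoms), model.bonds, excluded_separations)
    coords = model.coordinates()
    lj_sum = elec_sum = hb_sum = 0.0
    n = len(model.atoms)
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excluded:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r < _MIN_DISTANCE:
                ai, aj = model.atoms[i], model.atoms[j]
                raise NumericError(
                    f"atoms {ai.name}/{ai.residue_index} and "
                    f"{aj.name}/{aj.residue_index} overlap (r = {r:.2e} A)"
                )
            lj, elec, hb = nonbonded_pair_energy(
                model.atoms[i].atom_class, model.atoms[j].atom_class, r,
                params, hbond_mode)
            lj_sum += lj; elec_sum += elec; hb_sum += hb
    return EnergyBreakdown(lj=lj_sum, electrostatic=elec_sum, hbond=hb_sum,
                           torsion=torsion_energy(state, params))
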