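"""Readers and writers for the package's on-disk formats.

Covers FASTA input, a strict subset of PDB v3.3 for model output and native
structures, the line-delimited fragment-library format, the sectioned
parameter/topology table format, and YAML run configuration.  All formats
are plain text so fixtures stay human-diffable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from .errors import ConfigurationError, FormatError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "AMINO_ACIDS",
    "AminoAcidSequence",
    "EnergyParameterSet",
    "ResidueTopology",
    "TopologyTable",
    "read_fasta",
    "write_pdb",
    "read_pdb",
    "save_fragment_library",
    "load_fragment_library",
    "load_parameter_set",
    "load_topology",
    "load_run_config",
]


@dataclass(frozen=True)
class AminoAcidSequence:
    """A peptide sequence in one-letter code, case-normalized to upper."""

    id: str
    residues: str

    def __post_init__(self):
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) < 1:
            raise FormatError(f"sequence {self.id!r} is empty")
        for ch in self.residues:
            if ch not in AMINO_ACIDS:
                raise FormatError(
                    f"sequence {self.id!r} contains non-amino-acid character {ch!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path) -> list[AminoAcidSequence]:
    """Parse a FASTA file into a list of :class:`AminoAcidSequence`.

    Raises :class:`FormatError` naming the offending line and character on a
    non-amino-acid symbol, and on an empty file.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        for ch in seq:
            if ch not in AMINO_ACIDS:
                lineno = _find_line(path, ch)
                raise FormatError(
                    f"{path}:{lineno}: invalid amino-acid character {ch!r} "
                    f"in record {rec.id!r}"
                )
        out.append(AminoAcidSequence(rec.id, seq))
    return out


def _find_line(path: Path, ch: str) -> int:
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(">") and ch in line.upper():
            return i
    return 0


# ---------------------------------------------------------------------------
# PDB v3.3 (strict single-chain subset)
# ---------------------------------------------------------------------------

def write_pdb(model, path) -> None:
    """Write an atom model as fixed-width PDB v3.3 ATOM records.

    Single chain ``A``, residues numbered from 1, coordinates rounded to
    three decimals, terminated by TER/END.
    """
    lines = []
    for serial, atom in enumerate(model.atoms, start=1):
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
        x, y, z = atom.xyz
        lines.append(
            f"ATOM  {serial:5d} {name:<4s} {atom.res_name:>3s} A"
            f"{atom.residue_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}"
        )
    last = model.atoms[-1]
    lines.append(
        f"TER   {len(model.atoms) + 1:5d}      {last.res_name:>3s} A"
        f"{last.residue_index:4d}"
    )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path):
    """Read ATOM records from a PDB file into an :class:`~torsionfold.geometry.AtomModel`.

    Recovers atom names, residue names/indices and coordinates; classes,
    charges and the bond graph are not encoded in PDB and are left empty.
    Raises :class:`FormatError` with the line number on a malformed record.
    """
    from .geometry import Atom, AtomModel  # local import to keep the module DAG acyclic

    path = Path(path)
    atoms = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith("ATOM"):
            continue
        if len(line) < 54:
            raise FormatError(f"{path}:{lineno}: truncated ATOM record")
        try:
            name = line[12:16].strip()
            res_name = line[17:20].strip()
            residue_index = int(line[22:26])
            xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed ATOM record: {exc}") from exc
        atoms.append(Atom(name=name, residue_index=residue_index, atom_class="",
                          charge=0.0, xyz=xyz, res_name=res_name))
    if not atoms:
        raise FormatError(f"{path}: no ATOM records found")
    return AtomModel(atoms=atoms, bonds=[])


# ---------------------------------------------------------------------------
# Fragment library: one fragment per line
#   SEQUENCE  LABEL  phi1..phi6  psi1..psi6  omega1..omega6
# ---------------------------------------------------------------------------

_SS_LABELS = ("alpha", "beta", "loop")


def save_fragment_library(library, path) -> None:
    """Serialize a fragment library as line-delimited text (lossless floats)."""
    lines = ["# torsionfold fragment library: seq label 6*phi 6*psi 6*omega (deg)"]
    for fr in library.fragments:
        angles = list(fr.phi) + list(fr.psi) + list(fr.omega)
        lines.append(
            f"{fr.sequence} {fr.ss_label} " + " ".join(repr(float(a)) for a in angles)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_fragment_library(path):
    """Load a fragment library saved by :func:`save_fragment_library`."""
    from .fragments import Fragment, FragmentLibrary

    path = Path(path)
    fragments = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if len(toks) != 20:
            raise FormatError(
                f"{path}:{lineno}: expected sequence, label and 18 angles, "
                f"got {len(toks)} fields"
            )
        seq, label = toks[0], toks[1]
        if label not in _SS_LABELS:
            raise FormatError(f"{path}:{lineno}: unknown secondary-structure label {label!r}")
        try:
            angles = [float(t) for t in toks[2:]]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad angle value: {exc}") from exc
        fragments.append(
            Fragment(sequence=seq, phi=tuple(angles[0:6]), psi=tuple(angles[6:12]),
                     omega=tuple(angles[12:18]), ss_label=label)
        )
    return FragmentLibrary(fragments=fragments)


# ---------------------------------------------------------------------------
# Sectioned parameter tables
# ---------------------------------------------------------------------------

def _parse_sections(text: str, origin: str) -> dict[str, list[tuple[int, list[str]]]]:
    sections: dict[str, list[tuple[int, list[str]]]] = {}
    current = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections.setdefault(current, [])
            continue
        if current is None:
            raise FormatError(f"{origin}:{lineno}: data before any [section] header")
        sections[current].append((lineno, line.replace("=", " ").split()))
    return sections


@dataclass(frozen=True)
class EnergyParameterSet:
    """Empirical-potential parameter tables.

    ``pair_params`` maps an unordered atom-class pair to (A, B) of the 12-6
    term; ``hbond_params`` maps (donor-H class, acceptor class) to (C, D) of
    the 12-10 term; ``charges`` holds partial charges in elementary-charge
    units; ``torsion_params`` maps a torsion kind to (U, k, sign).
    Lookups are explicit: a missing entry raises — no combining rules.
    """

    pair_params: dict[frozenset, tuple[float, float]]
    hbond_params: dict[tuple[str, str], tuple[float, float]]
    charges: dict[str, float]
    dielectric: float
    coulomb_constant: float
    torsion_params: dict[str, tuple[float, int, int]]

    def pair(self, class_a: str, class_b: str) -> tuple[float, float]:
        key = frozenset((class_a, class_b))
        try:
            return self.pair_params[key]
        except KeyError:
            raise ConfigurationError(
                f"no 12-6 parameters for atom-class pair ({class_a}, {class_b})"
            ) from None

    def charge(self, atom_class: str) -> float:
        try:
            return self.charges[atom_class]
        except KeyError:
            raise ConfigurationError(f"no partial charge for atom class {atom_class!r}") from None

    def hbond(self, donor_h: str, acceptor: str):
        return self.hbond_params.get((donor_h, acceptor))

    def torsion(self, kind: str) -> tuple[float, int, int]:
        try:
            return self.torsion_params[kind]
        except KeyError:
            raise ConfigurationError(f"no torsion parameters for kind {kind!r}") from None


@dataclass(frozen=True)
class ResidueTopology:
    letter: str
    name: str
    chi_count: int
    side_atoms: tuple[str, ...]


@dataclass(frozen=True)
class TopologyTable:
    """Rigid-geometry tables: bond lengths, bond angles and residue templates."""

    bonds: dict[frozenset, float]
    angles: dict[tuple[str, str, str], float]
    residues: dict[str, ResidueTopology] = field(default_factory=dict)

    def bond_length(self, class_a: str, class_b: str) -> float:
        try:
            return self.bonds[frozenset((class_a, class_b))]
        except KeyError:
            raise ConfigurationError(
                f"no bond length for class pair ({class_a}, {class_b})"
            ) from None

    def bond_angle(self, a: str, apex: str, c: str) -> float:
        for key in ((a, apex, c), (c, apex, a)):
            if key in self.angles:
                return self.angles[key]
        raise ConfigurationError(f"no bond angle for classes {a}-{apex}-{c}")

    def residue(self, letter: str) -> ResidueTopology:
        try:
            return self.residues[letter]
        except KeyError:
            raise ConfigurationError(f"no topology for residue type {letter!r}") from None

    def atom_classes(self) -> set[str]:
        """Every atom class the residue templates can reference."""
        classes = {"N", "H", "CA", "C", "O"}
        if any(r.side_atoms for r in self.residues.values()):
            classes.add("CS")
        return classes


def _bundled_text(filename: str) -> str:
    return (importlib.resources.files("torsionfold.data") / filename).read_text()


def load_topology(path: str | Path = "bundled") -> TopologyTable:
    """Load the residue-topology / rigid-geometry table."""
    origin = "bundled:topology.params" if path == "bundled" else str(path)
    text = _bundled_text("topology.params") if path == "bundled" else Path(path).read_text()
    sec = _parse_sections(text, origin)
    bonds = {}
    for lineno, toks in sec.get("bonds", []):
        if len(toks) != 3:
            raise FormatError(f"{origin}:{lineno}: bond entry needs 3 fields")
        bonds[frozenset((toks[0], toks[1]))] = float(toks[2])
    angles = {}
    for lineno, toks in sec.get("angles", []):
        if len(toks) != 4:
            raise FormatError(f"{origin}:{lineno}: angle entry needs 4 fields")
        angles[(toks[0], toks[1], toks[2])] = float(toks[3])
    residues = {}
    for lineno, toks in sec.get("residues", []):
        if len(toks) != 4:
            raise FormatError(f"{origin}:{lineno}: residue entry needs 4 fields")
        letter, name, chi_count, side = toks
        side_atoms = () if side == "-" else tuple(side.split(","))
        residues[letter] = ResidueTopology(letter, name, int(chi_count), side_atoms)
    return TopologyTable(bonds=bonds, angles=angles, residues=residues)


def load_parameter_set(path: str | Path = "bundled",
                       topology: TopologyTable | None = None) -> EnergyParameterSet:
    """Load an energy parameter table, validating coverage against a topology.

    With the default ``"bundled"`` argument the packaged reduced table is
    loaded and validated against the bundled residue topology: every atom
    class must have a charge and every unordered class pair a 12-6 entry.
    """
    origin = "bundled:energy.params" if path == "bundled" else str(path)
    text = _bundled_text("energy.params") if path == "bundled" else Path(path).read_text()
    sec = _parse_sections(text, origin)

    options = {toks[0]: float(toks[1]) for _, toks in sec.get("options", [])}
    charges = {}
    for lineno, toks in sec.get("charges", []):
        if len(toks) != 2:
            raise FormatError(f"{origin}:{lineno}: charge entry needs 2 fields")
        charges[toks[0]] = float(toks[1])
    pair_params = {}
    for lineno, toks in sec.get("pairs", []):
        if len(toks) != 4:
            raise FormatError(f"{origin}:{lineno}: pair entry needs 4 fields")
        pair_params[frozenset((toks[0], toks[1]))] = (float(toks[2]), float(toks[3]))
    hbond_params = {}
    for lineno, toks in sec.get("hbond", []):
        if len(toks) != 4:
            raise FormatError(f"{origin}:{lineno}: hbond entry needs 4 fields")
        hbond_params[(toks[0], toks[1])] = (float(toks[2]), float(toks[3]))
    torsion_params = {}
    for lineno, toks in sec.get("torsions", []):
        if len(toks) != 4 or toks[3] not in ("+", "-"):
            raise FormatError(f"{origin}:{lineno}: torsion entry needs kind U k +/-")
        torsion_params[toks[0]] = (float(toks[1]), int(toks[2]), +1 if toks[3] == "+" else -1)

    params = EnergyParameterSet(
        pair_params=pair_params,
        hbond_params=hbond_params,
        charges=charges,
        dielectric=options.get("dielectric", 2.0),
        coulomb_constant=options.get("coulomb_constant", 332.0),
        torsion_params=torsion_params,
    )
    if params.dielectric <= 0:
        raise ConfigurationError("dielectric must be positive")

    if topology is None:
        topology = load_topology("bundled") if path == "bundled" else None
    if topology is not None:
        classes = sorted(topology.atom_classes())
        for cls in classes:
            if cls not in params.charges:
                raise ConfigurationError(
                    f"{origin}: topology atom class {cls!r} has no charge entry"
                )
        for i, a in enumerate(classes):
            for b in classes[i:]:
                if frozenset((a, b)) not in params.pair_params:
                    raise ConfigurationError(
                        f"{origin}: missing 12-6 parameters for class pair ({a}, {b})"
                    )
    return params


def load_run_config(path) -> dict:
    """Load a YAML run-configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: run configuration must be a mapping")
    return cfg
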