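"""Bonded force-field parameters around a new azo nitrogen atom type.

Introducing an azobenzene side chain into a protein force field requires a
new atom type for the diazo nitrogens (here called ``NX``).  Equilibrium
bond lengths, angles and dihedrals involving the new type are measured
directly from an optimized geometry; force constants are adopted from
user-supplied analog atom-type combinations.  The cis/trans state of the
azobenzene is enforced with a stiff dihedral restraint on the C–N=N–C
torsion (k = 1000 kJ·mol⁻¹·rad⁻², target 180° for trans, 0° for cis).

Dihedral sign convention: IUPAC, cis = 0°, signed in (−180°, 180°].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Restraint force constant on the cis/trans dihedral, kJ·mol⁻¹·rad⁻².
RESTRAINT_K = 1000.0

ISOMER_TARGETS = {"trans": 180.0, "cis": 0.0}


@dataclass(frozen=True)
class BondTerm:
    atoms: tuple[int, int]
    types: tuple[str, str]
    r0: float  # Å

    def __post_init__(self) -> None:
        if not self.r0 > 0:
            raise ValueError(f"bond {self.atoms}: r0 must be positive")


@dataclass(frozen=True)
class AngleTerm:
    atoms: tuple[int, int, int]
    types: tuple[str, str, str]
    theta0: float  # deg

    def __post_init__(self) -> None:
        if not (0.0 < self.theta0 <= 180.0):
            raise ValueError(f"angle {self.atoms}: theta0 outside (0, 180]")


@dataclass(frozen=True)
class DihedralTerm:
    atoms: tuple[int, int, int, int]
    types: tuple[str, str, str, str]
    phi0: float  # deg, signed, cis = 0

    def __post_init__(self) -> None:
        if not (-180.0 < self.phi0 <= 180.0):
            raise ValueError(f"dihedral {self.atoms}: phi0 outside "
                             "(-180, 180]")


@dataclass(frozen=True)
class Restraint:
    atoms: tuple[int, int, int, int]
    target: float  # deg
    k: float = RESTRAINT_K

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("restraint force constant must be positive")


@dataclass
class BondedParamSet:
    """Measured equilibrium bonded terms plus adopted force constants.

    ``force_constants`` maps a sorted atom-type tuple (see
    :func:`canonical_types`) to its adopted force constant; terms without
    an entry cannot be emitted.
    """

    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    dihedrals: list[DihedralTerm] = field(default_factory=list)
    force_constants: dict[tuple[str, ...], float] = field(default_factory=dict)
    restraint: Restraint | None = None


def canonical_types(types) -> tuple[str, ...]:
    """Direction-independent key for an atom-type sequence.

    A term read in either direction is the same interaction, so the
    lexicographically smaller of (types, reversed) is used.
    """
    t = tuple(types)
    return min(t, t[::-1])


# ---------------------------------------------------------------------------
# Geometry measurement
# ---------------------------------------------------------------------------

def bond_length(coords: np.ndarray, i: int, j: int) -> float:
    d = float(np.linalg.norm(coords[i] - coords[j]))
    if d < 1e-6:
        raise ValueError(f"degenerate geometry: atoms {i},{j} coincide")
    return d


def bond_angle(coords: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle at the central atom j, degrees in [0, 180]."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-6 or nv < 1e-6:
        raise ValueError(f"degenerate geometry in angle {i}-{j}-{k}")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral_angle(coords: np.ndarray, i: int, j: int, k: int,
                   l: int) -> float:
    """Signed dihedral i-j-k-l, degrees in (−180, 180], cis = 0 (IUPAC).

    Standard four-point atan2 formulation; the sign flips under mirror
    reflection of the geometry.
    """
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n2 = np.linalg.norm(b2)
    if n2 < 1e-6:
        raise ValueError(f"degenerate geometry in dihedral {i}-{j}-{k}-{l}")
    x = np.dot(np.cross(b1, b2), np.cross(b2, b3))
    y = np.dot(np.cross(np.cross(b1, b2), np.cross(b2, b3)), b2) / n2
    phi = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if phi == -180.0 else phi


def _angles_from_bonds(bonds):
    adj: dict[int, set[int]] = {}
    for i, j in bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    angles = []
    for center, nbrs in sorted(adj.items()):
        ns = sorted(nbrs)
        for a in range(len(ns)):
            for b in range(a + 1, len(ns)):
                angles.append((ns[a], center, ns[b]))
    return angles, adj


def measure_internal_coordinates(coords: np.ndarray, bonded_topology,
                                 atom_types, atom_type_filter: str = "NX",
                                 force_constants=None,
                                 ) -> BondedParamSet:
    """Measure equilibrium bonded terms touching a filtered atom type.

    Parameters
    ----------
    coords : (n_atoms, 3) array, Å.
    bonded_topology : iterable of (i, j) bonded atom-index pairs.
    atom_types : sequence of atom-type strings, one per atom.
    atom_type_filter : only terms containing at least one atom of this
        type are retained (e.g. the new azo nitrogen type ``NX``).
    force_constants : optional mapping from canonical atom-type tuples to
        adopted force constants, stored on the result.

    Bond lengths are Euclidean distances, angles are measured at the
    central atom, dihedrals use the signed IUPAC convention (cis = 0°).
    All measurements are invariant under rigid-body motion of the input.
    """
    coords = np.asarray(coords, dtype=float)
    atom_types = list(atom_types)
    if coords.shape != (len(atom_types), 3):
        raise ValueError("coords shape inconsistent with atom_types")
    bonds = sorted({tuple(sorted(map(int, b))) for b in bonded_topology})
    for i, j in bonds:
        if not (0 <= i < len(atom_types) and 0 <= j < len(atom_types)):
            raise ValueError(f"bond ({i},{j}) references unknown atom")

    def touches(ixs) -> bool:
        return any(atom_types[i] == atom_type_filter for i in ixs)

    out = BondedParamSet(force_constants=dict(force_constants or {}))
    for i, j in bonds:
        if touches((i, j)):
            out.bonds.append(BondTerm(
                atoms=(i, j), types=(atom_types[i], atom_types[j]),
                r0=bond_length(coords, i, j)))

    angles, adj = _angles_from_bonds(bonds)
    for i, j, k in angles:
        if touches((i, j, k)):
            out.angles.append(AngleTerm(
                atoms=(i, j, k),
                types=(atom_types[i], atom_types[j], atom_types[k]),
                theta0=bond_angle(coords, i, j, k)))

    for j, k in bonds:
        for i in sorted(adj[j] - {k}):
            for l in sorted(adj[k] - {j}):
                if i == l:
                    continue
                if touches((i, j, k, l)):
                    out.dihedrals.append(DihedralTerm(
                        atoms=(i, j, k, l),
                        types=tuple(atom_types[m] for m in (i, j, k, l)),
                        phi0=dihedral_angle(coords, i, j, k, l)))
    return out


def default_azo_force_constants() -> dict[tuple[str, ...], float]:
    """Analog force constants for the azobenzene bonded terms.

    Adopted from aromatic carbon/nitrogen terms of a standard protein
    force field (bond constants in kJ·mol⁻¹·nm⁻², angle and dihedral
    constants in kJ·mol⁻¹(·rad⁻²)); order-of-magnitude placeholders for
    use with the synthetic idealized geometry.
    """
    return {
        canonical_types(("NX", "NX")): 400000.0,
        canonical_types(("CA", "NX")): 300000.0,
        canonical_types(("CA", "CA")): 392000.0,
        canonical_types(("CA", "NX", "NX")): 500.0,
        canonical_types(("CA", "CA", "NX")): 500.0,
        canonical_types(("CA", "CA", "CA")): 527.0,
        canonical_types(("CA", "NX", "NX", "CA")): 30.0,
        canonical_types(("CA", "CA", "NX", "NX")): 15.0,
        canonical_types(("CA", "CA", "CA", "NX")): 15.0,
        canonical_types(("CA", "CA", "CA", "CA")): 15.0,
    }


def azo_restraint(params: BondedParamSet, isomer: str,
                  filter_type: str = "NX") -> Restraint:
    """Build the cis/trans restraint on the C–N=N–C dihedral.

    Picks the dihedral whose two central atoms are both of the azo type
    and targets 180° (trans) or 0° (cis) with k = 1000 kJ·mol⁻¹·rad⁻².
    """
    if isomer not in ISOMER_TARGETS:
        raise ValueError("isomer must be 'trans' or 'cis'")
    for d in params.dihedrals:
        if d.types[1] == filter_type and d.types[2] == filter_type:
            return Restraint(atoms=d.atoms, target=ISOMER_TARGETS[isomer])
    raise ValueError(f"no dihedral with central {filter_type}-{filter_type} "
                     "bond found")


# ---------------------------------------------------------------------------
# Parameter-block emission (GROMACS-style dialect)
# ---------------------------------------------------------------------------
#
# Grammar: section headers in brackets; one term per line.
#   [ bonds ]               i j  type_i type_j  r0(nm)      k
#   [ angles ]              i j k  types...     theta0(deg) k
#   [ dihedrals ]           i j k l  types...   phi0(deg)   k
#   [ dihedral_restraints ] i j k l  target(deg) k
# Atom indices are 1-based in the emitted block; lengths are emitted in nm
# (measured in Å internally).  Lines are sorted by atom indices, floats
# fixed to 6 decimals, so emission is deterministic and round-trips
# byte-identically through parse_parameter_block.

_ANGSTROM_PER_NM = 10.0


def emit_parameter_block(params: BondedParamSet,
                         isomer: str | None = None) -> str:
    """Serialize a BondedParamSet to a deterministic text block.

    Every term must have a force constant under its canonical type key.
    If ``isomer`` is given (or ``params.restraint`` is set) a dihedral
    restraint targeting 180° (trans) or 0° (cis) is appended.
    """
    def k_for(types, atoms):
        key = canonical_types(types)
        if key not in params.force_constants:
            raise ValueError(
                f"missing force constant for term {'-'.join(types)} "
                f"(atoms {atoms})")
        return params.force_constants[key]

    lines = ["; azocoil bonded parameter block"]
    lines.append("[ bonds ]")
    for b in sorted(params.bonds, key=lambda t: t.atoms):
        k = k_for(b.types, b.atoms)
        lines.append(f"{b.atoms[0] + 1:5d} {b.atoms[1] + 1:5d}  "
                     f"{b.types[0]:<4s} {b.types[1]:<4s}  "
                     f"{b.r0 / _ANGSTROM_PER_NM:.6f}  {k:.6f}")
    lines.append("[ angles ]")
    for a in sorted(params.angles, key=lambda t: t.atoms):
        k = k_for(a.types, a.atoms)
        lines.append(f"{a.atoms[0] + 1:5d} {a.atoms[1] + 1:5d} "
                     f"{a.atoms[2] + 1:5d}  "
                     f"{a.types[0]:<4s} {a.types[1]:<4s} {a.types[2]:<4s}  "
                     f"{a.theta0:.6f}  {k:.6f}")
    lines.append("[ dihedrals ]")
    for d in sorted(params.dihedrals, key=lambda t: t.atoms):
        k = k_for(d.types, d.atoms)
        lines.append(f"{d.atoms[0] + 1:5d} {d.atoms[1] + 1:5d} "
                     f"{d.atoms[2] + 1:5d} {d.atoms[3] + 1:5d}  "
                     f"{d.types[0]:<4s} {d.types[1]:<4s} "
                     f"{d.types[2]:<4s} {d.types[3]:<4s}  "
                     f"{d.phi0:.6f}  {k:.6f}")
    restraint = params.restraint
    if isomer is not None:
        restraint = azo_restraint(params, isomer)
    if restraint is not None:
        lines.append("[ dihedral_restraints ]")
        lines.append(f"{restraint.atoms[0] + 1:5d} "
                     f"{restraint.atoms[1] + 1:5d} "
                     f"{restraint.atoms[2] + 1:5d} "
                     f"{restraint.atoms[3] + 1:5d}  "
                     f"{restraint.target:.6f}  {restraint.k:.6f}")
    return "\n".join(lines) + "\n"


def parse_parameter_block(text: str) -> BondedParamSet:
    """Parse a block produced by :func:`emit_parameter_block`.

    emit → parse → emit is byte-identical.
    """
    out = BondedParamSet()
    section = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("["):
            section = line.strip("[] ").strip()
            continue
        parts = line.split()
        if section == "bonds":
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            types = (parts[2], parts[3])
            r0 = float(parts[4]) * _ANGSTROM_PER_NM
            k = float(parts[5])
            out.bonds.append(BondTerm(atoms=(i, j), types=types, r0=r0))
            out.force_constants[canonical_types(types)] = k
        elif section == "angles":
            ixs = tuple(int(p) - 1 for p in parts[:3])
            types = tuple(parts[3:6])
            out.angles.append(AngleTerm(atoms=ixs, types=types,
                                        theta0=float(parts[6])))
            out.force_constants[canonical_types(types)] = float(parts[7])
        elif section == "dihedrals":
            ixs = tuple(int(p) - 1 for p in parts[:4])
            types = tuple(parts[4:8])
            out.dihedrals.append(DihedralTerm(atoms=ixs, types=types,
                                              phi0=float(parts[8])))
            out.force_constants[canonical_types(types)] = float(parts[9])
        elif section == "dihedral_restraints":
            ixs = tuple(int(p) - 1 for p in parts[:4])
            out.restraint = Restraint(atoms=ixs, target=float(parts[4]),
                                      k=float(parts[5]))
        else:
            raise ValueError(f"line outside a known section: {raw!r}")
    return out
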