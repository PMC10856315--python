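"""Surface, contact, interface, superposition and symmetry geometry.

The quantities computed here are the structural half of the assessment
pipeline: buried solvent-accessible surface areas (SASA) define the main
and minor interfaces a Cul3 chain forms with adjacent subunits of a
pentameric BTB assembly, typed inter-chain contacts (H-bond, salt bridge,
hydrophobic) inventory what stabilizes them, and Kabsch superposition plus
a cyclic-permutation score quantify model-vs-experiment agreement and Cn
symmetry.

SASA uses the Shrake-Rupley sphere-sampling algorithm with a deterministic
golden-spiral point lattice.  The lattice is expressed in a body frame
derived from the coordinates themselves, so areas are exactly invariant
under proper rigid motion of the model (the lattice rotates with it) —
important because buried areas are differences of three SASA evaluations
and quadrature jitter would otherwise leak into them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AssemblySpec, AtomRecord, Residue, StructureModel

__all__ = [
    "ContactRecord",
    "ContactCriteria",
    "InterfaceSummary",
    "SegmentAnnotation",
    "SuperpositionResult",
    "VDW_RADII",
    "sasa",
    "buried_interface_area",
    "detect_contacts",
    "partition_interfaces",
    "kabsch_superpose",
    "cn_symmetry_score",
]

#: Van der Waals radii (Angstrom), Bondi-style values as used by common
#: SASA implementations.  Unknown elements raise unless a fallback is given.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "D": 1.20,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ContactRecord:
    """One typed inter-chain interaction with atom-level provenance."""

    kind: str  # hbond | salt_bridge | hydrophobic
    res_a: tuple[str, int, str]  # (chain, seq_number, aa3)
    res_b: tuple[str, int, str]
    atom_a: str
    atom_b: str
    distance: float
    interface: str = "none"  # main | minor | none
    backbone_involved: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("hbond", "salt_bridge", "hydrophobic"):
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if self.res_a[0] == self.res_b[0]:
            raise ValueError("contact residues must lie on different chains")
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")

    @property
    def pair_key(self) -> tuple:
        return (self.kind, self.res_a[:2], self.res_b[:2])


@dataclass(frozen=True)
class ContactCriteria:
    """Distance cutoffs (Angstrom) for heavy-atom contact detection."""

    hbond_cutoff: float = 3.5
    salt_bridge_cutoff: float = 4.0
    hydrophobic_cutoff: float = 4.5

    @property
    def max_cutoff(self) -> float:
        return max(self.hbond_cutoff, self.salt_bridge_cutoff, self.hydrophobic_cutoff)


@dataclass
class InterfaceSummary:
    """Main/minor interface partition of one Cul3 chain against a BTB assembly."""

    cul3_chain: str
    main_kctd_chain: "str | None"
    minor_kctd_chain: "str | None"
    area_main: float
    area_minor: float
    contacts: list[ContactRecord] = field(default_factory=list)
    cul3_helices_touched: set[str] = field(default_factory=set)
    kctd_segments_touched: set[str] = field(default_factory=set)
    per_chain_areas: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.area_main < self.area_minor:
            raise ValueError("main interface area must be >= minor interface area")
        if self.main_kctd_chain is not None and self.main_kctd_chain == self.minor_kctd_chain:
            raise ValueError("main and minor chains must be distinct")


@dataclass(frozen=True)
class SegmentAnnotation:
    """A named secondary-structure segment (1-based inclusive range)."""

    chain: str
    label: str
    start_res: int
    end_res: int

    def __post_init__(self) -> None:
        if self.start_res > self.end_res:
            raise ValueError("segment start after end")

    def __contains__(self, seq_number: int) -> bool:
        return self.start_res <= seq_number <= self.end_res


#: Cul3 N-terminal helix boundaries (author numbering of the construct used
#: in the predictions; helices H1-H6 span residues 17-154).
CUL3_HELIX_SEGMENTS: tuple[SegmentAnnotation, ...] = (
    SegmentAnnotation("Cul3", "H1", 17, 28),
    SegmentAnnotation("Cul3", "H2", 33, 62),
    SegmentAnnotation("Cul3", "H3", 66, 80),
    SegmentAnnotation("Cul3", "H4", 83, 96),
    SegmentAnnotation("Cul3", "H5", 103, 134),
    SegmentAnnotation("Cul3", "H6", 139, 154),
)


@dataclass
class SuperpositionResult:
    """Optimal rigid superposition: x_fit = rotation @ x_mobile + translation."""

    rotation: np.ndarray  # (3, 3), proper
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# SASA


def _sphere_lattice(n_points: int) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere lattice, shape (n_points, 3)."""
    k = np.arange(n_points, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n_points
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _body_frame(coords: np.ndarray) -> np.ndarray:
    """Orthonormal frame built from the first non-degenerate atom triple.

    Rotating the model rotates this frame identically, which pins the
    sampling lattice to the molecule and makes SASA exactly invariant
    under proper rigid motion.
    """
    n = len(coords)
    if n < 2:
        return np.eye(3)
    u1 = None
    for i in range(1, n):
        v = coords[i] - coords[0]
        if np.linalg.norm(v) > 1e-6:
            u1 = v / np.linalg.norm(v)
            break
    if u1 is None:
        return np.eye(3)
    u2 = None
    for j in range(1, n):
        v = coords[j] - coords[0]
        w = v - (v @ u1) * u1
        if np.linalg.norm(w) > 1e-6:
            u2 = w / np.linalg.norm(w)
            break
    if u2 is None:  # collinear set: azimuth is arbitrary but geometry is symmetric
        a = np.zeros(3)
        a[int(np.argmin(np.abs(u1)))] = 1.0
        w = a - (a @ u1) * u1
        u2 = w / np.linalg.norm(w)
    u3 = np.cross(u1, u2)
    return np.column_stack([u1, u2, u3])


def atom_radii(
    model: StructureModel,
    radii: "dict[str, float] | None" = None,
    fallback: "float | None" = None,
) -> np.ndarray:
    table = radii if radii is not None else VDW_RADII
    out = []
    for res, atom in model.iter_atoms():
        r = table.get(atom.element.upper())
        if r is None:
            if fallback is None:
                raise KeyError(
                    f"no van der Waals radius for element {atom.element!r} "
                    f"(atom {atom.name} in {res.chain_id}:{res.seq_number}); "
                    "supply a fallback radius"
                )
            r = fallback
        out.append(r)
    return np.array(out, dtype=float)


def sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii: "dict[str, float] | None" = None,
    fallback_radius: "float | None" = None,
) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Returns ``(per_atom_areas, total_area)`` in Angstrom^2, atoms in model
    iteration order.  Deterministic for fixed ``n_points``.
    """
    coords = model.coords()
    rads = atom_radii(model, radii, fallback_radius) + probe_radius
    frame = _body_frame(coords)
    lattice = _sphere_lattice(n_points) @ frame.T

    n = len(coords)
    areas = np.zeros(n)
    tree = cKDTree(coords)
    rmax = rads.max()
    for i in range(n):
        ri = rads[i]
        neighbors = [
            j for j in tree.query_ball_point(coords[i], ri + rmax)
            if j != i and np.linalg.norm(coords[j] - coords[i]) < ri + rads[j]
        ]
        pts = coords[i] + ri * lattice
        if neighbors:
            nb = np.asarray(neighbors, dtype=int)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            accessible = np.all(d2 >= (rads[nb] ** 2)[None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * math.pi * ri * ri * frac
    return areas, float(areas.sum())


def buried_interface_area(
    model: StructureModel,
    group_a: list[str],
    group_b: list[str],
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """Buried area between two chain groups: (SASA_A + SASA_B - SASA_AB) / 2.

    Only atoms with at least one cross-group neighbor inside the expanded
    contact radius are evaluated: under the shared deterministic lattice
    the alone-vs-complexed terms of every other atom cancel exactly, so
    this equals the three-SASA difference while touching a fraction of the
    atoms.  Symmetric in its arguments (the lattice frame comes from the
    union in canonical chain order) and clamped at zero.
    """
    ga, gb = list(group_a), list(group_b)
    if not ga or not gb:
        raise ValueError("chain groups must be non-empty")
    if set(ga) & set(gb):
        raise ValueError(f"chain groups share chains: {sorted(set(ga) & set(gb))}")
    if sorted(gb) < sorted(ga):  # canonical order => bit-exact symmetry
        ga, gb = gb, ga

    sub_a, sub_b = model.subset(ga), model.subset(gb)
    xyz_a, xyz_b = sub_a.coords(), sub_b.coords()
    rad_a = atom_radii(sub_a) + probe_radius
    rad_b = atom_radii(sub_b) + probe_radius
    union = model.subset(sorted(ga + gb))
    lattice = _sphere_lattice(n_points) @ _body_frame(union.coords()).T

    buried = 0.0
    for xyz_s, rad_s, xyz_o, rad_o in (
        (xyz_a, rad_a, xyz_b, rad_b),
        (xyz_b, rad_b, xyz_a, rad_a),
    ):
        tree_self = cKDTree(xyz_s)
        tree_other = cKDTree(xyz_o)
        cross = tree_self.query_ball_tree(tree_other, rad_s.max() + rad_o.max())
        for i, js in enumerate(cross):
            js = [j for j in js
                  if np.linalg.norm(xyz_o[j] - xyz_s[i]) < rad_s[i] + rad_o[j]]
            if not js:
                continue
            ri = rad_s[i]
            pts = xyz_s[i] + ri * lattice
            own = [k for k in tree_self.query_ball_point(xyz_s[i], 2 * rad_s.max())
                   if k != i and np.linalg.norm(xyz_s[k] - xyz_s[i]) < ri + rad_s[k]]
            if own:
                d2 = ((pts[:, None, :] - xyz_s[own][None, :, :]) ** 2).sum(axis=2)
                alone = np.all(d2 >= (rad_s[own] ** 2)[None, :], axis=1)
            else:
                alone = np.ones(n_points, dtype=bool)
            d2x = ((pts[:, None, :] - xyz_o[js][None, :, :]) ** 2).sum(axis=2)
            blocked = np.any(d2x < (rad_o[js] ** 2)[None, :], axis=1)
            lost = float((alone & blocked).mean())
            buried += 4.0 * math.pi * ri * ri * lost
    return max(0.0, buried / 2.0)


# ---------------------------------------------------------------------------
# contacts

#: Heavy-atom H-bond donors (atoms carrying at least one polar hydrogen).
_HBOND_DONORS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "LYS": frozenset({"NZ"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "TRP": frozenset({"NE1"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "CYS": frozenset({"SG"}),
}

#: Basic side-chain nitrogens / acidic side-chain oxygens for salt bridges.
#: His counts as potentially charged: His-Asp/Glu pairs behave as
#: electrostatic interactions at these interfaces.
_SALT_BASIC: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "LYS": frozenset({"NZ"}),
    "HIS": frozenset({"ND1", "NE2"}),
}
_SALT_ACIDIC: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}

#: Apolar residues and their side-chain carbons eligible for hydrophobic
#: contacts (Tyr contributes its ring only, not CB/OH).
_APOLAR_SIDECHAIN: dict[str, frozenset[str]] = {
    "ALA": frozenset({"CB"}),
    "VAL": frozenset({"CB", "CG1", "CG2"}),
    "LEU": frozenset({"CB", "CG", "CD1", "CD2"}),
    "ILE": frozenset({"CB", "CG1", "CG2", "CD1"}),
    "MET": frozenset({"CB", "CG", "CE"}),
    "PHE": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    "PRO": frozenset({"CB", "CG", "CD"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
}

_BACKBONE = frozenset({"N", "CA", "C", "O", "OXT"})


def _is_hbond_donor(res: Residue, atom: AtomRecord) -> bool:
    if atom.name == "N" and res.aa3 != "PRO":
        return True  # backbone amide
    return atom.name in _HBOND_DONORS.get(res.aa3, frozenset())


def _is_hbond_acceptor(res: Residue, atom: AtomRecord) -> bool:
    return atom.element.upper() in ("N", "O")


def _pair_kinds(
    res_i: Residue, atom_i: AtomRecord, res_j: Residue, atom_j: AtomRecord,
    dist: float, criteria: ContactCriteria,
) -> list[str]:
    """All contact kinds a qualifying atom pair realizes (order-free)."""
    kinds = []
    if dist <= criteria.hbond_cutoff and (
        (_is_hbond_donor(res_i, atom_i) and _is_hbond_acceptor(res_j, atom_j))
        or (_is_hbond_donor(res_j, atom_j) and _is_hbond_acceptor(res_i, atom_i))
    ):
        kinds.append("hbond")
    if dist <= criteria.salt_bridge_cutoff and (
        (
            atom_i.name in _SALT_BASIC.get(res_i.aa3, frozenset())
            and atom_j.name in _SALT_ACIDIC.get(res_j.aa3, frozenset())
        )
        or (
            atom_j.name in _SALT_BASIC.get(res_j.aa3, frozenset())
            and atom_i.name in _SALT_ACIDIC.get(res_i.aa3, frozenset())
        )
    ):
        kinds.append("salt_bridge")
    if (
        dist <= criteria.hydrophobic_cutoff
        and atom_i.name in _APOLAR_SIDECHAIN.get(res_i.aa3, frozenset())
        and atom_j.name in _APOLAR_SIDECHAIN.get(res_j.aa3, frozenset())
    ):
        kinds.append("hydrophobic")
    return kinds


def detect_contacts(
    model: StructureModel,
    group_a: list[str],
    group_b: list[str],
    criteria: "ContactCriteria | None" = None,
    all_atom_pairs: bool = False,
) -> list[ContactRecord]:
    """Typed inter-chain contacts between two chain groups.

    Criteria (heavy-atom, no hydrogens required):

    * ``hbond``: donor N/O/S with protonated chemistry to any N/O acceptor,
      distance <= 3.5 A;
    * ``salt_bridge``: side-chain N of Lys/Arg/His to side-chain O of
      Asp/Glu, <= 4.0 A;
    * ``hydrophobic``: side-chain carbon to side-chain carbon between
      apolar residues, <= 4.5 A.

    By default each residue pair is reported once per kind at its minimal
    qualifying atom pair; ``all_atom_pairs=True`` dumps every pair.
    """
    criteria = criteria or ContactCriteria()
    ga, gb = list(group_a), list(group_b)
    if not ga or not gb:
        raise ValueError("chain groups must be non-empty")
    if set(ga) & set(gb):
        raise ValueError("chain groups must be disjoint")

    atoms_a = [(r, a) for r, a in model.iter_atoms(ga)]
    atoms_b = [(r, a) for r, a in model.iter_atoms(gb)]
    if not atoms_a or not atoms_b:
        raise ValueError("a chain group contains no atoms")
    xyz_a = np.array([a.coords for _, a in atoms_a])
    xyz_b = np.array([a.coords for _, a in atoms_b])
    tree_b = cKDTree(xyz_b)
    pairs = cKDTree(xyz_a).query_ball_tree(tree_b, criteria.max_cutoff)

    best: dict[tuple, ContactRecord] = {}
    dump: list[ContactRecord] = []
    for i, js in enumerate(pairs):
        res_i, atom_i = atoms_a[i]
        for j in js:
            res_j, atom_j = atoms_b[j]
            dist = float(np.linalg.norm(xyz_a[i] - xyz_b[j]))
            if dist <= 0:
                continue
            for kind in _pair_kinds(res_i, atom_i, res_j, atom_j, dist, criteria):
                rec = ContactRecord(
                    kind=kind,
                    res_a=(res_i.chain_id, res_i.seq_number, res_i.aa3),
                    res_b=(res_j.chain_id, res_j.seq_number, res_j.aa3),
                    atom_a=atom_i.name,
                    atom_b=atom_j.name,
                    distance=dist,
                    backbone_involved=(atom_i.name in _BACKBONE or atom_j.name in _BACKBONE),
                )
                if all_atom_pairs:
                    dump.append(rec)
                else:
                    key = rec.pair_key
                    if key not in best or dist < best[key].distance:
                        best[key] = rec
    out = dump if all_atom_pairs else list(best.values())
    out.sort(key=lambda c: (c.res_a[:2], c.res_b[:2], c.kind, c.distance))
    return out


# ---------------------------------------------------------------------------
# interface partition


def _touched_segments(
    contacts: list[ContactRecord],
    side: str,
    segments: "tuple[SegmentAnnotation, ...] | None",
) -> set[str]:
    if not segments:
        return set()
    touched = set()
    for c in contacts:
        res = c.res_a if side == "a" else c.res_b
        for seg in segments:
            if res[1] in seg:
                touched.add(seg.label)
    return touched


def partition_interfaces(
    model: StructureModel,
    assembly: AssemblySpec,
    min_minor_area: float = 25.0,
    criteria: "ContactCriteria | None" = None,
    cul3_segments: "tuple[SegmentAnnotation, ...] | None" = None,
    kctd_segments: "tuple[SegmentAnnotation, ...] | None" = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> list[InterfaceSummary]:
    """Main/minor interface assignment for every Cul3 chain.

    For each Cul3 chain the buried area against every KCTD chain is
    computed individually; the largest patch is the main interface, the
    second largest (if above ``min_minor_area``) the minor one.  In 1:1
    assemblies only a main interface can exist.  A Cul3 chain burying no
    area is reported with a ``no_interface`` flag — that is the non-binder
    geometry, not an error.
    """
    for cid in assembly.kctd_chain_ids + assembly.cul3_chain_ids:
        if cid not in model.chains:
            raise KeyError(f"assembly chain {cid!r} absent from model")
    summaries = []
    for cul3 in assembly.cul3_chain_ids:
        areas = {
            k: buried_interface_area(
                model.subset([k, cul3]), [k], [cul3],
                probe_radius=probe_radius, n_points=n_points,
            )
            for k in assembly.kctd_chain_ids
        }
        ranked = sorted(areas, key=lambda k: (-areas[k], k))
        main = ranked[0] if areas[ranked[0]] > 0 else None
        minor = None
        if main is not None and len(ranked) > 1 and areas[ranked[1]] > min_minor_area:
            minor = ranked[1]
        contacts: list[ContactRecord] = []
        for role, kchain in (("main", main), ("minor", minor)):
            if kchain is None:
                continue
            for c in detect_contacts(model, [kchain], [cul3], criteria=criteria):
                c.interface = role
                contacts.append(c)
        flags = [] if main is not None else ["no_interface"]
        summaries.append(
            InterfaceSummary(
                cul3_chain=cul3,
                main_kctd_chain=main,
                minor_kctd_chain=minor,
                area_main=areas[main] if main else 0.0,
                area_minor=areas[minor] if minor else 0.0,
                contacts=contacts,
                cul3_helices_touched=_touched_segments(contacts, "b", cul3_segments),
                kctd_segments_touched=_touched_segments(contacts, "a", kctd_segments),
                per_chain_areas=areas,
                flags=flags,
            )
        )
    return summaries


# ---------------------------------------------------------------------------
# superposition & symmetry


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of paired coordinate sets (Kabsch).

    Rows of ``mobile`` and ``reference`` are corresponding atoms.  The
    returned rotation is always proper (reflections are excluded).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = len(mobile)
    if n < 3:
        raise ValueError("superposition needs at least 3 atom pairs")
    ref_c = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("reference atoms are collinear; superposition is degenerate")
    mob_c = mobile - mobile.mean(axis=0)
    h = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = reference.mean(axis=0) - rot @ mobile.mean(axis=0)
    fitted = mobile @ rot.T + trans
    rmsd = float(np.sqrt(((fitted - reference) ** 2).sum() / n))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=n)


def superpose_models(
    mobile: StructureModel,
    reference: StructureModel,
    atom_name: str = "CA",
) -> SuperpositionResult:
    """Superpose two models on equivalent named atoms (paired by residue order)."""
    def _pick(m: StructureModel) -> np.ndarray:
        pts = []
        for res in m.residues():
            for a in res.atoms:
                if a.name == atom_name:
                    pts.append(a.coords)
                    break
        return np.array(pts)

    xa, xb = _pick(mobile), _pick(reference)
    if len(xa) != len(xb):
        raise ValueError(
            f"models pair {len(xa)} vs {len(xb)} {atom_name} atoms; "
            "residue inventories differ"
        )
    return kabsch_superpose(xa, xb)


def cn_symmetry_score(
    model: StructureModel,
    n: int = 5,
    chains: "list[str] | None" = None,
) -> tuple[float, np.ndarray]:
    """Cyclic-symmetry score: RMSD of the assembly onto itself under the
    one-step cyclic chain permutation.  0 for ideal Cn; returns
    ``(rmsd, axis)`` with the fitted rotation axis (unit vector).

    For a 5:5 assembly pass the ten chains ordered as pairs
    (kctd1, cul3_1, kctd2, cul3_2, ...) grouped per symmetry unit.
    """
    if n < 2:
        raise ValueError("cyclic order n must be >= 2")
    chains = list(chains) if chains is not None else model.chain_ids
    if len(chains) % n != 0:
        raise ValueError(f"{len(chains)} chains cannot split into {n} symmetry units")
    per_unit = len(chains) // n
    counts = [model.n_atoms(chains[k * per_unit:(k + 1) * per_unit]) for k in range(n)]
    if len(set(counts)) != 1:
        raise ValueError(
            f"symmetry units have unequal atom counts {counts}; "
            "chain sequences likely mismatch"
        )
    reference = np.concatenate(
        [model.coords(chains[k * per_unit:(k + 1) * per_unit]) for k in range(n)]
    )
    permuted = np.concatenate(
        [model.coords(chains[((k + 1) % n) * per_unit:(((k + 1) % n) + 1) * per_unit])
         for k in range(n)]
    )
    sup = kabsch_superpose(permuted, reference)
    # rotation axis = eigenvector of the fitted rotation with eigenvalue 1
    w, v = np.linalg.eig(sup.rotation)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    axis /= np.linalg.norm(axis)
    return sup.rmsd, axis
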