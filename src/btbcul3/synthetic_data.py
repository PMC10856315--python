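"""Ground-truth synthetic fixtures for every pipeline stage.

Three generators, all seeded with numpy's PCG64 so outputs are
byte-identical across runs and platforms:

* :func:`make_cn_complex` — an idealized Cn ring of helical-hairpin
  subunits (poly-Ala) with an optional partner helix (poly-Gly) placed to
  straddle subunits 1 (main interface) and 2 (minor interface).  Requested
  contacts are engineered by mutating one residue on each side and placing
  the side-chain atoms along the inter-residue axis so the designated atom
  pair sits at its target distance exactly; the generator then re-detects
  contacts and refuses to emit a fixture whose realized contact set
  differs from the manifest.
* :func:`make_confidence_bundle` — pLDDT/PAE bundles with binder-like
  (low cross-block error) or non-binder-like (saturated cross-block
  error) statistics, mirroring the confidence signatures of predicted
  complexes that do or do not form a real interface.
* :func:`make_trajectory` — Gaussian jitter around a reference topology
  with a known per-residue amplitude, optionally composed with a rigid
  drift, so RMSD/RMSF estimators can be checked against closed forms.

These fixtures emulate the *inputs* of the analysis (geometry with known
contacts and areas; confidence matrices with known block statistics;
trajectories with known fluctuation amplitudes), not the physics that
produces real ones: subunits are not folded proteins and confidence
values carry none of a real predictor's error correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .confidence import ConfidenceBundle
from .geometry import (
    _APOLAR_SIDECHAIN as _APOLAR_FIXTURE,
    ContactCriteria,
    ContactRecord,
    detect_contacts,
)
from .metadata import FAMILY_TABLE, FamilyEntry
from .structure_io import AssemblySpec, AtomRecord, Residue, StructureModel
from .trajectory import TrajectoryEnsemble

__all__ = [
    "SyntheticComplexSpec",
    "SyntheticConfidenceSpec",
    "SyntheticTrajectorySpec",
    "ComplexManifest",
    "make_cn_complex",
    "make_confidence_bundle",
    "make_benchmark_bundles",
    "make_trajectory",
    "DEFAULT_CONTACTS",
]

#: Default engineered contacts: one of each kind at the main interface plus
#: one H-bond at the minor interface, all inside their detection cutoffs.
DEFAULT_CONTACTS: tuple[tuple[str, str, float], ...] = (
    ("salt_bridge", "main", 2.8),
    ("hbond", "main", 3.0),
    ("hydrophobic", "main", 4.0),
    ("hbond", "minor", 3.2),
)


@dataclass(frozen=True)
class SyntheticComplexSpec:
    n_fold: int = 5
    subunit_size: int = 24  # residues per hairpin subunit
    partner: bool = False
    partner_size: int = 16
    engineered_contacts: tuple[tuple[str, str, float], ...] = DEFAULT_CONTACTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fold < 1:
            raise ValueError("n_fold must be >= 1")
        cutoffs = {"hbond": 3.5, "salt_bridge": 4.0, "hydrophobic": 4.5}
        for kind, role, dist in self.engineered_contacts:
            if kind not in cutoffs:
                raise ValueError(f"unknown contact kind {kind!r}")
            if role not in ("main", "minor"):
                raise ValueError(f"contact role must be main or minor, got {role!r}")
            if not 0 < dist <= cutoffs[kind]:
                raise ValueError(
                    f"{kind} target distance {dist} outside its cutoff {cutoffs[kind]}"
                )


@dataclass(frozen=True)
class SyntheticConfidenceSpec:
    label: str = "binder"  # binder | non_binder
    intra_pae_range: tuple[float, float] = (2.0, 6.0)
    cross_pae_range: "tuple[float, float] | None" = None  # default by label
    plddt_mean_sd: "tuple[float, float] | None" = None  # default by label
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in ("binder", "non_binder"):
            raise ValueError("label must be binder or non_binder")

    @property
    def cross_range(self) -> tuple[float, float]:
        if self.cross_pae_range is not None:
            return self.cross_pae_range
        return (3.0, 8.0) if self.label == "binder" else (22.0, 30.0)

    @property
    def plddt_params(self) -> tuple[float, float]:
        if self.plddt_mean_sd is not None:
            return self.plddt_mean_sd
        return (85.0, 5.0) if self.label == "binder" else (75.0, 8.0)


@dataclass(frozen=True)
class SyntheticTrajectorySpec:
    n_frames: int = 100
    dt: float = 1.0  # ns
    sigma: float = 0.5  # per-coordinate Gaussian amplitude, A (uniform default)
    sigma_profile: "dict[tuple[str, int], float] | None" = None  # per-residue override
    rigid_drift: "tuple[float, np.ndarray] | None" = None  # (deg/frame about z, shift/frame)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class ComplexManifest:
    """Machine-checkable ground truth of a generated assembly."""

    spec: SyntheticComplexSpec
    assembly: AssemblySpec
    main_chain: "str | None"
    minor_chain: "str | None"
    contacts: list[ContactRecord] = field(default_factory=list)
    buried_positive_pairs: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# subunit and partner construction

_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TWIST = np.deg2rad(100.0)


def _helix_ca(n_res: int, center: np.ndarray, up: bool) -> np.ndarray:
    """CA trace of an ideal alpha-helix along +/-z, centred at ``center``."""
    k = np.arange(n_res, dtype=float)
    z = (k - (n_res - 1) / 2.0) * _HELIX_RISE * (1.0 if up else -1.0)
    phi = k * _HELIX_TWIST
    return center + np.column_stack(
        [_HELIX_RADIUS * np.cos(phi), _HELIX_RADIUS * np.sin(phi), z]
    )


def _residues_from_ca(
    ca: np.ndarray, chain_id: str, aa3: str, start_serial: int, start_seq: int,
    with_cb: bool,
) -> list[Residue]:
    """Backbone (N, CA, C, O) plus optional CB around a CA trace.

    Offsets live in a local frame from the trace, so rigid motion of the
    trace moves the whole residue rigidly.
    """
    n = len(ca)
    residues = []
    serial = start_serial
    for i in range(n):
        prev_pt = ca[i - 1] if i > 0 else ca[i] - np.array([0.0, 0.0, 1.0])
        next_pt = ca[i + 1] if i < n - 1 else ca[i] + np.array([0.0, 0.0, 1.0])
        t = next_pt - prev_pt
        t = t / np.linalg.norm(t)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(t @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = ref - (ref @ t) * t
        u = u / np.linalg.norm(u)
        b = np.cross(t, u)
        atoms = [
            AtomRecord(serial, "N", "N", ca[i] - 1.20 * t + 0.50 * b),
            AtomRecord(serial + 1, "CA", "C", ca[i]),
            AtomRecord(serial + 2, "C", "C", ca[i] + 1.20 * t + 0.50 * b),
            AtomRecord(serial + 3, "O", "O", ca[i] + 1.40 * t + 1.60 * b),
        ]
        serial += 4
        if with_cb:
            atoms.append(AtomRecord(serial, "CB", "C", ca[i] + 1.53 * u))
            serial += 1
        residues.append(Residue(chain_id, start_seq + i, "", aa3, atoms))
    return residues


def _build_subunit(chain_id: str, n_res: int) -> list[Residue]:
    """Helical hairpin: two antiparallel helices joined by a short loop."""
    n1 = (n_res - 3) // 2
    n2 = n_res - 3 - n1
    ca1 = _helix_ca(n1, np.array([0.0, -4.0, 0.0]), up=True)
    ca2 = _helix_ca(n2, np.array([0.0, 4.0, 0.0]), up=False)
    top1, top2 = ca1[-1], ca2[0]
    loop = np.array([top1 + (top2 - top1) * f + np.array([0, 0, 2.0]) for f in (0.25, 0.5, 0.75)])
    ca = np.vstack([ca1, loop, ca2])
    return _residues_from_ca(ca, chain_id, "ALA", 1, 1, with_cb=True)


def _rotate_z(coords: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return coords @ rot.T


def _transform_residues(
    residues: list[Residue], chain_id: str, angle: float, radius: float
) -> list[Residue]:
    out = []
    for res in residues:
        atoms = [
            AtomRecord(
                a.serial, a.name, a.element,
                _rotate_z(a.coords + np.array([radius, 0.0, 0.0]), angle),
                a.occupancy, a.bfactor,
            )
            for a in res.atoms
        ]
        out.append(Residue(chain_id, res.seq_number, "", res.aa3, atoms))
    return out


# side-chain recipes: ordered (atom name, element, fraction along the
# contact axis, perpendicular offset).  The last entry is the contact atom
# at fraction 1.0 with no offset.
_SIDECHAINS: dict[str, list[tuple[str, str, float, float]]] = {
    "ASP": [("CB", "C", 0.40, 0.3), ("CG", "C", 0.70, 0.2), ("OD1", "O", 0.80, 1.1),
            ("OD2", "O", 1.0, 0.0)],
    "ARG": [("CB", "C", 0.24, 0.3), ("CG", "C", 0.40, 0.2), ("CD", "C", 0.56, 0.3),
            ("NE", "N", 0.70, 0.2), ("CZ", "C", 0.82, 0.0), ("NH1", "N", 0.86, 1.25),
            ("NH2", "N", 1.0, 0.0)],
    "GLN": [("CB", "C", 0.30, 0.3), ("CG", "C", 0.55, 0.2), ("CD", "C", 0.78, 0.0),
            ("OE1", "O", 0.84, 1.1), ("NE2", "N", 1.0, 0.0)],
    "GLNO": [("CB", "C", 0.30, 0.3), ("CG", "C", 0.55, 0.2), ("CD", "C", 0.78, 0.0),
             ("NE2", "N", 0.84, 1.1), ("OE1", "O", 1.0, 0.0)],
    "SER": [("CB", "C", 0.55, 0.3), ("OG", "O", 1.0, 0.0)],
    "MET": [("CB", "C", 0.33, 0.3), ("CG", "C", 0.58, 0.2), ("SD", "S", 0.80, 0.2),
            ("CE", "C", 1.0, 0.0)],
    "LEU": [("CB", "C", 0.35, 0.3), ("CG", "C", 0.66, 0.2), ("CD2", "C", 0.72, 1.25),
            ("CD1", "C", 1.0, 0.0)],
    "LYS": [("CB", "C", 0.22, 0.3), ("CG", "C", 0.42, 0.2), ("CD", "C", 0.61, 0.3),
            ("CE", "C", 0.80, 0.2), ("NZ", "N", 1.0, 0.0)],
}

#: extended CA -> contact-atom reach (A) of each recipe
_REACH = {"ASP": 3.7, "ARG": 6.4, "GLN": 5.0, "GLNO": 5.0, "SER": 2.4,
          "MET": 4.8, "LEU": 3.9, "LYS": 6.0}

#: residue types used on (ring subunit, partner) for each engineered kind;
#: the contact atom pair is the last recipe entry on each side.
_KIND_TYPES = {
    "salt_bridge": ("ASP", "ARG"),
    "hbond": ("GLNO", "LYS"),
    "hydrophobic": ("MET", "LEU"),
}


def _mutate_with_sidechain(
    res: Residue, recipe_key: str, axis: np.ndarray, perp: np.ndarray, reach: float
) -> AtomRecord:
    """Replace a residue's side chain by an extended rotamer along ``axis``.

    Returns the contact atom (the recipe's last entry, at ``reach`` from CA).
    """
    aa3 = "GLN" if recipe_key in ("GLN", "GLNO") else recipe_key
    ca = res.atom("CA").coords
    res.aa3 = aa3
    res.atoms = [a for a in res.atoms if a.is_backbone]
    serial = max(a.serial for a in res.atoms)
    contact_atom = None
    for name, element, frac, off in _SIDECHAINS[recipe_key]:
        serial += 1
        pos = ca + axis * (frac * reach) + perp * off
        atom = AtomRecord(serial, name, element, pos)
        res.atoms.append(atom)
        if frac == 1.0:
            contact_atom = atom
    assert contact_atom is not None
    return contact_atom


def _place_partner(
    model_chains: dict[str, list[Residue]],
    partner: list[Residue],
    ring_radius: float,
    gap_main: float,
    gap_minor: float,
) -> list[Residue]:
    """Radially position the partner so its closest approach to subunit A
    is ``gap_main`` and to subunit B about ``gap_minor`` (sets the azimuth)."""
    part_xyz = np.array([a.coords for r in partner for a in r.atoms])
    sub_xyz = {
        c: np.array([a.coords for r in model_chains[c] for a in r.atoms])
        for c in ("A", "B")
        if c in model_chains
    }

    def _min_dist(azimuth: float, radius: float, chain: str) -> float:
        placed = _rotate_z(part_xyz + np.array([radius, 0.0, 0.0]), azimuth)
        d2 = ((placed[:, None, :] - sub_xyz[chain][None, :, :]) ** 2).sum(axis=2)
        return float(np.sqrt(d2.min()))

    azimuth = np.deg2rad(20.0)
    radius = ring_radius + 6.0
    for _ in range(40):  # alternate radial / azimuthal relaxation
        lo, hi = ring_radius, ring_radius + 30.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if _min_dist(azimuth, mid, "A") < gap_main:
                lo = mid
            else:
                hi = mid
        radius = hi
        if "B" not in sub_xyz:  # monomer: no minor subunit to straddle
            break
        err = _min_dist(azimuth, radius, "B") - gap_minor
        if abs(err) < 0.02:
            break
        azimuth += np.clip(err * 0.02, -0.05, 0.05)
    return _transform_residues(partner, "X", azimuth, radius)


def make_cn_complex(
    spec: SyntheticComplexSpec,
) -> tuple[StructureModel, ComplexManifest]:
    """Generate a Cn ring (plus optional partner) with a ground-truth manifest.

    The ring subunits play the oligomeric-adaptor role (chains A, B, ...);
    the partner helix (chain X) plays the scaffold role, straddling
    subunits A (main) and B (minor).  Engineered contacts are realized
    within 0.05 A of their target distance; the generator verifies that
    contact detection on the emitted model recovers exactly the manifest
    and raises if the requested set is geometrically infeasible.
    """
    rng = np.random.default_rng(spec.seed)
    ring_radius = 14.0
    chain_ids = [chr(ord("A") + k) for k in range(spec.n_fold)]

    template = _build_subunit("T", spec.subunit_size)
    chains: dict[str, list[Residue]] = {}
    for k, cid in enumerate(chain_ids):
        chains[cid] = _transform_residues(
            template, cid, 2.0 * np.pi * k / spec.n_fold, ring_radius
        )

    manifest_contacts: list[ContactRecord] = []
    buried_pairs: list[tuple[str, str]] = []
    if spec.partner:
        if spec.n_fold < 2 and any(r == "minor" for _, r, _ in spec.engineered_contacts):
            raise ValueError("minor-interface contacts need n_fold >= 2")
        gap_main = 4.9 + rng.uniform(-0.1, 0.1)
        gap_minor = 5.4 + rng.uniform(-0.1, 0.1)
        partner_ca = _helix_ca(spec.partner_size, np.zeros(3), up=True)
        partner_t = _residues_from_ca(partner_ca, "X", "GLY", 1, 1, with_cb=False)
        placed = _place_partner(chains, partner_t, ring_radius, gap_main, gap_minor)
        chains["X"] = placed

        used_sub: dict[str, set[int]] = {"A": set(), "B": set()}
        used_par: set[int] = set()

        def _recipe_info(
            recipe_key: str, ca: np.ndarray, axis: np.ndarray, perp: np.ndarray, reach: float
        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
            """Positions plus polar / apolar-carbon masks of a tentative rotamer."""
            pos, polar, apolar = [], [], []
            aa3 = "GLN" if recipe_key in ("GLN", "GLNO") else recipe_key
            apolar_names = _APOLAR_FIXTURE.get(aa3, frozenset())
            for name, element, frac, off in _SIDECHAINS[recipe_key]:
                pos.append(ca + axis * (frac * reach) + perp * off)
                polar.append(element in ("N", "O"))
                apolar.append(name in apolar_names)
            return np.array(pos), np.array(polar), np.array(apolar)

        def _chain_profile(
            cid: str, skip_res: "int | None" = None
        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
            pts, polar, apolar = [], [], []
            for idx, r in enumerate(chains[cid]):
                apolar_names = _APOLAR_FIXTURE.get(r.aa3, frozenset())
                for a in r.atoms:
                    if idx == skip_res and not a.is_backbone:
                        continue  # side chain about to be replaced
                    pts.append(a.coords)
                    polar.append(a.element in ("N", "O"))
                    apolar.append(a.name in apolar_names and not a.is_backbone)
            return np.array(pts), np.array(polar), np.array(apolar)

        def _clear(new, other) -> bool:
            """No unintended qualifying pair between a tentative rotamer and
            the other chain: polar-polar pairs stay beyond the H-bond/salt
            cutoffs, apolar-carbon pairs beyond the hydrophobic cutoff."""
            pos_n, pol_n, apo_n = new
            pos_o, pol_o, apo_o = other
            d = np.linalg.norm(pos_n[:, None, :] - pos_o[None, :, :], axis=2)
            if pol_n.any() and pol_o.any():
                if d[np.ix_(pol_n, pol_o)].min() < 4.1:
                    return False
            if apo_n.any() and apo_o.any():
                if d[np.ix_(apo_n, apo_o)].min() < 4.6:
                    return False
            return True

        for kind, role, dist in spec.engineered_contacts:
            sub_chain = "A" if role == "main" else "B"
            sub_key, par_key = _KIND_TYPES[kind]
            reach_total = _REACH[sub_key] + _REACH[par_key]
            need = reach_total + dist
            candidates = []
            for i, rs in enumerate(chains[sub_chain]):
                if any(abs(i - u) < 3 for u in used_sub[sub_chain]):
                    continue
                ca_s = rs.atom("CA").coords
                for j, rp in enumerate(chains["X"]):
                    if any(abs(j - u) < 3 for u in used_par):
                        continue
                    span = float(np.linalg.norm(rp.atom("CA").coords - ca_s))
                    # scale in [1, 1.25]: side chains at or slightly beyond
                    # extended reach keep contact atoms clear of backbones
                    if need <= span <= need + 0.25 * reach_total:
                        candidates.append((span - need, i, j, span))
            candidates.sort()
            placed_ok = False
            for _, i, j, span in candidates:
                rs, rp = chains[sub_chain][i], chains["X"][j]
                ca_s, ca_p = rs.atom("CA").coords, rp.atom("CA").coords
                axis = (ca_p - ca_s) / span
                perp = np.cross(axis, np.array([0.0, 0.0, 1.0]))
                if np.linalg.norm(perp) < 1e-6:
                    perp = np.cross(axis, np.array([1.0, 0.0, 0.0]))
                perp /= np.linalg.norm(perp)
                scale = (span - dist) / reach_total
                new_s = _recipe_info(sub_key, ca_s, axis, perp, scale * _REACH[sub_key])
                new_p = _recipe_info(par_key, ca_p, -axis, -perp, scale * _REACH[par_key])
                if not _clear(new_s, _chain_profile("X", skip_res=j)):
                    continue
                if not _clear(new_p, _chain_profile(sub_chain, skip_res=i)):
                    continue
                a_s = _mutate_with_sidechain(rs, sub_key, axis, perp, scale * _REACH[sub_key])
                a_p = _mutate_with_sidechain(rp, par_key, -axis, -perp, scale * _REACH[par_key])
                used_sub[sub_chain].add(i)
                used_par.add(j)
                placed_ok = True
                break
            if not placed_ok:
                raise ValueError(
                    f"infeasible contact set: no clear residue pair can realize "
                    f"{kind}@{role} at {dist} A (needs span ~{need:.1f} A)"
                )
            realized = float(np.linalg.norm(a_p.coords - a_s.coords))
            assert abs(realized - dist) < 0.05
            manifest_contacts.append(
                ContactRecord(
                    kind=kind,
                    res_a=(sub_chain, rs.seq_number, rs.aa3),
                    res_b=("X", rp.seq_number, rp.aa3),
                    atom_a=a_s.name,
                    atom_b=a_p.name,
                    distance=realized,
                    interface=role,
                )
            )
            if kind == "salt_bridge" and dist <= 3.5:
                # the same atom pair inevitably satisfies the H-bond criterion
                manifest_contacts.append(
                    ContactRecord(
                        kind="hbond",
                        res_a=(sub_chain, rs.seq_number, rs.aa3),
                        res_b=("X", rp.seq_number, rp.aa3),
                        atom_a=a_s.name,
                        atom_b=a_p.name,
                        distance=realized,
                        interface=role,
                    )
                )
        buried_pairs = [("A", "X")] + ([("B", "X")] if spec.n_fold >= 2 else [])

    model = StructureModel(f"cn{spec.n_fold}_seed{spec.seed}", chains, source="synthetic")
    model.validate()
    assembly = AssemblySpec(
        kctd_chain_ids=tuple(chain_ids),
        cul3_chain_ids=("X",) if spec.partner else (),
        stoichiometry=(spec.n_fold, 1 if spec.partner else 0),
    )
    manifest = ComplexManifest(
        spec=spec,
        assembly=assembly,
        main_chain="A" if spec.partner else None,
        minor_chain="B" if spec.partner else None,
        contacts=manifest_contacts,
        buried_positive_pairs=buried_pairs,
    )

    if spec.partner:
        detected = detect_contacts(model, chain_ids, ["X"], ContactCriteria())
        want = {c.pair_key + (c.atom_a, c.atom_b) for c in manifest_contacts}
        got = {c.pair_key + (c.atom_a, c.atom_b) for c in detected}
        if want != got:
            raise ValueError(
                "infeasible contact set: detection does not recover the manifest "
                f"(missing={sorted(want - got)}, extra={sorted(got - want)})"
            )
    return model, manifest


# ---------------------------------------------------------------------------
# confidence bundles


def make_confidence_bundle(
    spec: SyntheticConfidenceSpec,
    partition: list[tuple[str, tuple[int, int]]],
    assembly: AssemblySpec,
) -> tuple[ConfidenceBundle, str]:
    """Sample a pLDDT/PAE bundle with the stated block statistics.

    Within-chain and adaptor-adaptor blocks draw from ``intra_pae_range``;
    adaptor-scaffold cross-blocks draw from the binder or non-binder range.
    The diagonal is zero.  Returns ``(bundle, label)``.
    """
    rng = np.random.default_rng(spec.seed)
    n = max(stop for _, (start, stop) in partition)
    pae = rng.uniform(*spec.intra_pae_range, size=(n, n))
    cul3 = set(assembly.cul3_chain_ids)
    kctd = set(assembly.kctd_chain_ids)
    lo, hi = spec.cross_range
    for ca, (sa, ea) in partition:
        for cb, (sb, eb) in partition:
            cross = (ca in kctd and cb in cul3) or (ca in cul3 and cb in kctd)
            if cross:
                pae[sa:ea, sb:eb] = rng.uniform(lo, hi, size=(ea - sa, eb - sb))
    np.fill_diagonal(pae, 0.0)
    mean, sd = spec.plddt_params
    plddt = np.clip(rng.normal(mean, sd, size=n), 0.0, 100.0)
    bundle = ConfidenceBundle(plddt=plddt, pae=pae, partition=partition, assembly=assembly)
    return bundle, spec.label


def make_benchmark_bundles(
    seed: int = 0,
    residues_per_chain: int = 30,
) -> list[tuple[FamilyEntry, ConfidenceBundle, str]]:
    """One confidence bundle per family-table row (16 binder-patterned,
    11 non-binder-patterned), each with its own derived seed."""
    out = []
    for i, entry in enumerate(FAMILY_TABLE):
        n_k, n_c = entry.stoichiometry
        kctd = tuple(chr(ord("A") + k) for k in range(n_k))
        cul3 = tuple(chr(ord("A") + n_k + k) for k in range(n_c))
        partition = []
        pos = 0
        for cid in kctd + cul3:
            partition.append((cid, (pos, pos + residues_per_chain)))
            pos += residues_per_chain
        assembly = AssemblySpec(kctd, cul3, (n_k, n_c))
        sub_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(i,)).generate_state(1)[0] % (2 ** 31))
        spec = SyntheticConfidenceSpec(
            label="binder" if entry.binds_cul3 else "non_binder", seed=sub_seed
        )
        bundle, label = make_confidence_bundle(spec, partition, assembly)
        out.append((entry, bundle, label))
    return out


# ---------------------------------------------------------------------------
# trajectories


def make_trajectory(
    spec: SyntheticTrajectorySpec,
    topology: StructureModel,
) -> tuple[TrajectoryEnsemble, dict]:
    """Gaussian-jitter trajectory around a topology with known amplitudes.

    Frame k adds i.i.d. per-coordinate noise with each residue's sigma to
    every atom of the residue, optionally composed with a rigid drift
    (rotation about z plus translation, linear per frame).  The manifest
    records the sigma profile and drift so estimator recovery is
    machine-checkable (isotropic sigma implies RMSF = sqrt(3) * sigma).
    """
    rng = np.random.default_rng(spec.seed)
    ref = topology.coords()
    sigmas = []
    for res in topology.residues():
        s = spec.sigma
        if spec.sigma_profile is not None:
            s = spec.sigma_profile.get((res.chain_id, res.seq_number), spec.sigma)
        sigmas.extend([s] * len(res.atoms))
    sigma_atoms = np.array(sigmas)[:, None]

    frames = np.empty((spec.n_frames, len(ref), 3))
    for k in range(spec.n_frames):
        noisy = ref + rng.normal(0.0, 1.0, size=ref.shape) * sigma_atoms
        if spec.rigid_drift is not None:
            rate_deg, shift = spec.rigid_drift
            noisy = _rotate_z(noisy, np.deg2rad(rate_deg * k)) + np.asarray(shift) * k
        frames[k] = noisy
    times = np.arange(spec.n_frames) * spec.dt
    ensemble = TrajectoryEnsemble(
        topology=topology, frames=frames, times=times, selections={}
    )
    manifest = {
        "seed": spec.seed,
        "n_frames": spec.n_frames,
        "dt_ns": spec.dt,
        "sigma": spec.sigma,
        "sigma_profile": dict(spec.sigma_profile) if spec.sigma_profile else None,
        "rigid_drift": (
            (spec.rigid_drift[0], list(np.asarray(spec.rigid_drift[1], dtype=float)))
            if spec.rigid_drift else None
        ),
        "expected_rmsf": {"uniform": float(np.sqrt(3.0) * spec.sigma)},
    }
    return ensemble, manifest
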