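"""Independent oracles used by the test suite.

These deliberately re-derive results by brute force or closed form,
without calling the implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from btbcul3.structure_io import AtomRecord, Residue, StructureModel

# ---------------------------------------------------------------------------
# contact chemistry tables (restated independently of the implementation)

BRUTE_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"}, "ASN": {"ND2"}, "GLN": {"NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
BRUTE_BASIC = {"ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"}}
BRUTE_ACIDIC = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
BRUTE_APOLAR = {
    "ALA": {"CB"}, "VAL": {"CB", "CG1", "CG2"}, "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"}, "MET": {"CB", "CG", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "PRO": {"CB", "CG", "CD"}, "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
}


def _donor(res, atom):
    if atom.name == "N" and res.aa3 != "PRO":
        return True
    return atom.name in BRUTE_DONORS.get(res.aa3, set())


def brute_force_contacts(model, group_a, group_b, criteria):
    """All-pairs scan; returns {(kind, resA, resB, atomA, atomB, round(d, 6))}."""
    atoms_a = [(r, a) for r, a in model.iter_atoms(list(group_a))]
    atoms_b = [(r, a) for r, a in model.iter_atoms(list(group_b))]
    best = {}
    for ri, ai in atoms_a:
        for rj, aj in atoms_b:
            d = float(np.linalg.norm(ai.coords - aj.coords))
            if d <= 0:
                continue
            kinds = []
            if d <= criteria.hbond_cutoff:
                acc_i = ai.element.upper() in ("N", "O")
                acc_j = aj.element.upper() in ("N", "O")
                if (_donor(ri, ai) and acc_j) or (_donor(rj, aj) and acc_i):
                    kinds.append("hbond")
            if d <= criteria.salt_bridge_cutoff:
                basic_i = ai.name in BRUTE_BASIC.get(ri.aa3, set())
                basic_j = aj.name in BRUTE_BASIC.get(rj.aa3, set())
                acid_i = ai.name in BRUTE_ACIDIC.get(ri.aa3, set())
                acid_j = aj.name in BRUTE_ACIDIC.get(rj.aa3, set())
                if (basic_i and acid_j) or (basic_j and acid_i):
                    kinds.append("salt_bridge")
            if d <= criteria.hydrophobic_cutoff:
                if ai.name in BRUTE_APOLAR.get(ri.aa3, set()) and aj.name in BRUTE_APOLAR.get(rj.aa3, set()):
                    kinds.append("hydrophobic")
            for kind in kinds:
                key = (kind, (ri.chain_id, ri.seq_number), (rj.chain_id, rj.seq_number))
                if key not in best or d < best[key][0]:
                    best[key] = (d, ai.name, aj.name)
    return {
        (kind, ra, rb, an, bn, round(d, 6))
        for (kind, ra, rb), (d, an, bn) in best.items()
    }


def contact_set(records):
    return {
        (c.kind, c.res_a[:2], c.res_b[:2], c.atom_a, c.atom_b, round(c.distance, 6))
        for c in records
    }


# random contact-rich fixtures -------------------------------------------------

_ATOM_TEMPLATES = {
    "GLY": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")],
    "ALA": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")],
    "SER": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("OG", "O")],
    "ASP": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C"),
            ("OD1", "O"), ("OD2", "O")],
    "GLU": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C"),
            ("CD", "C"), ("OE1", "O"), ("OE2", "O")],
    "LYS": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C"),
            ("CD", "C"), ("CE", "C"), ("NZ", "N")],
    "ARG": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C"),
            ("CD", "C"), ("NE", "N"), ("CZ", "C"), ("NH1", "N"), ("NH2", "N")],
    "HIS": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C"),
            ("ND1", "N"), ("CD2", "C"), ("CE1", "C"), ("NE2", "N")],
    "MET": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C"),
            ("SD", "S"), ("CE", "C")],
    "LEU": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C"),
            ("CD1", "C"), ("CD2", "C")],
    "PHE": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C"),
            ("CD1", "C"), ("CD2", "C"), ("CE1", "C"), ("CE2", "C"), ("CZ", "C")],
    "GLN": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C"),
            ("CD", "C"), ("OE1", "O"), ("NE2", "N")],
    "TYR": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C"),
            ("CD1", "C"), ("CD2", "C"), ("CE1", "C"), ("CE2", "C"), ("CZ", "C"), ("OH", "O")],
    "PRO": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C"), ("CD", "C")],
}


def random_two_chain_model(rng, n_res_per_chain=8, box=10.0):
    """Two interleaved chains of random residue types at random coordinates
    inside a shared box: dense in qualifying and near-miss pairs."""
    aa_pool = list(_ATOM_TEMPLATES)
    chains = {}
    serial = 1
    for cid in ("A", "B"):
        residues = []
        for k in range(n_res_per_chain):
            aa3 = aa_pool[rng.integers(len(aa_pool))]
            atoms = []
            for name, element in _ATOM_TEMPLATES[aa3]:
                atoms.append(
                    AtomRecord(serial, name, element, rng.uniform(0, box, size=3))
                )
                serial += 1
            residues.append(Residue(cid, k + 1, "", aa3, atoms))
        chains[cid] = residues
    return StructureModel("random", chains, source="synthetic")


# ---------------------------------------------------------------------------
# superposition oracles


def quaternion_grid_rmsd(mobile, reference, n_grid=6000, seed=0):
    """Best superposition RMSD via a quaternion grid plus local refinement;
    independent of the Kabsch solution."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)

    def rmsd_of(rot):
        return float(np.sqrt((((mob_c @ rot.T) - ref_c) ** 2).sum() / len(mob_c)))

    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n_grid, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    best = min(
        (rmsd_of(Rotation.from_quat(q).as_matrix()), tuple(q)) for q in quats
    )
    q0 = np.array(best[1])

    def objective(rv):
        return rmsd_of(Rotation.from_rotvec(rv).as_matrix())

    res = minimize(
        objective, Rotation.from_quat(q0).as_rotvec(),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
    )
    return min(best[0], float(res.fun))


def two_sphere_sasa(r1, r2, d, probe):
    """Analytic accessible area of two overlapping spheres."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * math.pi * (R1 * R1 + R2 * R2)
    h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2 * d)
    h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2 * d)
    a1 = 4 * math.pi * R1 * R1 - 2 * math.pi * R1 * max(h1, 0.0)
    a2 = 4 * math.pi * R2 * R2 - 2 * math.pi * R2 * max(h2, 0.0)
    return a1 + a2


def rigid_transform(rng):
    """A random proper rigid transform (rotation matrix, translation)."""
    rot = Rotation.from_quat(
        rng.normal(size=4) / np.linalg.norm(rng.normal(size=4))
    )
    q = rng.normal(size=4)
    rot = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    trans = rng.uniform(-20, 20, size=3)
    return rot, trans


def apply_rigid_to_model(model, rot, trans):
    import copy

    out = copy.deepcopy(model)
    for res in out.residues():
        for atom in res.atoms:
            atom.coords = rot @ atom.coords + trans
    return out
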