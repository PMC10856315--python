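"""Coordinate and confidence-matrix I/O.

Reads predicted or experimental structures from PDB / minimal mmCIF into a
light validated in-memory model, writes them back losslessly at PDB
precision, parses predicted-aligned-error (PAE) matrices in the two JSON
dialects emitted by AlphaFold-style servers, and selects construct regions
by author residue numbering (1-based, ranges inclusive on both ends).

Predicted models carry per-residue confidence (pLDDT, 0-100) in the
B-factor column; :func:`plddt_profile` extracts it per residue.

Hydrogens, waters and heteroatoms are dropped on read by default: the
downstream interface analyses are heavy-atom only, and solvated MD
structures would otherwise leak thousands of waters into SASA and contact
scans.  Alternate locations keep the highest-occupancy conformer (ties go
to altloc 'A').
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "StructureModel",
    "AssemblySpec",
    "ConstructSpec",
    "StructureParseError",
    "STANDARD_AA3",
    "read_structure",
    "read_all_models",
    "write_structure",
    "write_multi_model",
    "read_pae_json",
    "write_pae_json",
    "select_region",
    "plddt_profile",
]

#: The 20 standard three-letter amino-acid codes.
STANDARD_AA3 = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class StructureParseError(ValueError):
    """Raised when a coordinate or confidence file cannot be parsed."""


@dataclass
class AtomRecord:
    """One heavy atom with PDB-convention naming (e.g. ``NH2``, ``OD2``)."""

    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) in Angstrom
    occupancy: float = 1.0
    bfactor: float = 0.0  # pLDDT 0-100 for predicted models
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.bfactor < 0:
            raise ValueError(f"atom {self.name}: negative B-factor {self.bfactor}")

    @property
    def is_backbone(self) -> bool:
        return self.name in ("N", "CA", "C", "O", "OXT")


@dataclass
class Residue:
    """A residue identified by (chain, author seq number, insertion code)."""

    chain_id: str
    seq_number: int
    insertion_code: str
    aa3: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def is_standard(self) -> bool:
        return self.aa3 in STANDARD_AA3

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not found in {self.chain_id}:{self.seq_number}")

    @property
    def representative_atom(self) -> AtomRecord:
        """CA when present, else the first atom."""
        for a in self.atoms:
            if a.name == "CA":
                return a
        return self.atoms[0]


@dataclass
class StructureModel:
    """An ordered collection of chains, each an ordered list of residues."""

    model_id: str
    chains: dict[str, list[Residue]]  # insertion-ordered
    source: str = "predicted"  # predicted | experimental | synthetic

    def __post_init__(self) -> None:
        if self.source not in ("predicted", "experimental", "synthetic"):
            raise ValueError(f"unknown source {self.source!r}")

    def validate(self) -> None:
        if not self.chains:
            raise ValueError("model has no chains")
        seen: set[tuple[str, int, str]] = set()
        for cid, residues in self.chains.items():
            if not residues:
                raise ValueError(f"chain {cid} is empty")
            for res in residues:
                if not res.atoms:
                    raise ValueError(f"residue {cid}:{res.seq_number} has no atoms")
                if res.key in seen:
                    raise ValueError(f"duplicate residue identifier {res.key}")
                seen.add(res.key)

    # -- convenience accessors ------------------------------------------------

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residues(self, chain_ids: "list[str] | None" = None) -> Iterator[Residue]:
        for cid, residues in self.chains.items():
            if chain_ids is None or cid in chain_ids:
                yield from residues

    def iter_atoms(
        self, chain_ids: "list[str] | None" = None
    ) -> Iterator[tuple[Residue, AtomRecord]]:
        for res in self.residues(chain_ids):
            for atom in res.atoms:
                yield res, atom

    def n_atoms(self, chain_ids: "list[str] | None" = None) -> int:
        return sum(1 for _ in self.iter_atoms(chain_ids))

    def coords(self, chain_ids: "list[str] | None" = None) -> np.ndarray:
        """All atom coordinates in file order, shape (n_atoms, 3)."""
        pts = [a.coords for _, a in self.iter_atoms(chain_ids)]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def subset(self, chain_ids: list[str], model_id: "str | None" = None) -> "StructureModel":
        missing = [c for c in chain_ids if c not in self.chains]
        if missing:
            raise KeyError(f"chains not in model: {missing}")
        return StructureModel(
            model_id=model_id or self.model_id,
            chains={c: self.chains[c] for c in chain_ids},
            source=self.source,
        )


@dataclass(frozen=True)
class AssemblySpec:
    """Which chains play the adaptor (KCTD) and scaffold (Cul3) roles."""

    kctd_chain_ids: tuple[str, ...]
    cul3_chain_ids: tuple[str, ...]
    stoichiometry: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "kctd_chain_ids", tuple(self.kctd_chain_ids))
        object.__setattr__(self, "cul3_chain_ids", tuple(self.cul3_chain_ids))
        object.__setattr__(self, "stoichiometry", tuple(self.stoichiometry))
        if set(self.kctd_chain_ids) & set(self.cul3_chain_ids):
            raise ValueError("KCTD and Cul3 chain id lists must be disjoint")
        if (len(self.kctd_chain_ids), len(self.cul3_chain_ids)) != self.stoichiometry:
            raise ValueError(
                f"chain lists {self.kctd_chain_ids}/{self.cul3_chain_ids} do not "
                f"match stoichiometry {self.stoichiometry}"
            )


@dataclass(frozen=True)
class ConstructSpec:
    """A named residue range, e.g. the BTB domain boundaries of one KCTD."""

    protein_name: str
    domain_label: str
    start_res: int
    end_res: int

    def __post_init__(self) -> None:
        if self.start_res > self.end_res:
            raise ValueError(f"start {self.start_res} > end {self.end_res}")

    def __len__(self) -> int:
        return self.end_res - self.start_res + 1


# ---------------------------------------------------------------------------
# reading


def _validate_pdb_text(path: Path) -> None:
    """Pre-pass over PDB text: reject non-numeric coordinate fields.

    gemmi is forgiving about malformed fixed-column records; the contract
    here is a parse error naming the offending line, not a silent skip.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fld = line[lo:hi].strip()
                try:
                    float(fld)
                except ValueError:
                    raise StructureParseError(
                        f"{path}, line {lineno}: non-numeric {what} coordinate {fld!r}"
                    ) from None


def _sniff_format(path: Path) -> str:
    if path.suffix.lower() in (".cif", ".mmcif"):
        return "mmcif"
    if path.suffix.lower() in (".pdb", ".ent"):
        return "pdb"
    with open(path) as fh:
        head = fh.read(4096)
    return "mmcif" if head.lstrip().startswith("data_") else "pdb"


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties go to altloc 'A' (then lexicographic)."""
    return min(atoms, key=lambda a: (-a.occ, a.altloc or "A"))


def _convert_model(
    gmodel: gemmi.Model,
    model_id: str,
    source: str,
    keep_hydrogens: bool,
    keep_het: bool,
) -> StructureModel:
    chains: dict[str, list[Residue]] = {}
    for gchain in gmodel:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.name in _WATER_NAMES:
                continue
            if not keep_het and gres.het_flag == "H" and gres.name not in STANDARD_AA3:
                continue
            groups: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                if not keep_hydrogens and ga.element.name in ("H", "D"):
                    continue
                groups.setdefault(ga.name, []).append(ga)
            atoms = []
            for name, cands in groups.items():
                ga = _pick_altloc(cands)
                atoms.append(
                    AtomRecord(
                        serial=ga.serial,
                        name=name,
                        element=ga.element.name,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=round(float(ga.occ), 2),
                        bfactor=round(float(ga.b_iso), 2),  # field precision; avoids f32 dust
                        altloc="",
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        chain_id=gchain.name,
                        seq_number=gres.seqid.num,
                        insertion_code=(gres.seqid.icode or "").strip(),
                        aa3=gres.name,
                        atoms=atoms,
                    )
                )
        if residues:
            chains[gchain.name] = residues
    model = StructureModel(model_id=model_id, chains=chains, source=source)
    model.validate()
    return model


def read_structure(
    path: "str | Path",
    format: str = "auto",
    model_index: int = 0,
    source: str = "predicted",
    keep_hydrogens: bool = False,
    keep_het: bool = False,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Multi-model files return the model at ``model_index`` (default: first).
    Chain order is preserved.  Waters are always dropped; hydrogens and
    non-standard HETATM residues are dropped unless requested.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _sniff_format(path)
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r} (expected pdb, mmcif or auto)")
    if format == "pdb":
        _validate_pdb_text(path)
    gfmt = gemmi.CoorFormat.Pdb if format == "pdb" else gemmi.CoorFormat.Mmcif
    try:
        st = gemmi.read_structure(str(path), format=gfmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: file contains no models")
    if not 0 <= model_index < len(st):
        raise IndexError(f"model index {model_index} out of range (file has {len(st)})")
    model = _convert_model(
        st[model_index], model_id=path.stem, source=source,
        keep_hydrogens=keep_hydrogens, keep_het=keep_het,
    )
    if not model.chains:
        raise StructureParseError(f"{path}: model {model_index} holds no atoms after filtering")
    return model


def read_all_models(
    path: "str | Path", source: str = "predicted", **kwargs
) -> list[StructureModel]:
    """Read every MODEL block of a multi-model file (for trajectories)."""
    path = Path(path)
    fmt = _sniff_format(path)
    if fmt == "pdb":
        _validate_pdb_text(path)
    gfmt = gemmi.CoorFormat.Pdb if fmt == "pdb" else gemmi.CoorFormat.Mmcif
    try:
        st = gemmi.read_structure(str(path), format=gfmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: file contains no models")
    return [
        _convert_model(m, model_id=f"{path.stem}#{k}", source=source, keep_hydrogens=False, keep_het=False)
        for k, m in enumerate(st)
    ]


# ---------------------------------------------------------------------------
# writing


def write_structure(model: StructureModel, path: "str | Path") -> None:
    """Write a model as fixed-column PDB (coordinates at 3 decimals)."""
    model.validate()
    _write_pdb_lines([model], Path(path), multi_model=False)


def write_multi_model(models: list[StructureModel], path: "str | Path") -> None:
    """Write a trajectory-style multi-model PDB (MODEL/ENDMDL blocks)."""
    if not models:
        raise ValueError("no models to write")
    for m in models:
        m.validate()
    _write_pdb_lines(models, Path(path), multi_model=True)


def _write_pdb_lines(models: list[StructureModel], path: Path, multi_model: bool) -> None:
    lines: list[str] = []
    for imodel, model in enumerate(models, start=1):
        if multi_model:
            lines.append(f"MODEL     {imodel:4d}")
        serial = 0
        for cid, residues in model.chains.items():
            for res in residues:
                for a in res.atoms:
                    serial += 1
                    name = a.name if len(a.name) >= 4 or len(a.element) == 2 else f" {a.name}"
                    lines.append(
                        f"ATOM  {serial:5d} {name:<4.4s}{'':1s}{res.aa3:>3.3s} "
                        f"{cid:1.1s}{res.seq_number:4d}{res.insertion_code or ' ':1.1s}   "
                        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                        f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2.2s}"
                    )
            lines.append("TER")
        if multi_model:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PAE matrices

_PAE_KEYS = ("predicted_aligned_error", "pae")


def read_pae_json(path: "str | Path") -> tuple[np.ndarray, "float | None"]:
    """Read a PAE matrix from either JSON dialect.

    Recognizes the flat dialect ``{"predicted_aligned_error": [[...]], ...}``
    (also under the key ``"pae"``) and the list-wrapped server dialect
    ``[{"predicted_aligned_error": ...}]``.  Returns ``(matrix, max_value)``
    with the matrix as an N x N float array in Angstrom.
    """
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, list):
        if not payload or not isinstance(payload[0], dict):
            raise StructureParseError(f"{path}: empty or malformed list-wrapped PAE JSON")
        payload = payload[0]
    if not isinstance(payload, dict):
        raise StructureParseError(f"{path}: PAE JSON must be an object or a list of objects")
    for key in _PAE_KEYS:
        if key in payload:
            raw = payload[key]
            break
    else:
        raise StructureParseError(
            f"{path}: no PAE matrix found; recognized keys are {list(_PAE_KEYS)}"
        )
    mat = np.asarray(raw, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise StructureParseError(f"{path}: PAE matrix is not square (shape {mat.shape})")
    if np.any(mat < 0) or not np.all(np.isfinite(mat)):
        raise StructureParseError(f"{path}: PAE entries must be finite and >= 0")
    max_value = payload.get("max_predicted_aligned_error")
    return mat, (float(max_value) if max_value is not None else None)


def write_pae_json(
    path: "str | Path",
    pae: np.ndarray,
    max_value: "float | None" = None,
    dialect: str = "colabfold",
) -> None:
    """Serialize a PAE matrix in either dialect (round-trip counterpart)."""
    pae = np.asarray(pae, dtype=float)
    obj: dict = {"predicted_aligned_error": pae.tolist()}
    obj["max_predicted_aligned_error"] = float(max_value if max_value is not None else pae.max())
    if dialect == "colabfold":
        payload: object = obj
    elif dialect == "afserver":
        payload = [obj]
    else:
        raise ValueError(f"unknown PAE dialect {dialect!r}")
    with open(path, "w") as fh:
        json.dump(payload, fh)


# ---------------------------------------------------------------------------
# region selection and confidence profile


def select_region(model: StructureModel, spec: ConstructSpec) -> StructureModel:
    """Keep residues with ``start_res <= seq_number <= end_res`` (inclusive).

    Applied to every chain; chains left empty are dropped.  Selecting zero
    residues overall raises, since that almost always signals a numbering
    convention mismatch between construct table and coordinates.
    """
    chains: dict[str, list[Residue]] = {}
    for cid, residues in model.chains.items():
        kept = [r for r in residues if spec.start_res <= r.seq_number <= spec.end_res]
        if kept:
            chains[cid] = kept
    if not chains:
        raise ValueError(
            f"construct {spec.protein_name}/{spec.domain_label} "
            f"({spec.start_res}-{spec.end_res}) selects no residues; "
            "check the residue numbering convention"
        )
    return StructureModel(model_id=model.model_id, chains=chains, source=model.source)


def plddt_profile(model: StructureModel) -> dict[tuple[str, int], float]:
    """Per-residue pLDDT from the B-factor of the representative atom (CA rule).

    Values outside [0, 100] on a predicted model are clamped with a warning
    (never silently).
    """
    if model.source != "predicted":
        raise ValueError(f"pLDDT profile requires a predicted model, got source={model.source!r}")
    profile: dict[tuple[str, int], float] = {}
    clamped = []
    for res in model.residues():
        v = res.representative_atom.bfactor
        if not 0.0 <= v <= 100.0:
            clamped.append((res.chain_id, res.seq_number, v))
            v = min(max(v, 0.0), 100.0)
        profile[(res.chain_id, res.seq_number)] = v
    if clamped:
        warnings.warn(
            f"{len(clamped)} residue(s) had B-factors outside the pLDDT range "
            f"[0, 100] and were clamped (first: {clamped[0]})",
            stacklevel=2,
        )
    return profile
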