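"""Cross-complex interface comparison on a family alignment.

Interface residues found on each adaptor are projected onto the columns
of a family multiple sequence alignment, so that conserved scaffold-side
hot spots and the variability of the main binding loop (the loop between
helix alpha2 and strand beta3 of the BTB fold) can be read per column.
Scaffold-side (Cul3) conservation is a presence count across complexes —
how many complexes use a given Cul3 residue in at least one contact of
each kind — not an information-theoretic score.

Annotation categories per (sequence, column) follow the display rule of
family-alignment figures: ``main_both`` dominates when a residue has both
an H-bond and a hydrophobic contact at the main interface; minor-interface
hydrophobic contacts are recorded in the contact tables but carry no
dedicated display category.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

from .geometry import ContactRecord, InterfaceSummary, SegmentAnnotation
from .structure_io import ConstructSpec

__all__ = [
    "AlignmentColumnMap",
    "read_alignment",
    "map_interface_to_alignment",
    "tally_cul3_conservation",
    "loop_diagnostics",
    "read_segment_annotations",
]

#: proteins excluded from conservation tallies by default: complexes not
#: predicted with high reliability contribute noise, not signal.
DEFAULT_TALLY_EXCLUDE: tuple[str, ...] = ("KCTD11",)

CATEGORY_PRECEDENCE = ("main_both", "main_hbond", "main_hydrophobic", "minor_hbond", "none")


def read_alignment(path: "str | Path", format: str = "auto") -> MultipleSeqAlignment:
    """Read a CLUSTAL or aligned-FASTA alignment (ragged rows raise)."""
    path = Path(path)
    if format == "auto":
        with open(path) as fh:
            head = fh.read(64)
        format = "clustal" if head.upper().startswith(("CLUSTAL", "MUSCLE")) else "fasta"
    if format not in ("clustal", "fasta"):
        raise ValueError(f"unknown alignment format {format!r}")
    with open(path) as fh:
        aln = AlignIO.read(fh, format)
    length = aln.get_alignment_length()
    for rec in aln:
        if len(rec.seq) != length:
            raise ValueError(f"ragged alignment: {rec.id} has length {len(rec.seq)}")
    return aln


@dataclass
class AlignmentColumnMap:
    """Gap-aware residue-number -> column-index maps for one alignment."""

    alignment_id: str
    maps: dict[str, dict[int, int]]  # seq id -> {seq_number: 0-based column}

    @classmethod
    def from_alignment(
        cls,
        alignment: MultipleSeqAlignment,
        start_numbers: "dict[str, int] | None" = None,
        gap_chars: str = "-.",
    ) -> "AlignmentColumnMap":
        """Build the map; ``start_numbers[seq_id]`` is the author residue
        number of the first non-gap position (default 1)."""
        start_numbers = start_numbers or {}
        maps: dict[str, dict[int, int]] = {}
        for rec in alignment:
            num = start_numbers.get(rec.id, 1)
            cols: dict[int, int] = {}
            for col, ch in enumerate(str(rec.seq)):
                if ch in gap_chars:
                    continue
                cols[num] = col
                num += 1
            maps[rec.id] = cols
        return cls(alignment_id=getattr(alignment, "annotations", {}).get("id", "aln"), maps=maps)

    def column_of(self, seq_id: str, seq_number: int) -> int:
        try:
            return self.maps[seq_id][seq_number]
        except KeyError:
            raise KeyError(f"residue {seq_number} of {seq_id!r} is not in the alignment") from None

    def residue_at(self, seq_id: str, column: int) -> "int | None":
        for num, col in self.maps[seq_id].items():
            if col == column:
                return num
        return None


def _kctd_side(contact: ContactRecord, kctd_chains: set[str]) -> "tuple[str, int, str] | None":
    if contact.res_a[0] in kctd_chains:
        return contact.res_a
    if contact.res_b[0] in kctd_chains:
        return contact.res_b
    return None


def map_interface_to_alignment(
    contacts_by_complex: dict[str, list[ContactRecord]],
    alignment: MultipleSeqAlignment,
    construct_specs: dict[str, ConstructSpec],
    kctd_chains_by_complex: dict[str, set[str]],
) -> pd.DataFrame:
    """Project per-complex interface residues onto alignment columns.

    ``contacts_by_complex`` maps a complex id (also its alignment sequence
    id) to contact records whose interface field is set; the construct
    spec supplies the residue number of the alignment's first position.
    Returns a frame (complex, column, seq_number, category) with one row
    per annotated column and categories in {main_hbond, main_hydrophobic,
    main_both, minor_hbond}.  A contact residue outside the construct
    range raises, naming the residue — the usual symptom of an offset bug.
    """
    ids = {rec.id for rec in alignment}
    missing = set(contacts_by_complex) - ids
    if missing:
        raise KeyError(f"complex sequences not in alignment: {sorted(missing)}")
    starts = {cid: construct_specs[cid].start_res for cid in contacts_by_complex}
    colmap = AlignmentColumnMap.from_alignment(alignment, start_numbers=starts)

    rows = []
    for cid, contacts in contacts_by_complex.items():
        spec = construct_specs[cid]
        kinds_per_res: dict[int, set[tuple[str, str]]] = {}
        for c in contacts:
            side = _kctd_side(c, kctd_chains_by_complex[cid])
            if side is None or c.interface == "none":
                continue
            resnum = side[1]
            if not (spec.start_res <= resnum <= spec.end_res):
                raise ValueError(
                    f"contact residue {side[0]}:{resnum} of {cid} lies outside "
                    f"construct {spec.start_res}-{spec.end_res}"
                )
            kinds_per_res.setdefault(resnum, set()).add((c.interface, c.kind))
        for resnum, kinds in sorted(kinds_per_res.items()):
            main_h = ("main", "hbond") in kinds or ("main", "salt_bridge") in kinds
            main_p = ("main", "hydrophobic") in kinds
            if main_h and main_p:
                category = "main_both"
            elif main_h:
                category = "main_hbond"
            elif main_p:
                category = "main_hydrophobic"
            elif ("minor", "hbond") in kinds or ("minor", "salt_bridge") in kinds:
                category = "minor_hbond"
            else:
                continue  # minor hydrophobic: recorded upstream, no display category
            rows.append(
                {
                    "complex": cid,
                    "column": colmap.column_of(cid, resnum),
                    "seq_number": resnum,
                    "category": category,
                }
            )
    return pd.DataFrame(rows, columns=["complex", "column", "seq_number", "category"])


def tally_cul3_conservation(
    summaries: dict[str, InterfaceSummary],
    exclude: tuple[str, ...] = DEFAULT_TALLY_EXCLUDE,
) -> pd.DataFrame:
    """Count, per scaffold residue, the complexes using it in each contact kind.

    ``summaries`` maps complex id -> interface summary (contacts labeled).
    H-bonds and salt bridges pool into the H-bond tally.  Sorted by
    descending H-bond count, then hydrophobic count.
    """
    if not summaries:
        raise ValueError("at least one interface summary required")
    per_res: dict[int, dict[str, set[str]]] = {}
    aa_of: dict[int, str] = {}
    for cid, summary in summaries.items():
        if cid in exclude or any(cid.startswith(e) for e in exclude):
            continue
        for c in summary.contacts:
            cul3_res = c.res_b if c.res_b[0] == summary.cul3_chain else c.res_a
            key = cul3_res[1]
            aa_of[key] = cul3_res[2]
            slot = per_res.setdefault(key, {"hbond": set(), "hydrophobic": set()})
            if c.kind in ("hbond", "salt_bridge"):
                slot["hbond"].add(cid)
            elif c.kind == "hydrophobic":
                slot["hydrophobic"].add(cid)
    rows = [
        {
            "cul3_residue": resnum,
            "aa3": aa_of[resnum],
            "n_complexes_hbond": len(slot["hbond"]),
            "n_complexes_hydrophobic": len(slot["hydrophobic"]),
            "complexes": ";".join(sorted(slot["hbond"] | slot["hydrophobic"])),
        }
        for resnum, slot in per_res.items()
    ]
    df = pd.DataFrame(
        rows,
        columns=["cul3_residue", "aa3", "n_complexes_hbond",
                 "n_complexes_hydrophobic", "complexes"],
    )
    return df.sort_values(
        ["n_complexes_hbond", "n_complexes_hydrophobic", "cul3_residue"],
        ascending=[False, False, True],
    ).reset_index(drop=True)


def loop_diagnostics(
    alignment: MultipleSeqAlignment,
    segment_annotations: dict[str, list[SegmentAnnotation]],
    binder_labels: "dict[str, bool] | None" = None,
    reference: str = "KCTD2",
    start_numbers: "dict[str, int] | None" = None,
) -> pd.DataFrame:
    """Per-protein diagnostics of the alpha2-beta3 binding loop.

    Long insertions in this loop, secondary structure inside it, or a
    rigidifying proline are the structural signatures that distinguish
    non-binders.  Reports ungapped loop length, insertion length relative
    to the reference protein, proline count, and a helix-in-loop flag when
    the annotations provide secondary structure inside the loop range.
    Proteins lacking the loop annotation are flagged incomplete, not
    dropped.
    """
    seqs = {rec.id: str(rec.seq) for rec in alignment}
    if reference not in seqs:
        raise KeyError(f"reference protein {reference!r} not in alignment")
    colmap = AlignmentColumnMap.from_alignment(alignment, start_numbers=start_numbers)

    def _loop_residues(pid: str) -> "list[int] | None":
        segs = segment_annotations.get(pid, [])
        loop = next((s for s in segs if s.label == "α2β3_loop"), None)
        if loop is None:
            return None
        return [n for n in colmap.maps[pid] if loop.start_res <= n <= loop.end_res]

    ref_loop = _loop_residues(reference)
    ref_len = len(ref_loop) if ref_loop is not None else None

    rows = []
    for pid in seqs:
        loop_res = _loop_residues(pid)
        if loop_res is None:
            rows.append(
                {"protein": pid, "binder": (binder_labels or {}).get(pid),
                 "loop_length": None, "insertion_vs_reference": None,
                 "proline_count": None, "helix_in_loop": None, "incomplete": True}
            )
            continue
        cols = [colmap.column_of(pid, n) for n in loop_res]
        seq = seqs[pid]
        prolines = sum(1 for c in cols if seq[c].upper() == "P")
        helix = any(
            s.label in ("α1", "α2", "α3", "α4", "α5", "helix")
            and any(s.start_res <= n <= s.end_res for n in loop_res)
            for s in segment_annotations.get(pid, [])
            if s.label != "α2β3_loop"
        )
        rows.append(
            {
                "protein": pid,
                "binder": (binder_labels or {}).get(pid),
                "loop_length": len(loop_res),
                "insertion_vs_reference": (len(loop_res) - ref_len) if ref_len is not None else None,
                "proline_count": prolines,
                "helix_in_loop": helix,
                "incomplete": False,
            }
        )
    return pd.DataFrame(rows)


def read_segment_annotations(path: "str | Path") -> dict[str, list[SegmentAnnotation]]:
    """Read BED-like TSV segment annotations: protein, label, start, end
    (1-based inclusive), '#' comments allowed."""
    out: dict[str, list[SegmentAnnotation]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}, line {lineno}: expected 4 tab-separated fields")
            protein, label, start, end = parts
            out.setdefault(protein, []).append(
                SegmentAnnotation(protein, label, int(start), int(end))
            )
    return out
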