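"""MD-trajectory statistics: RMSD time series, plateau detection, RMSF,
and named atom-pair distance traces.

Input is a multi-model PDB (every MD engine can export one), carried as a
frame stack over a fixed topology.  All statistics that require
superposition use the Kabsch fit from :mod:`btbcul3.geometry`, so they are
invariant under a global rigid transform applied to every frame.

The equilibration diagnostic formalizes "a stable plateau within X
Angstrom" as a sliding-window range criterion: the plateau onset is the
earliest time after which every window of the requested span has
max - min <= tol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import kabsch_superpose
from .structure_io import StructureModel, read_all_models, read_structure

__all__ = [
    "TrajectoryEnsemble",
    "TrajectoryStats",
    "read_trajectory",
    "rmsd_timeseries",
    "rmsf",
    "pair_distance_series",
    "plateau_detect",
    "parse_pair_spec",
]


@dataclass
class TrajectoryEnsemble:
    """A frame stack (n_frames, n_atoms, 3) over a fixed topology."""

    topology: StructureModel
    frames: np.ndarray
    times: np.ndarray  # ns, strictly increasing
    selections: dict[str, np.ndarray]  # name -> atom index array

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        n_top = self.topology.n_atoms()
        if self.frames.ndim != 3 or self.frames.shape[1] != n_top or self.frames.shape[2] != 3:
            raise ValueError(
                f"frames must be (n_frames, {n_top}, 3); got {self.frames.shape}"
            )
        if len(self.times) != len(self.frames):
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    # -- selections ----------------------------------------------------------

    def atom_index(
        self,
        chain_ids: "list[str] | None" = None,
        atom_names: "tuple[str, ...] | None" = None,
    ) -> np.ndarray:
        idx = []
        for i, (res, atom) in enumerate(self.topology.iter_atoms()):
            if chain_ids is not None and res.chain_id not in chain_ids:
                continue
            if atom_names is not None and atom.name not in atom_names:
                continue
            idx.append(i)
        return np.array(idx, dtype=int)

    def selection(self, name_or_index: "str | np.ndarray | None") -> np.ndarray:
        if name_or_index is None:
            return np.arange(self.frames.shape[1])
        if isinstance(name_or_index, str):
            if name_or_index == "backbone":
                return self.atom_index(atom_names=("N", "CA", "C", "O"))
            if name_or_index == "CA":
                return self.atom_index(atom_names=("CA",))
            if name_or_index in self.selections:
                return np.asarray(self.selections[name_or_index], dtype=int)
            if name_or_index in self.topology.chains:
                return self.atom_index(chain_ids=[name_or_index])
            raise KeyError(f"unknown selection {name_or_index!r}")
        sel = np.asarray(name_or_index, dtype=int)
        if sel.size == 0:
            raise ValueError("empty atom selection")
        return sel


def read_trajectory(
    topology_path: "str | Path",
    frames_path: "str | Path",
    dt: "float | None" = None,
    times: "np.ndarray | None" = None,
    source: str = "predicted",
) -> TrajectoryEnsemble:
    """Load a multi-model PDB trajectory against a topology.

    Times come from an explicit per-frame array or uniform spacing ``dt``
    (ns); default is a 1-ns grid.  Every MODEL block must carry the same
    atom inventory as the topology; a mismatch reports the frame index.
    """
    topology = read_structure(topology_path, source=source)
    models = read_all_models(frames_path, source=source)
    n_top = topology.n_atoms()
    frames = np.empty((len(models), n_top, 3))
    for k, m in enumerate(models):
        n_k = m.n_atoms()
        if n_k != n_top:
            raise ValueError(
                f"frame {k} has {n_k} atoms but the topology has {n_top}"
            )
        frames[k] = m.coords()
    if times is None:
        step = dt if dt is not None else 1.0
        times = np.arange(len(models)) * step
    times = np.asarray(times, dtype=float)
    return TrajectoryEnsemble(topology=topology, frames=frames, times=times, selections={})


@dataclass
class TrajectoryStats:
    """Bundle of the per-trajectory statistics (see module docstring)."""

    rmsd_series: dict[str, pd.Series]
    rmsf: "pd.Series | None" = None
    plateau_time: "float | None" = None
    pair_distances: "pd.DataFrame | None" = None


def _fit_frames(
    frames: np.ndarray, reference: np.ndarray, fit_idx: np.ndarray
) -> np.ndarray:
    """Kabsch-fit every frame to the reference on ``fit_idx`` atoms."""
    out = np.empty_like(frames)
    ref = reference[fit_idx]
    for k in range(len(frames)):
        sup = kabsch_superpose(frames[k][fit_idx], ref)
        out[k] = sup.apply(frames[k])
    return out


def rmsd_timeseries(
    traj: TrajectoryEnsemble,
    fit_selection: "str | np.ndarray | None" = None,
    measure_selection: "str | np.ndarray | None" = None,
    reference: "int | StructureModel" = 0,
) -> pd.Series:
    """Per-frame RMSD after Kabsch fitting.

    Each frame is superposed onto the reference (frame index or external
    model with the same atom inventory) using ``fit_selection``, and RMSD
    is then measured on ``measure_selection``.  Fitting and measuring on
    different selections supports per-domain dissection: fit on the whole
    complex to see a domain move, or fit on the domain itself to see its
    internal deformation.
    """
    fit_idx = traj.selection(fit_selection)
    measure_idx = traj.selection(measure_selection)
    if fit_idx.size == 0 or measure_idx.size == 0:
        raise ValueError("selections must be non-empty")
    if isinstance(reference, StructureModel):
        ref = reference.coords()
        if ref.shape != traj.frames.shape[1:]:
            raise ValueError("reference model atom count differs from trajectory")
    else:
        ref = traj.frames[int(reference)]
    fitted = _fit_frames(traj.frames, ref, fit_idx)
    diff = fitted[:, measure_idx, :] - ref[measure_idx]
    values = np.sqrt((diff ** 2).sum(axis=2).mean(axis=1))
    return pd.Series(values, index=pd.Index(traj.times, name="time_ns"), name="rmsd_A")


def rmsf(
    traj: TrajectoryEnsemble,
    selection: "str | np.ndarray | None" = None,
    window: "tuple[float, float] | None" = None,
) -> pd.Series:
    """Per-residue RMSF of the CA atom over an equilibrated time window.

    Frames in the window are superposed to their mean structure (two
    iterations of mean-fitting), then RMSF is the RMS deviation of each
    residue's CA from its mean position.  Indexed by (chain, seq_number).
    """
    if window is None:
        mask = np.ones(traj.n_frames, dtype=bool)
    else:
        t0, t1 = window
        if t0 > traj.times[-1] or t1 < traj.times[0]:
            raise ValueError(f"window {window} outside trajectory time range")
        mask = (traj.times >= t0) & (traj.times <= t1)
    if mask.sum() < 10:
        raise ValueError(f"RMSF window holds {int(mask.sum())} frames; need >= 10")
    sel = traj.selection(selection)
    ca_idx, labels = [], []
    pos = 0
    for res in traj.topology.residues():
        for atom in res.atoms:
            if atom.name == "CA" and pos in sel:
                ca_idx.append(pos)
                labels.append((res.chain_id, res.seq_number))
            pos += 1
    if not ca_idx:
        # fall back to every selected atom when the topology has no CA
        ca_idx = list(sel)
        labels = [("", i) for i in sel]
    frames = traj.frames[mask]
    fit_idx = np.asarray(ca_idx, dtype=int)
    mean = frames.mean(axis=0)
    for _ in range(2):
        frames = _fit_frames(frames, mean, fit_idx)
        mean = frames.mean(axis=0)
    disp = frames[:, fit_idx, :] - mean[fit_idx]
    values = np.sqrt((disp ** 2).sum(axis=2).mean(axis=0))
    index = pd.MultiIndex.from_tuples(labels, names=["chain", "seq_number"])
    return pd.Series(values, index=index, name="rmsf_A")


_PAIR_RE = re.compile(r"^([^:]+):(-?\d+):([A-Za-z0-9']+)$")


def parse_pair_spec(spec: str) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
    """Parse ``"A:84:NH2-B:121:OD2"`` into two (chain, resnum, atom) triples."""
    halves = spec.split("-")
    if len(halves) != 2:
        raise ValueError(f"pair spec {spec!r} must be 'chain:res:atom-chain:res:atom'")
    out = []
    for half in halves:
        m = _PAIR_RE.match(half.strip())
        if not m:
            raise ValueError(f"cannot parse atom spec {half!r}")
        out.append((m.group(1), int(m.group(2)), m.group(3)))
    return out[0], out[1]


def _resolve_atom(traj: TrajectoryEnsemble, ref: tuple[str, int, str]) -> int:
    chain, resnum, atom_name = ref
    pos = 0
    for res in traj.topology.residues():
        for atom in res.atoms:
            if res.chain_id == chain and res.seq_number == resnum and atom.name == atom_name:
                return pos
            pos += 1
    raise KeyError(f"atom {chain}:{resnum}:{atom_name} not found in topology")


def pair_distance_series(
    traj: TrajectoryEnsemble,
    pairs: "list[str | tuple]",
) -> pd.DataFrame:
    """Euclidean distance per frame for named atom pairs (no fitting).

    Pairs are mini-language strings (``"A:84:NH2-B:121:OD2"``) or pairs of
    (chain, resnum, atom) triples.  Column names echo the spec.
    """
    columns = {}
    for p in pairs:
        if isinstance(p, str):
            a, b = parse_pair_spec(p)
            name = p
        else:
            a, b = p
            name = f"{a[0]}:{a[1]}:{a[2]}-{b[0]}:{b[1]}:{b[2]}"
        if a == b:
            raise ValueError(f"pair {name!r} names the same atom twice")
        ia, ib = _resolve_atom(traj, a), _resolve_atom(traj, b)
        d = np.linalg.norm(traj.frames[:, ia, :] - traj.frames[:, ib, :], axis=1)
        columns[name] = d
    return pd.DataFrame(columns, index=pd.Index(traj.times, name="time_ns"))


def plateau_detect(
    series: pd.Series,
    window_span: float = 10.0,
    tol: float = 1.0,
) -> "float | None":
    """Earliest plateau onset of a time series.

    Returns the earliest time ``t`` such that within every sliding window
    of span ``window_span`` starting at or after ``t``, max - min of the
    series is <= ``tol``; ``None`` if no such time exists.  The series
    (indexed by time) must cover at least twice the window span.
    """
    times = np.asarray(series.index, dtype=float)
    values = np.asarray(series, dtype=float)
    total = times[-1] - times[0]
    if total < 2 * window_span:
        raise ValueError(
            f"series spans {total} but plateau detection needs >= {2 * window_span}"
        )
    starts = [i for i, t in enumerate(times) if t + window_span <= times[-1] + 1e-12]
    ok = np.empty(len(starts), dtype=bool)
    for w, i in enumerate(starts):
        j = np.searchsorted(times, times[i] + window_span, side="right")
        seg = values[i:j]
        ok[w] = (seg.max() - seg.min()) <= tol
    # earliest start index from which every subsequent window passes
    onset = None
    for w in range(len(starts) - 1, -1, -1):
        if not ok[w]:
            break
        onset = times[starts[w]]
    return onset
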