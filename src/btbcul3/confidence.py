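"""Stability classification of predicted complexes from confidence data.

A predicted assembly comes with a per-residue confidence vector (pLDDT,
0-100) and a predicted-aligned-error matrix (PAE, Angstrom): entry (i, j)
is the expected positional error of residue j when the prediction is
aligned on residue i.  Low inter-chain PAE blocks mean the predictor is
confident about the relative placement of the two chains — the signature
of a real interface — while non-binders show saturated (~25-30 A)
cross-blocks.

The visual "red vs. blue cross-block" judgment is made reproducible here
as a two-threshold rule on the size-weighted mean of the adaptor-scaffold
cross-blocks, with an ambiguous band in between and a pLDDT gate on the
stable side (defaults: stable <= 10 A and pLDDT >= 70; no-stable >= 20 A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import AssemblySpec, StructureModel

__all__ = [
    "ConfidenceBundle",
    "ClassifierThresholds",
    "StabilityCall",
    "interchain_pae_blocks",
    "classify_complex",
    "stability_report",
    "VERDICT_STRINGS",
]

VERDICT_STRINGS = {
    "stable": "Stable complex detected",
    "no_stable": "No stable complex detected",
    "ambiguous": "Ambiguous prediction",
}


@dataclass
class ConfidenceBundle:
    """pLDDT vector + PAE matrix + the chain partition of the residue axis."""

    plddt: np.ndarray  # (N,)
    pae: np.ndarray  # (N, N); directional, symmetry not assumed
    partition: list[tuple[str, tuple[int, int]]]  # chain -> half-open span [start, stop)
    assembly: AssemblySpec

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.pae = np.asarray(self.pae, dtype=float)
        n = self.pae.shape[0]
        if self.pae.ndim != 2 or self.pae.shape != (n, n):
            raise ValueError("PAE must be a square matrix")
        if np.any(self.pae < 0):
            raise ValueError("PAE entries must be >= 0")
        if self.plddt.shape != (n,):
            raise ValueError("pLDDT length must match the PAE axis")
        if np.any((self.plddt < 0) | (self.plddt > 100)):
            raise ValueError("pLDDT values must lie in [0, 100]")
        spans = sorted(s for _, s in self.partition)
        covered = sum(stop - start for start, stop in spans)
        if covered != n or any(
            spans[i][1] != spans[i + 1][0] for i in range(len(spans) - 1)
        ) or (spans and (spans[0][0] != 0 or spans[-1][1] != n)):
            raise ValueError("partition spans must tile the residue axis exactly")

    def span(self, chain_id: str) -> tuple[int, int]:
        for cid, s in self.partition:
            if cid == chain_id:
                return s
        raise KeyError(f"chain {chain_id!r} not in partition")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds for the stable / no-stable call."""

    stable_pae_max: float = 10.0  # A; cross-block mean at or below => candidate stable
    unstable_pae_min: float = 20.0  # A; cross-block mean at or above => no stable complex
    plddt_min: float = 70.0  # interface pLDDT gate for the stable verdict
    interface_distance: float = 8.0  # A; CA-CA radius defining interface residues

    def __post_init__(self) -> None:
        if self.stable_pae_max > self.unstable_pae_min:
            raise ValueError(
                f"inverted thresholds: stable_pae_max {self.stable_pae_max} > "
                f"unstable_pae_min {self.unstable_pae_min}"
            )


@dataclass
class StabilityCall:
    """Outcome of the decision rule, with the statistics that forced it."""

    verdict: str  # stable | no_stable | ambiguous
    interchain_pae_mean: float
    interchain_pae_min_block: float
    interface_plddt_mean: float
    per_pair_scores: pd.DataFrame
    flags: list[str] = field(default_factory=list)

    @property
    def verdict_string(self) -> str:
        return VERDICT_STRINGS[self.verdict]


def interchain_pae_blocks(bundle: ConfidenceBundle) -> pd.DataFrame:
    """Statistics of every adaptor x scaffold PAE cross-block.

    For each (kctd_chain, cul3_chain) pair the two directional blocks
    (kctd rows x cul3 columns and vice versa) are pooled.  Returns a frame
    indexed by (kctd_chain, cul3_chain) with mean / median / min / n; the
    size-weighted global mean equals ``np.average(mean, weights=n)``.
    """
    asm = bundle.assembly
    if not asm.kctd_chain_ids or not asm.cul3_chain_ids:
        raise ValueError("assembly must name at least one chain of each role")
    rows = []
    for k in asm.kctd_chain_ids:
        ks, ke = bundle.span(k)
        for c in asm.cul3_chain_ids:
            cs, ce = bundle.span(c)
            block = np.concatenate(
                [bundle.pae[ks:ke, cs:ce].ravel(), bundle.pae[cs:ce, ks:ke].ravel()]
            )
            rows.append(
                {
                    "kctd_chain": k,
                    "cul3_chain": c,
                    "mean": float(block.mean()),
                    "median": float(np.median(block)),
                    "min": float(block.min()),
                    "n": int(block.size),
                }
            )
    return pd.DataFrame(rows).set_index(["kctd_chain", "cul3_chain"])


def _interface_plddt(
    bundle: ConfidenceBundle, model: StructureModel, cutoff: float
) -> float:
    """Mean pLDDT over residues whose CA lies within ``cutoff`` of the partner."""
    asm = bundle.assembly

    def _ca(chain_ids: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
        pts, idx = [], []
        for cid in chain_ids:
            start, _ = bundle.span(cid)
            for offset, res in enumerate(model.chains[cid]):
                pts.append(res.representative_atom.coords)
                idx.append(start + offset)
        return np.array(pts), np.array(idx)

    kctd_xyz, kctd_idx = _ca(asm.kctd_chain_ids)
    cul3_xyz, cul3_idx = _ca(asm.cul3_chain_ids)
    tree_k, tree_c = cKDTree(kctd_xyz), cKDTree(cul3_xyz)
    near_k = np.array([len(x) > 0 for x in tree_c.query_ball_point(kctd_xyz, cutoff)])
    near_c = np.array([len(x) > 0 for x in tree_k.query_ball_point(cul3_xyz, cutoff)])
    sel = np.concatenate([kctd_idx[near_k], cul3_idx[near_c]])
    if sel.size == 0:
        return float(bundle.plddt.mean())
    return float(bundle.plddt[sel].mean())


def classify_complex(
    bundle: ConfidenceBundle,
    thresholds: "ClassifierThresholds | None" = None,
    model: "StructureModel | None" = None,
    flags: "list[str] | None" = None,
    include_intersubunit: bool = False,
) -> StabilityCall:
    """Apply the two-threshold stable / no-stable decision rule.

    * stable: global cross-block PAE mean <= ``stable_pae_max`` and
      interface pLDDT mean >= ``plddt_min``;
    * no_stable: global cross-block PAE mean >= ``unstable_pae_min``;
    * ambiguous otherwise.

    Interface pLDDT is computed over residues within
    ``thresholds.interface_distance`` of the partner when coordinates are
    supplied, else over all residues.  ``include_intersubunit`` adds a
    kctd-kctd cross-block statistic to the flags for loose oligomers; it
    never changes the verdict.
    """
    thr = thresholds or ClassifierThresholds()
    blocks = interchain_pae_blocks(bundle)
    pae_mean = float(np.average(blocks["mean"], weights=blocks["n"]))
    pae_min_block = float(blocks["mean"].min())
    if model is not None:
        plddt_mean = _interface_plddt(bundle, model, thr.interface_distance)
    else:
        plddt_mean = float(bundle.plddt.mean())

    out_flags = list(flags or [])
    if include_intersubunit and len(bundle.assembly.kctd_chain_ids) > 1:
        kids = bundle.assembly.kctd_chain_ids
        vals = []
        for i, a in enumerate(kids):
            sa = bundle.span(a)
            for b in kids[i + 1:]:
                sb = bundle.span(b)
                vals.append(bundle.pae[sa[0]:sa[1], sb[0]:sb[1]].mean())
                vals.append(bundle.pae[sb[0]:sb[1], sa[0]:sa[1]].mean())
        out_flags.append(f"intersubunit_pae_mean={np.mean(vals):.2f}")

    if pae_mean >= thr.unstable_pae_min:
        verdict = "no_stable"
    elif pae_mean <= thr.stable_pae_max and plddt_mean >= thr.plddt_min:
        verdict = "stable"
    else:
        verdict = "ambiguous"
    return StabilityCall(
        verdict=verdict,
        interchain_pae_mean=pae_mean,
        interchain_pae_min_block=pae_min_block,
        interface_plddt_mean=plddt_mean,
        per_pair_scores=blocks,
        flags=out_flags,
    )


def stability_report(
    calls: list[StabilityCall],
    metadata: "list[dict] | None" = None,
) -> pd.DataFrame:
    """One row per complex: cluster, construct, stoichiometry, verdict, scores.

    ``metadata`` rows (aligned with ``calls``) may carry ``cluster``,
    ``complex`` and ``stoichiometry`` keys.  The frame serializes to TSV via
    ``df.to_csv(sep="\\t", index=False)``.
    """
    metadata = metadata or [{}] * len(calls)
    if len(metadata) != len(calls):
        raise ValueError("metadata length must match calls")
    rows = []
    for call, meta in zip(calls, metadata):
        rows.append(
            {
                "cluster": meta.get("cluster", ""),
                "complex": meta.get("complex", ""),
                "stoichiometry": meta.get("stoichiometry", ""),
                "verdict": call.verdict_string,
                "pae_mean": round(call.interchain_pae_mean, 3),
                "pae_min_block": round(call.interchain_pae_min_block, 3),
                "plddt_mean": round(call.interface_plddt_mean, 2),
                "flags": ";".join(call.flags),
            }
        )
    columns = [
        "cluster", "complex", "stoichiometry", "verdict",
        "pae_mean", "pae_min_block", "plddt_mean", "flags",
    ]
    return pd.DataFrame(rows, columns=columns)
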