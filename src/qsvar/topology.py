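"""Quaternary-structure topology classes from pairwise interface overlap.

Two homomers with the same subunit count share a topology when the overlap of
their interfaces — the fraction of the smaller interface whose residues are
structurally aligned onto the other interface — is at least 0.5.  Topology
classes within a subunit-count stratum are the single-linkage connected
components of that relation; a monomer is its own singleton topology.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import pandas as pd

OVERLAP_THRESHOLD = 0.5

Residue = tuple[str, int]  # (chain_id, residue_index)


@dataclass
class AlignmentMap:
    """One-to-one structurally aligned residue pairs between two proteins."""

    protein_a: str
    protein_b: str
    pairs: list[tuple[Residue, Residue]]

    def __post_init__(self) -> None:
        seen_a: set[Residue] = set()
        seen_b: set[Residue] = set()
        for ra, rb in self.pairs:
            if ra in seen_a or rb in seen_b:
                raise ValueError(f"alignment is not one-to-one at {ra} / {rb}")
            seen_a.add(ra)
            seen_b.add(rb)

    def reversed(self) -> "AlignmentMap":
        return AlignmentMap(
            self.protein_b, self.protein_a, [(rb, ra) for ra, rb in self.pairs]
        )


def read_alignment_maps(path) -> list[AlignmentMap]:
    """Read alignment maps from a TSV (protein_a, chain_a, resid_a, protein_b, chain_b, resid_b)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str,
                                            "chain_a": str, "chain_b": str})
    maps = []
    for (pa, pb), grp in df.groupby(["protein_a", "protein_b"], sort=True):
        pairs = [
            ((str(r.chain_a), int(r.resid_a)), (str(r.chain_b), int(r.resid_b)))
            for r in grp.itertuples()
        ]
        maps.append(AlignmentMap(str(pa), str(pb), pairs))
    return maps


def write_alignment_maps(maps: list[AlignmentMap], path) -> None:
    rows = [
        {"protein_a": m.protein_a, "chain_a": ra[0], "resid_a": ra[1],
         "protein_b": m.protein_b, "chain_b": rb[0], "resid_b": rb[1]}
        for m in maps
        for ra, rb in m.pairs
    ]
    pd.DataFrame(
        rows, columns=["protein_a", "chain_a", "resid_a", "protein_b", "chain_b", "resid_b"]
    ).to_csv(path, sep="\t", index=False)


def parse_tmalign(text: str, protein_a: str, protein_b: str,
                  chain_a: str = "A", chain_b: str = "A") -> AlignmentMap:
    """Build an AlignmentMap from TM-align's plain-text pairwise alignment block.

    Convenience reader for the three-line alignment at the end of TM-align's
    main output (sequence A / match line / sequence B).  Residues are numbered
    sequentially from 1 per chain; columns whose match character is ':' or '.'
    (structurally aligned) become pairs.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    block = None
    for i in range(len(lines) - 2):
        a, m, b = lines[i], lines[i + 1], lines[i + 2]
        if (re.fullmatch(r"[A-Za-z\-]+", a.strip()) and re.fullmatch(r"[A-Za-z\-]+", b.strip())
                and set(m.strip()) <= {":", ".", " "} and m.strip()):
            block = (a.rstrip("\n"), m, b.rstrip("\n"))
            break
    if block is None:
        raise ValueError("no TM-align alignment block found")
    seq_a, match, seq_b = block
    pairs: list[tuple[Residue, Residue]] = []
    ia = ib = 0
    for col in range(max(len(seq_a), len(seq_b))):
        ca = seq_a[col] if col < len(seq_a) else "-"
        cb = seq_b[col] if col < len(seq_b) else "-"
        cm = match[col] if col < len(match) else " "
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
        if ca != "-" and cb != "-" and cm in (":", "."):
            pairs.append(((chain_a, ia), (chain_b, ib)))
    return AlignmentMap(protein_a, protein_b, pairs)


def interface_overlap(
    amap: AlignmentMap, iface_a: set[Residue], iface_b: set[Residue]
) -> float:
    """Aligned interface–interface pairs over the size of the smaller interface.

    Symmetric in (a, b); NaN when either interface is empty (undefined).
    """
    if not iface_a or not iface_b:
        return math.nan
    n_aligned = sum(1 for ra, rb in amap.pairs if ra in iface_a and rb in iface_b)
    return n_aligned / min(len(iface_a), len(iface_b))


def same_topology(
    n_subunits_a: int,
    n_subunits_b: int,
    overlap: float,
    threshold: float = OVERLAP_THRESHOLD,
    missing_as_same: bool = False,
) -> bool:
    """Equal subunit counts and interface overlap at or above the threshold.

    Structures with the same subunit count but overlap below 0.5 are
    topologically different.  A missing overlap (NaN) between equal-count
    structures is conservatively treated as different unless
    ``missing_as_same`` is set.
    """
    if n_subunits_a != n_subunits_b:
        return False
    if overlap is None or (isinstance(overlap, float) and math.isnan(overlap)):
        return missing_as_same
    return overlap >= threshold


def assign_topologies(
    structures: list[tuple[str, int]],
    overlaps: dict[tuple[str, str], float],
    threshold: float = OVERLAP_THRESHOLD,
    missing_as_same: bool = False,
) -> dict[str, str]:
    """Partition structures into topology classes.

    Within each subunit-count stratum, classes are the single-linkage
    connected components of the graph whose edges join pairs with overlap at
    or above the threshold.  The class id is "<n_subunits>:<smallest member
    id>", so the labelling is deterministic and order-independent.  Overlaps
    may be given under either key order.
    """
    parent: dict[str, str] = {sid: sid for sid, _ in structures}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            # keep the lexicographically smaller id as the root
            if ry < rx:
                rx, ry = ry, rx
            parent[ry] = rx

    count_of = dict(structures)
    ids = sorted(count_of)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if count_of[a] != count_of[b]:
                continue
            if count_of[a] == 1:
                # monomers have no interface: all share the one monomer topology
                union(a, b)
                continue
            ov = overlaps.get((a, b), overlaps.get((b, a), math.nan))
            if same_topology(count_of[a], count_of[b], ov, threshold, missing_as_same):
                union(a, b)

    return {sid: f"{count_of[sid]}:{find(sid)}" for sid in count_of}


def qs_per_protein(
    entries: list[tuple[str, int]],
    overlaps: dict[tuple[str, str], float],
    threshold: float = OVERLAP_THRESHOLD,
    missing_as_same: bool = False,
) -> int:
    """Number of distinct QS topologies among one protein's PDB entries.

    Entries with different subunit counts are always different QSs; entries
    with the same count but interface overlap below the threshold are also
    counted as different.
    """
    if not entries:
        raise ValueError("at least one entry required")
    classes = assign_topologies(entries, overlaps, threshold, missing_as_same)
    return len(set(classes.values()))
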