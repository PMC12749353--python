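"""Interface and surface residue classification from solvent accessibility.

A residue belongs to a homomer interface when it is solvent-exposed in the
isolated (monomeric) subunit — relative solvent accessibility (RSA) of at
least 0.2 against the residue type's theoretical maximum area — and loses at
least 10% of that accessibility upon complex formation.  Residues that are
exposed but not buried by oligomerisation are surface; everything else is
buried.  The per-subunit interface area is the total accessible area lost on
assembly divided by the number of subunits.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import pandas as pd

#: default classification thresholds
RSA_THRESHOLD = 0.2
BURIAL_THRESHOLD = 0.10

SASA_COLUMNS = [
    "protein_id",
    "chain_id",
    "residue_index",
    "residue_type",
    "sasa_complex",
    "sasa_monomer",
]


def load_max_areas() -> dict[str, float]:
    """Packaged theoretical maximum accessible areas (Å²) per residue type.

    Values are the theoretical maximum allowed solvent accessibilities of
    Tien et al. (2013), the standard denominators for RSA.
    """
    ref = importlib.resources.files("qsvar.data") / "max_areas.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    areas = dict(zip(df["residue_type"], df["max_area"].astype(float)))
    if len(areas) != 20 or any(v <= 0 for v in areas.values()):
        raise ValueError("packaged max-area table is malformed")
    return areas


def compute_rsa(sasa: float, residue_type: str, max_areas: dict[str, float]) -> float:
    """Relative solvent accessibility: SASA / theoretical maximum area.

    Not clamped at 1; values slightly above 1 occur for extended conformations.
    """
    if sasa < 0:
        raise ValueError(f"negative SASA ({sasa}) for residue type {residue_type!r}")
    try:
        max_area = max_areas[residue_type]
    except KeyError:
        raise KeyError(
            f"unknown residue type {residue_type!r}: no maximum area available"
        ) from None
    return sasa / max_area


def read_sasa_table(path) -> pd.DataFrame:
    """Read a headered per-residue SASA TSV (complex and monomer columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "chain_id": str})
    missing = [c for c in SASA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SASA table {path} lacks columns: {missing}")
    return df


def write_sasa_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=SASA_COLUMNS)


def classify_residues(
    table: pd.DataFrame,
    max_areas: dict[str, float] | None = None,
    rsa_threshold: float = RSA_THRESHOLD,
    burial_threshold: float = BURIAL_THRESHOLD,
    rsa_context: str = "monomer",
    fallback_max_area: float | None = None,
) -> pd.DataFrame:
    """Label every residue interface / surface / buried.

    Parameters
    ----------
    table
        Per-residue SASA rows (see :data:`SASA_COLUMNS`).
    rsa_context
        Which SASA feeds the exposure gate: ``"monomer"`` (default — a residue
        buried by oligomerisation keeps its pre-assembly exposure and can pass
        the gate) or ``"complex"``.

    Returns a copy of ``table`` with ``rsa``, ``burial_fraction`` and ``label``
    columns.  Nonstandard residue types are rejected with an error unless
    ``fallback_max_area`` supplies a denominator for them.
    Rules, with boundary semantics: interface iff rsa >= rsa_threshold
    and burial_fraction >= burial_threshold; surface iff not interface and
    rsa > rsa_threshold; otherwise buried.  Burial is relative to the monomer
    SASA; negative burial (numerical noise) counts as zero, and residues with
    zero monomer SASA are never interface.
    """
    if table is None or len(table) == 0:
        raise ValueError("empty SASA table")
    if rsa_context not in ("monomer", "complex"):
        raise ValueError(f"rsa_context must be 'monomer' or 'complex', got {rsa_context!r}")
    if max_areas is None:
        max_areas = load_max_areas()

    out = table.copy()
    if (out["sasa_complex"] < 0).any() or (out["sasa_monomer"] < 0).any():
        bad = out[(out["sasa_complex"] < 0) | (out["sasa_monomer"] < 0)]
        raise ValueError(f"negative SASA values for residues: {bad['residue_index'].tolist()}")

    unknown = set(out["residue_type"]) - set(max_areas)
    if unknown and fallback_max_area is None:
        raise KeyError(f"unknown residue types with no maximum area: {sorted(unknown)}")

    max_col = out["residue_type"].map(max_areas)
    if fallback_max_area is not None:
        max_col = max_col.fillna(float(fallback_max_area))
    sasa_gate = out["sasa_monomer"] if rsa_context == "monomer" else out["sasa_complex"]
    rsa = sasa_gate / max_col

    burial = (out["sasa_monomer"] - out["sasa_complex"]).clip(lower=0.0)
    burial_fraction = burial.where(out["sasa_monomer"] > 0, 0.0) / out[
        "sasa_monomer"
    ].where(out["sasa_monomer"] > 0, 1.0)

    is_interface = (rsa >= rsa_threshold) & (burial_fraction >= burial_threshold) & (
        out["sasa_monomer"] > 0
    )
    is_surface = ~is_interface & (rsa > rsa_threshold)

    out["rsa"] = rsa
    out["burial_fraction"] = burial_fraction
    out["label"] = "buried"
    out.loc[is_surface, "label"] = "surface"
    out.loc[is_interface, "label"] = "interface"
    return out


def interface_area(
    total_sasa_monomers: float, total_sasa_complex: float, n_subunits: int
) -> float:
    """Per-subunit buried area: (ΣSASA_monomers − SASA_complex) / n_subunits."""
    if n_subunits < 1:
        raise ValueError(f"n_subunits must be >= 1, got {n_subunits}")
    if total_sasa_monomers < 0 or total_sasa_complex < 0:
        raise ValueError("SASA totals must be non-negative")
    return max(0.0, total_sasa_monomers - total_sasa_complex) / n_subunits


@dataclass
class InterfaceSummary:
    """Per-protein interface call: residue sets and per-subunit buried area."""

    protein_id: str
    n_subunits: int
    interface_area: float
    interface_residues: set[tuple[str, int]] = field(default_factory=set)
    surface_residues: set[tuple[str, int]] = field(default_factory=set)


def summarize_interface(
    table: pd.DataFrame,
    n_subunits: int,
    max_areas: dict[str, float] | None = None,
    **classify_kwargs,
) -> InterfaceSummary:
    """Classify residues and aggregate into an :class:`InterfaceSummary`.

    The SASA table lists the residues of one representative subunit; the
    monomer total is scaled by the subunit count in the area formula.  A
    monomer (n_subunits == 1) has, by definition, no interface.
    """
    cls = classify_residues(table, max_areas=max_areas, **classify_kwargs)
    protein_id = str(cls["protein_id"].iloc[0])
    if n_subunits == 1:
        surface = set(
            zip(cls.loc[cls["label"] != "buried", "chain_id"],
                cls.loc[cls["label"] != "buried", "residue_index"])
        )
        return InterfaceSummary(protein_id, 1, 0.0, set(), surface)
    area = interface_area(
        n_subunits * float(cls["sasa_monomer"].sum()),
        n_subunits * float(cls["sasa_complex"].sum()),
        n_subunits,
    )
    iface = set(
        zip(cls.loc[cls["label"] == "interface", "chain_id"],
            cls.loc[cls["label"] == "interface", "residue_index"])
    )
    surf = set(
        zip(cls.loc[cls["label"] == "surface", "chain_id"],
            cls.loc[cls["label"] == "surface", "residue_index"])
    )
    return InterfaceSummary(protein_id, n_subunits, area, iface, surf)


def conservation_difference(
    classification: pd.DataFrame,
    per_residue_conservation: dict[tuple[str, int], float],
) -> float:
    """Mean conservation of interface residues minus that of surface residues.

    Returns NaN when either residue set is empty (the quantity is undefined);
    conservation scores must cover every interface and surface residue.
    """
    scores = {"interface": [], "surface": []}
    for _, row in classification.iterrows():
        label = row["label"]
        if label in scores:
            key = (row["chain_id"], row["residue_index"])
            if key not in per_residue_conservation:
                raise KeyError(f"no conservation score for residue {key}")
            scores[label].append(per_residue_conservation[key])
    if not scores["interface"] or not scores["surface"]:
        return math.nan
    return sum(scores["interface"]) / len(scores["interface"]) - sum(
        scores["surface"]
    ) / len(scores["surface"])
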