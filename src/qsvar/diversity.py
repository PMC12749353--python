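"""Orthogroup-level quaternary-structure variability metrics.

Four summaries per orthogroup, each over one representative structure per
protein (the last one also uses every PDB entry of a protein):

1. average number of subunits (monomers included);
2. QS diversity — the number of distinct QS topologies;
3. Shannon index, −Σ p_i ln p_i over topology-class frequencies;
4. average number of distinct QSs per protein across its PDB entries.

Group comparisons use orthogroups with at least three proteins; the metrics
themselves are computable (and flagged) for smaller orthogroups.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

MIN_MEMBERS_FOR_COMPARISON = 3


@dataclass
class OrthogroupQSProfile:
    """QS labels of an orthogroup's members: (protein_id, n_subunits, topology_class)."""

    orthogroup_id: str
    members: list[tuple[str, int, str]]
    qs_per_protein: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"orthogroup {self.orthogroup_id} has no members")

    @property
    def n_proteins(self) -> int:
        return len(self.members)

    @property
    def comparable(self) -> bool:
        return self.n_proteins >= MIN_MEMBERS_FOR_COMPARISON


def avg_subunits(profile: OrthogroupQSProfile) -> float:
    """Arithmetic mean subunit count over members, monomers counted as 1."""
    return sum(n for _, n, _ in profile.members) / profile.n_proteins


def _class_frequencies(profile: OrthogroupQSProfile) -> Counter:
    classes = [c for _, _, c in profile.members]
    if any(c is None or c == "" for c in classes):
        raise ValueError(
            f"orthogroup {profile.orthogroup_id}: topology classes not assigned"
        )
    return Counter(classes)


def qs_diversity(profile: OrthogroupQSProfile) -> int:
    """Number of distinct QS topologies present in the orthogroup."""
    return len(_class_frequencies(profile))


def shannon_index(profile: OrthogroupQSProfile) -> float:
    """−Σ p_i ln p_i, p_i the frequency of each QS topology among members.

    0 for a single topology; maximal (ln k) when the k topologies are equally
    frequent, so a 5:5 monomer/dimer orthogroup scores higher than a 1:9 one.
    """
    counts = _class_frequencies(profile)
    n = profile.n_proteins
    return -sum((c / n) * math.log(c / n) for c in counts.values()) + 0.0


def avg_qs_per_protein(profile: OrthogroupQSProfile) -> float:
    """Mean over members of the number of distinct QSs among their PDB entries."""
    if profile.qs_per_protein is None:
        raise ValueError(
            f"orthogroup {profile.orthogroup_id}: per-protein QS counts missing"
        )
    try:
        counts = [profile.qs_per_protein[pid] for pid, _, _ in profile.members]
    except KeyError as exc:
        raise ValueError(f"missing per-protein QS count for {exc.args[0]!r}") from None
    return sum(counts) / len(counts)


def profile_table(
    profiles: list[OrthogroupQSProfile], mo_flags: dict[str, bool] | None = None
) -> pd.DataFrame:
    """Tabulate all four metrics per orthogroup (TSV-ready)."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "orthogroup_id": p.orthogroup_id,
                "n_proteins": p.n_proteins,
                "avg_subunits": avg_subunits(p),
                "qs_diversity": qs_diversity(p),
                "shannon": shannon_index(p),
                "avg_qs_per_protein": (
                    avg_qs_per_protein(p) if p.qs_per_protein is not None else math.nan
                ),
                "comparable": p.comparable,
                "is_MO": mo_flags.get(p.orthogroup_id) if mo_flags else None,
            }
        )
    return pd.DataFrame(rows)
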