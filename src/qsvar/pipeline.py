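"""End-to-end study orchestration.

Runs the full comparison of quaternary-structure variability between
moonlighting (MO) and non-moonlighting orthogroups on a study bundle —
either real exported tables or a synthetic bundle from
:mod:`qsvar.synthetic_data`:

record filtering → interface classification → topology classes → diversity
metrics → per-tree ancestral reconstruction and change rates (stratified by
root type) → annotation richness → group statistics with one global BH pass.

Every stage logs counts in/out and writes its table under the output
directory, so each number in the report is traceable to a stage file.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotations as ann_mod
from . import diversity as div_mod
from . import phylo as phylo_mod
from . import stats_compare as stats_mod
from . import topology as topo_mod
from .interfaces import load_max_areas, read_sasa_table, summarize_interface
from .topology import read_alignment_maps

logger = logging.getLogger("qsvar")


@dataclass
class RunConfig:
    """Thresholds and switches of a study run (defaults are the study values)."""

    input_dir: str = "."
    output_dir: str = "qsvar_out"
    rsa_threshold: float = 0.2
    burial_threshold: float = 0.10
    rsa_context: str = "monomer"
    overlap_threshold: float = 0.5
    missing_overlap_as_same: bool = False
    resolution_max: float = 3.0        # strict: "better than 3 A"
    coverage_min: float = 0.80         # strict: "more than 80%"
    length_min: int = 100
    small_interface_area: float = 1000.0
    small_interface_as_monomer: bool = False
    resolve_threshold: float = 0.51
    outlier_k: float = 3.0
    min_orthogroup_size: int = 3
    min_tree_tips: int = 10
    evidence_mode: str = "all"
    root_prior: str = "uniform"
    use_predicted_moonlighting: bool = True
    asr_method: str = "ml"             # "ml" or "acctran"

    def validate(self) -> None:
        for name in ("rsa_threshold", "burial_threshold", "overlap_threshold",
                     "resolution_max", "coverage_min", "small_interface_area",
                     "resolve_threshold", "outlier_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.length_min < 1 or self.min_orthogroup_size < 1 or self.min_tree_tips < 3:
            raise ValueError("size thresholds out of range")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


REQUIRED_RECORD_FIELDS = ["protein_id", "orthogroup_id", "resolution",
                          "coverage", "length", "n_subunits", "is_moonlighting"]


def filter_protein_records(records: pd.DataFrame, config: RunConfig | None = None
                           ) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the structure-quality filters; log every exclusion with a reason.

    Keeps records with resolution strictly better than 3 Å, coverage
    strictly above 80% of the sequence, and length of at least 100 residues.
    """
    config = config or RunConfig()
    missing_cols = [c for c in REQUIRED_RECORD_FIELDS if c not in records.columns]
    if missing_cols:
        raise ValueError(f"protein records lack fields: {missing_cols}")
    exclusions: list[dict] = []
    keep_mask = []
    for row in records.itertuples():
        for f in ("resolution", "coverage", "length"):
            if pd.isna(getattr(row, f)):
                raise ValueError(f"record {row.protein_id!r} missing field {f!r}")
        reasons = []
        if not row.resolution < config.resolution_max:
            reasons.append(f"resolution {row.resolution} not better than {config.resolution_max}")
        if not row.coverage > config.coverage_min:
            reasons.append(f"coverage {row.coverage} not above {config.coverage_min}")
        if not row.length >= config.length_min:
            reasons.append(f"length {row.length} below {config.length_min}")
        if reasons:
            exclusions.append({"protein_id": row.protein_id, "reason": "; ".join(reasons)})
        keep_mask.append(not reasons)
    retained = records[pd.Series(keep_mask, index=records.index)].copy()
    logger.info("record filter: %d in, %d retained, %d excluded",
                len(records), len(retained), len(exclusions))
    return retained, exclusions


def define_mo_groups(records: pd.DataFrame, use_predicted: bool = True
                     ) -> dict[str, bool]:
    """MO flag per orthogroup: at least one moonlighting member.

    With ``use_predicted=False`` (used in annotation comparisons, which GO
    predictions would contaminate), members flagged only through predicted
    sources do not count.
    """
    flags = records["is_moonlighting"].astype(bool)
    if not use_predicted and "is_predicted_moonlighting" in records.columns:
        flags = flags & ~records["is_predicted_moonlighting"].astype(bool)
    return records.assign(_f=flags).groupby("orthogroup_id")["_f"].any().to_dict()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_interfaces(sasa: pd.DataFrame, subunits: dict[str, int],
                     config: RunConfig) -> dict[str, "object"]:
    """Interface summaries per protein; optional small-interface relabeling.

    With ``small_interface_as_monomer`` set, homomers burying less than the
    small-interface cutoff (1000 Å² per subunit by default) are relabeled as
    monomers — the sensitivity analysis for weak crystal-contact interfaces.
    """
    max_areas = load_max_areas()
    summaries = {}
    for pid, grp in sasa.groupby("protein_id", sort=True):
        n_sub = subunits.get(str(pid))
        if n_sub is None:
            raise ValueError(f"no subunit count for protein {pid!r}")
        s = summarize_interface(grp, n_sub, max_areas=max_areas,
                                rsa_threshold=config.rsa_threshold,
                                burial_threshold=config.burial_threshold,
                                rsa_context=config.rsa_context)
        if (config.small_interface_as_monomer and s.n_subunits > 1
                and s.interface_area < config.small_interface_area):
            s.n_subunits = 1
            s.interface_area = 0.0
            s.surface_residues |= s.interface_residues
            s.interface_residues = set()
        summaries[str(pid)] = s
    return summaries


def stage_topology(summaries: dict, records: pd.DataFrame,
                   amaps: list, config: RunConfig) -> dict[str, str]:
    """Assign a topology class to every protein, orthogroup by orthogroup."""
    amap_index = {}
    for m in amaps:
        amap_index[(m.protein_a, m.protein_b)] = m
    classes: dict[str, str] = {}
    for og, grp in records.groupby("orthogroup_id", sort=True):
        pids = [str(p) for p in grp["protein_id"]]
        structures = [(p, summaries[p].n_subunits) for p in pids if p in summaries]
        overlaps = {}
        for i, (pa, na) in enumerate(structures):
            for pb, nb in structures[i + 1:]:
                if na != nb or na == 1:
                    continue
                m = amap_index.get((pa, pb))
                if m is None:
                    m = amap_index.get((pb, pa))
                    if m is not None:
                        m = m.reversed()
                if m is None:
                    continue
                overlaps[(pa, pb)] = topo_mod.interface_overlap(
                    m, summaries[pa].interface_residues,
                    summaries[pb].interface_residues)
        classes.update(topo_mod.assign_topologies(
            structures, overlaps, config.overlap_threshold,
            config.missing_overlap_as_same))
    return classes


def stage_diversity(records: pd.DataFrame, summaries: dict, classes: dict,
                    mo_flags: dict, entries_qs: dict[str, int] | None = None
                    ) -> pd.DataFrame:
    """Per-orthogroup QS variability metrics table."""
    profiles = []
    for og, grp in records.groupby("orthogroup_id", sort=True):
        members = [(str(p), summaries[str(p)].n_subunits, classes[str(p)])
                   for p in grp["protein_id"] if str(p) in summaries]
        if not members:
            continue
        counts = ({pid: entries_qs.get(pid, 1) for pid, _, _ in members}
                  if entries_qs is not None else {pid: 1 for pid, _, _ in members})
        profiles.append(div_mod.OrthogroupQSProfile(str(og), members, counts))
    return div_mod.profile_table(profiles, mo_flags)


def stage_phylo(tree_dir: Path, records: pd.DataFrame, summaries: dict,
                classes: dict, config: RunConfig) -> pd.DataFrame:
    """Per-tree rooting, ancestral reconstruction and change-rate summary.

    Only orthogroups with at least ``min_tree_tips`` retained proteins enter;
    tips are the protein ids, states their topology-class labels.  Outlier
    tips are dropped (single pass), the tree is MAD-rooted, and the ER ML
    (or parsimony) reconstruction yields the change-rate statistics and the
    root stratum.
    """
    rows = []
    for og, grp in records.groupby("orthogroup_id", sort=True):
        path = tree_dir / f"{og}.nwk"
        if not path.exists():
            continue
        pids = {str(p) for p in grp["protein_id"] if str(p) in classes}
        tree = phylo_mod.read_newick(str(path))
        present = [t.label for t in tree.taxon_namespace if t.label in pids]
        if len(present) < config.min_tree_tips:
            continue
        if len(present) < len(tree.taxon_namespace):
            tree = phylo_mod.prune_to(tree, present)
        retained, excluded = phylo_mod.filter_outliers(tree, config.outlier_k)
        if len(retained) < config.min_tree_tips:
            continue
        if excluded:
            tree = phylo_mod.prune_to(tree, retained)
        rooted = phylo_mod.mad_root(tree).tree
        tip_states = {pid: classes[pid] for pid in retained}
        if config.asr_method == "acctran":
            score, asr = phylo_mod.acctran_asr(rooted, tip_states)
            fit = None
        else:
            fit, asr = phylo_mod.fit_er_asr(
                rooted, tip_states, root_prior=config.root_prior,
                resolve_threshold=config.resolve_threshold)
        summary = phylo_mod.qs_change_rate(asr)
        rtype = phylo_mod.root_type(asr, threshold=config.resolve_threshold)
        iface_areas = [summaries[p].interface_area for p in retained]
        rows.append({
            "orthogroup_id": str(og), "n_tips": len(retained),
            "n_outliers_excluded": len(excluded),
            "root_type": rtype, "er_rate": fit.rate if fit else math.nan,
            "rate_total": summary.rate_total, "rate_gain": summary.rate_gain,
            "rate_loss": summary.rate_loss, "n_lateral": summary.n_lateral,
            "n_pairs_used": summary.n_pairs_used,
            "mean_interface_area": float(np.mean(iface_areas)),
        })
        logger.info("phylo %s: %d tips, root=%s, rate_total=%.3f",
                    og, len(retained), rtype, summary.rate_total)
    return pd.DataFrame(rows)


def stage_annotations(ann_table, dag, records: pd.DataFrame,
                      mo_flags_go: dict, config: RunConfig) -> pd.DataFrame:
    """Per-orthogroup mean annotation count per protein, after hierarchy filtering."""
    table = ann_mod.evidence_subset(ann_table, config.evidence_mode)
    rows = []
    for og, grp in records.groupby("orthogroup_id", sort=True):
        pids = {str(p) for p in grp["protein_id"]}
        for source in sorted(table.sources):
            rows.append({
                "orthogroup_id": str(og), "source": source,
                "mean_terms_per_protein": ann_mod.richness(table, pids, source, dag),
                "is_MO": bool(mo_flags_go.get(str(og), False)),
            })
    return pd.DataFrame(rows)


def stage_stats(diversity_df: pd.DataFrame, phylo_df: pd.DataFrame,
                ann_df: pd.DataFrame, records: pd.DataFrame,
                mo_flags: dict) -> stats_mod.StudyResults:
    """The study's test battery; BH correction is applied across all of it."""
    study = stats_mod.StudyResults()

    comp = diversity_df[diversity_df["comparable"] & diversity_df["is_MO"].notna()]
    for metric in ("avg_subunits", "qs_diversity", "shannon", "avg_qs_per_protein"):
        mo = comp.loc[comp["is_MO"].astype(bool), metric].dropna()
        non = comp.loc[~comp["is_MO"].astype(bool), metric].dropna()
        if len(mo) and len(non):
            study.add(stats_mod.wilcoxon_rank_sum(mo, non, f"diversity_{metric}"))

    is_mo_protein = records["orthogroup_id"].map(mo_flags).astype(bool)
    homomer = records["n_subunits"] > 1
    k1, n1 = int((homomer & is_mo_protein).sum()), int(is_mo_protein.sum())
    k2, n2 = int((homomer & ~is_mo_protein).sum()), int((~is_mo_protein).sum())
    if n1 and n2:
        study.add(stats_mod.prop_test_ci(k1, n1, k2, n2, "homomer_fraction"))

    if len(phylo_df):
        pmo = phylo_df["orthogroup_id"].map(mo_flags).astype(bool)
        for stratum in ("homomer", "monomer"):
            sel = phylo_df["root_type"] == stratum
            for metric in ("rate_total", "rate_gain", "rate_loss"):
                mo = phylo_df.loc[sel & pmo, metric].dropna()
                non = phylo_df.loc[sel & ~pmo, metric].dropna()
                if len(mo) >= 2 and len(non) >= 2:
                    study.add(stats_mod.wilcoxon_rank_sum(
                        mo, non, f"change_{metric}_{stratum}_root"))
        # change rate adjusted for orthogroup size (parametric and rank-based)
        ok = phylo_df["rate_total"].notna()
        sizes = phylo_df.loc[ok, "n_tips"].astype(float)
        y = phylo_df.loc[ok, "rate_total"].astype(float)
        g = pmo[ok].astype(int)
        if 0 < g.sum() < len(g) and g.map(g.value_counts()).min() >= 3:
            try:
                study.add(stats_mod.ancova_group_effect(
                    y, g, sizes, "change_rate_ancova_size"))
            except ValueError:
                pass
            if len(y) >= 4:
                study.add(stats_mod.spearman_partial(
                    y, g.astype(float), sizes, "change_rate_partial_size"))

    if len(ann_df):
        for source in sorted(ann_df["source"].unique()):
            sel = ann_df["source"] == source
            mo = ann_df.loc[sel & ann_df["is_MO"], "mean_terms_per_protein"]
            non = ann_df.loc[sel & ~ann_df["is_MO"], "mean_terms_per_protein"]
            if len(mo) and len(non):
                study.add(stats_mod.wilcoxon_rank_sum(mo, non, f"richness_{source}"))

    study.finalize()
    return study


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

STAGE_ORDER = ["filter", "interfaces", "topology", "diversity", "phylo",
               "annotations", "stats"]


def run_stages(config: RunConfig, upto: str = "stats") -> dict:
    """Execute the pipeline through the named stage, writing stage tables.

    Stages run in the fixed order filter → interfaces → topology → diversity
    → phylo → annotations → stats; each consumes the artifacts of the ones
    before it.  Returns the accumulated artifacts (dataframes, summaries,
    the StudyResults) keyed by stage name.
    """
    if upto not in STAGE_ORDER:
        raise ValueError(f"unknown stage {upto!r}; choose from {STAGE_ORDER}")
    config.validate()
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    last = STAGE_ORDER.index(upto)
    art: dict = {}

    records = pd.read_csv(in_dir / "orthogroups.tsv", sep="\t",
                          dtype={"protein_id": str, "orthogroup_id": str})
    retained, exclusions = filter_protein_records(records, config)
    pd.DataFrame(exclusions, columns=["protein_id", "reason"]).to_csv(
        out_dir / "exclusions.tsv", sep="\t", index=False)
    art["filter"] = {"records_in": records, "retained": retained,
                     "exclusions": exclusions}
    if last < 1:
        return art

    states = pd.read_csv(in_dir / "states.tsv", sep="\t", dtype={"protein_id": str})
    subunits = dict(zip(states["protein_id"], states["n_subunits"].astype(int)))
    sasa = read_sasa_table(in_dir / "sasa.tsv")
    sasa = sasa[sasa["protein_id"].isin(set(retained["protein_id"]))]
    summaries = stage_interfaces(sasa, subunits, config)
    pd.DataFrame(
        [{"protein_id": p, "n_subunits": s.n_subunits,
          "interface_area": s.interface_area,
          "n_interface_residues": len(s.interface_residues),
          "n_surface_residues": len(s.surface_residues)}
         for p, s in sorted(summaries.items())]
    ).to_csv(out_dir / "interfaces.tsv", sep="\t", index=False)
    art["interfaces"] = summaries
    if last < 2:
        return art

    amaps = (read_alignment_maps(in_dir / "alignments.tsv")
             if (in_dir / "alignments.tsv").exists() else [])
    classes = stage_topology(summaries, retained, amaps, config)
    pd.DataFrame(sorted(classes.items()), columns=["protein_id", "topology_class"]
                 ).to_csv(out_dir / "topologies.tsv", sep="\t", index=False)
    art["topology"] = classes
    if last < 3:
        return art

    mo_flags = define_mo_groups(retained, config.use_predicted_moonlighting)
    mo_flags_go = define_mo_groups(retained, use_predicted=False)
    art["mo_flags"] = mo_flags

    diversity_df = stage_diversity(retained, summaries, classes, mo_flags)
    diversity_df.to_csv(out_dir / "diversity.tsv", sep="\t", index=False)
    art["diversity"] = diversity_df
    if last < 4:
        return art

    phylo_df = stage_phylo(in_dir / "trees", retained, summaries, classes, config)
    phylo_df.to_csv(out_dir / "change_rates.tsv", sep="\t", index=False)
    art["phylo"] = phylo_df
    if last < 5:
        return art

    ann_df = pd.DataFrame()
    if (in_dir / "annotations.tsv").exists():
        dag = (ann_mod.read_obo(in_dir / "ontology.obo")
               if (in_dir / "ontology.obo").exists() else None)
        ann_table = ann_mod.read_annotations(in_dir / "annotations.tsv")
        ann_df = stage_annotations(ann_table, dag, retained, mo_flags_go, config)
        ann_df.to_csv(out_dir / "annotation_richness.tsv", sep="\t", index=False)
    art["annotations"] = ann_df
    if last < 6:
        return art

    study = stage_stats(diversity_df, phylo_df, ann_df, retained, mo_flags)
    study.to_frame().to_csv(out_dir / "stats.tsv", sep="\t", index=False)
    art["stats"] = study
    return art


def run_study(config: RunConfig) -> dict:
    """Execute every stage on a bundle directory and write the report.

    Outputs under ``config.output_dir``: exclusions.tsv, interfaces.tsv,
    topologies.tsv, diversity.tsv, change_rates.tsv, annotation_richness.tsv,
    stats.tsv and report.json.  Deterministic given inputs and config.
    """
    art = run_stages(config, "stats")
    out_dir = Path(config.output_dir)
    records = art["filter"]["records_in"]
    retained = art["filter"]["retained"]
    exclusions = art["filter"]["exclusions"]
    mo_flags = art["mo_flags"]
    phylo_df = art["phylo"]
    study = art["stats"]

    report = {
        "config": asdict(config),
        "counts": {
            "proteins_in": int(len(records)),
            "proteins_retained": int(len(retained)),
            "proteins_excluded": len(exclusions),
            "orthogroups": int(retained["orthogroup_id"].nunique()),
            "mo_orthogroups": int(sum(mo_flags.values())),
            "trees_analyzed": int(len(phylo_df)),
            "trees_homomer_root": int((phylo_df["root_type"] == "homomer").sum())
            if len(phylo_df) else 0,
            "trees_monomer_root": int((phylo_df["root_type"] == "monomer").sum())
            if len(phylo_df) else 0,
            "trees_unresolved_root": int((phylo_df["root_type"] == "unresolved").sum())
            if len(phylo_df) else 0,
        },
        "tests": [
            {"test_id": r.test_id, "statistic": r.statistic, "p_raw": r.p_raw,
             "p_adj": r.p_adjusted, "effect": r.effect, "n1": r.n1, "n2": r.n2}
            for r in study.results
        ],
        "provenance": {
            "diversity": "diversity.tsv", "change_rates": "change_rates.tsv",
            "annotation_richness": "annotation_richness.tsv",
            "stats": "stats.tsv", "exclusions": "exclusions.tsv",
        },
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
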