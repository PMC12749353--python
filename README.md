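# qsvar — quaternary-structure variability of protein orthogroups

Many proteins work as homomers — complexes of several copies of one chain —
and the number of subunits and the interfaces that hold them together change
over evolution. `qsvar` is a pipeline for asking whether groups of
orthologous proteins (orthogroups) differ in how variable their quaternary
structure (QS) is, with the motivating comparison being orthogroups that
contain *moonlighting* proteins (proteins with two or more unrelated
functions; "MO" orthogroups) versus orthogroups without them.

The pipeline covers, as importable modules and as CLI stages:

- **interfaces** — classify residues as interface / surface / buried from
  per-residue solvent-accessible surface areas (SASA) of the complex and the
  isolated chain. A residue is *interface* when its relative solvent
  accessibility RSA = SASA/maxASA is ≥ 0.2 in the isolated subunit **and**
  it loses ≥ 10% of that SASA upon assembly; *surface* when exposed
  (RSA > 0.2) but not buried by assembly. Per-subunit interface area is
  (ΣSASA_monomers − SASA_complex)/n_subunits.
- **topology** — interface overlap between two homomers is the fraction of
  the smaller interface whose residues are structurally aligned onto the
  other interface; same subunit count with overlap < 0.5 means different QS
  topologies. Topology classes are single-linkage components of the
  overlap ≥ 0.5 relation within each subunit-count stratum.
- **diversity** — four per-orthogroup metrics: mean subunit count, number of
  distinct QS topologies, the Shannon index −Σᵢ pᵢ ln pᵢ over topology
  frequencies, and the mean number of distinct QSs per protein across its
  structure entries.
- **phylo** — long-branch tip exclusion (mean cophenetic distance above the
  grand mean + 3 SD), Minimal Ancestor Deviation (MAD) rooting, ancestral QS
  reconstruction by the equal-rates Mk model (maximum likelihood, marginal
  probabilities via the pruning algorithm) and by Fitch parsimony with
  accelerated-transformation resolution, and the QS change rate: the
  fraction of parent–child node pairs with different QS, skipping pairs with
  a node whose best state has probability ≤ 0.51, split into subunit gains,
  losses and lateral (interface-only) changes.
- **annotations** — OBO ontology handling; when two annotated terms sit on
  one ancestor–descendant path (is_a/part_of, within a namespace) only the
  most specific term is kept; evidence-code subsets; mean terms per protein.
- **stats_compare** — two-sided Wilcoxon rank-sum (exact for small tie-free
  samples), two-proportion chi-square with Wilson 95% CIs, ANCOVA group
  effects, Spearman partial correlation, and a single Benjamini–Hochberg
  pass over every p-value a study run produces.
- **synthetic_data** — generates every input with known ground truth: Yule
  trees, QS characters evolved under a gain/loss ladder (1↔2↔4↔8 subunits),
  toy complexes as SASA tables with planted interfaces, identity alignment
  maps, a small GO-style ontology, and MO/non-MO tables with controllable
  effect sizes.
- **pipeline / CLI** — record filtering (resolution better than 3 Å,
  coverage above 80%, length ≥ 100), MO group definition, and the
  end-to-end run emitting per-stage tables and a JSON report.

## Worked example

Generate a synthetic study with 20 orthogroups per arm in which MO trees
change quaternary structure at twice the base rate, then run every stage:

```bash
qsvar simulate --seed 7 --n-orthogroups 20 --qs-effect 2.0 --out demo/bundle
qsvar run-all --input-dir demo/bundle --output-dir demo/out
```

which prints the stage counts

```
{
 "proteins_in": 378,
 "proteins_retained": 378,
 "proteins_excluded": 0,
 "orthogroups": 40,
 "mo_orthogroups": 20,
 "trees_analyzed": 16,
 "trees_homomer_root": 5,
 "trees_monomer_root": 4,
 "trees_unresolved_root": 7
}
```

— 378 simulated proteins in 40 orthogroups pass the structure-quality
filters; 16 orthogroups have the ≥ 10 proteins needed for the phylogenetic
stage, and of those 9 have a root state resolved above the 0.51 probability
threshold (5 homomer-rooted, 4 monomer-rooted). `demo/out/stats.tsv` then
holds the test battery:

```
                 test_id  statistic    p_raw    p_adj  n1  n2   effect
  diversity_avg_subunits 240.000000 0.284988 0.576700  20  20 0.455159
  diversity_qs_diversity 184.000000 0.657852 0.877136  20  20 0.000000
       diversity_shannon 192.000000 0.838956 0.958807  20  20 0.041272
        homomer_fraction   7.123155 0.007609 0.030438 197 181 0.132036
 change_rate_ancova_size   0.947964 0.360437 0.576700   8   8 0.022280
             richness_GO 353.500000 0.000035 0.000279  20  20 2.358333
```

Read: the four QS-diversity metrics do not separate the arms at this effect
size, the MO arm has a higher homomer fraction (+13 percentage points,
adjusted p ≈ 0.03), and the planted 1.5× annotation-richness effect is
detected (≈ 2.4 more terms per protein, adjusted p ≈ 3 × 10⁻⁴). `p_adj` is
the BH-adjusted value over the whole battery.

Every stage is also importable directly, e.g.

```python
from qsvar import fit_er_asr, mad_root, phylo
tree = phylo.read_newick("((a:1,b:1):1,(c:1,d:1):1);")
fit, asr = fit_er_asr(tree, {"a": 1, "b": 1, "c": 2, "d": 2})
print(fit.rate, asr.root_probs)   # ML transition rate, root state probabilities
```

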