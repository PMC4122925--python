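"""Ortholog clusters and the pangenome class ledger.

Fosmid genes are grouped into ortholog (OG) clusters by single-linkage over
pairwise similarity hits, each cluster is assigned a pangenome class from its
presence across reference genomes —

* ``archaeal_core``  — present in every reference genome of both archaeal
  lineages (universal genes included);
* ``lineage_core``   — present in all, or all but ``allow_missing``, reference
  genomes of the cluster's own lineage and nowhere else in archaea;
* ``shell``          — present in only a subset of strains, or with just 1-3
  database homologs, or with homologs only outside Archaea;
* ``orphan``         — a single gene without any homolog

— and the class x HGT-verdict matrix is summarized into the per-lineage count
table with derived HGT percentages.  Genome equivalents (how many genomes a
fosmid collection represents) come from mean copy numbers of single-copy
marker families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

CLASSES = ("archaeal_core", "lineage_core", "shell", "orphan")

DEFAULT_MAX_EVALUE = 1e-5
DEFAULT_MIN_IDENTITY = 30.0
DEFAULT_MIN_COVERAGE = 0.70


@dataclass
class OrthologCluster:
    id: str
    members: list[str]
    presence: dict[str, bool] = field(default_factory=dict)
    db_hit_count: int = 0
    cluster_class: str | None = None
    lineage: str | None = None


@dataclass
class ReferencePanel:
    """Reference genome ids per archaeal lineage plus the cross-domain panel.

    ``allow_missing`` per lineage defaults to 1 when a lineage has three or
    more reference genomes (tolerating a single-lineage loss) and 0 otherwise
    (a single composite reference genome must contain the gene).
    """

    lineages: dict[str, list[str]]
    allow_missing: dict[str, int] | None = None

    def missing_allowance(self, lineage: str) -> int:
        if self.allow_missing and lineage in self.allow_missing:
            return self.allow_missing[lineage]
        return 1 if len(self.lineages[lineage]) >= 3 else 0

    def all_genomes(self) -> list[str]:
        return [g for refs in self.lineages.values() for g in refs]


@dataclass
class PangenomeSummary:
    lineage: str
    counts: dict[str, int]  # the five origin-class counts
    orphan_count: int
    total_clusters: int
    pct_hgt_total: float
    pct_hgt_early: float
    pct_hgt_late: float
    donor_breakdown: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class GenomeEquivalentEstimate:
    per_marker: dict[str, int]
    mean: float
    rrna_count: int | None = None


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def cluster_orthologs(
    hit_table: pd.DataFrame,
    gene_ids: list[str],
    gene_lengths: dict[str, int] | None = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[OrthologCluster]:
    """Single-linkage ortholog clusters over a pairwise hit table.

    An edge joins two genes when a hit between them passes all three
    thresholds; coverage is ``align_length / min(len(query), len(subject))``
    when gene lengths are supplied, else coverage filtering is skipped.
    Clusters are the connected components, with deterministic ids ordered by
    each component's smallest member id.  Genes without qualifying hits (and
    an empty hit table) become singleton clusters.
    """
    g = nx.Graph()
    g.add_nodes_from(gene_ids)
    known = set(gene_ids)
    for row in hit_table.itertuples(index=False):
        q, s = row.query, row.subject
        if q == s or q not in known or s not in known:
            continue
        if float(row.e_value) > max_evalue:
            continue
        if float(row.percent_identity) < min_identity:
            continue
        if gene_lengths is not None:
            shorter = min(gene_lengths[q], gene_lengths[s])
            if shorter > 0 and float(row.align_length) / shorter < min_coverage:
                continue
        g.add_edge(q, s)
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0]
    )
    return [
        OrthologCluster(id=f"OG{i:05d}", members=members)
        for i, members in enumerate(comps)
    ]


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_cluster(
    cluster: OrthologCluster,
    reference_panel: ReferencePanel,
    lineage: str,
    archaeal_homologs: bool | None = None,
) -> str:
    """Assign one of archaeal_core / lineage_core / shell / orphan.

    ``cluster.presence`` maps reference genome ids to presence;
    ``archaeal_homologs`` says whether the family has archaeal homologs
    beyond the references at all (None means unknown, treated as the
    presence profile implies).
    """
    if lineage not in reference_panel.lineages:
        raise ValueError(f"unknown lineage {lineage!r}")
    unknown = set(cluster.presence) - set(reference_panel.all_genomes())
    if unknown:
        raise ValueError(f"unknown reference ids: {sorted(unknown)}")

    if len(cluster.members) == 1 and cluster.db_hit_count == 0:
        return "orphan"

    def n_present(genomes):
        return sum(1 for g in genomes if cluster.presence.get(g, False))

    if all(
        n_present(refs) == len(refs) for refs in reference_panel.lineages.values()
    ):
        return "archaeal_core"

    own = reference_panel.lineages[lineage]
    if n_present(own) >= len(own) - reference_panel.missing_allowance(lineage):
        return "lineage_core"

    # few database homologs, archaeal-absent families, and everything present
    # in only a subset of strains fall through to shell
    return "shell"


# ---------------------------------------------------------------------------
# Summary arithmetic
# ---------------------------------------------------------------------------

ORIGIN_CLASSES = (
    "archaeal_core",
    "lineage_core_native",
    "lineage_core_early_hgt",
    "shell_native",
    "shell_late_hgt",
)


def round_half_up(x: float, decimals: int = 1) -> float:
    factor = 10**decimals
    return math.floor(x * factor + 0.5) / factor


def summarize_counts(
    lineage: str,
    counts: dict[str, int],
    orphan_count: int,
    donor_breakdown: dict[str, dict[str, float]] | None = None,
) -> PangenomeSummary:
    """Derive the HGT percentages from a printed-style class count matrix.

    The denominator is total OG clusters plus orphan genes; percentages are
    rounded half-up to one decimal at this report layer only.
    """
    missing = [c for c in ORIGIN_CLASSES if c not in counts]
    if missing:
        raise ValueError(f"missing class counts: {missing}")
    total_clusters = sum(counts[c] for c in ORIGIN_CLASSES)
    denom = total_clusters + orphan_count
    if denom == 0:
        raise ValueError("empty pangenome: zero clusters and orphans")
    early = counts["lineage_core_early_hgt"]
    late = counts["shell_late_hgt"]
    return PangenomeSummary(
        lineage=lineage,
        counts=dict(counts),
        orphan_count=orphan_count,
        total_clusters=total_clusters,
        pct_hgt_total=round_half_up(100.0 * (early + late) / denom),
        pct_hgt_early=round_half_up(100.0 * early / denom),
        pct_hgt_late=round_half_up(100.0 * late / denom),
        donor_breakdown=donor_breakdown or {},
    )


def summarize_pangenome(clusters: list[OrthologCluster], verdicts: dict) -> dict[str, PangenomeSummary]:
    """Count classified clusters x timed verdicts into per-lineage summaries.

    Every non-orphan cluster must carry a verdict (unresolved/excluded
    verdicts count as non-HGT in their class, keeping the estimate
    conservative, as in the manual-curation protocol this automates).
    """
    by_lineage: dict[str, dict[str, int]] = {}
    orphans: dict[str, int] = {}
    for cl in clusters:
        lin = cl.lineage or "all"
        if cl.cluster_class == "orphan":
            orphans[lin] = orphans.get(lin, 0) + 1
            continue
        v = verdicts.get(cl.id)
        if v is None:
            raise ValueError(f"cluster {cl.id} has no HGT verdict")
        key = _origin_class(cl.cluster_class, v)
        by_lineage.setdefault(lin, {c: 0 for c in ORIGIN_CLASSES})
        by_lineage[lin][key] += 1
    out = {}
    for lin, counts in by_lineage.items():
        out[lin] = summarize_counts(lin, counts, orphans.get(lin, 0))
    return out


def _origin_class(cluster_class: str, verdict) -> str:
    hgt = verdict.status == "hgt"
    if cluster_class == "archaeal_core":
        return "archaeal_core"
    if cluster_class == "lineage_core":
        return "lineage_core_early_hgt" if hgt else "lineage_core_native"
    return "shell_late_hgt" if hgt else "shell_native"


# ---------------------------------------------------------------------------
# Genome equivalents and shared-transfer overlap
# ---------------------------------------------------------------------------


def estimate_genome_equivalents(
    clusters: list[OrthologCluster],
    marker_family_ids: list[str],
    rrna_count: int | None = None,
) -> GenomeEquivalentEstimate:
    """Mean copy number of single-copy marker families across the fosmid set.

    Each marker family's copy count is the number of fosmid genes in its
    cluster; under full coverage the mean estimates the number of genome
    equivalents the library contains.
    """
    by_id = {c.id: c for c in clusters}
    missing = [m for m in marker_family_ids if m not in by_id]
    if missing or not marker_family_ids:
        raise ValueError(f"marker families not found among clusters: {missing}")
    per = {m: len(by_id[m].members) for m in marker_family_ids}
    mean = round_half_up(sum(per.values()) / len(per), 1)
    return GenomeEquivalentEstimate(per_marker=per, mean=mean, rrna_count=rrna_count)


def shared_hgt_with_outgroup(
    ht_clusters: list[OrthologCluster],
    outgroup_genes: set[str],
    hit_table: pd.DataFrame,
    verdicts: dict | None = None,
    trees: dict | None = None,
    tax: dict | None = None,
) -> tuple[int, dict[str, bool]]:
    """Count early-HGT clusters whose transfer is shared with an outgroup.

    An outgroup genome that diverged from the lineage ancestor after an early
    transfer should carry a homolog of the transferred family that groups
    with the query clade.  With ``trees`` and a taxonomy map the grouping is
    checked on the gene tree (the outgroup leaf must fall on the query side
    of the query clade's smallest enclosing split); without trees the count
    degrades to homology-only and is an upper bound (flagged by returning all
    homolog-bearing clusters).
    """
    links: dict[str, set[str]] = {}
    member_index = {}
    for cl in ht_clusters:
        for m in cl.members:
            member_index[m] = cl.id
    for row in hit_table.itertuples(index=False):
        for a, b in ((row.query, row.subject), (row.subject, row.query)):
            if a in member_index and b in outgroup_genes:
                links.setdefault(member_index[a], set()).add(b)

    flags: dict[str, bool] = {}
    for cl in ht_clusters:
        homologs = links.get(cl.id, set())
        if not homologs:
            flags[cl.id] = False
            continue
        if trees is not None and tax is not None and cl.id in trees:
            from . import phylo_hgt

            leaves, splits = phylo_hgt.tree_splits(
                trees[cl.id].newick if hasattr(trees[cl.id], "newick") else trees[cl.id]
            )
            query = frozenset(
                l for l in leaves if tax[l].is_query and l not in outgroup_genes
            )
            og_leaves = homologs & leaves
            flags[cl.id] = bool(og_leaves) and _groups_with_query(
                leaves, splits, query, og_leaves
            )
        else:
            flags[cl.id] = True  # homology-only upper bound
    return sum(flags.values()), flags


def _groups_with_query(leaves, splits, query, og_leaves) -> bool:
    """True when some split places the outgroup homologs with the query clade
    against at least as many leaves outside."""
    target = query | og_leaves
    for side in list(splits) + [leaves - s for s in splits]:
        if target <= side and len(side) <= len(leaves) - len(side) + len(target):
            if len(side - target) <= len(target):
                return True
    return False
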