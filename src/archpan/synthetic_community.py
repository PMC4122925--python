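"""Synthetic archaeal fosmid communities with planted gene origins.

The generator emulates the study design the pipeline targets: two uncultured
archaeal lineages (one thaumarchaeote-like at ~47% GC, one GII/III
euryarchaeote-like at ~55% GC) sampled as mosaic ~36-kb fosmid inserts, whose
genes fall into six origin classes — archaeal core, lineage-specific core
(native or early-transferred), shell (native or late-transferred) and orphan.
For every non-orphan gene family it also fabricates the database side of the
analysis: aligned homolog sequences from bacterial phyla, other archaea and
(for transferred families) a donor phylum inside which the archaeal copies
branch, so that tree inference plus the topology-reading rules can recover
the planted truth.

Design choices, briefly: proteins evolve by a Jukes-Cantor-like per-site
substitution process on the 20-letter alphabet (topology recovery, not
realism, is what downstream tests need); nucleotide sequences are produced
by back-translation with a lineage-specific GC-tuned codon table, which both
realizes the configured genomic GC and ameliorates transferred genes to host
codon usage; class and donor assignments are stratified (largest-remainder
rounding of the configured proportions) so the planted composition matches
the configuration exactly rather than up to multinomial noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .codon_metrics import STOP_CODONS, SYNONYMS
from .composition_profile import revcomp
from .phylo_hgt import AA_ALPHABET, LeafTaxon, TaxonomyMap
from .sequence_io import FosmidRecord, GeneRecord

ORIGIN_CLASSES = (
    "archaeal_core",
    "lineage_core_native",
    "lineage_core_early_hgt",
    "shell_native",
    "shell_late_hgt",
    "orphan",
)

DEFAULT_CLASS_PROPORTIONS = {
    "archaeal_core": 0.25,
    "lineage_core_native": 0.165,
    "lineage_core_early_hgt": 0.115,
    "shell_native": 0.18,
    "shell_late_hgt": 0.125,
    "orphan": 0.165,
}

DEFAULT_DONOR_PHYLA = {
    "Proteobacteria": 0.40,
    "Actinobacteria": 0.25,
    "Firmicutes": 0.20,
    "Cyanobacteria": 0.15,
}

LINEAGES = ("A", "B")
LINEAGE_PHYLUM = {"A": "Thaumarchaeota", "B": "Euryarchaeota"}
OTHER_ARCHAEA = ("Crenarchaeota", "Euryarchaeota", "Korarchaeota")

# branch lengths (expected substitutions/site) of the planted scaffolds;
# chosen so NJ on ~150-residue alignments recovers the planted placement of
# the query clade in >=90% of families
BL_STRAIN = 0.05
BL_QUERY_STEM = 0.30
BL_WITHIN_PHYLUM = 0.15
BL_PHYLUM_STEM = 0.45
BL_DEEP = 0.25


@dataclass
class CommunityConfig:
    n_genomes: int = 8  # per lineage
    lineage_gc: dict[str, float] = field(
        default_factory=lambda: {"A": 0.4713, "B": 0.5482}
    )
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    donor_phyla: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DONOR_PHYLA)
    )
    fosmid_length_mean: int = 36178
    genes_per_genome: int = 60  # drawn families per lineage
    n_marker_families: int = 6
    n_ribosomal_families: int = 6
    n_ref_genomes: dict[str, int] = field(default_factory=lambda: {"A": 3, "B": 1})
    protein_length: int = 150
    strain_divergence: float = BL_STRAIN
    taxa_per_phylum: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if self.genes_per_genome < 1:
            raise ValueError("genes_per_genome must be >= 1")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions sum to {total}, not 1")
        for name, frac in {**self.class_proportions, **self.lineage_gc}.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction out of [0,1]: {name}={frac}")
        unknown = set(self.class_proportions) - set(ORIGIN_CLASSES)
        if unknown:
            raise ValueError(f"unknown origin classes: {sorted(unknown)}")


@dataclass
class GeneFamily:
    id: str
    lineage: str
    origin_class: str
    donor_phylum: str | None
    carriers: list[int]  # genome indices within the lineage
    ref_presence: dict[str, bool]
    query_seqs: dict[int, str]  # genome index -> aligned protein
    homolog_seqs: dict[str, str]  # database taxon label -> aligned protein
    homolog_taxonomy: TaxonomyMap
    marker: bool = False
    ribosomal: bool = False


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _largest_remainder(weights: dict[str, float], n: int) -> dict[str, int]:
    """Integer counts summing to n, proportional to weights (deterministic)."""
    keys = sorted(weights)
    raw = {k: weights[k] * n for k in keys}
    counts = {k: int(math.floor(raw[k])) for k in keys}
    short = n - sum(counts.values())
    by_frac = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_frac[:short]:
        counts[k] += 1
    return counts


def _evolve(seq: np.ndarray, bl: float, rng: np.random.Generator) -> np.ndarray:
    """One JC-like step: each site substitutes w.p. 1-exp(-bl), uniformly to
    one of the 19 other residues."""
    p = 1.0 - math.exp(-bl)
    out = seq.copy()
    hit = rng.random(seq.shape[0]) < p
    n_hit = int(hit.sum())
    if n_hit:
        shifts = rng.integers(1, 20, size=n_hit)
        out[hit] = (out[hit] + shifts) % 20
    return out


def _to_str(seq: np.ndarray) -> str:
    return "".join(AA_ALPHABET[i] for i in seq)


class _TreeSim:
    """Simulate sequences down an explicitly built scaffold tree."""

    #: internal (backbone) branch length inside a clade; long enough that
    #: NJ bootstrap recovers the clade's internal edges with high support
    BL_BACKBONE = 0.10

    def __init__(self, length: int, rng: np.random.Generator):
        self.length = length
        self.rng = rng
        self.tips: dict[str, np.ndarray] = {}

    def root(self) -> np.ndarray:
        return self.rng.integers(0, 20, size=self.length)

    def clade(
        self,
        parent: np.ndarray,
        labels: list[str],
        bl_stem: float,
        bl_tip: float,
        inner_builder=None,
    ):
        """A resolved (caterpillar) clade: tips branch off a backbone of
        supported internal edges.  When ``inner_builder`` is given it is
        attached mid-backbone, so the inner group branches *within* the
        clade, surrounded by its tips on both sides."""
        node = _evolve(parent, bl_stem, self.rng)
        inner_at = len(labels) // 2 if inner_builder else None
        for i, lab in enumerate(labels):
            self.tips[lab] = _evolve(node, bl_tip, self.rng)
            if inner_at is not None and i == inner_at:
                inner_builder(_evolve(node, self.BL_BACKBONE / 2, self.rng))
            if i < len(labels) - 1:
                node = _evolve(node, self.BL_BACKBONE, self.rng)
        return node

    def nested_clade(
        self,
        parent: np.ndarray,
        outer_labels: list[str],
        inner_builder,
        bl_stem: float,
        bl_tip: float,
    ):
        return self.clade(parent, outer_labels, bl_stem, bl_tip, inner_builder)


# ---------------------------------------------------------------------------
# simulate_species_forest
# ---------------------------------------------------------------------------


def simulate_species_forest(config: CommunityConfig) -> list[GeneFamily]:
    """Generate per-family planted trees and aligned protein sequences.

    For every lineage, ``genes_per_genome`` families are assigned origin
    classes by largest-remainder rounding of ``class_proportions``; marker
    and ribosomal-protein families are appended as extra single-copy
    archaeal-core families.  Native families place the query genomes inside
    an archaeal neighborhood with bacterial phyla as distant outgroups;
    transferred families nest the query clade inside the donor phylum.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    families: list[GeneFamily] = []
    counter = 0
    for lineage in LINEAGES:
        class_counts = _largest_remainder(
            config.class_proportions, config.genes_per_genome
        )
        n_special = config.n_marker_families + config.n_ribosomal_families
        if class_counts.get("archaeal_core", 0) < n_special:
            raise ValueError(
                "archaeal_core allocation too small for the requested marker "
                "and ribosomal families"
            )
        classes: list[tuple[str, bool, bool]] = []
        for cls in ORIGIN_CLASSES:
            for i in range(class_counts.get(cls, 0)):
                marker = cls == "archaeal_core" and i < config.n_marker_families
                ribo = (
                    cls == "archaeal_core"
                    and config.n_marker_families <= i < n_special
                )
                classes.append((cls, marker, ribo))
        n_hgt = sum(1 for c, _, _ in classes if c.endswith("_hgt"))
        donor_counts = _largest_remainder(config.donor_phyla, n_hgt)
        donor_pool = [p for p in sorted(donor_counts) for _ in range(donor_counts[p])]
        rng.shuffle(donor_pool)  # which HGT family gets which donor
        di = 0
        for cls, marker, ribo in classes:
            donor = None
            if cls.endswith("_hgt"):
                donor = donor_pool[di]
                di += 1
            families.append(
                _make_family(
                    f"fam{counter:05d}", lineage, cls, donor, marker, ribo, config, rng
                )
            )
            counter += 1
    return families


def _make_family(
    fam_id: str,
    lineage: str,
    cls: str,
    donor: str | None,
    marker: bool,
    ribo: bool,
    config: CommunityConfig,
    rng: np.random.Generator,
) -> GeneFamily:
    n = config.n_genomes
    # which genomes carry the gene
    if cls == "orphan":
        carriers = [int(rng.integers(0, n))]
    elif cls.startswith("shell"):
        k = int(rng.integers(1, max(2, n // 2 + 1)))
        carriers = sorted(rng.choice(n, size=k, replace=False).tolist())
    elif cls.startswith("lineage_core") and n > 1 and rng.random() < 0.3:
        drop = int(rng.integers(0, n))
        carriers = [i for i in range(n) if i != drop]  # all but one
    else:
        carriers = list(range(n))
    if marker or ribo:
        carriers = list(range(n))

    own_refs = [f"ref_{lineage}{i}" for i in range(config.n_ref_genomes.get(lineage, 0))]
    all_refs = [
        f"ref_{lin}{i}"
        for lin in LINEAGES
        for i in range(config.n_ref_genomes.get(lin, 0))
    ]
    if cls == "archaeal_core":
        # universal archaeal genes sit in every reference genome
        ref_presence = {r: True for r in all_refs}
    elif cls.startswith("lineage_core"):
        ref_presence = {r: r in own_refs for r in all_refs}
        if len(own_refs) >= 3 and rng.random() < 0.2:
            ref_presence[own_refs[int(rng.integers(0, len(own_refs)))]] = False
    else:
        ref_presence = {r: False for r in all_refs}

    sim = _TreeSim(config.protein_length, rng)
    tax: TaxonomyMap = {}
    query_anc_holder: dict[str, np.ndarray] = {}

    def build_query(anc: np.ndarray):
        q = _evolve(anc, BL_QUERY_STEM, rng)
        query_anc_holder["q"] = q

    if cls == "orphan":
        root = sim.root()
        build_query(root)
    elif donor is None:
        root = sim.root()
        # archaeal neighborhood: query nested among other archaea
        arch_labels = []
        for p in OTHER_ARCHAEA:
            for i in range(2):
                lab = f"{fam_id}|arch_{p}_{i}"
                arch_labels.append(lab)
                tax[lab] = LeafTaxon("Archaea", p)
        sim.nested_clade(root, arch_labels, build_query, BL_DEEP, BL_WITHIN_PHYLUM)
        # distant bacterial outgroups: two phyla
        phyla = sorted(config.donor_phyla)
        chosen = [phyla[int(i)] for i in rng.choice(len(phyla), 2, replace=False)]
        for ph in chosen:
            labs = [f"{fam_id}|{ph}_{i}" for i in range(config.taxa_per_phylum)]
            for lab in labs:
                tax[lab] = LeafTaxon("Bacteria", ph)
            sim.clade(root, labs, BL_PHYLUM_STEM, BL_WITHIN_PHYLUM)
    else:
        root = sim.root()
        # donor phylum with the query nested inside
        labs = [f"{fam_id}|{donor}_{i}" for i in range(config.taxa_per_phylum)]
        for lab in labs:
            tax[lab] = LeafTaxon("Bacteria", donor)
        sim.nested_clade(root, labs, build_query, BL_PHYLUM_STEM, BL_WITHIN_PHYLUM)
        # other bacterial phyla
        for ph in sorted(set(config.donor_phyla) - {donor}):
            labs = [f"{fam_id}|{ph}_{i}" for i in range(config.taxa_per_phylum)]
            for lab in labs:
                tax[lab] = LeafTaxon("Bacteria", ph)
            sim.clade(root, labs, BL_PHYLUM_STEM, BL_WITHIN_PHYLUM)
        # distant archaeal homologs (the native paralog neighborhood)
        if rng.random() < 0.5:
            labs = [f"{fam_id}|arch_{OTHER_ARCHAEA[0]}_{i}" for i in range(3)]
            for lab in labs:
                tax[lab] = LeafTaxon("Archaea", OTHER_ARCHAEA[0])
            sim.clade(root, labs, BL_PHYLUM_STEM + BL_DEEP, BL_WITHIN_PHYLUM)

    q_anc = query_anc_holder["q"]
    query_seqs = {
        g: _to_str(_evolve(q_anc, config.strain_divergence, rng)) for g in carriers
    }
    return GeneFamily(
        id=fam_id,
        lineage=lineage,
        origin_class=cls,
        donor_phylum=donor,
        carriers=carriers,
        ref_presence=ref_presence,
        query_seqs=query_seqs,
        homolog_seqs={lab: _to_str(sim.tips[lab]) for lab in sorted(sim.tips)},
        homolog_taxonomy=tax,
        marker=marker,
        ribosomal=ribo,
    )


# ---------------------------------------------------------------------------
# Back-translation with GC control
# ---------------------------------------------------------------------------


def _gc_of(codon: str) -> int:
    return sum(1 for c in codon if c in "GC")


def codon_weights_for_gc(target_gc: float) -> dict[str, float]:
    """Within-family codon weights exp(lam*GC(codon)) tuned so the expected
    coding GC over a uniform amino-acid composition equals ``target_gc``.

    Raises when the target is outside the range the code can realize
    (roughly 0.26-0.74 for uniform amino-acid usage).
    """

    def expected_gc(lam: float) -> float:
        total = 0.0
        for aa, codons in SYNONYMS.items():
            ws = np.array([math.exp(lam * _gc_of(c)) for c in codons])
            ws /= ws.sum()
            gc = np.array([_gc_of(c) / 3.0 for c in codons])
            total += float((ws * gc).sum())
        return total / len(SYNONYMS)

    lo, hi = -12.0, 12.0
    if not expected_gc(lo) < target_gc < expected_gc(hi):
        raise ValueError(f"target GC {target_gc} outside achievable range")
    lam = brentq(lambda l: expected_gc(l) - target_gc, lo, hi, xtol=1e-10)
    out: dict[str, float] = {}
    for aa, codons in SYNONYMS.items():
        ws = np.array([math.exp(lam * _gc_of(c)) for c in codons])
        ws /= ws.sum()
        for c, w in zip(codons, ws):
            out[c] = float(w)
    return out


def back_translate(
    protein: str, weights: dict[str, float], rng: np.random.Generator
) -> str:
    codons = []
    for aa in protein:
        syn = SYNONYMS.get(aa)
        if syn is None:
            raise ValueError(f"cannot back-translate residue {aa!r}")
        ws = np.array([weights[c] for c in syn])
        codons.append(syn[int(rng.choice(len(syn), p=ws / ws.sum()))])
    codons.append(STOP_CODONS[int(rng.integers(0, len(STOP_CODONS)))])
    return "".join(codons)


def _random_nt(length: int, gc: float, rng: np.random.Generator) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


# ---------------------------------------------------------------------------
# emit_fosmid_library
# ---------------------------------------------------------------------------


@dataclass
class FosmidLibrary:
    fosmids: list[FosmidRecord]
    truth: pd.DataFrame
    families: list[GeneFamily]
    ref_inventory: dict[str, list[tuple[str, str]]]  # ref genome -> (gene, family)
    ref_seqs: dict[str, str]  # ref gene id -> protein
    config: CommunityConfig


def emit_fosmid_library(
    config: CommunityConfig, families: list[GeneFamily] | None = None
) -> FosmidLibrary:
    """Lay families out on genomes, back-translate, and cut into fosmids.

    Genes are tiled without overlap on alternating random strands with
    random intergenic spacers; fosmid lengths are drawn around
    ``fosmid_length_mean`` (sd 5% of the mean) and truncated at gene
    boundaries, so feature-table coordinates always cover whole genes.
    """
    config.validate()
    if families is None:
        families = simulate_species_forest(config)
    rng = np.random.default_rng(config.seed + 1)
    weights = {lin: codon_weights_for_gc(config.lineage_gc[lin]) for lin in LINEAGES}

    fosmids: list[FosmidRecord] = []
    truth_rows = []
    ref_inventory: dict[str, list[tuple[str, str]]] = {}
    ref_seqs: dict[str, str] = {}
    gene_counter = 0

    for lineage in LINEAGES:
        fams = [f for f in families if f.lineage == lineage]
        gc = config.lineage_gc[lineage]
        # reference genome inventories (gene lists only; no nucleotide layout)
        for f in fams:
            for ref, present in f.ref_presence.items():
                ref_inventory.setdefault(ref, [])
                if present:
                    gid = f"{ref}|{f.id}"
                    ref_inventory[ref].append((gid, f.id))
                    # a reference's copy: mildly diverged from the query pool
                    ref_seqs[gid] = next(iter(sorted(f.query_seqs.items())))[1]
        for genome in range(config.n_genomes):
            carried = [f for f in fams if genome in f.carriers]
            order = rng.permutation(len(carried))
            segments: list[tuple[str, GeneFamily | None]] = []
            for oi in order:
                fam = carried[oi]
                cds = back_translate(fam.query_seqs[genome], weights[lineage], rng)
                segments.append((cds, fam))
            genome_fosmids = _cut_fosmids(
                lineage, genome, segments, gc, config, rng
            )
            for fosmid, gene_rows in genome_fosmids:
                fosmids.append(fosmid)
                for g, fam in gene_rows:
                    g.id = f"g{gene_counter:06d}"
                    gene_counter += 1
                    g.family_id = fam.id
                    if fam.marker:
                        g.annotation = f"single-copy marker {fam.id}"
                    elif fam.ribosomal:
                        g.annotation = f"ribosomal protein {fam.id}"
                    fosmid.genes.append(g)
                    truth_rows.append(
                        {
                            "gene_id": g.id,
                            "family_id": fam.id,
                            "origin_class": fam.origin_class,
                            "donor_phylum": fam.donor_phylum or "",
                            "lineage": lineage,
                            "genome": f"{lineage}{genome}",
                            "fosmid_id": fosmid.id,
                            "marker": fam.marker,
                            "ribosomal": fam.ribosomal,
                        }
                    )
    truth = pd.DataFrame(truth_rows)
    return FosmidLibrary(
        fosmids=fosmids,
        truth=truth,
        families=families,
        ref_inventory=ref_inventory,
        ref_seqs=ref_seqs,
        config=config,
    )


def _cut_fosmids(lineage, genome, segments, gc, config, rng):
    """Tile CDS segments with spacers into a genome string, then cut it into
    fosmid-sized pieces at gene boundaries.  A genome tail shorter than 40%
    of the configured insert length is merged into the preceding fosmid
    rather than emitted as an implausibly short insert."""
    groups: list[tuple[list[str], list[tuple[GeneRecord, GeneFamily]], int]] = []
    current_seq: list[str] = []
    current_genes: list[tuple[GeneRecord, GeneFamily]] = []
    pos = 0
    target = _draw_length(config, rng)

    def flush():
        nonlocal current_seq, current_genes, pos, target
        if not current_genes:
            return
        groups.append((current_seq, current_genes, pos))
        current_seq, current_genes, pos = [], [], 0
        target = _draw_length(config, rng)

    for cds, fam in segments:
        spacer = _random_nt(int(rng.integers(20, 200)), gc, rng)
        current_seq.append(spacer)
        pos += len(spacer)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = cds if strand == "+" else revcomp(cds)
        g = GeneRecord(
            id="",
            fosmid_id="",
            start=pos,
            end=pos + len(cds),
            strand=strand,
            translation=fam.query_seqs[genome],
        )
        current_seq.append(placed)
        pos += len(cds)
        current_genes.append((g, fam))
        if pos >= target:
            flush()
    flush()

    if len(groups) > 1 and groups[-1][2] < 0.4 * config.fosmid_length_mean:
        seq_tail, genes_tail, len_tail = groups.pop()
        seq_prev, genes_prev, len_prev = groups.pop()
        for g, _ in genes_tail:
            g.start += len_prev
            g.end += len_prev
        groups.append((seq_prev + seq_tail, genes_prev + genes_tail, len_prev + len_tail))

    out = []
    for fosmid_idx, (seq_parts, genes, _) in enumerate(groups):
        fid = f"{lineage}{genome}_f{fosmid_idx}"
        rec = FosmidRecord(id=fid, sequence="".join(seq_parts), library=f"SIM_{lineage}")
        for g, _ in genes:
            g.fosmid_id = fid
        out.append((rec, genes))
    return out


def _draw_length(config, rng) -> int:
    mean = config.fosmid_length_mean
    return max(1000, int(rng.normal(mean, 0.05 * mean)))


# ---------------------------------------------------------------------------
# Derived inputs for the pipeline
# ---------------------------------------------------------------------------


def homology_hit_table(library: FosmidLibrary) -> pd.DataFrame:
    """All-vs-all within-family hit table (fosmid genes, reference genes and
    database homolog taxa), in the tabular pairwise-search format."""
    rows = []
    genes_by_family: dict[str, list[tuple[str, str]]] = {}
    for fos in library.fosmids:
        for g in fos.genes:
            genes_by_family.setdefault(g.family_id, []).append((g.id, g.translation))
    ref_by_family: dict[str, list[tuple[str, str]]] = {}
    for ref, inv in library.ref_inventory.items():
        for gid, fam in inv:
            ref_by_family.setdefault(fam, []).append((gid, library.ref_seqs[gid]))
    for fam in library.families:
        members = genes_by_family.get(fam.id, [])
        refs = ref_by_family.get(fam.id, [])
        homologs = [(lab, seq) for lab, seq in fam.homolog_seqs.items()]
        everything = members + refs + homologs
        for i in range(len(everything)):
            for j in range(i + 1, len(everything)):
                (qa, sa), (qb, sb) = everything[i], everything[j]
                ident = _pct_identity(sa, sb)
                rows.append(
                    {
                        "query": qa,
                        "subject": qb,
                        "percent_identity": ident,
                        "align_length": len(sa),
                        "e_value": 1e-50,
                        "bitscore": 200.0,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["query", "subject", "percent_identity", "align_length", "e_value", "bitscore"],
    )


def _pct_identity(a: str, b: str) -> float:
    same = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * same / max(len(a), 1)


def family_alignment(
    library: FosmidLibrary, fam: GeneFamily
) -> tuple[list[tuple[str, str]], TaxonomyMap]:
    """The per-family aligned sequences (query genes + database homologs)
    and leaf taxonomy, ready for tree inference."""
    align: list[tuple[str, str]] = []
    tax: TaxonomyMap = {}
    for fos in library.fosmids:
        for g in fos.genes:
            if g.family_id == fam.id:
                align.append((g.id, g.translation))
                tax[g.id] = LeafTaxon(
                    "Archaea", LINEAGE_PHYLUM[fam.lineage], is_query=True
                )
    for lab, seq in sorted(fam.homolog_seqs.items()):
        align.append((lab, seq))
        tax[lab] = fam.homolog_taxonomy[lab]
    return align, tax
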