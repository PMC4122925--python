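"""Codon usage tables, the codon adaptation index, and codon-usage PCA.

CAI (Sharp & Li) scores how closely a gene's synonymous codon choices track
those of a highly expressed reference set — here ribosomal-protein genes.
For each codon c encoding amino acid a, relative adaptiveness is
``w(c) = f(c) / max_{c' syn a} f(c')`` from reference counts (zero counts
smoothed to 0.5 before normalization), and a gene's CAI is the geometric
mean of w over its codons, excluding Met, Trp (no synonymous choice) and
stops.  CAI is 1 exactly when every countable codon is the reference-modal
one.

Codon-usage PCA embeds genes as 59-dimensional synonymous-frequency vectors
(64 codons minus 3 stops, ATG and TGG) via the shared PCA operation, which
is how lineage-level GC/codon divergence and the (absent) origin-class
signature are visualized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .composition_profile import pca_embed

_TABLE = CodonTable.unambiguous_dna_by_id[11]
STOP_CODONS = tuple(_TABLE.stop_codons)

#: amino acid -> tuple of synonymous codons (table 11)
SYNONYMS: dict[str, tuple[str, ...]] = {}
for codon, aa in _TABLE.forward_table.items():
    SYNONYMS.setdefault(aa, ())
    SYNONYMS[aa] = SYNONYMS[aa] + (codon,)

#: codons carrying synonymous information (excludes stops and the
#: single-codon families Met/ATG and Trp/TGG)
INFORMATIVE_CODONS = tuple(
    c
    for aa, codons in sorted(SYNONYMS.items())
    for c in sorted(codons)
    if len(codons) > 1
)

CODON_TO_AA = dict(_TABLE.forward_table)


@dataclass
class CodonUsageTable:
    counts: dict[str, float]
    frequency: dict[str, float]  # within synonymous family, sums to 1
    w: dict[str, float]  # relative adaptiveness, max 1 per family
    reference_id: str = ""


@dataclass
class CaiResult:
    gene_id: str
    cai: float
    reference_id: str
    n_codons: int
    flagged: bool = False


def codons_of(cds: str) -> list[str]:
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def usage_table(
    reference_cds: list[str], reference_id: str = "", pseudo: float = 0.5
) -> CodonUsageTable:
    """Codon usage of a reference gene set.

    Genes with premature internal stops are skipped (trailing stop codons are
    fine and excluded from counting).  Codons unseen in the reference get
    ``pseudo`` counts before frequencies and w are formed, so no gene scores
    an exact zero.
    """
    counts = {c: 0.0 for c in CODON_TO_AA}
    for cds in reference_cds:
        codons = codons_of(cds)
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        if any(c in STOP_CODONS for c in codons):
            continue  # premature internal stop: skip the gene
        for c in codons:
            if c in counts:
                counts[c] += 1.0
    for c in counts:
        if counts[c] == 0.0:
            counts[c] = pseudo
    frequency: dict[str, float] = {}
    w: dict[str, float] = {}
    for aa, codons in SYNONYMS.items():
        total = sum(counts[c] for c in codons)
        peak = max(counts[c] for c in codons)
        for c in codons:
            frequency[c] = counts[c] / total
            w[c] = counts[c] / peak
    return CodonUsageTable(counts=counts, frequency=frequency, w=w, reference_id=reference_id)


def cai(cds: str, table: CodonUsageTable, gene_id: str = "") -> CaiResult:
    """Geometric-mean relative adaptiveness of a gene's codons.

    Met, Trp and stop codons are excluded (they carry no synonymous choice);
    a gene with zero countable codons is flagged with CAI 1.0 by convention.
    """
    countable = [
        c
        for c in codons_of(cds)
        if c in CODON_TO_AA and len(SYNONYMS[CODON_TO_AA[c]]) > 1
    ]
    if not countable:
        return CaiResult(gene_id, 1.0, table.reference_id, 0, flagged=True)
    log_sum = sum(math.log(table.w[c]) for c in countable)
    return CaiResult(
        gene_id,
        math.exp(log_sum / len(countable)),
        table.reference_id,
        len(countable),
    )


def synonymous_frequency_vector(cds: str) -> np.ndarray:
    """Per-gene 59-dim within-family codon frequency vector."""
    counts = {c: 0 for c in INFORMATIVE_CODONS}
    for c in codons_of(cds):
        if c in counts:
            counts[c] += 1
    vec = np.zeros(len(INFORMATIVE_CODONS))
    for i, c in enumerate(INFORMATIVE_CODONS):
        aa = CODON_TO_AA[c]
        fam_total = sum(counts[x] for x in SYNONYMS[aa] if x in counts)
        if fam_total:
            vec[i] = counts[c] / fam_total
    return vec


def usage_pca(
    cds_by_gene: dict[str, str], n_components: int = 2
):
    """PCA embedding of genes in synonymous-codon-frequency space.

    Returns ``(gene_ids, coordinates, explained_variance_ratio)``.  Genes
    whose informative codon families are all empty embed at the origin of
    the frequency space (flag them upstream if needed).
    """
    if len(cds_by_gene) < 2:
        raise ValueError("need at least 2 genes")
    ids = sorted(cds_by_gene)
    X = np.stack([synonymous_frequency_vector(cds_by_gene[g]) for g in ids])
    coords, evr, _ = pca_embed(X, n_components=n_components)
    return ids, coords, evr
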