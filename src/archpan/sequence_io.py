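"""Reading, writing and gene finding on fosmid-sized nucleotide records.

The pipeline's unit of input is a fosmid: a ~36-kb cloned environmental DNA
insert carrying a handful of physically linked genes.  This module holds the
on-disk formats (FASTA for sequences, a GFF3-like tab-separated feature table
for genes, BLAST-style tabular hit tables) and the two gene-level operations
that precede everything else: six-frame ORF calling and similarity-based gene
validation.

Coordinates are 0-based half-open on the forward strand everywhere in memory;
the feature-table writer converts to 1-based inclusive for interoperability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = set("ACGTN")
START_CODONS = ("ATG", "GTG", "TTG")
TRANSLATION_TABLE = 11

#: Column order of the de-facto tabular pairwise-search format.
HIT_COLUMNS = [
    "query",
    "subject",
    "percent_identity",
    "align_length",
    "e_value",
    "bitscore",
]

FEATURE_COLUMNS = [
    "fosmid_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "family_id",
    "annotation",
    "origin_class",
    "translation",
]


@dataclass
class GeneRecord:
    """One predicted gene on a fosmid.

    ``start``/``end`` are 0-based half-open forward-strand coordinates; the
    interval includes the stop codon when one is present, so a complete CDS
    satisfies ``(end - start) % 3 == 0`` and ``len(translation) ==
    (end - start) // 3 - 1``.
    """

    id: str
    fosmid_id: str
    start: int
    end: int
    strand: str
    translation: str
    annotation: str = ""
    cog_class: str | None = None
    kegg_class: str | None = None
    origin_class: str | None = None
    family_id: str | None = None
    provisional: bool = False


@dataclass
class FosmidRecord:
    """A fosmid insert with its predicted genes."""

    id: str
    sequence: str
    library: str = ""
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - NUCLEOTIDES
        if bad:
            raise ValueError(f"non-nucleotide characters in {self.id}: {sorted(bad)}")
        self.sequence = self.sequence.upper()


# ---------------------------------------------------------------------------
# ORF calling
# ---------------------------------------------------------------------------


def _orfs_one_strand(seq: str, min_aa: int):
    """Yield (start, end, translation) for ORFs on the given forward string.

    Stop-to-stop frames are scanned in each of the three reading frames; the
    CDS starts at the first ATG/GTG/TTG downstream of the previous stop and
    runs through the stop codon (or the end of the frame when no stop
    follows, for genes truncated at the insert boundary).
    """
    n = len(seq)
    stops = {"TAA", "TAG", "TGA"}
    for frame in range(3):
        region_start = frame
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if codon in stops:
                yield from _emit_orf(seq, region_start, pos + 3, True, min_aa)
                region_start = pos + 3
                pos += 3
                continue
            pos += 3
        # trailing region without a stop codon (truncated at the edge)
        yield from _emit_orf(seq, region_start, pos, False, min_aa)


def _emit_orf(seq: str, region_start: int, region_end: int, has_stop: bool, min_aa: int):
    # locate the first start codon within the stop-to-stop region
    cds_start = None
    limit = region_end - 3 if has_stop else region_end
    for p in range(region_start, limit, 3):
        if seq[p : p + 3] in START_CODONS:
            cds_start = p
            break
    if cds_start is None:
        return
    cds = seq[cds_start:region_end]
    if len(cds) < 3:
        return
    aa = str(Seq(cds).translate(table=TRANSLATION_TABLE))
    if has_stop:
        aa = aa[:-1]
    if len(aa) >= min_aa:
        yield cds_start, region_end, aa


def find_orfs(record: FosmidRecord, min_aa: int = 30) -> list[GeneRecord]:
    """Call candidate CDS on both strands of a fosmid.

    All maximal stop-to-stop frames with a start codon and a translation of
    at least ``min_aa`` residues are returned, translated with the bacterial
    / archaeal / plastid genetic code (table 11).  ``N`` bases are tolerated
    and translate to ``X``.  Coordinates are always reported on the forward
    strand, so a minus-strand ORF's ``start`` is the genomic position of its
    stop codon's last base minus the CDS length.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = record.sequence
    out: list[GeneRecord] = []
    n = len(seq)
    for start, end, aa in _orfs_one_strand(seq, min_aa):
        out.append(_make_candidate(record.id, start, end, "+", aa, len(out)))
    rc = str(Seq(seq).reverse_complement())
    for start, end, aa in _orfs_one_strand(rc, min_aa):
        out.append(_make_candidate(record.id, n - end, n - start, "-", aa, len(out)))
    out.sort(key=lambda g: (g.start, g.end, g.strand))
    for i, g in enumerate(out):
        g.id = f"{record.id}_orf{i:04d}"
    return out


def _make_candidate(fosmid_id, start, end, strand, aa, idx) -> GeneRecord:
    return GeneRecord(
        id=f"{fosmid_id}_tmp{idx}",
        fosmid_id=fosmid_id,
        start=start,
        end=end,
        strand=strand,
        translation=aa,
    )


# ---------------------------------------------------------------------------
# Gene validation
# ---------------------------------------------------------------------------

#: Hit sources treated as motif/profile evidence rather than full-length
#: similarity; these validate a candidate only at the stricter motif cutoff.
MOTIF_SOURCES = {"cdd", "cog", "pfam", "motif", "smart", "tigr", "prk", "kog"}


def validate_genes(
    candidates: list[GeneRecord],
    hit_table: pd.DataFrame | None,
    evalue_gene: float = 1e-10,
    evalue_motif: float = 1e-5,
    min_orphan_aa: int = 100,
    rna_features: list[tuple[str, int, int]] | None = None,
) -> list[GeneRecord]:
    """Filter ORF candidates into validated genes.

    A candidate is accepted when its best database hit has e-value at or
    below ``evalue_gene`` (inclusive), or — when its only evidence is a
    motif/profile source — at or below ``evalue_motif``.  Hitless candidates
    shorter than ``min_orphan_aa`` residues are dropped as small orphans;
    longer hitless candidates are kept (they may be genuine lineage-specific
    genes).  Candidates overlapping structural-RNA features are dropped.
    With no hit table at all, every candidate passes as a provisional gene.
    """
    rna = rna_features or []
    kept: list[GeneRecord] = []
    if hit_table is None:
        for c in candidates:
            if _overlaps_rna(c, rna):
                continue
            kept.append(replace(c, provisional=True))
        return kept

    best = _best_hits(hit_table)
    for c in candidates:
        if _overlaps_rna(c, rna):
            continue
        hit = best.get(c.id)
        if hit is None:
            if len(c.translation) >= min_orphan_aa:
                kept.append(c)
            continue
        evalue, source, annotation = hit
        threshold = evalue_motif if source in MOTIF_SOURCES else evalue_gene
        if evalue <= threshold:
            g = replace(c)
            if annotation:
                g.annotation = annotation
            kept.append(g)
    return kept


def _best_hits(hit_table: pd.DataFrame) -> dict[str, tuple[float, str, str]]:
    best: dict[str, tuple[float, str, str]] = {}
    source_col = "source" in hit_table.columns
    ann_col = "annotation" in hit_table.columns
    for row in hit_table.itertuples(index=False):
        ev = float(row.e_value)
        src = str(getattr(row, "source", "")).lower() if source_col else ""
        ann = str(getattr(row, "annotation", "")) if ann_col else ""
        cur = best.get(row.query)
        if cur is None or ev < cur[0]:
            best[row.query] = (ev, src, ann)
    return best


def _overlaps_rna(gene: GeneRecord, rna: list[tuple[str, int, int]]) -> bool:
    return any(
        fid == gene.fosmid_id and gene.start < end and start < gene.end
        for fid, start, end in rna
    )


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def write_fasta(records: list[FosmidRecord], path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.library) for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> list[FosmidRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(
            FosmidRecord(id=rec.id, sequence=str(rec.seq), library=rec.description.split(" ", 1)[-1] if " " in rec.description else "")
        )
    return out


def write_feature_table(records: list[FosmidRecord], path) -> None:
    """Write genes as a GFF3-like TSV with 1-based inclusive coordinates."""
    rows = []
    for r in records:
        for g in r.genes:
            rows.append(
                {
                    "fosmid_id": g.fosmid_id,
                    "gene_id": g.id,
                    "start": g.start + 1,
                    "end": g.end,
                    "strand": g.strand,
                    "family_id": g.family_id or "",
                    "annotation": g.annotation,
                    "origin_class": g.origin_class or "",
                    "translation": g.translation,
                }
            )
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> dict[str, list[GeneRecord]]:
    """Read a feature table back into per-fosmid gene lists (0-based)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    out: dict[str, list[GeneRecord]] = {}
    for row in df.itertuples(index=False):
        g = GeneRecord(
            id=row.gene_id,
            fosmid_id=row.fosmid_id,
            start=int(row.start) - 1,
            end=int(row.end),
            strand=row.strand,
            translation=row.translation,
            annotation=row.annotation,
            origin_class=row.origin_class or None,
            family_id=row.family_id or None,
        )
        out.setdefault(g.fosmid_id, []).append(g)
    return out


def attach_features(records: list[FosmidRecord], table: dict[str, list[GeneRecord]]) -> None:
    for r in records:
        r.genes = table.get(r.id, [])


def read_hit_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    return df


def write_hit_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def gc_content(sequences) -> float:
    """Fraction of G+C over one or more sequences (Ns ignored)."""
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = total = 0
    for s in sequences:
        s = s.upper()
        gc += s.count("G") + s.count("C")
        total += len(s) - s.count("N")
    if total == 0:
        return math.nan
    return gc / total
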