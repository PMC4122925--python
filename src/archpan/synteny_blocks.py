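"""Synteny blocks of same-origin genes and their bounding-couple statistics.

A synteny block is a maximal run of contiguous genes of the same origin class
along a fosmid (five classes: archaeal core, lineage-specific core, early HT,
late HT, other).  Because a block's two flanks each take one of the five
classes, every interior block falls into one of 15 = 5+4+3+2+1 unordered
bounding-couple categories; the per-(lineage x class) couple-count matrix and
the per-class mean block length measure whether transferred genes arrive and
persist as single insertions scattered among native genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

BLOCK_CLASSES = (
    "archaeal_core",
    "lineage_core",
    "early_hgt",
    "late_hgt",
    "other",
)


@dataclass
class SyntenyBlock:
    fosmid_id: str
    origin_class: str
    start: int  # gene index, 0-based half-open
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def build_blocks(fosmid_id: str, classes: list[str]) -> list[SyntenyBlock]:
    """Run-length encode a fosmid's ordered gene classes into blocks."""
    blocks: list[SyntenyBlock] = []
    start = 0
    for i in range(1, len(classes) + 1):
        if i == len(classes) or classes[i] != classes[start]:
            blocks.append(SyntenyBlock(fosmid_id, classes[start], start, i))
            start = i
    return blocks


def couple_categories(k_classes: int, class_names=None) -> list[tuple]:
    """The k(k+1)/2 unordered flank-class pairs."""
    if k_classes < 1:
        raise ValueError("k_classes must be >= 1")
    names = list(class_names) if class_names else list(range(k_classes))
    if len(names) != k_classes:
        raise ValueError("class_names length must equal k_classes")
    return list(combinations_with_replacement(sorted(names, key=str), 2))


def couple_matrix(
    blocks_per_fosmid: dict[str, list[SyntenyBlock]],
    k_classes: int = 5,
    class_names=BLOCK_CLASSES,
    row_key=None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Bounding-couple occurrence matrix.

    Rows are block classes (or ``row_key(block)`` labels, e.g. lineage x
    class); columns the unordered flank pairs.  Terminal blocks have at most
    one flank, contribute no couple, and are tallied separately in the
    returned dict so totals stay auditable.
    """
    cats = couple_categories(k_classes, class_names)
    col_names = [f"{a}|{b}" for a, b in cats]
    col_index = {frozenset((a, b)): f"{a}|{b}" for a, b in cats}
    label = row_key or (lambda b: b.origin_class)
    rows: dict[str, dict[str, int]] = {}
    terminal = 0
    for blocks in blocks_per_fosmid.values():
        for i, b in enumerate(blocks):
            if i == 0 or i == len(blocks) - 1:
                terminal += 1
                continue
            couple = frozenset((blocks[i - 1].origin_class, blocks[i + 1].origin_class))
            col = col_index[couple]
            rows.setdefault(label(b), {c: 0 for c in col_names})
            rows[label(b)][col] += 1
    df = pd.DataFrame.from_dict(rows, orient="index", columns=col_names).fillna(0).astype(int)
    df = df.sort_index()
    return df, {"terminal_blocks": terminal}


def mean_block_length(blocks: list[SyntenyBlock]) -> dict[str, float]:
    """Arithmetic mean block length (in genes) per origin class.

    Classes with no blocks are absent from the result, not reported as zero.
    """
    sums: dict[str, list[int]] = {}
    for b in blocks:
        sums.setdefault(b.origin_class, []).append(b.length)
    return {c: sum(v) / len(v) for c, v in sums.items()}


def cluster_couple_patterns(matrix: pd.DataFrame):
    """Average-linkage clustering of row-normalized couple counts.

    Rows are sorted by label first so scipy's deterministic agglomeration
    gives a reproducible tree; returns ``(linkage_matrix, leaf_labels,
    newick)``.
    """
    if len(matrix) < 1:
        raise ValueError("empty matrix")
    matrix = matrix.sort_index()
    labels = list(matrix.index)
    if len(matrix) == 1:
        return np.zeros((0, 4)), labels, f"({labels[0]});"
    X = matrix.to_numpy(dtype=float)
    row_sums = X.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    Xn = X / row_sums
    Z = linkage(pdist(Xn, metric="euclidean"), method="average")
    return Z, labels, linkage_to_newick(Z, labels)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    nodes: dict[int, str] = {i: labels[i] for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    for i, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nodes[n + i] = f"({nodes[a]}:{la:.6f},{nodes[b]}:{lb:.6f})"
        heights[n + i] = h
    return nodes[n + len(Z) - 1] + ";"
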