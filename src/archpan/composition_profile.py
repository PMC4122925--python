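"""Compositional signatures for binning fosmids without reference genomes.

Two signals are computed per fosmid: k-mer (tetra/pentanucleotide) z-scores
against a maximal-order Markov null, used with PCA to separate archaeal
lineages by genome-wide composition; and per-fosmid taxon-affiliation
percentage profiles, partitioned by quality-threshold (QT) clustering.

The z-score of word ``w = n1..nk`` compares its observed count with the
expectation under a Markov chain of order k-2 fitted to the same sequence:

    E(w) = N(n1..nk-1) * N(n2..nk) / N(n2..nk-1)
    V(w) = E(w) * (N(core)-N(prefix)) * (N(core)-N(suffix)) / N(core)^2
    z(w) = (obs(w) - E(w)) / sqrt(V(w))

Counts are strand-symmetric: words are counted on the sequence and on its
reverse complement and summed, so a fosmid and its reverse complement yield
identical profiles regardless of cloning orientation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

TAXON_CATEGORIES = [
    "Archaea",
    "Bacteria",
    "Eucarya",
    "viruses",
    "Crenarchaeota",
    "Euryarchaeota",
    "Thaumarchaeota",
    "Nanoarchaeota",
    "Korarchaeota",
    "unclassified archaea",
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def kmer_words(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


@dataclass
class TetraProfile:
    fosmid_id: str
    k: int
    z: np.ndarray
    undefined: np.ndarray  # flags: True where variance was undefined

    @property
    def words(self) -> list[str]:
        return kmer_words(self.k)


def _count_words(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for strand in (seq, revcomp(seq)):
        for i in range(len(strand) - k + 1):
            w = strand[i : i + k]
            counts[w] = counts.get(w, 0) + 1
    return counts


def kmer_zscores(sequence: str, k: int = 4, fosmid_id: str = "") -> TetraProfile:
    """Markov-null z-score profile of all 4^k words of a sequence.

    Words containing ambiguous bases are skipped by construction (they never
    match an ACGT word).  Words whose null variance is undefined or
    non-positive get z = 0 and a flag.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(sequence) < k + 2:
        raise ValueError("sequence shorter than k + 2")
    seq = sequence.upper()
    ck = _count_words(seq, k)
    ck1 = _count_words(seq, k - 1)
    ck2 = _count_words(seq, k - 2) if k > 2 else None

    words = kmer_words(k)
    z = np.zeros(len(words))
    undefined = np.zeros(len(words), dtype=bool)
    total_k2 = None
    if ck2 is None:
        # k == 2: the core is the empty word; its count is the number of
        # counted positions, making the null a zero-order (mononucleotide) one
        total_k2 = sum(ck1.values())
    for i, w in enumerate(words):
        obs = ck.get(w, 0)
        n_pre = ck1.get(w[:-1], 0)
        n_suf = ck1.get(w[1:], 0)
        n_core = ck2.get(w[1:-1], 0) if ck2 is not None else total_k2
        if n_core == 0:
            undefined[i] = True
            continue
        e = n_pre * n_suf / n_core
        v = e * (n_core - n_pre) * (n_core - n_suf) / n_core**2
        if v <= 0:
            undefined[i] = True
            continue
        z[i] = (obs - e) / np.sqrt(v)
    return TetraProfile(fosmid_id=fosmid_id, k=k, z=z, undefined=undefined)


# ---------------------------------------------------------------------------
# PCA embedding
# ---------------------------------------------------------------------------


def pca_embed(
    matrix: np.ndarray,
    n_components: int = 2,
    scale: bool = False,
):
    """Center (optionally scale) rows of profile matrix and embed by PCA.

    Returns ``(coordinates, explained_variance_ratio, components)``.  Signs
    are fixed so the largest-magnitude loading of every component is
    positive, making the embedding deterministic across runs and platforms.
    A constant (zero-variance) input yields all-zero coordinates.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    if not np.any(Xc):
        n = min(n_components, min(X.shape))
        return np.zeros((X.shape[0], n)), np.zeros(n), np.zeros((n, X.shape[1]))
    n = min(n_components, min(X.shape[0] - 1, X.shape[1]))
    pca = PCA(n_components=n, svd_solver="full")
    coords = pca.fit_transform(Xc)
    comps = pca.components_
    for j in range(n):
        i_max = np.argmax(np.abs(comps[j]))
        if comps[j, i_max] < 0:
            comps[j] = -comps[j]
            coords[:, j] = -coords[:, j]
    return coords, pca.explained_variance_ratio_, comps


# ---------------------------------------------------------------------------
# QT clustering of taxon profiles
# ---------------------------------------------------------------------------


@dataclass
class TaxProfile:
    """Percentages of a fosmid's genes affiliating to broad taxon categories."""

    fosmid_id: str
    percentages: dict[str, float] = field(default_factory=dict)

    def vector(self) -> np.ndarray:
        return np.array([self.percentages.get(c, 0.0) for c in TAXON_CATEGORIES])


def _diameter(dist: np.ndarray, members: tuple[int, ...]) -> float:
    if len(members) < 2:
        return 0.0
    idx = np.array(members)
    return float(dist[np.ix_(idx, idx)].max())


def qt_cluster(profiles: list[TaxProfile], diameter: float = 30.0) -> list[list[str]]:
    """Quality-threshold partition of taxon profiles.

    Repeatedly extracts the largest set of profiles whose maximum pairwise
    Euclidean distance does not exceed ``diameter`` (i.e. a maximum clique of
    the threshold graph), breaking ties by lowest realized diameter and then
    by smallest member id, until all profiles are assigned.  Singletons are
    allowed.  Exact rather than seed-grown: worst case is exponential, which
    is acceptable at per-library fosmid counts.
    """
    import networkx as nx

    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    if not profiles:
        return []
    ids = [p.fosmid_id for p in profiles]
    X = np.stack([p.vector() for p in profiles])
    dist = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))

    remaining = list(range(len(profiles)))
    clusters: list[list[str]] = []
    while remaining:
        g = nx.Graph()
        g.add_nodes_from(remaining)
        for a, b in itertools.combinations(remaining, 2):
            if dist[a, b] <= diameter:
                g.add_edge(a, b)
        best: tuple | None = None
        for clique in nx.find_cliques(g):
            cand = tuple(sorted(clique, key=lambda i: ids[i]))
            key = (-len(cand), _diameter(dist, cand), tuple(ids[i] for i in cand))
            if best is None or key < best[0]:
                best = (key, cand)
        members = best[1]
        clusters.append([ids[i] for i in members])
        taken = set(members)
        remaining = [i for i in remaining if i not in taken]
    return clusters
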