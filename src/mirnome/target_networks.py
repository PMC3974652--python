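"""Seed-site target prediction and tissue regulatory networks.

Targets are exact reverse-complement matches of the miRNA seed (mature
positions 2-7) in 3'UTRs, classified 6mer / 7mer-1A / 7mer-m8 / 8mer by
flanking matches, pruned near the UTR boundary, filtered by expression
anti-correlation across tissues, and assembled into per-tissue
bipartite networks (permissive: down-miRNA -> up-mRNA; repressive:
up-miRNA -> down-mRNA) over a protein-interaction backbone.  Satellite
analyses: tissue clustering with resampling node support, 5p/3p arm
ratios, family enrichment, lincRNA sponge detection, quantile
normalization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from ._seq import Interval, revcomp

DEFAULT_END_EXCLUSION = 15
DEFAULT_ANTICORR_THRESHOLD = -0.7
DEFAULT_SPONGE_THRESHOLD = 0.9
DEFAULT_OVERLAP_THRESHOLD = 40.0
DEFAULT_MAX_GAP = 50_000
DEFAULT_TAIL_LEN = 894


# ---------------------------------------------------------------------------
# transcript redundancy filter
# ---------------------------------------------------------------------------


def dedupe_transcripts(
    clusters: dict[str, Interval],
    annotated: dict[str, Interval],
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> dict[str, Interval]:
    """Drop a cluster iff it overlaps an annotated transcript by more
    than ``overlap_threshold`` percent of the cluster's own length."""
    retained = {}
    for cid, civ in clusters.items():
        frac = max(
            (civ.overlap(aiv) / len(civ) for aiv in annotated.values()),
            default=0.0,
        )
        if frac * 100.0 <= overlap_threshold:
            retained[cid] = civ
    return retained


# ---------------------------------------------------------------------------
# UTR derivation from alignment chains
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UtrRecord:
    transcript_id: str
    source: str  # "annotated" | "tail-894"
    sequence: str
    interval: Interval | None = None


def _best_chain(
    blocks: list[Interval], max_gap: int
) -> list[Interval]:
    """Most extended co-linear chain (max total aligned length).

    Blocks chain when consecutive (in genomic order) with an
    inter-block gap <= ``max_gap``.  Exhaustive over maximal runs: a
    chain is a run of consecutive blocks all within gap range, so the
    optimum is a contiguous run after sorting.
    """
    blocks = sorted(blocks, key=lambda b: b.start)
    best: list[Interval] = []
    best_len = -1
    i = 0
    while i < len(blocks):
        chain = [blocks[i]]
        j = i
        while (
            j + 1 < len(blocks)
            and blocks[j + 1].start - blocks[j].end - 1 <= max_gap
        ):
            chain.append(blocks[j + 1])
            j += 1
        total = sum(len(b) for b in chain)
        if total > best_len:
            best, best_len = chain, total
        i = j + 1
    return best


def derive_utr(
    transcript_id: str,
    blocks: list[Interval],
    genome: str,
    strand: str = "+",
    max_gap: int = DEFAULT_MAX_GAP,
    tail_len: int = DEFAULT_TAIL_LEN,
) -> UtrRecord:
    """Chain alignment blocks and take the covered tail toward the 3' end.

    The returned sequence concatenates the covered (block) positions of
    the best chain, truncated to the last ``tail_len`` nucleotides in
    transcript orientation (strand-aware).
    """
    if not blocks:
        raise ValueError(f"{transcript_id}: no alignment blocks")
    chain = _best_chain(blocks, max_gap)
    covered = "".join(genome[b.start - 1 : b.end] for b in chain)
    if strand == "-":
        covered = revcomp(covered)
    tail = covered[-tail_len:]
    span = Interval(chain[0].start, chain[-1].end, strand)
    return UtrRecord(transcript_id, "tail-894", tail, span)


# ---------------------------------------------------------------------------
# seed-site prediction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    position: int  # 1-based start of the seed match in the UTR
    site_class: str  # 6mer | 7mer-1A | 7mer-m8 | 8mer

    @property
    def distance_to_utr_start(self) -> int:
        return self.position


def seed_of(mature_sequence: str) -> str:
    """Seed = mature positions 2-7."""
    seq = mature_sequence.upper().replace("U", "T")
    if len(seq) < 8:
        raise ValueError("mature sequence too short for a seed")
    return seq[1:7]


def _classify_site(utr: str, i: int, mature: str) -> str:
    """Site class at 0-based UTR offset ``i`` of the 6-nt seed match."""
    m8_match = False
    if i > 0 and len(mature) >= 8:
        # UTR base 5' of the seed match pairs mature position 8
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        m8_match = utr[i - 1] == comp.get(mature[7], "?")
    a1 = i + 6 < len(utr) and utr[i + 6] == "A"
    if m8_match and a1:
        return "8mer"
    if m8_match:
        return "7mer-m8"
    if a1:
        return "7mer-1A"
    return "6mer"


def predict_targets(
    matures: dict[str, str],
    utrs: dict[str, str] | list[UtrRecord],
    end_exclusion: int = DEFAULT_END_EXCLUSION,
    exclusion_side: str = "5prime",
) -> list[TargetSite]:
    """Exact seed-complement scan over each UTR.

    ``matures`` maps miRNA id to mature sequence.  Sites closer than
    ``end_exclusion`` to the excluded UTR boundary are removed
    (``exclusion_side`` selects which boundary; default the 5'
    post-stop-codon side).
    """
    if isinstance(utrs, list):
        utrs = {u.transcript_id: u.sequence for u in utrs}
    sites: list[TargetSite] = []
    for mirna_id, mature in sorted(matures.items()):
        mature = mature.upper().replace("U", "T")
        seed = seed_of(mature)
        if any(b not in "ACGT" for b in seed):
            raise ValueError(f"{mirna_id}: degenerate seed {seed}")
        probe = revcomp(seed)
        for transcript_id, utr in sorted(utrs.items()):
            utr_u = utr.upper().replace("U", "T")
            start = 0
            while True:
                i = utr_u.find(probe, start)
                if i < 0:
                    break
                start = i + 1
                pos = i + 1  # 1-based
                if exclusion_side == "5prime":
                    if pos < end_exclusion:
                        continue
                else:  # distance from the 3' terminus
                    if len(utr_u) - (i + 6) < end_exclusion:
                        continue
                sites.append(
                    TargetSite(
                        mirna_id, transcript_id, pos, _classify_site(utr_u, i, mature)
                    )
                )
    return sites


# ---------------------------------------------------------------------------
# anti-correlation filter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilteredTarget:
    site: TargetSite
    pearson_r: float
    passes: bool
    n_sites: int = 1


def _pearson_rows(
    a: pd.Series, b: pd.Series
) -> float | None:
    x = a.to_numpy(dtype=float)
    y = b.to_numpy(dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        return None
    x, y = x[mask], y[mask]
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return None
    return float(np.corrcoef(x, y)[0, 1])


def anticorrelation_filter(
    sites: list[TargetSite],
    mirna_matrix: pd.DataFrame,
    mrna_matrix: pd.DataFrame,
    threshold: float = DEFAULT_ANTICORR_THRESHOLD,
) -> list[FilteredTarget]:
    """Per (miRNA, transcript) pair, Pearson r across tissues.

    Multiple sites on one transcript collapse to one record (site count
    kept).  Pairs with undefined correlation (zero variance) are
    excluded.  Passes iff r <= threshold.
    """
    if list(mirna_matrix.columns) != list(mrna_matrix.columns):
        raise ValueError("miRNA and mRNA matrices must share tissue columns")
    if mirna_matrix.shape[1] < 3:
        raise ValueError("need at least 3 tissues")
    pairs: dict[tuple[str, str], list[TargetSite]] = {}
    for s in sites:
        pairs.setdefault((s.mirna_id, s.transcript_id), []).append(s)
    out: list[FilteredTarget] = []
    for (mirna_id, transcript_id), group in sorted(pairs.items()):
        if mirna_id not in mirna_matrix.index or transcript_id not in mrna_matrix.index:
            continue
        r = _pearson_rows(
            mirna_matrix.loc[mirna_id], mrna_matrix.loc[transcript_id]
        )
        if r is None:
            continue
        best = min(group, key=lambda s: s.position)
        out.append(FilteredTarget(best, r, r <= threshold, n_sites=len(group)))
    return out


# ---------------------------------------------------------------------------
# tissue networks
# ---------------------------------------------------------------------------


@dataclass
class RegulatoryNetwork:
    tissue: str
    graph: nx.Graph  # node attrs: kind, log2_ratio, state; edge attrs: kind, partition
    modules: dict[str, int] = field(default_factory=dict)

    def partition_edges(self, side: str) -> list[tuple[str, str]]:
        return [
            (u, v)
            for u, v, d in self.graph.edges(data=True)
            if d.get("partition") == side
        ]

    def validate(self) -> None:
        """Assert bipartition soundness and edge typing."""
        for u, v, d in self.graph.edges(data=True):
            if d["kind"] == "targeting":
                mir, mr = (u, v) if self.graph.nodes[u]["kind"] == "miRNA" else (v, u)
                if self.graph.nodes[mir]["kind"] != "miRNA":
                    raise AssertionError("targeting edge without a miRNA end")
                if self.graph.nodes[mr]["kind"] != "mRNA":
                    raise AssertionError("targeting edge without an mRNA end")
                ms = self.graph.nodes[mir]["state"]
                rs = self.graph.nodes[mr]["state"]
                if d["partition"] == "permissive" and not (ms < 0 < rs):
                    raise AssertionError("permissive edge with wrong signs")
                if d["partition"] == "repressive" and not (rs < 0 < ms):
                    raise AssertionError("repressive edge with wrong signs")


def _log2_states(
    matrix: pd.DataFrame, tissue: str, dead_zone: float
) -> dict[str, tuple[float, int]]:
    """id -> (log2 ratio vs across-tissue mean, sign state); NaN skipped."""
    out: dict[str, tuple[float, int]] = {}
    for name, row in matrix.iterrows():
        vals = row.to_numpy(dtype=float)
        v = row[tissue]
        mean = np.nanmean(vals)
        if not np.isfinite(v) or not np.isfinite(mean) or v <= 0 or mean <= 0:
            continue  # below-detection semantics: excluded
        ratio = float(np.log2(v / mean))
        state = 0
        if ratio > dead_zone:
            state = 1
        elif ratio < -dead_zone:
            state = -1
        out[str(name)] = (ratio, state)
    return out


def build_tissue_network(
    filtered_targets: list[FilteredTarget],
    interaction_edges: list[tuple[str, str]],
    mirna_matrix: pd.DataFrame,
    mrna_matrix: pd.DataFrame,
    tissue: str,
    dead_zone: float = 0.0,
) -> RegulatoryNetwork:
    """Assemble one tissue's bipartite regulatory network.

    Nodes carry log2(tissue / across-tissue mean) and its sign;
    below-detection nodes are excluded.  Passing targeting edges join
    down-miRNA -> up-mRNA (permissive) or up-miRNA -> down-mRNA
    (repressive); sign patterns matching neither side are dropped for
    this tissue.  Interaction edges connect expressed mRNAs and inherit
    the partition of the targeting edges in their component (interaction
    edges bridging no targeting edge stay unpartitioned).
    """
    if tissue not in mirna_matrix.columns or tissue not in mrna_matrix.columns:
        raise ValueError(f"tissue {tissue!r} absent from matrices")
    mir_states = _log2_states(mirna_matrix, tissue, dead_zone)
    mrna_states = _log2_states(mrna_matrix, tissue, dead_zone)

    g = nx.Graph(tissue=tissue)

    def add_node(name: str, kind: str, states: dict) -> bool:
        if name not in states:
            return False
        ratio, state = states[name]
        g.add_node(name, kind=kind, log2_ratio=ratio, state=state)
        return True

    for ft in filtered_targets:
        if not ft.passes:
            continue
        mir, mr = ft.site.mirna_id, ft.site.transcript_id
        if mir not in mir_states or mr not in mrna_states:
            continue
        ms = mir_states[mir][1]
        rs = mrna_states[mr][1]
        if ms < 0 < rs:
            side = "permissive"
        elif rs < 0 < ms:
            side = "repressive"
        else:
            continue
        add_node(mir, "miRNA", mir_states)
        add_node(mr, "mRNA", mrna_states)
        g.add_edge(
            mir,
            mr,
            kind="targeting",
            partition=side,
            pearson_r=ft.pearson_r,
            n_sites=ft.n_sites,
        )
    for a, b in interaction_edges:
        if a in mrna_states and b in mrna_states and a != b:
            add_node(a, "mRNA", mrna_states)
            add_node(b, "mRNA", mrna_states)
            if not g.has_edge(a, b):
                g.add_edge(a, b, kind="interaction", partition=None)

    # interaction edges inherit the partition of targeting edges in
    # their connected component (bipartite layout per component)
    for comp in nx.connected_components(g):
        sides = {
            d["partition"]
            for u, v, d in g.subgraph(comp).edges(data=True)
            if d["kind"] == "targeting"
        }
        if len(sides) == 1:
            side = sides.pop()
            for u, v, d in g.subgraph(comp).edges(data=True):
                if d["kind"] == "interaction":
                    g.edges[u, v]["partition"] = side

    net = RegulatoryNetwork(tissue=tissue, graph=g)
    net.modules = decompose_modules(net)
    return net


def decompose_modules(network: RegulatoryNetwork) -> dict[str, int]:
    """Connected components per partition side, largest first.

    Components are ordered by (node count desc, edge count desc, then
    lexicographically smallest member) and numbered from 1; every node
    of the component gets the module label.
    """
    g = network.graph
    comps = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        comps.append((-len(comp), -sub.number_of_edges(), sorted(comp)[0], comp))
    comps.sort(key=lambda t: t[:3])
    labels: dict[str, int] = {}
    for i, (_, _, _, comp) in enumerate(comps, start=1):
        for node in comp:
            labels[node] = i
    return labels


# ---------------------------------------------------------------------------
# satellite analyses
# ---------------------------------------------------------------------------


def _corr_linkage(matrix: np.ndarray) -> np.ndarray:
    """Average linkage on 1 - Pearson distance between columns."""
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(matrix.T)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    condensed = dist[np.triu_indices(dist.shape[0], k=1)]
    return hierarchy.linkage(condensed, method="average")


def _node_leafsets(link: np.ndarray, n: int) -> list[frozenset[int]]:
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    sets: list[frozenset[int]] = []
    for i, (a, b, _, _) in enumerate(link):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        sets.append(merged)
    return sets


def cluster_tissues(
    matrix: pd.DataFrame,
    n_resamples: int = 100,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, list[str], dict[frozenset[str], float]]:
    """Hierarchical clustering of samples with resampling node support.

    Returns (linkage matrix, sample labels, support per internal-node
    leafset): support is the fraction of feature-resampled clusterings
    containing the same leaf bipartition.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    X = matrix.to_numpy(dtype=float)
    labels = [str(c) for c in matrix.columns]
    link = _corr_linkage(X)
    base_sets = _node_leafsets(link, X.shape[1])
    hits = dict.fromkeys(base_sets, 0)
    for _ in range(n_resamples):
        rows = rng.integers(0, X.shape[0], size=X.shape[0])
        rlink = _corr_linkage(X[rows])
        rsets = set(_node_leafsets(rlink, X.shape[1]))
        for s in hits:
            if s in rsets:
                hits[s] += 1
    support = {
        frozenset(labels[i] for i in s): hits[s] / n_resamples for s in base_sets
    }
    return link, labels, support


def arm_ratio_profiles(
    mature_matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-hairpin 5p/3p log2 ratios and cross-arm Pearson correlation.

    Row ids must end in ``_5p`` / ``_3p`` (underscore ID convention);
    hairpins lacking either arm are skipped.  Below-detection (NaN)
    entries propagate as missing.
    """
    arms: dict[str, dict[str, str]] = {}
    for rid in mature_matrix.index:
        srid = str(rid)
        if srid.endswith(("_5p", "_3p")):
            arms.setdefault(srid[:-3], {})[srid[-2:]] = srid
    ratio_rows = {}
    corr = {}
    for hp, d in sorted(arms.items()):
        if {"5p", "3p"} - set(d):
            continue
        five = mature_matrix.loc[d["5p"]].astype(float)
        three = mature_matrix.loc[d["3p"]].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio_rows[hp] = np.log2(five / three)
        r = _pearson_rows(five, three)
        corr[hp] = np.nan if r is None else r
    ratios = pd.DataFrame(ratio_rows).T
    if not ratios.empty:
        ratios.columns = mature_matrix.columns
    return ratios, pd.Series(corr, dtype=float)


def family_enrichment(
    subset: set[str],
    families: dict[str, set[str]],
    universe: set[str],
) -> dict[str, float]:
    """One-sided hypergeometric enrichment of each family in the subset.

    p = P(X >= k) with N = |universe|, K = |family ∩ universe|,
    n = |subset|.  Families with no members in the universe are skipped.
    """
    if not subset <= universe:
        raise ValueError("subset must be contained in the universe")
    N, n = len(universe), len(subset)
    out: dict[str, float] = {}
    for fam, members in sorted(families.items()):
        K = len(members & universe)
        if K == 0:
            continue
        k = len(members & subset)
        out[fam] = float(stats.hypergeom.sf(k - 1, N, K, n))
    return out


def sponge_candidates(
    linc_matrix: pd.DataFrame,
    mirna_matrix: pd.DataFrame,
    threshold: float = DEFAULT_SPONGE_THRESHOLD,
) -> list[tuple[str, str, float]]:
    """(lincRNA, miRNA, r) pairs with Pearson r >= threshold."""
    if list(linc_matrix.columns) != list(mirna_matrix.columns):
        raise ValueError("lincRNA and miRNA matrices must share tissue columns")
    out = []
    for linc, mir in itertools.product(
        sorted(map(str, linc_matrix.index)), sorted(map(str, mirna_matrix.index))
    ):
        r = _pearson_rows(linc_matrix.loc[linc], mirna_matrix.loc[mir])
        if r is not None and r >= threshold:
            out.append((linc, mir, r))
    return out


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the identical (row-mean) distribution.

    Ties receive the mean of the reference values they span.
    """
    values = matrix.to_numpy(dtype=float)
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average") - 1
        out[:, j] = np.interp(ranks, np.arange(len(reference)), reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
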