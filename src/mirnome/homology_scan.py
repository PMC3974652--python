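"""Conserved precursor discovery by local alignment against a genome.

A reference precursor is called conserved at a genomic locus when the
best local alignment covers at least half of the precursor with
identities (similarity >= 50% of the full precursor length) AND the
6-nt seed (mature positions 2-7) aligns gap-free with perfect identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from scipy import stats

from ._seq import Interval, revcomp

DEFAULT_MIN_SIMILARITY = 50.0


@dataclass(frozen=True)
class ConservationHit:
    reference_id: str
    chrom: str
    interval: Interval
    similarity_pct: float
    seed_exact: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity_pct <= 100.0:
            raise ValueError("similarity_pct outside [0, 100]")


@dataclass(frozen=True)
class SpeciesConservationRecord:
    species: str
    n_reference: int
    n_conserved: int
    phylo_distance: float

    @property
    def fraction_conserved(self) -> float:
        return self.n_conserved / self.n_reference


def _make_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _alignment_stats(
    alignment, seed_query: tuple[int, int]
) -> tuple[int, bool, int, int]:
    """(identities, seed gap-free & identical, target start, target end).

    ``seed_query`` is the 0-based half-open query range of the seed.
    Coordinates returned are 0-based half-open on the alignment target.
    """
    identities = 0
    seed_cols = 0
    seed_identical = 0
    seed_target_positions: list[int] = []
    tseq, qseq = alignment.target, alignment.query
    for (tb, te), (qb, qe) in zip(*alignment.aligned):
        for t, q in zip(range(tb, te), range(qb, qe)):
            same = tseq[t].upper() == qseq[q].upper()
            identities += int(same)
            if seed_query[0] <= q < seed_query[1]:
                seed_cols += 1
                seed_identical += int(same)
                seed_target_positions.append(t)
    seed_len = seed_query[1] - seed_query[0]
    seed_ok = (
        seed_cols == seed_len
        and seed_identical == seed_len
        and len(seed_target_positions) == seed_len
        and seed_target_positions[-1] - seed_target_positions[0] == seed_len - 1
    )
    tstart = int(alignment.aligned[0][0][0])
    tend = int(alignment.aligned[0][-1][1])
    return identities, seed_ok, tstart, tend


def conserved_scan(
    reference,
    genome: dict[str, str],
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    max_loci: int = 3,
    aligner_params: dict | None = None,
) -> list[ConservationHit]:
    """Scan each reference precursor against both strands of the genome.

    ``reference`` is an iterable of records with attributes
    ``precursor_id``, ``sequence``, ``mature_start`` (1-based within the
    precursor) and ``mature_len``.  Secondary loci are found by masking
    already-hit intervals and re-aligning, up to ``max_loci`` per
    precursor and chromosome strand; hits overlapping >50% keep the
    higher similarity.
    """
    aligner = _make_aligner(**(aligner_params or {}))
    hits: list[ConservationHit] = []
    for rec in reference:
        query = rec.sequence.upper()
        if len(query) < rec.mature_start - 1 + rec.mature_len:
            raise ValueError(
                f"{rec.precursor_id}: precursor shorter than its annotated mature"
            )
        # seed = mature positions 2-7 -> 0-based query indices
        s0 = rec.mature_start  # (mature_start - 1) + 1
        seed_q = (s0, s0 + 6)
        per_precursor: list[ConservationHit] = []
        for chrom, seq in genome.items():
            for strand in "+-":
                target = seq.upper() if strand == "+" else revcomp(seq.upper())
                masked = target
                for _ in range(max_loci):
                    alns = aligner.align(masked, query)
                    if len(alns) == 0 or alns.score <= 0:
                        break
                    best = alns[0]
                    identities, seed_ok, tstart, tend = _alignment_stats(best, seed_q)
                    similarity = 100.0 * identities / len(query)
                    if strand == "+":
                        iv = Interval(tstart + 1, tend, "+")
                    else:
                        n = len(seq)
                        iv = Interval(n - tend + 1, n - tstart, "-")
                    if similarity >= min_similarity and seed_ok:
                        per_precursor.append(
                            ConservationHit(
                                rec.precursor_id, chrom, iv, similarity, True
                            )
                        )
                    masked = masked[:tstart] + "N" * (tend - tstart) + masked[tend:]
                    if similarity < min_similarity:
                        break  # weaker loci only from here on
        hits.extend(_dedupe_hits(per_precursor))
    return hits


def _dedupe_hits(hits: list[ConservationHit]) -> list[ConservationHit]:
    """Among hits of one precursor, drop intervals overlapping >50%."""
    kept: list[ConservationHit] = []
    for h in sorted(hits, key=lambda x: -x.similarity_pct):
        shadowed = False
        for k in kept:
            if k.chrom != h.chrom:
                continue
            ov = k.interval.overlap(h.interval)
            if ov > 0.5 * min(len(k.interval), len(h.interval)):
                shadowed = True
                break
        if not shadowed:
            kept.append(h)
    kept.sort(key=lambda x: (x.chrom, x.interval.start))
    return kept


def conservation_by_species(
    hits: list[ConservationHit],
    reference,
    distances: dict[str, float],
) -> list[SpeciesConservationRecord]:
    """Per-species conserved counts; species without references excluded."""
    hit_ids = {h.reference_id for h in hits}
    by_species: dict[str, list] = {}
    for rec in reference:
        by_species.setdefault(rec.species, []).append(rec)
    records = []
    for species in sorted(by_species):
        refs = by_species[species]
        n_conserved = sum(r.precursor_id in hit_ids for r in refs)
        records.append(
            SpeciesConservationRecord(
                species=species,
                n_reference=len(refs),
                n_conserved=n_conserved,
                phylo_distance=float(distances[species]),
            )
        )
    return records


def conservation_distance_correlation(
    records: list[SpeciesConservationRecord],
) -> float:
    """Sample Pearson r between phylogenetic distance and conserved fraction."""
    if len(records) < 3:
        raise ValueError("need at least 3 species records")
    x = np.array([r.phylo_distance for r in records], dtype=float)
    y = np.array([r.fraction_conserved for r in records], dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)
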