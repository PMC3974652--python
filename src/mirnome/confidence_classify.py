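"""High/medium/low confidence classification from small-RNA coverage.

Reads are filtered (drop anything mapping to annotated non-miRNA
transcripts, >2 mismatches, or >3 reported alignments), per-nt depth is
accumulated over each hairpin, and the mean depth over the mature
interval decides the label: >=10 high, >=3 and <10 medium, else low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import Interval, revcomp

MAX_MISMATCHES = 2
MAX_ALIGNMENTS = 3
HIGH_COVERAGE = 10.0
MEDIUM_COVERAGE = 3.0


@dataclass(frozen=True)
class ReadAlignment:
    """One reported alignment (1-based leftmost position on the reference)."""

    read_id: str
    ref_id: str
    pos: int
    length: int
    n_mismatches: int

    def __post_init__(self) -> None:
        if self.pos < 1 or self.length < 1 or self.n_mismatches < 0:
            raise ValueError(f"malformed alignment record for {self.read_id}")

    @property
    def end(self) -> int:
        return self.pos + self.length - 1


@dataclass
class CoverageProfile:
    hairpin_id: str
    depth: np.ndarray  # per-nt, over the whole hairpin
    mature_interval: Interval  # 1-based within the hairpin

    @property
    def mature_mean_coverage(self) -> float:
        iv = self.mature_interval
        return float(self.depth[iv.start - 1 : iv.end].mean())


@dataclass(frozen=True)
class ConfidenceLabel:
    hairpin_id: str
    label: str  # "high" | "medium" | "low"
    mature_mean_coverage: float


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_reads(
    alignments: list[ReadAlignment],
    non_mirna_refs: set[str],
    max_mismatches: int = MAX_MISMATCHES,
    max_alignments: int = MAX_ALIGNMENTS,
) -> list[ReadAlignment]:
    """Apply the read-retention rules; idempotent.

    Per alignment: at most ``max_mismatches`` mismatches.  Per read:
    discard entirely if any alignment hits an annotated non-miRNA
    reference, or if it reports more than ``max_alignments`` alignments
    after the mismatch filter.
    """
    by_read: dict[str, list[ReadAlignment]] = {}
    tainted: set[str] = set()
    for a in alignments:
        if a.ref_id in non_mirna_refs:
            tainted.add(a.read_id)
        if a.n_mismatches <= max_mismatches:
            by_read.setdefault(a.read_id, []).append(a)
    retained: list[ReadAlignment] = []
    for read_id, alns in by_read.items():
        if read_id in tainted or len(alns) > max_alignments:
            continue
        retained.extend(alns)
    retained.sort(key=lambda a: (a.ref_id, a.pos, a.read_id))
    return retained


# ---------------------------------------------------------------------------
# built-in matcher (SAM input optional)
# ---------------------------------------------------------------------------


def match_reads(
    reads: list[tuple[str, str]],
    references: dict[str, str],
    max_mismatches: int = MAX_MISMATCHES,
    max_hits: int = MAX_ALIGNMENTS + 1,
    both_strands: bool = False,
) -> list[ReadAlignment]:
    """Naive exact/<=k-mismatch substring matcher for synthetic scale.

    Reports up to ``max_hits`` alignments per read (one more than the
    downstream cap, so over-mapped reads are still droppable).
    """
    out: list[ReadAlignment] = []
    for read_id, seq in reads:
        seq = seq.upper()
        queries = [seq, revcomp(seq)] if both_strands else [seq]
        hits: list[ReadAlignment] = []
        for ref_id, ref in references.items():
            ref = ref.upper()
            for q in queries:
                m = len(q)
                for start in range(len(ref) - m + 1):
                    mm = sum(a != b for a, b in zip(q, ref[start : start + m]))
                    if mm <= max_mismatches:
                        hits.append(
                            ReadAlignment(read_id, ref_id, start + 1, m, mm)
                        )
                    if len(hits) >= max_hits:
                        break
                if len(hits) >= max_hits:
                    break
            if len(hits) >= max_hits:
                break
        out.extend(hits)
    return out


def read_sam(path: str) -> list[ReadAlignment]:
    """Parse a text SAM file into alignment records.

    Unmapped reads are skipped; secondary alignments count as reported
    alignments.  Mismatches are taken from the NM tag when present.
    """
    out: list[ReadAlignment] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            flag = int(fields[1])
            if flag & 0x4:  # unmapped
                continue
            nm = 0
            for tag in fields[11:]:
                if tag.startswith("NM:i:"):
                    nm = int(tag[5:])
            out.append(
                ReadAlignment(
                    read_id=fields[0],
                    ref_id=fields[2],
                    pos=int(fields[3]),
                    length=len(fields[9]) if fields[9] != "*" else 1,
                    n_mismatches=nm,
                )
            )
    return out


# ---------------------------------------------------------------------------
# coverage + classification
# ---------------------------------------------------------------------------


def coverage_profile(
    alignments: list[ReadAlignment],
    hairpin_id: str,
    hairpin_length: int,
    mature_interval: Interval,
) -> CoverageProfile:
    """Per-nt depth over one hairpin (depth semantics: partial overlaps
    count toward every covered base)."""
    if mature_interval.end > hairpin_length:
        raise ValueError("mature interval outside hairpin")
    depth = np.zeros(hairpin_length, dtype=float)
    for a in alignments:
        if a.ref_id != hairpin_id:
            continue
        lo = max(a.pos, 1) - 1
        hi = min(a.end, hairpin_length)
        depth[lo:hi] += 1.0
    return CoverageProfile(hairpin_id, depth, mature_interval)


def classify_confidence(profile: CoverageProfile) -> ConfidenceLabel:
    """>=10 high; >=3 and <10 medium; otherwise low."""
    cov = profile.mature_mean_coverage
    if cov >= HIGH_COVERAGE:
        label = "high"
    elif cov >= MEDIUM_COVERAGE:
        label = "medium"
    else:
        label = "low"
    return ConfidenceLabel(profile.hairpin_id, label, cov)
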