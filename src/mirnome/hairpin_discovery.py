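"""De-novo pre-miRNA candidate discovery.

The scan slides a window over both strands and asks a pluggable folding
engine for the best locally stable fold-back.  The built-in
:class:`StemFoldEngine` aligns the window against its own reverse
complement (so a stem is a local alignment whose gaps are bulges) and
scores pairs with nearest-neighbor stacking increments.  Candidates are
filtered on length / free energy / loop count, encoded as 32-dim
triplet feature vectors, and classified with a seeded probabilistic
classifier.  A structure-only surrogate scores the putative nuclear
cleavage site (accept iff score < 0); it is NOT equivalent to any
published cleavage-site model and is labeled as such.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from sklearn.linear_model import LogisticRegression

from ._seq import Interval, revcomp

# ---------------------------------------------------------------------------
# candidate + config types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HairpinCandidate:
    chrom: str
    interval: Interval
    sequence: str
    structure: str
    free_energy: float

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure/sequence length mismatch")
        if self.structure.count("(") != self.structure.count(")"):
            raise ValueError("unbalanced structure")
        if not np.isfinite(self.free_energy):
            raise ValueError("free energy must be finite")

    @property
    def loops(self) -> list[int]:
        return loop_lengths(self.structure)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HairpinFilterConfig:
    """Retention thresholds; all bounds exclusive where noted."""

    min_len_exclusive: int = 54
    max_len_exclusive: int = 217
    max_energy_exclusive: float = -27.0
    max_loops: int = 2
    loop_len_range: tuple[int, int] = (3, 30)


@dataclass(frozen=True)
class ClassifierDecision:
    candidate: HairpinCandidate
    probability: float
    threshold: float
    accepted: bool


# ---------------------------------------------------------------------------
# structure helpers
# ---------------------------------------------------------------------------


def loop_lengths(
    structure: str, loop_range: tuple[int, int] = (3, 30)
) -> list[int]:
    """Lengths of unpaired runs between the first and last bracket.

    Runs shorter than ``loop_range[0]`` are ignored; any run longer
    than ``loop_range[1]`` is still reported (the filter uses it to
    disqualify).  Exterior unpaired tails are never loops.
    """
    first = structure.find("(")
    last = structure.rfind(")")
    if first < 0 or last < 0:
        return []
    runs: list[int] = []
    run = 0
    for ch in structure[first : last + 1]:
        if ch == ".":
            run += 1
        else:
            if run >= loop_range[0]:
                runs.append(run)
            run = 0
    return runs


def pair_table(structure: str) -> dict[int, int]:
    """0-based map i -> j for every '(' ... ')' pair (both directions)."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
    if stack:
        raise ValueError("unbalanced structure")
    return pairs


# ---------------------------------------------------------------------------
# built-in folding engine
# ---------------------------------------------------------------------------

#: pair stabilities (kcal/mol-like magnitudes) for the stem model
PAIR_STRENGTH = {
    ("G", "C"): 3.0,
    ("C", "G"): 3.0,
    ("A", "T"): 2.0,
    ("T", "A"): 2.0,
    ("G", "T"): 1.0,
    ("T", "G"): 1.0,
}
#: stacking increment applied per contiguously stacked pair
STACK_BONUS = 0.25
TERMINAL_LOOP_PENALTY = 3.0
INTERNAL_UNPAIRED_PENALTY = 1.2
MIN_LOOP = 3


def _fold_substitution_matrix() -> substitution_matrices.Array:
    """Scores for aligning a sequence against its reverse complement.

    Aligning window position i with reverse-complement position j means
    pairing residue i with residue n-1-j; the score of column (x, c) is
    therefore the pairing strength of x with complement(c).
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for c in alphabet:
            partner = comp[c]
            m[x, c] = PAIR_STRENGTH.get((x, partner), -4.0)
            if "N" in (x, c):
                m[x, c] = -8.0  # N never pairs
    return m


class StemFoldEngine:
    """Default folding engine: self-reverse-complement local alignment.

    Finds the best single fold-back (stem with bulges/internal loops and
    a terminal loop) in a window.  Energy = -(sum of pair strengths) -
    stacking bonuses + loop penalties; more negative is more stable.
    """

    def __init__(self, gap_open: float = 6.0, gap_extend: float = 4.0):
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.substitution_matrix = _fold_substitution_matrix()
        self._aligner.open_gap_score = -gap_open
        self._aligner.extend_gap_score = -gap_extend

    def fold(self, seq: str) -> tuple[str, float] | None:
        """Best fold-back of ``seq`` as (dot-bracket, energy) or None."""
        seq = seq.upper()
        n = len(seq)
        if n < 2 * MIN_LOOP:
            return None
        rc = revcomp(seq)
        alns = self._aligner.align(seq, rc)
        if len(alns) == 0 or alns.score <= 0:
            return None
        best = alns[0]
        pairs: list[tuple[int, int]] = []
        for (tb, te), (qb, qe) in zip(*best.aligned):
            for i, j in zip(range(tb, te), range(qb, qe)):
                k = n - 1 - j
                if i >= k - MIN_LOOP:
                    continue  # crossed the fold point / loop too small
                if PAIR_STRENGTH.get((seq[i], seq[k])) is None:
                    continue  # aligned mismatch column: unpaired
                pairs.append((i, k))
        # keep the nested monotone subset (alignment order guarantees
        # i increasing and k decreasing until the crossing point)
        nested: list[tuple[int, int]] = []
        for i, k in pairs:
            if nested and (i <= nested[-1][0] or k >= nested[-1][1]):
                continue
            nested.append((i, k))
        if not nested:
            return None
        structure = ["."] * n
        for i, k in nested:
            structure[i] = "("
            structure[k] = ")"
        return "".join(structure), self._energy(seq, nested)

    @staticmethod
    def _energy(seq: str, pairs: list[tuple[int, int]]) -> float:
        strength = sum(PAIR_STRENGTH[(seq[i], seq[k])] for i, k in pairs)
        stacks = sum(
            1
            for (i1, k1), (i2, k2) in itertools.pairwise(pairs)
            if i2 == i1 + 1 and k2 == k1 - 1
        )
        innermost_i, innermost_k = pairs[-1]
        internal_unpaired = 0
        for (i1, k1), (i2, k2) in itertools.pairwise(pairs):
            internal_unpaired += (i2 - i1 - 1) + (k1 - k2 - 1)
        return float(
            -strength
            - STACK_BONUS * stacks
            + TERMINAL_LOOP_PENALTY
            + INTERNAL_UNPAIRED_PENALTY * internal_unpaired
        )


# ---------------------------------------------------------------------------
# scan / filter
# ---------------------------------------------------------------------------


def _trim_candidate(
    window_seq: str, structure: str, energy: float, window_start: int, chrom: str,
    strand: str, seq_len: int,
) -> HairpinCandidate:
    """Cut the candidate down to its paired span (loop included)."""
    first = structure.find("(")
    last = structure.rfind(")")
    sub_seq = window_seq[first : last + 1]
    sub_struct = structure[first : last + 1]
    # window coordinates are on the scanned strand; map to + frame
    s = window_start + first
    e = window_start + last
    if strand == "-":
        s, e = seq_len - e + 1, seq_len - s + 1
    return HairpinCandidate(
        chrom=chrom,
        interval=Interval(s, e, strand),
        sequence=sub_seq,
        structure=sub_struct,
        free_energy=energy,
    )


def scan_local_structures(
    sequence: str,
    chrom: str = "seq",
    engine: StemFoldEngine | None = None,
    window: int = 300,
    step: int = 50,
    both_strands: bool = True,
    min_pairs: int = 5,
) -> list[HairpinCandidate]:
    """Slide a window over the sequence (both strands) and fold each one.

    Overlapping candidates (>80% interval overlap) collapse to the
    lowest-energy representative.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if window < 2 * MIN_LOOP + 2:
        raise ValueError("window shorter than the minimum hairpin")
    engine = engine or StemFoldEngine()
    n = len(sequence)
    candidates: list[HairpinCandidate] = []
    strands = "+-" if both_strands else "+"
    for strand in strands:
        seq_s = sequence.upper() if strand == "+" else revcomp(sequence.upper())
        starts = list(range(0, max(n - window, 0) + 1, step))
        if starts[-1] + window < n:
            starts.append(n - window)
        for w0 in starts:
            sub = seq_s[w0 : w0 + window]
            folded = engine.fold(sub)
            if folded is None:
                continue
            structure, energy = folded
            if structure.count("(") < min_pairs:
                continue
            candidates.append(
                _trim_candidate(sub, structure, energy, w0 + 1, chrom, strand, n)
            )
    return dedupe_candidates(candidates)


def dedupe_candidates(
    candidates: list[HairpinCandidate], min_overlap: float = 0.8
) -> list[HairpinCandidate]:
    """Collapse candidates sharing >``min_overlap`` interval overlap."""
    kept: list[HairpinCandidate] = []
    for c in sorted(candidates, key=lambda x: x.free_energy):
        dup = False
        for k in kept:
            if k.chrom != c.chrom or k.interval.strand != c.interval.strand:
                continue
            ov = k.interval.overlap(c.interval)
            if ov > min_overlap * min(len(k.interval), len(c.interval)):
                dup = True
                break
        if not dup:
            kept.append(c)
    kept.sort(key=lambda x: (x.chrom, x.interval.start, x.interval.strand))
    return kept


def filter_hairpins(
    candidates: list[HairpinCandidate],
    config: HairpinFilterConfig | None = None,
) -> list[HairpinCandidate]:
    """Retain canonical candidates.

    Length strictly between the exclusive bounds, energy strictly below
    the cap, at most ``max_loops`` unpaired runs of 3-30 nt, and no
    unpaired run longer than 30 nt anywhere inside the stem.
    """
    config = config or HairpinFilterConfig()
    lo, hi = config.loop_len_range
    retained = []
    for c in candidates:
        if not (config.min_len_exclusive < len(c) < config.max_len_exclusive):
            continue
        if not c.free_energy < config.max_energy_exclusive:
            continue
        runs = loop_lengths(c.structure, (1, 10**9))  # every unpaired run
        if any(r > hi for r in runs):
            continue
        n_loops = sum(1 for r in runs if lo <= r <= hi)
        if n_loops > config.max_loops:
            continue
        retained.append(c)
    return retained


# ---------------------------------------------------------------------------
# triplet features
# ---------------------------------------------------------------------------

TRIPLET_STATES = ["".join(p) for p in itertools.product("(.", repeat=3)]
TRIPLET_KEYS = [f"{nt}{state}" for nt in "ACGT" for state in TRIPLET_STATES]


def triplet_features(sequence: str, structure: str) -> np.ndarray:
    """32-dim frequency vector of (middle base, local pairing pattern).

    Brackets are collapsed to paired/unpaired before encoding; windows
    whose middle base is N are skipped.  Frequencies sum to 1 for
    non-degenerate input.
    """
    if len(sequence) != len(structure):
        raise ValueError("sequence/structure length mismatch")
    collapsed = "".join("(" if ch in "()" else "." for ch in structure)
    seq = sequence.upper().replace("U", "T")
    counts = dict.fromkeys(TRIPLET_KEYS, 0)
    total = 0
    for i in range(1, len(seq) - 1):
        mid = seq[i]
        if mid not in "ACGT":
            continue
        key = mid + collapsed[i - 1 : i + 2]
        counts[key] += 1
        total += 1
    vec = np.array([counts[k] for k in TRIPLET_KEYS], dtype=float)
    if total > 0:
        vec /= total
    return vec


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

MODEL_FORMAT_VERSION = 1
DEFAULT_PROBABILITY_THRESHOLD = 0.998


class HairpinClassifier:
    """Probabilistic triplet-feature classifier (logistic, low reg).

    Probability is a monotone function of the linear margin; training
    is deterministic given the seed.
    """

    def __init__(self, seed: int = 0, C: float = 1e5):
        self.seed = seed
        self._model = LogisticRegression(
            C=C, max_iter=10_000, random_state=seed, solver="lbfgs"
        )
        self.fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "HairpinClassifier":
        if len(np.unique(y)) < 2:
            raise ValueError("training requires both classes")
        self._model.fit(X, y)
        self.fitted = True
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("classifier is untrained")
        return self._model.predict_proba(np.atleast_2d(X))[:, 1]

    def save(self, path: str) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "kind": "triplet-logistic",
            "seed": self.seed,
            "coef": self._model.coef_.tolist(),
            "intercept": self._model.intercept_.tolist(),
            "classes": self._model.classes_.tolist(),
            "feature_names": TRIPLET_KEYS,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "HairpinClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model file version")
        obj = cls(seed=payload["seed"])
        obj._model.coef_ = np.array(payload["coef"])
        obj._model.intercept_ = np.array(payload["intercept"])
        obj._model.classes_ = np.array(payload["classes"])
        obj.fitted = True
        return obj


def candidate_features(candidates) -> np.ndarray:
    return np.array(
        [triplet_features(c.sequence, c.structure) for c in candidates]
    )


def train_hairpin_classifier(
    positives, negatives, seed: int = 0
) -> HairpinClassifier:
    """Train on known precursors (with structures) vs pseudo-hairpins.

    Inputs are iterables of objects with ``sequence`` and ``structure``
    attributes, or plain (sequence, structure) tuples.
    """

    def feats(items) -> list[np.ndarray]:
        out = []
        for it in items:
            seq, struct = (
                (it.sequence, it.structure) if hasattr(it, "sequence") else it
            )
            out.append(triplet_features(seq, struct))
        return out

    pos, neg = feats(positives), feats(negatives)
    if not pos or not neg:
        raise ValueError("both classes must be non-empty")
    X = np.array(pos + neg)
    y = np.array([1] * len(pos) + [0] * len(neg))
    return HairpinClassifier(seed=seed).fit(X, y)


def classify_hairpins(
    candidates: list[HairpinCandidate],
    classifier: HairpinClassifier,
    threshold: float = DEFAULT_PROBABILITY_THRESHOLD,
) -> list[ClassifierDecision]:
    """Accept iff probability is strictly greater than the threshold."""
    if not candidates:
        return []
    probs = classifier.predict_proba(candidate_features(candidates))
    return [
        ClassifierDecision(c, float(p), threshold, bool(p > threshold))
        for c, p in zip(candidates, probs)
    ]


# ---------------------------------------------------------------------------
# cleavage-site surrogate
# ---------------------------------------------------------------------------


def drosha_site_score(candidate: HairpinCandidate) -> float:
    """Structure-only surrogate for nuclear cleavage-site plausibility.

    Accept iff score < 0.  The score rewards deep stems with a single
    terminal loop: score = 21.5 - (total base pairs) + 8 per extra
    terminal loop (+10 when there is no loop at all).  This surrogate is
    deliberately simple and is NOT equivalent to the original
    SVM-based cleavage-site model; it only uses the predicted structure,
    never the sequence.
    """
    n_pairs = candidate.structure.count("(")
    n_loops = _count_terminal_loops(candidate.structure)
    score = 21.5 - n_pairs + 8.0 * max(0, n_loops - 1)
    if n_loops == 0:
        score += 10.0
    return float(score)


def _count_terminal_loops(structure: str) -> int:
    count = 0
    last_open = False
    for ch in structure:
        if ch == "(":
            last_open = True
        elif ch == ")":
            if last_open:
                count += 1
            last_open = False
    return count
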