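"""Synthetic benchmark generators with planted ground truth.

Every input the pipeline consumes can be produced here: a genome with
planted fold-back hairpins and decoy tRNA/CDS-like negatives, a
"foreign species" reference precursor collection, tiling-array
fluorescence with planted endpoint peaks and spike-in titrations,
small-RNA reads sampled from planted matures, and tissue expression
matrices with planted anti-correlated miRNA-target pairs and positively
correlated lincRNA sponges.

All generators are pure functions of their configuration (including the
RNG seed): the same seed yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import Interval, mutate_seq, random_seq, revcomp

MATURE_LEN = 22
#: probes per tiling group, keyed by assay
ASSAY_SIZES = {"3p-assay": 22, "5p-assay": 16}


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs shared by all generators.

    ``planted_target_correlation`` is the exact sample Pearson r imposed
    on planted (miRNA, target) profile pairs; sponges use its absolute
    value with positive sign.
    """

    rng_seed: int = 0
    n_hairpins: int = 20
    n_decoys: int = 20
    stem_length_range: tuple[int, int] = (28, 40)
    loop_length_range: tuple[int, int] = (4, 8)
    mutation_rate: float = 0.0
    noise_sd: float = 0.3
    signal_fold: float = 10.0
    coverage_mean: float = 20.0
    n_tissues: int = 14
    planted_target_correlation: float = -0.9
    spacer_length: int = 120
    genome_length: int | None = None

    def __post_init__(self) -> None:
        for name in ("stem_length_range", "loop_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} {lo}-{hi} is empty or invalid")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate outside [0, 1]")
        if not -1.0 <= self.planted_target_correlation <= 0.0:
            raise ValueError("planted_target_correlation must lie in [-1, 0]")
        if self.noise_sd < 0 or self.signal_fold <= 0 or self.coverage_mean < 0:
            raise ValueError("noise_sd/signal_fold/coverage_mean out of range")
        if self.n_hairpins < 0 or self.n_decoys < 0:
            raise ValueError("counts must be non-negative")
        if self.stem_length_range[0] < MATURE_LEN:
            raise ValueError(f"stems must hold a {MATURE_LEN}-nt mature")


@dataclass(frozen=True)
class HairpinTruth:
    """Planted hairpin record: all intervals 1-based inclusive, genomic."""

    hairpin_id: str
    interval: Interval
    strand: str
    mature_5p: Interval
    mature_3p: Interval

    def precursor_sequence(self, genome: str) -> str:
        seq = genome[self.interval.start - 1 : self.interval.end]
        return seq if self.strand == "+" else revcomp(seq)

    def mature_sequence(self, genome: str, arm: str) -> str:
        iv = self.mature_5p if arm == "5p" else self.mature_3p
        seq = genome[iv.start - 1 : iv.end]
        return seq if self.strand == "+" else revcomp(seq)


@dataclass(frozen=True)
class DecoyTruth:
    decoy_id: str
    interval: Interval
    decoy_class: str  # "tRNA-like" | "CDS-like"


@dataclass
class PlantedGenome:
    sequence: str
    hairpin_truth: list[HairpinTruth]
    decoy_truth: list[DecoyTruth]
    name: str = "chrS"

    def validate(self) -> None:
        bounds = Interval(1, len(self.sequence))
        for h in self.hairpin_truth:
            if not bounds.contains(h.interval):
                raise ValueError(f"{h.hairpin_id} exceeds genome bounds")
            if not (
                h.interval.contains(h.mature_5p) and h.interval.contains(h.mature_3p)
            ):
                raise ValueError(f"{h.hairpin_id} matures exit the hairpin")
        for d in self.decoy_truth:
            if not bounds.contains(d.interval):
                raise ValueError(f"{d.decoy_id} exceeds genome bounds")


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------


def _build_hairpin(rng: np.random.Generator, cfg: SimulationConfig) -> tuple[str, int]:
    """Return (hairpin sequence, stem length); perfect stem, then mutated."""
    stem = int(rng.integers(cfg.stem_length_range[0], cfg.stem_length_range[1] + 1))
    loop = int(rng.integers(cfg.loop_length_range[0], cfg.loop_length_range[1] + 1))
    arm5 = random_seq(rng, stem)
    seq = arm5 + random_seq(rng, loop) + revcomp(arm5)
    if cfg.mutation_rate > 0:
        seq = mutate_seq(seq, cfg.mutation_rate, rng)
    return seq, stem


def _build_decoy(rng: np.random.Generator, kind: str) -> str:
    if kind == "tRNA-like":
        # short, GC-rich, unstructured by construction
        length = int(rng.integers(70, 91))
        return "".join(rng.choice(list("ACGT"), size=length, p=[0.2, 0.3, 0.3, 0.2]))
    # CDS-like: codon-patterned, avoids in-frame stops
    n_codons = int(rng.integers(40, 70))
    stops = {"TAA", "TAG", "TGA"}
    codons: list[str] = []
    while len(codons) < n_codons:
        c = random_seq(rng, 3)
        if c not in stops:
            codons.append(c)
    return "".join(codons)


def generate_genome(config: SimulationConfig) -> PlantedGenome:
    """Plant hairpins and decoys into random background sequence.

    Hairpins are perfect fold-backs (5' arm + loop + reverse-complement
    arm) point-mutated at ``config.mutation_rate``.  Mature arms are the
    first/last 22 nt of the precursor.  Raises ``ValueError`` when a
    fixed ``genome_length`` cannot hold the planted elements.
    """
    rng = np.random.default_rng(config.rng_seed)
    parts: list[str] = []
    hairpins: list[HairpinTruth] = []
    decoys: list[DecoyTruth] = []
    pos = 1  # next genomic coordinate to fill

    def emit(seq: str) -> int:
        nonlocal pos
        parts.append(seq)
        start = pos
        pos += len(seq)
        return start

    elements: list[tuple[str, str, int | None]] = []
    for i in range(config.n_hairpins):
        seq, stem = _build_hairpin(rng, config)
        elements.append((f"hp{i:04d}", seq, stem))
    for i in range(config.n_decoys):
        kind = "tRNA-like" if i % 2 == 0 else "CDS-like"
        elements.append((f"decoy{i:04d}:{kind}", _build_decoy(rng, kind), None))
    order = rng.permutation(len(elements))

    for idx in order:
        name, seq, stem = elements[idx]
        emit(random_seq(rng, config.spacer_length))
        start = emit(seq)
        end = start + len(seq) - 1
        if stem is not None:
            strand = "+" if rng.random() < 0.5 else "-"
            m5 = Interval(start, start + MATURE_LEN - 1)
            m3 = Interval(end - MATURE_LEN + 1, end)
            if strand == "-":
                m5, m3 = m3, m5  # the 5' arm reads from the genomic right end
            hairpins.append(HairpinTruth(name, Interval(start, end), strand, m5, m3))
        else:
            decoy_id, kind = name.split(":")
            decoys.append(DecoyTruth(decoy_id, Interval(start, end), kind))
    emit(random_seq(rng, config.spacer_length))

    sequence = "".join(parts)
    if config.genome_length is not None:
        if len(sequence) > config.genome_length:
            raise ValueError(
                f"planted elements need {len(sequence)} nt but genome_length "
                f"is {config.genome_length}"
            )
        sequence += random_seq(rng, config.genome_length - len(sequence))

    hairpins.sort(key=lambda h: h.interval.start)
    genome = PlantedGenome(sequence, hairpins, decoys)
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# reference ("foreign species") precursor collection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceRecord:
    """A homolog precursor attributed to a synthetic foreign species."""

    species: str
    precursor_id: str
    sequence: str
    mature_start: int  # 1-based start of the 5p mature within the precursor
    mature_len: int
    arm: str
    source_hairpin: str
    divergence: float

    @property
    def seed(self) -> str:
        """Seed = mature positions 2-7."""
        s = self.mature_start  # 1-based; position 2 of the mature is s+1
        return self.sequence[s : s + 6]


def generate_reference_set(
    genome: PlantedGenome,
    divergence_levels: list[float],
    preserve_seed: bool = True,
    rng_seed: int = 0,
) -> list[ReferenceRecord]:
    """Emit one mutated homolog per (planted hairpin, divergence level).

    Each divergence level is attributed to one synthetic species.  Seed
    positions (mature positions 2-7) stay intact iff ``preserve_seed``.
    """
    for d in divergence_levels:
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"divergence {d} outside [0, 1]")
    rng = np.random.default_rng(rng_seed)
    records: list[ReferenceRecord] = []
    for li, d in enumerate(divergence_levels):
        species = f"species{li:02d}"
        for h in genome.hairpin_truth:
            precursor = h.precursor_sequence(genome.sequence)
            protect = set(range(1, 7)) if preserve_seed else None
            mutated = mutate_seq(precursor, d, rng, protect=protect)
            records.append(
                ReferenceRecord(
                    species=species,
                    precursor_id=f"{species}-{h.hairpin_id}",
                    sequence=mutated,
                    mature_start=1,
                    mature_len=MATURE_LEN,
                    arm="5p",
                    source_hairpin=h.hairpin_id,
                    divergence=d,
                )
            )
    return records


# ---------------------------------------------------------------------------
# tiling fluorescence
# ---------------------------------------------------------------------------

BASELINE_FLUORESCENCE = 1000.0


@dataclass
class TilingExperiment:
    """Replicate fluorescence over per-hairpin probe tilings.

    ``data`` is tidy with columns hairpin_id, arm, probe_offset,
    replicate, fluorescence.  ``truth`` maps (hairpin_id, arm) to the
    planted endpoint probe offset; ``anchors`` maps the same key to the
    genomic position of probe offset 0 so calls can be genomic.
    """

    assay: str
    end_type: str  # "3prime" | "5prime"
    n_probes: int
    replicates: int
    data: pd.DataFrame
    truth: dict[tuple[str, str], int]
    anchors: dict[tuple[str, str], int]
    spikes: pd.DataFrame | None = None

    def group_values(self, hairpin_id: str, arm: str, replicate: int) -> np.ndarray:
        sub = self.data[
            (self.data.hairpin_id == hairpin_id)
            & (self.data.arm == arm)
            & (self.data.replicate == replicate)
        ].sort_values("probe_offset")
        return sub.fluorescence.to_numpy()

    def groups(self) -> list[tuple[str, str]]:
        return sorted(self.truth)


def generate_tiling(
    genome: PlantedGenome,
    end: str,
    replicates: int,
    config: SimulationConfig,
    with_spikes: bool = True,
) -> TilingExperiment:
    """Per hairpin arm, a probe group with one planted endpoint peak.

    Fluorescence is log-normal around a constant baseline; the probe at
    the planted mature end is multiplied by ``config.signal_fold``.
    ``end`` selects the assay: "3p-assay" (22 probes) or "5p-assay"
    (16 probes).
    """
    if end not in ASSAY_SIZES:
        raise ValueError(f"unknown assay {end!r}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    n_probes = ASSAY_SIZES[end]
    end_type = "3prime" if end == "3p-assay" else "5prime"
    rng = np.random.default_rng(config.rng_seed + 1)

    rows: list[tuple] = []
    truth: dict[tuple[str, str], int] = {}
    anchors: dict[tuple[str, str], int] = {}
    for h in genome.hairpin_truth:
        for arm in ("5p", "3p"):
            iv = h.mature_5p if arm == "5p" else h.mature_3p
            if end_type == "3prime":
                end_pos = iv.end if h.strand == "+" else iv.start
            else:
                end_pos = iv.start if h.strand == "+" else iv.end
            peak = int(rng.integers(2, n_probes - 2))
            truth[(h.hairpin_id, arm)] = peak
            anchors[(h.hairpin_id, arm)] = end_pos - peak
            for rep in range(replicates):
                noise = rng.normal(0.0, config.noise_sd, size=n_probes)
                values = BASELINE_FLUORESCENCE * np.exp(noise)
                values[peak] *= config.signal_fold
                for off in range(n_probes):
                    rows.append((h.hairpin_id, arm, off, rep, float(values[off])))

    data = pd.DataFrame(
        rows, columns=["hairpin_id", "arm", "probe_offset", "replicate", "fluorescence"]
    )
    spikes = None
    if with_spikes:
        amounts = np.logspace(-18, -14, 5)
        spike_rows = []
        for rep in range(replicates):
            for i, amt in enumerate(amounts):
                fluor = 50.0 * (amt / 1e-18) ** 0.8
                fluor *= float(np.exp(rng.normal(0.0, config.noise_sd / 10)))
                spike_rows.append((f"spike{i}", amt, rep, fluor))
        spikes = pd.DataFrame(
            spike_rows, columns=["spike_id", "amount_mol", "replicate", "fluorescence"]
        )
    return TilingExperiment(
        assay=end,
        end_type=end_type,
        n_probes=n_probes,
        replicates=replicates,
        data=data,
        truth=truth,
        anchors=anchors,
        spikes=spikes,
    )


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticRead:
    read_id: str
    sequence: str
    source_id: str  # mature/hairpin id, or decoy id
    is_decoy: bool


@dataclass(frozen=True)
class TruthAlignment:
    """SAM-convention truth record (1-based leftmost position)."""

    read_id: str
    ref_id: str
    pos: int
    length: int
    n_mismatches: int


def generate_reads(
    matures: list[tuple[str, str]],
    coverage_mean: float,
    mismatch_rate: float = 0.0,
    decoy_fraction: float = 0.0,
    rng: np.random.Generator | int = 0,
    genome: PlantedGenome | None = None,
) -> tuple[list[SyntheticRead], list[TruthAlignment]]:
    """Sample full-length reads from mature sequences at Poisson coverage.

    Each mature receives Poisson(``coverage_mean``) full-length reads, so
    per-nt depth has mean ``coverage_mean``.  Decoy reads are substrings
    of planted decoy regions (requires ``genome``).
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    reads: list[SyntheticRead] = []
    truth: list[TruthAlignment] = []
    counter = 0
    for mature_id, seq in matures:
        for _ in range(int(rng.poisson(coverage_mean))):
            read_seq = (
                mutate_seq(seq, mismatch_rate, rng) if mismatch_rate > 0 else seq
            )
            n_mm = sum(a != b for a, b in zip(read_seq, seq))
            rid = f"read{counter:07d}"
            counter += 1
            reads.append(SyntheticRead(rid, read_seq, mature_id, False))
            truth.append(TruthAlignment(rid, mature_id, 1, len(seq), n_mm))
    if decoy_fraction > 0:
        if genome is None or not genome.decoy_truth:
            raise ValueError("decoy reads need a genome with planted decoys")
        n_decoy = int(round(decoy_fraction * max(len(reads), 1)))
        for _ in range(n_decoy):
            d = genome.decoy_truth[int(rng.integers(len(genome.decoy_truth)))]
            span = len(d.interval)
            rlen = min(MATURE_LEN, span)
            off = int(rng.integers(0, span - rlen + 1))
            start = d.interval.start + off
            seq = genome.sequence[start - 1 : start - 1 + rlen]
            rid = f"read{counter:07d}"
            counter += 1
            reads.append(SyntheticRead(rid, seq, d.decoy_id, True))
            truth.append(TruthAlignment(rid, d.decoy_id, off + 1, rlen, 0))
    return reads, truth


# ---------------------------------------------------------------------------
# tissue expression
# ---------------------------------------------------------------------------


def _exact_corr_partner(
    base: np.ndarray, r: float, rng: np.random.Generator
) -> np.ndarray:
    """A vector whose sample Pearson correlation with ``base`` is exactly r."""
    n = base.size
    z = base - base.mean()
    nz = np.linalg.norm(z)
    if nz == 0:
        raise ValueError("base profile has zero variance")
    z = z / nz
    while True:
        e = rng.normal(size=n)
        e = e - e.mean()
        e = e - (e @ z) * z
        ne = np.linalg.norm(e)
        if ne > 1e-12:
            break
    e = e / ne
    v = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * e
    return 8.0 + 2.0 * np.sqrt(n) * v  # affine rescale: Pearson unchanged


def generate_tissue_expression(
    n_tissues: int,
    planted_pairs: list[tuple[str, str]],
    planted_sponges: list[tuple[str, str]],
    interaction_edges: list[tuple[str, str]],
    config: SimulationConfig,
    extra_mirnas: int = 0,
    extra_mrnas: int = 0,
    extra_lincs: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[tuple[str, str]]]:
    """miRNA / mRNA / lincRNA matrices plus an mRNA interaction edge list.

    Planted (miRNA, target) pairs achieve sample Pearson r equal to
    ``config.planted_target_correlation`` exactly (construction by
    orthogonal decomposition, no rejection sampling); sponge pairs
    achieve +|r|.  Non-planted profiles are independent.
    """
    if n_tissues < 3:
        raise ValueError("need at least 3 tissues for defined correlations")
    rng = np.random.default_rng(config.rng_seed + 2)
    tissues = [f"tissue{t:02d}" for t in range(n_tissues)]
    r = config.planted_target_correlation

    mirna_ids = sorted(
        {m for m, _ in planted_pairs} | {m for _, m in planted_sponges}
    )
    mirna_ids += [f"mir-extra{i:03d}" for i in range(extra_mirnas)]
    mirna = {
        m: 8.0 + 2.0 * rng.normal(size=n_tissues) for m in mirna_ids
    }

    mrna: dict[str, np.ndarray] = {}
    for m, target in planted_pairs:
        mrna[target] = _exact_corr_partner(mirna[m], r, rng)
    edge_mrnas = {a for a, _ in interaction_edges} | {b for _, b in interaction_edges}
    for t in sorted(edge_mrnas - set(mrna)):
        mrna[t] = 8.0 + 2.0 * rng.normal(size=n_tissues)
    for i in range(extra_mrnas):
        mrna[f"mrna-extra{i:03d}"] = 8.0 + 2.0 * rng.normal(size=n_tissues)

    linc: dict[str, np.ndarray] = {}
    for lincrna, m in planted_sponges:
        linc[lincrna] = _exact_corr_partner(mirna[m], abs(r), rng)
    for i in range(extra_lincs):
        linc[f"linc-extra{i:03d}"] = 8.0 + 2.0 * rng.normal(size=n_tissues)

    def frame(d: dict[str, np.ndarray]) -> pd.DataFrame:
        return pd.DataFrame(d, index=tissues).T.sort_index()

    return frame(mirna), frame(mrna), frame(linc), list(interaction_edges)


# ---------------------------------------------------------------------------
# convenience: UTRs with planted seed-complement sites
# ---------------------------------------------------------------------------


def generate_utrs(
    planted_pairs: list[tuple[str, str]],
    mirna_seeds: dict[str, str],
    utr_len: int = 400,
    min_site_pos: int = 30,
    rng_seed: int = 0,
    extra_utrs: list[str] | None = None,
) -> dict[str, str]:
    """Random UTRs carrying one reverse-complement seed site per planted pair.

    Sites are placed uniformly at positions >= ``min_site_pos`` so the
    default near-end exclusion of the target scanner never removes them.
    ``extra_utrs`` transcripts get pure random sequence.
    """
    rng = np.random.default_rng(rng_seed)
    utrs: dict[str, str] = {}
    sites: dict[str, list[tuple[int, str]]] = {}
    for mirna_id, transcript in planted_pairs:
        seed = mirna_seeds[mirna_id]
        if len(seed) != 6:
            raise ValueError(f"seed for {mirna_id} is not 6 nt")
        pos = int(rng.integers(min_site_pos, utr_len - len(seed) - 10))
        sites.setdefault(transcript, []).append((pos, revcomp(seed)))
    for transcript, placed in sites.items():
        seq = list(random_seq(rng, utr_len))
        for pos, site in placed:
            seq[pos : pos + len(site)] = site
        utrs[transcript] = "".join(seq)
    for t in extra_utrs or []:
        if t not in utrs:
            utrs[t] = random_seq(rng, utr_len)
    return utrs
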