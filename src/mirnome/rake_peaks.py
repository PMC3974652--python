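"""Mature-end calling from tiling fluorescence, plus spike-in calibration.

The caller holds each probe out in turn and bootstraps the remaining
k-1 values: the endpoint probability is the fraction of ``n_boot``
resampled groups (size k-1, drawn with replacement) whose mean is
strictly lower than the held-out value.  An end is called when the
probability exceeds its end-type threshold in all required replicates
(3'-ends: 0.75 in 4 replicates; 5'-ends: 0.65 in 3, with a relaxed
low-stringency tier above 0.58).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic_data import TilingExperiment

DEFAULT_THRESHOLDS = {"3prime": 0.75, "5prime": 0.65, "relaxed_5prime": 0.58}
DEFAULT_REQUIRED_REPLICATES = {"3prime": 4, "5prime": 3}
DEFAULT_LENGTH_WINDOW = (18, 26)
DEFAULT_LINEAR_RANGE = (1e-18, 1e-14)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def endpoint_bootstrap(
    group_values: np.ndarray,
    index: int,
    n_boot: int = 10_000,
    rng: np.random.Generator | int = 0,
) -> float:
    """Leave-one-out bootstrap endpoint probability for one probe.

    Probability = (# resampled groups of size k-1, drawn with
    replacement from the k-1 remaining values, whose mean is strictly
    lower than the held-out value) / n_boot.
    """
    values = np.asarray(group_values, dtype=float)
    k = values.size
    if k < 3:
        raise ValueError("probe group must have at least 3 values")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0 <= index < k:
        raise IndexError(f"held-out index {index} out of range for group of {k}")
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    held = values[index]
    remaining = np.delete(values, index)
    draws = rng.integers(0, k - 1, size=(n_boot, k - 1))
    means = remaining[draws].mean(axis=1)
    return float(np.mean(means < held))


def group_bootstrap_probabilities(
    group_values: np.ndarray,
    n_boot: int = 10_000,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Endpoint probability for every probe of one replicate's group.

    Vectorized over held-out indices; numerically identical in
    distribution to calling :func:`endpoint_bootstrap` per index.
    """
    values = np.asarray(group_values, dtype=float)
    k = values.size
    if k < 3:
        raise ValueError("probe group must have at least 3 values")
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    probs = np.empty(k)
    for i in range(k):
        remaining = np.delete(values, i)
        draws = rng.integers(0, k - 1, size=(n_boot, k - 1))
        means = remaining[draws].mean(axis=1)
        probs[i] = np.mean(means < values[i])
    return probs


# ---------------------------------------------------------------------------
# endpoint calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EndpointCall:
    hairpin_id: str
    arm: str
    end_type: str  # "5prime" | "3prime"
    position: int  # 1-based genomic
    probe_offset: int
    probability: float  # minimum over passing replicates
    n_replicates_passing: int
    mean_fluorescence: float
    low_stringency: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability outside [0, 1]")


def call_endpoints(
    experiment: TilingExperiment,
    thresholds: dict[str, float] | None = None,
    required_replicates: dict[str, int] | None = None,
    n_boot: int = 10_000,
    master_seed: int = 0,
    consensus: str = "all",
) -> list[EndpointCall]:
    """Call endpoints from a tiling experiment.

    A probe is called when its bootstrap probability exceeds the
    end-type threshold in every replicate (``consensus="all"``) or in a
    majority (``consensus="majority"``).  5'-end probes clearing only
    the relaxed threshold in all replicates are emitted flagged
    ``low_stringency``.  The bootstrap RNG is seeded per
    (hairpin, arm, replicate) from ``master_seed``.
    """
    thresholds = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    required_replicates = {
        **DEFAULT_REQUIRED_REPLICATES,
        **(required_replicates or {}),
    }
    end_type = experiment.end_type
    if end_type not in required_replicates:
        raise ValueError(f"no replicate requirement for end type {end_type!r}")
    need = required_replicates[end_type]
    if experiment.replicates < need:
        raise ValueError(
            f"{end_type} calls need {need} replicates, "
            f"experiment has {experiment.replicates}"
        )
    if consensus not in {"all", "majority"}:
        raise ValueError("consensus must be 'all' or 'majority'")

    strict = thresholds[end_type]
    relaxed = thresholds.get("relaxed_5prime") if end_type == "5prime" else None
    calls: list[EndpointCall] = []
    for gi, (hairpin_id, arm) in enumerate(experiment.groups()):
        prob_rows = []
        fluor_rows = []
        for rep in range(experiment.replicates):
            values = experiment.group_values(hairpin_id, arm, rep)
            rng = np.random.default_rng(
                np.random.SeedSequence([master_seed, gi, rep])
            )
            prob_rows.append(
                group_bootstrap_probabilities(values, n_boot=n_boot, rng=rng)
            )
            fluor_rows.append(values)
        probs = np.vstack(prob_rows)  # replicates x probes
        fluor = np.vstack(fluor_rows)
        anchor = experiment.anchors[(hairpin_id, arm)]
        for off in range(experiment.n_probes):
            col = probs[:, off]
            if consensus == "all":
                passing_strict = np.all(col > strict)
                passing_relaxed = relaxed is not None and np.all(col > relaxed)
            else:
                half = experiment.replicates / 2
                passing_strict = np.sum(col > strict) > half
                passing_relaxed = (
                    relaxed is not None and np.sum(col > relaxed) > half
                )
            if passing_strict or passing_relaxed:
                calls.append(
                    EndpointCall(
                        hairpin_id=hairpin_id,
                        arm=arm,
                        end_type=end_type,
                        position=anchor + off,
                        probe_offset=off,
                        probability=float(col.min()),
                        n_replicates_passing=int(
                            np.sum(col > (strict if passing_strict else relaxed))
                        ),
                        mean_fluorescence=float(fluor[:, off].mean()),
                        low_stringency=not passing_strict,
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# mature reconstruction
# ---------------------------------------------------------------------------


def format_mirna_id(
    prefix: str, chrom: str | int, start: int, stop: int, strand: str, arm: str
) -> str:
    """Underscore-delimited ID: name_chrom_start_stop_strand_arm."""
    return f"{prefix}_{chrom}_{start}_{stop}_{strand}_{arm}"


@dataclass(frozen=True)
class MatureCall:
    hairpin_id: str
    arm: str
    five_prime: int  # 1-based genomic
    three_prime: int
    sequence: str
    seed: str
    id_string: str
    joint_probability: float
    mean_fluorescence: float
    isomiR_of: str | None = None

    def __post_init__(self) -> None:
        if len(self.seed) != 6:
            raise ValueError("seed must be 6 nt")


@dataclass(frozen=True)
class HairpinReference:
    """Minimal hairpin record needed to place mature calls."""

    hairpin_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str  # precursor sequence in 5'->3' orientation

    def genomic_to_precursor(self, pos: int) -> int:
        """1-based offset of a genomic position within the precursor."""
        if self.strand == "+":
            return pos - self.start + 1
        return self.end - pos + 1


def reconstruct_mature(
    calls: list[EndpointCall],
    hairpins: dict[str, HairpinReference],
    length_window: tuple[int, int] = DEFAULT_LENGTH_WINDOW,
    id_prefix: str = "P",
) -> list[MatureCall]:
    """Pair 5'/3' calls on the same arm into mature sequences.

    Every (5', 3') pair with a length inside ``length_window`` and fully
    inside its hairpin becomes a call; per arm, the pair with the
    highest joint probability (ties: higher mean fluorescence, then
    5'-most) is canonical and the rest are isomiRs annotated with the
    canonical sequence's coordinates.
    """
    lo, hi = length_window
    by_group: dict[tuple[str, str], dict[str, list[EndpointCall]]] = {}
    for c in calls:
        by_group.setdefault((c.hairpin_id, c.arm), {}).setdefault(
            c.end_type, []
        ).append(c)

    out: list[MatureCall] = []
    for (hairpin_id, arm), ends in sorted(by_group.items()):
        hp = hairpins.get(hairpin_id)
        if hp is None or "5prime" not in ends or "3prime" not in ends:
            continue
        combos: list[MatureCall] = []
        for c5 in ends["5prime"]:
            for c3 in ends["3prime"]:
                if hp.strand == "+":
                    start, end = c5.position, c3.position
                else:
                    start, end = c3.position, c5.position
                length = end - start + 1
                if not lo <= length <= hi:
                    continue
                if start < hp.start or end > hp.end:
                    continue
                p_lo = hp.genomic_to_precursor(c5.position)
                p_hi = hp.genomic_to_precursor(c3.position)
                seq = hp.sequence[p_lo - 1 : p_hi]
                combos.append(
                    MatureCall(
                        hairpin_id=hairpin_id,
                        arm=arm,
                        five_prime=c5.position,
                        three_prime=c3.position,
                        sequence=seq,
                        seed=seq[1:7],
                        id_string=format_mirna_id(
                            id_prefix, hp.chrom, hp.start, hp.end, hp.strand, arm
                        ),
                        joint_probability=c5.probability * c3.probability,
                        mean_fluorescence=(
                            c5.mean_fluorescence + c3.mean_fluorescence
                        )
                        / 2,
                    )
                )
        if not combos:
            continue
        five_key = (1 if hp.strand == "+" else -1)
        combos.sort(
            key=lambda m: (
                -m.joint_probability,
                -m.mean_fluorescence,
                five_key * m.five_prime,
            )
        )
        canonical = combos[0]
        out.append(canonical)
        for iso in combos[1:]:
            out.append(
                MatureCall(
                    **{
                        **iso.__dict__,
                        "isomiR_of": canonical.id_string,
                    }
                )
            )
    return out


# ---------------------------------------------------------------------------
# spike-in calibration
# ---------------------------------------------------------------------------


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class SpikeCalibration:
    slope: float
    intercept: float  # log(fluorescence) = slope * log(amount) + intercept
    detection_floor: float  # fitted fluorescence at the lowest spike amount
    linear_range: tuple[float, float] = DEFAULT_LINEAR_RANGE
    points: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def fluorescence_at(self, amount: float) -> float:
        return float(np.exp(self.slope * np.log(amount) + self.intercept))


@dataclass(frozen=True)
class Quantification:
    amount_mol: float | None
    below_detection: bool
    in_linear_range: bool


def spikein_calibrate(
    points: list[tuple[float, float]],
    linear_range: tuple[float, float] = DEFAULT_LINEAR_RANGE,
) -> SpikeCalibration:
    """Least-squares log-log fit of fluorescence against known amount.

    Raises :class:`CalibrationError` when fewer than 2 distinct points
    are given or the series is not monotone increasing.
    """
    pts = sorted(points)
    if len({a for a, _ in pts}) < 2:
        raise CalibrationError("need at least 2 distinct spike amounts")
    amounts = np.array([a for a, _ in pts], dtype=float)
    fluor = np.array([f for _, f in pts], dtype=float)
    if np.any(amounts <= 0) or np.any(fluor <= 0):
        raise CalibrationError("amounts and fluorescence must be positive")
    if np.any(np.diff(fluor) <= 0):
        raise CalibrationError("spike series must be monotone increasing")
    slope, intercept = np.polyfit(np.log(amounts), np.log(fluor), 1)
    cal = SpikeCalibration(
        slope=float(slope),
        intercept=float(intercept),
        detection_floor=float(
            np.exp(slope * np.log(amounts[0]) + intercept)
        ),
        linear_range=linear_range,
        points=tuple((float(a), float(f)) for a, f in pts),
    )
    return cal


def quantify(calibration: SpikeCalibration, fluorescence: float) -> Quantification:
    """Invert the calibration; flag below-detection and out-of-range."""
    if fluorescence < calibration.detection_floor * (1.0 - 1e-9):
        return Quantification(None, True, False)
    amount = float(
        np.exp((np.log(fluorescence) - calibration.intercept) / calibration.slope)
    )
    lo, hi = calibration.linear_range
    return Quantification(amount, False, lo <= amount <= hi)


# ---------------------------------------------------------------------------
# spike-anchored normalization
# ---------------------------------------------------------------------------


def normalize_mirna_matrix(
    raw: pd.DataFrame,
    spike_ids: list[str],
    lowess_frac: float = 0.7,
) -> pd.DataFrame:
    """Intensity-dependent per-array correction anchored on spike-ins.

    For each array (column), a smooth trend of log residuals
    (log observed spike - log cross-array reference spike) is fitted
    against log intensity and subtracted from every value.  With few
    spikes the trend degenerates to a constant/linear correction.
    Below-detection entries (NaN) are preserved.
    """
    missing = [s for s in spike_ids if s not in raw.index]
    if missing or not spike_ids:
        raise ValueError(f"missing spike rows: {missing or spike_ids}")
    log = np.log(raw.where(raw > 0))
    ref = log.loc[spike_ids].mean(axis=1)  # per-spike cross-array reference
    out = log.copy()
    for col in raw.columns:
        obs = log.loc[spike_ids, col]
        resid = (obs - ref).to_numpy()
        x = obs.to_numpy()
        order = np.argsort(x)
        if len(spike_ids) >= 4:
            trend = sm.nonparametric.lowess(
                resid[order], x[order], frac=lowess_frac, return_sorted=True
            )
            xs, ys = trend[:, 0], trend[:, 1]
        else:
            xs, ys = x[order], resid[order]
        correction = np.interp(out[col].to_numpy(), xs, ys)
        out[col] = out[col] - correction
    return np.exp(out)
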