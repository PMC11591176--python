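"""Synthetic 12-lead ECG cohorts with known ground truth.

The generator produces 10 s, 500 Hz, 12-lead recordings whose beats are sums
of Gaussian wavelets (one per P/Q/R/S/T wave) placed at RR-jittered beat
times on three latent source channels (frontal-plane dipole x, y and a
precordial component z) and projected to the 12 standard leads through a
fixed Dower-style 12x3 matrix.  Because the morphology is analytic, every
fiducial point (R peak, QRS onset, ST junction, T-wave end) is known exactly,
and a configurable "planted" class-dependent effect (amplitude/width
rescaling of a chosen wave on chosen leads) provides a discriminative signal
whose location is ground truth for recovery experiments.

Left-ventricular ejection fraction (LVEF) classes follow the clinical
convention: pEF (preserved, >=50%), mrEF (mildly reduced, 40-<50%) and
rEF (reduced, <40%).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

SAMPLING_RATE = 500
DURATION_S = 10.0
N_SAMPLES = int(SAMPLING_RATE * DURATION_S)
MS_PER_SAMPLE = 1000.0 / SAMPLING_RATE

LEAD_NAMES = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

WAVES = ("P", "Q", "R", "S", "T")

EF_CLASSES = ("pEF", "mrEF", "rEF")

#: LVEF intervals (percent) per class; sampling is uniform within class.
LVEF_RANGES = {"pEF": (50.0, 75.0), "mrEF": (40.0, 50.0), "rEF": (15.0, 40.0)}


def ef_class_of(lvef: float) -> str:
    """Map an LVEF percentage to its class label (<40 rEF, 40-<50 mrEF, >=50 pEF)."""
    if lvef < 40.0:
        return "rEF"
    if lvef < 50.0:
        return "mrEF"
    return "pEF"


def _dower_projection() -> np.ndarray:
    """Fixed 12x3 source-to-lead matrix.

    Leads I, II and V1-V6 use Dower-transform style coefficients; the four
    derived limb leads are computed from I and II by their defining algebraic
    relations, so limb-lead closure (III = II - I, aVR = -(I+II)/2, ...)
    holds exactly for any source signal.
    """
    lead_i = np.array([0.632, -0.235, 0.059])
    lead_ii = np.array([0.235, 1.066, -0.132])
    rows = {
        "I": lead_i,
        "II": lead_ii,
        "III": lead_ii - lead_i,
        "aVR": -(lead_i + lead_ii) / 2.0,
        "aVL": lead_i - lead_ii / 2.0,
        "aVF": lead_ii - lead_i / 2.0,
        "V1": np.array([-0.515, 0.157, -0.917]),
        "V2": np.array([0.044, 0.164, -1.387]),
        "V3": np.array([0.882, 0.098, -1.277]),
        "V4": np.array([1.213, 0.127, -0.601]),
        "V5": np.array([1.125, 0.127, -0.086]),
        "V6": np.array([0.831, 0.076, 0.230]),
    }
    return np.stack([rows[name] for name in LEAD_NAMES])


DEFAULT_PROJECTION = _dower_projection()

#: Unit-ish directions of each wave's dipole in (x, y, z) source space.
#: Chosen so the projected leads show the usual morphology (dominant positive
#: R in II/V4-V6, negative aVR, R-wave progression across V1-V6).
WAVE_DIRECTIONS = {
    "P": np.array([0.50, 0.85, 0.10]),
    "Q": np.array([-0.55, -0.25, 0.75]),
    "R": np.array([0.60, 0.65, -0.47]),
    "S": np.array([-0.50, -0.30, 0.81]),
    "T": np.array([0.58, 0.50, -0.64]),
}


@dataclass(frozen=True)
class WaveParams:
    """Gaussian wavelet parameters for one of the five ECG waves.

    amplitude in mV (sign carries polarity), width is the Gaussian sigma in
    ms, latency is the wavelet centre relative to the R peak in ms.
    """

    amplitude: float
    width_ms: float
    latency_ms: float

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError(f"wave width must be positive, got {self.width_ms}")


#: Default morphology: amplitudes (mV), sigmas (ms), latencies vs R peak (ms).
DEFAULT_WAVES = {
    "P": WaveParams(0.12, 22.0, -170.0),
    "Q": WaveParams(-0.12, 9.0, -32.0),
    "R": WaveParams(1.10, 11.0, 0.0),
    "S": WaveParams(-0.25, 10.0, 32.0),
    "T": WaveParams(0.35, 55.0, 240.0),
}

#: Wave-group labels accepted by EffectSpec, mapped to the member wavelets.
EFFECT_WAVE_GROUPS = {"P": ("P",), "QRS": ("Q", "R", "S"), "ST-T": ("T",)}


def _check_wave_order(waves: dict[str, WaveParams]) -> None:
    lat = [waves[w].latency_ms for w in WAVES]
    if not all(a < b for a, b in zip(lat, lat[1:])):
        raise ValueError(f"wave latencies must be ordered P<Q<R<S<T, got {lat}")
    if waves["R"].amplitude <= 0:
        raise ValueError("R amplitude must be positive")


@dataclass(frozen=True)
class EffectSpec:
    """A planted class-dependent morphology effect.

    Rescales the amplitude and/or width of one wave group (P, QRS or ST-T)
    on a subset of leads, for records of the listed LVEF classes only.  The
    effect location is the ground truth that lead/segment recovery
    experiments try to find.
    """

    target_wave: str
    target_leads: tuple[str, ...]
    amplitude_multiplier: float = 1.0
    width_multiplier: float = 1.0
    applies_to_classes: tuple[str, ...] = ("mrEF", "rEF")

    def __post_init__(self) -> None:
        if self.target_wave not in EFFECT_WAVE_GROUPS:
            raise ValueError(
                f"target_wave must be one of {sorted(EFFECT_WAVE_GROUPS)}, "
                f"got {self.target_wave!r}"
            )
        if not self.target_leads:
            raise ValueError("target_leads must be non-empty")
        unknown = set(self.target_leads) - set(LEAD_NAMES)
        if unknown:
            raise ValueError(f"unknown lead names: {sorted(unknown)}")
        if self.amplitude_multiplier <= 0 or self.width_multiplier <= 0:
            raise ValueError("effect multipliers must be positive")
        unknown_cls = set(self.applies_to_classes) - set(EF_CLASSES)
        if unknown_cls:
            raise ValueError(f"unknown EF classes: {sorted(unknown_cls)}")


@dataclass
class CohortConfig:
    """Everything needed to generate a reproducible synthetic cohort."""

    n_cases: dict[str, int] = field(
        default_factory=lambda: {"pEF": 60, "mrEF": 20, "rEF": 20}
    )
    heart_rate_mean: float = 70.0
    heart_rate_sd: float = 8.0
    rr_jitter_sd_ms: float = 20.0
    af_fraction: dict[str, float] = field(
        default_factory=lambda: {"pEF": 0.0, "mrEF": 0.0, "rEF": 0.0}
    )
    noise_sd: float = 0.01
    baseline_wander_amp: float = 0.05
    baseline_wander_freq: float = 0.25
    lead_projection: np.ndarray = field(
        default_factory=lambda: DEFAULT_PROJECTION.copy()
    )
    waves: dict[str, WaveParams] = field(default_factory=lambda: dict(DEFAULT_WAVES))
    effects: list[EffectSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, n in self.n_cases.items():
            if cls not in EF_CLASSES:
                raise ValueError(f"unknown EF class {cls!r}")
            if n < 0:
                raise ValueError("case counts must be >= 0")
        for cls, f in self.af_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError("af_fraction must be within [0, 1]")
        self.lead_projection = np.asarray(self.lead_projection, dtype=float)
        if self.lead_projection.ndim != 2 or self.lead_projection.shape[0] != 12:
            raise ValueError(
                f"lead_projection must have 12 rows, got shape "
                f"{self.lead_projection.shape}"
            )
        if self.heart_rate_mean <= 0:
            raise ValueError("heart_rate_mean must be positive")
        _check_wave_order(self.waves)


@dataclass(frozen=True)
class BeatAnnotation:
    """Per-beat fiducials in 0-based sample indices (500 Hz)."""

    r_peak: int
    qrs_onset: int
    st_junction: int
    t_end: int

    def __post_init__(self) -> None:
        if not (self.qrs_onset < self.r_peak < self.st_junction < self.t_end):
            raise ValueError(
                "fiducials must satisfy qrs_onset < r_peak < st_junction < t_end, "
                f"got {(self.qrs_onset, self.r_peak, self.st_junction, self.t_end)}"
            )
        if self.qrs_onset < 0 or self.t_end >= N_SAMPLES:
            raise ValueError(
                f"fiducials must lie within [0, {N_SAMPLES}), got "
                f"{(self.qrs_onset, self.t_end)}"
            )


@dataclass
class EcgRecord:
    """One 10 s, 500 Hz, 12-lead recording with case metadata."""

    case_id: str
    signal: np.ndarray  # 12 x 5000, mV, rows in LEAD_NAMES order
    lvef: float
    ef_class: str
    af: bool = False
    sampling_rate: int = SAMPLING_RATE
    truth: list[BeatAnnotation] | None = None  # generator only
    truth_waves: dict[str, WaveParams] | None = None  # generator only

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.shape != (12, N_SAMPLES):
            raise ValueError(
                f"signal must be 12 x {N_SAMPLES}, got {self.signal.shape}"
            )
        if self.ef_class != ef_class_of(self.lvef):
            raise ValueError(
                f"ef_class {self.ef_class!r} inconsistent with lvef={self.lvef}"
            )


def _beat_times(config: CohortConfig, heart_rate: float, af: bool,
                rng: np.random.Generator) -> np.ndarray:
    """R-peak times in seconds. First beat at 0.3*RR so the single-beat
    window (250 ms pre-R) fits; subsequent intervals are jittered (sinus) or
    i.i.d. uniform with wide spread (AF)."""
    if heart_rate <= 0:
        raise ValueError("heart rate must be positive")
    rr = 60.0 / heart_rate
    times = []
    t = 0.3 * rr
    while t < DURATION_S:
        times.append(t)
        if af:
            step = rr * rng.uniform(0.65, 1.35)
        else:
            step = rr + rng.normal(0.0, config.rr_jitter_sd_ms / 1000.0)
        t += max(step, 0.3)
    return np.asarray(times)


def _truth_annotation(r_sample: int, waves: dict[str, WaveParams]
                      ) -> BeatAnnotation | None:
    """Exact fiducials of the beat at ``r_sample``; None when the beat is
    truncated by the record edge (its fiducials would leave [0, 5000))."""
    q, s, t = waves["Q"], waves["S"], waves["T"]
    onset = r_sample + int(round((q.latency_ms - 2.5 * q.width_ms) / MS_PER_SAMPLE))
    st_j = r_sample + int(round((s.latency_ms + 2.5 * s.width_ms) / MS_PER_SAMPLE))
    t_end = r_sample + int(round((t.latency_ms + 2.5 * t.width_ms) / MS_PER_SAMPLE))
    if onset < 0 or t_end >= N_SAMPLES:
        return None
    return BeatAnnotation(r_peak=r_sample, qrs_onset=onset,
                          st_junction=st_j, t_end=t_end)


def _effect_multipliers(config: CohortConfig, ef_class: str
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-(lead, wave) amplitude and width multipliers for one record."""
    n_leads = config.lead_projection.shape[0]
    amp = np.ones((n_leads, len(WAVES)))
    wid = np.ones((n_leads, len(WAVES)))
    lead_index = {name: i for i, name in enumerate(LEAD_NAMES)}
    for eff in config.effects:
        if ef_class not in eff.applies_to_classes:
            continue
        rows = [lead_index[lead] for lead in eff.target_leads]
        cols = [WAVES.index(w) for w in EFFECT_WAVE_GROUPS[eff.target_wave]]
        for r in rows:
            for c in cols:
                amp[r, c] *= eff.amplitude_multiplier
                wid[r, c] *= eff.width_multiplier
    return amp, wid


def simulate_record(config: CohortConfig, lvef: float, af: bool,
                    rng: np.random.Generator,
                    case_id: str = "SYN-0000") -> EcgRecord:
    """Simulate one 12-lead record with exact truth fiducials.

    The signal decomposes linearly into per-wave, per-lead Gaussian
    components, so planted effects are applied exactly as multipliers on the
    targeted components.
    """
    if not 0.0 < lvef <= 100.0:
        raise ValueError(f"lvef must be in (0, 100], got {lvef}")
    ef_class = ef_class_of(lvef)
    heart_rate = float(np.clip(
        rng.normal(config.heart_rate_mean, config.heart_rate_sd), 40.0, 160.0))
    beat_t = _beat_times(config, heart_rate, af, rng)
    r_samples = np.round(beat_t * SAMPLING_RATE).astype(int)
    r_samples = r_samples[r_samples < N_SAMPLES]

    waves = dict(config.waves)
    if af:
        waves["P"] = dataclasses.replace(waves["P"], amplitude=0.0)

    amp_mult, wid_mult = _effect_multipliers(config, ef_class)
    proj = config.lead_projection
    n_leads = proj.shape[0]
    t_grid = np.arange(N_SAMPLES) / SAMPLING_RATE  # seconds

    signal = np.zeros((n_leads, N_SAMPLES))
    for wi, wname in enumerate(WAVES):
        wp = waves[wname]
        if wp.amplitude == 0.0:
            continue
        # base lead coefficients: projection of this wave's dipole direction
        coef = wp.amplitude * (proj @ WAVE_DIRECTIONS[wname])  # (n_leads,)
        centres = beat_t[: len(r_samples)] + wp.latency_ms / 1000.0
        # group leads by effective width so each distinct profile is built once
        widths = wid_mult[:, wi] * (wp.width_ms / 1000.0)
        for width in np.unique(widths):
            mask = widths == width
            prof = np.zeros(N_SAMPLES)
            half = 5.0 * width
            for c in centres:
                lo = max(0, int((c - half) * SAMPLING_RATE))
                hi = min(N_SAMPLES, int((c + half) * SAMPLING_RATE) + 1)
                seg = t_grid[lo:hi] - c
                prof[lo:hi] += np.exp(-0.5 * (seg / width) ** 2)
            signal[mask] += (coef[mask] * amp_mult[mask, wi])[:, None] * prof[None, :]

    if config.baseline_wander_amp > 0:
        # wander lives on the source channels so limb-lead closure is preserved
        phases = rng.uniform(0.0, 2 * np.pi, size=proj.shape[1])
        amps = config.baseline_wander_amp * rng.uniform(0.5, 1.0, size=proj.shape[1])
        wander = amps[:, None] * np.sin(
            2 * np.pi * config.baseline_wander_freq * t_grid[None, :]
            + phases[:, None])
        signal += proj @ wander
    if config.noise_sd > 0:
        signal += rng.normal(0.0, config.noise_sd, size=signal.shape)

    truth = [ann for r in r_samples
             if (ann := _truth_annotation(int(r), waves)) is not None]
    return EcgRecord(case_id=case_id, signal=signal, lvef=float(lvef),
                     ef_class=ef_class, af=af, truth=truth, truth_waves=waves)


def make_cohort(config: CohortConfig) -> list[EcgRecord]:
    """Generate the full cohort: exact per-class counts, uniform LVEF within
    each class interval, AF assigned by per-class fraction, reproducible
    bitwise from ``config.seed``."""
    total = sum(config.n_cases.values())
    if total == 0:
        raise ValueError("cohort must contain at least one case")
    records: list[EcgRecord] = []
    master = np.random.SeedSequence(config.seed)
    # one child stream per record plus one for cohort-level draws
    children = master.spawn(total + 1)
    cohort_rng = np.random.default_rng(children[0])
    idx = 0
    for cls in EF_CLASSES:
        n = config.n_cases.get(cls, 0)
        lo, hi = LVEF_RANGES[cls]
        af_frac = config.af_fraction.get(cls, 0.0)
        for _ in range(n):
            lvef = float(cohort_rng.uniform(lo, hi))
            af = bool(cohort_rng.uniform() < af_frac)
            rec_rng = np.random.default_rng(children[idx + 1])
            records.append(simulate_record(
                config, lvef, af, rec_rng, case_id=f"SYN-{idx:04d}"))
            idx += 1
    return records
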