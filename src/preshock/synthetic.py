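"""Synthetic VF-like ECG generator with known ground truth.

The clinical pre-shock dataset this package targets is not publicly
deposited, so validation runs on synthetic records: trains of biphasic
QRS-like templates (a pair of opposed Gaussian lobes) placed at jittered
RR intervals, plus band-limited Gaussian noise.  Every injected quantity
(R-peak times, peak-to-trough amplitude, extremum gap, noise power) is
returned as ground truth, which lets the downstream detector and feature
extractors be tested for parameter *recovery* rather than plausibility.

Class-conditional feature summaries — per-class Gaussian mean/SD for the
six features — drive cohort sampling.  The default ``ROEA_SPEC`` /
``NOROEA_SPEC`` values are the published summaries of a 251-record
out-of-hospital cardiac-arrest development cohort (successful vs.
unsuccessful shocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .features import FEATURE_NAMES
from .records import ECGRecord, LABEL_NOROEA, LABEL_ROEA, LABEL_TO_CODE, VALID_LABELS

#: Default conditions for cohort synthesis.
DEFAULT_FS = 250.0
DEFAULT_DURATION = 9.0
DEFAULT_NOISE_POWER = 0.001  # mV^2, low relative to even 3-SD-small templates
DEFAULT_RR_JITTER = 0.05  # fraction of the mean RR interval

#: Records keep this margin (s) between the first/last beat and the edges,
#: so no template is truncated.
_EDGE_MARGIN_S = 0.3

#: Fraction of the class mean used as the positivity floor when sampling
#: physically nonnegative quantities from a Gaussian summary.
_FLOOR_FRACTION = 0.01


@dataclass(frozen=True)
class WaveformParams:
    """Generation parameters for a single synthetic record."""

    target_hr: float  # beats/min
    qrs_amplitude: float = 1.5  # mV, template peak-to-trough
    qrs_extremum_gap: float = 85.0  # ms between template max and min
    rr_jitter: float = DEFAULT_RR_JITTER  # fraction of mean RR
    noise_power: float = DEFAULT_NOISE_POWER  # mV^2 mean square
    duration: float = DEFAULT_DURATION  # s
    fs: float = DEFAULT_FS  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.target_hr > 0:
            raise ValueError("target_hr must be positive")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not self.qrs_amplitude > 0:
            raise ValueError("qrs_amplitude must be positive")
        if not self.qrs_extremum_gap > 0:
            raise ValueError("qrs_extremum_gap must be positive")
        if self.noise_power < 0:
            raise ValueError("noise_power must be >= 0")
        if not 0 <= self.rr_jitter < 1:
            raise ValueError("rr_jitter must be in [0, 1)")
        f_max = _template_max_frequency(self.qrs_extremum_gap / 1000.0)
        if self.noise_power > 0:
            f_max = max(f_max, 48.0)
        if self.fs < 2 * f_max:
            raise ValueError(
                f"fs={self.fs} Hz is below twice the highest generated "
                f"frequency (~{f_max:.1f} Hz); raise fs or widen the template"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Injected quantities for one synthetic record."""

    r_peak_times: np.ndarray  # s, template centers, strictly increasing
    beat_amplitudes: np.ndarray  # mV, per beat
    beat_extremum_gaps: np.ndarray  # ms, per beat
    noise_power: float  # mV^2

    def __post_init__(self) -> None:
        t = np.asarray(self.r_peak_times, dtype=float)
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("r_peak_times must be strictly increasing")
        object.__setattr__(self, "r_peak_times", t)
        object.__setattr__(self, "beat_amplitudes", np.asarray(self.beat_amplitudes, float))
        object.__setattr__(self, "beat_extremum_gaps", np.asarray(self.beat_extremum_gaps, float))

    @property
    def n_beats(self) -> int:
        return int(self.r_peak_times.size)


@dataclass(frozen=True)
class ClassSpec:
    """Gaussian feature summaries (mean, SD) for one outcome class."""

    label: str
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        for d, what in ((self.means, "means"), (self.sds, "sds")):
            if set(d) != set(FEATURE_NAMES):
                raise ValueError(
                    f"{what} must provide exactly the features {FEATURE_NAMES}"
                )
        if any(s <= 0 for s in self.sds.values()):
            raise ValueError("all standard deviations must be > 0")


#: Successful-shock class: slower, larger, more organized VF.
ROEA_SPEC = ClassSpec(
    label=LABEL_ROEA,
    means={
        "heart_rate": 110.0,
        "amplitude_qrs": 1.5,
        "qrs_duration": 85.0,
        "total_power2": 0.6,
        "lf_power2": 0.25,
        "hf_power2": 0.08,
    },
    sds={
        "heart_rate": 12.0,
        "amplitude_qrs": 0.4,
        "qrs_duration": 8.0,
        "total_power2": 0.12,
        "lf_power2": 0.06,
        "hf_power2": 0.02,
    },
)

#: Unsuccessful-shock class: faster, lower-amplitude, lower-power VF.
NOROEA_SPEC = ClassSpec(
    label=LABEL_NOROEA,
    means={
        "heart_rate": 130.0,
        "amplitude_qrs": 0.9,
        "qrs_duration": 105.0,
        "total_power2": 0.35,
        "lf_power2": 0.12,
        "hf_power2": 0.04,
    },
    sds={
        "heart_rate": 18.0,
        "amplitude_qrs": 0.3,
        "qrs_duration": 12.0,
        "total_power2": 0.09,
        "lf_power2": 0.04,
        "hf_power2": 0.01,
    },
)

DEFAULT_CLASS_SPECS = (ROEA_SPEC, NOROEA_SPEC)


def _template_sigma(gap_s: float) -> float:
    # Lobe width tied to the extremum gap; keeps template energy in 2-25 Hz
    # for physiological gaps so the 0.5-48 Hz bandpass passes it unchanged.
    return gap_s / 4.0


def _template_max_frequency(gap_s: float) -> float:
    # Gaussian lobe of width sigma has spectral SD 1/(2*pi*sigma); content
    # beyond 4 spectral SDs is negligible.
    return 2.0 / (np.pi * _template_sigma(gap_s))


def _solve_lobe_separation(gap_s: float, sigma: float) -> tuple[float, float, float]:
    """Half-separation c so the template's extrema are exactly gap_s apart.

    Opposed Gaussian lobes at +/-c pull each other's extrema inward, so c
    is found by bisection against the observed extremum gap on a fine grid.
    Returns (c, scale_to_unit_amplitude, fine_grid_dt).
    """
    dt = sigma / 200.0

    def observed(c: float) -> tuple[float, float]:
        half = c + 6 * sigma
        t = np.arange(-half, half + dt, dt)
        v = np.exp(-0.5 * ((t + c) / sigma) ** 2) - np.exp(-0.5 * ((t - c) / sigma) ** 2)
        gap = t[np.argmin(v)] - t[np.argmax(v)]
        return gap, float(v.max() - v.min())

    lo, hi = gap_s / 2.0, 1.5 * gap_s
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        g, _ptt = observed(mid)
        if g < gap_s:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    _g, ptt = observed(c)
    return c, 1.0 / ptt, dt


def _qrs_template(t_rel: np.ndarray, amplitude: float, gap_s: float) -> np.ndarray:
    """Biphasic QRS-like deflection centered at t_rel = 0 (max before min)."""
    sigma = _template_sigma(gap_s)
    c, unit_scale, _ = _solve_lobe_separation(gap_s, sigma)
    v = np.exp(-0.5 * ((t_rel + c) / sigma) ** 2) - np.exp(-0.5 * ((t_rel - c) / sigma) ** 2)
    return amplitude * unit_scale * v


def _band_limited_noise(
    n: int, fs: float, power: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean noise band-limited to 0.5-48 Hz with exact mean square."""
    white = rng.standard_normal(n)
    sos = _signal.butter(4, [0.5, 48.0], btype="bandpass", fs=fs, output="sos")
    shaped = _signal.sosfiltfilt(sos, white)
    shaped -= shaped.mean()
    ms = np.mean(shaped**2)
    return shaped * np.sqrt(power / ms) if ms > 0 else shaped


def synth_waveform(params: WaveformParams) -> tuple[ECGRecord, GroundTruth]:
    """Generate one synthetic VF-like record plus its ground truth.

    Beats are placed at RR intervals drawn around 60/target_hr with
    multiplicative Gaussian jitter (clipped at 3 SD so intervals stay
    positive and ordered); every beat uses the same template realisation.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.fs))
    t = np.arange(n) / params.fs

    mean_rr = 60.0 / params.target_hr
    gap_s = params.qrs_extremum_gap / 1000.0

    centers = []
    pos = _EDGE_MARGIN_S
    limit = params.duration - _EDGE_MARGIN_S
    while pos <= limit:
        centers.append(pos)
        z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
        pos += mean_rr * (1.0 + params.rr_jitter * z)
    centers = np.asarray(centers)

    samples = np.zeros(n)
    for tc in centers:
        samples += _qrs_template(t - tc, params.qrs_amplitude, gap_s)
    if params.noise_power > 0:
        samples += _band_limited_noise(n, params.fs, params.noise_power, rng)

    record = ECGRecord(samples=samples, fs=params.fs, record_id=f"synth-{params.seed}")
    truth = GroundTruth(
        r_peak_times=centers,
        beat_amplitudes=np.full(centers.size, params.qrs_amplitude),
        beat_extremum_gaps=np.full(centers.size, params.qrs_extremum_gap),
        noise_power=params.noise_power,
    )
    return record, truth


def _positive_draw(rng: np.random.Generator, mean: float, sd: float) -> float:
    return max(float(rng.normal(mean, sd)), _FLOOR_FRACTION * mean)


def synth_cohort(
    specs=DEFAULT_CLASS_SPECS,
    n_per_class: int = 100,
    seed: int = 0,
    duration: float = DEFAULT_DURATION,
    fs: float = DEFAULT_FS,
    noise_power: float = DEFAULT_NOISE_POWER,
    rr_jitter: float = DEFAULT_RR_JITTER,
) -> tuple[list[ECGRecord], np.ndarray, list[GroundTruth]]:
    """Generate a labeled cohort of synthetic records.

    Per-record heart rate, QRS amplitude and extremum gap are drawn from
    each class's Gaussian summaries; waveform noise and jitter come from a
    per-record substream derived from the master seed, so a fixed seed
    yields a bit-identical cohort.

    Returns ``(records, labels, truths)`` with integer class codes
    (1 = NoROEA, 2 = ROEA) as labels.
    """
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    master = np.random.default_rng(seed)
    records: list[ECGRecord] = []
    labels: list[int] = []
    truths: list[GroundTruth] = []
    for spec in specs:
        for i in range(n_per_class):
            sub_seed = int(master.integers(0, 2**31))
            rng = np.random.default_rng(sub_seed)
            params = WaveformParams(
                target_hr=_positive_draw(rng, spec.means["heart_rate"], spec.sds["heart_rate"]),
                qrs_amplitude=_positive_draw(
                    rng, spec.means["amplitude_qrs"], spec.sds["amplitude_qrs"]
                ),
                qrs_extremum_gap=_positive_draw(
                    rng, spec.means["qrs_duration"], spec.sds["qrs_duration"]
                ),
                rr_jitter=rr_jitter,
                noise_power=noise_power,
                duration=duration,
                fs=fs,
                seed=sub_seed,
            )
            record, truth = synth_waveform(params)
            record = ECGRecord(
                samples=record.samples,
                fs=record.fs,
                record_id=f"{spec.label}-{i:04d}",
                label=spec.label,
            )
            records.append(record)
            labels.append(LABEL_TO_CODE[spec.label])
            truths.append(truth)
    return records, np.asarray(labels), truths


def sample_feature_table(
    specs=DEFAULT_CLASS_SPECS,
    n_per_class: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw a feature table directly from the class Gaussian summaries.

    Features are sampled independently per class (the published summaries
    are marginal only); physically nonnegative draws are floored at 1% of
    the class mean.  Used for classifier-level experiments that bypass the
    waveform path.
    """
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    rng = np.random.default_rng(seed)
    blocks = []
    labels = []
    for spec in specs:
        cols = {
            name: np.maximum(
                rng.normal(spec.means[name], spec.sds[name], size=n_per_class),
                _FLOOR_FRACTION * spec.means[name],
            )
            for name in FEATURE_NAMES
        }
        blocks.append(pd.DataFrame(cols, columns=list(FEATURE_NAMES)))
        labels.append(np.full(n_per_class, LABEL_TO_CODE[spec.label]))
    X = pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame(columns=list(FEATURE_NAMES))
    y = np.concatenate(labels) if labels else np.asarray([], dtype=int)
    return X, y
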