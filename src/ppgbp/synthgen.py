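"""Synthetic cohort generator for cuffless blood-pressure experiments.

Real studies of PPG/ECG-based blood-pressure estimation collect synchronized
fingertip photoplethysmograms and lead-II electrocardiograms together with
cuff reference pressures.  Such recordings are rarely shared, so this module
produces seeded surrogate cohorts with the same shape: 20 s two-channel
records sampled at 500 Hz, per-record subject metadata (height, weight,
gender) and reference SBP/DBP values generated from a documented function of
the latent beat parameters.

Every pulse is rendered as the sum of a systolic and a dicrotic Gaussian
component, which guarantees the six canonical PPG fiducial points per beat
(onset *b*, maximum-slope *a*, systolic peak *c*, minimum-slope *e*,
dicrotic notch *f*, dicrotic peak *g*) and makes their true locations
available to downstream detector tests.  The ECG channel carries one
triangular R-spike per beat, preceding the pulse onset by a controllable
transit time, which is all that R-peak based timing features require.

The reference pressures follow

    SBP = beta0 + beta1 / PTT + beta2 * HR + beta3 * DAR + eps

(and analogously for DBP), where PTT is the planted R-to-onset transit time
in seconds, HR the heart rate in bpm, DAR the dicrotic-to-systolic amplitude
ratio and eps Gaussian noise with subject-specific standard deviation.  The
coefficients are stored on the subject profile and echoed into every
record's metadata, so the ground-truth mapping is recoverable by regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SubjectProfile",
    "BeatTruth",
    "SyntheticRecord",
    "NoiseConfig",
    "Cohort",
    "DEFAULT_TRAIN_RECORD_COUNTS",
    "make_subject",
    "render_record",
    "make_cohort",
]

#: Per-subject record counts of the default training cohort layout
#: (17 subjects, 775 records in total).
DEFAULT_TRAIN_RECORD_COUNTS: tuple[int, ...] = (
    44, 61, 51, 52, 52, 31, 40, 53,          # male training subjects
    27, 47, 41, 28, 64, 55, 20, 55, 54,      # female training subjects
)

#: Nominal operating point at which a subject's base pressures are attained.
_NOMINAL_PTT = 0.20     # s
_NOMINAL_HR = 70.0      # bpm
_NOMINAL_DAR = 0.45     # dicrotic/systolic amplitude ratio


@dataclass(frozen=True, eq=False)
class SubjectProfile:
    """Latent description of one synthetic subject."""

    subject_id: str
    gender: int                 # 0 = female, 1 = male
    height: float               # m
    weight: float               # kg
    base_sbp: float             # mmHg at the nominal operating point
    base_dbp: float             # mmHg
    #: rows (sbp, dbp) x columns (1/PTT, HR, DAR) slope coefficients
    coupling: np.ndarray = field(
        default_factory=lambda: np.array([[8.0, 0.35, -12.0],
                                          [4.0, 0.25, -6.0]])
    )
    noise_sd: float = 1.5       # mmHg, measurement noise of the cuff reference

    def __post_init__(self) -> None:
        if self.height <= 0 or self.weight <= 0:
            raise ValueError("height and weight must be positive")
        if self.base_dbp >= self.base_sbp:
            raise ValueError("base_dbp must be below base_sbp")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.gender not in (0, 1):
            raise ValueError("gender must be coded 0 (female) or 1 (male)")
        object.__setattr__(self, "coupling", np.asarray(self.coupling, float))
        if self.coupling.shape != (2, 3):
            raise ValueError("coupling must be a 2x3 coefficient array")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SubjectProfile):
            return NotImplemented
        for name in ("subject_id", "gender", "height", "weight",
                     "base_sbp", "base_dbp", "noise_sd"):
            if getattr(self, name) != getattr(other, name):
                return False
        return np.array_equal(self.coupling, other.coupling)

    def __hash__(self) -> int:
        return hash((self.subject_id, self.height, self.weight))

    @property
    def bmi(self) -> float:
        """Body mass index, kg/m^2."""
        return self.weight / self.height ** 2

    def intercepts(self) -> np.ndarray:
        """beta0 for (sbp, dbp) so that base pressures hold at nominal latents."""
        latents = np.array([1.0 / _NOMINAL_PTT, _NOMINAL_HR, _NOMINAL_DAR])
        return np.array([self.base_sbp, self.base_dbp]) - self.coupling @ latents


@dataclass(frozen=True)
class BeatTruth:
    """Planted fiducial geometry of one rendered beat.

    Times are in seconds from the beat onset *b*; ``onset_index`` is the
    absolute sample index of *b* in the parent record.  The R-spike occurs
    ``r_offset`` seconds before the onset.
    """

    t_b: float
    t_a: float
    t_c: float
    t_e: float
    t_f: float
    t_g: float
    amp_b: float
    amp_a: float
    amp_c: float
    amp_e: float
    amp_f: float
    amp_g: float
    r_offset: float
    period: float
    onset_index: int

    def __post_init__(self) -> None:
        order = (self.t_b, self.t_a, self.t_c, self.t_e, self.t_f, self.t_g)
        if not all(x < y for x, y in zip(order, order[1:])) or self.t_b != 0.0:
            raise ValueError("fiducial times must satisfy 0 = b < a < c < e < f < g")
        if self.t_g >= self.period:
            raise ValueError("fiducials must fall within one period")
        if self.r_offset <= 0:
            raise ValueError("r_offset must be positive")
        amps = (self.amp_b, self.amp_a, self.amp_e, self.amp_f, self.amp_g)
        if any(a > self.amp_c for a in amps):
            raise ValueError("the systolic peak c must be the beat maximum")


@dataclass(frozen=True)
class NoiseConfig:
    """Additive disturbances applied to the rendered channels."""

    baseline_amp: float = 0.0       # amplitude of the baseline-wander sinusoid
    baseline_freq: float = 0.25     # Hz, must stay <= 0.5 Hz
    powerline_amp: float = 0.0      # amplitude of the 50 Hz interference
    white_sd: float = 0.0           # white-noise standard deviation

    def __post_init__(self) -> None:
        if self.baseline_freq > 0.5:
            raise ValueError("baseline wander is limited to <= 0.5 Hz")
        if min(self.baseline_amp, self.powerline_amp, self.white_sd) < 0:
            raise ValueError("noise amplitudes must be non-negative")


@dataclass(frozen=True)
class SyntheticRecord:
    """One 20 s (by default) two-channel record with planted truth."""

    ppg: np.ndarray
    ecg: np.ndarray
    fs: float
    beats: tuple[BeatTruth, ...]
    sbp_ref: float
    dbp_ref: float
    subject_id: str
    record_id: str
    #: latent parameters and the BP function, recorded for provenance
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ppg) != len(self.ecg):
            raise ValueError("ppg and ecg must have equal length")
        if self.sbp_ref <= self.dbp_ref:
            raise ValueError("sbp_ref must exceed dbp_ref")

    @property
    def duration(self) -> float:
        return len(self.ppg) / self.fs

    @property
    def r_indices(self) -> np.ndarray:
        """Planted R-peak sample indices."""
        return np.array(
            [b.onset_index - int(round(b.r_offset * self.fs)) for b in self.beats]
        )


def make_subject(seed: int, **overrides) -> SubjectProfile:
    """Draw a subject profile from seeded population distributions.

    Any :class:`SubjectProfile` field may be overridden; derived quantities
    (BMI, intercepts) follow from the final field values.
    """
    rng = np.random.default_rng(seed)
    gender = int(rng.integers(0, 2))
    height = float(rng.normal(1.62 if gender == 0 else 1.74, 0.06))
    weight = float(max(rng.normal(56.0 if gender == 0 else 68.0, 7.0), 35.0))
    # anthropometry informs the resting pressures (higher BMI and male sex
    # shift both up), leaving only a small idiosyncratic offset per subject
    bmi = weight / height**2
    base_sbp = float(
        100.0 + 1.5 * (bmi - 22.0) + 6.0 * gender + rng.normal(0.0, 3.0)
    )
    base_dbp = float(
        65.0 + 0.9 * (bmi - 22.0) + 3.0 * gender + rng.normal(0.0, 2.5)
    )
    base_dbp = min(base_dbp, base_sbp - 25.0)
    defaults = dict(
        subject_id=f"S{seed}",
        gender=gender,
        height=round(height, 3),
        weight=round(weight, 1),
        base_sbp=round(base_sbp, 2),
        base_dbp=round(base_dbp, 2),
    )
    defaults.update(overrides)
    return SubjectProfile(**defaults)


def _beat_template(
    t: np.ndarray, period: float, dicrotic_ratio: float
) -> np.ndarray:
    """Noise-free pulse shape on grid ``t`` (s from onset), unit systolic amp.

    Component widths scale with the period so the dicrotic notch survives at
    every admissible heart rate.
    """
    t_sys = 0.30 * period
    t_dic = 0.62 * period
    sys_width = 0.09 * period
    dic_width = 1.1 * sys_width
    return np.exp(-0.5 * ((t - t_sys) / sys_width) ** 2) + dicrotic_ratio * np.exp(
        -0.5 * ((t - t_dic) / dic_width) ** 2
    )


def _locate_fiducials(pulse: np.ndarray, fs: float) -> dict[str, int]:
    """Fiducial sample offsets of one noiseless pulse rendered on its grid."""
    d = np.gradient(pulse)
    c = int(np.argmax(pulse))
    a = int(np.argmax(d[: c + 1]))
    # e: minimum slope after the peak, searched before the dicrotic rise
    tail = d[c + 1 :]
    e = c + 1 + int(np.argmin(tail))
    # f: first local minimum after e; g: first local maximum after f
    f = g = None
    for i in range(e, len(pulse) - 1):
        if pulse[i] <= pulse[i - 1] and pulse[i] < pulse[i + 1]:
            f = i
            break
    if f is not None:
        for i in range(f + 1, len(pulse) - 1):
            if pulse[i] >= pulse[i - 1] and pulse[i] > pulse[i + 1]:
                g = i
                break
    if f is None or g is None:
        raise ValueError("pulse shape lacks a dicrotic notch/peak")
    return {"b": 0, "a": a, "c": c, "e": e, "f": f, "g": g}


def render_record(
    profile: SubjectProfile,
    *,
    duration: float = 20.0,
    hr: float = 70.0,
    r_offset: float = 0.20,
    dicrotic_ratio: float = 0.45,
    noise: NoiseConfig | None = None,
    fs: float = 500.0,
    seed: int = 0,
    record_id: str = "r0",
) -> SyntheticRecord:
    """Render one synchronized PPG+ECG record for ``profile``.

    Parameters
    ----------
    duration, hr
        Record length in seconds and heart rate in bpm (30-200).
    r_offset
        R-peak-to-pulse-onset transit time in seconds; the first pulse onset
        is placed at ``r_offset`` so every beat's R-spike falls inside the
        record.
    dicrotic_ratio
        Amplitude of the dicrotic component relative to the systolic one.
    noise
        Additive disturbances; ``None`` renders a clean record.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not 30.0 <= hr <= 200.0:
        raise ValueError("hr must lie in [30, 200] bpm")
    period = 60.0 / hr
    if duration < period:
        raise ValueError("duration must cover at least one beat")
    if not 0.0 < r_offset < 0.45 * period:
        raise ValueError("r_offset must be positive and well below one period")
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    ppg = np.zeros(n)
    ecg = np.zeros(n)

    # one period worth of template, fiducials located once (beats identical)
    tmpl_t = np.arange(int(round(period * fs))) / fs
    tmpl = _beat_template(tmpl_t, period, dicrotic_ratio)
    fid = _locate_fiducials(tmpl, fs)

    onsets = []
    # 100 ms lead-in keeps the first R-spike away from the record edge
    start = r_offset + 0.1
    while start < duration:
        onsets.append(start)
        start += period

    beats = []
    for onset in onsets:
        i0 = int(round(onset * fs))
        seg = min(len(tmpl), n - i0)
        ppg[i0 : i0 + seg] += tmpl[:seg]
        # triangular R-spike of 20 ms total width centred r_offset before b
        r_idx = i0 - int(round(r_offset * fs))
        half = int(round(0.010 * fs))
        for j in range(-half, half + 1):
            if 0 <= r_idx + j < n:
                ecg[r_idx + j] += 1.0 - abs(j) / half
        if i0 + fid["g"] < n:
            beats.append(
                BeatTruth(
                    t_b=0.0,
                    t_a=fid["a"] / fs,
                    t_c=fid["c"] / fs,
                    t_e=fid["e"] / fs,
                    t_f=fid["f"] / fs,
                    t_g=fid["g"] / fs,
                    amp_b=float(tmpl[0]),
                    amp_a=float(tmpl[fid["a"]]),
                    amp_c=float(tmpl[fid["c"]]),
                    amp_e=float(tmpl[fid["e"]]),
                    amp_f=float(tmpl[fid["f"]]),
                    amp_g=float(tmpl[fid["g"]]),
                    r_offset=r_offset,
                    period=period,
                    onset_index=i0,
                )
            )

    ppg += noise.baseline_amp * np.sin(2 * np.pi * noise.baseline_freq * t)
    ppg += noise.powerline_amp * np.sin(2 * np.pi * 50.0 * t)
    ecg += noise.powerline_amp * np.sin(2 * np.pi * 50.0 * t)
    if noise.white_sd > 0:
        ppg += rng.normal(0.0, noise.white_sd, n)
        ecg += rng.normal(0.0, noise.white_sd, n)

    latents = np.array([1.0 / r_offset, hr, dicrotic_ratio])
    beta0 = profile.intercepts()
    eps = rng.normal(0.0, profile.noise_sd, 2) if profile.noise_sd > 0 else np.zeros(2)
    sbp = float(beta0[0] + profile.coupling[0] @ latents + eps[0])
    dbp = float(beta0[1] + profile.coupling[1] @ latents + eps[1])

    meta = {
        "bp_function": "bp = beta0 + beta1/ptt + beta2*hr + beta3*dar + eps",
        "latents": {"ptt": r_offset, "hr": hr, "dar": dicrotic_ratio},
        "beta0": beta0.tolist(),
        "coupling": profile.coupling.tolist(),
        "noise_sd": profile.noise_sd,
        "seed": seed,
    }
    return SyntheticRecord(
        ppg=ppg,
        ecg=ecg,
        fs=fs,
        beats=tuple(beats),
        sbp_ref=sbp,
        dbp_ref=dbp,
        subject_id=profile.subject_id,
        record_id=record_id,
        meta=meta,
    )


@dataclass(frozen=True)
class Cohort:
    """Subject-wise train/test partition of synthetic records."""

    train_subjects: tuple[SubjectProfile, ...]
    test_subjects: tuple[SubjectProfile, ...]
    train_records: tuple[SyntheticRecord, ...]
    test_records: tuple[SyntheticRecord, ...]

    @property
    def n_train_records(self) -> int:
        return len(self.train_records)

    @property
    def n_test_records(self) -> int:
        return len(self.test_records)


def _subject_records(
    profile: SubjectProfile,
    n_records: int,
    rng: np.random.Generator,
    noise: NoiseConfig,
    fs: float,
    duration: float,
) -> list[SyntheticRecord]:
    records = []
    for k in range(n_records):
        hr = float(np.clip(rng.normal(72.0, 9.0), 48.0, 110.0))
        # transit time shortens as the cycle does; keep it clear of the period
        ptt_hi = min(0.32, 0.40 * 60.0 / hr)
        ptt = float(np.clip(rng.normal(0.21, 0.03), 0.12, ptt_hi))
        dar = float(np.clip(rng.normal(0.45, 0.07), 0.25, 0.65))
        records.append(
            render_record(
                profile,
                duration=duration,
                hr=hr,
                r_offset=ptt,
                dicrotic_ratio=dar,
                noise=noise,
                fs=fs,
                seed=int(rng.integers(0, 2**31 - 1)),
                record_id=f"{profile.subject_id}_r{k:03d}",
            )
        )
    return records


def make_cohort(
    n_train_subjects: int = 17,
    n_test_subjects: int = 10,
    records_per_subject: int | tuple[int, ...] | None = None,
    *,
    test_records_per_subject: int = 12,
    seed: int = 0,
    noise: NoiseConfig | None = None,
    fs: float = 500.0,
    duration: float = 20.0,
) -> Cohort:
    """Generate a seeded cohort split by subject.

    ``records_per_subject`` may be one count for all training subjects or a
    per-subject tuple; by default the 17-subject layout in
    :data:`DEFAULT_TRAIN_RECORD_COUNTS` is used when ``n_train_subjects`` is
    17, otherwise 30 records per subject.  Test subjects contribute
    ``test_records_per_subject`` records each (12 by default, the first half
    of which downstream personalization uses for calibration).
    """
    if n_train_subjects < 0 or n_test_subjects < 0:
        raise ValueError("subject counts must be non-negative")
    if records_per_subject is None:
        if n_train_subjects == len(DEFAULT_TRAIN_RECORD_COUNTS):
            counts = DEFAULT_TRAIN_RECORD_COUNTS
        else:
            counts = (30,) * n_train_subjects
    elif isinstance(records_per_subject, int):
        counts = (records_per_subject,) * n_train_subjects
    else:
        counts = tuple(records_per_subject)
        if len(counts) != n_train_subjects:
            raise ValueError("records_per_subject length must match n_train_subjects")
    noise = noise or NoiseConfig()
    root = np.random.default_rng(seed)

    train_subjects, train_records = [], []
    for i, n_rec in enumerate(counts):
        sub_seed = int(root.integers(0, 2**31 - 1))
        profile = make_subject(sub_seed, subject_id=f"train{i + 1:02d}")
        train_subjects.append(profile)
        sub_rng = np.random.default_rng(sub_seed + 1)
        train_records.extend(
            _subject_records(profile, n_rec, sub_rng, noise, fs, duration)
        )

    test_subjects, test_records = [], []
    for i in range(n_test_subjects):
        sub_seed = int(root.integers(0, 2**31 - 1))
        profile = make_subject(sub_seed, subject_id=f"test{i + 1:02d}")
        test_subjects.append(profile)
        sub_rng = np.random.default_rng(sub_seed + 1)
        test_records.extend(
            _subject_records(
                profile, test_records_per_subject, sub_rng, noise, fs, duration
            )
        )

    return Cohort(
        train_subjects=tuple(train_subjects),
        test_subjects=tuple(test_subjects),
        train_records=tuple(train_records),
        test_records=tuple(test_records),
    )
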