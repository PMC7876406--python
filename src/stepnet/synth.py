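"""Synthetic task-evoked EEG cohorts.

Generates stimulus sequences, multi-subject epoched EEG and behavioral
records with the statistical structure the downstream analysis assumes:
64-channel 250 Hz recordings, auditory-oddball (AOB) and Go/NoGo (GNG)
paradigms, planted N100/P200/N2/P3a components with group-level latency,
amplitude and trial-jitter differences between healthy controls and
15q13.3-microdeletion-like patients, trial-to-trial jitter, additive noise,
blink transients, and reaction-time/accuracy records.

The default parameter values are the study conditions: AOB with 600 tones
(80% Frequent / 10% Target / 10% Novel, one tone per 1.5 s, epochs
−200…+1200 ms), GNG with 300 tones (80% Go / 20% NoGo, ISI uniform on
1000–2000 ms, epochs −200…+800 ms), 30 healthy + 9 patient subjects, two
visits. Behavioral means/SDs default to the published group summaries.

Seed policy: one master seed; every subject × visit × task stream derives
its generator from ``numpy.random.SeedSequence(master, spawn_key=...)`` so a
single subject can be regenerated without simulating the whole cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import EpochedEEG
from .montage import ChannelGeometry, standard_montage

SFREQ = 250.0

#: conditions that require a button press; NoGo requires withholding one
RESPONSE_CONDITIONS = ("Target", "Go")
INHIBITION_CONDITIONS = ("NoGo",)


class ConfigurationError(ValueError):
    """Raised when a task/component specification is internally inconsistent."""


# ---------------------------------------------------------------------------
# task specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskSpec:
    """One cognitive task: trial mix, tone frequencies, timing, epoch window."""

    name: str
    n_trials: int
    condition_probs: dict[str, float]
    tone_freqs: dict[str, float | None]
    isi_ms: tuple[float, float]  # (lo, hi); lo == hi means fixed interval
    epoch_window_ms: tuple[float, float]
    min_correct: float = 0.65

    def validate(self) -> None:
        total = sum(self.condition_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"condition probabilities sum to {total}, expected 1"
            )
        pre, post = self.epoch_window_ms
        if not (post > 0 >= pre):
            raise ConfigurationError("epoch window must straddle stimulus onset")
        if self.isi_ms[0] > self.isi_ms[1] or self.isi_ms[0] <= 0:
            raise ConfigurationError("invalid ISI range")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.condition_probs)


def aob_task(n_trials: int = 600) -> TaskSpec:
    """Auditory oddball: frequent standards, rare targets, rare novels."""
    return TaskSpec(
        name="AOB",
        n_trials=n_trials,
        condition_probs={"Frequent": 0.8, "Target": 0.1, "Novel": 0.1},
        tone_freqs={"Frequent": 2000.0, "Target": 1000.0, "Novel": None},
        isi_ms=(1500.0, 1500.0),
        epoch_window_ms=(-200.0, 1200.0),
    )


def gng_task(n_trials: int = 300) -> TaskSpec:
    """Go/NoGo: frequent Go tones, rare NoGo tones, jittered ISI."""
    return TaskSpec(
        name="GNG",
        n_trials=n_trials,
        condition_probs={"Go": 0.8, "NoGo": 0.2},
        tone_freqs={"Go": 2000.0, "NoGo": 1000.0},
        isi_ms=(1000.0, 2000.0),
        epoch_window_ms=(-200.0, 800.0),
    )


def generate_task_sequence(spec: TaskSpec, seed: int) -> pd.DataFrame:
    """Ordered stimulus sequence: condition, onset time, tone frequency.

    Per-condition counts equal ``round(n_trials × prob)`` (any rounding
    remainder is assigned by largest fractional part); order is a seeded
    permutation. Novel sounds, which differ on every trial, get a per-trial
    random frequency.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    raw = {c: spec.n_trials * p for c, p in spec.condition_probs.items()}
    counts = {c: int(round(v)) for c, v in raw.items()}
    short = spec.n_trials - sum(counts.values())
    if short:  # distribute remainder by descending fractional part
        order = sorted(raw, key=lambda c: raw[c] - math.floor(raw[c]), reverse=True)
        for c in order[: abs(short)]:
            counts[c] += int(np.sign(short))

    labels = np.repeat(list(counts), list(counts.values()))
    rng.shuffle(labels)

    lo, hi = spec.isi_ms
    isi = np.full(spec.n_trials, lo) if lo == hi else rng.uniform(lo, hi, spec.n_trials)
    onsets = np.concatenate([[0.0], np.cumsum(isi[:-1])])

    freqs = np.empty(spec.n_trials)
    for i, c in enumerate(labels):
        f = spec.tone_freqs.get(c)
        freqs[i] = rng.uniform(300.0, 3000.0) if f is None else f

    return pd.DataFrame(
        {"condition": labels, "onset_ms": onsets, "tone_hz": freqs}
    )


# ---------------------------------------------------------------------------
# subject parameterization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentSpec:
    """One evoked ERP component (a smooth spatiotemporal bump).

    The temporal kernel is a Gaussian envelope of SD ``temporal_sd_ms``
    centered at ``latency_mean``; components whose energy lives above the
    delta band additionally carry a cosine oscillation at ``carrier_hz``
    (peak aligned with the latency), making each component band-limited to
    its nominal frequency band — a slow delta bump for P3a, theta wavelets
    for N100/P200, an alpha wavelet for N2. The spatial kernel is an
    isotropic Gaussian over the projected scalp positions, centered at
    ``topo_center`` with scale ``topo_spread`` (disc radii).
    ``latency_sd``/``amplitude_sd`` are between-subject variation used when
    sampling a cohort.
    """

    label: str
    polarity: int
    topo_center: tuple[float, float]
    topo_spread: float
    latency_mean: float
    latency_sd: float
    amplitude_mean: float
    amplitude_sd: float
    band: str
    conditions: frozenset[str]
    temporal_sd_ms: float = 40.0
    carrier_hz: float | None = None

    def validate(self, epoch_window_ms: tuple[float, float]) -> None:
        if self.amplitude_mean <= 0:
            raise ConfigurationError(f"{self.label}: amplitude_mean must be > 0")
        if not (0.0 <= self.latency_mean < epoch_window_ms[1]):
            raise ConfigurationError(
                f"{self.label}: latency {self.latency_mean} ms outside "
                f"post-stimulus window {epoch_window_ms}"
            )
        if self.polarity not in (-1, 1):
            raise ConfigurationError(f"{self.label}: polarity must be ±1")


def default_components() -> list[ComponentSpec]:
    """The four scored components with canonical topographies and timings."""
    return [
        ComponentSpec("N100", -1, (0.0, 0.25), 0.45, 100.0, 8.0, 4.0, 0.8,
                      "theta", frozenset({"Frequent", "Target", "Novel", "Go", "NoGo"}),
                      temporal_sd_ms=35.0, carrier_hz=5.5),
        ComponentSpec("P200", +1, (0.0, -0.10), 0.45, 200.0, 10.0, 4.0, 0.8,
                      "theta", frozenset({"Frequent", "Target", "Novel", "Go", "NoGo"}),
                      temporal_sd_ms=40.0, carrier_hz=5.5),
        ComponentSpec("N2", -1, (0.0, 0.35), 0.40, 250.0, 12.0, 3.0, 0.6,
                      "alpha", frozenset({"NoGo"}), temporal_sd_ms=35.0, carrier_hz=10.0),
        ComponentSpec("P3a", +1, (0.0, 0.30), 0.50, 300.0, 15.0, 8.0, 1.3,
                      "delta", frozenset({"Novel", "NoGo"}), temporal_sd_ms=50.0),
    ]


@dataclass(frozen=True)
class SubjectParams:
    """Everything needed to simulate one subject's EEG and behavior."""

    group: str  # "healthy" | "patient"
    components: tuple[ComponentSpec, ...]
    trial_latency_jitter_sd: float = 20.0   # ms
    trial_amplitude_jitter_sd: float = 1.0  # μV
    noise_sd: float = 6.0                   # μV per sample
    pink_noise: bool = False
    blink_rate: float = 4.0                 # events/min
    blink_amplitude: float = 120.0          # μV at the ocular site
    rt_mean: dict[str, float] = field(default_factory=dict)   # ms, per condition
    rt_sd: dict[str, float] = field(default_factory=dict)     # ms, per condition
    error_rate: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for v in (self.trial_latency_jitter_sd, self.trial_amplitude_jitter_sd,
                  self.noise_sd, self.blink_rate):
            if v < 0:
                raise ConfigurationError("all SDs and rates must be ≥ 0")
        for e in self.error_rate.values():
            if not 0.0 <= e <= 1.0:
                raise ConfigurationError("error_rate must be in [0, 1]")


# behavioral defaults follow the published group summaries (ms / proportions)
_HEALTHY_BEHAVIOR = dict(
    rt_mean={"Target": 455.13, "Go": 374.07},
    rt_sd={"Target": 92.22, "Go": 102.96},
    error_rate={"Target": 0.0201, "Go": 0.0166, "NoGo": 0.1267},
)
_PATIENT_BEHAVIOR = dict(
    rt_mean={"Target": 570.68, "Go": 499.32},
    rt_sd={"Target": 143.46, "Go": 159.98},
    error_rate={"Target": 0.0583, "Go": 0.1259, "NoGo": 0.0907},
)


def healthy_params(components: list[ComponentSpec] | None = None) -> SubjectParams:
    return SubjectParams(
        group="healthy",
        components=tuple(components or default_components()),
        **_HEALTHY_BEHAVIOR,
    )


@dataclass(frozen=True)
class GroupEffect:
    """Patient-vs-control deltas applied to component and jitter parameters."""

    dlatency_ms: dict[str, float] = field(default_factory=dict)
    amplitude_scale: dict[str, float] = field(default_factory=dict)
    jitter_scale: float = 1.0

    def apply(self, params: SubjectParams) -> SubjectParams:
        comps = tuple(
            replace(
                c,
                latency_mean=c.latency_mean + self.dlatency_ms.get(c.label, 0.0),
                amplitude_mean=c.amplitude_mean * self.amplitude_scale.get(c.label, 1.0),
            )
            for c in params.components
        )
        # the jitter factor scales every trial-level stochastic source —
        # component amplitude/latency jitter and additive sensor noise —
        # emulating globally elevated neural noise, which is what raises
        # trial-to-trial ERP variability in every condition
        return replace(
            params,
            components=comps,
            trial_latency_jitter_sd=params.trial_latency_jitter_sd * self.jitter_scale,
            trial_amplitude_jitter_sd=params.trial_amplitude_jitter_sd * self.jitter_scale,
            noise_sd=params.noise_sd * self.jitter_scale,
        )


def default_group_effect() -> GroupEffect:
    """Planted patient effect: later & smaller P3a, noisier trials."""
    return GroupEffect(
        dlatency_ms={"P3a": 50.0},
        amplitude_scale={"P3a": 0.7},
        jitter_scale=1.5,
    )


def null_group_effect() -> GroupEffect:
    return GroupEffect()


def patient_params(
    components: list[ComponentSpec] | None = None,
    effect: GroupEffect | None = None,
) -> SubjectParams:
    base = SubjectParams(
        group="patient",
        components=tuple(components or default_components()),
        **_PATIENT_BEHAVIOR,
    )
    return (effect or default_group_effect()).apply(base)


# ---------------------------------------------------------------------------
# EEG simulation
# ---------------------------------------------------------------------------

def _pink(rng: np.random.Generator, shape: tuple[int, ...], sd: float) -> np.ndarray:
    """1/f-shaped Gaussian noise along the last axis, unit-free SD ``sd``."""
    white = rng.standard_normal(shape)
    f = np.fft.rfftfreq(shape[-1], d=1.0 / SFREQ)
    scale = np.where(f > 0, 1.0 / np.sqrt(f), 0.0)
    x = np.fft.irfft(np.fft.rfft(white, axis=-1) * scale, n=shape[-1], axis=-1)
    x *= sd / x.std()
    return x


def _blink_waveform(n: int, sfreq: float) -> np.ndarray:
    """Stereotyped biphasic 300-ms blink transient, peak value 1."""
    t = np.arange(n) / sfreq * 1000.0  # ms
    w = np.exp(-0.5 * ((t - 90.0) / 35.0) ** 2) - 0.35 * np.exp(
        -0.5 * ((t - 210.0) / 45.0) ** 2
    )
    return w / np.abs(w).max()


def simulate_subject_eeg(
    sequence: pd.DataFrame,
    params: SubjectParams,
    montage: ChannelGeometry | None = None,
    seed: int | np.random.SeedSequence = 0,
    epoch_window_ms: tuple[float, float] = (-200.0, 1200.0),
    sfreq: float = SFREQ,
) -> EpochedEEG:
    """Simulate epoched EEG for one subject performing one task.

    Every epoch is the sum, over the components evoked by its condition, of
    ``polarity × amplitude × spatial_kernel × temporal_kernel`` with per-trial
    jittered amplitude and latency, plus additive sensor noise and (on
    frontal channels) blink transients. Independent sub-streams are used for
    signal jitter, noise and blinks, so e.g. zeroing the blink rate leaves
    the other draws untouched.
    """
    params.validate()
    montage = montage or standard_montage()
    for comp in params.components:
        comp.validate(epoch_window_ms)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_sig, rng_noise, rng_blink = map(np.random.default_rng, ss.spawn(3))

    pre, post = epoch_window_ms
    n_times = int(round((post - pre) * sfreq / 1000.0))
    times = pre + np.arange(n_times) * 1000.0 / sfreq
    n_epochs = len(sequence)
    conditions = sequence["condition"].to_numpy()

    data = np.zeros((n_epochs, montage.n_channels, n_times))

    for comp in params.components:
        evoked = np.isin(conditions, list(comp.conditions))
        if not evoked.any():
            continue
        k = int(evoked.sum())
        amp = comp.amplitude_mean + rng_sig.normal(
            0.0, params.trial_amplitude_jitter_sd, k
        )
        lat = comp.latency_mean + rng_sig.normal(
            0.0, params.trial_latency_jitter_sd, k
        )
        d = montage.positions - np.asarray(comp.topo_center)
        spatial = np.exp(-0.5 * (np.linalg.norm(d, axis=1) / comp.topo_spread) ** 2)
        temporal = np.exp(
            -0.5 * ((times[None, :] - lat[:, None]) / comp.temporal_sd_ms) ** 2
        )
        if comp.carrier_hz is not None:
            temporal *= np.cos(
                2e-3 * np.pi * comp.carrier_hz * (times[None, :] - lat[:, None])
            )
        data[evoked] += (
            comp.polarity
            * amp[:, None, None]
            * spatial[None, :, None]
            * temporal[:, None, :]
        )

    if params.noise_sd > 0:
        if params.pink_noise:
            data += _pink(rng_noise, data.shape, params.noise_sd)
        else:
            data += rng_noise.normal(0.0, params.noise_sd, data.shape)

    if params.blink_rate > 0:
        epoch_s = (post - pre) / 1000.0
        ocular = np.array([0.0, 1.2])
        decay = np.exp(
            -np.linalg.norm(montage.positions - ocular, axis=1) / 0.25
        )
        n_blink_samp = int(round(0.3 * sfreq))
        wave = _blink_waveform(n_blink_samp, sfreq)
        counts = rng_blink.poisson(params.blink_rate * epoch_s / 60.0, n_epochs)
        for ep in np.nonzero(counts)[0]:
            for _ in range(counts[ep]):
                start = rng_blink.integers(0, max(1, n_times - n_blink_samp))
                seg = slice(start, start + n_blink_samp)
                data[ep, :, seg] += (
                    params.blink_amplitude * decay[:, None] * wave[None, :]
                )

    return EpochedEEG(
        data=data,
        sfreq=sfreq,
        tmin_ms=pre,
        montage=montage,
        conditions=conditions,
        meta={"group": params.group},
    )


# ---------------------------------------------------------------------------
# behavior simulation
# ---------------------------------------------------------------------------

def _trunc_normal_rt(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Positive reaction times ~ normal(mean, sd) truncated at 0."""
    if sd == 0:
        return np.full(n, mean)
    a = (0.0 - mean) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_behavior(
    sequence: pd.DataFrame, params: SubjectParams, seed: int | np.random.SeedSequence = 0
) -> pd.DataFrame:
    """Per-trial responses: correctness flags and reaction times.

    Response-required trials (Target, Go) are correct with probability
    1 − error_rate and then carry a truncated-normal RT; misses carry none.
    NoGo trials are commission errors (with an RT) with probability
    error_rate and correct inhibitions otherwise. Conditions without a
    response mapping (Frequent, Novel) have no correctness defined.
    """
    params.validate()
    rng = np.random.default_rng(
        seed if not isinstance(seed, np.random.SeedSequence) else seed
    )
    n = len(sequence)
    conditions = sequence["condition"].to_numpy()
    responded = np.zeros(n, dtype=bool)
    correct = np.full(n, None, dtype=object)
    rt = np.full(n, np.nan)

    for cond in np.unique(conditions):
        idx = np.nonzero(conditions == cond)[0]
        err = params.error_rate.get(cond)
        if cond in RESPONSE_CONDITIONS:
            ok = rng.random(idx.size) >= (err or 0.0)
            responded[idx] = ok
            correct[idx] = ok
            hits = idx[ok]
            rt[hits] = _trunc_normal_rt(
                rng, params.rt_mean[cond], params.rt_sd[cond], hits.size
            )
        elif cond in INHIBITION_CONDITIONS:
            commission = rng.random(idx.size) < (err or 0.0)
            responded[idx] = commission
            correct[idx] = ~commission
            slips = idx[commission]
            mean = params.rt_mean.get("Go", 350.0)
            sd = params.rt_sd.get("Go", 80.0)
            rt[slips] = _trunc_normal_rt(rng, mean, sd, slips.size)

    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "condition": conditions,
            "responded": responded,
            "correct": correct,
            "rt_ms": rt,
        }
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Study design: group sizes, visits, planted group effect, task sizes."""

    n_healthy: int = 30
    n_patient: int = 9
    visits: int = 2
    seed: int = 0
    group_effect: GroupEffect = field(default_factory=default_group_effect)
    tasks: tuple[TaskSpec, ...] = field(
        default_factory=lambda: (aob_task(), gng_task())
    )
    n_channels: int = 64

    def validate(self) -> None:
        if min(self.n_healthy, self.n_patient, self.visits) <= 0:
            raise ConfigurationError("counts must be positive")


@dataclass(frozen=True)
class SubjectEntry:
    subject_id: str
    index: int
    group: str
    params: SubjectParams
    age_years: float
    sex: str


def draw_subject_params(
    group: str,
    rng: np.random.Generator,
    effect: GroupEffect | None = None,
) -> SubjectParams:
    """Sample one subject's parameters around the group defaults.

    Component latencies/amplitudes vary between subjects by the
    ComponentSpec SDs; sensor noise and trial-jitter SDs get lognormal
    between-subject spread; behavioral means get modest spread (30 ms on RT
    means, lognormal factor on error rates). Patients additionally receive
    the group effect.
    """
    base = healthy_params() if group == "healthy" else SubjectParams(
        group="patient", components=tuple(default_components()),
        **_PATIENT_BEHAVIOR,
    )
    comps = tuple(
        replace(
            c,
            latency_mean=c.latency_mean + rng.normal(0.0, c.latency_sd),
            amplitude_mean=max(
                0.2 * c.amplitude_mean,
                c.amplitude_mean + rng.normal(0.0, c.amplitude_sd),
            ),
        )
        for c in base.components
    )
    params = replace(
        base,
        components=comps,
        noise_sd=base.noise_sd * rng.lognormal(0.0, 0.15),
        trial_latency_jitter_sd=base.trial_latency_jitter_sd * rng.lognormal(0.0, 0.2),
        trial_amplitude_jitter_sd=base.trial_amplitude_jitter_sd * rng.lognormal(0.0, 0.2),
        rt_mean={k: v + rng.normal(0.0, 30.0) for k, v in base.rt_mean.items()},
        error_rate={
            k: float(np.clip(v * rng.lognormal(0.0, 0.3), 0.0, 0.9))
            for k, v in base.error_rate.items()
        },
    )
    if group == "patient" and effect is not None:
        params = effect.apply(params)
    return params


class Cohort:
    """A simulated study cohort with lazily materialized recordings.

    Subject-level parameters (component means, behavior rates, demographics)
    are drawn once per subject; each subject × visit × task recording is
    simulated on demand from a seed derived by spawn key, so repeated calls
    return identical data and the full cohort never has to fit in memory at
    once. Visit 2 reuses the subject's parameters with a fresh noise stream,
    which is what makes test–retest reliability positive.
    """

    def __init__(self, config: CohortConfig):
        config.validate()
        self.config = config
        self.montage = standard_montage(config.n_channels)
        self.subjects: list[SubjectEntry] = []
        for i in range(config.n_healthy + config.n_patient):
            group = "healthy" if i < config.n_healthy else "patient"
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(0, i))
            )
            params = draw_subject_params(group, rng, config.group_effect)
            self.subjects.append(
                SubjectEntry(
                    subject_id=f"S{i:03d}",
                    index=i,
                    group=group,
                    params=params,
                    age_years=float(rng.uniform(14.0, 18.0)),
                    sex="F" if rng.random() < 0.1 else "M",
                )
            )

    # -- lookup helpers -----------------------------------------------------
    def _entry(self, subject_id: str) -> SubjectEntry:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def _task(self, task_name: str) -> tuple[int, TaskSpec]:
        for j, t in enumerate(self.config.tasks):
            if t.name == task_name:
                return j, t
        raise KeyError(task_name)

    def _seed(self, subj_index: int, visit: int, task_index: int, stream: int
              ) -> np.random.SeedSequence:
        return np.random.SeedSequence(
            self.config.seed, spawn_key=(1 + stream, subj_index, visit, task_index)
        )

    # -- materialization ----------------------------------------------------
    def sequence(self, subject_id: str, visit: int, task_name: str) -> pd.DataFrame:
        s = self._entry(subject_id)
        j, spec = self._task(task_name)
        seq_seed = int(self._seed(s.index, visit, j, 0).generate_state(1)[0] % (2**31))
        return generate_task_sequence(spec, seq_seed)

    def epochs(self, subject_id: str, visit: int, task_name: str) -> EpochedEEG:
        s = self._entry(subject_id)
        j, spec = self._task(task_name)
        eeg = simulate_subject_eeg(
            self.sequence(subject_id, visit, task_name),
            s.params,
            montage=self.montage,
            seed=self._seed(s.index, visit, j, 1),
            epoch_window_ms=spec.epoch_window_ms,
        )
        eeg.meta.update(subject=subject_id, visit=visit, task=task_name, group=s.group)
        return eeg

    def behavior(self, subject_id: str, visit: int, task_name: str) -> pd.DataFrame:
        s = self._entry(subject_id)
        j, _ = self._task(task_name)
        rec = simulate_behavior(
            self.sequence(subject_id, visit, task_name),
            s.params,
            seed=np.random.default_rng(self._seed(s.index, visit, j, 2)),
        )
        rec.insert(0, "subject", subject_id)
        rec.insert(1, "visit", visit)
        rec.insert(2, "task", self.config.tasks[j].name)
        return rec

    def demographics(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
                "age_years": [s.age_years for s in self.subjects],
            }
        )


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Build a cohort per the study design (default: 30 healthy + 9 patients,
    two visits, planted P3a/jitter patient effect)."""
    return Cohort(config or CohortConfig())
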