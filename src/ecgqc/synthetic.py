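"""Synthetic 8-lead ECG generation under the linear mixing model.

Records are built as x(t) = A s(t) + n(t): N cardiac source series s(t)
(sum-of-Gaussians beat templates, mutually decorrelated by construction),
an 8 x N full-column-rank mixing matrix A of volume-conductor
attenuations, and an additive noise term n(t) assembled from configurable
contamination events.  Amplitudes are in ADC counts, matching a 16-bit
digitiser at a conventional ECG gain, so that clean records land in the
same eigenvalue decade as real acceptable recordings
(log10(lambda_1) of roughly 3-5).

This is a covariance-structure simulator, not a physiological one: beat
morphology is schematic, rhythm is a constant rate with small timing
jitter, and no attempt is made to model respiration or autonomic
variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .errors import ConfigError
from .io import ANALYSIS_LEADS, EcgRecord, QualityLabel

#: Default ADC counts per unit source amplitude.  Chosen so that a clean
#: record's dominant eigenvalue sits near log10(lambda_1) = 4, the middle
#: of the acceptable range for unscaled digital ECGs.
DEFAULT_AMPLITUDE_SCALE = 330.0

#: Saturation ceiling of a 16-bit ADC.
ADC_CEILING = 2**15 - 1

_NOISE_KINDS = {
    "white",
    "powerline",
    "baseline_wander",
    "flat_lead",
    "clipping",
    "transient_artifact",
}

# Beat template: (center offset s relative to the R wave, width s, amplitude)
# for P, Q, R, S and T deflections.
_BEAT_WAVES = (
    (-0.20, 0.040, 0.15),
    (-0.03, 0.010, -0.10),
    (0.00, 0.012, 1.00),
    (0.03, 0.010, -0.25),
    (0.28, 0.060, 0.35),
)


@dataclass(frozen=True)
class NoiseEvent:
    """One contamination event applied to a subset of leads.

    ``amplitude`` is the noise standard deviation for ``white`` and
    ``transient_artifact``, the peak amplitude for ``powerline`` and
    ``baseline_wander``, the constant value for ``flat_lead``, and the
    saturation ceiling for ``clipping`` (all in ADC counts).
    """

    kind: str
    leads: tuple[int, ...] = tuple(range(1, 9))  # 1-based lead indices
    amplitude: float = 0.0
    frequency: float | None = None  # Hz, for periodic kinds
    onset: float = 0.0  # s, for transient_artifact
    duration: float | None = None  # s, None = rest of record

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ConfigError(f"unknown noise kind {self.kind!r}")
        if self.kind != "flat_lead" and self.amplitude < 0:
            raise ConfigError("noise amplitude must be non-negative")
        if any(not 1 <= l <= 8 for l in self.leads):
            raise ConfigError("target leads must be in 1..8")
        if self.onset < 0 or (self.duration is not None and self.duration < 0):
            raise ConfigError("onset/duration must be non-negative")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults give a noise-free 3-source record."""

    n_sources: int = 3
    mixing: np.ndarray | None = None  # 8 x N; random full-column-rank if None
    heart_rate: float = 72.0  # beats/min
    sampling_rate: float = 500.0  # Hz
    duration: float = 10.0  # s
    amplitude_scale: float = DEFAULT_AMPLITUDE_SCALE  # ADC counts / unit source
    noise_events: tuple[NoiseEvent, ...] = ()
    seed: int = 0
    record_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_sources < 1:
            raise ConfigError("need at least one cardiac source")
        if self.n_sources > 8:
            raise ConfigError("at most 8 sources for 8 leads")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ConfigError("duration and sampling_rate must be positive")
        if self.heart_rate <= 0:
            raise ConfigError("heart_rate must be positive")
        if self.amplitude_scale <= 0:
            raise ConfigError("amplitude_scale must be positive")
        if self.mixing is not None:
            m = np.asarray(self.mixing, dtype=float)
            if m.shape != (8, self.n_sources):
                raise ConfigError(
                    f"mixing matrix must be 8 x {self.n_sources}, got {m.shape}"
                )
            if np.linalg.matrix_rank(m) < self.n_sources:
                raise ConfigError("mixing matrix must have full column rank")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


def _beat_train(
    t: np.ndarray, heart_rate: float, rng: np.random.Generator,
    wave_jitter: np.ndarray,
) -> np.ndarray:
    """Periodic sum-of-Gaussians beats with small per-beat timing jitter."""
    period = 60.0 / heart_rate
    n_beats = int(np.ceil(t[-1] / period)) + 2
    centers = np.arange(n_beats) * period + 0.5 * period
    centers = centers + rng.normal(0.0, 0.01, size=n_beats)
    out = np.zeros_like(t)
    for (off, width, amp), (doff, dwid, damp) in zip(_BEAT_WAVES, wave_jitter):
        w = width * (1.0 + dwid)
        for c in centers:
            mu = c + off + doff
            lo = np.searchsorted(t, mu - 5 * w)
            hi = np.searchsorted(t, mu + 5 * w)
            seg = t[lo:hi] - mu
            out[lo:hi] += amp * (1.0 + damp) * np.exp(-0.5 * (seg / w) ** 2)
    return out


def make_sources(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Generate the N x K matrix of zero-mean, mutually decorrelated sources.

    Each source starts from a randomly perturbed beat template; the raw
    trains are then orthogonalised (QR on the centered series) and scaled
    to geometrically decaying powers, so pairwise sample correlations are
    zero by construction and the mixed record has N well-separated
    signal-space eigenvalues.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k = config.n_samples
    if k < 2:
        raise ConfigError("duration too short for the sampling rate")
    t = np.arange(k) / config.sampling_rate

    raw = np.empty((config.n_sources, k))
    for i in range(config.n_sources):
        jitter = np.column_stack(
            [
                rng.normal(0.0, 0.015, len(_BEAT_WAVES)),  # center offsets (s)
                rng.uniform(-0.3, 0.3, len(_BEAT_WAVES)),  # relative widths
                rng.uniform(-0.4, 0.4, len(_BEAT_WAVES)),  # relative amplitudes
            ]
        )
        raw[i] = _beat_train(t, config.heart_rate, rng, jitter)
    raw -= raw.mean(axis=1, keepdims=True)
    # independence guard: beat trains are near-collinear across sources, so
    # nudge with a little zero-mean shape noise before orthogonalising
    raw += 1e-3 * rng.standard_normal(raw.shape)
    raw -= raw.mean(axis=1, keepdims=True)

    q, r = np.linalg.qr(raw.T)  # K x N, orthonormal zero-mean columns
    rms = np.sqrt(np.mean(raw[0] ** 2))
    powers = rms**2 * 0.4 ** np.arange(config.n_sources)
    sources = (q * np.sqrt(k * powers)).T
    return sources


def _random_mixing(n_sources: int, rng: np.random.Generator) -> np.ndarray:
    """Random attenuation matrix: |a| in [0.2, 1] with sign flips, well
    conditioned by rejection."""
    for _ in range(100):
        a = rng.uniform(0.2, 1.0, size=(8, n_sources))
        a *= rng.choice([-1.0, 1.0], size=a.shape)
        s = np.linalg.svd(a, compute_uv=False)
        if s[-1] > 0.15 * s[0]:
            return a
    raise ConfigError("could not draw a well-conditioned mixing matrix")


def _hann(n: int) -> np.ndarray:
    if n <= 1:
        return np.ones(max(n, 0))
    return 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / (n - 1))


def _additive_noise(
    event: NoiseEvent, t: np.ndarray, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Noise samples for one additive event, shape (len(leads), K)."""
    k = t.size
    out = np.zeros((len(event.leads), k))
    if event.kind == "white":
        out[:] = rng.normal(0.0, event.amplitude, size=out.shape)
    elif event.kind == "powerline":
        freq = event.frequency if event.frequency is not None else 50.0
        phase = rng.uniform(0, 2 * np.pi)  # common mains phase
        gains = rng.uniform(0.5, 1.0, size=len(event.leads))
        out[:] = gains[:, None] * event.amplitude * np.sin(
            2 * np.pi * freq * t + phase
        )
    elif event.kind == "baseline_wander":
        freq = event.frequency if event.frequency is not None else 0.3
        for j in range(len(event.leads)):
            phase = rng.uniform(0, 2 * np.pi)
            out[j] = event.amplitude * np.sin(2 * np.pi * freq * t + phase)
    elif event.kind == "transient_artifact":
        dur = event.duration if event.duration is not None else t[-1] - event.onset
        lo = int(round(event.onset * fs))
        hi = min(int(round((event.onset + dur) * fs)), k)
        if hi <= lo:
            return out
        win = _hann(hi - lo)
        freq = event.frequency if event.frequency is not None else 7.0
        for j in range(len(event.leads)):
            phase = rng.uniform(0, 2 * np.pi)
            burst = np.sin(2 * np.pi * freq * t[lo:hi] + phase)
            burst += 0.3 * rng.standard_normal(hi - lo)
            out[j, lo:hi] = event.amplitude * win * burst
    return out


class CohortItem(NamedTuple):
    record: EcgRecord
    label: QualityLabel
    report: dict


def mix_and_contaminate(config: SyntheticConfig) -> tuple[EcgRecord, dict]:
    """Generate one 8-lead record plus a ground-truth contamination report.

    Additive events (white, powerline, baseline wander, transient
    artifacts) are summed onto the mixed cardiac signal; ``flat_lead``
    events then overwrite their leads with a constant; ``clipping`` events
    finally saturate at the configured ceiling.  The report lists every
    injected event with its measured injected power (summed per-lead
    variance, ADC-count^2).
    """
    rng = np.random.default_rng(config.seed)
    sources = make_sources(config, rng)
    mixing = (
        np.asarray(config.mixing, dtype=float)
        if config.mixing is not None
        else _random_mixing(config.n_sources, rng)
    )
    clean = config.amplitude_scale * (mixing @ sources)
    t = np.arange(config.n_samples) / config.sampling_rate

    signals = clean.copy()
    events_report = []
    additive = [e for e in config.noise_events if e.kind not in ("flat_lead", "clipping")]
    flats = [e for e in config.noise_events if e.kind == "flat_lead"]
    clips = [e for e in config.noise_events if e.kind == "clipping"]

    for event in additive:
        noise = _additive_noise(event, t, config.sampling_rate, rng)
        rows = [l - 1 for l in event.leads]
        signals[rows] += noise
        events_report.append(
            {**_event_dict(event), "injected_power": float(noise.var(axis=1).sum())}
        )
    for event in flats:
        rows = [l - 1 for l in event.leads]
        signals[rows] = event.amplitude
        events_report.append({**_event_dict(event), "injected_power": 0.0})
    for event in clips:
        ceiling = event.amplitude if event.amplitude > 0 else ADC_CEILING
        rows = [l - 1 for l in event.leads]
        signals[rows] = np.clip(signals[rows], -ceiling, ceiling)
        events_report.append({**_event_dict(event), "injected_power": 0.0})

    record = EcgRecord(
        record_id=config.record_id,
        sampling_rate=config.sampling_rate,
        lead_names=list(ANALYSIS_LEADS),
        signals=signals,
    )
    centered = clean - clean.mean(axis=1, keepdims=True)
    report = {
        "record_id": config.record_id,
        "seed": config.seed,
        "n_sources": config.n_sources,
        "clean_power": float((centered**2).mean(axis=1).sum()),
        "events": events_report,
    }
    return record, report


def _event_dict(event: NoiseEvent) -> dict:
    return {
        "kind": event.kind,
        "leads": list(event.leads),
        "amplitude": event.amplitude,
        "frequency": event.frequency,
        "onset": event.onset,
        "duration": event.duration,
    }


# ---------------------------------------------------------------------------
# Labeled cohorts
# ---------------------------------------------------------------------------

def _clean_config(
    template: SyntheticConfig, rng: np.random.Generator, record_id: str
) -> SyntheticConfig:
    """An acceptable-quality draw: cardiac model plus a small white sensor
    noise floor emulating amplifier/quantisation noise."""
    sensor = NoiseEvent(kind="white", amplitude=float(rng.uniform(2.0, 6.0)))
    return replace(
        template,
        record_id=record_id,
        seed=int(rng.integers(2**31)),
        heart_rate=float(rng.uniform(55.0, 95.0)),
        amplitude_scale=template.amplitude_scale * 10 ** float(rng.uniform(-0.3, 0.3)),
        noise_events=(sensor,),
    )


def _contaminated_config(
    template: SyntheticConfig, rng: np.random.Generator, record_id: str
) -> SyntheticConfig:
    """An unacceptable-quality draw from a three-mode contamination mixture:
    a disconnected (flat) lead, high-power transient artifacts on two leads,
    or broadband noise swamping every lead."""
    base = _clean_config(template, rng, record_id)
    mode = rng.choice(["flat_lead", "artifact", "broadband"])
    events = list(base.noise_events)
    if mode == "flat_lead":
        lead = int(rng.integers(1, 9))
        events.append(
            NoiseEvent(
                kind="flat_lead", leads=(lead,),
                amplitude=float(rng.uniform(-100.0, 100.0)),
            )
        )
    elif mode == "artifact":
        # Two independent high-power artifacts (e.g. electrode motion),
        # each injecting >= 100x the cardiac power, plus broadband shake.
        probe = replace(base, noise_events=(), record_id="probe")
        _, rep = mix_and_contaminate(probe)
        target = 100.0 * rep["clean_power"] * float(rng.uniform(1.0, 3.0))
        leads = rng.choice(np.arange(1, 9), size=2, replace=False)
        for lead in leads:
            dur = float(rng.uniform(1.5, 3.5))
            onset = float(rng.uniform(0.0, template.duration - dur))
            # windowed sinusoid power ~= amp^2/2 * mean(win^2) over the record
            mean_win2 = 0.375 * dur / template.duration
            amp = float(np.sqrt(2.0 * target / mean_win2))
            events.append(
                NoiseEvent(
                    kind="transient_artifact", leads=(int(lead),),
                    amplitude=amp, onset=onset, duration=dur,
                    frequency=float(rng.uniform(4.0, 12.0)),
                )
            )
        events.append(NoiseEvent(kind="white", amplitude=float(rng.uniform(20.0, 60.0))))
    else:  # broadband
        events.append(
            NoiseEvent(kind="white", amplitude=float(rng.uniform(400.0, 700.0)))
        )
        events.append(
            NoiseEvent(
                kind="powerline", amplitude=float(rng.uniform(200.0, 800.0)),
                frequency=50.0,
            )
        )
        events.append(
            NoiseEvent(kind="baseline_wander", amplitude=float(rng.uniform(100.0, 400.0)))
        )
    return replace(base, noise_events=tuple(events))


def generate_cohort(
    n_records: int,
    ac_fraction: float = 0.5,
    template: SyntheticConfig | None = None,
    seed: int = 0,
) -> list[CohortItem]:
    """Generate a labeled cohort of synthetic records.

    Acceptable records are clean-model draws with a sensor-noise floor;
    unacceptable records carry at least one contamination event from the
    documented mixture.  Fully deterministic given ``seed``.
    """
    if n_records < 1:
        raise ConfigError("n_records must be >= 1")
    if not 0.0 <= ac_fraction <= 1.0:
        raise ConfigError("ac_fraction must be in [0, 1]")
    template = template or SyntheticConfig()
    rng = np.random.default_rng(seed)
    n_ac = int(round(ac_fraction * n_records))
    labels = [QualityLabel.AC] * n_ac + [QualityLabel.UN] * (n_records - n_ac)
    rng.shuffle(labels)

    items = []
    for i, label in enumerate(labels):
        record_id = f"syn{i:04d}"
        if label == QualityLabel.AC:
            cfg = _clean_config(template, rng, record_id)
        else:
            cfg = _contaminated_config(template, rng, record_id)
        record, report = mix_and_contaminate(cfg)
        report["label"] = label.value
        items.append(CohortItem(record=record, label=label, report=report))
    return items
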