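"""Synthetic ABP generator with ground-truth beats for every rhythm class.

Rhythm definitions (instantaneous beat rate, bpm):

========  ==========================================================
healthy   stationary rate around a resting baseline
EB        extreme bradycardia — rate < 40 bpm for >= 5 consecutive beats
ET        extreme tachycardia — rate > 140 bpm for >= 17 beats
VT        ventricular tachycardia — >= 5 beats at rate > 100 bpm with
          reduced pulse amplitude
VF        ventricular flutter — rapid oscillation lasting >= 4 s
========  ==========================================================

A record is a background rhythm (AR(1)-modulated beat rate) with one
embedded episode meeting its class minimum.  Beats are rendered as a
two-Gaussian pulse (systolic peak plus a dicrotic bump); VF episodes are
rendered as a low-amplitude sinusoidal oscillation replacing the pulses.
Three noise classes can be superimposed: mains-frequency AC interference,
slow sinusoidal baseline drift and band-limited EMG-like noise.  Every
record carries its true peak positions, so the whole upstream pipeline
can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .types import ABPRecord

__all__ = [
    "RHYTHM_LABELS",
    "LABEL_NAMES",
    "RhythmSpec",
    "NoiseSpec",
    "gen_ppi",
    "render_abp",
    "add_noise",
    "make_record",
    "make_dataset",
    "satisfies_definition",
]

#: Fixed class-label mapping used throughout.
RHYTHM_LABELS = {"healthy": 1, "EB": 2, "ET": 3, "VT": 4, "VF": 5}
LABEL_NAMES = {v: k for k, v in RHYTHM_LABELS.items()}


@dataclass(frozen=True)
class RhythmSpec:
    """Generator parameters of one rhythm class.

    Rates are in bpm, amplitudes in the record's pressure units (the
    normal pulse amplitude is the unit).  ``episode_rate_bpm`` and the
    episode size are pre-set per class so that the generated episode
    meets its defining minimum with margin; ``variability_bpm`` is the
    stationary standard deviation of the AR(1) beat-rate modulation.
    """

    kind: str
    base_rate_bpm: float = 70.0
    variability_bpm: float = 3.0
    episode_rate_bpm: float | None = None
    episode_beats: int | None = None
    episode_seconds: float | None = None
    amplitude_mean: float = 1.0
    amplitude_jitter: float = 0.05
    ar_coeff: float = 0.8
    vt_amplitude_frac: float = 0.5
    vf_freq_hz: float = 4.5
    vf_amplitude_frac: float = 0.3
    lead_beats: int = 6

    @staticmethod
    def for_kind(kind: str, **overrides) -> "RhythmSpec":
        """Per-class defaults: episode rates/sizes meeting each definition."""
        defaults = {
            "healthy": {},
            "EB": {"episode_rate_bpm": 33.0, "episode_beats": 8},
            "ET": {"episode_rate_bpm": 160.0, "episode_beats": 18},
            "VT": {"episode_rate_bpm": 130.0, "episode_beats": 10},
            "VF": {"episode_seconds": 5.0},
        }
        if kind not in defaults:
            raise ValueError(f"unknown rhythm kind {kind!r}")
        kw = dict(defaults[kind])
        kw.update(overrides)
        return RhythmSpec(kind=kind, **kw)

    @property
    def label(self) -> int:
        return RHYTHM_LABELS[self.kind]


@dataclass(frozen=True)
class NoiseSpec:
    """Amplitudes of the three noise classes (pressure units).

    ``ac_amplitude`` at the mains frequency, ``drift_amplitude`` per slow
    sinusoid (frequencies well below the pulse band, where the 0 Hz notch
    tooth still attenuates strongly), and ``emg_amplitude`` as the
    standard deviation of band-limited noise above ``emg_low_hz``.
    """

    ac_amplitude: float = 0.2
    ac_freq: float = 50.0
    drift_amplitude: float = 0.3
    drift_freqs: tuple[float, ...] = (0.05, 0.1)
    emg_amplitude: float = 0.1
    emg_low_hz: float = 70.0

    def __post_init__(self) -> None:
        for a in (self.ac_amplitude, self.drift_amplitude, self.emg_amplitude):
            if a < 0:
                raise ValueError("noise amplitudes must be non-negative")


# Table-defined minima: (threshold bpm, direction, minimum consecutive beats)
_EPISODE_RULES = {
    "EB": (40.0, "below", 5),
    "ET": (140.0, "above", 17),
    "VT": (100.0, "above", 5),
}


def satisfies_definition(kind: str, ppi_ms: np.ndarray, episode: tuple[int, int] | None) -> bool:
    """Check a PPI sequence symbolically against its rhythm definition.

    ``episode`` is the (start, stop) interval-index range of the embedded
    episode.  For VF the rule is duration (>= 4 s of oscillation); for the
    rate-defined classes the episode rates must all clear the bpm
    threshold over at least the required run length.
    """
    ppi_ms = np.asarray(ppi_ms, dtype=float)
    if kind == "healthy":
        return episode is None
    if episode is None:
        return False
    lo, hi = episode
    ep = ppi_ms[lo:hi]
    if kind == "VF":
        return float(ep.sum()) >= 4000.0
    thr, direction, min_beats = _EPISODE_RULES[kind]
    rates = 60000.0 / ep
    if ep.size < min_beats:
        return False
    return bool(np.all(rates < thr) if direction == "below" else np.all(rates > thr))


def gen_ppi(
    spec: RhythmSpec,
    n_beats: int,
    seed: int | np.random.Generator = 0,
    fs: float | None = 250.0,
) -> tuple[np.ndarray, np.ndarray, tuple[int, int] | None]:
    """Generate a per-beat interval and amplitude sequence with one episode.

    Returns ``(ppi_ms, amplitudes, episode)`` where ``ppi_ms`` has length
    ``n_beats - 1`` (intervals between ``n_beats`` peaks), ``amplitudes``
    has length ``n_beats``, and ``episode`` is the (start, stop)
    interval-index range of the embedded episode (``None`` for healthy).
    The episode always meets its class minimum by construction.

    With ``fs`` given (the default), beat times are quantised to the
    sampling grid — the resolution at which any detector can observe them
    — so the returned intervals are exactly renderable; pass ``fs=None``
    for continuous-time intervals.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_iv = n_beats - 1
    if n_iv < 1:
        raise ValueError("need at least two beats")

    # class-specific episode intervals
    if spec.kind == "healthy":
        ep_ppi = np.empty(0)
        ep_len = 0
    elif spec.kind == "VF":
        seconds = spec.episode_seconds or 5.0
        if seconds < 4.0:
            raise ValueError("a VF episode must last at least 4 s")
        period_ms = 1000.0 / spec.vf_freq_hz
        ep_len = int(np.ceil(seconds * 1000.0 / period_ms))
        ep_ppi = np.full(ep_len, period_ms)
    else:
        thr, direction, min_beats = _EPISODE_RULES[spec.kind]
        ep_len = spec.episode_beats or min_beats
        if ep_len < min_beats:
            raise ValueError(
                f"{spec.kind} episodes need at least {min_beats} beats, got {ep_len}"
            )
        rates = spec.episode_rate_bpm + 0.02 * spec.episode_rate_bpm * rng.standard_normal(ep_len)
        margin = 0.03 * thr
        rates = np.minimum(rates, thr - margin) if direction == "below" else np.maximum(rates, thr + margin)
        ep_ppi = 60000.0 / rates

    lead = min(spec.lead_beats, n_iv - ep_len) if ep_len else 0
    if ep_len and n_iv < ep_len + 2:
        raise ValueError(
            f"{n_beats} beats cannot host a {ep_len}-interval {spec.kind} episode"
        )
    n_bg = n_iv - ep_len

    # AR(1)-modulated background rate, clipped away from the class thresholds
    e = np.zeros(n_bg)
    innov = rng.standard_normal(n_bg) * spec.variability_bpm * np.sqrt(
        max(1.0 - spec.ar_coeff**2, 1e-12)
    )
    for i in range(1, n_bg):
        e[i] = spec.ar_coeff * e[i - 1] + innov[i]
    bg_rates = np.clip(spec.base_rate_bpm + e, 45.0, 95.0)
    bg_ppi = 60000.0 / bg_rates

    if ep_len:
        ppi = np.concatenate([bg_ppi[:lead], ep_ppi, bg_ppi[lead:]])
        episode = (lead, lead + ep_len)
    else:
        ppi = bg_ppi
        episode = None

    if fs is not None:
        # quantise beat times to the sampling grid; the class margins are
        # wide enough that a half-sample shift never crosses a threshold
        times = np.concatenate([[0.0], np.cumsum(ppi)])
        ppi = np.diff(np.round(times * fs / 1000.0)) * 1000.0 / fs

    amps = spec.amplitude_mean * (
        1.0 + spec.amplitude_jitter * rng.standard_normal(n_beats)
    )
    amps = np.clip(amps, 0.3 * spec.amplitude_mean, None)
    if episode is not None and spec.kind in ("VT", "VF"):
        frac = spec.vt_amplitude_frac if spec.kind == "VT" else spec.vf_amplitude_frac
        # beats lo..hi bound the episode intervals
        amps[episode[0] : episode[1] + 1] *= frac
    return ppi, amps, episode


def render_abp(
    ppis: np.ndarray,
    amplitudes: np.ndarray,
    fs: float,
    episode: tuple[int, int] | None = None,
    oscillatory: bool = False,
    vf_freq_hz: float = 4.5,
    lead_in_s: float = 2.0,
    tail_s: float = 2.0,
    dc_offset: float = 80.0,
    sys_width_s: float = 0.05,
    dicrotic_width_s: float = 0.12,
    dicrotic_frac: float = 0.4,
    dicrotic_offset_frac: float = 0.3,
    dicrotic_offset_max_s: float = 0.3,
    meta: dict | None = None,
) -> ABPRecord:
    """Render beats as two-Gaussian pulse waves and annotate true peaks.

    Each beat contributes a systolic Gaussian of width ``sys_width_s``
    scaled by its amplitude plus a dicrotic bump at ``dicrotic_frac`` of
    that amplitude, offset by ``dicrotic_offset_frac`` of the local
    interval (capped at ``dicrotic_offset_max_s`` — the dicrotic wave does
    not drift arbitrarily late in slow rhythms).  When ``oscillatory`` and
    an episode range are given, that span is rendered as a raised-cosine
    oscillation at ``vf_freq_hz`` instead of discrete pulses.  Annotations
    are refined to the exact sample of each rendered local maximum.
    """
    ppis = np.asarray(ppis, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    n_beats = amplitudes.size
    if ppis.size != n_beats - 1:
        raise ValueError("need exactly one interval between consecutive beats")
    peak_times = lead_in_s + np.concatenate([[0.0], np.cumsum(ppis)]) / 1000.0
    total = peak_times[-1] + tail_s
    n = int(round(total * fs))
    t = np.arange(n) / fs
    x = np.full(n, float(dc_offset))

    ep_beats = set()
    if oscillatory and episode is not None:
        ep_beats = set(range(episode[0], episode[1] + 1))

    for k in range(n_beats):
        if k in ep_beats and k != max(ep_beats):
            continue  # covered by the oscillation below (last beat bridges out)
        tk = peak_times[k]
        local_ppi = (ppis[k] if k < n_beats - 1 else ppis[-1]) / 1000.0
        off = min(dicrotic_offset_frac * local_ppi, dicrotic_offset_max_s)
        lo = max(0, int((tk - 4 * sys_width_s) * fs))
        hi = min(n, int((tk + off + 4 * dicrotic_width_s) * fs) + 1)
        tt = t[lo:hi]
        x[lo:hi] += amplitudes[k] * (
            np.exp(-0.5 * ((tt - tk) / sys_width_s) ** 2)
            + dicrotic_frac * np.exp(-0.5 * ((tt - tk - off) / dicrotic_width_s) ** 2)
        )

    if ep_beats:
        # raised-cosine oscillation phase-locked to the beat times (one
        # crest per episode beat); it fades out at a trough half a cycle
        # before the bridge beat, so the exit pulse does not ride a crest
        k0, k1 = min(ep_beats), max(ep_beats)
        t0, t1 = peak_times[k0], peak_times[k1]
        half = 0.5 / vf_freq_hz
        m = (t >= t0 - half) & (t <= t1 - half)
        knots = np.concatenate([[t0 - half], peak_times[k0 : k1 + 1]])
        cycles = np.concatenate([[-0.5], np.arange(k1 - k0 + 1, dtype=float)])
        phase = np.interp(t[m], knots, cycles)
        amp = float(np.mean(amplitudes[k0 : k1 + 1]))
        x[m] += amp * 0.5 * (1.0 + np.cos(2.0 * np.pi * phase))

    # annotations: snap nominal peak times to the rendered local maxima
    ann = np.round(peak_times * fs).astype(np.int64)
    w = max(1, int(0.02 * fs))
    for k in range(n_beats):
        lo = max(0, ann[k] - w)
        ann[k] = lo + int(np.argmax(x[lo : min(n, ann[k] + w + 1)]))

    info = {"ppi_ms": ppis.copy(), "amplitudes": amplitudes.copy(), "episode": episode}
    if meta:
        info.update(meta)
    return ABPRecord(samples=x, fs=fs, annotations=ann, meta=info)


def add_noise(record: ABPRecord, spec: NoiseSpec, seed: int | np.random.Generator = 0) -> ABPRecord:
    """Superimpose AC interference, baseline drift and EMG-like noise.

    Ground-truth annotations and metadata are preserved; with all
    amplitudes zero the record is returned unchanged (same samples).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = record.samples.copy()
    t = record.times
    if spec.ac_amplitude > 0:
        x += spec.ac_amplitude * np.sin(
            2.0 * np.pi * spec.ac_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if spec.drift_amplitude > 0:
        for f in spec.drift_freqs:
            x += spec.drift_amplitude * np.sin(
                2.0 * np.pi * f * t + rng.uniform(0, 2 * np.pi)
            )
    if spec.emg_amplitude > 0 and x.size > 30:
        white = rng.standard_normal(x.size)
        b, a = butter(4, spec.emg_low_hz / (record.fs / 2.0), btype="high")
        emg = filtfilt(b, a, white)
        sd = emg.std()
        if sd > 0:
            x += spec.emg_amplitude * emg / sd
    return ABPRecord(
        samples=x,
        fs=record.fs,
        annotations=record.annotations,
        transient_samples=record.transient_samples,
        meta=dict(record.meta),
    )


#: Default beat counts per record; sized so that 16-beat windows nearly all
#: overlap the embedded episode.
_DEFAULT_BEATS = {"healthy": 26, "EB": 26, "ET": 30, "VT": 26, "VF": 36}


def make_record(
    kind: str,
    fs: float = 250.0,
    n_beats: int | None = None,
    noise: NoiseSpec | None = None,
    seed: int | np.random.Generator = 0,
    record_id: str = "",
    **spec_overrides,
) -> ABPRecord:
    """Generate one labelled, annotated, optionally noisy ABP record."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = RhythmSpec.for_kind(kind, **spec_overrides)
    n_beats = n_beats or _DEFAULT_BEATS[kind]
    ppis, amps, episode = gen_ppi(spec, n_beats, rng, fs=fs)
    rec = render_abp(
        ppis,
        amps,
        fs,
        episode=episode,
        oscillatory=(kind == "VF"),
        vf_freq_hz=spec.vf_freq_hz,
        meta={"kind": kind, "label": spec.label, "record_id": record_id},
    )
    if noise is not None:
        rec = add_noise(rec, noise, rng)
    return rec


@dataclass
class SyntheticDataset:
    """Labelled segments plus their feature matrix and source records."""

    records: list
    segments: list
    features: pd.DataFrame


def make_dataset(
    n_segments_per_class: int = 100,
    kinds: tuple[str, ...] = ("healthy", "EB", "ET", "VT", "VF"),
    fs: float = 250.0,
    noise: NoiseSpec | None = None,
    window_beats: int = 16,
    step_beats: int = 1,
    seed: int = 0,
    use_annotations: bool = False,
) -> SyntheticDataset:
    """Run the full generator -> preprocess -> detect -> feature pipeline.

    Records of each class are generated (with default per-class noise
    when ``noise`` is None) until the requested number of labelled
    segments is reached; extras are truncated, so each class contributes
    exactly ``n_segments_per_class`` rows.  Deterministic under ``seed``.
    """
    from .pipeline import records_to_features  # deferred to avoid a cycle

    if noise is None:
        noise = NoiseSpec()
    records = []
    for kind in kinds:
        ss = np.random.SeedSequence((seed, RHYTHM_LABELS[kind]))
        # overshoot the nominal per-record yield by ~15% so that occasional
        # detection shortfalls cannot leave a class under-filled
        have = 0.0
        i = 0
        per_record = None
        while have < n_segments_per_class:
            rng = np.random.default_rng(ss.spawn(1)[0])
            rec = make_record(
                kind, fs=fs, noise=noise, seed=rng, record_id=f"{kind}-{i:03d}"
            )
            records.append(rec)
            if per_record is None:
                n_iv = rec.annotations.size - 1
                per_record = max(1, (n_iv - window_beats) // step_beats + 1)
            have += 0.85 * per_record
            i += 1
    segments, features = records_to_features(
        records,
        window_beats=window_beats,
        step_beats=step_beats,
        use_annotations=use_annotations,
    )
    # truncate each class to the requested count
    keep_rows = []
    for kind in kinds:
        label = RHYTHM_LABELS[kind]
        rows = features.index[features["label"] == label][:n_segments_per_class]
        if len(rows) < n_segments_per_class:
            raise RuntimeError(
                f"only {len(rows)} {kind} segments extracted of "
                f"{n_segments_per_class} requested; beat detection lost "
                "more records than the generation margin allows"
            )
        keep_rows.extend(rows)
    features = features.loc[keep_rows].reset_index(drop=True)
    segments = [segments[i] for i in keep_rows]
    return SyntheticDataset(records=records, segments=segments, features=features)
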