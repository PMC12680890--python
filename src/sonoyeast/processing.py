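"""Preprocessing and echo feature extraction for pulse-echo A-scans.

The measurement chain records one-dimensional amplitude-vs-time signals
(A-scans) from a buffer-rod pulse-echo cell.  Three echoes are expected in
fixed time windows: E1 from the buffer-rod/sample interface, E2 from the
sample/reflector interface (path 2d through the suspension), and E3 after an
additional traversal cycle (path 4d).  Processing follows the acquisition
protocol:

1. zero-phase Butterworth bandpass around the 2 MHz transducer resonance,
2. block averaging of every five consecutive signals,
3. moving-window-maximum envelope of the averaged signal,
4. per-echo features: envelope peak amplitude ``A_max``, peak time ``t_max``
   and rectified signal sum ``A_sum``, giving nine features per averaged
   signal.

All window boundaries are specified in nanoseconds and converted to sample
indices at the signal's own sampling rate, so the same configuration applies
at the 1 GHz acquisition rate and at reduced rates used for simulation work.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "AScan",
    "EchoWindow",
    "Envelope",
    "EchoFeatureSet",
    "PipelineConfig",
    "DEFAULT_ECHO_WINDOWS",
    "FEATURE_NAMES",
    "bandpass_zero_phase",
    "block_average",
    "envelope",
    "extract_echo_features",
    "feature_vector",
]

NS_PER_S = 1e9


@dataclass
class AScan:
    """One recorded or simulated waveform with provenance metadata.

    ``raw`` holds the as-acquired samples x0(t); ``filtered`` is populated by
    :func:`bandpass_zero_phase` (and carried through block averaging).  The
    "active" signal used downstream is the filtered one when present.
    """

    raw: np.ndarray
    sampling_rate: float  # Hz
    filtered: np.ndarray | None = None
    t0_offset_ns: float = 0.0
    measurement_id: str = ""
    signal_index: int = 0
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 1:
            raise ValueError("AScan.raw must be one-dimensional")
        if not np.all(np.isfinite(self.raw)):
            raise ValueError("AScan.raw contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def signal(self) -> np.ndarray:
        """Filtered samples when available, raw otherwise."""
        return self.raw if self.filtered is None else self.filtered

    @property
    def n_samples(self) -> int:
        return self.raw.shape[0]

    def times_ns(self) -> np.ndarray:
        """Sample times in nanoseconds."""
        return self.t0_offset_ns + np.arange(self.n_samples) * (NS_PER_S / self.sampling_rate)


@dataclass(frozen=True)
class EchoWindow:
    """Fixed gating interval [a, b] (ns, inclusive) for echo ``index``."""

    index: int
    a_ns: float
    b_ns: float

    def __post_init__(self) -> None:
        if self.index not in (1, 2, 3):
            raise ValueError("echo index must be 1, 2 or 3")
        if not self.a_ns < self.b_ns:
            raise ValueError("echo window requires a < b")

    def to_indices(self, sampling_rate: float, t0_offset_ns: float = 0.0) -> tuple[int, int]:
        """Inclusive (start, stop) sample indices at the given rate."""
        a = int(round((self.a_ns - t0_offset_ns) * sampling_rate / NS_PER_S))
        b = int(round((self.b_ns - t0_offset_ns) * sampling_rate / NS_PER_S))
        return a, b


DEFAULT_ECHO_WINDOWS: tuple[EchoWindow, ...] = (
    EchoWindow(1, 10_000.0, 15_000.0),
    EchoWindow(2, 60_000.0, 65_000.0),
    EchoWindow(3, 72_000.0, 77_000.0),
)


@dataclass
class Envelope:
    """Moving-window-maximum envelope e(t) of |x(t)|."""

    values: np.ndarray
    window_ns: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class EchoFeatureSet:
    """The nine echo-derived features of one averaged signal.

    Flattening order is fixed: (A_max_1, t_max_1, A_sum_1, ..., A_sum_3).
    ``A_max`` is in envelope amplitude units, ``t_max`` in ns, ``A_sum`` in
    amplitude units summed over window samples.
    """

    A_max_1: float
    t_max_1: float
    A_sum_1: float
    A_max_2: float
    t_max_2: float
    A_sum_2: float
    A_max_3: float
    t_max_3: float
    A_sum_3: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in dataclasses.fields(EchoFeatureSet))


@dataclass
class PipelineConfig:
    """Parameters of the preprocessing/feature-extraction chain."""

    passband_hz: tuple[float, float] = (1.5e6, 2.5e6)
    filter_order: int = 8  # effective magnitude order after forward-backward pass
    average_block: int = 5
    envelope_window_ns: float = 1000.0
    echo_windows: tuple[EchoWindow, ...] = field(default=DEFAULT_ECHO_WINDOWS)

    def __post_init__(self) -> None:
        lo, hi = self.passband_hz
        if not 0 < lo < hi:
            raise ValueError("passband must satisfy 0 < low < high")
        if self.filter_order < 2 or self.filter_order % 2:
            raise ValueError("filter_order must be an even integer >= 2")
        if self.average_block < 1:
            raise ValueError("average_block must be >= 1")
        if self.envelope_window_ns <= 0:
            raise ValueError("envelope_window_ns must be positive")

    def design_sos(self, sampling_rate: float) -> np.ndarray:
        """Second-order sections of the single-pass (half-order) bandpass.

        The stated eighth-order zero-phase response is realized as a
        fourth-order Butterworth applied forward and backward, which squares
        the magnitude response (effective order 8) and cancels the phase.
        """
        lo, hi = self.passband_hz
        if hi >= sampling_rate / 2:
            raise ValueError(
                f"passband high edge {hi:g} Hz is not below Nyquist for rate {sampling_rate:g} Hz"
            )
        return butter(self.filter_order // 2, [lo, hi], btype="bandpass", fs=sampling_rate, output="sos")


def bandpass_zero_phase(scan: AScan, cfg: PipelineConfig | None = None) -> AScan:
    """Apply the zero-phase bandpass, returning a copy with ``filtered`` set.

    Forward-backward filtering preserves the temporal structure of the
    echoes (no group delay) while doubling the stopband attenuation of the
    underlying design; the DC component falls inside the stopband.
    """
    cfg = cfg or PipelineConfig()
    sos = cfg.design_sos(scan.sampling_rate)
    filtered = sosfiltfilt(sos, scan.raw)
    return dataclasses.replace(scan, filtered=np.asarray(filtered))


def block_average(signals: Sequence[AScan], block: int | None = None, cfg: PipelineConfig | None = None) -> list[AScan]:
    """Average every ``block`` consecutive signals sample-wise.

    Raw and (when present on all inputs) filtered arrays are both averaged;
    averaging is linear, so filtering and averaging commute per block.  The
    input length must be an exact multiple of ``block``; partial blocks are
    an error rather than silently dropped.
    """
    if block is None:
        block = (cfg or PipelineConfig()).average_block
    if block < 1:
        raise ValueError("block must be >= 1")
    n = len(signals)
    if n == 0:
        return []
    if n % block:
        raise ValueError(f"{n} signals cannot be grouped into blocks of {block}")
    lengths = {s.n_samples for s in signals}
    rates = {s.sampling_rate for s in signals}
    if len(lengths) != 1 or len(rates) != 1:
        raise ValueError("all signals must share length and sampling rate")
    have_filtered = all(s.filtered is not None for s in signals)
    out: list[AScan] = []
    for b in range(n // block):
        chunk = signals[b * block : (b + 1) * block]
        raw = np.mean([s.raw for s in chunk], axis=0)
        filt = np.mean([s.filtered for s in chunk], axis=0) if have_filtered else None
        first = chunk[0]
        out.append(
            AScan(
                raw=raw,
                sampling_rate=first.sampling_rate,
                filtered=filt,
                t0_offset_ns=first.t0_offset_ns,
                measurement_id=first.measurement_id,
                signal_index=b,
                timestamp_s=first.timestamp_s,
            )
        )
    return out


def envelope(scan: AScan | np.ndarray, cfg: PipelineConfig | None = None, sampling_rate: float | None = None) -> Envelope:
    """Moving-window maximum of the rectified signal.

    The window is specified in time units and converted to samples at the
    signal's rate (1000 ns is 1000 samples at 1 GHz).  The window is centered
    with half-width ``floor(W/2)`` and truncates at the record edges, so the
    envelope dominates |x| at every sample by construction.
    """
    cfg = cfg or PipelineConfig()
    if isinstance(scan, AScan):
        x = scan.signal
        rate = scan.sampling_rate
    else:
        x = np.asarray(scan, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required when passing a bare array")
        rate = sampling_rate
    w_samples = int(round(cfg.envelope_window_ns * rate / NS_PER_S))
    if w_samples < 1:
        raise ValueError("envelope window shorter than one sample at this rate")
    half = w_samples // 2
    # |x| >= 0, so constant zero padding reproduces the truncated-window max.
    values = maximum_filter1d(np.abs(x), size=2 * half + 1, mode="constant", cval=0.0)
    return Envelope(values=values, window_ns=cfg.envelope_window_ns)


def extract_echo_features(scan: AScan, env: Envelope, window: EchoWindow) -> tuple[float, float, float]:
    """(A_max, t_max, A_sum) of one echo window.

    A_max and t_max come from the envelope (argmax ties resolved to the
    earliest sample); A_sum is the rectified sum of the signal itself over the
    inclusive window, not of the envelope.
    """
    a, b = window.to_indices(scan.sampling_rate, scan.t0_offset_ns)
    if a < 0 or b >= scan.n_samples:
        raise ValueError(
            f"echo window [{window.a_ns:g}, {window.b_ns:g}] ns falls outside the recorded signal"
        )
    seg_env = env.values[a : b + 1]
    k = int(np.argmax(seg_env))  # earliest index on exact ties
    a_max = float(seg_env[k])
    t_max = scan.t0_offset_ns + (a + k) * NS_PER_S / scan.sampling_rate
    a_sum = float(np.sum(np.abs(scan.signal[a : b + 1])))
    return a_max, t_max, a_sum


def feature_vector(signals: Sequence[AScan], cfg: PipelineConfig | None = None) -> list[EchoFeatureSet]:
    """Full chain for one measurement: filter, block-average, gate, extract.

    A default 50-signal measurement yields 10 averaged signals and hence 10
    nine-feature sets.
    """
    cfg = cfg or PipelineConfig()
    filtered = [bandpass_zero_phase(s, cfg) for s in signals]
    averaged = block_average(filtered, cfg.average_block)
    out: list[EchoFeatureSet] = []
    for scan in averaged:
        env = envelope(scan, cfg)
        vals: list[float] = []
        for w in sorted(cfg.echo_windows, key=lambda w: w.index):
            vals.extend(extract_echo_features(scan, env, w))
        out.append(EchoFeatureSet(*vals))
    return out
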