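"""Parametric pulse-echo simulator for yeast suspensions in wort.

The generative model mirrors a buffer-rod pulse-echo cell: a 2 MHz toneburst
excites the sample, and three echoes return — E1 from the buffer-rod/sample
interface, E2 after a 2d round trip through the suspension, and E3 after an
additional reverberation cycle (4d attenuation path).  Each echo is a
Gaussian-windowed sinusoid

    x0(t) = sum_i A_i * exp(-(t - t_i)^2 / (2 sigma^2)) * sin(2 pi f0 (t - t_i)) + noise

with amplitudes and arrival times driven by suspension physics:

* sound velocity ``c`` rises with dissolved extract (wort) and with yeast
  load, shifting E2 earlier;
* attenuation ``alpha`` rises with wort and, strain-dependently, with yeast
  concentration, shrinking A2 (2d path) and A3 (4d path) exponentially;
* E1 never enters the sample, so its amplitude is concentration-independent.

The experimental design is a full factorial: 3 strains x 3 wort extract
levels (10/12/14 wt%) x 6 yeast levels (0.0-1.0 wt% in 0.2 steps) x
replicates, with 50 signals per measurement acquired at 0.5 s intervals.
Hemocytometer counting is emulated as a linear strain-specific count per
weight fraction plus multiplicative error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Sequence

import numpy as np

from .processing import DEFAULT_ECHO_WINDOWS, NS_PER_S, AScan, EchoWindow

__all__ = [
    "Strain",
    "VesselGeometry",
    "SampleRecord",
    "AcousticParams",
    "SimConfig",
    "SimulationConfigError",
    "make_gradient_design",
    "cell_count_from_fraction",
    "echo_parameters",
    "synth_ascan",
    "simulate_measurement",
    "iter_design_measurements",
    "WORT_LEVELS",
    "YEAST_LEVELS",
]

WORT_LEVELS: tuple[float, ...] = (10.0, 12.0, 14.0)
YEAST_LEVELS: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


class Strain(str, Enum):
    """The three Saccharomyces strains of the factorial design.

    Enum order fixes the class index used by one-hot encoding and the
    classifier output layer.
    """

    S_CEREVISIAE = "S_CEREVISIAE"  # top-fermenting baker's/ale strain
    WB06 = "WB06"  # S. cerevisiae var. diastaticus (wheat beer)
    W3470 = "W3470"  # S. pastorianus lager strain

    @classmethod
    def coerce(cls, value: "Strain | str") -> "Strain":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError as exc:
            raise ValueError(f"unknown strain {value!r}; expected one of {[s.value for s in cls]}") from exc


class SimulationConfigError(ValueError):
    """Raised when supplied parameters place an echo outside its gate."""


@dataclass(frozen=True)
class VesselGeometry:
    """Sample-cell geometry: vessel diameter d and buffer-rod diameter d_b (mm)."""

    sample_diameter_mm: float = 37.5
    buffer_rod_diameter_mm: float = 17.0

    def __post_init__(self) -> None:
        if self.sample_diameter_mm <= 0 or self.buffer_rod_diameter_mm <= 0:
            raise ValueError("geometry diameters must be strictly positive")

    @property
    def sample_diameter_m(self) -> float:
        return self.sample_diameter_mm * 1e-3


@dataclass(frozen=True)
class SampleRecord:
    """One physical suspension in the gradient design."""

    strain: Strain
    wort_wt_pct: float
    yeast_wt_pct: float
    replicate: int
    true_cell_count: float = float("nan")  # cells/mL
    measured_cell_count: float = float("nan")  # hemocytometer surrogate, cells/mL

    def __post_init__(self) -> None:
        object.__setattr__(self, "strain", Strain.coerce(self.strain))
        if self.yeast_wt_pct < 0 or self.yeast_wt_pct > 1:
            raise ValueError("yeast_wt_pct must lie in [0, 1]")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    @property
    def measurement_id(self) -> str:
        return (
            f"{self.strain.value}_w{self.wort_wt_pct:g}_y{self.yeast_wt_pct:.1f}_r{self.replicate}"
        )


def _per_strain(values: Mapping[Strain, float]) -> dict[Strain, float]:
    return {Strain.coerce(k): float(v) for k, v in values.items()}


@dataclass
class AcousticParams:
    """Physical and label-model parameters of the simulator.

    Defaults are chosen so that, across the full design, every echo peak
    stays inside its gating window and the three strains are separable
    through their attenuation slope, velocity slope and interface gain.
    Count slopes place the 1.0 wt% level at each strain's maximum observed
    concentration (cells/mL).
    """

    excitation_amplitude: float = 1.0  # A0, arbitrary units
    echo1_gain: float = 0.6  # r1: buffer-rod interface reflection
    echo2_gain: dict[Strain, float] = field(
        default_factory=lambda: {Strain.S_CEREVISIAE: 0.50, Strain.WB06: 0.55, Strain.W3470: 0.45}
    )
    echo3_gain: float = 0.25
    base_attenuation: dict[float, float] = field(  # alpha0 per wort wt%, Np/m
        default_factory=lambda: {10.0: 4.0, 12.0: 5.0, 14.0: 6.0}
    )
    attenuation_slope: dict[Strain, float] = field(  # k_alpha, Np/m per yeast wt%
        default_factory=lambda: {Strain.S_CEREVISIAE: 18.0, Strain.WB06: 24.0, Strain.W3470: 12.0}
    )
    base_velocity: float = 1482.0  # m/s, water-like medium at 20 C
    velocity_wort_slope: float = 4.0  # m/s per wt% extract above 12
    velocity_yeast_slope: dict[Strain, float] = field(  # m/s per yeast wt%
        default_factory=lambda: {Strain.S_CEREVISIAE: 8.0, Strain.WB06: 12.0, Strain.W3470: 5.0}
    )
    echo1_time_ns: float = 12_500.0
    echo3_reverb_delay_ns: float = 12_000.0
    toneburst_frequency_hz: float = 2e6
    toneburst_sigma_ns: float = 500.0
    noise_std: float = 1e-3
    count_slope: dict[Strain, float] = field(  # cells/mL per yeast wt%
        default_factory=lambda: {Strain.S_CEREVISIAE: 245e6, Strain.WB06: 315e6, Strain.W3470: 165e6}
    )
    count_cv: float = 0.05

    def __post_init__(self) -> None:
        self.echo2_gain = _per_strain(self.echo2_gain)
        self.attenuation_slope = _per_strain(self.attenuation_slope)
        self.velocity_yeast_slope = _per_strain(self.velocity_yeast_slope)
        self.count_slope = _per_strain(self.count_slope)
        self.base_attenuation = {float(k): float(v) for k, v in self.base_attenuation.items()}
        gains = [self.echo1_gain, self.echo3_gain, *self.echo2_gain.values()]
        if any(not 0 < g <= 1 for g in gains):
            raise ValueError("echo gains must lie in (0, 1]")
        if any(v < 0 for v in self.base_attenuation.values()) or any(
            v < 0 for v in self.attenuation_slope.values()
        ):
            raise ValueError("attenuation parameters must be >= 0")
        if self.noise_std < 0 or self.count_cv < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class SimConfig:
    """Acquisition schedule and discretization."""

    sampling_rate: float = 1e9  # Hz; reduced rates are accepted for simulation studies
    record_length_ns: float = 80_000.0
    signals_per_measurement: int = 50
    signal_interval_s: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.record_length_ns < DEFAULT_ECHO_WINDOWS[-1].b_ns:
            raise ValueError(
                f"record_length_ns must cover the last echo window "
                f"(>= {DEFAULT_ECHO_WINDOWS[-1].b_ns:g} ns)"
            )
        if self.signals_per_measurement < 1:
            raise ValueError("signals_per_measurement must be >= 1")
        if self.signal_interval_s < 0:
            raise ValueError("signal_interval_s must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.record_length_ns * self.sampling_rate / NS_PER_S))

    def validate_against(self, params: AcousticParams) -> None:
        if self.sampling_rate < 10 * params.toneburst_frequency_hz:
            raise ValueError("sampling_rate must be at least 10x the toneburst frequency")


def make_gradient_design(
    replicates: int,
    params: AcousticParams | None = None,
    rng: np.random.Generator | None = None,
) -> list[SampleRecord]:
    """Enumerate the full factorial design in deterministic order.

    Order: strain, wort, yeast level, replicate (all ascending).  When
    ``params`` is given, cell-count labels are drawn via
    :func:`cell_count_from_fraction` (supply ``rng`` for a noisy
    hemocytometer surrogate; without it counts are noise-free).
    """
    if replicates < 0:
        raise ValueError("replicates must be >= 0")
    records: list[SampleRecord] = []
    for strain in Strain:
        for wort in WORT_LEVELS:
            for yeast in YEAST_LEVELS:
                for rep in range(1, replicates + 1):
                    if params is not None:
                        true_c, meas_c = cell_count_from_fraction(strain, yeast, params, rng)
                    else:
                        true_c = meas_c = float("nan")
                    records.append(
                        SampleRecord(strain, wort, yeast, rep, true_c, meas_c)
                    )
    return records


def cell_count_from_fraction(
    strain: Strain | str,
    yeast_wt_pct: float,
    params: AcousticParams,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Linear count label plus multiplicative counting error.

    ``true = slope[strain] * wt%``; the measured surrogate is
    ``true * (1 + eps)`` with ``eps ~ N(0, count_cv)``, truncated at zero.
    A blank suspension counts exactly zero.
    """
    strain = Strain.coerce(strain)
    if yeast_wt_pct < 0:
        raise ValueError("yeast_wt_pct must be >= 0")
    true_count = params.count_slope[strain] * yeast_wt_pct
    if yeast_wt_pct == 0:
        return 0.0, 0.0
    if rng is None or params.count_cv == 0:
        return true_count, true_count
    eps = rng.normal(0.0, params.count_cv)
    return true_count, max(0.0, true_count * (1.0 + eps))


def echo_parameters(
    record: SampleRecord,
    params: AcousticParams,
    geometry: VesselGeometry,
) -> list[tuple[float, float]]:
    """Deterministic (amplitude, arrival time ns) of the three echoes."""
    strain = record.strain
    if record.wort_wt_pct not in params.base_attenuation:
        raise ValueError(
            f"no base attenuation configured for wort {record.wort_wt_pct:g} wt%"
        )
    d = geometry.sample_diameter_m
    c = (
        params.base_velocity
        + params.velocity_wort_slope * (record.wort_wt_pct - 12.0)
        + params.velocity_yeast_slope[strain] * record.yeast_wt_pct
    )
    alpha = params.base_attenuation[record.wort_wt_pct] + params.attenuation_slope[strain] * record.yeast_wt_pct
    a0 = params.excitation_amplitude
    t1 = params.echo1_time_ns
    t2 = t1 + (2.0 * d / c) * NS_PER_S
    t3 = t2 + params.echo3_reverb_delay_ns
    amp1 = a0 * params.echo1_gain
    amp2 = a0 * params.echo2_gain[strain] * np.exp(-2.0 * alpha * d)
    amp3 = a0 * params.echo3_gain * np.exp(-4.0 * alpha * d)
    return [(amp1, t1), (amp2, t2), (amp3, t3)]


def _check_windows(echoes: Sequence[tuple[float, float]], windows: Sequence[EchoWindow]) -> None:
    for (_, t_ns), win in zip(echoes, sorted(windows, key=lambda w: w.index)):
        if not win.a_ns <= t_ns <= win.b_ns:
            raise SimulationConfigError(
                f"echo {win.index} center {t_ns:.0f} ns falls outside its gate "
                f"[{win.a_ns:g}, {win.b_ns:g}] ns; adjust acoustic parameters"
            )


def synth_ascan(
    record: SampleRecord,
    params: AcousticParams,
    geometry: VesselGeometry | None = None,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    *,
    windows: Sequence[EchoWindow] = DEFAULT_ECHO_WINDOWS,
    signal_index: int = 0,
    timestamp_s: float = 0.0,
) -> AScan:
    """Synthesize one raw A-scan for a sample record.

    Echo centers are validated against the gating windows: a parameter set
    that pushes an echo out of its window is a misconfiguration, not data.
    """
    geometry = geometry or VesselGeometry()
    config = config or SimConfig()
    config.validate_against(params)
    echoes = echo_parameters(record, params, geometry)
    _check_windows(echoes, windows)

    t_ns = np.arange(config.n_samples) * (NS_PER_S / config.sampling_rate)
    x = np.zeros_like(t_ns)
    f0_per_ns = params.toneburst_frequency_hz / NS_PER_S
    sigma = params.toneburst_sigma_ns
    for amp, tc in echoes:
        dt = t_ns - tc
        x += amp * np.exp(-(dt**2) / (2.0 * sigma**2)) * np.sin(2.0 * np.pi * f0_per_ns * dt)
    if params.noise_std > 0:
        if rng is None:
            raise ValueError("rng is required when noise_std > 0")
        x = x + rng.normal(0.0, params.noise_std, size=x.shape)
    return AScan(
        raw=x,
        sampling_rate=config.sampling_rate,
        measurement_id=record.measurement_id,
        signal_index=signal_index,
        timestamp_s=timestamp_s,
    )


def simulate_measurement(
    record: SampleRecord,
    params: AcousticParams,
    geometry: VesselGeometry | None = None,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[AScan]:
    """Acquire one measurement: ``signals_per_measurement`` A-scans.

    The deterministic echo structure is fixed within the measurement; only
    the additive noise differs between signals.  Acquisition timestamps sit
    on the ``signal_interval_s`` grid starting at zero.
    """
    config = config or SimConfig()
    return [
        synth_ascan(
            record,
            params,
            geometry,
            config,
            rng,
            signal_index=k,
            timestamp_s=k * config.signal_interval_s,
        )
        for k in range(config.signals_per_measurement)
    ]


def iter_design_measurements(
    records: Sequence[SampleRecord],
    params: AcousticParams,
    geometry: VesselGeometry | None = None,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Iterator[tuple[SampleRecord, list[AScan]]]:
    """Generate measurements one at a time to bound memory."""
    for record in records:
        yield record, simulate_measurement(record, params, geometry, config, rng)
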