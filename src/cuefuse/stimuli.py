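"""Stimulus synthesis: echo-delay click pairs and log-normal bubble fields.

The audio cue is a pair of identical short clicks; the delay between them is
the round-trip travel time of sound to the target (2d / 350 m/s), so longer
delays signal farther targets.  The visual cue is a 3D "violin" of bubbles
whose outline follows a mirrored log-normal density along the response line;
its widest cross-section marks the most probable target location.
"""

from __future__ import annotations

import logging
import wave
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "SPEED_OF_SOUND",
    "RESPONSE_RANGE",
    "ClickPair",
    "BubbleField",
    "PackingError",
    "echo_delay",
    "synthesize_click_pair",
    "make_bubble_field",
    "write_wav",
]

#: Speed of sound used to convert distance to echo delay (m/s).
SPEED_OF_SOUND = 350.0

#: Nearest and farthest possible positions on the response line (m).
RESPONSE_RANGE = (10.0, 35.0)

#: Duration of a single click (s).
CLICK_DURATION = 0.005

#: Silence before the emission click (s) and minimum total buffer (s).
EMISSION_LEAD = 0.050
MIN_BUFFER = 1.0


def echo_delay(distance_m: float) -> float:
    """Round-trip echo delay (s) for a target at ``distance_m`` meters.

    The emission travels to the target and back, so the delay is
    ``2 * distance / 350``.  At the 10 m near limit this is about 57 ms.
    """
    d = float(distance_m)
    if not np.isfinite(d) or d <= 0:
        raise ValueError(f"distance_m must be positive and finite, got {distance_m!r}")
    return 2.0 * d / SPEED_OF_SOUND


@dataclass
class ClickPair:
    """An emission click and its exact copy delayed by the echo delay."""

    samples: np.ndarray
    sample_rate: int
    frequency: float
    delay_s: float
    distance_m: float
    emission_onset_sample: int
    echo_onset_sample: int
    click_length: int

    @property
    def emission(self) -> np.ndarray:
        i = self.emission_onset_sample
        return self.samples[i : i + self.click_length]

    @property
    def echo(self) -> np.ndarray:
        i = self.echo_onset_sample
        return self.samples[i : i + self.click_length]

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


def _click_waveform(frequency: float, sample_rate: int) -> np.ndarray:
    """5 ms sine click: first half-period scaled by 0.6, then an exponential
    decay mask whose exponent ramps linearly from 0 to -10 between 1.5
    periods and the 5 ms end."""
    n = round(CLICK_DURATION * sample_rate)
    t = np.arange(n) / sample_rate
    w = np.sin(2 * np.pi * frequency * t)
    w[t < 0.5 / frequency] *= 0.6
    t0 = 1.5 / frequency
    decay = t >= t0
    m = np.zeros(n)
    m[decay] = -10.0 * (t[decay] - t0) / (CLICK_DURATION - t0)
    return w * np.exp(m)


def synthesize_click_pair(
    distance_m: float,
    frequency: float = 4000.0,
    sample_rate: int = 96_000,
) -> ClickPair:
    """Synthesize the echo-delay audio cue for a target at ``distance_m``.

    Parameters
    ----------
    distance_m : float
        Target distance in meters; sets the emission-to-echo delay.
    frequency : float
        Click carrier frequency in Hz (4000 or 2000 in the standard design;
        other values are allowed with a warning).
    sample_rate : int
        Samples per second; must satisfy Nyquist for ``frequency``.
    """
    delay = echo_delay(distance_m)
    if frequency not in (2000.0, 4000.0):
        log.warning("non-standard click frequency %s Hz", frequency)
    if sample_rate < 2 * frequency:
        raise ValueError("sample_rate must be at least twice the click frequency")

    click = _click_waveform(frequency, sample_rate)
    lead = round(EMISSION_LEAD * sample_rate)
    shift = round(delay * sample_rate)
    total = round(MIN_BUFFER * sample_rate)
    needed = lead + shift + len(click)
    if needed > total:
        log.info("extending audio buffer to %d samples for %.1f m", needed, distance_m)
        total = needed
    samples = np.zeros(total)
    samples[lead : lead + len(click)] += click
    samples[lead + shift : lead + shift + len(click)] += click
    peak = np.max(np.abs(samples))
    if peak > 1.0:  # only possible when emission and echo overlap (d < 10 m)
        log.warning("click pair clipped at peak %.3f; rescaling", peak)
        samples /= peak
    return ClickPair(
        samples=samples,
        sample_rate=sample_rate,
        frequency=frequency,
        delay_s=delay,
        distance_m=float(distance_m),
        emission_onset_sample=lead,
        echo_onset_sample=lead + shift,
        click_length=len(click),
    )


class PackingError(RuntimeError):
    """Raised when the bubble packing cannot place the requested count."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"bubble packing placed only {placed} of {requested} bubbles"
        )


@dataclass
class BubbleField:
    """A violin-shaped cloud of non-touching bubbles along the response line.

    ``bubble_positions`` holds one row per bubble: along-line position (m),
    lateral offset (m), vertical offset (m).  The outline half-width at
    along-line position x is proportional to the log-normal density with
    median ``center_m`` and log-scale SD ``sd_log``, so the widest section
    sits at the distribution mode.
    """

    center_m: float
    sd_log: float
    bubble_positions: np.ndarray
    n_bubbles: int = 256
    radius_m: float = 0.15
    max_halfwidth_m: float = field(default=0.0)

    @property
    def mode_m(self) -> float:
        return self.center_m * np.exp(-self.sd_log**2)


def _halfwidth_scale(dist, n_bubbles: int, radius_m: float) -> float:
    """Half-width at the mode, chosen so the violin volume comfortably holds
    ``n_bubbles`` spheres under random sequential packing."""
    lo, hi = RESPONSE_RANGE
    xs = np.linspace(lo, hi, 2000)
    pdf = dist.pdf(xs)
    peak = pdf.max()
    profile_sq_integral = np.trapezoid((pdf / peak) ** 2, xs)
    target_volume = 3.0 * n_bubbles * (2 * radius_m) ** 3
    h = np.sqrt(target_volume / (np.pi * max(profile_sq_integral, 1e-12)))
    return max(h, 6 * radius_m)


def make_bubble_field(
    center_m: float,
    sd_log: float,
    n_bubbles: int = 256,
    radius_m: float = 0.15,
    seed: int = 0,
    max_attempts: int = 100_000,
) -> BubbleField:
    """Pack ``n_bubbles`` non-touching bubbles into the log-normal violin.

    The outer edge of the outline is lined first, then the interior is
    filled by rejection sampling (along-line positions drawn from the
    log-normal itself, so the cloud is densest at the mode).  Deterministic
    under ``seed``.
    """
    lo, hi = RESPONSE_RANGE
    if not (lo <= center_m <= hi):
        raise ValueError(f"center_m must lie in [{lo}, {hi}], got {center_m}")
    if sd_log <= 0:
        raise ValueError("sd_log must be positive")
    if n_bubbles < 1:
        raise ValueError("n_bubbles must be >= 1")

    dist = stats.lognorm(s=sd_log, scale=center_m)
    mode = center_m * np.exp(-sd_log**2)
    peak = dist.pdf(mode)
    h_max = _halfwidth_scale(dist, n_bubbles, radius_m)

    def halfwidth(x):
        return h_max * dist.pdf(x) / peak

    if n_bubbles == 1:
        return BubbleField(center_m, sd_log, np.array([[mode, 0.0, 0.0]]), 1,
                           radius_m, h_max)

    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []

    def far_enough(p):
        if not placed:
            return True
        arr = np.asarray(placed)
        return np.min(np.sum((arr - p) ** 2, axis=1)) > (2 * radius_m) ** 2

    # Edge ring: walk the upper then lower outline in the horizontal plane,
    # dropping a bubble whenever one fits.
    xs = np.linspace(lo, hi, 4000)
    for sign in (1.0, -1.0):
        for x in xs:
            if len(placed) >= n_bubbles:
                break
            hw = halfwidth(x)
            if hw < radius_m:
                continue
            p = np.array([x, sign * hw, 0.0])
            if far_enough(p):
                placed.append(p)

    # Interior fill: rejection sampling inside the solid of revolution.
    attempts = 0
    while len(placed) < n_bubbles and attempts < max_attempts:
        attempts += 1
        x = dist.rvs(random_state=rng)
        if not (lo <= x <= hi):
            continue
        rho = halfwidth(x) * np.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        p = np.array([x, rho * np.cos(theta), rho * np.sin(theta)])
        if far_enough(p):
            placed.append(p)

    if len(placed) < n_bubbles:
        raise PackingError(len(placed), n_bubbles)
    positions = np.asarray(placed[:n_bubbles])
    return BubbleField(center_m, sd_log, positions, n_bubbles, radius_m, h_max)


def write_wav(path, samples: np.ndarray, sample_rate: int = 96_000) -> None:
    """Write a mono waveform as 24-bit PCM WAV."""
    x = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0)
    ints = np.round(x * (2**23 - 1)).astype(np.int32)
    raw = ints.astype("<i4").tobytes()
    # keep the three low bytes of each little-endian int32
    b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 4)[:, :3].tobytes()
    with wave.open(str(path), "wb") as fh:
        fh.setnchannels(1)
        fh.setsampwidth(3)
        fh.setframerate(sample_rate)
        fh.writeframes(b)
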