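"""Rate coding of intensity images as Poisson spike rasters.

Each input neuron corresponds to one pixel and fires a Poisson spike train
whose rate is proportional to the pixel intensity: intensity / divisor Hz,
so with the default divisor of 4 the maximum intensity 255 maps to 63.75 Hz.
If a presentation drives fewer than a minimum number of excitatory spikes,
the whole rate map is rescaled so its maximum rises by ``boost_hz``
(default 32 Hz, preserving proportionality between pixels) and the image is
presented again with a fresh Poisson draw, until the network responds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RateMap",
    "RetryLimitError",
    "intensity_to_rate",
    "boosted_rates",
    "sample_poisson_raster",
    "present_with_retry",
]


class RetryLimitError(RuntimeError):
    """The retry loop failed to elicit the minimum response within the cap."""


@dataclass
class RateMap:
    """Firing rate per input neuron (Hz) plus the current additive boost."""

    rates: np.ndarray   # Hz, flattened over pixels, all >= 0
    boost: float = 0.0  # current additive increase of the maximum rate (Hz)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=np.float64).ravel()
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")


def intensity_to_rate(image, divisor: float = 4.0) -> RateMap:
    """Map pixel intensities (0-255) to firing rates intensity/divisor Hz."""
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    img = np.asarray(image, dtype=np.float64)
    return RateMap(rates=img.ravel() / divisor, boost=0.0)


def boosted_rates(r: RateMap, boost_hz: float) -> RateMap:
    """Rescale the map multiplicatively so its maximum rises by ``boost_hz``.

    Proportionality between pixels is preserved.  An all-zero map cannot be
    boosted by rescaling and is returned unchanged (the retry loop's cap then
    converts the dead input into an explicit fault).
    """
    base_max = r.rates.max(initial=0.0)
    new_boost = r.boost + boost_hz
    if base_max <= 0:
        return RateMap(rates=r.rates.copy(), boost=new_boost)
    peak = base_max - r.boost  # un-boosted maximum of the original map
    scale = (peak + new_boost) / base_max
    return RateMap(rates=r.rates * scale, boost=new_boost)


def sample_poisson_raster(
    r: RateMap,
    duration_ms: float,
    dt_ms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a Bernoulli-per-step approximation of Poisson spike trains.

    Returns a boolean array of shape (n_steps, n_neurons); each entry is an
    independent Bernoulli(rate * dt) event.  At the default dt of 0.5 ms and
    a 63.75 Hz maximum rate the per-step probability is about 0.032, well in
    the regime where the approximation is accurate.  Rejects rate*dt >= 1.
    """
    if duration_ms <= 0 or dt_ms <= 0:
        raise ValueError("duration and dt must be positive")
    prob = r.rates * (dt_ms / 1000.0)
    if np.any(prob >= 1.0):
        raise ValueError("rate*dt >= 1; decrease dt or the firing rates")
    n_steps = int(round(duration_ms / dt_ms))
    return rng.random((n_steps, r.rates.shape[0])) < prob


def present_with_retry(
    handle,
    image,
    learning: bool,
    rng: np.random.Generator,
    max_retries: int = 20,
):
    """Present an image, re-presenting with boosted rates until the network
    responds with at least ``min_exc_spikes`` excitatory spikes.

    Each attempt draws a fresh Poisson raster at the current rate scale; a
    failed attempt is followed by a rest phase (so residual conductances do
    not leak across attempts), a boost of the maximum rate by
    ``rate_boost_hz``, and a new presentation.  Learning, when enabled,
    applies on every attempt.  Returns ``(SpikeRecord, retries)`` for the
    final (successful) attempt.  Raises :class:`RetryLimitError` after
    ``max_retries`` failed boosts — in particular for an all-zero image,
    which multiplicative rescaling cannot rescue.
    """
    cfg = handle.cfg
    rate_map = intensity_to_rate(image, cfg.intensity_divisor)
    for retries in range(max_retries + 1):
        raster = sample_poisson_raster(rate_map, cfg.presentation_ms, cfg.dt, rng)
        record = handle.run_presentation(raster, learning=learning)
        if int(record.counts.sum()) >= cfg.min_exc_spikes:
            return record, retries
        handle.run_rest()
        rate_map = boosted_rates(rate_map, cfg.rate_boost_hz)
    raise RetryLimitError(
        f"no {cfg.min_exc_spikes}-spike response after {max_retries} boosts "
        f"(+{cfg.rate_boost_hz} Hz each); pathological input"
    )
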