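"""Causal low-pass Bessel filtering, mimicking the acquisition hardware.

Patch-clamp amplifiers apply an analog 8-pole low-pass Bessel filter; the
analysis refilters traces at 1 kHz or 100 Hz before computing blockade and
noise statistics.  The digital filter here is magnitude-normalized so that
the response is -3 dB at the cutoff, has unit DC gain, and is applied
forward-only (causal), like the hardware.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = ["bessel_sos", "bessel_filter_array", "bessel_lowpass"]


def bessel_sos(cutoff_hz: float, sampling_rate_hz: float, poles: int = 8) -> np.ndarray:
    """Second-order sections of the digital 8-pole Bessel low-pass."""
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff_hz >= sampling_rate_hz / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie below the Nyquist frequency "
            f"{sampling_rate_hz / 2} Hz"
        )
    return signal.bessel(
        poles, cutoff_hz, btype="low", norm="mag", output="sos", fs=sampling_rate_hz
    )


def bessel_filter_array(
    x: np.ndarray, cutoff_hz: float, sampling_rate_hz: float, poles: int = 8
) -> np.ndarray:
    """Causal Bessel filtering of a bare sample array.

    A segment cut out of a longer trace must not acquire a startup
    transient (it would leak into the lowest periodogram bins), so the
    start is reflect-padded over one filter settling length and the state
    is primed with the local mean; the pad is discarded after filtering.
    """
    x = np.asarray(x, dtype=float)
    sos = bessel_sos(cutoff_hz, sampling_rate_hz, poles)
    pad = min(x.size - 1, int(4.0 * sampling_rate_hz / cutoff_hz))
    lead = x[: max(1, pad)]
    zi = signal.sosfilt_zi(sos) * lead.mean()
    if pad > 0:
        xp = np.concatenate([x[1 : pad + 1][::-1], x])
    else:
        xp = x
    y, _ = signal.sosfilt(sos, xp, zi=zi)
    return y[pad:]


def bessel_lowpass(trace, cutoff_hz: float, poles: int = 8):
    """Return a new, causally filtered copy of a Trace.

    The applied filter is appended to the trace's ``filter_state`` list so
    downstream stages know the effective bandwidth.
    """
    from .events import Trace  # local import to avoid a cycle

    y = bessel_filter_array(trace.current_pA, cutoff_hz, trace.sampling_rate, poles)
    return Trace(
        current_pA=y,
        sampling_rate=trace.sampling_rate,
        applied_voltage_mv=trace.applied_voltage_mv,
        filter_state=list(trace.filter_state) + [("bessel", poles, float(cutoff_hz))],
        provenance=trace.provenance,
    )


def bessel_power_response(
    freqs_hz: np.ndarray, cutoff_hz: float, sampling_rate_hz: float, poles: int = 8
) -> np.ndarray:
    """|H(f)|² of the digital filter, used by the generator calibration."""
    sos = bessel_sos(cutoff_hz, sampling_rate_hz, poles)
    _, h = signal.sosfreqz(sos, worN=np.asarray(freqs_hz, dtype=float), fs=sampling_rate_hz)
    return np.abs(h) ** 2
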