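"""Digital twins of the analog signal-conditioning front-ends.

Two acquisition chains are modelled:

* respiration (piezoelectric belt): charge/voltage amplification with a
  combined gain of 80, a second-order active low-pass at 88.46 Hz, and a DC
  boost so the microprocessor ADC sees a unipolar signal;
* ECG (instrumentation chip): programmable gain 1000 followed by a 24-bit
  ADC; no analog filter is modelled.

Analog filters are realized as bilinear-transform Butterworth designs of the
stated order and cutoff (maximally flat is the standard default when only
"second-order active low-pass" is known). ADC emulation rounds to the LSB
grid of ``adc_range / 2**adc_bits`` without saturation, i.e. an ideal
infinite-range quantizer: quantization error is bounded by half an LSB while
large test signals pass through undistorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = ["FilterSpec", "ConditioningChain", "respiration_chain", "ecg_chain",
           "apply_chain"]


@dataclass(frozen=True)
class FilterSpec:
    order: int
    cutoff_hz: float
    kind: str = "lowpass"
    design: str = "butterworth"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff must be positive")
        if self.kind not in ("lowpass", "highpass", "bandpass", "notch"):
            raise ValueError(f"unknown filter kind {self.kind!r}")


@dataclass(frozen=True)
class ConditioningChain:
    gain: float
    filters: tuple[FilterSpec, ...] = ()
    dc_offset: float = 0.0
    adc_bits: int = 12
    adc_range: float = 3.3

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if not 8 <= self.adc_bits <= 32:
            raise ValueError("adc_bits must be within 8..32")

    @property
    def lsb(self) -> float:
        return self.adc_range / 2 ** self.adc_bits


def respiration_chain() -> ConditioningChain:
    """Breathing-coil conditioning: gain 80, second-order low-pass at
    88.46 Hz, DC boost to mid-rail, 12-bit ADC emulation."""
    return ConditioningChain(
        gain=80.0,
        filters=(FilterSpec(order=2, cutoff_hz=88.46, kind="lowpass"),),
        dc_offset=3.3 / 2,
        adc_bits=12,
        adc_range=3.3,
    )


def ecg_chain() -> ConditioningChain:
    """ECG conditioning: chip gain 1000 and 24-bit ADC; bipolar, no offset."""
    return ConditioningChain(gain=1000.0, filters=(), dc_offset=0.0,
                             adc_bits=24, adc_range=4.8)


def quantize(samples: np.ndarray, chain: ConditioningChain) -> np.ndarray:
    """Round to the ADC's LSB grid (no saturation)."""
    lsb = chain.lsb
    return np.round(np.asarray(samples, dtype=float) / lsb) * lsb


def filter_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    if spec.cutoff_hz >= fs / 2:
        raise ValueError(
            f"FilterSpec(order={spec.order}, cutoff_hz={spec.cutoff_hz}, "
            f"kind={spec.kind!r}): cutoff at or above Nyquist ({fs / 2} Hz)")
    if spec.kind == "notch":
        b, a = sps.iirnotch(spec.cutoff_hz, Q=30.0, fs=fs)
        return sps.tf2sos(b, a)
    return sps.butter(spec.order, spec.cutoff_hz, btype=spec.kind, fs=fs,
                      output="sos")


def apply_chain(chain: ConditioningChain, samples: np.ndarray, fs: float,
                emulate_adc: bool = True) -> np.ndarray:
    """Run samples through gain, filters, DC boost and ADC quantization.

    output = quantize(filter(gain * input) + dc_offset). The gain+filter
    stage is linear; set ``emulate_adc=False`` to observe it exactly.
    """
    y = chain.gain * np.asarray(samples, dtype=float)
    for spec in chain.filters:
        y = sps.sosfilt(filter_sos(spec, fs), y)
    y = y + chain.dc_offset
    if emulate_adc:
        y = quantize(y, chain)
    return y


def frequency_response(spec: FilterSpec, fs: float,
                       freqs_hz: np.ndarray) -> np.ndarray:
    """Magnitude response of the digital realization at the given
    frequencies (used to verify the -3 dB point and roll-off)."""
    sos = filter_sos(spec, fs)
    _, h = sps.sosfreqz(sos, worN=np.asarray(freqs_hz, dtype=float), fs=fs)
    return np.abs(h)
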