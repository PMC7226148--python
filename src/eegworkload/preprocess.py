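"""Band-pass filtering and regression-based ocular-artifact removal.

Stage order follows standard practice for wearable-EEG workload analysis:
filter first (0.5-32 Hz Butterworth, all channels identically, EOG included),
then regress the horizontal and vertical EOG channels out of each scalp
channel by ordinary least squares and subtract the fitted contribution.

The default filter is zero-phase (forward-backward). Because two passes
square the magnitude response, the design cutoffs are pre-warped so that the
NET response is -3 dB at the requested band edges; a single-pass variant with
conventional cutoffs is available via ``passes="single"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import brentq

from eegworkload.io import EEG, EOG_H, EOG_V, Recording

__all__ = [
    "FilterSpec",
    "EogModel",
    "design_bandpass",
    "apply_bandpass",
    "fit_eog_model",
    "remove_eog",
]


@dataclass
class FilterSpec:
    """A designed Butterworth band-pass filter.

    ``low_hz``/``high_hz`` are the requested -3 dB edges of the NET response;
    ``design_low``/``design_high`` are the (possibly pre-warped) cutoffs
    actually passed to the design routine. ``sos`` holds second-order
    sections.
    """

    low_hz: float
    high_hz: float
    fs: float
    order: int = 4
    family: str = "butterworth"
    passes: str = "zero_phase"
    design_low: float = 0.0
    design_high: float = 0.0
    sos: np.ndarray = field(default=None, repr=False)

    def response(self, freqs) -> np.ndarray:
        """Net magnitude response at ``freqs`` (Hz): |H| for a single pass,
        |H|^2 for the zero-phase two-pass filter."""
        freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
        _, h = sps.sosfreqz(self.sos, worN=2.0 * np.pi * freqs / self.fs)
        mag = np.abs(h)
        return mag**2 if self.passes == "zero_phase" else mag

    def gain_db(self, freqs) -> np.ndarray:
        return 20.0 * np.log10(np.maximum(self.response(freqs), 1e-300))


def _design(low: float, high: float, fs: float, order: int) -> np.ndarray:
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def design_bandpass(
    low_hz: float,
    high_hz: float,
    fs: float,
    order: int = 4,
    passes: str = "zero_phase",
) -> FilterSpec:
    """Design a Butterworth band-pass whose net -3 dB points sit at the edges.

    For ``passes="single"`` the standard design applies (Butterworth is
    -3 dB at its cutoffs by construction). For ``passes="zero_phase"`` the
    cutoffs are pre-warped -- analytically to first order, then refined on
    the realized digital response -- so that after the forward-backward pass
    the net response is -3 dB at ``low_hz`` and ``high_hz``.
    """
    if not 0.0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= fs / 2.0:
        raise ValueError(f"high_hz ({high_hz}) must be below Nyquist ({fs / 2.0})")
    if order < 1:
        raise ValueError("order must be >= 1")
    if passes not in ("single", "zero_phase"):
        raise ValueError("passes must be 'single' or 'zero_phase'")

    if passes == "single":
        dl, dh = low_hz, high_hz
    else:
        # per-pass target 2^(-1/4) at each edge: (f/fc)^(2n) = sqrt(2) - 1
        stretch = (np.sqrt(2.0) - 1.0) ** (1.0 / (2.0 * order))
        dl, dh = low_hz * stretch, min(high_hz / stretch, 0.999 * fs / 2.0)
        target = 1.0 / np.sqrt(2.0)

        def net_gain(edge_freq, dlo, dhi):
            sos = _design(dlo, dhi, fs, order)
            _, h = sps.sosfreqz(sos, worN=[2.0 * np.pi * edge_freq / fs])
            return np.abs(h[0]) ** 2

        for _ in range(3):  # edges are far apart; alternation converges fast
            dl = brentq(lambda x: net_gain(low_hz, x, dh) - target,
                        0.2 * low_hz, low_hz)
            dh = brentq(lambda x: net_gain(high_hz, dl, x) - target,
                        high_hz, min(4.0 * high_hz, 0.999 * fs / 2.0))

    sos = _design(dl, dh, fs, order)
    return FilterSpec(
        low_hz=low_hz, high_hz=high_hz, fs=fs, order=order, passes=passes,
        design_low=dl, design_high=dh, sos=sos,
    )


def apply_bandpass(recording: Recording, spec: FilterSpec) -> Recording:
    """Filter every channel (EEG and EOG alike) with the designed band-pass.

    Zero-phase filtering uses forward-backward application with odd
    reflection padding; the single-pass variant reflection-pads, filters
    causally, and trims, so length is preserved either way.
    """
    if abs(recording.fs - spec.fs) > 1e-9:
        raise ValueError(
            f"recording fs ({recording.fs}) does not match filter design fs ({spec.fs})"
        )
    x = recording.data
    if not np.all(np.isfinite(x)):
        raise ValueError("recording contains non-finite samples; cannot filter")
    n = x.shape[1]
    if spec.passes == "zero_phase":
        padlen = min(n - 1, int(3.0 * spec.fs / spec.low_hz))
        y = sps.sosfiltfilt(spec.sos, x, axis=1, padlen=padlen)
    else:
        pad = min(n - 1, int(3.0 * spec.fs / spec.low_hz))
        xp = np.pad(x, ((0, 0), (pad, 0)), mode="reflect")
        y = sps.sosfilt(spec.sos, xp, axis=1)[:, pad:]
    out = recording.copy_with(y)
    out.meta["filtered"] = f"butterworth {spec.low_hz}-{spec.high_hz} Hz, {spec.passes}"
    return out


@dataclass
class EogModel:
    """OLS model of ocular contamination: EEG ~ [EOG_H, EOG_V, 1].

    ``coefficients`` is EEG-channel x 2 (columns ordered [EOG_H, EOG_V]),
    ``intercepts`` per EEG channel in µV.
    """

    coefficients: np.ndarray
    intercepts: np.ndarray
    eeg_labels: list[str]
    eog_labels: list[str]
    fit_span: tuple[float, float] | None = None

    def coefficient(self, eeg_label: str, role: str) -> float:
        col = {EOG_H: 0, EOG_V: 1}[role]
        return float(self.coefficients[self.eeg_labels.index(eeg_label), col])


def fit_eog_model(
    recording: Recording, fit_span: tuple[float, float] | None = None
) -> EogModel:
    """Fit each EEG channel on [EOG_H, EOG_V, 1] by ordinary least squares.

    ``fit_span`` is a (start_s, stop_s) interval; default is the whole
    recording. Intended to run AFTER band-pass filtering, so that the linear
    mixing the regression assumes is preserved (all channels pass through the
    identical filter).
    """
    ih = recording.eog_index(EOG_H)
    iv = recording.eog_index(EOG_V)
    if fit_span is None:
        sl = slice(None)
    else:
        s0 = int(round(fit_span[0] * recording.fs))
        s1 = int(round(fit_span[1] * recording.fs))
        if not 0 <= s0 < s1 <= recording.n_samples:
            raise ValueError("fit_span outside recording")
        sl = slice(s0, s1)
    eog = recording.data[[ih, iv]][:, sl]
    if np.ptp(eog[0]) == 0.0 or np.ptp(eog[1]) == 0.0:
        raise ValueError(
            "an EOG channel is constant (zero variance); no regression is "
            "identifiable -- use an identity correction (skip EOG removal)"
        )
    eeg_idx = recording.eeg_indices
    y = recording.data[eeg_idx][:, sl]
    design = np.column_stack([eog[0], eog[1], np.ones(eog.shape[1])])
    beta, *_ = np.linalg.lstsq(design, y.T, rcond=None)  # (3, n_eeg)
    return EogModel(
        coefficients=beta[:2].T.copy(),
        intercepts=beta[2].copy(),
        eeg_labels=[recording.labels[i] for i in eeg_idx],
        eog_labels=[recording.labels[ih], recording.labels[iv]],
        fit_span=fit_span,
    )


def remove_eog(recording: Recording, model: EogModel) -> Recording:
    """Subtract the fitted EOG contribution from each EEG channel.

    Each EEG channel becomes its OLS residual plus its own mean (the DC level
    is not attributed to the eyes). EOG channels are retained unchanged for
    audit and flagged in the recording metadata.
    """
    eeg_idx = recording.eeg_indices
    labels = [recording.labels[i] for i in eeg_idx]
    if labels != model.eeg_labels:
        raise ValueError(
            f"montage mismatch: model fitted on {model.eeg_labels}, "
            f"recording has {labels}"
        )
    ih = recording.eog_index(EOG_H)
    iv = recording.eog_index(EOG_V)
    eog = recording.data[[ih, iv]]
    data = recording.data.copy()
    y = data[eeg_idx]
    fitted = model.coefficients @ eog + model.intercepts[:, None]
    resid = y - fitted
    data[eeg_idx] = resid + y.mean(axis=1, keepdims=True) - resid.mean(axis=1, keepdims=True)
    out = recording.copy_with(data)
    out.meta["eog_corrected_against"] = list(model.eog_labels)
    return out
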