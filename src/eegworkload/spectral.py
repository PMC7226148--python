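"""Epoching, artifact rejection, averaged-periodogram spectra, band power.

Continuous data are sliced per scenario annotation into non-overlapping 2-s
epochs (trailing partial epoch dropped). An epoch is rejected if ANY sample
on ANY scalp EEG channel leaves the closed [-threshold, +threshold] µV
interval -- rejection is recording-wide per epoch, and discarded seconds are
accounted per condition.

Spectra are averaged modified periodograms over the valid epochs: per epoch
and channel the mean is removed, a Hamming window applied, and the one-sided
power spectral density computed as ``|X(f)|^2 / (fs * sum(w^2))`` with
interior bins doubled, in µV²/Hz. Averaging non-overlapping windowed
segments is the zero-overlap limit of Welch's estimator (Bartlett-style
segmenting with a Hamming taper). With fs=256 and 2-s epochs the frequency
grid has 0.5 Hz steps, and theta band power is the arithmetic mean of the
PSD over the nine bins with 4 <= f <= 8 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from eegworkload.io import Recording, ScenarioAnnotation

__all__ = [
    "EpochSet",
    "PowerSpectrum",
    "slice_and_epoch",
    "reject_epochs",
    "average_periodogram",
    "band_power",
    "build_band_power_table",
    "THETA_BAND",
]

THETA_BAND = (4.0, 8.0)
DEFAULT_EPOCH_LENGTH_S = 2.0
DEFAULT_REJECT_UV = 100.0


@dataclass
class EpochSet:
    """Non-overlapping fixed-length epochs from one annotated interval."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples), µV
    fs: float
    labels: list[str]
    roles: list[str]
    condition_label: str
    epoch_length_s: float = DEFAULT_EPOCH_LENGTH_S
    valid_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.epochs.shape[0], dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def discarded_s(self) -> float:
        return self.epoch_length_s * float((~self.valid_mask).sum())

    @property
    def eeg_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == "EEG"]


@dataclass
class PowerSpectrum:
    """One-sided averaged PSD per channel, µV²/Hz."""

    freqs: np.ndarray
    psd: np.ndarray  # (n_channels, n_freqs)
    labels: list[str]
    n_epochs_averaged: int
    condition_label: str = ""

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def slice_and_epoch(
    recording: Recording,
    annotation: ScenarioAnnotation,
    epoch_length_s: float = DEFAULT_EPOCH_LENGTH_S,
) -> EpochSet:
    """Cut one annotated interval into non-overlapping whole epochs.

    ``floor(duration / epoch_length)`` epochs are produced; a trailing
    partial epoch is dropped. The interval must lie within the recording and
    hold at least one epoch.
    """
    fs = recording.fs
    start = annotation.start_s - recording.start_time
    s0 = int(round(start * fs))
    s1 = int(round((start + annotation.duration_s) * fs))
    if s0 < 0 or s1 > recording.n_samples:
        raise ValueError(
            f"annotation {annotation.label!r} [{annotation.start_s}, "
            f"{annotation.stop_s}) s lies outside the recording"
        )
    n_per = int(round(epoch_length_s * fs))
    n_ep = (s1 - s0) // n_per
    if n_ep < 1:
        raise ValueError(
            f"interval {annotation.label!r} shorter than one {epoch_length_s}-s epoch"
        )
    seg = recording.data[:, s0 : s0 + n_ep * n_per]
    epochs = seg.reshape(recording.n_channels, n_ep, n_per).transpose(1, 0, 2).copy()
    return EpochSet(
        epochs=epochs,
        fs=fs,
        labels=list(recording.labels),
        roles=list(recording.roles),
        condition_label=annotation.label,
        epoch_length_s=epoch_length_s,
    )


def reject_epochs(
    epoch_set: EpochSet, threshold_uv: float = DEFAULT_REJECT_UV
) -> tuple[EpochSet, dict]:
    """Mark epochs with any EEG sample outside the closed ±threshold interval.

    The interval is closed: a sample exactly at the threshold is kept. One
    offending sample on one scalp channel discards the whole epoch on all
    channels. Returns the EpochSet (mask updated in a copy) and a discard
    report dict.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    eeg = epoch_set.epochs[:, epoch_set.eeg_indices, :]
    bad = np.any(np.abs(eeg) > threshold_uv, axis=(1, 2))
    mask = epoch_set.valid_mask & ~bad
    out = EpochSet(
        epochs=epoch_set.epochs,
        fs=epoch_set.fs,
        labels=epoch_set.labels,
        roles=epoch_set.roles,
        condition_label=epoch_set.condition_label,
        epoch_length_s=epoch_set.epoch_length_s,
        valid_mask=mask,
    )
    report = {
        "condition": epoch_set.condition_label,
        "n_epochs": out.n_epochs,
        "n_rejected": int(bad.sum()),
        "discarded_s": out.discarded_s,
        "threshold_uv": threshold_uv,
    }
    return out, report


def average_periodogram(epoch_set: EpochSet) -> PowerSpectrum:
    """Average Hamming-windowed periodograms over the valid epochs.

    Per valid epoch and channel: remove the epoch mean, apply a Hamming
    window, and compute the one-sided density-scaled periodogram
    ``P(f) = |X(f)|^2 / (fs * sum(w^2))`` with interior bins doubled; the
    estimates are then averaged across epochs.
    """
    valid = epoch_set.epochs[epoch_set.valid_mask]
    if valid.shape[0] == 0:
        raise ValueError(
            f"no valid epochs left for condition {epoch_set.condition_label!r}"
        )
    n = valid.shape[-1]
    w = np.hamming(n)  # symmetric Hamming taper
    x = valid - valid.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(x * w, axis=-1)
    p = (np.abs(spec) ** 2) / (epoch_set.fs * np.sum(w**2))
    p[..., 1:-1] *= 2.0  # one-sided: double interior bins (not DC/Nyquist)
    if n % 2:  # odd length: no Nyquist bin, double the last bin too
        p[..., -1] *= 2.0
    psd = p.mean(axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / epoch_set.fs)
    return PowerSpectrum(
        freqs=freqs,
        psd=psd,
        labels=list(epoch_set.labels),
        n_epochs_averaged=int(valid.shape[0]),
        condition_label=epoch_set.condition_label,
    )


def band_power(
    power_spectrum: PowerSpectrum, band: tuple[float, float] = THETA_BAND
) -> np.ndarray:
    """Arithmetic mean of the PSD over bins with band[0] <= f <= band[1].

    Both endpoints are inclusive (nine 0.5-Hz bins for the 4-8 Hz theta band
    at fs=256 with 2-s epochs). Returns one value per channel, µV²/Hz.
    """
    lo, hi = band
    if not 0.0 <= lo < hi:
        raise ValueError("invalid band")
    if hi > power_spectrum.freqs[-1] + 1e-9:
        raise ValueError("band exceeds the spectrum's Nyquist limit")
    sel = (power_spectrum.freqs >= lo - 1e-9) & (power_spectrum.freqs <= hi + 1e-9)
    if not np.any(sel):
        raise ValueError("band contains no frequency bins")
    return power_spectrum.psd[:, sel].mean(axis=1)


def build_band_power_table(
    subject_spectra: dict[int, dict[str, PowerSpectrum]],
    band: tuple[float, float] = THETA_BAND,
    eeg_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the long-format subject x condition x channel power table.

    ``subject_spectra`` maps subject id -> {condition label -> PowerSpectrum}.
    Subjects may miss conditions (recording failures); missing rows are simply
    absent and downstream statistics handle them listwise. Channel sets must
    agree across all spectra.
    """
    rows = []
    ref_labels = None
    for subj in sorted(subject_spectra):
        for cond, spec in subject_spectra[subj].items():
            labels = eeg_labels if eeg_labels is not None else spec.labels
            idx = [spec.labels.index(lab) for lab in labels]
            if ref_labels is None:
                ref_labels = labels
            elif list(labels) != list(ref_labels):
                raise ValueError(
                    f"inconsistent channel sets: subject {subj} has {labels}, "
                    f"expected {ref_labels}"
                )
            bp = band_power(spec, band)
            for lab, i in zip(labels, idx):
                rows.append(
                    {
                        "subject": subj,
                        "condition": cond,
                        "channel": lab,
                        "theta_power": float(bp[i]),
                    }
                )
    return pd.DataFrame(rows)


def condition_channel_matrix(table: pd.DataFrame, conditions: list[str]) -> pd.DataFrame:
    """Channel x condition matrix of cohort-mean band power, plus a 'Mean' row
    averaging the channels (the overall theta-activity summary)."""
    piv = (
        table.groupby(["channel", "condition"])["theta_power"]
        .mean()
        .unstack("condition")
    )
    channels = [c for c in table["channel"].unique() if c in piv.index]
    piv = piv.loc[channels, [c for c in conditions if c in piv.columns]]
    piv.loc["Mean"] = piv.mean(axis=0)
    return piv
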