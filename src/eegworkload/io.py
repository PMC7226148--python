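"""Recording and annotation I/O with strict unit and montage handling.

Signals live in memory as channel x sample matrices in microvolts (µV);
conversion from on-disk calibration happens at read time and nowhere else.
The on-disk format for recordings is EDF (16-bit); scenario annotations and
behavioral tables are sidecar CSVs.

EDF reading goes through :func:`mne.io.read_raw_edf`; writing is implemented
here (16-bit EDF with per-signal physical/digital calibration), so round-trip
tests exercise an independent reader against this writer.
"""

from __future__ import annotations

import datetime as _dt
import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "ScenarioAnnotation",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "read_behavioral",
    "write_behavioral",
    "EEG",
    "EOG_H",
    "EOG_V",
]

EEG = "EEG"
EOG_H = "EOG_H"
EOG_V = "EOG_V"
_ROLES = (EEG, EOG_H, EOG_V)

#: Channel labels ignored by default when reading (status/trigger channels).
DEFAULT_IGNORE = frozenset({"STATUS", "MARKER", "EVENT", "TRIGGER", "ANNOTATIONS", "EDF ANNOTATIONS"})


def _infer_role(label: str) -> str | None:
    """Default label -> role heuristic (case-insensitive).

    Labels containing 'EOG' are ocular channels, split into horizontal /
    vertical by an adjacent H or V; anything in DEFAULT_IGNORE is dropped;
    everything else is scalp EEG.
    """
    u = label.upper().strip()
    if u in DEFAULT_IGNORE:
        return None
    if "EOG" in u:
        rest = u.replace("EOG", "")
        if "H" in rest:
            return EOG_H
        if "V" in rest:
            return EOG_V
        return None
    return EEG


@dataclass
class Recording:
    """Multichannel biosignal in µV referenced to a common electrode.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal matrix in µV.
    fs : float
        Sampling rate in Hz, shared by all channels.
    labels : list of str
        Unique channel labels (10/20 names for scalp sites).
    roles : list of str
        Per-channel role, one of ``EEG``, ``EOG_H``, ``EOG_V``.
    reference : str
        Reference electrode label (default CZ, vertex reference).
    start_time : float
        Offset of the first sample in seconds.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    roles: list[str]
    reference: str = "CZ"
    start_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channel x sample (2-D)")
        n_ch = self.data.shape[0]
        if len(self.labels) != n_ch or len(self.roles) != n_ch:
            raise ValueError("labels/roles length must match channel count")
        if len(set(self.labels)) != n_ch:
            raise ValueError("channel labels must be unique")
        for r in self.roles:
            if r not in _ROLES:
                raise ValueError(f"unknown channel role {r!r}")
        if EEG not in self.roles:
            raise ValueError("at least one EEG channel is required")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None

    def role_indices(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == role]

    @property
    def eeg_indices(self) -> list[int]:
        return self.role_indices(EEG)

    def eog_index(self, role: str) -> int:
        idx = self.role_indices(role)
        if not idx:
            raise KeyError(f"recording has no {role} channel")
        return idx[0]

    def copy_with(self, data: np.ndarray) -> "Recording":
        return replace(self, data=np.asarray(data, dtype=float), meta=dict(self.meta))


@dataclass(frozen=True)
class ScenarioAnnotation:
    """Labeled half-open time interval [start_s, stop_s) within a recording.

    ``complexity_rank`` orders the driving scenarios by terrain complexity
    (1=low, 2=medium, 3=high); rank 0 marks task-free baseline intervals
    (eyes-open resting state).
    """

    label: str
    complexity_rank: int
    start_s: float
    stop_s: float

    def __post_init__(self):
        if not self.stop_s > self.start_s:
            raise ValueError(
                f"annotation {self.label!r}: stop_s ({self.stop_s}) must exceed start_s ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s


# ---------------------------------------------------------------------------
# EDF writing (16-bit, one data record per second)
# ---------------------------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} (max {width})")
    return s.ljust(width).encode("ascii")


def write_recording(recording: Recording, path, physical_range_uv: float = 500.0) -> int:
    """Write a Recording to EDF and return the number of clipped samples.

    The physical range is symmetric, ±``physical_range_uv`` µV, mapped onto
    the full 16-bit digital range. Samples outside the range are clipped and
    counted; a non-zero clip count triggers a warning (never silent).
    The default ±500 µV leaves headroom above the ±100 µV artifact-rejection
    threshold used downstream.
    """
    path = Path(path)
    if not np.all(np.isfinite(recording.data)):
        raise ValueError("cannot write non-finite sample values")
    if physical_range_uv <= 0:
        raise ValueError("physical_range_uv must be positive")
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))

    n_ch = recording.n_channels
    n_records = int(np.ceil(recording.n_samples / fs))
    # pad the trailing partial record with zeros (whole-second records)
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, : recording.n_samples] = recording.data

    pmin, pmax = -physical_range_uv, physical_range_uv
    clipped = int(np.count_nonzero((padded < pmin) | (padded > pmax)))
    if clipped:
        warnings.warn(
            f"{clipped} samples outside ±{physical_range_uv} µV were clipped at EDF write",
            stacklevel=2,
        )
    scaled = (np.clip(padded, pmin, pmax) - pmin) / (pmax - pmin)
    digital = np.rint(scaled * (_DIG_MAX - _DIG_MIN) + _DIG_MIN).astype("<i2")

    now = _dt.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate X X X X", 80),
            _ascii(now.strftime("%d.%m.%y"), 8),
            _ascii(now.strftime("%H.%M.%S"), 8),
            _ascii(256 * (1 + n_ch), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(1, 8),  # record duration, seconds
            _ascii(n_ch, 4),
        ]
    )
    sig_fields = [
        [_ascii(lab, 16) for lab in recording.labels],
        [_ascii("", 80)] * n_ch,  # transducer
        [_ascii("uV", 8)] * n_ch,
        [_ascii(f"{pmin:g}", 8)] * n_ch,
        [_ascii(f"{pmax:g}", 8)] * n_ch,
        [_ascii(_DIG_MIN, 8)] * n_ch,
        [_ascii(_DIG_MAX, 8)] * n_ch,
        [_ascii("", 80)] * n_ch,  # prefiltering
        [_ascii(fs, 8)] * n_ch,
        [_ascii("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in sig_fields:
            fh.write(b"".join(group))
        for rec in range(n_records):
            block = digital[:, rec * fs : (rec + 1) * fs]
            fh.write(block.tobytes())  # signal-major within each record
    return clipped


def _edf_sample_rates(path) -> dict[str, float]:
    """Peek per-signal sampling rates from an EDF header (for validation)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_ch = int(head[252:256].decode("ascii"))
        rec_dur = float(head[244:252].decode("ascii"))
        sig = fh.read(256 * n_ch)
    labels = [sig[16 * i : 16 * (i + 1)].decode("ascii").strip() for i in range(n_ch)]
    off = n_ch * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    spr = [
        int(sig[off + 8 * i : off + 8 * (i + 1)].decode("ascii"))
        for i in range(n_ch)
    ]
    return {lab: n / rec_dur for lab, n in zip(labels, spr)}


def read_recording(path, label_map: dict[str, str] | None = None,
                   required: tuple[str, ...] = ()) -> Recording:
    """Read an EDF/EDF+ file into a µV-calibrated Recording.

    Parameters
    ----------
    path : path-like
        EDF or EDF+ file.
    label_map : dict, optional
        Maps channel labels to roles (``"EEG"``, ``"EOG_H"``, ``"EOG_V"``) or
        ``None`` to drop the channel. Labels absent from the map fall back to
        the default heuristic (labels containing "EOG" are ocular, status-like
        labels are dropped, the rest are EEG).
    required : tuple of str
        Channel labels that must be present; a missing one raises with its
        name.
    """
    import mne

    path = Path(path)
    rates = _edf_sample_rates(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")

    labels, roles = [], []
    for lab in raw.ch_names:
        if label_map is not None and lab in label_map:
            role = label_map[lab]
        else:
            role = _infer_role(lab)
        if role is None:
            continue
        if role not in _ROLES:
            raise ValueError(f"label map assigns unknown role {role!r} to {lab!r}")
        labels.append(lab)
        roles.append(role)

    missing = [lab for lab in required if lab not in labels]
    if missing:
        raise ValueError(f"required channels missing from {path.name}: {', '.join(missing)}")

    kept_rates = {rates[lab] for lab in labels if lab in rates}
    if len(kept_rates) > 1:
        raise ValueError(
            f"mixed per-channel sampling rates are unsupported: {sorted(kept_rates)}"
        )

    data = raw.get_data(picks=labels, units="uV")
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        labels=labels,
        roles=roles,
        meta={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# Annotation and behavioral-table CSVs
# ---------------------------------------------------------------------------

_ANNOT_COLS = ["label", "rank", "start_s", "stop_s"]


def read_annotations(path) -> list[ScenarioAnnotation]:
    """Read scenario annotations from CSV (columns label,rank,start_s,stop_s).

    Intervals are validated (positive duration, no overlap) and returned
    sorted by start time. Errors name the offending CSV row. Ranks that do not
    form a permutation of 0..k or 1..k only warn: ranks are labels, not
    indices.
    """
    df = pd.read_csv(path)
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation CSV missing columns: {missing}")
    annots = []
    for i, row in df.iterrows():
        if not row["stop_s"] > row["start_s"]:
            raise ValueError(
                f"annotation row {i + 1} ({row['label']!r}): non-positive duration"
            )
        annots.append(
            ScenarioAnnotation(
                label=str(row["label"]),
                complexity_rank=int(row["rank"]),
                start_s=float(row["start_s"]),
                stop_s=float(row["stop_s"]),
            )
        )
    order = np.argsort([a.start_s for a in annots], kind="stable")
    annots = [annots[j] for j in order]
    for prev, nxt in zip(annots, annots[1:]):
        if nxt.start_s < prev.stop_s:
            row = 1 + next(
                i for i, a in df.iterrows() if str(a["label"]) == nxt.label
            )
            raise ValueError(
                f"annotation row {row} ({nxt.label!r}) overlaps {prev.label!r}"
            )
    ranks = sorted(a.complexity_rank for a in annots if a.complexity_rank > 0)
    if ranks and ranks != list(range(1, len(ranks) + 1)):
        warnings.warn(
            f"scenario ranks {ranks} are not a permutation of 1..{len(ranks)}; "
            "treating them as ordinal labels",
            stacklevel=2,
        )
    return annots


def write_annotations(annotations: list[ScenarioAnnotation], path) -> None:
    pd.DataFrame(
        [
            {
                "label": a.label,
                "rank": a.complexity_rank,
                "start_s": a.start_s,
                "stop_s": a.stop_s,
            }
            for a in annotations
        ]
    ).to_csv(path, index=False)


_BEHAV_COLS = ["subject", "condition", "tlx", "stops", "sss"]


def read_behavioral(path) -> pd.DataFrame:
    """Read a behavioral table CSV (subject,condition,tlx,stops,sss)."""
    df = pd.read_csv(path)
    missing = [c for c in _BEHAV_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"behavioral CSV missing columns: {missing}")
    return df


def write_behavioral(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
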