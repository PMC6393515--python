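"""Core domain containers and I/O for simultaneous SEEG-MEG sessions.

The analysis manipulates five kinds of objects: multichannel recordings
(MEG magnetometers in fT, bipolar SEEG in µV), instantaneous spike markers
carrying an anatomical label, the SEEG contact montage, fixed-length epochs
cut around markers, and the affine clock model that co-registers the two
acquisition systems from their shared jittered triggers.

Tabular side formats are plain TSV (markers, montages, result tables);
recordings are stored as a ``.npy`` array plus a JSON sidecar describing
sampling rate, channel identities and units.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("deepmeg")

#: Controlled anatomical vocabulary for SEEG channel / marker labels.
ANATOMY_VOCABULARY = (
    "hippocampus",
    "amygdala",
    "internal temporal pole",
    "entorhinal",
    "parahippocampal gyrus",
    "collateral sulcus",
    "fusiform gyrus",
    "external temporal pole",
    "occipito-temporal sulcus",
    "lateral temporal neocortex",
    "lateral frontal neocortex",
    "orbitofrontal",
    "insula",
    "putamen",
    "thalamus",
    "other",
)

TISSUE_KINDS = ("gray", "white", "other")

CHANNEL_KINDS = ("meg_mag", "seeg_bipolar", "aux")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """Multichannel time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Field values; fT for MEG magnetometers, µV for bipolar SEEG.
    fs : float
        Sampling rate in Hz (> 0).
    channel_ids : sequence of str
        Unique channel identifiers, one per data row.
    channel_kinds : sequence of str
        One of :data:`CHANNEL_KINDS` per channel (a single string is
        broadcast to all channels).
    t0 : float
        Time of the first sample, in seconds of this recording's own clock.
    """

    data: np.ndarray
    fs: float
    channel_ids: Sequence[str]
    channel_kinds: Sequence[str] | str = "meg_mag"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        self.channel_ids = list(self.channel_ids)
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if self.data.shape[0] != len(self.channel_ids):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_ids)} channel ids were given"
            )
        if isinstance(self.channel_kinds, str):
            self.channel_kinds = [self.channel_kinds] * len(self.channel_ids)
        self.channel_kinds = list(self.channel_kinds)
        for kind in self.channel_kinds:
            if kind not in CHANNEL_KINDS:
                raise ValueError(f"unknown channel kind {kind!r}")
        if len(self.channel_kinds) != len(self.channel_ids):
            raise ValueError("channel_kinds length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def pick(self, channel_ids: Sequence[str]) -> "Recording":
        idx = [self.channel_ids.index(c) for c in channel_ids]
        return Recording(
            self.data[idx],
            self.fs,
            [self.channel_ids[i] for i in idx],
            [self.channel_kinds[i] for i in idx],
            self.t0,
        )


@dataclass
class EventMarkers:
    """Instantaneous spike markers.

    ``times`` are strictly increasing seconds in the clock of the system on
    which the spikes were marked (SEEG); ``structures`` hold the anatomical
    label of the marked structure, ``channels`` the source SEEG channel.
    """

    times: np.ndarray
    structures: Sequence[str]
    channels: Sequence[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.structures = list(self.structures)
        self.channels = list(self.channels)
        if not (len(self.times) == len(self.structures) == len(self.channels)):
            raise ValueError("times/structures/channels lengths differ")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("marker times must be strictly increasing")
        for s in self.structures:
            if s not in ANATOMY_VOCABULARY:
                raise ValueError(f"unknown structure label {s!r}")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Contact:
    """A single SEEG contact."""

    contact_id: str
    electrode: str
    index: int  # on-electrode index; 1 = deepest / most mesial
    position_mm: tuple[float, float, float]
    label: str
    tissue: str


@dataclass(frozen=True)
class BipolarChannel:
    """Difference of two adjacent contacts on one electrode."""

    channel_id: str
    anode: Contact  # deeper contact (lower on-electrode index)
    cathode: Contact
    label: str  # anatomical label attributed to the channel

    @property
    def midpoint_mm(self) -> np.ndarray:
        return (
            np.asarray(self.anode.position_mm) + np.asarray(self.cathode.position_mm)
        ) / 2.0


@dataclass
class ContactMontage:
    contacts: list[Contact]
    bipolar_channels: list[BipolarChannel] = field(default_factory=list)

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.bipolar_channels]

    def channel(self, channel_id: str) -> BipolarChannel:
        for ch in self.bipolar_channels:
            if ch.channel_id == channel_id:
                return ch
        raise KeyError(channel_id)

    def channels_for_label(self, label: str) -> list[BipolarChannel]:
        return [c for c in self.bipolar_channels if c.label == label]


@dataclass
class Epochs:
    """Fixed-length trials cut around instantaneous markers.

    ``data`` has shape (n_trials, n_channels, n_samples); the window is a
    closed symmetric interval around each marker with an odd sample count,
    the centre sample being the marker sample (nearest-sample convention).
    ``marker_index_map`` maps trial index -> original marker index, so that
    dropped edge trials keep the correspondence.
    """

    data: np.ndarray
    window: float
    fs: float
    marker_index_map: list[int]
    channel_ids: Sequence[str] | None = None

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def rel_times(self) -> np.ndarray:
        half = (self.n_samples - 1) // 2
        return (np.arange(self.n_samples) - half) / self.fs

    def concatenate(self) -> np.ndarray:
        """Trials concatenated along time -> (n_channels, n_trials*n_samples)."""
        return np.concatenate(list(self.data), axis=-1)


@dataclass
class ClockModel:
    """Affine map between two acquisition clocks: ``b = offset + drift * a``."""

    offset: float
    drift: float
    residual_rms: float

    def a_to_b(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.offset + self.drift * np.asarray(t, dtype=float)

    def b_to_a(self, t: np.ndarray | float) -> np.ndarray | float:
        return (np.asarray(t, dtype=float) - self.offset) / self.drift


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def build_bipolar_montage(contacts: Iterable[Contact]) -> ContactMontage:
    """Construct bipolar channels from adjacent contacts of each electrode.

    One channel is created per adjacent contact pair having at least one
    gray-matter contact. The channel label is attributed to the more mesial
    (deeper, lower-indexed) gray contact of the pair, since correlated
    activity is conventionally ascribed to the deepest gray contact of the
    derivation. Electrodes with fewer than two contacts yield no channels.
    """
    contacts = list(contacts)
    for c in contacts:
        if c.tissue not in TISSUE_KINDS:
            raise ValueError(f"unknown tissue label {c.tissue!r} on {c.contact_id}")
    by_electrode: dict[str, list[Contact]] = {}
    for c in contacts:
        by_electrode.setdefault(c.electrode, []).append(c)
    channels: list[BipolarChannel] = []
    for electrode in sorted(by_electrode):
        elec_contacts = sorted(by_electrode[electrode], key=lambda c: c.index)
        for deep, shallow in zip(elec_contacts[:-1], elec_contacts[1:]):
            if shallow.index != deep.index + 1:
                continue  # non-adjacent gap in the contact numbering
            grays = [c for c in (deep, shallow) if c.tissue == "gray"]
            if not grays:
                continue
            label = grays[0].label  # deeper gray contact first in (deep, shallow)
            channels.append(
                BipolarChannel(
                    channel_id=f"{deep.contact_id}-{shallow.contact_id}",
                    anode=deep,
                    cathode=shallow,
                    label=label,
                )
            )
    return ContactMontage(contacts=contacts, bipolar_channels=channels)


def align_clocks(triggers_a: np.ndarray, triggers_b: np.ndarray) -> ClockModel:
    """Least-squares affine co-registration of two trigger time series.

    Both systems receive the same physical triggers; fitting
    ``b ~ offset + drift * a`` recovers the clock offset and relative drift.
    """
    a = np.asarray(triggers_a, dtype=float)
    b = np.asarray(triggers_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("trigger sequences must be 1-D and matched in length")
    if len(a) < 3:
        raise ValueError("at least 3 matched triggers are required")
    if not (np.all(np.diff(a) > 0) and np.all(np.diff(b) > 0)):
        raise ValueError("trigger times must be strictly increasing")
    design = np.column_stack([np.ones_like(a), a])
    coef, _, _, _ = np.linalg.lstsq(design, b, rcond=None)
    offset, drift = float(coef[0]), float(coef[1])
    residuals = b - (offset + drift * a)
    return ClockModel(offset, drift, float(np.sqrt(np.mean(residuals**2))))


def extract_epochs(
    rec: Recording,
    markers: EventMarkers | np.ndarray,
    window: float,
) -> Epochs:
    """Cut fixed-length trials centred on instantaneous markers.

    The window is the closed interval [-window/2, +window/2]; each trial has
    ``2*floor(window/2*fs) + 1`` samples so that the marker falls on the
    centre sample (nearest-sample mapping). Markers too close to a recording
    edge are dropped with a warning; ``marker_index_map`` records survivors.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    times = markers.times if isinstance(markers, EventMarkers) else np.asarray(markers)
    half = int(np.floor(window / 2.0 * rec.fs))
    centers = np.rint((times - rec.t0) * rec.fs).astype(int)
    trials = []
    kept: list[int] = []
    for i, c in enumerate(centers):
        if c - half < 0 or c + half >= rec.n_samples:
            warnings.warn(
                f"marker {i} at t={times[i]:.3f}s too close to a recording edge; "
                "trial dropped",
                stacklevel=2,
            )
            continue
        trials.append(rec.data[:, c - half : c + half + 1])
        kept.append(i)
    data = (
        np.stack(trials)
        if trials
        else np.empty((0, rec.n_channels, 2 * half + 1))
    )
    return Epochs(
        data=data,
        window=window,
        fs=rec.fs,
        marker_index_map=kept,
        channel_ids=list(rec.channel_ids),
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_MARKER_COLUMNS = ("time_s", "structure", "channel")
_MONTAGE_COLUMNS = (
    "contact_id",
    "electrode",
    "index",
    "x_mm",
    "y_mm",
    "z_mm",
    "label",
    "tissue",
)


class SchemaError(ValueError):
    """A table is missing a mandatory column or contains a malformed row."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} table is missing mandatory column {col!r}")


def write_markers(markers: EventMarkers, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": markers.times,
            "structure": markers.structures,
            "channel": markers.channels,
        }
    ).to_csv(path, sep="\t", index=False)


def read_markers(path: str | Path) -> EventMarkers:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _check_columns(df, _MARKER_COLUMNS, "marker")
    times = np.empty(len(df))
    for i, raw in enumerate(df["time_s"]):
        try:
            times[i] = float(raw)
        except (TypeError, ValueError) as exc:
            # +2: one for the header line, one for 1-based numbering
            raise SchemaError(f"malformed time_s value {raw!r} at line {i + 2}") from exc
    return EventMarkers(times, list(df["structure"]), list(df["channel"]))


def write_montage_table(montage: ContactMontage, path: str | Path) -> None:
    rows = [
        {
            "contact_id": c.contact_id,
            "electrode": c.electrode,
            "index": c.index,
            "x_mm": c.position_mm[0],
            "y_mm": c.position_mm[1],
            "z_mm": c.position_mm[2],
            "label": c.label,
            "tissue": c.tissue,
        }
        for c in montage.contacts
    ]
    pd.DataFrame(rows, columns=list(_MONTAGE_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_montage_table(path: str | Path) -> ContactMontage:
    """Read a contact table and rebuild the bipolar montage from it."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _check_columns(df, _MONTAGE_COLUMNS, "montage")
    contacts = []
    for i, row in df.iterrows():
        try:
            contacts.append(
                Contact(
                    contact_id=str(row["contact_id"]),
                    electrode=str(row["electrode"]),
                    index=int(row["index"]),
                    position_mm=(
                        float(row["x_mm"]),
                        float(row["y_mm"]),
                        float(row["z_mm"]),
                    ),
                    label=str(row["label"]),
                    tissue=str(row["tissue"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"malformed montage row at line {i + 2}") from exc
    return build_bipolar_montage(contacts)


def write_recording(rec: Recording, prefix: str | Path) -> None:
    """Store a recording as ``<prefix>.npy`` + ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), rec.data)
    sidecar = {
        "fs": rec.fs,
        "channel_ids": list(rec.channel_ids),
        "channel_kinds": list(rec.channel_kinds),
        "t0": rec.t0,
        "units": {"meg_mag": "fT", "seeg_bipolar": "uV", "aux": "a.u."},
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(prefix: str | Path) -> Recording:
    prefix = Path(prefix)
    data = np.load(prefix.with_suffix(".npy"))
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    for key in ("fs", "channel_ids", "channel_kinds", "t0"):
        if key not in sidecar:
            raise SchemaError(f"recording sidecar is missing mandatory field {key!r}")
    return Recording(
        data,
        sidecar["fs"],
        sidecar["channel_ids"],
        sidecar["channel_kinds"],
        sidecar["t0"],
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, required: Sequence[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if required:
        _check_columns(df, required, "result")
    return df
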