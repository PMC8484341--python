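"""Pulse-shape binary I/O, H/A/W derivation, and event-table linkage.

The instrument records one pulse shape (PS) per event and channel: at
defaults, 8 channels x 80 samples of 16-bit ADC counts, sampled at 10 MHz
over an 8 microsecond window with the acquisition trigger at 2 microseconds.
Pulses are stored raw (not baseline-subtracted); a linked FCS 3.0 list-mode
file carries the conventional per-channel height/area/width parameters and
the fluorescence scalars used as reference labels.

The ``.psb`` container defined here is versioned and fixed-stride so that
event *i* can be seeked in O(1):

    magic ``PSB1`` | version u16 | sampling_rate f64 | window_us f64 |
    trigger_us f64 | lowpass_hz f64 | n_channels u16 | adc_bits u16 |
    per channel: name length u8 + ASCII name | n_events u64 |
    per event: event_id u32 + n_channels*n_samples u16 samples

All integers and floats are little-endian.
"""

from __future__ import annotations

import logging
import struct
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, CorruptionError, FormatError, LinkageError
from .fcs import read_fcs, write_fcs

logger = logging.getLogger(__name__)

_MAGIC = b"PSB1"
_VERSION = 1

DEFAULT_CHANNELS = ("SSC", "FSCL", "FSCM", "FSCU", "FL-PI", "FL-FITC", "AUX1", "AUX2")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Digitizer settings for pulse-shape recording.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (default 10 MHz, i.e. 0.1 us resolution).
    window_us : float
        Length of the recorded window in microseconds (default 8, max 16).
    trigger_time_us : float
        Position of the trigger point inside the window (default 2 us).
    n_channels : int
        Number of detection channels (default 8).
    adc_bits : int
        ADC resolution; samples live in ``[0, 2**adc_bits - 1]``.
    lowpass_cutoff : float
        Analog low-pass cutoff in Hz applied before digitization (7 MHz).
    channel_names : tuple of str
        Detector labels in storage order.
    """

    sampling_rate: float = 1e7
    window_us: float = 8.0
    trigger_time_us: float = 2.0
    n_channels: int = 8
    adc_bits: int = 16
    lowpass_cutoff: float = 7e6
    channel_names: tuple = DEFAULT_CHANNELS

    def __post_init__(self):
        ns = self.window_us * 1e-6 * self.sampling_rate
        if not (ns > 0 and abs(ns - round(ns)) < 1e-9):
            raise ContractError(
                f"window x sampling_rate must be a positive integer number of "
                f"samples, got {ns}"
            )
        if self.window_us > 16.0:
            raise ContractError("window exceeds the 16 us maximum trigger window")
        if not 0 <= self.trigger_time_us < self.window_us:
            raise ContractError("trigger time must fall inside the window")
        if len(self.channel_names) != self.n_channels:
            raise ContractError("channel_names length must equal n_channels")

    @property
    def n_samples(self) -> int:
        return int(round(self.window_us * 1e-6 * self.sampling_rate))

    @property
    def sample_period_us(self) -> float:
        return 1e6 / self.sampling_rate

    @property
    def trigger_index(self) -> int:
        return int(round(self.trigger_time_us * 1e-6 * self.sampling_rate))

    @property
    def adc_max(self) -> int:
        return 2 ** self.adc_bits - 1

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ContractError(f"unknown channel {name!r}; have {self.channel_names}")


@dataclass
class PulseDataset:
    """Per-event multichannel pulse matrices plus acquisition metadata."""

    config: AcquisitionConfig
    data: np.ndarray  # (n_events, n_channels, n_samples) uint16
    event_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.event_ids is None:
            self.event_ids = np.arange(self.data.shape[0], dtype=np.uint32)
        self.event_ids = np.asarray(self.event_ids, dtype=np.uint32)
        self.validate()

    def validate(self):
        if self.data.ndim != 3:
            raise ContractError("data must be (n_events, n_channels, n_samples)")
        n_events, n_channels, n_samples = self.data.shape
        if n_channels != self.config.n_channels:
            raise ContractError("channel count disagrees with config")
        if n_samples != self.config.n_samples:
            raise ContractError(
                f"n_samples {n_samples} disagrees with config ({self.config.n_samples})"
            )
        if self.data.dtype != np.uint16:
            if self.data.min(initial=0) < 0 or self.data.max(initial=0) > self.config.adc_max:
                raise ContractError("samples outside ADC range")
            self.data = self.data.astype(np.uint16)
        if self.config.adc_bits < 16 and self.data.size and self.data.max() > self.config.adc_max:
            raise ContractError("samples outside ADC range")
        if len(self.event_ids) != n_events:
            raise ContractError("event_ids length disagrees with data")
        if n_events > 1 and not np.all(np.diff(self.event_ids.astype(np.int64)) > 0):
            raise ContractError("event_ids must be strictly increasing")

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """All pulses of one channel as a float array, shape (n_events, n_samples)."""
        return self.data[:, self.config.channel_index(name), :].astype(np.float64)

    def __eq__(self, other):
        return (
            isinstance(other, PulseDataset)
            and self.config == other.config
            and np.array_equal(self.event_ids, other.event_ids)
            and np.array_equal(self.data, other.data)
        )


@dataclass(frozen=True)
class HAWRecord:
    """Conventional list-mode parameters of a single pulse."""

    height: float  # ADC counts above baseline
    area: float    # counts * us above baseline
    width: float   # us, between fractional-height crossings


# ---------------------------------------------------------------------------
# .psb container


def write_psb(dataset: PulseDataset, destination) -> None:
    """Write a :class:`PulseDataset` to the versioned ``.psb`` binary format."""
    dataset.validate()
    cfg = dataset.config
    with open(destination, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<H", _VERSION))
        fh.write(struct.pack(
            "<ddddHH",
            cfg.sampling_rate, cfg.window_us, cfg.trigger_time_us,
            cfg.lowpass_cutoff, cfg.n_channels, cfg.adc_bits,
        ))
        for name in cfg.channel_names:
            enc = name.encode("ascii")
            fh.write(struct.pack("<B", len(enc)))
            fh.write(enc)
        fh.write(struct.pack("<Q", dataset.n_events))
        payload = dataset.data.reshape(dataset.n_events, -1)
        for eid, row in zip(dataset.event_ids, payload):
            fh.write(struct.pack("<I", int(eid)))
            fh.write(row.astype("<u2").tobytes())


def read_psb(source) -> PulseDataset:
    """Read a ``.psb`` file, restoring all dataset invariants.

    Raises :class:`FormatError` on a bad magic/version and
    :class:`CorruptionError` (with the byte offset) on a truncated payload.
    """
    with open(source, "rb") as fh:
        raw = fh.read()
    if raw[:4] != _MAGIC:
        raise FormatError(f"not a .psb file (magic {raw[:4]!r})")
    (version,) = struct.unpack_from("<H", raw, 4)
    if version != _VERSION:
        raise FormatError(f"unsupported .psb version {version}")
    off = 6
    rate, window, trigger, lowpass, n_channels, adc_bits = struct.unpack_from("<ddddHH", raw, off)
    off += struct.calcsize("<ddddHH")
    names = []
    for _ in range(n_channels):
        (ln,) = struct.unpack_from("<B", raw, off)
        off += 1
        names.append(raw[off:off + ln].decode("ascii"))
        off += ln
    (n_events,) = struct.unpack_from("<Q", raw, off)
    off += 8
    config = AcquisitionConfig(
        sampling_rate=rate, window_us=window, trigger_time_us=trigger,
        n_channels=n_channels, adc_bits=adc_bits, lowpass_cutoff=lowpass,
        channel_names=tuple(names),
    )
    n_samples = config.n_samples
    stride = 4 + 2 * n_channels * n_samples
    expected = off + stride * n_events
    if len(raw) < expected:
        raise CorruptionError(
            f"truncated payload: expected {expected} bytes, file has {len(raw)}",
            byte_offset=len(raw),
        )
    event_ids = np.empty(n_events, dtype=np.uint32)
    data = np.empty((n_events, n_channels, n_samples), dtype=np.uint16)
    for i in range(n_events):
        (event_ids[i],) = struct.unpack_from("<I", raw, off)
        off += 4
        data[i] = np.frombuffer(raw, dtype="<u2", count=n_channels * n_samples, offset=off)\
            .reshape(n_channels, n_samples)
        off += 2 * n_channels * n_samples
    return PulseDataset(config=config, data=data, event_ids=event_ids)


# ---------------------------------------------------------------------------
# H/A/W derivation


def estimate_baseline(pulse: np.ndarray, n_pre: int = 5) -> float:
    """Baseline estimate: median of the first ``n_pre`` pre-trigger samples."""
    pulse = np.asarray(pulse, dtype=np.float64)
    return float(np.median(pulse[..., :n_pre], axis=-1))


def derive_haw(
    pulse: np.ndarray,
    config: AcquisitionConfig,
    baseline: float | None = None,
    width_fraction: float = 0.5,
) -> HAWRecord:
    """Derive height, area and width from a single pulse.

    Height is the maximum above baseline; area integrates the
    baseline-subtracted pulse (negative excursions clipped at zero) over
    time; width is the time between the first and last crossings of
    ``baseline + width_fraction * height``, linearly interpolated between
    samples (FWHM at the default fraction of 0.5).
    """
    pulse = np.asarray(pulse, dtype=np.float64)
    if pulse.ndim != 1 or len(pulse) != config.n_samples:
        raise ContractError(f"pulse must have {config.n_samples} samples")
    if not 0 < width_fraction < 1:
        raise ContractError("width_fraction must lie strictly between 0 and 1")
    if baseline is None:
        baseline = estimate_baseline(pulse)
    dt = config.sample_period_us
    x = pulse - baseline
    height = float(x.max())
    if height <= 0:
        return HAWRecord(height=max(height, 0.0), area=0.0, width=0.0)
    area = float(np.clip(x, 0, None).sum() * dt)
    level = width_fraction * height
    above = x >= level
    idx = np.flatnonzero(above)
    first, last = idx[0], idx[-1]
    # linear interpolation toward the neighbouring sub-level samples
    if first == 0:
        t_first = 0.0
    else:
        x0, x1 = x[first - 1], x[first]
        t_first = (first - 1 + (level - x0) / (x1 - x0)) * dt
    if last == len(x) - 1:
        t_last = (len(x) - 1) * dt
    else:
        x0, x1 = x[last], x[last + 1]
        t_last = (last + (x0 - level) / (x0 - x1)) * dt
    return HAWRecord(height=height, area=area, width=float(t_last - t_first))


def derive_haw_table(
    dataset: PulseDataset,
    channels: list[str] | None = None,
    width_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-event H/A/W for every requested channel, as ``<CH>-H/-A/-W`` columns."""
    channels = list(channels) if channels is not None else list(dataset.config.channel_names)
    out = {"event_id": dataset.event_ids.astype(np.int64)}
    for ch in channels:
        pulses = dataset.channel(ch)
        h = np.empty(dataset.n_events)
        a = np.empty(dataset.n_events)
        w = np.empty(dataset.n_events)
        for i, p in enumerate(pulses):
            rec = derive_haw(p, dataset.config, width_fraction=width_fraction)
            h[i], a[i], w[i] = rec.height, rec.area, rec.width
        out[f"{ch}-H"] = h
        out[f"{ch}-A"] = a
        out[f"{ch}-W"] = w
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# FCS 3.0 list-mode export / import


def export_fcs(events: pd.DataFrame, destination, extra_keywords: dict | None = None) -> None:
    """Write an event table to a standards-valid FCS 3.0 file.

    Every numeric column becomes one parameter; ``event_id`` is stored as the
    ``EVENT_ID`` parameter so the file can be re-linked to its pulse data.
    Non-numeric columns (flags, labels) are not exported.
    """
    cols = [c for c in events.columns if pd.api.types.is_numeric_dtype(events[c])]
    frame = events[cols].rename(columns={"event_id": "EVENT_ID"})
    write_fcs(destination, frame, extra_keywords=extra_keywords)


def import_fcs(source) -> pd.DataFrame:
    """Read an FCS 3.0 file back into an event table."""
    _, frame = read_fcs(source)
    if "EVENT_ID" in frame.columns:
        frame = frame.rename(columns={"EVENT_ID": "event_id"})
        frame["event_id"] = frame["event_id"].round().astype(np.int64)
    return frame


# ---------------------------------------------------------------------------
# Linkage


def link_events(fcs_table: pd.DataFrame, pulses: PulseDataset) -> tuple[pd.DataFrame, PulseDataset]:
    """Inner-join the list-mode table with the pulse file on ``event_id``.

    Events present in only one source are reported (warning + log) and
    dropped; the output follows the pulse-file event order. Returns the
    joined table and the pulse dataset restricted to the common events.
    """
    if "event_id" not in fcs_table.columns:
        raise ContractError("fcs_table must carry an event_id column")
    fcs_ids = set(fcs_table["event_id"].astype(int))
    pulse_ids = pulses.event_ids.astype(np.int64)
    common_mask = np.fromiter((int(i) in fcs_ids for i in pulse_ids), dtype=bool,
                              count=len(pulse_ids))
    common = pulse_ids[common_mask]
    if common.size == 0:
        raise LinkageError("no common event ids between FCS table and pulse file")
    dropped_fcs = sorted(fcs_ids - set(common.tolist()))
    dropped_psb = sorted(set(pulse_ids.tolist()) - set(common.tolist()))
    if dropped_fcs or dropped_psb:
        msg = (f"linkage dropped {len(dropped_fcs)} FCS-only and {len(dropped_psb)} "
               f"pulse-only events (FCS-only ids: {dropped_fcs[:20]}...)" if len(dropped_fcs) > 20
               else f"linkage dropped {len(dropped_fcs)} FCS-only events {dropped_fcs} and "
                    f"{len(dropped_psb)} pulse-only events {dropped_psb}")
        warnings.warn(msg)
        logger.info(msg)
    table = fcs_table.set_index("event_id").loc[common].reset_index()
    subset = PulseDataset(
        config=pulses.config,
        data=pulses.data[common_mask],
        event_ids=pulses.event_ids[common_mask],
    )
    return table, subset
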