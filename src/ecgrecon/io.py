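"""Multichannel ECG records: container, CSV/WFDB I/O and lead derivation.

Amplitudes are millivolts everywhere inside the package; microvolts appear
only in reported figures of merit.  Samples are 0-based and intervals are
half-open ``[start, end)``.

Two on-disk formats are supported:

* CSV — comma separated, a header row of channel names, one sample per row,
  ``.`` decimal separator.  The sampling rate travels in a ``<stem>.meta.json``
  sidecar written by :func:`write_record` (or is passed explicitly to
  :func:`read_record`).
* WFDB — a minimal single-segment subset (``.hea`` header plus interleaved
  little-endian format-16 ``.dat``), honouring per-signal gain, baseline and
  physical units (mV, uV/µV or V).  Round-trip accuracy is limited by 16-bit
  quantisation: with the auto-chosen gain the error is below half an LSB,
  i.e. ``max|x| / 64000`` mV per channel.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    LeadDefinitionError,
    RecordFormatError,
    UnsupportedUnitError,
)

__all__ = [
    "EcgRecord",
    "LeadDefinition",
    "read_record",
    "write_record",
    "derive_leads",
    "LIMB_LEAD_DEFS",
    "precordial_lead_defs",
    "standard_12_defs",
    "EASI_LEAD_DEFS",
    "PROPOSED_LEAD_DEFS",
    "STANDARD_12_LEAD_NAMES",
]


@dataclass
class EcgRecord:
    """A multichannel sampled waveform.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (Hz), strictly positive.
    channels : list of str
        Ordered, unique channel names.
    signals : ndarray, shape (n_channels, n_samples)
        Amplitudes in millivolts; one row per channel.
    record_id : str
        Free-text label.
    """

    sampling_rate: float
    channels: list[str]
    signals: np.ndarray
    record_id: str = ""

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channels) == 0:
            raise ValueError("record must have at least one channel")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if self.signals.shape[0] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channel names but "
                f"{self.signals.shape[0]} signal rows"
            )
        if self.signals.shape[1] < 1:
            raise ValueError("record must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        """Return the sample row for a named channel."""
        try:
            return self.signals[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not in record") from None

    def subset(self, names: Sequence[str]) -> np.ndarray:
        """Stack the named channels into a (len(names), N) matrix."""
        return np.vstack([self.channel(n) for n in names])

    def with_signals(self, signals: np.ndarray) -> "EcgRecord":
        """Copy of the record with replaced sample data (same channels)."""
        return EcgRecord(self.sampling_rate, list(self.channels), signals,
                         self.record_id)


@dataclass
class LeadDefinition:
    """A lead as a signed weighted sum of electrode (or channel) potentials."""

    name: str
    terms: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"lead {self.name!r} has no terms")
        weights = np.array([w for _, w in self.terms], dtype=float)
        if not np.all(np.isfinite(weights)) or np.all(weights == 0):
            raise ValueError(
                f"lead {self.name!r} weights must be finite and not all zero"
            )


# --- built-in lead algebra -------------------------------------------------

#: Einthoven limb leads and Goldberger augmented leads from RA/LA/LL.
LIMB_LEAD_DEFS: list[LeadDefinition] = [
    LeadDefinition("I", [("LA", 1.0), ("RA", -1.0)]),
    LeadDefinition("II", [("LL", 1.0), ("RA", -1.0)]),
    LeadDefinition("III", [("LL", 1.0), ("LA", -1.0)]),
    LeadDefinition("aVR", [("RA", 1.0), ("LA", -0.5), ("LL", -0.5)]),
    LeadDefinition("aVL", [("LA", 1.0), ("RA", -0.5), ("LL", -0.5)]),
    LeadDefinition("aVF", [("LL", 1.0), ("RA", -0.5), ("LA", -0.5)]),
]


def precordial_lead_defs(
    electrodes: Sequence[str] = ("V1", "V2", "V3", "V4", "V5", "V6"),
) -> list[LeadDefinition]:
    """V1..V6 referenced to the Wilson central terminal (RA+LA+LL)/3."""
    wct = [("RA", -1.0 / 3.0), ("LA", -1.0 / 3.0), ("LL", -1.0 / 3.0)]
    return [LeadDefinition(e, [(e, 1.0), *wct]) for e in electrodes]


def standard_12_defs() -> list[LeadDefinition]:
    """The full Standard 12-Lead System from the ten electrode potentials."""
    return LIMB_LEAD_DEFS + precordial_lead_defs()


#: EASI reduced montage: three quasi-orthogonal leads from electrodes E/A/S/I.
EASI_LEAD_DEFS: list[LeadDefinition] = [
    LeadDefinition("ES", [("E", 1.0), ("S", -1.0)]),
    LeadDefinition("AS", [("A", 1.0), ("S", -1.0)]),
    LeadDefinition("AI", [("A", 1.0), ("I", -1.0)]),
]

#: Alternative montage: electrodes P7/P8 parasternal, B8 on the back, plus V2.
PROPOSED_LEAD_DEFS: list[LeadDefinition] = [
    LeadDefinition("P8-P7", [("P8", 1.0), ("P7", -1.0)]),
    LeadDefinition("V2-B8", [("V2", 1.0), ("B8", -1.0)]),
    LeadDefinition("P8-B8", [("P8", 1.0), ("B8", -1.0)]),
]

STANDARD_12_LEAD_NAMES: list[str] = [
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
]


def derive_leads(record: EcgRecord,
                 defs: Sequence[LeadDefinition]) -> EcgRecord:
    """Form lead voltages as weighted sums of a record's channels.

    Every electrode named in ``defs`` must exist as a channel of ``record``;
    missing names raise :class:`LeadDefinitionError` listing them.
    """
    missing = sorted(
        {name for d in defs for name, _ in d.terms
         if name not in record.channels}
    )
    if missing:
        raise LeadDefinitionError(
            f"unknown electrode name(s) in lead definitions: {missing}"
        )
    weights = np.zeros((len(defs), len(record.channels)))
    for k, d in enumerate(defs):
        for name, w in d.terms:
            weights[k, record.channels.index(name)] += w
    return EcgRecord(
        record.sampling_rate,
        [d.name for d in defs],
        weights @ record.signals,
        record.record_id,
    )


# --- CSV -------------------------------------------------------------------

def _csv_sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def _read_csv(path: Path, sampling_rate: float | None, scale: float,
              record_id: str | None) -> EcgRecord:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed shape / encoding
        raise RecordFormatError(f"cannot parse CSV {path}: {exc}") from exc
    bad = df.columns[~df.dtypes.map(
        lambda t: np.issubdtype(t, np.number))]
    if len(bad):
        col = bad[0]
        coerced = pd.to_numeric(df[col], errors="coerce")
        row = int(coerced.isna().idxmax())
        raise RecordFormatError(
            f"non-numeric cell in {path} at row {row + 2} "
            f"(1-based, incl. header), column {col!r}"
        )
    if sampling_rate is None:
        sidecar = _csv_sidecar(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            sampling_rate = float(meta["sampling_rate"])
            if record_id is None:
                record_id = meta.get("record_id")
        else:
            raise RecordFormatError(
                f"sampling rate for CSV {path} not given and no sidecar "
                f"{sidecar.name} found"
            )
    return EcgRecord(
        sampling_rate,
        [str(c) for c in df.columns],
        df.to_numpy(dtype=float).T * scale,
        record_id or path.stem,
    )


def _write_csv(record: EcgRecord, path: Path) -> Path:
    df = pd.DataFrame(record.signals.T, columns=record.channels)
    df.to_csv(path, index=False, float_format="%.8g")
    _csv_sidecar(path).write_text(json.dumps(
        {"sampling_rate": record.sampling_rate,
         "record_id": record.record_id}))
    return path


# --- minimal WFDB (single segment, format 16) ------------------------------

_UNIT_TO_MV = {"mV": 1.0, "uV": 1e-3, "µV": 1e-3, "V": 1e3}

# "gain(baseline)/units" with every part optional, per the WFDB header spec
_GAIN_RE = re.compile(
    r"^(?P<gain>[-+0-9.eE]+)?(?:\((?P<baseline>[-+0-9]+)\))?"
    r"(?:/(?P<units>\S+))?$"
)


def _wfdb_base(path: Path) -> Path:
    return path.with_suffix("") if path.suffix in (".hea", ".dat") else path


def _read_wfdb(path: Path, record_id: str | None) -> EcgRecord:
    base = _wfdb_base(path)
    hea = base.with_suffix(".hea")
    lines = [ln.strip() for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise RecordFormatError(f"{hea}: header line needs name/nsig/fs/nsamp")
    n_sig = int(head[1])
    fs = float(head[2])
    n_samples = int(head[3])
    names, gains, baselines, unit_scales = [], [], [], []
    dat_name = None
    for i, ln in enumerate(lines[1:1 + n_sig]):
        tok = ln.split()
        if len(tok) < 2:
            raise RecordFormatError(f"{hea}: bad signal line {i + 1}")
        dat_name = tok[0]
        if tok[1] != "16":
            raise RecordFormatError(
                f"{hea}: only WFDB format 16 is supported, got {tok[1]}"
            )
        gain, baseline, units = 200.0, 0, "mV"
        if len(tok) >= 3:
            m = _GAIN_RE.match(tok[2])
            if m is None:
                raise RecordFormatError(f"{hea}: bad gain spec {tok[2]!r}")
            if m.group("gain"):
                gain = float(m.group("gain"))
            if m.group("baseline"):
                baseline = int(m.group("baseline"))
            if m.group("units"):
                units = m.group("units")
        if units not in _UNIT_TO_MV:
            raise UnsupportedUnitError(
                f"{hea}: unsupported physical unit {units!r} "
                f"(supported: {sorted(_UNIT_TO_MV)})"
            )
        names.append(tok[-1] if len(tok) >= 9 else f"sig{i}")
        gains.append(gain)
        baselines.append(baseline)
        unit_scales.append(_UNIT_TO_MV[units])
    dat = base.parent / dat_name
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size != n_sig * n_samples:
        raise RecordFormatError(
            f"{dat}: expected {n_sig * n_samples} samples, found {raw.size}"
        )
    adc = raw.reshape(n_samples, n_sig).T.astype(float)
    signals = ((adc - np.array(baselines)[:, None])
               / np.array(gains)[:, None]
               * np.array(unit_scales)[:, None])
    return EcgRecord(fs, names, signals, record_id or base.stem)


def _write_wfdb(record: EcgRecord, path: Path) -> Path:
    base = _wfdb_base(path)
    n_sig, n_samples = record.signals.shape
    # per-channel gain so the signal spans most of the int16 range
    peak = np.maximum(np.abs(record.signals).max(axis=1), 1e-6)
    gains = 32000.0 / peak
    adc = np.rint(record.signals * gains[:, None]).astype("<i2")
    lines = [f"{base.stem} {n_sig} {record.sampling_rate:g} {n_samples}"]
    for k, name in enumerate(record.channels):
        checksum = int(adc[k].astype(np.int64).sum() % 65536)
        lines.append(
            f"{base.stem}.dat 16 {gains[k]:.6f}(0)/mV 16 0 "
            f"{int(adc[k, 0])} {checksum} 0 {name}"
        )
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    adc.T.tofile(base.with_suffix(".dat"))
    return base.with_suffix(".hea")


# --- public I/O ------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    if path.suffix == ".csv":
        return "csv"
    if path.suffix in (".hea", ".dat"):
        return "wfdb"
    raise RecordFormatError(
        f"cannot infer format of {path}; pass format='csv' or 'wfdb'"
    )


def read_record(path, format: str | None = None, *,
                sampling_rate: float | None = None,
                scale: float = 1.0,
                record_id: str | None = None) -> EcgRecord:
    """Read a record from CSV or (minimal) WFDB.

    Parameters
    ----------
    path : path-like
        ``.csv`` file, or a WFDB ``.hea``/``.dat`` path or record base name.
    format : {'csv', 'wfdb'}, optional
        Inferred from the suffix when omitted.
    sampling_rate : float, optional
        Required for CSV files without a ``.meta.json`` sidecar.  Ignored for
        WFDB (the header carries it).
    scale : float
        Multiplier applied to CSV amplitudes to convert them to millivolts
        (e.g. ``0.001`` for a file stated in microvolts).  Ignored for WFDB,
        whose units are honoured from the header.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    probe = path if fmt == "csv" else _wfdb_base(path).with_suffix(".hea")
    if not probe.exists():
        raise FileNotFoundError(f"record file not found: {probe}")
    if fmt == "csv":
        return _read_csv(path, sampling_rate, scale, record_id)
    if fmt == "wfdb":
        return _read_wfdb(path, record_id)
    raise RecordFormatError(f"unknown format {fmt!r}")


def write_record(record: EcgRecord, path, format: str | None = None) -> Path:
    """Write a record to CSV (plus sampling-rate sidecar) or WFDB.

    Returns the path of the written main file (.csv or .hea).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _write_csv(record, path)
    if fmt == "wfdb":
        return _write_wfdb(record, path)
    raise RecordFormatError(f"unknown format {fmt!r}")
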