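"""Reading, writing and validation of foot-mounted IMU recordings.

The on-disk dialect is deliberately plain: a block of ``# key=value`` header
lines followed by a CSV table with columns ``t, acc_x, acc_y, acc_z, gyr_x,
gyr_y, gyr_z``.  Acceleration may be stored in ``g`` or ``m/s2`` (converted to
m/s² at ingest, with ``G = 9.81`` m/s² per g exactly); angular rate is always
°/s.  Axis convention: x anterior (direction of progression at midstance),
y superior, z mediolateral, so the sagittal rotation is ``gyr_z``.

Values beyond the physical sensor ranges (±6 g accelerometer, ±500 °/s
gyroscope) are clipped at ingest — mirroring saturation of the hardware —
and counted in the recording's metadata rather than rejected.
"""

from __future__ import annotations

import io as _stdio
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Gravity constant used for the g ↔ m/s² conversion (exact, by convention).
G = 9.81

#: Accelerometer saturation bound, m/s² (±6 g sensor range).
ACC_RANGE = 6.0 * G

#: Gyroscope saturation bound, °/s (±500 °/s sensor range).
GYR_RANGE = 500.0

#: Nominal sampling rate of the wireless sensor platform, Hz.
DEFAULT_FS = 51.2

_DATA_COLUMNS = ["t", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"]


class FormatError(ValueError):
    """Malformed file: missing column, bad header, unparsable value."""


class RateError(ValueError):
    """Declared sampling rate disagrees with the expected rate."""


class DataError(ValueError):
    """Structurally valid file with invalid data (e.g. non-monotone time)."""


@dataclass
class ImuRecording:
    """One foot's 6-axis inertial signal for a single walk.

    Attributes
    ----------
    side : {"left", "right"}
    fs : float
        Sampling rate in Hz.
    t : ndarray, shape (n,)
        Sample timestamps in seconds; strictly increasing and uniform.
    acc : ndarray, shape (n, 3)
        Acceleration (specific force) in m/s², columns x, y, z.
    gyr : ndarray, shape (n, 3)
        Angular rate in °/s, columns x, y, z.
    subject_id, walk_id : str
        Opaque identifiers.
    meta : dict
        Free-form metadata (e.g. clipped-sample counts).
    """

    side: str
    fs: float
    t: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    subject_id: str = ""
    walk_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.side not in ("left", "right"):
            raise DataError(f"side must be 'left' or 'right', got {self.side!r}")
        if not self.fs > 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        n = self.t.shape[0]
        if n < 1:
            raise DataError("recording must contain at least one sample")
        if self.acc.shape != (n, 3) or self.gyr.shape != (n, 3):
            raise DataError(
                f"channel shape mismatch: t has {n} samples, "
                f"acc {self.acc.shape}, gyr {self.gyr.shape}"
            )
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise DataError("timestamps must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.fs)) > 1e-6:
                raise DataError("timestamps not uniform at the declared rate")
        tol = 1e-9
        if np.any(np.abs(self.acc) > ACC_RANGE + tol):
            raise DataError("acceleration exceeds the ±6 g sensor range")
        if np.any(np.abs(self.gyr) > GYR_RANGE + tol):
            raise DataError("angular rate exceeds the ±500 °/s sensor range")

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    @property
    def duration(self) -> float:
        """Recording duration, n / fs, in seconds."""
        return self.n_samples / self.fs


@dataclass
class GaitTemplate:
    """Multi-channel normalized stride signal used for msDTW matching.

    ``data`` has shape (length, n_channels) and is z-scored per channel.
    """

    channels: list[str]
    data: np.ndarray
    normalization: str = "zscore_per_channel"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] < 8:
            raise DataError("template must be at least 8 samples long")
        if self.data.shape[1] != len(self.channels):
            raise DataError("template channel count does not match data")
        if np.any(self.data.std(axis=0) < 1e-12):
            raise DataError("template has a constant channel after normalization")

    @property
    def length(self) -> int:
        return self.data.shape[0]


@dataclass
class SubjectRecord:
    """Clinical metadata for one subject at one visit.

    PD subjects carry Hoehn & Yahr stage and UPDRS-III fields; controls do
    not.  Enrolment required independent walking (H&Y < 4, gait item < 3);
    records violating this are flagged, not dropped.
    """

    subject_id: str
    group: str  # "PD" | "control"
    age: float | None = None
    height: float | None = None  # m
    weight: float | None = None  # kg
    hoehn_yahr: int | None = None
    updrs_iii_total: int | None = None
    gait_item: int | None = None
    postural_stability_item: int | None = None
    visit_date: str | None = None
    eligibility_flag: bool = False
    schema_warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in ("PD", "control"):
            raise DataError(f"group must be 'PD' or 'control', got {self.group!r}")


# ---------------------------------------------------------------------------
# recording format


def _parse_header(lines: Iterable[str]) -> dict:
    header = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if not body or "=" not in body:
            continue
        key, _, value = body.partition("=")
        header[key.strip()] = value.strip()
    return header


def read_imu_recording(path, expected_fs: float | None = None) -> ImuRecording:
    """Read a recording file, converting acceleration to m/s².

    Out-of-range samples are clipped to the sensor bounds; the number of
    clipped values is stored in ``meta['n_clipped_acc'/'n_clipped_gyr']``
    and reported through a warning.

    Raises
    ------
    FormatError
        Missing column or malformed header.
    RateError
        Declared fs differs from ``expected_fs`` by more than 0.1 %.
    DataError
        Non-monotone timestamps or other invariant violations.
    """
    path = Path(path)
    text = path.read_text()
    header_lines = [ln for ln in text.splitlines() if ln.startswith("#")]
    header = _parse_header(header_lines)

    for key in ("side", "fs"):
        if key not in header:
            raise FormatError(f"{path}: missing header key {key!r}")
    try:
        fs = float(header["fs"])
    except ValueError as exc:
        raise FormatError(f"{path}: unparsable fs {header['fs']!r}") from exc
    if expected_fs is not None and abs(fs - expected_fs) > 1e-3 * expected_fs:
        raise RateError(
            f"{path}: declared fs {fs} Hz differs from expected {expected_fs} Hz"
        )

    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("#"))
    try:
        df = pd.read_csv(_stdio.StringIO(body))
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: unparsable data table: {exc}") from exc
    missing = [c for c in _DATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if df[_DATA_COLUMNS].isna().any().any():
        raise DataError(f"{path}: non-numeric or missing values in data table")

    acc = df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float)
    gyr = df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy(dtype=float)
    acc_units = header.get("acc_units", "m/s2")
    if acc_units == "g":
        acc = acc * G
    elif acc_units not in ("m/s2", "m/s^2"):
        raise FormatError(f"{path}: unknown acc_units {acc_units!r}")
    gyr_units = header.get("gyr_units", "deg/s")
    if gyr_units not in ("deg/s", "°/s"):
        raise FormatError(f"{path}: unknown gyr_units {gyr_units!r}")

    n_clip_acc = int(np.sum(np.abs(acc) > ACC_RANGE))
    n_clip_gyr = int(np.sum(np.abs(gyr) > GYR_RANGE))
    if n_clip_acc or n_clip_gyr:
        warnings.warn(
            f"{path}: clipped {n_clip_acc} accelerometer and {n_clip_gyr} "
            "gyroscope samples to the sensor range",
            stacklevel=2,
        )
    acc = np.clip(acc, -ACC_RANGE, ACC_RANGE)
    gyr = np.clip(gyr, -GYR_RANGE, GYR_RANGE)

    return ImuRecording(
        side=header["side"],
        fs=fs,
        t=df["t"].to_numpy(dtype=float),
        acc=acc,
        gyr=gyr,
        subject_id=header.get("subject_id", ""),
        walk_id=header.get("walk_id", ""),
        meta={"n_clipped_acc": n_clip_acc, "n_clipped_gyr": n_clip_gyr},
    )


def write_imu_recording(rec: ImuRecording, path) -> Path:
    """Write ``rec`` in the columnar text dialect (full float precision)."""
    rec.validate()
    path = Path(path)
    header = [
        "# stridekit imu v1",
        f"# side={rec.side}",
        f"# fs={rec.fs!r}",
        "# acc_units=m/s2",
        "# gyr_units=deg/s",
        f"# subject_id={rec.subject_id}",
        f"# walk_id={rec.walk_id}",
        f"# n_samples={rec.n_samples}",
        f"# duration_s={rec.duration!r}",
    ]
    df = pd.DataFrame(
        np.column_stack([rec.t, rec.acc, rec.gyr]), columns=_DATA_COLUMNS
    )
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g", lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# stride templates


def write_template(template: GaitTemplate, path) -> Path:
    path = Path(path)
    header = [
        "# stridekit imu v1",
        "# template=true",
        f"# channels={','.join(template.channels)}",
        f"# normalization={template.normalization}",
    ]
    df = pd.DataFrame(template.data, columns=template.channels)
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g", lineterminator="\n")
    return path


def read_template(path) -> GaitTemplate:
    path = Path(path)
    text = path.read_text()
    header = _parse_header(ln for ln in text.splitlines() if ln.startswith("#"))
    if header.get("template", "false").lower() != "true":
        raise FormatError(f"{path}: not a template file (template=true missing)")
    channels = [c for c in header.get("channels", "").split(",") if c]
    if not channels:
        raise FormatError(f"{path}: template header lacks channels")
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("#"))
    df = pd.read_csv(_stdio.StringIO(body))
    missing = [c for c in channels if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing template column(s) {missing}")
    return GaitTemplate(
        channels=channels,
        data=df[channels].to_numpy(dtype=float),
        normalization=header.get("normalization", "zscore_per_channel"),
    )


# ---------------------------------------------------------------------------
# subject metadata tables

_SUBJECT_COLUMNS = {
    "subject_id": str,
    "group": str,
}
_PD_FIELDS = ("hoehn_yahr", "updrs_iii_total", "gait_item", "postural_stability_item")


def _opt_number(row, key, kind=float):
    value = row.get(key)
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        return kind(value)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"malformed numeric {key}={value!r}") from exc


def read_subject_table(path) -> list[SubjectRecord]:
    """Read a subject metadata CSV into validated :class:`SubjectRecord`s.

    PD rows violating the enrolment criteria (H&Y ≥ 4 or gait item ≥ 3) get
    ``eligibility_flag=True``; control rows carrying UPDRS/H&Y fields get a
    schema warning.  Neither is silently dropped.
    """
    df = pd.read_csv(path)
    missing = [c for c in _SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        row = row.to_dict()
        group = str(row["group"])
        rec = SubjectRecord(
            subject_id=str(row["subject_id"]),
            group=group,
            age=_opt_number(row, "age"),
            height=_opt_number(row, "height"),
            weight=_opt_number(row, "weight"),
            hoehn_yahr=_opt_number(row, "hoehn_yahr", int),
            updrs_iii_total=_opt_number(row, "updrs_iii_total", int),
            gait_item=_opt_number(row, "gait_item", int),
            postural_stability_item=_opt_number(row, "postural_stability_item", int),
            visit_date=None
            if row.get("visit_date") in (None, "")
            or (isinstance(row.get("visit_date"), float) and np.isnan(row["visit_date"]))
            else str(row["visit_date"]),
        )
        if group == "PD":
            if rec.hoehn_yahr is not None and rec.hoehn_yahr >= 4:
                rec.eligibility_flag = True
            if rec.gait_item is not None and rec.gait_item >= 3:
                rec.eligibility_flag = True
        else:
            present = [f for f in _PD_FIELDS if rec.__dict__[f] is not None]
            if present:
                rec.schema_warnings.append(
                    f"control row carries PD-only field(s): {', '.join(present)}"
                )
        records.append(rec)
    return records


def write_subject_table(records: Sequence[SubjectRecord], path) -> Path:
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "age": r.age,
                "height": r.height,
                "weight": r.weight,
                "hoehn_yahr": r.hoehn_yahr,
                "updrs_iii_total": r.updrs_iii_total,
                "gait_item": r.gait_item,
                "postural_stability_item": r.postural_stability_item,
                "visit_date": r.visit_date,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
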