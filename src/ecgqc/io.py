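"""Reading, writing and labelling of multi-lead ECG records.

Records are kept in *digital* units (raw ADC counts) end to end: the
downstream eigenvalue thresholds were learned on unscaled digital
amplitudes, so no gain conversion to millivolts is ever applied.

Supported on-disk formats are the WFDB header + signal pair (format 16,
the layout used by PhysioNet telemonitoring recordings) and plain CSV
with one column per lead.
"""

from __future__ import annotations

import enum
import os
import re
from fractions import Fraction
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InputError, MissingLeadError

#: The eight linearly independent leads of the standard 12-lead ECG, in
#: canonical analysis order.  Limb leads III, aVR, aVL and aVF are linear
#: combinations of I and II and are excluded from the analysis.
ANALYSIS_LEADS: tuple[str, ...] = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: Numerical value of each annotator letter grade.
GRADE_VALUES: dict[str, float] = {"A": 0.95, "B": 0.85, "C": 0.75, "D": 0.6, "F": 0.0}


class QualityLabel(str, enum.Enum):
    """Binary clinical-quality label: Acceptable or Unacceptable."""

    AC = "AC"
    UN = "UN"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class EcgRecord:
    """A multi-lead digitised ECG.

    Parameters
    ----------
    record_id
        Identifier of the record (file stem for on-disk records).
    sampling_rate
        Samples per second, identical for all leads.  Expected 500 Hz for
        10-second telemonitoring records but not enforced.
    lead_names
        One unique name per lead, in signal order.
    signals
        ``(n_leads, K)`` array of digital amplitudes (ADC counts).
    """

    record_id: str
    sampling_rate: float
    lead_names: list[str]
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise InputError("signals must be a 2-D (n_leads, K) array")
        if self.signals.shape[0] != len(self.lead_names):
            raise InputError(
                f"{len(self.lead_names)} lead names but "
                f"{self.signals.shape[0]} signal rows"
            )
        if self.signals.shape[1] < 2:
            raise InputError("records must hold at least 2 samples per lead")
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be positive")
        lowered = [name.lower() for name in self.lead_names]
        if len(set(lowered)) != len(lowered):
            raise InputError("lead names must be unique")

    @property
    def n_leads(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class LeadMatrix:
    """The 8 x K data matrix X of the analysis leads.

    Rows follow :data:`ANALYSIS_LEADS` order.  ``centered`` records whether
    each row has had its temporal mean removed.
    """

    values: np.ndarray
    centered: bool = False
    lead_names: tuple[str, ...] = field(default=ANALYSIS_LEADS)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(ANALYSIS_LEADS):
            raise InputError("LeadMatrix must be 8 x K")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# WFDB header + format-16 signal files
# ---------------------------------------------------------------------------

def _signed16(total: int) -> int:
    """Fold an integer into the signed 16-bit range (WFDB checksum rule)."""
    return ((int(total) & 0xFFFF) ^ 0x8000) - 0x8000


_GAIN_RE = re.compile(
    r"^(?P<gain>[-+0-9.eE]+)?(?:\((?P<baseline>[-+0-9]+)\))?(?:/(?P<units>\S+))?$"
)


def _parse_header(hea_path: str) -> tuple[str, int, float, int, list[dict]]:
    try:
        with open(hea_path) as fh:
            lines = [
                ln.strip()
                for ln in fh
                if ln.strip() and not ln.lstrip().startswith("#")
            ]
    except OSError as exc:
        raise InputError(f"cannot read WFDB header {hea_path!r}: {exc}") from exc
    if not lines:
        raise FormatError(f"WFDB header {hea_path!r} is empty")

    rec_fields = lines[0].split()
    if len(rec_fields) < 2:
        raise FormatError(f"malformed record line in {hea_path!r}: {lines[0]!r}")
    record_name = rec_fields[0].split("/")[0]
    try:
        n_sig = int(rec_fields[1])
        fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
        n_samp = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    except ValueError as exc:
        raise FormatError(f"malformed record line in {hea_path!r}") from exc

    if len(lines) - 1 < n_sig:
        raise FormatError(
            f"header {hea_path!r} declares {n_sig} signals but lists "
            f"{len(lines) - 1}"
        )

    specs = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split(None, 8)
        if len(parts) < 2:
            raise FormatError(f"malformed signal line in {hea_path!r}: {ln!r}")
        fmt = parts[1].split("x")[0].split(":")[0].split("+")[0]
        spec = {
            "filename": parts[0],
            "format": fmt,
            "checksum": int(parts[6]) if len(parts) > 6 else None,
            "description": parts[8].strip() if len(parts) > 8 else None,
        }
        if len(parts) > 2:
            m = _GAIN_RE.match(parts[2])
            spec["units"] = m.group("units") if m else None
        specs.append(spec)
    return record_name, n_sig, fs, n_samp, specs


def read_wfdb_record(path: str) -> EcgRecord:
    """Read a WFDB header/signal pair, returning raw digital amplitudes.

    ``path`` may point at the ``.hea`` file or at the record stem.  Only
    single-file format-16 records (interleaved 16-bit little-endian
    two's-complement samples) are supported; gain and baseline fields are
    deliberately *not* applied.
    """
    stem = path[:-4] if path.endswith(".hea") else path
    hea_path = stem + ".hea"
    if not os.path.exists(hea_path):
        raise InputError(f"WFDB header not found: {hea_path!r}")

    record_name, n_sig, fs, n_samp, specs = _parse_header(hea_path)

    fmts = {s["format"] for s in specs}
    if fmts != {"16"}:
        raise FormatError(
            f"unsupported WFDB signal format(s) {sorted(fmts)} in {hea_path!r}; "
            "only format 16 is supported"
        )
    filenames = {s["filename"] for s in specs}
    if len(filenames) != 1:
        raise FormatError(f"multi-file WFDB records are unsupported ({hea_path!r})")

    dat_path = os.path.join(os.path.dirname(hea_path), specs[0]["filename"])
    if not os.path.exists(dat_path):
        raise InputError(f"WFDB signal file not found: {dat_path!r}")
    raw = np.fromfile(dat_path, dtype="<i2")

    if raw.size % n_sig != 0:
        raise FormatError(
            f"signal file {dat_path!r} holds {raw.size} samples, not a "
            f"multiple of {n_sig} signals"
        )
    if n_samp and raw.size != n_sig * n_samp:
        raise FormatError(
            f"header declares {n_sig} x {n_samp} samples but signal file "
            f"{dat_path!r} holds {raw.size}"
        )

    signals = raw.reshape(-1, n_sig).T.astype(float)
    for i, spec in enumerate(specs):
        if spec["checksum"] is not None:
            actual = _signed16(signals[i].astype(np.int64).sum())
            if actual != spec["checksum"]:
                raise FormatError(
                    f"checksum mismatch on signal {i} of {dat_path!r} "
                    f"(header {spec['checksum']}, data {actual})"
                )

    lead_names = [
        spec["description"] if spec["description"] else f"sig{i}"
        for i, spec in enumerate(specs)
    ]
    return EcgRecord(
        record_id=record_name,
        sampling_rate=fs,
        lead_names=lead_names,
        signals=signals,
    )


def write_wfdb_record(record: EcgRecord, directory: str) -> tuple[str, str]:
    """Write ``record`` as a WFDB header + format-16 signal pair.

    Samples are rounded to the nearest integer and clipped to the 16-bit
    range before writing.  Returns the (header, signal) paths.
    """
    os.makedirs(directory, exist_ok=True)
    hea_path = os.path.join(directory, record.record_id + ".hea")
    dat_name = record.record_id + ".dat"
    dat_path = os.path.join(directory, dat_name)

    digital = np.clip(np.rint(record.signals), -32768, 32767).astype(np.int16)
    fs = record.sampling_rate
    fs_repr = f"{fs:g}"
    lines = [f"{record.record_id} {record.n_leads} {fs_repr} {record.n_samples}"]
    for i, name in enumerate(record.lead_names):
        checksum = _signed16(digital[i].astype(np.int64).sum())
        first = int(digital[i, 0])
        lines.append(f"{dat_name} 16 200/mV 16 0 {first} {checksum} 0 {name}")
    with open(hea_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    digital.T.reshape(-1).astype("<i2").tofile(dat_path)
    return hea_path, dat_path


# ---------------------------------------------------------------------------
# CSV records
# ---------------------------------------------------------------------------

def read_csv_record(
    path: str,
    sampling_rate: float,
    lead_names: list[str] | None = None,
    *,
    header: bool = False,
    delimiter: str = ",",
    record_id: str | None = None,
) -> EcgRecord:
    """Read a numeric CSV with one column per lead.

    With ``header=True`` the first row supplies the lead names; otherwise
    ``lead_names`` must be given.  Any non-numeric or missing cell is a
    format error — samples are never imputed.
    """
    if not os.path.exists(path):
        raise InputError(f"CSV record not found: {path!r}")
    try:
        frame = pd.read_csv(
            path, header=0 if header else None, sep=delimiter, comment="#"
        )
    except Exception as exc:
        raise FormatError(f"cannot parse CSV {path!r}: {exc}") from exc

    if header:
        lead_names = [str(c).strip() for c in frame.columns]
    if lead_names is None:
        raise InputError("lead_names is required when the CSV has no header row")
    if len(lead_names) != frame.shape[1]:
        raise FormatError(
            f"{len(lead_names)} lead names given but CSV {path!r} has "
            f"{frame.shape[1]} columns"
        )

    values = frame.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = int(np.isnan(values).sum())
        raise FormatError(
            f"CSV {path!r} contains {bad} non-numeric or missing cell(s); "
            "missing samples are rejected, not imputed"
        )

    rid = record_id or os.path.splitext(os.path.basename(path))[0]
    return EcgRecord(
        record_id=rid,
        sampling_rate=sampling_rate,
        lead_names=list(lead_names),
        signals=values.T,
    )


def write_csv_record(record: EcgRecord, path: str, *, header: bool = True) -> str:
    """Write a record as CSV, one column per lead."""
    frame = pd.DataFrame(record.signals.T, columns=record.lead_names)
    frame.to_csv(path, index=False, header=header)
    return path


def read_record(
    path: str,
    *,
    fmt: str | None = None,
    sampling_rate: float = 500.0,
    lead_names: list[str] | None = None,
    csv_header: bool = True,
) -> EcgRecord:
    """Dispatch on file extension (``.hea``/``.dat`` → WFDB, ``.csv`` → CSV)."""
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = "csv" if ext == ".csv" else "wfdb"
    if fmt == "wfdb":
        return read_wfdb_record(path)
    if fmt == "csv":
        return read_csv_record(
            path, sampling_rate, lead_names, header=csv_header
        )
    raise InputError(f"unknown record format {fmt!r}")


# ---------------------------------------------------------------------------
# Lead selection and annotation aggregation
# ---------------------------------------------------------------------------

def select_leads(record: EcgRecord) -> LeadMatrix:
    """Extract the 8 analysis leads in canonical order (uncentered).

    Lead-name matching is case-insensitive; extra leads (III, aVR, aVL,
    aVF, or anything else) are discarded.  The four derived limb leads add
    no information beyond quantisation noise, so the analysis rank is 8.
    """
    index = {name.lower(): i for i, name in enumerate(record.lead_names)}
    rows = []
    for lead in ANALYSIS_LEADS:
        i = index.get(lead.lower())
        if i is None:
            raise MissingLeadError(lead)
        rows.append(record.signals[i])
    return LeadMatrix(values=np.array(rows, dtype=float), centered=False)


def aggregate_annotations(grades: list[str]) -> QualityLabel:
    """Reduce annotator letter grades to the binary reference label.

    Grades map to A=0.95, B=0.85, C=0.75, D=0.6, F=0 and are averaged.
    The record is Acceptable iff at least two grades are available, the
    average exceeds 0.7, and at most one grade is F; otherwise (including
    an average of exactly 0.7, resolved conservatively) it is
    Unacceptable.  An empty grade list therefore yields UN.  The average
    is taken in exact rational arithmetic so the 0.7 boundary is sharp.
    """
    for g in grades:
        if g not in GRADE_VALUES:
            raise InputError(f"illegal grade {g!r}; expected one of A B C D F")
    if len(grades) < 2:
        return QualityLabel.UN
    # grade values in hundredths, exactly representable as integers
    mean = Fraction(sum(round(100 * GRADE_VALUES[g]) for g in grades), len(grades))
    n_f = sum(1 for g in grades if g == "F")
    if mean > 70 and n_f <= 1:
        return QualityLabel.AC
    return QualityLabel.UN
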