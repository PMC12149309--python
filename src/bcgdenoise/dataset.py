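"""Readers and writers for the published BCG dataset layout.

Each recording lives in a folder ``hdata<SubjectID><EJ|XJ|ZJ>`` where the
suffix names the M-mode echocardiography site (EJ = mitral valve, XJ =
left ventricle, ZJ = aortic valve) and contains:

* ``signal.csv`` — three headerless columns at 100 Hz: raw BCG, ECG,
  denoised BCG;
* ``<folder>_BCG.csv`` / ``<folder>_ECG.csv`` — J-peak / R-peak
  annotations as (sample index, time in seconds) pairs;
* ``<folder>_UCG.AVI`` and ``signal.pdf`` — enumerated, never decoded.

A sibling ``EF_ALLsubject`` folder holds one EF image per participant,
and a ``Subject_Info.xlsx`` table carries demographics.  Every reader
here has a matching writer so the whole pipeline is testable from
synthetic fixtures without downloading anything.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .beats import PeakAnnotations
from .signal_model import TimeSeries

__all__ = [
    "SITES",
    "SubjectRecord",
    "RecordingBundle",
    "DatasetReport",
    "parse_record_name",
    "format_record_name",
    "read_signal_csv",
    "write_signal_csv",
    "read_peak_csv",
    "write_peak_csv",
    "read_recording",
    "scan_dataset",
    "read_subject_info",
    "write_subject_info",
    "summarize_metadata",
]

logger = logging.getLogger(__name__)

SIGNAL_RATE_HZ = 100.0

#: folder-name suffix -> echocardiography site
SITES = {"EJ": "mitral_valve", "XJ": "left_ventricle", "ZJ": "aortic_valve"}
_SITE_TO_SUFFIX = {v: k for k, v in SITES.items()}
_NAME_RE = re.compile(r"^hdata(\d+)(EJ|XJ|ZJ)$")


@dataclass(frozen=True)
class SubjectRecord:
    """One row of the subject metadata table."""

    id: int
    sex: str
    weight: float  # kg
    height: float  # cm
    age: float  # years
    heart_rate: float  # bpm
    ef: float  # %
    group: str | None = None  # sinus | arrhythmia | hf when derivable

    def __post_init__(self) -> None:
        if not (0 < self.ef <= 100):
            raise ValueError(f"EF must be in (0, 100], got {self.ef}")
        if self.weight <= 0 or self.height <= 0:
            raise ValueError("weight and height must be positive")

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2


@dataclass(frozen=True)
class RecordingBundle:
    subject_id: int
    site: str
    raw_bcg: TimeSeries
    ecg: TimeSeries
    denoised_bcg: TimeSeries
    j_peaks: PeakAnnotations | None = None
    r_peaks: PeakAnnotations | None = None
    video_path: Path | None = None  # enumerated only, never decoded


@dataclass
class DatasetReport:
    n_recordings: int = 0
    per_site: dict = field(default_factory=lambda: {s: 0 for s in SITES.values()})
    subjects: set = field(default_factory=set)
    ef_folder_present: bool = False
    n_ef_images: int = 0
    missing_files: dict = field(default_factory=dict)  # folder -> [missing names]
    unrecognized: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_recordings": self.n_recordings,
            "per_site": dict(self.per_site),
            "n_subjects": len(self.subjects),
            "subjects": sorted(self.subjects),
            "ef_folder_present": self.ef_folder_present,
            "n_ef_images": self.n_ef_images,
            "missing_files": self.missing_files,
            "unrecognized": self.unrecognized,
        }


def parse_record_name(folder_name: str) -> tuple[int, str]:
    """Decode ``hdata<ID><EJ|XJ|ZJ>`` into (subject id, site)."""
    m = _NAME_RE.match(folder_name.strip())
    if not m:
        raise ValueError(
            f"folder name {folder_name!r} does not match the expected pattern 'hdata<ID><EJ|XJ|ZJ>'"
        )
    return int(m.group(1)), SITES[m.group(2)]


def format_record_name(subject_id: int, site: str) -> str:
    if site not in _SITE_TO_SUFFIX:
        raise ValueError(f"unknown site {site!r}; choose from {sorted(_SITE_TO_SUFFIX)}")
    return f"hdata{int(subject_id)}{_SITE_TO_SUFFIX[site]}"


def read_signal_csv(path: str | Path, rate: float = SIGNAL_RATE_HZ) -> tuple[TimeSeries, TimeSeries, TimeSeries]:
    """Read a 3-column ``signal.csv``: raw BCG, ECG, denoised BCG."""
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty signal file") from exc
    if df.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 columns (raw BCG, ECG, denoised BCG), found {df.shape[1]}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric value in column {col + 1}, row {bad[0] + 1}")
        if vals.isna().any():
            raise ValueError(f"{path}: missing value in column {col + 1}, row {int(vals.index[vals.isna()][0]) + 1}")
        df[col] = vals
    arr = df.to_numpy(dtype=np.float64)
    return tuple(TimeSeries(arr[:, i], rate) for i in range(3))


def write_signal_csv(path: str | Path, raw_bcg: TimeSeries, ecg: TimeSeries, denoised_bcg: TimeSeries) -> Path:
    if not (raw_bcg.n == ecg.n == denoised_bcg.n):
        raise ValueError("the three series must have equal length")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for a, b, c in zip(raw_bcg.values, ecg.values, denoised_bcg.values):
            fh.write(f"{repr(float(a))},{repr(float(b))},{repr(float(c))}\n")
    return path


def read_peak_csv(path: str | Path, rate: float = SIGNAL_RATE_HZ) -> PeakAnnotations:
    """Read a two-column (index, time_s) peak annotation file.

    Index/time cross-consistency is checked to within half a sample.  The
    index base is assumed 0; if a uniform 1-based interpretation fits the
    time column better the offset is corrected and logged.  Discrepancies
    beyond half a sample are logged as warnings, never fatal.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        return PeakAnnotations.from_indices(np.array([], dtype=np.int64), rate)
    df = pd.read_csv(path, header=None)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns (index, time_s), found {df.shape[1]}")
    idx = df[0].to_numpy(dtype=np.int64)
    times = df[1].to_numpy(dtype=np.float64)
    if np.any(np.diff(idx) <= 0):
        raise ValueError(f"{path}: peak indices are not strictly increasing")
    half = 0.5 / rate
    err0 = np.abs(idx / rate - times)
    err1 = np.abs((idx - 1) / rate - times)
    if np.all(err1 <= half) and not np.all(err0 <= half):
        logger.info("%s: indices fit the time column as 1-based; correcting by -1", path)
        idx = idx - 1
        err0 = err1
    n_bad = int(np.sum(err0 > half + 1e-9))
    if n_bad:
        logger.warning("%s: %d peak rows have index/time mismatch beyond half a sample", path, n_bad)
    return PeakAnnotations(idx, idx / rate, rate)


def write_peak_csv(path: str | Path, ann: PeakAnnotations) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i, t in zip(ann.indices, ann.times):
            fh.write(f"{int(i)},{t:.2f}\n")
    return path


def read_recording(folder: str | Path) -> RecordingBundle:
    """Load one ``hdata<ID><site>`` recording folder."""
    folder = Path(folder)
    subject_id, site = parse_record_name(folder.name)
    raw, ecg, den = read_signal_csv(folder / "signal.csv")
    j_path = folder / f"{folder.name}_BCG.csv"
    r_path = folder / f"{folder.name}_ECG.csv"
    video = folder / f"{folder.name}_UCG.AVI"
    return RecordingBundle(
        subject_id=subject_id,
        site=site,
        raw_bcg=raw,
        ecg=ecg,
        denoised_bcg=den,
        j_peaks=read_peak_csv(j_path) if j_path.exists() else None,
        r_peaks=read_peak_csv(r_path) if r_path.exists() else None,
        video_path=video if video.exists() else None,
    )


_EXPECTED_FILES = ("{name}_BCG.csv", "{name}_ECG.csv", "{name}_UCG.AVI", "signal.csv", "signal.pdf")


def scan_dataset(root: str | Path) -> DatasetReport:
    """Integrity scan of a dataset root: counts, coverage, missing files.

    Nothing is decoded from AVI/JPG beyond existence; missing items are
    reported, never raised.
    """
    root = Path(root)
    report = DatasetReport()
    if not root.exists():
        return report
    for entry in sorted(root.iterdir()):
        if not entry.is_dir():
            continue
        if entry.name == "EF_ALLsubject":
            report.ef_folder_present = True
            report.n_ef_images = sum(1 for p in entry.iterdir() if p.suffix.lower() in (".jpg", ".jpeg"))
            continue
        try:
            subject_id, site = parse_record_name(entry.name)
        except ValueError:
            report.unrecognized.append(entry.name)
            continue
        report.n_recordings += 1
        report.per_site[site] += 1
        report.subjects.add(subject_id)
        missing = [
            tmpl.format(name=entry.name)
            for tmpl in _EXPECTED_FILES
            if not (entry / tmpl.format(name=entry.name)).exists()
        ]
        if missing:
            report.missing_files[entry.name] = missing
    return report


# -- subject metadata ---------------------------------------------------------

_HEADER_MAP = {
    "id": "id",
    "subjectid": "id",
    "subject id": "id",
    "sex": "sex",
    "gender": "sex",
    "weight": "weight",
    "weight (kg)": "weight",
    "height": "height",
    "height (cm)": "height",
    "age": "age",
    "age (years)": "age",
    "heart rate": "heart_rate",
    "heart rate (bpm)": "heart_rate",
    "hr": "heart_rate",
    "hr (bpm)": "heart_rate",
    "ef": "ef",
    "ef (%)": "ef",
    "ef(%)": "ef",
    "group": "group",
}


def read_subject_info(path: str | Path) -> list[SubjectRecord]:
    """Read a ``Subject_Info.xlsx``-style metadata table (tolerant headers)."""
    df = pd.read_excel(path)
    renames = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in _HEADER_MAP:
            renames[col] = _HEADER_MAP[key]
    df = df.rename(columns=renames)
    required = {"id", "sex", "weight", "height", "age", "heart_rate", "ef"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata table is missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SubjectRecord(
                id=int(row["id"]),
                sex=str(row["sex"]),
                weight=float(row["weight"]),
                height=float(row["height"]),
                age=float(row["age"]),
                heart_rate=float(row["heart_rate"]),
                ef=float(row["ef"]),
                group=str(row["group"]) if "group" in df.columns and pd.notna(row.get("group")) else None,
            )
        )
    return records


def write_subject_info(path: str | Path, records: list[SubjectRecord]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "ID": [r.id for r in records],
            "Sex": [r.sex for r in records],
            "Weight (Kg)": [r.weight for r in records],
            "Height (cm)": [r.height for r in records],
            "Age (years)": [r.age for r in records],
            "Heart Rate (bpm)": [r.heart_rate for r in records],
            "EF (%)": [r.ef for r in records],
            "Group": [r.group for r in records],
        }
    )
    df.to_excel(path, index=False)
    return path


_SUMMARY_VARS = ("age", "height", "weight", "bmi", "heart_rate", "ef")


def summarize_metadata(records: list[SubjectRecord], group: str | None = None) -> pd.DataFrame:
    """Per-variable mean, sample SD, and range, optionally for one group.

    BMI is recomputed from weight and height.  A single-subject group
    reports SD = 0 with ``sd_flag`` set (degenerate-sample convention).
    """
    if group is not None:
        records = [r for r in records if r.group == group]
    if not records:
        raise ValueError(f"no records in group {group!r}")
    rows = []
    for var in _SUMMARY_VARS:
        vals = np.array([getattr(r, var) for r in records], dtype=np.float64)
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append(
            {
                "variable": var,
                "n": vals.size,
                "mean": float(np.mean(vals)),
                "sd": sd,
                "min": float(np.min(vals)),
                "max": float(np.max(vals)),
                "sd_flag": vals.size == 1,
            }
        )
    return pd.DataFrame(rows).set_index("variable")
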