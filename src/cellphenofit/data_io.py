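"""Reading, writing and validating experiment workbooks.

A dataset is a single spreadsheet workbook (XLSX/XLS; a CSV bundle is
accepted as a fallback) holding per-condition time series of live / dead
/ total cell counts with replicates, plus experiment metadata and user
identity.  Layout:

``Data_<Observable>`` (one sheet per observable: Live, Dead, Total)
    Column 1 is time; each further column is one replicate, headed by a
    unique column label.
``Conditions``
    Maps each replicate column label to a condition label and optional
    environment variables (e.g. drug, dose).  If absent, all replicates
    belong to one condition named "default".
``Metadata`` / ``User``
    Key-value sheets: cell_line_name, media, notes, time_unit; name,
    contact.

Times are converted to hours on load (accepted units: h, min, day).
Counts may also be optical densities, treated as proportional counts and
flagged.  Parsing never silently coerces text: every failure surfaces
with sheet/row/column coordinates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import openpyxl

from .growth_models import InvalidInputError

__all__ = [
    "ReplicateSeries",
    "Condition",
    "ExperimentDataset",
    "Issue",
    "FormatError",
    "read_workbook",
    "write_workbook",
    "read_csv_bundle",
    "write_csv_bundle",
    "validate_dataset",
    "subsample_series",
]

OBSERVABLES = ("Live", "Dead", "Total")
TIME_FACTORS = {"h": 1.0, "hour": 1.0, "hours": 1.0,
                "min": 1.0 / 60.0, "minute": 1.0 / 60.0, "minutes": 1.0 / 60.0,
                "day": 24.0, "days": 24.0, "d": 24.0}


class FormatError(InvalidInputError):
    """Workbook or bundle does not match the expected layout."""


@dataclass
class ReplicateSeries:
    times: np.ndarray                 # hours
    counts: np.ndarray                # cells (or OD units if flagged)
    replicate_id: str
    is_optical_density: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.size != self.counts.size:
            raise InvalidInputError(
                f"replicate {self.replicate_id!r}: {self.times.size} times vs "
                f"{self.counts.size} counts"
            )


@dataclass
class Condition:
    label: str
    environment: dict[str, object] = field(default_factory=dict)
    replicates: dict[str, list[ReplicateSeries]] = field(default_factory=dict)


@dataclass
class ExperimentDataset:
    conditions: list[Condition]
    metadata: dict[str, object] = field(default_factory=dict)
    user_info: dict[str, object] = field(default_factory=dict)
    source_path: str | None = None

    def condition(self, label: str) -> Condition:
        for c in self.conditions:
            if c.label == label:
                return c
        raise KeyError(f"no condition {label!r}")


@dataclass
class Issue:
    severity: str      # "error" | "warning"
    location: str      # e.g. "Data_Live!C4" or "condition 'drugA@1'"
    message: str


# ---------------------------------------------------------------------------
# workbook reading

def _cell_ref(sheet: str, row: int, col: int) -> str:
    return f"{sheet}!{openpyxl.utils.get_column_letter(col)}{row}"


def _parse_number(value, where: str) -> float:
    if value is None:
        raise FormatError(f"{where}: empty cell where a number was expected")
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    try:
        return float(str(value).strip())
    except ValueError:
        raise FormatError(f"{where}: cannot interpret {value!r} as a number") from None


def _read_kv_sheet(wb, name: str) -> dict[str, object]:
    if name not in wb.sheetnames:
        return {}
    out: dict[str, object] = {}
    for row in wb[name].iter_rows(values_only=True):
        if not row or row[0] is None:
            continue
        key = str(row[0]).strip()
        val = row[1] if len(row) > 1 else None
        out[key] = val
    return out


def _read_data_sheet(ws, sheet_name: str, time_factor: float):
    """Return (column labels, times[h], counts matrix columns)."""
    rows = list(ws.iter_rows(values_only=True))
    rows = [r for r in rows if any(v is not None for v in r)]
    if len(rows) < 2:
        raise FormatError(f"{sheet_name}: sheet has no data rows")
    header = rows[0]
    labels = [str(h).strip() for h in header[1:] if h is not None]
    if not labels:
        raise FormatError(f"{sheet_name}: no replicate columns in header")
    times, columns = [], [[] for _ in labels]
    for i, row in enumerate(rows[1:], start=2):
        t = _parse_number(row[0], _cell_ref(sheet_name, i, 1))
        times.append(t * time_factor)
        for j in range(len(labels)):
            v = row[j + 1] if len(row) > j + 1 else None
            columns[j].append(_parse_number(v, _cell_ref(sheet_name, i, j + 2)))
    return labels, np.asarray(times), [np.asarray(c) for c in columns]


def _resolve_time_factor(metadata: dict) -> float:
    unit = str(metadata.get("time_unit") or "h").strip().lower()
    if unit not in TIME_FACTORS:
        raise FormatError(f"Metadata: unknown time_unit {unit!r} "
                          f"(accepted: h, min, day)")
    return TIME_FACTORS[unit]


def _assemble(data_by_obs, condition_map, metadata, user_info, source) -> ExperimentDataset:
    """Build conditions from per-observable column data and the column map.

    ``condition_map`` maps column label -> (condition label, environment).
    """
    od_flag = bool(metadata.get("optical_density"))
    conditions: dict[str, Condition] = {}
    order: list[str] = []
    for obs, (labels, times, columns) in data_by_obs.items():
        for label, counts in zip(labels, columns):
            cond_label, env = condition_map.get(label, ("default", {}))
            if cond_label not in conditions:
                conditions[cond_label] = Condition(cond_label, dict(env))
                order.append(cond_label)
            cond = conditions[cond_label]
            cond.replicates.setdefault(obs, []).append(
                ReplicateSeries(times, counts, replicate_id=label,
                                is_optical_density=od_flag)
            )
    if not conditions:
        raise FormatError("no data columns found in any Data_* sheet")
    return ExperimentDataset(
        conditions=[conditions[k] for k in order],
        metadata=metadata,
        user_info=user_info,
        source_path=str(source),
    )


def _read_conditions_rows(rows) -> dict[str, tuple[str, dict]]:
    rows = [r for r in rows if r and any(v not in (None, "") for v in r)]
    if not rows:
        return {}
    header = [str(h).strip() if h is not None else "" for h in rows[0]]
    env_keys = header[2:]
    cmap: dict[str, tuple[str, dict]] = {}
    for row in rows[1:]:
        col_label = str(row[0]).strip()
        cond_label = str(row[1]).strip() if len(row) > 1 and row[1] is not None else "default"
        env = {}
        for k, v in zip(env_keys, row[2:]):
            if k and v is not None:
                env[k] = v
        cmap[col_label] = (cond_label, env)
    return cmap


def read_workbook(path) -> ExperimentDataset:
    """Parse an XLSX/XLS workbook (or a CSV-bundle manifest) into a dataset."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        return read_csv_bundle(path)
    wb = openpyxl.load_workbook(path, data_only=True, read_only=True)
    try:
        metadata = _read_kv_sheet(wb, "Metadata")
        user_info = _read_kv_sheet(wb, "User")
        factor = _resolve_time_factor(metadata)
        data_by_obs = {}
        for obs in OBSERVABLES:
            name = f"Data_{obs}"
            if name in wb.sheetnames:
                data_by_obs[obs] = _read_data_sheet(wb[name], name, factor)
        if not data_by_obs:
            raise FormatError(
                "workbook has no Data_Live / Data_Dead / Data_Total sheet"
            )
        cmap = {}
        if "Conditions" in wb.sheetnames:
            cmap = _read_conditions_rows(
                list(wb["Conditions"].iter_rows(values_only=True))
            )
    finally:
        wb.close()
    metadata["time_unit"] = "h"  # times now in hours
    return _assemble(data_by_obs, cmap, metadata, user_info, path)


# ---------------------------------------------------------------------------
# workbook writing

def _fix_zip_timestamps(path: Path) -> None:
    """Rewrite an xlsx (zip) with fixed entry timestamps for reproducibility."""
    import zipfile

    buf = []
    with zipfile.ZipFile(path) as zin:
        for info in zin.infolist():
            buf.append((info.filename, zin.read(info.filename)))
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zout:
        for name, data in buf:
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o600 << 16
            zout.writestr(info, data)


def _deterministic_save(wb, path: Path) -> None:
    import datetime

    epoch = datetime.datetime(2000, 1, 1)
    wb.properties.created = epoch
    wb.properties.modified = epoch
    wb.save(path)
    _fix_zip_timestamps(path)


def write_workbook(dataset: ExperimentDataset, path) -> Path:
    """Write a dataset back to the workbook layout (lossless round trip).

    Times are written in hours.  Output is byte-reproducible: identical
    datasets produce identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wb = openpyxl.Workbook()
    wb.remove(wb.active)

    env_keys: list[str] = []
    for cond in dataset.conditions:
        for k in cond.environment:
            if k not in env_keys:
                env_keys.append(k)

    ws = wb.create_sheet("Conditions")
    ws.append(["column", "condition", *env_keys])
    seen = set()
    per_obs: dict[str, list[tuple[str, ReplicateSeries]]] = {}
    for cond in dataset.conditions:
        for obs, reps in cond.replicates.items():
            for rep in reps:
                col_label = f"{cond.label}:{rep.replicate_id}" \
                    if not rep.replicate_id.startswith(cond.label) else rep.replicate_id
                per_obs.setdefault(obs, []).append((col_label, rep))
                if col_label not in seen:
                    seen.add(col_label)
                    ws.append([col_label, cond.label,
                               *[cond.environment.get(k) for k in env_keys]])

    for obs in OBSERVABLES:
        if obs not in per_obs:
            continue
        ws = wb.create_sheet(f"Data_{obs}")
        cols = per_obs[obs]
        ws.append(["time", *[label for label, _ in cols]])
        grid = cols[0][1].times
        for i, t in enumerate(grid):
            ws.append([float(t), *[float(rep.counts[i]) for _, rep in cols]])

    ws = wb.create_sheet("Metadata")
    meta = dict(dataset.metadata)
    meta.setdefault("time_unit", "h")
    for k, v in meta.items():
        ws.append([k, v])
    ws = wb.create_sheet("User")
    for k, v in dataset.user_info.items():
        ws.append([k, v])

    _deterministic_save(wb, path)
    return path


# ---------------------------------------------------------------------------
# CSV bundle fallback

def write_csv_bundle(dataset: ExperimentDataset, directory) -> Path:
    """Write the dataset as CSV files plus a manifest (UTF-8).

    Produces ``manifest.csv``, ``conditions.csv`` and one
    ``data_<observable>.csv`` per observable, mirroring the workbook
    sheets column-for-column.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    env_keys: list[str] = []
    for cond in dataset.conditions:
        for k in cond.environment:
            if k not in env_keys:
                env_keys.append(k)

    per_obs: dict[str, list[tuple[str, ReplicateSeries]]] = {}
    cond_rows, seen = [], set()
    for cond in dataset.conditions:
        for obs, reps in cond.replicates.items():
            for rep in reps:
                col_label = f"{cond.label}:{rep.replicate_id}" \
                    if not rep.replicate_id.startswith(cond.label) else rep.replicate_id
                per_obs.setdefault(obs, []).append((col_label, rep))
                if col_label not in seen:
                    seen.add(col_label)
                    cond_rows.append([col_label, cond.label,
                                      *[cond.environment.get(k, "") for k in env_keys]])

    with open(directory / "conditions.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["column", "condition", *env_keys])
        w.writerows(cond_rows)

    observables = []
    for obs in OBSERVABLES:
        if obs not in per_obs:
            continue
        observables.append(obs)
        cols = per_obs[obs]
        with open(directory / f"data_{obs.lower()}.csv", "w", newline="",
                  encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["time", *[label for label, _ in cols]])
            grid = cols[0][1].times
            for i, t in enumerate(grid):
                w.writerow([repr(float(t)),
                            *[repr(float(rep.counts[i])) for _, rep in cols]])

    meta = dict(dataset.metadata)
    meta.setdefault("time_unit", "h")
    with open(directory / "manifest.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["key", "value"])
        w.writerow(["observables", ";".join(observables)])
        for k, v in meta.items():
            w.writerow([f"metadata.{k}", v])
        for k, v in dataset.user_info.items():
            w.writerow([f"user.{k}", v])
    return directory / "manifest.csv"


def read_csv_bundle(manifest_path) -> ExperimentDataset:
    """Read a CSV bundle written by :func:`write_csv_bundle`."""
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    metadata: dict[str, object] = {}
    user_info: dict[str, object] = {}
    observables: list[str] = []
    with open(manifest_path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            key, value = row["key"], row["value"]
            if key == "observables":
                observables = [o for o in value.split(";") if o]
            elif key.startswith("metadata."):
                metadata[key[len("metadata."):]] = value
            elif key.startswith("user."):
                user_info[key[len("user."):]] = value
    factor = _resolve_time_factor(metadata)

    data_by_obs = {}
    for obs in observables:
        fname = directory / f"data_{obs.lower()}.csv"
        if not fname.exists():
            raise FormatError(f"manifest lists observable {obs!r} but "
                              f"{fname.name} is missing")
        with open(fname, newline="", encoding="utf-8") as fh:
            rows = [r for r in csv.reader(fh) if r]
        if len(rows) < 2:
            raise FormatError(f"{fname.name}: no data rows")
        labels = rows[0][1:]
        times, columns = [], [[] for _ in labels]
        for i, row in enumerate(rows[1:], start=2):
            times.append(_parse_number(row[0], f"{fname.name} row {i} col 1")
                         * factor)
            for j in range(len(labels)):
                v = row[j + 1] if len(row) > j + 1 else None
                columns[j].append(
                    _parse_number(v, f"{fname.name} row {i} col {j + 2}"))
        data_by_obs[obs] = (labels, np.asarray(times),
                            [np.asarray(c) for c in columns])

    cmap = {}
    cond_file = directory / "conditions.csv"
    if cond_file.exists():
        with open(cond_file, newline="", encoding="utf-8") as fh:
            cmap = _read_conditions_rows(list(csv.reader(fh)))
    metadata["time_unit"] = "h"
    return _assemble(data_by_obs, cmap, metadata, user_info, manifest_path)


# ---------------------------------------------------------------------------
# validation and subsampling

def validate_dataset(dataset: ExperimentDataset) -> list[Issue]:
    """Check a parsed dataset; an empty list means it is fit-ready."""
    issues: list[Issue] = []
    if not dataset.conditions:
        issues.append(Issue("error", "dataset", "no conditions present"))
    for cond in dataset.conditions:
        if not cond.replicates:
            issues.append(Issue("error", f"condition {cond.label!r}",
                                "no replicate series"))
        for obs, reps in cond.replicates.items():
            grids = [rep.times for rep in reps]
            for rep in reps:
                loc = f"condition {cond.label!r}, {obs}, replicate {rep.replicate_id!r}"
                if rep.times.size < 2:
                    issues.append(Issue("warning", loc,
                                        "unfittable replicate: fewer than 2 time points"))
                if np.any(~np.isfinite(rep.counts)) or np.any(~np.isfinite(rep.times)):
                    issues.append(Issue("error", loc, "non-finite value"))
                    continue
                if np.any(rep.counts < 0):
                    i = int(np.argmax(rep.counts < 0))
                    issues.append(Issue("error", f"{loc}, point {i}",
                                        f"negative count {rep.counts[i]}"))
                if np.any(rep.times < 0):
                    issues.append(Issue("error", loc, "negative time"))
                if rep.times.size > 1 and np.any(np.diff(rep.times) <= 0):
                    issues.append(Issue("error", loc,
                                        "times not strictly increasing "
                                        "(duplicate or out-of-order time)"))
            if len(grids) > 1:
                t0 = grids[0]
                for rep, t in zip(reps[1:], grids[1:]):
                    if t.size != t0.size or np.any(np.abs(t - t0) > 1e-6):
                        issues.append(Issue(
                            "error",
                            f"condition {cond.label!r}, {obs}, replicate "
                            f"{rep.replicate_id!r}",
                            "time grid differs from first replicate"))
    return issues


def subsample_series(series: ReplicateSeries, interval: float) -> ReplicateSeries:
    """Thin a series to roughly one point per ``interval`` hours.

    Keeps the points nearest to t0 + k*interval (k = 0, 1, ...) within
    the native span; anchored at the first point, truncated at the last,
    deterministic and seedless.  ``interval`` must be at least the native
    spacing.
    """
    t = series.times
    if t.size < 2:
        return ReplicateSeries(t.copy(), series.counts.copy(),
                               series.replicate_id, series.is_optical_density)
    native = float(np.min(np.diff(t)))
    if interval < native - 1e-9:
        raise InvalidInputError(
            f"interval {interval} h is below the native spacing {native} h"
        )
    targets = t[0] + interval * np.arange(
        0, int(np.floor((t[-1] - t[0]) / interval + 1e-9)) + 1
    )
    idx = np.unique([int(np.argmin(np.abs(t - target))) for target in targets])
    return ReplicateSeries(t[idx], series.counts[idx],
                           series.replicate_id, series.is_optical_density)
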