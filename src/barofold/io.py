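"""Reading and writing the delimited text formats, manifests and reports.

All data files are two-column delimited text (comma or tab, auto-detected)
with a mandatory header row. Datasets on disk are a directory of data files
plus manifest tables carrying the per-file metadata (pressure, branch, cycle,
channel for spectra; initial/final pressure and cycle for traces). Result
reports are JSON with stable key ordering, embedding sha256 digests of the
input files so results are traceable.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from barofold.errors import ParseError, ValidationError
from barofold.kinetics import RelaxationTrace, DEFAULT_DEAD_TIME
from barofold.sec import Chromatogram, Standard
from barofold.spectra import Spectrum
from barofold.units import DEFAULT_T


def _detect_delimiter(header_line: str) -> str:
    if "\t" in header_line:
        return "\t"
    if "," in header_line:
        return ","
    raise ParseError("could not detect delimiter (expected comma or tab) in header")


def _read_table(path: Path | str) -> tuple[list[str], list[list[str]]]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ParseError(f"{path}: empty file")
        delim = _detect_delimiter(first)
        header = [c.strip() for c in first.strip().split(delim)]
        rows = list(csv.reader(fh, delimiter=delim))
    return header, rows


def _read_two_numeric_columns(path: Path | str) -> tuple[np.ndarray, np.ndarray]:
    header, rows = _read_table(path)
    if len(header) < 2:
        raise ParseError(f"{path}: expected two columns, header has {len(header)}")
    a, b = [], []
    for i, row in enumerate(rows, start=2):  # header is line 1
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 2:
            raise ParseError(f"{path}: line {i}: expected two columns")
        try:
            a.append(float(row[0]))
            b.append(float(row[1]))
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: non-numeric value ({exc})") from exc
    return np.array(a), np.array(b)


def read_spectrum_file(
    path: Path | str,
    pressure: float = 0.1,
    channel: str = "tryptophan",
) -> Spectrum:
    """Read a (wavelength_nm, intensity) file; rows are sorted by wavelength.

    Duplicate wavelengths are rejected (the grid must be strictly
    increasing). Pressure and channel normally come from the manifest.
    """
    wl, it = _read_two_numeric_columns(path)
    order = np.argsort(wl, kind="stable")
    wl, it = wl[order], it[order]
    if np.any(np.diff(wl) == 0):
        raise ValidationError(f"{path}: duplicate wavelengths in grid")
    return Spectrum(wavelengths=wl, intensities=it, pressure=pressure, channel=channel)


def write_spectrum_file(spectrum: Spectrum, path: Path | str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["wavelength_nm", "intensity"])
        for lam, it in zip(spectrum.wavelengths, spectrum.intensities):
            w.writerow([f"{lam:.6g}", f"{it:.10g}"])


def read_trace_file(
    path: Path | str,
    p_initial: float,
    p_final: float,
    cycle: int = 1,
    dead_time: float = DEFAULT_DEAD_TIME,
) -> RelaxationTrace:
    """Read a (time_s, intensity) relaxation trace; jump metadata from caller."""
    t, y = _read_two_numeric_columns(path)
    return RelaxationTrace(
        times=t, intensities=y, p_initial=p_initial, p_final=p_final,
        cycle=cycle, dead_time=dead_time,
    )


def write_trace_file(trace: RelaxationTrace, path: Path | str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "intensity"])
        for t, y in zip(trace.times, trace.intensities):
            w.writerow([f"{t:.10g}", f"{y:.10g}"])


def read_chromatogram_file(path: Path | str) -> Chromatogram:
    v, s = _read_two_numeric_columns(path)
    return Chromatogram(volumes=v, signal=np.clip(s, 0.0, None))


def write_chromatogram_file(chrom: Chromatogram, path: Path | str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["volume_ml", "signal"])
        for v, s in zip(chrom.volumes, chrom.signal):
            w.writerow([f"{v:.6g}", f"{s:.10g}"])


def read_standards_file(path: Path | str) -> list[Standard]:
    """Read a (name, mass_da, ve_ml) standards table."""
    header, rows = _read_table(path)
    if len(header) < 3:
        raise ParseError(f"{path}: expected columns name, mass_da, ve_ml")
    out = []
    for i, row in enumerate(rows, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            out.append(Standard(row[0].strip(), float(row[1]), float(row[2])))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from exc
    return out


def write_standards_file(standards: Sequence[Standard], path: Path | str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "mass_da", "ve_ml"])
        for s in standards:
            w.writerow([s.name, f"{s.mass_da:.10g}", f"{s.ve_ml:.10g}"])


# --------------------------------------------------------------------------
# dataset directories


def write_experiment(exp, root: Path | str) -> Path:
    """Write a simulated experiment as a dataset directory.

    Layout: spectra/<files> + spectra_manifest.csv,
            traces/<files>  + traces_manifest.csv.
    """
    root = Path(root)
    (root / "spectra").mkdir(parents=True, exist_ok=True)
    (root / "traces").mkdir(parents=True, exist_ok=True)

    with open(root / "spectra_manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "pressure_MPa", "branch", "cycle", "channel"])
        for (cycle, branch), series in sorted(exp.series.items()):
            for j, sp in enumerate(series):
                name = f"spectra/c{cycle}_{branch}_{j:03d}.csv"
                write_spectrum_file(sp, root / name)
                w.writerow([name, f"{sp.pressure:.6g}", branch, cycle, sp.channel])

    with open(root / "traces_manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "p_initial_MPa", "p_final_MPa", "cycle"])
        for j, tr in enumerate(exp.traces):
            name = f"traces/jump_{j:03d}.csv"
            write_trace_file(tr, root / name)
            w.writerow([name, f"{tr.p_initial:.6g}", f"{tr.p_final:.6g}", tr.cycle])
    return root


def load_experiment(root: Path | str):
    """Load a dataset directory written by :func:`write_experiment`.

    Returns (series, traces): series maps (cycle, branch) to the
    acquisition-ordered list of Spectrum objects.
    """
    root = Path(root)
    series: dict = {}
    header, rows = _read_table(root / "spectra_manifest.csv")
    col = {name: k for k, name in enumerate(header)}
    for name in ("filename", "pressure_MPa", "branch", "cycle", "channel"):
        if name not in col:
            raise ParseError(f"spectra manifest missing column {name!r}")
    for i, row in enumerate(rows, start=2):
        if not row:
            continue
        fn = root / row[col["filename"]]
        sp = read_spectrum_file(
            fn,
            pressure=float(row[col["pressure_MPa"]]),
            channel=row[col["channel"]].strip(),
        )
        key = (int(row[col["cycle"]]), row[col["branch"]].strip())
        series.setdefault(key, []).append(sp)

    traces = []
    tm = root / "traces_manifest.csv"
    if tm.exists():
        header, rows = _read_table(tm)
        col = {name: k for k, name in enumerate(header)}
        for row in rows:
            if not row:
                continue
            traces.append(
                read_trace_file(
                    root / row[col["filename"]],
                    p_initial=float(row[col["p_initial_MPa"]]),
                    p_final=float(row[col["p_final_MPa"]]),
                    cycle=int(row[col["cycle"]]),
                )
            )
    return series, traces


# --------------------------------------------------------------------------
# manifests, digests and reports


def file_digest(path: Path | str) -> str:
    """sha256 hex digest of a file's bytes."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to rerun an analysis: data paths and configuration."""

    dataset: Path
    temperature: float = DEFAULT_T
    eq_source_cycle: int = 2
    eq_source_branch: str = "decreasing"
    eq_source_observable: str = "intensity"
    seed: Optional[int] = None
    software_version: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dataset = Path(self.dataset)
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if not self.dataset.exists():
            raise ValidationError(f"dataset not found: {self.dataset}")

    def digests(self) -> dict:
        out = {}
        for p in sorted(self.dataset.rglob("*.csv")):
            out[str(p.relative_to(self.dataset))] = file_digest(p)
        return out


def report_to_json(report: dict, path: Optional[Path | str] = None) -> str:
    """Serialize a report dict as diff-friendly JSON (sorted keys)."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    text = json.dumps(report, sort_keys=True, indent=2, default=default)
    if path is not None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(text + "\n")
    return text
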