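"""Stage-tagged peak lists and their on-disk formats (CSV, minimal MGF).

Readers reject silently-corrupting input (NaN, negative intensity,
non-positive m/z) with line-numbered errors instead of coercing. mzML is
deliberately out of scope; these two plain-text formats are the extension
point.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

from ..chem import AdductSpec
from ..errors import DataError

STAGES = ("precursor", "CID", "OzID")


@dataclass(frozen=True)
class Spectrum:
    """An acquisition-stage-tagged list of (m/z, intensity) peaks.

    Peaks are sorted ascending by m/z on construction; m/z must be
    strictly positive and intensities non-negative and finite.
    """

    stage: str
    peaks: tuple[tuple[float, float], ...]
    precursor_mz: float | None = None
    adduct: AdductSpec | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise DataError(f"stage must be one of {STAGES}, got {self.stage!r}")
        validated = []
        for mz, intensity in self.peaks:
            mz = float(mz)
            intensity = float(intensity)
            if not math.isfinite(mz) or mz <= 0:
                raise DataError(f"non-positive or non-finite m/z: {mz}")
            if not math.isfinite(intensity) or intensity < 0:
                raise DataError(f"negative or non-finite intensity at m/z {mz}")
            validated.append((mz, intensity))
        validated.sort()
        object.__setattr__(self, "peaks", tuple(validated))

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mzs(self) -> tuple[float, ...]:
        return tuple(p[0] for p in self.peaks)

    @property
    def intensities(self) -> tuple[float, ...]:
        return tuple(p[1] for p in self.peaks)

    def base_peak_intensity(self) -> float:
        return max(self.intensities, default=0.0)

    def match(self, mz: float, tol_mz: float) -> tuple[float, float] | None:
        """Most intense peak within ``tol_mz`` of ``mz``, or None."""
        hits = [p for p in self.peaks if abs(p[0] - mz) <= tol_mz]
        return max(hits, key=lambda p: p[1]) if hits else None


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "mgf"):
            raise DataError(f"unknown peak-list format {fmt!r} (use csv or mgf)")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "mgf"):
        return suffix
    raise DataError(
        f"cannot infer format from {path.name!r}; pass format='csv' or 'mgf'"
    )


def read_peaklist(
    path: str | Path,
    fmt: str | None = None,
    stage: str = "precursor",
    adduct: AdductSpec | None = None,
) -> Spectrum:
    """Read a peak list from a two-column CSV or a minimal MGF file."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"peak list not found: {path}")
    fmt = _detect_format(path, fmt)
    if fmt == "csv":
        return _read_csv(path, stage, adduct)
    return _read_mgf(path, stage, adduct)


def _parse_number(token: str, what: str, path: Path, line_no: int) -> float:
    try:
        value = float(token)
    except ValueError:
        raise DataError(f"{path}:{line_no}: unparseable {what} {token!r}") from None
    if not math.isfinite(value):
        raise DataError(f"{path}:{line_no}: non-finite {what} {token!r}")
    return value


def _read_csv(path: Path, stage: str, adduct: AdductSpec | None) -> Spectrum:
    peaks = []
    with path.open(newline="") as handle:
        for line_no, row in enumerate(csv.reader(handle), start=1):
            if not row or row[0].startswith("#"):
                continue
            if line_no == 1 and row[0].strip().lower() in ("mz", "m/z"):
                continue  # header
            if len(row) < 2:
                raise DataError(f"{path}:{line_no}: expected mz,intensity columns")
            mz = _parse_number(row[0].strip(), "m/z", path, line_no)
            intensity = _parse_number(row[1].strip(), "intensity", path, line_no)
            peaks.append((mz, intensity))
    return Spectrum(stage=stage, peaks=tuple(peaks), adduct=adduct, source=str(path))


def _read_mgf(path: Path, stage: str, adduct: AdductSpec | None) -> Spectrum:
    peaks = []
    precursor_mz = None
    in_block = False
    with path.open() as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                in_block = True
                continue
            if line == "END IONS":
                in_block = False
                continue
            if not in_block:
                continue
            if "=" in line:
                key, _, value = line.partition("=")
                if key.upper() == "PEPMASS":
                    precursor_mz = _parse_number(
                        value.split()[0], "PEPMASS", path, line_no
                    )
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise DataError(f"{path}:{line_no}: expected 'mz intensity' pair")
            mz = _parse_number(tokens[0], "m/z", path, line_no)
            intensity = _parse_number(tokens[1], "intensity", path, line_no)
            peaks.append((mz, intensity))
    return Spectrum(
        stage=stage,
        peaks=tuple(peaks),
        precursor_mz=precursor_mz,
        adduct=adduct,
        source=str(path),
    )


def write_peaklist(spectrum: Spectrum, path: str | Path, fmt: str | None = None) -> None:
    """Write peaks at full precision; CSV gets an ``mz,intensity`` header."""
    path = Path(path)
    fmt = _detect_format(path, fmt)
    with path.open("w", newline="") as handle:
        if fmt == "csv":
            handle.write("mz,intensity\n")
            for mz, intensity in spectrum.peaks:
                handle.write(f"{mz!r},{intensity!r}\n")
        else:
            handle.write("BEGIN IONS\n")
            if spectrum.precursor_mz is not None:
                handle.write(f"PEPMASS={spectrum.precursor_mz!r}\n")
            for mz, intensity in spectrum.peaks:
                handle.write(f"{mz!r} {intensity!r}\n")
            handle.write("END IONS\n")
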