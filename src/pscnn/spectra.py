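"""Containers and I/O for processed 1D ¹H NMR spectra.

A :class:`Spectrum` is a uniformly sampled chemical-shift axis (ppm) plus an
intensity vector; a :class:`SpectralLibrary` is an ordered collection of named
pure-compound spectra sharing one grid.  Spectra can be read from Bruker
processed-1D directories, AFFN JCAMP-DX files, or two-column ppm/intensity
text, and libraries round-trip losslessly through a single HDF5 container.

Conventions
-----------
* The ppm axis is stored high→low (NMR display convention); readers flip
  ascending input on ingest.
* Spectra are assumed baseline-corrected: resampling outside the recorded
  ppm range fills with zero.
* Interpolation is linear, which preserves the additivity of NMR signals —
  the property the mixture-augmentation model relies on.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np

__all__ = [
    "Spectrum",
    "SpectralLibrary",
    "SpectrumError",
    "SpectrumReadError",
    "SpectrumFormatError",
    "NormalizationError",
    "default_grid",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "normalize_max",
    "mask_regions",
    "write_library",
    "load_library",
]

#: relative tolerance on grid-spacing uniformity
_GRID_RTOL = 1e-9


class SpectrumError(ValueError):
    """Invalid spectrum data (non-uniform grid, NaNs, length mismatch...)."""


class SpectrumReadError(IOError):
    """A spectrum file is missing, empty or unreadable."""


class SpectrumFormatError(SpectrumError):
    """A file parsed but violates the expected format."""


class NormalizationError(SpectrumError):
    """Spectrum cannot be max-normalized (no strictly positive intensity)."""


def default_grid(n_points: int = 16384, low: float = -1.0, high: float = 11.0) -> np.ndarray:
    """Default internal ppm grid: ``n_points`` from ``high`` down to ``low``.

    The −1…11 ppm window covers the usual ¹H range of small molecules in
    DMSO-d6 referenced to TMS.
    """
    if n_points < 2:
        raise ValueError("grid needs at least 2 points")
    if not high > low:
        raise ValueError("high must exceed low")
    return np.linspace(float(high), float(low), int(n_points))


def _check_uniform(ppm: np.ndarray) -> None:
    diffs = np.diff(ppm)
    step = diffs.mean()
    if step == 0:
        raise SpectrumError("ppm axis is constant")
    if not np.allclose(diffs, step, rtol=0.0, atol=_GRID_RTOL * abs(step) + 1e-15):
        raise SpectrumFormatError("ppm axis spacing is not uniform")


@dataclass
class Spectrum:
    """A processed 1D NMR spectrum on a uniform ppm grid.

    Parameters
    ----------
    ppm : ndarray
        Chemical-shift axis in ppm, uniformly spaced.  Ascending input is
        flipped so the stored axis runs high→low.
    intensities : ndarray
        Real intensities, same length as ``ppm``, finite.
    name : str
        Compound or sample identifier.
    meta : dict
        Free-form annotations (e.g. ``{"sf_mhz": 400.13, "source": ...}``).
    """

    ppm: np.ndarray
    intensities: np.ndarray
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.ppm.ndim != 1 or self.intensities.ndim != 1:
            raise SpectrumError("ppm and intensities must be 1-D")
        if self.ppm.size != self.intensities.size:
            raise SpectrumError(
                f"length mismatch: {self.ppm.size} ppm values vs "
                f"{self.intensities.size} intensities"
            )
        if self.ppm.size < 2:
            raise SpectrumError("spectrum needs at least 2 points")
        if not np.all(np.isfinite(self.intensities)):
            raise SpectrumError("intensities contain NaN or Inf")
        if not np.all(np.isfinite(self.ppm)):
            raise SpectrumError("ppm axis contains NaN or Inf")
        if self.ppm[0] < self.ppm[-1]:  # normalize direction to high→low
            self.ppm = self.ppm[::-1].copy()
            self.intensities = self.intensities[::-1].copy()
        _check_uniform(self.ppm)

    def __len__(self) -> int:
        return self.ppm.size

    @property
    def step(self) -> float:
        """Grid spacing in ppm (positive)."""
        return float(abs(self.ppm[1] - self.ppm[0]))

    def copy(self, **changes) -> "Spectrum":
        kw = dict(
            ppm=self.ppm.copy(),
            intensities=self.intensities.copy(),
            name=self.name,
            meta=dict(self.meta),
        )
        kw.update(changes)
        return Spectrum(**kw)

    def same_grid(self, other: "Spectrum", atol: float = 1e-9) -> bool:
        return self.ppm.size == other.ppm.size and np.allclose(
            self.ppm, other.ppm, rtol=0.0, atol=atol
        )


@dataclass
class SpectralLibrary:
    """Ordered collection of named pure-compound spectra on a shared grid."""

    entries: list[Spectrum]

    def __post_init__(self) -> None:
        names = [s.name for s in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SpectrumFormatError(f"duplicate entry names: {dupes}")
        for s in self.entries[1:]:
            if not self.entries[0].same_grid(s):
                raise SpectrumError(f"entry {s.name!r} is not on the library grid")

    @property
    def grid(self) -> np.ndarray:
        if not self.entries:
            raise SpectrumError("empty library has no grid")
        return self.entries[0].ppm

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.entries]

    def matrix(self) -> np.ndarray:
        """Entry intensities stacked as an (N, L) array in library order."""
        return np.stack([s.intensities for s in self.entries])

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.entries)

    def __getitem__(self, key: int | str) -> Spectrum:
        if isinstance(key, str):
            for s in self.entries:
                if s.name == key:
                    return s
            raise KeyError(key)
        return self.entries[key]


# ---------------------------------------------------------------------------
# basic operations


def resample(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid``; outside range fills 0."""
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("target grid must be 1-D with at least 2 points")
    # np.interp needs ascending abscissae
    x_asc = spectrum.ppm[::-1]
    y_asc = spectrum.intensities[::-1]
    out = np.interp(grid, x_asc, y_asc, left=0.0, right=0.0)
    # exact outside-range zeros (np.interp clamps to edge values)
    out = np.where((grid < x_asc[0]) | (grid > x_asc[-1]), 0.0, out)
    return Spectrum(grid.copy(), out, name=spectrum.name, meta=dict(spectrum.meta))


def normalize_max(spectrum: Spectrum) -> Spectrum:
    """Scale intensities so the maximum equals 1."""
    peak = spectrum.intensities.max()
    if not peak > 0:
        raise NormalizationError(
            f"spectrum {spectrum.name!r} has no strictly positive intensity"
        )
    return spectrum.copy(intensities=spectrum.intensities / peak)


def mask_regions(spectrum: Spectrum, windows: Sequence[tuple[float, float]]) -> Spectrum:
    """Zero intensities inside the given ppm windows (e.g. solvent regions)."""
    out = spectrum.intensities.copy()
    for lo, hi in windows:
        lo, hi = min(lo, hi), max(lo, hi)
        out[(spectrum.ppm >= lo) & (spectrum.ppm <= hi)] = 0.0
    return spectrum.copy(intensities=out)


# ---------------------------------------------------------------------------
# readers / writers


def read_spectrum(path: str | Path, format: str | None = None) -> Spectrum:
    """Read a 1D spectrum from ``path``.

    Parameters
    ----------
    path : path
        File (table/JCAMP) or Bruker processed-data directory.
    format : {"bruker_1d", "jcamp", "table"}, optional
        Auto-detected from the path when omitted: directories → Bruker,
        ``.dx``/``.jdx`` → JCAMP, anything else → two-column table.
    """
    path = Path(path)
    if not path.exists():
        raise SpectrumReadError(f"no such file: {path}")
    if format is None:
        if path.is_dir():
            format = "bruker_1d"
        elif path.suffix.lower() in {".dx", ".jdx", ".jcamp"}:
            format = "jcamp"
        else:
            format = "table"
    readers = {"bruker_1d": _read_bruker_1d, "jcamp": _read_jcamp, "table": _read_table}
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; choose from {sorted(readers)}")
    return readers[format](path)


def _read_table(path: Path) -> Spectrum:
    ppm, inten, meta, name = [], [], {}, path.stem
    try:
        text = path.read_text()
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise SpectrumReadError(f"cannot read {path}: {exc}") from exc
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*(\w+)\s*:\s*(.*)", line)
            if m:
                key, val = m.group(1), m.group(2).strip()
                if key == "name":
                    name = val
                else:
                    meta[key] = val
            continue
        parts = re.split(r"[,\s;]+", line)
        if len(parts) < 2:
            raise SpectrumFormatError(f"{path}: expected two columns, got {line!r}")
        try:
            ppm.append(float(parts[0]))
            inten.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumFormatError(f"{path}: non-numeric row {line!r}") from exc
    if not ppm:
        raise SpectrumReadError(f"{path}: no data rows")
    meta.setdefault("source", str(path))
    try:
        return Spectrum(np.array(ppm), np.array(inten), name=name, meta=meta)
    except SpectrumError as exc:
        raise SpectrumFormatError(f"{path}: {exc}") from exc


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as a two-column table with ``# key: value`` headers."""
    path = Path(path)
    lines = [f"# name: {spectrum.name}"]
    for key, val in spectrum.meta.items():
        lines.append(f"# {key}: {val}")
    for x, y in zip(spectrum.ppm, spectrum.intensities):
        lines.append(f"{x:.12g}\t{y:.12g}")
    path.write_text("\n".join(lines) + "\n")


def _read_jcamp(path: Path) -> Spectrum:
    """Minimal AFFN JCAMP-DX reader for 1D data (XYDATA=(X++(Y..Y)))."""
    text = path.read_text()
    if not text.strip():
        raise SpectrumReadError(f"{path}: empty file")
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for raw in text.splitlines():
        line = raw.split("$$")[0].rstrip()  # strip comments
        if not line:
            continue
        if line.startswith("##"):
            in_data = False
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            val = val.strip()
            fields[key] = val
            if key == "XYDATA":
                if "X++" not in val.replace(" ", ""):
                    raise SpectrumFormatError(
                        f"{path}: unsupported XYDATA form {val!r} (need (X++(Y..Y)))"
                    )
                in_data = True
        elif in_data:
            data_lines.append(line)
    if "XYDATA" not in fields:
        raise SpectrumFormatError(f"{path}: no ##XYDATA record")
    try:
        xfac = float(fields.get("XFACTOR", "1"))
        yfac = float(fields.get("YFACTOR", "1"))
        firstx = float(fields["FIRSTX"])
        lastx = float(fields["LASTX"])
        npoints = int(float(fields["NPOINTS"]))
    except (KeyError, ValueError) as exc:
        raise SpectrumFormatError(f"{path}: missing/invalid JCAMP header: {exc}") from exc
    ys: list[float] = []
    for line in data_lines:
        toks = re.split(r"[\s,]+", line.strip())
        if not toks:
            continue
        for tok in toks[1:]:  # first token is the X of the line
            if re.search(r"[A-DF-Za-df-z%@]", tok):
                raise SpectrumFormatError(
                    f"{path}: compressed (SQZ/DIF) JCAMP data not supported"
                )
            ys.append(float(tok))
    if len(ys) != npoints:
        raise SpectrumFormatError(
            f"{path}: NPOINTS={npoints} but {len(ys)} Y values found"
        )
    del xfac  # X tokens are ignored in favour of the FIRSTX/LASTX header range
    ppm = np.linspace(firstx, lastx, npoints)
    inten = np.asarray(ys) * yfac
    meta = {"source": str(path)}
    if "XUNITS" in fields:
        meta["xunits"] = fields["XUNITS"]
    if ".OBSERVEFREQUENCY" in fields:
        meta["sf_mhz"] = fields[".OBSERVEFREQUENCY"]
    name = fields.get("TITLE", path.stem) or path.stem
    try:
        return Spectrum(ppm, inten, name=name, meta=meta)
    except SpectrumError as exc:
        raise SpectrumFormatError(f"{path}: {exc}") from exc


def _parse_bruker_params(path: Path) -> dict[str, str]:
    params: dict[str, str] = {}
    for line in path.read_text().splitlines():
        m = re.match(r"##\$?([A-Za-z_0-9]+)=\s*(.*)", line)
        if m:
            params[m.group(1)] = m.group(2).strip()
    return params


def _read_bruker_1d(path: Path) -> Spectrum:
    """Read a Bruker processed-1D directory (``1r`` + ``procs``).

    ``path`` may point at the ``pdata/<n>`` directory itself or any parent
    containing exactly one ``1r`` below it.
    """
    candidates = sorted(path.rglob("1r")) if path.is_dir() else []
    if not candidates:
        raise SpectrumReadError(f"{path}: no Bruker '1r' file found")
    one_r = candidates[0]
    procs_path = one_r.parent / "procs"
    if not procs_path.exists():
        raise SpectrumReadError(f"{one_r.parent}: missing 'procs' parameter file")
    procs = _parse_bruker_params(procs_path)
    try:
        si = int(procs["SI"])
        sf = float(procs["SF"])
        sw_p = float(procs["SW_p"])
        offset = float(procs["OFFSET"])
    except (KeyError, ValueError) as exc:
        raise SpectrumFormatError(f"{procs_path}: missing parameter {exc}") from exc
    nc_proc = int(procs.get("NC_proc", "0"))
    byteorder = "<" if procs.get("BYTORDP", "0") == "0" else ">"
    dtype = np.dtype(f"{byteorder}i4")
    if procs.get("DTYPP", "0") == "2":  # double precision processed data
        dtype = np.dtype(f"{byteorder}f8")
    raw = np.fromfile(one_r, dtype=dtype)
    if raw.size < si:
        raise SpectrumFormatError(f"{one_r}: expected {si} points, file has {raw.size}")
    inten = raw[:si].astype(np.float64) * (2.0**nc_proc)
    sw_ppm = sw_p / sf
    # Bruker convention: first point at OFFSET ppm, descending by SW/SI per point
    ppm = offset - np.arange(si) * (sw_ppm / si)
    meta = {"source": str(one_r), "sf_mhz": sf, "sw_ppm": sw_ppm}
    return Spectrum(ppm, inten, name=path.name, meta=meta)


# ---------------------------------------------------------------------------
# library container (HDF5)


def write_library(library: SpectralLibrary, path: str | Path) -> None:
    """Persist a library to one HDF5 file (grid, intensity matrix, names, meta)."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.attrs["container"] = "pscnn-spectral-library"
        fh.attrs["version"] = 1
        if len(library):
            fh.create_dataset("grid", data=library.grid)
            fh.create_dataset("intensities", data=library.matrix())
            fh.create_dataset(
                "names", data=np.array(library.names, dtype=h5py.string_dtype())
            )
            fh.create_dataset(
                "meta",
                data=np.array(
                    [json.dumps(s.meta, default=str) for s in library],
                    dtype=h5py.string_dtype(),
                ),
            )
        else:
            fh.attrs["empty"] = True


def load_library(path: str | Path) -> SpectralLibrary:
    path = Path(path)
    if not path.exists():
        raise SpectrumReadError(f"no such file: {path}")
    with h5py.File(path, "r") as fh:
        if fh.attrs.get("container") != "pscnn-spectral-library":
            raise SpectrumFormatError(f"{path}: not a spectral-library container")
        if "grid" not in fh:
            return SpectralLibrary(entries=[])
        grid = fh["grid"][()]
        inten = fh["intensities"][()]
        names = [n.decode() if isinstance(n, bytes) else n for n in fh["names"][()]]
        metas = [json.loads(m) for m in fh["meta"][()]]
    entries = [
        Spectrum(grid.copy(), row, name=name, meta=meta)
        for row, name, meta in zip(inten, names, metas)
    ]
    return SpectralLibrary(entries=entries)
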