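"""Plain-text readers and writers for the formats the pipeline touches.

Two-column spectra and transition tables (whitespace- or comma-delimited,
``#``/``;`` comments), XYZ and a minimal PDB subset (ATOM/HETATM
coordinates, atom names and residue numbers only), and JSON fit reports.
All I/O is UTF-8.  Readers normalize spectra to ascending wavelength and
fail loudly — with line numbers — rather than guessing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectra import Spectrum, TransitionSet


class ParseError(ValueError):
    """A text file could not be parsed; message carries the line number."""


@dataclass
class GeometryRecord:
    """Atomic geometry: element symbols and Cartesian coordinates in Angstrom.

    ``atom_names`` (PDB-style, e.g. N/CA/C/O) and ``residue_index`` are
    populated when the source format carries them (PDB); XYZ input leaves
    them ``None``.
    """

    atom_symbols: list[str]
    coords_angstrom: np.ndarray
    atom_names: list[str] | None = None
    residue_index: list[int] | None = None

    def __post_init__(self) -> None:
        self.coords_angstrom = np.asarray(self.coords_angstrom, dtype=float).reshape(-1, 3)
        if len(self.atom_symbols) != len(self.coords_angstrom):
            raise ValueError("symbol list and coordinate list differ in length")
        if self.atom_names is not None and len(self.atom_names) != len(self.atom_symbols):
            raise ValueError("atom_names length mismatch")
        if self.residue_index is not None:
            if len(self.residue_index) != len(self.atom_symbols):
                raise ValueError("residue_index length mismatch")
            if any(b < a for a, b in zip(self.residue_index, self.residue_index[1:])):
                raise ValueError("residue indices must be non-decreasing")

    def __len__(self) -> int:
        return len(self.atom_symbols)


def _data_lines(path: str | Path):
    """Yield (lineno, payload) for non-blank, non-comment lines."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith(";"):
                continue
            yield lineno, line


def _two_columns(line: str, lineno: int, path: str | Path) -> tuple[float, float]:
    fields = line.replace(",", " ").split()
    if len(fields) < 2:
        raise ParseError(f"{path}:{lineno}: expected at least 2 numeric fields")
    try:
        return float(fields[0]), float(fields[1])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: malformed numeric field: {line!r}") from exc


def read_spectrum_table(path: str | Path, unit_tag: str = "arbitrary") -> Spectrum:
    """Read a two-column wavelength/value table into a :class:`Spectrum`.

    Either wavelength ordering is accepted on disk; the result is always
    ascending.  Duplicate wavelengths are rejected rather than averaged, so
    acquisition glitches surface instead of being silently smoothed over.
    """
    wl, vals = [], []
    for lineno, line in _data_lines(path):
        w, v = _two_columns(line, lineno, path)
        wl.append(w)
        vals.append(v)
    if len(wl) < 2:
        raise ParseError(f"{path}: a spectrum needs at least 2 points, got {len(wl)}")
    wl_arr = np.asarray(wl)
    vals_arr = np.asarray(vals)
    order = np.argsort(wl_arr, kind="stable")
    wl_arr, vals_arr = wl_arr[order], vals_arr[order]
    if np.any(np.diff(wl_arr) == 0):
        dup = wl_arr[np.flatnonzero(np.diff(wl_arr) == 0)[0]]
        raise ParseError(f"{path}: duplicate wavelength {dup:g} nm")
    return Spectrum(wl_arr, vals_arr, unit_tag)


def write_spectrum_table(spec: Spectrum, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# wavelength_nm value ({spec.unit})\n")
        for w, v in zip(spec.wavelengths_nm, spec.values):
            fh.write(f"{w:.9g} {v:.12g}\n")


def read_transitions_table(path: str | Path) -> TransitionSet:
    """Read a two-column wavelength / rotational-strength table.

    Zero-strength lines are retained; an empty file is a valid empty set.
    """
    wl, st = [], []
    for lineno, line in _data_lines(path):
        w, r = _two_columns(line, lineno, path)
        if w <= 0:
            raise ParseError(f"{path}:{lineno}: transition wavelength must be > 0, got {w:g}")
        wl.append(w)
        st.append(r)
    return TransitionSet(np.asarray(wl), np.asarray(st))


def write_transitions_table(transitions: TransitionSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# wavelength_nm rotational_strength\n")
        for w, r in zip(transitions.wavelengths_nm, transitions.strengths):
            fh.write(f"{w:.9g} {r:.12g}\n")


# --- geometries -----------------------------------------------------------


def read_geometry(path: str | Path, format: str | None = None) -> GeometryRecord:
    """Read an XYZ file or a minimal PDB (first model, ATOM/HETATM only).

    ``format`` is ``"xyz"`` or ``"pdb"``; when omitted it is taken from the
    file suffix.
    """
    if format is None:
        format = Path(path).suffix.lstrip(".").lower()
    if format == "xyz":
        return _read_xyz(path)
    if format == "pdb":
        return _read_pdb(path)
    raise ValueError(f"unsupported geometry format {format!r} (expected 'xyz' or 'pdb')")


def _read_xyz(path: str | Path) -> GeometryRecord:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty XYZ file")
    try:
        count = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}:1: XYZ count line is not an integer") from exc
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != count:
        raise ParseError(
            f"{path}: XYZ header declares {count} atoms but body has {len(body)}"
        )
    symbols, coords = [], []
    for off, line in enumerate(body):
        fields = line.split()
        if len(fields) < 4:
            raise ParseError(f"{path}:{off + 3}: expected 'symbol x y z'")
        try:
            xyz = [float(f) for f in fields[1:4]]
        except ValueError as exc:
            raise ParseError(f"{path}:{off + 3}: malformed coordinate") from exc
        symbols.append(fields[0])
        coords.append(xyz)
    return GeometryRecord(symbols, np.asarray(coords))


def write_xyz(geom: GeometryRecord, path: str | Path, comment: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(geom)}\n{comment}\n")
        for sym, (x, y, z) in zip(geom.atom_symbols, geom.coords_angstrom):
            fh.write(f"{sym:<3s} {x:15.9f} {y:15.9f} {z:15.9f}\n")


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    return (name[:1] if name[:1].isalpha() else name[1:2]).upper()


def _read_pdb(path: str | Path) -> GeometryRecord:
    symbols, coords, names, resids = [], [], [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "ENDMDL":
                break  # first model only
            if rec not in ("ATOM", "HETATM"):
                continue
            try:
                names.append(line[12:16].strip())
                resids.append(int(line[22:26]))
                coords.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: unparsable ATOM/HETATM record") from exc
            element = line[76:78].strip() if len(line) >= 78 else ""
            symbols.append(element or _guess_element(names[-1]))
    if not symbols:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return GeometryRecord(symbols, np.asarray(coords), names, resids)


def write_pdb(geom: GeometryRecord, path: str | Path, residue_names: list[str] | None = None) -> None:
    """Write a minimal single-chain PDB (coordinates, names, residue numbers)."""
    names = geom.atom_names or [s.upper() for s in geom.atom_symbols]
    resids = geom.residue_index or [1] * len(geom)
    with open(path, "w", encoding="utf-8") as fh:
        for i, (sym, name, resid, (x, y, z)) in enumerate(
            zip(geom.atom_symbols, names, resids, geom.coords_angstrom), start=1
        ):
            resname = residue_names[resid - 1] if residue_names else "UNK"
            fh.write(
                f"ATOM  {i:5d} {name:<4s} {resname:<3s} A{resid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {sym:>2s}\n"
            )
        fh.write("END\n")


# --- fit reports ----------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a conformer-population fit.

    ``weights`` are non-negative abundances (fractions, not percent) of the
    chosen conformer subset; ``similarity`` is the cosine between the fitted
    combination and the target spectrum (``None`` when the subset is empty).
    ``settings`` echoes the fit configuration so any reported abundance is
    traceable to its HWHM / grid / constraint choices.
    """

    subset: list[str]
    weights: np.ndarray
    similarity: float | None
    settings: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.subset):
            raise ValueError("one weight per subset member required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    @property
    def weights_percent(self) -> np.ndarray:
        return 100.0 * self.weights


def write_fit_report(fit: FitResult, path: str | Path) -> None:
    """Serialize a fit result to JSON (weights reported as percentages)."""
    doc = {
        "conformers": list(fit.subset),
        "weights_percent": [float(w) for w in fit.weights_percent],
        "similarity": None if fit.similarity is None else float(fit.similarity),
        "settings": fit.settings,
        "diagnostics": fit.diagnostics,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_fit_report(path: str | Path) -> FitResult:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return FitResult(
        subset=list(doc["conformers"]),
        weights=np.asarray(doc["weights_percent"], dtype=float) / 100.0,
        similarity=doc["similarity"],
        settings=doc.get("settings", {}),
        diagnostics=doc.get("diagnostics", {}),
    )
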