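"""Emission-scan data model and delimited-file I/O.

A scan is a two-column CSV (``wavelength_nm,intensity``) with optional
``#``-prefixed comment lines and at most one header line.  Metadata
(excitation wavelength, condition label, replicate id, slit bandpass,
integration time) is embedded in ``# key: value`` comments by
:func:`write_scan` and recovered by :func:`read_scan`; keyword arguments to
:func:`read_scan` override embedded values.

Emission points at or below ``excitation + bandpass`` are excluded at read
time (Rayleigh-scatter contract); the second-order grating line at twice the
excitation wavelength is *not* removed unless requested, since deep-UV scans
legitimately carry signal there.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "SpectrumGroup",
    "Table1Block",
    "Table1Fixture",
    "ScanFormatError",
    "read_scan",
    "write_scan",
    "read_manifest",
    "write_manifest",
    "load_table1",
]

#: tolerance for declaring two replicate wavelength grids identical (nm)
GRID_TOL_NM = 1e-6

_META_KEYS = ("excitation_nm", "condition", "replicate_id", "bandpass_nm", "integration_s")


class ScanFormatError(ValueError):
    """Raised for malformed scan files; message names the offending line."""


@dataclass(eq=False)
class Spectrum:
    """One emission scan at a single excitation wavelength.

    Parameters
    ----------
    excitation_nm
        Excitation wavelength in nm.
    wavelengths
        Strictly increasing emission wavelengths (nm); all above
        ``excitation_nm``.
    intensities
        Non-negative intensities in arbitrary units, same length as
        ``wavelengths``.
    condition
        Group label, typically ``"AD"`` or ``"N"``.
    replicate_id
        Identifier of the replicate scan within its group.
    bandpass_nm
        Monochromator slit bandpass (nm).
    integration_s
        Detector integration time per point (s).
    """

    excitation_nm: float
    wavelengths: np.ndarray
    intensities: np.ndarray
    condition: str = "other"
    replicate_id: str = "1"
    bandpass_nm: float = 2.0
    integration_s: float = 0.2

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavelengths and intensities must be 1-D")
        if len(self.wavelengths) == 0:
            raise ValueError("spectrum must contain at least one point")
        if len(self.wavelengths) != len(self.intensities):
            raise ValueError(
                f"length mismatch: {len(self.wavelengths)} wavelengths vs "
                f"{len(self.intensities)} intensities"
            )
        if not np.all(np.isfinite(self.wavelengths)) or not np.all(np.isfinite(self.intensities)):
            raise ValueError("wavelengths and intensities must be finite")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if not math.isfinite(self.excitation_nm) or self.excitation_nm <= 0:
            raise ValueError("excitation_nm must be a positive finite number")
        if self.wavelengths[0] <= self.excitation_nm:
            raise ValueError(
                f"emission wavelengths must exceed excitation "
                f"({self.wavelengths[0]:g} nm <= {self.excitation_nm:g} nm)"
            )
        self.condition = str(self.condition)
        self.replicate_id = str(self.replicate_id)

    def __len__(self) -> int:
        return len(self.wavelengths)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.excitation_nm == other.excitation_nm
            and self.condition == other.condition
            and self.replicate_id == other.replicate_id
            and self.bandpass_nm == other.bandpass_nm
            and self.integration_s == other.integration_s
            and np.array_equal(self.wavelengths, other.wavelengths)
            and np.array_equal(self.intensities, other.intensities)
        )

    def scaled(self, factor: float) -> "Spectrum":
        """Return a copy with intensities multiplied by ``factor`` (>= 0)."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return replace(self, intensities=self.intensities * factor)


@dataclass(eq=False)
class SpectrumGroup:
    """Replicate scans of one condition at one excitation wavelength."""

    excitation_nm: float
    condition: str
    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("a SpectrumGroup needs at least one spectrum")
        ref = self.spectra[0]
        for s in self.spectra:
            if s.excitation_nm != self.excitation_nm:
                raise ValueError(
                    f"replicate {s.replicate_id}: excitation {s.excitation_nm} nm "
                    f"!= group excitation {self.excitation_nm} nm"
                )
            if s.condition != self.condition:
                raise ValueError(
                    f"replicate {s.replicate_id}: condition {s.condition!r} "
                    f"!= group condition {self.condition!r}"
                )
            if len(s) != len(ref) or np.any(np.abs(s.wavelengths - ref.wavelengths) > GRID_TOL_NM):
                raise ValueError(
                    f"replicate {s.replicate_id} is not on the shared wavelength grid"
                )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.spectra[0].wavelengths

    def intensity_matrix(self) -> np.ndarray:
        """Replicate intensities stacked as an (n_replicates, n_points) array."""
        return np.stack([s.intensities for s in self.spectra])

    def scaled(self, factor: float) -> "SpectrumGroup":
        return SpectrumGroup(
            self.excitation_nm, self.condition, [s.scaled(factor) for s in self.spectra]
        )


# ---------------------------------------------------------------------------
# scan files


def _parse_value(token: str, kind: str, lineno: int, path: Path) -> float:
    try:
        return float(token)
    except ValueError:
        raise ScanFormatError(
            f"{path}: line {lineno}: non-numeric {kind} {token!r}"
        ) from None


def read_scan(
    path: str | Path,
    *,
    excitation_nm: float | None = None,
    condition: str | None = None,
    replicate_id: str | None = None,
    bandpass_nm: float | None = None,
    integration_s: float | None = None,
) -> Spectrum:
    """Parse a two-column delimited scan file into a :class:`Spectrum`.

    Keyword metadata overrides any ``# key: value`` comments embedded in the
    file.  Rows with emission wavelength at or below
    ``excitation + bandpass`` are dropped (count logged at DEBUG level).

    Raises
    ------
    ScanFormatError
        On empty files, non-numeric rows, or non-monotone wavelengths; the
        message names the offending line.
    ValueError
        If no excitation wavelength is available from either source.
    """
    path = Path(path)
    meta: dict[str, object] = {}
    wl: list[float] = []
    inten: list[float] = []
    header_seen = False
    last_wl: float | None = None

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    key = key.strip()
                    if key in _META_KEYS:
                        meta[key] = value.strip()
                continue
            parts = [p for p in line.replace("\t", ",").split(",") if p.strip() != ""]
            if len(parts) < 2:
                raise ScanFormatError(f"{path}: line {lineno}: expected two columns, got {line!r}")
            try:
                w = float(parts[0])
                i = float(parts[1])
            except ValueError:
                if not header_seen and not wl:
                    header_seen = True  # one non-numeric header line tolerated
                    continue
                raise ScanFormatError(
                    f"{path}: line {lineno}: non-numeric row {line!r}"
                ) from None
            if last_wl is not None and w <= last_wl:
                raise ScanFormatError(
                    f"{path}: line {lineno}: wavelength {w:g} not increasing "
                    f"(previous {last_wl:g})"
                )
            last_wl = w
            wl.append(w)
            inten.append(i)

    if not wl:
        raise ScanFormatError(f"{path}: line 1: no data rows")

    if excitation_nm is None:
        if "excitation_nm" not in meta:
            raise ValueError(f"{path}: excitation_nm not given and not embedded in file")
        excitation_nm = float(meta["excitation_nm"])  # type: ignore[arg-type]
    if bandpass_nm is None:
        bandpass_nm = float(meta.get("bandpass_nm", 2.0))  # type: ignore[arg-type]
    if integration_s is None:
        integration_s = float(meta.get("integration_s", 0.2))  # type: ignore[arg-type]
    if condition is None:
        condition = str(meta.get("condition", "other"))
    if replicate_id is None:
        replicate_id = str(meta.get("replicate_id", "1"))

    wl_arr = np.array(wl)
    inten_arr = np.array(inten)
    keep = wl_arr > excitation_nm + bandpass_nm
    dropped = int((~keep).sum())
    if dropped:
        logger.debug(
            "%s: dropped %d point(s) at or below excitation+bandpass (%g nm)",
            path, dropped, excitation_nm + bandpass_nm,
        )
    if not keep.any():
        raise ScanFormatError(
            f"{path}: line 1: no emission points above excitation+bandpass "
            f"({excitation_nm + bandpass_nm:g} nm)"
        )

    return Spectrum(
        excitation_nm=excitation_nm,
        wavelengths=wl_arr[keep],
        intensities=inten_arr[keep],
        condition=condition,
        replicate_id=replicate_id,
        bandpass_nm=bandpass_nm,
        integration_s=integration_s,
    )


def write_scan(spectrum: Spectrum, path: str | Path, *, header_comments: Sequence[str] = ()) -> Path:
    """Write ``spectrum`` as CSV; :func:`read_scan` recovers an equal Spectrum.

    Values are written with shortest round-trip float representation, so the
    write/read cycle is exact.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write(f"# excitation_nm: {float(spectrum.excitation_nm)!r}\n")
        fh.write(f"# condition: {spectrum.condition}\n")
        fh.write(f"# replicate_id: {spectrum.replicate_id}\n")
        fh.write(f"# bandpass_nm: {float(spectrum.bandpass_nm)!r}\n")
        fh.write(f"# integration_s: {float(spectrum.integration_s)!r}\n")
        fh.write("wavelength_nm,intensity\n")
        for w, i in zip(spectrum.wavelengths, spectrum.intensities):
            fh.write(f"{float(w)!r},{float(i)!r}\n")
    return path


# ---------------------------------------------------------------------------
# manifests


def write_manifest(
    groups: Sequence[SpectrumGroup],
    directory: str | Path,
    *,
    manifest_name: str = "manifest.yaml",
    meta: Mapping[str, object] | None = None,
    scan_comments: Sequence[str] = (),
) -> Path:
    """Write every spectrum of ``groups`` as a CSV plus a YAML manifest.

    The manifest maps ``condition -> excitation -> [scan paths]`` (relative
    to the manifest's directory). Extra metadata goes under a ``_meta`` key,
    which :func:`read_manifest` ignores.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tree: dict[str, dict[int | float, list[str]]] = {}
    for group in groups:
        ex = group.excitation_nm
        ex_key = int(ex) if float(ex).is_integer() else float(ex)
        for spec in group:
            name = f"{spec.condition}_ex{ex_key}_rep{spec.replicate_id}.csv"
            write_scan(spec, directory / name, header_comments=scan_comments)
            tree.setdefault(spec.condition, {}).setdefault(ex_key, []).append(name)
    doc: dict[str, object] = dict(tree)
    if meta:
        doc["_meta"] = dict(meta)
    manifest = directory / manifest_name
    with open(manifest, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
    return manifest


def read_manifest(path: str | Path) -> list[SpectrumGroup]:
    """Load all groups listed in a YAML manifest (paths relative to it)."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or not any(not k.startswith("_") for k in doc):
        raise ValueError(f"{path}: empty or malformed manifest")
    groups: list[SpectrumGroup] = []
    missing: list[str] = []
    for condition, per_ex in sorted(doc.items()):
        if condition.startswith("_"):
            continue
        for excitation, scan_paths in sorted(per_ex.items()):
            spectra = []
            for rel in scan_paths:
                scan_path = path.parent / rel
                if not scan_path.exists():
                    missing.append(str(scan_path))
                    continue
                spectra.append(
                    read_scan(scan_path, excitation_nm=float(excitation), condition=condition)
                )
            if missing:
                continue
            groups.append(SpectrumGroup(float(excitation), condition, spectra))
    if missing:
        raise FileNotFoundError("missing scan files: " + ", ".join(missing))
    return groups


# ---------------------------------------------------------------------------
# packaged replicate-table fixture


@dataclass(frozen=True)
class Table1Block:
    """Printed replicate rows for one (excitation, condition) block.

    Each replicate row is ``(peak1 intensity, peak2 intensity, ratio)`` in
    normalized units; ``mean`` is the printed mean row (stored verbatim, not
    recomputed — two printed mean cells disagree with recomputation from the
    replicate rows in the source table and are kept as printed).
    """

    excitation_nm: int
    condition: str
    replicates: tuple[tuple[float, float, float], ...]
    mean: tuple[float, float, float]

    @property
    def peak1(self) -> tuple[float, ...]:
        return tuple(r[0] for r in self.replicates)

    @property
    def peak2(self) -> tuple[float, ...]:
        return tuple(r[1] for r in self.replicates)

    @property
    def ratios(self) -> tuple[float, ...]:
        return tuple(r[2] for r in self.replicates)


@dataclass(frozen=True)
class Table1Fixture:
    """Packaged published replicate peak intensities and ratios."""

    blocks: Mapping[tuple[int, str], Table1Block]
    peak_labels: Mapping[int, tuple[tuple[str, int], tuple[str, int]]]

    def __getitem__(self, key: tuple[int, str]) -> Table1Block:
        excitation, condition = key
        return self.blocks[(int(excitation), condition)]

    @property
    def excitations(self) -> tuple[int, ...]:
        return tuple(sorted({ex for ex, _ in self.blocks}))

    @property
    def conditions(self) -> tuple[str, ...]:
        return ("AD", "N")

    def fluorophores(self, excitation_nm: int) -> tuple[str, str]:
        (f1, _), (f2, _) = self.peak_labels[int(excitation_nm)]
        return f1, f2


def load_table1() -> Table1Fixture:
    """Load the packaged replicate table of published peak values."""
    text = resources.files("fluorospec.data").joinpath("table1.json").read_text("utf-8")
    raw = json.loads(text)
    blocks: dict[tuple[int, str], Table1Block] = {}
    labels: dict[int, tuple[tuple[str, int], tuple[str, int]]] = {}
    for ex_str, entry in raw.items():
        ex = int(ex_str)
        p1 = entry["peak_labels"]["peak1"]
        p2 = entry["peak_labels"]["peak2"]
        labels[ex] = (
            (p1["fluorophore"], int(p1["wavelength_nm"])),
            (p2["fluorophore"], int(p2["wavelength_nm"])),
        )
        for condition in ("AD", "N"):
            block = entry[condition]
            blocks[(ex, condition)] = Table1Block(
                excitation_nm=ex,
                condition=condition,
                replicates=tuple(tuple(row) for row in block["replicates"]),
                mean=tuple(block["mean"]),
            )
    return Table1Fixture(blocks=blocks, peak_labels=labels)
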