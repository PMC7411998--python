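"""Centroided MS/MS spectra and MGF input/output.

A :class:`Spectrum` is a precursor plus a sorted centroid peak list, tagged
with its provenance (``sample``, ``medium_blank`` or ``solvent_blank``) so
that blank-derived nodes can be excluded later in the pipeline.

The on-disk carrier is MGF (Mascot Generic Format):

    BEGIN IONS
    TITLE=<id>
    PEPMASS=<precursor m/z>
    CHARGE=1+
    SOURCE=<label>            (optional; defaults to sample)
    RTINSECONDS=<rt>          (optional)
    <mz> <intensity>
    ...
    END IONS

Reading is delegated to :mod:`pyteomics.mgf`; writing uses a deterministic
serializer (fixed field order, 6-decimal m/z, 4-significant-digit intensity)
so that identical inputs always produce byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from pyteomics import mgf as _mgf

__all__ = ["Peak", "Spectrum", "SOURCE_LABELS", "read_mgf", "write_mgf"]

SOURCE_LABELS = ("sample", "medium_blank", "solvent_blank")


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass(frozen=True)
class Spectrum:
    """One centroided MS/MS spectrum."""

    id: str
    precursor_mz: float
    peaks: tuple[Peak, ...] = ()
    charge: int = 1
    source: str = "sample"
    retention_time: float | None = None

    def __post_init__(self) -> None:
        if self.precursor_mz <= 50:
            raise ValueError(f"implausible precursor m/z {self.precursor_mz} (must be > 50)")
        if self.source not in SOURCE_LABELS:
            raise ValueError(f"unknown source label {self.source!r}")
        merged: dict[float, float] = {}
        for p in self.peaks:
            if p.mz <= 0:
                raise ValueError(f"non-positive peak m/z {p.mz}")
            if p.intensity < 0:
                raise ValueError(f"negative intensity at m/z {p.mz}")
            key = round(p.mz, 6)
            # duplicate centroids at 6-decimal resolution merge by intensity sum
            merged[key] = merged.get(key, 0.0) + p.intensity
        object.__setattr__(
            self, "peaks", tuple(Peak(mz, i) for mz, i in sorted(merged.items()))
        )

    @property
    def mz(self):  # convenience array view
        import numpy as np

        return np.fromiter((p.mz for p in self.peaks), float, len(self.peaks))

    @property
    def intensity(self):
        import numpy as np

        return np.fromiter((p.intensity for p in self.peaks), float, len(self.peaks))

    def with_peaks(self, peaks: Iterable[Peak]) -> "Spectrum":
        return replace(self, peaks=tuple(peaks))

    @property
    def is_blank(self) -> bool:
        return self.source.endswith("_blank")


class MGFFormatError(ValueError):
    pass


def _parse_entry(entry: dict, index: int, path: str) -> Spectrum:
    params = entry.get("params", {})
    try:
        pepmass = params["pepmass"]
        precursor = pepmass[0] if isinstance(pepmass, (tuple, list)) else float(pepmass)
        title = str(params.get("title", f"scan_{index}"))
        charge = int(params["charge"][0]) if "charge" in params else 1
        source = str(params.get("source", "sample")).lower()
        rt = params.get("rtinseconds")
        rt = float(rt) if rt is not None else None
        peaks = [Peak(float(m), float(i)) for m, i in zip(entry["m/z array"], entry["intensity array"])]
        return Spectrum(
            id=title,
            precursor_mz=float(precursor),
            peaks=tuple(peaks),
            charge=charge,
            source=source,
            retention_time=rt,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise MGFFormatError(f"{path}: malformed MGF block {index}: {exc}") from exc


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into a list of spectra (one per BEGIN IONS block).

    Peaks are sorted ascending on load; a ``SOURCE=`` line sets the
    provenance label (default ``sample``).  Malformed blocks raise
    :class:`MGFFormatError` naming the block index; an empty file yields an
    empty list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for index, entry in enumerate(reader):
            spectra.append(_parse_entry(entry, index, str(path)))
    return spectra


def _format_intensity(value: float) -> str:
    if value == 0:
        return "0"
    # 4 significant digits, plain decimal notation
    digits = 3 - int(math.floor(math.log10(abs(value))))
    return f"{value:.{max(digits, 0)}f}"


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Serialize spectra to MGF deterministically (see module docstring)."""
    path = Path(path)
    lines: list[str] = []
    for s in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={s.id}")
        lines.append(f"PEPMASS={s.precursor_mz:.6f}")
        sign = "+" if s.charge >= 0 else "-"
        lines.append(f"CHARGE={abs(s.charge)}{sign}")
        lines.append(f"SOURCE={s.source}")
        if s.retention_time is not None:
            lines.append(f"RTINSECONDS={s.retention_time:.3f}")
        for p in s.peaks:
            lines.append(f"{p.mz:.6f} {_format_intensity(p.intensity)}")
        lines.append("END IONS")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
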