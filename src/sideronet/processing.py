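"""Spectrum-cleaning filters applied before similarity scoring.

These are the standard molecular-networking preprocessing steps: removal of
fragment ions near the precursor (which carry no structural information and
inflate self-similarity), a sliding window filter keeping only the locally
most intense centroids, and precursor-level blank subtraction.  All filters
are pure functions: they return new spectra and never mutate their input.
Both peak filters are idempotent and never increase the peak count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .spectra import Spectrum

__all__ = [
    "remove_precursor_window",
    "window_filter_top_k",
    "subtract_blanks",
    "BlankSubtractionReport",
]


def remove_precursor_window(s: Spectrum, half_width: float = 17.0) -> Spectrum:
    """Drop fragment peaks within +/- ``half_width`` Da of the precursor m/z.

    The interval is closed: a peak exactly ``half_width`` away is removed.
    """
    kept = [p for p in s.peaks if abs(p.mz - s.precursor_mz) > half_width]
    return s.with_peaks(kept)


def window_filter_top_k(s: Spectrum, k: int = 6, half_width: float = 50.0) -> Spectrum:
    """Keep a peak only if it ranks among the ``k`` most intense peaks within
    the +/- ``half_width`` Da neighborhood centred on itself.

    This is the sliding per-peak neighborhood rule (each peak judged in its
    own window), with intensity ties broken in favour of the lower m/z.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    peaks = s.peaks
    kept = []
    for p in peaks:
        stronger = 0
        for q in peaks:
            if abs(q.mz - p.mz) <= half_width and (
                q.intensity > p.intensity
                or (q.intensity == p.intensity and q.mz < p.mz)
            ):
                stronger += 1
        if stronger < k:
            kept.append(p)
    return s.with_peaks(kept)


@dataclass
class BlankSubtractionReport:
    """Which sample spectra were dropped, and which blank they matched."""

    dropped: list[tuple[str, str, float]] = field(default_factory=list)
    # (sample id, blank id, precursor delta in ppm)

    @property
    def dropped_ids(self) -> list[str]:
        return [d[0] for d in self.dropped]


def subtract_blanks(
    spectra: list[Spectrum],
    ppm_tol: float = 10.0,
    rt_tol: float | None = None,
) -> tuple[list[Spectrum], BlankSubtractionReport]:
    """Exclude sample spectra whose precursor matches any blank precursor.

    Matching is precursor-level (whole spectra are dropped, not peaks) within
    ``ppm_tol``; if ``rt_tol`` is given, retention times must also agree
    within that many seconds (spectra lacking a retention time always match
    on that axis).  Blank spectra themselves are not returned.
    """
    blanks = [s for s in spectra if s.is_blank]
    samples = [s for s in spectra if not s.is_blank]
    report = BlankSubtractionReport()
    if not blanks:
        warnings.warn("subtract_blanks called without any blank spectra; nothing removed")
        return samples, report
    kept = []
    for s in samples:
        hit = None
        for b in blanks:
            delta_ppm = 1e6 * abs(s.precursor_mz - b.precursor_mz) / b.precursor_mz
            if delta_ppm > ppm_tol:
                continue
            if (
                rt_tol is not None
                and s.retention_time is not None
                and b.retention_time is not None
                and abs(s.retention_time - b.retention_time) > rt_tol
            ):
                continue
            hit = (s.id, b.id, delta_ppm)
            break
        if hit is None:
            kept.append(s)
        else:
            report.dropped.append(hit)
    return kept, report
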