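"""Centroided spectra and plain-text peak-list I/O.

Peaks are held as parallel numpy arrays sorted ascending in m/z.  The on-disk
format is a TSV with columns ``mz`` and ``intensity`` (one file per scan) or
``scan_id``, ``mz``, ``intensity`` for multi-scan containers; ``#`` comment
lines before the header may carry ``key=value`` metadata such as the
precursor mass of a fragment scan (``# precursor_mass_da=...``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, NamedTuple, Optional, Tuple, Union

import numpy as np

#: m/z gap below which two centroids are considered duplicates, Th.
DUPLICATE_MZ_EPS = 1e-6


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """A centroided spectrum: sorted m/z and intensity arrays plus metadata.

    ``resolution_mode`` distinguishes medium-resolution full scans (isotopes
    unresolved, charge inferred from envelope spacing) from high-resolution
    scans.
    """

    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    resolution_mode: str = "medium"
    scan_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity length mismatch")
        if self.mz.size:
            if not np.all(np.isfinite(self.mz)) or not np.all(np.isfinite(self.intensity)):
                raise ValueError("non-finite peak values")
            if np.any(self.mz <= 0) or np.any(self.intensity < 0):
                raise ValueError("peaks require mz > 0 and intensity >= 0")
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            if np.any(np.diff(self.mz) < DUPLICATE_MZ_EPS):
                raise ValueError(
                    f"duplicate m/z within {DUPLICATE_MZ_EPS} Th; merge peaks first"
                )
        if self.ms_level not in (1, 2):
            raise ValueError(f"ms_level must be 1 or 2, got {self.ms_level}")
        if self.resolution_mode not in ("medium", "high"):
            raise ValueError(f"unknown resolution_mode {self.resolution_mode!r}")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> List[Peak]:
        return [Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensity)]

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0

    @classmethod
    def from_peaks(
        cls,
        peaks: Iterable[Tuple[float, float]],
        merge_duplicates: bool = True,
        **kwargs,
    ) -> "Spectrum":
        """Build a spectrum, summing intensities of near-coincident centroids."""
        pk = sorted((float(m), float(i)) for m, i in peaks)
        mz: List[float] = []
        inten: List[float] = []
        for m, i in pk:
            if merge_duplicates and mz and m - mz[-1] < DUPLICATE_MZ_EPS:
                inten[-1] += i
            else:
                mz.append(m)
                inten.append(i)
        return cls(np.array(mz), np.array(inten), **kwargs)


def _parse_metadata(lines: List[str]) -> dict:
    meta = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if "=" in body:
            k, v = body.split("=", 1)
            k, v = k.strip(), v.strip()
            try:
                meta[k] = float(v)
            except ValueError:
                meta[k] = v
    return meta


def read_peaklist_tsv(
    path: Union[str, Path],
    ms_level: int = 1,
    resolution_mode: str = "medium",
) -> Spectrum:
    """Read a single-scan peak-list TSV (columns mz, intensity)."""
    path = Path(path)
    comments: List[str] = []
    rows: List[Tuple[float, float]] = []
    header_seen = False
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            comments.append(ln)
            continue
        parts = ln.split("\t")
        if not header_seen:
            header_seen = True
            if parts[0].lower() == "mz":
                continue
        rows.append((float(parts[0]), float(parts[1])))
    meta = _parse_metadata(comments)
    mode = meta.get("resolution_mode", resolution_mode)
    level = int(meta.get("ms_level", ms_level))
    return Spectrum.from_peaks(
        rows, ms_level=level, resolution_mode=str(mode), scan_id=path.stem,
        metadata=meta,
    )


def write_peaklist_tsv(
    path: Union[str, Path],
    spectrum: Spectrum,
    metadata: Optional[dict] = None,
) -> None:
    """Write a scan as TSV; metadata (and spectrum metadata) become # comments."""
    meta = dict(spectrum.metadata)
    if metadata:
        meta.update(metadata)
    meta.setdefault("ms_level", spectrum.ms_level)
    meta.setdefault("resolution_mode", spectrum.resolution_mode)
    lines = [f"# {k}={v}" for k, v in sorted(meta.items())]
    lines.append("mz\tintensity")
    for m, i in zip(spectrum.mz, spectrum.intensity):
        lines.append(f"{m:.6f}\t{i:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_multiscan_tsv(path: Union[str, Path], ms_level: int = 1) -> List[Spectrum]:
    """Read a 3-column TSV (scan_id, mz, intensity) into one Spectrum per scan."""
    by_scan: dict = {}
    header_seen = False
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if not header_seen:
            header_seen = True
            if parts[0].lower() in ("scan_id", "scan"):
                continue
        by_scan.setdefault(parts[0], []).append((float(parts[1]), float(parts[2])))
    return [
        Spectrum.from_peaks(rows, ms_level=ms_level, scan_id=sid)
        for sid, rows in by_scan.items()
    ]


def write_multiscan_tsv(path: Union[str, Path], spectra: Iterable[Spectrum]) -> None:
    lines = ["scan_id\tmz\tintensity"]
    for s in spectra:
        for m, i in zip(s.mz, s.intensity):
            lines.append(f"{s.scan_id}\t{m:.6f}\t{i:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")
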