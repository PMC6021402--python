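"""Charge assignment and neutral-mass inference for isotopically unresolved spectra.

Two entry points mirror the two acquisition regimes:

* :func:`fit_envelope` — fit one charge-state envelope by scanning all
  consecutive-charge assignments and minimizing the RMS *relative* deviation
  of the per-peak implied masses (native MS; works from 5 kDa to multi-MDa
  because the error functional is scale-free).
* :func:`deconvolute_scan` — greedy on-line extraction of every envelope in a
  medium-resolution full scan: seed on the most intense unassigned peak, grow
  a consecutive-charge series along predicted m/z positions, accept when long
  and self-consistent enough.  This emulates on-the-fly full-scan
  deconvolution used to drive data-dependent precursor selection.

Plus the supporting pieces: charge from adjacent-peak spacing, precursor
selection with proteoform-level dynamic exclusion, scan combining, and
tolerant mass-list matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import PROTON_MASS, mass_from_mz, mz_from_mass
from .spectra import Spectrum

#: Default ceiling on the envelope RMS relative mass error (medium resolution).
DEFAULT_RMS_CEILING = 2e-4

#: Charge-assignment ties within this rms difference pick the lower charge.
_TIE_EPS = 1e-12


@dataclass
class EnvelopeFit:
    """One fitted charge-state envelope.

    ``charges`` are strictly consecutive and descend with increasing m/z;
    ``neutral_mass`` is the intensity-weighted mean of the per-peak implied
    masses, ``mass_sd`` their (unweighted) standard deviation — reported as
    the familiar "M ± sd" native-MS style.
    """

    peak_indices: np.ndarray
    charges: np.ndarray
    neutral_mass: float
    mass_sd: float
    rms_relative_error: float
    intensity_sum: float
    runner_up_rms: float = float("inf")

    @property
    def charge_range(self) -> Tuple[int, int]:
        return int(self.charges.min()), int(self.charges.max())


@dataclass
class DeconvolvedMass:
    """A neutral mass extracted from a full scan, with its member peaks."""

    mass: float
    total_intensity: float
    best_charge: int
    member_peaks: np.ndarray
    member_mzs: np.ndarray
    member_charges: np.ndarray
    member_intensities: np.ndarray
    source_scan: str = ""
    mass_sd: float = 0.0
    rms_relative_error: float = 0.0


@dataclass
class ExclusionEntry:
    """Dynamic-exclusion record for one already-selected proteoform mass."""

    mass: float
    excluded_mz_windows: List[Tuple[float, float]]
    expiry: int

    def __post_init__(self):
        # normalize: sort and merge overlapping windows
        wins = sorted(self.excluded_mz_windows)
        merged: List[Tuple[float, float]] = []
        for lo, hi in wins:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
            else:
                merged.append((lo, hi))
        self.excluded_mz_windows = merged


@dataclass
class PrecursorSelection:
    """One isolation target: the single most intense charge state of a proteoform."""

    mass: float
    charge: int
    mz: float
    intensity: float
    source: DeconvolvedMass


def infer_charge_from_spacing(mz_high: float, mz_low: float) -> Tuple[int, float]:
    """Charge of the higher-m/z peak from the spacing of two adjacent charge states.

    For one species at consecutive charges z (higher m/z) and z+1,
    z = (mz_low − m_proton) / (mz_high − mz_low).  Returns (rounded, raw).
    """
    spacing = mz_high - mz_low
    if spacing <= 0:
        raise ValueError("nonpositive m/z spacing between adjacent charge states")
    if mz_low <= PROTON_MASS:
        raise ValueError("m/z at or below the proton mass")
    estimate = (mz_low - PROTON_MASS) / spacing
    return int(round(estimate)), estimate


def fit_envelope(
    s: Spectrum,
    candidate_peaks: Sequence[int],
    charge_range: Tuple[int, int],
    rms_ceiling: float = DEFAULT_RMS_CEILING,
) -> Optional[EnvelopeFit]:
    """Fit consecutive charges to the candidate peaks by error minimization.

    Every assignment giving the highest-m/z peak a charge z in
    ``charge_range`` (peaks below it z+1, z+2, ...) is scored by the RMS
    relative deviation of implied masses from their mean; the minimum wins,
    ties (within 1e-12) going to the lower charge.  Returns ``None`` when no
    assignment beats ``rms_ceiling`` ("no consistent envelope").
    """
    idx = np.asarray(sorted(candidate_peaks, key=lambda i: s.mz[i]), dtype=int)
    if idx.size < 2:
        raise ValueError("need at least 2 candidate peaks")
    z_min, z_max = charge_range
    if not (1 <= z_min < z_max <= 200):
        raise ValueError(f"bad charge range {charge_range}")
    mzs = s.mz[idx]
    intens = s.intensity[idx]
    n = idx.size
    best_z = None
    best_rms = np.inf
    runner_up = np.inf
    for z_top in range(z_min, z_max + 1):
        charges = z_top + np.arange(n - 1, -1, -1)  # descending with m/z
        masses = charges * (mzs - PROTON_MASS)
        mean = masses.mean()
        rms = np.sqrt(np.mean(((masses - mean) / mean) ** 2))
        if rms < best_rms - _TIE_EPS:
            runner_up = best_rms
            best_rms = rms
            best_z = z_top
        elif rms < runner_up:
            runner_up = rms
    if best_z is None or best_rms > rms_ceiling:
        return None
    charges = best_z + np.arange(n - 1, -1, -1)
    masses = charges * (mzs - PROTON_MASS)
    neutral = float(np.average(masses, weights=intens)) if intens.sum() > 0 else float(masses.mean())
    return EnvelopeFit(
        peak_indices=idx,
        charges=charges,
        neutral_mass=neutral,
        mass_sd=float(masses.std(ddof=0)),
        rms_relative_error=float(best_rms),
        intensity_sum=float(intens.sum()),
        runner_up_rms=float(runner_up),
    )


def deconvolute_scan(
    s: Spectrum,
    charge_range: Tuple[int, int] = (5, 100),
    mass_range: Tuple[float, float] = (5_000.0, 100_000.0),
    min_series_length: int = 3,
    mz_tol_ppm: float = 20.0,
    rms_ceiling: float = DEFAULT_RMS_CEILING,
    abundance_threshold: float = 0.10,
) -> Tuple[List[DeconvolvedMass], pd.DataFrame]:
    """Greedy full-scan deconvolution: assign charge and mass to every peak.

    Repeatedly seeds on the most intense unassigned peak above
    ``abundance_threshold`` × base peak (per-scan base-peak semantics), tries
    every seed charge in range, grows a consecutive-charge series at predicted
    m/z positions within ``mz_tol_ppm``, and accepts the best series if it has
    at least ``min_series_length`` members and an envelope RMS below the
    ceiling.  Returns masses sorted by total intensity (descending) and a
    per-peak assignment table (peak index, mz, intensity, charge, mass,
    series id; unassigned peaks carry series id −1).
    """
    if s.ms_level != 1:
        raise ValueError("deconvolute_scan expects an MS1 spectrum")
    n = len(s)
    results: List[DeconvolvedMass] = []
    assigned = np.zeros(n, dtype=bool)
    series_of = np.full(n, -1, dtype=int)
    charge_of = np.zeros(n, dtype=int)
    mass_of = np.full(n, np.nan)
    if n == 0:
        return results, _assignment_table(s, series_of, charge_of, mass_of)
    z_min, z_max = charge_range
    base = s.base_peak_intensity
    order = np.argsort(-s.intensity, kind="stable")

    def find_peak(target_mz: float, tol: float) -> int:
        lo = np.searchsorted(s.mz, target_mz - tol)
        hi = np.searchsorted(s.mz, target_mz + tol)
        best, best_d = -1, tol
        for j in range(lo, hi):
            if assigned[j]:
                continue
            d = abs(s.mz[j] - target_mz)
            if d <= best_d:
                best, best_d = j, d
        return best

    for seed in order:
        if assigned[seed] or s.intensity[seed] < abundance_threshold * base:
            continue
        best_series: Optional[Tuple[List[int], List[int], float]] = None
        for z_seed in range(z_min, z_max + 1):
            m_est = mass_from_mz(s.mz[seed], z_seed)
            if not (mass_range[0] <= m_est <= mass_range[1]):
                continue
            members = [seed]
            charges = [z_seed]
            # grow to higher charges (lower m/z) then lower charges
            for direction in (1, -1):
                z = z_seed + direction
                while z_min <= z <= z_max:
                    pred = mz_from_mass(m_est, z)
                    j = find_peak(pred, pred * mz_tol_ppm * 1e-6)
                    if j < 0 or j in members:
                        break
                    members.append(j)
                    charges.append(z)
                    z += direction
            if len(members) < min_series_length:
                continue
            marr = np.array([mass_from_mz(s.mz[j], z) for j, z in zip(members, charges)])
            mean = marr.mean()
            rms = float(np.sqrt(np.mean(((marr - mean) / mean) ** 2)))
            if rms > rms_ceiling:
                continue
            key = (len(members), -rms)
            if best_series is None or key > (len(best_series[0]), -best_series[2]):
                best_series = (members, charges, rms)
        if best_series is None:
            continue
        members, charges, rms = best_series
        order_mz = np.argsort([s.mz[j] for j in members])
        members = [members[k] for k in order_mz]
        charges = [charges[k] for k in order_mz]
        marr = np.array([mass_from_mz(s.mz[j], z) for j, z in zip(members, charges)])
        inten = s.intensity[members]
        mass = float(np.average(marr, weights=inten))
        sid = len(results)
        for j, z, m in zip(members, charges, marr):
            assigned[j] = True
            series_of[j] = sid
            charge_of[j] = z
            mass_of[j] = m
        best_charge = int(charges[int(np.argmax(inten))])
        results.append(
            DeconvolvedMass(
                mass=mass,
                total_intensity=float(inten.sum()),
                best_charge=best_charge,
                member_peaks=np.array(members, dtype=int),
                member_mzs=s.mz[members].copy(),
                member_charges=np.array(charges, dtype=int),
                member_intensities=inten.copy(),
                source_scan=s.scan_id,
                mass_sd=float(marr.std(ddof=0)),
                rms_relative_error=rms,
            )
        )
    results.sort(key=lambda d: -d.total_intensity)
    return results, _assignment_table(s, series_of, charge_of, mass_of)


def _assignment_table(s, series_of, charge_of, mass_of) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak": np.arange(len(s)),
            "mz": s.mz,
            "intensity": s.intensity,
            "series": series_of,
            "charge": charge_of,
            "mass": mass_of,
        }
    )


def select_precursors(
    deconvolved: Sequence[DeconvolvedMass],
    top_n: int = 3,
    exclusion: Optional[List[ExclusionEntry]] = None,
    mass_tol: float = 1.0,
    isolation_width: float = 2.0,
    expiry_scans: int = 5,
) -> Tuple[List[PrecursorSelection], List[ExclusionEntry]]:
    """Pick up to ``top_n`` proteoform masses for fragmentation.

    For each selected mass the single most intense charge state is isolated;
    m/z windows of all its *other* charge states join the exclusion list (the
    proteoform mass itself is excluded for ``expiry_scans`` subsequent calls),
    removing the redundancy of re-fragmenting other charge states of the same
    proteoform.  Pre-existing exclusion entries are aged by one scan.
    """
    exclusion = [replace(e, excluded_mz_windows=list(e.excluded_mz_windows), expiry=e.expiry - 1)
                 for e in (exclusion or [])]
    exclusion = [e for e in exclusion if e.expiry > 0]
    selections: List[PrecursorSelection] = []
    half = isolation_width / 2.0
    ranked = sorted(deconvolved, key=lambda d: -d.total_intensity)
    for d in ranked:
        if len(selections) >= top_n:
            break
        if any(abs(d.mass - e.mass) <= mass_tol for e in exclusion):
            continue
        if any(abs(d.mass - sel.mass) <= mass_tol for sel in selections):
            continue
        k = int(np.argmax(d.member_intensities))
        selections.append(
            PrecursorSelection(
                mass=d.mass,
                charge=int(d.member_charges[k]),
                mz=float(d.member_mzs[k]),
                intensity=float(d.member_intensities[k]),
                source=d,
            )
        )
        windows = [
            (float(mz - half), float(mz + half))
            for j, mz in enumerate(d.member_mzs)
            if j != k
        ]
        exclusion.append(
            ExclusionEntry(mass=d.mass, excluded_mz_windows=windows, expiry=expiry_scans)
        )
    return selections, exclusion


def combine_scans(spectra: Sequence[Spectrum], mz_tol_ppm: float = 10.0) -> Spectrum:
    """Merge repeated scans of the same species into one averaged spectrum.

    Peaks within ``mz_tol_ppm`` across scans are clustered; each cluster
    reports the intensity-weighted mean m/z and the summed intensity.
    """
    if not spectra:
        raise ValueError("no spectra to combine")
    levels = {sp.ms_level for sp in spectra}
    if len(levels) > 1:
        raise ValueError(f"mixed ms_level in combine_scans: {sorted(levels)}")
    mz = np.concatenate([sp.mz for sp in spectra])
    inten = np.concatenate([sp.intensity for sp in spectra])
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    out_mz: List[float] = []
    out_int: List[float] = []
    for m, i in zip(mz, inten):
        if out_mz and (m - out_mz[-1]) <= out_mz[-1] * mz_tol_ppm * 1e-6:
            w = out_int[-1] + i
            out_mz[-1] = (out_mz[-1] * out_int[-1] + m * i) / w if w > 0 else m
            out_int[-1] = w
        else:
            out_mz.append(float(m))
            out_int.append(float(i))
    first = spectra[0]
    return Spectrum(
        np.array(out_mz), np.array(out_int),
        ms_level=first.ms_level, resolution_mode=first.resolution_mode,
        scan_id="+".join(sp.scan_id for sp in spectra if sp.scan_id),
    )


def match_mass_lists(
    a: Sequence[float],
    b: Sequence[float],
    tol: float = 1.0,
) -> Tuple[List[Tuple[int, int, float]], List[int], List[int]]:
    """Greedy nearest-mass pairing of two mass lists within ``tol`` Da.

    Accepts plain masses or DeconvolvedMass objects.  Each element is used at
    most once; pairs are formed smallest distance first, equal distances
    resolved toward the lower mass.  Returns (pairs as (i, j, delta) with
    delta = a[i] − b[j], unmatched a-indices, unmatched b-indices).
    """
    am = np.array([getattr(x, "mass", x) for x in a], dtype=float)
    bm = np.array([getattr(x, "mass", x) for x in b], dtype=float)
    cands = []
    for i, x in enumerate(am):
        for j, y in enumerate(bm):
            d = abs(x - y)
            if d <= tol:
                cands.append((d, min(x, y), i, j))
    cands.sort()
    used_a, used_b = set(), set()
    pairs: List[Tuple[int, int, float]] = []
    for _d, _m, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j, float(am[i] - bm[j])))
    return (
        pairs,
        [i for i in range(am.size) if i not in used_a],
        [j for j in range(bm.size) if j not in used_b],
    )
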