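"""Top-down proteoform identification from HCD fragment spectra.

The workflow: generate theoretical b/y ladders for a candidate proteoform,
match them to the observed fragment peaks at ppm tolerance, z-score the
matched intensities, and score candidates by matched-fragment count.  An
extended precursor-mass window ("absolute mass" search, up to 5 kDa) lets a
protein be found from one terminus's fragments even when the other terminus
is processed; dedicated routines then pin down terminal truncations and
localize integer multiples of a unit mass shift (e.g. 14 Da methylations)
along the ladders.  Decoy (shuffled-database) searches estimate the FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .chem import (
    MASS_TABLE,
    PROTON_MASS,
    WATER_AVG,
    WATER_MONO,
    MassScale,
    Modification,
    ProteinSequence,
    Proteoform,
    load_modification_registry,
    mz_from_mass,
    proteoform_mass,
)
from .spectra import Spectrum


@dataclass
class SearchParams:
    """Database-search settings.

    ``precursor_window`` is the absolute-mass window in Da (500 by default,
    extendable to 5000 to catch heavy terminal processing); ``fragment_tol_ppm``
    the fragment-matching tolerance; ``min_matched`` the acceptance threshold
    on matched-fragment count below which a PrSM is not reported.
    """

    precursor_window: float = 500.0
    fragment_tol_ppm: float = 10.0
    max_candidates: int = 50
    decoy: bool = False
    min_matched: int = 5
    max_fragment_charge: int = 1
    scale: MassScale = "monoisotopic"

    def __post_init__(self):
        if self.precursor_window < 0:
            raise ValueError("precursor window must be >= 0")
        if self.fragment_tol_ppm <= 0:
            raise ValueError("fragment tolerance must be > 0")


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical b or y ion of a proteoform."""

    series: str  # "b" | "y"
    index: int  # 1..n-1
    charge: int
    theoretical_mz: float
    covers: Tuple[int, int]  # residue range in base coordinates


@dataclass
class FragmentMatch:
    ion: FragmentIon
    peak_index: int
    peak_mz: float
    peak_intensity: float
    ppm_error: float
    z_score: float = 0.0
    ambiguous: bool = False


@dataclass
class PrSM:
    """A proteoform-spectrum match.

    Score is the matched-fragment count; ties are broken downstream by the
    smaller precursor residual, then the smaller summed |ppm error|.
    """

    proteoform: Proteoform
    precursor_mass: float
    mass_delta: float  # observed − theoretical
    matches: List[FragmentMatch]
    nterm_coverage: int = 0
    cterm_coverage: int = 0

    @property
    def n_matched(self) -> int:
        return len(self.matches)

    @property
    def score(self) -> int:
        return self.n_matched

    @property
    def ppm_error_sum(self) -> float:
        return float(sum(abs(m.ppm_error) for m in self.matches))

    def sort_key(self):
        return (-self.n_matched, abs(self.mass_delta), self.ppm_error_sum)


def _ladder_neutral_masses(
    p: Proteoform, scale: MassScale = "monoisotopic"
) -> Tuple[np.ndarray, np.ndarray]:
    """Neutral masses of b_1..b_{n-1} and y_1..y_{n-1} fragments.

    b_i is the sum of the first i retained residues (plus modifications
    localized within them); y_j the last j residues plus water.  Unlocalized
    modifications contribute to neither ladder (their position is unknown, so
    no fragment mass can be predicted).
    """
    water = WATER_MONO if scale == "monoisotopic" else WATER_AVG
    seq = p.sequence
    n = len(seq)
    res = np.array(
        [MASS_TABLE.residue_mass(c, scale, "protein", p.start_index + i) for i, c in enumerate(seq)]
    )
    mod_at = np.zeros(n)
    for mod, site in p.modifications:
        if site is not None:
            mod_at[site - p.start_index] += mod.delta(scale)
    cum = np.cumsum(res + mod_at)
    b = cum[:-1]
    y = (cum[-1] - cum[:-1])[::-1] + water
    return b, y


def generate_ladders(
    p: Proteoform,
    max_fragment_charge: int = 1,
    scale: MassScale = "monoisotopic",
) -> List[FragmentIon]:
    """All theoretical b/y ions of ``p`` up to ``max_fragment_charge``."""
    if len(p) < 2:
        raise ValueError("proteoform too short to fragment")
    b, y = _ladder_neutral_masses(p, scale)
    n = len(p)
    ions: List[FragmentIon] = []
    for i, mass in enumerate(b, start=1):
        for z in range(1, max_fragment_charge + 1):
            ions.append(
                FragmentIon(
                    "b", i, z, (mass + z * PROTON_MASS) / z,
                    (p.start_index, p.start_index + i - 1),
                )
            )
    for j, mass in enumerate(y, start=1):
        for z in range(1, max_fragment_charge + 1):
            ions.append(
                FragmentIon(
                    "y", j, z, (mass + z * PROTON_MASS) / z,
                    (p.end_index - j + 1, p.end_index),
                )
            )
    return ions


def match_fragments(
    ions: Sequence[FragmentIon],
    s: Spectrum,
    tol_ppm: float = 10.0,
) -> List[FragmentMatch]:
    """Match each theoretical ion to its nearest peak within ``tol_ppm``.

    A peak may satisfy several ions (complementary b/y coincidences); such
    matches are flagged ambiguous.
    """
    if s.ms_level != 2:
        raise ValueError("fragment matching expects an MS2 spectrum")
    matches: List[FragmentMatch] = []
    peak_use: Dict[int, List[int]] = {}
    for ion in ions:
        tol = ion.theoretical_mz * tol_ppm * 1e-6
        lo = np.searchsorted(s.mz, ion.theoretical_mz - tol)
        hi = np.searchsorted(s.mz, ion.theoretical_mz + tol)
        if lo >= hi:
            continue
        window = s.mz[lo:hi]
        j = int(lo + np.argmin(np.abs(window - ion.theoretical_mz)))
        ppm = (s.mz[j] - ion.theoretical_mz) / ion.theoretical_mz * 1e6
        matches.append(
            FragmentMatch(
                ion=ion,
                peak_index=j,
                peak_mz=float(s.mz[j]),
                peak_intensity=float(s.intensity[j]),
                ppm_error=float(ppm),
            )
        )
        peak_use.setdefault(j, []).append(len(matches) - 1)
    for idxs in peak_use.values():
        if len(idxs) > 1:
            for k in idxs:
                matches[k].ambiguous = True
    return matches


def zscore_intensities(matches: List[FragmentMatch]) -> List[FragmentMatch]:
    """Populate z-scores over the matched-intensity population (sample sd, n−1).

    Degenerate populations (single match or zero spread) get all-zero scores.
    """
    if not matches:
        return matches
    inten = np.array([m.peak_intensity for m in matches])
    if inten.size < 2:
        sd = 0.0
    else:
        sd = float(inten.std(ddof=1))
    mean = float(inten.mean())
    for m in matches:
        m.z_score = 0.0 if sd == 0 else (m.peak_intensity - mean) / sd
    return matches


def score_candidate(
    p: Proteoform,
    precursor_mass: float,
    s: Spectrum,
    params: SearchParams,
) -> PrSM:
    """Build a PrSM for one candidate proteoform against one fragment spectrum."""
    ions = generate_ladders(p, params.max_fragment_charge, params.scale)
    matches = match_fragments(ions, s, params.fragment_tol_ppm)
    zscore_intensities(matches)
    theo = proteoform_mass(p, params.scale)
    return PrSM(
        proteoform=p,
        precursor_mass=precursor_mass,
        mass_delta=precursor_mass - theo,
        matches=matches,
        nterm_coverage=sum(1 for m in matches if m.ion.series == "b"),
        cterm_coverage=sum(1 for m in matches if m.ion.series == "y"),
    )


def absolute_mass_search(
    precursor_mass: float,
    s: Spectrum,
    db: Sequence[ProteinSequence],
    params: Optional[SearchParams] = None,
) -> List[PrSM]:
    """Extended-window database search against intact sequences.

    Every database entry whose intact mass lies within ``precursor_window`` of
    the precursor is fragment-matched with both ladders; PrSMs passing the
    ``min_matched`` threshold are ranked by (matched count, |precursor
    residual|, summed |ppm error|).  A large window plus one-sided fragment
    support (e.g. only y ions, negative mass delta) is the signature of
    N-terminal processing.
    """
    params = params or SearchParams()
    prsms: List[PrSM] = []
    for entry in db:
        theo = entry.backbone_mass(params.scale)
        if abs(theo - precursor_mass) > params.precursor_window:
            continue
        p = Proteoform(base=entry)
        prsm = score_candidate(p, precursor_mass, s, params)
        if prsm.n_matched >= params.min_matched:
            prsms.append(prsm)
    prsms.sort(key=PrSM.sort_key)
    return prsms[: params.max_candidates]


@dataclass
class TerminalSearchResult:
    """Ranked terminal-processing hypotheses plus the best mass residual seen."""

    forms: List[PrSM]
    best_residual: float = float("inf")

    def co_optimal(self) -> List[PrSM]:
        """All forms tied with the top hit on matched count."""
        if not self.forms:
            return []
        top = self.forms[0].n_matched
        return [f for f in self.forms if f.n_matched == top]


def infer_terminal_processing(
    candidate: ProteinSequence,
    precursor_mass: float,
    s: Spectrum,
    params: Optional[SearchParams] = None,
    max_nterm_trim: int = 120,
    max_cterm_trim: int = 60,
    mass_tol: float = 2.2,
    terminal_mods: Optional[Sequence[Optional[Modification]]] = None,
) -> TerminalSearchResult:
    """Find (start, end) truncations whose mass explains the precursor.

    Enumerates retained spans with up to ``max_nterm_trim`` residues removed
    N-terminally and ``max_cterm_trim`` C-terminally — bounds that comfortably
    cover chloroplast transit peptides — optionally combined with one terminal
    modification (N-terminal acetylation by default).  Spans matching the
    precursor within ``mass_tol`` are fragment-rescored; results are ranked by
    (matched count, |mass residual|).  The default 2.2 Da tolerance absorbs a
    monoisotopic/average scale mismatch at ~30 kDa plus deconvolution error.
    """
    params = params or SearchParams()
    if terminal_mods is None:
        registry = load_modification_registry()
        terminal_mods = [None, registry["acetylation"]]
    n = len(candidate)
    scale = params.scale
    res = np.array(
        [MASS_TABLE.residue_mass(c, scale, "protein", i + 1) for i, c in enumerate(candidate.residues)]
    )
    prefix = np.concatenate([[0.0], np.cumsum(res)])
    water = WATER_MONO if scale == "monoisotopic" else WATER_AVG
    total = prefix[-1] + water
    forms: List[PrSM] = []
    best_residual = float("inf")
    for start in range(1, min(max_nterm_trim + 1, n - 1) + 1):
        for end in range(n, max(n - max_cterm_trim, start + 1) - 1, -1):
            span_mass = prefix[end] - prefix[start - 1] + water
            for mod in terminal_mods:
                theo = span_mass + (mod.delta(scale) if mod else 0.0)
                residual = precursor_mass - theo
                if abs(residual) < abs(best_residual):
                    best_residual = residual
                if abs(residual) > mass_tol:
                    continue
                mods = ((mod, start),) if mod else ()
                p = Proteoform(
                    base=candidate, start_index=start, end_index=end, modifications=mods
                )
                forms.append(score_candidate(p, precursor_mass, s, params))
    forms.sort(key=PrSM.sort_key)
    return TerminalSearchResult(forms=forms, best_residual=float(best_residual))


@dataclass
class LocalizationResult:
    """Outcome of walking the ladders for unit-mass-shift placement."""

    localized_sites: Set[int]
    ambiguous: List[Tuple[FrozenSet, int]]  # (candidate interval ∩ candidates, count)
    conflict: bool = False
    conflict_detail: str = ""
    cleavage_counts: Dict[int, int] = field(default_factory=dict)


def localize_unit_shifts(
    p: Proteoform,
    s: Spectrum,
    n_units: int,
    unit_mass: float = 14.01565,
    candidate_residues: Optional[Set[int]] = None,
    tol_ppm: float = 10.0,
    scale: MassScale = "monoisotopic",
) -> LocalizationResult:
    """Localize ``n_units`` copies of a unit mass shift along the backbone.

    At every cleavage site each ladder is probed at theoretical + k·unit for
    k = 0..n_units; the best-matching k gives the cumulative shift count up to
    that cleavage (counted from the N-terminus; y-ion counts are converted via
    the precursor total).  Count increments between consecutive observed
    cleavages localize modification sites; intervals are intersected with
    ``candidate_residues`` (base coordinates).  Non-monotone counts along the
    sequence produce a conflict report instead of assignments.
    """
    if s.ms_level != 2:
        raise ValueError("localization expects an MS2 spectrum")
    b, y = _ladder_neutral_masses(p, scale)
    n = len(p)
    # cleavage c (1..n-1) splits retained residues [1..c] | [c+1..n] (local coords)
    counts: Dict[int, int] = {}

    def probe(neutral: float) -> Optional[int]:
        """Best shift count k whose predicted 1+ m/z hits a peak; None if no hit."""
        best_k, best_ppm = None, tol_ppm
        for k in range(0, n_units + 1):
            target = neutral + k * unit_mass + PROTON_MASS
            tol = target * tol_ppm * 1e-6
            lo = np.searchsorted(s.mz, target - tol)
            hi = np.searchsorted(s.mz, target + tol)
            if lo >= hi:
                continue
            ppm = float(
                np.min(np.abs(s.mz[lo:hi] - target)) / target * 1e6
            )
            if ppm < best_ppm:
                best_k, best_ppm = k, ppm
        return best_k

    conflict = False
    detail = ""
    for c in range(1, n):
        kb = probe(b[c - 1])
        ky = probe(y[n - c - 1])
        implied = []
        if kb is not None:
            implied.append(kb)
        if ky is not None:
            implied.append(n_units - ky)
        if not implied:
            continue
        if len(implied) == 2 and implied[0] != implied[1]:
            conflict = True
            detail = (
                f"cleavage {c}: b-ladder count {implied[0]} vs "
                f"y-ladder count {implied[1]}"
            )
            break
        counts[c] = implied[0]
    if not conflict:
        prev_c, prev_k = 0, 0
        items = sorted(counts.items())
        for c, k in items:
            if k < prev_k:
                conflict = True
                detail = f"count drops from {prev_k} at cleavage {prev_c} to {k} at {c}"
                break
            prev_c, prev_k = c, k
    if conflict:
        return LocalizationResult(set(), [], True, detail, counts)

    localized: Set[int] = set()
    ambiguous: List[Tuple[FrozenSet, int]] = []
    # walk increments between observed cleavages; terminal segments implied by
    # totals 0 at cleavage 0 and n_units at cleavage n
    boundary = [(0, 0)] + sorted(counts.items()) + [(n, n_units)]
    for (c1, k1), (c2, k2) in zip(boundary[:-1], boundary[1:]):
        inc = k2 - k1
        if inc == 0:
            continue
        interval = set(range(p.start_index + c1, p.start_index + c2))  # base coords
        if candidate_residues is not None:
            interval &= set(candidate_residues)
        if inc == len(interval):
            localized |= interval
        else:
            ambiguous.append((frozenset(interval), inc))
    return LocalizationResult(localized, ambiguous, False, "", counts)


def shuffle_database(
    db: Sequence[ProteinSequence], seed: int
) -> List[ProteinSequence]:
    """Decoy database: within-protein residue shuffle preserving length/composition."""
    rng = np.random.default_rng(seed)
    out = []
    for entry in db:
        arr = np.array(list(entry.residues))
        rng.shuffle(arr)
        out.append(
            ProteinSequence(
                identifier=f"DECOY_{entry.identifier}",
                residues="".join(arr),
                description="shuffled decoy",
            )
        )
    return out


@dataclass
class DecoyFdrResult:
    fdr: Optional[float]  # None when no PrSMs at all ("n/a")
    n_target: int
    n_decoy: int
    table: pd.DataFrame
    seed: int


def decoy_fdr(
    target_db: Sequence[ProteinSequence],
    spectra: Sequence[Tuple[float, Spectrum]],
    params: Optional[SearchParams] = None,
    seed: int = 0,
) -> DecoyFdrResult:
    """Estimate the PrSM false-discovery rate with a shuffled-sequence decoy search.

    Each (precursor mass, spectrum) pair is searched in parallel against the
    target and the shuffled database and yields at most one accepted PrSM —
    the better-scoring of the two search winners (target–decoy competition,
    the standard estimator; a decoy sharing a protein's residue composition
    always produces a few exact subset-sum fragment coincidences, which
    competition discounts against the full target match).
    FDR = decoy wins / (target wins + decoy wins) above the acceptance
    threshold.  Returns n/a (None) for an empty spectrum set or no accepted
    PrSMs.
    """
    params = params or SearchParams()
    decoys = shuffle_database(target_db, seed)
    rows = []
    n_target = n_decoy = 0
    for i, (prec, s) in enumerate(spectra):
        t_hits = absolute_mass_search(prec, s, target_db, params)
        d_hits = absolute_mass_search(prec, s, decoys, params)
        best_t = t_hits[0] if t_hits else None
        best_d = d_hits[0] if d_hits else None
        if best_t is None and best_d is None:
            continue
        if best_t is not None and (
            best_d is None or best_t.sort_key() <= best_d.sort_key()
        ):
            winner, kind = best_t, "target"
            n_target += 1
        else:
            winner, kind = best_d, "decoy"
            n_decoy += 1
        for label, h in (("target", best_t), ("decoy", best_d)):
            if h is None:
                continue
            rows.append(
                {
                    "spectrum": i,
                    "database": label,
                    "protein": h.proteoform.base.identifier,
                    "n_matched": h.n_matched,
                    "mass_delta": h.mass_delta,
                    "accepted": h is winner,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["spectrum", "database", "protein", "n_matched", "mass_delta", "accepted"],
    )
    total = n_target + n_decoy
    fdr = None if total == 0 else n_decoy / total
    return DecoyFdrResult(fdr=fdr, n_target=n_target, n_decoy=n_decoy, table=table, seed=seed)


def proteoform_report(
    prsms: Sequence[PrSM],
    ms1_masses: Optional[Sequence] = None,
    registry: Optional[dict] = None,
    match_tol: float = 1.0,
    annotation_tol: float = 0.5,
) -> pd.DataFrame:
    """Per-protein proteoform table: mass delta vs backbone, normalized intensity.

    Mass deltas are taken against the *unmodified full backbone* of each
    protein; intensities come from MS1 deconvolved masses matched within
    ``match_tol`` Da (1 Da by default) and are normalized to sum to 1 within
    each protein.  Deltas within ``annotation_tol`` of a registry modification
    are labeled with it (all candidates joined by "|"); near-zero deltas are
    "unmodified", everything else "UNK".
    """
    registry = registry if registry is not None else load_modification_registry()
    rows = []
    ms1 = list(ms1_masses or [])
    ms1_vals = [getattr(x, "mass", x) for x in ms1]
    ms1_int = [getattr(x, "total_intensity", 1.0) for x in ms1]
    for prsm in prsms:
        backbone = prsm.proteoform.base.backbone_mass()
        delta = prsm.precursor_mass - backbone
        intensity = 1.0
        if ms1_vals:
            dists = [abs(prsm.precursor_mass - m) for m in ms1_vals]
            j = int(np.argmin(dists))
            if dists[j] <= match_tol:
                intensity = float(ms1_int[j])
        labels = sorted(
            name
            for name, mod in registry.items()
            if abs(delta - mod.delta_monoisotopic) <= annotation_tol
        )
        if labels:
            annotation = "|".join(labels)
        elif abs(delta) <= annotation_tol:
            annotation = "unmodified"
        else:
            annotation = "UNK"
        rows.append(
            {
                "protein": prsm.proteoform.base.identifier,
                "proteoform": prsm.proteoform.describe(),
                "mass_delta": delta,
                "intensity": intensity,
                "annotation": annotation,
            }
        )
    df = pd.DataFrame(
        rows, columns=["protein", "proteoform", "mass_delta", "intensity", "annotation"]
    )
    if not df.empty:
        df["normalized_intensity"] = df.groupby("protein")["intensity"].transform(
            lambda x: x / x.sum()
        )
        df = df.sort_values(["protein", "mass_delta"], kind="stable").reset_index(drop=True)
    else:
        df["normalized_intensity"] = pd.Series(dtype=float)
    return df
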