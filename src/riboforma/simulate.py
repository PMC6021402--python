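"""Synthetic spectra and databases with controlled ground truth.

Generates every input the pipeline consumes: multi-charge electrospray
envelopes of intact species (5 kDa–2.5 MDa, charges 5–100, optional adduct
load and m/z jitter emulating incomplete desolvation), HCD b/y fragment
spectra with partial coverage and noise peaks, superposed complex
subpopulations, and random protein databases with planted truncations,
ragged N-termini and modifications.  Every artifact ships a machine-readable
ground truth, and identical (config, seed) always yields identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .chem import (
    Modification,
    ProteinSequence,
    Proteoform,
    load_modification_registry,
    mz_from_mass,
    proteoform_mass,
    write_fasta,
)
from .spectra import Spectrum
from .topdown import generate_ladders

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic instrument.

    * ``charge_center``/``charge_width`` — truncated discrete Gaussian charge
      profile; center defaults to the electrospray scaling 0.08·√M when None.
    * ``adduct_mean``/``adduct_sd`` — per-peak nonnegative mass offset (Da)
      mimicking metal-ion attachment and incomplete desolvation.
    * ``mz_jitter_ppm`` — Gaussian centroid position noise.
    * ``fragment_coverage`` — fraction of the b/y ladders present in MS2.
    * ``noise_peaks`` — uniform-m/z noise centroids per spectrum, intensities
      below the 20th percentile of the signal peaks.
    """

    seed: int
    charge_center: Optional[float] = None
    charge_width: float = 2.0
    noise_peaks: int = 0
    mz_jitter_ppm: float = 0.0
    adduct_mean: float = 0.0
    adduct_sd: float = 0.0
    fragment_coverage: float = 1.0
    intensity_sigma: float = 0.5
    base_intensity: float = 1000.0


@dataclass
class GroundTruth:
    """What was planted: per species, the neutral mass and its provenance."""

    species: List[dict] = field(default_factory=list)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps({"species": self.species}, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "GroundTruth":
        return cls(species=json.loads(Path(path).read_text())["species"])


def _charge_profile(mass: float, cfg: SimulationConfig, charges=None):
    """Charges and relative weights of a truncated discrete Gaussian envelope."""
    if charges is not None:
        z = np.asarray(sorted(charges), dtype=int)
        if z.size == 0:
            raise ValueError("charge profile contains no charges")
        center = cfg.charge_center if cfg.charge_center is not None else z.mean()
    else:
        center = cfg.charge_center if cfg.charge_center is not None else 0.08 * np.sqrt(mass)
        lo = max(1, int(np.floor(center - 3 * cfg.charge_width)))
        hi = int(np.ceil(center + 3 * cfg.charge_width))
        z = np.arange(lo, hi + 1)
    if z.size == 0:
        raise ValueError("charge profile contains no charges")
    w = np.exp(-0.5 * ((z - center) / max(cfg.charge_width, 1e-9)) ** 2)
    return z, w / w.max()


def _add_noise(mz: list, inten: list, cfg: SimulationConfig, rng) -> None:
    if cfg.noise_peaks <= 0:
        return
    if mz:
        lo, hi = 0.8 * min(mz), 1.2 * max(mz)
        cap = float(np.percentile(inten, 20))
    else:
        lo, hi = 400.0, 12_000.0
        cap = cfg.base_intensity * 0.1
    for _ in range(cfg.noise_peaks):
        mz.append(float(rng.uniform(lo, hi)))
        inten.append(float(rng.uniform(0, cap)))


def simulate_envelope(
    mass_or_proteoform: Union[float, Proteoform, None],
    cfg: SimulationConfig,
    charges: Optional[Sequence[int]] = None,
    label: str = "species",
    _rng=None,
) -> Tuple[Spectrum, GroundTruth]:
    """One species' MS1 charge-state envelope plus ground truth.

    Peak positions are mz_from_mass(M + adduct draw, z) with per-peak adduct
    draws (truncated at zero) and optional relative m/z jitter.  Passing
    ``None`` yields a noise-only spectrum with empty ground truth.
    """
    rng = _rng if _rng is not None else np.random.default_rng(cfg.seed)
    if mass_or_proteoform is None:
        mz: List[float] = []
        inten: List[float] = []
        _add_noise(mz, inten, cfg, rng)
        return (
            Spectrum.from_peaks(zip(mz, inten), ms_level=1, scan_id="noise"),
            GroundTruth(),
        )
    if isinstance(mass_or_proteoform, Proteoform):
        mass = proteoform_mass(mass_or_proteoform)
        desc = mass_or_proteoform.describe()
    else:
        mass = float(mass_or_proteoform)
        desc = label
    mz: List[float] = []
    inten: List[float] = []
    adducts: List[float] = []
    z_list, weights = _charge_profile(mass, cfg, charges)
    for z, w in zip(z_list, weights):
        adduct = max(0.0, rng.normal(cfg.adduct_mean, cfg.adduct_sd)) if (
            cfg.adduct_mean or cfg.adduct_sd
        ) else 0.0
        adducts.append(adduct)
        m = mz_from_mass(mass + adduct, int(z))
        if cfg.mz_jitter_ppm:
            m *= 1.0 + rng.normal(0.0, cfg.mz_jitter_ppm * 1e-6)
        mz.append(m)
        inten.append(cfg.base_intensity * w)
    _add_noise(mz, inten, cfg, rng)
    truth = GroundTruth(
        species=[
            {
                "label": desc,
                "neutral_mass": mass,
                "charges": [int(z) for z in z_list],
                "mean_adduct": float(np.mean(adducts)) if adducts else 0.0,
                "abundance": 1.0,
            }
        ]
    )
    return Spectrum.from_peaks(zip(mz, inten), ms_level=1, scan_id=desc), truth


def simulate_fragment_spectrum(
    p: Proteoform,
    cfg: SimulationConfig,
) -> Tuple[Spectrum, float, GroundTruth]:
    """An HCD b/y fragment spectrum of one proteoform.

    A seeded uniform subset of the singly charged b/y ions at
    ``fragment_coverage``; log-normal intensities (σ = ``intensity_sigma``);
    noise peaks; precursor mass = proteoform mass with a seeded error within
    10 ppm.  Returns (MS2 spectrum, precursor mass, truth).
    """
    if not (0 < cfg.fragment_coverage <= 1):
        raise ValueError("fragment coverage must be in (0, 1]")
    rng = np.random.default_rng(cfg.seed)
    ions = generate_ladders(p, max_fragment_charge=1)
    n_keep = max(1, int(round(cfg.fragment_coverage * len(ions))))
    keep = rng.choice(len(ions), size=n_keep, replace=False)
    mz: List[float] = []
    inten: List[float] = []
    kept_ions = []
    for k in sorted(keep):
        ion = ions[k]
        m = ion.theoretical_mz
        if cfg.mz_jitter_ppm:
            m *= 1.0 + rng.normal(0.0, cfg.mz_jitter_ppm * 1e-6)
        mz.append(m)
        inten.append(float(cfg.base_intensity * rng.lognormal(0.0, cfg.intensity_sigma)))
        kept_ions.append(f"{ion.series}{ion.index}")
    _add_noise(mz, inten, cfg, rng)
    mass = proteoform_mass(p)
    precursor = mass * (1.0 + rng.uniform(-10e-6, 10e-6))
    truth = GroundTruth(
        species=[
            {
                "label": p.describe(),
                "neutral_mass": mass,
                "precursor_mass": precursor,
                "start_index": p.start_index,
                "end_index": p.end_index,
                "modifications": [
                    {"name": m.name, "site": s} for m, s in p.modifications
                ],
                "fragments": kept_ions,
                "abundance": 1.0,
            }
        ]
    )
    spec = Spectrum.from_peaks(
        zip(mz, inten), ms_level=2, resolution_mode="high", scan_id=p.describe(),
        metadata={"precursor_mass_da": precursor},
    )
    return spec, precursor, truth


def simulate_complex_population(
    species: Sequence[Tuple[str, float, float]],
    cfg: SimulationConfig,
    charges: Optional[Sequence[int]] = None,
) -> Tuple[Spectrum, GroundTruth]:
    """Superposed envelopes of co-occurring assemblies.

    ``species`` is a list of (label, neutral mass, abundance); abundances
    scale peak intensities.  Zero-abundance species are omitted from the
    spectrum but stay in the ground truth.
    """
    if not species:
        raise ValueError("need at least one composition")
    rng = np.random.default_rng(cfg.seed)
    peaks: List[Tuple[float, float]] = []
    truth = GroundTruth()
    for label, mass, abundance in species:
        truth.species.append(
            {"label": label, "neutral_mass": float(mass), "abundance": float(abundance)}
        )
        if abundance <= 0:
            continue
        sub_cfg = SimulationConfig(**{**asdict(cfg), "noise_peaks": 0})
        spec, _ = simulate_envelope(mass, sub_cfg, charges=charges, label=label, _rng=rng)
        peaks.extend((m, i * abundance) for m, i in zip(spec.mz, spec.intensity))
    mz = [m for m, _ in peaks]
    inten = [i for _, i in peaks]
    _add_noise(mz, inten, cfg, rng)
    return Spectrum.from_peaks(zip(mz, inten), ms_level=1, scan_id="population"), truth


def make_fixture_database(
    n_proteins: int,
    length_range: Tuple[int, int] = (50, 120),
    events: Optional[Sequence[dict]] = None,
    seed: int = 0,
    out_dir: Optional[Union[str, Path]] = None,
) -> Tuple[List[ProteinSequence], List[Proteoform], GroundTruth]:
    """Random protein database with optional planted proteoform events.

    Event dicts (``protein`` is a 0-based index into the database):

    * ``{"protein": i, "kind": "truncation", "start": 59, "end": 181}`` —
      terminal processing (transit-peptide style); omitted bounds default to
      the intact terminus.
    * ``{"protein": i, "kind": "modification", "name": "methylation",
      "sites": [39, 55, 58], "residue": "C"}`` — localized modifications;
      ``residue`` forces a compatible residue at each site.
    * ``{"protein": i, "kind": "ragged", "starts": [61, 62, 63],
      "acetylated": [61]}`` — multiple N-terminal start points, a subset
      N-terminally acetylated.

    Returns (database, planted proteoforms, truth); writes ``db.fasta`` and
    ``truth.json`` under ``out_dir`` when given.
    """
    if n_proteins < 1:
        raise ValueError("need at least one protein")
    rng = np.random.default_rng(seed)
    registry = load_modification_registry()
    seqs: List[str] = []
    for _ in range(n_proteins):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seqs.append("".join(rng.choice(list(_AA20), size=length)))
    events = list(events or [])
    # force residues required by modification events before freezing sequences
    for ev in events:
        if ev.get("kind") == "modification" and ev.get("residue"):
            i = ev["protein"]
            s = list(seqs[i])
            for site in ev["sites"]:
                s[site - 1] = ev["residue"]
            seqs[i] = "".join(s)
    db = [
        ProteinSequence(identifier=f"FIX{i:03d}", residues=s, description="synthetic fixture")
        for i, s in enumerate(seqs)
    ]
    proteoforms: List[Proteoform] = []
    truth = GroundTruth()
    for ev in events:
        base = db[ev["protein"]]
        kind = ev["kind"]
        if kind == "truncation":
            start = int(ev.get("start", 1))
            end = int(ev.get("end", len(base)))
            forms = [Proteoform(base=base, start_index=start, end_index=end)]
        elif kind == "modification":
            mod = registry[ev["name"]]
            mods = tuple((mod, int(s)) for s in ev["sites"])
            forms = [Proteoform(base=base, modifications=mods)]
        elif kind == "ragged":
            acetyl = registry["acetylation"]
            acetylated = set(ev.get("acetylated", []))
            forms = [
                Proteoform(
                    base=base,
                    start_index=int(st),
                    modifications=((acetyl, int(st)),) if st in acetylated else (),
                )
                for st in ev["starts"]
            ]
        else:
            raise ValueError(f"unknown event kind {kind!r}")
        for p in forms:
            proteoforms.append(p)
            truth.species.append(
                {
                    "label": p.describe(),
                    "protein": base.identifier,
                    "neutral_mass": proteoform_mass(p),
                    "start_index": p.start_index,
                    "end_index": p.end_index,
                    "modifications": [
                        {"name": m.name, "site": s} for m, s in p.modifications
                    ],
                    "abundance": 1.0,
                }
            )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "db.fasta", db)
        truth.to_json(out / "truth.json")
    return db, proteoforms, truth
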