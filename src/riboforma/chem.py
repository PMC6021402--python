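"""Sequence, modification and mass bookkeeping shared by all pipeline stages.

All masses are in daltons (Da); mass-to-charge ratios in thomson (Th).
Two mass scales are carried throughout: ``"monoisotopic"`` (lightest-isotope
masses, appropriate for isotopically resolved data) and ``"average"``
(isotope-abundance-weighted, what an unresolved charge-state envelope yields).
A single proton mass and water mass are the source of truth for every module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MassScale = Literal["monoisotopic", "average"]

#: Mass of a proton (positive-mode electrospray charge carrier), Da.
PROTON_MASS = 1.007276

#: Mass of water added on polymer condensation, Da.
WATER_MONO = 18.010565
WATER_AVG = 18.0153

#: Monoisotopic mass of a phosphate group (HPO3), Da; optional RNA 5'-phosphate.
PHOSPHATE_MONO = 79.96633
PHOSPHATE_AVG = 79.9799

# Residue (= monomer minus water) masses, Da.  Monoisotopic values are the
# standard Unimod/IUPAC table; average values the 2013 IUPAC atomic weights.
_AA_MONO = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047678, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}
_AA_AVG = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
# Ribonucleotide-monophosphate residues (nucleoside-5'-monophosphate − water).
_RNA_MONO = {"A": 329.052520, "C": 305.041287, "G": 345.047435, "U": 306.025302}
_RNA_AVG = {"A": 329.2059, "C": 305.1812, "G": 345.2053, "U": 306.1660}


class UnknownResidueError(ValueError):
    """Raised when a residue code is absent from the mass table."""

    def __init__(self, code: str, position: int, polymer: str):
        self.code = code
        self.position = position
        super().__init__(
            f"unknown {polymer} residue code {code!r} at position {position}"
        )


@dataclass(frozen=True)
class ResidueMassTable:
    """Residue mass lookup for the 20 standard amino acids and 4 ribonucleotides.

    Protein and RNA namespaces are kept separate because single-letter codes
    collide (A = alanine or adenosine).
    """

    protein_mono: dict = field(default_factory=lambda: dict(_AA_MONO))
    protein_avg: dict = field(default_factory=lambda: dict(_AA_AVG))
    rna_mono: dict = field(default_factory=lambda: dict(_RNA_MONO))
    rna_avg: dict = field(default_factory=lambda: dict(_RNA_AVG))

    def residue_mass(
        self,
        code: str,
        scale: MassScale = "monoisotopic",
        polymer: Literal["protein", "rna"] = "protein",
        position: int = 0,
    ) -> float:
        table = getattr(self, f"{polymer}_{'mono' if scale == 'monoisotopic' else 'avg'}")
        try:
            return table[code]
        except KeyError:
            raise UnknownResidueError(code, position, polymer) from None

    def validate(self) -> None:
        for mono, avg, what in (
            (self.protein_mono, self.protein_avg, "protein"),
            (self.rna_mono, self.rna_avg, "rna"),
        ):
            for code in mono:
                if mono[code] <= 0:
                    raise ValueError(f"nonpositive mass for {what} {code}")
                if mono[code] >= avg[code]:
                    raise ValueError(
                        f"monoisotopic >= average for {what} residue {code}"
                    )


#: Default shared mass table.
MASS_TABLE = ResidueMassTable()


@dataclass(frozen=True)
class Modification:
    """A covalent mass modification (PTM or processing event).

    ``allowed_targets`` holds single-letter residue codes plus the terminus
    flags ``"N-term"`` / ``"C-term"``.  ``delta_average`` defaults to the
    monoisotopic delta when no curated average value exists.
    """

    name: str
    delta_monoisotopic: float
    delta_average: Optional[float] = None
    allowed_targets: frozenset = frozenset()
    max_per_protein: int = 10

    def delta(self, scale: MassScale = "monoisotopic") -> float:
        if scale == "average" and self.delta_average is not None:
            return self.delta_average
        return self.delta_monoisotopic

    def targets_residue(self, code: str) -> bool:
        return not self.allowed_targets or code in self.allowed_targets


def load_modification_registry(extra_path: Optional[Union[str, Path]] = None) -> dict:
    """Load the packaged modification registry, optionally merged with a user JSON.

    Returns a mapping ``name -> Modification``.
    """
    text = resources.files("riboforma").joinpath("data/modifications.json").read_text()
    entries = json.loads(text)
    if extra_path is not None:
        entries.extend(json.loads(Path(extra_path).read_text()))
    registry = {}
    for e in entries:
        registry[e["name"]] = Modification(
            name=e["name"],
            delta_monoisotopic=float(e["delta_monoisotopic"]),
            delta_average=e.get("delta_average"),
            allowed_targets=frozenset(e.get("allowed_targets", [])),
            max_per_protein=int(e.get("max_per_protein", 10)),
        )
    return registry


@dataclass(frozen=True)
class ProteinSequence:
    """A database protein entry: identifier plus ordered residue codes."""

    identifier: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"empty sequence for {self.identifier!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def backbone_mass(
        self, scale: MassScale = "monoisotopic", table: ResidueMassTable = MASS_TABLE
    ) -> float:
        water = WATER_MONO if scale == "monoisotopic" else WATER_AVG
        return (
            sum(
                table.residue_mass(c, scale, "protein", i + 1)
                for i, c in enumerate(self.residues)
            )
            + water
        )


# A modification placement: (Modification, 1-based site in base coordinates)
# or (Modification, None) for an unlocalized mass shift.
ModPlacement = tuple


@dataclass(frozen=True)
class Proteoform:
    """One molecular form of a protein: retained span plus modifications.

    ``start_index``/``end_index`` are 1-based inclusive positions in the base
    sequence; truncations at either terminus (e.g. a cleaved chloroplast
    transit peptide) are expressed by moving them inward.  Modification sites
    are in base-sequence coordinates; ``None`` marks an unlocalized shift.
    """

    base: ProteinSequence
    start_index: int = 1
    end_index: Optional[int] = None
    modifications: tuple = ()
    label: str = ""

    def __post_init__(self):
        end = self.end_index if self.end_index is not None else len(self.base)
        object.__setattr__(self, "end_index", end)
        if not (1 <= self.start_index <= end <= len(self.base)):
            raise ValueError(
                f"invalid span [{self.start_index}, {end}] for length {len(self.base)}"
            )
        object.__setattr__(self, "modifications", tuple(self.modifications))
        for mod, site in self.modifications:
            if site is not None:
                if not (self.start_index <= site <= end):
                    raise ValueError(
                        f"modification {mod.name} site {site} outside retained span"
                    )
                code = self.base.residues[site - 1]
                if mod.allowed_targets and not (
                    mod.targets_residue(code)
                    or (site == self.start_index and "N-term" in mod.allowed_targets)
                    or (site == end and "C-term" in mod.allowed_targets)
                ):
                    raise ValueError(
                        f"modification {mod.name} not allowed on residue "
                        f"{code!r} at {site}"
                    )

    @property
    def sequence(self) -> str:
        return self.base.residues[self.start_index - 1 : self.end_index]

    def __len__(self) -> int:
        return self.end_index - self.start_index + 1

    def describe(self) -> str:
        mods = ",".join(
            f"{m.name}@{s if s is not None else '?'}" for m, s in self.modifications
        )
        return (
            f"{self.base.identifier}[{self.start_index}-{self.end_index}]"
            + (f"+{mods}" if mods else "")
        )


def proteoform_mass(
    p: Proteoform,
    scale: MassScale = "monoisotopic",
    table: ResidueMassTable = MASS_TABLE,
) -> float:
    """Neutral mass of a proteoform: retained residues + water + modification deltas."""
    water = WATER_MONO if scale == "monoisotopic" else WATER_AVG
    total = water
    for offset, code in enumerate(p.sequence):
        total += table.residue_mass(code, scale, "protein", p.start_index + offset)
    for mod, _site in p.modifications:
        total += mod.delta(scale)
    return total


def mz_from_mass(neutral_mass: float, z: int) -> float:
    """m/z of a neutral mass carrying z protons (positive-mode electrospray)."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    if neutral_mass <= 0:
        raise ValueError(f"mass must be positive, got {neutral_mass}")
    return (neutral_mass + z * PROTON_MASS) / z


def mass_from_mz(mz: float, z: int) -> float:
    """Neutral mass implied by an m/z at charge z; exact inverse of mz_from_mass."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return z * (mz - PROTON_MASS)


def rna_mass(
    seq: str,
    scale: MassScale = "monoisotopic",
    five_prime_phosphate: bool = False,
    table: ResidueMassTable = MASS_TABLE,
) -> float:
    """Neutral mass of a linear RNA over {A,C,G,U}.

    Default terminal state is 5'-OH / 3'-OH (sum of nucleotide-monophosphate
    residues plus water); ``five_prime_phosphate`` adds one HPO3.  In-vitro
    transcripts vary in their 5' state, so both are exposed.
    """
    if not seq:
        raise ValueError("empty RNA sequence")
    water = WATER_MONO if scale == "monoisotopic" else WATER_AVG
    total = water
    for i, code in enumerate(seq):
        total += table.residue_mass(code, scale, "rna", i + 1)
    if five_prime_phosphate:
        total += PHOSPHATE_MONO if scale == "monoisotopic" else PHOSPHATE_AVG
    return total


# ---------------------------------------------------------------------------
# FASTA I/O (Biopython-backed)

def read_fasta(path: Union[str, Path]) -> list:
    """Read a FASTA file into ProteinSequence records.

    The identifier is the first whitespace-delimited token of the header; the
    remainder becomes the description.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinSequence(
                identifier=rec.id,
                residues=str(rec.seq).upper(),
                description=rec.description[len(rec.id):].strip(),
            )
        )
    return records


def write_fasta(path: Union[str, Path], sequences: Iterable[ProteinSequence]) -> None:
    recs = [
        SeqRecord(Seq(s.residues), id=s.identifier, description=s.description)
        for s in sequences
    ]
    SeqIO.write(recs, str(path), "fasta")
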