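"""Explain measured native-MS masses of intact assemblies.

Given an accurately measured complex mass and an inventory of candidate
subunit masses with count bounds, enumerate every integer stoichiometry whose
theoretical mass falls within tolerance (e.g. the L10·(L7/L12)6 heptameric
stalk at 103.4 kDa).  Companion routines assign subpopulation mass deficits
to missing subunits and match binding-induced mass shifts to candidate
ligands, including integer (n:1) stoichiometry checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

#: Hard cap on the enumeration lattice size.
MAX_ENUMERATION = 10_000_000

#: Sentinel margin when only one deficit candidate exists.
MARGIN_SENTINEL = float("inf")


@dataclass(frozen=True)
class Component:
    name: str
    mass: float
    min_count: int = 0
    max_count: int = 1

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"component {self.name!r} mass must be positive")
        if not (0 <= self.min_count <= self.max_count):
            raise ValueError(f"bad count bounds for {self.name!r}")


@dataclass
class ComponentInventory:
    """Candidate subunits with per-component count bounds."""

    components: List[Component]
    note: str = ""

    def __post_init__(self):
        self.components = [
            c if isinstance(c, Component) else Component(*c) for c in self.components
        ]

    @property
    def enumeration_size(self) -> int:
        size = 1
        for c in self.components:
            size *= c.max_count - c.min_count + 1
        return size

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "ComponentInventory":
        """Read an inventory TSV with columns name, mass_da, min, max."""
        df = pd.read_csv(path, sep="\t", comment="#")
        comps = [
            Component(str(r["name"]), float(r["mass_da"]), int(r["min"]), int(r["max"]))
            for _, r in df.iterrows()
        ]
        return cls(components=comps)

    def to_tsv(self, path: Union[str, Path]) -> None:
        lines = ["name\tmass_da\tmin\tmax"]
        for c in self.components:
            lines.append(f"{c.name}\t{c.mass:.4f}\t{c.min_count}\t{c.max_count}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class CompositionSolution:
    """One integer stoichiometry consistent with the measured mass."""

    counts: Dict[str, int]
    theoretical_mass: float
    residual: float  # measured − theoretical
    abs_residual_ppm: float

    @property
    def total_subunits(self) -> int:
        return sum(self.counts.values())


def theoretical_complex_mass(inv: ComponentInventory, counts: Dict[str, int]) -> float:
    """Dot product of counts and component masses (counts must respect bounds)."""
    by_name = {c.name: c for c in inv.components}
    total = 0.0
    for name, k in counts.items():
        c = by_name[name]
        if not (c.min_count <= k <= c.max_count):
            raise ValueError(
                f"count {k} for {name!r} outside bounds [{c.min_count}, {c.max_count}]"
            )
        total += k * c.mass
    return total


def solve_stoichiometry(
    measured: float,
    inv: ComponentInventory,
    tol: float,
) -> List[CompositionSolution]:
    """Exhaustive bounded enumeration of stoichiometries within ``tol`` of measured.

    Branch-and-bound over the count lattice (pruned by the reachable mass
    range of the remaining components, so large-but-sparse inventories stay
    fast).  Solutions sorted by |residual|, ties by fewer total subunits
    (Occam rule), then lexicographic counts for determinism.
    """
    if measured <= 0:
        raise ValueError("measured mass must be positive")
    if inv.enumeration_size > MAX_ENUMERATION:
        raise ValueError(
            f"enumeration size {inv.enumeration_size} exceeds {MAX_ENUMERATION}; "
            "tighten the count bounds"
        )
    comps = inv.components
    n = len(comps)
    # reachable mass range of components i..end
    min_rest = np.zeros(n + 1)
    max_rest = np.zeros(n + 1)
    for i in range(n - 1, -1, -1):
        min_rest[i] = min_rest[i + 1] + comps[i].min_count * comps[i].mass
        max_rest[i] = max_rest[i + 1] + comps[i].max_count * comps[i].mass
    solutions: List[CompositionSolution] = []
    counts = [0] * n

    def recurse(i: int, mass_so_far: float) -> None:
        if i == n:
            residual = measured - mass_so_far
            if abs(residual) <= tol:
                solutions.append(
                    CompositionSolution(
                        counts={c.name: k for c, k in zip(comps, counts)},
                        theoretical_mass=mass_so_far,
                        residual=residual,
                        abs_residual_ppm=abs(residual) / measured * 1e6,
                    )
                )
            return
        c = comps[i]
        for k in range(c.min_count, c.max_count + 1):
            m = mass_so_far + k * c.mass
            # prune: remaining components cannot bridge the gap
            if m + min_rest[i + 1] > measured + tol:
                break
            if m + max_rest[i + 1] < measured - tol:
                continue
            counts[i] = k
            recurse(i + 1, m)
        counts[i] = 0

    recurse(0, 0.0)
    solutions.sort(
        key=lambda sol: (
            abs(sol.residual),
            sol.total_subunits,
            tuple(sorted(sol.counts.items())),
        )
    )
    return solutions


@dataclass
class DeficitAssignment:
    deficit: float
    best: Optional[str]
    best_mass: Optional[float]
    margin: float


def assign_subpopulation_deficit(
    main_mass: float,
    sub_mass: float,
    candidates: Sequence[Tuple[str, float]],
) -> DeficitAssignment:
    """Assign a subpopulation's mass deficit to the closest missing-subunit candidate.

    deficit = main − sub; the winner minimizes |deficit − candidate mass| and
    ``margin`` is how much farther the runner-up is (infinite sentinel when
    only one candidate exists).
    """
    if main_mass <= sub_mass:
        raise ValueError("main_mass must exceed sub_mass")
    deficit = main_mass - sub_mass
    if not candidates:
        return DeficitAssignment(deficit, None, None, MARGIN_SENTINEL)
    dists = sorted(
        ((abs(deficit - m), name, m) for name, m in candidates),
        key=lambda t: (t[0], t[2]),
    )
    best_d, best_name, best_mass = dists[0]
    margin = dists[1][0] - best_d if len(dists) > 1 else MARGIN_SENTINEL
    return DeficitAssignment(deficit, best_name, best_mass, margin)


@dataclass
class BindingShift:
    shift: float
    matched: Optional[str]
    relative_error: float
    stoichiometry: int
    multi_candidates: List[Tuple[str, int, float]]  # (ligand, n, rel error of n:1)


def binding_mass_shift(
    free_mass: float,
    bound_mass: float,
    ligands: Sequence[Tuple[str, float]],
    rel_tol: float = 0.05,
) -> BindingShift:
    """Match a binding-induced mass increase to a ligand at relative tolerance.

    ``matched`` is the nearest ligand within ``rel_tol`` assuming 1:1 binding;
    independently, every ligand is tested for integer n:1 binding and the
    consistent (ligand, n) pairs are reported, so e.g. a shift of three ligand
    masses surfaces as an n = 3 candidate even when no 1:1 match exists.
    """
    if bound_mass <= free_mass:
        raise ValueError("bound_mass must exceed free_mass")
    shift = bound_mass - free_mass
    matched = None
    best_err = float("inf")
    for name, m in ligands:
        err = abs(shift - m) / m
        if err < best_err:
            best_err, matched = err, name
    if best_err > rel_tol:
        matched = None
    multi: List[Tuple[str, int, float]] = []
    for name, m in ligands:
        k = int(round(shift / m))
        if k >= 1:
            err = abs(shift - k * m) / (k * m)
            if err <= rel_tol:
                multi.append((name, k, err))
    stoich = 0
    if matched is not None:
        stoich = int(round(shift / dict(ligands)[matched]))
    return BindingShift(
        shift=shift,
        matched=matched,
        relative_error=best_err,
        stoichiometry=stoich,
        multi_candidates=multi,
    )


def format_kda(mass_da: float) -> str:
    """Render a mass in kDa with one decimal, half-up (prints 5745 Da as '5.7')."""
    kda = Decimal(repr(mass_da)) / Decimal(1000)
    return str(kda.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
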