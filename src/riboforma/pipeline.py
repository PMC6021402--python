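"""End-to-end orchestration and paper-style summary tables.

``run_pipeline`` chains full-scan deconvolution → top-down identification →
(optional) terminal-processing inference → stoichiometry solving, and writes
deterministic TSV reports plus a JSON provenance record (config, seed,
package version, config hash) that can reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd

from . import __version__
from .chem import read_fasta
from .composition import ComponentInventory, solve_stoichiometry
from .deconvolution import deconvolute_scan
from .spectra import read_multiscan_tsv, read_peaklist_tsv
from .topdown import (
    SearchParams,
    absolute_mass_search,
    infer_terminal_processing,
    proteoform_report,
)

logger = logging.getLogger("riboforma")


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved."""


@dataclass
class RunConfig:
    """Serializable run configuration.

    Defaults follow the standard acquisition/search settings: 10 ppm fragment
    tolerance, 500 Da precursor window, charge 5–100 and 5–100 kDa mass range
    for full-scan deconvolution, 1 Da MS1/proteoform mass matching.
    """

    out_dir: str = "riboforma_out"
    seed: int = 0
    ms1_paths: List[str] = field(default_factory=list)
    ms2_paths: List[str] = field(default_factory=list)
    db_fasta: Optional[str] = None
    inventory_tsv: Optional[str] = None
    measured_complex_mass: Optional[float] = None
    complex_tol: float = 500.0
    charge_range: Tuple[int, int] = (5, 100)
    mass_range: Tuple[float, float] = (5_000.0, 100_000.0)
    min_series_length: int = 3
    mz_tol_ppm: float = 20.0
    precursor_window: float = 500.0
    fragment_tol_ppm: float = 10.0
    min_matched: int = 5
    ms1_match_tol: float = 1.0
    infer_truncation: bool = False
    max_nterm_trim: int = 120
    max_cterm_trim: int = 60
    log_level: str = "INFO"

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.canonical_json() + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data.pop("_provenance", None)
        cfg = cls(**data)
        cfg.charge_range = tuple(cfg.charge_range)
        cfg.mass_range = tuple(cfg.mass_range)
        return cfg

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:12]


def _provenance_header(cfg: RunConfig) -> List[str]:
    return [
        f"# riboforma={__version__}",
        f"# config_hash={cfg.config_hash}",
        f"# seed={cfg.seed}",
    ]


def _write_tsv(path: Path, df: pd.DataFrame, cfg: RunConfig) -> None:
    lines = _provenance_header(cfg)
    lines.append(df.to_csv(sep="\t", index=False, float_format="%.6f").rstrip("\n"))
    path.write_text("\n".join(lines) + "\n")


@dataclass
class ReportBundle:
    ms1_masses: list
    prsms: list
    proteoform_overview: pd.DataFrame
    compositions: list
    out_dir: Path


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute deconvolve → identify → (optional truncation) → compose.

    Outputs under ``cfg.out_dir``: ``ms1_masses.tsv``, ``prsms.tsv``,
    ``proteoform_overview.tsv`` (protein, Δmass, normalized intensity),
    ``composition.tsv`` and ``provenance.json``.  Raises
    :class:`PipelineError` on stage failure with partial outputs preserved.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------------------ MS1
    ms1_masses = []
    stage = "deconvolve"
    try:
        spectra = []
        for path in cfg.ms1_paths:
            p = Path(path)
            if not p.exists():
                raise PipelineError(f"[{stage}] missing input {p}")
            if _is_multiscan(p):
                spectra.extend(read_multiscan_tsv(p))
            else:
                spectra.append(read_peaklist_tsv(p))
        for s in spectra:
            masses, _table = deconvolute_scan(
                s,
                charge_range=cfg.charge_range,
                mass_range=cfg.mass_range,
                min_series_length=cfg.min_series_length,
                mz_tol_ppm=cfg.mz_tol_ppm,
            )
            ms1_masses.extend(masses)
        rows = [
            {
                "scan": d.source_scan,
                "mass": d.mass,
                "mass_sd": d.mass_sd,
                "total_intensity": d.total_intensity,
                "best_charge": d.best_charge,
                "n_peaks": len(d.member_peaks),
            }
            for d in sorted(ms1_masses, key=lambda d: (d.source_scan, d.mass))
        ]
        _write_tsv(
            out / "ms1_masses.tsv",
            pd.DataFrame(rows, columns=["scan", "mass", "mass_sd", "total_intensity",
                                        "best_charge", "n_peaks"]),
            cfg,
        )
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(f"[{stage}] {exc}") from exc

    # ------------------------------------------------------------------ MS2
    stage = "identify"
    prsms = []
    if cfg.ms2_paths and not cfg.db_fasta:
        raise PipelineError(f"[{stage}] MS2 spectra given but no database FASTA")
    if cfg.ms2_paths:
        db = read_fasta(cfg.db_fasta)
        params = SearchParams(
            precursor_window=cfg.precursor_window,
            fragment_tol_ppm=cfg.fragment_tol_ppm,
            min_matched=cfg.min_matched,
        )
        for path in cfg.ms2_paths:
            s = read_peaklist_tsv(path, ms_level=2, resolution_mode="high")
            precursor = s.metadata.get("precursor_mass_da")
            if precursor is None:
                raise PipelineError(
                    f"[{stage}] {path} lacks a '# precursor_mass_da=' header"
                )
            hits = absolute_mass_search(float(precursor), s, db, params)
            if hits and cfg.infer_truncation and abs(hits[0].mass_delta) > cfg.ms1_match_tol:
                refined = infer_terminal_processing(
                    hits[0].proteoform.base, float(precursor), s, params,
                    max_nterm_trim=cfg.max_nterm_trim,
                    max_cterm_trim=cfg.max_cterm_trim,
                )
                if refined.forms:
                    hits[0] = refined.forms[0]
            prsms.extend(hits[:1])
        rows = [
            {
                "protein": h.proteoform.base.identifier,
                "proteoform": h.proteoform.describe(),
                "precursor_mass": h.precursor_mass,
                "mass_delta": h.mass_delta,
                "n_matched": h.n_matched,
                "nterm_coverage": h.nterm_coverage,
                "cterm_coverage": h.cterm_coverage,
            }
            for h in sorted(
                prsms, key=lambda h: (h.proteoform.base.identifier, h.mass_delta)
            )
        ]
        _write_tsv(
            out / "prsms.tsv",
            pd.DataFrame(rows, columns=["protein", "proteoform", "precursor_mass",
                                        "mass_delta", "n_matched", "nterm_coverage",
                                        "cterm_coverage"]),
            cfg,
        )

    overview = proteoform_report(prsms, ms1_masses, match_tol=cfg.ms1_match_tol)
    _write_tsv(out / "proteoform_overview.tsv", overview, cfg)

    # ---------------------------------------------------------------- compose
    stage = "compose"
    compositions = []
    if cfg.inventory_tsv and cfg.measured_complex_mass:
        inv = ComponentInventory.from_tsv(cfg.inventory_tsv)
        compositions = solve_stoichiometry(
            cfg.measured_complex_mass, inv, cfg.complex_tol
        )
        rows = [
            {
                "rank": i,
                "counts": ";".join(f"{k}x{v}" for k, v in sorted(sol.counts.items())),
                "theoretical_mass": sol.theoretical_mass,
                "residual": sol.residual,
                "abs_residual_ppm": sol.abs_residual_ppm,
                "total_subunits": sol.total_subunits,
            }
            for i, sol in enumerate(compositions)
        ]
        _write_tsv(
            out / "composition.tsv",
            pd.DataFrame(rows, columns=["rank", "counts", "theoretical_mass",
                                        "residual", "abs_residual_ppm",
                                        "total_subunits"]),
            cfg,
        )

    provenance = json.loads(cfg.canonical_json())
    provenance["_provenance"] = {
        "version": __version__,
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True) + "\n")
    return ReportBundle(
        ms1_masses=ms1_masses,
        prsms=prsms,
        proteoform_overview=overview,
        compositions=compositions,
        out_dir=out,
    )


def _is_multiscan(path: Path) -> bool:
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        return ln.split("\t")[0].lower() in ("scan_id", "scan")
    return False


def render_proteoform_overview(
    report: pd.DataFrame, scale_limit: float = 120.0
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Split the proteoform table for dot-plot rendering.

    Rows with |Δmass| within ``scale_limit`` Da form the plot data
    (protein, Δmass, relative abundance, annotation); larger shifts — e.g.
    alanine-repeat insertions of hundreds of Da — are routed to a separate
    out-of-scale list.
    """
    cols = ["protein", "mass_delta", "normalized_intensity", "annotation"]
    if report.empty:
        empty = pd.DataFrame(columns=cols)
        return empty, empty.copy()
    data = report[cols].copy()
    in_scale = data[data["mass_delta"].abs() <= scale_limit].reset_index(drop=True)
    outliers = data[data["mass_delta"].abs() > scale_limit].reset_index(drop=True)
    return in_scale, outliers


def plot_proteoform_overview(report: pd.DataFrame, ax=None, scale_limit: float = 120.0):
    """Dot plot of proteoform mass deltas, marker size ∝ relative abundance."""
    import matplotlib.pyplot as plt

    in_scale, _ = render_proteoform_overview(report, scale_limit)
    if ax is None:
        _fig, ax = plt.subplots(figsize=(8, 4))
    proteins = sorted(in_scale["protein"].unique())
    xpos = {p: i for i, p in enumerate(proteins)}
    ax.scatter(
        [xpos[p] for p in in_scale["protein"]],
        in_scale["mass_delta"],
        s=20 + 300 * in_scale["normalized_intensity"],
        alpha=0.6,
    )
    ax.set_xticks(range(len(proteins)))
    ax.set_xticklabels(proteins, rotation=90, fontsize=7)
    ax.set_ylabel("Δ mass vs backbone (Da)")
    ax.axhline(0.0, color="0.8", lw=0.8)
    return ax
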