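"""Plate-screen statistics: viability normalization, Z'-factor QC,
positive-control-anchored hit calling, and bioactivity group partitioning.

The screening design uses three cell models — HCT 116 colon-carcinoma
spheroids (3D), HCT 116 monolayers (2D), and the non-carcinogenic brain
endothelial line hCMEC/D3 (2D).  Hits are selected on the spheroid model
only, against a threshold anchored to a known cytotoxic fraction (the
positive control); the monolayer data then split hits into a
strongly-cytotoxic group A and a spheroid-selective group B.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem_mass import round_half_away

__all__ = [
    "AssayMeasurement",
    "FractionViability",
    "ScreenConfig",
    "GroupAssignment",
    "normalize_viability",
    "summarize_plate",
    "zprime",
    "hit_threshold",
    "call_hits",
    "assign_groups",
    "hit_rate",
    "fraction_from_time",
    "read_plate_csv",
    "load_reference_screen",
    "load_collection_program",
]

CELL_MODELS = ("3D_HCT116", "2D_HCT116", "2D_hCMEC/D3")

#: Z' below this value indicates a poorly separated assay window.
ZPRIME_POOR_SEPARATION = 0.5


@dataclass(frozen=True)
class AssayMeasurement:
    """Raw replicate absorbances for one fraction in one cell model."""

    fraction_id: str
    cell_model: str
    absorbances: tuple[float, ...]
    role: str = "test"  # test | solvent_control | positive_control | reference_drug

    def __post_init__(self) -> None:
        if len(self.absorbances) < 1:
            raise ValueError("at least one replicate required")
        if any(a < 0 for a in self.absorbances):
            raise ValueError("absorbances must be non-negative")


@dataclass(frozen=True)
class FractionViability:
    """Per-fraction, per-cell-model viability summary (% of solvent control)."""

    fraction_id: str
    cell_model: str
    mean_viability: float
    sd_viability: float
    n: int = 3
    role: str = "test"

    def __post_init__(self) -> None:
        if self.sd_viability < 0 or self.n < 1:
            raise ValueError("sd must be >= 0 and n >= 1")


@dataclass(frozen=True)
class ScreenConfig:
    """Hit-calling and group-partition parameters."""

    k_sigma: float = 3.0
    group_a_2d_cutoff: float = 40.0
    library_size: int = 512

    def __post_init__(self) -> None:
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if not 0 < self.group_a_2d_cutoff < 100:
            raise ValueError("group_a_2d_cutoff must be in (0, 100)")


@dataclass(frozen=True)
class GroupAssignment:
    fraction_id: str
    group: str  # "A" | "B" | "C/inactive"


def normalize_viability(sample: AssayMeasurement, solvent: AssayMeasurement) -> float:
    """% viability = 100 × mean(sample absorbance) / mean(solvent absorbance)."""
    if sample.cell_model != solvent.cell_model:
        raise ValueError("sample and solvent control are from different cell models")
    control_mean = float(np.mean(solvent.absorbances))
    if control_mean <= 0:
        raise ValueError("degenerate control: solvent mean absorbance <= 0")
    return 100.0 * float(np.mean(sample.absorbances)) / control_mean


def summarize_plate(
    measurements: Iterable[AssayMeasurement],
) -> list[FractionViability]:
    """Summarize raw plate absorbances into per-fraction viability (mean ± SD).

    Each test/positive-control well is normalized to the mean of the
    solvent-control wells of its cell model; the SD is that of the
    per-replicate viabilities (ddof=1 when n > 1).
    """
    measurements = list(measurements)
    solvent = {
        m.cell_model: m for m in measurements if m.role == "solvent_control"
    }
    out: list[FractionViability] = []
    for m in measurements:
        if m.role == "solvent_control":
            continue
        if m.cell_model not in solvent:
            raise ValueError(f"no solvent control for cell model {m.cell_model}")
        ctrl_mean = float(np.mean(solvent[m.cell_model].absorbances))
        if ctrl_mean <= 0:
            raise ValueError("degenerate control: solvent mean absorbance <= 0")
        viab = 100.0 * np.asarray(m.absorbances) / ctrl_mean
        sd = float(np.std(viab, ddof=1)) if len(viab) > 1 else 0.0
        out.append(
            FractionViability(
                m.fraction_id, m.cell_model, float(viab.mean()), sd, len(viab), m.role
            )
        )
    return out


def zprime(positive: FractionViability, solvent: FractionViability) -> float:
    """Z'-factor: 1 − 3(σ_pos + σ_solv)/|μ_pos − μ_solv| (may be negative).

    Values ≥ 0.5 indicate a well-separated screening window; compare with
    :data:`ZPRIME_POOR_SEPARATION`.
    """
    window = abs(positive.mean_viability - solvent.mean_viability)
    if window == 0:
        raise ValueError("no assay window: positive and solvent means are equal")
    return 1.0 - 3.0 * (positive.sd_viability + solvent.sd_viability) / window


def hit_threshold(positive: FractionViability, k: float = 3.0) -> float:
    """Hit-calling viability threshold μ_pos + k·σ_pos, rounded to 2 dp."""
    if k <= 0:
        raise ValueError("k must be positive")
    return round_half_away(positive.mean_viability + k * positive.sd_viability, 2)


def call_hits(
    viabilities: Sequence[FractionViability],
    threshold: float,
    cell_model: str,
) -> list[str]:
    """Fractions whose mean viability falls strictly below the threshold.

    The positive-control fraction anchoring the threshold is excluded from
    its own hit list.  Output is ordered by ascending viability.
    """
    rows = [
        v
        for v in viabilities
        if v.cell_model == cell_model
        and v.role != "positive_control"
        and v.mean_viability < threshold
    ]
    rows.sort(key=lambda v: (v.mean_viability, v.fraction_id))
    return [v.fraction_id for v in rows]


def assign_groups(
    viabilities: Sequence[FractionViability],
    cfg: ScreenConfig = ScreenConfig(),
) -> list[GroupAssignment]:
    """Partition fractions into bioactivity groups A, B, and C/inactive.

    A fraction is a hit when its 3D-spheroid viability is strictly below
    the positive-control-anchored threshold (positive control included
    here: it partitions like any other fraction).  Hits with 2D HCT 116
    viability below ``group_a_2d_cutoff`` are group A (broadly cytotoxic);
    remaining hits are group B (spheroid-selective); non-hits are
    C/inactive.  Missing 2D values are treated as inactive in 2D.
    """
    by_fraction: dict[str, dict[str, FractionViability]] = {}
    for v in viabilities:
        by_fraction.setdefault(v.fraction_id, {})[v.cell_model] = v
    positive = [
        v
        for v in viabilities
        if v.role == "positive_control" and v.cell_model == "3D_HCT116"
    ]
    if not positive:
        raise ValueError("no 3D positive control to anchor the hit threshold")
    threshold = hit_threshold(positive[0], cfg.k_sigma)

    out: list[GroupAssignment] = []
    for fid in by_fraction:
        models = by_fraction[fid]
        if "3D_HCT116" not in models:
            raise ValueError(f"fraction {fid} lacks a 3D viability value")
        is_hit = models["3D_HCT116"].mean_viability < threshold
        if not is_hit:
            group = "C/inactive"
        else:
            v2d = models.get("2D_HCT116")
            if v2d is not None and v2d.mean_viability < cfg.group_a_2d_cutoff:
                group = "A"
            else:
                group = "B"
        out.append(GroupAssignment(fid, group))
    return out


def hit_rate(n_hits: int, library_size: int) -> float:
    """Hit rate as a percentage of the fraction library, rounded to 1 dp."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if not 0 <= n_hits <= library_size:
        raise ValueError("n_hits out of range")
    return round_half_away(100.0 * n_hits / library_size, 1)


def fraction_from_time(rt: float, program: pd.DataFrame) -> str:
    """Map a retention time (minutes) to the HPLC collection-window letter.

    ``program`` has columns start_min, end_min, fraction with sorted,
    non-overlapping half-open windows [start, end).  Times outside every
    window return ``"uncollected"``.
    """
    prog = program.sort_values("start_min").reset_index(drop=True)
    ends = prog["end_min"].to_numpy()
    starts = prog["start_min"].to_numpy()
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError("collection windows overlap")
    for start, end, letter in zip(starts, ends, prog["fraction"]):
        if start <= rt < end:
            return str(letter)
    return "uncollected"


def read_plate_csv(path) -> list[AssayMeasurement]:
    """Read raw plate data: fraction_id, cell_model, role, rep_1..rep_k."""
    df = pd.read_csv(path)
    rep_cols = [c for c in df.columns if c.startswith("rep_")]
    if not rep_cols:
        raise ValueError("plate CSV has no replicate (rep_*) columns")
    out = []
    for _, row in df.iterrows():
        reps = tuple(float(row[c]) for c in rep_cols if pd.notna(row[c]))
        out.append(
            AssayMeasurement(row["fraction_id"], row["cell_model"], reps, row["role"])
        )
    return out


def load_reference_screen() -> list[FractionViability]:
    """Bundled viability summary of the 24 fractions characterized in the
    cyanobacterial fraction-library screen (mean ± SD per cell model)."""
    with resources.files("cyanoprio.data").joinpath("reference_screen.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        FractionViability(
            r.fraction_id,
            r.cell_model,
            float(r.mean_viability),
            float(r.sd_viability),
            int(r.n),
            r.role,
        )
        for r in df.itertuples()
    ]


def load_reference_screen_df() -> pd.DataFrame:
    """The bundled screen summary as a DataFrame (includes published groups)."""
    with resources.files("cyanoprio.data").joinpath("reference_screen.csv").open() as fh:
        return pd.read_csv(fh)


def load_collection_program() -> pd.DataFrame:
    """Bundled HPLC collection program (retention-time → fraction letter)."""
    with resources.files("cyanoprio.data").joinpath("collection_program.csv").open() as fh:
        return pd.read_csv(fh)
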