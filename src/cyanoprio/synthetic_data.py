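"""Ground-truthed synthetic inputs for every pipeline stage.

Emulates the study's data shapes without any instrument data: a
plate-screen of a fraction library (solvent and positive controls,
designated active fractions), an MZmine-style MS1 quantification table
with spiked compounds appearing as adduct/dimer series and Cl/Br
isotopologue features, MS2 spectra with shared scaffold fragments so
that structural analogs network together, and the compound database.
Every generated well and feature is traceable to a manifest entry, and
generation is deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_mass import (
    adduct_mz,
    get_adduct,
    load_adducts,
    monoisotopic_mass,
    parse_formula,
    simulate_envelope,
)
from .dereplication import CompoundRecord, load_compound_db
from .networking import MS2Spectrum

__all__ = [
    "GeneratorConfig",
    "SpikeSpec",
    "ScreenResult",
    "FeatureGenResult",
    "generate_screen",
    "generate_features",
    "bundled_reference_db",
    "write_quant_csv",
    "write_plate_csv",
    "write_group_map_csv",
]

#: Nominal A+1 / A+2 isotopologue m/z spacings (13C and 37Cl-dominated).
_A1_SPACING = 1.00336
_A2_SPACING = 1.99705


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for the synthetic generators.

    The defaults mirror the screened library's design: 64 extracts of 8
    HPLC fractions each (512 fractions), triplicate wells, a positive
    control centred at 68.32 ± 4.60 % viability in spheroids and
    9.13 ± 2.64 % in monolayers, 5 + 6 designated active fractions, and
    an 18-sample (6 active vs 12 control) feature-table design.
    Intensity noise is multiplicative log-normal, the standard model for
    LC-MS peak areas; m/z error spans 5 ppm peak-to-peak; intensities
    below the limit of detection are written as 0 (missing).
    """

    seed: int
    n_strains: int = 64
    fractions_per_strain: int = 8
    n_replicates: int = 3
    n_active_a: int = 5   # active in spheroids and monolayers
    n_active_b: int = 6   # spheroid-selective actives
    positive_control: dict = field(
        default_factory=lambda: {
            "3D_HCT116": (68.32, 4.60),
            "2D_HCT116": (9.13, 2.64),
            "2D_hCMEC/D3": (12.83, 3.35),
        }
    )
    k_sigma: float = 3.0
    control_absorbance: float = 0.66
    solvent_rep_sd: float = 4.0       # % viability, replicate scatter
    active_rep_sd: float = 3.0
    active_3d_range: tuple[float, float] = (50.0, 65.0)
    inactive_3d_range: tuple[float, float] = (92.0, 108.0)
    n_active_samples: int = 6
    n_control_samples: int = 12
    base_intensity: float = 1e8
    lognormal_sigma: float = 0.2
    isotopologue_sigma: float = 0.02  # within-scan isotope-ratio scatter
    mz_ppm_halfwidth: float = 2.5     # uniform m/z error, 5 ppm peak-to-peak
    lod: float = 1e4
    envelope_floor: float = 0.05      # min relative abundance emitted as a feature
    n_decoys: int = 30
    adduct_probs: dict = field(
        default_factory=lambda: {"[M+Na]+": 0.6, "[2M+H]+": 0.35, "[2M+Na]+": 0.35}
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_strains", "fractions_per_strain", "n_replicates",
                     "n_active_samples", "n_control_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be >= 0")


# ---------------------------------------------------------------------------
# plate screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenResult:
    plate: pd.DataFrame        # fraction_id, cell_model, role, rep_1..rep_k
    manifest: dict


def generate_screen(cfg: GeneratorConfig) -> ScreenResult:
    """Generate a triplicate plate screen with known active/inactive labels.

    Solvent controls are centred at 100 % viability; the positive-control
    fraction at the configured per-model mean/SD.  Designated group A
    actives fall below the hit threshold in spheroids *and* below 40 % in
    monolayers; group B actives only in spheroids; all other fractions
    are drawn well above the threshold.
    """
    rng = np.random.default_rng(cfg.seed)
    models = list(cfg.positive_control)
    thresh_3d = cfg.positive_control["3D_HCT116"][0] + cfg.k_sigma * cfg.positive_control["3D_HCT116"][1]
    if cfg.active_3d_range[1] >= thresh_3d - 2 * cfg.active_rep_sd:
        raise ValueError(
            "infeasible config: designated active viabilities reach the hit threshold"
        )

    fraction_ids = [
        f"S{istr + 1:02d}_{chr(ord('A') + j)}"
        for istr in range(cfg.n_strains)
        for j in range(cfg.fractions_per_strain)
    ]
    n_act = cfg.n_active_a + cfg.n_active_b
    actives = list(rng.choice(fraction_ids, size=n_act, replace=False))
    group_a, group_b = actives[: cfg.n_active_a], actives[cfg.n_active_a :]

    def true_viability(fid: str, model: str) -> float:
        if model == "3D_HCT116":
            if fid in actives:
                return rng.uniform(*cfg.active_3d_range)
            return rng.uniform(*cfg.inactive_3d_range)
        if model == "2D_HCT116":
            if fid in group_a:
                return rng.uniform(10.0, 30.0)
            if fid in group_b:
                return rng.uniform(45.0, 75.0)
            return rng.uniform(42.0, 85.0)
        if fid in group_a:
            return rng.uniform(10.0, 40.0)
        return rng.uniform(20.0, 80.0)

    rows = []

    def add_row(fid: str, model: str, role: str, mean_v: float, sd: float) -> None:
        reps = np.clip(mean_v + rng.normal(0.0, sd, size=cfg.n_replicates), 0.0, None)
        absorb = reps / 100.0 * cfg.control_absorbance
        rows.append(
            {"fraction_id": fid, "cell_model": model, "role": role}
            | {f"rep_{i + 1}": float(a) for i, a in enumerate(absorb)}
        )

    manifest_fractions = {}
    for model in models:
        add_row("DMSO", model, "solvent_control", 100.0, cfg.solvent_rep_sd)
        mu, sd = cfg.positive_control[model]
        add_row("POSCTRL_C", model, "positive_control", mu, sd)
    for fid in fraction_ids:
        grp = "A" if fid in group_a else ("B" if fid in group_b else "C/inactive")
        for model in models:
            sd = cfg.active_rep_sd if fid in actives else cfg.solvent_rep_sd
            add_row(fid, model, "test", true_viability(fid, model), sd)
        manifest_fractions[fid] = {"active_3d": fid in actives, "group": grp}

    plate = pd.DataFrame(rows)
    manifest = {
        "seed": cfg.seed,
        "threshold_3d": thresh_3d,
        "fractions": manifest_fractions,
        "n_active_3d": n_act,
    }
    return ScreenResult(plate, manifest)


def write_plate_csv(result: ScreenResult, path) -> None:
    result.plate.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# feature tables + MS2
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeSpec:
    """One compound spiked into the synthetic metabolome.

    ``active_only`` compounds are absent (0) from control samples; else
    ``ratio`` sets the generating active/control abundance ratio.
    ``scaffold`` labels compounds sharing MS2 backbone fragments, so that
    analogs cluster in the molecular network.
    """

    name: str
    formula: str
    base_intensity: float | None = None
    active_only: bool = True
    ratio: float = 1.0
    scaffold: str | None = None


@dataclass(frozen=True)
class FeatureGenResult:
    quant: pd.DataFrame        # MZmine-dialect quantification table
    spectra: list[MS2Spectrum]
    sample_groups: dict[str, str]
    manifest: dict


def bundled_reference_db() -> list[CompoundRecord]:
    """The bundled compound database of the study's annotated metabolites
    (portoamides A–C, minutissamide A, six chlorophyll-degradation
    tetrapyrroles, and a mass-only leptochelin record)."""
    return load_compound_db()


def _default_spikes() -> list[SpikeSpec]:
    return [
        SpikeSpec(rec.name, str(rec.formula), scaffold=rec.note.split(";")[0])
        for rec in bundled_reference_db()
        if rec.formula is not None
    ]


def generate_features(
    cfg: GeneratorConfig, spikes: Sequence[SpikeSpec] | None = None
) -> FeatureGenResult:
    """Generate an MS1 quantification table, MS2 spectra, and manifest.

    Each spiked compound appears as an [M+H]+ feature plus a probabilistic
    [M+Na]+/[2M+H]+/[2M+Na]+ series at a shared retention time; Cl/Br
    formulas additionally emit isotopologue (A+1, A+2, ...) features with
    abundances from the simulated envelope.  Active-only compounds have 0
    (missing) intensity in control samples.  Decoy noise features appear
    in both groups at comparable abundance.
    """
    spikes = list(spikes) if spikes is not None else _default_spikes()
    rng = np.random.default_rng(cfg.seed)
    adducts = load_adducts()
    samples = [f"A_{i + 1}" for i in range(cfg.n_active_samples)] + [
        f"C_{i + 1}" for i in range(cfg.n_control_samples)
    ]
    sample_groups = {
        s: ("active_A" if s.startswith("A_") else "control_C") for s in samples
    }

    scaffold_frags: dict[str, np.ndarray] = {}

    def frags_for(scaffold: str) -> np.ndarray:
        if scaffold not in scaffold_frags:
            sub = np.random.default_rng(
                (cfg.seed * 10007 + abs(hash(scaffold)) % 100000) % 2**31
            )
            scaffold_frags[scaffold] = np.sort(sub.uniform(100.0, 480.0, size=10))
        return scaffold_frags[scaffold]

    feat_rows = []
    spectra: list[MS2Spectrum] = []
    manifest_features = {}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"F{counter:04d}"

    def sample_values(level: float, active_only: bool, ratio: float) -> dict[str, float]:
        vals = {}
        for s in samples:
            is_active = sample_groups[s] == "active_A"
            if active_only and not is_active:
                vals[s] = 0.0
                continue
            mu = level if is_active else level / ratio
            v = mu * rng.lognormal(0.0, cfg.lognormal_sigma)
            vals[s] = v if v >= cfg.lod else 0.0
        return vals

    def jitter(mz: float) -> float:
        return mz * (1.0 + rng.uniform(-cfg.mz_ppm_halfwidth, cfg.mz_ppm_halfwidth) * 1e-6)

    for spike in spikes:
        formula = parse_formula(spike.formula)
        M = monoisotopic_mass(formula)
        rt = float(rng.uniform(2.0, 14.5))
        base = spike.base_intensity or cfg.base_intensity
        series = ["[M+H]+"]
        for name, p in cfg.adduct_probs.items():
            if rng.random() < p:
                series.append(name)
        factors = {"[M+H]+": 1.0, "[M+Na]+": 0.4, "[2M+H]+": 0.25, "[2M+Na]+": 0.15}
        parent_vals: dict[str, float] | None = None
        for aname in series:
            a = get_adduct(aname, adducts)
            true_mz = adduct_mz(M, a)
            if not 150.0 <= true_mz <= 2000.0:
                continue
            vals = sample_values(base * factors[aname], spike.active_only, spike.ratio)
            fid = next_id()
            feat_rows.append({"feature_id": fid, "mz": jitter(true_mz), "rt": rt} | vals)
            manifest_features[fid] = {
                "compound": spike.name,
                "adduct": aname,
                "isotopologue": 0,
                "true_mz": true_mz,
                "decoy": False,
            }
            if aname == "[M+H]+":
                parent_vals = vals
                parent_fid = fid
        # isotopologue features for the [M+H]+ ion
        env = simulate_envelope(formula, max_peaks=9)
        halogens = formula.counts.get("Cl", 0) + formula.counts.get("Br", 0)
        if halogens and parent_vals is not None:
            a0 = env.peaks[0][1]
            parent_mz = adduct_mz(M, get_adduct("[M+H]+", adducts))
            for off, ab in env.peaks[1:]:
                rel = ab / a0
                if rel < cfg.envelope_floor:
                    continue
                k = int(round(off))
                iso_mz = parent_mz + (k // 2) * _A2_SPACING + (k % 2) * _A1_SPACING
                vals = {
                    s: (
                        v * rel * rng.lognormal(0.0, cfg.isotopologue_sigma)
                        if v > 0
                        else 0.0
                    )
                    for s, v in parent_vals.items()
                }
                fid = next_id()
                feat_rows.append(
                    {"feature_id": fid, "mz": jitter(iso_mz), "rt": rt} | vals
                )
                manifest_features[fid] = {
                    "compound": spike.name,
                    "adduct": "[M+H]+",
                    "isotopologue": k,
                    "true_mz": iso_mz,
                    "decoy": False,
                    "parent": parent_fid,
                }
        # MS2 spectrum for the protonated molecule
        scaffold = spike.scaffold or spike.name
        backbone = frags_for(scaffold)
        prec = adduct_mz(M, get_adduct("[M+H]+", adducts))
        frag_int = np.round(rng.uniform(0.2, 1.0, size=backbone.size), 6)
        own = np.sort(rng.uniform(500.0, max(520.0, prec - 20.0), size=4))
        own_int = np.round(rng.uniform(0.2, 1.0, size=own.size), 6)
        peaks = tuple(
            sorted(
                [(float(m), float(i)) for m, i in zip(backbone, frag_int)]
                + [(float(m), float(i)) for m, i in zip(own, own_int)]
            )
        )
        spectra.append(MS2Spectrum(parent_fid, float(prec), rt, peaks))

    for _ in range(cfg.n_decoys):
        mz = float(rng.uniform(150.0, 1900.0))
        rt = float(rng.uniform(1.0, 15.0))
        vals = sample_values(cfg.base_intensity / 10.0, active_only=False, ratio=1.0)
        fid = next_id()
        feat_rows.append({"feature_id": fid, "mz": mz, "rt": rt} | vals)
        manifest_features[fid] = {
            "compound": None,
            "adduct": None,
            "isotopologue": 0,
            "true_mz": mz,
            "decoy": True,
        }
        frag = np.sort(rng.uniform(100.0, max(120.0, mz - 10.0), size=8))
        fint = np.round(rng.uniform(0.2, 1.0, size=frag.size), 6)
        spectra.append(
            MS2Spectrum(fid, mz, rt, tuple((float(m), float(i)) for m, i in zip(frag, fint)))
        )

    quant = pd.DataFrame(feat_rows)
    quant = quant.rename(
        columns={"feature_id": "row ID", "mz": "row m/z", "rt": "row retention time"}
    )
    quant = quant.rename(columns={s: f"{s} Peak area" for s in samples})
    manifest = {
        "seed": cfg.seed,
        "samples": sample_groups,
        "features": manifest_features,
        "spikes": [s.name for s in spikes],
    }
    return FeatureGenResult(quant, spectra, sample_groups, manifest)


def write_quant_csv(result: FeatureGenResult, path) -> None:
    result.quant.to_csv(path, index=False)


def write_group_map_csv(result: FeatureGenResult, path) -> None:
    pd.DataFrame(
        {"sample": list(result.sample_groups), "group": list(result.sample_groups.values())}
    ).to_csv(path, index=False)
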