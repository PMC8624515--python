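"""MS1 feature tables and group-wise fold-change prioritization.

Reads MZmine-style quantification exports (feature id, m/z, retention
time, per-sample peak areas), applies the literal missing-value rule used
for unpaired fold-change analysis (absent/zero cells replaced by a
constant, default 1, with no filtering or normalization), and ranks
features by log2 fold change between an active and a control sample
group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FeatureTable",
    "FoldChangeResult",
    "PrioritizedFeature",
    "read_quant_table",
    "impute_missing",
    "fold_change",
    "prioritize",
    "write_fold_change_tsv",
]

MZ_RANGE = (150.0, 2000.0)  # instrument full-MS scan range


@dataclass(frozen=True)
class FeatureTable:
    """MS1 features × samples intensity matrix with group metadata.

    ``intensities`` is indexed by feature_id with sample columns; missing
    (undetected) cells are NaN.  ``detected`` preserves the pre-imputation
    detection mask.  ``sample_groups`` maps every sample column to a study
    group label (e.g. active_A / control_C).
    """

    features: pd.DataFrame  # columns: feature_id, mz, rt
    intensities: pd.DataFrame
    sample_groups: dict[str, str]
    detected: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.features["feature_id"].duplicated().any():
            raise ValueError("duplicate feature ids")
        missing = set(self.intensities.columns) - set(self.sample_groups)
        if missing:
            raise ValueError(f"samples without a group: {sorted(missing)}")
        if self.detected is None:
            object.__setattr__(self, "detected", self.intensities.notna())

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.sample_groups[s] == group]

    def mz_of(self, feature_id) -> float:
        row = self.features.loc[self.features["feature_id"] == feature_id]
        return float(row["mz"].iloc[0])


@dataclass(frozen=True)
class FoldChangeResult:
    feature_id: object
    fc: float
    log2fc: float
    group_pair: tuple[str, str]
    mz: float = float("nan")


@dataclass(frozen=True)
class PrioritizedFeature:
    feature_id: object
    log2fc: float
    source_fractions: tuple[str, ...]
    tier: str  # "network" (log2fc >= network_cut) or "top" (>= top_cut)


def _load_group_map(sample_groups) -> dict[str, str]:
    if isinstance(sample_groups, Mapping):
        return dict(sample_groups)
    with open(sample_groups) as fh:
        if str(sample_groups).endswith((".yaml", ".yml")):
            return dict(yaml.safe_load(fh))
        df = pd.read_csv(fh)
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_quant_table(path, sample_groups) -> FeatureTable:
    """Read an MZmine-style quantification CSV.

    Expects columns ``row ID``, ``row m/z``, ``row retention time`` and one
    peak-area column per sample ("<sample> Peak area" or bare sample
    names).  Zero and absent areas are marked missing (MZmine exports
    undetected features as 0).  ``sample_groups`` is a mapping or the path
    of a sidecar CSV/YAML mapping sample → group.
    """
    df = pd.read_csv(path)
    required = ["row ID", "row m/z", "row retention time"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"quant table lacks required column {col!r}")
    if df["row ID"].duplicated().any():
        dup = df.loc[df["row ID"].duplicated(), "row ID"].iloc[0]
        raise ValueError(f"duplicate feature id {dup!r}")
    sample_cols = [c for c in df.columns if c not in required and not df[c].isna().all()]
    rename = {
        c: c.removesuffix(" Peak area").strip() for c in sample_cols
    }
    inten = df[sample_cols].rename(columns=rename)
    for col in inten.columns:
        bad = pd.to_numeric(inten[col], errors="coerce").isna() & inten[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric peak area in column {col!r}, row {int(bad.idxmax())}"
            )
    inten = inten.apply(pd.to_numeric)
    inten.index = df["row ID"]
    inten = inten.mask(inten <= 0)  # zeros are undetected
    features = pd.DataFrame(
        {
            "feature_id": df["row ID"],
            "mz": df["row m/z"].astype(float),
            "rt": df["row retention time"].astype(float),
        }
    )
    return FeatureTable(features, inten, _load_group_map(sample_groups))


def impute_missing(t: FeatureTable, value: float = 1.0) -> FeatureTable:
    """Replace every missing cell by ``value`` (default 1); idempotent."""
    if value <= 0:
        raise ValueError("imputation value must be positive")
    return replace(t, intensities=t.intensities.fillna(value), detected=t.detected)


def fold_change(
    t: FeatureTable, active: str = "active_A", control: str = "control_C"
) -> list[FoldChangeResult]:
    """Per-feature fold change between two unpaired sample groups.

    fc = mean(active intensities) / mean(control intensities), on raw
    (unnormalized) areas with imputation already applied.  Raises if the
    table still contains missing cells.
    """
    act = t.samples_in_group(active)
    ctl = t.samples_in_group(control)
    if not act or not ctl:
        raise ValueError("both groups must be non-empty")
    sub = t.intensities[act + ctl]
    if sub.isna().any().any():
        raise ValueError("missing values present: run impute_missing first")
    a = sub[act].mean(axis=1)
    c = sub[ctl].mean(axis=1)
    fc = a / c
    mz = dict(zip(t.features["feature_id"], t.features["mz"]))
    return [
        FoldChangeResult(fid, float(f), float(np.log2(f)), (active, control), mz[fid])
        for fid, f in fc.items()
    ]


def prioritize(
    fc: Sequence[FoldChangeResult],
    t: FeatureTable | None = None,
    network_cut: float = 2.0,
    top_cut: float = 20.0,
) -> list[PrioritizedFeature]:
    """Select candidate bioactive features by log2 fold change.

    Features at or above ``network_cut`` enter the network tier; those at
    or above ``top_cut`` are additionally flagged top.  Output sorted by
    descending log2fc, ties broken by ascending m/z.  When a table is
    supplied, ``source_fractions`` lists the samples where the feature was
    originally detected.
    """
    if network_cut <= 0 or top_cut < network_cut:
        raise ValueError("cuts must satisfy 0 < network_cut <= top_cut")
    selected = [r for r in fc if r.log2fc >= network_cut]
    selected.sort(key=lambda r: (-r.log2fc, r.mz))
    out = []
    for r in selected:
        if t is not None:
            det = t.detected.loc[r.feature_id]
            sources = tuple(s for s in t.samples if bool(det[s]))
        else:
            sources = ()
        tier = "top" if r.log2fc >= top_cut else "network"
        out.append(PrioritizedFeature(r.feature_id, r.log2fc, sources, tier))
    return out


def write_fold_change_tsv(
    path, fc: Sequence[FoldChangeResult], t: FeatureTable, top_cut: float = 20.0,
    network_cut: float = 2.0,
) -> None:
    """Write the fold-change ranking as TSV (feature_id, mz, rt, fc, log2fc, tier)."""
    rt = dict(zip(t.features["feature_id"], t.features["rt"]))
    rows = sorted(fc, key=lambda r: (-r.log2fc, r.mz))
    df = pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in rows],
            "mz": [r.mz for r in rows],
            "rt": [rt[r.feature_id] for r in rows],
            "fc": [r.fc for r in rows],
            "log2fc": [r.log2fc for r in rows],
            "tier": [
                "top" if r.log2fc >= top_cut
                else ("network" if r.log2fc >= network_cut else "-")
                for r in rows
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)
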