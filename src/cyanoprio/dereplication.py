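"""Exact-mass dereplication of prioritized mass features.

Co-eluting ions related by adduct/multimer arithmetic are collapsed to a
common neutral mass, matched against a local compound database with a
ppm tolerance across the supported adduct forms, screened for Cl/Br
isotope signatures (M+2 partner features), and — when unmatched — offered
single-step derivative annotations via the biotransformation delta
library (e.g. a methylation-state ±CH2 shift).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_mass import (
    AdductForm,
    HalogenCandidate,
    IsotopeEnvelope,
    MassDelta,
    MolecularFormula,
    adduct_mz,
    get_adduct,
    halogen_score,
    load_adducts,
    load_delta_library,
    monoisotopic_mass,
    neutral_from_adduct,
    parse_formula,
    ppm_error,
)

__all__ = [
    "CompoundRecord",
    "RelatedIonGroup",
    "DereplicationHit",
    "HalogenCall",
    "load_compound_db",
    "load_annotated_ions",
    "group_related_ions",
    "match_database",
    "annotate_derivatives",
    "detect_halogenation",
    "write_report_tsv",
]

#: Accepted M+2 isotopologue spacing window in Da (covers 37Cl and 81Br).
A2_SPACING = (1.987, 2.007)


@dataclass(frozen=True)
class CompoundRecord:
    """A local compound-database entry.

    Either a parseable molecular formula or — for compounds whose
    structure is not established — a mass-only record carrying the
    literature-reported ion m/z.
    """

    name: str
    formula: MolecularFormula | None
    reference_mz: float | None = None
    note: str = ""

    @property
    def neutral_mass(self) -> float | None:
        return monoisotopic_mass(self.formula) if self.formula is not None else None


def load_compound_db(path=None) -> list[CompoundRecord]:
    """Load a compound database CSV (name, formula, reference_mz, reference).

    With no path, returns the bundled mini-database of compounds annotated
    in the cyanobacterial fraction-screening study (portoamides,
    minutissamide A, chlorophyll-degradation tetrapyrroles, and the
    mass-only leptochelin record).
    """
    if path is None:
        fh = resources.files("cyanoprio.data").joinpath("compound_db.csv").open()
    else:
        fh = open(path)
    with fh:
        df = pd.read_csv(fh)
    if df["name"].duplicated().any():
        raise ValueError("compound names must be unique")
    out = []
    for r in df.itertuples():
        formula = (
            parse_formula(r.formula) if isinstance(r.formula, str) and r.formula else None
        )
        ref_mz = float(r.reference_mz) if pd.notna(r.reference_mz) else None
        note = r.reference if isinstance(r.reference, str) else ""
        out.append(CompoundRecord(r.name, formula, ref_mz, note))
    return out


def load_annotated_ions() -> pd.DataFrame:
    """Bundled reference ion annotations from the fraction-screening study:
    observed m/z, retention time, log2 fold change, adduct form, and (where
    established) the annotated compound and molecular formula."""
    with resources.files("cyanoprio.data").joinpath("annotated_ions.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class RelatedIonGroup:
    """Co-eluting features explained as adduct/multimer ions of one neutral."""

    group_id: int
    neutral_mass: float
    rt: float
    assignments: tuple[tuple[str, str, float], ...]  # (feature_id, adduct, observed m/z)
    flag: str | None = None  # "unconfirmed" for singleton [M+H]+ hypotheses

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(a[0] for a in self.assignments)


def group_related_ions(
    features: pd.DataFrame,
    adducts: Sequence[AdductForm] | None = None,
    mz_tol_ppm: float = 10.0,
    rt_tol: float = 0.1,
) -> list[RelatedIonGroup]:
    """Greedy adduct-series clustering of an m/z–rt feature list.

    Features (columns feature_id, mz, rt) are visited in ascending m/z;
    each unexplained feature is hypothesized to be the [M+H]+ ion and
    co-eluting features (|Δrt| ≤ rt_tol) explained as other adducts or
    multimers of the same neutral within ``mz_tol_ppm`` are absorbed.
    Groups with ≥ 2 consistent members are emitted as confirmed; the rest
    become singletons flagged "unconfirmed".  Each feature joins at most
    one group.  The group neutral mass is the mean of the member-implied
    neutrals, and every member m/z is checked to reconstruct from it.
    """
    adducts = list(adducts) if adducts is not None else load_adducts()
    proto = get_adduct("[M+H]+", adducts)
    others = [a for a in adducts if a.name != "[M+H]+"]
    feats = features.sort_values(["mz", "feature_id"]).reset_index(drop=True)
    assigned: set[str] = set()
    groups: list[RelatedIonGroup] = []
    for row in feats.itertuples():
        if row.feature_id in assigned:
            continue
        neutral = neutral_from_adduct(row.mz, proto)
        members = [(str(row.feature_id), "[M+H]+", float(row.mz))]
        implied = [neutral]
        for other in feats.itertuples():
            if other.feature_id == row.feature_id or other.feature_id in assigned:
                continue
            if abs(other.rt - row.rt) > rt_tol:
                continue
            for a in others:
                predicted = adduct_mz(neutral, a)
                if abs(ppm_error(other.mz, predicted)) <= mz_tol_ppm:
                    members.append((str(other.feature_id), a.name, float(other.mz)))
                    implied.append(neutral_from_adduct(other.mz, a))
                    break
        if len(members) >= 2:
            mean_neutral = float(np.mean(implied))
            for fid, aname, mz in members:
                recon = adduct_mz(mean_neutral, get_adduct(aname, adducts))
                assert abs(ppm_error(mz, recon)) <= 2 * mz_tol_ppm
            groups.append(
                RelatedIonGroup(len(groups), mean_neutral, float(row.rt), tuple(members))
            )
            assigned.update(fid for fid, _, _ in members)
        else:
            groups.append(
                RelatedIonGroup(
                    len(groups), neutral, float(row.rt), tuple(members), flag="unconfirmed"
                )
            )
            assigned.add(str(row.feature_id))
    return groups


@dataclass(frozen=True)
class DereplicationHit:
    """A feature/group ↔ compound match."""

    group_id: int
    feature_id: str
    compound: str
    adduct: str
    observed_mz: float
    calculated_mz: float
    delta_ppm: float
    tier: str  # "direct" or "derivative(<delta name>)"


def match_database(
    group: RelatedIonGroup,
    db: Sequence[CompoundRecord],
    ppm_tol: float = 5.0,
    adducts: Sequence[AdductForm] | None = None,
) -> list[DereplicationHit]:
    """Match a related-ion group against the compound database.

    Every member ion is compared with the calculated m/z of every
    (compound, adduct form) pair; mass-only database records are compared
    directly on the reported ion m/z.  Hits within ``ppm_tol`` are
    returned sorted by |Δppm|; an empty list is the unannotated case.
    """
    if not db:
        raise ValueError("compound database is empty")
    adducts = list(adducts) if adducts is not None else load_adducts()
    hits: list[DereplicationHit] = []
    for rec in db:
        for fid, _aname, obs in group.assignments:
            if rec.formula is not None:
                M = rec.neutral_mass
                for a in adducts:
                    calc = adduct_mz(M, a)
                    dppm = ppm_error(obs, calc)
                    if abs(dppm) <= ppm_tol:
                        hits.append(
                            DereplicationHit(
                                group.group_id, fid, rec.name, a.name, obs, calc, dppm, "direct"
                            )
                        )
            elif rec.reference_mz is not None:
                dppm = ppm_error(obs, rec.reference_mz)
                if abs(dppm) <= ppm_tol:
                    hits.append(
                        DereplicationHit(
                            group.group_id,
                            fid,
                            rec.name,
                            "as-reported",
                            obs,
                            rec.reference_mz,
                            dppm,
                            "direct",
                        )
                    )
    hits.sort(key=lambda h: (abs(h.delta_ppm), h.compound, h.feature_id))
    return hits


def annotate_derivatives(
    groups: Sequence[RelatedIonGroup],
    db: Sequence[CompoundRecord],
    delta_library: Sequence[MassDelta] | None = None,
    ppm_tol: float = 5.0,
    delta_tol: float = 0.01,
    adducts: Sequence[AdductForm] | None = None,
) -> list[DereplicationHit]:
    """Single-step derivative annotation of groups left unmatched.

    For each group with no direct database hit, the inferred neutral mass
    is compared with every database neutral shifted by ± one transformation
    delta; agreement within ``delta_tol`` Da yields a
    ``derivative(±<name>)`` hit.  Direct and derivative hits are disjoint
    by construction.
    """
    lib = list(delta_library) if delta_library is not None else load_delta_library()
    out: list[DereplicationHit] = []
    for group in groups:
        if match_database(group, db, ppm_tol, adducts):
            continue
        anchor_fid, _, anchor_mz = group.assignments[0]
        for rec in db:
            if rec.formula is None:
                continue
            diff = group.neutral_mass - rec.neutral_mass
            for d in lib:
                for sign, label in ((1.0, "+"), (-1.0, "-")):
                    if abs(diff - sign * d.delta) <= delta_tol:
                        out.append(
                            DereplicationHit(
                                group.group_id,
                                anchor_fid,
                                rec.name,
                                "[M+H]+",
                                anchor_mz,
                                rec.neutral_mass + sign * d.delta,
                                ppm_error(
                                    group.neutral_mass, rec.neutral_mass + sign * d.delta
                                ),
                                f"derivative({label}{d.name})",
                            )
                        )
    out.sort(key=lambda h: (h.group_id, abs(h.delta_ppm)))
    return out


@dataclass(frozen=True)
class HalogenCall:
    feature_id: str
    n_cl: int
    n_br: int
    score: float
    halogenated: bool
    flag: str | None = None
    candidates: tuple[HalogenCandidate, ...] = ()


def detect_halogenation(
    feature_id: str,
    features: pd.DataFrame,
    max_cl: int = 3,
    max_br: int = 3,
    rt_tol: float = 0.1,
    spacing: tuple[float, float] = A2_SPACING,
) -> HalogenCall:
    """Assemble an M+2k envelope from co-eluting isotopologue features and
    score halogen counts.

    ``features`` needs columns feature_id, mz, rt, intensity.  Partner
    features are accepted at successive spacings within ``spacing`` Da of
    2·k from the monoisotopic feature.  Features whose top candidate is
    not (0, 0) are flagged halogenated; with no partner at all the call is
    (0, 0) with flag "no envelope".
    """
    feats = features.set_index(features["feature_id"].astype(str))
    if str(feature_id) not in feats.index:
        raise KeyError(f"unknown feature {feature_id!r}")
    row = feats.loc[str(feature_id)]
    peaks = [(0.0, float(row["intensity"]))]
    k = 1
    while True:
        lo = row["mz"] + k * spacing[0]
        hi = row["mz"] + k * spacing[1]
        cand = features[
            (features["mz"] >= lo)
            & (features["mz"] <= hi)
            & (np.abs(features["rt"] - row["rt"]) <= rt_tol)
        ]
        if cand.empty:
            break
        best = cand.sort_values("intensity", ascending=False).iloc[0]
        peaks.append((2.0 * k, float(best["intensity"])))
        k += 1
    if len(peaks) < 2:
        return HalogenCall(str(feature_id), 0, 0, 1.0, False, flag="no envelope")
    total = sum(p[1] for p in peaks)
    env = IsotopeEnvelope(tuple((off, ab / total) for off, ab in peaks))
    ranked = halogen_score(env, max_cl, max_br)
    top = ranked[0]
    return HalogenCall(
        str(feature_id),
        top.n_cl,
        top.n_br,
        top.score,
        halogenated=(top.n_cl, top.n_br) != (0, 0),
        candidates=tuple(ranked),
    )


def write_report_tsv(
    path,
    groups: Sequence[RelatedIonGroup],
    hits: Sequence[DereplicationHit],
    halogen_calls: Sequence[HalogenCall] = (),
) -> None:
    """Write the dereplication report (one row per group, best hit first)."""
    best: dict[int, DereplicationHit] = {}
    for h in sorted(hits, key=lambda h: (h.group_id, abs(h.delta_ppm))):
        best.setdefault(h.group_id, h)
    hal = {c.feature_id: c for c in halogen_calls}
    rows = []
    for g in groups:
        h = best.get(g.group_id)
        c = hal.get(g.member_ids[0])
        rows.append(
            {
                "group_id": g.group_id,
                "anchor_mz": g.assignments[0][2],
                "rt": g.rt,
                "neutral_mass": g.neutral_mass,
                "members": ";".join(g.member_ids),
                "adducts": ";".join(a for _, a, _ in g.assignments),
                "annotation": h.compound if h else "no matches",
                "adduct": h.adduct if h else "",
                "delta_ppm": round(h.delta_ppm, 2) if h else "",
                "tier": h.tier if h else "",
                "halogen_call": f"Cl{c.n_cl}Br{c.n_br}" if c else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
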