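"""Exact-mass calculus for small-molecule dereplication.

Molecular-formula parsing, monoisotopic masses, adduct m/z arithmetic,
ppm errors, nominal-mass isotope-envelope simulation, halogen-count
scoring from M+2 patterns, and a biotransformation mass-delta library.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

from .constants import ISOTOPES, MONOISOTOPIC_MASS, PROTON_MASS, SUPPORTED_ELEMENTS

__all__ = [
    "MolecularFormula",
    "AdductForm",
    "IsotopeEnvelope",
    "MassDelta",
    "HalogenCandidate",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "neutral_from_adduct",
    "ppm_error",
    "round_half_away",
    "simulate_envelope",
    "halogen_score",
    "delta_match",
    "load_adducts",
    "load_delta_library",
    "get_adduct",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown element symbols."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element → count map with monoisotopic mass calculus.

    Counts are non-negative integers over the supported element table.
    The all-zero (empty) formula has mass 0.
    """

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el, n in self.counts.items():
            if el not in SUPPORTED_ELEMENTS:
                raise FormulaError(f"unsupported element: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"negative or non-integer count for {el}: {n!r}")

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical
        order = sorted(
            (el for el, n in self.counts.items() if n > 0),
            key=lambda e: (e != "C", e != "H", e),
        )
        return "".join(f"{el}{self.counts[el] if self.counts[el] != 1 else ''}" for el in order)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string such as ``"C35H36N4O5"``.

    An omitted count means 1.  Unknown element symbols and malformed
    strings raise :class:`FormulaError` naming the offending token.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula near {text[pos:]!r}")
        el, num = m.group(1), m.group(2)
        if el not in SUPPORTED_ELEMENTS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula | str) -> float:
    """Sum of most-abundant-isotope masses in Da; additive over formula union."""
    if isinstance(f, str):
        f = parse_formula(f)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f.counts.items())


@dataclass(frozen=True)
class AdductForm:
    """A positive-mode ESI ion species ``[nM+X]z+``.

    m/z reconstructs as ``(multimer * M + mass_offset) / charge`` and is
    strictly increasing in the neutral mass M.
    """

    name: str
    multimer: int
    charge: int
    mass_offset: float

    def __post_init__(self) -> None:
        if self.multimer < 1 or self.charge < 1:
            raise ValueError("multimer and charge must be >= 1")


def load_adducts() -> list[AdductForm]:
    """Load the bundled adduct-form table (editable YAML resource)."""
    raw = resources.files("cyanoprio.data").joinpath("adducts.yaml").read_text()
    spec = yaml.safe_load(raw)
    return [AdductForm(**entry) for entry in spec["adducts"]]


def get_adduct(name: str, adducts: Sequence[AdductForm] | None = None) -> AdductForm:
    for a in adducts if adducts is not None else load_adducts():
        if a.name == name:
            return a
    raise KeyError(f"unknown adduct form {name!r}")


def adduct_mz(M: float, a: AdductForm) -> float:
    """m/z of adduct form ``a`` for neutral monoisotopic mass ``M``."""
    return (a.multimer * M + a.mass_offset) / a.charge


def neutral_from_adduct(mz: float, a: AdductForm) -> float:
    """Invert :func:`adduct_mz`: recover the neutral mass from an ion m/z."""
    return (mz * a.charge - a.mass_offset) / a.multimer


def ppm_error(observed: float, calculated: float) -> float:
    """Relative mass error (observed − calculated)/calculated × 1e6 in ppm.

    Negative when the observed m/z is below the calculated one.  Report
    with :func:`round_half_away` to 2 dp for table output.
    """
    if calculated <= 0:
        raise ValueError("calculated m/z must be positive")
    return (observed - calculated) / calculated * 1e6


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the sign convention of reported Δppm)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Nominal-mass isotopologue pattern: (offset in Da from A, abundance).

    Offsets are non-negative, sorted; abundances normalized to sum 1.
    """

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        offs = [p[0] for p in self.peaks]
        if any(o < 0 for o in offs) or list(offs) != sorted(offs):
            raise ValueError("offsets must be non-negative and sorted")
        total = sum(p[1] for p in self.peaks)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {total})")

    def as_bins(self, n_bins: int) -> np.ndarray:
        """Abundance vector over integer nominal offsets 0..n_bins-1."""
        v = np.zeros(n_bins)
        for off, ab in self.peaks:
            k = int(round(off))
            if 0 <= k < n_bins:
                v[k] += ab
        return v


def _element_distribution(el: str, n: int) -> np.ndarray:
    """Isotopologue distribution of n atoms of one element over nominal bins."""
    isos = ISOTOPES[el]
    width = max(off for off, _, _ in isos) + 1
    base = np.zeros(width)
    for off, _, ab in isos:
        base[off] = ab
    dist = np.array([1.0])
    # exponentiation by squaring on the convolution monoid
    power = base
    k = n
    while k:
        if k & 1:
            dist = np.convolve(dist, power)
        k >>= 1
        if k:
            power = np.convolve(power, power)
    return dist


def simulate_envelope(f: MolecularFormula | str, max_peaks: int = 8) -> IsotopeEnvelope:
    """Isotope envelope of a formula on nominal A+k bins.

    Relative isotopologue abundances are obtained by convolving the
    per-element isotope distributions, truncated to ``max_peaks`` bins and
    renormalized to sum 1.  Fine structure within a nominal bin is ignored.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    if max_peaks < 1:
        raise ValueError("max_peaks must be >= 1")
    dist = np.array([1.0])
    for el, n in f.counts.items():
        if n > 0:
            dist = np.convolve(dist, _element_distribution(el, n))
    dist = dist[:max_peaks]
    total = dist.sum()
    if total == 0:  # empty formula
        dist = np.array([1.0])
        total = 1.0
    dist = dist / total
    return IsotopeEnvelope(tuple((float(k), float(a)) for k, a in enumerate(dist)))


@dataclass(frozen=True)
class HalogenCandidate:
    n_cl: int
    n_br: int
    score: float
    flag: str | None = None


def halogen_score(
    observed: IsotopeEnvelope,
    max_cl: int = 3,
    max_br: int = 3,
) -> list[HalogenCandidate]:
    """Rank halogen counts (nCl, nBr) by fit to an observed M+2k pattern.

    The fit statistic is the cosine similarity between the observed and
    the simulated candidate envelopes restricted to the even nominal
    offsets A, A+2, ..., where the Cl/Br signature lives and the A+1
    carbon envelope does not intrude.  The halogen-free candidate (0, 0)
    is always included as the null hypothesis; ties rank the candidate
    with fewer total halogen atoms first.
    """
    if len(observed.peaks) < 2:
        return [HalogenCandidate(0, 0, 1.0, flag="insufficient envelope")]
    n_even = max_cl + max_br + 1
    obs = observed.as_bins(2 * n_even)[::2]
    obs_norm = np.linalg.norm(obs)
    if obs_norm == 0:
        return [HalogenCandidate(0, 0, 1.0, flag="insufficient envelope")]
    out: list[HalogenCandidate] = []
    for ncl in range(max_cl + 1):
        for nbr in range(max_br + 1):
            sim_env = simulate_envelope(
                MolecularFormula({"Cl": ncl, "Br": nbr}), max_peaks=2 * n_even
            )
            sim = sim_env.as_bins(2 * n_even)[::2]
            score = float(obs @ sim / (obs_norm * np.linalg.norm(sim)))
            out.append(HalogenCandidate(ncl, nbr, score))
    out.sort(key=lambda c: (-c.score, c.n_cl + c.n_br, c.n_cl, c.n_br))
    return out


@dataclass(frozen=True)
class MassDelta:
    """A named biotransformation mass difference in Da (always positive)."""

    name: str
    delta: float
    direction: str = "signed"

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")


def load_delta_library() -> list[MassDelta]:
    """Load the bundled transformation-delta table (editable CSV resource)."""
    raw = resources.files("cyanoprio.data").joinpath("mass_deltas.csv").read_text()
    reader = csv.DictReader(raw.splitlines())
    return [
        MassDelta(row["name"], float(row["delta"]), row["direction"]) for row in reader
    ]


def delta_match(
    diff: float, library: Iterable[MassDelta] | None = None, tol: float = 0.01
) -> list[MassDelta]:
    """Transformation deltas within ``tol`` Da of |diff|, sorted by closeness."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    lib = list(library) if library is not None else load_delta_library()
    hits = [d for d in lib if abs(abs(diff) - d.delta) <= tol]
    hits.sort(key=lambda d: abs(abs(diff) - d.delta))
    return hits


#: Convenience re-export: proton mass used for [M+H]+ arithmetic.
PROTON = PROTON_MASS
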