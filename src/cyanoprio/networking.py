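"""Molecular networking of MS2 spectra.

Modified-cosine spectral similarity (fragment matches either direct or
shifted by the precursor mass difference), network construction with the
classic feature-based molecular-networking topology constraints (score
threshold, minimum matched peaks, mutual top-K edges, bounded component
size), and majority-vote chemical-class propagation over connected
components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from pyteomics import mgf as _mgf

from .features import FoldChangeResult

__all__ = [
    "MS2Spectrum",
    "ComponentClassSummary",
    "modified_cosine",
    "build_network",
    "annotate_nodes",
    "propagate_class",
    "read_mgf",
    "write_mgf",
    "write_graphml",
]


@dataclass(frozen=True)
class MS2Spectrum:
    """One MS2 scan per feature: precursor m/z plus a fragment peak list."""

    feature_id: str
    precursor_mz: float
    rt: float
    peaks: tuple[tuple[float, float], ...]  # (fragment m/z, intensity), sorted by m/z

    def __post_init__(self) -> None:
        mzs = [p[0] for p in self.peaks]
        if mzs != sorted(mzs):
            object.__setattr__(self, "peaks", tuple(sorted(self.peaks)))
        if any(p[1] <= 0 for p in self.peaks):
            raise ValueError("fragment intensities must be positive")

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])


def modified_cosine(
    a: MS2Spectrum, b: MS2Spectrum, frag_tol: float = 0.02
) -> tuple[float, int]:
    """Modified cosine similarity between two MS2 spectra.

    Fragment pairs match either directly (|Δm/z| ≤ frag_tol) or shifted by
    the precursor mass difference, so that structural analogs sharing a
    modified scaffold still align.  Matched pairs are assigned one-to-one
    greedily by descending product of square-root-transformed intensities;
    the score is the cosine of the matched sqrt-intensity vectors.
    Symmetric; reduces to the plain cosine when both precursors coincide.
    """
    if not a.peaks or not b.peaks:
        raise ValueError("spectra must be non-empty")
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    shift = b.precursor_mz - a.precursor_mz
    sa = np.sqrt(a.intensity_array)
    sb = np.sqrt(b.intensity_array)
    mza, mzb = a.mz_array, b.mz_array

    pairs: list[tuple[float, int, int]] = []
    seen: set[tuple[int, int]] = set()
    for delta in (0.0, shift):
        d = np.abs(mza[:, None] + delta - mzb[None, :])
        for i, j in zip(*np.nonzero(d <= frag_tol)):
            if (i, j) not in seen:
                seen.add((int(i), int(j)))
                pairs.append((float(sa[i] * sb[j]), int(i), int(j)))
    # greedy one-to-one assignment, deterministic tie-break on indices
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    score = 0.0
    matched = 0
    for prod, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += prod
        matched += 1
    denom = np.linalg.norm(sa) * np.linalg.norm(sb)
    return min(score / denom, 1.0), matched


def build_network(
    spectra: Sequence[MS2Spectrum],
    min_cosine: float = 0.7,
    min_matched: int = 6,
    top_k: int = 10,
    max_component: int = 100,
    frag_tol: float = 0.02,
) -> nx.Graph:
    """Construct a molecular network from MS2 spectra.

    Candidate edges require cosine ≥ ``min_cosine`` and at least
    ``min_matched`` matched fragment pairs; an edge survives only if it
    ranks within the ``top_k`` strongest for *both* endpoints; components
    larger than ``max_component`` are pruned by removing their weakest
    edges.  Construction is deterministic and permutation-invariant
    (ties broken by cosine, then lexicographic feature ids).
    """
    if min_cosine <= 0 or min_matched < 1 or top_k < 1 or max_component < 1:
        raise ValueError("thresholds must be positive")
    spectra = sorted(spectra, key=lambda s: s.feature_id)
    g = nx.Graph()
    for s in spectra:
        g.add_node(s.feature_id, mz=s.precursor_mz, rt=s.rt)

    candidates = []
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            cos, matched = modified_cosine(spectra[i], spectra[j], frag_tol)
            if cos >= min_cosine and matched >= min_matched:
                u, v = spectra[i].feature_id, spectra[j].feature_id
                delta = abs(spectra[i].precursor_mz - spectra[j].precursor_mz)
                candidates.append((u, v, cos, matched, delta))

    # mutual top-K rule
    ranked: dict[str, list[tuple[float, str]]] = {}
    for u, v, cos, matched, delta in candidates:
        ranked.setdefault(u, []).append((cos, v))
        ranked.setdefault(v, []).append((cos, u))
    keep: dict[str, set[str]] = {}
    for node, lst in ranked.items():
        lst.sort(key=lambda t: (-t[0], t[1]))
        keep[node] = {other for _, other in lst[:top_k]}
    for u, v, cos, matched, delta in candidates:
        if v in keep.get(u, ()) and u in keep.get(v, ()):
            g.add_edge(u, v, cosine=cos, matched_peaks=matched, precursor_delta=delta)

    # bound component size by dropping weakest edges
    while True:
        oversized = [c for c in nx.connected_components(g) if len(c) > max_component]
        if not oversized:
            break
        comp = oversized[0]
        edges = sorted(
            g.subgraph(comp).edges(data=True),
            key=lambda e: (e[2]["cosine"], *sorted((e[0], e[1]))),
        )
        u, v, _ = edges[0]
        g.remove_edge(u, v)
    return g


def annotate_nodes(
    net: nx.Graph,
    fc: Iterable[FoldChangeResult] = (),
    class_map: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Attach fold-change node sizes and chemical-class labels in place.

    Node size = log2fc floored at 0 (networks are drawn with fold change
    as node size); features without a class entry get "no matches".
    Unknown feature ids in ``class_map`` are skipped with a warning.
    """
    fc_by_id = {r.feature_id: r for r in fc}
    unknown = set(fc_by_id) - set(net.nodes)
    if unknown:
        raise ValueError(f"fold-change ids not in network: {sorted(unknown)[:5]}")
    class_map = dict(class_map or {})
    for fid in list(class_map):
        if fid not in net.nodes:
            import warnings

            warnings.warn(f"class_map id {fid!r} not in network; skipped")
            class_map.pop(fid)
    for node in net.nodes:
        r = fc_by_id.get(node)
        net.nodes[node]["log2fc"] = r.log2fc if r else 0.0
        net.nodes[node]["size"] = max(r.log2fc, 0.0) if r else 0.0
        net.nodes[node]["chem_class"] = class_map.get(node, "no matches")
    return net


@dataclass(frozen=True)
class ComponentClassSummary:
    component_id: int
    members: tuple[str, ...]
    chem_class: str  # propagated label, "ambiguous", or "no matches"


def propagate_class(
    net: nx.Graph, selected_nodes: Sequence[str] | None = None
) -> tuple[list[ComponentClassSummary], dict[str, float]]:
    """Majority-vote class propagation over connected components.

    Each component takes the modal class among its labelled members
    (ties → "ambiguous"; all-unlabelled → "no matches").  Also returns the
    class-share table: the percentage of ``selected_nodes`` (default: all
    nodes) whose propagated class is each label.
    """
    components = sorted(nx.connected_components(net), key=lambda c: sorted(c)[0])
    summaries: list[ComponentClassSummary] = []
    node_class: dict[str, str] = {}
    for cid, comp in enumerate(components):
        labels = [
            net.nodes[n].get("chem_class", "no matches")
            for n in comp
        ]
        labels = [l for l in labels if l and l != "no matches"]
        if not labels:
            cls = "no matches"
        else:
            counts: dict[str, int] = {}
            for l in labels:
                counts[l] = counts.get(l, 0) + 1
            best = max(counts.values())
            modal = sorted(k for k, v in counts.items() if v == best)
            cls = modal[0] if len(modal) == 1 else "ambiguous"
        members = tuple(sorted(comp))
        summaries.append(ComponentClassSummary(cid, members, cls))
        for n in comp:
            node_class[n] = cls
    selected = list(selected_nodes) if selected_nodes is not None else list(net.nodes)
    shares: dict[str, float] = {}
    if selected:
        for n in selected:
            cls = node_class.get(n, "no matches")
            shares[cls] = shares.get(cls, 0.0) + 1.0
        shares = {k: 100.0 * v / len(selected) for k, v in sorted(shares.items())}
    return summaries, shares


def read_mgf(path) -> list[MS2Spectrum]:
    """Read an MGF spectral summary (one spectrum per feature).

    Feature ids come from SCANS or FEATURE_ID; precursor m/z from PEPMASS;
    retention time from RTINSECONDS (converted to minutes) when present.
    """
    out = []
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            fid = str(params.get("feature_id", params.get("scans", "")))
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            pep = params["pepmass"]
            prec = float(pep[0] if isinstance(pep, (tuple, list)) else pep)
            peaks = tuple(
                (float(m), float(i))
                for m, i in zip(spec["m/z array"], spec["intensity array"])
                if i > 0
            )
            out.append(MS2Spectrum(fid, prec, rt, peaks))
    return out


def write_mgf(path, spectra: Sequence[MS2Spectrum]) -> None:
    entries = [
        {
            "m/z array": s.mz_array,
            "intensity array": s.intensity_array,
            "params": {
                "feature_id": s.feature_id,
                "scans": s.feature_id,
                "pepmass": s.precursor_mz,
                "rtinseconds": s.rt * 60.0,
                "charge": "1+",
            },
        }
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")


def write_graphml(path, net: nx.Graph) -> None:
    """Write the network with node/edge attributes, tagging components."""
    g = net.copy()
    for cid, comp in enumerate(
        sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    ):
        for n in comp:
            g.nodes[n]["component"] = cid
    nx.write_graphml(g, str(path))
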