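"""Modified-cosine similarity and molecular-network topology."""

import itertools

import networkx as nx
import numpy as np
import pytest

from cyanoprio.features import FoldChangeResult
from cyanoprio.networking import (
    MS2Spectrum,
    annotate_nodes,
    build_network,
    modified_cosine,
    propagate_class,
    read_mgf,
    write_mgf,
)


def spec(fid, prec, peaks, rt=5.0):
    return MS2Spectrum(fid, prec, rt, tuple(peaks))


def exhaustive_modified_cosine(a, b, frag_tol=0.02):
    """Oracle: optimal one-to-one assignment by full enumeration (tiny spectra)."""
    shift = b.precursor_mz - a.precursor_mz
    sa, sb = np.sqrt(a.intensity_array), np.sqrt(b.intensity_array)
    pairs = [
        (i, j)
        for i in range(len(a.peaks))
        for j in range(len(b.peaks))
        if abs(a.peaks[i][0] - b.peaks[j][0]) <= frag_tol
        or abs(a.peaks[i][0] + shift - b.peaks[j][0]) <= frag_tol
    ]
    best = 0.0
    for r in range(len(pairs) + 1):
        for combo in itertools.combinations(pairs, r):
            if len({i for i, _ in combo}) < r or len({j for _, j in combo}) < r:
                continue
            best = max(best, sum(sa[i] * sb[j] for i, j in combo))
    return best / (np.linalg.norm(sa) * np.linalg.norm(sb))


class TestModifiedCosine:
    def test_identical_spectra(self):
        s = spec("a", 500.0, [(100.0, 1.0), (200.0, 2.0), (300.0, 0.5)])
        cos, matched = modified_cosine(s, s)
        assert cos == pytest.approx(1.0)
        assert matched == 3

    def test_disjoint_spectra(self):
        a = spec("a", 500.0, [(100.0, 1.0), (200.0, 1.0)])
        b = spec("b", 500.0, [(150.0, 1.0), (250.0, 1.0)])
        assert modified_cosine(a, b) == (0.0, 0)

    def test_uniform_precursor_shift_matches_fully(self):
        a = spec("a", 500.0, [(100.0, 1.0), (180.0, 2.0), (260.0, 0.7)])
        delta = 14.0157
        b = spec("b", 500.0 + delta, [(m + delta, i) for m, i in a.peaks])
        cos, matched = modified_cosine(a, b)
        assert cos == pytest.approx(1.0)
        assert matched == 3

    def test_symmetry(self, rng):
        for _ in range(20):
            a = spec("a", 400.0, [(float(m), float(i)) for m, i in
                                  zip(np.sort(rng.uniform(50, 380, 5)), rng.uniform(0.1, 1, 5))])
            b = spec("b", 430.0, [(float(m), float(i)) for m, i in
                                  zip(np.sort(rng.uniform(50, 410, 5)), rng.uniform(0.1, 1, 5))])
            assert modified_cosine(a, b) == modified_cosine(b, a)

    def test_equals_plain_cosine_for_equal_precursors(self):
        a = spec("a", 500.0, [(100.0, 1.0), (200.0, 4.0)])
        b = spec("b", 500.0, [(100.0, 2.0), (200.0, 1.0)])
        cos, _ = modified_cosine(a, b)
        va = np.sqrt([1.0, 4.0])
        vb = np.sqrt([2.0, 1.0])
        assert cos == pytest.approx(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))

    def test_empty_spectrum_rejected(self):
        a = spec("a", 500.0, [(100.0, 1.0)])
        with pytest.raises(ValueError):
            modified_cosine(a, MS2Spectrum("b", 400.0, 1.0, ()))

    def test_greedy_never_exceeds_exhaustive_oracle(self, rng):
        """Greedy assignment lower-bounds the optimal; equals it >=95% of runs."""
        equal = 0
        n = 100
        for _ in range(n):
            a = spec("a", 300.0, [(float(m), float(i)) for m, i in
                                  zip(np.sort(rng.uniform(50, 280, 4)), rng.uniform(0.1, 1, 4))])
            shift = float(rng.uniform(-20, 20))
            # overlap some peaks directly and some shifted to stress the assignment
            mix = [(m + (shift if k % 2 else 0.0) + float(rng.normal(0, 0.005)), float(rng.uniform(0.1, 1)))
                   for k, (m, _) in enumerate(a.peaks)]
            b = spec("b", 300.0 + shift, sorted(mix))
            greedy, _ = modified_cosine(a, b)
            oracle = exhaustive_modified_cosine(a, b)
            assert greedy <= oracle + 1e-9
            equal += greedy == pytest.approx(oracle, abs=1e-9)
        assert equal / n >= 0.95

    def test_matches_independent_reference_implementation(self):
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        a = spec("a", 500.0, [(100.0, 1.0), (180.0, 2.0), (260.0, 0.7), (400.0, 1.5)])
        b = spec("b", 514.0157, [(100.0, 0.9), (194.0157, 1.8), (274.0157, 1.0), (380.0, 0.3)])
        ours, matched = modified_cosine(a, b)
        # matchms scores raw intensities; pre-apply the sqrt transform so both
        # compute the same quantity
        ref = ModifiedCosine(tolerance=0.02).pair(
            matchms.Spectrum(
                mz=a.mz_array, intensities=np.sqrt(a.intensity_array),
                metadata={"precursor_mz": a.precursor_mz},
            ),
            matchms.Spectrum(
                mz=b.mz_array, intensities=np.sqrt(b.intensity_array),
                metadata={"precursor_mz": b.precursor_mz},
            ),
        )
        assert ours == pytest.approx(float(ref["score"]), abs=1e-6)
        assert matched == int(ref["matches"])


def analog_pair(n_shared=7, delta=14.0157):
    frags = np.linspace(110, 410, n_shared)
    a = spec("p1", 600.0, [(float(m), 1.0) for m in frags])
    b = spec("p2", 600.0 + delta, [(float(m), 1.0) for m in frags])
    return a, b


class TestBuildNetwork:
    def test_analog_pair_forms_single_edge(self):
        a, b = analog_pair()
        g = build_network([a, b])
        assert g.number_of_edges() == 1
        assert g.has_edge("p1", "p2")
        assert g.edges["p1", "p2"]["matched_peaks"] >= 6

    def test_dissimilar_spectra_stay_singletons(self, rng):
        spectra = [
            spec(f"s{k}", 300.0 + 50 * k,
                 [(float(m), 1.0) for m in np.sort(rng.uniform(50, 280, 6)) + 37 * k])
            for k in range(5)
        ]
        g = build_network(spectra)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 5

    def test_halogenated_pair_scenario(self):
        """Two co-eluting ions sharing shifted backbone fragments cluster."""
        delta = 43.9494  # Cl<->Br analog spacing
        frags = np.linspace(120, 420, 8)
        a = spec("x851", 851.1284, [(float(m), 1.0) for m in frags])
        b = spec("x895", 895.0778, [(float(m + delta), 1.0) for m in frags])
        g = build_network([a, b])
        comps = list(nx.connected_components(g))
        assert {"x851", "x895"} in comps

    def test_degree_bounded_by_top_k(self, rng):
        base = np.linspace(100, 400, 10)
        spectra = [
            spec(f"s{k}", 500.0, [(float(m), 1.0) for m in base]) for k in range(8)
        ]
        g = build_network(spectra, top_k=3)
        assert max(dict(g.degree).values()) <= 3

    def test_component_size_bounded(self):
        base = np.linspace(100, 400, 10)
        spectra = [
            spec(f"s{k:02d}", 500.0, [(float(m), 1.0) for m in base]) for k in range(12)
        ]
        g = build_network(spectra, top_k=11, max_component=5)
        assert max(len(c) for c in nx.connected_components(g)) <= 5

    def test_permutation_invariance(self, rng):
        spectra = []
        base = np.linspace(100, 400, 8)
        for k in range(6):
            keep = rng.uniform(0.1, 1.0, base.size)
            spectra.append(
                spec(f"s{k}", 500.0 + k, [(float(m + (k % 2) * 0.001), float(i))
                                          for m, i in zip(base, keep)])
            )
        g1 = build_network(spectra)
        order = list(rng.permutation(len(spectra)))
        g2 = build_network([spectra[i] for i in order])
        assert set(g1.edges) == set(g2.edges)


class TestAnnotationAndPropagation:
    def make_net(self):
        a, b = analog_pair()
        c = spec("p3", 900.0, [(float(m), 1.0) for m in np.linspace(500, 880, 6)])
        return build_network([a, b, c])

    def test_node_size_is_log2fc(self):
        g = self.make_net()
        fc = [FoldChangeResult("p1", 2.0**25.71, 25.71, ("active_A", "control_C"))]
        annotate_nodes(g, fc, {"p1": "cyclic peptide"})
        assert g.nodes["p1"]["size"] == pytest.approx(25.71)
        assert g.nodes["p3"]["chem_class"] == "no matches"

    def test_majority_vote(self):
        g = self.make_net()
        annotate_nodes(g, [], {"p1": "peptide", "p2": "peptide"})
        summaries, _ = propagate_class(g)
        by_members = {s.members: s.chem_class for s in summaries}
        assert by_members[("p1", "p2")] == "peptide"
        assert by_members[("p3",)] == "no matches"

    def test_tie_is_ambiguous(self):
        g = self.make_net()
        annotate_nodes(g, [], {"p1": "peptide", "p2": "lipid"})
        summaries, _ = propagate_class(g)
        assert {s.chem_class for s in summaries if len(s.members) == 2} == {"ambiguous"}

    def test_class_shares_use_selected_denominator(self):
        g = self.make_net()
        annotate_nodes(g, [], {"p1": "peptide", "p2": "peptide"})
        _, shares = propagate_class(g, selected_nodes=["p1", "p2", "p3"])
        assert shares["peptide"] == pytest.approx(100 * 2 / 3)
        assert sum(shares.values()) == pytest.approx(100.0)

    def test_unknown_class_map_id_warns_and_skips(self):
        g = self.make_net()
        with pytest.warns(UserWarning):
            annotate_nodes(g, [], {"nope": "peptide"})
        assert all(g.nodes[n]["chem_class"] == "no matches" for n in g.nodes)


class TestMgfRoundTrip:
    def test_write_read(self, tmp_path):
        a, b = analog_pair()
        path = tmp_path / "spectra.mgf"
        write_mgf(path, [a, b])
        back = read_mgf(path)
        assert [s.feature_id for s in back] == ["p1", "p2"]
        assert back[0].precursor_mz == pytest.approx(a.precursor_mz)
        np.testing.assert_allclose(back[0].mz_array, a.mz_array)
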