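"""Spectral preprocessing, modified cosine, networking and loss annotation."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from mutchemo import msnetwork as msn
from mutchemo import simdata
from mutchemo.msnetwork import (
    NetworkParams,
    Spectrum,
    annotate_losses,
    build_network,
    dedup_isomers,
    modified_cosine,
    preprocess_spectrum,
    read_mgf,
    write_mgf,
)

PARAMS = NetworkParams()


def _spec(sid, prec, peaks, processed=False):
    mz, inten = zip(*peaks)
    return Spectrum(sid, prec, np.array(mz, float), np.array(inten, float), processed=processed)


def brute_force_score(a: Spectrum, b: Spectrum, params: NetworkParams = PARAMS):
    """Exhaustive enumeration over all one-to-one peak matchings."""
    delta = a.precursor_mz - b.precursor_mz
    pairs = {
        (i, j)
        for i in range(a.n_peaks)
        for j in range(b.n_peaks)
        if abs(a.mz[i] - b.mz[j]) <= params.fragment_tol
        or abs(a.mz[i] - b.mz[j] - delta) <= params.fragment_tol
    }
    best, best_n = 0.0, 0
    for r in range(min(a.n_peaks, b.n_peaks) + 1):
        for asel in itertools.combinations(range(a.n_peaks), r):
            for bsel in itertools.permutations(range(b.n_peaks), r):
                matching = list(zip(asel, bsel))
                if all(p in pairs for p in matching):
                    s = sum(a.intensity[i] * b.intensity[j] for i, j in matching)
                    if s > best:
                        best, best_n = s, r
    return best, best_n


def _random_pair(rng, shifted=True):
    na, nb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
    prec_a = float(rng.uniform(500, 1000))
    prec_b = prec_a - 162.0528 if shifted else float(rng.uniform(500, 1000))
    a = preprocess_spectrum(
        Spectrum("a", prec_a, rng.uniform(50, 450, na), rng.uniform(25, 1000, na))
    )
    n_common = nb // 2
    b_mz = np.concatenate(
        [
            a.mz[:n_common] + rng.normal(0, 0.2, min(n_common, a.n_peaks))[: n_common],
            rng.uniform(50, 450, nb - n_common),
        ]
    )
    b = preprocess_spectrum(Spectrum("b", prec_b, b_mz, rng.uniform(25, 1000, nb)))
    return a, b


class TestPreprocess:
    def test_intensity_floor_and_normalisation(self):
        s = _spec("s", 500.0, [(100.0, 24.0), (200.0, 26.0)])
        p = preprocess_spectrum(s)
        assert p.n_peaks == 1
        assert p.mz[0] == 200.0
        assert p.intensity[0] == pytest.approx(1.0)
        # original untouched
        assert s.n_peaks == 2 and s.intensity.max() == 26.0

    def test_empty_spectrum_stays_empty(self):
        p = preprocess_spectrum(Spectrum("e", 500.0, np.array([]), np.array([])))
        assert p.is_empty and p.processed

    def test_processed_intensities_are_unit_norm(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(1, 30))
            s = Spectrum("s", 800.0, rng.uniform(50, 700, n), rng.uniform(26, 5000, n))
            p = preprocess_spectrum(s)
            assert np.sum(p.intensity**2) == pytest.approx(1.0)


class TestModifiedCosine:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(1)
        s = preprocess_spectrum(
            Spectrum("s", 700.0, rng.uniform(50, 600, 12), rng.uniform(25, 900, 12))
        )
        cosine, matched = modified_cosine(s, s)
        assert cosine == pytest.approx(1.0, abs=1e-9)
        assert matched == s.n_peaks

    def test_disjoint_spectra_score_zero(self):
        a = _spec("a", 500.0, [(100.0, 1.0)], processed=True)
        b = _spec("b", 500.0, [(300.0, 1.0)], processed=True)
        assert modified_cosine(a, b) == (0.0, 0)

    def test_equals_exhaustive_matching_oracle_small_spectra(self):
        """Greedy one-to-one matching attains the optimum on every random
        <=6-peak instance (and never exceeds it)."""
        rng = np.random.default_rng(7)
        n_checked = 0
        for trial in range(150):
            a, b = _random_pair(rng, shifted=bool(trial % 2))
            got, got_n = modified_cosine(a, b)
            best, _ = brute_force_score(a, b)
            assert got <= best + 1e-12
            assert got == pytest.approx(best, abs=1e-9)
            n_checked += 1
        assert n_checked == 150

    def test_zero_precursor_delta_reduces_to_plain_cosine(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(2, 6))
            mz = rng.uniform(50, 450, n)
            a = preprocess_spectrum(Spectrum("a", 600.0, mz, rng.uniform(25, 900, n)))
            b = preprocess_spectrum(
                Spectrum("b", 600.0, mz + rng.normal(0, 0.1, n), rng.uniform(25, 900, n))
            )
            got, _ = modified_cosine(a, b)
            best, _ = brute_force_score(a, b)  # with delta=0 only direct matches exist
            assert got == pytest.approx(best, abs=1e-9)

    def test_symmetric(self):
        rng = np.random.default_rng(9)
        for trial in range(30):
            a, b = _random_pair(rng, shifted=bool(trial % 2))
            assert modified_cosine(a, b) == modified_cosine(b, a)

    def test_agrees_with_independent_library_implementation(self):
        """Scores and matched-peak counts match matchms's ModifiedCosine on
        identically preprocessed spectra."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        scorer = ModifiedCosine(tolerance=PARAMS.fragment_tol)
        rng = np.random.default_rng(11)
        for trial in range(40):
            a, b = _random_pair(rng, shifted=bool(trial % 2))
            got, got_n = modified_cosine(a, b)
            ref = scorer.pair(
                matchms.Spectrum(
                    mz=a.mz, intensities=a.intensity,
                    metadata={"precursor_mz": a.precursor_mz},
                    metadata_harmonization=False,
                ),
                matchms.Spectrum(
                    mz=b.mz, intensities=b.intensity,
                    metadata={"precursor_mz": b.precursor_mz},
                    metadata_harmonization=False,
                ),
            )
            assert got == pytest.approx(float(ref["score"]), abs=1e-9)
            assert got_n == int(ref["matches"])

    def test_requires_preprocessed_inputs(self):
        s = _spec("s", 500.0, [(100.0, 50.0)])
        with pytest.raises(ValueError, match="preprocess"):
            modified_cosine(s, s)


class TestBuildNetwork:
    def test_identical_pair_forms_single_component_with_unit_edge(self):
        rng = np.random.default_rng(2)
        mz, inten = rng.uniform(50, 600, 8), rng.uniform(26, 900, 8)
        a = Spectrum("a", 700.0, mz, inten)
        b = Spectrum("b", 700.0, mz.copy(), inten.copy())
        g = build_network([a, b])
        assert g.number_of_edges() == 1
        assert g.edges["a", "b"]["cosine"] == pytest.approx(1.0, abs=1e-9)

    def test_unrelated_singleton_removed_by_cluster_size_gate(self):
        rng = np.random.default_rng(3)
        mz, inten = rng.uniform(50, 600, 8), rng.uniform(26, 900, 8)
        spectra = [
            Spectrum("a", 700.0, mz, inten),
            Spectrum("b", 700.0, mz.copy(), inten.copy()),
            Spectrum("lonely", 900.0, rng.uniform(700, 880, 6), rng.uniform(26, 900, 6)),
        ]
        g = build_network(spectra)
        assert set(g.nodes) == {"a", "b"}

    def test_simulated_series_connects_into_one_component(self):
        spectra = simdata.simulate_spectra(simdata.SimConfig(seed=4))
        g = build_network(spectra)
        comps = list(nx.connected_components(g))
        a1 = {s.spectrum_id for s in spectra if "A-1" in s.spectrum_id or s.spectrum_id.endswith("avenacin A")}
        (comp_of_parent,) = [c for c in comps if "avenacin A-1" in c]
        assert a1 <= comp_of_parent

    def test_edge_set_invariant_to_input_order(self):
        spectra = simdata.simulate_spectra(simdata.SimConfig(seed=5))
        g1 = build_network(spectra)
        g2 = build_network(list(reversed(spectra)))
        assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))


class TestDedupIsomers:
    def _network_with_duplicate(self):
        rng = np.random.default_rng(6)
        mz, inten = rng.uniform(50, 600, 8), rng.uniform(26, 900, 8)
        a = Spectrum("a", 700.0, mz, inten)
        twin = Spectrum("twin", 700.0, mz.copy(), inten * 2.0)
        c = Spectrum("c", 700.3, mz + 0.3, inten.copy())
        return build_network([a, twin, c])

    def test_same_mass_nodes_collapse_to_highest_intensity(self):
        g = self._network_with_duplicate()
        assert g.number_of_nodes() == 3
        deduped = dedup_isomers(g, mass_tol=0.01)
        assert "twin" in deduped.nodes and "a" not in deduped.nodes
        assert "c" in deduped.nodes  # distinct precursor survives
        # original graph untouched
        assert g.number_of_nodes() == 3

    def test_all_distinct_precursors_unchanged(self):
        spectra = simdata.simulate_spectra(simdata.SimConfig(seed=7))
        g = build_network(spectra)
        deduped = dedup_isomers(g)
        assert set(deduped.nodes) == set(g.nodes)
        assert set(map(frozenset, deduped.edges)) == set(map(frozenset, g.edges))


class TestAnnotateLosses:
    def _edge_graph(self, prec_a, prec_b):
        g = nx.Graph()
        g.add_edge("x", "y", cosine=0.9, matched_peaks=5, precursor_delta=prec_a - prec_b)
        return g

    def test_printed_ion_pair_annotated_as_hexosyl_162(self):
        g = annotate_losses(self._edge_graph(959.49, 797.43))
        attrs = g.edges["x", "y"]
        assert attrs["loss_annotation"] == "hexosyl"
        assert attrs["nominal_loss"] == 162

    def test_zero_delta_is_isomer_candidate_not_a_loss(self):
        g = annotate_losses(self._edge_graph(700.0, 700.0))
        assert g.edges["x", "y"]["loss_annotation"] == "none"

    @pytest.mark.parametrize(
        "delta,name",
        [(133.053, "N-methylanthraniloyl"), (104.026, "benzoyl")],
    )
    def test_library_masses_from_elemental_formulas(self, delta, name):
        g = annotate_losses(self._edge_graph(800.0 + delta, 800.0))
        assert g.edges["x", "y"]["loss_annotation"] == name

    def test_overlapping_library_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            annotate_losses(self._edge_graph(800.0, 700.0), {"x": 100.0, "y": 100.05})


class TestMgfIO:
    def test_round_trip(self, tmp_path):
        spectra = simdata.simulate_spectra(simdata.SimConfig(seed=8))
        path = tmp_path / "series.mgf"
        write_mgf(spectra, path)
        loaded = read_mgf(path)
        assert [s.spectrum_id for s in loaded] == [s.spectrum_id for s in spectra]
        for got, want in zip(loaded, spectra):
            assert got.precursor_mz == pytest.approx(want.precursor_mz)
            assert got.polarity == "negative"
            assert np.allclose(got.mz, want.mz)
            assert np.allclose(got.intensity, want.intensity)
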