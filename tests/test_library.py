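"""Spectral-library construction, cosine matching and run identification.

The pairing oracle enumerates every one-to-one peak assignment within
tolerance and keeps the one maximising (number of pairs, cross product);
greedy pairing must reproduce it on randomly generated peptide-like
spectra (sparse peaks, 0.02 Da tolerance).
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from polysorb.digest import tryptic_digest, ProteinEntry
from polysorb.library import (
    MatchResult,
    SpectralLibraryEntry,
    accept,
    build_library_from_truth,
    export_library,
    greedy_pair,
    identify_run,
    import_library,
    match_spectrum,
    read_msp,
)
from polysorb.spectra import AcquisitionScheme, Run, Spectrum


def q_spec(mz, inten, scan_id=1, precursor=500.0, width=1.0):
    return Spectrum(
        scan_id=scan_id, ms_level=2, mz=np.asarray(mz, float),
        intensity=np.asarray(inten, float), precursor_mz=precursor,
        isolation_width=width,
    )


def lib_entry(mz, inten, peptide_id="PEP", charge=1, precursor=500.0):
    return SpectralLibraryEntry(
        peptide_id=peptide_id, protein_id="prot", sequence="",
        charge=charge, precursor_mz=precursor,
        fragment_mz=np.asarray(mz, float),
        fragment_intensity=np.asarray(inten, float),
    )


def oracle_pair(mz_a, mz_b, tol):
    """Exhaustive optimal one-to-one pairing: max count, then max closeness."""
    edges = [
        (i, j)
        for i in range(len(mz_a))
        for j in range(len(mz_b))
        if abs(mz_a[i] - mz_b[j]) <= tol
    ]
    best = (0, -math.inf, [])

    def rec(k, used_a, used_b, chosen, dist):
        nonlocal best
        if k == len(edges):
            key = (len(chosen), -dist)
            if key > best[:2]:
                best = (len(chosen), -dist, list(chosen))
            return
        i, j = edges[k]
        rec(k + 1, used_a, used_b, chosen, dist)
        if i not in used_a and j not in used_b:
            rec(
                k + 1, used_a | {i}, used_b | {j},
                chosen + [(i, j)], dist + abs(mz_a[i] - mz_b[j]),
            )

    rec(0, frozenset(), frozenset(), [], 0.0)
    return best[0]


class TestGreedyPairing:
    def test_matches_exhaustive_oracle_on_random_instances(self):
        """1000 random peptide-like spectra pairs, <= 8 peaks per side."""
        rng = np.random.default_rng(42)
        tol = 0.02
        for _ in range(1000):
            n_a = rng.integers(1, 9)
            n_b = rng.integers(1, 9)
            base = np.sort(rng.uniform(100.0, 1000.0, size=n_b))
            take = rng.integers(0, 2, size=min(n_a, n_b)).astype(bool)
            jitters = rng.uniform(-0.03, 0.03, size=min(n_a, n_b))
            mz_a = list(base[: min(n_a, n_b)][take] + jitters[take])
            while len(mz_a) < n_a:
                mz_a.append(rng.uniform(100.0, 1000.0))
            mz_a = np.sort(np.array(mz_a))
            pairs = greedy_pair(mz_a, base, tol)
            assert len(pairs) == oracle_pair(list(mz_a), list(base), tol)

    def test_one_to_one_within_tolerance(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            mz_a = np.sort(rng.uniform(100, 200, size=6))
            mz_b = np.sort(rng.uniform(100, 200, size=6))
            pairs = greedy_pair(mz_a, mz_b, 5.0)
            assert len({i for i, _ in pairs}) == len(pairs)
            assert len({j for _, j in pairs}) == len(pairs)
            assert all(abs(mz_a[i] - mz_b[j]) <= 5.0 for i, j in pairs)


class TestMatchSpectrum:
    def test_self_similarity_is_one(self):
        entry = lib_entry([100.0, 200.0, 300.0], [1.0, 5.0, 2.0])
        query = q_spec([100.0, 200.0, 300.0], [1.0, 5.0, 2.0])
        m = match_spectrum(query, entry)
        assert m.cosine == pytest.approx(1.0)
        assert m.n_matched == 3

    def test_disjoint_spectra_score_zero(self):
        entry = lib_entry([100.0, 200.0], [1.0, 1.0])
        query = q_spec([150.0, 250.0], [1.0, 1.0])
        m = match_spectrum(query, entry)
        assert m.cosine == 0.0 and m.n_matched == 0 and not m.accepted

    def test_worked_union_cosine_example(self):
        """Frozen value from the exhaustive pairing + union-norm definition:
        cross = 1·2 + 2·4 = 10, ‖lib‖ = 3, ‖query‖ = √21 → 10/(3√21)."""
        entry = lib_entry([100.0, 200.0, 300.0], [1.0, 2.0, 2.0])
        query = q_spec([100.005, 200.010, 400.0], [2.0, 4.0, 1.0])
        m = match_spectrum(query, entry, frag_tol=0.02)
        assert m.n_matched == 2
        assert m.cosine == pytest.approx(10.0 / (3.0 * math.sqrt(21.0)), abs=1e-9)
        assert not m.accepted

    def test_empty_query_yields_null_result(self):
        entry = lib_entry([100.0], [1.0])
        query = q_spec([], [])
        m = match_spectrum(query, entry)
        assert (m.cosine, m.n_matched, m.accepted) == (0.0, 0, False)

    def test_cosine_symmetry_and_scale_invariance_random(self):
        """Symmetry under operand swap and invariance to intensity scaling."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            n1, n2 = rng.integers(1, 10, size=2)
            mz1 = np.sort(rng.uniform(100, 500, n1))
            mz2 = np.sort(rng.uniform(100, 500, n2))
            i1 = rng.uniform(0.1, 100, n1)
            i2 = rng.uniform(0.1, 100, n2)
            tol = float(rng.uniform(0.01, 5.0))
            a_as_entry = lib_entry(mz1, i1)
            b_as_entry = lib_entry(mz2, i2)
            ab = match_spectrum(q_spec(mz2, i2), a_as_entry, frag_tol=tol)
            ba = match_spectrum(q_spec(mz1, i1), b_as_entry, frag_tol=tol)
            assert ab.cosine == pytest.approx(ba.cosine, abs=1e-9)
            c = float(rng.uniform(0.01, 50))
            scaled = match_spectrum(q_spec(mz2, i2 * c), a_as_entry, frag_tol=tol)
            assert scaled.cosine == pytest.approx(ab.cosine, rel=1e-9)

    def test_noise_peaks_never_raise_cosine(self):
        rng = np.random.default_rng(5)
        entry = lib_entry([100.0, 200.0, 300.0, 400.0], [1.0, 2.0, 3.0, 4.0])
        base_mz = np.array([100.0, 200.0, 300.0, 400.0])
        base_int = np.array([1.1, 1.9, 3.2, 4.1])
        base = match_spectrum(q_spec(base_mz, base_int), entry).cosine
        noise_mz_all = 500.0 + 7.0 * np.arange(5)  # all unmatched (> tol away)
        noise_int_all = rng.uniform(0.5, 5.0, 5)
        prev = base
        for k in range(1, 6):
            mz = np.concatenate([base_mz, noise_mz_all[:k]])
            inten = np.concatenate([base_int, noise_int_all[:k]])
            cos = match_spectrum(q_spec(mz, inten), entry).cosine
            assert cos <= prev + 1e-12
            prev = cos

    def test_matched_only_vectorization_ignores_unmatched(self):
        entry = lib_entry([100.0, 200.0], [1.0, 1.0])
        query = q_spec([100.0, 200.0, 900.0], [1.0, 1.0, 100.0])
        union = match_spectrum(query, entry, vectorization="union")
        matched = match_spectrum(query, entry, vectorization="matched")
        assert union.cosine < 1.0
        assert matched.cosine == pytest.approx(1.0)


class TestAcceptance:
    @pytest.mark.parametrize(
        "cosine, n_matched, expected",
        [(0.95, 10, False), (0.99, 4, False), (0.99, 5, True), (0.951, 5, True)],
    )
    def test_strict_cosine_and_min_fragments(self, cosine, n_matched, expected):
        assert accept(cosine, n_matched) is expected


class TestBuildLibrary:
    def _gffytpk(self):
        protein = ProteinEntry(id="ins", name="ins", chains=("GFFYTPK",))
        return tryptic_digest(protein, 0)[0]

    def test_fragment_count_is_2n_minus_2(self):
        entries = build_library_from_truth([self._gffytpk()], [1])
        assert len(entries) == 1
        assert entries[0].fragment_mz.size == 12  # b1..b6 + y1..y6

    def test_entry_count_is_peptides_times_charges(self):
        protein = ProteinEntry(id="p", name="p", chains=("AAAKGGGR",))
        peps = tryptic_digest(protein, 0)
        entries = build_library_from_truth(peps, [1, 2])
        assert len(entries) == len(peps) * 2
        assert build_library_from_truth(peps, []) == []


class TestLibraryIO:
    def test_csv_round_trip(self, tmp_path):
        entries = build_library_from_truth(
            tryptic_digest(ProteinEntry(id="p", name="p", chains=("GFFYTPK",)), 0),
            [1, 2],
        )
        path = tmp_path / "lib.csv"
        export_library(entries, path)
        back = import_library(path)
        assert len(back) == len(entries)
        for a, b in zip(entries, back):
            assert a.key == b.key
            assert a.precursor_mz == b.precursor_mz
            assert np.array_equal(a.fragment_mz, b.fragment_mz)
            assert np.array_equal(a.fragment_intensity, b.fragment_intensity)

    def test_msp_block_parsed(self, tmp_path):
        path = tmp_path / "one.msp"
        path.write_text(
            "Name: GFFYTPK/2\n"
            "PrecursorMZ: 430.2211\n"
            "Protein: insulin\n"
            "Num peaks: 2\n"
            "147.1128 100.0\n"
            "205.0972 55.5\n"
        )
        entries = read_msp(path)
        assert len(entries) == 1
        e = entries[0]
        assert e.peptide_id == "GFFYTPK" and e.charge == 2
        assert e.precursor_mz == pytest.approx(430.2211)
        assert list(e.fragment_intensity) == [100.0, 55.5]

    def test_malformed_peak_line_names_lineno(self, tmp_path):
        path = tmp_path / "bad.msp"
        path.write_text(
            "Name: PEPK/1\nPrecursorMZ: 300.0\nNum peaks: 1\nnot_a_peak\n"
        )
        with pytest.raises(ValueError, match=":4"):
            read_msp(path)


class TestIdentifyRun:
    def _setup(self):
        protein = ProteinEntry(id="p", name="p", chains=("GFFYTPKAAAGYKLLNR",))
        peps = [p for p in tryptic_digest(protein, 0) if len(p.sequence) >= 2]
        library = build_library_from_truth(peps, [1, 2])
        return library

    def test_exact_copies_all_accepted(self):
        library = self._setup()
        spectra = []
        for i, entry in enumerate(library, start=1):
            spectra.append(
                q_spec(
                    entry.fragment_mz, entry.fragment_intensity,
                    scan_id=i, precursor=entry.precursor_mz,
                )
            )
        run = Run("r", spectra, cycle_length=10)
        results = identify_run(run, library)
        assert all(m.accepted for m in results)
        assert [(m.peptide_id, m.charge) for m in results] == [e.key for e in library]

    def test_noise_only_scans_rejected(self):
        library = self._setup()
        rng = np.random.default_rng(0)
        spectra = []
        for i, entry in enumerate(library, start=1):
            # off-grid noise: shift the true fragments well beyond tolerance
            mz = np.sort(entry.fragment_mz + rng.uniform(0.5, 3.0, entry.fragment_mz.size))
            spectra.append(
                q_spec(mz, rng.uniform(1, 100, mz.size), scan_id=i,
                       precursor=entry.precursor_mz)
            )
        run = Run("r", spectra, cycle_length=10)
        assert not any(m.accepted for m in identify_run(run, library))

    def test_isolation_window_is_half_open(self):
        entry = lib_entry([100.0, 110.0, 120.0, 130.0, 140.0],
                          [1.0] * 5, precursor=500.51)
        # window [499.5, 500.5): entry at 500.51 is excluded
        query = q_spec([100.0, 110.0, 120.0, 130.0, 140.0], [1.0] * 5,
                       precursor=500.0, width=1.0)
        results = identify_run(Run("r", [query]), [entry])
        assert results[0].peptide_id is None and not results[0].accepted
        at_lower = lib_entry([100.0, 110.0, 120.0, 130.0, 140.0],
                             [1.0] * 5, precursor=499.5)
        results = identify_run(Run("r", [query]), [at_lower])
        assert results[0].peptide_id == "PEP"  # lower bound inclusive
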