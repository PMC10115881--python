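import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepscreen import (
    ChainStructure,
    InterfaceComplex,
    InterfaceFixture,
    Segment,
    count_pd_go,
    deconvolve,
    extract_interface_segments,
    propose_extensions,
    rank_matches,
    scan_peptide,
)
from pepscreen.target_deconvolution import annotate_pd_go, hamming

from conftest import LEAD_PEPTIDE

AA = "ACDEFGHIKLMNPQRSTVWY"


def _fixture_from_segments(segments: list[str]) -> InterfaceFixture:
    complexes = []
    for i, seg in enumerate(segments):
        pid = f"P{i}"
        complexes.append(
            InterfaceComplex(
                complex_id=f"C{i:03d}",
                partners=(pid, pid + "x"),
                segments=[Segment(partner=pid, sequence=seg, start=1)],
                chain_sequences={pid: seg, pid + "x": "A" * 10},
            )
        )
    return InterfaceFixture(complexes=complexes)


def brute_force_scan(peptide, segments, max_mismatch):
    """Independent oracle: enumerate every window of every segment."""
    out = []
    k = len(peptide)
    for si, seg in enumerate(segments):
        for i in range(len(seg) - k + 1):
            mm = sum(a != b for a, b in zip(peptide, seg[i : i + k]))
            if mm <= max_mismatch:
                out.append((si, i + 1, mm))
    return sorted(out)


class TestScanPeptide:
    def test_lead_peptide_best_window_in_printed_segment(self, chmp2b_fixture):
        matches = scan_peptide(LEAD_PEPTIDE, chmp2b_fixture, max_mismatch=3)
        best = [m for m in matches if m.is_best and m.complex_id == "2JQK"]
        assert len(best) == 1
        assert best[0].window == "IERQLKA"
        assert best[0].mismatches == 2
        assert best[0].identity == pytest.approx(5 / 7)

    def test_verbatim_window_has_zero_mismatches(self):
        fx = _fixture_from_segments(["GGGIPIQLKAGGG"])
        matches = scan_peptide(LEAD_PEPTIDE, fx)
        assert min(m.mismatches for m in matches) == 0

    def test_zero_mismatch_scan_equals_substring_search(self):
        seg = "QWIPIQLKAYYIPIQLKA"
        fx = _fixture_from_segments([seg])
        matches = scan_peptide(LEAD_PEPTIDE, fx, max_mismatch=0)
        offsets = sorted(m.offset - 1 for m in matches)
        oracle = [i for i in range(len(seg) - 6) if seg[i : i + 7] == LEAD_PEPTIDE]
        assert offsets == oracle

    def test_match_count_monotone_in_max_mismatch(self):
        fx = _fixture_from_segments(["IPIQLKAWWGHIERQLKADNK"])
        sizes = [len(scan_peptide(LEAD_PEPTIDE, fx, max_mismatch=m)) for m in range(8)]
        assert sizes == sorted(sizes)
        assert sizes[7] == 15  # every window matches at k mismatches

    def test_short_segment_yields_no_windows(self):
        fx = _fixture_from_segments(["QLK"])
        assert scan_peptide(LEAD_PEPTIDE, fx) == []

    def test_empty_peptide_rejected(self, chmp2b_fixture):
        with pytest.raises(ValueError):
            scan_peptide("", chmp2b_fixture)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_matches_brute_force_oracle(self, data):
        rng_seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(rng_seed)
        peptide = "".join(rng.choice(list(AA), 7))
        segments = [
            "".join(rng.choice(list(AA), int(rng.integers(5, 25))))
            for _ in range(int(rng.integers(1, 5)))
        ]
        max_mm = int(rng.integers(0, 5))
        fx = _fixture_from_segments(segments)
        got = sorted(
            (int(m.complex_id[1:]), m.offset, m.mismatches)
            for m in scan_peptide(peptide, fx, max_mismatch=max_mm)
        )
        assert got == brute_force_scan(peptide, segments, max_mm)


class TestPdGoCounting:
    def _cplx(self):
        return InterfaceComplex(
            complex_id="X", partners=("a", "b"), segments=[], chain_sequences={}
        )

    def test_disjoint_annotations_share_nothing(self):
        ann = {"a": {"GO:1"}, "b": {"GO:2"}}
        assert count_pd_go(self._cplx(), ann, {"GO:1", "GO:2"}) == 0

    def test_hand_built_shared_terms(self):
        ann = {"a": {"GO:1", "GO:2", "GO:9"}, "b": {"GO:1", "GO:2", "GO:8"}}
        assert count_pd_go(self._cplx(), ann, {"GO:1", "GO:2", "GO:3"}) == 2

    def test_empty_pd_terms_or_missing_annotation(self):
        ann = {"a": {"GO:1"}, "b": {"GO:1"}}
        assert count_pd_go(self._cplx(), ann, set()) == 0
        assert count_pd_go(self._cplx(), {"a": {"GO:1"}}, {"GO:1"}) == 0


class TestRankMatches:
    def test_planted_complex_ranks_first(self, chmp2b_fixture):
        ranked = deconvolve(LEAD_PEPTIDE, chmp2b_fixture, max_mismatch=6)
        assert ranked[0].complex_id == "2JQK"
        assert ranked[0].mismatches == 2
        assert ranked[0].pd_go_count == 2  # GO:1, GO:2 shared by both partners

    def test_single_match_gets_rank_one(self, chmp2b_fixture):
        matches = [
            m for m in scan_peptide(LEAD_PEPTIDE, chmp2b_fixture, 3) if m.is_best
        ]
        ranked = rank_matches(annotate_pd_go(matches, chmp2b_fixture))
        assert ranked[0].rank == 1 and len(ranked) == 1

    def test_ranking_stable_under_input_permutation(self, chmp2b_fixture, rng):
        matches = [
            m for m in scan_peptide(LEAD_PEPTIDE, chmp2b_fixture, 6) if m.is_best
        ]
        annotate_pd_go(matches, chmp2b_fixture)
        baseline = [
            (m.complex_id, m.offset) for m in rank_matches(list(matches))
        ]
        for _ in range(5):
            shuffled = list(matches)
            rng.shuffle(shuffled)
            assert [
                (m.complex_id, m.offset) for m in rank_matches(shuffled)
            ] == baseline

    def test_unannotated_matches_rejected(self, chmp2b_fixture):
        matches = scan_peptide(LEAD_PEPTIDE, chmp2b_fixture, 3)
        with pytest.raises(ValueError):
            rank_matches(matches)


class TestProposeExtensions:
    def test_printed_variants_recovered(self, chmp2b_fixture):
        best = deconvolve(LEAD_PEPTIDE, chmp2b_fixture)[0]
        ten = propose_extensions(best, [10], chmp2b_fixture)
        twelve = propose_extensions(best, [12], chmp2b_fixture)
        assert "EIERQLKALG" in ten
        assert "DEEIERQLKALG" in twelve

    def test_candidates_contain_window_in_n_to_c_order(self, chmp2b_fixture):
        best = deconvolve(LEAD_PEPTIDE, chmp2b_fixture)[0]
        cands = propose_extensions(best, [9], chmp2b_fixture)
        assert all("IERQLKA" in c for c in cands)
        chain = chmp2b_fixture.complexes[0].chain_sequences["CHMP2B"]
        starts = [chain.index(c) for c in cands]
        assert starts == sorted(starts) and len(cands) == 3

    def test_length_k_returns_exactly_the_window(self, chmp2b_fixture):
        best = deconvolve(LEAD_PEPTIDE, chmp2b_fixture)[0]
        assert propose_extensions(best, [7], chmp2b_fixture) == [best.window]

    def test_overlong_length_skipped_with_warning(self, chmp2b_fixture):
        best = deconvolve(LEAD_PEPTIDE, chmp2b_fixture)[0]
        with pytest.warns(UserWarning):
            assert propose_extensions(best, [10_000], chmp2b_fixture) == []
        with pytest.raises(ValueError):
            propose_extensions(best, [3], chmp2b_fixture)


def _chain(chain_id, residue_positions, sequence=None, atoms_per_residue=1,
           jitter=0.0, rng=None):
    coords, res_idx = [], []
    for ri, pos in enumerate(residue_positions):
        for a in range(atoms_per_residue):
            p = np.asarray(pos, dtype=float)
            if jitter and rng is not None:
                p = p + rng.normal(0, jitter, 3)
            coords.append(p)
            res_idx.append(ri)
    return ChainStructure(
        chain_id=chain_id, coords=np.asarray(coords),
        atom_residue=np.asarray(res_idx), sequence=sequence,
    )


class TestExtractInterfaceSegments:
    def test_distant_chains_have_no_segments(self):
        a = _chain("A", [(0, 0, 0), (3, 0, 0), (6, 0, 0)])
        b = _chain("B", [(0, 0, 100), (3, 0, 100), (6, 0, 100)])
        segs = extract_interface_segments((a, b), cutoff=5.0, min_run=1)
        assert segs == {"A": [], "B": []}

    def test_close_toy_chains_form_one_segment_each(self):
        a = _chain("A", [(0, 0, 0), (3, 0, 0), (6, 0, 0)], sequence="MKL")
        b = _chain("B", [(0, 3, 0), (3, 3, 0), (6, 3, 0)], sequence="WYR")
        segs = extract_interface_segments((a, b), cutoff=5.0, min_run=1)
        assert len(segs["A"]) == 1 and len(segs["B"]) == 1
        assert segs["A"][0].start == 1 and segs["A"][0].sequence == "MKL"

    def test_min_run_filters_short_contacts(self):
        # residues 0-1 in contact, the rest far away: run of 2 < min_run 5
        close = [(i * 3.0, 0, 0) for i in range(2)]
        far = [(i * 3.0, 0, 80.0) for i in range(2, 10)]
        a = _chain("A", close + far)
        b = _chain("B", [(i * 3.0, 3.0, 0) for i in range(10)])
        segs = extract_interface_segments((a, b), cutoff=5.0, min_run=5)
        assert segs["A"] == []

    def test_single_residue_gap_is_bridged(self):
        pos = [(i * 3.0, 0, 0) for i in range(7)]
        pos[3] = (9.0, 0, 50.0)  # residue 3 pulled far out of the interface
        a = _chain("A", pos)
        b = _chain("B", [(i * 3.0, 3.0, 0) for i in range(7)])
        segs = extract_interface_segments((a, b), cutoff=5.0, min_run=5)
        assert len(segs["A"]) == 1 and segs["A"][0].start == 1

    def test_interfacial_set_matches_all_pairs_oracle(self, rng):
        from pepscreen.target_deconvolution import _interfacial_residues

        for _ in range(5):
            a = _chain("A", rng.uniform(0, 20, (8, 3)), atoms_per_residue=3,
                       jitter=0.8, rng=rng)
            b = _chain("B", rng.uniform(0, 20, (8, 3)), atoms_per_residue=3,
                       jitter=0.8, rng=rng)
            cutoff = 6.0
            # brute force over all atom pairs
            d = np.linalg.norm(a.coords[:, None, :] - b.coords[None, :, :], axis=-1)
            oracle_a = {
                int(a.atom_residue[i]) for i in np.where(d.min(axis=1) <= cutoff)[0]
            }
            assert _interfacial_residues(a, b, cutoff) == oracle_a

    def test_single_chain_rejected(self):
        a = _chain("A", [(0, 0, 0)])
        with pytest.raises(ValueError):
            extract_interface_segments([a])


class TestFixtureIO:
    def test_json_round_trip(self, tmp_path, chmp2b_fixture):
        path = tmp_path / "fixture.json"
        chmp2b_fixture.to_json(path)
        back = InterfaceFixture.from_json(path)
        assert back.pd_terms == chmp2b_fixture.pd_terms
        assert back.annotations == chmp2b_fixture.annotations
        assert [c.complex_id for c in back.complexes] == ["2JQK", "9ZZZ"]
        back.validate()

    def test_validate_catches_mismatched_segment(self):
        fx = InterfaceFixture(
            complexes=[
                InterfaceComplex(
                    complex_id="BAD", partners=("p", "q"),
                    segments=[Segment(partner="p", sequence="WWW", start=2)],
                    chain_sequences={"p": "AAAAA", "q": "CCCCC"},
                )
            ]
        )
        with pytest.raises(ValueError, match="BAD"):
            fx.validate()


def test_hamming_requires_equal_lengths():
    assert hamming("AAA", "ABA") == 1
    with pytest.raises(ValueError):
        hamming("AA", "AAA")
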