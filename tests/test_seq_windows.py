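"""Window extraction, candidate enumeration, redundancy filtering and
negative sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carbmotif import (
    Dataset,
    Fragment,
    ProteinRecord,
    SiteAnnotation,
    build_candidate_sites,
    extract_fragment,
    reduce_redundancy,
    sample_negatives,
)
from carbmotif.seq_windows import (
    fragment_identity,
    read_fasta,
    read_fragments_tsv,
    read_sites_tsv,
    write_fasta,
    write_fragments_tsv,
    write_sites_tsv,
)
from conftest import frag, random_window

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class TestExtractFragment:
    def test_padding_near_n_terminus(self):
        # site 5 of a 12-mer with n=10: 6 leading dummies, whole protein,
        # 3 trailing dummies
        prot = ProteinRecord(id="P", sequence="MKVLKACDEFGH")
        f = extract_fragment(prot, 5, n=10)
        assert len(f.window) == 21
        assert f.window == "-" * 6 + "MKVLKACDEFGH" + "-" * 3
        assert f.center_residue == "K"

    def test_exact_fit_no_padding(self):
        seq = "ACDEFGHIKLMNPQRSTVWYA"
        prot = ProteinRecord(id="P", sequence=seq)
        f = extract_fragment(prot, 11, n=10)
        assert f.window == seq
        assert "-" not in f.window

    @pytest.mark.parametrize("position", [1, 7, 21, 40])
    def test_window_length_always_2n_plus_1(self, position, rng):
        seq = "".join(
            np.array(list(PROTEIN_ALPHABET))[rng.integers(0, 20, 40)]
        )
        prot = ProteinRecord(id="P", sequence=seq)
        f = extract_fragment(prot, position, n=10)
        assert len(f.window) == 21

    def test_round_trip_matches_source(self, rng):
        seq = "".join(
            np.array(list(PROTEIN_ALPHABET))[rng.integers(0, 20, 60)]
        )
        prot = ProteinRecord(id="P", sequence=seq)
        for pos in (1, 5, 30, 60):
            f = extract_fragment(prot, pos, n=10)
            core = f.window.strip("-")
            lo = max(pos - 1 - 10, 0)
            hi = min(pos + 10, 60)
            assert core == seq[lo:hi]

    def test_out_of_range_errors_identify_site(self):
        prot = ProteinRecord(id="PX", sequence="MKV")
        with pytest.raises(ValueError, match="PX"):
            extract_fragment(prot, 4, n=10)
        with pytest.raises(ValueError, match="4"):
            extract_fragment(prot, 4, n=10)

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            ProteinRecord(id="P", sequence="MKXB")


class TestBuildCandidateSites:
    def test_negatives_enumerate_unannotated_residues(self):
        prot = ProteinRecord(id="P", sequence="KAKAK")
        ann = [SiteAnnotation("P", 1, "K")]
        ds = build_candidate_sites([prot], ann, "K", n=2)
        assert [f.source for f in ds.positives] == [("P", 1)]
        assert sorted(f.source[1] for f in ds.negatives) == [3, 5]

    def test_no_occurrences_gives_empty_dataset(self):
        prot = ProteinRecord(id="P", sequence="AAAA")
        ds = build_candidate_sites([prot], [], "K", n=1)
        assert ds.positives == [] and ds.negatives == []

    def test_annotation_sequence_mismatch_names_record(self):
        prot = ProteinRecord(id="PROT7", sequence="KARAK")
        with pytest.raises(ValueError, match="PROT7"):
            build_candidate_sites([prot], [SiteAnnotation("PROT7", 2, "K")],
                                  "K", n=1)

    def test_positive_negative_disjoint(self):
        prot = ProteinRecord(id="P", sequence="KKKKK")
        ann = [SiteAnnotation("P", 2, "K"), SiteAnnotation("P", 4, "K")]
        ds = build_candidate_sites([prot], ann, "K", n=2)
        assert {f.source for f in ds.positives}.isdisjoint(
            {f.source for f in ds.negatives}
        )


class TestReduceRedundancy:
    def test_identical_fragments_collapse(self):
        a = frag("AKA", source=("P", 1))
        b = frag("AKA", source=("P", 9))
        assert reduce_redundancy([a, b], 0.5) == [a]

    def test_disjoint_fragments_kept(self):
        a = frag("AKA", source=("P", 1))
        b = frag("CKC", source=("P", 9))
        kept = reduce_redundancy([a, b], 1.0)
        assert kept == [a, b]

    def test_reference_removes_lookalike_negatives(self):
        pos = frag("AKA", source=("P", 1))
        neg = frag("AKA", "negative", source=("Q", 5))
        assert reduce_redundancy([neg], 0.5, reference=[pos]) == []

    def test_matches_bruteforce_greedy_filter(self, rng):
        frags = [
            frag(random_window(rng), source=("P", i)) for i in range(100)
        ]
        got = reduce_redundancy(frags, 0.5)
        # independent brute-force: all-pairs greedy in order
        kept = []
        for f in frags:
            sims = [
                sum(x == y for x, y in zip(f.window, k.window)) / 21
                for k in kept
            ]
            if not any(s >= 0.5 for s in sims):
                kept.append(f)
        assert got == kept

    def test_idempotent(self, rng):
        frags = [
            frag(random_window(rng), source=("P", i)) for i in range(60)
        ]
        once = reduce_redundancy(frags, 0.5)
        assert reduce_redundancy(once, 0.5) == once

    def test_dummy_positions_excluded_from_identity(self):
        a = frag("--KAA", source=("P", 1))
        b = frag("CCKAA", source=("P", 9))
        # compared positions: 3 non-dummy; all match -> identity 1
        assert fragment_identity(a, b) == 1.0

    def test_mixed_lengths_error(self):
        with pytest.raises(ValueError, match="length"):
            reduce_redundancy([frag("AKA"), frag("AAKAA")], 0.5)


class TestSampleNegatives:
    def _dataset(self, n_pos, n_neg, rng):
        pos = [frag(random_window(rng, 2), source=("P", i))
               for i in range(n_pos)]
        neg = [frag(random_window(rng, 2), "negative", source=("N", i))
               for i in range(n_neg)]
        return Dataset(residue="K", positives=pos, negatives=neg, n=2)

    def test_two_to_one_ratio(self, rng):
        ds = self._dataset(50, 300, rng)
        out = sample_negatives(ds, ratio=2, seed=7)
        assert len(out.negatives) == 100
        assert set(f.source for f in out.negatives) <= {
            f.source for f in ds.negatives
        }

    def test_deterministic_and_seed_sensitive(self, rng):
        ds = self._dataset(100, 1000, rng)
        a = sample_negatives(ds, 2, seed=3)
        b = sample_negatives(ds, 2, seed=3)
        c = sample_negatives(ds, 2, seed=4)
        assert [f.source for f in a.negatives] == [f.source for f in b.negatives]
        assert [f.source for f in a.negatives] != [f.source for f in c.negatives]

    def test_thirty_seeds_exact_size(self, rng):
        ds = self._dataset(20, 200, rng)
        for seed in range(30):
            out = sample_negatives(ds, ratio=2, seed=seed)
            assert len(out.negatives) == 40

    def test_shortfall_reported(self, rng):
        ds = self._dataset(50, 60, rng)
        with pytest.raises(ValueError, match="short by 40"):
            sample_negatives(ds, ratio=2, seed=0)


class TestFragmentInvariants:
    def test_center_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Fragment(window="AKA", center_residue="R", label="positive",
                     source=("P", 1))

    def test_interior_dummy_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            Fragment(window="A-KAA", center_residue="K", label="positive",
                     source=("P", 1))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(1, 200), st.integers(1, 15))
    def test_extraction_length_property(self, pos, n):
        rng = np.random.default_rng(pos * 31 + n)
        seq = "".join(np.array(list(PROTEIN_ALPHABET))[rng.integers(0, 20, 200)])
        prot = ProteinRecord(id="P", sequence=seq)
        f = extract_fragment(prot, pos, n=n)
        assert len(f.window) == 2 * n + 1
        assert f.window[n] == seq[pos - 1]


class TestIO:
    def test_fasta_round_trip(self, tmp_path, rng):
        prots = [
            ProteinRecord(id=f"P{i}", sequence="".join(
                np.array(list(PROTEIN_ALPHABET))[rng.integers(0, 20, 80)]
            ))
            for i in range(3)
        ]
        path = tmp_path / "p.fasta"
        write_fasta(prots, path)
        assert read_fasta(path) == prots

    def test_sites_tsv_round_trip_with_comments(self, tmp_path):
        sites = [SiteAnnotation("P1", 5, "K"), SiteAnnotation("P2", 9, "R",
                                                              "negative")]
        path = tmp_path / "sites.tsv"
        write_sites_tsv(sites, path)
        text = path.read_text()
        path.write_text("# curated sites\n" + text)
        assert read_sites_tsv(path) == sites

    def test_fragments_tsv_round_trip(self, tmp_path, rng):
        frags = [frag(random_window(rng), source=("P", i)) for i in range(5)]
        path = tmp_path / "frags.tsv"
        write_fragments_tsv(frags, path)
        assert read_fragments_tsv(path) == frags
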