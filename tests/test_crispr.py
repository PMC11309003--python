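"""CRISPR detection, spacer matching and host linkage."""

import edlib
import numpy as np
import pytest

from holovir import (CrisprParams, Spacer, detect_crispr_arrays, extract_spacers,
                     link_hosts_by_crispr, match_spacer)
from holovir._align import revcomp
from conftest import random_seq


def _build_array(rng, repeat_len=28, spacer_lens=(32, 32, 32)):
    repeat = random_seq(rng, repeat_len)
    spacers = [random_seq(rng, sl) for sl in spacer_lens]
    parts = [repeat]
    for sp in spacers:
        parts += [sp, repeat]
    return repeat, spacers, "".join(parts)


class TestDetection:
    def test_constructed_array_found_at_planted_coordinates(self, rng):
        repeat, spacers, array = _build_array(rng)
        left, right = random_seq(rng, 500), random_seq(rng, 500)
        contig = left + array + right
        found = detect_crispr_arrays("c1", contig)
        assert len(found) == 1
        arr = found[0]
        assert arr.repeat_consensus == repeat
        assert len(arr.repeat_positions) == 4
        assert [s.sequence for s in arr.spacers] == spacers
        assert arr.repeat_positions[0] == (500, 500 + 28)

    def test_two_repeat_copies_not_reported(self, rng):
        repeat = random_seq(rng, 28)
        contig = (random_seq(rng, 300) + repeat + random_seq(rng, 32)
                  + repeat + random_seq(rng, 300))
        assert detect_crispr_arrays("c1", contig) == []

    def test_random_sequence_has_no_arrays(self, rng):
        contig = random_seq(rng, 50000)
        assert detect_crispr_arrays("c1", contig) == []

    def test_non_acgt_rejected_beyond_allowance(self):
        with pytest.raises(ValueError, match="c1"):
            detect_crispr_arrays("c1", "N" * 1000)

    def test_repeat_count_spacer_count_invariant(self, small_dataset):
        for cid, seq in small_dataset.hosts.items():
            for arr in detect_crispr_arrays(cid, seq):
                assert len(arr.repeat_positions) == len(arr.spacers) + 1
                # intervals alternate and are sorted
                spans = sorted([*arr.repeat_positions,
                                *[s.interval for s in arr.spacers]])
                for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                    assert b1 == a2  # contiguous alternation


class TestExtraction:
    def test_spacers_in_order_and_resliceable(self, rng):
        _, spacers, array = _build_array(rng, spacer_lens=(20, 30, 40))
        contig = random_seq(rng, 200) + array + random_seq(rng, 200)
        arrays = detect_crispr_arrays("cX", contig)
        out = extract_spacers(arrays)
        assert [s.sequence for s in out] == spacers
        for s in out:
            assert contig[s.interval[0] : s.interval[1]] == s.sequence

    def test_two_arrays_on_one_contig_ids_do_not_collide(self, rng):
        _, _, array1 = _build_array(rng)
        _, _, array2 = _build_array(rng)
        contig = (random_seq(rng, 200) + array1 + random_seq(rng, 400)
                  + array2 + random_seq(rng, 200))
        arrays = detect_crispr_arrays("cY", contig)
        assert len(arrays) == 2
        ids = [s.spacer_id for s in extract_spacers(arrays)]
        assert len(ids) == len(set(ids))


def _spacer(seq, sid="sp", host="h1"):
    return Spacer(sid, host, seq, (0, len(seq)))


class TestMatching:
    def test_exact_substring_single_match(self, rng):
        virus = random_seq(rng, 2000)
        sp = virus[700:724]
        (m,) = match_spacer(_spacer(sp), "v", virus)
        assert (m.strand, m.edit_distance, m.virus_interval) == ("+", 0, (700, 724))

    def test_reverse_complement_match(self, rng):
        virus = random_seq(rng, 2000)
        sp = revcomp(virus[700:724])
        (m,) = match_spacer(_spacer(sp), "v", virus)
        assert m.strand == "-"
        assert m.virus_interval == (700, 724)

    def test_three_substitutions_rejected_at_default(self, rng):
        virus = random_seq(rng, 2000)
        w = list(virus[700:730])
        for pos in (3, 12, 25):
            w[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[w[pos]]
        sp = "".join(w)
        # confirmed by an exhaustive scan: no window within 2 edits
        best = edlib.align(sp, virus, mode="HW")["editDistance"]
        best = min(best, edlib.align(sp, revcomp(virus), mode="HW")["editDistance"])
        assert best == 3
        assert match_spacer(_spacer(sp), "v", virus) == []

    def test_short_spacer_rejected_even_if_exact(self, rng):
        virus = random_seq(rng, 2000)
        sp = virus[100:119]  # 19 bp, below the >=20 nt length filter
        assert match_spacer(_spacer(sp), "v", virus) == []

    def test_matches_verified_against_bruteforce_scan(self, rng):
        """Matcher output equals an exhaustive edit-distance window scan."""
        virus = random_seq(rng, 3000)
        planted = [virus[i : i + 26] for i in (40, 950, 2100)]
        cases = [planted[0],                         # exact
                 planted[1][:10] + "A" + planted[1][10:],  # 1 insertion
                 revcomp(planted[2][2:])]            # revcomp, truncated start
        for sp in cases:
            got = match_spacer(_spacer(sp), "v", virus, max_edits=2)
            assert got, sp
            for m in got:
                s, e = m.virus_interval
                window = virus[s:e] if m.strand == "+" else revcomp(virus[s:e])
                assert edlib.align(sp, window, mode="NW")["editDistance"] == \
                    m.edit_distance
            # recall: the best achievable distance is reported somewhere
            best = min(edlib.align(sp, virus, mode="HW")["editDistance"],
                       edlib.align(sp, revcomp(virus), mode="HW")["editDistance"])
            assert min(m.edit_distance for m in got) == best

    def test_strand_symmetry(self, rng):
        virus = random_seq(rng, 1500)
        sp = virus[333:360][:12] + "T" + virus[333:360][12:]
        fwd = match_spacer(_spacer(sp), "v", virus)
        rev = match_spacer(_spacer(revcomp(sp)), "v", virus)
        assert {(m.virus_interval, m.edit_distance) for m in fwd} == \
            {(m.virus_interval, m.edit_distance) for m in rev}
        assert {m.strand for m in fwd} == {"-" if s == "+" else "+"
                                           for s in {m.strand for m in rev}}

    def test_match_set_monotone_in_edit_budget(self, rng):
        virus = random_seq(rng, 2000)
        sp = virus[500:530][:15] + "G" + virus[500:530][15:]
        prev = set()
        for k in (0, 1, 2, 3):
            got = {(m.virus_interval, m.strand)
                   for m in match_spacer(_spacer(sp), "v", virus, max_edits=k)}
            assert prev <= got
            prev = got


class TestLinking:
    def test_two_spacers_one_virus_dedupe_to_one_link(self, rng):
        virus = random_seq(rng, 3000)
        spacers = [_spacer(virus[100:130], "a", "hostA"),
                   _spacer(virus[900:932], "b", "hostA")]
        links = link_hosts_by_crispr(spacers, {"v1": virus})
        assert len(links) == 1
        assert (links[0].virus_id, links[0].host_id) == ("v1", "hostA")
        # best supporting match is the minimum-edit, then longest spacer
        assert links[0].detail.edit_distance == 0
        assert links[0].detail.spacer_id == "b"

    def test_planted_truth_recovery(self, small_dataset):
        """Precision and recall are 1.0 on edits in {0,1,2}."""
        ds = small_dataset
        arrays = []
        for cid, seq in ds.hosts.items():
            arrays.extend(detect_crispr_arrays(cid, seq))
        links = link_hosts_by_crispr(extract_spacers(arrays), ds.viruses)
        found = {(l.virus_id, l.host_id) for l in links}
        assert found == ds.truth.expected_crispr_pairs(max_edits=2)

    def test_planted_edit3_yields_no_links(self):
        from holovir import SynthConfig, generate_all
        cfg = SynthConfig(seed=21, n_viruses=4, n_host_contigs=3,
                          virus_len_range=(4000, 5000),
                          host_len_range=(12000, 16000),
                          provirus_fraction=0.0,
                          spacer_edit_distribution={3: 1.0})
        ds = generate_all(cfg)
        arrays = []
        for cid, seq in ds.hosts.items():
            arrays.extend(detect_crispr_arrays(cid, seq))
        spacers = extract_spacers(arrays)
        assert spacers  # arrays are still detectable
        assert link_hosts_by_crispr(spacers, ds.viruses) == []
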