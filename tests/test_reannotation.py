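"""Probe-to-transcript exact mapping and the three assignment criteria."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncarray.reannotation import (
    ProbeRecord,
    TranscriptRecord,
    build_transcript_index,
    map_probe,
    reannotate,
    reverse_complement,
)

from conftest import random_transcripts


def naive_scan(transcripts, seq):
    """Brute-force sliding-window oracle: all exact placements of seq."""
    hits = []
    for t in transcripts:
        for off in range(len(t.sequence) - len(seq) + 1):
            if t.sequence[off : off + len(seq)] == seq:
                hits.append((t.transcript_id, off))
    return sorted(hits)


class TestIndex:
    def test_substring_of_indexed_transcript_is_found(self):
        rng = np.random.default_rng(0)
        (t,) = random_transcripts(rng, 1, length=(100, 101))
        idx = build_transcript_index([t])
        assert idx.query(t.sequence[10:35]) == [(t.transcript_id, 10)]

    def test_absent_kmer_has_zero_hits(self):
        t = TranscriptRecord("t1", "ACGT" * 30)
        idx = build_transcript_index([t])
        assert idx.query("T" * 25) == []

    def test_empty_reference_and_duplicate_ids_error(self):
        with pytest.raises(ValueError):
            build_transcript_index([])
        t = TranscriptRecord("t1", "ACGT" * 10)
        with pytest.raises(ValueError, match="duplicate"):
            build_transcript_index([t, t])

    def test_window_with_N_never_matches(self):
        t = TranscriptRecord("t1", "ACGTACGTACGTNACGTACGTACGTACG")
        idx = build_transcript_index([t])
        # the probe equals the transcript window spanning the N except at N
        probe = t.sequence.replace("N", "A")
        assert idx.query(probe[:25]) == []

    @pytest.mark.parametrize("word_size", [8, 12, 20])
    def test_index_equals_naive_scan_on_random_reference(self, word_size):
        """Oracle equivalence: seeded 5-transcript reference, exhaustive queries."""
        rng = np.random.default_rng(42)
        transcripts = random_transcripts(rng, 5, length=(60, 120))
        idx = build_transcript_index(transcripts, word_size=word_size)
        # true substrings, mutated substrings, and random 25-mers
        queries = []
        for t in transcripts:
            for off in range(0, len(t.sequence) - 25, 7):
                queries.append(t.sequence[off : off + 25])
        for q in list(queries[:20]):
            pos = int(rng.integers(25))
            alt = "ACGT"[("ACGT".index(q[pos]) + 1) % 4]
            queries.append(q[:pos] + alt + q[pos + 1 :])
        for _ in range(30):
            queries.append("".join(rng.choice(list("ACGT"), 25)))
        for q in queries:
            assert sorted(idx.query(q)) == naive_scan(transcripts, q)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_index_matches_oracle_property(self, seed):
        rng = np.random.default_rng(seed)
        transcripts = random_transcripts(rng, int(rng.integers(1, 8)), length=(40, 90))
        idx = build_transcript_index(transcripts)
        for _ in range(5):
            t = transcripts[int(rng.integers(len(transcripts)))]
            off = int(rng.integers(len(t.sequence) - 25))
            q = t.sequence[off : off + 25]
            assert sorted(idx.query(q)) == naive_scan(transcripts, q)


class TestMapProbe:
    def test_probe_at_transcript_start(self):
        t = TranscriptRecord("t1", "ACGTTGCA" * 10)
        idx = build_transcript_index([t])
        probe = ProbeRecord("ps1", 0, t.sequence[:25])
        (m,) = [x for x in map_probe(idx, probe) if x.offset == 0]
        assert (m.transcript_id, m.orientation) == ("t1", "sense")

    def test_single_mismatch_yields_zero_matches(self):
        rng = np.random.default_rng(3)
        (t,) = random_transcripts(rng, 1)
        idx = build_transcript_index([t])
        window = t.sequence[5:30]
        alt = "ACGT"[("ACGT".index(window[12]) + 1) % 4]
        probe = ProbeRecord("ps1", 0, window[:12] + alt + window[13:])
        assert map_probe(idx, probe) == []

    def test_revcomp_only_with_flag(self):
        rng = np.random.default_rng(4)
        (t,) = random_transcripts(rng, 1)
        idx = build_transcript_index([t])
        probe = ProbeRecord("ps1", 0, reverse_complement(t.sequence[10:35]))
        assert map_probe(idx, probe, allow_revcomp=False) == []
        (m,) = map_probe(idx, probe, allow_revcomp=True)
        assert (m.offset, m.orientation) == (10, "revcomp")

    def test_non_acgt_probe_rejected_at_construction(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            ProbeRecord("ps1", 0, "ACGTN" * 5)


def _probeset_from(transcript, psid, n, start=0, step=30):
    return [
        ProbeRecord(psid, j, transcript.sequence[start + j * step : start + j * step + 25])
        for j in range(n)
    ]


class TestReannotate:
    def test_seven_of_eleven_probes_assign_the_set(self):
        """Synthetic analog of the worked example: an 11-probe set in which 7
        probes map exactly and 4 match nothing is assigned with evidence 7."""
        rng = np.random.default_rng(7)
        transcripts = random_transcripts(rng, 4, length=(400, 500))
        probes = _probeset_from(transcripts[0], "236065_at", 7)
        probes += [
            ProbeRecord("236065_at", 7 + j, "".join(rng.choice(list("ACGT"), 25)))
            for j in range(4)
        ]
        (a,) = reannotate(probes, transcripts, min_probes=4)
        assert a.status == "assigned"
        assert a.transcript_id == transcripts[0].transcript_id
        assert (a.n_probes_total, a.n_probes_matched) == (11, 7)
        assert a.matched_probe_indices == tuple(range(7))

    def test_three_matching_probes_rejected_too_few(self):
        rng = np.random.default_rng(8)
        transcripts = random_transcripts(rng, 2, length=(300, 400))
        probes = _probeset_from(transcripts[0], "ps1", 3)
        (a,) = reannotate(probes, transcripts, min_probes=4)
        assert a.status == "rejected_too_few"
        assert a.transcript_id is None

    def test_every_probe_multi_mapping_rejected_nonunique(self):
        rng = np.random.default_rng(9)
        (t1,) = random_transcripts(rng, 1, length=(300, 400))
        t2 = TranscriptRecord("copy", t1.sequence)  # duplicate sequence, new id
        probes = _probeset_from(t1, "ps1", 5)
        (a,) = reannotate(probes, [t1, t2], min_probes=4)
        assert a.status == "rejected_nonunique"

    def test_two_transcripts_reaching_threshold_is_ambiguous(self):
        rng = np.random.default_rng(10)
        t1, t2 = random_transcripts(rng, 2, length=(300, 400))
        probes = _probeset_from(t1, "ps1", 4) + [
            ProbeRecord("ps1", 4 + j, t2.sequence[j * 30 : j * 30 + 25]) for j in range(4)
        ]
        (a,) = reannotate(probes, [t1, t2], min_probes=4)
        assert a.status == "rejected_ambiguous"

    def test_planted_map_recovered_exactly(self, clean_reference):
        ref = clean_reference
        assignments = reannotate(ref.probes, ref.transcripts, min_probes=4)
        got = {a.probeset_id: a.transcript_id for a in assignments if a.status == "assigned"}
        assert got == ref.truth.probeset_map
        assert all(a.status == "assigned" for a in assignments)

    def test_output_invariant_to_input_ordering(self, clean_reference):
        ref = clean_reference
        rng = np.random.default_rng(0)
        probes = list(ref.probes)
        transcripts = list(ref.transcripts)
        rng.shuffle(probes)
        rng.shuffle(transcripts)
        assert reannotate(probes, transcripts) == reannotate(ref.probes, ref.transcripts)

    def test_min_probes_monotonicity(self, clean_reference):
        ref = clean_reference
        by_threshold = {
            m: {a.probeset_id for a in reannotate(ref.probes, ref.transcripts, min_probes=m)
                if a.status == "assigned"}
            for m in (1, 4, 8, 12)
        }
        assert by_threshold[12] <= by_threshold[8] <= by_threshold[4] <= by_threshold[1]

    def test_min_probes_below_one_errors(self, clean_reference):
        with pytest.raises(ValueError):
            reannotate(clean_reference.probes, clean_reference.transcripts, min_probes=0)

    def test_lncRNA_only_scope_ignores_coding_cross_hits(self):
        rng = np.random.default_rng(13)
        (t1,) = random_transcripts(rng, 1, length=(300, 400))
        lnc = TranscriptRecord("lnc1", t1.sequence, biotype="lncRNA")
        coding = TranscriptRecord("pc1", t1.sequence, biotype="protein_coding")
        probes = _probeset_from(lnc, "ps1", 5)
        (whole,) = reannotate(probes, [lnc, coding], min_probes=4)
        assert whole.status == "rejected_nonunique"
        (only_lnc,) = reannotate(probes, [lnc, coding], min_probes=4, unique_scope="lncRNA_only")
        assert (only_lnc.status, only_lnc.transcript_id) == ("assigned", "lnc1")

    def test_duplicate_probe_rows_collapse_and_conflicts_error(self):
        rng = np.random.default_rng(14)
        (t,) = random_transcripts(rng, 1, length=(300, 400))
        probes = _probeset_from(t, "ps1", 4)
        (a,) = reannotate(probes + [probes[0]], [t], min_probes=4)
        assert a.n_probes_total == 4
        clash = ProbeRecord("ps1", 0, t.sequence[200:225])
        with pytest.raises(ValueError, match="conflicting"):
            reannotate(probes + [clash], [t])
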