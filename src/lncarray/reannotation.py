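"""Exact-sequence re-annotation of array probe sets to transcripts.

3' expression arrays measure each target with a set of ~11-22 25-nt
oligonucleotide probes.  Vendor probe-set definitions age as transcript
annotation improves, and many probe sets in fact interrogate long non-coding
RNAs absent from the original annotation.  This module discards the vendor
definitions and rebuilds probeset -> transcript assignments by mapping every
individual probe sequence against a supplied transcript reference, keeping an
assignment only when

  (i)   the transcript is detected by at least ``min_probes`` distinct probes
        of the set (default 4, i.e. "more than three"),
  (ii)  every contributing probe matches the transcript exactly, full length,
        with zero mismatches, and
  (iii) every contributing probe matches exactly one transcript in the
        uniqueness scope (whole reference by default).

Matching is case-insensitive (sequences are uppercased on construction) and
any transcript window containing ``N`` never matches.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Tuple

__all__ = [
    "ProbeRecord",
    "TranscriptRecord",
    "ProbeMatch",
    "ProbeSetAssignment",
    "SequenceIndex",
    "build_transcript_index",
    "map_probe",
    "reannotate",
    "reverse_complement",
]

_PROBE_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Biotype = Literal["lncRNA", "protein_coding", "other"]
Status = Literal["assigned", "rejected_too_few", "rejected_nonunique", "rejected_ambiguous"]


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ProbeRecord:
    """One oligonucleotide probe of a probe set.

    ``probe_index`` is the position of the probe within its set (any
    non-negative integer unique within the set, e.g. the probe-tab
    interrogation position or a running index).
    """

    probeset_id: str
    probe_index: int
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ValueError(f"probe {self.probeset_id}:{self.probe_index} has empty sequence")
        bad = set(self.sequence) - _PROBE_ALPHABET
        if bad:
            raise ValueError(
                f"probe {self.probeset_id}:{self.probe_index} has non-ACGT characters {sorted(bad)}"
            )
        if self.probe_index < 0:
            raise ValueError("probe_index must be non-negative")


@dataclass(frozen=True)
class TranscriptRecord:
    """A reference transcript with optional gene symbol and biotype."""

    transcript_id: str
    sequence: str
    gene_symbol: Optional[str] = None
    biotype: Biotype = "other"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ValueError(f"transcript {self.transcript_id} has empty sequence")


@dataclass(frozen=True)
class ProbeMatch:
    """An exact full-length placement of a probe on a transcript."""

    probeset_id: str
    probe_index: int
    transcript_id: str
    offset: int
    orientation: Literal["sense", "revcomp"] = "sense"


@dataclass(frozen=True)
class ProbeSetAssignment:
    """Re-annotation outcome for one probe set.

    ``transcript_id`` is ``None`` unless ``status == "assigned"``.
    ``n_probes_matched`` is the evidence count for the best transcript:
    the number of distinct probe indices that map uniquely (criterion iii)
    to it.
    """

    probeset_id: str
    transcript_id: Optional[str]
    n_probes_total: int
    n_probes_matched: int
    matched_probe_indices: Tuple[int, ...]
    status: Status


class SequenceIndex:
    """Exact-substring index over a transcript reference.

    Seeds queries with their first ``word_size``-mer and verifies each
    candidate placement against the transcript string, so correctness does
    not depend on ``word_size`` (only speed does).  Queries shorter than
    ``word_size`` fall back to a naive scan.  k-mers containing ``N`` are not
    indexed, and verification can never succeed across an ``N``.
    """

    def __init__(self, transcripts: Sequence[TranscriptRecord], word_size: int = 12):
        if word_size < 8:
            raise ValueError("word_size must be >= 8")
        transcripts = list(transcripts)
        if not transcripts:
            raise ValueError("empty transcript reference")
        seen = set()
        for t in transcripts:
            if t.transcript_id in seen:
                raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
            seen.add(t.transcript_id)
        self.word_size = word_size
        self.transcripts: Dict[str, TranscriptRecord] = {t.transcript_id: t for t in transcripts}
        self._kmers: Dict[str, List[Tuple[str, int]]] = collections.defaultdict(list)
        for t in transcripts:
            seq = t.sequence
            for off in range(len(seq) - word_size + 1):
                kmer = seq[off : off + word_size]
                if "N" not in kmer:
                    self._kmers[kmer].append((t.transcript_id, off))

    def query(self, seq: str) -> List[Tuple[str, int]]:
        """All exact full-length placements of ``seq``: (transcript_id, offset)."""
        seq = seq.upper()
        if not seq:
            return []
        n = len(seq)
        if n < self.word_size:
            hits = []
            for tid, t in self.transcripts.items():
                start = t.sequence.find(seq)
                while start != -1:
                    if "N" not in seq:
                        hits.append((tid, start))
                    start = t.sequence.find(seq, start + 1)
            return hits
        seed = seq[: self.word_size]
        hits = []
        for tid, off in self._kmers.get(seed, ()):
            t = self.transcripts[tid]
            if t.sequence[off : off + n] == seq:
                hits.append((tid, off))
        return hits


def build_transcript_index(
    transcripts: Sequence[TranscriptRecord], word_size: int = 12
) -> SequenceIndex:
    """Build an exact-substring :class:`SequenceIndex` over ``transcripts``."""
    return SequenceIndex(transcripts, word_size=word_size)


def map_probe(
    index: SequenceIndex, probe: ProbeRecord, allow_revcomp: bool = False
) -> List[ProbeMatch]:
    """All exact, full-length, zero-mismatch placements of one probe.

    With ``allow_revcomp`` the reverse complement of the probe is also
    queried; a placement found both ways (palindromic probe) is reported
    once, as sense.  An empty list is a valid result.
    """
    matches = {}
    for tid, off in index.query(probe.sequence):
        matches[(tid, off)] = ProbeMatch(probe.probeset_id, probe.probe_index, tid, off, "sense")
    if allow_revcomp:
        for tid, off in index.query(reverse_complement(probe.sequence)):
            matches.setdefault(
                (tid, off),
                ProbeMatch(probe.probeset_id, probe.probe_index, tid, off, "revcomp"),
            )
    return sorted(matches.values(), key=lambda m: (m.transcript_id, m.offset))


def _dedupe_probes(probes: Iterable[ProbeRecord]) -> List[ProbeRecord]:
    by_key: Dict[Tuple[str, int], ProbeRecord] = {}
    for p in probes:
        key = (p.probeset_id, p.probe_index)
        prev = by_key.get(key)
        if prev is None:
            by_key[key] = p
        elif prev.sequence != p.sequence:
            raise ValueError(
                f"conflicting sequences for probe {p.probeset_id}:{p.probe_index}"
            )
    return [by_key[k] for k in sorted(by_key)]


def reannotate(
    probes: Iterable[ProbeRecord],
    transcripts: Sequence[TranscriptRecord],
    min_probes: int = 4,
    unique_scope: Literal["whole_reference", "lncRNA_only"] = "whole_reference",
    allow_revcomp: bool = False,
    word_size: int = 12,
    index: Optional[SequenceIndex] = None,
) -> List[ProbeSetAssignment]:
    """Rebuild probeset -> transcript assignments under criteria (i)-(iii).

    A probe contributes evidence for a transcript only when it maps to
    exactly one transcript within ``unique_scope`` (criterion iii; with
    ``lncRNA_only`` matches to non-lncRNA transcripts are disregarded before
    the uniqueness check).  A probe set is ``assigned`` to transcript T iff
    the number of distinct contributing probes for T reaches ``min_probes``
    (criterion i) and no second transcript also reaches ``min_probes``
    from the same set (else ``rejected_ambiguous``).  Sets whose matching
    probes were all discarded as multi-transcript are ``rejected_nonunique``;
    the rest are ``rejected_too_few``.  Every input probe set appears exactly
    once in the output, sorted by probeset id, so the result is invariant to
    input ordering.
    """
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    if index is None:
        index = build_transcript_index(transcripts, word_size=word_size)
    in_scope = {
        t.transcript_id
        for t in index.transcripts.values()
        if unique_scope == "whole_reference" or t.biotype == "lncRNA"
    }

    probe_list = _dedupe_probes(probes)
    by_set: Dict[str, List[ProbeRecord]] = collections.defaultdict(list)
    for p in probe_list:
        by_set[p.probeset_id].append(p)

    out: List[ProbeSetAssignment] = []
    for psid in sorted(by_set):
        members = by_set[psid]
        evidence: Dict[str, set] = collections.defaultdict(set)  # tid -> probe indices
        n_multi = 0
        for p in members:
            tids = {m.transcript_id for m in map_probe(index, p, allow_revcomp)} & in_scope
            if len(tids) == 1:
                evidence[next(iter(tids))].add(p.probe_index)
            elif len(tids) > 1:
                n_multi += 1
        candidates = {tid: idxs for tid, idxs in evidence.items() if len(idxs) >= min_probes}
        if len(candidates) == 1:
            tid, idxs = next(iter(candidates.items()))
            out.append(
                ProbeSetAssignment(
                    psid, tid, len(members), len(idxs), tuple(sorted(idxs)), "assigned"
                )
            )
            continue
        if len(candidates) > 1:
            status: Status = "rejected_ambiguous"
        elif not evidence and n_multi > 0:
            status = "rejected_nonunique"
        else:
            status = "rejected_too_few"
        best_idxs: Tuple[int, ...] = ()
        if evidence:
            best_tid = max(evidence, key=lambda t: (len(evidence[t]), t))
            best_idxs = tuple(sorted(evidence[best_tid]))
        out.append(
            ProbeSetAssignment(psid, None, len(members), len(best_idxs), best_idxs, status)
        )
    return out
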