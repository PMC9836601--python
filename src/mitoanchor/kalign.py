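"""K-mer seeded local read placement on a circular query genome.

Seeds are exact k-mer matches chained per diagonal; each candidate
diagonal cluster is extended by a local affine-gap alignment restricted to
a window around the cluster (Bio.Align.PairwiseAligner does the DP).
Two stringency presets, ``high`` and ``low``, stand in for high- and
moderate-similarity nucleotide search settings.

Gap cost convention: a gap of length L costs ``gap_open + L * gap_extend``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio import Align

from .errors import ParameterError
from .seqio import NamedSequence, read_fastq, reverse_complement

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class AlignPreset:
    """Stringency preset: seeding word size, acceptance thresholds and
    scoring scheme."""

    name: str
    k: int
    min_identity: float
    min_aln_len: int
    band: int = 8
    match: int = 1
    mismatch: int = -2
    gap_open: int = 4
    gap_extend: int = 2

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ParameterError("k must be >= 8")
        if not 0 < self.min_identity <= 1:
            raise ParameterError("min_identity must be in (0, 1]")


PRESETS: dict[str, AlignPreset] = {
    "high": AlignPreset(name="high", k=16, min_identity=0.92, min_aln_len=40),
    "low": AlignPreset(name="low", k=11, min_identity=0.80, min_aln_len=30),
}


@dataclass
class LocalAlignment:
    """One read placed on the query.

    Query coordinates are 0-based half-open modulo the circle; a
    query_end <= query_start signals an origin-spanning placement. Blocks
    hold the gap-free aligned segments in unwrapped query coordinates and
    coordinates of the query-oriented read (the reverse complement of the
    input read when strand is '-').
    """

    read_id: str
    strand: str
    query_start: int
    query_end: int
    read_start: int
    read_end: int
    matches: int
    mismatches: int
    gap_columns: int
    identity: float
    score: float
    blocks: list[tuple[int, int, int, int]] = field(default_factory=list)

    @property
    def aln_len(self) -> int:
        return self.matches + self.mismatches + self.gap_columns


class SeedIndex:
    """Exact k-mer lookup over a (possibly circular) query.

    Circular queries are unwrapped by appending ``pad`` leading bases so
    that seeds and extensions can cross the origin; stored positions are
    reported modulo the query length. K-mers containing ambiguity codes
    are skipped.
    """

    def __init__(self, query: NamedSequence, k: int, pad: int | None = None):
        if k > len(query):
            raise ParameterError(
                f"k={k} exceeds query length {len(query)}"
            )
        self.k = k
        self.query_id = query.id
        self.query_length = len(query)
        self.circular = query.circular
        if pad is None:
            pad = k - 1 + 150 + 32  # seed wrap + read span + band slack
        self.pad = min(pad, self.query_length) if query.circular else 0
        self.padded = query.residues + query.residues[: self.pad]
        kmers: dict[str, list[int]] = {}
        n_index = self.query_length if query.circular else self.query_length - k + 1
        for i in range(n_index):
            word = self.padded[i:i + k]
            if len(word) < k or not _ACGT.issuperset(word):
                continue
            kmers.setdefault(word, []).append(i)
        self.kmers = kmers
        if not kmers:
            logger.warning(
                "seed index for %r is empty (no unambiguous %d-mers)",
                query.id, k,
            )


def build_index(query: NamedSequence, k: int, pad: int | None = None) -> SeedIndex:
    """Build a SeedIndex (see class docstring)."""
    return SeedIndex(query, k, pad=pad)


def _make_aligner(preset: AlignPreset) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = preset.match
    aligner.mismatch_score = preset.mismatch
    # PairwiseAligner charges open_gap_score for the first gap column and
    # extend_gap_score for each further one; fold the convention
    # open + L*extend into that.
    aligner.open_gap_score = -(preset.gap_open + preset.gap_extend)
    aligner.extend_gap_score = -preset.gap_extend
    return aligner


def _seed_diagonals(read: str, index: SeedIndex) -> dict[int, int]:
    """Map diagonal (query_pos - read_pos, unwrapped coords) -> seed count."""
    k = index.k
    diags: dict[int, int] = {}
    for i in range(len(read) - k + 1):
        word = read[i:i + k]
        for p in index.kmers.get(word, ()):
            d = p - i
            diags[d] = diags.get(d, 0) + 1
    return diags


def _cluster_diagonals(diags: dict[int, int], band: int) -> list[tuple[int, int, int]]:
    """Group nearby diagonals; returns (d_min, d_max, seed_count) per cluster."""
    clusters: list[tuple[int, int, int]] = []
    for d in sorted(diags):
        if clusters and d - clusters[-1][1] <= band:
            dmin, _dmax, cnt = clusters[-1]
            clusters[-1] = (dmin, d, cnt + diags[d])
        else:
            clusters.append((d, d, diags[d]))
    clusters.sort(key=lambda c: -c[2])
    return clusters


_MAX_CLUSTERS = 50


def _circular_overlap(s0: int, l0: int, s1: int, l1: int, L: int) -> bool:
    """Do two intervals (start, length) on a circle of size L overlap?"""
    for shift in (-L, 0, L):
        if min(s0 + l0, s1 + l1 + shift) > max(s0, s1 + shift):
            return True
    return False


def _extend_cluster(read: str, index: SeedIndex, preset: AlignPreset,
                    aligner: Align.PairwiseAligner,
                    cluster: tuple[int, int, int]) -> dict | None:
    """Run windowed local alignment for one diagonal cluster; returns the
    alignment summary or None when below thresholds."""
    dmin, dmax, _count = cluster
    slack = preset.band + 8
    w0 = max(0, dmin - slack)
    w1 = min(len(index.padded), dmax + len(read) + slack)
    window = index.padded[w0:w1]
    if len(window) < preset.min_aln_len:
        return None
    alns = aligner.align(window, read)
    if alns.score <= 0:
        return None
    best = alns[0]
    t_blocks, q_blocks = best.aligned
    matches = mismatches = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for a, b in zip(window[ts:te], read[qs:qe]):
            if a == b:
                matches += 1
            else:
                mismatches += 1
    gap_columns = 0
    for i in range(1, len(t_blocks)):
        gap_columns += (t_blocks[i][0] - t_blocks[i - 1][1])
        gap_columns += (q_blocks[i][0] - q_blocks[i - 1][1])
    aln_len = matches + mismatches + gap_columns
    if aln_len == 0:
        return None
    identity = matches / aln_len
    if identity < preset.min_identity or aln_len < preset.min_aln_len:
        return None
    qstart_unwrapped = w0 + int(t_blocks[0][0])
    qend_unwrapped = w0 + int(t_blocks[-1][1])
    blocks = [(w0 + int(ts), w0 + int(te), int(qs), int(qe))
              for (ts, te), (qs, qe) in zip(t_blocks, q_blocks)]
    return {
        "score": float(alns.score),
        "matches": matches,
        "mismatches": mismatches,
        "gap_columns": gap_columns,
        "identity": identity,
        "q0": qstart_unwrapped,
        "q1": qend_unwrapped,
        "r0": int(q_blocks[0][0]),
        "r1": int(q_blocks[-1][1]),
        "blocks": blocks,
    }


def align_read(read: NamedSequence | tuple[str, str], index: SeedIndex,
               preset: AlignPreset) -> LocalAlignment | None:
    """Place one read; returns the best-scoring LocalAlignment meeting the
    preset thresholds, or None.

    Both orientations are tried. Candidates are deduplicated modulo the
    circle; a read whose best score is achieved at two distinct query loci
    is dropped as ambiguous (returns None). Ties at one locus break toward
    (leftmost query start, plus strand).
    """
    if isinstance(read, tuple):
        read_id, residues = read
    else:
        read_id, residues = read.id, read.residues
    if len(residues) < max(preset.min_aln_len, index.k):
        return None
    aligner = _make_aligner(preset)
    L = index.query_length
    candidates: list[tuple[str, dict]] = []
    for strand in ("+", "-"):
        oriented = residues if strand == "+" else reverse_complement(residues)
        diags = _seed_diagonals(oriented, index)
        if not diags:
            continue
        for cluster in _cluster_diagonals(diags, preset.band)[:_MAX_CLUSTERS]:
            hit = _extend_cluster(oriented, index, preset, aligner, cluster)
            if hit is not None:
                candidates.append((strand, hit))
    if not candidates:
        return None
    # Deduplicate placements that are the same locus modulo the circle or
    # overlapping windows that found the identical alignment.
    seen: dict[tuple[str, int, int], tuple[str, dict]] = {}
    for strand, hit in candidates:
        key = (strand, hit["q0"] % L, hit["q1"] % L if L else hit["q1"])
        prev = seen.get(key)
        if prev is None or hit["score"] > prev[1]["score"]:
            seen[key] = (strand, hit)
    uniq = list(seen.values())
    uniq.sort(key=lambda c: (-c[1]["score"], c[1]["q0"] % L, c[0] != "+"))
    best_strand, best = uniq[0]
    # ambiguity: equal best score at a second, non-overlapping query locus
    for _strand, hit in uniq[1:]:
        if hit["score"] < best["score"]:
            break
        if not _circular_overlap(best["q0"] % L, best["q1"] - best["q0"],
                                 hit["q0"] % L, hit["q1"] - hit["q0"], L):
            return None
    n_oriented = len(residues)
    if best_strand == "+":
        read_start, read_end = best["r0"], best["r1"]
    else:
        read_start, read_end = n_oriented - best["r1"], n_oriented - best["r0"]
    return LocalAlignment(
        read_id=read_id,
        strand=best_strand,
        query_start=best["q0"] % L,
        query_end=best["q1"] % L,
        read_start=read_start,
        read_end=read_end,
        matches=best["matches"],
        mismatches=best["mismatches"],
        gap_columns=best["gap_columns"],
        identity=best["identity"],
        score=best["score"],
        blocks=best["blocks"],
    )


def align_reads(reads: Iterable[tuple[str, str]], query: NamedSequence,
                preset: AlignPreset | str = "high",
                index: SeedIndex | None = None,
                ) -> tuple[list[LocalAlignment], dict]:
    """Align an in-memory read iterable; returns (alignments, summary)."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if index is None:
        index = build_index(query, preset.k)
    alignments: list[LocalAlignment] = []
    n_in = 0
    for rid, residues in reads:
        n_in += 1
        aln = align_read((rid, residues), index, preset)
        if aln is not None:
            alignments.append(aln)
    summary = {
        "reads_in": n_in,
        "aligned": len(alignments),
        "aligned_fraction": len(alignments) / n_in if n_in else 0.0,
        "preset": preset.name,
        "query_id": query.id,
    }
    return alignments, summary


def align_library(fastq_paths: Sequence[str], query: NamedSequence,
                  preset: AlignPreset | str = "high",
                  ) -> tuple[list[LocalAlignment], dict]:
    """Align every read of the given FASTQ files (mates treated as
    independent single-end reads) against the query."""

    def reads() -> Iterator[tuple[str, str]]:
        for p in fastq_paths:
            for rec in read_fastq(p):
                yield rec.id, rec.residues

    return align_reads(reads(), query, preset)


def write_alignments(alignments: Iterable[LocalAlignment], path: str) -> None:
    """Write alignments as TSV."""
    cols = ("read_id", "strand", "query_start", "query_end", "read_start",
            "read_end", "matches", "mismatches", "gaps", "identity", "score")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for a in alignments:
            fh.write(
                f"{a.read_id}\t{a.strand}\t{a.query_start}\t{a.query_end}\t"
                f"{a.read_start}\t{a.read_end}\t{a.matches}\t{a.mismatches}\t"
                f"{a.gap_columns}\t{a.identity:.4f}\t{a.score:g}\n"
            )
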