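"""Query-anchored pileup and per-site IUPAC consensus calling.

Every aligned read base (strand-normalized into query orientation) is
tallied per query position; the call at each position is N where nothing
aligned, the read base where reads agree (flipping the query base when
they disagree with it), and the IUPAC code for the observed base set when
reads disagree with each other. Output length always equals query length:
read insertions are skipped and deletions only increment a counter, so the
coordinate frame of the anchor is preserved throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import ConsistencyError
from .kalign import LocalAlignment
from .seqio import NamedSequence, code_for_bases, reverse_complement

_BASE_ORDER = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASE_ORDER)}

STATUS_MISSING = "missing"
STATUS_CONCORDANT = "concordant"
STATUS_SUBSTITUTED = "substituted"
STATUS_AMBIGUOUS = "ambiguous"


@dataclass
class PileupMatrix:
    """Per-query-position counts of read bases (A, C, G, T), deletions and
    depth (= A+C+G+T)."""

    query_id: str
    length: int
    counts: np.ndarray          # (length, 4) int
    deletions: np.ndarray       # (length,) int

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def site_counts(self, pos: int) -> dict[str, int]:
        return {b: int(self.counts[pos, i]) for b, i in _BASE_IDX.items()}


@dataclass(frozen=True)
class CallPolicy:
    """Explicit stand-in for manual judgement: depth and minor-allele
    thresholds for including a base in the call set."""

    min_depth_call: int = 1
    min_minor_count: int = 1
    min_minor_frac: float = 0.25
    max_alleles: int = 4

    def __post_init__(self) -> None:
        if self.min_depth_call < 1:
            raise ValueError("min_depth_call must be >= 1")
        if not 0.0 <= self.min_minor_frac <= 1.0:
            raise ValueError("min_minor_frac must be in [0, 1]")


@dataclass
class ConsensusCall:
    position: int
    call: str
    depth: int
    status: str


@dataclass
class ReconstructedGenome:
    """The anchored reconstruction: sequence, per-site calls, provenance."""

    sequence: NamedSequence
    calls: list[ConsensusCall]
    query_id: str
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)

    def tally(self) -> dict:
        """Length, N count/fraction, per-ambiguity-symbol counts and the
        number of substituted sites."""
        n = len(self.sequence)
        n_missing = sum(1 for c in self.calls if c.status == STATUS_MISSING)
        symbol_counts: dict[str, int] = {}
        for c in self.calls:
            if c.status == STATUS_AMBIGUOUS:
                symbol_counts[c.call] = symbol_counts.get(c.call, 0) + 1
        return {
            "length": n,
            "n_count": n_missing,
            "n_fraction": n_missing / n if n else 0.0,
            "ambiguity_counts": dict(sorted(symbol_counts.items())),
            "substituted": sum(1 for c in self.calls
                               if c.status == STATUS_SUBSTITUTED),
            "concordant": sum(1 for c in self.calls
                              if c.status == STATUS_CONCORDANT),
            "ambiguous": sum(1 for c in self.calls
                             if c.status == STATUS_AMBIGUOUS),
        }


def build_pileup(alignments: Iterable[LocalAlignment],
                 reads: Mapping[str, str],
                 query: NamedSequence) -> PileupMatrix:
    """Aggregate alignments into per-position base counts.

    Minus-strand reads are complemented into query orientation. Alignment
    blocks carry unwrapped query coordinates; positions wrap modulo the
    query length for circular queries. Read insertions relative to the
    query are skipped; read deletions increment the deletion counter.
    """
    L = len(query)
    counts = np.zeros((L, 4), dtype=np.int64)
    deletions = np.zeros(L, dtype=np.int64)
    for aln in alignments:
        try:
            raw = reads[aln.read_id]
        except KeyError:
            raise ConsistencyError(
                f"alignment references unknown read {aln.read_id!r}"
            ) from None
        oriented = raw if aln.strand == "+" else reverse_complement(raw)
        prev_qe: int | None = None
        for qs, qe, rs, re_ in aln.blocks:
            if prev_qe is not None and qs > prev_qe:
                # read gap: deleted query positions
                for p in range(prev_qe, qs):
                    deletions[p % L] += 1
            for off in range(qe - qs):
                base = oriented[rs + off]
                idx = _BASE_IDX.get(base)
                if idx is not None:  # ambiguous read bases are not counted
                    counts[(qs + off) % L, idx] += 1
            prev_qe = qe
    return PileupMatrix(query_id=query.id, length=L, counts=counts,
                        deletions=deletions)


def call_site(counts: Mapping[str, int], query_base: str,
              policy: CallPolicy = CallPolicy(), position: int = 0,
              ) -> ConsensusCall:
    """Call one site from its base counts.

    Depth below min_depth_call gives N/missing. The allele set is the
    bases passing both minor-allele filters (thresholds inclusive); a
    single allele is called directly (concordant when it equals the query
    base, substituted otherwise); two or more alleles yield the IUPAC code
    denoting exactly that set.
    """
    depth = sum(counts.get(b, 0) for b in _BASE_ORDER)
    if depth < policy.min_depth_call:
        return ConsensusCall(position=position, call="N", depth=depth,
                             status=STATUS_MISSING)
    alleles = [
        b for b in _BASE_ORDER
        if counts.get(b, 0) >= policy.min_minor_count
        and counts.get(b, 0) / depth >= policy.min_minor_frac
    ]
    if not alleles or len(alleles) > policy.max_alleles:
        return ConsensusCall(position=position, call="N", depth=depth,
                             status=STATUS_MISSING)
    if len(alleles) == 1:
        base = alleles[0]
        status = STATUS_CONCORDANT if base == query_base else STATUS_SUBSTITUTED
        return ConsensusCall(position=position, call=base, depth=depth,
                             status=status)
    code = code_for_bases(alleles)
    if code == "N":  # all four bases pass: indistinguishable from missing
        return ConsensusCall(position=position, call="N", depth=depth,
                             status=STATUS_MISSING)
    return ConsensusCall(position=position, call=code, depth=depth,
                         status=STATUS_AMBIGUOUS)


def reconstruct(pileup: PileupMatrix, query: NamedSequence,
                policy: CallPolicy = CallPolicy(),
                provenance: dict | None = None) -> ReconstructedGenome:
    """Apply call_site at every query position."""
    if pileup.length != len(query):
        raise ConsistencyError(
            f"pileup length {pileup.length} != query length {len(query)}"
        )
    calls: list[ConsensusCall] = []
    residues: list[str] = []
    for pos in range(pileup.length):
        call = call_site(pileup.site_counts(pos), query.residues[pos],
                         policy, position=pos)
        calls.append(call)
        residues.append(call.call)
    prov = {"query_id": query.id, "policy": {
        "min_depth_call": policy.min_depth_call,
        "min_minor_count": policy.min_minor_count,
        "min_minor_frac": policy.min_minor_frac,
        "max_alleles": policy.max_alleles,
    }}
    if provenance:
        prov.update(provenance)
    seq = NamedSequence(id=f"{query.id}_reconstruction",
                        residues="".join(residues), circular=query.circular)
    return ReconstructedGenome(sequence=seq, calls=calls, query_id=query.id,
                               provenance=prov)


def write_calls_tsv(recon: ReconstructedGenome, pileup: PileupMatrix,
                    query: NamedSequence, path: str) -> None:
    """Per-site call table: pos (1-based), query base, A/C/G/T/del counts,
    depth, call, status."""
    with open(path, "w") as fh:
        fh.write("pos\tquery_base\tA\tC\tG\tT\tdel\tdepth\tcall\tstatus\n")
        for c in recon.calls:
            p = c.position
            a, cc, g, t = (int(x) for x in pileup.counts[p])
            fh.write(
                f"{p + 1}\t{query.residues[p]}\t{a}\t{cc}\t{g}\t{t}\t"
                f"{int(pileup.deletions[p])}\t{c.depth}\t{c.call}\t{c.status}\n"
            )
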