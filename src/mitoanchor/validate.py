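"""Robustness checks: completeness reporting and query-independence.

A reconstruction that depends on which related genome anchored it would be
suspect; `query_independence` reconstructs the same read set against two or
more queries and compares the calls over sites recovered in all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .consensus import (
    STATUS_MISSING,
    CallPolicy,
    ReconstructedGenome,
    build_pileup,
    reconstruct,
)
from .errors import ParameterError
from .kalign import AlignPreset, align_reads
from .seqio import NamedSequence


def completeness_report(reconstruction: ReconstructedGenome) -> dict:
    """Length, N count and percent (1 decimal), per-ambiguity-symbol
    counts, substituted count, and mean depth over non-N sites."""
    tally = reconstruction.tally()
    covered_depths = [c.depth for c in reconstruction.calls
                      if c.status != STATUS_MISSING]
    mean_depth = (sum(covered_depths) / len(covered_depths)
                  if covered_depths else 0.0)
    return {
        "length": tally["length"],
        "n_count": tally["n_count"],
        "n_percent": round(100.0 * tally["n_fraction"], 1),
        "ambiguity_counts": tally["ambiguity_counts"],
        "substituted": tally["substituted"],
        "mean_depth_non_n": mean_depth,
    }


@dataclass
class DiscordanceReport:
    """Outcome of the query-independence check."""

    status: str                     # "pass" | "fail" | "insufficient_overlap"
    n_queries: int
    n_cocalled: int
    n_discordant: int
    n_discordant_unambiguous: int
    discordant_positions: list[int] = field(default_factory=list)
    per_query_calls: dict[int, list[str]] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return self.status == "pass"

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "n_queries": self.n_queries,
            "n_cocalled": self.n_cocalled,
            "n_discordant": self.n_discordant,
            "n_discordant_unambiguous": self.n_discordant_unambiguous,
            "discordant_positions": self.discordant_positions,
        }


def _query_position_map(ref: NamedSequence, other: NamedSequence) -> dict[int, int]:
    """Map positions of `other` onto `ref` via a global pairwise alignment;
    indel columns are absent from the map."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    best = aligner.align(ref.residues, other.residues)[0]
    ref_blocks, other_blocks = best.aligned
    mapping: dict[int, int] = {}
    for (rs, re_), (os_, oe) in zip(ref_blocks, other_blocks):
        for off in range(re_ - rs):
            mapping[os_ + off] = rs + off
    return mapping


def reconstruct_with_query(reads: list[tuple[str, str]], query: NamedSequence,
                           preset: AlignPreset | str = "high",
                           policy: CallPolicy = CallPolicy(),
                           ) -> ReconstructedGenome:
    """Align reads to the query and call the consensus (one-stop helper)."""
    alignments, summary = align_reads(reads, query, preset)
    pileup = build_pileup(alignments, dict(reads), query)
    return reconstruct(pileup, query, policy,
                       provenance={"align_summary": summary})


def query_independence(reads: list[tuple[str, str]],
                       queries: list[NamedSequence],
                       preset: AlignPreset | str = "high",
                       policy: CallPolicy = CallPolicy(),
                       min_cocalled: int = 1) -> DiscordanceReport:
    """Reconstruct once per query and compare calls over sites called
    (non-N) in every reconstruction.

    Queries of unequal length are reconciled onto the first query's frame
    by a global pairwise alignment of the queries themselves; indel columns
    are excluded. Full IUPAC symbols are compared; a second tally restricted
    to sites unambiguous in all reconstructions is also reported.
    """
    if len(queries) < 2:
        raise ParameterError("query_independence needs at least two queries")
    recons = [reconstruct_with_query(reads, q, preset, policy) for q in queries]

    ref = queries[0]
    # per reconstruction: map from ref position -> called symbol
    call_maps: list[dict[int, str]] = []
    for q, recon in zip(queries, recons):
        if len(q) == len(ref):
            pos_map = {i: i for i in range(len(q))}
        else:
            pos_map = _query_position_map(ref, q)
        cm = {
            pos_map[c.position]: c.call
            for c in recon.calls
            if c.status != STATUS_MISSING and c.position in pos_map
        }
        call_maps.append(cm)

    common = set(call_maps[0])
    for cm in call_maps[1:]:
        common &= set(cm)
    n_cocalled = len(common)
    if n_cocalled < min_cocalled:
        return DiscordanceReport(status="insufficient_overlap",
                                 n_queries=len(queries),
                                 n_cocalled=n_cocalled, n_discordant=0,
                                 n_discordant_unambiguous=0)
    discordant: list[int] = []
    discordant_unambig = 0
    per_query: dict[int, list[str]] = {}
    for pos in sorted(common):
        calls = [cm[pos] for cm in call_maps]
        if len(set(calls)) > 1:
            discordant.append(pos)
            per_query[pos] = calls
            if all(c in "ACGT" for c in calls):
                discordant_unambig += 1
    status = "pass" if not discordant else "fail"
    return DiscordanceReport(
        status=status,
        n_queries=len(queries),
        n_cocalled=n_cocalled,
        n_discordant=len(discordant),
        n_discordant_unambiguous=discordant_unambig,
        discordant_positions=discordant,
        per_query_calls=per_query,
    )


def write_discordance_tsv(report: DiscordanceReport, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("position\t" + "\t".join(
            f"query{i}" for i in range(report.n_queries)) + "\n")
        for pos in report.discordant_positions:
            calls = report.per_query_calls.get(pos, [])
            fh.write(f"{pos + 1}\t" + "\t".join(calls) + "\n")
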