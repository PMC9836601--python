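"""Deamination signature statistics from a reconstruction's ambiguity calls.

Hydrolytic deamination of cytosine reads out as C->T (and as G->A via the
opposite strand), so a damaged library produces an excess of C/T ambiguity
calls at query-C sites and A/G calls at query-G sites over every other
two-or-more-base call. This module tabulates that matrix and tests the
excess against a symmetric-noise null.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import binomtest

from .consensus import STATUS_AMBIGUOUS, ReconstructedGenome
from .errors import ConsistencyError
from .seqio import NamedSequence

_QUERY_BASES = ("A", "C", "G", "T", "N")
#: every multi-base IUPAC symbol
_AMBIG_CODES = ("R", "Y", "S", "W", "K", "M", "B", "D", "H", "V")


@dataclass
class AmbiguitySummary:
    """Counts of ambiguous calls indexed by (query base, call symbol)."""

    matrix: pd.DataFrame  # rows: query base A/C/G/T/N; cols: ambiguity codes

    def cell(self, query_base: str, code: str) -> int:
        return int(self.matrix.at[query_base, code])

    @property
    def total(self) -> int:
        return int(self.matrix.to_numpy().sum())

    def to_tsv(self, path: str) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="query_base")


@dataclass
class DamageReport:
    """Deamination-consistency statistic.

    n_consistent counts Y calls at query-C plus R calls at query-G sites
    (the two classes deamination produces); n_other counts every other
    ambiguous call. The binomial test compares n_consistent against the
    ambiguous calls at C/G query sites under a null proportion of 1/3
    (three two-base codes contain C, of which deamination explains one;
    likewise for G).
    """

    n_consistent: int
    n_other: int
    asymmetry_ratio: float
    binom_p: float
    pseudocount: float
    n_cg_ambiguous: int
    null_proportion: float

    def to_dict(self) -> dict:
        return {
            "n_consistent": self.n_consistent,
            "n_other": self.n_other,
            "asymmetry_ratio": self.asymmetry_ratio,
            "binom_p": self.binom_p,
            "pseudocount": self.pseudocount,
            "n_cg_ambiguous": self.n_cg_ambiguous,
            "null_proportion": self.null_proportion,
        }

    def to_text(self) -> str:
        lines = [
            "Deamination signature",
            "---------------------",
            f"consistent calls (Y at C + R at G): {self.n_consistent}",
            f"other ambiguous calls:              {self.n_other}",
            f"asymmetry ratio (pseudocount {self.pseudocount:g}):  "
            f"{self.asymmetry_ratio:.3f}",
            f"one-sided binomial p (null {self.null_proportion:.3f}, "
            f"n={self.n_cg_ambiguous}): {self.binom_p:.3g}",
        ]
        return "\n".join(lines)


def summarize_ambiguities(reconstruction: ReconstructedGenome,
                          query: NamedSequence) -> AmbiguitySummary:
    """Classify every ambiguous call by the query base beneath it."""
    if len(reconstruction) != len(query):
        raise ConsistencyError(
            f"reconstruction length {len(reconstruction)} != query length "
            f"{len(query)}"
        )
    matrix = pd.DataFrame(0, index=list(_QUERY_BASES), columns=list(_AMBIG_CODES))
    for call in reconstruction.calls:
        if call.status != STATUS_AMBIGUOUS:
            continue
        qb = query.residues[call.position]
        if qb not in _QUERY_BASES:
            qb = "N"  # fold rare query ambiguity codes into N
        matrix.at[qb, call.call] += 1
    return AmbiguitySummary(matrix=matrix)


def deamination_asymmetry(summary: AmbiguitySummary, pseudocount: float = 1.0,
                          null_proportion: float = 1.0 / 3.0) -> DamageReport:
    """Compute the consistency ratio and exact one-sided binomial test."""
    n_consistent = summary.cell("C", "Y") + summary.cell("G", "R")
    n_other = summary.total - n_consistent
    ratio = n_consistent / (n_other + pseudocount)
    n_cg = int(summary.matrix.loc[["C", "G"]].to_numpy().sum())
    if n_cg > 0:
        binom_p = binomtest(n_consistent, n_cg, null_proportion,
                            alternative="greater").pvalue
    else:
        binom_p = 1.0
    return DamageReport(
        n_consistent=n_consistent,
        n_other=n_other,
        asymmetry_ratio=ratio,
        binom_p=float(binom_p),
        pseudocount=pseudocount,
        n_cg_ambiguous=n_cg,
        null_proportion=null_proportion,
    )
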