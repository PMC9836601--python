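"""Annotation transfer onto the reconstruction and per-feature recovery.

Because the consensus is anchored to the query's coordinate frame (output
length equals query length by contract), liftover is the identity map on
coordinates; the value added here is the per-feature recovery report: how
much of each gene is missing (N), how much carries ambiguity codes, and
whether a feature is entirely unrecovered.
"""

from __future__ import annotations

import pandas as pd

from .consensus import ReconstructedGenome
from .errors import ConsistencyError
from .seqio import Annotation, NamedSequence, reverse_complement

_AMBIG = set("RYSWKMBDHV")


def liftover_annotation(query_annotation: Annotation,
                        reconstruction: ReconstructedGenome) -> Annotation:
    """Copy features, coordinates and strands unchanged onto the
    reconstruction's id (valid by the equal-length contract)."""
    if query_annotation.genome_length != len(reconstruction):
        raise ConsistencyError(
            f"annotation genome length {query_annotation.genome_length} != "
            f"reconstruction length {len(reconstruction)}"
        )
    return Annotation(
        genome_id=reconstruction.sequence.id,
        genome_length=query_annotation.genome_length,
        features=list(query_annotation.features),
    )


def feature_missingness(reconstruction: ReconstructedGenome,
                        annotation: Annotation) -> pd.DataFrame:
    """Per-feature recovery: length, N count, %N, ambiguity count and a
    fully_missing flag; a genome-wide roll-up row named '*genome*' last.

    Ambiguity codes count as recovered sequence.
    """
    if annotation.genome_length != len(reconstruction):
        raise ConsistencyError(
            f"annotation genome length {annotation.genome_length} != "
            f"reconstruction length {len(reconstruction)}"
        )
    seq = reconstruction.sequence.residues
    rows = []
    for f in annotation.features:
        sub = seq[f.start:f.end]
        n_count = sub.count("N")
        length = len(sub)
        rows.append({
            "name": f.name,
            "type": f.ftype,
            "strand": f.strand,
            "start": f.start,
            "end": f.end,
            "length": length,
            "n_count": n_count,
            "pct_n": 100.0 * n_count / length if length else 0.0,
            "ambiguous_count": sum(1 for ch in sub if ch in _AMBIG),
            "fully_missing": n_count == length,
        })
    total_n = seq.count("N")
    rows.append({
        "name": "*genome*",
        "type": "genome",
        "strand": "+",
        "start": 0,
        "end": len(seq),
        "length": len(seq),
        "n_count": total_n,
        "pct_n": 100.0 * total_n / len(seq) if seq else 0.0,
        "ambiguous_count": sum(1 for ch in seq if ch in _AMBIG),
        "fully_missing": total_n == len(seq),
    })
    return pd.DataFrame(rows)


def extract_feature_sequences(reconstruction: ReconstructedGenome,
                              annotation: Annotation) -> list[NamedSequence]:
    """Per-feature sequences; minus-strand features reverse-complemented."""
    seq = reconstruction.sequence.residues
    out: list[NamedSequence] = []
    for f in annotation.features:
        sub = seq[f.start:f.end]
        if f.strand == "-":
            sub = reverse_complement(sub)
        out.append(NamedSequence(id=f.name, residues=sub))
    return out
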