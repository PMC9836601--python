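"""Packaged fixtures."""

from importlib.resources import files

from ..seqio import Annotation, read_annotation


def vertebrate_annotation() -> Annotation:
    """The canonical vertebrate mitogenome feature layout: 13 CDS, 22 tRNA
    (8 on the minus strand), 2 rRNA and one control region."""
    path = files(__package__).joinpath("vertebrate_mito_annotation.tsv")
    return read_annotation(str(path))
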