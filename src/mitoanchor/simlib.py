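"""Synthetic degraded shotgun libraries and diverged anchor genomes.

Emulates the data regime of low-coverage historical specimens: short
inserts sampled uniformly from a circular template, terminal cytosine
deamination (C->T on each physical strand, appearing as G->A when the
minus strand is read in plus orientation), a small endogenous fraction
diluted in background reads, and uniform sequencing error. Every fragment
carries a truth record so downstream accuracy is measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import ParameterError
from .seqio import NamedSequence, reverse_complement, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
#: transition partner per base index (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1])
#: the two transversion partners per base index
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


@dataclass(frozen=True)
class DamageParams:
    """Positional cytosine-deamination model.

    A cytosine at distance ``i`` from its strand's 5' end converts to
    thymine with probability ``d_max * decay**i + floor``.
    """

    d_max: float = 0.0
    decay: float = 0.5
    floor: float = 0.0

    def __post_init__(self) -> None:
        for name in ("d_max", "decay", "floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.d_max < self.floor:
            raise ParameterError("d_max must be >= floor")

    @property
    def enabled(self) -> bool:
        return self.d_max > 0 or self.floor > 0

    def rate(self, i: np.ndarray | int) -> np.ndarray | float:
        return np.minimum(self.d_max * self.decay ** i + self.floor, 1.0)


@dataclass(frozen=True)
class LibraryParams:
    """Shotgun library shape: pair count, read length, insert distribution,
    endogenous fraction, per-base error, seed."""

    n_pairs: int
    read_len: int = 150
    insert_mean: float = 150.0
    insert_sd: float = 30.0
    endogenous_fraction: float = 1.0
    seq_error: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise ParameterError("n_pairs must be >= 0")
        if self.read_len < 30:
            raise ParameterError("read_len must be >= 30")
        if not 0.0 <= self.endogenous_fraction <= 1.0:
            raise ParameterError("endogenous_fraction must be in [0, 1]")
        if not 0.0 <= self.seq_error < 1.0:
            raise ParameterError("seq_error must be in [0, 1)")
        if self.insert_mean <= 0:
            raise ParameterError("insert_mean must be positive")


@dataclass
class TruthRecord:
    """Provenance of one simulated fragment/read pair."""

    pair_id: str
    source: str            # "mito" | "background"
    start: int             # 0-based on the source circle
    end: int               # exclusive; may exceed source length when wrapped
    strand: str            # strand read 1 was sequenced from
    damaged_positions: list[int] = field(default_factory=list)  # fragment-relative

    @property
    def insert_len(self) -> int:
        return self.end - self.start


@dataclass
class Fragment:
    """A double-stranded insert represented on the template plus strand."""

    residues: str
    truth: TruthRecord


def _seq_to_array(residues: str) -> np.ndarray:
    return np.frombuffer(residues.encode(), dtype=np.uint8)


def _array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def mutate_genome(genome: NamedSequence, divergence: float,
                  ts_tv_ratio: float = 2.0,
                  seed: int | np.random.Generator = 0) -> NamedSequence:
    """Apply i.i.d. substitutions (no indels) at rate `divergence`.

    Transitions are favored so that the expected transition:transversion
    count ratio equals `ts_tv_ratio`.
    """
    if not 0.0 <= divergence <= 0.25:
        raise ParameterError(f"divergence must be in [0, 0.25], got {divergence}")
    if ts_tv_ratio <= 0:
        raise ParameterError("ts_tv_ratio must be positive")
    rng = np.random.default_rng(seed)
    arr = _seq_to_array(genome.residues).copy()
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        codes[arr == ord(b)] = i
    mutable = codes >= 0  # ambiguity codes in the template are left alone
    hit = mutable & (rng.random(arr.shape) < divergence)
    idx = np.nonzero(hit)[0]
    if idx.size:
        old = codes[idx]
        is_ts = rng.random(idx.size) < ts_tv_ratio / (ts_tv_ratio + 1.0)
        tv_pick = rng.integers(0, 2, size=idx.size)
        new = np.where(is_ts, _TRANSITION[old],
                       _TRANSVERSIONS[old, tv_pick])
        arr[idx] = _BASES[new]
    return NamedSequence(id=f"{genome.id}_div{divergence:g}",
                         residues=_array_to_seq(arr), circular=genome.circular)


def _draw_insert_lengths(n: int, params: LibraryParams,
                         rng: np.random.Generator) -> np.ndarray:
    """Normal insert sizes truncated to [30, 2*insert_mean] by redraw."""
    lo, hi = 30, max(31, int(round(2 * params.insert_mean)))
    out = np.rint(rng.normal(params.insert_mean, params.insert_sd, size=n)).astype(int)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = np.rint(
            rng.normal(params.insert_mean, params.insert_sd, size=int(bad.sum()))
        ).astype(int)
        bad = (out < lo) | (out > hi)
    return out


def simulate_fragments(genome: NamedSequence, params: LibraryParams,
                       rng: np.random.Generator, n: int | None = None,
                       source: str = "mito",
                       id_prefix: str = "frag") -> list[Fragment]:
    """Sample `n` fragments uniformly from the circular template.

    Start positions are uniform on the circle; fragments crossing the
    origin wrap; the read-1 strand is uniform.
    """
    if params.insert_mean < params.read_len / 2:
        raise ParameterError("insert_mean must be >= read_len / 2")
    n = params.n_pairs if n is None else n
    L = len(genome)
    starts = rng.integers(0, L, size=n)
    lengths = _draw_insert_lengths(n, params, rng)
    strands = np.where(rng.integers(0, 2, size=n) == 0, "+", "-")
    frags: list[Fragment] = []
    for j in range(n):
        s, ln = int(starts[j]), int(lengths[j])
        residues = genome.slice_circular(s, ln)
        truth = TruthRecord(pair_id=f"{id_prefix}{j:06d}", source=source,
                            start=s, end=s + ln, strand=str(strands[j]))
        frags.append(Fragment(residues=residues, truth=truth))
    return frags


def apply_damage(fragment: Fragment, damage: DamageParams,
                 rng: np.random.Generator) -> Fragment:
    """Deaminate cytosines on both physical strands of the insert.

    On the plus-strand representation: a C at position ``i`` converts to T
    with probability rate(i) (plus-strand 5' end at 0); a G at position
    ``j`` converts to A with probability rate(L-1-j) (minus-strand C whose
    5' distance is L-1-j). No other bases change. Damaged positions are
    recorded in the fragment's truth record (plus-strand coordinates).
    """
    if not damage.enabled:
        return fragment
    arr = _seq_to_array(fragment.residues).copy()
    L = arr.size
    pos = np.arange(L)
    u = rng.random(L)
    c_hit = (arr == ord("C")) & (u < damage.rate(pos))
    u2 = rng.random(L)
    g_hit = (arr == ord("G")) & (u2 < damage.rate(L - 1 - pos))
    arr[c_hit] = ord("T")
    arr[g_hit] = ord("A")
    damaged = sorted(np.nonzero(c_hit | g_hit)[0].tolist())
    fragment.residues = _array_to_seq(arr)
    fragment.truth.damaged_positions = [int(p) for p in damaged]
    return fragment


def _apply_seq_error(read: str, p: float, rng: np.random.Generator) -> str:
    if p <= 0 or not read:
        return read
    arr = _seq_to_array(read).copy()
    hit = np.nonzero(rng.random(arr.size) < p)[0]
    for i in hit:
        cur = chr(arr[i])
        choices = [b for b in "ACGT" if b != cur]
        arr[i] = ord(choices[rng.integers(0, len(choices))])
    return _array_to_seq(arr)


def fragment_to_reads(fragment: Fragment, read_len: int) -> tuple[str, str]:
    """Sequence both ends of an insert. Read 1 starts at the 5' end of the
    truth strand; read 2 at the 5' end of the opposite strand. Inserts
    shorter than read_len read through to the insert length (no adapter)."""
    f = fragment.residues
    n = min(read_len, len(f))
    if fragment.truth.strand == "+":
        r1 = f[:n]
        r2 = reverse_complement(f)[:n]
    else:
        r1 = reverse_complement(f)[:n]
        r2 = f[:n]
    return r1, r2


def simulate_library(mito_genome: NamedSequence,
                     background_genome: NamedSequence | None,
                     lib_params: LibraryParams,
                     damage_params: DamageParams | None = None,
                     ) -> tuple[list[tuple[str, str]], list[tuple[str, str]], list[TruthRecord]]:
    """Generate a paired-end library.

    Each pair is drawn from the mitogenome with probability
    ``endogenous_fraction`` and otherwise from the background genome
    (an i.i.d. random circle is synthesized when none is given). Damage is
    applied per insert, then each end is sequenced and per-base error
    applied. Fully deterministic under ``lib_params.seed``.

    Returns (reads_1, reads_2, truth) where reads_* are (id, residues).
    """
    damage_params = damage_params or DamageParams()
    rng = np.random.default_rng(lib_params.seed)
    if background_genome is None:
        bg_len = max(4 * len(mito_genome), 2 * lib_params.read_len)
        bg = _array_to_seq(_BASES[rng.integers(0, 4, size=bg_len)])
        background_genome = NamedSequence(id="background_random", residues=bg,
                                          circular=True)

    n = lib_params.n_pairs
    is_mito = rng.random(n) < lib_params.endogenous_fraction
    reads1: list[tuple[str, str]] = []
    reads2: list[tuple[str, str]] = []
    truths: list[TruthRecord] = []
    lengths = _draw_insert_lengths(n, lib_params, rng) if n else np.empty(0, int)
    for j in range(n):
        source = "mito" if is_mito[j] else "background"
        genome = mito_genome if is_mito[j] else background_genome
        start = int(rng.integers(0, len(genome)))
        ln = int(lengths[j])
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        pair_id = f"pair{j:06d}"
        frag = Fragment(residues=genome.slice_circular(start, ln),
                        truth=TruthRecord(pair_id=pair_id, source=source,
                                          start=start, end=start + ln,
                                          strand=strand))
        frag = apply_damage(frag, damage_params, rng)
        r1, r2 = fragment_to_reads(frag, lib_params.read_len)
        r1 = _apply_seq_error(r1, lib_params.seq_error, rng)
        r2 = _apply_seq_error(r2, lib_params.seq_error, rng)
        reads1.append((f"{pair_id}/1", r1))
        reads2.append((f"{pair_id}/2", r2))
        truths.append(frag.truth)
    return reads1, reads2, truths


def write_library(reads1: Iterable[tuple[str, str]],
                  reads2: Iterable[tuple[str, str]],
                  truths: Iterable[TruthRecord],
                  out_prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write paired FASTQ files (_1/_2) and the truth table TSV."""
    out_prefix = Path(out_prefix)
    fq1 = out_prefix.parent / (out_prefix.name + "_1.fastq")
    fq2 = out_prefix.parent / (out_prefix.name + "_2.fastq")
    tt = out_prefix.parent / (out_prefix.name + "_truth.tsv")
    write_fastq(reads1, fq1)
    write_fastq(reads2, fq2)
    with open(tt, "w") as fh:
        fh.write("pair_id\tsource\tstart\tend\tstrand\tdamaged_positions\n")
        for t in truths:
            dmg = ",".join(map(str, t.damaged_positions))
            fh.write(f"{t.pair_id}\t{t.source}\t{t.start}\t{t.end}\t{t.strand}\t{dmg}\n")
    return fq1, fq2, tt


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    """Load a truth table written by write_library."""
    out: list[TruthRecord] = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("pair_id")
        for line in fh:
            pid, src, s, e, strand, dmg = line.rstrip("\n").split("\t")
            positions = [int(x) for x in dmg.split(",")] if dmg else []
            out.append(TruthRecord(pair_id=pid, source=src, start=int(s),
                                   end=int(e), strand=strand,
                                   damaged_positions=positions))
    return out


def random_genome(length: int, seed: int | np.random.Generator = 0,
                  gc: float = 0.45, circular: bool = True,
                  id: str = "truth") -> NamedSequence:
    """An i.i.d. random genome with the given GC content."""
    if length <= 0:
        raise ParameterError("length must be positive")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = _BASES[rng.choice(4, size=length, p=p)]
    return NamedSequence(id=id, residues=_array_to_seq(arr), circular=circular)
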