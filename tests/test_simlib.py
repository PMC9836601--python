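import numpy as np
import pytest
from scipy import stats

from mitoanchor.errors import ParameterError
from mitoanchor.seqio import reverse_complement
from mitoanchor.simlib import (
    DamageParams,
    Fragment,
    LibraryParams,
    TruthRecord,
    apply_damage,
    fragment_to_reads,
    mutate_genome,
    random_genome,
    read_truth_table,
    simulate_fragments,
    simulate_library,
    write_library,
)


def identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestMutateGenome:
    def test_zero_divergence_identity(self, truth_genome):
        out = mutate_genome(truth_genome, 0.0, seed=1)
        assert out.residues == truth_genome.residues

    def test_divergence_out_of_range(self, truth_genome):
        with pytest.raises(ParameterError):
            mutate_genome(truth_genome, 0.3, seed=1)

    def test_realized_identity_within_binomial_ci(self):
        g = random_genome(16000, seed=7)
        out = mutate_genome(g, 0.05, seed=8)
        mismatches = sum(a != b for a, b in zip(g.residues, out.residues))
        lo, hi = stats.binom.interval(0.95, 16000, 0.05)
        assert lo <= mismatches <= hi

    def test_identity_in_congeneric_band(self):
        # 5% divergence lands in the ~94.6-96.5% identity band typical of
        # congeneric mitogenome comparisons
        g = random_genome(16000, seed=9)
        out = mutate_genome(g, 0.05, seed=10)
        assert 0.946 <= identity(g.residues, out.residues) <= 0.965

    def test_transitions_favored(self):
        g = random_genome(50000, seed=11)
        out = mutate_genome(g, 0.1, ts_tv_ratio=2.0, seed=12)
        ts = tv = 0
        pairs = {frozenset("AG"), frozenset("CT")}
        for a, b in zip(g.residues, out.residues):
            if a != b:
                if frozenset((a, b)) in pairs:
                    ts += 1
                else:
                    tv += 1
        # expected ratio 2; binomial noise on ~5000 events is small
        assert 1.7 < ts / tv < 2.3

    def test_no_indels(self, truth_genome):
        out = mutate_genome(truth_genome, 0.1, seed=13)
        assert len(out) == len(truth_genome)


class TestSimulateFragments:
    def test_deterministic_under_seed(self, truth_genome):
        params = LibraryParams(n_pairs=50, read_len=60, insert_mean=90,
                               insert_sd=15, seed=4)
        a = simulate_fragments(truth_genome, params,
                               np.random.default_rng(4))
        b = simulate_fragments(truth_genome, params,
                               np.random.default_rng(4))
        assert [f.residues for f in a] == [f.residues for f in b]
        assert [f.truth.start for f in a] == [f.truth.start for f in b]

    def test_origin_spanning_fraction(self):
        g = random_genome(16000, seed=20)
        params = LibraryParams(n_pairs=10000, read_len=60, insert_mean=100,
                               insert_sd=1, seed=5)
        frags = simulate_fragments(g, params, np.random.default_rng(5),
                                   n=10000)
        spanning = sum(1 for f in frags if f.truth.end > 16000)
        expected = 10000 * 100 / 16000  # ~insert_mean / L per fragment
        sd = np.sqrt(expected)
        assert abs(spanning - expected) < 4 * sd

    def test_mean_insert_length(self, truth_genome):
        params = LibraryParams(n_pairs=5000, read_len=60, insert_mean=120,
                               insert_sd=20, seed=6)
        frags = simulate_fragments(truth_genome, params,
                                   np.random.default_rng(6), n=5000)
        mean = np.mean([f.truth.insert_len for f in frags])
        assert abs(mean - 120) < 2

    def test_wrapped_fragment_sequence_matches_circle(self, truth_genome):
        params = LibraryParams(n_pairs=200, read_len=60, insert_mean=90,
                               insert_sd=15, seed=7)
        doubled = truth_genome.residues * 2
        for f in simulate_fragments(truth_genome, params,
                                    np.random.default_rng(7), n=200):
            assert f.residues == doubled[f.truth.start:f.truth.end]

    def test_insert_mean_too_small(self, truth_genome):
        params = LibraryParams(n_pairs=1, read_len=100, insert_mean=40,
                               insert_sd=5, seed=1)
        with pytest.raises(ParameterError):
            simulate_fragments(truth_genome, params, np.random.default_rng(1))


class TestApplyDamage:
    def _frag(self, residues):
        return Fragment(residues=residues,
                        truth=TruthRecord(pair_id="p0", source="mito",
                                          start=0, end=len(residues),
                                          strand="+"))

    def test_no_damage_no_change(self, rng):
        f = self._frag("ACGTCCGG")
        out = apply_damage(f, DamageParams(d_max=0.0, floor=0.0), rng)
        assert out.residues == "ACGTCCGG"

    def test_saturating_damage_converts_every_c_and_g(self, rng):
        f = self._frag("ACGTCCGG")
        out = apply_damage(f, DamageParams(d_max=1.0, decay=1.0, floor=1.0),
                           rng)
        assert out.residues == "ATATTTAA".replace("T", "T")  # C->T, G->A
        assert out.residues == "ATATTTAA"

    def test_positional_profile(self):
        # C->T frequency at 5' position 0 ~ d_max, halving per position
        rng = np.random.default_rng(30)
        d = DamageParams(d_max=0.3, decay=0.5, floor=0.0)
        n = 100_000
        converted = np.zeros(4)
        for _ in range(n):
            f = self._frag("CCCC" + "A" * 20)  # Gs absent: isolate 5' Cs
            out = apply_damage(f, d, rng)
            for i in range(4):
                if out.residues[i] == "T":
                    converted[i] += 1
        freqs = converted / n
        for i, expected in enumerate([0.3, 0.15, 0.075, 0.0375]):
            assert abs(freqs[i] - expected) < 0.01

    def test_damage_asymmetry_classes(self, rng):
        # only C->T and G->A ever occur
        f = self._frag("ACGT" * 50)
        out = apply_damage(f, DamageParams(d_max=0.5, decay=0.9, floor=0.1),
                           rng)
        for a, b in zip("ACGT" * 50, out.residues):
            if a != b:
                assert (a, b) in {("C", "T"), ("G", "A")}

    def test_damaged_positions_recorded(self, rng):
        f = self._frag("CCCCCCCC")
        out = apply_damage(f, DamageParams(d_max=1.0, decay=1.0, floor=1.0),
                           rng)
        assert out.truth.damaged_positions == list(range(8))

    def test_d_max_below_floor_rejected(self):
        with pytest.raises(ParameterError):
            DamageParams(d_max=0.1, floor=0.2)


class TestSimulateLibrary:
    def test_endogenous_fraction_binomial(self):
        mito = random_genome(2000, seed=40)
        lib = LibraryParams(n_pairs=20000, read_len=50, insert_mean=80,
                            insert_sd=10, endogenous_fraction=0.002, seed=41)
        _, _, truths = simulate_library(mito, None, lib)
        n_mito = sum(1 for t in truths if t.source == "mito")
        expected = 20000 * 0.002
        sd = np.sqrt(20000 * 0.002 * 0.998)
        assert abs(n_mito - expected) <= 3 * sd

    def test_clean_reads_exact_substrings(self, truth_genome):
        lib = LibraryParams(n_pairs=100, read_len=60, insert_mean=90,
                            insert_sd=15, seed=42)
        r1, r2, truths = simulate_library(truth_genome, None, lib)
        doubled = truth_genome.residues * 2
        for (rid, seq), t in zip(r1, truths):
            frag = doubled[t.start:t.end]
            expected = frag if t.strand == "+" else reverse_complement(frag)
            assert seq == expected[:60]
        for (rid, seq), t in zip(r2, truths):
            frag = doubled[t.start:t.end]
            expected = reverse_complement(frag) if t.strand == "+" else frag
            assert seq == expected[:60]

    def test_expected_depth_matches_truth_table(self, truth_genome):
        lib = LibraryParams(n_pairs=1000, read_len=60, insert_mean=90,
                            insert_sd=15, seed=43)
        _, _, truths = simulate_library(truth_genome, None, lib)
        n_mito = sum(1 for t in truths if t.source == "mito")
        bases = sum(2 * min(60, t.insert_len) for t in truths)
        depth = bases / len(truth_genome)
        expected = n_mito * 2 * 60 / len(truth_genome)
        assert abs(depth - expected) / expected < 0.05

    def test_empty_library_valid(self, truth_genome):
        lib = LibraryParams(n_pairs=0, read_len=50, insert_mean=80, seed=1)
        r1, r2, truths = simulate_library(truth_genome, None, lib)
        assert r1 == [] and r2 == [] and truths == []

    def test_full_determinism(self, truth_genome):
        lib = LibraryParams(n_pairs=50, read_len=60, insert_mean=90,
                            insert_sd=15, seq_error=0.01, seed=44)
        dmg = DamageParams(d_max=0.3, decay=0.5, floor=0.01)
        a = simulate_library(truth_genome, None, lib, dmg)
        b = simulate_library(truth_genome, None, lib, dmg)
        assert a == b

    def test_truth_table_round_trip(self, truth_genome, tmp_path):
        lib = LibraryParams(n_pairs=30, read_len=60, insert_mean=90,
                            insert_sd=15, seed=45)
        dmg = DamageParams(d_max=0.5, decay=0.5, floor=0.05)
        r1, r2, truths = simulate_library(truth_genome, None, lib, dmg)
        fq1, fq2, tt = write_library(r1, r2, truths, tmp_path / "lib")
        back = read_truth_table(tt)
        assert back == truths

    def test_mismatch_classes_symmetric_without_damage(self, truth_genome):
        # with damage off and sequencing error on, no mismatch class
        # dominates; with damage on, C->T + G->A dominate
        lib = LibraryParams(n_pairs=400, read_len=60, insert_mean=90,
                            insert_sd=15, seq_error=0.02, seed=46)
        classes = self._mismatch_classes(truth_genome, lib, DamageParams())
        ct_ga = classes[("C", "T")] + classes[("G", "A")]
        total = sum(classes.values())
        assert total > 100
        # 12 classes; the damage pair should be ~2/12 of mismatches
        assert ct_ga / total < 0.3

        dmg = DamageParams(d_max=0.5, decay=0.5, floor=0.05)
        lib2 = LibraryParams(n_pairs=400, read_len=60, insert_mean=90,
                             insert_sd=15, seq_error=0.0, seed=47)
        classes2 = self._mismatch_classes(truth_genome, lib2, dmg)
        total2 = sum(classes2.values())
        ct_ga2 = classes2[("C", "T")] + classes2[("G", "A")]
        assert total2 > 100
        assert ct_ga2 / total2 == 1.0

    @staticmethod
    def _mismatch_classes(truth, lib, dmg):
        r1, _, truths = simulate_library(truth, None, lib, dmg)
        doubled = truth.residues * 2
        classes: dict[tuple, int] = {}
        for (rid, seq), t in zip(r1, truths):
            frag = doubled[t.start:t.end]
            template = frag if t.strand == "+" else reverse_complement(frag)
            for a, b in zip(template[:len(seq)], seq):
                if a != b:
                    classes[(a, b)] = classes.get((a, b), 0) + 1
        return classes


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(n_pairs=-1),
        dict(n_pairs=1, read_len=20),
        dict(n_pairs=1, endogenous_fraction=1.5),
        dict(n_pairs=1, insert_mean=0),
    ])
    def test_library_params(self, kwargs):
        with pytest.raises(ParameterError):
            LibraryParams(**kwargs)

    def test_damage_params_range(self):
        with pytest.raises(ParameterError):
            DamageParams(d_max=1.2)
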