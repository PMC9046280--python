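"""Motif scanning, hypergeometric enrichment, ranking and rank differential."""

import math

import numpy as np
import pytest

from regulink import (
    EnrichmentRow,
    GenomicInterval,
    Genome,
    Motif,
    PeakSet,
    SimulationConfig,
    UsageError,
    enrich_motifs,
    filter_peaks_with_motif,
    log_hypergeom_sf,
    hypergeom_sf,
    peak_has_motif,
    rank_by_logp,
    rank_differential,
    scan,
    simulate_study,
)
from regulink.genome import reverse_complement
from regulink.motifs import read_motifs, write_motifs

from oracles import exact_hypergeom_upper_tail

EBOX = Motif(name="EBOX", consensus="CAGCTG")


class TestScan:
    def test_palindrome_hits_both_strands_at_same_offset(self):
        hits = scan("AACAGCTGTT", EBOX)
        assert [(h.offset, h.strand) for h in hits] == [(2, "+"), (2, "-")]

    def test_iupac_n_matches_anything(self):
        hits = scan("CATTTG", Motif(name="m", consensus="CANNTG"))
        assert {h.strand for h in hits} == {"+", "-"}
        assert all(h.offset == 0 for h in hits)

    def test_no_hits_in_nonmatching_sequence(self):
        assert scan("TTTTTT", EBOX) == []

    def test_sequence_shorter_than_motif_is_empty_not_error(self):
        assert scan("CAG", EBOX) == []

    def test_n_in_sequence_never_matches_concrete_code(self):
        assert scan("CANCTG", EBOX) == []

    def test_overlapping_hits_all_reported(self):
        hits = scan("AAAA", Motif(name="m", consensus="AA"))
        assert [h.offset for h in hits if h.strand == "+"] == [0, 1, 2]

    def test_reverse_complement_mirrors_hits(self):
        seq = "AACAGCTGTTGGATCCA"
        motif = Motif(name="m", consensus="GGATCC")
        fwd = scan(seq, motif)
        rev = scan(reverse_complement(seq), motif)
        mirrored = sorted(
            (len(seq) - h.offset - motif.width, {"+": "-", "-": "+"}[h.strand])
            for h in rev
        )
        assert mirrored == sorted((h.offset, h.strand) for h in fwd)

    def test_matrix_mode_matches_strong_consensus(self):
        # a sharp matrix for CAGCTG
        cols = []
        for b in "CAGCTG":
            cols.append([0.97 if x == b else 0.01 for x in "ACGT"])
        m = Motif(name="m", matrix=tuple(zip(*cols)), log_odds_threshold=8.0)
        hits = scan("AACAGCTGTT", m)
        assert [(h.offset, h.strand) for h in hits] == [(2, "+"), (2, "-")]
        assert all(h.score > 8.0 for h in hits)

    def test_matrix_mode_rejects_below_threshold(self):
        cols = [[0.97 if x == b else 0.01 for x in "ACGT"] for b in "CAGCTG"]
        m = Motif(name="m", matrix=tuple(zip(*cols)), log_odds_threshold=8.0)
        assert scan("AACAGGTGTT", m) == []  # one mismatch kills the score


class TestHypergeometricKernel:
    def test_worked_value_13013_over_184756(self):
        assert hypergeom_sf(5, 20, 6, 10) == pytest.approx(
            13013 / 184756, rel=1e-12
        )

    def test_upper_tail_from_zero_is_exactly_one(self):
        assert log_hypergeom_sf(0, 20, 6, 10) == 0.0

    def test_small_enumeration_value(self):
        assert hypergeom_sf(2, 4, 2, 2) == pytest.approx(1 / 6, rel=1e-12)

    def test_matches_exact_enumeration_for_all_small_populations(self):
        # exhaustive sweep N <= 30 at 1e-10 relative error
        for N in range(1, 31):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        exact = float(exact_hypergeom_upper_tail(k, N, K, n))
                        got = hypergeom_sf(k, N, K, n)
                        assert got == pytest.approx(exact, rel=1e-10), (
                            k, N, K, n
                        )

    def test_monotone_non_increasing_in_k(self):
        values = [log_hypergeom_sf(k, 40, 15, 20) for k in range(16)]
        assert all(later <= earlier
                   for earlier, later in zip(values, values[1:]))

    def test_complementary_tail_relationship(self):
        # P(X >= k) + P(X <= k-1) = 1; the lower tail equals the upper tail
        # of the relabelled draw (k' = n - k + 1 failures among N - K)
        N, K, n = 25, 9, 11
        for k in range(min(n, K) + 1):
            upper = hypergeom_sf(k, N, K, n)
            lower = hypergeom_sf(n - k + 1, N, N - K, n)  # = P(X <= k-1)
            assert upper + lower == pytest.approx(1.0, abs=1e-12)


def _window_genome(sequences):
    """One chromosome per window, each 100 bp."""
    return Genome({f"w{i}": s for i, s in enumerate(sequences)})


def _window_peaks(label, ids):
    return PeakSet(
        label, [GenomicInterval(f"w{i}", 0, 100, name=f"w{i}") for i in ids]
    )


def _planted_windows(rng, n, rate, motif="CAGCTG"):
    """Random 100 bp windows with the motif planted at a known rate."""
    seqs, carriers = [], []
    for _ in range(n):
        seq = "".join(rng.choice(list("ACGT"), size=100))
        carrier = bool(rng.random() < rate)
        if carrier and motif not in seq:
            pos = int(rng.integers(0, 100 - len(motif)))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
        if not carrier:
            while scan(seq, EBOX):  # scrub chance occurrences
                seq = "".join(rng.choice(list("ACGT"), size=100))
        seqs.append(seq)
        carriers.append(carrier)
    return seqs, carriers


class TestPeakHasMotif:
    def test_window_with_motif(self):
        genome = _window_genome(["T" * 40 + "CAGCTG" + "T" * 54])
        peak = GenomicInterval("w0", 0, 100)
        assert peak_has_motif(peak, genome, EBOX)

    def test_window_without_motif(self):
        genome = _window_genome(["T" * 100])
        assert not peak_has_motif(GenomicInterval("w0", 0, 100), genome, EBOX)

    def test_missing_chromosome_names_it(self):
        genome = _window_genome(["T" * 100])
        with pytest.raises(Exception, match="chrX"):
            peak_has_motif(GenomicInterval("chrX", 0, 100), genome, EBOX)

    def test_planted_carrier_truth_recovered_exactly(self):
        rng = np.random.default_rng(5)
        seqs, carriers = _planted_windows(rng, 300, 0.4)
        genome = _window_genome(seqs)
        peaks = _window_peaks("all", range(300))
        kept = filter_peaks_with_motif(peaks, genome, EBOX)
        expected = {f"w{i}" for i, c in enumerate(carriers) if c}
        assert {p.name for p in kept} == expected
        assert kept.label == "all|EBOX"


class TestEnrichment:
    def test_counts_and_pvalue_against_construction(self):
        rng = np.random.default_rng(5)
        seqs, carriers = _planted_windows(rng, 30, 0.5)
        genome = _window_genome(seqs)
        target = _window_peaks("t", range(10))
        background = _window_peaks("b", range(10, 30))
        (row,) = enrich_motifs(target, background, [EBOX], genome)
        k = sum(carriers[:10])
        K = sum(carriers)
        assert (row.k, row.n, row.K, row.N) == (k, 10, K, 30)
        expected = float(exact_hypergeom_upper_tail(k, 30, K, 10))
        assert row.p_value == pytest.approx(expected, rel=1e-10)

    def test_empty_sets_rejected(self):
        genome = _window_genome(["A" * 100])
        peaks = _window_peaks("t", [0])
        with pytest.raises(UsageError):
            enrich_motifs(peaks, PeakSet("b", []), [EBOX], genome)

    def test_planted_motif_attains_rank_one(self):
        """200 carriers-enriched targets vs 2000 background windows."""
        cfg = SimulationConfig(
            seed=23, n_chroms=2, chrom_length=500_000, n_genes=10,
            n_shared=150, n_unique=(150, 100),
            n_activated=0, n_repressed=0,
        )
        study = simulate_study(cfg)
        target = study.gained            # unique to treated, carrier rate 0.6
        background = study.peak_sets["baseline"]    # shared + unique baseline
        rows = rank_by_logp(
            enrich_motifs(target, background, cfg.motifs, study.genome)
        )
        assert rows[0].motif_name == "ASCL1_EBOX"
        assert rows[0].p_value < 1e-10


class TestRanking:
    def _rows(self, pairs):
        return [
            EnrichmentRow(motif_name=name, k=1, n=2, K=2, N=4,
                          p_value=p, log_p=math.log(p))
            for name, p in pairs
        ]

    def test_rank_orders_by_pvalue(self):
        rows = self._rows([("b", 1e-3), ("a", 0.5), ("c", 1e-9)])
        ranked = rank_by_logp(rows)
        assert [(r.motif_name, r.rank) for r in ranked] == [
            ("c", 1), ("b", 2), ("a", 3)
        ]

    def test_ties_break_alphabetically(self):
        ranked = rank_by_logp(self._rows([("z", 0.1), ("a", 0.1)]))
        assert [(r.motif_name, r.rank) for r in ranked] == [("a", 1), ("z", 2)]

    def test_input_order_is_irrelevant(self):
        rows = self._rows([("a", 0.2), ("b", 0.1), ("c", 0.05)])
        r1 = rank_by_logp(rows)
        r2 = rank_by_logp(rows[::-1])
        assert [(r.motif_name, r.rank) for r in r1] == [
            (r.motif_name, r.rank) for r in r2
        ]


class TestRankDifferential:
    def _ranked(self, order):
        return [
            EnrichmentRow(motif_name=name, k=1, n=2, K=2, N=4, p_value=0.5,
                          log_p=math.log(0.5), rank=i + 1)
            for i, name in enumerate(order)
        ]

    def test_large_climb_gives_large_positive_shift(self):
        # a motif at rank 126 in A rising to rank 8 in B shifts by +118
        names = [f"m{i:03d}" for i in range(150)]
        rows_a = self._ranked(names)
        reordered = names.copy()
        reordered.remove("m125")
        reordered.insert(7, "m125")
        rows_b = self._ranked(reordered)
        shifts = rank_differential(rows_a, rows_b)
        assert shifts[0].motif_name == "m125"
        assert shifts[0].shift == 126 - 8

    def test_identical_inputs_give_zero_shifts(self):
        rows = self._ranked(["a", "b", "c"])
        assert all(s.shift == 0 for s in rank_differential(rows, rows))

    def test_mismatched_universe_rejected(self):
        with pytest.raises(UsageError, match="x"):
            rank_differential(self._ranked(["a", "x"]), self._ranked(["a", "y"]))

    def test_condition_specific_planted_motif_has_largest_shift(self):
        """A motif enriched only in condition-B unique peaks climbs the most."""
        rates = {name: {"default": 0.05}
                 for name in SimulationConfig().motif_consensus}
        rates["ASCL1_EBOX"] = {"default": 0.05, "unique_treated": 0.7}
        cfg = SimulationConfig(
            seed=9, n_chroms=2, chrom_length=400_000, n_genes=10,
            n_shared=150, n_unique=(120, 120),
            n_activated=0, n_repressed=0, motif_carrier_rates=rates,
        )
        study = simulate_study(cfg)
        shared_baseline = study.group_peaks("shared", "baseline")
        rows_a = rank_by_logp(enrich_motifs(
            study.lost, shared_baseline, cfg.motifs, study.genome))
        rows_b = rank_by_logp(enrich_motifs(
            study.gained, shared_baseline, cfg.motifs, study.genome))
        shifts = rank_differential(rows_a, rows_b)
        positive = [s for s in shifts if s.shift > 0]
        assert shifts[0].motif_name == "ASCL1_EBOX"
        assert positive[0].shift > max(
            (s.shift for s in positive[1:]), default=0
        )


def test_motif_file_round_trip(tmp_path):
    cols = [[0.7, 0.1, 0.1, 0.1], [0.1, 0.7, 0.1, 0.1]]
    motifs = [
        Motif(name="cons", consensus="CANNTG", log_odds_threshold=0.0),
        Motif(name="mat", matrix=tuple(zip(*cols)), log_odds_threshold=2.5),
    ]
    path = tmp_path / "motifs.txt"
    write_motifs(path, motifs)
    back = read_motifs(path)
    assert back[0].consensus == "CANNTG"
    assert back[1].log_odds_threshold == 2.5
    assert np.allclose(back[1].matrix, motifs[1].matrix)
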