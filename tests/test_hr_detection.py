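"""Palindrome scanning, hr clustering, consensus, and in silico PCR."""

import numpy as np
import pytest

from baculokit.genome_core import CircularGenome, GenomicInterval, reverse_complement
from baculokit.hr_detection import (
    HrRegion,
    PalindromeUnit,
    check_duplicate_primers,
    cluster_into_hrs,
    hr_consensus,
    insilico_pcr,
    palindrome_score,
    scan_palindromes,
)
from baculokit.synthetic_data import SimConfig, generate_genome

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _score_oracle(w):
    """Independent pairing count (no reuse of the library helper)."""
    L = len(w)
    return sum(1 for i in range(L) if _COMP.get(w[L - 1 - i]) == w[i]) / L


class TestPalindromeScore:
    @pytest.mark.parametrize("w,s", [("GAATTC", 1.0), ("AAAAAA", 0.0), ("ACGT", 1.0)])
    def test_examples(self, w, s):
        assert palindrome_score(w) == s

    def test_symmetric_under_revcomp_and_matches_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            w = "".join(rng.choice(list("ACGT"), 38))
            s = palindrome_score(w)
            assert s == pytest.approx(_score_oracle(w))
            assert s == pytest.approx(palindrome_score(reverse_complement(w)))

    def test_random_mean_is_quarter(self):
        rng = np.random.default_rng(2)
        scores = [palindrome_score("".join(rng.choice(list("ACGT"), 38))) for _ in range(2000)]
        # each position pairs with probability 1/4 under uniform bases
        assert np.mean(scores) == pytest.approx(0.25, abs=0.01)


def _exhaustive_units(seq, unit_len, min_score):
    """Oracle: score every window, then the same greedy local-max suppression."""
    L = len(seq)
    ext = seq + seq[: unit_len - 1]
    scored = []
    for i in range(L):
        scored.append((i, _score_oracle(ext[i : i + unit_len])))
    qual = [(i, s) for i, s in scored if s >= min_score]
    qual.sort(key=lambda t: (-t[1], t[0]))
    taken = []
    for i, s in qual:
        if all(min(abs(i - t), L - abs(i - t)) >= unit_len for t, _ in taken):
            taken.append((i, s))
    return sorted(taken)


class TestScanPalindromes:
    def test_single_planted_perfect_palindrome(self):
        rng = np.random.default_rng(3)
        left = "".join(rng.choice(list("ACGT"), 19))
        unit = left + reverse_complement(left)
        bg = "".join(rng.choice(["A", "C"], 2000))  # A/C background cannot pair
        seq = bg[:700] + unit + bg[700:]
        g = CircularGenome("p", seq)
        units = scan_palindromes(g, 38, 0.9)
        assert len(units) == 1
        assert units[0].interval.start == 700
        assert units[0].palindromicity == 1.0

    def test_equals_exhaustive_windowing(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 4000))
        g = CircularGenome("r", seq)
        got = [(u.interval.start, u.palindromicity) for u in scan_palindromes(g, 20, 0.55)]
        oracle = _exhaustive_units(seq, 20, 0.55)
        assert [(s, pytest.approx(sc)) for s, sc in oracle] == got

    def test_high_threshold_on_random_sequence_finds_nothing(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        g = CircularGenome("r", seq)
        assert scan_palindromes(g, 38, 0.95) == []

    def test_diverged_planted_units_recovered(self):
        # planted units at 10% divergence still score above 0.6 in 20/20 seeds
        found = 0
        total = 0
        for seed in range(1, 21):
            cfg = SimConfig(
                genome_length=8000, n_orfs=0, n_hrs=1, units_per_hr_range=(4, 4),
                unit_divergence=0.10, restriction_sites_planted={}, seed=seed,
            )
            g, truth = generate_genome(cfg)
            starts = {u.interval.start for u in scan_palindromes(g, 38, 0.6)}
            for f in truth.features:
                if f.kind == "repeat_unit":
                    total += 1
                    found += f.interval.start in starts
        assert found / total >= 0.8

    def test_rotation_invariance_including_origin_spanning_cluster(self):
        cfg = SimConfig(
            genome_length=9000, n_orfs=0, n_hrs=2, unit_divergence=0.05,
            restriction_sites_planted={}, seed=8,
        )
        g, _ = generate_genome(cfg)
        L = g.length
        base = {u.interval.start for u in scan_palindromes(g)}
        # rotate so a cluster straddles the origin
        anchor = sorted(base)[0] + 10
        rot = CircularGenome("rot", g.sequence[anchor:] + g.sequence[:anchor])
        got = {(u.interval.start + anchor) % L for u in scan_palindromes(rot)}
        assert got == base
        regions = cluster_into_hrs(scan_palindromes(rot), L)
        assert len(regions) == 2  # cluster spanning the origin still one region


class TestClustering:
    def _unit(self, start, L=10_000):
        iv = GenomicInterval(start, 38, "+")
        return PalindromeUnit(interval=iv, palindromicity=1.0, sequence="A" * 38)

    def test_gap_rule_and_min_units(self):
        units = [self._unit(0), self._unit(138), self._unit(276), self._unit(6000)]
        regions = cluster_into_hrs(units, 10_000, max_gap=500, min_units=2, circular=False)
        assert len(regions) == 1 and regions[0].n_units == 3

    def test_max_gap_zero_drops_everything_unless_abutting(self):
        units = [self._unit(0), self._unit(38), self._unit(500)]
        regions = cluster_into_hrs(units, 10_000, max_gap=0, min_units=2, circular=False)
        assert len(regions) == 1 and regions[0].n_units == 2

    def test_seven_planted_hrs_recovered(self):
        cfg = SimConfig(seed=14)  # defaults: 120 kb, 7 hrs, unit 38
        g, truth = generate_genome(cfg)
        regions = cluster_into_hrs(scan_palindromes(g), g.length)
        assert len(regions) == 7
        # every region overlaps exactly one planted hr hull
        planted = sorted((f.interval.start, f.interval.span) for f in truth.hrs)
        got = sorted((r.interval.start, r.interval.span) for r in regions)
        for (gs, gsp), (ps, psp) in zip(got, planted):
            assert gs <= ps + psp and ps <= gs + gsp  # overlap
        # labels run clockwise from the origin
        assert [r.label for r in regions] == [f"hr{i}" for i in range(1, 8)]
        # hull sum rule
        for r in regions:
            assert r.interval.span >= 38 * r.n_units

    def test_consensus_majority_and_ties(self):
        def mk(seq):
            return PalindromeUnit(GenomicInterval(0, len(seq), "+"), 1.0, seq)

        region = HrRegion(GenomicInterval(0, 10, "+"), [mk("AAAA"), mk("AAAA"), mk("CAAT")], "")
        cons, conserv = hr_consensus(region)
        assert cons == "AAAA"
        assert conserv == [2 / 3, 1.0, 1.0, 2 / 3]
        single = HrRegion(GenomicInterval(0, 4, "+"), [mk("ACGT")], "")
        assert hr_consensus(single)[0] == "ACGT"

    def test_consensus_close_to_master_at_divergence(self):
        bad = 0
        for seed in range(1, 21):
            cfg = SimConfig(
                genome_length=8000, n_orfs=0, n_hrs=1, units_per_hr_range=(6, 6),
                unit_divergence=0.1, restriction_sites_planted={}, seed=seed,
            )
            g, truth = generate_genome(cfg)
            master = truth.master_unit
            regions = cluster_into_hrs(scan_palindromes(g), g.length)
            assert len(regions) == 1
            cons = regions[0].consensus
            d = sum(1 for a, b in zip(cons, master) if a != b)
            bad += d > 2
        assert bad <= 2  # majority vote concentrates on the master


class TestInsilicoPcr:
    def test_planted_pair_yields_one_product_of_known_size(self):
        rng = np.random.default_rng(11)
        bg = "".join(rng.choice(["A", "C"], 3000))
        fwd = "AGAGTTGGAAATTTCGCGCTC"
        rev = "GTTTTTACTCTGTCCGCGCG"
        seq = bg[:400] + fwd + bg[400:1200] + reverse_complement(rev) + bg[1200:]
        g = CircularGenome("p", seq)
        products = insilico_pcr(g, fwd, rev)
        assert len(products) == 1
        # product spans fwd footprint start to rev footprint end
        assert products[0].size == (1200 + len(fwd) - 400) + len(rev)

    def test_forward_only_no_product(self):
        rng = np.random.default_rng(12)
        bg = "".join(rng.choice(["A", "C"], 2000))
        fwd = "AGAGTTGGAAATTTCGCGCTC"
        g = CircularGenome("p", bg[:100] + fwd + bg[100:])
        assert insilico_pcr(g, fwd, "GTTTTTACTCTGTCCGCGCG") == []

    def test_wrapping_product(self):
        rng = np.random.default_rng(13)
        bg = "".join(rng.choice(["A", "C"], 3000))
        fwd = "AGAGTTGGAAATTTCGCGCTC"
        rev = "GTTTTTACTCTGTCCGCGCG"
        # fwd near the end, rev target just after the origin
        seq = bg[:50] + reverse_complement(rev) + bg[50:2800] + fwd + bg[2800:]
        g = CircularGenome("p", seq)
        products = insilico_pcr(g, fwd, rev)
        assert len(products) == 1
        assert products[0].interval.wraps(g.length)

    def test_published_style_primers_with_spaces_parse(self):
        rng = np.random.default_rng(14)
        g = CircularGenome("p", "".join(rng.choice(list("ACGT"), 2000)))
        # spaced triplet formatting accepted verbatim
        out = insilico_pcr(g, "AGA GTT GGA AAT TTC GCG CTC", "GTT TTT ACT CTG TCC GCG CG")
        assert isinstance(out, list)

    def test_duplicate_primer_flagging(self):
        table = {
            "hr1": ("AGA GTT GGA AAT TTC GCG CTC", "GTT TTT ACT CTG TCC GCG CG"),
            "hr6": ("AGA GTT GGA AAT TTC GCG CTC", "TCA TGT CGG CCA ATG AGG AC"),
        }
        flags = check_duplicate_primers(table)
        assert any(a == "hr1" and b == "hr6" for a, b, _ in flags)
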