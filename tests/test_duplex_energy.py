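from collections import Counter

import numpy as np
import pytest
from scipy import stats

from _oracles import brute_duplex_mfe
from mirabind.duplex_energy import (
    DEFAULT_PARAMS,
    GumbelNull,
    calibrate_null,
    dinucleotide_shuffle,
    duplex_mfe,
    fit_gumbel,
    hybrid_pvalue,
    seed_constraint_ok,
)
from mirabind.sequence_io import reverse_complement


def _random_pair(rng, max_m=8, max_w=12):
    lm = int(rng.integers(2, max_m + 1))
    lw = int(rng.integers(2, max_w + 1))
    mir = "".join("ACGU"[i] for i in rng.integers(0, 4, lm))
    win = "".join("ACGT"[i] for i in rng.integers(0, 4, lw))
    return mir, win


class TestDuplexMfe:
    def test_full_gc_helix_energy_is_pairs_plus_stacks(self):
        hit = duplex_mfe("GGGGGGG", "AACCCCCCCAA")
        expected = 7 * DEFAULT_PARAMS.e_gc + 6 * DEFAULT_PARAMS.e_stack
        assert hit.dG_duplex == pytest.approx(expected)
        assert (hit.target_start, hit.target_end) == (2, 9)
        assert hit.n_pairs == 7

    def test_no_complementary_pairs_returns_none(self):
        assert duplex_mfe("AAAAAA", "AAAAAA") is None

    def test_matches_bruteforce_on_random_pairs(self, rng):
        for _ in range(80):
            mir, win = _random_pair(rng)
            expected = brute_duplex_mfe(mir, win, DEFAULT_PARAMS)
            hit = duplex_mfe(mir, win)
            got = None if hit is None else hit.dG_duplex
            if expected is None:
                assert got is None, (mir, win)
            else:
                assert got == pytest.approx(expected, abs=1e-9), (mir, win)

    def test_planted_reverse_complement_site_is_found_exactly(self, rng):
        pm = DEFAULT_PARAMS.pair_matrix()
        from mirabind.duplex_energy import encode

        for _ in range(10):
            mir = "".join("ACGU"[i] for i in rng.integers(0, 4, 18))
            site = reverse_complement(mir.replace("U", "T"))
            flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 6))
            win = flank + site + flank
            hit = duplex_mfe(mir, win)
            em, es = encode(mir), encode(site)[::-1]
            helix = float(sum(pm[a, b] for a, b in zip(es, em)))
            helix += (len(mir) - 1) * DEFAULT_PARAMS.e_stack
            assert hit.dG_duplex <= helix + 1e-9
            assert set(range(len(flank), len(flank) + len(site))) <= set(
                range(hit.target_start, hit.target_end)
            )

    def test_appending_nonpairing_bases_never_improves_mfe(self, rng):
        mir = "CCCCCCCC"  # pairs only with G
        core = "AAGGGGGAA"
        hit0 = duplex_mfe(mir, core)
        for tail in ("A", "CT", "ACTACT"):
            hit = duplex_mfe(mir, core + tail)
            assert hit.dG_duplex >= hit0.dG_duplex - 1e-12

    def test_deterministic_output(self):
        a = duplex_mfe("GGAAGGAA", "TTCCTTCCTTCC")
        b = duplex_mfe("GGAAGGAA", "TTCCTTCCTTCC")
        assert a == b

    def test_illegal_characters_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            duplex_mfe("ACGX", "ACGT")


class TestSeedConstraint:
    def test_constraint_checks_paired_interval(self):
        hit = duplex_mfe("GGGGGGG", "AACCCCCCCAA")  # positions 1..7 paired
        assert seed_constraint_ok(hit, 1, 7, 7)
        assert seed_constraint_ok(hit, None, None, 7)
        mixed = duplex_mfe("GGGGAGGG", "CCCTCCCC")
        # position 5 (the A) may be unpaired; a constraint spanning it fails
        if 4 not in mixed.mirna_paired:
            assert not seed_constraint_ok(mixed, 1, 8, 8)

    def test_out_of_range_seed_errors(self):
        hit = duplex_mfe("GGGGGGG", "AACCCCCCCAA")
        with pytest.raises(ValueError, match="seed range"):
            seed_constraint_ok(hit, 0, 5, 7)
        with pytest.raises(ValueError, match="seed range"):
            seed_constraint_ok(hit, 2, 9, 7)


class TestDinucleotideShuffle:
    def test_dinucleotide_counts_preserved(self, rng):
        seq = "ACGTACGGTCAGGATCCGATCGATTTACG"
        target = Counter(zip(seq, seq[1:]))
        for _ in range(200):
            s = dinucleotide_shuffle(seq, rng)
            assert len(s) == len(seq)
            assert Counter(zip(s, s[1:])) == target

    def test_homopolymer_fixed_point_and_short_input(self, rng):
        assert dinucleotide_shuffle("AAAA", rng) == "AAAA"
        with pytest.raises(ValueError):
            dinucleotide_shuffle("AC", rng)

    def test_seeded_shuffle_is_deterministic(self):
        a = dinucleotide_shuffle("ACGTACGGTCAGG", np.random.default_rng(5))
        b = dinucleotide_shuffle("ACGTACGGTCAGG", np.random.default_rng(5))
        assert a == b


class TestGumbelNull:
    def test_empirical_rank_pvalue(self):
        scores = tuple(float(i) for i in range(1, 200))  # 199 nulls, max 199
        null = GumbelNull(mu=100.0, beta=10.0, n_shuffles=199, scores=scores)
        _, p_emp = hybrid_pvalue(-199.0, null)  # observed equals the largest null
        assert p_emp == pytest.approx(2 / 200)

    def test_gumbel_closed_form_limits(self):
        null = GumbelNull(mu=10.0, beta=2.0, n_shuffles=100, scores=(0.0,) * 100)
        p_at_mu, _ = hybrid_pvalue(-10.0, null)
        assert p_at_mu == pytest.approx(1 - np.exp(-1), rel=1e-6)
        p_far, _ = hybrid_pvalue(-1e6, null)
        assert p_far < 1e-300 or p_far == pytest.approx(0.0, abs=1e-300)

    def test_moment_fit_recovers_parameters(self, rng):
        x = stats.gumbel_r.rvs(loc=10.0, scale=2.0, size=10_000, random_state=rng)
        mu, beta = fit_gumbel(x)
        assert mu == pytest.approx(10.0, abs=0.1)
        assert beta == pytest.approx(2.0, abs=0.1)

    def test_pvalue_monotone_in_score(self, rng):
        mir = "GGAUGGAAGCUAGGGAUCCAUU"
        win = "".join("ACGT"[i] for i in rng.integers(0, 4, 35))
        null = calibrate_null(mir, win, 100, rng)
        ps = [hybrid_pvalue(-x, null)[0] for x in (5.0, 10.0, 20.0, 40.0)]
        assert ps == sorted(ps, reverse=True)

    def test_degenerate_null_gives_p_one(self):
        null = GumbelNull(mu=0.0, beta=0.0, n_shuffles=100, scores=(0.0,) * 100)
        p, _ = hybrid_pvalue(-5.0, null)
        assert p == 1.0
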