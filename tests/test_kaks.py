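"""NG86 Ka/Ks internals, dating arithmetic, and simulation recovery."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from famscan.kaks import (
    CodonAlignment,
    SENSE_CODONS,
    build_codon_alignment,
    codon_differences,
    codon_sites,
    kaks_pair,
    ratio_and_date,
)
from famscan.synth import SyntheticConfig, gen_duplicate_pair


def oracle_sites(codon):
    """Independent site counter via Biopython translation."""
    aa = str(Seq(codon).translate())
    syn = 0.0
    for pos, base in itertools.product(range(3), "ACGT"):
        if base == codon[pos]:
            continue
        mutant = codon[:pos] + base + codon[pos + 1:]
        if str(Seq(mutant).translate()) == aa:  # stop '*' never equals aa
            syn += 1 / 3
    return syn, 3 - syn


def oracle_differences(ca, cb):
    """Independent minimal-path enumerator via Biopython translation.

    Stop-passing paths are excluded; if every path is blocked the
    unrestricted average over all orders is used instead."""
    diff = [i for i in range(3) if ca[i] != cb[i]]

    def enumerate_paths(exclude_stops):
        results = []
        for order in itertools.permutations(diff):
            cur, syn, nsyn, ok = ca, 0, 0, True
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if str(Seq(nxt).translate()) == "*" and exclude_stops:
                    ok = False
                    break
                if str(Seq(nxt).translate()) == str(Seq(cur).translate()):
                    syn += 1
                else:
                    nsyn += 1
                cur = nxt
            if ok:
                results.append((syn, nsyn))
        return results

    results = enumerate_paths(True) or enumerate_paths(False)
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


class TestCodonCounting:
    def test_phenylalanine_sites(self):
        assert codon_sites("TTT") == pytest.approx((1 / 3, 8 / 3))

    def test_methionine_fully_nonsynonymous(self):
        assert codon_sites("ATG") == pytest.approx((0.0, 3.0))

    def test_sites_partition_to_three_for_all_sense_codons(self):
        for codon in SENSE_CODONS:
            s, n = codon_sites(codon)
            assert s + n == pytest.approx(3.0)
            assert (s, n) == pytest.approx(oracle_sites(codon))

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_sites("TAA")

    @pytest.mark.parametrize("seed", range(4))
    def test_differences_match_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            ca, cb = rng.choice(SENSE_CODONS, size=2)
            expected = oracle_differences(ca, cb)
            assert codon_differences(ca, cb) == pytest.approx(expected)


class TestKaksPair:
    def test_identical_pair_is_zero(self):
        cds = "ATGGCTGGT" * 10
        r = kaks_pair(CodonAlignment(cds, cds))
        assert r.ka == r.ks == 0.0 and r.ratio is None

    def test_single_synonymous_third_position_change(self):
        # 10 codons; GGT -> GGC is synonymous (both Gly)
        a = "ATGGCTGGTACTTTACGTGATGAACATTGG"
        b = a[:8] + "C" + a[9:]
        aln = CodonAlignment(a, b)
        r = kaks_pair(aln)
        assert (r.sd, r.nd) == (1.0, 0.0)
        expected_s = sum(
            (codon_sites(a[i:i + 3])[0] + codon_sites(b[i:i + 3])[0]) / 2
            for i in range(0, 30, 3)
        )
        ps = 1.0 / expected_s
        assert r.ks == pytest.approx(-0.75 * math.log(1 - 4 * ps / 3))
        assert r.ka == 0.0

    def test_pair_is_symmetric(self):
        pair = gen_duplicate_pair(SyntheticConfig(seed=4), 0)
        fwd = kaks_pair(CodonAlignment(pair.cds_a.sequence, pair.cds_b.sequence))
        rev = kaks_pair(CodonAlignment(pair.cds_b.sequence, pair.cds_a.sequence))
        assert fwd.ks == pytest.approx(rev.ks) and fwd.ka == pytest.approx(rev.ka)

    def test_random_pairs_match_oracle_totals(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a = "".join(rng.choice(SENSE_CODONS, size=30))
            b = "".join(rng.choice(SENSE_CODONS, size=30))
            r = kaks_pair(CodonAlignment(a, b))
            sd = nd = 0.0
            for i in range(0, 90, 3):
                expected = oracle_differences(a[i:i + 3], b[i:i + 3])
                sd += expected[0]
                nd += expected[1]
            assert (r.sd, r.nd) == pytest.approx((sd, nd))

    def test_gapped_codons_skipped_and_frame_gaps_rejected(self):
        a = "ATGGCT---GGT"
        b = "ATGGCTAAAGGT"
        r = kaks_pair(CodonAlignment(a, b))
        assert r.n_codons == 3
        with pytest.raises(ValueError, match="frame"):
            CodonAlignment("ATG-CTAAA", "ATGGCTAAA")

    def test_all_gap_alignment_is_an_error(self):
        with pytest.raises(ValueError):
            kaks_pair(CodonAlignment("---", "ATG"))

    def test_sites_partition_invariant(self):
        pair = gen_duplicate_pair(SyntheticConfig(seed=6), 0)
        r = kaks_pair(CodonAlignment(pair.cds_a.sequence, pair.cds_b.sequence))
        assert r.s_sites + r.n_sites == pytest.approx(3 * r.n_codons)

    def test_protein_guided_alignment_threads_codons(self):
        # second sequence lacks one internal codon; the protein
        # alignment must re-thread the frame around the deletion
        a = "ATGGCTAAACGTGATGAACATTGGTTTGGA"
        b = "ATGGCTCGTGATGAACATTGGTTTGGA"
        aln = build_codon_alignment(a, b)
        assert len(aln.seq_a) == 30 and "---" in aln.seq_b
        r = kaks_pair(aln)
        assert r.n_codons == 9 and r.ks == 0.0 and r.ka == 0.0


class TestRatioAndDate:
    def test_printed_duplication_row(self):
        ratio, mya, sel = ratio_and_date(0.0258, 0.1829)
        assert round(ratio, 6) == 0.141061
        assert round(mya, 5) == 14.06923
        assert sel == "purifying"

    def test_zero_ks_dates_to_zero_with_undefined_ratio(self):
        ratio, mya, sel = ratio_and_date(0.01, 0.0)
        assert ratio is None and mya == 0.0 and sel == "undefined"

    def test_selection_thresholds(self):
        assert ratio_and_date(0.0993 * 2, 0.0993)[2] == "positive"
        assert ratio_and_date(0.0993, 0.0993)[2] == "neutral"
        assert ratio_and_date(0.01, 0.0993)[2] == "purifying"

    def test_mya_increasing_in_ks_and_scaling_in_lambda(self):
        myas = [ratio_and_date(0.0, ks)[1] for ks in (0.1, 0.2, 0.5, 1.0)]
        assert all(a < b for a, b in zip(myas, myas[1:]))
        half = ratio_and_date(0.0, 0.2, lambda_rate=3.25e-9)[1]
        assert half == pytest.approx(2 * ratio_and_date(0.0, 0.2)[1])


class TestSimulationRecovery:
    def test_monotone_in_target_ks(self):
        from scipy.stats import spearmanr

        targets = np.linspace(0.05, 0.5, 10)
        estimates = []
        for i, ks in enumerate(targets):
            config = SyntheticConfig(seed=100 + i, target_ks=float(ks),
                                     n_codons=300)
            pair = gen_duplicate_pair(config, 0)
            r = kaks_pair(
                CodonAlignment(pair.cds_a.sequence, pair.cds_b.sequence)
            )
            estimates.append(r.ks)
        rho = spearmanr(targets, estimates).statistic
        assert rho > 0.95

    def test_estimates_recover_realized_truth(self):
        errs_ks, errs_ka = [], []
        for seed in range(20):
            pair = gen_duplicate_pair(SyntheticConfig(seed=seed), 0)
            r = kaks_pair(
                CodonAlignment(pair.cds_a.sequence, pair.cds_b.sequence)
            )
            errs_ks.append(r.ks - pair.true_ks)
            errs_ka.append(r.ka - pair.true_ka)
        assert abs(np.mean(errs_ks)) < 0.1 * 0.18  # mean bias < 10% of target
        assert abs(np.mean(errs_ka)) < 0.01
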