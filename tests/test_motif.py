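import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omegatx.io_formats import PromoterSet
from omegatx.motif import (
    MotifAlignment,
    SpacerConstraint,
    admissible_offsets_minus10,
    align_minus10,
    align_minus35,
    annotate_elements,
    build_logo,
    compare_element_ic,
    detect_extended_minus10,
    information_content,
    spacer_at_fraction,
    window_ic,
)

from conftest import make_planted_promoters


def brute_force_minus10(seqs, width=6, starts=None):
    """Independent enumeration of every per-sequence offset combination."""
    if starts is None:
        starts = admissible_offsets_minus10(L=seqs.length, width=width)
    gene_ids = sorted(seqs.gene_ids)
    best = None
    for combo in itertools.product(starts, repeat=len(gene_ids)):
        offsets = dict(zip(gene_ids, combo))
        score = brute_ic(seqs, offsets, width)
        if best is None or score > best[0] + 1e-12:
            best = (score, offsets)
    return best


def brute_force_minus35(seqs, minus10_offsets, width=6, gaps=(16, 17, 18)):
    gene_ids = sorted(minus10_offsets)
    best = None
    for combo in itertools.product(sorted(gaps, reverse=True), repeat=len(gene_ids)):
        offsets = {
            g: minus10_offsets[g] - gap - width
            for g, gap in zip(gene_ids, combo)
        }
        score = brute_ic(seqs, offsets, width)
        if best is None or score > best[0] + 1e-12:
            best = (score, offsets)
    return best


def brute_ic(seqs, offsets, width):
    """Plain-Python column IC sum, written independently of the package."""
    total = 0.0
    for j in range(width):
        column = [
            seqs[g][offsets[g] + seqs.length + j] for g in offsets
        ]
        column = [b for b in column if b != "N"]
        if not column:
            continue
        n = len(column)
        h = 0.0
        for b in "ACGT":
            f = column.count(b) / n
            if f > 0:
                h -= f * math.log2(f)
        total += 2.0 - h
    return total


def random_promoters(rng, n, L=60):
    return PromoterSet({
        f"g{i:03d}": "".join(rng.choice(list("ACGT"), size=L)) for i in range(n)
    })


class TestInformationContent:
    @pytest.mark.parametrize("counts,expected", [
        ((10, 0, 0, 0), 2.0),        # full conservation
        ((1, 1, 1, 1), 0.0),         # uniform
        ((2, 1, 1, 0), 0.5),         # H = 1.5 by direct entropy evaluation
        ((0, 0, 5, 5), 1.0),
    ])
    def test_closed_forms(self, counts, expected):
        assert information_content(counts) == pytest.approx(expected)

    def test_small_sample_correction(self):
        n = 10
        expected = 2.0 - 3.0 / (2.0 * math.log(2.0) * n)
        assert information_content((10, 0, 0, 0), correction=True) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            information_content((0, 0, 0, 0))

    @given(counts=st.lists(st.integers(0, 50), min_size=4, max_size=4)
           .filter(lambda c: sum(c) >= 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounds(self, counts):
        ic = information_content(counts)
        assert -1e-12 <= ic <= 2.0 + 1e-12


class TestAdmissibleOffsets:
    def test_defaults_give_five_starts(self):
        assert admissible_offsets_minus10() == [-14, -13, -12, -11, -10]

    def test_width_fills_window(self):
        assert admissible_offsets_minus10(width=10) == [-14]

    def test_impossible_geometry(self):
        with pytest.raises(ValueError):
            admissible_offsets_minus10(width=11)


class TestWindowIC:
    def test_identical_sequences_reach_maximum(self):
        ps = PromoterSet({f"g{i}": "ACGTA" * 12 for i in range(4)})
        offsets = {g: -12 for g in ps.gene_ids}
        assert window_ic(ps, offsets) == pytest.approx(12.0)

    def test_matches_hand_pfm(self, rng):
        ps = random_promoters(rng, 4)
        offsets = {g: s for g, s in zip(sorted(ps.gene_ids), [-14, -12, -11, -10])}
        assert window_ic(ps, offsets) == pytest.approx(brute_ic(ps, offsets, 6))

    def test_total_bounded_by_two_bits_per_column(self, rng):
        ps = random_promoters(rng, 6)
        offsets = {g: -12 for g in ps.gene_ids}
        assert window_ic(ps, offsets) <= 12.0 + 1e-12


class TestAlignMinus10:
    def test_planted_motif_recovered_exactly(self, planted_promoters):
        ps, offsets, _ = planted_promoters
        aln = align_minus10(ps, strategy="exhaustive")
        assert aln.total_ic == pytest.approx(12.0)
        assert [aln.offsets[g] for g in sorted(aln.offsets)] == offsets
        assert aln.consensus() == "TATAAT"
        assert aln.verified_exhaustive

    def test_single_sequence_tie_break_most_upstream(self, rng):
        ps = random_promoters(rng, 1)
        aln = align_minus10(ps)
        assert aln.total_ic == pytest.approx(12.0)
        assert list(aln.offsets.values()) == [-14]

    def test_exhaustive_equals_independent_brute_force(self, rng):
        ps = random_promoters(rng, 5)
        aln = align_minus10(ps, strategy="exhaustive")
        score, offsets = brute_force_minus10(ps)
        assert aln.total_ic == pytest.approx(score, abs=1e-9)

    def test_coordinate_ascent_local_optimality(self, rng):
        ps = random_promoters(rng, 30)
        aln = align_minus10(ps, strategy="coordinate_ascent", restarts=5, seed=3)
        starts = admissible_offsets_minus10()
        for g in aln.offsets:
            for alt in starts:
                perturbed = dict(aln.offsets)
                perturbed[g] = alt
                assert window_ic(ps, perturbed) <= aln.total_ic + 1e-9

    def test_determinism(self, rng):
        ps = random_promoters(rng, 40)
        a = align_minus10(ps, strategy="coordinate_ascent", restarts=10, seed=11)
        b = align_minus10(ps, strategy="coordinate_ascent", restarts=10, seed=11)
        assert a.offsets == b.offsets
        assert np.array_equal(a.pfm, b.pfm)

    def test_gibbs_finds_planted_optimum(self, planted_promoters):
        ps, offsets, _ = planted_promoters
        aln = align_minus10(ps, strategy="gibbs", restarts=3, seed=5)
        assert aln.total_ic == pytest.approx(12.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            align_minus10(PromoterSet({}))

    def test_all_n_sequences_excluded(self, caplog):
        seqs = {"g1": "A" * 60, "g2": "N" * 60}
        with caplog.at_level("WARNING"):
            aln = align_minus10(PromoterSet(seqs))
        assert set(aln.offsets) == {"g1"}
        assert "g2" in caplog.text


class TestAlignMinus35:
    def test_planted_spacer_recovered(self):
        ps = make_planted_promoters([-12] * 8, [17] * 8, seed=3)
        m10 = align_minus10(ps, strategy="exhaustive")
        m35 = align_minus35(ps, m10, strategy="exhaustive")
        assert m35.total_ic == pytest.approx(12.0)
        assert all(s == 17 for s in m35.spacers.values())
        assert m35.consensus() == "TTGACA"

    def test_gap_coordinate_arithmetic(self):
        # -10 at -12 with gap 16 puts the -35 at -34..-29
        ps = make_planted_promoters([-12] * 4, [16] * 4, seed=4)
        m10 = align_minus10(ps, strategy="exhaustive")
        m35 = align_minus35(ps, m10, strategy="exhaustive")
        assert all(v == -34 for v in m35.offsets.values())

    def test_exhaustive_equals_independent_brute_force(self, rng):
        ps = random_promoters(rng, 8)
        m10 = align_minus10(ps, strategy="coordinate_ascent", restarts=5, seed=1)
        m35 = align_minus35(ps, m10, strategy="exhaustive")
        score, offsets = brute_force_minus35(ps, m10.offsets)
        assert m35.total_ic == pytest.approx(score, abs=1e-9)

    def test_null_spacers_roughly_uniform(self):
        counts = {16: 0, 17: 0, 18: 0}
        for seed in range(12):
            rng = np.random.default_rng(1000 + seed)
            ps = random_promoters(rng, 25)
            m10 = align_minus10(ps, strategy="coordinate_ascent", restarts=5,
                                seed=seed)
            m35 = align_minus35(ps, m10, strategy="coordinate_ascent",
                                restarts=5, seed=seed)
            for s in m35.spacers.values():
                counts[s] += 1
        total = sum(counts.values())
        for s, c in counts.items():
            assert 0.15 < c / total < 0.55  # no spacer dominates under the null

    def test_start_to_start_mode(self):
        ps = make_planted_promoters([-12] * 4, [17] * 4, seed=4)
        m10 = align_minus10(ps, strategy="exhaustive")
        m35 = align_minus35(ps, m10, strategy="exhaustive",
                            spacer_mode="start_to_start")
        for g in m35.offsets:
            assert 16 <= m10.offsets[g] - m35.offsets[g] <= 18


class TestElementCharacterization:
    def test_extended_minus10_all_and_none(self):
        with_tg = PromoterSet({
            f"g{i}": "C" * 46 + "TGTATAAT" + "C" * 6 for i in range(5)
        })
        m10 = MotifAlignment.from_offsets(with_tg, {g: -12 for g in with_tg.gene_ids})
        frac, flags = detect_extended_minus10(with_tg, m10)
        assert frac == 1.0 and all(flags.values())
        without = PromoterSet({f"g{i}": "C" * 60 for i in range(5)})
        m10b = MotifAlignment.from_offsets(without, {g: -12 for g in without.gene_ids})
        assert detect_extended_minus10(without, m10b)[0] == 0.0

    def test_background_tg_frequency(self):
        hits = 0
        trials = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ps = random_promoters(rng, 200)
            m10 = MotifAlignment.from_offsets(ps, {g: -12 for g in ps.gene_ids})
            frac, flags = detect_extended_minus10(ps, m10)
            hits += sum(flags.values())
            trials += len(flags)
        p = hits / trials
        # binomial expectation 1/16; 4 sd bound for 1000 trials
        assert abs(p - 1 / 16) < 4 * math.sqrt((1 / 16) * (15 / 16) / trials)

    @pytest.mark.parametrize("spacer_seq,expected", [
        ("AATTAAATTTAAATTT", 1.0),
        ("GCGCGCGCGCGCGCGC", 0.0),
        ("AATTGGCCAATTGGCC", 0.5),
    ])
    def test_spacer_at_fraction_hand_cases(self, spacer_seq, expected):
        # -35 at -34..-29, spacer of 16 at -28..-13, -10 at -12..-7
        seq = "C" * 26 + "TTGACA" + spacer_seq + "TATAAT" + "C" * 6
        ps = PromoterSet({"g1": seq})
        m10 = MotifAlignment.from_offsets(ps, {"g1": -12})
        m35 = MotifAlignment.from_offsets(ps, {"g1": -34})
        agg, per = spacer_at_fraction(ps, m10, m35)
        assert agg == pytest.approx(expected)

    def test_annotation_geometry(self, planted_promoters):
        ps, _, _ = planted_promoters
        m10 = align_minus10(ps, strategy="exhaustive")
        m35 = align_minus35(ps, m10, strategy="exhaustive")
        table = annotate_elements(ps, m10, m35)
        assert set(table["spacer_len"]) <= {16, 17, 18}
        assert (table["minus35_start"] >= -60).all()
        assert (table["minus10_start"] + 5 <= -1).all()
        assert (table["spacer_len"] ==
                table["minus10_start"] - table["minus35_start"] - 6).all()


class TestBuildLogo:
    def test_equal_spacers_full_effective_counts(self):
        ps = make_planted_promoters([-12] * 6, [17] * 6, seed=9)
        m10 = align_minus10(ps, strategy="exhaustive")
        m35 = align_minus35(ps, m10, strategy="exhaustive")
        logo = build_logo(ps, m10, m35, flank=2)
        counts = logo[["count_A", "count_C", "count_G", "count_T"]].to_numpy()
        assert np.allclose(counts.sum(axis=1), 6.0)
        freqs = logo[["freq_A", "freq_C", "freq_G", "freq_T"]].to_numpy()
        assert np.allclose(freqs.sum(axis=1), 1.0)

    def test_planted_elements_show_full_ic(self):
        ps = make_planted_promoters([-12] * 10, [17] * 10, background="C", seed=0)
        m10 = align_minus10(ps, strategy="coordinate_ascent", restarts=5, seed=0)
        # background is constant so everything is conserved; check element cols
        m35 = align_minus35(ps, m10, strategy="coordinate_ascent", seed=0)
        logo = build_logo(ps, m10, m35, flank=0)
        assert np.allclose(logo["ic"], 2.0)


class TestCompareElementIC:
    def test_identical_sets_null(self, planted_promoters):
        ps, _, _ = planted_promoters
        aln = align_minus10(ps, strategy="exhaustive")
        report = compare_element_ic(aln, aln, ps, ps, n_perm=19, seed=0)
        assert report["difference"] == 0.0
        assert report["perm_pvalue"] == 1.0

    def test_conserved_vs_random_significant(self, rng):
        conserved = make_planted_promoters([-12] * 12, [17] * 12, seed=2)
        random_set = random_promoters(rng, 12)
        a = align_minus10(conserved, strategy="coordinate_ascent", restarts=10,
                          seed=1)
        b = align_minus10(random_set, strategy="coordinate_ascent", restarts=10,
                          seed=1)
        n_perm = 19
        report = compare_element_ic(a, b, conserved, random_set,
                                    n_perm=n_perm, seed=3)
        assert report["difference"] > 3.0
        assert report["perm_pvalue"] <= 2 / (n_perm + 1)

    def test_planted_conservation_gradient_recovered(self):
        from omegatx.synth import PromoterSimConfig, generate_promoters
        strong, _ = generate_promoters(
            PromoterSimConfig(n_seqs=40, conservation=0.9, seed=10))
        weak, _ = generate_promoters(
            PromoterSimConfig(n_seqs=40, conservation=0.5, seed=11))
        a = align_minus10(strong, strategy="coordinate_ascent", restarts=10, seed=0)
        b = align_minus10(weak, strategy="coordinate_ascent", restarts=10, seed=0)
        report = compare_element_ic(a, b)
        assert report["difference"] > 0
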