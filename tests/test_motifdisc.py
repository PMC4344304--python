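"""IUPAC motif enumeration, matching, and enrichment statistics."""

import itertools

import numpy as np
import pytest

from _oracles import (motif_space_size_closed_form, oracle_fisher_two_sided,
                      oracle_motif_match)
from mirmeth.motifdisc import (ALPHABET15, BackgroundModel, ContingencyTable,
                               MotifSpaceForm, bonferroni, build_contingency,
                               enumerate_motif_space,
                               estimate_background_model, expand_motif,
                               fisher_two_sided, model_pvalue,
                               motif_matches_sequence, occurrence_probability,
                               rank_motifs)
from mirmeth.synthetic import simulate_motif_sets


class TestEnumeration:
    def test_length_one_no_degeneracy_is_the_plain_alphabet(self):
        assert list(enumerate_motif_space(MotifSpaceForm(1, 0, 0, 0))) == \
            ["A", "C", "G", "U"]

    def test_3_2_2_0_count_matches_closed_form(self):
        n = sum(1 for _ in enumerate_motif_space(MotifSpaceForm(3, 2, 2, 0)))
        assert n == motif_space_size_closed_form(3, 2, 2, 0) == 2464

    def test_2_1_1_1_equals_bruteforce_filter(self):
        form = MotifSpaceForm(2, 1, 1, 1)
        want = sorted(
            "".join(t) for t in itertools.product(ALPHABET15, repeat=2)
            if form.admits("".join(t))
        )
        assert list(enumerate_motif_space(form)) == want
        assert len(want) == motif_space_size_closed_form(2, 1, 1, 1)

    def test_lexicographic_and_unique(self):
        got = list(enumerate_motif_space(MotifSpaceForm(3, 1, 1, 0)))
        assert got == sorted(got) and len(got) == len(set(got))

    def test_space_monotone_in_caps(self):
        small = set(enumerate_motif_space(MotifSpaceForm(3, 1, 0, 0)))
        large = set(enumerate_motif_space(MotifSpaceForm(3, 2, 1, 1)))
        assert small <= large

    def test_all_forms_up_to_k5_match_closed_form(self):
        """Exhaustive degeneracy-class histogram vs the multinomial count."""
        for k in range(1, 6):
            hist = np.zeros((k + 1, k + 1, k + 1), dtype=np.int64)
            for t in itertools.product(ALPHABET15, repeat=k):
                n2 = sum(c in "RYKMWS" for c in t)
                n3 = sum(c in "BDHV" for c in t)
                nn = t.count("N")
                hist[n2, n3, nn] += 1
            for x in range(k + 1):
                for y in range(k + 1):
                    for n in range(k + 1):
                        direct = int(hist[: x + 1, : y + 1, : n + 1].sum())
                        assert direct == motif_space_size_closed_form(
                            k, x, y, n
                        ), (k, x, y, n)

    def test_form_validation_and_parse(self):
        with pytest.raises(ValueError):
            MotifSpaceForm(0, 0, 0, 0)
        with pytest.raises(ValueError):
            MotifSpaceForm(3, 4, 0, 0)
        assert MotifSpaceForm.parse("5-3-2-1") == MotifSpaceForm(5, 3, 2, 1)


class TestMatching:
    @pytest.mark.parametrize(
        "motif,seq,expected",
        [
            ("RAC", "GGACU", True),
            ("RRACH", "GGACU", True),
            ("RAC", "CCCCC", False),
            ("NNN", "AU", False),  # motif longer than sequence
            ("GAC", "GGAUACGAC", True),
            ("UAC", "GGTACG", True),  # U/T equivalence both ways
        ],
    )
    def test_examples(self, motif, seq, expected):
        assert motif_matches_sequence(motif, seq) is expected

    def test_agrees_with_expansion_oracle(self, rng):
        motifs = ["".join(rng.choice(list(ALPHABET15),
                                     size=int(rng.integers(2, 6))))
                  for _ in range(300)]
        for motif in motifs:
            for _ in range(10):
                seq = "".join(rng.choice(list("ACGU"),
                                         size=int(rng.integers(3, 15))))
                assert motif_matches_sequence(motif, seq) == \
                    oracle_motif_match(motif, seq), (motif, seq)

    def test_expansion_size(self):
        assert len(expand_motif("RRACH")) == 2 * 2 * 1 * 1 * 3


class TestContingency:
    def test_extreme_table(self):
        t = build_contingency("AAA", ["AAAU", "GAAAC"], ["CCCC", "GGGG"])
        assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 2)

    def test_hand_counted_fixture(self):
        ip = ["GGACU", "AGACC", "UUUUU", "CGACA", "AAAAA"]
        bg = ["GACGA", "CCCCC", "UGGGG", "AUCAA", "GGGAC"]
        t = build_contingency("RAC", ip, bg)  # RAC = [AG]AC
        assert (t.a, t.b, t.c, t.d) == (3, 2, 2, 3)

    def test_margins_always_match_set_sizes(self, rng):
        ip = ["".join(rng.choice(list("ACGU"), size=8)) for _ in range(7)]
        bg = ["".join(rng.choice(list("ACGU"), size=8)) for _ in range(11)]
        t = build_contingency("RAC", ip, bg)
        assert t.a + t.b == 7 and t.c + t.d == 11

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestFisher:
    def test_identical_proportions_give_one(self):
        assert fisher_two_sided(ContingencyTable(10, 10, 10, 10)) == \
            pytest.approx(1.0)

    def test_rac_published_table(self):
        p = fisher_two_sided(ContingencyTable(119, 120, 803, 1513))
        assert f"{p:.0e}" == "5e-06"

    def test_rrach_published_table(self):
        p = fisher_two_sided(ContingencyTable(78, 161, 457, 1859))
        assert f"{p:.0e}" == "8e-06"

    def test_matches_bruteforce_hypergeometric_sum(self, rng):
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 26, size=4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            got = fisher_two_sided(ContingencyTable(a, b, c, d))
            want = oracle_fisher_two_sided(a, b, c, d)
            assert got == pytest.approx(want, rel=1e-6), (a, b, c, d)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(1e-10, 2464, 2.464e-7), (0.5, 10, 1.0), (0.0, 1000, 0.0)],
    )
    def test_adjustment(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_adjusted_never_below_raw(self, rng):
        for _ in range(50):
            p = float(rng.uniform(0, 1))
            assert bonferroni(p, int(rng.integers(1, 1000))) >= p


class TestBackgroundModel:
    def test_single_sequence_hand_count(self):
        model = estimate_background_model(["AAAA"], k=2)
        # AA seen 3 times; add-one smoothing: P(A|A) = (3+1)/(3+4)
        assert model.next_prob("A", "A") == pytest.approx(4 / 7)

    def test_conditionals_sum_to_one(self, rng):
        seqs = ["".join(rng.choice(list("ACGU"), size=20)) for _ in range(10)]
        model = estimate_background_model(seqs, k=3)
        for ctx, probs in model.transitions.items():
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_background_is_uniform(self):
        seqs = ["".join(p) for p in itertools.product("ACGU", repeat=3)]
        model = estimate_background_model(seqs, k=2)
        for probs in model.transitions.values():
            assert np.allclose(probs, 0.25)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            estimate_background_model([], k=3)


def uniform_model(order=0):
    return BackgroundModel(
        order=order,
        initial={"": 1.0} if order == 0 else None,
        transitions={"": np.full(4, 0.25)},
    )


class TestModelPvalue:
    def test_absent_motif_gives_one(self):
        model = uniform_model()
        assert model_pvalue("A", ["CCC", "GGG"], model) == 1.0

    def test_single_base_closed_form(self):
        # one sequence of length 1, uniform model: q = P(A) = 1/4
        model = uniform_model()
        assert model_pvalue("A", ["A"], model) == pytest.approx(0.25)

    def test_occurrence_probability_closed_form_length2(self):
        # P(no A in 2 iid uniform draws) = (3/4)^2
        model = uniform_model()
        assert occurrence_probability("A", 2, model) == \
            pytest.approx(1 - 0.75 ** 2)

    def test_tail_decreases_as_count_increases(self):
        from scipy import stats as sps

        qs = [0.3] * 10
        pmf = sps.binom.pmf(np.arange(11), 10, 0.3)
        tails = [pmf[a:].sum() for a in range(1, 11)]
        assert all(t1 > t2 for t1, t2 in zip(tails, tails[1:]))
        model = uniform_model()
        seqs = ["A", "A", "C", "G"]  # a = 2
        p2 = model_pvalue("A", seqs, model)
        p1 = model_pvalue("A", ["A", "C", "C", "G"], model)  # a = 1
        assert p2 < p1


class TestRankMotifs:
    def test_empty_ip_set_rejected(self):
        with pytest.raises(ValueError):
            rank_motifs(MotifSpaceForm(3, 2, 2, 0), [], ["ACGU"])

    def test_planted_motif_generalization_ranks_first(self):
        ip, bg = simulate_motif_sets(200, 2000, 22, "GGACU", 0.6, 0.2, seed=5)
        df = rank_motifs(MotifSpaceForm(3, 2, 2, 0), ip, bg, model_p_top=5)
        top = df.iloc[0]
        assert motif_matches_sequence(top["motif"], "GGACU")
        assert top["bonferroni_p"] < 0.05
        assert top["model_p"] <= 0.05  # text-model score concurs
        assert (df["bonferroni_p"] >= df["fisher_p"]).all()

    def test_null_simulation_has_no_bonferroni_significant_motif(self):
        for seed in (11, 13):
            ip, bg = simulate_motif_sets(200, 2000, 22, "GGACU", 0.0, 0.0,
                                         seed=seed)
            df = rank_motifs(MotifSpaceForm(3, 2, 2, 0), ip, bg,
                             model_p_top=0)
            assert df["bonferroni_p"].min() >= 0.05

    def test_counts_in_report_match_direct_containment(self, rng):
        ip = ["".join(rng.choice(list("ACGU"), size=12)) for _ in range(15)]
        bg = ["".join(rng.choice(list("ACGU"), size=12)) for _ in range(25)]
        df = rank_motifs(MotifSpaceForm(2, 1, 0, 0), ip, bg, model_p_top=0)
        for row in df.sample(10, random_state=1).itertuples():
            t = build_contingency(row.motif, ip, bg)
            assert (row.a, row.b, row.c, row.d) == (t.a, t.b, t.c, t.d)
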