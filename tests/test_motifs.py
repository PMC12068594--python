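import io
from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regconverge.errors import InputError, ParseError
from regconverge.motifs import (
    NEG_SENTINEL,
    PWM,
    BindingStrengthMatrix,
    ScoreModel,
    bh_fdr,
    binding_strength,
    load_pwm,
    log_odds,
    promoter_background,
    scan,
    scan_promoters,
    score_pvalue,
)
from tests.conftest import make_promoter, random_pwm

# ---------------------------------------------------------------------------
# oracles


def naive_hit_set(seq, pwm, alpha_raw, model=None):
    """Brute-force enumeration of every offset x strand, pure Python."""
    model = model or ScoreModel(pwm)
    L = len(pwm)
    rc = model.int_scores[::-1, ::-1]
    out = set()
    for strand, mat in (("+", model.int_scores), ("-", rc)):
        for off in range(len(seq) - L + 1):
            total, ok = 0, True
            for i, ch in enumerate(seq[off : off + L]):
                j = "ACGT".find(ch)
                if j < 0 or mat[i, j] == NEG_SENTINEL:
                    ok = False
                    break
                total += int(mat[i, j])
            if ok and model.pvalue(total) <= alpha_raw:
                out.add((off, strand, total))
    return out


def hit_set(hits, precision=1e-4):
    return {(h.offset, h.strand, int(round(h.score / precision))) for h in hits}


def exhaustive_pvalue(model, threshold_int):
    """Tail mass over all 4^L windows computed by explicit enumeration."""
    bg = model.pwm.background
    total = 0.0
    L = len(model.pwm)
    for word in product(range(4), repeat=L):
        s = 0
        ok = True
        for i, b in enumerate(word):
            v = model.int_scores[i, b]
            if v == NEG_SENTINEL:
                ok = False
                break
            s += int(v)
        if ok and s >= threshold_int:
            p = 1.0
            for i, b in enumerate(word):
                p *= bg[b]
            total += p
    return total


# ---------------------------------------------------------------------------
# PWM model + loading


class TestPWM:
    def test_probabilities_normalize(self, aagt_pwm):
        assert np.allclose(aagt_pwm.probabilities.sum(axis=1), 1.0)

    def test_consensus(self, aagt_pwm):
        assert aagt_pwm.consensus == "AAGT"

    def test_zero_column_without_pseudocount(self):
        with pytest.raises(ParseError):
            PWM("bad", np.zeros((3, 4)), pseudocount=0.0)

    def test_negative_counts(self):
        with pytest.raises(ParseError):
            PWM("bad", np.array([[-1, 1, 1, 1]], float))

    def test_reverse_complement_involution(self, aagt_pwm):
        rc = aagt_pwm.reverse_complement()
        assert rc.consensus == "ACTT"
        assert np.array_equal(rc.reverse_complement().matrix, aagt_pwm.matrix)


JASPAR_TOY = """>MA0000.1 toy
A [10  0  0  0]
C [ 0 10  0  0]
G [ 0  0 10  0]
T [ 0  0  0 10]
"""

MEME_TOY = """MEME version 4

ALPHABET= ACGT

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF toy
letter-probability matrix: alength= 4 w= 4 nsites= 10 E= 0
1.0 0.0 0.0 0.0
0.0 1.0 0.0 0.0
0.0 0.0 1.0 0.0
0.0 0.0 0.0 1.0
"""


class TestLoadPWM:
    def test_jaspar(self):
        p = load_pwm(io.StringIO(JASPAR_TOY), "jaspar")
        assert len(p) == 4 and p.consensus == "ACGT"

    def test_cross_dialect_equality(self):
        pj = load_pwm(io.StringIO(JASPAR_TOY), "jaspar", pseudocount=0.5)
        pm = load_pwm(io.StringIO(MEME_TOY), "meme", pseudocount=0.5)
        assert np.allclose(pj.probabilities, pm.probabilities)
        assert np.allclose(log_odds(pj), log_odds(pm))

    def test_zero_column_no_pseudocount_is_parse_error(self):
        bad = ">M1 z\nA [0 0]\nC [0 0]\nG [0 0]\nT [0 0]\n"
        with pytest.raises(ParseError):
            load_pwm(io.StringIO(bad), "jaspar", pseudocount=0.0)

    def test_garbage_is_parse_error(self):
        with pytest.raises(ParseError):
            load_pwm(io.StringIO("not a motif"), "jaspar")

    def test_unknown_dialect(self):
        with pytest.raises(InputError):
            load_pwm(io.StringIO(JASPAR_TOY), "transfac")


class TestLogOdds:
    def test_pure_column_two_bits(self, aagt_pwm):
        lo = log_odds(aagt_pwm)
        assert lo[0, 0] == pytest.approx(2.0)
        assert lo[0, 1] == -np.inf

    def test_uniform_column_zero(self):
        p = PWM("u", np.full((2, 4), 5.0))
        assert np.allclose(log_odds(p), 0.0)

    def test_pseudocount_arithmetic(self):
        p = PWM("p", np.array([[10, 0, 0, 0]], float), pseudocount=1.0)
        expected = np.log2((11 / 14) / 0.25)
        assert log_odds(p)[0, 0] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# scanning


class TestScan:
    def test_forward_hit(self, aagt_pwm):
        hits = scan(make_promoter("CCAAGTCC"), aagt_pwm, alpha_raw=0.01)
        assert [(h.offset, h.strand) for h in hits] == [(2, "+")]

    def test_reverse_hit(self, aagt_pwm):
        hits = scan(make_promoter("CCACTTCC"), aagt_pwm, alpha_raw=0.01)
        assert [(h.offset, h.strand) for h in hits] == [(2, "-")]

    def test_all_n_never_hits(self, aagt_pwm):
        assert scan(make_promoter("N" * 50), aagt_pwm, alpha_raw=1.0) == []

    def test_motif_longer_than_window_warns_empty(self, aagt_pwm):
        with pytest.warns(UserWarning):
            assert scan(make_promoter("ACG"), aagt_pwm) == []

    def test_genomic_mapping_minus_strand(self, aagt_pwm):
        prom = make_promoter("CCAAGTCC", strand="-", start=100)
        (h,) = scan(prom, aagt_pwm, alpha_raw=0.01)
        # offset 2 in an 8-nt '-' window starting at 100 -> genomic 100+8-2-4
        assert h.genomic_start == 102

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pwm = random_pwm(rng, int(rng.integers(3, 9)))
        n = int(rng.integers(20, 200))
        seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.24] * 4 + [0.04]))
        prom = make_promoter(seq)
        model = ScoreModel(pwm)
        got = hit_set(scan(prom, pwm, alpha_raw=0.05, model=model))
        assert got == naive_hit_set(seq, pwm, 0.05, model)

    @pytest.mark.parametrize("seed", range(5))
    def test_revcomp_symmetry(self, seed):
        """Scanning the revcomp sequence with the revcomp PWM mirrors hits."""
        from regconverge.seq import revcomp

        rng = np.random.default_rng(seed)
        pwm = random_pwm(rng, 5)
        seq = "".join(rng.choice(list("ACGT"), size=80))
        fwd = scan(make_promoter(seq), pwm, alpha_raw=0.05)
        rev = scan(make_promoter(revcomp(seq)), pwm.reverse_complement(),
                   alpha_raw=0.05)
        L = len(pwm)
        mirrored = {(len(seq) - h.offset - L, h.strand) for h in rev}
        assert {(h.offset, h.strand) for h in fwd} == mirrored


class TestScorePvalue:
    def test_consensus_len2(self):
        pwm = PWM("t", np.array([[5, 0, 0, 0], [0, 5, 0, 0]], float))
        max_bits = log_odds(pwm)[0, 0] + log_odds(pwm)[1, 1]
        assert score_pvalue(pwm, max_bits) == pytest.approx(0.0625)

    def test_neg_inf_is_one(self, aagt_pwm):
        assert score_pvalue(aagt_pwm, -np.inf) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_dp_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(2, 7))
        bg = rng.dirichlet([5, 5, 5, 5])
        pwm = PWM(
            "r",
            rng.integers(0, 15, size=(L, 4)).astype(float) + 0.01,
            pseudocount=0.5,
            background=bg,
        )
        model = ScoreModel(pwm)
        thresholds = [model.max_int_score, model._support_min,
                      (model.max_int_score + model._support_min) // 2]
        for t in thresholds:
            assert model.pvalue(t) == pytest.approx(
                exhaustive_pvalue(model, t), abs=1e-9
            )


# ---------------------------------------------------------------------------
# BH and binding strength


class TestBH:
    def test_hand_computed_n4(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_singleton_one(self):
        assert bh_fdr([1.0]) == pytest.approx([1.0])

    def test_out_of_range(self):
        with pytest.raises(InputError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_padj_at_least_p_and_capped(self, ps):
        adj = bh_fdr(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_against_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        ps = rng.random(200)
        ours = bh_fdr(ps)
        theirs = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)


def _hits_frame(rows):
    cols = ["tf_id", "gene_id", "transcript_id", "offset", "strand",
            "score", "pvalue", "padj", "contig", "genomic_start"]
    return pd.DataFrame(rows, columns=cols)


class TestBindingStrength:
    def test_threshold_counting(self):
        hits = _hits_frame([
            ("tfA", "g1", "g1.t1", 5, "+", 8.0, 1e-4, 0.01, "c", 105),
            ("tfA", "g1", "g1.t1", 9, "+", 8.0, 1e-3, 0.2, "c", 109),
        ])
        m = binding_strength(hits, ["tfA"], ["g1", "g2"])
        assert m.counts.loc["tfA", "g1"] == 1
        assert m.counts.loc["tfA", "g2"] == 0

    def test_unannotated_gene_masked(self):
        m = binding_strength(_hits_frame([]), ["tfA"], ["g1", "g2"],
                             annotated={"g1": True, "g2": False})
        assert not m.annotated["g2"]
        assert m.counts.loc["tfA", "g2"] == 0

    def test_isoform_dedupe_by_genomic_coordinate(self):
        rows = [
            ("tfA", "g1", "g1.t1", 5, "+", 8.0, 1e-4, 0.01, "c", 105),
            ("tfA", "g1", "g1.t2", 15, "+", 8.0, 1e-4, 0.01, "c", 105),  # same site
            ("tfA", "g1", "g1.t2", 40, "+", 8.0, 1e-4, 0.01, "c", 140),
        ]
        m = binding_strength(_hits_frame(rows), ["tfA"], ["g1"])
        assert m.counts.loc["tfA", "g1"] == 2

    def test_counts_monotone_in_fdr_alpha(self):
        rng = np.random.default_rng(0)
        rows = [
            ("tfA", "g1", "g1.t1", i, "+", 5.0, 1e-4, rng.random(), "c", i)
            for i in range(50)
        ]
        hits = _hits_frame(rows)
        prev = None
        for alpha in (0.5, 0.2, 0.05, 0.01):
            c = binding_strength(hits, ["tfA"], ["g1"], fdr_alpha=alpha).counts
            if prev is not None:
                assert c.loc["tfA", "g1"] <= prev
            prev = c.loc["tfA", "g1"]

    def test_mask_violation_rejected(self):
        counts = pd.DataFrame([[2]], index=["tfA"], columns=["g1"])
        with pytest.raises(InputError):
            BindingStrengthMatrix(counts=counts,
                                  annotated=pd.Series({"g1": False}))


class TestScanPromoters:
    def test_family_fdr_and_planted_consensus(self, aagt_pwm):
        rng = np.random.default_rng(1)
        proms = []
        for i in range(4):
            seq = list(rng.choice(list("ACGT"), size=120))
            seq[30:34] = list("AAGT")
            proms.append(make_promoter("".join(seq), gene=f"g{i}", tx=f"g{i}.t1"))
        hits = scan_promoters(proms, [aagt_pwm], alpha_raw=0.01,
                              background="uniform")
        assert (hits["padj"] >= hits["pvalue"] - 1e-12).all()
        at30 = hits[(hits["offset"] == 30) & (hits["strand"] == "+")]
        assert len(at30) == 4

    def test_promoter_background_composition(self):
        proms = [make_promoter("AAAACCCCGGGGTTTT")]
        assert np.allclose(promoter_background(proms), 0.25)
        gc = [make_promoter("GGGGCCCC")]
        bg = promoter_background(gc)
        assert bg[1] + bg[2] > 0.99
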