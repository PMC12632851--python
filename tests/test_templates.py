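"""Template model: A-B-A' detection, motif prediction, design, prevalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repeatweaver import (
    ABAPattern,
    ABASearchParams,
    NcRNATemplate,
    batch_aba_prevalence,
    design_template,
    find_aba_patterns,
    predict_repeat_motif,
)
from conftest import LOOP_RNA, random_rna
from oracles import brute_aba_patterns

WHOLE = ABASearchParams(restrict_to_loop=False)


class TestFindPatterns:
    def test_native_loop_top_pattern(self, loop_template):
        """The characterized DRT10 loop yields A=CAAU, B=GAUUC, motif GAATCATTG."""
        top = find_aba_patterns(loop_template, WHOLE)[0]
        assert (top.a_start, top.a_len, top.b_len, top.aprime_start) == (1, 4, 5, 10)
        assert top.motif_dna == "GAATCATTG"

    def test_no_repeated_kmer_gives_empty(self):
        assert find_aba_patterns(NcRNATemplate("x", "ACGU"), WHOLE) == []

    def test_geometry_invariant(self, loop_template):
        for p in find_aba_patterns(loop_template, WHOLE):
            assert p.aprime_start - p.a_start == len(p.motif_dna)
            assert loop_template.sequence[p.a_start - 1 : p.a_start - 1 + p.a_len] == \
                loop_template.sequence[p.aprime_start - 1 : p.aprime_start - 1 + p.a_len]

    def test_subpattern_suppression(self, loop_template):
        """Shorter-A variants of the same A/A' placement are not reported."""
        triples = {(p.a_start, p.a_len, p.b_len) for p in find_aba_patterns(loop_template, WHOLE)}
        assert (1, 4, 5) in triples
        assert (1, 3, 6) not in triples and (1, 2, 7) not in triples
        assert (2, 3, 6) not in triples  # leftward-extensible into (1, 4, 5)

    def test_determinism(self, loop_template):
        a = find_aba_patterns(loop_template, WHOLE)
        b = find_aba_patterns(loop_template, WHOLE)
        assert a == b

    def test_restrict_to_loop_requires_interval(self, loop_template):
        with pytest.raises(ValueError, match="restrict_to_loop"):
            find_aba_patterns(loop_template, ABASearchParams())

    def test_loop_from_structure(self):
        """With a dot-bracket structure, the search runs in the maximal
        unpaired run."""
        seq = "GGG" + LOOP_RNA + "CCC"
        structure = "(((" + "." * len(LOOP_RNA) + ")))"
        t = NcRNATemplate("s", seq, structure=structure)
        top = find_aba_patterns(t, ABASearchParams())[0]
        assert top.a_start == 4 and top.motif_dna == "GAATCATTG"

    def test_non_rna_characters_rejected(self):
        with pytest.raises(ValueError, match="non-RNA"):
            NcRNATemplate("bad", "CAATGATTCCAAT")

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(8, 60),
        min_a=st.sampled_from([2, 3, 4]),
        min_motif=st.integers(2, 6),
    )
    def test_matches_bruteforce_oracle(self, seed, n, min_a, min_motif):
        """Exhaustive enumeration over all (a_start, a_len, b_len) triples
        agrees with the detector on random sequences."""
        rng = np.random.default_rng(seed)
        seq = random_rna(rng, n)
        params = ABASearchParams(
            min_a=min_a, max_a=min_a + 4, min_motif=min_motif,
            max_motif=min_motif + 12, restrict_to_loop=False,
        )
        got = [
            (p.a_start, p.a_len, p.b_len)
            for p in find_aba_patterns(NcRNATemplate("r", seq), params)
        ]
        expected = brute_aba_patterns(
            seq, 1, n, params.min_a, params.max_a, params.min_motif, params.max_motif
        )
        assert got == expected


class TestPredictAndDesign:
    def test_native_motif_prediction(self, loop_template, loop_pattern):
        assert predict_repeat_motif(loop_pattern, loop_template) == "GAATCATTG"

    def test_telomeric_repeat_mapping(self):
        """The human telomerase A+B analogue CCCUAA templates TTAGGG."""
        t = NcRNATemplate("telo", "CCCUAACCC")
        p = ABAPattern.from_coords(t, 1, 3, 3)
        assert predict_repeat_motif(p, t) == "TTAGGG"

    def test_single_base(self):
        t = NcRNATemplate("one", "AA")
        p = ABAPattern.from_coords(t, 1, 1, 0)
        assert predict_repeat_motif(p, t) == "T"

    def test_out_of_bounds_pattern_rejected(self, loop_template):
        good = ABAPattern.from_coords(loop_template, 1, 4, 5)
        shifted = ABAPattern(
            a_start=8, a_len=good.a_len, b_len=good.b_len,
            aprime_start=8 + good.a_len + good.b_len, motif_dna=good.motif_dna,
        )
        with pytest.raises(ValueError, match="out of bounds"):
            predict_repeat_motif(shifted, loop_template)

    def test_design_examples(self):
        assert design_template("GAATCATTG", 4) == "CAAUGAUUCCAAU"
        assert design_template("TTAGGG", 3) == "CCCUAACCC"

    def test_design_a_len_bounds(self):
        with pytest.raises(ValueError, match="a_len"):
            design_template("GAATCATTG", 9)

    @staticmethod
    def _non_degenerate(template_rna: str, a_len: int) -> bool:
        """True when the designed template has no repeated a-mer besides the
        designed A/A' pair, so the designed pattern must rank first."""
        words = [template_rna[i : i + a_len] for i in range(len(template_rna) - a_len + 1)]
        dup = [w for w in set(words) if words.count(w) > 1]
        return dup == [template_rna[:a_len]] and words.count(template_rna[:a_len]) == 2

    def test_design_roundtrip_100_motifs(self):
        """design -> find -> predict reproduces 100 random motifs (4-30 nt).

        Motifs whose designed template is self-similar are excluded: their
        internal repeats legitimately outrank the designed pattern under
        longest-A-first ordering.
        """
        rng = np.random.default_rng(2024)
        accepted = 0
        while accepted < 100:
            length = int(rng.integers(4, 31))
            motif = "".join(rng.choice(list("ACGT"), size=length))
            a_len = int(rng.integers(2, min(7, length)))
            rna = design_template(motif, a_len)
            if not self._non_degenerate(rna, a_len):
                continue
            accepted += 1
            t = NcRNATemplate(f"d{accepted}", rna)
            params = ABASearchParams(
                min_a=2, max_a=10, min_motif=4, max_motif=30, restrict_to_loop=False
            )
            pats = find_aba_patterns(t, params)
            assert pats, motif
            assert predict_repeat_motif(pats[0], t) == motif
            assert (pats[0].a_start, pats[0].a_len, pats[0].b_len) == (
                1, a_len, length - a_len,
            )


class TestBatchPrevalence:
    def test_two_of_three(self):
        templates = [
            NcRNATemplate("a", LOOP_RNA),
            NcRNATemplate("b", design_template("TTAGGGCC", 3)),
            NcRNATemplate("c", "ACGUGGGG"),  # only adjacent GG repeats: no valid pattern
        ]
        result = batch_aba_prevalence(templates, WHOLE)
        assert list(result.table["has_pattern"]) == [True, True, False]
        assert result.fraction == pytest.approx(2 / 3)

    def test_designed_in_random_flanks(self):
        """50 seeded designs embedded in random flanks are all recovered with
        the embedded motif when the search is loop-restricted."""
        rng = np.random.default_rng(7)
        templates, motifs = [], []
        while len(templates) < 50:
            length = int(rng.integers(6, 16))
            motif = "".join(rng.choice(list("ACGT"), size=length))
            a_len = 4 if length > 4 else 3
            rna = design_template(motif, a_len)
            words = [rna[i : i + a_len] for i in range(len(rna) - a_len + 1)]
            if words.count(rna[:a_len]) != 2 or any(
                words.count(w) > 1 for w in set(words) if w != rna[:a_len]
            ):
                continue
            left = random_rna(rng, 20)
            right = random_rna(rng, 20)
            templates.append(
                NcRNATemplate(
                    f"t{len(templates)}", left + rna + right,
                    loop_interval=(21, 20 + len(rna)),
                )
            )
            motifs.append(motif)
        result = batch_aba_prevalence(templates, ABASearchParams())
        assert result.fraction == 1.0
        assert list(result.table["motif_dna"]) == motifs

    def test_empty_input_fraction_missing(self):
        result = batch_aba_prevalence([], WHOLE)
        assert len(result.table) == 0
        assert result.fraction is None

    def test_midpoint(self, loop_template):
        result = batch_aba_prevalence([loop_template], WHOLE)
        # span 1..13 -> midpoint 7
        assert result.table["motif_midpoint"].iloc[0] == pytest.approx(7.0)
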