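"""Mechanistic repeat-addition simulator and synthetic read generator."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from repeatweaver import (
    ABAPattern,
    NcRNATemplate,
    RealignRules,
    SimConfig,
    generate_dataset,
    simulate_product,
)
from repeatweaver.seqio import write_fastq
from conftest import LOOP_RNA, make_datasets

ALWAYS = RealignRules(p_success_by_matchlen={2: 1.0, 3: 1.0, 4: 1.0})


def deterministic_config(max_cycles):
    """Continuation certain, realignment certain, length decay disabled."""
    return SimConfig(
        p_continue=1.0, max_cycles=max_cycles, realign_rules=ALWAYS,
        template_len_midpoint=1000.0, seed=0,
    )


class TestSimulateProduct:
    def test_no_continuation_single_unit(self, loop_template, loop_pattern):
        cfg = SimConfig(p_continue=0.0, seed=1)
        p = simulate_product(loop_template, loop_pattern, cfg)
        assert p.sequence == "GAATCATTG" and p.n_repeats == 1
        assert p.protein_primed_5prime

    def test_forced_five_cycles(self, loop_template, loop_pattern):
        p = simulate_product(loop_template, loop_pattern, deterministic_config(5))
        assert p.sequence == "GAATCATTG" * 5
        assert p.n_repeats == 5
        assert p.realign_sites == (10,) * 4  # canonical A' start every cycle

    @pytest.mark.parametrize(
        "sequence",
        ["GUAUGAUUCCAAU", "CAAUGAUUCGUAU"],  # A mutated alone, A' mutated alone
        ids=["mutate_A", "mutate_Aprime"],
    )
    def test_single_sided_mutation_blocks_repeat_addition(self, sequence):
        t = NcRNATemplate("mut", sequence)
        pat = ABAPattern.from_coords(t, 1, 4, 5, check_identity=False)
        rng = np.random.default_rng(11)
        cfg = SimConfig(seed=0)
        singles = sum(
            1 for _ in range(200) if simulate_product(t, pat, cfg, rng).n_repeats == 1
        )
        assert singles >= 190  # >= 95%

    def test_compensatory_mutation_restores_mutated_repeat(self):
        """Jointly mutating A and A' restores processive synthesis of the
        correspondingly mutated motif."""
        t = NcRNATemplate("comp", "GUAUGAUUCGUAU")
        pat = ABAPattern.from_coords(t, 1, 4, 5, check_identity=False)
        assert pat.motif_dna == "GAATCATAC"
        rng = np.random.default_rng(13)
        cfg = SimConfig(seed=0)
        prods = [simulate_product(t, pat, cfg, rng) for _ in range(200)]
        multi = [p for p in prods if p.n_repeats >= 3]
        assert len(multi) >= 100
        for p in multi[:20]:
            assert p.sequence == "GAATCATAC" * p.n_repeats

    def test_mean_repeats_monotone_in_p_continue(self, loop_template, loop_pattern):
        grid = [0.2, 0.5, 0.8, 0.95, 0.99]
        means = []
        for pc in grid:
            rng = np.random.default_rng(5)
            cfg = SimConfig(p_continue=pc, seed=0)
            means.append(
                np.mean([
                    simulate_product(loop_template, loop_pattern, cfg, rng).n_repeats
                    for _ in range(1000)
                ])
            )
        rho = stats.spearmanr(grid, means).statistic
        assert rho > 0
        assert means == sorted(means)

    def test_mean_repeats_monotone_in_success_probs(self, loop_template, loop_pattern):
        means = []
        for scale in (0.2, 0.6, 1.0):
            rules = RealignRules(
                p_success_by_matchlen={2: 0.05 * scale, 3: 0.5 * scale, 4: 0.95 * scale}
            )
            rng = np.random.default_rng(6)
            cfg = SimConfig(realign_rules=rules, seed=0)
            means.append(
                np.mean([
                    simulate_product(loop_template, loop_pattern, cfg, rng).n_repeats
                    for _ in range(1000)
                ])
            )
        assert means == sorted(means)

    @pytest.mark.parametrize("b_len,lo,hi", [(5, 0.80, 1.0), (10, 0.10, 0.80), (20, 0.0, 0.01)])
    def test_template_length_effect(self, b_len, lo, hi):
        """Native B supports processive addition, a 10-mer B attenuates it,
        a 20-mer B abolishes it (below a 1% multi-repeat fraction)."""
        rng0 = np.random.default_rng(3)
        b = "GAUUC" if b_len == 5 else "".join(rng0.choice(list("ACGU"), size=b_len))
        t = NcRNATemplate(f"B{b_len}", "CAAU" + b + "CAAU")
        pat = ABAPattern.from_coords(t, 1, 4, b_len)
        rng = np.random.default_rng(17)
        cfg = SimConfig(seed=0)
        multi = sum(
            1 for _ in range(2000)
            if simulate_product(t, pat, cfg, rng).n_repeats >= 2
        )
        assert lo <= multi / 2000 <= hi

    def test_cryptic_site_in_b_gives_irregular_units(self):
        """A copy of A inside B offers a cryptic re-annealing register that
        outscores the canonical A', producing mixed repeat-unit lengths."""
        t = NcRNATemplate("cryptic", "CAAU" + "CAAUC" + "CAAU")
        pat = ABAPattern.from_coords(t, 1, 4, 5)
        rng = np.random.default_rng(23)
        cfg = SimConfig(seed=0)
        sites = set()
        unit_lengths = set()
        for _ in range(300):
            p = simulate_product(t, pat, cfg, rng)
            sites.update(p.realign_sites)
            if p.n_repeats > 1:
                unit_lengths.add(len(p.sequence) % 9)
        assert any(s != pat.aprime_start for s in sites)
        assert len(unit_lengths) > 1  # irregular spacing

    def test_pattern_out_of_bounds_rejected(self, loop_template, loop_pattern):
        bad = ABAPattern(
            a_start=6, a_len=4, b_len=5, aprime_start=15, motif_dna="GAATCATTG"
        )
        with pytest.raises(ValueError, match="out of bounds"):
            simulate_product(loop_template, bad, SimConfig(seed=0))


class TestGenerateDataset:
    def test_seeded_fastq_byte_identical(self, tmp_path, loop_template, loop_pattern):
        ref = "ACGT" * 100
        cfg = SimConfig(read_len=50, seed=99)
        paths = []
        for name in ("a.fastq", "b.fastq"):
            rs = generate_dataset(loop_template, loop_pattern, ref, cfg, 300, "WT")
            path = tmp_path / name
            write_fastq(path, [(r.id, r.sequence) for r in rs])
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_background_fraction_one_is_null(self, loop_template, loop_pattern):
        cfg = SimConfig(background_fraction=1.0, seed=4)
        rs = generate_dataset(loop_template, loop_pattern, "ACGT" * 200, cfg, 500, "WT")
        assert all(r.truth == "background" for r in rs)

    def test_repeat_fraction_matches_binomial_expectation(self, loop_template, loop_pattern):
        """10,000 WT reads at background_fraction 0.7 carry ~30% +/- 2%
        repeat-product truth labels."""
        cfg = SimConfig(seq_error_rate=0.0, seed=12)
        rs = generate_dataset(loop_template, loop_pattern, "ACGT" * 800, cfg, 10000, "WT")
        frac = sum(1 for r in rs if r.truth == "repeat_product") / len(rs)
        assert abs(frac - 0.30) <= 0.02

    def test_rt_dead_is_background_only(self):
        cfg = SimConfig(seed=5)
        rs = generate_dataset(None, None, "ACGT" * 200, cfg, 400, "RT_dead")
        assert all(r.truth == "background" for r in rs)
        assert {r.condition for r in rs} == {"RT_dead"}

    def test_read_lengths_bounded(self, loop_template, loop_pattern):
        cfg = SimConfig(read_len=80, seed=8)
        rs = generate_dataset(loop_template, loop_pattern, "ACGT" * 200, cfg, 500, "WT")
        assert all(len(r.sequence) <= 80 for r in rs)
        n_background = sum(1 for r in rs if r.truth == "background")
        # artifacts are background-labeled but excluded from the CPM denominator
        assert 0 < rs.n_reference_mapping <= n_background

    def test_invalid_n_reads(self, loop_template, loop_pattern):
        with pytest.raises(ValueError, match="n_reads"):
            generate_dataset(loop_template, loop_pattern, "ACGT" * 50, SimConfig(seed=1), 0)

    def test_wt_requires_pattern(self):
        with pytest.raises(ValueError, match="pattern"):
            generate_dataset(None, None, "ACGT" * 50, SimConfig(seed=1), 10, "WT")

    def test_seed_required(self, loop_template, loop_pattern):
        with pytest.raises(ValueError, match="seed"):
            generate_dataset(loop_template, loop_pattern, "ACGT" * 50, SimConfig(), 10)
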