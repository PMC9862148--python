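"""The QC -> invariant-filter -> pattern-match pipeline on hand-built toy
tables, cross-checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinscope.config import SimulationConfig
from twinscope.errors import TwinscopeError
from twinscope.genetics import (
    GenotypeTable,
    annotate_snps,
    apply_gencall_qc,
    background_comparison,
    drop_family_invariant_snps,
    find_cosegregating_snps,
    normalize_genotype,
    split_panel_background,
)
from twinscope.panel import GenePanel, GeneInterval
from twinscope.synthdata import simulate_genotypes

SUBJECTS = ["mother", "father", "proband", "td_twin", "older_sibling"]
AFFECTED = ("proband", "older_sibling")
DISCORDANT = "td_twin"


def make_table(rows, subjects=SUBJECTS):
    """rows: list of (pos, {subject: (gt or None, gc)}) on one chromosome."""
    data = []
    for i, (pos, calls) in enumerate(rows):
        row = {
            "snp_id": f"t{i:03d}", "chrom": "1", "pos": pos,
            "ref": "A", "alt": "G", "gene_symbol": "", "functional_class": "",
        }
        for s in subjects:
            gt, gc = calls.get(s, ("A/A", 0.9))
            row[f"gt_{s}"] = normalize_genotype(gt)
            row[f"gc_{s}"] = gc
        data.append(row)
    return GenotypeTable(pd.DataFrame(data), subjects)


class TestGenCallQC:
    def test_boundary_score_becomes_missing(self):
        t = make_table([(100, {"proband": ("A/G", 0.15)})])
        out = apply_gencall_qc(t, 0.15)
        assert out.df.gt_proband.iloc[0] is None

    def test_just_above_boundary_is_retained(self):
        t = make_table([(100, {"proband": ("A/G", 0.1500001)})])
        out = apply_gencall_qc(t, 0.15)
        assert out.df.gt_proband.iloc[0] == "A/G"

    def test_identity_when_all_scores_high(self):
        t = make_table([(100, {}), (200, {"father": ("A/G", 1.0)})])
        out = apply_gencall_qc(t, 0.15)
        pd.testing.assert_frame_equal(out.df, t.df)

    @given(
        scores=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20),
        t_low=st.floats(0, 1, allow_nan=False),
        t_high=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_lower_threshold_never_drops_more_calls(self, scores, t_low, t_high):
        t_low, t_high = sorted((t_low, t_high))
        t = make_table([(100 + 10 * i, {"proband": ("A/G", gc)}) for i, gc in enumerate(scores)])
        kept_low = apply_gencall_qc(t, t_low).df.gt_proband.notna().sum()
        kept_high = apply_gencall_qc(t, t_high).df.gt_proband.notna().sum()
        assert kept_low >= kept_high


class TestInvariantFilter:
    def test_snp_identical_in_all_five_is_removed(self):
        t = make_table([(100, {s: ("A/A", 0.9) for s in SUBJECTS})])
        assert len(drop_family_invariant_snps(t)) == 0

    def test_single_differing_subject_retains_snp(self):
        t = make_table([(100, {"father": ("A/G", 0.9)})])
        assert len(drop_family_invariant_snps(t)) == 1

    def test_toy_table_counts_match_enumeration(self):
        """10 SNPs: 3 invariant, 1 with a missing call, 6 variable -> 6 kept."""
        rows = []
        for i in range(3):  # invariant
            rows.append((100 + i, {s: ("G/G", 0.9) for s in SUBJECTS}))
        rows.append((200, {"mother": (None, 0.9), "father": ("A/G", 0.9)}))  # missing
        for i in range(6):  # variable
            rows.append((300 + i, {"proband": ("A/G", 0.9)}))
        t = make_table(rows)
        out = drop_family_invariant_snps(t)
        assert len(out) == 6
        # brute-force oracle over the same rows
        expected = 0
        for _, calls in rows:
            gts = [normalize_genotype(calls.get(s, ("A/A", 0.9))[0]) for s in SUBJECTS]
            if all(g is not None for g in gts) and len(set(gts)) >= 2:
                expected += 1
        assert len(out) == expected

    def test_empty_subject_list_raises(self):
        t = make_table([(100, {})])
        with pytest.raises(TwinscopeError):
            drop_family_invariant_snps(t, [])


class TestCosegregationPattern:
    def test_affected_share_twin_differs_matches(self):
        t = make_table([(100, {"proband": ("A/G", .9), "older_sibling": ("A/G", .9),
                               "td_twin": ("A/A", .9)})])
        res = find_cosegregating_snps(t, AFFECTED, DISCORDANT)
        assert res.matching_snps == ["t000"]

    def test_allele_order_is_ignored(self):
        t = make_table([(100, {"proband": ("A/G", .9), "older_sibling": ("G/A", .9),
                               "td_twin": ("A/G", .9)})])
        res = find_cosegregating_snps(t, AFFECTED, DISCORDANT)
        assert res.matching_snps == []

    def test_missing_sibling_call_excludes_snp(self):
        t = make_table([(100, {"proband": ("A/G", .9), "older_sibling": ("A/G", .9),
                               "td_twin": (None, .9)})])
        res = find_cosegregating_snps(t, AFFECTED, DISCORDANT)
        assert res.matching_snps == [] and res.n_pattern_evaluated == 0

    def test_tallies_sum_to_match_count(self, cohort, panel, small_cfg):
        sim = simulate_genotypes(cohort, panel, small_cfg)
        variable = drop_family_invariant_snps(apply_gencall_qc(sim.table))
        res = find_cosegregating_snps(variable, AFFECTED, DISCORDANT)
        n = len(res.matching_snps)
        assert sum(res.per_gene_counts.values()) == n
        assert sum(res.per_class_counts.values()) == n

    def test_matches_brute_force_triple_loop(self, cohort, panel):
        cfg = SimulationConfig(seed=17, n_snps_panel=200, n_snps_background=100,
                               coseg_fraction=0.12, invariant_rate=0.1, missing_rate=0.02)
        sim = simulate_genotypes(cohort, panel, cfg)
        table = drop_family_invariant_snps(apply_gencall_qc(sim.table))
        res = find_cosegregating_snps(table, AFFECTED, DISCORDANT)
        expected = []
        for row in table.df.itertuples():  # independent brute force
            g1 = getattr(row, "gt_proband")
            g2 = getattr(row, "gt_older_sibling")
            g3 = getattr(row, "gt_td_twin")
            if g1 is None or g2 is None or g3 is None:
                continue
            if sorted(g1.split("/")) == sorted(g2.split("/")) and \
               sorted(g1.split("/")) != sorted(g3.split("/")):
                expected.append(row.snp_id)
        assert sorted(res.matching_snps) == sorted(expected)

    def test_pipeline_is_idempotent(self, cohort, panel, small_cfg):
        sim = simulate_genotypes(cohort, panel, small_cfg)
        once = drop_family_invariant_snps(apply_gencall_qc(sim.table))
        twice = drop_family_invariant_snps(apply_gencall_qc(once))
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestAnnotation:
    TOY_PANEL = GenePanel(
        genes=[GeneInterval("GENEA", "1", 1000, 2000),
               GeneInterval("GENEB", "1", 10_000, 12_000)],
        flank_bp=500,
    )

    def test_containment_and_flank_rules(self):
        t = make_table([(1500, {}), (9_600, {}), (50_000, {})])
        out = annotate_snps(t, self.TOY_PANEL)
        assert list(out.df.gene_symbol) == ["GENEA", "GENEB", ""]
        assert list(out.df.functional_class) == ["intronic", "intergenic", "unannotated"]

    def test_existing_annotation_is_honoured(self):
        t = make_table([(1500, {})])
        t.df["functional_class"] = ["utr3"]
        out = annotate_snps(t, self.TOY_PANEL)
        assert list(out.df.functional_class) == ["utr3"]

    def test_assignments_match_brute_force_scan(self):
        positions = [900, 1000, 2000, 2600, 9_400, 11_999]
        t = make_table([(p, {}) for p in positions])
        out = annotate_snps(t, self.TOY_PANEL)
        for pos, sym in zip(positions, out.df.gene_symbol):
            hits = [g.symbol for g in self.TOY_PANEL.genes
                    if g.start - 500 <= pos <= g.end + 500]
            assert sym == (hits[0] if hits else "")


class TestBackgroundComparison:
    def test_equal_planting_gives_matching_proportions(self, cohort, panel):
        cfg = SimulationConfig(seed=5, n_snps_panel=400, n_snps_background=400,
                               coseg_fraction=0.10, invariant_rate=0.0, missing_rate=0.0)
        sim = simulate_genotypes(cohort, panel, cfg)
        variable = drop_family_invariant_snps(sim.table)
        pt, bt = split_panel_background(variable, panel)
        res = find_cosegregating_snps(pt, AFFECTED, DISCORDANT)
        p_panel, p_bg = background_comparison(res, bt, AFFECTED, DISCORDANT)
        assert p_panel == pytest.approx(0.10, abs=0.02)
        assert p_bg == pytest.approx(0.10, abs=0.02)

    def test_zero_background_planting_gives_zero_proportion(self, cohort, panel):
        cfg = SimulationConfig(seed=6, n_snps_panel=50, n_snps_background=200,
                               coseg_fraction=0.0, invariant_rate=0.0, missing_rate=0.0)
        sim = simulate_genotypes(cohort, panel, cfg)
        variable = drop_family_invariant_snps(sim.table)
        pt, bt = split_panel_background(variable, panel)
        res = find_cosegregating_snps(pt, AFFECTED, DISCORDANT)
        _, p_bg = background_comparison(res, bt, AFFECTED, DISCORDANT)
        assert p_bg == 0.0
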