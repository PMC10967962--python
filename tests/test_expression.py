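"""FPKM ingestion, percentile thresholds, reaction mapping and binning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tigsmm.expression import (
    ExpressionProfile,
    ThresholdConfig,
    bin_expression,
    compute_threshold,
    map_expression,
    read_fpkm,
    write_fpkm,
)
from tigsmm.model_io import MetabolicModel, Metabolite, Reaction, ReactionKind, parse_gpr


def _micro_model(gpr_text):
    return MetabolicModel(
        id="micro",
        metabolites=[Metabolite("A_c")],
        reactions=[
            Reaction("EX", {"A_c": -1.0}, lb=-1.0, kind=ReactionKind.EXCHANGE),
            Reaction("R1", {"A_c": -1.0}, gpr=parse_gpr(gpr_text) if gpr_text else None),
            Reaction("BIO", {"A_c": -1.0}, kind=ReactionKind.BIOMASS),
        ],
        compartments={"c": "c"},
        biomass_id="BIO",
    )


class TestReadFpkm:
    def test_two_condition_table(self, tmp_path):
        path = tmp_path / "fpkm.tsv"
        path.write_text("gene_id\tLG\tLS\ng1\t1.5\t0\ng2\t10\t3.2\ng3\t0\t100\n")
        profiles = read_fpkm(path)
        assert [p.condition for p in profiles] == ["LG", "LS"]
        assert all(len(p.values) == 3 for p in profiles)
        assert profiles[1].values["g3"] == 100.0

    @pytest.mark.parametrize(
        "body",
        [
            "gene_id\tLG\ng1\t1\ng1\t2\n",  # duplicate gene
            "gene_id\tLG\ng1\t-3\n",  # negative FPKM
            "gene_id\tLG\ng1\tabc\n",  # non-numeric
            "",  # empty file
        ],
    )
    def test_bad_tables_rejected(self, tmp_path, body):
        path = tmp_path / "bad.tsv"
        path.write_text(body)
        with pytest.raises(Exception):
            read_fpkm(path)

    def test_roundtrip_through_writer(self, tmp_path):
        profiles = [
            ExpressionProfile("LG", {"g1": 1.0, "g2": 5.5}),
            ExpressionProfile("LS", {"g1": 0.0, "g2": 9.25}),
        ]
        write_fpkm(profiles, tmp_path / "f.tsv")
        back = read_fpkm(tmp_path / "f.tsv")
        assert back[0].values == profiles[0].values
        assert back[1].values == profiles[1].values


class TestThreshold:
    def test_p50_linear_interpolation(self):
        prof = ExpressionProfile("x", {f"g{i}": v for i, v in enumerate([1, 2, 3, 4])})
        cfg = ThresholdConfig(percentile=50, population="all_genes")
        assert compute_threshold(prof, None, cfg) == pytest.approx(2.5)

    def test_single_value_any_percentile(self):
        prof = ExpressionProfile("x", {"g": 7.0})
        for p in (0, 33, 50, 99, 100):
            cfg = ThresholdConfig(percentile=p, population="all_genes")
            assert compute_threshold(prof, None, cfg) == pytest.approx(7.0)

    def test_matches_sort_based_oracle_on_large_sample(self):
        rng = np.random.default_rng(42)
        vals = rng.lognormal(2, 1.2, size=1412)
        prof = ExpressionProfile("x", {f"g{i}": v for i, v in enumerate(vals)})
        # independent oracle: sort and interpolate between order statistics
        srt = np.sort(vals)
        h = (len(srt) - 1) * 0.5
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        expected = srt[lo] + (h - lo) * (srt[hi] - srt[lo])
        cfg = ThresholdConfig(percentile=50, population="all_genes")
        assert compute_threshold(prof, None, cfg) == pytest.approx(expected, rel=1e-12)

    def test_metabolic_population_restricts_to_model_genes(self, textbook):
        values = {g: 100.0 for g in ["g1", "g2", "g3", "g4"]}
        values.update({f"other{i}": 0.0 for i in range(100)})
        prof = ExpressionProfile("x", values)
        assert compute_threshold(prof, textbook, ThresholdConfig()) == pytest.approx(100.0)
        all_cfg = ThresholdConfig(population="all_genes")
        assert compute_threshold(prof, None, all_cfg) == pytest.approx(0.0)

    def test_monotone_in_percentile_with_exact_endpoints(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 50, size=101)
        prof = ExpressionProfile("x", {f"g{i}": v for i, v in enumerate(vals)})
        thresholds = [
            compute_threshold(prof, None, ThresholdConfig(percentile=p, population="all_genes"))
            for p in range(0, 101, 10)
        ]
        assert thresholds == sorted(thresholds)
        assert thresholds[0] == pytest.approx(vals.min())
        assert thresholds[-1] == pytest.approx(vals.max())

    def test_empty_population_rejected(self, textbook):
        prof = ExpressionProfile("x", {"unrelated": 1.0})
        with pytest.raises(ValueError):
            compute_threshold(prof, textbook, ThresholdConfig())


class TestMapExpression:
    def test_or_takes_max_under_both_rules(self):
        m = _micro_model("g1 or g2")
        prof = ExpressionProfile("x", {"g1": 5.0, "g2": 10.0})
        for rule in ("max_over_genes", "gpr_aware"):
            assert map_expression(m, prof, rule).values["R1"] == 10.0

    def test_and_takes_min_only_when_gpr_aware(self):
        m = _micro_model("g1 and g2")
        prof = ExpressionProfile("x", {"g1": 5.0, "g2": 10.0})
        assert map_expression(m, prof, "gpr_aware").values["R1"] == 5.0
        assert map_expression(m, prof, "max_over_genes").values["R1"] == 10.0

    def test_no_gpr_or_no_scored_gene_is_unscored(self):
        m = _micro_model(None)
        prof = ExpressionProfile("x", {"g1": 5.0})
        rxn_expr = map_expression(m, prof)
        assert not rxn_expr.is_scored("R1") and not rxn_expr.is_scored("EX")
        m2 = _micro_model("gZ")  # gene absent from the profile
        assert not map_expression(m2, prof).is_scored("R1")

    def test_gpr_aware_never_exceeds_max_rule(self, textbook):
        rng = np.random.default_rng(1)
        prof = ExpressionProfile(
            "x", {g: float(rng.lognormal(2, 1)) for g in sorted(textbook.genes)}
        )
        hi = map_expression(textbook, prof, "max_over_genes")
        lo = map_expression(textbook, prof, "gpr_aware")
        for rxn_id, val in lo.values.items():
            assert val <= hi.values[rxn_id] + 1e-12


class TestBins:
    def test_example_partition(self):
        prof = ExpressionProfile(
            "x", dict(zip("abcde", [0.0, 0.5, 5.0, 50.0, 500.0]))
        )
        bins = bin_expression(prof)
        assert bins.counts == {"sub_1": 1, "1_10": 1, "10_100": 1, "ge_100": 1}
        assert bins.zero == 1
        assert bins.fraction_expressed == pytest.approx(0.8)

    def test_all_zero(self):
        bins = bin_expression(ExpressionProfile("x", {f"g{i}": 0.0 for i in range(4)}))
        assert sum(bins.counts.values()) == 0 and bins.zero == 4

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1e6, allow_nan=False), min_size=1, max_size=60))
    def test_bins_partition_every_gene_exactly_once(self, values):
        prof = ExpressionProfile("x", {f"g{i}": v for i, v in enumerate(values)})
        bins = bin_expression(prof)
        assert sum(bins.counts.values()) + bins.zero == len(values)
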