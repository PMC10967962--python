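"""Model containers, GPR parsing and the two on-disk dialects."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from tigsmm.model_io import (
    GprExpr,
    GprParseError,
    MetabolicModel,
    Metabolite,
    ModelIOError,
    ModelValidationError,
    Reaction,
    ReactionKind,
    census,
    parse_gpr,
    read_model,
    write_model,
)


class TestGprParsing:
    @pytest.mark.parametrize(
        "text,expected",
        [
            (
                "CCM_04436 and CCM_04437",
                GprExpr.and_(GprExpr.gene_("CCM_04436"), GprExpr.gene_("CCM_04437")),
            ),
            ("g1", GprExpr.gene_("g1")),
            (
                "(g1 and g2) or g3",
                GprExpr.or_(
                    GprExpr.and_(GprExpr.gene_("g1"), GprExpr.gene_("g2")),
                    GprExpr.gene_("g3"),
                ),
            ),
            # "and" binds tighter than "or" without parentheses
            (
                "g1 or g2 and g3",
                GprExpr.or_(
                    GprExpr.gene_("g1"),
                    GprExpr.and_(GprExpr.gene_("g2"), GprExpr.gene_("g3")),
                ),
            ),
            # case-insensitive keywords, n-ary flattening
            (
                "g1 AND g2 And g3",
                GprExpr(
                    "and",
                    children=(
                        GprExpr.gene_("g1"),
                        GprExpr.gene_("g2"),
                        GprExpr.gene_("g3"),
                    ),
                ),
            ),
        ],
    )
    def test_grammar(self, text, expected):
        assert parse_gpr(text) == expected

    @pytest.mark.parametrize(
        "bad", ["", "(g1 and g2", "g1 and", "and g1", "g1 or or g2", "g1)"]
    )
    def test_malformed_text_raises_with_position(self, bad):
        with pytest.raises(GprParseError):
            parse_gpr(bad)

    def test_node_invariants(self):
        with pytest.raises(ValueError):
            GprExpr("and", children=(GprExpr.gene_("g1"),))
        with pytest.raises(ValueError):
            GprExpr("gene", gene="")

    _gene_ids = st.from_regex(r"g_[a-z0-9]{1,4}", fullmatch=True)
    _trees = st.recursive(
        st.builds(GprExpr.gene_, _gene_ids),
        lambda kids: st.builds(
            lambda kind, cs: GprExpr(kind, children=tuple(cs)),
            st.sampled_from(["and", "or"]),
            st.lists(kids, min_size=2, max_size=3),
        ),
        max_leaves=10,
    )

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(_trees)
    def test_serialize_parse_roundtrip_is_identity(self, tree):
        assert parse_gpr(tree.serialize()) == tree


def _toy_model():
    return MetabolicModel(
        id="toy",
        metabolites=[Metabolite("A_c", compartment="c"), Metabolite("B_c", compartment="c")],
        reactions=[
            Reaction("EX_A", {"A_c": -1.0}, lb=-5.0, kind=ReactionKind.EXCHANGE),
            Reaction("R1", {"A_c": -1.0, "B_c": 1.0}, gpr=parse_gpr("gX"), lb=0.0),
            Reaction("BIO", {"B_c": -1.0}, lb=0.0, kind=ReactionKind.BIOMASS),
        ],
        compartments={"c": "cytosol"},
        biomass_id="BIO",
    )


class TestValidation:
    def test_valid_model_passes(self):
        _toy_model().validate()

    def test_missing_biomass_rejected(self):
        m = _toy_model()
        m.biomass_id = None
        m.reactions[2].kind = ReactionKind.ENZYMATIC
        with pytest.raises(ModelValidationError):
            m.validate()

    def test_unresolved_metabolite_names_reaction(self):
        m = _toy_model()
        m.reactions[1].stoich["ghost_c"] = 1.0
        with pytest.raises(ModelValidationError, match="R1.*ghost_c"):
            m.validate()

    def test_crossed_bounds_rejected(self):
        m = _toy_model()
        m.reactions[1].lb, m.reactions[1].ub = 5.0, 1.0
        with pytest.raises(ModelValidationError):
            m.validate()

    def test_multi_metabolite_exchange_rejected(self):
        m = _toy_model()
        m.reactions[0].stoich["B_c"] = 1.0
        with pytest.raises(ModelValidationError):
            m.validate()


class TestCensus:
    def test_textbook_counts(self, textbook):
        c = census(textbook)
        assert (c.n_genes, c.n_metabolites, c.n_reactions) == (4, 6, 10)
        assert (c.n_exchange, c.n_biomass, c.n_transport, c.n_spontaneous) == (3, 1, 2, 1)

    def test_kind_counts_partition_reactions(self, textbook):
        c = census(textbook)
        assert c.n_enzymatic + c.n_nonenzymatic == c.n_reactions
        assert (
            c.n_spontaneous + c.n_transport + c.n_exchange + c.n_biomass
            == c.n_nonenzymatic
        )

    def test_empty_model_all_zeros(self):
        c = census(MetabolicModel(id="empty"))
        assert all(v == 0 for v in c.as_dict().values())


class TestRoundTrips:
    def test_tsv_roundtrip_preserves_everything(self, textbook, tmp_path):
        write_model(textbook, tmp_path / "m", dialect="tsv")
        back = read_model(tmp_path / "m", dialect="tsv")
        assert census(back) == census(textbook)
        for a, b in zip(textbook.reactions, back.reactions):
            assert (a.id, a.kind, a.lb, a.ub, a.subsystem) == (b.id, b.kind, b.lb, b.ub, b.subsystem)
            assert a.stoich == b.stoich
            assert (a.gpr is None) == (b.gpr is None)
            if a.gpr is not None:
                assert a.gpr == b.gpr

    def test_sbml_roundtrip_preserves_everything(self, textbook, tmp_path):
        write_model(textbook, tmp_path / "m.xml", dialect="sbml_fbc")
        back = read_model(tmp_path / "m.xml", dialect="sbml_fbc")
        assert census(back) == census(textbook)
        assert back.biomass_id == textbook.biomass_id
        for a, b in zip(textbook.reactions, back.reactions):
            assert a.kind == b.kind and a.gpr == b.gpr
            assert a.stoich.keys() == b.stoich.keys()
            for met in a.stoich:
                assert math.isclose(a.stoich[met], b.stoich[met], abs_tol=1e-9)
            assert math.isclose(a.lb, b.lb, abs_tol=1e-9)
            assert math.isclose(a.ub, b.ub, abs_tol=1e-9)

    def test_exotic_compartment_preserved(self, tmp_path):
        m = _toy_model()
        m.compartments = {"c": "cytosol", "px9": "weird organelle"}
        m.metabolites[1].compartment = "px9"
        for dialect, path in [("tsv", tmp_path / "t"), ("sbml_fbc", tmp_path / "m.xml")]:
            write_model(m, path, dialect=dialect)
            back = read_model(path, dialect=dialect)
            assert back.metabolites[1].compartment == "px9"

    def test_duplicate_reaction_id_rejected(self, tmp_path):
        (tmp_path / "metabolites.tsv").write_text("id\tname\tcompartment\nA_c\t\tc\n")
        (tmp_path / "reactions.tsv").write_text(
            "id\tname\tequation\tlb\tub\tgpr\tsubsystem\tkind\n"
            "R1\t\tA_c -->\t0\t10\t\t\tbiomass\n"
            "R1\t\tA_c -->\t0\t10\t\t\texchange\n"
        )
        with pytest.raises(ModelIOError, match="duplicate"):
            read_model(tmp_path, dialect="tsv")

    def test_default_bounds_follow_arrow(self, tmp_path):
        (tmp_path / "metabolites.tsv").write_text("id\tname\tcompartment\nA_c\t\tc\nB_c\t\tc\n")
        (tmp_path / "reactions.tsv").write_text(
            "id\tname\tequation\tlb\tub\tgpr\tsubsystem\tkind\n"
            "EX\t\tA_c <=>\t\t\t\t\texchange\n"
            "R1\t\tA_c --> B_c\t\t\t\t\t\n"
            "BIO\t\tB_c -->\t\t\t\t\tbiomass\n"
        )
        m = read_model(tmp_path, dialect="tsv")
        assert (m.get_reaction("EX").lb, m.get_reaction("EX").ub) == (-1000.0, 1000.0)
        assert (m.get_reaction("R1").lb, m.get_reaction("R1").ub) == (0.0, 1000.0)
        # kind inference: single-metabolite without label -> exchange
        assert m.get_reaction("R1").kind == ReactionKind.SPONTANEOUS
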