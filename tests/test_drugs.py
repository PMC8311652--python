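"""Drug parsing, filtering, the interaction matrix, and the 2x2 chi-square."""

import io

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from epipharm.drugs import (
    FOSTAMATINIB_EPIGENETIC_GENES,
    DrugRecord,
    TargetRecord,
    build_interaction_matrix,
    category_histogram,
    coverage_statistics,
    group_counts,
    parse_drug_database,
    percentage,
    select_drugs,
    two_by_two_chi_square,
    write_drug_database,
)
from epipharm.registry import classify_substrate
from epipharm.synthetic import SyntheticSpec, generate_drug_database, generate_enzyme_registry


def drug(drug_id="D1", name=None, groups=("approved",), categories=(), targets=()):
    return DrugRecord(
        drug_id=drug_id,
        name=name or drug_id,
        groups=frozenset(groups),
        categories=frozenset(categories),
        targets=tuple(targets),
    )


def target(gene, organism="Humans"):
    return TargetRecord(uniprot_id=f"U_{gene}", organism=organism, gene_symbol=gene)


class TestParse:
    XML = """<drugs>
      <drug id="DB1"><name>one</name>
        <groups><group>approved</group><group>investigational</group></groups>
        <categories><category>kinase inhibitors</category></categories>
        <targets><target><uniprot_id>P1</uniprot_id><organism>Humans</organism>
          <gene_symbol>HDAC1</gene_symbol></target></targets>
      </drug>
      <drug id="DB2"><name>two</name><groups><group>experimental</group></groups>
        <categories/><targets/></drug>
      <drug id="DB3"><name>three</name><groups><group>approved</group></groups>
        <categories/><targets/></drug>
    </drugs>"""

    def test_dual_membership_preserved(self):
        drugs = parse_drug_database(io.StringIO(self.XML))
        assert len(drugs) == 3
        counts = group_counts(drugs)
        assert sum(counts.values()) == 4  # dual membership counted per group

    def test_empty_database(self):
        assert parse_drug_database(io.StringIO("<drugs/>")) == []

    def test_roundtrip_with_writer(self, tmp_path):
        drugs = parse_drug_database(io.StringIO(self.XML))
        path = tmp_path / "drugs.xml"
        write_drug_database(drugs, path)
        assert parse_drug_database(path) == drugs


class TestSelect:
    def test_experimental_excluded(self):
        assert select_drugs([drug(groups=("experimental",))]) == []

    def test_dual_group_included_once(self):
        selected = select_drugs([drug(groups=("approved", "investigational"))])
        assert len(selected) == 1

    def test_nonhuman_targets_dropped(self):
        d = drug(targets=(target("HDAC1"), target("Gsk3b", organism="Mouse")))
        (selected,) = select_drugs([d])
        assert [t.gene_symbol for t in selected.targets] == ["HDAC1"]

    def test_idempotent(self):
        drugs = [
            drug("D1", groups=("approved",), targets=(target("A"), target("B", "Mouse"))),
            drug("D2", groups=("withdrawn",)),
        ]
        once = select_drugs(drugs)
        assert select_drugs(once) == once


class TestInteractionMatrix:
    def test_fostamatinib_row_marginal_is_20(self, reference_registry):
        targets = [target(g) for g in FOSTAMATINIB_EPIGENETIC_GENES]
        targets += [target(f"DECOY{i}") for i in range(30)]
        fosta = drug("DB12010", name="fostamatinib", targets=targets)
        matrix = build_interaction_matrix([fosta], reference_registry)
        assert matrix.row_marginals["fostamatinib"] == 20

    def test_fostamatinib_targets_all_histone_substrate(self, reference_registry):
        actions = {r.gene_symbol: r.enzyme_action for r in reference_registry}
        assert all(
            classify_substrate(actions[g]) == "histone"
            for g in FOSTAMATINIB_EPIGENETIC_GENES
        )

    def test_all_decoys_gives_empty_matrix(self, reference_registry):
        d = drug(targets=tuple(target(f"DECOY{i}") for i in range(5)))
        matrix = build_interaction_matrix([d], reference_registry)
        assert matrix.total_interactions == 0
        assert matrix.drug_names == [] and matrix.enzyme_symbols == []

    def test_shared_enzyme_column_marginal(self, reference_registry):
        drugs = [
            drug("D1", targets=(target("HDAC1"),)),
            drug("D2", targets=(target("HDAC1"),)),
        ]
        matrix = build_interaction_matrix(drugs, reference_registry)
        assert matrix.column_marginals["HDAC1"] == 2
        assert matrix.total_interactions == 2

    def test_marginal_sums_equal_total_on_synthetic(self, tmp_path):
        for seed in (1, 5, 9):
            spec = SyntheticSpec(seed=seed, n_drugs=40)
            registry, _ = generate_enzyme_registry(spec, tmp_path / str(seed))
            drugs, truth = generate_drug_database(spec, registry, tmp_path / str(seed))
            matrix = build_interaction_matrix(select_drugs(drugs), registry)
            assert matrix.total_interactions == matrix.row_marginals.sum()
            assert matrix.total_interactions == matrix.column_marginals.sum()
            assert matrix.total_interactions == truth["total_interactions"]

    def test_empty_registry_rejected(self):
        from epipharm.registry import EnzymeRegistry

        with pytest.raises(ValueError):
            build_interaction_matrix([drug()], EnzymeRegistry())


class TestCategoryHistogram:
    def test_threshold(self):
        drugs = [drug(f"D{i}", categories=("antineoplastic agents",)) for i in range(6)]
        drugs += [drug(f"E{i}", categories=("rare",)) for i in range(4)]
        table = category_histogram(drugs, min_count=5)
        assert table.to_dict("records") == [
            {"category": "antineoplastic agents", "n_drugs": 6}
        ]

    def test_drug_counted_once_per_category(self):
        # categories is a set on the record: double listing is impossible by type,
        # and one drug contributes one count
        d = drug(categories=("kinase inhibitors",))
        table = category_histogram([d], min_count=1)
        assert int(table["n_drugs"].iloc[0]) == 1


def chi_square_oracle(table):
    """Direct Pearson evaluation: sum (O - E)^2 / E over the four cells."""
    t = np.asarray(table, dtype=float)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row @ col / t.sum()
    stat = ((t - expected) ** 2 / expected).sum()
    return stat, float(chi2_dist.sf(stat, 1))


class TestChiSquare:
    def test_hand_example(self):
        result = two_by_two_chi_square([[10, 90], [20, 80]])
        assert result.chi_square == pytest.approx(3.9216, abs=1e-4)
        assert result.degrees_of_freedom == 1

    def test_identical_proportions(self):
        result = two_by_two_chi_square([[10, 30], [20, 60]])
        assert result.chi_square == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_matches_analytic_oracle_on_random_tables(self):
        rng = np.random.default_rng(77)
        for _ in range(1000):
            table = rng.integers(1, 200, size=(2, 2))
            result = two_by_two_chi_square(table)
            stat, p = chi_square_oracle(table)
            assert result.chi_square == pytest.approx(stat, abs=1e-9)
            assert result.p_value == pytest.approx(p, abs=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            two_by_two_chi_square([[0, 0], [5, 5]])


class TestCoverage:
    @pytest.mark.parametrize(
        "part,whole,decimals,expected",
        [(82, 2914, 2, 2.81), (0, 10, 2, 0.0), (15, 7213, 1, 0.2), (3051, 109645, 2, 2.78)],
    )
    def test_percentage_reporting(self, part, whole, decimals, expected):
        assert percentage(part, whole, decimals) == expected

    def test_summary_counts(self, reference_registry):
        drugs = select_drugs([drug("D1", targets=(target("HDAC1"), target("X")))])
        matrix = build_interaction_matrix(drugs, reference_registry)
        stats = coverage_statistics(
            drugs, matrix, reference_registry, all_drug_count=100, all_target_count=200
        )
        assert stats["total_interactions"] == 1
        assert stats["interacting_drug_share_pct"] == 1.0
        assert stats["enzyme_target_share_pct"] == 0.5
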