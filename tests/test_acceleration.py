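"""GO-category binomial test: null, tail accuracy, contrast labelling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import oracle_binomial_tail
from wgdkit.acceleration import (
    DiffCounts,
    MIN_ORTHOLOGS,
    OrthologTriple,
    UndefinedNullError,
    binomial_tail,
    category_test,
    genome_wide_expectation,
    two_lineage_contrast,
)
from wgdkit.acceleration import test_categories as run_category_tests  # noqa: avoid pytest collection
from wgdkit.simulate import simulate_ortholog_counts


def _triple(i, focal, other):
    return OrthologTriple(
        gene_focal=f"g{i}",
        gene_other=f"h{i}",
        gene_outgroup=f"og{i}",
        counts_focal=DiffCounts(*focal, 300.0, 100.0),
        counts_other=DiffCounts(*other, 300.0, 100.0),
    )


class TestExpectation:
    def test_balanced_counts_give_half(self):
        triples = [_triple(i, (5, 5), (2, 2)) for i in range(10)]
        assert genome_wide_expectation(triples, "focal") == pytest.approx(0.5)

    def test_single_ortholog_ratio(self):
        assert genome_wide_expectation([_triple(0, (3, 1), (1, 1))]) == pytest.approx(0.75)

    def test_zero_differences_undefined(self):
        with pytest.raises(UndefinedNullError):
            genome_wide_expectation([_triple(0, (0, 0), (1, 1))], "focal")

    def test_matches_simulation_bookkeeping(self):
        rng = np.random.default_rng(31)
        cats = simulate_ortholog_counts(50, 30, p_null=0.375, rng=rng)
        n = sum(c[0] for members in cats.values() for c in members)
        s = sum(c[1] for members in cats.values() for c in members)
        total = n + s
        se = np.sqrt(0.375 * 0.625 / total)
        assert abs(n / total - 0.375) < 2 * se + 1e-12


class TestBinomialTail:
    def test_exact_tail_example(self):
        # 30 nonsynonymous of 40 differences under p = 0.5
        assert binomial_tail(30, 40, 0.5) == pytest.approx(
            oracle_binomial_tail(30, 40, 0.5), abs=1e-12
        )

    @given(
        st.integers(min_value=1, max_value=500),
        st.floats(min_value=0.05, max_value=0.95),
        st.integers(min_value=0, max_value=500),
    )
    def test_matches_brute_force_summation(self, n, p, a):
        a = min(a, n)
        assert binomial_tail(a, n, p) == pytest.approx(oracle_binomial_tail(a, n, p), abs=1e-12)

    def test_edge_cases(self):
        assert binomial_tail(0, 10, 0.3) == 1.0
        assert binomial_tail(11, 10, 0.3) == 0.0


class TestCategoryTest:
    def test_null_consistent_category_not_significant(self):
        members = [(1, 1)] * 30  # composition equals p_expect = 0.5 exactly
        result = category_test("GO:x", members, 0.5)
        assert result.p_value >= 0.5

    def test_category_size_threshold(self):
        members_21 = [(1, 1)] * MIN_ORTHOLOGS
        members_20 = [(1, 1)] * (MIN_ORTHOLOGS - 1)
        assert category_test("GO:a", members_21, 0.5).status == "tested"
        assert category_test("GO:b", members_20, 0.5).status == "skipped"

    def test_zero_difference_category_untestable(self):
        result = category_test("GO:z", [(0, 0)] * 25, 0.5)
        assert result.status == "untestable"
        assert result.p_value is None

    def test_statuses_partition_the_go_universe(self):
        triples = (
            [_triple(i, (2, 2), (2, 2)) for i in range(30)]
            + [_triple(100 + i, (0, 0), (1, 1)) for i in range(25)]
        )
        gene2go = {t.gene_focal: ["GO:big"] for t in triples[:30]}
        gene2go.update({t.gene_focal: ["GO:zero"] for t in triples[30:]})
        gene2go[triples[0].gene_focal].append("GO:small")
        table = run_category_tests(triples, gene2go, "focal")
        assert set(table["go_id"]) == {"GO:big", "GO:zero", "GO:small"}
        by_id = table.set_index("go_id")["status"]
        assert by_id["GO:big"] == "tested"
        assert by_id["GO:small"] == "skipped"
        assert by_id["GO:zero"] == "untestable"


class TestContrast:
    def _results(self, p_focal, p_other):
        def frame(ps, lineage):
            return pd.DataFrame(
                {
                    "go_id": [f"GO:{i}" for i in range(len(ps))],
                    "lineage": lineage,
                    "n_orthologs": 30,
                    "a_obs": 10.0,
                    "s_obs": 10.0,
                    "p_expect": 0.5,
                    "p_value": ps,
                    "status": "tested",
                }
            )

        return frame(p_focal, "focal"), frame(p_other, "other")

    def test_labels(self):
        focal, other = self._results([0.01, 0.5, 0.01, 0.7], [0.5, 0.01, 0.02, 0.8])
        out = two_lineage_contrast(focal, other).set_index("go_id")
        assert out.loc["GO:0", "label"] == "focal"
        assert out.loc["GO:1", "label"] == "other"
        assert out.loc["GO:2", "label"] == "both"
        assert out.loc["GO:3", "label"] == "neither"

    def test_mismatched_universe_rejected(self):
        focal, other = self._results([0.5], [0.5, 0.6])
        with pytest.raises(ValueError, match="universes differ"):
            two_lineage_contrast(focal, other)

    def test_sorted_by_min_p(self):
        focal, other = self._results([0.9, 0.001, 0.4], [0.5, 0.9, 0.01])
        out = two_lineage_contrast(focal, other)
        assert list(out["go_id"]) == ["GO:1", "GO:2", "GO:0"]


class TestCalibration:
    def test_type_one_error_near_alpha(self):
        rng = np.random.default_rng(41)
        p_null = 0.375
        cats = simulate_ortholog_counts(500, 50, p_null=p_null, rng=rng)
        hits = 0
        for members in cats.values():
            result = category_test("GO:x", members, p_null)
            hits += result.p_value < 0.05
        rate = hits / len(cats)
        assert 0.02 <= rate <= 0.08

    def test_power_against_threefold_enrichment(self):
        rng = np.random.default_rng(43)
        p_null = 0.375
        enriched = {f"GO:{i + 1:07d}": 3.0 for i in range(10)}
        cats = simulate_ortholog_counts(10, 50, p_null=p_null, rng=rng, enriched=enriched)
        detected = sum(
            category_test(go, members, p_null).p_value < 0.05 for go, members in cats.items()
        )
        assert detected >= 9


class TestOntologyPropagation:
    def test_annotations_propagate_to_ancestor_terms(self, tmp_path):
        from wgdkit.acceleration import propagate_gene2go

        obo = tmp_path / "mini.obo"
        obo.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: root\n\n"
            "[Term]\nid: GO:0000002\nname: mid\nis_a: GO:0000001 ! root\n\n"
            "[Term]\nid: GO:0000003\nname: leaf\nis_a: GO:0000002 ! mid\n"
        )
        mapping = propagate_gene2go({"g1": ["GO:0000003"], "g2": ["GO:9999999"]}, obo)
        assert mapping["g1"] == ["GO:0000001", "GO:0000002", "GO:0000003"]
        assert mapping["g2"] == ["GO:9999999"]  # unknown terms pass through
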