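"""TE-to-nearest-gene distances and the intact/fragmentary contrast."""

import numpy as np
import pandas as pd
import pytest

from oracles import oracle_nearest_distances
from wgdkit.proximity import (
    AnnotatedGenomeModel,
    group_summaries,
    nearest_gene_distance,
    proximity_test,
    read_gff3_genes,
    read_te_table,
)
from wgdkit.simulate import SimulationConfig, TELayout, simulate_annotations, write_gff3, write_te_table


def _model(genes, tes, chrom_len=100_000, chroms=("chr1",)):
    gene_df = pd.DataFrame(
        [
            {"chrom": c, "start": s, "end": e, "strand": "+", "id": f"g{i}"}
            for i, (c, s, e) in enumerate(genes)
        ],
        columns=["chrom", "start", "end", "strand", "id"],
    )
    te_df = pd.DataFrame(
        [
            {
                "chrom": c,
                "start": s,
                "end": e,
                "id": f"t{i}",
                "superfamily": "Gypsy",
                "status": "intact",
            }
            for i, (c, s, e) in enumerate(tes)
        ],
        columns=["chrom", "start", "end", "id", "superfamily", "status"],
    )
    return AnnotatedGenomeModel({c: chrom_len for c in chroms}, gene_df, te_df)


class TestNearestDistance:
    def test_gap_arithmetic(self):
        model = _model([("chr1", 300, 400)], [("chr1", 100, 200)])
        assert nearest_gene_distance(model)["distance_bp"].iloc[0] == 100

    def test_overlap_is_zero(self):
        model = _model([("chr1", 150, 400)], [("chr1", 100, 200)])
        assert nearest_gene_distance(model)["distance_bp"].iloc[0] == 0

    def test_te_containing_gene_is_zero(self):
        model = _model([("chr1", 150, 160)], [("chr1", 100, 200)])
        assert nearest_gene_distance(model)["distance_bp"].iloc[0] == 0

    def test_geneless_chromosome_flagged_missing(self):
        model = _model([("chr1", 10, 20)], [("chr2", 100, 200)], chroms=("chr1", "chr2"))
        out = nearest_gene_distance(model)
        assert np.isnan(out["distance_bp"].iloc[0])
        assert out["flags"].iloc[0] == "no_gene_on_chromosome"

    def test_matches_brute_force_on_random_models(self, rng):
        for _ in range(5):
            genes = [
                ("chr1", int(s), int(s + rng.integers(50, 500)))
                for s in rng.integers(0, 90_000, size=40)
            ]
            tes = [
                ("chr1", int(s), int(s + rng.integers(50, 2000)))
                for s in rng.integers(0, 90_000, size=200)
            ]
            model = _model(genes, tes)
            sweep = nearest_gene_distance(model)["distance_bp"].to_numpy()
            brute = oracle_nearest_distances(genes, tes)
            np.testing.assert_array_equal(sweep, np.array(brute, dtype=float))

    def test_invariant_under_coordinate_reversal(self, rng):
        length = 100_000
        genes = [("chr1", int(s), int(s) + 100) for s in rng.integers(0, 90_000, size=30)]
        tes = [("chr1", int(s), int(s) + 500) for s in rng.integers(0, 90_000, size=100)]
        fwd = nearest_gene_distance(_model(genes, tes, chrom_len=length))
        rev_genes = [("chr1", length - e, length - s) for _, s, e in genes]
        rev_tes = [("chr1", length - e, length - s) for _, s, e in tes]
        rev = nearest_gene_distance(_model(rev_genes, rev_tes, chrom_len=length))
        np.testing.assert_array_equal(
            fwd["distance_bp"].to_numpy(), rev["distance_bp"].to_numpy()
        )

    def test_out_of_bounds_interval_names_record(self):
        with pytest.raises(ValueError, match="t0"):
            _model([("chr1", 0, 10)], [("chr1", 99_990, 100_010)])


class TestProximityTest:
    def _distance_frame(self, intact, fragmentary):
        rows = []
        for status, values in (("intact", intact), ("fragmentary", fragmentary)):
            for i, d in enumerate(values):
                rows.append(
                    {
                        "chrom": "chr1",
                        "start": 0,
                        "end": 1,
                        "id": f"{status}{i}",
                        "superfamily": "Gypsy",
                        "status": status,
                        "distance_bp": float(d),
                        "flags": "",
                    }
                )
        return pd.DataFrame(rows)

    def test_maximal_separation_is_overwhelming(self):
        frame = self._distance_frame([0.0] * 50, [10_000.0] * 50)
        report = proximity_test(frame).set_index("scope")
        assert report.loc["all", "closer_group"] == "intact"
        assert report.loc["all", "chi2_p"] < 1e-6

    def test_null_false_positive_rate_near_alpha(self, rng):
        reps = 300
        hits = 0
        for _ in range(reps):
            pool = rng.exponential(5000.0, size=1000)
            frame = self._distance_frame(pool[:500], pool[500:])
            report = proximity_test(frame, per_superfamily=False)
            hits += report["chi2_p"].iloc[0] < 0.05
        assert 0.02 <= hits / reps <= 0.09

    def test_empty_group_named(self):
        frame = self._distance_frame([1.0] * 30, [])
        with pytest.raises(ValueError, match="fragmentary"):
            proximity_test(frame)

    def test_planted_layout_detected_in_right_direction(self):
        cfg = SimulationConfig(
            seed=47,
            te_layout=TELayout(n_intact=300, n_fragmentary=300, near_gene_fraction=0.9),
        )
        model, _ = simulate_annotations(cfg)
        distances = nearest_gene_distance(model)
        report = proximity_test(distances).set_index("scope")
        assert report.loc["all", "closer_group"] == "intact"
        assert report.loc["all", "chi2_p"] < 0.001
        assert report.loc["all", "ranksum_p"] < 0.001

    def test_fully_planted_intact_median_within_near_window(self):
        cfg = SimulationConfig(
            seed=53,
            te_layout=TELayout(n_intact=100, n_fragmentary=100, near_gene_fraction=1.0),
        )
        model, _ = simulate_annotations(cfg)
        distances = nearest_gene_distance(model)
        summaries = group_summaries(distances).set_index(["status", "superfamily"])
        for fam in ("Gypsy", "Copia"):
            assert summaries.loc[("intact", fam), "median_bp"] <= 500


class TestIO:
    def test_gff3_and_te_table_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=59, n_genes=40)
        model, _ = simulate_annotations(cfg)
        gff = tmp_path / "genes.gff3"
        bed = tmp_path / "tes.bed"
        write_gff3(model, gff)
        write_te_table(model, bed)
        genes = read_gff3_genes(gff)
        tes = read_te_table(bed)
        pd.testing.assert_frame_equal(
            genes.reset_index(drop=True), model.genes.reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(
            tes.reset_index(drop=True), model.tes.reset_index(drop=True)
        )

    def test_unknown_status_rejected(self, tmp_path):
        path = tmp_path / "tes.bed"
        path.write_text("chrom\tstart\tend\tid\tsuperfamily\tstatus\nchr1\t0\t10\tt1\tGypsy\tbroken\n")
        with pytest.raises(ValueError, match="status"):
            read_te_table(path)
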