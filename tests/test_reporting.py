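import numpy as np
import pandas as pd
import pytest

from bicodon_bias.counting import build_groups, count_sample
from bicodon_bias.reporting import (
    cluster_axes,
    export_heatmap,
    occupancy_candidates,
    read_heatmap_tsv,
    shared_bicodons,
    snp_effect,
    write_heatmap_tsv,
)
from bicodon_bias.sequence_io import CodingSequence
from bicodon_bias.stats import compute_bicodon_stats


def minimal_stats(index, **overrides):
    """A stats-like frame with neutral defaults, overridable per column."""
    n = len(index)
    frame = pd.DataFrame(
        {
            "dipeptide": list(index.dipeptides),
            "bicodon": list(index.bicodons),
            "pi": np.zeros(n),
            "p_value": np.ones(n),
            "chi2_L": np.zeros(n),
            "chi2_H": np.zeros(n),
            "z_L": np.zeros(n),
            "z_H": np.zeros(n),
        }
    )
    for col, mapping in overrides.items():
        for bicodon, value in mapping.items():
            frame.loc[frame["bicodon"] == bicodon, col] = value
    return frame


class TestClusterAxes:
    def test_identical_rows_adjacent(self, rng):
        mat = rng.normal(size=(6, 8))
        mat[4] = mat[1]
        rows, _ = cluster_axes(mat)
        pos = {r: i for i, r in enumerate(rows)}
        assert abs(pos[1] - pos[4]) == 1

    def test_two_blocks_stay_contiguous(self):
        # 4 rows in two well-separated blocks {0, 2} and {1, 3}
        mat = np.array(
            [[0.0, 0.1, 0.0, 0.2],
             [5.0, 5.2, 4.9, 5.1],
             [0.1, 0.0, 0.1, 0.1],
             [5.1, 5.0, 5.0, 5.2]]
        )
        rows, _ = cluster_axes(mat)
        order = list(rows)
        assert {abs(order.index(0) - order.index(2)),
                abs(order.index(1) - order.index(3))} == {1}

    def test_deterministic(self, rng):
        mat = rng.normal(size=(10, 12))
        first = cluster_axes(mat)
        second = cluster_axes(mat)
        assert np.array_equal(first[0], second[0])
        assert np.array_equal(first[1], second[1])

    def test_masked_cells_treated_as_zero(self, rng):
        mat = rng.normal(size=(6, 6))
        with_nan = mat.copy()
        with_nan[2, 3] = np.nan
        filled = mat.copy()
        filled[2, 3] = 0.0
        assert np.array_equal(cluster_axes(with_nan)[0], cluster_axes(filled)[0])


class TestHeatmap:
    def test_masked_cell_count(self, index):
        hm = export_heatmap(minimal_stats(index), index, "pi")
        assert int(np.isnan(hm.values).sum()) == 64 * 64 - 3904  # = 192

    def test_every_bicodon_appears_once(self, index):
        stats = minimal_stats(index)
        stats["pi"] = np.arange(len(index), dtype=float)
        hm = export_heatmap(stats, index, "pi")
        present = hm.values[~np.isnan(hm.values)]
        assert np.array_equal(np.sort(present), np.arange(3904, dtype=float))

    def test_identical_samples_give_zero_matrix(self, index, null_proteome):
        seqs, _ = null_proteome
        c = count_sample(seqs[:40], index)
        stats = compute_bicodon_stats(c, c, index, build_groups(index, c, c))
        hm = export_heatmap(stats, index, "pi")
        assert not np.nan_to_num(hm.values).any()

    def test_tsv_round_trip(self, index, rng, tmp_path):
        stats = minimal_stats(index)
        stats["pi"] = rng.normal(size=len(index))
        hm = export_heatmap(stats, index, "pi")
        path = tmp_path / "hm.tsv"
        write_heatmap_tsv(hm, path)
        back = read_heatmap_tsv(path)
        assert np.array_equal(back.row_order, hm.row_order)
        assert np.array_equal(back.col_order, hm.col_order)
        a, b = hm.ordered(), back.ordered()
        assert np.allclose(np.nan_to_num(a), np.nan_to_num(b), atol=1e-9)
        assert np.array_equal(np.isnan(a), np.isnan(b))


class TestSharedBicodons:
    def make(self, index, hits):
        return minimal_stats(
            index,
            pi={b: s for b, s in hits},
            p_value={b: 1e-6 for b, _ in hits},
            z_L={b: 5.0 for b, _ in hits},
        )

    def test_single_organism_degenerates_to_filter(self, index):
        stats = self.make(index, [("GTACGA", 1.0), ("AAGAAG", -1.0)])
        out = shared_bicodons({"yeast": stats}, direction="low")
        assert list(out["bicodon"]) == ["GTACGA"]

    def test_disjoint_sets_give_empty_table(self, index):
        a = self.make(index, [("GTACGA", 1.0)])
        b = self.make(index, [("AAAAAA", 1.0)])
        assert shared_bicodons({"a": a, "b": b}, direction="low").empty

    def test_shared_hit_found_in_all(self, index):
        hit = ("GTACGA", 1.0)
        organisms = {
            name: self.make(index, [hit, (extra, 1.0)])
            for name, extra in [("a", "AAAAAA"), ("b", "CCGCCG"), ("c", "GGTGGT")]
        }
        out = shared_bicodons(organisms, direction="low")
        assert list(out["bicodon"]) == ["GTACGA"]
        assert {"chi2_sum_a", "neg_log10_p_b", "z_max_c"} <= set(out.columns)

    def test_monotone_in_thresholds(self, index, rng):
        stats = minimal_stats(index)
        stats["pi"] = rng.normal(size=len(index))
        stats["p_value"] = rng.random(len(index))
        stats["z_L"] = rng.normal(2.0, 2.0, len(index))
        loose = shared_bicodons({"x": stats}, alpha=0.05, z_threshold=2.0)
        tight_a = shared_bicodons({"x": stats}, alpha=0.01, z_threshold=2.0)
        tight_z = shared_bicodons({"x": stats}, alpha=0.05, z_threshold=4.0)
        assert set(tight_a["bicodon"]) <= set(loose["bicodon"])
        assert set(tight_z["bicodon"]) <= set(loose["bicodon"])


class TestOccupancyCandidates:
    def test_boundaries_are_strict(self, index):
        stats = minimal_stats(
            index,
            pi={"GTACGA": 0.75, "GTGCGA": 0.76},
            p_value={"GTACGA": 1e-3, "GTGCGA": 1e-3},
        )
        occ = {"GTACGA": 0.05, "GTGCGA": 0.03}
        # GTACGA fails pi == 0.75 (strict), GTGCGA fails occ == 0.03 (strict)
        assert occupancy_candidates(stats, occ).empty

    def test_passing_row_returned(self, index):
        stats = minimal_stats(
            index, pi={"GTACGA": 0.9}, p_value={"GTACGA": 1e-3}
        )
        out = occupancy_candidates(stats, {"GTACGA": 0.05})
        assert list(out["bicodon"]) == ["GTACGA"]
        assert out["occupancy"].iloc[0] == 0.05

    def test_empty_occupancy_gives_empty_list(self, index):
        stats = minimal_stats(index, pi={"GTACGA": 0.9}, p_value={"GTACGA": 1e-3})
        assert occupancy_candidates(stats, {}).empty


class TestSnpEffect:
    CDS = CodingSequence("MDR1-like", "ATGGCCATCGTGTAA")  # M A I V *

    def fixture_stats(self, index):
        return minimal_stats(
            index,
            pi={"ATCGTG": 0.1, "ATTGTG": -0.8, "ATAGTG": -0.55,
                "GCCATC": 0.2, "GCCATT": 0.05, "GCCATA": 0.0},
        )

    def test_downstream_delta_for_c_to_t_variant(self, index):
        rep = snp_effect(self.CDS, 3, "ATT", self.fixture_stats(index))
        assert rep.pi_downstream_ref == pytest.approx(0.1)
        assert rep.pi_downstream_alt == pytest.approx(-0.8)
        assert rep.delta_pi_downstream == pytest.approx(-0.9)

    def test_third_synonymous_variant(self, index):
        rep = snp_effect(self.CDS, 3, "ATA", self.fixture_stats(index))
        assert rep.pi_downstream_alt == pytest.approx(-0.55)

    def test_ref_equals_alt_all_deltas_zero(self, index):
        rep = snp_effect(self.CDS, 3, "ATC", self.fixture_stats(index))
        assert rep.delta_pi_downstream == 0.0
        assert rep.delta_pi_upstream == 0.0

    def test_antisymmetry(self, index):
        stats = self.fixture_stats(index)
        fwd = snp_effect(self.CDS, 3, "ATT", stats)
        alt_cds = CodingSequence("alt", "ATGGCCATTGTGTAA")
        back = snp_effect(alt_cds, 3, "ATC", stats)
        assert back.delta_pi_downstream == pytest.approx(-fwd.delta_pi_downstream)
        assert back.delta_pi_upstream == pytest.approx(-fwd.delta_pi_upstream)

    def test_non_synonymous_rejected(self, index):
        with pytest.raises(ValueError, match="synonymous"):
            snp_effect(self.CDS, 3, "AAG", self.fixture_stats(index))

    def test_missing_stats_reported_absent(self, index):
        stats = minimal_stats(index, pi={"ATCGTG": 0.1})
        stats = stats[stats["bicodon"] != "ATTGTG"]
        rep = snp_effect(self.CDS, 3, "ATT", stats)
        assert rep.pi_downstream_alt is None
        assert rep.delta_pi_downstream is None

    def test_edge_position_one_sided(self, index):
        rep = snp_effect(self.CDS, 1, "ATG", self.fixture_stats(index))
        assert rep.upstream_ref is None and rep.downstream_ref == "ATGGCC"
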