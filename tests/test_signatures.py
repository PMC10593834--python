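"""DEG signature extraction, universe restriction, and GMT I/O."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tenoscreen.signatures import (
    ExpressionMatrix,
    GeneSignature,
    compute_deg_signature,
    deg_records_to_frame,
    read_expression_tsv,
    read_gmt,
    restrict_to_universe,
    write_expression_tsv,
    write_gmt,
)
from tenoscreen.synthetic import SimulationConfig, simulate_expression


def small_matrix(values: np.ndarray, genes=None) -> ExpressionMatrix:
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    half = n_samples // 2
    samples = [f"s{i}" for i in range(n_samples)]
    groups = {s: ("case" if i < half else "ctrl") for i, s in enumerate(samples)}
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), groups,
        group_levels=("case", "ctrl"),
    )


class TestDEGCalling:
    def test_planted_recovery(self):
        cfg = SimulationConfig.test_scale(seed=3, n_genes=800, n_up=40, n_down=60)
        expr, truth = simulate_expression(cfg)
        sig, records = compute_deg_signature(expr, max_up=40, max_down=60)
        sens = (len(sig.up & set(truth.planted_up))
                + len(sig.down & set(truth.planted_down))) / 100
        negatives = set(expr.gene_ids) - set(truth.planted_up) - set(truth.planted_down)
        fp = len((sig.up | sig.down) & negatives)
        assert sens >= 0.95
        assert 1 - fp / len(negatives) >= 0.99
        assert len(records) == cfg.n_genes

    def test_up_down_disjoint_and_in_universe(self):
        cfg = SimulationConfig.test_scale(seed=4, n_genes=500, n_up=20, n_down=20)
        expr, _ = simulate_expression(cfg)
        sig, records = compute_deg_signature(expr)
        assert not (sig.up & sig.down)
        assert (sig.up | sig.down) <= set(expr.gene_ids)
        by_id = {r.gene_id: r for r in records}
        for g in sig.up:
            assert by_id[g].log2_fold_change > 0 and by_id[g].direction == "up"
        for g in sig.down:
            assert by_id[g].log2_fold_change < 0 and by_id[g].direction == "down"

    def test_null_pass_rate_matches_threshold(self):
        """Under identical group distributions the fraction of genes with
        P < alpha is alpha, within binomial error."""
        cfg = SimulationConfig(n_genes=10000, effect_size=0.0,
                               n_up=1, n_down=1, seed=5)
        expr, _ = simulate_expression(cfg)
        _, records = compute_deg_signature(expr, p_threshold=0.05)
        frac = np.mean([r.p_value < 0.05 for r in records])
        # 0.05 +/- 4 binomial SD at n = 10,000
        assert abs(frac - 0.05) < 4 * np.sqrt(0.05 * 0.95 / 10000) + 1e-9

    def test_sensitivity_monotone_in_effect_size(self):
        sens = []
        for effect in (0.3, 0.8, 2.0):
            cfg = SimulationConfig.test_scale(
                seed=6, n_genes=400, n_up=30, n_down=30, effect_size=effect
            )
            expr, truth = simulate_expression(cfg)
            sig, _ = compute_deg_signature(expr)
            hits = (len(sig.up & set(truth.planted_up))
                    + len(sig.down & set(truth.planted_down)))
            sens.append(hits / 60)
        assert sens[0] <= sens[1] <= sens[2]

    def test_insufficient_replication(self):
        values = np.random.default_rng(0).normal(size=(10, 3))
        expr = ExpressionMatrix(
            pd.DataFrame(values, index=[f"g{i}" for i in range(10)],
                         columns=["a", "b", "c"]),
            {"a": "case", "b": "ctrl", "c": "ctrl"},
        )
        with pytest.raises(ValueError, match="insufficient replication"):
            compute_deg_signature(expr)

    def test_constant_rows_get_p_one(self):
        values = np.vstack([np.full(6, 3.0),  # constant everywhere
                            np.r_[np.ones(3), np.zeros(3)]])  # deterministic diff
        expr = small_matrix(values)
        _, records = compute_deg_signature(expr)
        by_id = {r.gene_id: r for r in records}
        assert by_id["g0"].p_value == 1.0
        assert by_id["g1"].p_value == 0.0

    def test_invariant_to_sample_and_gene_order(self, rng):
        cfg = SimulationConfig.test_scale(seed=7, n_genes=200, n_up=10, n_down=10)
        expr, _ = simulate_expression(cfg)
        sig1, rec1 = compute_deg_signature(expr)
        shuffled = ExpressionMatrix(
            expr.values.sample(frac=1, axis=0, random_state=1)
                       .sample(frac=1, axis=1, random_state=2),
            expr.sample_groups, expr.group_levels,
        )
        sig2, rec2 = compute_deg_signature(shuffled)
        assert sig1.up == sig2.up and sig1.down == sig2.down
        p1 = {r.gene_id: r.p_value for r in rec1}
        p2 = {r.gene_id: r.p_value for r in rec2}
        for g in p1:
            assert p1[g] == pytest.approx(p2[g], rel=1e-9)

    def test_truncation_keeps_largest_fold_changes(self):
        cfg = SimulationConfig.test_scale(seed=8, n_genes=300, n_up=30, n_down=30)
        expr, _ = simulate_expression(cfg)
        full, records = compute_deg_signature(expr)
        trimmed, _ = compute_deg_signature(expr, max_up=5, max_down=5)
        assert len(trimmed.up) == 5 and len(trimmed.down) == 5
        lfc = {r.gene_id: abs(r.log2_fold_change) for r in records}
        kept_min = min(lfc[g] for g in trimmed.up)
        dropped_max = max((lfc[g] for g in full.up - trimmed.up), default=0.0)
        assert kept_min >= dropped_max

    def test_bh_adjustment_is_more_conservative(self):
        cfg = SimulationConfig.test_scale(seed=9, n_genes=2000, n_up=5, n_down=5,
                                          effect_size=0.5)
        expr, _ = simulate_expression(cfg)
        raw, _ = compute_deg_signature(expr, adjust="none")
        bh, _ = compute_deg_signature(expr, adjust="bh")
        assert (bh.up | bh.down) <= (raw.up | raw.down)

    def test_deg_table_columns(self):
        cfg = SimulationConfig.test_scale(seed=10, n_genes=50, n_up=5, n_down=5)
        expr, _ = simulate_expression(cfg)
        sig, records = compute_deg_signature(expr)
        frame = deg_records_to_frame(records, sig)
        assert list(frame.columns) == [
            "gene_id", "log2_fold_change", "p_value", "direction", "selected"
        ]
        assert frame["selected"].sum() == len(sig.up) + len(sig.down)


class TestRestrictToUniverse:
    def test_stemness_factors_outside_universe_dropped(self):
        sig = GeneSignature({"Nestin", "Sox2", "Nanog", "DDX56", "OCT4"},
                            set(), "stemness")
        universe = ["Nestin", "Sox2", "Nanog", "Klf4", "Myc"]
        with pytest.warns(UserWarning) as captured:
            out = restrict_to_universe(sig, universe)
        assert out.up == {"Nestin", "Sox2", "Nanog"}
        assert len(captured) == 2
        warned = " ".join(str(w.message) for w in captured)
        assert "DDX56" in warned and "OCT4" in warned

    def test_identity_when_fully_inside(self):
        sig = GeneSignature({"a", "b"}, {"c"}, "s")
        out = restrict_to_universe(sig, ["a", "b", "c", "d"])
        assert out.up == sig.up and out.down == sig.down

    def test_partial_down_with_empty_up(self):
        sig = GeneSignature({"x", "y"}, {"c", "d", "e"}, "s")
        with pytest.warns(UserWarning) as captured:
            out = restrict_to_universe(sig, ["c", "d", "q"])
        assert out.up == set()
        assert out.down == {"c", "d"}
        assert len(captured) == 3  # x, y, e dropped

    def test_disjoint_universe_raises(self):
        sig = GeneSignature({"a"}, {"b"}, "s")
        with pytest.raises(ValueError, match="disjoint from universe"):
            with pytest.warns(UserWarning):
                restrict_to_universe(sig, ["q", "r"])


class TestGMT:
    def test_roundtrip(self, tmp_path):
        sigs = [
            GeneSignature({"a", "b", "c"}, {"d", "e"}, "tendon", "prov"),
            GeneSignature({"Nestin", "Sox2"}, set(), "stemness"),
        ]
        path = tmp_path / "sigs.gmt"
        write_gmt(sigs, path)
        back = read_gmt(path)
        assert [s.name for s in back] == ["tendon", "stemness"]
        assert back[0].up == sigs[0].up and back[0].down == sigs[0].down
        assert back[1].up == sigs[1].up and back[1].down == set()

    def test_lone_up_set(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("mysig_UP\tna\tg1\tg2\n")
        (sig,) = read_gmt(path)
        assert sig.up == {"g1", "g2"} and sig.down == set()

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("nameonly\n")
        with pytest.raises(ValueError, match="line 1"):
            read_gmt(path)

    def test_duplicate_set_names(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("s_UP\tna\tg1\ns_UP\tna\tg2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(path)


def test_expression_tsv_roundtrip(tmp_path):
    cfg = SimulationConfig.test_scale(seed=11, n_genes=40, n_up=4, n_down=4)
    expr, _ = simulate_expression(cfg)
    write_expression_tsv(expr, tmp_path / "e.tsv", tmp_path / "g.tsv")
    back = read_expression_tsv(tmp_path / "e.tsv", tmp_path / "g.tsv",
                               group_levels=expr.group_levels)
    pd.testing.assert_frame_equal(back.values, expr.values)
    assert back.sample_groups == expr.sample_groups
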