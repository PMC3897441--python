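"""Propagating front, UV marking, elimination protocol, outcomes."""

import numpy as np
import pytest

from conemosaic.geometry import CellType, Parameters, descend_sweeps
from conemosaic.growth import (GrowthConfig, GrowthExhausted, advance_front,
                               eliminate_uv, initialize_growth,
                               run_growth_experiment)


class TestAdvanceFront:
    def test_first_column_marks_every_sixth_cell(self):
        """24-cell first column: 4 UV cones with five cones between."""
        rng = np.random.default_rng(11)
        p, front = initialize_growth(0, 1, 24, Parameters(), rng=rng,
                                     settle=False)
        p, front = advance_front(p, front, rng)
        col = front.current_column
        rows = sorted(p.cells[c].row for c in front.uv_cells[col])
        assert len(rows) == 4
        gaps = [(rows[(i + 1) % 4] - rows[i]) % 24 - 1 for i in range(4)]
        assert gaps == [5, 5, 5, 5]

    def test_midpoint_rule_picks_cell_nearest_pair_midpoint(self):
        """New-column UV cells sit nearest the midpoints of the previous
        column's UV pairs; brute-force recomputation agrees."""
        rng = np.random.default_rng(3)
        p, front = initialize_growth(2, 3, 12, Parameters(), rng=rng,
                                     settle=False)
        for _ in range(3):
            p, front = advance_front(p, front, rng)
            col = front.current_column
            prev = sorted(front.uv_marks[col - 1])
            ids = [c for c in front.columns[col]]
            cys = {c: float(p.cell_centroid(c)[1]) for c in ids}
            expected = set()
            taken = set()
            for i, y1 in enumerate(prev):
                y2 = prev[(i + 1) % len(prev)]
                mid = (y1 + 0.5 * ((y2 - y1) % p.Ly)) % p.Ly
                best = min((c for c in ids if c not in taken),
                           key=lambda c: min(abs(cys[c] - mid),
                                             p.Ly - abs(cys[c] - mid)))
                taken.add(best)
                expected.add(best)
            assert set(front.uv_cells[col]) == expected

    def test_uv_flanked_by_green_and_types_assigned(self):
        rng = np.random.default_rng(5)
        p, front = initialize_growth(1, 1, 12, Parameters(), rng=rng,
                                     settle=False)
        p, front = advance_front(p, front, rng)
        col = front.current_column
        ids = front.columns[col]
        types = [p.cells[c].type for c in ids]
        for i, t in enumerate(types):
            if t is CellType.UV:
                assert types[(i - 1) % len(ids)] is CellType.GREEN
                assert types[(i + 1) % len(ids)] is CellType.GREEN

    def test_growth_exhausted_when_no_precursors(self):
        rng = np.random.default_rng(0)
        p, front = initialize_growth(1, 1, 12, Parameters(), rng=rng,
                                     settle=False, n_buffer=0)
        p, front = advance_front(p, front, rng)
        with pytest.raises(GrowthExhausted):
            advance_front(p, front, rng)


class TestEliminateUv:
    def test_preferred_area_follows_shrink_schedule(self):
        """A0 after k intervals equals 0.4^k of the original."""
        rho = Parameters().shrink_factor
        assert rho == 0.4
        assert rho ** 3 == pytest.approx(0.064)

    def test_elimination_removes_cell_and_conserves_cones(self):
        rng = np.random.default_rng(2)
        p, front = initialize_growth(2, 1, 12, Parameters(), rng=rng)
        p, front = advance_front(p, front, rng)
        descend_sweeps(p, 10)
        col = front.current_column
        n_cones_before = sum(1 for c in p.cells.values()
                             if c.type.is_cone and c.type is not CellType.UV)
        uv = front.uv_cells[col][0]
        p, ev = eliminate_uv(p, front, uv, "fast")
        assert uv not in p.cells
        assert ev.outcome in ("column_intact", "column_broken")
        assert ev.final_area < 5 * p.params.cutoff_area
        assert ev.shrink_steps >= 1
        p.validate()
        n_cones_after = sum(1 for c in p.cells.values()
                            if c.type.is_cone and c.type is not CellType.UV)
        assert n_cones_after == n_cones_before

    def test_rejects_non_uv_cell(self):
        rng = np.random.default_rng(2)
        p, front = initialize_growth(2, 1, 12, Parameters(), rng=rng,
                                     settle=False)
        p, front = advance_front(p, front, rng)
        col = front.current_column
        green = next(c for c in front.columns[col]
                     if p.cells[c].type is CellType.GREEN)
        with pytest.raises(ValueError):
            eliminate_uv(p, front, green, "fast")

    def test_slow_relaxation_preserves_columns_better(self):
        """Across seeds, slow elimination yields strictly fewer broken
        outcomes than fast elimination at matched n."""
        results = {}
        for mode in ("fast", "slow"):
            broken = total = 0
            for seed in (1, 2, 3):
                cfg = GrowthConfig(n_columns=1, cells_per_column=12,
                                   n_established=2, mode="mutant",
                                   relaxation=mode, seed=seed)
                _, _, rep = run_growth_experiment(cfg)
                broken += rep.n_broken
                total += rep.n_events
            results[mode] = (broken, total)
        assert results["slow"][1] == results["fast"][1]
        assert results["slow"][0] < results["fast"][0]


class TestGrowthExperiment:
    def test_empty_report_for_zero_columns(self):
        cfg = GrowthConfig(n_columns=0, cells_per_column=12,
                           n_established=2, mode="mutant", seed=0)
        _, _, rep = run_growth_experiment(cfg)
        assert rep.n_events == 0
        assert np.isnan(rep.break_fraction)

    def test_wildtype_columns_straight_and_two_coordinated(
            self, wt_experiment):
        p, front, rep = wt_experiment
        assert rep.coordination_fractions.get(2, 0.0) > 0.9
        assert rep.column_straightness < 0.5

    def test_mutant_elevates_low_coordination(self, wt_experiment,
                                              mutant_experiment):
        _, _, wt = wt_experiment
        _, _, mut = mutant_experiment
        low_wt = wt.coordination_fractions.get(0, 0) + \
            wt.coordination_fractions.get(1, 0)
        low_mut = mut.coordination_fractions.get(0, 0) + \
            mut.coordination_fractions.get(1, 0)
        assert low_mut > low_wt
        assert mut.n_events > 0
        assert 0.0 <= mut.break_fraction <= 1.0

    def test_report_reproducible_given_seed(self):
        cfg = GrowthConfig(n_columns=2, cells_per_column=12,
                           n_established=2, mode="mutant",
                           relaxation="fast", seed=9)
        _, _, r1 = run_growth_experiment(cfg)
        _, _, r2 = run_growth_experiment(GrowthConfig(**{
            k: getattr(cfg, k) for k in
            ("n_columns", "cells_per_column", "n_established", "mode",
             "relaxation", "seed")}))
        assert r1.to_dict() == r2.to_dict()

    def test_break_fraction_seed_spread_consistent_with_binomial(self):
        """Per-seed break-fraction estimates scatter within sampling
        error of the pooled mean (scaled-down seed-robustness check)."""
        fracs, ns = [], []
        for seed in (1, 2, 3, 4):
            cfg = GrowthConfig(n_columns=2, cells_per_column=12,
                               n_established=2, mode="mutant",
                               relaxation="fast", seed=seed)
            _, _, rep = run_growth_experiment(cfg)
            fracs.append(rep.break_fraction)
            ns.append(rep.n_events)
        pooled = float(np.average(fracs, weights=ns))
        for f, n in zip(fracs, ns):
            se = np.sqrt(max(pooled * (1 - pooled), 0.05) / n)
            assert abs(f - pooled) <= 3 * se + 1e-9
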