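"""Vertex-model core: energy, forces, relaxation, T1 transitions."""

import numpy as np
import pytest

from conemosaic.geometry import (GeometryError, Packing,
                                 Parameters, descend_sweeps, energy, relax,
                                 remove_cell, t1_transition)
from conemosaic.lattice import build_columnar_packing


def total_pcp(packing):
    return {c: packing.cell_pcp_total(c) for c in packing.cells}


class TestEnergy:
    def test_zero_for_tensionless_relaxed_hexagons(self):
        pars = Parameters(reference_tension=0.0, contractility=0.0,
                          anisotropy=0.0)
        p = build_columnar_packing(4, 6, pars, periodic_x=True)
        # hexagonal packing at preferred area, no tension, no contractility
        assert energy(p) == pytest.approx(0.0, abs=1e-9)

    def test_matches_per_element_oracle(self, pcp_packing):
        """Vectorized energy equals an independent per-cell/per-edge sum."""
        p = pcp_packing
        pars = p.params
        e_cells = 0.0
        for cid in p.cells:
            a = p.cell_area(cid)
            per = p.cell_perimeter(cid)
            e_cells += 0.5 * pars.area_stiffness * \
                (a - p.cells[cid].preferred_area) ** 2
            e_cells += 0.5 * pars.contractility * per ** 2
        e_edges = 0.0
        for e in p.edges.values():
            L = p.edge_length(e.id)
            asum = sum(e.pcp_amount.values())
            lam = e.base_tension * e.tension_multiplier
            e_edges += lam * max(L - pars.pcp_tension_coupling * asum, 0.0)
        assert energy(p) == pytest.approx(e_cells + e_edges, rel=1e-10)

    def test_forces_are_gradient_of_frozen_concentration_surrogate(
            self, pcp_packing, rng):
        comp = pcp_packing.compiled()
        pos = comp.pos.copy()
        T = comp.effective_tension(pos)
        F = comp.forces(pos, tension=T)
        h = 1e-6
        for _ in range(20):
            i = int(rng.integers(len(pos)))
            j = int(rng.integers(2))
            pp, pm = pos.copy(), pos.copy()
            pp[i, j] += h
            pm[i, j] -= h
            g = (comp.energy(pp, tension=T) -
                 comp.energy(pm, tension=T)) / (2 * h)
            assert -g == pytest.approx(F[i, j], abs=5e-6)

    def test_nonsimple_polygon_raises_naming_cell(self, hex_packing):
        p = hex_packing
        cid = next(iter(p.cells))
        cyc = p.cell_vertex_cycle(cid)
        # fold the polygon into a bowtie by swapping two vertices
        a, b = cyc[0], cyc[2]
        p.vertices[a].pos, p.vertices[b].pos = \
            p.vertices[b].pos.copy(), p.vertices[a].pos.copy()
        p.invalidate()
        with pytest.raises(GeometryError):
            energy(p)


class TestRelax:
    def test_perturbed_hexagonal_lattice_returns_to_ground_state(
            self, hex_packing, rng):
        p = hex_packing
        l_ref = 1.0
        for v in p.vertices.values():
            v.pos = v.pos + rng.normal(scale=0.01 * l_ref, size=2)
        p.invalidate()
        e0 = energy(p)
        res = relax(p, tol=1e-4, max_steps=4000)
        assert res.converged
        assert res.energy_trace[-1] <= e0

    def test_energy_trace_monotone_nonincreasing(self, pcp_packing, rng):
        p = pcp_packing
        for v in p.vertices.values():
            v.pos = v.pos + rng.normal(scale=0.03, size=2)
        p.invalidate()
        res = relax(p, tol=1e-4, max_steps=2000)
        trace = np.array(res.energy_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_hexagonal_ground_state_energy_closed_form(self):
        """Relaxed defect-free isotropic lattice = regular hexagons."""
        pars = Parameters(anisotropy=0.0)
        p = build_columnar_packing(4, 6, pars, periodic_x=True)
        relax(p, tol=1e-6, max_steps=4000)
        n = len(p.cells)
        s = np.sqrt(2.0 / (3.0 * np.sqrt(3.0)))   # hexagon side, area 1
        e_hex = n * (0.5 * pars.contractility * (6 * s) ** 2
                     + 3 * pars.reference_tension * s)
        assert energy(p) == pytest.approx(e_hex, rel=1e-6)

    def test_two_cell_pressure_balance(self):
        """Interface relocates until K(A-A0) matches across it (pure
        area elasticity, so the 1-D analytic balance is exact)."""
        pars = Parameters(anisotropy=0.0, reference_tension=0.0,
                          contractility=0.0)
        p = build_columnar_packing(2, 2, pars, periodic_x=True)
        cells = sorted(p.cells)
        a0 = {cells[0]: 0.7, cells[1]: 1.1, cells[2]: 0.9, cells[3]: 1.0}
        for cid, v in a0.items():
            p.cells[cid].preferred_area = v
        p.invalidate()
        relax(p, tol=1e-7, max_steps=6000)
        slack = (p.box_area() - sum(a0.values())) / len(cells)
        residuals = [pars.area_stiffness * (p.cell_area(c) - a0[c])
                     for c in cells]
        assert np.ptp(residuals) < 1e-4
        for cid in cells:
            assert p.cell_area(cid) == pytest.approx(a0[cid] + slack,
                                                     abs=1e-3)


class TestT1:
    def _shrink_edge(self, p, eid, length=0.02):
        e = p.edges[eid]
        a, b = e.vertices
        m = p.vertices[a].pos + 0.5 * p.displacement(a, b)
        d = p.wrap_delta(p.vertices[b].pos - m)
        u = d / np.hypot(*d)
        p.vertices[a].pos = (m - 0.5 * length * u) % [p.Lx, p.Ly]
        p.vertices[b].pos = (m + 0.5 * length * u) % [p.Lx, p.Ly]
        p.invalidate()

    def _interior_edge(self, p):
        for eid, e in p.edges.items():
            if None not in e.cells:
                a, b = e.vertices
                if (len(p.edges_at_vertex(a)) == 3
                        and len(p.edges_at_vertex(b)) == 3):
                    return eid
        raise AssertionError("no interior edge")

    def test_symmetric_collapse_opens_perpendicular_edge(self, hex_packing):
        """With all tensions equal the new edge is perpendicular to the
        collapsed one (mirror symmetry of the pair forces)."""
        p = hex_packing
        eid = self._interior_edge(p)
        before = p.edge_vector(eid)
        before /= np.hypot(*before)
        self._shrink_edge(p, eid)
        res = t1_transition(p, eid, force=True)
        assert res.performed
        after = p.edge_vector(eid)
        after /= np.hypot(*after)
        assert abs(float(before @ after)) < 1e-6

    def test_unequal_tensions_near_energy_scan_optimum(self, hex_packing):
        """The force-based orientation is close to the orientation found
        by brute-force rotation of the new edge at 1-degree resolution."""
        p = hex_packing
        eid = self._interior_edge(p)
        e0 = p.edges[eid]
        a, b = e0.vertices
        # high tension on the two outer edges of one side cell
        W = e0.cells[0]
        for out in p.edges_at_vertex(a) + p.edges_at_vertex(b):
            if out != eid and W in p.edges[out].cells:
                p.edges[out].base_tension *= 3.0
        self._shrink_edge(p, eid)
        res = t1_transition(p, eid, force=True)
        assert res.performed
        comp = p.compiled()
        # rotate the new edge about its midpoint and scan the energy
        row_a = comp.vids.index(a)
        row_b = comp.vids.index(b)
        pos0 = comp.pos.copy()
        mid = pos0[row_a] + 0.5 * comp._wrap(
            pos0[None, row_b] - pos0[None, row_a])[0]
        L = np.hypot(*(comp._wrap(pos0[None, row_b] - pos0[None, row_a])[0]))
        energies = []
        angles = np.deg2rad(np.arange(0, 180, 1.0))
        for th in angles:
            u = np.array([np.cos(th), np.sin(th)])
            trial = pos0.copy()
            trial[row_a] = mid - 0.5 * L * u
            trial[row_b] = mid + 0.5 * L * u
            energies.append(comp.energy(trial))
        energies = np.array(energies)
        e_chosen = comp.energy(pos0)
        # chosen orientation is near-optimal over the scan
        assert e_chosen <= energies.min() + 0.05 * np.ptp(energies)

    def test_t1_conserves_pcp_totals_euler_and_confluence(
            self, pcp_packing, rng):
        """100 random T1s: per-cell protein totals to 1e-8, Euler
        characteristic and confluence preserved."""
        p = pcp_packing
        totals = total_pcp(p)
        chi0 = p.euler_characteristic()
        done = 0
        attempts = 0
        while done < 100 and attempts < 600:
            attempts += 1
            eid = int(rng.choice(list(p.edges)))
            if None in p.edges[eid].cells:
                continue
            self._shrink_edge(p, eid)
            if t1_transition(p, eid, force=True).performed:
                done += 1
                relax(p, tol=1e-3, max_steps=100)
        assert done == 100
        dev = max(abs(p.cell_pcp_total(c) - totals[c]) for c in p.cells)
        assert dev < 1e-8
        assert p.euler_characteristic() == chi0
        assert abs(p.total_area() - p.box_area()) / p.box_area() < 1e-6

    def test_uniform_concentration_preserved_on_new_edge(self, hex_packing):
        """All old edges at equal concentration -> new edge at the same
        concentration; totals unchanged (sigma-blend identity case)."""
        p = hex_packing
        c0 = 0.2
        eid = self._interior_edge(p)
        self._shrink_edge(p, eid)
        for e in p.edges.values():
            L = p.edge_length(e.id)
            for cid in e.cells:
                if cid is not None:
                    e.pcp_amount[cid] = 0.5 * c0 * L
        p.invalidate()
        totals = total_pcp(p)
        res = t1_transition(p, eid, force=True)
        assert res.performed
        e = p.edges[eid]
        L = p.edge_length(eid)
        conc = sum(e.pcp_amount.values()) / L
        assert conc == pytest.approx(c0, rel=1e-6)
        for cid, t in totals.items():
            assert p.cell_pcp_total(cid) == pytest.approx(t, abs=1e-10)

    def test_refractory_prevents_flip_flop(self, hex_packing):
        p = hex_packing
        eid = self._interior_edge(p)
        self._shrink_edge(p, eid, length=0.02)
        t1_transition(p, eid, force=True)
        n_cells = len(p.cells)
        descend_sweeps(p, 10)
        p.validate()
        assert len(p.cells) == n_cells


class TestRemoveCell:
    def test_triangle_removal_keeps_complex_consistent(self):
        pars = Parameters(anisotropy=0.0)
        p = build_columnar_packing(5, 6, pars, periodic_x=True)
        cid = sorted(p.cells)[12]
        p.cells[cid].tension_factor = 3.0
        p.invalidate()
        removed = False
        for _ in range(14):
            p.cells[cid].preferred_area *= 0.4
            p.invalidate()
            descend_sweeps(p, 5)
            if p.cell_area(cid) < 0.05:
                while len(p.cells[cid].edge_cycle) > 3:
                    short = min(p.cells[cid].edge_cycle, key=p.edge_length)
                    if not t1_transition(p, short, force=True).performed:
                        break
                if len(p.cells[cid].edge_cycle) == 3:
                    remove_cell(p, cid)
                    removed = True
                    break
        assert removed
        p.validate()
        assert p.euler_characteristic() == 0
        assert cid not in p.cells


class TestSerialization:
    def test_json_roundtrip(self, pcp_packing, tmp_path):
        p = pcp_packing
        path = tmp_path / "packing.json"
        p.to_json(path)
        q = Packing.from_json(path)
        assert set(q.cells) == set(p.cells)
        assert q.params.to_dict() == p.params.to_dict()
        assert energy(q) == pytest.approx(energy(p), rel=1e-12)
        for cid in p.cells:
            assert q.cells[cid].type is p.cells[cid].type
            assert q.cell_pcp_total(cid) == pytest.approx(
                p.cell_pcp_total(cid), abs=1e-12)
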