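import dataclasses
import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from vascufab.config import ChemoParams, ConvergenceSpec
from vascufab.core import Cell, CellArrays, CellKind, SoluteField, make_initial_state
from vascufab.morphogenesis import (
    TOL_OVERLAP,
    adhesion_force,
    chemotaxis_force,
    relax_shoving,
    run_morphogenesis,
    secretion_rate,
)


def vascular(i, x, y, r=2.0):
    return Cell(i, CellKind.VASCULAR, (x, y), r, 1.0)


class TestSecretionRate:
    def test_monod_zero_substrate(self):
        p = ChemoParams(mu_c=0.02, k=0.5)
        assert secretion_rate(vascular(0, 5, 5), 0.0, p) == 0.0

    def test_monod_saturation_limit(self):
        p = ChemoParams(mu_c=0.02, k=0.5)
        cell = vascular(0, 5, 5)
        rate = secretion_rate(cell, 1e9, p)
        assert rate == pytest.approx(0.02 * 1.0 / (math.pi * 4.0), rel=1e-6)

    def test_half_saturation_identity(self):
        p = ChemoParams(mu_c=0.02, k=0.5)
        cell = vascular(0, 5, 5)
        assert secretion_rate(cell, 0.5, p) == pytest.approx(
            0.5 * secretion_rate(cell, 1e12, p), rel=1e-4)

    def test_producers_do_not_secrete(self):
        p = ChemoParams()
        prod = Cell(0, CellKind.PRODUCER, (5, 5), 2.0, 1.0)
        with pytest.raises(ValueError, match="producer"):
            secretion_rate(prod, 1.0, p)

    def test_circulatory_cells_secrete(self):
        p = ChemoParams()
        circ = Cell(0, CellKind.CIRC_SOURCE, (5, 5), 2.0, 1.0)
        assert secretion_rate(circ, 1.0, p) > 0


class TestChemotaxisForce:
    def test_uniform_field_gives_no_force(self, rng):
        p = ChemoParams(lambda_=1.0, beta_sat=0.0)
        field = SoluteField("c", np.full((32, 32), 2.0), 1.0)
        for _ in range(10):
            assert chemotaxis_force(vascular(0, 16, 16), field, p, rng) is None

    def test_unsaturated_force_is_concentration_difference(self, rng):
        # beta=0 reduces the law to lambda*(C+ - C-); a linear-in-x field
        # gives C+ - C- = slope * 2r * cos(theta) along the sampled direction
        p = ChemoParams(lambda_=1.0, beta_sat=0.0)
        slope = 0.25
        values = np.tile(np.arange(64) * slope, (64, 1))
        field = SoluteField("c", values, 1.0)
        cell = vascular(0, 32.0, 32.0, r=2.0)
        for _ in range(20):
            f = chemotaxis_force(cell, field, p, rng)
            if f is None:
                continue
            mag = np.linalg.norm(f)
            cos_theta = abs(f[0]) / mag
            assert mag == pytest.approx(slope * 2 * 2.0 * cos_theta, rel=1e-6)
            assert f[0] > 0   # force points uphill (+x)

    def test_negative_drive_applies_no_force(self, rng):
        # lambda=1, beta=0.5, C+=2, C-=4 -> F = 2/(1+1) - 4/(1+2) = -1/3 < 0
        p = ChemoParams(lambda_=1.0, beta_sat=0.5)
        b = p.beta_sat
        F = 1.0 * (2 / (1 + b * 2) - 4 / (1 + b * 4))
        assert F == pytest.approx(1.0 - 4.0 / 3.0)
        # realized: a steep downhill step field; samples land on the two sides
        values = np.where(np.arange(64)[None, :] < 32, 4.0, 2.0)
        field = SoluteField("c", np.broadcast_to(values, (64, 64)).copy(), 1.0)
        cell = vascular(0, 32.0, 32.0, r=4.0)
        forces = [chemotaxis_force(cell, field, p, np.random.default_rng(s))
                  for s in range(30)]
        mags = [np.linalg.norm(f) for f in forces if f is not None]
        # downhill (negative-F) samples are dropped, so every applied force
        # is bounded by the positive branch of the law
        assert all(m <= 1.0 * (4 / 3 - 2 / 2) + 1e-9 for m in mags)

    def test_only_vascular_cells_respond(self, rng):
        p = ChemoParams()
        field = SoluteField("c", np.zeros((8, 8)), 1.0)
        with pytest.raises(ValueError, match="vascular"):
            chemotaxis_force(Cell(0, CellKind.PRODUCER, (4, 4), 2.0, 1.0),
                             field, p, rng)


class TestAdhesionForce:
    p = ChemoParams(adhesion_strength=0.5, adhesion_range=2.0)

    def test_zero_beyond_cutoff(self):
        a, b = vascular(0, 0, 0), vascular(1, 6.5, 0)   # gap 2.5 > range
        assert np.allclose(adhesion_force(a, b, self.p), 0.0)

    def test_magnitude_approaches_maximum_at_contact(self):
        a, b = vascular(0, 0, 0), vascular(1, 4.01, 0)  # gap 0.01
        f = adhesion_force(a, b, self.p)
        assert np.linalg.norm(f) == pytest.approx(0.5 * (1 - 0.01 / 2.0))
        assert f[0] > 0   # attraction toward b

    def test_newtons_third_law(self):
        a, b = vascular(0, 1.0, 2.0), vascular(1, 4.5, 4.0)
        np.testing.assert_allclose(adhesion_force(a, b, self.p),
                                   -adhesion_force(b, a, self.p))

    def test_overlapping_pair_has_no_adhesion(self):
        a, b = vascular(0, 0, 0), vascular(1, 3.0, 0)   # overlap
        assert np.allclose(adhesion_force(a, b, self.p), 0.0)


class TestRelaxShoving:
    def test_no_overlap_is_a_fixed_point(self):
        cells = [vascular(0, 0, 0), vascular(1, 10, 0)]
        out, disp = relax_shoving(cells, 10)
        assert disp == 0.0
        assert [c.position for c in out] == [c.position for c in cells]

    def test_symmetric_split_of_overlap(self):
        # two equal cells overlapping by 2 um move 1 um each, apart
        cells = [vascular(0, 10.0, 5.0), vascular(1, 12.0, 5.0)]
        out, _ = relax_shoving(cells, 50, domain=(40.0, 40.0))
        x0, x1 = out[0].position[0], out[1].position[0]
        assert x1 - x0 == pytest.approx(4.0, abs=2 * TOL_OVERLAP)
        assert (x0 + x1) / 2 == pytest.approx(11.0, abs=1e-6)

    def test_immovable_partner_takes_no_displacement(self):
        circ = Cell(0, CellKind.CIRC_SOURCE, (5.0, 5.0), 2.0, 1.0)
        cell = vascular(1, 8.0, 5.0)   # overlap 1 um
        out, _ = relax_shoving([circ, cell], 50, domain=(40.0, 40.0))
        assert out[0].position == (5.0, 5.0)
        assert out[1].position[0] == pytest.approx(9.0, abs=2 * TOL_OVERLAP)

    def test_random_population_resolves_overlaps(self, sparse_config, rng):
        # at moderate packing every pairwise overlap is fully resolvable
        cells = make_initial_state(sparse_config, rng)
        out, _ = relax_shoving(
            cells, 200,
            domain=(sparse_config.domain_width, sparse_config.domain_height))
        arr = CellArrays.from_cells(out)
        interior = arr.pos[arr.movable]
        d, _ = cKDTree(arr.pos).query(interior, k=2)
        worst = (2 * sparse_config.cell_radius - d[:, 1]).max()
        assert worst <= 5 * TOL_OVERLAP


class TestRunMorphogenesis:
    def test_zero_forces_freeze_positions(self, sparse_config, quiet_chemo):
        # with lambda=0 and no adhesion the final positions equal the
        # post-shoving initial positions and the loop stops on patience
        cfg = dataclasses.replace(
            sparse_config, chemo_params=quiet_chemo,
            convergence=ConvergenceSpec(max_steps=60, patience=5,
                                        eps_field=1.0),
        )
        rng = np.random.default_rng(3)
        init = make_initial_state(cfg, np.random.default_rng(cfg.seed))
        state = run_morphogenesis(cfg, rng, cells=init)
        assert state.converged
        assert state.step <= cfg.convergence.patience + 2
        shoved, _ = relax_shoving(
            init, 120, domain=(cfg.domain_width, cfg.domain_height))
        final = CellArrays.from_cells(state.cells).pos
        expected = CellArrays.from_cells(shoved).pos
        np.testing.assert_allclose(final, expected, atol=1e-9)

    def test_zero_vascular_fraction_converges_immediately(self, tiny_config):
        cfg = dataclasses.replace(
            tiny_config, vascular_fraction=0.0,
            convergence=ConvergenceSpec(max_steps=60, patience=5, eps_field=1.0))
        state = run_morphogenesis(cfg, np.random.default_rng(1))
        kinds = {c.kind for c in state.cells}
        assert CellKind.VASCULAR not in kinds
        assert state.converged

    def test_bit_identical_given_seed(self, tiny_config):
        cfg = dataclasses.replace(
            tiny_config, convergence=ConvergenceSpec(max_steps=25))
        a = run_morphogenesis(cfg, np.random.default_rng(7))
        b = run_morphogenesis(cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(CellArrays.from_cells(a.cells).pos,
                                      CellArrays.from_cells(b.cells).pos)
        np.testing.assert_array_equal(a.field_short.values, b.field_short.values)

    def test_cells_stay_inside_domain_and_unoverlapped(self, tiny_config):
        cfg = dataclasses.replace(
            tiny_config, convergence=ConvergenceSpec(max_steps=40))
        state = run_morphogenesis(cfg, np.random.default_rng(5))
        arr = CellArrays.from_cells(state.cells)
        assert (arr.pos[:, 0] >= 0).all() and (arr.pos[:, 0] < cfg.domain_width).all()
        assert (arr.pos[:, 1] >= 0).all() and (arr.pos[:, 1] < cfg.domain_height).all()
        movable_pos = arr.pos[arr.movable]
        d, _ = cKDTree(arr.pos).query(movable_pos, k=2)
        assert (2 * cfg.cell_radius - d[:, 1]).max() <= 6 * TOL_OVERLAP

    def test_fields_nonnegative_and_short_range_steeper(self, tiny_config):
        cfg = dataclasses.replace(
            tiny_config, convergence=ConvergenceSpec(max_steps=30))
        state = run_morphogenesis(cfg, np.random.default_rng(2))
        assert (state.field_short.values >= 0).all()
        assert (state.field_long.values >= 0).all()
        p = cfg.chemo_params
        assert math.sqrt(p.D_c / p.beta_v) < math.sqrt(p.D_c / p.beta_c)

    def test_decay_length_ordering_measured_empirically(self):
        # one secreting cell at the centre; the fast-decay field must fall
        # off over a shorter distance than the slow-decay field
        from vascufab.core import steady_state_field

        p = ChemoParams()
        src = np.zeros((129, 129))
        src[64, 64] = 1.0
        fshort = steady_state_field("s", src, p.beta_v, p.D_c, 1.0)
        flong = steady_state_field("l", src, p.beta_c, p.D_c, 1.0)

        def halfwidth(f):
            prof = f.values[64, 64:]
            return np.argmax(prof < prof[1] / math.e)

        assert halfwidth(fshort) < halfwidth(flong)

    def test_cord_formation_at_default_fraction(self, tiny_config):
        # vascular cells organize into touching cords: most end up with at
        # least one vascular neighbour within adhesion range (threshold
        # frozen from reference runs of the scaled profile)
        cfg = dataclasses.replace(
            tiny_config, vascular_fraction=0.30,
            convergence=ConvergenceSpec(max_steps=150))
        state = run_morphogenesis(cfg, np.random.default_rng(11))
        arr = CellArrays.from_cells(state.cells)
        v = arr.pos[arr.kind_mask(CellKind.VASCULAR)]
        reach = 2 * cfg.cell_radius + cfg.chemo_params.adhesion_range
        neighbours = cKDTree(v).query_ball_point(v, reach, return_length=True)
        assert (neighbours >= 2).mean() >= 0.80
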