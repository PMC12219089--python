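import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recurph.cubical import (
    PersistenceDiagram,
    PersistencePair,
    persistence_h0,
    read_diagram,
    sublevel_betti0,
    write_diagram,
)
from conftest import FIG2_BETTI, FIG2_ESSENTIAL, FIG2_FINITE_PAIRS


class TestSublevelBetti0:
    @pytest.mark.parametrize("r,expected", sorted(FIG2_BETTI.items()))
    def test_worked_example_counts(self, fig2_matrix, r, expected):
        assert sublevel_betti0(fig2_matrix, r) == expected

    def test_corner_contact_not_connected(self):
        # V-construction: edge adjacency only, so the two zero pixels on
        # the anti-diagonal of a 2x2 checkerboard stay separate
        assert sublevel_betti0([[0, 1], [1, 0]], 0) == 2

    def test_empty_sublevel_set(self):
        assert sublevel_betti0([[1.0, 2.0]], 0.5) == 0


class TestPersistenceH0:
    def test_worked_example_diagram(self, fig2_matrix):
        pd = persistence_h0(fig2_matrix)
        assert sorted((p.birth, p.death) for p in pd.finite_pairs) == FIG2_FINITE_PAIRS
        assert pd.essential_births == FIG2_ESSENTIAL

    def test_single_pixel(self):
        pd = persistence_h0([[4.2]])
        assert pd.finite_pairs == []
        assert pd.essential_births == [4.2]

    def test_oracle_equivalence_random_matrices(self):
        """PD-implied Betti-0 equals flood fill at every realized value."""
        rng = np.random.default_rng(7)
        for trial in range(200):
            h, w = rng.integers(1, 13, size=2)
            if trial % 2:
                mat = rng.integers(0, 6, size=(h, w)).astype(float)
            else:
                mat = rng.normal(size=(h, w))
            pd = persistence_h0(mat)
            for r in np.unique(mat):
                assert pd.betti0_at(r) == sublevel_betti0(mat, r), (trial, r)

    def test_stability_under_small_perturbation(self):
        """Counts of features with persistence > 2*eps survive an
        eps-bounded perturbation (bottleneck stability)."""
        rng = np.random.default_rng(11)
        eps = 0.1
        for _ in range(50):
            mat = rng.integers(0, 11, size=(20, 20)).astype(float)
            noise = rng.uniform(-eps, eps, size=mat.shape)
            count = lambda pd: sum(1 for p in pd.finite_pairs if p.persistence > 2 * eps)
            assert count(persistence_h0(mat)) == count(persistence_h0(mat + noise))

    def test_betti_at_zero_equals_matrix_size_for_distance_matrix(self, rng):
        from recurph.embedding import delay_embed, recurrence_distance_matrix

        d = recurrence_distance_matrix(delay_embed(rng.normal(size=30), k=3)).entries
        assert sublevel_betti0(d, 0.0) == d.shape[0]
        pd = persistence_h0(d)
        assert pd.betti0_at(0.0) == d.shape[0]

    def test_transpose_invariance_symmetric_input(self, rng):
        m = rng.normal(size=(15, 15))
        m = m + m.T
        a = persistence_h0(m).births_deaths()
        b = persistence_h0(m.T).births_deaths()
        assert np.array_equal(a, b)

    def test_zero_persistence_pairs_flag(self):
        flat = np.zeros((3, 3))
        assert len(persistence_h0(flat)) == 0
        kept = persistence_h0(flat, keep_zero_persistence=True)
        assert len(kept) == 8  # 9 pixels merge into one component
        assert all(p.persistence == 0 for p in kept.finite_pairs)

    def test_birth_location_is_component_minimum(self):
        mat = np.array([[5.0, 9, 1], [9, 9, 9], [0, 9, 9]], dtype=float)
        pd = persistence_h0(mat)
        locations = {p.birth_location for p in pd.finite_pairs}
        # dying components were born at the pixels holding 1 and 5
        assert locations <= {(0, 2), (0, 0)}

    @settings(deadline=None, max_examples=40)
    @given(seed=st.integers(0, 2**31 - 1), h=st.integers(1, 8), w=st.integers(1, 8))
    def test_essential_count_is_one_property(self, seed, h, w):
        """A full rectangular image is connected, so exactly one
        component never dies."""
        mat = np.random.default_rng(seed).normal(size=(h, w))
        pd = persistence_h0(mat)
        assert len(pd.essential_births) == 1
        assert pd.essential_births[0] == mat.min()


class TestDiagramIO:
    def test_round_trip(self, fig2_matrix, tmp_path):
        pd = persistence_h0(fig2_matrix)
        path = tmp_path / "pd.csv"
        write_diagram(pd, path)
        back = read_diagram(path)
        assert np.array_equal(back.births_deaths(), pd.births_deaths())
        assert back.essential_births == pd.essential_births
        assert "inf" in path.read_text()

    def test_empty_diagram(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_diagram(PersistenceDiagram(), path)
        back = read_diagram(path)
        assert len(back) == 0 and back.essential_births == []

    def test_malformed_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("dim,birth,death\n0,0.0,1.0\n0,nope,2.0\n")
        with pytest.raises(ValueError, match="line 3"):
            read_diagram(path)
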