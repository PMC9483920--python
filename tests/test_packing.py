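"""Torus+sphere packing geometry and derived-structure connectivity."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from salrshell.packing import (
    PackingSolution,
    chord_spacing,
    decompositions,
    derived_connectivity,
    generate_centerline,
    rotation_angle,
    select_packing,
    shell_inner_radius,
    structure_menu,
)

from conftest import quiet_shell


class TestRotationAngle:
    @pytest.mark.parametrize(
        "k, l, expected",
        [
            (4, 1, 2 * math.pi / 9),
            (2, 2, math.pi / 3),
            (5, 1, 2 * math.pi / 11),
            (3, 0, math.pi / 3),
            (4, 0, math.pi / 4),
        ],
    )
    def test_values(self, k, l, expected):
        assert rotation_angle(k, l) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            rotation_angle(4, 3)
        with pytest.raises(ValueError):
            rotation_angle(0, 1)


class TestShellInnerRadius:
    def test_exact_trig_values(self):
        assert shell_inner_radius(6, 5.0, 5.0) == pytest.approx(2.5)
        w = 3.0
        assert shell_inner_radius(4, w, w) == pytest.approx(
            w / (2 * math.sin(math.pi / 4)) - w / 2
        )
        assert shell_inner_radius(9, 5.0, 6.0) == pytest.approx(6.271, abs=1e-3)

    def test_touching_condition(self):
        # adjacent crossing chord equals the tube diameter by construction
        for n in (5, 8, 13):
            d = 4.7
            r_inn = shell_inner_radius(n, 5.0, d)
            assert chord_spacing(r_inn + 2.5, n) == pytest.approx(d)

    def test_no_valid_shell(self):
        with pytest.raises(ValueError):
            shell_inner_radius(3, 10.0, 1.0)


class TestSelectPacking:
    @pytest.mark.parametrize(
        "r_inn, r_out, n, kls",
        [
            (3.0, 8.0, 6, {(3, 0), (2, 2)}),
            (5.0, 10.0, 8, {(4, 0), (3, 2)}),
            (6.0, 11.0, 9, {(4, 1)}),
            (7.5, 12.5, 11, {(5, 1)}),
        ],
    )
    def test_studied_shells(self, r_inn, r_out, n, kls):
        sols = select_packing(quiet_shell(r_inn, r_out))
        assert {s.n for s in sols} == {n}
        assert {(s.k, s.l) for s in sols} == kls

    def test_spacing_field(self):
        sol = select_packing(quiet_shell(6, 11))[0]
        assert sol.spacing == pytest.approx(2 * 8.5 * math.sin(math.pi / 9))

    def test_default_spacing_calibration_window(self):
        """Brute-force over preferred spacings: the window reproducing all
        four studied packings (n = 6, 8, 9, 11) contains the default 5.6."""
        shells = [
            (quiet_shell(3, 8), 6),
            (quiet_shell(5, 10), 8),
            (quiet_shell(6, 11), 9),
            (quiet_shell(7.5, 12.5), 11),
        ]
        good = [
            d
            for d in np.arange(5.0, 6.001, 0.005)
            if all(
                {s.n for s in select_packing(sh, d_star=float(d))} == {n}
                for sh, n in shells
            )
        ]
        assert good, "no spacing reproduces all four shells"
        assert min(good) <= 5.6 <= max(good)

    def test_parity_decompositions(self):
        assert decompositions(9) == [(4, 1)]
        assert set(decompositions(8)) == {(4, 0), (3, 2)}


def _oracle_components(n, l_a, l_b, m):
    """Independent connectivity oracle: components of the two-matching
    multigraph built with networkx, with caps as pendant terminal nodes."""
    c_a = 0 if l_a >= 1 else 1
    g = nx.MultiGraph()
    g.add_nodes_from(range(n))
    two_n = 2 * n
    caps_a = {p for p in range(n) if (2 * p + c_a) % two_n in (0, n)}
    caps_b = {p for p in range(n) if (2 * p + c_a - m) % two_n in (0, n)}
    for p in range(n):
        if p not in caps_a:
            g.add_edge(p, (-c_a - p) % n, side="A")
        if p not in caps_b:
            g.add_edge(p, (m - c_a - p) % n, side="B")
    # deduplicate the double-listed involution edges
    h = nx.MultiGraph()
    h.add_nodes_from(range(n))
    seen = set()
    for u, v, d in g.edges(data=True):
        key = (min(u, v), max(u, v), d["side"])
        if key not in seen:
            seen.add(key)
            h.add_edge(u, v, side=d["side"])
    comps = []
    for nodes in nx.connected_components(h):
        sub = h.subgraph(nodes)
        if len(nodes) == 1 and sub.number_of_edges() == 0:
            comps.append(("sphere", 1))
        elif all(d == 2 for _, d in sub.degree()):
            comps.append(("closed", len(nodes)))
        else:
            comps.append(("open", len(nodes)))
    return sorted(comps)


def _all_valid_cases(n_max):
    for n in range(3, n_max + 1):
        ls = [(1, 1)] if n % 2 else [(0, 0), (2, 2), (0, 2), (2, 0)]
        for l_a, l_b in ls:
            c_a = 0 if l_a >= 1 else 1
            c_b = 0 if l_b >= 1 else 1
            for m in range(0, 2 * n):
                if (c_a - c_b - m) % 2 == 0:
                    yield n, l_a, l_b, m


class TestDerivedConnectivity:
    @pytest.mark.parametrize(
        "n, l_a, l_b, m, summary",
        [
            (9, 1, 1, 0, (4, 0, 1)),  # generating: 4 tori + 1 sphere
            (9, 1, 1, 6, (1, 1, 0)),  # 3*theta: open + closed
            (9, 1, 1, 2, (0, 1, 0)),  # theta: single open coil
            (9, 1, 1, 4, (0, 1, 0)),
            (9, 1, 1, 8, (0, 1, 0)),
            (11, 1, 1, 0, (5, 0, 1)),
            (6, 0, 0, 0, (3, 0, 0)),
            (6, 2, 2, 0, (2, 0, 2)),
            (6, 0, 2, 1, (0, 1, 0)),  # hybrid
            (6, 0, 2, 3, (1, 1, 0)),
            (8, 0, 2, 1, (0, 1, 0)),
        ],
    )
    def test_printed_structures(self, n, l_a, l_b, m, summary):
        assert derived_connectivity(n, l_a, l_b, m).summary() == summary

    def test_three_theta_hand_trace(self):
        """The 3*theta structure of the nine-crossing shell: open path
        0-6-3 between the caps and closed loop 1-8-7-2-4-5."""
        st_ = derived_connectivity(9, 1, 1, 6)
        open_ = [c for c in st_.components if c.kind == "open"][0]
        closed = [c for c in st_.components if c.kind == "closed"][0]
        assert set(open_.positions) == {0, 6, 3}
        assert set(closed.positions) == {1, 8, 7, 2, 4, 5}

    def test_all_rotations_n11_single_open(self):
        for m_prime in range(1, 6):
            st_ = derived_connectivity(11, 1, 1, 2 * m_prime)
            assert st_.summary() == (0, 1, 0)
            assert len(st_.components[0].positions) == 11

    def test_oracle_equivalence_exhaustive(self):
        """Trace vs independent graph-component oracle for every valid
        (n, l_a, l_b, m) with n <= 31."""
        checked = 0
        for n, l_a, l_b, m in _all_valid_cases(31):
            st_ = derived_connectivity(n, l_a, l_b, m)
            got = sorted(
                (c.kind, len(c.positions)) for c in st_.components
            )
            assert got == _oracle_components(n, l_a, l_b, m), (n, l_a, l_b, m)
            checked += 1
        assert checked > 500

    def test_prime_n_single_open_component(self):
        """For prime n with one polar sphere, every nonzero rotation gives
        exactly one open coil (verified exhaustively for n <= 31)."""
        for n in (5, 7, 11, 13, 17, 19, 23, 29, 31):
            for m_prime in range(1, (n - 1) // 2 + 1):
                st_ = derived_connectivity(n, 1, 1, 2 * m_prime)
                assert st_.summary() == (0, 1, 0), (n, m_prime)

    @given(st.integers(min_value=3, max_value=40), st.data())
    def test_partition_and_end_count(self, n, data):
        ls = [(1, 1)] if n % 2 else [(0, 0), (2, 2), (0, 2)]
        l_a, l_b = data.draw(st.sampled_from(ls))
        c_a = 0 if l_a >= 1 else 1
        c_b = 0 if l_b >= 1 else 1
        m = data.draw(
            st.integers(min_value=-2 * n, max_value=2 * n).filter(
                lambda m_: (c_a - c_b - m_) % 2 == 0
            )
        )
        st_ = derived_connectivity(n, l_a, l_b, m)
        all_pos = sorted(p for c in st_.components for p in c.positions)
        assert all_pos == list(range(n))
        ends = sum(c.n_open_ends for c in st_.components)
        spheres = sum(1 for c in st_.components if c.kind == "sphere")
        assert ends + 2 * spheres == l_a + l_b

    def test_parity_violations_rejected(self):
        with pytest.raises(ValueError):
            derived_connectivity(9, 1, 1, 3)  # odd rotation needs a hybrid
        with pytest.raises(ValueError):
            derived_connectivity(9, 0, 0, 0)  # l=0 inconsistent with odd n
        with pytest.raises(ValueError):
            derived_connectivity(8, 0, 2, 2)  # hybrid requires odd m


class TestCenterlines:
    def test_generating_structure_geometry(self, shell_6_11):
        """Identity rotation: k closed latitude circles plus an isolated
        polar point, all on the mid-shell sphere."""
        st_ = derived_connectivity(9, 1, 1, 0)
        curves = generate_centerline(st_, shell_6_11)
        assert len(curves) == 5
        for c in curves:
            r = np.linalg.norm(c, axis=1)
            assert np.allclose(r, 8.5, atol=1e-9)
        spheres = [c for c in curves if len(c) == 1]
        assert len(spheres) == 1
        assert spheres[0][0] == pytest.approx([0, 0, 8.5])
        for c in curves:
            if len(c) > 1:  # closed circles at constant latitude
                assert np.allclose(c[:, 2], c[0, 2], atol=1e-9)

    def test_length_conserved_under_rotation(self, shell_6_11):
        """Hemisphere rotations are isometries: total center-line length is
        the same for every derived structure of a packing."""
        def total_length(m):
            st_ = derived_connectivity(9, 1, 1, m)
            return sum(
                np.linalg.norm(np.diff(c, axis=0), axis=1).sum()
                for c in generate_centerline(st_, shell_6_11)
            )

        lengths = [total_length(m) for m in (0, 2, 4, 6, 8)]
        assert np.allclose(lengths, lengths[0], rtol=1e-9)

    def test_curves_continuous_at_cut_plane(self, shell_6_11):
        st_ = derived_connectivity(9, 1, 1, 2)
        (curve,) = generate_centerline(st_, shell_6_11)
        gaps = np.linalg.norm(np.diff(curve, axis=0), axis=1)
        assert gaps.max() < 0.5  # no jumps: half-circles join head to tail

    def test_opposite_rotations_are_mirror_images(self, shell_6_11):
        """+m and -m give left- and right-handed versions: reflecting the
        +m center-lines through the cut plane and rotating by -m*theta/2
        about the cut-plane normal reproduces the -m structure."""
        from scipy.spatial import cKDTree

        m = 4
        plus = generate_centerline(
            derived_connectivity(9, 1, 1, m), shell_6_11
        )
        minus = generate_centerline(
            derived_connectivity(9, 1, 1, -m), shell_6_11
        )
        phi = -m * math.pi / 9
        rot = np.array(
            [
                [math.cos(phi), 0, math.sin(phi)],
                [0, 1, 0],
                [-math.sin(phi), 0, math.cos(phi)],
            ]
        )
        mirrored = np.vstack(plus) * np.array([1.0, -1.0, 1.0]) @ rot.T
        target = np.vstack(minus)
        d, _ = cKDTree(target).query(mirrored)
        assert d.max() < 0.2  # same curves up to the sampling resolution

    def test_handedness_sign(self):
        assert derived_connectivity(9, 1, 1, 2).handedness == 1
        assert derived_connectivity(9, 1, 1, -2).handedness == -1
        assert derived_connectivity(9, 1, 1, 0).handedness == 0


def test_structure_menu_contents():
    menu = structure_menu(quiet_shell(3, 8))
    summaries = {s.summary() for s in menu}
    # printed small-shell menu: tori-only, tori+spheres, single closed
    # loop, single open coil, open + closed
    for expected in [(3, 0, 0), (2, 0, 2), (1, 0, 0), (0, 1, 0), (1, 1, 0)]:
        assert expected in summaries
    assert any(s.is_hybrid for s in menu)
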