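"""Geometric model: optimal packing of tori and spheres in a spherical shell.

A narrow shell of width ``W`` can be filled with ``k`` tori (horizontal
circles of tube diameter ``W`` stacked at latitudes) and ``l`` polar spheres
(``l = 0, 1, 2``).  Cutting such a *generating structure* along a meridian
plane and rotating one hemisphere about the axis perpendicular to the cut
plane by a multiple of the quantum ``theta = 2*pi/(2k + l)`` reconnects the
open tube ends into new, *derived* structures: coiled open tubes, closed
loops and mixtures.  When the two hemispheres come from the two degenerate
packings of the same shell (``k`` tori versus ``k - 1`` tori plus two
spheres, both even ``n = 2k + l``), odd multiples of ``theta/2`` produce
*hybrid* structures.

The connectivity of a derived structure is purely combinatorial.  The cut
plane intersects the tube center-lines in ``n`` equally spaced points on the
cut circle ("meridian positions").  Each hemisphere contributes a perfect
matching of its non-cap positions (every half-torus joins two positions that
are mirror images about that hemisphere's polar axis) while polar spheres
contribute half-sphere caps terminating a tube.  Components of the union of
the two matchings are the tubular clusters: alternating cycles are closed
tubes, alternating paths are open tubes ending at caps, and an isolated
doubly-capped position is a spherical cluster.

Angles are tracked in half-quanta of ``theta/2``: position ``p`` of the
final structure sits at angle ``alpha_p = (2p + c_A) * theta/2`` on the cut
circle, where the offset ``c_A`` is 0 when hemisphere A carries polar caps
and 1 (no polar position) otherwise.  A rotation by ``m`` half-quanta is a
pure rotation for even ``m`` and a hybrid construction for odd ``m``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ShellGeometry

__all__ = [
    "PackingSolution",
    "Component",
    "DerivedStructure",
    "rotation_angle",
    "shell_inner_radius",
    "chord_spacing",
    "decompositions",
    "select_packing",
    "derived_connectivity",
    "generate_centerline",
    "structure_menu",
]

#: Preferred center-to-center spacing of neighboring clusters (sigma units).
#: In the simulations the soft long-range repulsion sets the spacing close to
#: the bulk hexagonal lattice constant l0 ~ 6 sigma; 5.6 sigma reproduces the
#: packings observed in all four simulated shells (n = 6, 8, 9, 11).
DEFAULT_D_STAR = 5.6


def rotation_angle(k: int, l: int) -> float:
    """Rotation quantum theta = 2*pi/(2k + l) for k tori and l polar spheres."""
    if k < 1:
        raise ValueError("need at least one torus (k >= 1)")
    if l not in (0, 1, 2):
        raise ValueError("sphere count l must be 0, 1 or 2")
    return 2.0 * math.pi / (2 * k + l)


def chord_spacing(r_c: float, n: int) -> float:
    """Chord between adjacent meridian positions on the circle of radius r_c."""
    return 2.0 * r_c * math.sin(math.pi / n)


def shell_inner_radius(n: int, width: float, tube_diameter: float) -> float:
    """Inner shell radius that closely packs ``n = 2k + l`` tube crossings.

    The ``n`` circular tube cross-sections of diameter ``D`` are centered on
    the mid-shell meridian circle of radius ``R_c = R_inn + W/2``; close
    packing makes adjacent chords equal to ``D``, so
    ``R_inn = D / (2 sin(pi/n)) - W/2``.
    """
    if n < 3:
        raise ValueError("need at least three crossings (n >= 3)")
    if width <= 0 or tube_diameter <= 0:
        raise ValueError("width and tube diameter must be positive")
    r_inn = tube_diameter / (2.0 * math.sin(math.pi / n)) - 0.5 * width
    if r_inn <= 0:
        raise ValueError(
            f"no valid shell: n={n} crossings of diameter {tube_diameter} "
            f"do not fit a shell of width {width}"
        )
    return r_inn


def decompositions(n: int) -> list[tuple[int, int]]:
    """All (k, l) with 2k + l = n, l in {0, 1, 2}, k >= 1.

    Odd ``n`` admits exactly one decomposition (l = 1); even ``n`` admits the
    two degenerate ones (l = 0 and l = 2) that share the same shell size.
    """
    if n < 3:
        raise ValueError("n >= 3 required")
    if n % 2 == 1:
        return [((n - 1) // 2, 1)]
    out = [(n // 2, 0)]
    if n // 2 - 1 >= 1:
        out.append((n // 2 - 1, 2))
    return out


@dataclass(frozen=True)
class PackingSolution:
    """A generating packing of ``k`` tori and ``l`` polar spheres.

    ``n = 2k + l`` meridian crossings, rotation quantum ``theta = 2 pi / n``,
    mid-shell radius ``r_c`` and adjacent-crossing chord ``spacing``.
    """

    k: int
    l: int
    n: int
    theta: float
    r_c: float
    spacing: float
    tie: bool = False

    @classmethod
    def from_kl(cls, k: int, l: int, r_c: float, tie: bool = False) -> "PackingSolution":
        n = 2 * k + l
        return cls(
            k=k,
            l=l,
            n=n,
            theta=rotation_angle(k, l),
            r_c=r_c,
            spacing=chord_spacing(r_c, n),
            tie=tie,
        )


def select_packing(
    shell: ShellGeometry,
    d_star: float = DEFAULT_D_STAR,
    n_max: int = 64,
) -> list[PackingSolution]:
    """Packings whose crossing spacing best matches the preferred cluster
    spacing ``d_star``.

    Minimizes ``|2 R_c sin(pi/n) - d_star|`` over ``n >= 3`` and returns the
    parity-consistent (k, l) decompositions of the optimal ``n`` (both
    decompositions for even ``n``).  If two values of ``n`` tie to within
    1e-9 both are returned, flagged with ``tie=True``.
    """
    if d_star <= 0:
        raise ValueError("d_star must be positive")
    r_c = shell.mid_radius
    ns = np.arange(3, n_max + 1)
    diffs = np.abs(2.0 * r_c * np.sin(math.pi / ns) - d_star)
    best = diffs.min()
    winners = [int(n) for n, d in zip(ns, diffs) if d - best < 1e-9]
    tie = len(winners) > 1
    out: list[PackingSolution] = []
    for n in winners:
        for k, l in decompositions(n):
            out.append(PackingSolution.from_kl(k, l, r_c, tie=tie))
    return out


# ---------------------------------------------------------------------------
# Connectivity of derived structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Component:
    """One tubular cluster of a derived structure.

    ``kind`` is 'closed' (alternating cycle), 'open' (alternating path
    terminated by caps) or 'sphere' (a single doubly-capped position).
    ``positions`` lists the meridian positions in traversal order and
    ``edge_sides`` the hemisphere ('A' or 'B') providing each consecutive
    half-circle (cyclically for closed components).
    """

    kind: str
    positions: tuple[int, ...]
    edge_sides: tuple[str, ...]

    @property
    def n_open_ends(self) -> int:
        return 2 if self.kind == "open" else 0


@dataclass(frozen=True)
class DerivedStructure:
    """A structure derived by cutting and rotating a generating packing.

    ``m`` counts the rotation in half-quanta ``theta/2`` (even = pure
    rotation of ``m//2 * theta``, odd = hybrid).  ``l_a``/``l_b`` are the
    polar sphere counts of the two hemispheres, ``c_a`` the angular offset
    convention of the final position grid.
    """

    n: int
    l_a: int
    l_b: int
    m: int
    theta: float
    components: tuple[Component, ...]
    handedness: int

    @property
    def is_hybrid(self) -> bool:
        return self.l_a != self.l_b

    @property
    def c_a(self) -> int:
        return 0 if self.l_a >= 1 else 1

    @property
    def n_components(self) -> int:
        return len(self.components)

    def count(self, kind: str) -> int:
        return sum(1 for c in self.components if c.kind == kind)

    def summary(self) -> tuple[int, int, int]:
        """(closed, open, sphere) component counts."""
        return (self.count("closed"), self.count("open"), self.count("sphere"))


def _matchings(n: int, l_a: int, l_b: int, m: int):
    """Partner arrays and cap sets of the two hemisphere matchings.

    Returns ``(pa, pb, caps_a, caps_b, c_a)`` where ``pa[p]``/``pb[p]`` give
    the position joined to ``p`` by hemisphere A/B (or -1 at a cap).
    """
    if n < 3:
        raise ValueError("n >= 3 required")
    for l in (l_a, l_b):
        if l not in (0, 1, 2):
            raise ValueError("sphere counts must be 0, 1 or 2")
        if (n - l) % 2 != 0:
            raise ValueError(f"l={l} inconsistent with parity of n={n}")
    c_a = 0 if l_a >= 1 else 1
    c_b = 0 if l_b >= 1 else 1
    if (c_a - c_b - m) % 2 != 0:
        raise ValueError(
            f"rotation m={m} half-quanta incompatible with hemisphere caps "
            f"(l_a={l_a}, l_b={l_b}): tube ends do not meet"
        )
    two_n = 2 * n
    caps_a = {p for p in range(n) if (2 * p + c_a) % two_n in (0, n)}
    caps_b = {p for p in range(n) if (2 * p + c_a - m) % two_n in (0, n)}
    if len(caps_a) != l_a or len(caps_b) != l_b:
        raise ValueError("cap placement inconsistent with sphere counts")
    pa = np.full(n, -1, dtype=int)
    pb = np.full(n, -1, dtype=int)
    for p in range(n):
        if p not in caps_a:
            pa[p] = (-c_a - p) % n
        if p not in caps_b:
            pb[p] = (m - c_a - p) % n
    # each matching is an involution without fixed points off the caps
    for arr, caps in ((pa, caps_a), (pb, caps_b)):
        for p in range(n):
            if p in caps:
                continue
            if arr[p] == p or arr[arr[p]] != p:
                raise AssertionError("invalid hemisphere matching")
    return pa, pb, caps_a, caps_b, c_a


def derived_connectivity(n: int, l_a: int, l_b: int, m: int) -> DerivedStructure:
    """Trace the tubular clusters of the derived structure (n, l_a, l_b, m).

    ``m`` is the hemisphere rotation in units of ``theta/2``; even values are
    pure rotations by ``(m/2) theta``, odd values hybrids (which require even
    ``n`` and ``{l_a, l_b} = {0, 2}``).  Negative ``m`` gives the mirror
    (opposite handedness) structure.
    """
    pa, pb, caps_a, caps_b, c_a = _matchings(n, l_a, l_b, m)
    visited = np.zeros(n, dtype=bool)
    components: list[Component] = []

    # spheres: both hemispheres cap the same position
    for p in sorted(caps_a & caps_b):
        components.append(Component("sphere", (p,), ()))
        visited[p] = True

    def step(p: int, side: str) -> int:
        return int((pa if side == "A" else pb)[p])

    # open components start at a cap and alternate hemispheres
    for p0 in range(n):
        if visited[p0] or (p0 not in caps_a and p0 not in caps_b):
            continue
        side = "B" if p0 in caps_a else "A"  # first edge uses the uncapped side
        seq = [p0]
        sides = []
        visited[p0] = True
        cur = p0
        while True:
            nxt = step(cur, side)
            if nxt < 0:
                raise AssertionError("open trace hit a cap mid-walk")
            seq.append(nxt)
            sides.append(side)
            visited[nxt] = True
            cur = nxt
            side = "A" if side == "B" else "B"
            if (side == "A" and cur in caps_a) or (side == "B" and cur in caps_b):
                break
        components.append(Component("open", tuple(seq), tuple(sides)))

    # remaining positions belong to alternating cycles (closed tubes)
    for p0 in range(n):
        if visited[p0]:
            continue
        seq = [p0]
        sides = []
        visited[p0] = True
        cur = p0
        side = "A"
        while True:
            nxt = step(cur, side)
            sides.append(side)
            cur = nxt
            side = "A" if side == "B" else "B"
            if cur == p0 and side == "A":
                break
            seq.append(cur)
            visited[cur] = True
        components.append(Component("closed", tuple(seq), tuple(sides)))

    # invariants: partition + end bookkeeping
    all_pos = sorted(q for comp in components for q in comp.positions)
    if all_pos != list(range(n)):
        raise AssertionError("components do not partition the positions")
    n_ends = sum(c.n_open_ends for c in components) + 2 * sum(
        1 for c in components if c.kind == "sphere"
    )
    if n_ends != l_a + l_b:
        raise AssertionError("open-end count does not match cap count")

    return DerivedStructure(
        n=n,
        l_a=l_a,
        l_b=l_b,
        m=m,
        theta=2.0 * math.pi / n,
        components=tuple(components),
        handedness=(0 if m == 0 else (1 if m > 0 else -1)),
    )


# ---------------------------------------------------------------------------
# Center-line geometry
# ---------------------------------------------------------------------------


def _cut_circle_point(alpha: float, r_c: float) -> np.ndarray:
    """Point at angle alpha (from the north pole) on the cut circle, which
    lies in the xz-plane."""
    return np.array([r_c * math.sin(alpha), 0.0, r_c * math.cos(alpha)])


def _half_circle(
    alpha_p: float, side: str, phi_rot: float, r_c: float, n_pts: int
) -> np.ndarray:
    """Half-circle center-line of one half-torus, starting at position angle
    ``alpha_p`` on the cut circle.

    Hemisphere A occupies y >= 0; hemisphere B is the mirror image (y <= 0)
    rotated about the y-axis by ``phi_rot``.
    """
    psi = np.linspace(0.0, math.pi, n_pts)
    if side == "A":
        s, z = math.sin(alpha_p), r_c * math.cos(alpha_p)
        pts = np.column_stack(
            [r_c * s * np.cos(psi), r_c * abs(s) * np.sin(psi), np.full_like(psi, z)]
        )
        return pts
    beta = alpha_p - phi_rot
    s, z = math.sin(beta), r_c * math.cos(beta)
    pts = np.column_stack(
        [r_c * s * np.cos(psi), -r_c * abs(s) * np.sin(psi), np.full_like(psi, z)]
    )
    c, sn = math.cos(phi_rot), math.sin(phi_rot)
    x, zz = pts[:, 0].copy(), pts[:, 2].copy()
    pts[:, 0] = x * c + zz * sn
    pts[:, 2] = -x * sn + zz * c
    return pts


def generate_centerline(
    structure: DerivedStructure,
    shell: ShellGeometry | float,
    points_per_half_circle: int = 64,
) -> list[np.ndarray]:
    """Tube center-lines of a derived structure on the mid-shell sphere.

    Returns one polyline (M, 3) per component, in traversal order; 'sphere'
    components yield a single point (the polar sphere center).  Open curves
    start and end at the cap centers (the hemisphere pole positions on the
    cut circle); all points lie on the sphere of radius ``R_c``.
    """
    r_c = shell.mid_radius if isinstance(shell, ShellGeometry) else float(shell)
    theta_half = math.pi / structure.n
    c_a = structure.c_a
    phi_rot = structure.m * theta_half

    def alpha(p: int) -> float:
        return (2 * p + c_a) * theta_half

    curves: list[np.ndarray] = []
    for comp in structure.components:
        if comp.kind == "sphere":
            curves.append(_cut_circle_point(alpha(comp.positions[0]), r_c)[None, :])
            continue
        pieces = []
        pos = comp.positions
        n_edges = len(comp.edge_sides)
        for e in range(n_edges):
            p = pos[e]
            q = pos[(e + 1) % len(pos)]
            arc = _half_circle(
                alpha(p), comp.edge_sides[e], phi_rot, r_c, points_per_half_circle
            )
            # orient the arc to start at p's cut-circle point
            start = _cut_circle_point(alpha(p), r_c)
            end = _cut_circle_point(alpha(q), r_c)
            if np.linalg.norm(arc[0] - start) > np.linalg.norm(arc[-1] - start):
                arc = arc[::-1]
            if (
                np.linalg.norm(arc[0] - start) > 1e-9
                or np.linalg.norm(arc[-1] - end) > 1e-9
            ):
                raise AssertionError("half-circle does not join its positions")
            pieces.append(arc if e == 0 else arc[1:])
        curves.append(np.vstack(pieces))
    return curves


def structure_menu(
    shell: ShellGeometry,
    d_star: float = DEFAULT_D_STAR,
) -> list[DerivedStructure]:
    """All derived structures (up to mirror symmetry) for the packing
    selected by ``select_packing`` on this shell: the generating structures,
    their pure rotations, and for even ``n`` the hybrids at odd multiples of
    ``theta/2``."""
    solutions = select_packing(shell, d_star=d_star)
    n = solutions[0].n
    menu: list[DerivedStructure] = []
    for sol in solutions:
        for m_half in range(0, n + 1, 2):
            menu.append(derived_connectivity(n, sol.l, sol.l, m_half))
    if n % 2 == 0 and len(solutions) == 2:
        for m_half in range(1, n + 1, 2):
            menu.append(derived_connectivity(n, 0, 2, m_half))
    return menu
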