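"""Ideal particle configurations decorating packing-model structures.

The decorator fills the tube volume around each structure center-line (and
the balls of spherical components) with particles at a prescribed interior
density, giving geometric stand-ins for equilibrated cluster configurations:
the cluster analysis and density/iso-surface stages become testable without
long simulations, and the worked-example suite pairs one fixture with the
expected cluster summary for every structure menu of the four studied
shells.

Filling uses an FCC lattice clipped to the tube volume with a small random
jitter.  A lattice (rather than random sequential insertion) is used because
the interior density of clusters in the SALR hexagonal regime, ~0.9 per
sigma^3, exceeds the saturation density of random sequential packing of
hard spheres (~0.73 per sigma^3); the jitter washes out lattice artifacts in
density grids.  Jittered positions violating the hard core are re-drawn
deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model import Configuration, ShellGeometry
from .packing import DerivedStructure, derived_connectivity, generate_centerline

__all__ = [
    "FixtureSpec",
    "SuiteEntry",
    "decorate",
    "decorate_centerlines",
    "worked_example_suite",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Decoration parameters for one derived structure.

    ``tube_radius`` defaults to the equilibrium cluster radius r0 ~ 1.5
    sigma; ``target_density`` to 0.9 particles/sigma^3 (above the iso level
    0.4 so iso-surfaces are well formed, below jamming); ``jitter`` is the
    maximum radial displacement added to each lattice site.
    """

    structure: DerivedStructure
    tube_radius: float = 1.5
    target_density: float = 0.9
    jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tube_radius <= 0:
            raise ValueError("tube_radius must be positive")
        if self.target_density < 0:
            raise ValueError("target_density must be non-negative")
        if self.jitter < 0 or self.jitter >= 0.3 * self.tube_radius:
            raise ValueError("jitter must lie in [0, 0.3*tube_radius)")


def _fcc_lattice(lo: np.ndarray, hi: np.ndarray, a: float) -> np.ndarray:
    """FCC lattice points covering the box [lo, hi] with cubic cell a."""
    basis = np.array(
        [[0.0, 0.0, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]]
    )
    counts = np.ceil((hi - lo) / a).astype(int) + 1
    ii = np.arange(counts[0])
    jj = np.arange(counts[1])
    kk = np.arange(counts[2])
    cells = np.stack(np.meshgrid(ii, jj, kk, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3) * a + lo
    keep = np.all((pts >= lo - 1e-9) & (pts <= hi + a), axis=1)
    return pts[keep]


def _densify(curve: np.ndarray, ds: float = 0.1) -> np.ndarray:
    """Resample a polyline at arc-length spacing <= ds (single points pass
    through)."""
    if len(curve) == 1:
        return curve
    out = [curve[0]]
    for p, q in zip(curve[:-1], curve[1:]):
        seg = np.linalg.norm(q - p)
        if seg < 1e-12:
            continue
        k = max(int(math.ceil(seg / ds)), 1)
        for t in np.linspace(0.0, 1.0, k + 1)[1:]:
            out.append(p + t * (q - p))
    return np.array(out)


def decorate_centerlines(
    centerlines: list[np.ndarray],
    tube_radius: float = 1.5,
    target_density: float = 0.9,
    jitter: float = 0.1,
    seed: int = 0,
    shell: ShellGeometry | None = None,
    min_pair_distance: float = 1.0,
) -> Configuration:
    """Fill the tube volume around arbitrary center-line polylines.

    Particles end up within ``tube_radius + jitter`` of the nearest
    center-line point, at least ``min_pair_distance`` apart, and (when a
    shell is given) inside the shell.  Deterministic for a given seed.
    """
    if target_density == 0.0 or not centerlines:
        return Configuration.empty()
    if target_density < 0:
        raise ValueError("target_density must be non-negative")
    a = (4.0 / target_density) ** (1.0 / 3.0)
    nn = a / math.sqrt(2.0)
    if nn < min_pair_distance:
        raise ValueError(
            f"target_density {target_density} exceeds the lattice packing "
            f"compatible with the hard core"
        )
    samples = np.vstack([_densify(c) for c in centerlines])
    tree = cKDTree(samples)
    lo = samples.min(axis=0) - (tube_radius + a)
    hi = samples.max(axis=0) + (tube_radius + a)
    lattice = _fcc_lattice(lo, hi, a)
    dist, _ = tree.query(lattice, workers=-1)
    pts = lattice[dist <= tube_radius]

    rng = np.random.default_rng(seed)

    def ball_jitter(n: int) -> np.ndarray:
        v = rng.normal(size=(n, 3))
        v /= np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-300)
        r = jitter * rng.random(n) ** (1.0 / 3.0)
        return v * r[:, None]

    base = pts
    pts = base + ball_jitter(len(base))

    # resolve rare hard-core violations introduced by the jitter by
    # re-drawing the offenders' jitter at half amplitude
    for _ in range(100):
        bad = cKDTree(pts).query_pairs(
            min_pair_distance - 1e-12, output_type="ndarray"
        )
        if len(bad) == 0:
            break
        redo = np.unique(bad[:, 1])
        pts[redo] = base[redo] + 0.5 * ball_jitter(len(redo))
    else:
        # drop one particle of each remaining offending pair
        bad = cKDTree(pts).query_pairs(
            min_pair_distance - 1e-12, output_type="ndarray"
        )
        pts = np.delete(pts, np.unique(bad[:, 1]), axis=0)

    if shell is not None:
        r = np.linalg.norm(pts, axis=1)
        keep = (r >= shell.r_inn) & (r <= shell.r_out)
        pts = pts[keep]
    return Configuration(pts)


def decorate(spec: FixtureSpec, shell: ShellGeometry) -> Configuration:
    """Decorate a derived structure inside its shell."""
    curves = generate_centerline(spec.structure, shell)
    return decorate_centerlines(
        curves,
        tube_radius=spec.tube_radius,
        target_density=spec.target_density,
        jitter=spec.jitter,
        seed=spec.seed,
        shell=shell,
    )


# ---------------------------------------------------------------------------
# Worked-example suite
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SuiteEntry:
    """One worked example: a fixture plus the expected cluster summary.

    ``expected`` maps the structure to what the cluster analysis must
    recover: counts of closed tubes, open tubes and spherical clusters, the
    number of free tube ends, and (when stated) where the open ends sit
    ('same_pole' / 'opposite_poles')."""

    name: str
    shell: ShellGeometry
    spec: FixtureSpec
    n_closed: int
    n_open: int
    n_spherical: int
    ends_hint: str | None = None

    @property
    def n_clusters(self) -> int:
        return self.n_closed + self.n_open + self.n_spherical

    @property
    def n_free_ends(self) -> int:
        return 2 * self.n_open


def _shell(r_inn: float, r_out: float) -> ShellGeometry:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ShellGeometry(r_inn, r_out)


def worked_example_suite(seed: int = 0) -> list[SuiteEntry]:
    """One fixture per structure of the four studied shells, paired with the
    expected cluster composition.

    The expectations are the printed structure menus: for the small shell
    (3, 8) the six-crossing menu (three tori; two tori plus two spheres; a
    single closed loop; hybrids with one open coil, or an open plus a closed
    cluster); for (5, 10) the eight-crossing menu; for (6, 11) one sphere
    plus four tori and its rotations (all single open coils except 3*theta,
    which splits into one open and one closed cluster); for (7.5, 12.5) one
    sphere plus five tori whose rotations are all single open coils.
    """
    # (name, shell, (n, l_a, l_b, m_half), closed, open, spherical, hint)
    table = [
        ("fig3a_three_tori", (3, 8), (6, 0, 0, 0), 3, 0, 0, None),
        ("fig3a_two_tori_two_spheres", (3, 8), (6, 2, 2, 0), 2, 0, 2, None),
        ("fig3a_closed_loop_theta", (3, 8), (6, 0, 0, 2), 1, 0, 0, None),
        ("fig3a_hybrid_half_theta", (3, 8), (6, 0, 2, 1), 0, 1, 0, None),
        ("fig3a_hybrid_3half_theta", (3, 8), (6, 0, 2, 3), 1, 1, 0, None),
        ("fig3b_four_tori", (5, 10), (8, 0, 0, 0), 4, 0, 0, None),
        ("fig3b_three_tori_two_spheres", (5, 10), (8, 2, 2, 0), 3, 0, 2, None),
        ("fig3b_hybrid_half_theta", (5, 10), (8, 0, 2, 1), 0, 1, 0, None),
        ("fig4a_m0", (6, 11), (9, 1, 1, 0), 4, 0, 1, None),
        ("fig4a_m1", (6, 11), (9, 1, 1, 2), 0, 1, 0, "same_pole"),
        ("fig4a_m2", (6, 11), (9, 1, 1, 4), 0, 1, 0, None),
        ("fig4a_m3", (6, 11), (9, 1, 1, 6), 1, 1, 0, None),
        ("fig4a_m4", (6, 11), (9, 1, 1, 8), 0, 1, 0, "opposite_poles"),
        ("fig4b_m0", (7.5, 12.5), (11, 1, 1, 0), 5, 0, 1, None),
        ("fig4b_m1", (7.5, 12.5), (11, 1, 1, 2), 0, 1, 0, "same_pole"),
        ("fig4b_m2", (7.5, 12.5), (11, 1, 1, 4), 0, 1, 0, None),
        ("fig4b_m3", (7.5, 12.5), (11, 1, 1, 6), 0, 1, 0, None),
        ("fig4b_m4", (7.5, 12.5), (11, 1, 1, 8), 0, 1, 0, None),
        ("fig4b_m5", (7.5, 12.5), (11, 1, 1, 10), 0, 1, 0, None),
    ]
    out = []
    for name, (ri, ro), (n, la, lb, m), nc, no, ns, hint in table:
        structure = derived_connectivity(n, la, lb, m)
        out.append(
            SuiteEntry(
                name=name,
                shell=_shell(ri, ro),
                spec=FixtureSpec(structure=structure, seed=seed),
                n_closed=nc,
                n_open=no,
                n_spherical=ns,
                ends_hint=hint,
            )
        )
    return out
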