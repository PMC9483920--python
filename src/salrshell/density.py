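"""Three-dimensional local density accumulation and iso-density surfaces.

The simulation volume's bounding cube is divided into cubic cells of edge
sigma/2 (default).  Each sampled configuration increments the cell counts by
one per particle; the mean local density of cell c is
``rho(c) = counts(c) / (n_samples * cell_volume)``, so the density integral
over the grid recovers the mean particle number exactly.  Structures are
identified from the iso-density surface at ``rho_iso = 0.4`` extracted by
marching cubes.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

from .model import Configuration, ShellGeometry

__all__ = ["DensityField", "write_vtk_polydata"]


class DensityField:
    """Accumulating density histogram on a cubic grid.

    The grid spans ``[-half_extent, +half_extent]^3`` (rounded up to whole
    cells); for a shell it covers the bounding cube of the padded outer
    radius ``R_out + sigma/2``.
    """

    def __init__(self, half_extent: float, cell_edge: float = 0.5) -> None:
        if cell_edge <= 0:
            raise ValueError("cell edge must be positive")
        if half_extent <= 0:
            raise ValueError("half extent must be positive")
        m = int(math.ceil(2.0 * half_extent / cell_edge))
        self.cell_edge = float(cell_edge)
        self.shape = (m, m, m)
        self.origin = -0.5 * m * cell_edge * np.ones(3)
        self.counts = np.zeros(self.shape, dtype=np.int64)
        self.n_samples = 0

    @classmethod
    def for_shell(cls, shell: ShellGeometry, cell_edge: float = 0.5) -> "DensityField":
        return cls(shell.r_out + 0.5, cell_edge)

    @property
    def cell_volume(self) -> float:
        return self.cell_edge**3

    # -- accumulation -------------------------------------------------------

    def accumulate(self, config: Configuration | np.ndarray) -> None:
        """Bin one configuration: each particle increments exactly one cell."""
        pos = config.positions if isinstance(config, Configuration) else np.asarray(config)
        pos = pos.reshape(-1, 3)
        if len(pos):
            idx = np.floor((pos - self.origin) / self.cell_edge).astype(int)
            if idx.min() < 0 or idx.max() >= self.shape[0]:
                raise IndexError("particle outside the density grid")
            np.add.at(self.counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
        self.n_samples += 1

    def accumulate_trajectory(self, configs) -> None:
        for cfg in configs:
            self.accumulate(cfg)

    # -- reduction ----------------------------------------------------------

    def mean_density(self) -> np.ndarray:
        """Mean local density rho(cell) in sigma^-3; integrates to <N>."""
        if self.n_samples == 0:
            raise ValueError("no configurations accumulated")
        return self.counts / (self.n_samples * self.cell_volume)

    def extract_isosurface(self, rho_iso: float = 0.4) -> trimesh.Trimesh:
        """Marching-cubes triangulation of the iso-density level set.

        Cell values are taken at cell centers; mesh vertices are returned in
        the simulation frame (sigma units).  A level outside the data range
        yields an empty mesh with a warning.
        """
        rho = self.mean_density()
        if not (rho.min() < rho_iso < rho.max()):
            warnings.warn(
                f"iso level {rho_iso} outside the density range "
                f"[{rho.min():g}, {rho.max():g}]; returning an empty mesh",
                stacklevel=2,
            )
            return trimesh.Trimesh(
                vertices=np.empty((0, 3)), faces=np.empty((0, 3), dtype=int)
            )
        verts, faces, _, _ = measure.marching_cubes(
            rho, level=rho_iso, spacing=(self.cell_edge,) * 3
        )
        verts = verts + self.origin + 0.5 * self.cell_edge
        return trimesh.Trimesh(vertices=verts, faces=faces, process=False)

    # -- persistence --------------------------------------------------------

    def save(self, prefix) -> None:
        """Write the raw counts (flat binary, C order, int64) plus a JSON
        sidecar with the grid geometry."""
        prefix = Path(prefix)
        self.counts.tofile(prefix.with_suffix(".counts.bin"))
        meta = {
            "shape": list(self.shape),
            "origin": self.origin.tolist(),
            "cell_edge": self.cell_edge,
            "n_samples": self.n_samples,
            "dtype": "int64",
            "order": "C",
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix) -> "DensityField":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        field = cls.__new__(cls)
        field.shape = tuple(meta["shape"])
        field.cell_edge = float(meta["cell_edge"])
        field.origin = np.array(meta["origin"], dtype=float)
        field.n_samples = int(meta["n_samples"])
        field.counts = np.fromfile(
            prefix.with_suffix(".counts.bin"), dtype=np.int64
        ).reshape(field.shape)
        return field


def write_vtk_polydata(mesh: trimesh.Trimesh, path) -> None:
    """Write a triangle mesh as legacy ASCII VTK POLYDATA."""
    v = np.asarray(mesh.vertices)
    f = np.asarray(mesh.faces, dtype=int)
    lines = [
        "# vtk DataFile Version 3.0",
        "iso-density surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(v)} double",
    ]
    lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in v]
    lines.append(f"POLYGONS {len(f)} {4 * len(f)}")
    lines += [f"3 {a} {b} {c}" for a, b, c in f]
    Path(path).write_text("\n".join(lines) + "\n")
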