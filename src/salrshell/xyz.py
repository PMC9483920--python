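"""Extended XYZ trajectory reader/writer.

Each frame is ``N`` on the first line, a comment line of ``key=value``
tokens (step, mu*, T*, energy, ...) and one ``P x y z`` line per particle.
All quantities are in reduced units (lengths in sigma, energies in epsilon);
coordinates are written with 17 significant digits so a write-read round
trip is exact to the last bit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .model import Configuration

__all__ = ["read_xyz", "write_xyz", "XYZParseError"]


class XYZParseError(ValueError):
    """Malformed XYZ input; the message carries the offending line number."""


def _format_value(v) -> str:
    if isinstance(v, bool):
        return str(v).lower()
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, np.integer):
        return str(int(v))
    return str(v)


def _parse_value(tok: str):
    for cast in (int, float):
        try:
            return cast(tok)
        except ValueError:
            pass
    if tok in ("true", "false"):
        return tok == "true"
    return tok


def write_xyz(path, configurations, metadata=None, species: str = "P") -> None:
    """Write configurations as multi-frame extended XYZ.

    ``metadata`` may be one dict per frame (or a single dict reused for
    all); values must be scalars without whitespace.
    """
    configurations = list(configurations)
    if metadata is None:
        metadata = [{} for _ in configurations]
    elif isinstance(metadata, dict):
        metadata = [metadata] * len(configurations)
    if len(metadata) != len(configurations):
        raise ValueError("one metadata dict per frame required")
    lines = []
    for cfg, meta in zip(configurations, metadata):
        pos = cfg.positions if isinstance(cfg, Configuration) else np.asarray(cfg)
        pos = pos.reshape(-1, 3)
        lines.append(str(len(pos)))
        lines.append(
            " ".join(f"{k}={_format_value(v)}" for k, v in meta.items())
            or "frame"
        )
        for x, y, z in pos:
            lines.append(
                f"{species} {float(x)!r} {float(y)!r} {float(z)!r}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_xyz(path) -> list[tuple[Configuration, dict]]:
    """Read a multi-frame extended XYZ file; returns (configuration,
    metadata) pairs.  Raises :class:`XYZParseError` naming the frame and
    line on malformed input."""
    text = Path(path).read_text()
    lines = text.splitlines()
    out: list[tuple[Configuration, dict]] = []
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise XYZParseError(
                f"line {i + 1}: expected a particle count for frame {frame}"
            ) from exc
        if i + 1 >= len(lines):
            raise XYZParseError(
                f"line {i + 1}: frame {frame} truncated (missing comment line)"
            )
        meta = {}
        comment = lines[i + 1].strip()
        if comment and comment != "frame":
            for tok in comment.split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = _parse_value(v)
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise XYZParseError(
                f"line {i + 1}: frame {frame} declares {n} particles but the "
                f"file ends after {len(body)}"
            )
        pos = np.empty((n, 3))
        for j, ln in enumerate(body):
            parts = ln.split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"line {i + 3 + j}: malformed particle record in frame "
                    f"{frame}"
                )
            try:
                pos[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise XYZParseError(
                    f"line {i + 3 + j}: non-numeric coordinate in frame {frame}"
                ) from exc
        out.append((Configuration(pos), meta))
        i += 2 + n
        frame += 1
    return out
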