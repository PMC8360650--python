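"""STAR-dialect particle tables.

The dialect is deliberately small: one ``data_particles`` block containing
one ``loop_`` with named tags, RELION-style naming where a standard tag
exists.  Required tags::

    _rlnMicrographName _rlnCoordinateX _rlnCoordinateY
    _rlnAnglePsi _rlnHelicalTubeID

plus the package's own ``_kfSegmentIndex`` (position along the tube) and
``_rlnImagePixelSize``.  ``_rlnClassNumber`` is optional (0 = unassigned).
Unknown tags are carried through read → write untouched.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

from .core import ParticleRecord, ParticleTable

__all__ = ["read_particles", "write_particles", "StarSchemaError"]


class StarSchemaError(ValueError):
    """Raised when a STAR table lacks required columns or is malformed."""


_REQUIRED = (
    "_rlnMicrographName",
    "_rlnCoordinateX",
    "_rlnCoordinateY",
    "_rlnAnglePsi",
    "_rlnHelicalTubeID",
)
_KNOWN = _REQUIRED + (
    "_kfSegmentIndex",
    "_rlnClassNumber",
    "_rlnImagePixelSize",
)


def _parse_loop(text: str) -> dict[str, list[str]]:
    """Parse the first loop_ of the first data block into columns."""
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    try:
        i = next(k for k, ln in enumerate(lines) if ln.startswith("loop_"))
    except StopIteration:
        raise StarSchemaError("no loop_ block found") from None
    tags: list[str] = []
    i += 1
    while i < len(lines) and lines[i].startswith("_"):
        tags.append(lines[i].split()[0])
        i += 1
    if not tags:
        raise StarSchemaError("loop_ block declares no tags")
    columns: dict[str, list[str]] = {t: [] for t in tags}
    for ln in lines[i:]:
        if ln.startswith("data_") or ln.startswith("loop_"):
            break
        fields = ln.split()
        if len(fields) != len(tags):
            raise StarSchemaError(
                f"row has {len(fields)} fields, expected {len(tags)}: {ln!r}"
            )
        for t, v in zip(tags, fields):
            columns[t].append(v)
    return columns


def read_particles(path: Union[str, Path]) -> ParticleTable:
    """Read a particle table; unknown tags are kept on ``table.extra_columns``."""
    cols = _parse_loop(Path(path).read_text())
    missing = [t for t in _REQUIRED if t not in cols]
    if missing:
        raise StarSchemaError(f"missing required columns: {', '.join(missing)}")

    n = len(cols["_rlnCoordinateX"])
    seg = cols.get("_kfSegmentIndex")
    cls = cols.get("_rlnClassNumber")
    px = cols.get("_rlnImagePixelSize")
    pixel_size = float(px[0]) if px and n else 1.0

    records = []
    # default segment numbering: order of appearance within each tube
    per_tube_counter: dict[int, int] = {}
    for i in range(n):
        tube = int(cols["_rlnHelicalTubeID"][i])
        if seg is not None:
            s = int(seg[i])
        else:
            s = per_tube_counter.get(tube, 0)
            per_tube_counter[tube] = s + 1
        class_id = None
        if cls is not None:
            c = int(cls[i])
            class_id = c if c > 0 else None
        records.append(
            ParticleRecord(
                micrograph_id=cols["_rlnMicrographName"][i],
                x_px=float(cols["_rlnCoordinateX"][i]),
                y_px=float(cols["_rlnCoordinateY"][i]),
                psi_deg=float(cols["_rlnAnglePsi"][i]),
                tube_id=tube,
                segment_index=s,
                class_id=class_id,
            )
        )
    table = ParticleTable(records, pixel_size)
    table.extra_columns = {t: v for t, v in cols.items() if t not in _KNOWN}
    return table


def write_particles(table: ParticleTable, path: Union[str, Path]) -> None:
    extra = getattr(table, "extra_columns", {})
    tags = list(_KNOWN) + list(extra)
    lines = ["data_particles", "", "loop_"]
    lines += [f"{t} #{i + 1}" for i, t in enumerate(tags)]
    for i, r in enumerate(table):
        row = [
            r.micrograph_id,
            f"{r.x_px:.4f}",
            f"{r.y_px:.4f}",
            f"{r.psi_deg:.4f}",
            str(r.tube_id),
            str(r.segment_index),
            str(r.class_id if r.class_id is not None else 0),
            f"{table.pixel_size_A:.6f}",
        ]
        row += [str(extra[t][i]) for t in extra]
        lines.append(" ".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
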