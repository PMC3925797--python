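"""Slice contour stacks: the histology-style input representation.

A contour stack is the digitised equivalent of a step-sectioned whole-mount
specimen: an ordered list of axial slices at uniform spacing, each carrying
labelled closed polygons for the prostate capsule and any tumour foci
present on that slice.  A small line-oriented text format is defined so
user-supplied stacks can enter the pipeline without any binary dependency.

Format (one stack per file)::

    # biopsim contour stack v1
    slice_thickness_mm 5.0
    n_slices 4
    gleason lesion:1 7          # optional per-structure metadata
    slice 0 z -7.5
    structure capsule 64
    x0 y0
    x1 y1
    ...
    structure lesion:1 64
    ...

Coordinates are mm; the axial (z) coordinate is carried per slice; vertices
are ordered counter-clockwise and the polygon is closed implicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

__all__ = ["Slice", "ContourStack", "read_contour_stack", "write_contour_stack"]

CAPSULE = "capsule"


class ContourFormatError(ValueError):
    """Raised on malformed contour-stack files, with a line reference."""


@dataclass
class Slice:
    z: float
    structures: dict[str, np.ndarray] = field(default_factory=dict)

    def polygon(self, label: str) -> Polygon:
        return Polygon(self.structures[label])


@dataclass
class ContourStack:
    slice_thickness: float
    slices: list[Slice]
    metadata: dict[str, dict[str, str]] = field(default_factory=dict)
    missing_structures: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for sl in self.slices:
            for lab in sl.structures:
                seen.setdefault(lab, None)
        return list(seen)

    @property
    def z_positions(self) -> np.ndarray:
        return np.array([sl.z for sl in self.slices])

    def validate(self, rtol: float = 1e-6) -> None:
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")
        if not self.slices:
            raise ValueError("a contour stack needs at least one slice")
        z = self.z_positions
        if len(z) > 1:
            dz = np.diff(z)
            if np.any(dz <= 0):
                raise ValueError("axial positions must be strictly increasing")
            if not np.allclose(dz, self.slice_thickness, rtol=rtol, atol=1e-6):
                raise ValueError(
                    "axial spacing must be uniform and equal to slice_thickness"
                )
        for i, sl in enumerate(self.slices):
            for lab, verts in sl.structures.items():
                v = np.asarray(verts, float)
                if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
                    raise ValueError(f"slice {i} structure {lab!r}: not a polygon")
                poly = Polygon(v)
                if not poly.is_simple or poly.area <= 0:
                    raise ValueError(
                        f"slice {i} structure {lab!r}: polygon must be simple "
                        "and have positive area"
                    )

    def translated(self, offsets: np.ndarray) -> "ContourStack":
        """A copy with per-slice in-plane (x, y) translations applied."""
        offsets = np.asarray(offsets, float)
        out = []
        for sl, off in zip(self.slices, offsets):
            out.append(
                Slice(sl.z, {k: np.asarray(v, float) + off for k, v in sl.structures.items()})
            )
        return ContourStack(self.slice_thickness, out, dict(self.metadata),
                            list(self.missing_structures))


def write_contour_stack(stack: ContourStack, path) -> None:
    with open(path, "w") as fh:
        fh.write("# biopsim contour stack v1\n")
        fh.write(f"slice_thickness_mm {float(stack.slice_thickness)!r}\n")
        fh.write(f"n_slices {len(stack.slices)}\n")
        for label, meta in stack.metadata.items():
            for key, val in meta.items():
                fh.write(f"{key} {label} {val}\n")
        for i, sl in enumerate(stack.slices):
            fh.write(f"slice {i} z {float(sl.z)!r}\n")
            for label, verts in sl.structures.items():
                v = np.asarray(verts, float)
                fh.write(f"structure {label} {len(v)}\n")
                for x, y in v:
                    fh.write(f"{float(x)!r} {float(y)!r}\n")


_META_KEYS = {"gleason"}


def read_contour_stack(path) -> ContourStack:
    """Parse and validate a contour-stack file.

    Raises :class:`ContourFormatError` with a line number on malformed input.
    """

    def fail(lineno, msg):
        raise ContourFormatError(f"{path}:{lineno}: {msg}")

    with open(path) as fh:
        lines = fh.read().splitlines()
    it = iter(enumerate(lines, start=1))

    def next_content():
        for lineno, raw in it:
            text = raw.split("#", 1)[0].strip()
            if text:
                return lineno, text
        return None, None

    lineno, text = next_content()
    if text is None or not text.startswith("slice_thickness_mm"):
        fail(lineno or 1, "expected 'slice_thickness_mm <value>' header")
    try:
        thickness = float(text.split()[1])
    except (IndexError, ValueError):
        fail(lineno, "bad slice_thickness_mm value")
    lineno, text = next_content()
    if text is None or not text.startswith("n_slices"):
        fail(lineno or 1, "expected 'n_slices <count>' header")
    try:
        n_slices = int(text.split()[1])
    except (IndexError, ValueError):
        fail(lineno, "bad n_slices value")

    metadata: dict[str, dict[str, str]] = {}
    slices: list[Slice] = []
    current: Slice | None = None
    pending: tuple[str, int] | None = None  # (label, n remaining)
    verts: list[list[float]] = []

    def flush_structure(lineno):
        nonlocal pending, verts
        if pending is not None:
            label, remaining = pending
            if remaining > 0:
                fail(lineno, f"structure {label!r}: {remaining} vertices missing")
            current.structures[label] = np.asarray(verts, float)
            pending, verts = None, []

    lineno, text = next_content()
    while text is not None:
        parts = text.split()
        if parts[0] == "slice":
            flush_structure(lineno)
            if len(parts) != 4 or parts[2] != "z":
                fail(lineno, "expected 'slice <index> z <position>'")
            try:
                z = float(parts[3])
            except ValueError:
                fail(lineno, "bad slice z position")
            current = Slice(z)
            slices.append(current)
        elif parts[0] == "structure":
            flush_structure(lineno)
            if current is None:
                fail(lineno, "'structure' before any 'slice'")
            if len(parts) != 3:
                fail(lineno, "expected 'structure <label> <n_vertices>'")
            label = parts[1]
            if label != CAPSULE and not label.startswith("lesion:"):
                fail(lineno, f"unknown structure label {label!r}")
            try:
                nv = int(parts[2])
            except ValueError:
                fail(lineno, "bad vertex count")
            pending = (label, nv)
            verts = []
        elif parts[0] in _META_KEYS:
            if len(parts) != 3:
                fail(lineno, f"expected '{parts[0]} <label> <value>'")
            metadata.setdefault(parts[1], {})[parts[0]] = parts[2]
        else:
            if pending is None:
                fail(lineno, f"unexpected line {text!r}")
            if len(parts) != 2:
                fail(lineno, "expected 'x y' vertex line")
            try:
                verts.append([float(parts[0]), float(parts[1])])
            except ValueError:
                fail(lineno, "bad vertex coordinates")
            pending = (pending[0], pending[1] - 1)
        lineno, text = next_content()
    flush_structure(lineno or len(lines))

    if len(slices) != n_slices:
        raise ContourFormatError(
            f"{path}: header declares {n_slices} slices, found {len(slices)}"
        )
    stack = ContourStack(thickness, slices, metadata)
    stack.validate()
    empties = [i for i, sl in enumerate(stack.slices) if CAPSULE not in sl.structures]
    if empties:
        warnings.warn(f"{path}: slices without a capsule contour: {empties}")
    return stack
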