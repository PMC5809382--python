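"""Reading, writing and preconditioning of closed shell outlines.

An outline is an ordered sequence of (x, y) points tracing one view
(lateral or ventral) of a shell; the polygon is implicitly closed (the
last point connects back to the first).  Two plain-text dialects are
supported: the TPS landmark/outline format and a two-column CSV.
Preconditioning covers neighbourhood smoothing, equal-arc-length
resampling and orientation fixing, which together prepare an outline for
the elliptic Fourier integrals.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

VIEWS = ("lateral", "ventral")


class OutlineError(ValueError):
    """Raised for malformed, empty, or degenerate outline data."""


@dataclass
class Outline:
    """A closed planar outline of one view of one specimen.

    Points are in arbitrary planar units, y-axis up.  At least three
    points are required; consecutive duplicate points are dropped on
    construction so downstream arc-length computations are well posed.
    """

    specimen_id: str
    view: str
    points: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise OutlineError("points must be an (n, 2) array")
        # drop consecutive duplicates, including the closing repeat
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(np.diff(pts, axis=0) != 0.0, axis=1)
        pts = pts[keep]
        if len(pts) > 1 and np.all(pts[0] == pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise OutlineError(
                f"outline {self.specimen_id}/{self.view}: needs >= 3 distinct points"
            )
        self.points = pts

    @property
    def n_points(self) -> int:
        return len(self.points)

    def closed(self) -> np.ndarray:
        """Points with the first vertex appended, for perimeter/area sums."""
        return np.vstack([self.points, self.points[:1]])

    def perimeter(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.closed(), axis=0), axis=1)))

    def signed_area(self) -> float:
        """Shoelace area; positive for counter-clockwise traversal."""
        p = self.closed()
        return float(0.5 * np.sum(p[:-1, 0] * p[1:, 1] - p[1:, 0] * p[:-1, 1]))

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


# ---------------------------------------------------------------------------
# file I/O


def read_outlines(path: str | Path, dialect: str = "tps") -> list[Outline]:
    """Read outlines from ``path`` in the given dialect (``tps`` or ``csv``).

    The TPS dialect may hold several records per file; the CSV dialect
    holds a single outline whose id is taken from the file stem and whose
    view, when the stem ends with ``_lateral``/``_ventral``, is parsed
    from the stem as well.
    """
    path = Path(path)
    if not path.exists():
        raise OutlineError(f"no such outline file: {path}")
    if dialect == "tps":
        return _read_tps(path)
    if dialect == "csv":
        return [_read_csv(path)]
    raise OutlineError(f"unknown outline dialect: {dialect!r}")


def _read_tps(path: Path) -> list[Outline]:
    outlines: list[Outline] = []
    points: list[tuple[float, float]] = []
    expected: int | None = None
    spec_id = ""
    view = "lateral"
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    if not any(lines):
        raise OutlineError(f"{path}: empty TPS file")

    def flush(lineno: int) -> None:
        nonlocal points, expected, spec_id, view
        if expected is None and not points:
            return
        if expected is not None and len(points) != expected:
            raise OutlineError(
                f"{path}:{lineno}: record declared {expected} points, got {len(points)}"
            )
        sid, v = _split_id(spec_id, view)
        outlines.append(Outline(sid, v, np.array(points)))
        points, expected, spec_id, view = [], None, "", "lateral"

    for lineno, line in enumerate(lines, start=1):
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            flush(lineno)
        elif upper.startswith(("OUTLINES=", "CURVES=")):
            continue
        elif upper.startswith("POINTS="):
            try:
                expected = int(line.split("=", 1)[1])
            except ValueError as exc:
                raise OutlineError(f"{path}:{lineno}: bad POINTS line {line!r}") from exc
        elif upper.startswith("ID="):
            spec_id = line.split("=", 1)[1].strip()
        elif upper.startswith(("IMAGE=", "SCALE=", "COMMENT=")):
            continue
        else:
            parts = line.split()
            if len(parts) != 2:
                raise OutlineError(f"{path}:{lineno}: expected 'x y', got {line!r}")
            try:
                points.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise OutlineError(f"{path}:{lineno}: non-numeric coordinate") from exc
    flush(len(lines))
    if not outlines:
        raise OutlineError(f"{path}: no outline records found")
    return outlines


def _split_id(raw_id: str, default_view: str) -> tuple[str, str]:
    for v in VIEWS:
        if raw_id.endswith(f"_{v}"):
            return raw_id[: -len(v) - 1], v
    return raw_id, default_view


def _read_csv(path: Path) -> Outline:
    rows: list[tuple[float, float]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or not any(cell.strip() for cell in row):
                continue
            if lineno == 1 and not _is_numeric_row(row):
                continue  # header
            if len(row) < 2:
                raise OutlineError(f"{path}:{lineno}: expected two columns")
            try:
                rows.append((float(row[0]), float(row[1])))
            except ValueError as exc:
                raise OutlineError(f"{path}:{lineno}: non-numeric coordinate") from exc
    if not rows:
        raise OutlineError(f"{path}: empty CSV outline")
    sid, view = _split_id(path.stem, "lateral")
    return Outline(sid, view, np.array(rows))


def _is_numeric_row(row: list[str]) -> bool:
    try:
        [float(c) for c in row[:2]]
    except ValueError:
        return False
    return True


def write_outline_tps(outlines: list[Outline], path: str | Path) -> None:
    """Write outlines to one TPS file, one record per outline."""
    path = Path(path)
    with open(path, "w") as fh:
        for o in outlines:
            fh.write("LM=0\n")
            fh.write("OUTLINES=1\n")
            fh.write(f"POINTS={o.n_points}\n")
            for x, y in o.points:
                fh.write(f"{x:.12g} {y:.12g}\n")
            fh.write(f"ID={o.specimen_id}_{o.view}\n")


def write_outline_csv(outline: Outline, path: str | Path) -> None:
    """Write one outline to a two-column CSV with an ``x,y`` header."""
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y"])
        for x, y in outline.points:
            writer.writerow([f"{x:.12g}", f"{y:.12g}"])


# ---------------------------------------------------------------------------
# preconditioning


def smooth_outline(outline: Outline, iterations: int = 1) -> Outline:
    """Moving-average smoothing over cyclic nearest neighbours.

    Each pass replaces every point by the mean of itself and its two
    cyclic neighbours.  The point count is unchanged and the centroid is
    conserved exactly.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    pts = outline.points.copy()
    for _ in range(iterations):
        pts = (np.roll(pts, 1, axis=0) + pts + np.roll(pts, -1, axis=0)) / 3.0
    return replace(outline, points=pts)


def resample_outline(outline: Outline, n_points: int = 512) -> Outline:
    """Resample to ``n_points`` equally spaced by arc length.

    The first point of the input is preserved as the first output point.
    """
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    closed = outline.closed()
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise OutlineError(
            f"outline {outline.specimen_id}/{outline.view}: zero-length outline"
        )
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(n_points) * total / n_points
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return replace(outline, points=np.column_stack([x, y]))


def orient_outline(outline: Outline) -> Outline:
    """Fix traversal direction and a provisional start point.

    The outline is made counter-clockwise (positive shoelace area) and
    cyclically rotated so it starts at the point of maximum x (ties
    broken by maximum y).  This is only a provisional anchor: start-point
    invariance proper is established later by the Fourier normalization.
    """
    area = outline.signed_area()
    if area == 0.0:
        raise OutlineError(
            f"outline {outline.specimen_id}/{outline.view}: zero-area outline"
        )
    pts = outline.points
    if area < 0:
        pts = pts[::-1]
    # lexicographic argmax on (x, y)
    start = np.lexsort((pts[:, 1], pts[:, 0]))[-1]
    pts = np.roll(pts, -start, axis=0)
    return replace(outline, points=pts.copy())
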