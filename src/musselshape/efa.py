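"""Elliptic Fourier analysis (EFA) of closed outlines.

A closed outline traversed at constant speed decomposes into a sum of
harmonically related ellipses; harmonic ``n`` contributes four
coefficients ``(a_n, b_n, c_n, d_n)``::

    x(t) = A0 + sum_n a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T)
    y(t) = C0 + sum_n c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T)

The forward transform here uses the piecewise-linear (polygon)
formulation: the Fourier integrals are evaluated exactly over each
polygon segment rather than by an FFT of the sampled points, which makes
the coefficients exact for the polygon and robust to modest sampling
irregularity.  Normalization removes translation, size, rotation and
starting point following the usual first-harmonic-ellipse convention, so
that the remaining coefficients are pure shape descriptors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .outline_io import Outline

logger = logging.getLogger(__name__)


class EfaError(ValueError):
    """Raised for degenerate inputs to the Fourier transforms."""


@dataclass
class NormalizationRecord:
    """What :func:`efa_normalize` removed, kept for invertibility."""

    translation: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0
    rotation: float = 0.0  # radians, spatial
    start_phase: float = 0.0  # radians of parameter shift
    normalized: bool = False


@dataclass
class EFACoefficients:
    """Per-view harmonic quadruples plus the dc offset.

    ``harmonics`` is an (n, 4) array with columns ``a, b, c, d``;
    ``dc = (A0, C0)`` is the outline centroid with respect to arc-length
    parameterization.
    """

    view: str
    harmonics: np.ndarray = field(repr=False)
    dc: np.ndarray = field(default_factory=lambda: np.zeros(2), repr=False)
    normalization: NormalizationRecord = field(default_factory=NormalizationRecord)

    def __post_init__(self) -> None:
        self.harmonics = np.asarray(self.harmonics, dtype=float)
        if self.harmonics.ndim != 2 or self.harmonics.shape[1] != 4:
            raise EfaError("harmonics must be an (n, 4) array")
        if len(self.harmonics) < 1:
            raise EfaError("need at least one harmonic")
        self.dc = np.asarray(self.dc, dtype=float)

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonics)

    def copy(self) -> "EFACoefficients":
        return EFACoefficients(
            self.view,
            self.harmonics.copy(),
            self.dc.copy(),
            NormalizationRecord(**vars(self.normalization)),
        )


def efa_forward(
    outline: Outline,
    n_harmonics: int = 7,
    parameterization: str = "uniform",
) -> EFACoefficients:
    """Elliptic Fourier coefficients of a closed polygonal outline.

    The Fourier integrals are evaluated exactly over each polygon
    segment (the derivative dx/dt is constant per segment, so they
    reduce to sums of cosine/sine differences at the segment breaks).

    ``parameterization`` controls the curve parameter ``t``:

    * ``"uniform"`` (default): each vertex advances the parameter by an
      equal step, and the known spectral attenuation of linear
      interpolation (``sinc^2``) is divided out.  For an outline whose
      underlying curve is band-limited to ``n_harmonics`` this recovers
      the curve's coefficients to machine precision; intended for
      outlines that have been resampled to equal spacing (the pipeline
      default).
    * ``"chord"``: the classic chain-length parameterization where the
      parameter advances by each segment's chord length; robust for
      unevenly digitised outlines, with O(K^-2) interpolation bias.
    """
    if n_harmonics < 1:
        raise EfaError("n_harmonics must be >= 1")
    if parameterization not in ("uniform", "chord"):
        raise EfaError(f"unknown parameterization: {parameterization!r}")
    if outline.n_points < 2 * n_harmonics + 1:
        raise EfaError(
            f"outline has {outline.n_points} points; "
            f"need >= {2 * n_harmonics + 1} for {n_harmonics} harmonics"
        )
    closed = outline.closed()
    d = np.diff(closed, axis=0)  # (K, 2) segment steps
    K = len(d)
    if parameterization == "chord":
        dt = np.linalg.norm(d, axis=1)
        if np.any(dt == 0):
            raise EfaError("outline contains zero-length segments")
    else:
        dt = np.full(K, 1.0)
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]

    n = np.arange(1, n_harmonics + 1)[:, None]  # (N, 1)
    phi = 2.0 * np.pi * t[None, :] / T  # (1, K+1)
    cos = np.cos(n * phi)
    sin = np.sin(n * phi)
    dcos = np.diff(cos, axis=1)  # (N, K)
    dsin = np.diff(sin, axis=1)

    slope = d / dt[:, None]  # (K, 2) dx/dt, dy/dt per segment
    const = T / (2.0 * np.pi**2 * n.ravel() ** 2)  # (N,)
    a = const * (dcos @ slope[:, 0])
    b = const * (dsin @ slope[:, 0])
    c = const * (dcos @ slope[:, 1])
    dd = const * (dsin @ slope[:, 1])
    h = np.column_stack([a, b, c, dd])

    # parameter-average of the piecewise-linear coordinates
    mid = 0.5 * (closed[:-1] + closed[1:])
    dc = (mid * dt[:, None]).sum(axis=0) / T

    if parameterization == "uniform":
        # linear interpolation attenuates harmonic n by sinc^2(pi n / K);
        # dividing it out de-biases the estimate of the underlying curve
        att = np.sinc(n.ravel() / K) ** 2
        h /= att[:, None]
    return EFACoefficients(outline.view, h, dc)


def efa_inverse(
    coeffs: EFACoefficients,
    n_points: int = 512,
    specimen_id: str = "reconstruction",
) -> Outline:
    """Evaluate the truncated Fourier series on a uniform parameter grid."""
    if n_points < 8:
        raise ValueError("n_points >= 8 required")
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    n = np.arange(1, coeffs.n_harmonics + 1)[:, None]
    cos = np.cos(n * t[None, :])
    sin = np.sin(n * t[None, :])
    h = coeffs.harmonics
    x = coeffs.dc[0] + h[:, 0] @ cos + h[:, 1] @ sin
    y = coeffs.dc[1] + h[:, 2] @ cos + h[:, 3] @ sin
    return Outline(specimen_id, coeffs.view, np.column_stack([x, y]))


# ---------------------------------------------------------------------------
# normalization


def _shift_start(h: np.ndarray, phase: float) -> np.ndarray:
    """Shift the curve parameter start by ``phase`` radians (harmonic 1 scale)."""
    out = np.empty_like(h)
    n = np.arange(1, len(h) + 1)
    cn, sn = np.cos(n * phase), np.sin(n * phase)
    out[:, 0] = h[:, 0] * cn + h[:, 1] * sn
    out[:, 1] = -h[:, 0] * sn + h[:, 1] * cn
    out[:, 2] = h[:, 2] * cn + h[:, 3] * sn
    out[:, 3] = -h[:, 2] * sn + h[:, 3] * cn
    return out


def _rotate(h: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the curve spatially by ``-psi`` (align axis ``psi`` with +x)."""
    out = np.empty_like(h)
    c, s = np.cos(psi), np.sin(psi)
    out[:, 0] = c * h[:, 0] + s * h[:, 2]
    out[:, 1] = c * h[:, 1] + s * h[:, 3]
    out[:, 2] = -s * h[:, 0] + c * h[:, 2]
    out[:, 3] = -s * h[:, 1] + c * h[:, 3]
    return out


def _axis_phase(row: np.ndarray) -> float:
    """Parameter phase extremizing the radius of one harmonic's ellipse."""
    a, b, c, d = row
    return 0.5 * np.arctan2(2.0 * (a * b + c * d), a * a + c * c - b * b - d * d)


def _ellipse_axes(row: np.ndarray, phase: float) -> tuple[float, float]:
    a, b, c, d = row
    cp, sp = np.cos(phase), np.sin(phase)
    major = np.hypot(a * cp + b * sp, c * cp + d * sp)
    minor = np.hypot(-a * sp + b * cp, -c * sp + d * cp)
    return float(major), float(minor)


def _vertex_direction(row: np.ndarray, phase: float) -> float:
    """Spatial angle of one harmonic's ellipse point at parameter ``phase``."""
    a, b, c, d = row
    cp, sp = np.cos(phase), np.sin(phase)
    return float(np.arctan2(c * cp + d * sp, a * cp + b * sp))


def _normalize_candidate(
    h: np.ndarray, theta: float, psi: float, scale: float
) -> np.ndarray:
    return _rotate(_shift_start(h, theta), psi) / scale


def efa_normalize(
    coeffs: EFACoefficients,
    mode: str = "full",
    circular_ratio: float = 0.95,
) -> EFACoefficients:
    """Remove translation, size, rotation and starting point.

    Convention: scale by the first-harmonic ellipse's major semi-axis;
    rotate so that major axis lies along +x; shift the start point to the
    major-axis vertex (``mode="full"``) or leave the start point alone
    (``mode="size_rotation_only"``).  The residual 180-degree start
    ambiguity is broken by requiring the largest-magnitude harmonic-2
    element to be positive.  When the first ellipse is near-circular
    (axis ratio above ``circular_ratio``) its phase is numerically
    meaningless, so orientation and start are anchored on harmonic 2
    instead and the residual quarter-turn ambiguity is resolved by a
    deterministic lexicographic rule.
    """
    if mode not in ("full", "size_rotation_only"):
        raise ValueError(f"unknown normalization mode: {mode!r}")
    h = coeffs.harmonics.copy()

    theta = _axis_phase(h[0])
    major, minor = _ellipse_axes(h[0], theta)
    if minor > major:
        theta += 0.5 * np.pi
        major, minor = minor, major
    if major < 1e-12:
        raise EfaError("degenerate first-harmonic ellipse (zero magnitude)")

    near_circular = coeffs.n_harmonics >= 2 and minor / major > circular_ratio

    if mode == "size_rotation_only":
        psi = _vertex_direction(h[0], theta)
        h = _rotate(h, psi) / major
        record = NormalizationRecord(
            translation=(float(coeffs.dc[0]), float(coeffs.dc[1])),
            scale=major,
            rotation=psi,
            start_phase=0.0,
            normalized=True,
        )
        return EFACoefficients(coeffs.view, h, np.zeros(2), record)

    if not near_circular:
        psi = _vertex_direction(h[0], theta)
        hn = _normalize_candidate(h, theta, psi, major)
        start_phase = theta
        # 180-degree start ambiguity (start vertex vs its antipode) flips
        # the sign of even harmonics; fix it from the dominant harmonic-2
        # element when one exists.
        if coeffs.n_harmonics >= 2:
            j = int(np.argmax(np.abs(hn[1])))
            if hn[1, j] < 0:
                even = np.arange(1, len(hn), 2)  # harmonic 2, 4, ...
                hn[even] *= -1.0
                start_phase += np.pi
                psi += np.pi
    else:
        # anchor on harmonic 2: its phase advances at twice the parameter
        # rate, leaving four candidate start vertices a quarter turn apart
        phase2 = _axis_phase(h[1])
        maj2, min2 = _ellipse_axes(h[1], phase2)
        if min2 > maj2:
            phase2 += 0.5 * np.pi
        best = None
        for k in range(4):
            theta_k = phase2 / 2.0 + k * np.pi / 2.0
            psi_k = _vertex_direction(h[1], 2.0 * theta_k)
            cand = _normalize_candidate(h, theta_k, psi_k, major)
            key = tuple(np.round(cand.ravel(), 9))
            if best is None or key > best[0]:
                best = (key, cand, theta_k, psi_k)
        _, hn, start_phase, psi = best

    record = NormalizationRecord(
        translation=(float(coeffs.dc[0]), float(coeffs.dc[1])),
        scale=major,
        rotation=float(psi),
        start_phase=float(start_phase),
        normalized=True,
    )
    return EFACoefficients(coeffs.view, hn, np.zeros(2), record)


# ---------------------------------------------------------------------------
# harmonic power and calibration


def harmonic_power(coeffs: EFACoefficients) -> tuple[np.ndarray, np.ndarray]:
    """Per-harmonic power and cumulative power fraction.

    Power of harmonic n is ``(a_n^2 + b_n^2 + c_n^2 + d_n^2) / 2``.
    """
    h = coeffs.harmonics
    power = 0.5 * np.sum(h**2, axis=1)
    total = power.sum()
    if total == 0:
        raise EfaError("all-zero coefficients have no harmonic power")
    return power, np.cumsum(power) / total


class CalibrationError(RuntimeError):
    """Threshold not reachable within the allowed number of harmonics."""

    def __init__(self, threshold: float, max_harmonics: int, achieved: float):
        self.achieved = achieved
        super().__init__(
            f"cumulative harmonic power reaches only {achieved:.6f} "
            f"of target {threshold} at {max_harmonics} harmonics"
        )


def calibrate_harmonics(
    outlines: list[Outline],
    threshold: float = 0.98,
    max_harmonics: int = 20,
    reference_harmonics: int = 24,
) -> int:
    """Smallest harmonic count whose mean cumulative power fraction
    across ``outlines`` reaches ``threshold``.

    The total power in the denominator is evaluated at
    ``reference_harmonics`` (at least ``max_harmonics``, capped by the
    point count), so the fraction measures coverage of the outlines'
    full harmonic content, not merely of the retained harmonics.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if not outlines:
        raise ValueError("no outlines supplied")
    min_pts = min(o.n_points for o in outlines)
    total_h = min(max(max_harmonics, reference_harmonics), (min_pts - 1) // 2)
    total_h = max(total_h, max_harmonics)
    fracs = []
    for o in outlines:
        c = efa_forward(o, total_h)
        fracs.append(harmonic_power(c)[1])
    mean_frac = np.mean(fracs, axis=0)[:max_harmonics]
    hit = np.nonzero(mean_frac >= threshold)[0]
    if len(hit) == 0:
        raise CalibrationError(threshold, max_harmonics, float(mean_frac[-1]))
    return int(hit[0]) + 1


# ---------------------------------------------------------------------------
# dual-view fusion


def coefficient_labels(n_harmonics: int, views: tuple[str, str] = ("lateral", "ventral")) -> list[str]:
    """Column labels ``view_h<n>_<a|b|c|d>`` for the combined vector."""
    return [
        f"{view}_h{n}_{k}"
        for view in views
        for n in range(1, n_harmonics + 1)
        for k in "abcd"
    ]


def combine_views(lateral: EFACoefficients, ventral: EFACoefficients) -> np.ndarray:
    """Concatenate normalized coefficients of both views into one vector."""
    if lateral.view == ventral.view:
        raise ValueError("combine_views needs two distinct views")
    if {lateral.view, ventral.view} != {"lateral", "ventral"}:
        raise ValueError(
            f"expected views lateral+ventral, got {lateral.view!r}, {ventral.view!r}"
        )
    if lateral.view != "lateral":
        raise ValueError("arguments swapped: first argument must be the lateral view")
    if lateral.n_harmonics != ventral.n_harmonics:
        raise ValueError(
            f"harmonic count mismatch: {lateral.n_harmonics} vs {ventral.n_harmonics}"
        )
    if not (lateral.normalization.normalized and ventral.normalization.normalized):
        warnings.warn("combining non-normalized coefficients", stacklevel=2)
    return np.concatenate([lateral.harmonics.ravel(), ventral.harmonics.ravel()])


@dataclass
class ShapeMatrix:
    """Specimen-by-feature matrix of combined dual-view coefficients."""

    specimen_ids: list[str]
    X: np.ndarray = field(repr=False)
    columns: list[str] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[0] != len(self.specimen_ids):
            raise ValueError("row count does not match specimen ids")
        if self.columns and len(self.columns) != self.X.shape[1]:
            raise ValueError("column label count does not match features")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("shape matrix contains non-finite entries")


def assemble_shape_matrix(
    coeff_map: dict[str, dict[str, EFACoefficients]],
) -> ShapeMatrix:
    """Build a :class:`ShapeMatrix` from per-specimen, per-view coefficients.

    Specimens missing either view are excluded (and logged), since the
    combined feature vector needs both.
    """
    ids, rows = [], []
    n_harm = None
    for sid in sorted(coeff_map):
        views = coeff_map[sid]
        if "lateral" not in views or "ventral" not in views:
            logger.warning("specimen %s missing a view; excluded", sid)
            continue
        vec = combine_views(views["lateral"], views["ventral"])
        n_harm = views["lateral"].n_harmonics
        ids.append(sid)
        rows.append(vec)
    if not rows:
        raise ValueError("no specimen has both views")
    return ShapeMatrix(ids, np.vstack(rows), coefficient_labels(n_harm))
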