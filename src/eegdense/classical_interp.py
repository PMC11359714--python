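"""Classical spatial-interpolation baselines.

Two single-electrode baselines against which the learned interpolator is
judged:

* inverse-distance weighting (IDW): the prediction at a target electrode is
  the convex combination of the observed electrodes with normalized weights
  ``d^-1`` or ``d^-2`` of the planar inter-electrode distance;
* natural cubic spline along an electrode line: the observed electrodes on
  the target's horizontal row (e.g. the C row for Cz) or vertical column
  (the midline for Cz) serve as knots on a 1-D axis of cumulative planar
  distance, and a natural cubic spline is evaluated at the target's
  position on that axis, independently at every time sample.

Both are deterministic, stateless, and operate one instant at a time — they
use no temporal context, which is precisely the limitation the recurrent
interpolator addresses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .montage import ChannelSplit, Montage
from .preprocess import Recording

__all__ = [
    "IDWConfig",
    "SplineLine",
    "idw_predict",
    "idw_predict_series",
    "natural_cubic_spline",
    "build_spline_line",
    "spline_predict_series",
]


@dataclass(frozen=True)
class IDWConfig:
    """power 1 = reciprocal distance, power 2 = reciprocal squared distance."""

    power: int = 2

    def __post_init__(self) -> None:
        if self.power not in (1, 2):
            raise ValueError("power must be 1 or 2")


def _idw_weights(distances: np.ndarray, power: int) -> np.ndarray:
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance vector")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    w = np.zeros_like(d)
    zero = d == 0.0
    if zero.any():
        # coincident electrode: exact passthrough of the first such channel
        w[np.argmax(zero)] = 1.0
        return w
    w = d ** (-float(power))
    return w / w.sum()


def idw_predict(values, distances, cfg: IDWConfig = IDWConfig()) -> float:
    """Distance-weighted average of *values* at one time instant."""
    values = np.asarray(values, dtype=float)
    w = _idw_weights(distances, cfg.power)
    if values.shape != w.shape:
        raise ValueError("values and distances differ in length")
    return float(w @ values)


def idw_predict_series(rec: Recording, split: ChannelSplit, montage: Montage,
                       cfg: IDWConfig = IDWConfig()) -> np.ndarray:
    """IDW prediction of every target channel at every sample.

    Returns a (targets x samples) matrix in the order of ``split.targets``.
    Vectorized over time: the weights depend only on geometry, so each
    target row is a fixed convex combination of the observed rows.
    """
    if rec.n_channels != len(montage):
        raise ValueError("recording channel count does not match montage")
    obs_xy = montage.positions2d[split.observed_idx0]
    tgt_xy = montage.positions2d[split.targets_idx0]
    obs_data = rec.data[split.observed_idx0]
    out = np.empty((len(tgt_xy), rec.n_samples))
    for i, p in enumerate(tgt_xy):
        d = np.linalg.norm(obs_xy - p[None, :], axis=1)
        out[i] = _idw_weights(d, cfg.power) @ obs_data
    return out


def natural_cubic_spline(knots_x, knots_y) -> CubicSpline:
    """Natural cubic spline interpolant (zero second derivative at the ends).

    The C2 piecewise-cubic coefficients come from the standard tridiagonal
    moment system, as solved by scipy's natural-boundary ``CubicSpline``.
    """
    x = np.asarray(knots_x, dtype=float)
    y = np.asarray(knots_y, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need at least 3 knots for a cubic spline")
    if np.any(np.diff(x) <= 0):
        raise ValueError("knot abscissae must be strictly increasing")
    return CubicSpline(x, y, bc_type="natural")


# electrode rows that continue onto the temporal line: the coronal line
# through the vertex runs T9-T7-C5-...-Cz-...-T8-T10, and similarly the
# FT/TP electrodes extend the FC/CP rows.
_ROW_ALIAS = {"T": "C", "FT": "FC", "TP": "CP"}


def _row_col(label: str) -> tuple[str, str]:
    """(row key, column key) of an electrode label; 'z' marks the midline."""
    head = label.rstrip("0123456789z")
    suffix = label[len(head):]
    if head == "Nz"[:-1] and suffix == "z" and label == "Nz":
        return "Nz", "z"
    row = _ROW_ALIAS.get(head, head)
    if suffix == "z":
        return row, "z"
    n = int(suffix)
    # temporal labels use a different numeral for the same column
    if head in ("T", "FT", "TP"):
        col = {9: "9", 10: "9", 7: "7", 8: "7"}.get(n, str(n - (n % 2 == 0)))
    else:
        col = str(n - (n % 2 == 0))  # 3 and 4 share column "3", etc.
    side = "L" if n % 2 == 1 else "R"
    return row, col + side


@dataclass(frozen=True)
class SplineLine:
    """Knot layout for one spline-interpolated target electrode."""

    knot_indices: tuple[int, ...]  # 1-based montage indices, in line order
    abscissae: np.ndarray  # cumulative planar distance at each knot
    target_abscissa: float
    orientation: str  # "horizontal" | "vertical"

    def __post_init__(self) -> None:
        x = np.asarray(self.abscissae, dtype=float)
        object.__setattr__(self, "abscissae", x)
        if len(self.knot_indices) != len(x):
            raise ValueError("knot_indices/abscissae length mismatch")
        if len(x) < 3:
            raise ValueError("need at least 3 knots on the line")
        if np.any(np.diff(x) <= 0):
            raise ValueError("abscissae must be strictly increasing")
        if not (x[0] <= self.target_abscissa <= x[-1]):
            raise ValueError(
                "target lies outside the knot range; extrapolation refused"
            )


def _line_members(montage: Montage, split: ChannelSplit, target_index: int,
                  orientation: str) -> list[int]:
    """Observed 1-based indices on the target's row or column."""
    t_row, t_col = _row_col(montage.names[target_index - 1])
    members = []
    for idx in split.observed:
        row, col = _row_col(montage.names[idx - 1])
        if orientation == "horizontal" and row == t_row:
            members.append(idx)
        elif orientation == "vertical" and col == t_col:
            members.append(idx)
    return members


def build_spline_line(montage: Montage, split: ChannelSplit,
                      target_index: int) -> SplineLine:
    """Choose the knot line for *target_index* (1-based montage index).

    Of the target's horizontal row and vertical column, the orientation with
    more observed electrodes wins (ties go to horizontal).  Knots are ordered
    along the line and placed on a 1-D axis of cumulative planar
    (chord) distance; the target must fall strictly inside the knot range.
    """
    if target_index in split.observed:
        raise ValueError("target electrode is already observed")
    cand = {
        o: _line_members(montage, split, target_index, o)
        for o in ("horizontal", "vertical")
    }
    orientation = max(("horizontal", "vertical"), key=lambda o: len(cand[o]))
    members = cand[orientation]
    if len(members) < 3:
        raise ValueError(
            f"only {len(members)} observed electrodes on the "
            f"{orientation} line of {montage.names[target_index - 1]}"
        )
    # order along the line: lateral coordinate for rows, AP for columns
    axis = 0 if orientation == "horizontal" else 1
    seq = sorted(members + [target_index],
                 key=lambda i: montage.positions2d[i - 1][axis])
    pts = np.array([montage.positions2d[i - 1] for i in seq])
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    t_pos = seq.index(target_index)
    knots = [i for i in seq if i != target_index]
    abscissae = np.array([arc[seq.index(i)] for i in knots])
    return SplineLine(
        knot_indices=tuple(knots),
        abscissae=abscissae,
        target_abscissa=float(arc[t_pos]),
        orientation=orientation,
    )


def spline_predict_series(rec: Recording, split: ChannelSplit, montage: Montage,
                          line: SplineLine | None = None,
                          target_index: int | None = None) -> np.ndarray:
    """Per-sample natural-spline prediction of one target channel.

    Either pass a prebuilt :class:`SplineLine` or a 1-based *target_index*
    (the line is then built automatically).  Returns the predicted series.
    """
    if line is None:
        if target_index is None:
            raise ValueError("need a SplineLine or a target_index")
        line = build_spline_line(montage, split, target_index)
    knot_idx0 = np.asarray(line.knot_indices, dtype=int) - 1
    values = rec.data[knot_idx0]  # knots x samples
    spline = natural_cubic_spline(line.abscissae, values)
    return np.asarray(spline(line.target_abscissa), dtype=float)
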