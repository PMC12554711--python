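"""Schematic scalp topographies of per-channel statistics.

Values at the 16 montage electrodes are interpolated over the unit head
disc with a thin-plate-spline radial basis function on the schematic (non-
anatomical) layout coordinates. The maps are qualitative: they show where on
the scalp a statistic is large, not anatomically localized sources.
"""

from __future__ import annotations

from collections.abc import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.interpolate import RBFInterpolator

from .errors import ParameterError
from .montage import MONTAGE_16, layout_array


def _as_value_array(values) -> np.ndarray:
    if isinstance(values, Mapping):
        unknown = set(values) - set(MONTAGE_16)
        if unknown:
            raise ParameterError(f"unknown channel label(s): {sorted(unknown)}")
        return np.array([float(values.get(c, np.nan)) for c in MONTAGE_16])
    arr = np.asarray(values, dtype=float)
    if arr.shape != (len(MONTAGE_16),):
        raise ParameterError(f"expected one value per montage channel ({len(MONTAGE_16)})")
    return arr


def interpolate_field(
    values, grid_n: int = 64
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate channel values over the unit disc.

    Returns (xx, yy, field); points outside the disc are NaN. Channels whose
    value is NaN are masked out of the interpolation.
    """
    vals = _as_value_array(values)
    coords = layout_array()
    ok = np.isfinite(vals)
    if ok.sum() < 3:
        raise ParameterError("need at least 3 finite channel values to interpolate")
    interp = RBFInterpolator(coords[ok], vals[ok], kernel="thin_plate_spline")
    g = np.linspace(-1, 1, grid_n)
    xx, yy = np.meshgrid(g, g)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    field = interp(pts).reshape(grid_n, grid_n)
    field[xx**2 + yy**2 > 1] = np.nan
    return xx, yy, field


def render_topomap(values, out_path, title: str = "", grid_n: int = 64) -> None:
    """Render an interpolated head map with channel markers to ``out_path``.

    ``values`` is a dict {channel: value} (missing channels masked) or an
    array in montage order. Output is deterministic for fixed input.
    """
    vals = _as_value_array(values)
    coords = layout_array()
    xx, yy, field = interpolate_field(vals, grid_n)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.pcolormesh(xx, yy, field, shading="auto", cmap="RdBu_r")
    ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, lw=1.5))
    ax.plot([-0.08, 0, 0.08], [0.995, 1.06, 0.995], color="k", lw=1.5)  # nose
    ok = np.isfinite(vals)
    ax.scatter(coords[ok, 0], coords[ok, 1], s=12, c="k", zorder=3)
    for (x, y), lab in zip(coords, MONTAGE_16):
        ax.annotate(lab, (x, y), textcoords="offset points", xytext=(3, 3), fontsize=6)
    ax.set_xlim(-1.15, 1.15)
    ax.set_ylim(-1.15, 1.15)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.75)
    fig.savefig(out_path, dpi=110, bbox_inches="tight")
    plt.close(fig)
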