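"""Flux inference: PIV, rachis flux integration and flux-balance profiles.

Pipeline: two speckle frames -> block-correlation velocity field
(``piv_displacement``) -> axisymmetric flux profile Qr(x)
(``flux_from_field``); a cell table plus cell velocities -> cell-phase
flux Qc(x) (``cell_volume_flux``); smoothed derivatives then give the
cell-to-rachis current J = dQr/dx (``infer_J``) and the material uptake
S = d(Qc+Qr)/dx (``infer_S``).

Fluxes are fl/min (1 fl = 1 um^3); image velocities um/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.integrate import cumulative_trapezoid
from skimage.feature import match_template

from .types import GeometryError, VelocityField

__all__ = [
    "PivParams",
    "SignalQualityError",
    "piv_displacement",
    "flux_from_field",
    "cell_volume_flux",
    "infer_J",
    "infer_S",
    "um3_per_s_to_fl_per_min",
    "fl_per_min_to_um3_per_s",
    "zero_crossing_x",
    "main_zero_crossing_x",
]

# proximal-most fraction of the axis where centreline estimates are unreliable
LOW_CONFIDENCE_TAIL = 0.05
# distal cut-off for apoptosis-inhibited (irregular-geometry) samples, whose
# velocity fields are only steady beyond 16% gonad length
CED3_X_MIN = 0.16


class SignalQualityError(RuntimeError):
    """Raised when PIV produces no valid displacement estimate."""


def um3_per_s_to_fl_per_min(q):
    """1 um^3/s = 60 fl/min."""
    return np.asarray(q, dtype=float) * 60.0


def fl_per_min_to_um3_per_s(q):
    return np.asarray(q, dtype=float) / 60.0


@dataclass
class PivParams:
    """Block-correlation settings.

    template_px     : square template edge (px)
    overlap_px      : overlap between neighbouring templates (px)
    frame_interval  : s between the two frames
    pixel_size      : um per px
    search_margin_px: half-width of the search window beyond the template
    min_correlation : peak threshold below which a vector is invalid
    """

    template_px: int = 16
    overlap_px: int = 8
    frame_interval: float = 10.0
    pixel_size: float = 0.106
    search_margin_px: int | None = None
    min_correlation: float = 0.3

    def __post_init__(self) -> None:
        if self.template_px < 4:
            raise ValueError("template must be at least 4 px")
        if not 0 <= self.overlap_px < self.template_px:
            raise ValueError("overlap must satisfy 0 <= overlap < template")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be positive")
        if self.search_margin_px is None:
            self.search_margin_px = self.template_px // 2

    @property
    def step_px(self) -> int:
        return self.template_px - self.overlap_px


def _parabolic_peak(c: np.ndarray, i: int, j: int) -> tuple[float, float]:
    """3-point parabolic sub-pixel refinement of a correlation peak."""
    di = dj = 0.0
    if 0 < i < c.shape[0] - 1:
        den = c[i - 1, j] - 2.0 * c[i, j] + c[i + 1, j]
        if den < 0:
            di = 0.5 * (c[i - 1, j] - c[i + 1, j]) / den
    if 0 < j < c.shape[1] - 1:
        den = c[i, j - 1] - 2.0 * c[i, j] + c[i, j + 1]
        if den < 0:
            dj = 0.5 * (c[i, j - 1] - c[i, j + 1]) / den
    return di, dj


def piv_displacement(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    params: PivParams,
    mask: np.ndarray | None = None,
) -> VelocityField:
    """Velocity field between two frames by normalised cross-correlation.

    Each template block of ``frame_a`` is matched inside a search window of
    ``frame_b``; the correlation peak is refined to sub-pixel precision by
    a 3-point parabola in each axis.  Velocities are displacement *
    pixel_size / frame_interval (um/s); vectors whose correlation peak
    falls below ``min_correlation`` are flagged invalid and filled from the
    nearest valid neighbour.
    """
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must share a shape")
    if mask is not None and mask.shape != frame_a.shape:
        raise ValueError("mask must match frame shape")

    t = params.template_px
    m = params.search_margin_px
    step = params.step_px
    n_rows, n_cols = frame_a.shape
    r_starts = np.arange(0, n_rows - t + 1, step)
    c_starts = np.arange(0, n_cols - t + 1, step)
    if r_starts.size == 0 or c_starts.size == 0:
        raise ValueError("template does not fit inside the frames")

    u = np.zeros((r_starts.size, c_starts.size))
    v = np.zeros_like(u)
    corr = np.zeros_like(u)
    block_mask = np.ones_like(u, dtype=bool)

    for bi, r0 in enumerate(r_starts):
        for bj, c0 in enumerate(c_starts):
            if mask is not None:
                block_mask[bi, bj] = bool(mask[r0 + t // 2, c0 + t // 2])
            tpl = frame_a[r0 : r0 + t, c0 : c0 + t]
            if tpl.std() == 0:
                corr[bi, bj] = 0.0
                continue
            sr0, sr1 = max(r0 - m, 0), min(r0 + t + m, n_rows)
            sc0, sc1 = max(c0 - m, 0), min(c0 + t + m, n_cols)
            search = frame_b[sr0:sr1, sc0:sc1]
            if search.std() == 0:
                corr[bi, bj] = 0.0
                continue
            cc = match_template(search, tpl, pad_input=False)
            pi, pj = np.unravel_index(np.argmax(cc), cc.shape)
            corr[bi, bj] = float(cc[pi, pj])
            di, dj = _parabolic_peak(cc, pi, pj)
            v[bi, bj] = (sr0 + pi + di) - r0
            u[bi, bj] = (sc0 + pj + dj) - c0

    valid = corr >= params.min_correlation
    if not valid.any():
        raise SignalQualityError("no PIV block produced a correlation above threshold")
    if not valid.all():
        u = _fill_invalid(u, valid)
        v = _fill_invalid(v, valid)

    scale = params.pixel_size / params.frame_interval
    half = t / 2.0
    centre_cols = (c_starts + half) * params.pixel_size
    centreline = np.column_stack([centre_cols, np.full(c_starts.size, n_rows / 2.0 * params.pixel_size)])
    field = VelocityField(
        u=u * scale,
        v=v * scale,
        mask=block_mask,
        centreline=centreline,
        pixel_size=params.pixel_size * step,
        valid=valid,
    )
    # grid coordinates of block centres in um (row, col of the first block)
    field.origin_um = ((r_starts[0] + half) * params.pixel_size, (c_starts[0] + half) * params.pixel_size)
    field.n_filled = int((~valid).sum())
    return field


def _fill_invalid(a: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Nearest-valid-neighbour fill on a block grid."""
    from scipy.ndimage import distance_transform_edt

    _, idx = distance_transform_edt(~valid, return_indices=True)
    return a[tuple(idx)]


# ---------------------------------------------------------------------------
# flux integration
# ---------------------------------------------------------------------------

def _field_coordinates(field: VelocityField) -> tuple[np.ndarray, np.ndarray]:
    """(row_um, col_um) coordinates of grid points."""
    origin = getattr(field, "origin_um", None)
    if origin is None:
        origin = (field.pixel_size / 2.0, field.pixel_size / 2.0)
    n_rows, n_cols = field.shape
    rows = origin[0] + np.arange(n_rows) * field.pixel_size
    cols = origin[1] + np.arange(n_cols) * field.pixel_size
    return rows, cols


def flux_from_field(
    field: VelocityField,
    lumen_radius_um,
    gonad_length_um: float | None = None,
    n_radial: int = 64,
    x_min: float = 0.0,
) -> pd.DataFrame:
    """Axisymmetric rachis flux Qr(x) from a mid-plane velocity field.

    Assumes rotational symmetry about the centreline: at every axial
    station, Qr = int_0^a v_par(r) 2 pi r dr with the transverse mid-plane
    profile standing in for the radial one (the two half-profiles are
    averaged) and trapezoidal quadrature in r.  ``lumen_radius_um`` is a
    scalar or a per-column array.  Returns a frame with x (fraction of
    gonad length), Qr (fl/min) and a low-confidence flag for the
    proximal-most 5% where centreline estimates degrade.  ``x_min`` drops
    stations distal of it (use :data:`CED3_X_MIN` for apoptosis-inhibited
    samples whose distal geometry precludes steady velocity fields).
    """
    rows_um, cols_um = _field_coordinates(field)
    n_rows, n_cols = field.shape
    cl = field.centreline
    if cl.shape[0] < 2:
        raise GeometryError("centreline must have at least 2 points")
    if cl[:, 0].max() < cols_um[-1] - field.pixel_size:
        raise GeometryError("centreline does not span the field")
    a = np.broadcast_to(np.asarray(lumen_radius_um, dtype=float), (n_cols,))
    if np.any(a <= 0):
        raise GeometryError("lumen radius must be positive")
    if gonad_length_um is None:
        gonad_length_um = float(cols_um[-1] + field.pixel_size / 2.0)

    # local centreline height and tangent per column
    yc = np.interp(cols_um, cl[:, 0], cl[:, 1])
    dy = np.gradient(cl[:, 1], cl[:, 0])
    tangent_slope = np.interp(cols_um, cl[:, 0], dy)

    q = np.empty(n_cols)
    for j in range(n_cols):
        # velocity along the local tangent
        tx = 1.0 / np.hypot(1.0, tangent_slope[j])
        ty = tangent_slope[j] * tx
        v_par = field.u[:, j] * tx + field.v[:, j] * ty
        r_signed = rows_um - yc[j]
        rr = np.linspace(0.0, a[j], n_radial)
        v_up = np.interp(rr, r_signed, v_par)
        v_dn = np.interp(rr, -r_signed[::-1], v_par[::-1])
        v_mean = 0.5 * (v_up + v_dn)
        q[j] = np.trapezoid(2.0 * np.pi * rr * v_mean, rr)  # um^3/s

    x = cols_um / gonad_length_um
    out = pd.DataFrame(
        {
            "x": x,
            "Qr": um3_per_s_to_fl_per_min(q),
            "low_confidence": x > 1.0 - LOW_CONFIDENCE_TAIL,
        }
    )
    if x_min > 0:
        out = out[out["x"] >= x_min].reset_index(drop=True)
    return out


def cell_volume_flux(
    cells: pd.DataFrame,
    v_c_um_per_min,
    x_grid: np.ndarray,
    gonad_length_um: float,
    n_bins: int = 40,
) -> pd.DataFrame:
    """Cell-phase volume flux Qc(x) = rhoV(x) * v_c(x) / L.

    ``rhoV`` is the summed cell volume per unit fractional length per gonad
    arm (binned from the table and averaged over gonads); ``v_c`` is the
    cell velocity in um/min sampled on ``x_grid``; L is the gonad length in
    um, so Qc comes out in fl/min.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    v_c = np.broadcast_to(np.asarray(v_c_um_per_min, dtype=float), x_grid.shape)
    n_gonads = cells["gonad_id"].nunique()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    total_v, _ = np.histogram(
        cells["x"].to_numpy(dtype=float), bins=edges, weights=cells["volume_fl"].to_numpy(dtype=float)
    )
    rho_bins = total_v / np.diff(edges) / n_gonads
    centers = 0.5 * (edges[:-1] + edges[1:])
    rho = np.interp(x_grid, centers, rho_bins)
    return pd.DataFrame({"x": x_grid, "Qc": rho * v_c / gonad_length_um, "rhoV": rho})


# ---------------------------------------------------------------------------
# flux-balance derivatives
# ---------------------------------------------------------------------------

def _savgol_window(n: int, window: int | None) -> int:
    if window is None:
        window = max(n // 10, 5)
    window = int(window)
    if window % 2 == 0:
        window += 1
    return min(window, n - 1 if (n - 1) % 2 else n - 2)


def _smooth_derivative(x, y, window, polyorder):
    dx = float(np.mean(np.diff(x)))
    w = _savgol_window(len(x), window)
    dy = savgol_filter(y, w, polyorder, deriv=1, delta=dx)
    y0 = float(savgol_filter(y, w, polyorder)[0])
    # anchor the smoothed curve to the integral of its own derivative so
    # that cumulative trapezoid of the derivative reproduces it exactly
    y_smooth = y0 + cumulative_trapezoid(dy, x, initial=0.0)
    return dy, y_smooth


def infer_J(
    profile: pd.DataFrame,
    window: int | None = None,
    polyorder: int = 2,
    replicates: np.ndarray | None = None,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Cell-to-rachis current J = dQr/dx by Savitzky-Golay differentiation.

    Adds columns J and Qr_smooth (the anchored integral of J, so that
    ``cumtrapz(J) + Qr_smooth[0] == Qr_smooth`` holds to machine
    precision).  If per-gonad ``replicates`` (n_gonads x n_grid) are
    supplied, a bootstrap over gonads adds J_lo / J_hi 95% bands.
    """
    out = profile.copy()
    x = out["x"].to_numpy(dtype=float)
    J, qr_s = _smooth_derivative(x, out["Qr"].to_numpy(dtype=float), window, polyorder)
    out["J"] = J
    out["Qr_smooth"] = qr_s
    if replicates is not None:
        lo, hi = _bootstrap_derivative(x, replicates, window, polyorder, n_boot, rng)
        out["J_lo"], out["J_hi"] = lo, hi
    return out


def infer_S(
    profile: pd.DataFrame,
    window: int | None = None,
    polyorder: int = 2,
    replicates: np.ndarray | None = None,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Material uptake S = d(Qc+Qr)/dx, same smoothing contract as infer_J."""
    out = profile.copy()
    x = out["x"].to_numpy(dtype=float)
    total = out["Qc"].to_numpy(dtype=float) + out["Qr"].to_numpy(dtype=float)
    S, tot_s = _smooth_derivative(x, total, window, polyorder)
    out["S"] = S
    out["Qtot_smooth"] = tot_s
    if replicates is not None:
        lo, hi = _bootstrap_derivative(x, replicates, window, polyorder, n_boot, rng)
        out["S_lo"], out["S_hi"] = lo, hi
    return out


def _bootstrap_derivative(x, replicates, window, polyorder, n_boot, rng):
    if rng is None:
        rng = np.random.default_rng(0)
    replicates = np.asarray(replicates, dtype=float)
    n_rep = replicates.shape[0]
    draws = np.empty((n_boot, x.size))
    for b in range(n_boot):
        pick = rng.integers(0, n_rep, size=n_rep)
        mean = replicates[pick].mean(axis=0)
        draws[b], _ = _smooth_derivative(x, mean, window, polyorder)
    return np.quantile(draws, 0.025, axis=0), np.quantile(draws, 0.975, axis=0)


def main_zero_crossing_x(x: np.ndarray, y: np.ndarray) -> float:
    """Position of the dominant +/- sign change of y.

    Robust to small noise wiggles near the boundaries: the landmark is the
    zero of y between its main positive and main negative lobe, i.e. where
    the cumulative integral of y peaks; the crossing is then linearly
    interpolated between the neighbouring grid points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = cumulative_trapezoid(y, x, initial=0.0)
    k = int(np.argmax(c))
    if k == 0 or k == x.size - 1:
        return zero_crossing_x(x, y)
    i = k if y[k] > 0 else k - 1  # bracket the downward crossing around k
    i = int(np.clip(i, 0, x.size - 2))
    if y[i + 1] == y[i]:
        return float(x[i])
    return float(x[i] - y[i] * (x[i + 1] - x[i]) / (y[i + 1] - y[i]))


def zero_crossing_x(x: np.ndarray, y: np.ndarray) -> float:
    """Linearly interpolated position of the first sign change of y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sign = np.sign(y)
    idx = np.nonzero((sign[:-1] != sign[1:]) & (sign[:-1] != 0))[0]
    if idx.size == 0:
        return float("nan")
    i = idx[0]
    if y[i + 1] == y[i]:
        return float(x[i])
    return float(x[i] - y[i] * (x[i + 1] - x[i]) / (y[i + 1] - y[i]))
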