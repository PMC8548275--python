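"""Synthetic gonad generator.

Produces every input the analysis pipeline consumes — per-cell volume
tables, mid-plane rachis velocity fields, speckle image pairs for PIV, and
apoptosis/mitosis event streams — from a single seeded configuration, with
the statistical structure the downstream analysis assumes and with exact
internal flux bookkeeping (the "truth" profiles) for recovery tests.

Positions are fractions of gonad length (0 = distal tip, 1 = proximal
turn).  Volumes are fl, fluxes fl/min, velocities um/s in images.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter, map_coordinates

from .config import ConfigurationError, SyntheticConfig
from .types import GeometryError, VelocityField

__all__ = [
    "ground_truth_profiles",
    "mean_volume_curve",
    "generate_cell_table",
    "generate_velocity_field",
    "generate_image_pair",
    "generate_events",
    "AliasingError",
]


class AliasingError(ValueError):
    """Frame-to-frame displacement too large for the PIV template."""


# ---------------------------------------------------------------------------
# volume statistics along the axis
# ---------------------------------------------------------------------------

def _distal_mean(cfg: SyntheticConfig, x: np.ndarray) -> np.ndarray:
    """Homogeneous-growth mean volume, linear from start to end over [0, x*]."""
    frac = np.clip(x / cfg.transition_position, 0.0, 1.0)
    return cfg.distal_mean_start + (cfg.distal_mean_end - cfg.distal_mean_start) * frac


def _mixture_components(cfg: SyntheticConfig, x: np.ndarray):
    """Proximal mixture (weight_small, mean_small, mean_large) at positions x.

    The separation of the modes is chosen so that the *total* SD follows an
    exactly linear SD-vs-mean law with slope ``proximal_sd_slope`` (steeper
    than the distal coefficient of variation): the between-mode variance is
    whatever the target SD requires beyond the within-mode part.  This
    gives the slope-break detector a sharp corner and makes the separation
    grow continuously from zero at the transition.
    """
    xs = cfg.transition_position
    frac = np.clip((x - xs) / max(1.0 - xs, 1e-12), 0.0, 1.0)
    m0 = cfg.distal_mean_end
    mean_t = m0 + (cfg.proximal_mean_end - m0) * frac
    sd_t = cfg.volume_cv * m0 + cfg.proximal_sd_slope * (mean_t - m0)
    sd_within = cfg.volume_cv * mean_t
    sd_between = np.sqrt(np.maximum(sd_t**2 - sd_within**2, 0.0))
    w_small = 0.5 + (cfg.small_mode_weight_end - 0.5) * frac
    sep = sd_between / np.sqrt(w_small * (1.0 - w_small))
    m_small = mean_t - (1.0 - w_small) * sep
    m_large = m_small + sep
    # keep both modes inside the physical envelope
    m_small = np.maximum(m_small, cfg.proximal_small)
    m_large = np.minimum(m_large, cfg.proximal_large)
    return w_small, m_small, m_large


def mean_volume_curve(cfg: SyntheticConfig, x: np.ndarray) -> np.ndarray:
    """Expected cell volume at positions x (mixture mean beyond the transition)."""
    x = np.asarray(x, dtype=float)
    mean = _distal_mean(cfg, x)
    prox = x >= cfg.transition_position
    if np.any(prox):
        w, ms, ml = _mixture_components(cfg, x[prox])
        mean = mean.copy()
        mean[prox] = w * ms + (1 - w) * ml
    return mean


def _lognormal_around(rng: np.random.Generator, mean: np.ndarray, cv: float) -> np.ndarray:
    """Lognormal draws with the requested mean and coefficient of variation."""
    if cv == 0:
        return np.asarray(mean, dtype=float).copy()
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2))


def generate_cell_table(cfg: SyntheticConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample a per-cell volume table.

    Distal to the transition, volumes are unimodal lognormal with mean
    interpolating ``distal_mean_start -> distal_mean_end`` and SD
    proportional to the mean.  Proximal to it, volumes come from a
    two-component mixture whose modes drift apart towards
    ``proximal_small`` and ``proximal_large`` and whose small-mode weight
    decays linearly.  Deterministic under a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    frames = []
    for g in range(cfg.n_gonads):
        x = rng.uniform(0.0, 1.0, size=cfg.cells_per_gonad)
        vol = np.empty_like(x)
        prox = x >= cfg.transition_position
        dist = ~prox
        vol[dist] = _lognormal_around(rng, _distal_mean(cfg, x[dist]), cfg.volume_cv)
        if np.any(prox):
            w, ms, ml = _mixture_components(cfg, x[prox])
            pick_small = rng.uniform(size=prox.sum()) < w
            means = np.where(pick_small, ms, ml)
            vol[prox] = _lognormal_around(rng, means, cfg.volume_cv)
        # keep volumes inside the envelope seen in the data
        np.clip(vol, cfg.proximal_small, cfg.proximal_large, out=vol)
        frames.append(
            pd.DataFrame(
                {
                    "gonad_id": f"g{g:03d}",
                    "x": x,
                    "volume_fl": vol,
                    "alive": True,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    if (table["volume_fl"] <= 0).any():
        raise ConfigurationError("generated non-positive volume; check config")
    return table


# ---------------------------------------------------------------------------
# flux bookkeeping (the generator's ground truth)
# ---------------------------------------------------------------------------

def _uptake_profile(cfg: SyntheticConfig, x: np.ndarray) -> np.ndarray:
    """Material uptake S(x): positive sine lobe on [0, x*], negative on [x*, 1]."""
    xs = cfg.transition_position
    s = np.where(
        x < xs,
        cfg.uptake_amplitude * np.sin(np.pi * np.clip(x / xs, 0, 1)),
        -cfg.uptake_amplitude
        * cfg.uptake_export_fraction
        * np.sin(np.pi * np.clip((x - xs) / max(1 - xs, 1e-12), 0, 1)),
    )
    return s


def ground_truth_profiles(cfg: SyntheticConfig) -> pd.DataFrame:
    """Internally consistent axial profiles used by all generators.

    Construction guarantees the discrete balances exactly: Qr is the
    integral of a J profile with zero total, Qc the integral of S - J, so
    (Qc + Qr)(1) equals the integrated uptake (global volume conservation
    of the bookkeeping) and Qr(0) = Qr(1) = 0.
    """
    x = cfg.x_grid
    xs = cfg.transition_position
    S = _uptake_profile(cfg, x)

    # Qr rises, peaks at x*, falls back to zero; warp a half-sine so the
    # peak sits exactly at the transition.
    xp = max(1.0 - xs, 1e-12)
    g = np.where(x < xs, 0.5 * x / xs, 0.5 + 0.5 * (x - xs) / xp)
    Qr = cfg.rachis_flux_peak * np.sin(np.pi * g)
    dg = np.where(x < xs, 0.5 / xs, 0.5 / xp)
    J = cfg.rachis_flux_peak * np.pi * dg * np.cos(np.pi * g)

    # exact discrete bookkeeping: (Qc + Qr) is the trapezoid integral of S,
    # so the net export at x = 1 equals trapz(S) to machine precision
    Qc = cumulative_trapezoid(S, x, initial=0.0) - (Qr - Qr[0])

    # cell-phase density per gonad arm: cells per unit fractional length
    # (uniform) times the local mean volume
    rhoV = cfg.cells_per_gonad * mean_volume_curve(cfg, x)
    v_c = Qc * cfg.gonad_length / rhoV  # um/min

    return pd.DataFrame({"x": x, "S": S, "Qr": Qr, "J": J, "Qc": Qc, "rhoV": rhoV, "v_c": v_c})


# ---------------------------------------------------------------------------
# velocity fields and image pairs
# ---------------------------------------------------------------------------

def generate_velocity_field(
    cfg: SyntheticConfig,
    target_profile: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> VelocityField:
    """Build a mid-plane velocity field whose axisymmetric flux matches a target.

    At every axial position the axial component follows a Poiseuille
    (parabolic) profile across the lumen, scaled so that the axisymmetric
    integral ``int_0^a v 2 pi r dr`` equals ``target_profile['Qr']``
    (fl/min) before noise.  Gaussian noise of ``cfg.noise_sd_velocity``
    (um/s) is added inside the lumen.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    a_grid = cfg.rachis_radius_profile()
    if np.any(a_grid <= 0):
        raise GeometryError("lumen radius must be positive everywhere")

    px = cfg.pixel_size
    n_cols = max(int(round(cfg.gonad_length / px)), 4)
    n_rows = max(int(round(2 * cfg.gonad_radius / px)), 4)
    col_um = (np.arange(n_cols) + 0.5) * px
    row_um = (np.arange(n_rows) + 0.5) * px
    x_frac = col_um / cfg.gonad_length
    r_um = np.abs(row_um - cfg.gonad_radius)

    a_x = np.interp(x_frac, cfg.x_grid, a_grid)
    qr_x = np.interp(x_frac, target_profile["x"].to_numpy(), target_profile["Qr"].to_numpy())
    # fl/min -> um^3/s; Poiseuille peak = 2 * mean = 2 Q / (pi a^2)
    v_max = 2.0 * (qr_x / 60.0) / (np.pi * a_x**2)

    rr = r_um[:, None]
    aa = a_x[None, :]
    mask = rr < aa
    u = np.where(mask, v_max[None, :] * (1.0 - (rr / aa) ** 2), 0.0)
    v = np.zeros_like(u)
    if cfg.noise_sd_velocity > 0:
        u = u + np.where(mask, rng.normal(0.0, cfg.noise_sd_velocity, u.shape), 0.0)
        v = v + np.where(mask, rng.normal(0.0, cfg.noise_sd_velocity, v.shape), 0.0)

    centreline = np.column_stack([col_um, np.full(n_cols, cfg.gonad_radius)])
    return VelocityField(u=u, v=v, mask=mask, centreline=centreline, pixel_size=px)


def generate_image_pair(
    field: VelocityField,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
    max_displacement_px: float = 8.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render two speckle frames separated by one frame interval.

    The second frame is the first frame's random speckle texture advected
    by the velocity field (backward warp, linear interpolation); pixels
    outside the lumen mask keep a static texture.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    n_rows, n_cols = field.shape
    texture = rng.uniform(0.0, 1.0, size=(n_rows, n_cols))
    frame_a = gaussian_filter(texture, cfg.speckle_sigma_px)

    # displacement in pixels over one frame interval (u is axial = column)
    dc = field.u * cfg.frame_interval / field.pixel_size
    dr = field.v * cfg.frame_interval / field.pixel_size
    dc = np.where(field.mask, dc, 0.0)
    dr = np.where(field.mask, dr, 0.0)
    max_disp = float(np.hypot(dr, dc).max()) if dc.size else 0.0
    if max_disp > max_displacement_px:
        raise AliasingError(
            f"max displacement {max_disp:.2f} px exceeds {max_displacement_px} px; "
            "reduce frame_interval or flow speed"
        )

    rows, cols = np.mgrid[0:n_rows, 0:n_cols].astype(float)
    frame_b = map_coordinates(frame_a, [rows - dr, cols - dc], order=1, mode="nearest")
    return frame_a, frame_b


# ---------------------------------------------------------------------------
# event streams
# ---------------------------------------------------------------------------

def generate_events(
    cfg: SyntheticConfig,
    duration_h: float,
    n_cells: int | None = None,
    apoptosis_profile=None,
    mitosis_profile=None,
    rng: np.random.Generator | None = None,
    x_cells: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sample apoptosis and mitosis events over an imaging window.

    Each cell (positions ``x_cells``, or uniform draws on [0, 1]) emits
    events as a Poisson process with the position-dependent per-cell-hour
    intensity; by default apoptosis is confined to the configured 70-90%
    zone.
    """
    if duration_h < 0:
        raise ConfigurationError("duration must be non-negative")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    if apoptosis_profile is None:
        apoptosis_profile = cfg.apoptosis_rate_profile
    if mitosis_profile is None:
        mitosis_profile = cfg.mitosis_rate_profile

    if x_cells is None:
        if n_cells is None:
            n_cells = cfg.n_gonads * cfg.cells_per_gonad
        x_cells = rng.uniform(0.0, 1.0, size=n_cells)
    else:
        x_cells = np.asarray(x_cells, dtype=float)
    rows = []
    for kind, profile in (("apoptosis", apoptosis_profile), ("mitosis", mitosis_profile)):
        rates = np.asarray(profile(x_cells), dtype=float)
        if np.any(rates < 0) or np.any(rates > 1):
            raise ConfigurationError(f"{kind} rates must lie in [0, 1] per hour")
        counts = rng.poisson(rates * duration_h)
        for xi, k in zip(x_cells, counts):
            if k:
                for t in rng.uniform(0.0, duration_h, size=k):
                    rows.append((xi, t, kind))
    events = pd.DataFrame(rows, columns=["x", "t_h", "type"])
    return events.sort_values("t_h", kind="stable", ignore_index=True)
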