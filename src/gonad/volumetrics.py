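"""Locating the homogeneous-to-heterogeneous growth transition.

Three detectors operate on a per-cell volume table:

* ``detect_transition_slope`` — a continuous two-segment piecewise-linear
  fit of per-bin SD against per-bin mean volume (bins ordered along the
  axis); the sharp slope change marks the transition.
* ``detect_transition_bimodality`` — the first axial bin from which the
  volume distribution stays multimodal, judged either by the Hartigan dip
  test or by a 1-vs-2 component Gaussian-mixture BIC comparison on log
  volumes.

Confidence intervals come from bootstrap resampling over gonads and are
floored at one bin width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from ._dip import dip_pvalue, dip_statistic

__all__ = [
    "AnalysisError",
    "TransitionResult",
    "bin_volumes",
    "fit_two_segment",
    "detect_transition_slope",
    "dip_bimodality",
    "gmm_bimodality",
    "detect_transition_bimodality",
]

# improvement in SSR (relative) a breakpoint must deliver over a single line
DEGENERATE_IMPROVEMENT = 0.10
# margin of bins excluded from the breakpoint search at either edge
EDGE_MARGIN = 2


class AnalysisError(ValueError):
    """Raised when inputs cannot support the requested analysis."""


@dataclass
class TransitionResult:
    """Estimated transition position with confidence interval."""

    x_star: float
    ci_low: float
    ci_high: float
    method: str
    slopes: tuple[float, float] | None = None
    degenerate: bool = False
    found: bool = True
    bin_stats: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.found and not (self.ci_low <= self.x_star <= self.ci_high):
            raise AnalysisError("confidence interval must contain x_star")


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_volumes(cells: pd.DataFrame, n_bins: int = 40, min_occupancy: int = 5) -> pd.DataFrame:
    """Per-bin mean and sample SD of cell volume in equal-width axial bins.

    Returns a BinStats frame with columns x_center, n, mean_V, sd_V.
    Raises :class:`AnalysisError` naming the first empty/underfilled bin.
    """
    if n_bins < 4:
        raise AnalysisError("need at least 4 bins")
    x = cells["x"].to_numpy(dtype=float)
    v = cells["volume_fl"].to_numpy(dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        if n < min_occupancy:
            raise AnalysisError(
                f"bin {b} ([{edges[b]:.3f}, {edges[b + 1]:.3f})) has {n} cells, "
                f"fewer than the minimum occupancy {min_occupancy}"
            )
        vb = v[sel]
        rows.append(
            {
                "x_center": 0.5 * (edges[b] + edges[b + 1]),
                "n": n,
                "mean_V": float(vb.mean()),
                "sd_V": float(vb.std(ddof=1)) if n > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# slope-break detector
# ---------------------------------------------------------------------------

def _weighted_line(u, y, w):
    X = np.column_stack([np.ones_like(u), u]) * w[:, None]
    coef, _, _, _ = np.linalg.lstsq(X, y * w, rcond=None)
    resid = y * w - X @ coef
    return coef, float(resid @ resid)


def _hinge_ssr(u, y, w, right, c):
    """Continuous two-segment fit with the knee pinned at u = c."""
    du = u - c
    X = np.column_stack([np.ones_like(u), du, du * right]) * w[:, None]
    coef, _, _, _ = np.linalg.lstsq(X, y * w, rcond=None)
    resid = y * w - X @ coef
    return float(resid @ resid), (float(coef[1]), float(coef[1] + coef[2]))


def sd_weights(sd: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Inverse sampling error of a sample SD: weight = sqrt(2(n-1)) / sd.

    Without these weights the fit is dominated by the proximal bins, whose
    SDs (and their sampling noise) are an order of magnitude larger.
    """
    sd = np.asarray(sd, dtype=float)
    n = np.asarray(n, dtype=float)
    floor = max(sd[sd > 0].min(), 1e-12) if np.any(sd > 0) else 1.0
    return np.sqrt(2.0 * np.maximum(n - 1.0, 1.0)) / np.maximum(sd, floor)


@dataclass
class TwoSegmentFit:
    """Best continuous two-segment fit over all candidate breakpoints."""

    k: int                      # last index of the left segment
    breakpoint_u: float         # knee position on the abscissa
    ssr: float                  # weighted SSR of the chosen fit
    slopes: tuple[float, float]
    ssr_single: float           # weighted SSR of the one-line fit
    candidates: list = field(repr=False, default_factory=list)


def two_segment_candidates(u, y, w, margin: int = EDGE_MARGIN) -> list:
    """Exhaustive scan over split indices for a continuous two-line fit.

    For each split k (left = points 0..k in axial order, right = the rest)
    two weighted lines are fitted; if their intersection falls inside the
    abscissa gap (u[k], u[k+1]) that is the knee and the fit is
    unconstrained, otherwise the knee is clamped to the nearer gap edge and
    the constrained hinge model is refitted.  Returns tuples
    (k, ssr, knee_u, (slope_left, slope_right)).
    """
    n = u.size
    out = []
    idx = np.arange(n)
    for k in range(margin, n - margin - 1):
        (a1, b1), s1 = _weighted_line(u[: k + 1], y[: k + 1], w[: k + 1])
        (a2, b2), s2 = _weighted_line(u[k + 1 :], y[k + 1 :], w[k + 1 :])
        lo, hi = sorted((u[k], u[k + 1]))
        knee = (a1 - a2) / (b2 - b1) if abs(b2 - b1) > 1e-12 else 0.5 * (lo + hi)
        if lo <= knee <= hi:
            out.append((k, s1 + s2, knee, (float(b1), float(b2))))
        else:
            c = lo if knee < lo else hi
            ssr, slopes = _hinge_ssr(u, y, w, idx > k, c)
            out.append((k, ssr, c, slopes))
    return out


# Plateau rule: the corner point lies on both segments, so splits distal of
# the true corner cost almost nothing and sampling noise only ever drags the
# argmin distally.  Weighted residuals have unit variance, so an SSR excess
# of a few units is indistinguishable from noise; we take the most proximal
# split within PLATEAU_SSR of the minimum.
PLATEAU_SSR = 6.0


def fit_two_segment(u, y, weights=None, margin: int = EDGE_MARGIN,
                    plateau: float = PLATEAU_SSR) -> TwoSegmentFit:
    """Breakpoint search for a continuous two-segment fit, in axial order.

    Points must be ordered along the axis; the split index runs over that
    order (not over sorted u), excluding ``margin`` points at each edge.
    """
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(u) if weights is None else np.asarray(weights, dtype=float)
    n = u.size
    if n < 2 * margin + 4:
        raise AnalysisError(f"need at least {2 * margin + 4} bins for a two-segment fit")
    cand = two_segment_candidates(u, y, w, margin)
    ssr_min = min(c[1] for c in cand)
    k, ssr, knee, slopes = max(
        (c for c in cand if c[1] <= ssr_min + plateau), key=lambda c: c[0]
    )
    _, ssr_single = _weighted_line(u, y, w)
    return TwoSegmentFit(k=k, breakpoint_u=float(knee), ssr=float(ssr),
                         slopes=slopes, ssr_single=ssr_single, candidates=cand)


def detect_transition_slope(
    stats: pd.DataFrame,
    cells: pd.DataFrame | None = None,
    n_bootstrap: int = 0,
    rng: np.random.Generator | None = None,
    n_bins: int | None = None,
) -> TransitionResult:
    """Locate the transition from the slope change of SD vs mean volume.

    Bins are taken in axial order; the breakpoint minimising total squared
    residual of the continuous two-segment fit marks the transition.  If
    ``cells`` is given, a bootstrap over gonad ids yields the confidence
    interval (refitting on each resample); the CI is floored at one bin
    width.  A relative SSR improvement below ``DEGENERATE_IMPROVEMENT`` of
    the single-line fit flags the result degenerate (no clear break).
    """
    stats = stats.sort_values("x_center", ignore_index=True)
    if len(stats) < 8:
        raise AnalysisError("need at least 8 bins to place a breakpoint")
    fit = _fit_stats(stats)
    x_star = _knee_to_x(stats, fit)
    bin_width = float(np.median(np.diff(stats["x_center"])))
    degenerate = fit.ssr_single > 0 and (fit.ssr_single - fit.ssr) / fit.ssr_single < DEGENERATE_IMPROVEMENT

    lo, hi = x_star - bin_width / 2, x_star + bin_width / 2
    if cells is not None and n_bootstrap > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        nb = n_bins if n_bins is not None else len(stats)
        boot = _bootstrap_over_gonads(
            cells,
            n_bootstrap,
            rng,
            lambda tbl: _slope_break_position(tbl, nb),
        )
        if boot.size:
            lo, hi = _basic_bootstrap_ci(x_star, boot)
            lo, hi = _floor_ci(x_star, lo, hi, bin_width)
    return TransitionResult(
        x_star=x_star,
        ci_low=lo,
        ci_high=hi,
        method="slope_break",
        slopes=fit.slopes,
        degenerate=bool(degenerate),
        bin_stats=stats,
    )


def _fit_stats(stats: pd.DataFrame) -> TwoSegmentFit:
    w = sd_weights(stats["sd_V"].to_numpy(), stats["n"].to_numpy())
    return fit_two_segment(stats["mean_V"].to_numpy(), stats["sd_V"].to_numpy(), weights=w)


def _knee_to_x(stats: pd.DataFrame, fit: TwoSegmentFit) -> float:
    """Map the knee from mean-volume space back to an axial position."""
    u = stats["mean_V"].to_numpy()
    xc = stats["x_center"].to_numpy()
    k = fit.k
    lo, hi = u[k], u[k + 1]
    frac = (fit.breakpoint_u - lo) / (hi - lo) if hi != lo else 0.5
    frac = float(np.clip(frac, 0.0, 1.0))
    return float(xc[k] + frac * (xc[k + 1] - xc[k]))


def _slope_break_position(cells: pd.DataFrame, n_bins: int) -> float | None:
    try:
        stats = bin_volumes(cells, n_bins)
    except AnalysisError:
        return None
    return _knee_to_x(stats, _fit_stats(stats))


def _bootstrap_over_gonads(cells, n_boot, rng, estimator) -> np.ndarray:
    ids = cells["gonad_id"].unique()
    groups = {g: df for g, df in cells.groupby("gonad_id")}
    out = []
    for _ in range(n_boot):
        pick = rng.choice(ids, size=ids.size, replace=True)
        tbl = pd.concat([groups[g] for g in pick], ignore_index=True)
        est = estimator(tbl)
        if est is not None:
            out.append(est)
    return np.asarray(out, dtype=float)


def _basic_bootstrap_ci(x_star, boot, conf=0.95):
    """Basic (reflected) bootstrap CI: 2*estimate - opposite quantiles.

    The breakpoint estimator has a small one-sided (distal) bias that the
    plain percentile interval inherits; the reflected interval corrects it
    to first order.
    """
    a = (1.0 - conf) / 2.0
    lo = 2.0 * x_star - float(np.quantile(boot, 1.0 - a))
    hi = 2.0 * x_star - float(np.quantile(boot, a))
    return min(lo, x_star), max(hi, x_star)


def _floor_ci(x_star, lo, hi, bin_width):
    """CI never narrower than one bin width, centred on x_star if needed."""
    if hi - lo < bin_width:
        lo = min(lo, x_star - bin_width / 2)
        hi = max(hi, x_star + bin_width / 2)
    return lo, hi


# ---------------------------------------------------------------------------
# bimodality criteria
# ---------------------------------------------------------------------------

def dip_bimodality(
    values,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Hartigan dip-test p-value (bootstrap uniform null) for a volume sample."""
    values = np.asarray(values, dtype=float)
    if values.size < 20:
        raise AnalysisError("need at least 20 values for the dip test")
    _, p = dip_pvalue(values, n_boot=n_boot, rng=rng)
    return p


def gmm_bimodality(values, random_state: int = 0) -> float:
    """BIC(1 component) - BIC(2 components) on log volumes.

    Positive values favour bimodality.  Degenerate inputs (near-constant
    samples) return 0.0.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 20:
        raise AnalysisError("need at least 20 values for the mixture comparison")
    logv = np.log(values).reshape(-1, 1)
    if np.ptp(logv) < 1e-12:
        return 0.0
    bics = []
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, n_init=3, random_state=random_state, reg_covar=1e-9)
        gm.fit(logv)
        bics.append(gm.bic(logv))
    return float(bics[0] - bics[1])


def detect_transition_bimodality(
    cells: pd.DataFrame,
    method: str = "dip",
    n_bins: int = 40,
    alpha: float = 0.05,
    delta_bic_threshold: float = 10.0,
    n_bootstrap: int = 0,
    dip_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> TransitionResult:
    """First axial bin from which volume distributions stay multimodal.

    Scanning distal to proximal, the transition is placed at the first bin
    whose bimodality criterion fires and keeps firing for all more-proximal
    bins (one isolated non-significant bin is tolerated).  Criteria:
    ``dip`` (p < alpha) or ``gmm`` (delta BIC > threshold).
    """
    if method not in ("dip", "gmm"):
        raise AnalysisError(f"unknown bimodality method: {method!r}")
    if rng is None:
        rng = np.random.default_rng(0)

    x_star = _bimodality_onset(cells, method, n_bins, alpha, delta_bic_threshold, dip_boot, rng)
    bin_width = 1.0 / n_bins
    if x_star is None:
        return TransitionResult(
            x_star=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            method=method, found=False,
        )
    lo, hi = x_star - bin_width / 2, x_star + bin_width / 2
    if n_bootstrap > 0:
        boot = _bootstrap_over_gonads(
            cells,
            n_bootstrap,
            rng,
            lambda tbl: _bimodality_onset(
                tbl, method, n_bins, alpha, delta_bic_threshold, dip_boot, rng
            ),
        )
        if boot.size:
            lo, hi = _basic_bootstrap_ci(x_star, boot)
            lo, hi = _floor_ci(x_star, lo, hi, bin_width)
    return TransitionResult(x_star=x_star, ci_low=lo, ci_high=hi, method=method)


def _bimodality_onset(cells, method, n_bins, alpha, delta_bic_threshold, dip_boot, rng):
    x = cells["x"].to_numpy(dtype=float)
    v = cells["volume_fl"].to_numpy(dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    flags = np.zeros(n_bins, dtype=bool)
    for b in range(n_bins):
        vb = v[idx == b]
        if vb.size < 20:
            continue
        if method == "dip":
            # cached deterministic null table (independent of rng)
            flags[b] = dip_bimodality(vb, n_boot=dip_boot) < alpha
        else:
            flags[b] = gmm_bimodality(vb) > delta_bic_threshold
    # first bin whose flag persists proximally, tolerating isolated
    # non-significant bins (one, or 10% of the tail for long tails); the
    # transition is reported at the bin's distal edge (bimodality holds
    # from this bin on, so the onset lies at or before its left boundary)
    for b in range(n_bins):
        if not flags[b]:
            continue
        tail = flags[b:]
        if tail.sum() >= tail.size - max(1, tail.size // 10):
            return float(edges[b])
    return None
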