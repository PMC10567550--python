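"""AFM force-curve analysis: calibration, contact-point estimation,
spherical-indenter Hertz fitting, curve QC, Young's-modulus maps and region
comparison.

The contact model is the Hertz relation for a sphere of radius R pressed a
depth delta into an elastic half-space with Poisson ratio nu:

    F = 4 E sqrt(R) delta^{3/2} / (3 (1 - nu^2))

Internally everything is SI (m, N, Pa); maps and summaries report kPa. Only
the portion of the curve between configurable fractions of the maximum force
(default 20-80%) enters the fit, which is a least-squares slope of F on
delta^{3/2} through the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ForceCurve",
    "HertzFit",
    "StiffnessMap",
    "RegionComparison",
    "load_curve",
    "force_indentation",
    "estimate_contact_point",
    "hertz_fit",
    "fit_curve",
    "qc_filter",
    "build_stiffness_map",
    "compare_regions",
]

REQUIRED_METADATA = ("k_spring", "sensitivity", "R_tip", "nu")


@dataclass
class ForceCurve:
    """An approach force-distance curve after sensitivity calibration."""

    z: np.ndarray  # piezo extension, m, strictly increasing on approach
    d: np.ndarray  # deflection, m
    k_spring: float  # N/m
    sensitivity: float  # m/V
    R_tip: float  # m
    nu: float = 0.5
    direction: str = "approach"

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.z.shape != self.d.shape:
            raise ValueError("z and d must have the same length")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z must be strictly monotone increasing")
        if self.k_spring <= 0:
            raise ValueError("k_spring must be positive")
        if not 0 <= self.nu <= 0.5:
            raise ValueError("nu must lie in [0, 0.5]")


@dataclass
class HertzFit:
    E: float  # Pa; NaN when rejected
    z0: float
    window: tuple[float, float] = (0.2, 0.8)
    r_squared: float = float("nan")
    n_points: int = 0
    qc_flags: list[str] = field(default_factory=list)
    grid_pos: tuple[int, int] | None = None

    @property
    def accepted(self) -> bool:
        return not self.qc_flags and np.isfinite(self.E) and self.E > 0


@dataclass
class StiffnessMap:
    grid: np.ndarray  # E in Pa, NaN where masked/rejected
    mask: np.ndarray  # True = excluded position
    pixel_pitch: float  # m between measurement points

    def summary(self) -> dict:
        vals = self.grid[~self.mask & np.isfinite(self.grid)]
        return {
            "n_accepted": int(vals.size),
            "median_kPa": float(np.median(vals) / 1e3) if vals.size else float("nan"),
            "mean_kPa": float(np.mean(vals) / 1e3) if vals.size else float("nan"),
        }


@dataclass
class RegionComparison:
    median_a: float
    median_b: float
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------

def load_curve(path) -> ForceCurve:
    """Read a per-curve TSV with a '#'-prefixed metadata header.

    Required keys: k_spring (N/m), sensitivity (m/V), R_tip (m), nu.
    Data columns: piezo position (m), deflection (V); volts are converted to
    metres via the sensitivity.
    """
    path = Path(path)
    meta: dict[str, float] = {}
    zs, vs = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) >= 2:
                    meta[parts[0]] = float(parts[1])
                continue
            a, b = line.split("\t")
            zs.append(float(a))
            vs.append(float(b))
    for key in REQUIRED_METADATA:
        if key not in meta:
            raise ValueError(f"missing required metadata key {key!r} in {path.name}")
    d = np.asarray(vs) * meta["sensitivity"]
    return ForceCurve(
        z=np.asarray(zs), d=d, k_spring=meta["k_spring"],
        sensitivity=meta["sensitivity"], R_tip=meta["R_tip"], nu=meta["nu"],
    )


def force_indentation(curve: ForceCurve, z0: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Force and indentation for a given contact point.

    F = k d; delta = (z - z0) - d (piezo travel minus cantilever bending).
    Returns (F, delta, pre_contact mask); points with delta < 0 are flagged
    pre-contact and excluded from fitting.
    """
    F = curve.k_spring * curve.d
    delta = (curve.z - z0) - curve.d
    pre = delta < 0
    return F, delta, pre


def _linear_hertz_rss(curve: ForceCurve, z0: float, baseline: float) -> tuple[float, float]:
    """RSS of the through-origin fit of F on delta^{3/2} at candidate z0."""
    F = curve.k_spring * (curve.d - baseline)
    delta = (curve.z - z0) - (curve.d - baseline)
    m = delta > 0
    if m.sum() < 3:
        return float(np.sum(F ** 2)), 0.0
    x = delta[m] ** 1.5
    y = F[m]
    denom = float(x @ x)
    slope = float(x @ y) / denom if denom > 0 else 0.0
    slope = max(slope, 0.0)
    rss = float(np.sum((y - slope * x) ** 2)) + float(np.sum(F[~m] ** 2))
    return rss, slope


def estimate_contact_point(
    curve: ForceCurve,
    baseline_fraction: float = 0.2,
    min_improvement: float = 0.5,
) -> tuple[float, float, list[str]]:
    """Contact point by golden-section search on the linearized-Hertz RSS.

    The deflection baseline — the median over the earliest
    ``baseline_fraction`` of the approach (pre-contact on a proper ramp) — is
    removed first; candidate z0 values span the sampled range. Returns
    (z0, baseline, flags); when no candidate explains at least
    ``min_improvement`` of the total force variance over the baseline-only
    model, the flag "no contact" is raised.
    """
    if curve.z.size < 20:
        raise ValueError("need at least 20 samples to estimate a contact point")
    n_base = max(3, int(np.floor(baseline_fraction * curve.z.size)))
    baseline = float(np.median(curve.d[:n_base]))

    lo, hi = float(curve.z[0]), float(curve.z[-2])
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    spacing = float(np.min(np.diff(curve.z)))
    a, b = lo, hi
    c = b - phi * (b - a)
    e = a + phi * (b - a)
    fc, _ = _linear_hertz_rss(curve, c, baseline)
    fe, _ = _linear_hertz_rss(curve, e, baseline)
    # coarse pre-scan to avoid a wrong bracket on non-unimodal RSS
    coarse = np.linspace(lo, hi, 60)
    coarse_rss = [_linear_hertz_rss(curve, z, baseline)[0] for z in coarse]
    i0 = int(np.argmin(coarse_rss))
    a = coarse[max(0, i0 - 2)]
    b = coarse[min(len(coarse) - 1, i0 + 2)]
    c = b - phi * (b - a)
    e = a + phi * (b - a)
    fc, _ = _linear_hertz_rss(curve, c, baseline)
    fe, _ = _linear_hertz_rss(curve, e, baseline)
    while (b - a) > max(1e-13, 1e-5 * spacing):
        if fc < fe:
            b, e, fe = e, c, fc
            c = b - phi * (b - a)
            fc, _ = _linear_hertz_rss(curve, c, baseline)
        else:
            a, c, fc = c, e, fe
            e = a + phi * (b - a)
            fe, _ = _linear_hertz_rss(curve, e, baseline)
    z0 = 0.5 * (a + b)
    rss, slope = _linear_hertz_rss(curve, z0, baseline)
    F = curve.k_spring * (curve.d - baseline)
    rss0 = float(np.sum(F ** 2))
    flags: list[str] = []
    if rss0 <= 0 or (1.0 - rss / rss0) < min_improvement or slope <= 0:
        flags.append("no contact")
    return z0, baseline, flags


def hertz_fit(
    F: np.ndarray,
    delta: np.ndarray,
    R_tip: float,
    nu: float = 0.5,
    window: tuple[float, float] = (0.2, 0.8),
    z0: float = float("nan"),
) -> HertzFit:
    """Least-squares spherical Hertz fit in a force window.

    Points with window[0]*Fmax <= F <= window[1]*Fmax (and delta > 0) are
    kept; the through-origin slope m of F on delta^{3/2} gives
    E = 3 m (1 - nu^2) / (4 sqrt(R_tip)). A non-positive slope is rejected.
    """
    lo, hi = window
    if not (0 < lo < hi < 1):
        raise ValueError("window bounds must satisfy 0 < lower < upper < 1")
    F = np.asarray(F, dtype=float)
    delta = np.asarray(delta, dtype=float)
    fmax = np.max(F) if F.size else 0.0
    sel = (F >= lo * fmax) & (F <= hi * fmax) & (delta > 0)
    n_sel = int(sel.sum())
    if fmax <= 0 or n_sel < 5:
        return HertzFit(E=float("nan"), z0=z0, window=window, n_points=n_sel,
                        qc_flags=["too few points in window"])
    x = delta[sel] ** 1.5
    y = F[sel]
    slope = float(x @ y) / float(x @ x)
    if slope <= 0:
        return HertzFit(E=float("nan"), z0=z0, window=window, n_points=n_sel,
                        qc_flags=["negative slope"])
    E = 3.0 * slope * (1.0 - nu ** 2) / (4.0 * np.sqrt(R_tip))
    resid = y - slope * x
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / tss if tss > 0 else 1.0
    return HertzFit(E=float(E), z0=z0, window=window, r_squared=r2, n_points=n_sel)


def fit_curve(
    curve: ForceCurve,
    window: tuple[float, float] = (0.2, 0.8),
    grid_pos: tuple[int, int] | None = None,
) -> HertzFit:
    """Full per-curve pipeline: contact point, force/indentation, Hertz fit."""
    z0, baseline, flags = estimate_contact_point(curve)
    if flags:
        return HertzFit(E=float("nan"), z0=z0, window=window, qc_flags=flags,
                        grid_pos=grid_pos)
    corrected = ForceCurve(
        z=curve.z, d=curve.d - baseline, k_spring=curve.k_spring,
        sensitivity=curve.sensitivity, R_tip=curve.R_tip, nu=curve.nu,
    )
    F, delta, _pre = force_indentation(corrected, z0)
    fit = hertz_fit(F, delta, curve.R_tip, nu=curve.nu, window=window, z0=z0)
    fit.grid_pos = grid_pos
    return fit


def qc_filter(
    fits: list[HertzFit],
    r2_min: float = 0.9,
    E_max: float = 1e6,
) -> tuple[list[HertzFit], pd.DataFrame]:
    """Reject fits with poor r-squared, a no-contact flag, or an unphysically
    stiff modulus (substrate artefact). Returns (accepted, rejection log)."""
    accepted: list[HertzFit] = []
    log_rows = []
    for i, fit in enumerate(fits):
        reasons = []
        if "no contact" in fit.qc_flags:
            reasons.append("no contact")
        if any(f not in ("no contact",) for f in fit.qc_flags):
            reasons.extend(f for f in fit.qc_flags if f != "no contact")
        if np.isfinite(fit.r_squared) and fit.r_squared < r2_min:
            reasons.append(f"r_squared < {r2_min}")
        if np.isfinite(fit.E) and E_max is not None and fit.E > E_max:
            reasons.append("unphysically stiff")
        if reasons:
            log_rows.append({"curve": i, "reasons": "; ".join(reasons)})
        else:
            accepted.append(fit)
    return accepted, pd.DataFrame(log_rows, columns=["curve", "reasons"])


def build_stiffness_map(
    fits: list[HertzFit],
    shape: tuple[int, int] = (24, 24),
    mask: np.ndarray | None = None,
    scan_size: float = 40e-6,
) -> StiffnessMap:
    """Arrange accepted fits on the measurement grid.

    Each fit carries its (row, col); duplicates are an error. ``mask`` marks
    positions excluded a priori (e.g. hair shaft); rejected or masked cells
    hold NaN.
    """
    grid = np.full(shape, np.nan)
    mask = np.zeros(shape, dtype=bool) if mask is None else np.asarray(mask) != 0
    if mask.shape != shape:
        raise ValueError("mask shape must match the grid shape")
    seen: set[tuple[int, int]] = set()
    for fit in fits:
        if fit.grid_pos is None:
            raise ValueError("fit without grid coordinates")
        r, c = fit.grid_pos
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ValueError(f"grid coordinate ({r}, {c}) outside {shape}")
        if (r, c) in seen:
            raise ValueError(f"duplicate grid coordinate ({r}, {c})")
        seen.add((r, c))
        if fit.accepted and not mask[r, c]:
            grid[r, c] = fit.E
    pitch = scan_size / max(shape[0] - 1, 1)
    return StiffnessMap(grid=grid, mask=mask, pixel_pitch=pitch)


def compare_regions(E_samples_a, E_samples_b) -> RegionComparison:
    """Two-tailed Mann-Whitney U between two modulus samples (exact null
    distribution when both n <= 8, tie-corrected normal otherwise)."""
    a = np.asarray(E_samples_a, dtype=float)
    b = np.asarray(E_samples_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("both samples need at least 3 measurements")
    method = "exact" if (a.size <= 8 and b.size <= 8) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RegionComparison(
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_a=int(a.size),
        n_b=int(b.size),
    )
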