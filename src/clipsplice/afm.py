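"""Hertzian (Sneddon cone) analysis of AFM force-indentation curves.

Each pixel of a quantitative-imaging scan yields a force-distance curve.
After contact-point estimation the approach segment is fitted with the
conical-indenter closed form

    F(delta) = (2/pi) * tan(theta) * E / (1 - nu^2) * delta^2

with Poisson's ratio nu = 0.5 and half-cone angle theta = 22 degrees
fixed, Young's modulus E and a constant force offset free.  Fits are
restricted to indentation depths of 150-500 nm.  Per-colony modulus
samples are taken from the colony centers (height-image mask, eroded),
MAD-normalized for outlier flagging, and compared across groups with
Kruskal-Wallis plus Games-Howell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import stats as _stats

__all__ = [
    "ForceCurve",
    "ForceCurveSet",
    "HertzParams",
    "ModulusMap",
    "hertz_cone_force",
    "estimate_contact_point",
    "fit_modulus",
    "build_modulus_map",
    "colony_center_values",
    "mad_normalize",
    "compare_stiffness",
]

MAD_SCALE = 1.4826  # normal-consistency constant


def _linfit(x: np.ndarray, y: np.ndarray):
    """Closed-form least squares y = slope*x + intercept.

    The design columns here differ by ~13 orders of magnitude (delta^2 in
    m^2 vs. a constant), which makes SVD-based lstsq truncate the slope;
    the closed form has no such scale problem.
    """
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    denom = float(dx @ dx)
    slope = 0.0 if denom == 0 else float(dx @ (y - ym)) / denom
    return slope, float(ym - slope * xm)


@dataclass
class HertzParams:
    E: float  # Young's modulus, Pa
    nu: float = 0.5  # Poisson's ratio
    theta_deg: float = 22.0  # half-cone angle, degrees
    offset: float = 0.0  # contact offset, m

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not 0 <= self.nu <= 0.5:
            raise ValueError("nu must be in [0, 0.5]")
        if not 0 < self.theta_deg < 90:
            raise ValueError("theta must be in (0, 90) degrees")


@dataclass
class ForceCurve:
    z: np.ndarray  # piezo position on approach, m (increasing)
    force: np.ndarray  # N
    pixel: tuple = (0, 0)  # (row, col)
    spring_constant: float = 0.06  # N/m
    sensitivity: float = 50e-9  # m/V

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.z.shape != self.force.shape:
            raise ValueError("z and force must have equal length")


@dataclass
class ForceCurveSet:
    curves: list
    group: str = ""
    grid_shape: tuple = (0, 0)
    truth: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.curves)

    def __len__(self):
        return len(self.curves)

    def write_tsv(self, path) -> None:
        rows = []
        for c in self.curves:
            for z, f in zip(c.z, c.force):
                rows.append((c.pixel[0], c.pixel[1], z, f))
        pd.DataFrame(rows, columns=["pixel_row", "pixel_col", "z_m", "force_N"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read_tsv(cls, path, group: str = "") -> "ForceCurveSet":
        df = pd.read_csv(path, sep="\t")
        curves = []
        for (r, c), sub in df.groupby(["pixel_row", "pixel_col"], sort=True):
            curves.append(ForceCurve(z=sub["z_m"].to_numpy(), force=sub["force_N"].to_numpy(), pixel=(r, c)))
        shape = (df["pixel_row"].max() + 1, df["pixel_col"].max() + 1)
        return cls(curves=curves, group=group, grid_shape=shape)


@dataclass
class ModulusMap:
    modulus_kpa: np.ndarray  # NaN where unfit
    r_squared: np.ndarray
    height: np.ndarray  # m


def hertz_prefactor(nu: float = 0.5, theta_deg: float = 22.0) -> float:
    return (2.0 / np.pi) * np.tan(np.deg2rad(theta_deg)) / (1.0 - nu**2)


def hertz_cone_force(params: HertzParams, delta) -> np.ndarray:
    """Closed-form conical-indenter force at indentation ``delta`` (m)."""
    delta = np.asarray(delta, dtype=float)
    if (delta < 0).any():
        raise ValueError("indentation must be non-negative")
    return hertz_prefactor(params.nu, params.theta_deg) * params.E * delta**2 + params.offset


def estimate_contact_point(
    curve: ForceCurve,
    baseline_fraction: float = 0.3,
    noise_multiple: float = 3.0,
    persistence: int = 5,
):
    """Contact point: threshold crossing, refined by a piecewise fit.

    A coarse upper bound comes first: the baseline level and noise SD
    from the first ``baseline_fraction`` of the approach, and the first
    sample exceeding baseline + ``noise_multiple``*SD for
    ``persistence`` consecutive samples.  For a soft sample the
    quadratic force onset hides below the noise for tens to hundreds of
    nanometres, so the crossing is systematically late; the estimate is
    then refined by fitting the piecewise model

        F(z) = b + c * max(z - z_c, 0)^2

    over candidate contact positions at or before the crossing and
    keeping the least-squares best z_c (the model is linear in (b, c)
    given z_c, so each candidate is one small lstsq).

    Returns (contact index, baseline force).  Raises when the curve
    never exceeds the threshold (no post-contact data).
    """
    f = curve.force
    z = curve.z
    n_base = max(5, int(len(f) * baseline_fraction))
    baseline = float(np.median(f[:n_base]))
    sd = float(np.std(f[:n_base]))
    thresh = baseline + noise_multiple * max(sd, 1e-15)
    above = f > thresh
    run = 0
    coarse = None
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= persistence:
            coarse = i - persistence + 1
            break
    if coarse is None:
        # very soft curves can cross the threshold only near the ramp end;
        # accept if the curve tail is clearly above baseline
        tail = f[-max(10, persistence) :]
        if float(np.mean(tail)) > thresh:
            coarse = int(np.argmax(above))
        else:
            raise ValueError("no post-contact data: curve never exceeds baseline threshold")
    lo = 1
    hi = min(len(f) - 2, coarse + persistence)
    best_idx, best_sse = coarse, np.inf
    # coarse-to-fine scan keeps this O(n) lstsq calls cheap
    for step in (8, 1):
        cand = range(lo, hi + 1, step) if step > 1 else range(
            max(lo, best_idx - 8), min(hi, best_idx + 8) + 1
        )
        for idx in cand:
            d2 = np.clip(z - z[idx], 0.0, None) ** 2
            slope, intercept = _linfit(d2, f)
            sse = float(np.sum((f - slope * d2 - intercept) ** 2))
            if sse < best_sse:
                best_sse, best_idx = sse, idx
    return best_idx, baseline


def fit_modulus(
    curve: ForceCurve,
    nu: float = 0.5,
    theta_deg: float = 22.0,
    delta_range: tuple = (150e-9, 500e-9),
    min_points: int = 10,
) -> dict:
    """Least-squares Hertz-cone fit of one curve.

    The contact point is estimated, indentation re-zeroed there, and the
    fit restricted to ``delta_range``.  E and a constant force offset
    are free; the model is linear in both, so the fit is a direct linear
    least squares on [delta^2, 1].  Returns a dict with ``modulus_kpa``
    (NaN and ``fit_ok=False`` when fewer than ``min_points`` samples fall
    in range), ``r_squared``, ``offset_n``, ``contact_index`` and
    ``contact_z``.
    """
    idx, baseline = estimate_contact_point(curve)
    delta = curve.z - curve.z[idx]
    mask = (delta >= delta_range[0]) & (delta <= delta_range[1])
    out = {
        "modulus_kpa": np.nan,
        "r_squared": np.nan,
        "offset_n": np.nan,
        "contact_index": idx,
        "contact_z": float(curve.z[idx]),
        "fit_ok": False,
    }
    if mask.sum() < min_points:
        return out
    x = hertz_prefactor(nu, theta_deg) * delta[mask] ** 2
    f = curve.force[mask]
    e_pa, offset = _linfit(x, f)
    pred = e_pa * x + offset
    ss_res = float(np.sum((f - pred) ** 2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    out.update(
        modulus_kpa=e_pa / 1e3,
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        offset_n=offset,
        fit_ok=e_pa > 0,
    )
    return out


def build_modulus_map(curve_set: ForceCurveSet, **fit_kwargs) -> ModulusMap:
    """Fit every pixel and assemble modulus / R^2 / height images.

    Height is the sample surface elevation, taken as max(z) - z(contact)
    per pixel (taller sample -> contact earlier in the ramp).  Pixels
    whose fit fails stay NaN.
    """
    shape = curve_set.grid_shape
    mod = np.full(shape, np.nan)
    r2 = np.full(shape, np.nan)
    height = np.full(shape, np.nan)
    for curve in curve_set:
        r, c = curve.pixel
        try:
            res = fit_modulus(curve, **fit_kwargs)
        except ValueError:
            continue
        height[r, c] = float(curve.z.max() - res["contact_z"])
        if res["fit_ok"]:
            mod[r, c] = res["modulus_kpa"]
            r2[r, c] = res["r_squared"]
    return ModulusMap(modulus_kpa=mod, r_squared=r2, height=height)


def colony_center_values(
    modmap: ModulusMap,
    relative_threshold: float = 0.5,
    erode_margin: int = 2,
) -> np.ndarray:
    """Modulus values from the colony center.

    The colony mask is height above ``min + relative_threshold * (max -
    min)``; the center region is that mask eroded ``erode_margin`` times
    (0 keeps the full mask).  A flat height image yields an empty result
    with a warning.
    """
    h = modmap.height
    finite = h[np.isfinite(h)]
    if finite.size == 0 or np.ptp(finite) == 0:
        warnings.warn("flat height image: no colony detected")
        return np.array([])
    cut = finite.min() + relative_threshold * np.ptp(finite)
    mask = np.nan_to_num(h, nan=-np.inf) >= cut
    if erode_margin > 0:
        mask = ndimage.binary_erosion(mask, iterations=erode_margin)
    vals = modmap.modulus_kpa[mask]
    return vals[np.isfinite(vals)]


def mad_normalize(values, outlier_cutoff: float = 3.5) -> pd.DataFrame:
    """Robust z-scores v' = (v - median) / (1.4826 * MAD), with values at
    |v'| > ``outlier_cutoff`` flagged as outliers.

    Raises on constant input (MAD = 0: no scale to normalize by).
    """
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    mad = np.median(np.abs(v - med)) * MAD_SCALE
    if mad == 0:
        raise ValueError("MAD is zero: input has no variation around the median")
    norm = (v - med) / mad
    return pd.DataFrame(
        {"raw": v, "normalized": norm, "outlier": np.abs(norm) > outlier_cutoff}
    )


def compare_stiffness(groups: dict, drop_outliers: bool = True, outlier_cutoff: float = 3.5) -> dict:
    """Kruskal-Wallis omnibus plus Games-Howell pairwise comparison of
    per-group modulus values (kPa).

    With ``drop_outliers`` each group is MAD-normalized first and values
    beyond ``outlier_cutoff`` robust SDs are removed (the study's outlier
    handling for the box plots).
    """
    cleaned = {}
    for label, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if drop_outliers and v.size >= 3 and np.median(np.abs(v - np.median(v))) > 0:
            tab = mad_normalize(v, outlier_cutoff)
            v = tab.loc[~tab["outlier"], "raw"].to_numpy()
        cleaned[label] = v
    kw = _stats.kruskal_wallis(cleaned)
    gh = _stats.games_howell(cleaned)
    return {
        "kruskal": kw,
        "games_howell": gh,
        "group_medians": kw.group_medians,
        "group_quartiles": kw.group_quartiles,
    }
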