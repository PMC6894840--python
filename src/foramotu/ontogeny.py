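"""Raupian coiling parameters from ordered chamber series.

A trochospiral foraminiferal shell is summarized, chamber by chamber,
in the coordinate frame of its coiling axis: the radius r (distance of
the chamber centroid from the axis), the height z (signed distance of
the centroid from the proloculus centroid along the axis) and the angle
alpha between the radii of successive chambers.  From these follow the
Raup coiling parameters

    W = (r_k / r_{k-1}) ** (2*pi / alpha_k)   whorl expansion rate
    T = (z_k - z_{k-1}) / (r_k - r_{k-1})     translation rate
    D = (r_k - L_k/2) / (r_k + L_k/2)         relative axis distance
    S = H_k / L_k                             generating-curve shape

together with the cumulative whorl number and the per-chamber share of
the total inner volume.  The axis is either supplied (as for CT-scanned
specimens) or fitted to the centroids by least squares on the
helicospiral model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "ChamberSeries",
    "CoilingAxis",
    "estimate_axis",
    "raup_parameters",
    "volume_allocation",
    "detect_kummerform",
    "annotate_stages",
]

#: |delta r| below which the translation rate is undefined (um)
DR_TOLERANCE = 1e-3


@dataclass
class ChamberSeries:
    """Ordered chamber geometry of one specimen (1-based from the
    proloculus): volumes (um^3), centroids (um) and H/L extents."""

    specimen_id: str
    data: pd.DataFrame

    def __post_init__(self):
        req = {"chamber_index", "volume_um3", "x_um", "y_um", "z_um",
               "H_um", "L_um"}
        missing = req - set(self.data.columns)
        if missing:
            raise ValueError(f"chamber series missing columns: {missing}")
        self.data = self.data.sort_values("chamber_index").reset_index(drop=True)
        if len(self.data) < 2:
            raise ValueError("need at least 2 chambers")
        if (self.data["volume_um3"] <= 0).any():
            raise ValueError("chamber volumes must be positive")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   specimen_id: str | None = None) -> "ChamberSeries":
        sid = specimen_id or str(frame.get("specimen_id", pd.Series(["?"])).iloc[0])
        return cls(specimen_id=sid, data=frame.drop(
            columns=[c for c in ("specimen_id",) if c in frame.columns]
        ))

    @property
    def centroids(self) -> np.ndarray:
        return self.data[["x_um", "y_um", "z_um"]].to_numpy(float)

    @property
    def volumes(self) -> np.ndarray:
        return self.data["volume_um3"].to_numpy(float)


@dataclass
class CoilingAxis:
    """A point on the coiling axis and its unit direction; heights are
    referenced to the projection of the proloculus centroid."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, float)
        self.direction = np.asarray(self.direction, float)
        norm = np.linalg.norm(self.direction)
        if norm == 0:
            raise ValueError("axis direction must be non-zero")
        self.direction = self.direction / norm


def _cylindrical(centroids: np.ndarray, axis: CoilingAxis):
    """Radii, unwrapped angles and heights in the axis frame."""
    u = axis.direction
    rel = centroids - axis.point
    z = rel @ u
    radial = rel - np.outer(z, u)
    r = np.linalg.norm(radial, axis=1)
    # orthonormal frame perpendicular to the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    theta = np.unwrap(np.arctan2(radial @ e2, radial @ e1))
    return r, theta, z - z[0]


def estimate_axis(series: ChamberSeries, method: str = "fitted",
                  axis: CoilingAxis | None = None) -> CoilingAxis:
    """Coiling axis of a specimen.

    ``provided`` passes a user axis through unchanged; ``fitted``
    minimizes the residuals of the helicospiral model (log-linear radius
    in the winding angle, linear height in radius) over the axis
    direction and its in-plane offset, starting from the principal
    normal of the centroid cloud.
    """
    if method == "provided":
        if axis is None:
            raise ValueError("method='provided' requires an axis")
        return axis
    if method != "fitted":
        raise ValueError(f"unknown method {method!r}")
    pts = series.centroids
    if len(pts) < 4:
        raise ValueError("axis fitting requires at least 4 chambers")
    rel = pts - pts.mean(axis=0)
    _, sv, vt = np.linalg.svd(rel, full_matrices=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("collinear centroids: coiling axis undefined")
    u0 = vt[2]  # normal of the best-fit plane: direction seed

    def frame_of(u):
        helper = np.array([1.0, 0.0, 0.0])
        if abs(u @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(u, helper)
        e1 /= np.linalg.norm(e1)
        return e1, np.cross(u, e1)

    e1, e2 = frame_of(u0)
    # axis-position seed: curvature centers of consecutive centroid
    # triplets (projected into the u0 plane) cluster around the coil pole
    proj = np.stack([pts @ e1, pts @ e2], axis=1)
    centers = []
    for i in range(len(proj) - 2):
        a, b, c = proj[i], proj[i + 1], proj[i + 2]
        det = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1])
                   + c[0] * (a[1] - b[1]))
        if abs(det) < 1e-12:
            continue
        ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1])
              + (c @ c) * (a[1] - b[1])) / det
        uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0])
              + (c @ c) * (b[0] - a[0])) / det
        centers.append((ux, uy))
    c2d = (np.median(np.array(centers), axis=0) if centers
           else proj.mean(axis=0))
    anchor = c2d[0] * e1 + c2d[1] * e2 + (pts.mean(axis=0) @ u0) * u0
    spacing = float(np.median(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    scale = float(np.linalg.norm(rel, axis=1).mean())
    k = np.arange(len(pts), dtype=float)
    K = np.vstack([np.ones_like(k), k, k * k]).T

    def assemble(params):
        a, b, ox, oy = params
        u = u0 + a * e1 + b * e2
        u = u / np.linalg.norm(u)
        f1, f2 = frame_of(u)
        return CoilingAxis(point=anchor + ox * f1 + oy * f2, direction=u)

    def residuals(params):
        ax = assemble(params)
        r, _, z = _cylindrical(pts, ax)
        if (r <= 1e-12 * max(scale, 1.0)).any():
            return np.full(2 * len(pts), 1e3 * max(scale, 1.0))
        # log-spiral growth: log r smooth (quadratic) in chamber rank;
        # trochospiral translation: z linear in r
        coef, *_ = np.linalg.lstsq(K, np.log(r), rcond=None)
        res_r = (np.log(r) - K @ coef) * scale
        B = np.vstack([np.ones_like(r), r]).T
        coefz, *_ = np.linalg.lstsq(B, z, rcond=None)
        res_z = z - B @ coefz
        return np.concatenate([res_r, res_z])

    # escalating multi-start: the cost surface has local minima when the
    # trial axis threads the spiral at the wrong spot or the plane
    # normal is badly tilted; stop at the first (noise-free) optimum
    good_enough = (1e-7 * max(scale, 1.0)) ** 2
    starts = [(0.0, 0.0, 0.0, 0.0)]
    starts += [(0.0, 0.0, ox, oy)
               for ox in (-2.0, 2.0) for oy in (-2.0, 2.0)]
    starts += [(a0, b0, ox, oy)
               for a0 in (-0.7, -0.35, 0.0, 0.35, 0.7)
               for b0 in (-0.7, -0.35, 0.0, 0.35, 0.7)
               if (a0, b0) != (0.0, 0.0)
               for ox in (-2.0, 0.0, 2.0) for oy in (-2.0, 0.0, 2.0)]
    best = None
    for a0, b0, ox0, oy0 in starts:
        sol = least_squares(
            residuals, x0=[a0, b0, ox0 * spacing, oy0 * spacing],
            method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < good_enough:
            break
    axis = assemble(best.x)
    # orient the axis along increasing z of the shell
    _, _, z = _cylindrical(pts, axis)
    if z[-1] < 0:
        axis = CoilingAxis(point=axis.point, direction=-axis.direction)
    return axis


def raup_parameters(series: ChamberSeries, axis: CoilingAxis) -> pd.DataFrame:
    """Per-chamber Raup trajectory in the axis frame.

    Returns one row per chamber with r, z, alpha (radians, positive in
    the coiling direction), whorl number, W, T, D, S, the per-chamber
    volume fraction and its cumulative sum.  The first chamber has no
    alpha/W/T; T is undefined (NaN, flagged) when |delta r| falls below
    1e-3 um.
    """
    pts = series.centroids
    r, theta, z = _cylindrical(pts, axis)
    n = len(pts)
    dtheta = np.diff(theta)
    # dominant coiling direction; report alpha positive along it
    direction = 1.0 if np.sum(np.sign(dtheta)) >= 0 else -1.0
    alpha = np.concatenate([[np.nan], dtheta * direction])
    alpha_wrapped = np.where(
        np.isnan(alpha), np.nan, np.mod(alpha, 2.0 * math.pi)
    )
    alpha_wrapped[alpha_wrapped == 0.0] = 2.0 * math.pi
    whorl = np.concatenate([[0.0], np.cumsum(alpha_wrapped[1:]) / (2 * math.pi)])

    W = np.full(n, np.nan)
    T = np.full(n, np.nan)
    t_undefined = np.zeros(n, bool)
    for k in range(1, n):
        if r[k - 1] > 0 and r[k] > 0 and alpha_wrapped[k] > 0:
            W[k] = (r[k] / r[k - 1]) ** (2.0 * math.pi / alpha_wrapped[k])
        dr = r[k] - r[k - 1]
        if abs(dr) > DR_TOLERANCE:
            T[k] = (z[k] - z[k - 1]) / dr
        else:
            t_undefined[k] = True

    L = series.data["L_um"].to_numpy(float)
    H = series.data["H_um"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        D = (r - L / 2.0) / (r + L / 2.0)
        S = np.where(L > 0, H / L, np.nan)
    if (D < 0).any():
        logger.warning(
            "raup_parameters(%s): %d chambers overlap the axis; D clamped "
            "to 0", series.specimen_id, int((D < 0).sum())
        )
        D = np.clip(D, 0.0, None)

    frac = series.volumes / series.volumes.sum()
    return pd.DataFrame(
        {
            "chamber_index": series.data["chamber_index"].to_numpy(),
            "r_um": r,
            "z_um": z,
            "alpha_rad": alpha_wrapped,
            "alpha_deg": np.degrees(alpha_wrapped),
            "whorl_number": whorl,
            "W": W,
            "T": T,
            "T_undefined": t_undefined,
            "D": D,
            "S": S,
            "volume_fraction": frac,
            "cumulative_volume_fraction": np.cumsum(frac),
            "coiling_direction": "dextral" if direction > 0 else "sinistral",
        }
    )


def volume_allocation(series: ChamberSeries) -> dict:
    """Per-chamber volume fractions and terminal allocation statistics.

    The tail statistics report the percentage of the total inner volume
    held by the last one, two and three chambers.
    """
    v = series.volumes
    frac = v / v.sum()
    return {
        "fractions": frac,
        "last1_pct": 100.0 * frac[-1:].sum(),
        "last2_pct": 100.0 * frac[-2:].sum(),
        "last3_pct": 100.0 * frac[-3:].sum(),
    }


def detect_kummerform(series: ChamberSeries) -> tuple[bool, float]:
    """Diminutive (kummerform) final chamber: strictly smaller than the
    penultimate.  Returns (flag, final/penultimate volume ratio)."""
    v = series.volumes
    ratio = float(v[-1] / v[-2])
    return v[-1] < v[-2], ratio


def _growth_changepoint(series: ChamberSeries) -> int | None:
    """Single change point in the log-volume growth sequence.

    Fits two constant growth rates to log-volume increments split at
    every candidate chamber and returns the 1-based chamber index
    starting the second regime (minimum SSE), or None for <6 chambers.
    """
    logv = np.log(series.volumes)
    inc = np.diff(logv)
    if inc.size < 5:
        return None
    best = None
    for cut in range(2, inc.size - 1):
        left, right = inc[:cut], inc[cut:]
        sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if best is None or sse < best[0]:
            best = (sse, cut)
    return best[1] + 1  # increment index -> chamber index (1-based)


DEFAULT_STAGE_RULES = {
    # seeded from the printed ontogenetic-stage ranges: the juvenile
    # stage spans ~8-13 chambers, the neanic ~12-16
    "juvenile_last_chamber": 10,
    "neanic_last_chamber": 14,
    "changepoint_juvenile": False,
}


def annotate_stages(
    series: ChamberSeries,
    trajectory: pd.DataFrame | None = None,
    rules: dict | None = None,
) -> list[str]:
    """Per-chamber ontogenetic stage labels.

    Heuristic annotation: chamber 1 is always prolocular; the juvenile/
    neanic boundary comes from the rule table (or from a change point in
    the volume growth when ``changepoint_juvenile`` is set); a
    kummerform final chamber is terminal.  Labels are contiguous and
    ordered prolocular < juvenile < neanic < adult < terminal.
    """
    rules = {**DEFAULT_STAGE_RULES, **(rules or {})}
    n = len(series.data)
    juv_end = rules["juvenile_last_chamber"]
    if rules.get("changepoint_juvenile"):
        cp = _growth_changepoint(series)
        if cp is not None:
            juv_end = cp
    nean_end = rules["neanic_last_chamber"]
    if not 1 < juv_end < nean_end:
        raise ValueError(
            f"conflicting stage rules: juvenile ends at {juv_end}, "
            f"neanic at {nean_end}"
        )
    kummer, _ = detect_kummerform(series)
    labels = []
    for k in range(1, n + 1):
        if k == 1:
            labels.append("prolocular")
        elif k <= juv_end:
            labels.append("juvenile")
        elif k <= nean_end:
            labels.append("neanic")
        else:
            labels.append("adult")
    if kummer:
        labels[-1] = "terminal"
    return labels
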