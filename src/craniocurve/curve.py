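"""The polar "sinusoid curve" of a skull outline.

Each outline point is described by its distance from the cross-section
centroid and its angle from the occipital start direction, swept so the
patient's right side comes first.  Sampling at one ray per integer degree
gives a 360-sample radius profile; dividing by the mean radius makes the
curve size-independent (1.0 = the mean radius), which is what makes curves
of differently aged children comparable.

For a typical (star-shaped) skull outline every ray crosses the boundary
exactly once; for pathological polygons the outermost crossing is used and
a warning is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .errors import CenterOutside, InvalidRadius
from .outline import CurveFrame, Outline

__all__ = ["PolarCurve", "polar_sample", "normalize", "compute_curve"]


@dataclass(frozen=True)
class PolarCurve:
    """Normalized 360-sample polar radius profile.

    ``radii_rel[theta]`` is the relative radius at integer degree ``theta``
    (0..359) measured from the occipital start, sweeping past the patient's
    right first.  ``mean(radii_rel) == 1`` by construction.
    """

    radii_rel: np.ndarray
    radii_abs: np.ndarray
    mean_radius: float
    frame: CurveFrame | None = None

    def __post_init__(self):
        rel = np.asarray(self.radii_rel, dtype=float)
        absr = np.asarray(self.radii_abs, dtype=float)
        object.__setattr__(self, "radii_rel", rel)
        object.__setattr__(self, "radii_abs", absr)

    @property
    def n_samples(self) -> int:
        return len(self.radii_rel)

    @property
    def theta_deg(self) -> np.ndarray:
        return np.arange(self.n_samples) * (360.0 / self.n_samples)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "theta_deg": self.theta_deg.astype(int)
                if self.n_samples == 360
                else self.theta_deg,
                "radius_rel": self.radii_rel,
                "radius_mm": self.radii_abs,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PolarCurve":
        df = pd.read_csv(path)
        absr = df["radius_mm"].to_numpy(dtype=float)
        rel = df["radius_rel"].to_numpy(dtype=float)
        return cls(radii_rel=rel, radii_abs=absr, mean_radius=float(absr.mean()))

    def plot(self, path: str | Path, title: str | None = None) -> None:
        """Write a PNG of relative radius versus angle (x-axis 0-360 deg)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 3.5))
        ax.plot(self.theta_deg, self.radii_rel, lw=1.2)
        ax.axhline(1.0, color="grey", lw=0.6, ls="--")
        ax.set_xlim(0, 360)
        ax.set_xticks(range(0, 361, 45))
        ax.set_xlabel("angle from occipital start (deg)")
        ax.set_ylabel("relative radius")
        if title:
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def polar_sample(outline: Outline, frame: CurveFrame, n_samples: int = 360) -> np.ndarray:
    """Absolute radii (mm) of ``n_samples`` equiangular rays from the centre.

    The radius at angle theta is the distance from the centre to the
    outermost exact ray/segment intersection with the polygon boundary; no
    interpolation between polygon vertices is introduced beyond the segment
    geometry itself.
    """
    if not outline.polygon.contains(Point(frame.center)):
        raise CenterOutside("polar centre lies outside the outline polygon")

    theta = np.arange(n_samples) * (2.0 * np.pi / n_samples) * frame.right_first_sign
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    sd = frame.start_direction
    # rotate the start direction by each angle (CCW for positive theta)
    dirs = np.column_stack(
        [sd[0] * cos_t - sd[1] * sin_t, sd[0] * sin_t + sd[1] * cos_t]
    )  # (n, 2)

    p = outline.vertices
    q = np.roll(p, -1, axis=0)
    edge = q - p  # (m, 2)
    rel = p - frame.center  # (m, 2)

    # solve center + t*dir = p + w*edge for each (ray, edge) pair
    denom = dirs[:, 0, None] * edge[None, :, 1] - dirs[:, 1, None] * edge[None, :, 0]
    ok = np.abs(denom) > 1e-15
    safe = np.where(ok, denom, 1.0)
    # t = cross(rel, edge) / cross(dir, edge); w = cross(rel, dir) / cross(dir, edge)
    w = (rel[None, :, 0] * dirs[:, 1, None] - rel[None, :, 1] * dirs[:, 0, None]) / safe
    t = (rel[None, :, 0] * edge[None, :, 1] - rel[None, :, 1] * edge[None, :, 0]) / safe
    # the w tolerance keeps crossings that pass exactly through a polygon
    # vertex from being lost to rounding on both adjacent edges
    hit = ok & (w >= -1e-9) & (w < 1.0 + 1e-9) & (t > 0.0)

    if not np.all(hit.any(axis=1)):
        raise CenterOutside("a ray found no boundary intersection")
    radii = np.where(hit, t, -np.inf).max(axis=1)
    t_near = np.where(hit, t, np.inf).min(axis=1)
    if np.any(radii - t_near > 1e-6 * np.maximum(radii, 1.0)):
        warnings.warn(
            "outline is not star-shaped about the centroid; "
            "using the outermost ray intersection",
            RuntimeWarning,
            stacklevel=2,
        )
    return radii


def normalize(radii_abs: np.ndarray, frame: CurveFrame | None = None) -> PolarCurve:
    """Divide absolute radii by their arithmetic mean.

    The resulting relative curve has mean exactly 1, making it invariant to
    isotropic scaling of the skull (and hence to age-related size).
    """
    radii_abs = np.asarray(radii_abs, dtype=float)
    if np.any(radii_abs <= 0) or not np.all(np.isfinite(radii_abs)):
        raise InvalidRadius("all radii must be positive and finite")
    mean = float(radii_abs.mean())
    return PolarCurve(
        radii_rel=radii_abs / mean, radii_abs=radii_abs, mean_radius=mean, frame=frame
    )


def compute_curve(outline: Outline, frame: CurveFrame, n_samples: int = 360) -> PolarCurve:
    """Convenience: sample and normalize in one step."""
    return normalize(polar_sample(outline, frame, n_samples=n_samples), frame=frame)
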