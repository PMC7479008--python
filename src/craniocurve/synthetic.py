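"""Synthetic head phantoms for the five synostosis phenotypes and controls.

Real validation data for this pipeline are CT-derived head surfaces, which
cannot ship with a software package.  The generator instead produces
closed, watertight superellipsoid-based head surfaces whose horizontal
cross-sections realise the characteristic phenotype regimes:

* **control** -- mildly elongated oval (length/width about 1.3 at slice
  level), equal forehead and occiput peaks;
* **scaphocephaly** -- long and narrow (length/width >= 1.45), occiput the
  most prominent peak;
* **brachycephaly** -- short and wide (length/width <= 1.22) with a broad
  flattened forehead and equal-height peaks;
* **trigonocephaly** -- pointed (keel-shaped) forehead from a shrunken
  anterior superellipse exponent;
* **anterior plagiocephaly** -- unilateral frontal flattening realised as
  an apex skew: the frontal prominence is re-centred >= 15 degrees toward
  the affected side and the contralateral anterior quadrant is flattened,
  reproducing the laterally shifted forehead peak of unilateral coronal
  synostosis.

Landmarks (exocanthion and porion pairs) are placed analytically on the
surface at base-plane level, so the same phantoms serve landmark-jitter
reliability experiments.  All randomness is seeded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .errors import SpecError
from .geometry import LandmarkSet

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "generate_cohort", "PHENOTYPE_SPECS"]

#: Vertical semi-axis (mm) of the head ellipsoid and height of its centre
#: above the base plane; the analysis slice at +40 mm then sits well below
#: the vertex, the landmarks at 0 mm well above the lower pole.
VERTICAL_SEMI_AXIS = 90.0
CENTER_HEIGHT = 30.0

#: Azimuths (deg, from anterior, +left) of the surface landmarks.
EX_AZIMUTH_DEG = 40.0
PO_AZIMUTH_DEG = 105.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one phantom head.

    Lengths in mm, angles in degrees, amplitudes as fractions of the local
    radius.  ``apex_shift_deg`` is positive toward the patient's left;
    ``flatten_side`` names the affected (flattened) side of an anterior
    plagiocephaly and drives the sign of the skew.
    """

    label: str = "control"
    ap_front: float = 78.0  # anterior semi-axis (mm)
    ap_back: float = 78.0  # posterior semi-axis (mm)
    lateral: float = 60.0  # lateral semi-axis (mm)
    exponent_front: float = 2.0  # superellipse exponent, anterior half
    exponent_back: float = 2.15  # posterior half
    bump_amp: float = 0.0  # frontal prominence amplitude
    bump_sigma_deg: float = 28.0
    apex_anchor_amp: float = 0.0  # small narrow bump pinning the frontal apex
    apex_anchor_sigma_deg: float = 14.0
    occiput_bump_amp: float = 0.0  # occipital prominence amplitude
    occiput_bump_sigma_deg: float = 20.0
    flatten_amp: float = 0.0  # contralateral anterior flattening
    flatten_sigma_deg: float = 34.0
    flatten_side: str | None = None  # 'right' or 'left' (affected side)
    apex_shift_deg: float = 0.0  # unsigned magnitude of the apex skew
    noise_sd: float = 0.0  # vertex-wise radial Gaussian noise (mm)
    seed: int = 0
    subdivisions: int = 5  # icosphere resolution

    def __post_init__(self):
        if min(self.ap_front, self.ap_back, self.lateral) <= 0:
            raise SpecError("semi-axes must be positive")
        if min(self.exponent_front, self.exponent_back) <= 0.5:
            raise SpecError("superellipse exponents must exceed 0.5")
        if self.noise_sd < 0:
            raise SpecError("noise SD must be >= 0")
        if self.flatten_side not in (None, "left", "right"):
            raise SpecError(f"flatten_side must be left/right/None, got {self.flatten_side!r}")
        if self.subdivisions < 2:
            raise SpecError("subdivisions must be >= 2")


@dataclass(frozen=True)
class Phantom:
    """A generated head: surface mesh, landmarks, and the ground truth."""

    mesh: trimesh.Trimesh
    landmarks: LandmarkSet
    spec: PhantomSpec
    subject_id: str = "phantom"

    @property
    def label(self) -> str:
        return self.spec.label


def cross_section_radius(spec: PhantomSpec, psi: np.ndarray) -> np.ndarray:
    """Planar radius (mm) of the phantom cross-section at azimuth ``psi``.

    ``psi`` is measured in radians from the anterior direction, positive
    toward the patient's left.  This analytic profile is what every
    horizontal slice of the phantom realises (scaled by height), so it
    doubles as the ground-truth oracle for slice-based tests.
    """
    psi = np.asarray(psi, dtype=float)
    c, s = np.cos(psi), np.sin(psi)
    front = c > 0
    a = np.where(front, spec.ap_front, spec.ap_back)
    p = np.where(front, spec.exponent_front, spec.exponent_back)
    r = (np.abs(c / a) ** p + np.abs(s / spec.lateral) ** p) ** (-1.0 / p)

    # signed skew: positive apex shift toward the patient's left (+psi)
    sign = 0.0
    if spec.flatten_side == "right":
        sign = -1.0
    elif spec.flatten_side == "left":
        sign = 1.0
    if spec.bump_amp != 0.0:
        centre = np.deg2rad(sign * spec.apex_shift_deg)
        sig = np.deg2rad(spec.bump_sigma_deg)
        r = r * (1.0 + spec.bump_amp * np.exp(-0.5 * ((psi - centre) / sig) ** 2))
    if spec.apex_anchor_amp != 0.0:
        # a subtle, narrow frontal eminence that keeps the apex well defined
        # even when the broad forehead is nearly flat-topped
        centre = np.deg2rad(sign * spec.apex_shift_deg)
        sig = np.deg2rad(spec.apex_anchor_sigma_deg)
        r = r * (1.0 + spec.apex_anchor_amp * np.exp(-0.5 * ((psi - centre) / sig) ** 2))
    if spec.occiput_bump_amp != 0.0:
        sig = np.deg2rad(spec.occiput_bump_sigma_deg)
        dpsi = np.arctan2(np.sin(psi - np.pi), np.cos(psi - np.pi))
        r = r * (1.0 + spec.occiput_bump_amp * np.exp(-0.5 * (dpsi / sig) ** 2))
    if spec.flatten_amp != 0.0 and sign != 0.0:
        # flatten the anterior quadrant opposite the skew
        centre = np.deg2rad(-sign * 45.0)
        sig = np.deg2rad(spec.flatten_sigma_deg)
        r = r * (1.0 - spec.flatten_amp * np.exp(-0.5 * ((psi - centre) / sig) ** 2))
    return r


def _surface_point(spec: PhantomSpec, psi_deg: float, z: float) -> np.ndarray:
    """Analytic surface point at azimuth ``psi_deg`` and height ``z`` mm."""
    dz = (z - CENTER_HEIGHT) / VERTICAL_SEMI_AXIS
    if not -1 < dz < 1:
        raise SpecError(f"height {z} outside the phantom")
    s = float(np.sqrt(1.0 - dz * dz))
    psi = np.deg2rad(psi_deg)
    r = float(cross_section_radius(spec, np.array(psi))) * s
    return np.array([r * np.cos(psi), r * np.sin(psi), z])


def generate_phantom(spec: PhantomSpec, subject_id: str = "phantom") -> Phantom:
    """Build the phantom surface and its landmark set.

    The mesh is an icosphere warped so that every horizontal cross-section
    is the (scaled) analytic profile of :func:`cross_section_radius`;
    vertex-wise radial Gaussian noise (seeded) is added last.  Landmarks
    sit on the noise-free surface at base-plane height: exocanthia at
    +/- 40 degrees anterior azimuth, poria at +/- 105 degrees.
    """
    rng = np.random.default_rng(spec.seed)
    base = trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=1.0)
    d = base.vertices  # unit vectors
    psi = np.arctan2(d[:, 1], d[:, 0])
    r2 = cross_section_radius(spec, psi)
    verts = np.column_stack(
        [d[:, 0] * r2, d[:, 1] * r2, d[:, 2] * VERTICAL_SEMI_AXIS + CENTER_HEIGHT]
    )
    if spec.noise_sd > 0:
        # CT-derived surfaces are smooth at the centimetre scale: model the
        # per-subject surface error as a random low-order harmonic field in
        # azimuth (RMS = noise_sd), modulated along the height, plus a small
        # white-vertex component for mesh-level roughness.
        n_harm = 6
        amps = rng.normal(0.0, spec.noise_sd / np.sqrt(n_harm), size=(n_harm, 2))
        slope = rng.normal(0.0, 0.5)
        field = np.zeros(len(d))
        for k in range(1, n_harm + 1):
            field += amps[k - 1, 0] * np.cos(k * psi) + amps[k - 1, 1] * np.sin(k * psi)
        field *= 1.0 + slope * d[:, 2]
        field += rng.normal(0.0, 0.2 * spec.noise_sd, size=len(d))
        verts = verts + d * field[:, None]
    mesh = trimesh.Trimesh(vertices=verts, faces=base.faces, process=False)

    lm = LandmarkSet(
        ex_left=_surface_point(spec, +EX_AZIMUTH_DEG, 0.0),
        ex_right=_surface_point(spec, -EX_AZIMUTH_DEG, 0.0),
        po_left=_surface_point(spec, +PO_AZIMUTH_DEG, 0.0),
        po_right=_surface_point(spec, -PO_AZIMUTH_DEG, 0.0),
    )
    return Phantom(mesh=mesh, landmarks=lm, spec=spec, subject_id=subject_id)


#: Noise-free base specifications per phenotype.  Slice-level length/width
#: regimes: control ~1.30, scaphocephaly >= 1.45, brachycephaly <= 1.22,
#: trigonocephaly/plagiocephaly mildly elongated; the plagiocephalic apex
#: skew exceeds the 12-degree centred-peak band.
PHENOTYPE_SPECS: dict[str, PhantomSpec] = {
    "control": PhantomSpec(
        label="control", ap_front=76.0, ap_back=76.0, lateral=61.0,
        exponent_front=2.3, exponent_back=2.15,
        bump_amp=0.10, bump_sigma_deg=55.0,
        apex_anchor_amp=0.025, apex_anchor_sigma_deg=14.0,
    ),
    "scaphocephaly": PhantomSpec(
        label="scaphocephaly", ap_front=84.0, ap_back=92.0, lateral=58.0,
        exponent_front=2.0, exponent_back=2.1,
        bump_amp=0.06, bump_sigma_deg=50.0,
    ),
    "trigonocephaly": PhantomSpec(
        label="trigonocephaly", ap_front=80.0, ap_back=74.0, lateral=62.0,
        exponent_front=1.7, exponent_back=2.15,
    ),
    "brachycephaly": PhantomSpec(
        label="brachycephaly", ap_front=65.5, ap_back=66.5, lateral=61.0,
        exponent_front=2.0, exponent_back=2.15,
        bump_amp=0.11, bump_sigma_deg=62.0,
        apex_anchor_amp=0.02, apex_anchor_sigma_deg=14.0,
        occiput_bump_amp=0.04, occiput_bump_sigma_deg=18.0,
    ),
    "plagio_anterior_right": PhantomSpec(
        label="plagio_anterior_right", ap_front=75.0, ap_back=74.0, lateral=61.0,
        exponent_front=2.0, exponent_back=2.15,
        bump_amp=0.08, flatten_amp=0.08, flatten_side="right", apex_shift_deg=38.0,
    ),
    "plagio_anterior_left": PhantomSpec(
        label="plagio_anterior_left", ap_front=75.0, ap_back=74.0, lateral=61.0,
        exponent_front=2.0, exponent_back=2.15,
        bump_amp=0.08, flatten_amp=0.08, flatten_side="left", apex_shift_deg=38.0,
    ),
}

#: Per-subject multiplicative jitter SD of the shape parameters.  Controls
#: vary widely (unrestricted normal growth); synostotic skulls are
#: stereotyped by the fused suture, hence narrower variation.
JITTER_SD = {"control": 0.025, "synostosis": 0.009}


def generate_cohort(
    n_per_group: int,
    seed: int = 0,
    labels: tuple[str, ...] | None = None,
    noise_sd: float = 0.5,
    base_specs: dict[str, PhantomSpec] | None = None,
) -> list[Phantom]:
    """Seeded cohort of ``n_per_group`` phantoms per phenotype.

    Each subject perturbs the base spec's semi-axes (and, for
    plagiocephaly, the skew angle) with group-dependent multiplicative
    jitter; the same seed reproduces the cohort bit for bit.
    """
    if n_per_group < 0:
        raise SpecError("n_per_group must be >= 0")
    specs = base_specs or PHENOTYPE_SPECS
    labels = labels or tuple(specs)
    rng = np.random.default_rng(seed)
    cohort: list[Phantom] = []
    for label in labels:
        base = specs[label]
        sd = JITTER_SD["control" if label == "control" else "synostosis"]
        for i in range(n_per_group):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            jit = rng.normal(1.0, sd, size=3)
            kwargs = dict(
                ap_front=base.ap_front * jit[0],
                ap_back=base.ap_back * jit[1],
                lateral=base.lateral * jit[2],
                noise_sd=noise_sd,
                seed=sub_seed,
            )
            if base.flatten_side is not None:
                kwargs["apex_shift_deg"] = base.apex_shift_deg * float(
                    rng.normal(1.0, 0.08)
                )
            spec = dataclasses.replace(base, **kwargs)
            cohort.append(generate_phantom(spec, subject_id=f"{label}_{i:02d}"))
    return cohort


def cohort_manifest(cohort: list[Phantom]) -> pd.DataFrame:
    """One row per subject: id, label, seed and the spec parameters."""
    rows = []
    for ph in cohort:
        row = {"subject_id": ph.subject_id, "label": ph.label}
        row.update({k: v for k, v in dataclasses.asdict(ph.spec).items() if k != "label"})
        rows.append(row)
    return pd.DataFrame(rows)
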