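"""Procedural cardiac CCTA phantoms with AAOCA anatomy.

The generator builds a simplified chest from analytic primitives in a
canonical patient frame (+x right, +y anterior, +z superior, mm): a soft
tissue body, lungs, an LV cavity with a myocardial shell, an aortic root +
ascending aorta, a pulmonary artery, and two coronary arteries rasterized as
spline tubes.  The anomalous coronary's ostium sinus and proximal course
realize the clinical AAOCA taxonomy: pre-pulmonic, retro-aortic and
high take-off courses are low anatomical risk; inter-arterial and
sub-pulmonic courses are high risk.

Closed-form geometry means every downstream stage (root-point localization,
cropping, course classification) has an exact oracle.  The phantoms are a
deliberately schematic stand-in for clinical CCTA: their realism is not
validated against patient images.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import interpolate, ndimage
from scipy.spatial import cKDTree

from .volume import ImageVolume, Label, LabelMap, save_volume

__all__ = [
    "PhantomConfig",
    "CaseRecord",
    "COURSES",
    "COURSE_RISK",
    "generate_phantom",
    "generate_cohort",
    "generate_cohort_records",
    "simulate_phases",
    "parse_mix_key",
    "largest_remainder_counts",
]

COURSES = ("normal", "interarterial", "prepulmonic", "retroaortic", "high_takeoff", "subpulmonic")

#: Anatomical-risk label implied by each anomalous course.
COURSE_RISK = {
    "interarterial": "high",
    "subpulmonic": "high",
    "prepulmonic": "low",
    "retroaortic": "low",
    "high_takeoff": "low",
}

DEFAULT_TISSUE_HU = {
    "air": -1000.0,
    "lung": -800.0,
    "soft_tissue": 40.0,
    "myocardium": 80.0,
    "blood_pool_contrast": 400.0,
    "pa_blood": 150.0,
    "coronary_contrast": 350.0,
}


@dataclass
class PhantomConfig:
    """Parameters of one synthetic case.

    ``anomaly_class`` is ``normal``, ``R-AAOCA`` (anomalous right coronary)
    or ``L-AAOCA`` (anomalous left coronary); ``course`` must be ``normal``
    exactly when the class is normal.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 96)
    spacing_mm: tuple[float, float, float] = (1.25, 1.25, 1.25)
    tissue_hu: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_HU))
    noise_sigma_hu: float = 20.0
    coronary_radius_mm: float = 2.0
    anomaly_class: str = "normal"
    course: str = "normal"
    high_takeoff_mm: float = 12.0
    n_phases: int = 1
    phase_amplitude_mm: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 8 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be three axes of >= 8 voxels, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be strictly positive, got {self.spacing_mm}")
        if self.anomaly_class not in ("normal", "R-AAOCA", "L-AAOCA"):
            raise ValueError(f"unknown anomaly_class {self.anomaly_class!r}")
        if self.course not in COURSES:
            raise ValueError(f"unknown course {self.course!r}")
        if (self.course == "normal") != (self.anomaly_class == "normal"):
            raise ValueError("course must be 'normal' exactly when anomaly_class is 'normal'")
        if self.noise_sigma_hu < 0:
            raise ValueError("noise_sigma_hu must be >= 0")
        if self.coronary_radius_mm <= 0:
            raise ValueError("coronary_radius_mm must be > 0")
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")

    @property
    def risk(self) -> str | None:
        return None if self.course == "normal" else COURSE_RISK[self.course]


@dataclass
class CaseRecord:
    """One synthetic patient: phase volumes, ground-truth labels, metadata."""

    case_id: str
    volumes: list
    label_map: LabelMap
    y_anomaly: int
    y_origin: str | None = None
    y_risk: str | None = None
    group: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.y_anomaly not in (0, 1):
            raise ValueError("y_anomaly must be 0 or 1")
        if self.y_anomaly == 0 and (self.y_origin is not None or self.y_risk is not None):
            raise ValueError("origin/risk labels must be absent for normal cases")
        if self.y_anomaly == 1 and (self.y_origin is None or self.y_risk is None):
            raise ValueError("origin/risk labels required for anomalous cases")
        shapes = {v.shape for v in self.volumes}
        spacings = {v.spacing for v in self.volumes}
        if len(shapes) > 1 or len(spacings) > 1:
            raise ValueError("all phase volumes of a case must share grid shape and spacing")


# ---------------------------------------------------------------------------
# Fixed anatomy (mm, canonical frame, aorta axis through the origin)
# ---------------------------------------------------------------------------

AORTA_RADIUS = 13.0
AORTA_Z = (-5.0, 50.0)
ROOT_CENTER = np.array([0.0, 0.0, -12.0])
ROOT_RADIUS = 15.0
SINUS_Z = 0.0

PA_CENTER_XY = np.array([-14.0, 22.0])
PA_RADIUS = 8.0
PA_Z = (-15.0, 40.0)

LV_CENTER = np.array([-24.0, -8.0, -30.0])
LV_SEMI = np.array([18.0, 16.0, 21.0])
MYO_THICKNESS = 6.0

BODY_SEMI_XY = (76.0, 66.0)
LUNG_SEMI = np.array([20.0, 40.0, 45.0])
LUNG_CENTERS = (np.array([52.0, 0.0, -5.0]), np.array([-52.0, 0.0, -5.0]))

# sinus ostium directions (unit xy)
_RIGHT_SINUS = np.array([0.77, 0.64])
_LEFT_SINUS = np.array([-0.87, -0.50])

# per-structure physical bounds that must fit on the grid (name, lo, hi)
_REQUIRED_BOUNDS = [
    ("aorta", (-AORTA_RADIUS - 2, -AORTA_RADIUS - 2, ROOT_CENTER[2] - ROOT_RADIUS),
     (AORTA_RADIUS + 2, AORTA_RADIUS + 2, 25.0)),
    ("pulmonary artery", (PA_CENTER_XY[0] - PA_RADIUS, PA_CENTER_XY[0] - PA_RADIUS, PA_Z[0]),
     (PA_CENTER_XY[0] + PA_RADIUS, PA_CENTER_XY[1] + PA_RADIUS, 20.0)),
    ("left ventricle", tuple(LV_CENTER - LV_SEMI - MYO_THICKNESS),
     tuple(LV_CENTER + LV_SEMI + MYO_THICKNESS)),
]


def _check_grid_fits(cfg: PhantomConfig) -> None:
    half = np.asarray(cfg.grid_shape) * np.asarray(cfg.spacing_mm) / 2.0
    for name, lo, hi in _REQUIRED_BOUNDS:
        need = np.maximum(np.abs(np.asarray(lo)), np.abs(np.asarray(hi)))
        if np.any(need > half):
            raise ValueError(
                f"grid of physical half-extent {tuple(np.round(half, 1))} mm is too small to "
                f"contain the {name} (needs half-extent {tuple(np.round(need, 1))} mm)"
            )


def _coordinate_axes(cfg: PhantomConfig):
    """World coordinates of voxel centers, grid centered on the origin."""
    shape = np.asarray(cfg.grid_shape, dtype=int)
    sp = np.asarray(cfg.spacing_mm, dtype=float)
    origin = -(shape - 1) * sp / 2.0
    axes = [origin[k] + np.arange(shape[k]) * sp[k] for k in range(3)]
    return origin, axes


def _ellipsoid_mask(axes, center, semi) -> np.ndarray:
    x, y, z = axes
    q = (
        ((x[:, None, None] - center[0]) / semi[0]) ** 2
        + ((y[None, :, None] - center[1]) / semi[1]) ** 2
        + ((z[None, None, :] - center[2]) / semi[2]) ** 2
    )
    return q <= 1.0


def _zcylinder_mask(axes, cx, cy, radius, z_lo, z_hi) -> np.ndarray:
    x, y, z = axes
    inplane = ((x[:, None, None] - cx) ** 2 + (y[None, :, None] - cy) ** 2) <= radius**2
    zin = (z >= z_lo) & (z <= z_hi)
    return inplane & zin[None, None, :]


def _sphere_mask(axes, center, radius) -> np.ndarray:
    return _ellipsoid_mask(axes, center, (radius, radius, radius))


def _tube_mask(axes, centerline: np.ndarray, radius: float, shape) -> np.ndarray:
    """Voxels within ``radius`` of a densely sampled centerline."""
    x, y, z = axes
    lo = centerline.min(axis=0) - radius - 1.0
    hi = centerline.max(axis=0) + radius + 1.0
    ix = np.where((x >= lo[0]) & (x <= hi[0]))[0]
    iy = np.where((y >= lo[1]) & (y <= hi[1]))[0]
    iz = np.where((z >= lo[2]) & (z <= hi[2]))[0]
    mask = np.zeros(shape, dtype=bool)
    if ix.size == 0 or iy.size == 0 or iz.size == 0:
        return mask
    gx, gy, gz = np.meshgrid(x[ix], y[iy], z[iz], indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    dist, _ = cKDTree(centerline).query(pts, workers=-1)
    sub = (dist <= radius).reshape(gx.shape)
    mask[np.ix_(ix, iy, iz)] = sub
    return mask


def _spline_centerline(control: np.ndarray, step_mm: float = 0.3) -> np.ndarray:
    """Cubic-spline interpolation of control points, resampled ~uniformly."""
    control = np.asarray(control, dtype=float)
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(control, axis=0), axis=1))])
    k = min(3, len(control) - 1)
    spl = interpolate.make_interp_spline(chord, control, k=k)
    n = max(int(chord[-1] / step_mm), 2)
    return np.asarray(spl(np.linspace(0.0, chord[-1], n)))


def _ostium(direction_xy: np.ndarray, z: float = SINUS_Z) -> np.ndarray:
    d = np.asarray(direction_xy, dtype=float)
    d = d / np.linalg.norm(d)
    return np.array([AORTA_RADIUS * d[0], AORTA_RADIUS * d[1], z])


def coronary_centerline(vessel: str, course: str, high_takeoff_mm: float = 12.0) -> np.ndarray:
    """Control-point centerline (mm) for a coronary of a given course.

    ``vessel`` is ``"RCA"`` or ``"LCA"``; anomalous courses start at the
    opposite (or displaced) sinus and end in the vessel's own territory.
    """
    A = np.array([0.0, 0.0])
    P = PA_CENTER_XY
    u2 = (P - A) / np.linalg.norm(P - A)          # aorta -> PA direction
    w2 = np.array([u2[1], -u2[0]])                # perpendicular, pointing right
    u = np.array([u2[0], u2[1], 0.0])
    w = np.array([w2[0], w2[1], 0.0])
    t_mid = (AORTA_RADIUS + np.linalg.norm(P - A) - PA_RADIUS) / 2.0  # corridor midline

    rca_exit = [np.array([22.0, 4.0, -14.0]), np.array([25.0, -4.0, -24.0])]
    lca_exit = [np.array([-23.0, 0.0, -8.0]), np.array([-16.0, 9.0, -20.0])]

    if course == "normal":
        if vessel == "RCA":
            pts = [_ostium(_RIGHT_SINUS), np.array([16.0, 10.0, -5.0])] + rca_exit
        else:
            pts = [_ostium(_LEFT_SINUS), np.array([-17.0, -8.0, -4.0])] + lca_exit
    elif course == "interarterial":
        if vessel == "RCA":
            o = _ostium(u2 - 0.45 * w2)
            pts = [o, t_mid * u - 2 * w, t_mid * u + 8 * w + np.array([0, 0, -2.0]),
                   t_mid * u + 15 * w + np.array([0, 0, -6.0]),
                   np.array([18.0, 10.0, -14.0])] + rca_exit[1:]
        else:
            o = _ostium(u2 + 0.45 * w2)
            pts = [o, t_mid * u + 2 * w, t_mid * u - 8 * w + np.array([0, 0, -2.0]),
                   t_mid * u - 15 * w + np.array([0, 0, -6.0]),
                   np.array([-22.0, 2.0, -8.0])] + lca_exit[1:]
    elif course == "prepulmonic":
        if vessel == "LCA":
            pts = [_ostium(_RIGHT_SINUS), np.array([2.0, 26.0, -2.0]), np.array([-8.0, 34.0, -5.0]),
                   np.array([-20.0, 29.0, -8.0]), np.array([-21.0, 12.0, -16.0])] + lca_exit[1:]
        else:
            # anterior ostium, over the PA leftward, then a distal dive below
            # the PA before returning to the right AV groove
            pts = [_ostium(np.array([-0.2, 0.98])), np.array([0.0, 26.0, -2.0]),
                   np.array([-8.0, 34.0, -4.0]), np.array([-16.0, 33.0, -7.0]),
                   np.array([-20.0, 24.0, -10.0]), np.array([-14.0, 18.0, -17.0]),
                   np.array([-2.0, 14.0, -18.0]), np.array([12.0, 10.0, -18.0]),
                   np.array([22.0, 2.0, -18.0])] + rca_exit[1:]
    elif course == "retroaortic":
        if vessel == "LCA":
            pts = [_ostium(np.array([0.8, -0.6])), np.array([4.0, -16.0, -3.0]),
                   np.array([-8.0, -16.0, -6.0]), np.array([-16.0, -9.0, -10.0]),
                   np.array([-23.0, 2.0, -6.0])] + lca_exit[1:]
        else:
            pts = [_ostium(np.array([-0.55, -0.84])), np.array([-4.0, -16.0, -3.0]),
                   np.array([8.0, -16.0, -6.0]), np.array([16.0, -9.0, -10.0])] + rca_exit
    elif course == "high_takeoff":
        dz = np.array([0.0, 0.0, float(high_takeoff_mm)])
        if vessel == "RCA":
            pts = [_ostium(_RIGHT_SINUS) + dz, np.array([17.0, 10.0, 6.0]),
                   np.array([22.0, 4.0, -8.0]), rca_exit[1]]
        else:
            pts = [_ostium(_LEFT_SINUS) + dz, np.array([-19.0, -9.0, 4.0]),
                   np.array([-23.0, -1.0, -6.0]), lca_exit[1]]
    elif course == "subpulmonic":
        if vessel == "RCA":
            o = _ostium(u2 - 0.45 * w2, z=-4.0)
            pts = [o, np.array([-9.0, 12.0, -13.0]), np.array([-2.0, 20.0, -18.0]),
                   np.array([8.0, 18.0, -18.0]), np.array([18.0, 8.0, -16.0]), rca_exit[1]]
        else:
            o = _ostium(u2 + 0.45 * w2, z=-4.0)
            pts = [o, np.array([-2.0, 18.0, -14.0]), np.array([-8.0, 20.0, -18.0]),
                   np.array([-16.0, 12.0, -16.0]), lca_exit[1]]
    else:
        raise ValueError(f"unknown course {course!r}")
    return np.asarray(pts, dtype=float)


def great_vessel_geometry() -> dict:
    """Analytic centers/radii used by the generator (for geometric oracles)."""
    return {
        "aorta_center_xy": np.array([0.0, 0.0]),
        "aorta_radius": AORTA_RADIUS,
        "pa_center_xy": PA_CENTER_XY.copy(),
        "pa_radius": PA_RADIUS,
        "sinus_z": SINUS_Z,
        "pa_z": PA_Z,
    }


def generate_phantom(config: PhantomConfig) -> CaseRecord:
    """Rasterize one phantom case: image (HU + Gaussian noise) and label map."""
    config.validate()
    _check_grid_fits(config)
    rng = np.random.default_rng(config.seed)
    origin, axes = _coordinate_axes(config)
    shape = tuple(int(n) for n in config.grid_shape)
    hu = config.tissue_hu

    image = np.full(shape, hu["air"], dtype=np.float32)
    labels = np.zeros(shape, dtype=np.int16)

    x, y, z = axes
    body = ((x[:, None, None] / BODY_SEMI_XY[0]) ** 2 + (y[None, :, None] / BODY_SEMI_XY[1]) ** 2) <= 1.0
    body = np.broadcast_to(body, shape)
    image[body] = hu["soft_tissue"]
    for lc in LUNG_CENTERS:
        image[_ellipsoid_mask(axes, lc, LUNG_SEMI)] = hu["lung"]

    myo = _ellipsoid_mask(axes, LV_CENTER, LV_SEMI + MYO_THICKNESS)
    cavity = _ellipsoid_mask(axes, LV_CENTER, LV_SEMI)
    aorta = _sphere_mask(axes, ROOT_CENTER, ROOT_RADIUS) | _zcylinder_mask(
        axes, 0.0, 0.0, AORTA_RADIUS, AORTA_Z[0], min(AORTA_Z[1], z[-1] - 2.0)
    )
    pa = _zcylinder_mask(axes, PA_CENTER_XY[0], PA_CENTER_XY[1], PA_RADIUS,
                         PA_Z[0], min(PA_Z[1], z[-1] - 2.0))

    # priority order: later structures override earlier ones
    for mask, lab, tissue in [
        (myo, Label.LV_MYOCARDIUM, "myocardium"),
        (cavity, Label.LV_CAVITY, "blood_pool_contrast"),
        (pa, Label.PULMONARY_ARTERY, "pa_blood"),
        (aorta, Label.AORTA, "blood_pool_contrast"),
    ]:
        labels[mask] = lab
        image[mask] = hu[tissue]

    # coronaries: the anomalous vessel follows the configured course
    centerlines = {}
    course_of = {"RCA": "normal", "LCA": "normal"}
    if config.anomaly_class == "R-AAOCA":
        course_of["RCA"] = config.course
    elif config.anomaly_class == "L-AAOCA":
        course_of["LCA"] = config.course
    for vessel, lab in (("RCA", Label.CORONARY_RCA), ("LCA", Label.CORONARY_LCA)):
        ctrl = coronary_centerline(vessel, course_of[vessel], config.high_takeoff_mm)
        line = _spline_centerline(ctrl)
        centerlines[vessel] = line
        tube = _tube_mask(axes, line, config.coronary_radius_mm, shape)
        labels[tube] = lab
        image[tube] = hu["coronary_contrast"]

    if config.noise_sigma_hu > 0:
        image = image + rng.normal(0.0, config.noise_sigma_hu, size=shape).astype(np.float32)

    spacing = tuple(float(s) for s in config.spacing_mm)
    org = tuple(float(o) for o in origin)
    vol = ImageVolume(image.astype(np.float32), spacing=spacing, origin=org)
    lmap = LabelMap(labels, spacing=spacing, origin=org)

    y_anomaly = int(config.anomaly_class != "normal")
    y_origin = {"R-AAOCA": "right", "L-AAOCA": "left"}.get(config.anomaly_class)
    record = CaseRecord(
        case_id=f"case-{config.seed:08d}",
        volumes=[vol],
        label_map=lmap,
        y_anomaly=y_anomaly,
        y_origin=y_origin,
        y_risk=config.risk,
        group={"sex": "F" if rng.random() < 0.5 else "M"},
        meta={
            "centerlines": centerlines,
            "anomalous_vessel": {"R-AAOCA": "RCA", "L-AAOCA": "LCA"}.get(config.anomaly_class),
            "course": config.course,
            "config": config,
        },
    )
    if config.n_phases > 1:
        record = simulate_phases(record, config.n_phases, config.phase_amplitude_mm,
                                 seed=int(rng.integers(2**31)))
    return record


def simulate_phases(case: CaseRecord, n_phases: int, amplitude_mm: float, seed: int = 0) -> CaseRecord:
    """Append pseudo cardiac-phase reconstructions of phase 0.

    Each extra phase is phase 0 warped by a smooth random displacement field
    whose maximum norm is <= ``amplitude_mm``; labels are untouched, mimicking
    multi-phase reconstructions used as natural augmentation.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be >= 0")
    if not case.volumes:
        raise ValueError("case must have at least one volume")
    if n_phases <= 1:
        return case
    rng = np.random.default_rng(seed)
    ref = case.volumes[0]
    spacing = np.asarray(ref.spacing)
    shape = ref.shape
    idx = np.indices(shape, dtype=np.float32)
    new_volumes = list(case.volumes)
    for _ in range(n_phases - 1):
        coarse = rng.normal(size=(3, 5, 5, 4)).astype(np.float32)
        disp = np.stack([
            ndimage.zoom(coarse[k], np.asarray(shape) / np.asarray(coarse[k].shape), order=3)
            for k in range(3)
        ])
        disp = disp[:, : shape[0], : shape[1], : shape[2]]
        norms = np.sqrt(np.sum(disp**2, axis=0))
        peak = float(norms.max())
        if peak > 0:
            disp *= amplitude_mm * rng.uniform(0.5, 1.0) / peak
        coords = idx + disp / spacing[:, None, None, None]
        warped = ndimage.map_coordinates(ref.data.astype(np.float32), coords, order=1,
                                         mode="nearest")
        new_volumes.append(ImageVolume(warped, spacing=ref.spacing, origin=ref.origin))
    return dataclasses.replace(case, volumes=new_volumes)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def parse_mix_key(key: str) -> tuple[str, str]:
    """Parse a class-mix key: 'normal' or '<class>/<course>'."""
    if key == "normal":
        return "normal", "normal"
    cls, _, course = key.partition("/")
    if cls not in ("R-AAOCA", "L-AAOCA") or course not in COURSES or course == "normal":
        raise ValueError(f"bad class-mix key {key!r}")
    return cls, course


def largest_remainder_counts(n: int, weights: dict) -> dict:
    """Integer counts summing to n, by largest-remainder apportionment.

    Ties in the fractional remainders are broken by key order in ``weights``.
    """
    keys = list(weights)
    w = np.asarray([weights[k] for k in keys], dtype=float)
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-6):
        raise ValueError("mix proportions must be non-negative and sum to 1")
    exact = n * w / w.sum()
    base = np.floor(exact).astype(int)
    rem = exact - base
    short = n - int(base.sum())
    order = np.argsort(-rem, kind="stable")
    for j in order[:short]:
        base[j] += 1
    return dict(zip(keys, (int(b) for b in base)))


def generate_cohort_records(n_cases: int, class_mix: dict, base_config: PhantomConfig | None = None,
                            seed: int = 0) -> list[CaseRecord]:
    """Generate an in-memory cohort with the requested (class, course) mix."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    base = base_config or PhantomConfig()
    counts = largest_remainder_counts(n_cases, class_mix)
    case_seeds = (np.random.SeedSequence(seed).generate_state(n_cases, dtype=np.uint64)
                  % np.uint64(2**31)).astype(np.int64)
    records = []
    i = 0
    for key, count in counts.items():
        cls, course = parse_mix_key(key)
        for _ in range(count):
            cfg = dataclasses.replace(base, anomaly_class=cls, course=course,
                                      seed=int(case_seeds[i]))
            rec = generate_phantom(cfg)
            records.append(rec)
            i += 1
    # deterministic shuffle so case order carries no class information
    perm = np.random.default_rng(seed).permutation(len(records))
    records = [records[j] for j in perm]
    for i, rec in enumerate(records):
        rec.case_id = f"case-{i:04d}"
    return records


def generate_cohort(n_cases: int, class_mix: dict, out_dir, base_config: PhantomConfig | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Generate a cohort and write NIfTI volumes + a manifest CSV to disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in generate_cohort_records(n_cases, class_mix, base_config, seed):
        phase_paths = []
        for p, vol in enumerate(rec.volumes):
            path = out_dir / f"{rec.case_id}_phase{p}.nii.gz"
            save_volume(vol, path)
            phase_paths.append(path.name)
        label_path = out_dir / f"{rec.case_id}_labels.nii.gz"
        save_volume(rec.label_map, label_path)
        rows.append({
            "case_id": rec.case_id,
            "phase_paths": ";".join(phase_paths),
            "label_path": label_path.name,
            "y_anomaly": rec.y_anomaly,
            "y_origin": rec.y_origin or "",
            "y_risk": rec.y_risk or "",
            "group": rec.group.get("sex", ""),
            "seed": rec.meta["config"].seed,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
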