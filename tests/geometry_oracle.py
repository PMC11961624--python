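"""Independent geometric predicates for coronary courses.

All quantities (vessel axes, radii, centroids) are measured from the
generated label map itself, so the checks do not reuse the generator's
internal construction beyond the shared canonical frame.
"""

import numpy as np

from coroscreen.volume import Label


def _world_points(mask, label_map):
    idx = np.array(np.nonzero(mask), dtype=float).T
    return np.asarray(label_map.origin) + idx * np.asarray(label_map.spacing)


def vessel_axis_and_radius(label_map, label, z_range):
    """In-plane axis center and effective radius of a vertical vessel,
    measured from label-map voxels inside a z window (mm)."""
    pts = _world_points(label_map.mask(label), label_map)
    sel = pts[(pts[:, 2] >= z_range[0]) & (pts[:, 2] <= z_range[1])]
    center_xy = sel[:, :2].mean(axis=0)
    n_slices = len(np.unique(np.round(sel[:, 2], 3)))
    voxel_area = label_map.spacing[0] * label_map.spacing[1]
    area = len(sel) * voxel_area / n_slices
    return center_xy, float(np.sqrt(area / np.pi))


def measured_geometry(label_map):
    aorta_xy, r_a = vessel_axis_and_radius(label_map, Label.AORTA, (10.0, 30.0))
    pa_xy, r_p = vessel_axis_and_radius(label_map, Label.PULMONARY_ARTERY, (5.0, 30.0))
    aorta_centroid = _world_points(label_map.mask(Label.AORTA), label_map).mean(axis=0)
    pa_centroid = _world_points(label_map.mask(Label.PULMONARY_ARTERY), label_map).mean(axis=0)
    return {"aorta_xy": aorta_xy, "r_a": r_a, "pa_xy": pa_xy, "r_p": r_p,
            "aorta_centroid": aorta_centroid, "pa_centroid": pa_centroid}


def proximal(centerline, length_mm):
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    arc = np.r_[0.0, np.cumsum(seg)]
    return centerline[arc <= length_mm]


def check_course(course, centerline, geo, sinus_z=0.0, takeoff_mm=10.0):
    """True iff the centerline satisfies the geometric definition of its course."""
    A, P = geo["aorta_xy"], geo["pa_xy"]
    r_a, r_p = geo["r_a"], geo["r_p"]
    ap = P - A
    d_ap = np.linalg.norm(ap)
    u = ap / d_ap

    if course == "interarterial":
        pts = proximal(centerline, 20.0)
        for q in pts:
            qxy = q[:2]
            if np.linalg.norm(qxy - A) < r_a - 1.0:
                return False                      # inside the aorta
            if np.linalg.norm(qxy - P) < r_p - 1.0:
                return False                      # inside the PA
            t = (qxy - A) @ u
            if not (r_a - 2.0 <= t <= d_ap - r_p + 2.0):
                return False                      # not between the surfaces
            if np.linalg.norm(qxy - A - t * u) > r_a + 2.0:
                return False                      # not in the corridor
        return True
    # crossing windows exclude the peri-ostial region at the aortic wall
    if course == "prepulmonic":
        pts = proximal(centerline, 40.0)
        crossing = [q for q in pts if abs(q[0] - P[0]) <= r_p
                    and np.linalg.norm(q[:2] - A) > r_a + 1.0]
        return bool(crossing) and all(q[1] > geo["pa_centroid"][1] for q in crossing)
    if course == "retroaortic":
        pts = proximal(centerline, 40.0)
        crossing = [q for q in pts if abs(q[0] - A[0]) <= r_a
                    and np.linalg.norm(q[:2] - A) > r_a + 1.0]
        return bool(crossing) and all(q[1] < geo["aorta_centroid"][1] for q in crossing)
    if course == "high_takeoff":
        return centerline[0][2] >= sinus_z + takeoff_mm
    if course == "subpulmonic":
        pts = proximal(centerline, 30.0)
        return all(q[2] < geo["pa_centroid"][2] and q[1] > geo["aorta_centroid"][1]
                   for q in pts)
    raise ValueError(course)
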