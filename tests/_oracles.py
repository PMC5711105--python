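"""Independent brute-force oracles shared between test modules."""

import numpy as np


def brute_force_path(model, e_axis, u_target, opening_side, step=1e-3):
    """Walk the source ray in ~10 um steps and sum the steps falling inside
    the leaf material region (tip circle union body half-space, inside the
    slab)."""
    u = u_target * opening_side
    e = e_axis * opening_side
    sad, zl = model.source_to_iso_distance, model.source_to_leaf_plane
    R, t = model.tip_radius, model.leaf_thickness
    u_c = e * zl / sad - R
    slope = u / sad
    dz = step / np.sqrt(1.0 + slope * slope)
    z = np.arange(zl - t / 2, zl + t / 2, dz)
    line = slope * z - u_c
    inside = (line <= 0) | ((z - zl) ** 2 + line**2 <= R**2)
    return inside.sum() * step


def scan_crossings(u, v, level=50.0):
    """Check every adjacent sample pair for a sign change of
    (value - level) and interpolate linearly."""
    out = []
    d = np.asarray(v) - level
    for i in range(len(u) - 1):
        if d[i] == 0.0:
            out.append(u[i])
        elif d[i] * d[i + 1] < 0:
            out.append(u[i] + (u[i + 1] - u[i]) * d[i] / (d[i] - d[i + 1]))
    return np.asarray(out)
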