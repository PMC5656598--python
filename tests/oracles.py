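"""Independent oracles used by the tests.

These deliberately avoid the library's own evaluation paths: the bending
energy is integrated from the definition (squared second derivatives of the
fitted warp, analytic kernel Hessian, polar trapezoid integration refined
until stable), Bezier evaluation uses the de Casteljau recursion, and
point-to-mesh distances use an exhaustive per-face scan.
"""
import numpy as np


def tps_energy_integral(spline, rtol: float = 0.005) -> float:
    """Definitional 2D bending energy: integral of f_xx^2 + 2 f_xy^2 + f_yy^2.

    Integrates on polar grids of growing radius/resolution until the value
    changes by less than ``rtol``.
    """
    X = spline.source.points
    W = spline.weights
    scale = float(np.ptp(X, axis=0).max())
    center = X.mean(axis=0)

    def integrand(pts):
        d = pts[:, None, :] - X[None, :, :]
        r2 = np.maximum((d**2).sum(-1), 1e-300)
        lg = 0.5 * np.log(r2)
        base = 2 * lg + 1
        uxx = base + 2 * d[:, :, 0] ** 2 / r2
        uyy = base + 2 * d[:, :, 1] ** 2 / r2
        uxy = 2 * d[:, :, 0] * d[:, :, 1] / r2
        out = 0.0
        for dd in range(2):
            fxx = uxx @ W[:, dd]
            fyy = uyy @ W[:, dd]
            fxy = uxy @ W[:, dd]
            out = out + fxx**2 + 2 * fxy**2 + fyy**2
        return out

    prev = None
    for mult, nr, nt in ((40, 6000, 384), (40, 12000, 384), (40, 24000, 768)):
        radius = mult * scale
        rr = np.linspace(1e-9, radius, nr)
        tt = np.linspace(0, 2 * np.pi, nt, endpoint=False)
        rg, tg = np.meshgrid(rr, tt, indexing="ij")
        pts = center + np.stack(
            [rg.ravel() * np.cos(tg.ravel()), rg.ravel() * np.sin(tg.ravel())], axis=-1
        )
        chunks = [
            integrand(pts[i: i + 100_000]) for i in range(0, len(pts), 100_000)
        ]
        vals = np.concatenate(chunks).reshape(nr, nt)
        val = float(np.trapezoid(vals.mean(axis=1) * 2 * np.pi * rr, rr))
        if prev is not None and abs(val - prev) <= rtol * abs(val):
            return val
        prev = val
    raise RuntimeError(
        "bending-energy integral did not stabilise; configuration too sharp "
        "for the oracle's grids"
    )


def de_casteljau(control_points: np.ndarray, t: float) -> np.ndarray:
    pts = np.asarray(control_points, dtype=float).copy()
    while len(pts) > 1:
        pts = (1.0 - t) * pts[:-1] + t * pts[1:]
    return pts[0]


def brute_force_closest(points: np.ndarray, mesh) -> np.ndarray:
    """Unsigned distance to a mesh by exhaustive point-triangle minimisation."""
    tris = np.asarray(mesh.triangles)
    out = np.empty(len(points))
    for i, p in enumerate(points):
        best = np.inf
        for tri in tris:
            best = min(best, _point_triangle_distance(p, tri))
        out[i] = best
    return out


def _point_triangle_distance(p, tri, n: int = 48, levels: int = 3):
    """Distance to one triangle by nested barycentric grid search.

    Deliberately avoids the region-classification algorithm used by the
    implementation; accuracy after the refinement levels is far below the
    tolerances at which the oracle is compared.
    """
    a, b, c = tri
    u0, u1, v0, v1 = 0.0, 1.0, 0.0, 1.0
    best = np.inf
    for _ in range(levels):
        us = np.linspace(u0, u1, n)
        vs = np.linspace(v0, v1, n)
        uu, vv = np.meshgrid(us, vs, indexing="ij")
        uu, vv = uu.ravel(), vv.ravel()
        # clamp to the simplex u + v <= 1
        s = np.maximum(uu + vv, 1e-300)
        over = s > 1.0
        uu = np.where(over, uu / s, uu)
        vv = np.where(over, vv / s, vv)
        q = a + uu[:, None] * (b - a) + vv[:, None] * (c - a)
        d = np.linalg.norm(q - p, axis=1)
        i = int(np.argmin(d))
        best = min(best, float(d[i]))
        du, dv = (u1 - u0) / (n - 1), (v1 - v0) / (n - 1)
        u0, u1 = max(0.0, uu[i] - 2 * du), min(1.0, uu[i] + 2 * du)
        v0, v1 = max(0.0, vv[i] - 2 * dv), min(1.0, vv[i] + 2 * dv)
    return best
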