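"""Independent oracles, implemented without touching the package's code paths.

Each oracle recomputes a quantity by a different algorithm (quaternion
eigen-decomposition for superposition, exhaustive edge scanning for the
convex hull, plain nested loops for hydrogen bonds) so agreement with
the package is a genuine cross-check.
"""

import math

import numpy as np


def quaternion_rmsd(ref: np.ndarray, mob: np.ndarray) -> float:
    """Post-fit RMSD by Horn's quaternion eigenvalue method."""
    ref = ref - ref.mean(axis=0)
    mob = mob - mob.mean(axis=0)
    m = mob.T @ ref
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key).max()
    n = len(ref)
    ga = float((ref ** 2).sum())
    gb = float((mob ** 2).sum())
    return math.sqrt(max(0.0, (ga + gb - 2.0 * lam) / n))


def brute_hull_area(points: np.ndarray) -> float:
    """Convex-hull area by exhaustive directed-edge scanning + shoelace."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    n = len(pts)
    if n < 3:
        return 0.0
    edges = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a, b = pts[i], pts[j]
            cross = (b[0] - a[0]) * (pts[:, 1] - a[1]) - (b[1] - a[1]) * (pts[:, 0] - a[0])
            if np.all(cross >= -1e-12):
                edges[i] = j
    if not edges:
        return 0.0
    start = next(iter(edges))
    order = [start]
    cur = edges[start]
    while cur != start and len(order) <= n:
        order.append(cur)
        cur = edges[cur]
    poly = pts[order]
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _angle_at(vertex, a, b) -> float:
    v1 = [a[k] - vertex[k] for k in range(3)]
    v2 = [b[k] - vertex[k] for k in range(3)]
    n1 = math.sqrt(sum(c * c for c in v1))
    n2 = math.sqrt(sum(c * c for c in v2))
    if n1 * n2 == 0:
        return 0.0
    cosang = max(-1.0, min(1.0, sum(p * q for p, q in zip(v1, v2)) / (n1 * n2)))
    return math.degrees(math.acos(cosang))


def brute_hbonds(strand1: dict, strand16: dict, cutoff: float = 3.5,
                 angle_min: float = 120.0) -> set:
    """Nested-loop H-bond scan on residue dicts {resnum: {atom: (x,y,z)}}.

    Matches the package's rule: each donor N bonds to its nearest
    acceptor O within the cutoff satisfying the N···O=C angle gate,
    scanning both strand directions.  Returns {(donor, acceptor), ...}.
    """
    bonds = set()
    for donors, acceptors in ((strand1, strand16), (strand16, strand1)):
        for dres, datoms in donors.items():
            if "N" not in datoms:
                continue
            best = None
            for ares, aatoms in acceptors.items():
                if "O" not in aatoms or "C" not in aatoms:
                    continue
                d = math.dist(datoms["N"], aatoms["O"])
                if d > cutoff:
                    continue
                if _angle_at(aatoms["O"], datoms["N"], aatoms["C"]) < angle_min:
                    continue
                if best is None or d < best[0]:
                    best = (d, ares)
            if best is not None:
                bonds.add((dres, best[1]))
    return bonds
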