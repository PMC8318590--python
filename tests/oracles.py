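"""Independent reference implementations used only as test oracles.

Each function here deliberately uses a different algorithm (or a naive
brute-force formulation) than the package implementation it checks.
"""

import itertools

import numpy as np


def quaternion_rmsd(x, y):
    """Minimum RMSD after superposition via the quaternion eigenvalue
    method (Horn): largest eigenvalue of the 4x4 key matrix."""
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    m = x.T @ y
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(key)[-1]
    n = x.shape[0]
    msd = (np.sum(x ** 2) + np.sum(y ** 2) - 2.0 * lam) / n
    return np.sqrt(max(msd, 0.0))


def brute_force_contact_distance(degrees, ref_degrees, normalization):
    """(1/N)·sqrt(Σ(ΔD)²) with an explicit python loop."""
    total = 0.0
    for d, r in zip(degrees, ref_degrees):
        total += (d - r) * (d - r)
    return (total ** 0.5) / normalization


def direct_gaussian_sum(point, centers, sigmas, heights):
    """Bias at one point as an explicit loop over hills."""
    total = 0.0
    for c, s, h in zip(centers, sigmas, heights):
        arg = 0.0
        for k in range(len(point)):
            arg += ((point[k] - c[k]) / s[k]) ** 2
        total += h * np.exp(-0.5 * arg)
    return total


def gromos_reference(square, cutoff):
    """O(n³) GROMOS clustering: recount neighbours from scratch each
    round (ties: lowest frame index; boundary: <= cutoff)."""
    n = square.shape[0]
    alive = set(range(n))
    clusters = []
    while alive:
        best, best_count = None, -1
        for i in sorted(alive):
            count = sum(1 for j in alive if square[i, j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = sorted(j for j in alive if square[best, j] <= cutoff)
        clusters.append(members)
        alive -= set(members)
    return [c for _, c in sorted(enumerate(clusters),
                                 key=lambda t: (-len(t[1]), t[0]))]


def central_reference(members, square):
    """argmin over explicit row sums (ties: lowest index)."""
    members = sorted(members)
    best, best_sum = None, np.inf
    for m in members:
        s = sum(square[m, j] for j in members)
        if s < best_sum - 1e-15:
            best, best_sum = m, s
    return best


def minimax_barrier_reference(values, mask, start, end):
    """Barrier of the minimax path by level-set connectivity: the lowest
    threshold at which start and end fall in one connected component of
    {nodes with F <= threshold}."""
    levels = sorted(set(values[mask].ravel().tolist()))
    shape = values.shape
    for level in levels:
        if values[start] > level or values[end] > level:
            continue
        # BFS on nodes <= level
        seen = {start}
        queue = [start]
        while queue:
            node = queue.pop()
            if node == end:
                return level
            i, j = node
            for di, dj in itertools.product((-1, 0, 1), repeat=2):
                if di == dj == 0:
                    continue
                a, b = i + di, j + dj
                nb = (a, b)
                if (0 <= a < shape[0] and 0 <= b < shape[1]
                        and mask[nb] and values[nb] <= level
                        and nb not in seen):
                    seen.add(nb)
                    queue.append(nb)
    raise AssertionError("no connected path")


def pt_acceptance_quadrature(k, t_i, t_j, kb):
    """Mean Metropolis acceptance for coordinate swaps between two
    harmonic-well replicas, by 2D Gauss-Hermite quadrature over the two
    Boltzmann position distributions."""
    bi, bj = 1.0 / (kb * t_i), 1.0 / (kb * t_j)
    si, sj = np.sqrt(1.0 / (bi * k)), np.sqrt(1.0 / (bj * k))
    nodes, weights = np.polynomial.hermite_e.hermegauss(201)
    xi = nodes[:, None] * si
    xj = nodes[None, :] * sj
    u_i, u_j = 0.5 * k * xi ** 2, 0.5 * k * xj ** 2
    acc = np.minimum(1.0, np.exp((bi - bj) * (u_j - u_i)))
    w = weights[:, None] * weights[None, :]
    return float(np.sum(w * acc) / np.sum(w))
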