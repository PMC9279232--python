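"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: expected trajectories
are interpolated by hand, likelihoods are accumulated with explicit Python
loops, sequences are enumerated exhaustively, and Krippendorff's alpha is
computed from raw pairwise disagreements rather than a coincidence matrix.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def valid_permutations(grid):
    """All event orderings that keep each biomarker's levels ascending."""
    n = grid.n_events
    events = grid.events  # (biomarker index, level)
    out = []
    for perm in itertools.permutations(range(n)):
        ok = True
        for bi in range(grid.n_biomarkers):
            levels_seen = [events[e][1] for e in perm if events[e][0] == bi]
            if levels_seen != sorted(levels_seen):
                ok = False
                break
        if ok:
            out.append(np.array(perm, dtype=int))
    return out


def expected_value_oracle(seq, grid, bi, stage):
    """Hand-rolled piecewise-linear trajectory evaluation."""
    n = grid.n_events
    anchors = [(0.0, 0.0)]
    for rank, level in enumerate(grid.levels[bi]):
        e = int(grid.event_indices_of(bi)[rank])
        position = list(seq).index(e) + 1
        anchors.append((float(position), float(level)))
    if anchors[-1][0] < n:
        anchors.append((float(n), float(grid.z_max[bi])))
    x = float(stage)
    for (x0, y0), (x1, y1) in zip(anchors, anchors[1:]):
        if x0 <= x <= x1:
            if x1 == x0:
                return y1
            return y0 + (y1 - y0) * (x - x0) / (x1 - x0)
    return anchors[-1][1]


def sequence_ll_oracle(X, seq, grid, sigma):
    """Explicit-loop data log-likelihood with a uniform stage prior."""
    X = np.atleast_2d(X)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (grid.n_biomarkers,))
    n_stages = grid.n_events + 1
    total = 0.0
    for row in X:
        mix = 0.0
        for k in range(n_stages):
            like = 1.0
            for bi in range(grid.n_biomarkers):
                z = row[bi]
                if math.isnan(z):
                    continue
                mu = expected_value_oracle(seq, grid, bi, k)
                s = sigma[bi]
                like *= math.exp(-0.5 * ((z - mu) / s) ** 2) / (s * math.sqrt(2 * math.pi))
            mix += like / n_stages
        total += math.log(mix)
    return total


def stage_likelihoods_oracle(z, seq, grid, sigma):
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (grid.n_biomarkers,))
    out = []
    for k in range(grid.n_events + 1):
        like = 1.0
        for bi in range(grid.n_biomarkers):
            if math.isnan(z[bi]):
                continue
            mu = expected_value_oracle(seq, grid, bi, k)
            s = sigma[bi]
            like *= math.exp(-0.5 * ((z[bi] - mu) / s) ** 2) / (s * math.sqrt(2 * math.pi))
        out.append(like)
    return np.array(out)


def exact_pvd_oracle(X, grid, sigma):
    """Exact posterior over valid sequences (uniform prior), summarized as an
    event-by-position probability matrix."""
    seqs = valid_permutations(grid)
    logw = np.array([sequence_ll_oracle(X, s, grid, sigma) for s in seqs])
    w = np.exp(logw - logw.max())
    w /= w.sum()
    n = grid.n_events
    mat = np.zeros((n, n))
    for weight, seq in zip(w, seqs):
        for pos, e in enumerate(seq):
            mat[e, pos] += weight
    return mat


def kripp_alpha_oracle(units):
    """Nominal alpha from raw pairwise (dis)agreements, no coincidence matrix."""
    units = [list(u) for u in units if len(u) >= 2]
    n = sum(len(u) for u in units)
    # observed disagreement: ordered within-unit pairs, weight 1/(m-1)
    d_o = 0.0
    for u in units:
        m = len(u)
        for i in range(m):
            for j in range(m):
                if i != j and u[i] != u[j]:
                    d_o += 1.0 / (m - 1)
    d_o /= n
    # expected disagreement: ordered pairs across all pairable values
    values = [v for u in units for v in u]
    d_e = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and values[i] != values[j]:
                d_e += 1.0
    d_e /= n * (n - 1)
    if d_e == 0:
        raise ValueError("expected disagreement is zero")
    return 1.0 - d_o / d_e
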