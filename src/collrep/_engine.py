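"""Numba kernel for the reputation dynamics.

Implements exactly the process of :mod:`collrep.dynamics` — same group
sampling, threshold comparison, observation/misperception model, synchronous
update and accumulation — consuming random draws from the supplied
``numpy.random.Generator`` in the order documented there, so that engine and
pure-Python reference produce bit-identical trajectories for the same seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .dynamics import THRESHOLD_TOL


@njit(cache=False)
def _kernel(M, assess, act, pinned, lam, k, q, eps, ig_eps, steps, burn, rng,
            m_acc, part, act_sum, nc_sum, traj, record):
    N = M.shape[0]
    perm = np.empty(N, np.int64)
    group = np.empty(k, np.int64)
    actions = np.empty(k, np.int8)
    newvals = np.empty((N, k), np.int8)
    observed = np.empty(N, np.bool_)
    if record:
        for a in range(N):
            for b in range(N):
                traj[0, a, b] = M[a, b]
    for t in range(steps):
        # 1. group sampling (partial Fisher-Yates, k draws)
        for i in range(N):
            perm[i] = i
        for tpos in range(k):
            u = rng.random()
            j = tpos + int(u * (N - tpos))
            tmp = perm[tpos]
            perm[tpos] = perm[j]
            perm[j] = tmp
        for idx in range(k):
            group[idx] = perm[idx]
        # 2. actions (no draws)
        n_C = 0
        for idx in range(k):
            i = group[idx]
            good = 0
            for jdx in range(k):
                jj = group[jdx]
                if jj != i:
                    good += M[i, jj]
            rp = 1 if good >= lam[i] * (k - 1) - THRESHOLD_TOL else 0
            a = act[i, M[i, i], rp]
            actions[idx] = a
            n_C += a
        # 3. observation and assessment (reads pre-round M only)
        for h in range(N):
            in_group = False
            for idx in range(k):
                if group[idx] == h:
                    in_group = True
                    break
            if in_group:
                obs = True
            else:
                obs = rng.random() < q
            observed[h] = obs
            if not obs:
                continue
            e = ig_eps if in_group else eps
            rowsum = 0
            for idx in range(k):
                rowsum += M[h, group[idx]]
            for idx in range(k):
                i = group[idx]
                b = actions[idx]
                if i != h:
                    if rng.random() < e:
                        b = 1 - b
                ra = M[h, i]
                good = rowsum - ra
                rp = 1 if good >= lam[h] * (k - 1) - THRESHOLD_TOL else 0
                newvals[h, idx] = assess[h, ra, rp, b]
        # 4. synchronous application (pinned rows stay constant)
        for h in range(N):
            if observed[h] and pinned[h] == 0:
                for idx in range(k):
                    M[h, group[idx]] = newvals[h, idx]
        # 5. accumulation after burn-in (post-update matrix)
        if t >= burn:
            for a in range(N):
                for b in range(N):
                    m_acc[a, b] += M[a, b]
            for idx in range(k):
                i = group[idx]
                part[i] += 1
                act_sum[i] += actions[idx]
                nc_sum[i] += n_C
        if record:
            for a in range(N):
                for b in range(N):
                    traj[t + 1, a, b] = M[a, b]


def run_simulation(M, assess, act, pinned, lam, k, q, eps, ig_eps, steps, burn, rng,
                   m_acc, part, act_sum, nc_sum, traj, record):
    """Run the compiled kernel in place on the supplied buffers.

    ``eps`` is the misperception probability for out-group observers,
    ``ig_eps`` the one for fellow group members (0 unless in-group errors
    are enabled); the misperception draw is consumed either way.
    """
    _kernel(M, assess, act, pinned, lam, np.int64(k), float(q), float(eps),
            float(ig_eps), np.int64(steps), np.int64(burn), rng,
            m_acc, part, act_sum, nc_sum, traj, record)
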