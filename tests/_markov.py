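"""Exact Markov-chain oracle for the no-screening natural history.

Independent of the package internals: works on plain probability arrays
and computes occupancy and event flows by matrix products over an
expanded 12-state chain (4 undiagnosed states, diagnosed cancer split by
year-since-diagnosis 0..5+, two death states).  Event order matches the
engine contract: progression, then cancer death, then other-cause death,
then the year-since-diagnosis increment.
"""

import numpy as np

N = 12
UNDIAG = [0, 1, 2, 3]
DX = list(range(4, 10))  # years since diagnosis 0..4, then 5+ (survivor)
DEAD_CRC, DEAD_OTHER = 10, 11


def cycle_matrix(p_trans, q, p_other):
    """Row-stochastic one-cycle matrix for given annual probabilities.

    ``p_trans``: 4 forward-transition probabilities; ``q``: 5 annual
    cancer-death probabilities by year since diagnosis; ``p_other``:
    non-cancer death probability.
    """
    t1 = np.eye(N)
    for s in range(4):
        t1[s, s] = 1.0 - p_trans[s]
        t1[s, s + 1 if s < 3 else 4] = p_trans[s]
    t2 = np.eye(N)
    for j in range(5):
        t2[4 + j, 4 + j] = 1.0 - q[j]
        t2[4 + j, DEAD_CRC] = q[j]
    t3 = np.eye(N)
    for s in UNDIAG + DX:
        t3[s, s] = 1.0 - p_other
        t3[s, DEAD_OTHER] = p_other
    t4 = np.zeros((N, N))
    for s in UNDIAG + [DEAD_CRC, DEAD_OTHER]:
        t4[s, s] = 1.0
    for j in range(6):
        t4[4 + j, 4 + min(j + 1, 5)] = 1.0
    return t1 @ t2 @ t3 @ t4


def run(initial, p_trans_by_cycle, q, p_other_by_cycle, cycles):
    """Evolve the chain; returns (occupancy, incidence_flow, crc_death_flow).

    ``occupancy`` has shape (cycles+1, 12) with row 0 the initial
    distribution; flows have length ``cycles``.
    """
    v = np.zeros(N)
    v[:4] = initial
    occ = [v.copy()]
    inc, deaths = [], []
    for t in range(cycles):
        p = p_trans_by_cycle[t]
        inc.append(v[3] * p[3])
        t1 = cycle_matrix(p, q, p_other_by_cycle[t])
        # cancer-death flow needs the post-progression distribution
        m1 = np.eye(N)
        for s in range(4):
            m1[s, s] = 1.0 - p[s]
            m1[s, s + 1 if s < 3 else 4] = p[s]
        v1 = v @ m1
        deaths.append(sum(v1[4 + j] * q[j] for j in range(5)))
        v = v @ t1
        occ.append(v.copy())
    return np.array(occ), np.array(inc), np.array(deaths)
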