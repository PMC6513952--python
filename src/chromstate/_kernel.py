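"""Numba-compiled simulation kernel.

The inner loop is the hot path of every simulation and parameter sweep, so
it is compiled with numba and operates only on flat integer/float arrays.
The Python-level operations in :mod:`chromstate.engine` mirror the same
logic one step at a time for testing.

RNG contract (frozen for reproducibility): the kernel seeds numba's own
np.random stream once.  Per update step it consumes, in order:
four uniforms for the channel clocks (recruitment, beta, NURD, PR-DUB),
then the draws of the executed channel —
recruitment: recruiter index, [enzyme index if >1 recruiter], target index,
[acceptance uniform if acceptance probability < 1];
beta: half index, site index (0..2), [one uniform if the K27 site is
unmarked]; NURD / PR-DUB: half index.
A replication event consumes N uniforms.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Channel ids
RECRUIT, BETA, NURD, PRDUB = 0, 1, 2, 3


@njit(cache=True)
def simulate(
    seed,
    init_states,      # int8[n], 1..12
    beta,
    dn,
    dp,
    mult,             # float64[7] recruited-enzyme multipliers
    action,           # int8[7, 13]
    recruit_lists,    # int8[13, 7]
    recruit_counts,   # int8[13]
    k27_down,         # int8[13] direct-move tables
    k27_ac,
    k27_me3,
    k436_toggle,
    h2a_toggle,
    nurd_tab,
    prdub_tab,
    replication_on,   # bool
    gen_raw,          # raw-time generation interval (generation_time * n)
    dur_raw,          # raw-time duration (duration * n)
    samp_raw,         # raw-time sample spacing (sample_interval * n)
    max_samples,
    max_reps,
):
    np.random.seed(seed)
    n = init_states.shape[0]
    states = init_states.copy()

    samples = np.zeros((max_samples, n), dtype=np.int8)
    rep_times = np.zeros(max_reps, dtype=np.float64)
    # stats: attempts[4], executed[4], enzyme chosen[7], enzyme accepted[7],
    # replications -> length 23
    stats = np.zeros(23, dtype=np.int64)

    m_max = 1.0
    for k in range(mult.shape[0]):
        if mult[k] > m_max:
            m_max = mult[k]

    # sample 0 is the initial state at time 0
    samples[0, :] = states
    n_samp = 1
    next_boundary = samp_raw

    t = 0.0
    last_rep = 0.0
    n_rep = 0

    while t < dur_raw:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        r4 = np.random.random()
        t1 = -np.log(r1)
        t2 = -np.log(r2) / beta if beta > 0.0 else np.inf
        t3 = -np.log(r3) / dn if dn > 0.0 else np.inf
        t4 = -np.log(r4) / dp if dp > 0.0 else np.inf

        channel = RECRUIT
        dt = t1
        if t2 < dt:
            channel = BETA
            dt = t2
        if t3 < dt:
            channel = NURD
            dt = t3
        if t4 < dt:
            channel = PRDUB
            dt = t4

        t_new = t + dt

        # record samples for every boundary crossed; the array is constant
        # on [t, t_new) so boundaries in that window see the pre-move state
        while next_boundary <= t_new and next_boundary <= dur_raw and n_samp < max_samples:
            samples[n_samp, :] = states
            n_samp += 1
            next_boundary += samp_raw

        t = t_new
        if t >= dur_raw:
            break

        stats[channel] += 1
        if channel == RECRUIT:
            r = np.random.randint(0, n)
            s = states[r]
            cnt = recruit_counts[s]
            if cnt > 0:
                if cnt == 1:
                    e = recruit_lists[s, 0]
                else:
                    e = recruit_lists[s, np.random.randint(0, cnt)]
                stats[8 + e] += 1
                tgt = np.random.randint(0, n - 1)
                if tgt >= r:
                    tgt += 1
                new = action[e, states[tgt]]
                if new != 0:
                    p = mult[e] / m_max
                    ok = True
                    if p < 1.0:
                        ok = np.random.random() < p
                    if ok:
                        states[tgt] = new
                        stats[4 + RECRUIT] += 1
                        stats[15 + e] += 1
        elif channel == BETA:
            half = np.random.randint(0, n)
            site = np.random.randint(0, 3)
            s = states[half]
            if site == 0:
                if k27_down[s] != s:
                    states[half] = k27_down[s]
                    stats[4 + BETA] += 1
                else:
                    if np.random.random() < 0.5:
                        states[half] = k27_ac[s]
                    else:
                        states[half] = k27_me3[s]
                    stats[4 + BETA] += 1
            elif site == 1:
                states[half] = k436_toggle[s]
                stats[4 + BETA] += 1
            else:
                states[half] = h2a_toggle[s]
                stats[4 + BETA] += 1
        elif channel == NURD:
            half = np.random.randint(0, n)
            s = states[half]
            if nurd_tab[s] != s:
                states[half] = nurd_tab[s]
                stats[4 + NURD] += 1
        else:
            half = np.random.randint(0, n)
            s = states[half]
            if prdub_tab[s] != s:
                states[half] = prdub_tab[s]
                stats[4 + PRDUB] += 1

        if replication_on and t - last_rep >= gen_raw:
            for k in range(n):
                if np.random.random() < 0.5:
                    states[k] = 8
            if n_rep < max_reps:
                rep_times[n_rep] = t
            n_rep += 1
            last_rep = t
            stats[22] += 1

    return samples, n_samp, rep_times, n_rep, stats
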