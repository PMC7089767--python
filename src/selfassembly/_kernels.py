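"""Numba-compiled Gillespie kernels for the three model variants.

These are the production simulation paths.  Each kernel draws exponential
waiting times from the total propensity and picks a reaction channel with
probability proportional to its propensity (exact SSA).  The pure-Python
channel enumerations in :mod:`selfassembly.ring_gillespie` and
:mod:`selfassembly.variant_models` serve as independent oracles for the
propensity logic and are cross-checked against these kernels in the tests.

Ring kernel bookkeeping
-----------------------
The monomer-attachment ring kernel maintains the full propensity table
(activation, dimerization, left/right attachment, decay) incrementally: an
event touches O(1) occupation numbers, and a change of the active pool of one
species only affects the O(L) channels that consume that species.  Group and
row sums are updated alongside and re-derived from scratch every
``refresh_every`` events to cancel floating-point drift; termination is only
declared after an exact full recomputation yields zero total propensity.

The polymer-polymer and square kernels recompute all propensities each event
(their channel structure changes globally when structures join), using
per-species cumulative polymer counts to keep the cost at O(S*L) per event.
"""

import numpy as np
from numba import njit

TERM_ABSORBED = 0      # total propensity exactly zero (final state)
TERM_PLATEAU = 1       # yield unchanged over the plateau window (Lnuc > 2 recycling)
TERM_MAX_EVENTS = 2    # event budget exhausted
TERM_MASS_ERROR = 3    # mass conservation violated (debug mode only)


@njit(cache=True)
def ring_ssa_kernel(S, L, Lnuc, N, alpha, all_active, mu_vec, delta_vec, nu, V,
                    seed, max_events, plateau_window, snapshot_times,
                    check_mass, refresh_every):
    """Exact SSA for the monomer-attachment ring model.

    Returns ``(term, t, n_rings, n_events, yield_times, n_yield, snaps,
    max_poly, n0, n1, npoly)``.
    """
    np.random.seed(seed)
    n0 = np.zeros(S, dtype=np.int64)
    n1 = np.zeros(S, dtype=np.int64)
    if all_active:
        n1[:] = N
    else:
        n0[:] = N
    npoly = np.zeros((L, S), dtype=np.int64)
    n_rings = 0

    # growth rate constant for a structure of size l (l = 1 is dimerization)
    growth = np.zeros(L)
    for l in range(1, L):
        growth[l] = mu_vec[l - 1] if l < Lnuc else nu

    pact = np.zeros(S)
    pdim = np.zeros(S)
    pr = np.zeros((L, S))   # right-end attachment, rows 2..L-1
    pl = np.zeros((L, S))   # left-end attachment
    pdec = np.zeros((L, S))  # decay, rows 2..Lnuc-1
    rr = np.zeros(L)
    rl = np.zeros(L)
    sums = np.zeros(5)      # act, dim, attach_r, attach_l, decay

    def refresh():
        sums[:] = 0.0
        for s in range(S):
            pact[s] = alpha * n0[s]
            sums[0] += pact[s]
        for s in range(S):
            if S == 1:
                pdim[s] = growth[1] / V * n1[0] * (n1[0] - 1)
            else:
                pdim[s] = growth[1] / V * n1[s] * n1[(s + 1) % S]
            sums[1] += pdim[s]
        for l in range(2, L):
            rr[l] = 0.0
            rl[l] = 0.0
            for s in range(S):
                pr[l, s] = growth[l] / V * n1[(s + l) % S] * npoly[l, s]
                pl[l, s] = growth[l] / V * n1[(s - 1) % S] * npoly[l, s]
                rr[l] += pr[l, s]
                rl[l] += pl[l, s]
            sums[2] += rr[l]
            sums[3] += rl[l]
        for l in range(2, Lnuc):
            for s in range(S):
                pdec[l, s] = delta_vec[l - 2] * npoly[l, s]
                sums[4] += pdec[l, s]

    def upd_act(s):
        new = alpha * n0[s]
        sums[0] += new - pact[s]
        pact[s] = new

    def upd_dim(s):
        if S == 1:
            new = growth[1] / V * n1[0] * (n1[0] - 1)
        else:
            new = growth[1] / V * n1[s] * n1[(s + 1) % S]
        sums[1] += new - pdim[s]
        pdim[s] = new

    def upd_poly(l, s):
        new_r = growth[l] / V * n1[(s + l) % S] * npoly[l, s]
        sums[2] += new_r - pr[l, s]
        rr[l] += new_r - pr[l, s]
        pr[l, s] = new_r
        new_l = growth[l] / V * n1[(s - 1) % S] * npoly[l, s]
        sums[3] += new_l - pl[l, s]
        rl[l] += new_l - pl[l, s]
        pl[l, s] = new_l
        if l < Lnuc:
            new_d = delta_vec[l - 2] * npoly[l, s]
            sums[4] += new_d - pdec[l, s]
            pdec[l, s] = new_d

    def upd_n1(m):
        # channels consuming species-m active monomers
        upd_dim(m)
        if S > 1:
            upd_dim((m - 1) % S)
        for l in range(2, L):
            s_r = (m - l) % S
            if npoly[l, s_r] > 0 or pr[l, s_r] != 0.0:
                upd_poly(l, s_r)
            s_l = (m + 1) % S
            if s_l != s_r and (npoly[l, s_l] > 0 or pl[l, s_l] != 0.0):
                upd_poly(l, s_l)

    refresh()

    maxr = (N * S) // L
    yield_times = np.zeros(maxr + 1)
    n_snap = snapshot_times.shape[0]
    snaps = np.zeros((n_snap, L + 1))
    snap_idx = 0
    t = 0.0
    n_events = 0
    events_since_yield = 0
    cur_poly = 0
    max_poly = 0
    total_mass0 = np.int64(S) * np.int64(N)
    term = TERM_MAX_EVENTS

    amax = 0.0
    while n_events < max_events:
        atot = sums[0] + sums[1] + sums[2] + sums[3] + sums[4]
        if atot <= 1e-10 * amax or atot <= 0.0:
            # incremental sums have drifted to the noise floor; re-derive
            # exactly before deciding whether this is the final state
            refresh()
            atot = sums[0] + sums[1] + sums[2] + sums[3] + sums[4]
            if atot == 0.0:
                term = TERM_ABSORBED
                break
        if atot > amax:
            amax = atot
        wait = -np.log(np.random.random()) / atot
        while snap_idx < n_snap and t + wait >= snapshot_times[snap_idx]:
            snaps[snap_idx, 0] = n0.sum()
            snaps[snap_idx, 1] = n1.sum()
            for l in range(2, L):
                snaps[snap_idx, l] = npoly[l].sum()
            snaps[snap_idx, L] = n_rings
            snap_idx += 1
        t += wait
        r = np.random.random() * atot

        if r < sums[0]:
            # activation
            s = -1
            acc = 0.0
            for k in range(S):
                if pact[k] > 0.0:
                    s = k
                    acc += pact[k]
                    if r < acc:
                        break
            if s < 0:
                # stale group sum (float drift): re-derive and redraw
                refresh()
                continue
            n0[s] -= 1
            n1[s] += 1
            upd_act(s)
            upd_n1(s)
        else:
            r -= sums[0]
            if r < sums[1]:
                # dimerization (or direct ring closure when L == 2)
                s = -1
                acc = 0.0
                for k in range(S):
                    if pdim[k] > 0.0:
                        s = k
                        acc += pdim[k]
                        if r < acc:
                            break
                if s < 0:
                    refresh()
                    continue
                s2 = (s + 1) % S
                n1[s] -= 1
                n1[s2] -= 1
                if L == 2:
                    n_rings += 1
                    yield_times[n_rings - 1] = t
                    events_since_yield = -1
                else:
                    npoly[2, s] += 1
                    upd_poly(2, s)
                    cur_poly += 1
                    if cur_poly > max_poly:
                        max_poly = cur_poly
                upd_n1(s)
                if S > 1:
                    upd_n1(s2)
            else:
                r -= sums[1]
                grew = False
                if r < sums[2] + sums[3]:
                    # attachment at the right (s + l) or left (s - 1) end
                    right = r < sums[2]
                    if not right:
                        r -= sums[2]
                    row = rr if right else rl
                    l = -1
                    for k in range(2, L):
                        if row[k] > 0.0:
                            l = k
                            if r < row[k]:
                                break
                            r -= row[k]
                    tab = pr if right else pl
                    s = -1
                    if l > 0:
                        acc = 0.0
                        for k in range(S):
                            if tab[l, k] > 0.0:
                                s = k
                                acc += tab[l, k]
                                if r < acc:
                                    break
                    if l < 0 or s < 0:
                        refresh()
                        continue
                    m = (s + l) % S if right else (s - 1) % S
                    n1[m] -= 1
                    npoly[l, s] -= 1
                    upd_poly(l, s)
                    if l + 1 == L:
                        n_rings += 1
                        cur_poly -= 1
                        yield_times[n_rings - 1] = t
                        events_since_yield = -1
                    else:
                        snew = s if right else m
                        npoly[l + 1, snew] += 1
                        upd_poly(l + 1, snew)
                    upd_n1(m)
                    grew = True
                if not grew:
                    # decay of a sub-nucleation polymer into active monomers
                    r -= sums[2] + sums[3]
                    l = -1
                    s = -1
                    found = False
                    acc = 0.0
                    for k in range(2, Lnuc):
                        for q in range(S):
                            if pdec[k, q] > 0.0:
                                l = k
                                s = q
                                acc += pdec[k, q]
                                if r < acc:
                                    found = True
                                    break
                        if found:
                            break
                    if l < 0:
                        refresh()
                        continue
                    npoly[l, s] -= 1
                    cur_poly -= 1
                    upd_poly(l, s)
                    for k in range(l):
                        m = (s + k) % S
                        n1[m] += 1
                        upd_n1(m)

        n_events += 1
        events_since_yield += 1
        if check_mass:
            mass = np.int64(0)
            for s in range(S):
                mass += n0[s] + n1[s]
            for l in range(2, L):
                for s in range(S):
                    mass += l * npoly[l, s]
            mass += np.int64(L) * np.int64(n_rings)
            if mass != total_mass0:
                term = TERM_MASS_ERROR
                break
        if n_events % refresh_every == 0:
            refresh()
        if Lnuc > 2 and events_since_yield > plateau_window and n0.sum() == 0:
            term = TERM_PLATEAU
            break

    while snap_idx < n_snap:
        snaps[snap_idx, 0] = n0.sum()
        snaps[snap_idx, 1] = n1.sum()
        for l in range(2, L):
            snaps[snap_idx, l] = npoly[l].sum()
        snaps[snap_idx, L] = n_rings
        snap_idx += 1
    return term, t, n_rings, n_events, yield_times, n_rings, snaps, max_poly, n0, n1, npoly


@njit(cache=True)
def ring_pp_ssa_kernel(S, L, Lnuc, N, alpha, all_active, mu_vec, delta_vec, nu, V,
                       seed, max_events, plateau_window, snapshot_times,
                       check_mass, pp_enabled, closure_factor):
    """Exact SSA for the ring model with polymer-polymer binding.

    Two structures ``(s1, l1)`` and ``(s2, l2)`` join at rate ``nu/V`` per
    junction when ``s2 = s1 + l1 (mod S)`` and ``l1 + l2 <= L``; a combined
    length of exactly ``L`` closes the ring directly.  Ordered-pair
    enumeration counts a closing pair once per junction, so the default
    closure rate per unordered pair is ``2*nu/V`` (``closure_factor`` rescales
    the closing channels; 0.5 gives ``nu/V`` per pair).  With ``pp_enabled``
    false only the monomer channels remain and the model law coincides with
    the plain ring kernel.
    """
    np.random.seed(seed)
    n0 = np.zeros(S, dtype=np.int64)
    n1 = np.zeros(S, dtype=np.int64)
    if all_active:
        n1[:] = N
    else:
        n0[:] = N
    npoly = np.zeros((L, S), dtype=np.int64)
    n_rings = 0

    growth = np.zeros(L)
    for l in range(1, L):
        growth[l] = mu_vec[l - 1] if l < Lnuc else nu

    jrow = np.zeros((L, S))     # join propensity by (l1, s1), rows 2..L-2
    cum = np.zeros((S, L))      # cum[s, k] = sum_{l=2..k} npoly[l, s]

    maxr = (N * S) // L
    yield_times = np.zeros(maxr + 1)
    n_snap = snapshot_times.shape[0]
    snaps = np.zeros((n_snap, L + 1))
    snap_idx = 0
    t = 0.0
    n_events = 0
    events_since_yield = 0
    cur_poly = 0
    max_poly = 0
    total_mass0 = np.int64(S) * np.int64(N)
    term = TERM_MAX_EVENTS

    while n_events < max_events:
        # --- full propensity recomputation -------------------------------
        sact = 0.0
        for s in range(S):
            sact += alpha * n0[s]
        sdim = 0.0
        for s in range(S):
            if S == 1:
                sdim += growth[1] / V * n1[0] * (n1[0] - 1)
            else:
                sdim += growth[1] / V * n1[s] * n1[(s + 1) % S]
        satt_r = 0.0
        satt_l = 0.0
        for l in range(2, L):
            g = growth[l] / V
            for s in range(S):
                if npoly[l, s] > 0:
                    satt_r += g * n1[(s + l) % S] * npoly[l, s]
                    satt_l += g * n1[(s - 1) % S] * npoly[l, s]
        sdec = 0.0
        for l in range(2, Lnuc):
            for s in range(S):
                sdec += delta_vec[l - 2] * npoly[l, s]
        sjoin = 0.0
        if pp_enabled:
            for s in range(S):
                cum[s, 0] = 0.0
                cum[s, 1] = 0.0
                for k in range(2, L):
                    cum[s, k] = cum[s, k - 1] + npoly[k, s]
            gv = nu / V
            for l1 in range(2, L - 1):
                kmax = L - l1
                for s1 in range(S):
                    m = npoly[l1, s1]
                    if m == 0:
                        jrow[l1, s1] = 0.0
                        continue
                    s2 = (s1 + l1) % S
                    w = cum[s2, kmax]
                    if closure_factor != 1.0 and kmax >= 2:
                        w -= (1.0 - closure_factor) * npoly[kmax, s2]
                    if l1 % S == 0 and 2 * l1 <= L:
                        # self-pair: n^2 -> n(n-1), at the closure weight if 2*l1 == L
                        w -= closure_factor if 2 * l1 == L else 1.0
                    jrow[l1, s1] = gv * m * w
                    sjoin += jrow[l1, s1]

        atot = sact + sdim + satt_r + satt_l + sdec + sjoin
        if atot == 0.0:
            term = TERM_ABSORBED
            break
        wait = -np.log(np.random.random()) / atot
        while snap_idx < n_snap and t + wait >= snapshot_times[snap_idx]:
            snaps[snap_idx, 0] = n0.sum()
            snaps[snap_idx, 1] = n1.sum()
            for l in range(2, L):
                snaps[snap_idx, l] = npoly[l].sum()
            snaps[snap_idx, L] = n_rings
            snap_idx += 1
        t += wait
        r = np.random.random() * atot

        # --- channel selection and execution -----------------------------
        if r < sact:
            s = S - 1
            acc = 0.0
            for k in range(S):
                acc += alpha * n0[k]
                if r < acc:
                    s = k
                    break
            n0[s] -= 1
            n1[s] += 1
        elif r < sact + sdim:
            r -= sact
            s = S - 1
            acc = 0.0
            for k in range(S):
                p = (growth[1] / V * n1[0] * (n1[0] - 1) if S == 1
                     else growth[1] / V * n1[k] * n1[(k + 1) % S])
                acc += p
                if r < acc:
                    s = k
                    break
            s2 = (s + 1) % S
            n1[s] -= 1
            n1[s2] -= 1
            if L == 2:
                n_rings += 1
                yield_times[n_rings - 1] = t
                events_since_yield = -1
            else:
                npoly[2, s] += 1
                cur_poly += 1
                if cur_poly > max_poly:
                    max_poly = cur_poly
        elif r < sact + sdim + satt_r + satt_l:
            r -= sact + sdim
            right = r < satt_r
            if not right:
                r -= satt_r
            l = L - 1
            s = S - 1
            found = False
            acc = 0.0
            for k in range(2, L):
                g = growth[k] / V
                for q in range(S):
                    if npoly[k, q] == 0:
                        continue
                    m = (q + k) % S if right else (q - 1) % S
                    acc += g * n1[m] * npoly[k, q]
                    if r < acc:
                        l = k
                        s = q
                        found = True
                        break
                if found:
                    break
            m = (s + l) % S if right else (s - 1) % S
            n1[m] -= 1
            npoly[l, s] -= 1
            if l + 1 == L:
                n_rings += 1
                cur_poly -= 1
                yield_times[n_rings - 1] = t
                events_since_yield = -1
            else:
                npoly[l + 1, s if right else m] += 1
        elif r < sact + sdim + satt_r + satt_l + sdec:
            r -= sact + sdim + satt_r + satt_l
            l = Lnuc - 1
            s = S - 1
            found = False
            acc = 0.0
            for k in range(2, Lnuc):
                for q in range(S):
                    acc += delta_vec[k - 2] * npoly[k, q]
                    if r < acc:
                        l = k
                        s = q
                        found = True
                        break
                if found:
                    break
            npoly[l, s] -= 1
            cur_poly -= 1
            for k in range(l):
                n1[(s + k) % S] += 1
        else:
            # polymer-polymer join
            r -= sact + sdim + satt_r + satt_l + sdec
            l1 = 2
            s1 = 0
            found = False
            for k in range(2, L - 1):
                for q in range(S):
                    if r < jrow[k, q]:
                        l1 = k
                        s1 = q
                        found = True
                        break
                    r -= jrow[k, q]
                if found:
                    break
            # choose the right partner length within the row
            s2 = (s1 + l1) % S
            gvm = nu / V * npoly[l1, s1]
            kmax = L - l1
            l2 = 2
            last_pos = 2
            acc = 0.0
            chosen = False
            for k in range(2, kmax + 1):
                m2 = npoly[k, s2]
                if s2 == s1 and k == l1:
                    m2 -= 1
                if m2 <= 0:
                    continue
                w = closure_factor if l1 + k == L else 1.0
                acc += gvm * m2 * w
                last_pos = k
                if r < acc:
                    l2 = k
                    chosen = True
                    break
            if not chosen:
                l2 = last_pos
            npoly[l1, s1] -= 1
            npoly[l2, s2] -= 1
            if l1 + l2 == L:
                n_rings += 1
                cur_poly -= 2
                yield_times[n_rings - 1] = t
                events_since_yield = -1
            else:
                npoly[l1 + l2, s1] += 1
                cur_poly -= 1

        n_events += 1
        events_since_yield += 1
        if check_mass:
            mass = np.int64(0)
            for s in range(S):
                mass += n0[s] + n1[s]
            for l in range(2, L):
                for s in range(S):
                    mass += l * npoly[l, s]
            mass += np.int64(L) * np.int64(n_rings)
            if mass != total_mass0:
                term = TERM_MASS_ERROR
                break
        if Lnuc > 2 and events_since_yield > plateau_window and n0.sum() == 0:
            term = TERM_PLATEAU
            break

    while snap_idx < n_snap:
        snaps[snap_idx, 0] = n0.sum()
        snaps[snap_idx, 1] = n1.sum()
        for l in range(2, L):
            snaps[snap_idx, l] = npoly[l].sum()
        snaps[snap_idx, L] = n_rings
        snap_idx += 1
    return term, t, n_rings, n_events, yield_times, n_rings, snaps, max_poly, n0, n1, npoly


@njit(cache=True)
def square_ssa_kernel(G, N, alpha, all_active, nu, V, seed, max_events,
                      snapshot_times, check_mass):
    """Exact SSA for assembly of G x G squares from S = G^2 position-species.

    Active monomers at grid-adjacent positions dimerize at rate ``nu/V``;
    a monomer attaches to a cluster that is missing its position with ``b``
    occupied neighbours at rate ``b*nu/V``.  Clusters never merge; the full
    grid is absorbing.
    """
    np.random.seed(seed)
    S = G * G
    n0 = np.zeros(S, dtype=np.int64)
    n1 = np.zeros(S, dtype=np.int64)
    if all_active:
        n1[:] = N
    else:
        n0[:] = N
    nbr = np.full((S, 4), -1, dtype=np.int64)
    for i in range(G):
        for j in range(G):
            p = i * G + j
            if i > 0:
                nbr[p, 0] = (i - 1) * G + j
            if i < G - 1:
                nbr[p, 1] = (i + 1) * G + j
            if j > 0:
                nbr[p, 2] = i * G + j - 1
            if j < G - 1:
                nbr[p, 3] = i * G + j + 1

    maxc = (S * N) // 2 + 1
    occ = np.zeros((maxc, S), dtype=np.uint8)
    csize = np.zeros(maxc, dtype=np.int64)
    alive = np.zeros(maxc, dtype=np.uint8)
    free = np.empty(maxc, dtype=np.int64)
    for i in range(maxc):
        free[i] = maxc - 1 - i
    n_free = maxc
    high = 0
    n_squares = 0

    yield_times = np.zeros(N + 1)
    n_snap = snapshot_times.shape[0]
    snaps = np.zeros((n_snap, S + 1))
    snap_idx = 0
    t = 0.0
    n_events = 0
    cur_poly = 0
    max_poly = 0
    gv = nu / V
    total_mass0 = np.int64(S) * np.int64(N)
    term = TERM_MAX_EVENTS

    while n_events < max_events:
        sact = 0.0
        for p in range(S):
            sact += alpha * n0[p]
        sdim = 0.0
        for p in range(S):
            if n1[p] == 0:
                continue
            for d in range(4):
                q = nbr[p, d]
                if q > p:
                    sdim += gv * n1[p] * n1[q]
        satt = 0.0
        for i in range(high):
            if not alive[i]:
                continue
            for p in range(S):
                if occ[i, p]:
                    continue
                b = 0
                for d in range(4):
                    q = nbr[p, d]
                    if q >= 0 and occ[i, q]:
                        b += 1
                if b > 0 and n1[p] > 0:
                    satt += b * gv * n1[p]
        atot = sact + sdim + satt
        if atot == 0.0:
            term = TERM_ABSORBED
            break
        wait = -np.log(np.random.random()) / atot
        while snap_idx < n_snap and t + wait >= snapshot_times[snap_idx]:
            snaps[snap_idx, 0] = n0.sum()
            snaps[snap_idx, 1] = n1.sum()
            for i in range(high):
                if alive[i]:
                    snaps[snap_idx, csize[i]] += 1.0
            snaps[snap_idx, S] = n_squares
            snap_idx += 1
        t += wait
        r = np.random.random() * atot

        if r < sact:
            p = S - 1
            acc = 0.0
            for k in range(S):
                acc += alpha * n0[k]
                if r < acc:
                    p = k
                    break
            n0[p] -= 1
            n1[p] += 1
        elif r < sact + sdim:
            r -= sact
            pa = 0
            qa = 1
            found = False
            acc = 0.0
            for p in range(S):
                if n1[p] == 0:
                    continue
                for d in range(4):
                    q = nbr[p, d]
                    if q > p:
                        acc += gv * n1[p] * n1[q]
                        if r < acc:
                            pa = p
                            qa = q
                            found = True
                            break
                if found:
                    break
            n1[pa] -= 1
            n1[qa] -= 1
            n_free -= 1
            slot = free[n_free]
            if slot >= high:
                high = slot + 1
            occ[slot, pa] = 1
            occ[slot, qa] = 1
            csize[slot] = 2
            alive[slot] = 1
            cur_poly += 1
            if cur_poly > max_poly:
                max_poly = cur_poly
        else:
            r -= sact + sdim
            ia = 0
            pa = 0
            found = False
            acc = 0.0
            for i in range(high):
                if not alive[i]:
                    continue
                for p in range(S):
                    if occ[i, p] or n1[p] == 0:
                        continue
                    b = 0
                    for d in range(4):
                        q = nbr[p, d]
                        if q >= 0 and occ[i, q]:
                            b += 1
                    if b > 0:
                        acc += b * gv * n1[p]
                        if r < acc:
                            ia = i
                            pa = p
                            found = True
                            break
                if found:
                    break
            n1[pa] -= 1
            occ[ia, pa] = 1
            csize[ia] += 1
            if csize[ia] == S:
                n_squares += 1
                alive[ia] = 0
                csize[ia] = 0
                for p in range(S):
                    occ[ia, p] = 0
                free[n_free] = ia
                n_free += 1
                cur_poly -= 1
                yield_times[n_squares - 1] = t

        n_events += 1
        if check_mass:
            mass = np.int64(0)
            for p in range(S):
                mass += n0[p] + n1[p]
            for i in range(high):
                if alive[i]:
                    mass += csize[i]
            mass += np.int64(S) * np.int64(n_squares)
            if mass != total_mass0:
                term = TERM_MASS_ERROR
                break

    while snap_idx < n_snap:
        snaps[snap_idx, 0] = n0.sum()
        snaps[snap_idx, 1] = n1.sum()
        for i in range(high):
            if alive[i]:
                snaps[snap_idx, csize[i]] += 1.0
        snaps[snap_idx, S] = n_squares
        snap_idx += 1
    return term, t, n_squares, n_events, yield_times, n_squares, snaps, max_poly, n0, n1, occ, csize, alive, high
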