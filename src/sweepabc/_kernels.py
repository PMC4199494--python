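"""Numba-compiled numerical kernels.

Three hot loops live here, kept free of Python objects so batches of tens of
thousands of simulations stay affordable on one CPU:

* :func:`ehh_curve` — extended-haplotype-homozygosity decay scan.
* :func:`wf_trajectory` — forward Wright-Fisher allele-frequency trajectory
  of the focal variant in a two-deme demography (deterministic selection,
  symmetric migration, binomial drift), in rescaled units.
* :func:`conditioned_coalescent` — structured coalescent with recombination
  for the linked neutral variation, conditioned on a focal-site frequency
  trajectory: discrete-generation stepping while the variant exists or the
  demography changes every generation, exponential-jump sampling in the
  deep neutral phase.

All sizes, rates and times entering these kernels are already rescaled by
the caller (sizes N/λ, rates ×λ, generations /λ).

The region is discretised into ``K`` equal-width recombination loci (K ≤ 64,
bitmask in one machine word); mutation positions are continuous within a
locus. Per-lineage ancestral material is the locus bitmask plus, per locus,
a bitset of descendant sample rows, which lets segregating mutations be
emitted on the fly without storing the ancestral recombination graph. A
locus whose descendant set reaches the full sample has found its MRCA and is
pruned from the carrying lineage.
"""

import numpy as np
from numba import njit

# model codes
NTR = 0
SDN = 1
SSV = 2

# conditioned_coalescent status codes
COAL_OK = 0
COAL_OVERFLOW_SITES = 1
COAL_OVERFLOW_LINEAGES = 2

# indices into the mutable state vector shared with _merge
_ACOUNT = 0
_NFREE = 1


@njit(cache=True)
def wf_update(p, s, h):
    """Deterministic selection update with genotype fitnesses 1 : 1+hs : 1+s."""
    q = 1.0 - p
    wbar = p * p * (1.0 + s) + 2.0 * p * q * (1.0 + h * s) + q * q
    return (p * p * (1.0 + s) + p * q * (1.0 + h * s)) / wbar


@njit(cache=True)
def ehh_curve(hap):
    """EHH after successively including each column of ``hap``.

    ``hap`` holds the core-allele carriers only, columns ordered from the
    core outward. Entry ``j`` of the result is the fraction of carrier pairs
    identical over columns ``0..j`` inclusive.
    """
    k, S = hap.shape
    out = np.zeros(S)
    if k < 2:
        return out
    ids = np.zeros(k, np.int64)
    key = np.empty(k, np.int64)
    denom = float(k * (k - 1))
    for j in range(S):
        for i in range(k):
            key[i] = ids[i] * 2 + hap[i, j]
        order = np.argsort(key, kind="mergesort")
        cur = np.int64(-1)
        nid = np.int64(-1)
        cnt = 0
        hom = 0.0
        for t in range(k):
            i = order[t]
            if key[i] != cur:
                if cnt > 1:
                    hom += cnt * (cnt - 1)
                cur = key[i]
                nid += 1
                cnt = 0
            ids[i] = nid
            cnt += 1
        if cnt > 1:
            hom += cnt * (cnt - 1)
        out[j] = hom / denom
        if hom == 0.0:
            break  # homozygosity fully broken; remaining entries stay 0
    return out


@njit(cache=True)
def wf_trajectory(seed, model, g_a, g_m, f0, sA, sNA, h, Tsp,
                  N0, N1, M, G_cap, lam, X0, X1):
    """Forward WF trajectory of the focal variant; returns (ok, G_origin).

    The trajectory itself runs at full (unrescaled) per-generation
    resolution — sizes ``N0``/``N1``, migration ``M`` and the selection
    coefficients are unrescaled, and ``g_a``/``g_m``/``Tsp``/``G_cap`` are
    unrescaled generations before present. This keeps the
    boundary-dominated phases (establishment of a single copy, migrant
    colonisation of the second deme, approach to fixation, the reverse
    pre-onset path) free of rescaling artefacts; failed attempts die young,
    so the unrescaled loop stays cheap.

    Frequencies are recorded on the coalescent's rescaled grid: ``X0[g]``/
    ``X1[g]`` hold the frequency at unrescaled generation ``g * lam``;
    entries beyond the allele's existence stay 0, and the returned
    ``G_origin`` is the oldest grid index at which the allele exists
    (unrescaled origin ``o`` gives ``ceil(o / lam) - 1``).

    * NTR/SDN: one copy appears at generation ``g_a`` (ancestral deme if
      ``g_a >= Tsp``, else the African deme 0) and evolves with selection
      coefficients ``sA`` (deme 0 / ancestral) and ``sNA`` (deme 1); both
      are 0 for NTR.
    * SSV: frequency ``f0`` is imposed in both demes at ``g_m``; the shared
      pre-onset history is a reverse neutral WF path run backward until
      loss (backward fixation means the allele would be ancestral:
      rejected); forward of ``g_m`` deme 1 experiences ``sNA``, deme 0 is
      neutral throughout.

    ``ok`` is True only if the variant segregates (strictly inside (0,1))
    in both demes at present. A negative ``seed`` leaves the generator
    state untouched (used by the batch driver, which seeds once per block).
    """
    if seed >= 0:
        np.random.seed(seed)
    # every grid entry in [0, G_origin] is overwritten below; the single
    # entry beyond the origin that callers may read is zeroed on success
    # (full-array zeroing would dominate the cost of short-lived attempts)

    if model == SSV:
        p = f0
        if g_m % lam == 0:
            X0[g_m // lam] = p
            if g_m < Tsp:
                X1[g_m // lam] = p
        g = g_m
        while p > 0.0:
            g += 1
            if g > G_cap:
                return False, -1
            n2 = int(2.0 * N0[g])
            p = np.random.binomial(n2, p) / n2
            if p >= 1.0:
                return False, -1
            if g % lam == 0:
                X0[g // lam] = p
                if g < Tsp:
                    X1[g // lam] = p
        origin = g
        p0 = f0
        p1 = f0
        g = g_m
        s0 = 0.0
        s1 = sNA
    else:
        s0 = sA if model == SDN else 0.0
        s1 = sNA if model == SDN else 0.0
        origin = g_a
        if g_a >= Tsp:
            p = 1.0 / (2.0 * N0[g_a])
            if g_a % lam == 0:
                X0[g_a // lam] = p
            g = g_a
            while g > Tsp:
                pp = wf_update(p, s0, h)
                n2 = int(2.0 * N0[g - 1])
                p = np.random.binomial(n2, pp) / n2
                if p <= 0.0 or p >= 1.0:
                    return False, -1
                g -= 1
                if g % lam == 0:
                    X0[g // lam] = p
            p0 = p
            p1 = p
        else:
            p0 = 1.0 / (2.0 * N0[g_a])
            p1 = 0.0
            if g_a % lam == 0:
                X0[g_a // lam] = p0
            g = g_a

    while g > 0:
        a0 = wf_update(p0, s0, h)
        a1 = wf_update(p1, s1, h)
        m = M[g]
        b0 = (1.0 - m) * a0 + m * a1
        b1 = (1.0 - m) * a1 + m * a0
        n20 = int(2.0 * N0[g - 1])
        n21 = int(2.0 * N1[g - 1])
        p0 = np.random.binomial(n20, b0) / n20
        p1 = np.random.binomial(n21, b1) / n21
        lost0 = p0 <= 0.0
        lost1 = p1 <= 0.0
        fixed0 = p0 >= 1.0
        fixed1 = p1 >= 1.0
        if (lost0 and lost1) or (fixed0 and fixed1):
            return False, -1  # jointly absorbed; migration cannot recover
        g -= 1
        if g % lam == 0:
            gr = g // lam
            X0[gr] = p0
            if g < Tsp:
                X1[gr] = p1
            elif gr > 0:
                X1[gr] = 0.0

    ok = (0.0 < p0 < 1.0) and (0.0 < p1 < 1.0)
    G_origin = (origin + lam - 1) // lam - 1
    if G_origin < 0:
        G_origin = 0
    if ok:
        # grid entries in [0, G_origin] were all freshly written above;
        # clear the one readable entry beyond the origin and, for alleles
        # older than the split, the meaningless deme-1 entries beyond it
        for gr in range(G_origin + 1, min(G_origin + 3, X0.shape[0])):
            X0[gr] = 0.0
            X1[gr] = 0.0
        if Tsp < origin:
            for gr in range(Tsp // lam, min(G_origin + 1, X1.shape[0])):
                X1[gr] = 0.0
    return ok, G_origin


@njit(cache=True, inline="always")
def _popcount(x):
    x = x - ((x >> np.uint64(1)) & np.uint64(0x5555555555555555))
    x = (x & np.uint64(0x3333333333333333)) + (
        (x >> np.uint64(2)) & np.uint64(0x3333333333333333))
    x = (x + (x >> np.uint64(4))) & np.uint64(0x0F0F0F0F0F0F0F0F)
    return int((x * np.uint64(0x0101010101010101)) >> np.uint64(56))


@njit(cache=True)
def _span_update(i, mask, left, right, K, w):
    """Recompute the material extent of lineage ``i`` from its locus mask."""
    lo = -1
    hi = -1
    m = mask[i]
    for b in range(K):
        if (m >> np.uint64(b)) & np.uint64(1):
            if lo < 0:
                lo = b
            hi = b
    if lo < 0:
        left[i] = 0.0
        right[i] = 0.0
    else:
        left[i] = lo * w
        right[i] = (hi + 1) * w


@njit(cache=True)
def _retire(i, gid, gpos, glist, gcount, alist, apos, free, state):
    """Remove lineage ``i`` from its group and the alive list; free its slot."""
    grp = gid[i]
    pos_ = gpos[i]
    last = glist[grp, gcount[grp] - 1]
    glist[grp, pos_] = last
    gpos[last] = pos_
    gcount[grp] -= 1
    gid[i] = -1
    ap = apos[i]
    lasta = alist[state[_ACOUNT] - 1]
    alist[ap] = lasta
    apos[lasta] = ap
    state[_ACOUNT] -= 1
    free[state[_NFREE]] = i
    state[_NFREE] += 1


@njit(cache=True)
def _move_group(i, dst, gid, gpos, glist, gcount):
    grp = gid[i]
    pos_ = gpos[i]
    last = glist[grp, gcount[grp] - 1]
    glist[grp, pos_] = last
    gpos[last] = pos_
    gcount[grp] -= 1
    gid[i] = dst
    gpos[i] = gcount[dst]
    glist[dst, gcount[dst]] = i
    gcount[dst] += 1


@njit(cache=True)
def _merge(i, j, n, mask, desc, left, right, gid, gpos, glist, gcount,
           alist, apos, free, state, K, W, w, fullset, full_mask):
    """Coalesce lineage ``j`` into ``i``; prune loci that found their MRCA.

    ``j`` is always retired; ``i`` may also be retired if all of its loci
    are done afterwards.
    """
    mask[i] |= mask[j]
    for b in range(K):
        if (mask[j] >> np.uint64(b)) & np.uint64(1):
            full = True
            for q in range(W):
                desc[i, b, q] |= desc[j, b, q]
                if desc[i, b, q] != fullset[q]:
                    full = False
            if full:
                mask[i] &= ~(np.uint64(1) << np.uint64(b)) & full_mask
                for q in range(W):
                    desc[i, b, q] = np.uint64(0)
    mask[j] = np.uint64(0)
    _retire(j, gid, gpos, glist, gcount, alist, apos, free, state)
    if mask[i] == np.uint64(0):
        _retire(i, gid, gpos, glist, gcount, alist, apos, free, state)
    else:
        _span_update(i, mask, left, right, K, w)


@njit(cache=True)
def _split(i, b_bp, keep_left_on_i, n, mask, desc, left, right,
           gid, gpos, glist, gcount, alist, apos, free, state,
           K, W, w, full_mask, new_gid):
    """Recombination split of lineage ``i`` at ``b_bp``.

    The side indicated by ``keep_left_on_i`` stays on ``i``; the other side
    moves to a fresh lineage placed in group ``new_gid``. Returns the new
    lineage index, or -1 if no true split occurred (one side empty) or -2
    on lineage-capacity overflow.
    """
    lmask = np.uint64(0)
    for b in range(K):
        if (b + 0.5) * w < b_bp:
            lmask |= np.uint64(1) << np.uint64(b)
    matL = mask[i] & lmask
    matR = mask[i] & (~lmask & full_mask)
    if matL == np.uint64(0) or matR == np.uint64(0):
        return -1
    if state[_NFREE] == 0:
        return -2
    state[_NFREE] -= 1
    j = free[state[_NFREE]]
    keep = matL if keep_left_on_i else matR
    give = matR if keep_left_on_i else matL
    mask[j] = give
    mask[i] = keep
    for b in range(K):
        if (give >> np.uint64(b)) & np.uint64(1):
            for q in range(W):
                desc[j, b, q] = desc[i, b, q]
                desc[i, b, q] = np.uint64(0)
        else:
            for q in range(W):
                desc[j, b, q] = np.uint64(0)
    _span_update(i, mask, left, right, K, w)
    _span_update(j, mask, left, right, K, w)
    gid[j] = new_gid
    gpos[j] = gcount[new_gid]
    glist[new_gid, gcount[new_gid]] = j
    gcount[new_gid] += 1
    apos[j] = state[_ACOUNT]
    alist[state[_ACOUNT]] = j
    state[_ACOUNT] += 1
    return j


@njit(cache=True)
def _emit_mutation(i, n, mask, desc, focal_pos, K, W, w,
                   out_pos, out_desc, ns):
    """Place one mutation on a uniformly chosen material locus of ``i``.

    Only segregating mutations (carried by 0 < c < n sample rows) are
    recorded. Returns the new site count, or -1 on site-capacity overflow.
    """
    nb = _popcount(mask[i])
    if nb == 0:
        return ns
    tgt = np.random.randint(0, nb)
    loc = -1
    cnt = -1
    for b in range(K):
        if (mask[i] >> np.uint64(b)) & np.uint64(1):
            cnt += 1
            if cnt == tgt:
                loc = b
                break
    pos_bp = loc * w + np.random.random() * w
    if abs(pos_bp - focal_pos) < 1e-9:
        return ns
    csz = 0
    for q in range(W):
        csz += _popcount(desc[i, loc, q])
    if 0 < csz < n:
        if ns >= out_pos.shape[0]:
            return -1
        out_pos[ns] = pos_bp
        for q in range(W):
            out_desc[ns, q] = desc[i, loc, q]
        ns += 1
    return ns


@njit(cache=True)
def conditioned_coalescent(
    seed,
    n0, d0, n1, d1,
    Tsp, G_origin, G_step,
    N0, N1, M, X0, X1,
    ep_start, ep_N,
    L, focal_pos, K, mu_r, rec_r,
    out_pos, out_desc,
):
    """Structured coalescent conditioned on a focal-allele trajectory.

    Samples ``n0`` haplotypes from deme 0 (rows 0..n0-1, of which the first
    ``d0`` carry the derived focal allele) and ``n1`` from deme 1 (rows
    n0..n0+n1-1, first ``d1`` derived). Generations 0..G_step are stepped
    one by one; older history uses exponential-jump sampling over the
    piecewise-constant ancestral epochs ``ep_start``/``ep_N`` (start
    generations ascending, first at or below ``G_step``).

    The caller guarantees ``G_step > G_origin`` and that any exponential
    growth epochs lie inside the stepped phase, so the jump phase only ever
    sees one deme, one class and constant sizes.

    Returns ``(status, n_sites)``; mutations land in ``out_pos`` (bp) and
    ``out_desc`` (carrier-row bitsets, ``ceil(n/64)`` words per site).
    """
    np.random.seed(seed)
    n = n0 + n1
    W = out_desc.shape[1]
    w = L / K
    full_mask = np.uint64(0xFFFFFFFFFFFFFFFF) >> np.uint64(64 - K)

    C = 4 * n + 256
    mask = np.zeros(C, np.uint64)
    desc = np.zeros((C, K, W), np.uint64)
    left = np.zeros(C)
    right = np.zeros(C)
    gid = np.full(C, -1, np.int8)       # deme*2 + class, -1 = retired
    gpos = np.zeros(C, np.int32)
    glist = np.zeros((4, C), np.int32)
    gcount = np.zeros(4, np.int32)
    alist = np.zeros(C, np.int32)
    apos = np.zeros(C, np.int32)
    free = np.empty(C, np.int32)
    state = np.zeros(2, np.int64)       # [alive count, free count]
    for i in range(C - 1, n - 1, -1):
        free[state[_NFREE]] = i
        state[_NFREE] += 1

    fullset = np.zeros(W, np.uint64)
    for r in range(n):
        fullset[r >> 6] |= np.uint64(1) << np.uint64(r & 63)

    for i in range(n):
        mask[i] = full_mask
        left[i] = 0.0
        right[i] = L
        if i < n0:
            g_ = 1 if i < d0 else 0
        else:
            g_ = 3 if (i - n0) < d1 else 2
        gid[i] = g_
        gpos[i] = gcount[g_]
        glist[g_, gcount[g_]] = i
        gcount[g_] += 1
        apos[i] = state[_ACOUNT]
        alist[state[_ACOUNT]] = i
        state[_ACOUNT] += 1
        for loc in range(K):
            desc[i, loc, i >> 6] = np.uint64(1) << np.uint64(i & 63)

    ns = 0
    pbound = L * mu_r + L * rec_r  # per-lineage per-generation event bound

    # =============== phase 1: per-generation stepping ==================
    for g in range(G_step):
        if state[_ACOUNT] <= 1:
            break
        parent = g + 1
        xp0 = X0[parent] if parent < X0.shape[0] else 0.0
        xp1 = X1[parent] if parent < X1.shape[0] else 0.0
        two_demes = parent < Tsp

        # merge demes at the split
        if not two_demes and (gcount[2] > 0 or gcount[3] > 0):
            for c in range(2):
                src = 2 + c
                while gcount[src] > 0:
                    _move_group(glist[src, gcount[src] - 1], c,
                                gid, gpos, glist, gcount)

        # backward migration, per (deme, class) group
        if two_demes:
            m = M[parent]
            if m > 0.0:
                for grp in range(4):
                    k = gcount[grp]
                    if k == 0:
                        continue
                    d = grp >> 1
                    c = grp & 1
                    if d == 0:
                        x_own = xp0 if c == 1 else 1.0 - xp0
                        x_oth = xp1 if c == 1 else 1.0 - xp1
                    else:
                        x_own = xp1 if c == 1 else 1.0 - xp1
                        x_oth = xp0 if c == 1 else 1.0 - xp0
                    denom = (1.0 - m) * x_own + m * x_oth
                    if denom <= 0.0:
                        pm = 1.0 if x_oth > 0.0 else 0.0
                    else:
                        pm = min(m * x_oth / denom, 1.0)
                    if pm <= 0.0:
                        continue
                    nm = np.random.binomial(k, pm)
                    dst = (1 - d) * 2 + c
                    for _ in range(nm):
                        pos_ = np.random.randint(0, gcount[grp])
                        _move_group(glist[grp, pos_], dst,
                                    gid, gpos, glist, gcount)

        # mutation / recombination events, thinned against pbound
        conditioned = parent <= G_origin
        nev = np.random.binomial(state[_ACOUNT], pbound)
        for _ in range(nev):
            i = alist[np.random.randint(0, state[_ACOUNT])]
            if conditioned:
                lo = left[i] if left[i] < focal_pos else focal_pos
                hi = right[i] if right[i] > focal_pos else focal_pos
            else:
                lo = left[i]
                hi = right[i]
            span = hi - lo
            matbp = _popcount(mask[i]) * w
            u = np.random.random() * pbound
            if u < mu_r * matbp:
                ns = _emit_mutation(i, n, mask, desc, focal_pos, K, W, w,
                                    out_pos, out_desc, ns)
                if ns < 0:
                    return COAL_OVERFLOW_SITES, out_pos.shape[0]
            elif u < mu_r * matbp + rec_r * span:
                b_bp = lo + np.random.random() * span
                grp = gid[i]
                d = grp >> 1
                xd = 0.0
                if conditioned:
                    xd = xp0 if d == 0 else xp1
                focal_left = focal_pos < b_bp
                # the side carrying the focal position keeps the class
                cls_new = 1 if np.random.random() < xd else 0
                j = _split(i, b_bp, focal_left, n, mask, desc, left, right,
                           gid, gpos, glist, gcount, alist, apos, free,
                           state, K, W, w, full_mask, d * 2 + cls_new)
                if j == -2:
                    return COAL_OVERFLOW_LINEAGES, ns
                if j == -1:
                    # breakpoint between the material block and the focal
                    # site: the whole lineage hops onto a random background
                    material_left = right[i] <= b_bp
                    if material_left != focal_left and cls_new != (grp & 1):
                        _move_group(i, d * 2 + cls_new,
                                    gid, gpos, glist, gcount)

        # forced collapse of the derived class once the allele is gone
        if parent > G_origin:
            for d in range(2):
                grp = d * 2 + 1
                while gcount[grp] >= 2:
                    i = glist[grp, 0]
                    j = glist[grp, gcount[grp] - 1]
                    _merge(i, j, n, mask, desc, left, right, gid, gpos,
                           glist, gcount, alist, apos, free, state,
                           K, W, w, fullset, full_mask)
                if gcount[grp] == 1:
                    _move_group(glist[grp, 0], d * 2,
                                gid, gpos, glist, gcount)

        # coalescence within each (deme, class) group
        for grp in range(4):
            k = gcount[grp]
            if k < 2:
                continue
            d = grp >> 1
            c = grp & 1
            if d == 1 and not two_demes:
                continue
            if d == 0:
                Nd = N0[parent]
                xc = xp0 if c == 1 else 1.0 - xp0
            else:
                Nd = N1[parent]
                xc = xp1 if c == 1 else 1.0 - xp1
            Mi = int(2.0 * Nd * xc + 0.5)
            if Mi < 1:
                Mi = 1
            lam = 0.5 * k * (k - 1) / Mi
            if lam < 0.02:
                if np.random.random() < lam:
                    a_ = np.random.randint(0, k)
                    b_ = np.random.randint(0, k - 1)
                    if b_ >= a_:
                        b_ += 1
                    _merge(glist[grp, a_], glist[grp, b_], n, mask, desc,
                           left, right, gid, gpos, glist, gcount, alist,
                           apos, free, state, K, W, w, fullset, full_mask)
            else:
                draws = np.empty(k, np.int64)
                members = np.empty(k, np.int32)
                for t in range(k):
                    draws[t] = np.random.randint(0, Mi)
                    members[t] = glist[grp, t]
                order = np.argsort(draws, kind="mergesort")
                t = 0
                while t < k:
                    t2 = t + 1
                    i = members[order[t]]
                    while t2 < k and draws[order[t2]] == draws[order[t]]:
                        j = members[order[t2]]
                        if gid[j] == -1:
                            t2 += 1
                            continue
                        if gid[i] == -1:
                            i = j
                            t2 += 1
                            continue
                        _merge(i, j, n, mask, desc, left, right, gid, gpos,
                               glist, gcount, alist, apos, free, state,
                               K, W, w, fullset, full_mask)
                        t2 += 1
                    t = t2

    # =============== phase 2: deep neutral phase =======================
    t_now = float(G_step)
    n_ep = ep_start.shape[0]
    ei = 0
    while ei + 1 < n_ep and ep_start[ei + 1] <= t_now:
        ei += 1
    guard = 0
    while state[_ACOUNT] > 1:
        guard += 1
        if guard > 50_000_000:
            break
        k = int(state[_ACOUNT])
        span_sum = 0.0
        mat_sum = 0.0
        for t in range(k):
            i = alist[t]
            span_sum += right[i] - left[i]
            mat_sum += _popcount(mask[i]) * w
        rc = 0.5 * k * (k - 1) / (2.0 * ep_N[ei])
        rr = rec_r * span_sum
        rm = mu_r * mat_sum
        tot = rc + rr + rm
        if tot <= 0.0:
            break
        dt = -np.log(np.random.random()) / tot
        if ei + 1 < n_ep and t_now + dt > ep_start[ei + 1]:
            t_now = ep_start[ei + 1]
            ei += 1
            continue
        t_now += dt
        u = np.random.random() * tot
        if u < rc:
            a_ = np.random.randint(0, k)
            b_ = np.random.randint(0, k - 1)
            if b_ >= a_:
                b_ += 1
            _merge(alist[a_], alist[b_], n, mask, desc, left, right,
                   gid, gpos, glist, gcount, alist, apos, free, state,
                   K, W, w, fullset, full_mask)
        elif u < rc + rr:
            pick = (u - rc) / rec_r
            acc = 0.0
            i = alist[0]
            for t in range(k):
                i = alist[t]
                acc += right[i] - left[i]
                if acc >= pick:
                    break
            span = right[i] - left[i]
            if span <= 0.0:
                continue
            b_bp = left[i] + np.random.random() * span
            j = _split(i, b_bp, True, n, mask, desc, left, right,
                       gid, gpos, glist, gcount, alist, apos, free,
                       state, K, W, w, full_mask, gid[i])
            if j == -2:
                return COAL_OVERFLOW_LINEAGES, ns
        else:
            pick = (u - rc - rr) / mu_r
            acc = 0.0
            i = alist[0]
            for t in range(k):
                i = alist[t]
                acc += _popcount(mask[i]) * w
                if acc >= pick:
                    break
            ns = _emit_mutation(i, n, mask, desc, focal_pos, K, W, w,
                                out_pos, out_desc, ns)
            if ns < 0:
                return COAL_OVERFLOW_SITES, out_pos.shape[0]

    return COAL_OK, ns


@njit(cache=True)
def wf_trajectory_batch(seeds, models, g_a, g_m, f0, sA, sNA, h, Tsp,
                        N0, N1, M, G_cap, lam, X0, X1):
    """Run :func:`wf_trajectory` over a block of prior draws and return the
    index of the first draw whose trajectory satisfies the conditioning
    (with its origin grid index), or (-1, -1) if the whole block failed.

    The generator is seeded once per block (re-seeding per attempt would
    dominate the cost of short-lived rejected draws)."""
    np.random.seed(seeds[0])
    for t in range(seeds.shape[0]):
        ok, origin = wf_trajectory(
            -1, models[t], g_a[t], g_m[t], f0[t], sA[t], sNA[t],
            h, Tsp, N0, N1, M, G_cap, lam, X0, X1)
        if ok:
            return t, origin
    return -1, -1
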