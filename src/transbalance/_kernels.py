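"""Numba kernels for the structured-coalescent simulator.

Everything here works on flat float/int arrays so it can be JIT-compiled;
the friendly wrappers live in :mod:`transbalance.simdata`. Conventions:

* time runs backwards in generations; sizes are haploid lineage counts and
  a pair of lineages in a population of size N coalesces at rate 1/N;
* waiting times use hazard integration across rate breakpoints (a single
  Exp(1) draw is spent per event, never redrawn at an epoch boundary), so
  two models whose event rates coincide consume identical random streams;
* nodes of the returned genealogy are numbered 0..2n-2 with tips first and
  internal nodes in increasing time order; ``parent[root] == -1``.
* bases are encoded A=0, C=1, G=2, T=3.
"""

import numpy as np
from numba import njit

INF = 1.0e300


@njit(cache=True)
def _size_at(t, starts, sizes):
    idx = np.searchsorted(starts, t, side="right") - 1
    if idx < 0:
        idx = 0
    return sizes[idx]


@njit(cache=True)
def _next_breakpoint(t, starts_a, starts_c, split_time, origin_time, mig_lo, mig_hi):
    nxt = INF
    for arr in (starts_a, starts_c):
        for i in range(arr.shape[0]):
            if arr[i] > t and arr[i] < nxt:
                nxt = arr[i]
    for b in (split_time, origin_time, mig_lo, mig_hi):
        if b > t and b < nxt:
            nxt = b
    return nxt


@njit(cache=True)
def sim_genealogy(
    n_a,
    n_c,
    starts_a,
    sizes_a,
    starts_c,
    sizes_c,
    split_time,
    anc_size,
    back_rate_a,   # backwards per-lineage rate: lineage in A jumps to C
    back_rate_c,   # backwards per-lineage rate: lineage in C jumps to A
    mig_lo,
    mig_hi,
    tip_class,     # int8 array of length n_a+n_c, allelic class per tip
    f0,            # frequency of class 0 (1.0 for neutral, single class)
    exchange_rate,
    origin_time,
):
    """Simulate one genealogy under the two-species structured coalescent.

    Returns (parent, time) arrays of length 2n-1.
    """
    n = n_a + n_c
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes, dtype=np.float64)

    act_id = np.empty(n, dtype=np.int64)
    act_sp = np.empty(n, dtype=np.int8)
    act_cl = np.empty(n, dtype=np.int8)
    for i in range(n):
        act_id[i] = i
        act_sp[i] = 0 if i < n_a else 1
        act_cl[i] = tip_class[i]
    n_act = n
    next_node = n

    t = 0.0
    merged_species = split_time <= 0.0
    merged_classes = origin_time <= 0.0 or f0 >= 1.0
    if merged_species:
        for i in range(n_act):
            act_sp[i] = 0
    if merged_classes:
        for i in range(n_act):
            act_cl[i] = 0

    freqs = np.empty(2, dtype=np.float64)
    freqs[0] = f0
    freqs[1] = 1.0 - f0

    while n_act > 1:
        # draw the hazard budget for the next event
        target = -np.log(np.random.random())
        acc = 0.0
        while True:
            # deme counts
            k = np.zeros((2, 2), dtype=np.int64)
            for i in range(n_act):
                k[act_sp[i], act_cl[i]] += 1
            # per-deme sizes at current time
            if merged_species:
                n_pop_a = anc_size
                n_pop_c = anc_size
            else:
                n_pop_a = _size_at(t, starts_a, sizes_a)
                n_pop_c = _size_at(t, starts_c, sizes_c)
            lam = 0.0
            coal_rate = np.zeros((2, 2), dtype=np.float64)
            for s in range(2):
                for c in range(2):
                    kk = k[s, c]
                    if kk >= 2:
                        npop = n_pop_a if s == 0 else n_pop_c
                        fc = freqs[c] if not merged_classes else 1.0
                        r = kk * (kk - 1) * 0.5 / (fc * npop)
                        coal_rate[s, c] = r
                        lam += r
            mig_active = (not merged_species) and (t >= mig_lo) and (t < mig_hi)
            mrate_a = back_rate_a if mig_active else 0.0
            mrate_c = back_rate_c if mig_active else 0.0
            lam += (k[0, 0] + k[0, 1]) * mrate_a + (k[1, 0] + k[1, 1]) * mrate_c
            ex_rate = exchange_rate if not merged_classes else 0.0
            lam += n_act * ex_rate

            bp = _next_breakpoint(
                t, starts_a, starts_c, split_time, origin_time, mig_lo, mig_hi
            )
            if lam > 0.0 and acc + lam * (bp - t) >= target:
                t += (target - acc) / lam
                break
            # advance to the breakpoint, applying structural changes
            acc += lam * (bp - t)
            t = bp
            if t >= split_time and not merged_species:
                merged_species = True
                for i in range(n_act):
                    act_sp[i] = 0
            if t >= origin_time and not merged_classes:
                merged_classes = True
                for i in range(n_act):
                    act_cl[i] = 0
            if bp >= INF:
                # no events possible and no structure left: should not happen
                break

        # select the event class
        u = np.random.random() * lam
        # recompute category rates (same values as above at time t)
        chosen = -1  # 0..3 coal (s*2+c), 4 mig A->C, 5 mig C->A, 6 exchange
        acc2 = 0.0
        for s in range(2):
            for c in range(2):
                acc2 += coal_rate[s, c]
                if u < acc2:
                    chosen = s * 2 + c
                    break
            if chosen >= 0:
                break
        if chosen < 0:
            acc2 += (k[0, 0] + k[0, 1]) * mrate_a
            if u < acc2:
                chosen = 4
            else:
                acc2 += (k[1, 0] + k[1, 1]) * mrate_c
                if u < acc2:
                    chosen = 5
                else:
                    chosen = 6

        if chosen <= 3:
            s = chosen // 2
            c = chosen % 2
            # pick an unordered pair uniformly within deme (s, c)
            kk = k[s, c]
            i1 = int(np.random.random() * kk)
            i2 = int(np.random.random() * (kk - 1))
            if i2 >= i1:
                i2 += 1
            # map deme-local indices to active-array indices
            seen = 0
            a1 = -1
            a2 = -1
            for i in range(n_act):
                if act_sp[i] == s and act_cl[i] == c:
                    if seen == i1:
                        a1 = i
                    if seen == i2:
                        a2 = i
                    seen += 1
            node_time[next_node] = t
            parent[act_id[a1]] = next_node
            parent[act_id[a2]] = next_node
            # replace a1 with the new node, remove a2 (swap with last)
            act_id[a1] = next_node
            last = n_act - 1
            act_id[a2] = act_id[last]
            act_sp[a2] = act_sp[last]
            act_cl[a2] = act_cl[last]
            n_act -= 1
            next_node += 1
        elif chosen == 4 or chosen == 5:
            s = 0 if chosen == 4 else 1
            kk = k[s, 0] + k[s, 1]
            pick = int(np.random.random() * kk)
            seen = 0
            for i in range(n_act):
                if act_sp[i] == s:
                    if seen == pick:
                        act_sp[i] = 1 - s
                        break
                    seen += 1
        else:
            pick = int(np.random.random() * n_act)
            act_cl[pick] = 1 - act_cl[pick]

    return parent, node_time


@njit(cache=True)
def drop_mutations(parent, node_time, n_tips, anc, site_rates):
    """Place finite-sites mutations on a genealogy.

    Mutations are a Poisson process on branches with per-site rates
    ``site_rates``; each mutation replaces the current base by one of the
    other three uniformly (multiple hits allowed). Returns the tips x L
    genotype matrix (uint8 base codes).
    """
    n_nodes = parent.shape[0]
    L = anc.shape[0]
    total = 0.0
    cum = np.empty(L, dtype=np.float64)
    for i in range(L):
        total += site_rates[i]
        cum[i] = total

    states = np.empty((n_nodes, L), dtype=np.uint8)
    root = n_nodes - 1
    for j in range(L):
        states[root, j] = anc[j]

    # nodes are created in increasing time order, so descending id order
    # visits parents before children
    for node in range(n_nodes - 2, -1, -1):
        p = parent[node]
        for j in range(L):
            states[node, j] = states[p, j]
        blen = node_time[p] - node_time[node]
        if blen <= 0.0:
            continue
        nm = np.random.poisson(blen * total)
        if nm == 0:
            continue
        sites = np.empty(nm, dtype=np.int64)
        times = np.empty(nm, dtype=np.float64)
        for m in range(nm):
            u = np.random.random() * total
            sites[m] = np.searchsorted(cum, u, side="right")
            times[m] = node_time[node] + np.random.random() * blen
        order = np.argsort(-times)  # oldest first
        for oi in range(nm):
            m = order[oi]
            j = sites[m]
            cur = states[node, j]
            states[node, j] = (cur + 1 + int(np.random.random() * 3)) % 4

    return states[:n_tips, :]


@njit(cache=True)
def cpg_site_rates(anc, mu_base, cpg_multiplier):
    """Per-site rates: CpG class iff the centred trinucleotide has a CG
    dinucleotide overlapping the focal base (C followed by G)."""
    L = anc.shape[0]
    rates = np.empty(L, dtype=np.float64)
    for i in range(L):
        is_cpg = False
        if anc[i] == 1 and i + 1 < L and anc[i + 1] == 2:
            is_cpg = True
        if anc[i] == 2 and i - 1 >= 0 and anc[i - 1] == 1:
            is_cpg = True
        rates[i] = mu_base * cpg_multiplier if is_cpg else mu_base
    return rates


@njit(cache=True)
def draw_sequence(L, base_cum):
    seq = np.empty(L, dtype=np.uint8)
    for i in range(L):
        u = np.random.random()
        b = 0
        while b < 3 and u >= base_cum[b]:
            b += 1
        seq[i] = b
    return seq


@njit(cache=True)
def _column_counts(geno, col, lo, hi):
    counts = np.zeros(4, dtype=np.int64)
    for i in range(lo, hi):
        counts[geno[i, col]] += 1
    return counts


@njit(cache=True)
def shared_biallelic_columns(geno, n_a, maf_min):
    """Columns bi-allelic in both species with the identical allele pair and
    MAF > maf_min in each. Returns (columns, n_found)."""
    n, L = geno.shape
    out = np.empty(L, dtype=np.int64)
    found = 0
    for col in range(L):
        ca = _column_counts(geno, col, 0, n_a)
        cc = _column_counts(geno, col, n_a, n)
        na1 = 0
        nc1 = 0
        a_alleles = np.empty(2, dtype=np.int64)
        c_alleles = np.empty(2, dtype=np.int64)
        ok = True
        for b in range(4):
            if ca[b] > 0:
                if na1 < 2:
                    a_alleles[na1] = b
                na1 += 1
            if cc[b] > 0:
                if nc1 < 2:
                    c_alleles[nc1] = b
                nc1 += 1
        if na1 != 2 or nc1 != 2:
            continue
        if a_alleles[0] != c_alleles[0] or a_alleles[1] != c_alleles[1]:
            continue
        maf_a = min(ca[a_alleles[0]], ca[a_alleles[1]]) / n_a
        maf_c = min(cc[c_alleles[0]], cc[c_alleles[1]]) / (n - n_a)
        if maf_a > maf_min and maf_c > maf_min:
            out[found] = col
            found += 1
    return out[:found], found


@njit(cache=True)
def r2_pair(geno, col1, col2, lo, hi):
    """Haploid r^2 between two columns within rows [lo, hi).

    Returns -1.0 if either column is not bi-allelic within the slice."""
    c1 = _column_counts(geno, col1, lo, hi)
    c2 = _column_counts(geno, col2, lo, hi)
    a0 = -1
    b0 = -1
    n1 = 0
    n2 = 0
    for b in range(4):
        if c1[b] > 0:
            if a0 < 0:
                a0 = b
            n1 += 1
        if c2[b] > 0:
            if b0 < 0:
                b0 = b
            n2 += 1
    if n1 != 2 or n2 != 2:
        return -1.0
    n = hi - lo
    p = c1[a0] / n
    q = c2[b0] / n
    pab = 0.0
    for i in range(lo, hi):
        if geno[i, col1] == a0 and geno[i, col2] == b0:
            pab += 1.0
    pab /= n
    denom = p * (1 - p) * q * (1 - q)
    if denom <= 0.0:
        return -1.0
    d = pab - p * q
    return d * d / denom


@njit(cache=True)
def has_ld_pair(geno, cols, n_a, r2_min):
    """True if some pair of the given columns has r^2 > r2_min in both
    species. Also returns the qualifying column mask."""
    m = cols.shape[0]
    n = geno.shape[0]
    qual = np.zeros(m, dtype=np.uint8)
    any_pair = False
    for i in range(m):
        for j in range(i + 1, m):
            ra = r2_pair(geno, cols[i], cols[j], 0, n_a)
            if ra <= r2_min:
                continue
            rc = r2_pair(geno, cols[i], cols[j], n_a, n)
            if rc > r2_min:
                any_pair = True
                qual[i] = 1
                qual[j] = 1
    return any_pair, qual


@njit(cache=True)
def simulate_window_geno(
    seed,
    n_a,
    n_c,
    L,
    starts_a,
    sizes_a,
    starts_c,
    sizes_c,
    split_time,
    anc_size,
    back_rate_a,
    back_rate_c,
    mig_lo,
    mig_hi,
    tip_class,
    f0,
    exchange_rate,
    origin_time,
    mu_base,
    cpg_multiplier,
    base_cum,
):
    """One seeded window: ancestral draw + genealogy + mutations."""
    np.random.seed(seed)
    anc = draw_sequence(L, base_cum)
    rates = cpg_site_rates(anc, mu_base, cpg_multiplier)
    parent, node_time = sim_genealogy(
        n_a, n_c, starts_a, sizes_a, starts_c, sizes_c, split_time, anc_size,
        back_rate_a, back_rate_c, mig_lo, mig_hi,
        tip_class, f0, exchange_rate, origin_time,
    )
    geno = drop_mutations(parent, node_time, n_a + n_c, anc, rates)
    return geno, anc, parent, node_time


@njit(cache=True)
def neutral_window_screen_batch(
    seed,
    n_windows,
    n_a,
    n_c,
    L,
    starts_a,
    sizes_a,
    starts_c,
    sizes_c,
    split_time,
    anc_size,
    back_rate_a,
    back_rate_c,
    mig_lo,
    mig_hi,
    mu_base,
    cpg_multiplier,
    base_cum,
    maf_min,
    r2_min,
    max_keep,
):
    """Simulate a batch of neutral windows and screen them through the
    shared-SNP and LD stages of the scan criteria chain.

    Returns (n_with_shared, n_with_two_shared, n_ld_pass, kept_geno, n_kept)
    where ``kept_geno`` holds the genotype matrices of up to ``max_keep``
    windows that pass the LD stage (these still need tree classification).
    """
    np.random.seed(seed)
    tip_class = np.zeros(n_a + n_c, dtype=np.int8)
    c_shared = 0
    c_two = 0
    c_ld = 0
    kept = np.zeros((max_keep, n_a + n_c, L), dtype=np.uint8)
    n_kept = 0
    for _ in range(n_windows):
        anc = draw_sequence(L, base_cum)
        rates = cpg_site_rates(anc, mu_base, cpg_multiplier)
        parent, node_time = sim_genealogy(
            n_a, n_c, starts_a, sizes_a, starts_c, sizes_c, split_time,
            anc_size, back_rate_a, back_rate_c, mig_lo, mig_hi,
            tip_class, 1.0, 0.0, INF,
        )
        geno = drop_mutations(parent, node_time, n_a + n_c, anc, rates)
        cols, nf = shared_biallelic_columns(geno, n_a, maf_min)
        if nf >= 1:
            c_shared += 1
        if nf >= 2:
            c_two += 1
            ok, _qual = has_ld_pair(geno, cols, n_a, r2_min)
            if ok:
                c_ld += 1
                if n_kept < max_keep:
                    kept[n_kept, :, :] = geno
                    n_kept += 1
    return c_shared, c_two, c_ld, kept, n_kept


@njit(cache=True)
def sfs_branch_batch(
    seed,
    n_sims,
    n_a,
    n_c,
    starts_a,
    sizes_a,
    starts_c,
    sizes_c,
    split_time,
    anc_size,
    back_rate_a,
    back_rate_c,
    mig_lo,
    mig_hi,
    mu,
):
    """Monte-Carlo expected joint-SFS cell probabilities.

    Per simulated genealogy: the site is monomorphic with probability
    exp(-mu * L_tot); otherwise the (single) mutation lands on a branch with
    probability proportional to its length, contributing to the cell
    (i, j) = (derived tips in species A, in species C). Returns the
    (n_a+1) x (n_c+1) matrix of *summed per-sim probabilities* with the
    monomorphic mass in cell (0, 0); dividing by n_sims gives probabilities
    summing to 1. The known mutation rate anchors the absolute time scale.
    """
    np.random.seed(seed)
    tip_class = np.zeros(n_a + n_c, dtype=np.int8)
    n = n_a + n_c
    n_nodes = 2 * n - 1
    out = np.zeros((n_a + 1, n_c + 1), dtype=np.float64)
    for _ in range(n_sims):
        parent, node_time = sim_genealogy(
            n_a, n_c, starts_a, sizes_a, starts_c, sizes_c, split_time,
            anc_size, back_rate_a, back_rate_c, mig_lo, mig_hi,
            tip_class, 1.0, 0.0, INF,
        )
        da = np.zeros(n_nodes, dtype=np.int64)
        dc = np.zeros(n_nodes, dtype=np.int64)
        for i in range(n_a):
            da[i] = 1
        for i in range(n_a, n):
            dc[i] = 1
        total = 0.0
        for node in range(n_nodes - 1):
            p = parent[node]
            da[p] += da[node]
            dc[p] += dc[node]
            total += node_time[p] - node_time[node]
        p_mono = np.exp(-mu * total)
        out[0, 0] += p_mono
        w = (1.0 - p_mono) / total
        for node in range(n_nodes - 1):
            i = da[node]
            j = dc[node]
            blen = node_time[parent[node]] - node_time[node]
            out[i, j] += w * blen
    return out


@njit(cache=True)
def site_sfs_sample_batch(
    seed,
    n_sites,
    n_a,
    n_c,
    starts_a,
    sizes_a,
    starts_c,
    sizes_c,
    split_time,
    anc_size,
    back_rate_a,
    back_rate_c,
    mig_lo,
    mig_hi,
    mu,
):
    """Simulate independent sites: each site draws its own genealogy; it is
    polymorphic/divergent with probability 1 - exp(-mu * total_length) and
    the mutation lands on a branch chosen proportional to length. Returns
    the observed unfolded joint SFS counts (monomorphic mass at (0,0))."""
    np.random.seed(seed)
    tip_class = np.zeros(n_a + n_c, dtype=np.int8)
    n = n_a + n_c
    n_nodes = 2 * n - 1
    out = np.zeros((n_a + 1, n_c + 1), dtype=np.int64)
    for _ in range(n_sites):
        parent, node_time = sim_genealogy(
            n_a, n_c, starts_a, sizes_a, starts_c, sizes_c, split_time,
            anc_size, back_rate_a, back_rate_c, mig_lo, mig_hi,
            tip_class, 1.0, 0.0, INF,
        )
        total = 0.0
        for node in range(n_nodes - 1):
            total += node_time[parent[node]] - node_time[node]
        if np.random.random() >= 1.0 - np.exp(-mu * total):
            out[0, 0] += 1
            continue
        u = np.random.random() * total
        acc = 0.0
        hit = 0
        for node in range(n_nodes - 1):
            acc += node_time[parent[node]] - node_time[node]
            if u < acc:
                hit = node
                break
        da = np.zeros(n_nodes, dtype=np.int64)
        dc = np.zeros(n_nodes, dtype=np.int64)
        for i in range(n_a):
            da[i] = 1
        for i in range(n_a, n):
            dc[i] = 1
        for node in range(n_nodes - 1):
            p = parent[node]
            da[p] += da[node]
            dc[p] += dc[node]
        out[da[hit], dc[hit]] += 1
    return out
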