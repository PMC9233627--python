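"""numba kernels for the jump-chain inner loop.

The acceptance experiments need on the order of 10^5-10^6 branch
realizations and 10^4 whole-tree simulations, so the event loop (draw dwell
time, pick the event proportionally to its rate, apply it, refresh the
three affected rate rows) is JIT-compiled. The arithmetic mirrors
`substitution_model` exactly: one row of the rate table is the product
phi[target] * kappa^[ts] * omega_site^[nonsyn] * lam^[CpG] * scale, with
CpG context read from the flanking codons at the moment of the event.

numba's in-jit ``np.random`` implements the same MT19937 stream as NumPy's
legacy ``RandomState``; the pure-Python reference engine in `jump_chain`
consumes draws in the same order, and the two are tested for identical
output on the same seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_G = 2
_C = 1

# CpG-context codes; must match substitution_model
_CPG_ALWAYS = 1
_CPG_IF_NEXT_STARTS_G = 2
_CPG_IF_PREV_ENDS_C = 3


@njit(cache=True)
def _site_row(
    s, codons, rates, site_totals,
    phi, kappa, lam, omega_sites, scale,
    n_counts, n_to_nuc, n_syn, n_ts, cpg_code, codon_first, codon_last,
):
    """Recompute the 9 event rates of site s; returns nothing (in place)."""
    n = codons.shape[0]
    c = codons[s]
    cnt = n_counts[c]
    tot = 0.0
    for k in range(9):
        if k < cnt:
            r = phi[n_to_nuc[c, k]]
            if n_ts[c, k]:
                r *= kappa
            if not n_syn[c, k]:
                r *= omega_sites[s]
            code = cpg_code[c, k]
            if code != 0:
                cpg = False
                if code == _CPG_ALWAYS:
                    cpg = True
                elif code == _CPG_IF_NEXT_STARTS_G:
                    cpg = s + 1 < n and codon_first[codons[s + 1]] == _G
                elif code == _CPG_IF_PREV_ENDS_C:
                    cpg = s > 0 and codon_last[codons[s - 1]] == _C
                if cpg:
                    r *= lam
            r *= scale
        else:
            r = 0.0
        rates[s, k] = r
        tot += r
    site_totals[s] = tot


@njit(cache=True)
def _init_rates(
    codons, rates, site_totals,
    phi, kappa, lam, omega_sites, scale,
    n_counts, n_to_nuc, n_syn, n_ts, cpg_code, codon_first, codon_last,
):
    n = codons.shape[0]
    for s in range(n):
        _site_row(
            s, codons, rates, site_totals,
            phi, kappa, lam, omega_sites, scale,
            n_counts, n_to_nuc, n_syn, n_ts, cpg_code, codon_first, codon_last,
        )
    total = 0.0
    for s in range(n):
        total += site_totals[s]
    return total


@njit(cache=True)
def _pick_event(u, total, site_totals, rates):
    """Site-major, then slot-order (position-major, target A<C<G<T) pick."""
    n = site_totals.shape[0]
    target = u * total
    acc = 0.0
    site = n - 1
    for s in range(n):
        acc += site_totals[s]
        if target < acc:
            site = s
            break
    target -= acc - site_totals[site]
    acc2 = 0.0
    slot = -1
    for k in range(9):
        r = rates[site, k]
        if r > 0.0:
            acc2 += r
            slot = k
            if target < acc2:
                break
    return site, slot


@njit(cache=True)
def _event_klass(site, slot, codons, n_syn, n_ts, cpg_code, codon_first, codon_last):
    """0..5 index into the six rate classes, in the fixed class order."""
    n = codons.shape[0]
    c = codons[site]
    base = 0 if n_syn[c, slot] else 3
    if not n_ts[c, slot]:
        return base
    code = cpg_code[c, slot]
    cpg = False
    if code == _CPG_ALWAYS:
        cpg = True
    elif code == _CPG_IF_NEXT_STARTS_G:
        cpg = site + 1 < n and codon_first[codons[site + 1]] == _G
    elif code == _CPG_IF_PREV_ENDS_C:
        cpg = site > 0 and codon_last[codons[site - 1]] == _C
    return base + (2 if cpg else 1)


@njit(cache=True)
def _apply_and_refresh(
    site, slot, codons, rates, site_totals,
    phi, kappa, lam, omega_sites, scale,
    n_counts, n_state, n_to_nuc, n_syn, n_ts, cpg_code, codon_first, codon_last,
):
    n = codons.shape[0]
    codons[site] = n_state[codons[site], slot]
    lo = site - 1 if site > 0 else 0
    hi = site + 2 if site + 2 <= n else n
    for s in range(lo, hi):
        _site_row(
            s, codons, rates, site_totals,
            phi, kappa, lam, omega_sites, scale,
            n_counts, n_to_nuc, n_syn, n_ts, cpg_code, codon_first, codon_last,
        )
    total = 0.0
    for s in range(n):
        total += site_totals[s]
    return total


@njit(cache=True)
def _branch_core(
    codons, length,
    rates, site_totals, total,
    ev_site, ev_slot, ev_klass, ev_time,
    phi, kappa, lam, omega_sites, scale,
    n_counts, n_state, n_to_nuc, n_syn, n_ts, cpg_code, codon_first, codon_last,
):
    """Jump-chain loop along one branch. RNG must already be seeded.

    Returns (n_events, total); n_events == -1 signals that the event buffers
    were too small (the caller re-runs with larger ones and the same seed).
    """
    cap = ev_site.shape[0]
    n_ev = 0
    t = 0.0
    while True:
        u = np.random.random()
        t += -np.log(1.0 - u) / total
        if t > length:
            break
        u2 = np.random.random()
        site, slot = _pick_event(u2, total, site_totals, rates)
        if n_ev >= cap:
            return -1, total
        ev_site[n_ev] = site
        ev_slot[n_ev] = slot
        ev_klass[n_ev] = _event_klass(
            site, slot, codons, n_syn, n_ts, cpg_code, codon_first, codon_last
        )
        ev_time[n_ev] = t
        n_ev += 1
        total = _apply_and_refresh(
            site, slot, codons, rates, site_totals,
            phi, kappa, lam, omega_sites, scale,
            n_counts, n_state, n_to_nuc, n_syn, n_ts, cpg_code, codon_first, codon_last,
        )
    return n_ev, total


@njit(cache=True)
def simulate_branch_kernel(
    codons, length, seed,
    ev_site, ev_slot, ev_klass, ev_time,
    phi, kappa, lam, omega_sites, scale,
    n_counts, n_state, n_to_nuc, n_syn, n_ts, cpg_code, codon_first, codon_last,
):
    np.random.seed(seed)
    n = codons.shape[0]
    rates = np.empty((n, 9))
    site_totals = np.empty(n)
    total = _init_rates(
        codons, rates, site_totals,
        phi, kappa, lam, omega_sites, scale,
        n_counts, n_to_nuc, n_syn, n_ts, cpg_code, codon_first, codon_last,
    )
    n_ev, _ = _branch_core(
        codons, length, rates, site_totals, total,
        ev_site, ev_slot, ev_klass, ev_time,
        phi, kappa, lam, omega_sites, scale,
        n_counts, n_state, n_to_nuc, n_syn, n_ts, cpg_code, codon_first, codon_last,
    )
    return n_ev


@njit(cache=True)
def burn_in_kernel(
    codons, n_events, seed,
    phi, kappa, lam, omega_sites, scale,
    n_counts, n_state, n_to_nuc, n_syn, n_ts, cpg_code, codon_first, codon_last,
):
    """Apply n_events jump-chain events in place (no branch-length bound).

    Dwell times are irrelevant to the end state, so only the event-choice
    uniforms are drawn.
    """
    np.random.seed(seed)
    n = codons.shape[0]
    rates = np.empty((n, 9))
    site_totals = np.empty(n)
    total = _init_rates(
        codons, rates, site_totals,
        phi, kappa, lam, omega_sites, scale,
        n_counts, n_to_nuc, n_syn, n_ts, cpg_code, codon_first, codon_last,
    )
    for _ in range(n_events):
        u = np.random.random()
        site, slot = _pick_event(u, total, site_totals, rates)
        total = _apply_and_refresh(
            site, slot, codons, rates, site_totals,
            phi, kappa, lam, omega_sites, scale,
            n_counts, n_state, n_to_nuc, n_syn, n_ts, cpg_code, codon_first, codon_last,
        )


@njit(cache=True)
def branch_end_states_kernel(
    codons0, length, n_reps, seed,
    phi, kappa, lam, omega_sites, scale,
    n_counts, n_state, n_to_nuc, n_syn, n_ts, cpg_code, codon_first, codon_last,
):
    """End states of n_reps independent branch realizations from one start."""
    np.random.seed(seed)
    n = codons0.shape[0]
    out = np.empty((n_reps, n), dtype=np.int64)
    rates = np.empty((n, 9))
    site_totals = np.empty(n)
    for rep in range(n_reps):
        codons = codons0.copy()
        total = _init_rates(
            codons, rates, site_totals,
            phi, kappa, lam, omega_sites, scale,
            n_counts, n_to_nuc, n_syn, n_ts, cpg_code, codon_first, codon_last,
        )
        t = 0.0
        while True:
            u = np.random.random()
            t += -np.log(1.0 - u) / total
            if t > length:
                break
            u2 = np.random.random()
            site, slot = _pick_event(u2, total, site_totals, rates)
            total = _apply_and_refresh(
                site, slot, codons, rates, site_totals,
                phi, kappa, lam, omega_sites, scale,
                n_counts, n_state, n_to_nuc, n_syn, n_ts, cpg_code,
                codon_first, codon_last,
            )
        out[rep] = codons
    return out
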