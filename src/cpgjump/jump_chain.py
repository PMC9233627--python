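"""Event-by-event (jump-chain) simulation of the codon process over a tree.

The simulator never builds a sequence-space rate matrix (61^N states); it
alternates two draws along each branch:

1. a dwell time t = -ln(1 - U) / R, where R is the total rate away from the
   current sequence (the sum of the rates of all accessible single-nucleotide
   events), computed by inverse transform of the Exponential(R) law;
2. the next event, drawn with probability proportional to its rate among the
   accessible events (site-major order, then position, then target
   nucleotide A < C < G < T).

Events are applied until a dwell time overshoots the branch end; the
overshooting draw is discarded (the exponential is memoryless, and sibling
branches must evolve independently from the node state). The recursion then
bifurcates: both children start from the parent's final sequence, each with
its own deterministic RNG substream, so a whole simulation is reproducible
bit-for-bit from one master seed.

Root states come from the closed-form stationary distribution of the
site-independent (lam=1) model, from a burn-in (a long artificial branch of
events that converges to the intractable stationary distribution of the
site-interdependent model), or from a user-supplied sequence.

Two engines exist: a numba-compiled kernel (used everywhere) and a
pure-Python reference built from the documented single-step operations
(`draw_dwell`, `draw_event`, `update_rate_table`); they are tested to
produce identical realizations from the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .genetic_code import (
    CODON_NUCS,
    NEIGHBOR_COUNTS,
    NEIGHBOR_POS,
    NEIGHBOR_STATE,
    NEIGHBOR_SYN,
    NEIGHBOR_TO,
    NEIGHBOR_TS,
    STANDARD_CODE,
)
from .phylo_io import Alignment, Phylogeny
from .substitution_model import (
    CpGModelParams,
    EVENT_CLASSES,
    RateTable,
    SequenceState,
    build_rate_table,
    rate_scale,
    resolve_site_omega,
    stationary_m0,
    update_rate_table,
)

#: Default burn-in length, in events per codon site. The burn-in starts from
#: the lam=1 stationary draw, which is already close to the lam!=1
#: stationary state, so a modest number of events per site suffices.
BURN_IN_EVENTS_PER_SITE = 50


@dataclass(frozen=True)
class AppliedEvent:
    """One realized substitution: where, when, what."""

    time: float          # offset from the parent end of the branch
    site: int            # 0-based codon site
    position: int        # 1-3 within the codon
    from_codon: str
    to_codon: str
    klass: str           # one of EVENT_CLASSES


@dataclass
class SubstitutionHistory:
    """Full realization of the process: all events plus every node state."""

    branch_events: dict[str, list[AppliedEvent]] = field(default_factory=dict)
    node_states: dict[str, SequenceState] = field(default_factory=dict)
    class_totals: np.ndarray = field(
        default_factory=lambda: np.zeros(len(EVENT_CLASSES), dtype=np.int64)
    )

    @property
    def n_events(self) -> int:
        return int(self.class_totals.sum())

    def class_counts(self) -> dict[str, int]:
        return {k: int(c) for k, c in zip(EVENT_CLASSES, self.class_totals)}


# ---------------------------------------------------------------------------
# Single-step operations (the documented jump-chain primitives)
# ---------------------------------------------------------------------------

def draw_dwell(R: float, U: float) -> float:
    """Dwell time by inverse transform: t = -ln(1 - U) / R."""
    if R <= 0:
        raise ValueError(f"total rate away must be positive, got {R}")
    if not (0.0 <= U < 1.0):
        raise ValueError(f"U must be in [0, 1), got {U}")
    return -math.log(1.0 - U) / R


def draw_event(table: RateTable, U: float) -> tuple[int, int]:
    """Pick the next event with probability proportional to its rate.

    Returns the (site, slot) coordinates into the rate table; the event's
    full description is ``table.event_at(site, slot)``. Enumeration order is
    site-major, then position, then target nucleotide A < C < G < T.
    """
    if table.total <= 0:
        raise ValueError("rate table has no accessible events")
    site, slot = _kernels._pick_event.py_func(
        U, table.total, table.site_totals, table.rates
    )
    return int(site), int(slot)


# ---------------------------------------------------------------------------
# Engines
# ---------------------------------------------------------------------------

class JumpChainEngine:
    """Compiled branch simulator for one (params, per-site omega) setting."""

    def __init__(self, params: CpGModelParams, site_omega: np.ndarray):
        self.params = params
        self.site_omega = np.ascontiguousarray(site_omega, dtype=float)
        self.n_sites = int(self.site_omega.size)
        cpg_code = params.cpg_code_table()
        self._args = (
            params.phi_array,
            float(params.kappa),
            float(params.lam),
            self.site_omega,
            float(rate_scale(params)),
            NEIGHBOR_COUNTS,
            NEIGHBOR_STATE,
            NEIGHBOR_TO,
            NEIGHBOR_SYN,
            NEIGHBOR_TS,
            cpg_code,
            np.ascontiguousarray(CODON_NUCS[:, 0]),
            np.ascontiguousarray(CODON_NUCS[:, 2]),
        )

    def _describe(self, codons_before, ev_site, ev_slot, ev_klass, ev_time, n_ev):
        """Turn kernel event coordinates into AppliedEvent records."""
        events = []
        codons = codons_before.copy()
        for e in range(n_ev):
            s = int(ev_site[e])
            c = int(codons[s])
            slot = int(ev_slot[e])
            j = int(NEIGHBOR_STATE[c, slot])
            events.append(
                AppliedEvent(
                    time=float(ev_time[e]),
                    site=s,
                    position=int(NEIGHBOR_POS[c, slot]) + 1,
                    from_codon=STANDARD_CODE.index_to_codon[c],
                    to_codon=STANDARD_CODE.index_to_codon[j],
                    klass=EVENT_CLASSES[int(ev_klass[e])],
                )
            )
            codons[s] = j
        return events

    def simulate_branch(
        self, start: SequenceState, length: float, seed: int, want_events: bool = True
    ) -> tuple[SequenceState, list[AppliedEvent] | None, np.ndarray]:
        """Returns (end state, event records or None, per-class event counts)."""
        if length < 0:
            raise ValueError("branch length must be >= 0")
        if length == 0.0:
            return start.copy(), ([] if want_events else None), np.zeros(6, np.int64)
        cap = max(64, int(4 * length * self.n_sites * max(1.0, self.params.lam)) + 64)
        while True:
            codons = start.codons.copy()
            ev_site = np.empty(cap, dtype=np.int64)
            ev_slot = np.empty(cap, dtype=np.int64)
            ev_klass = np.empty(cap, dtype=np.int64)
            ev_time = np.empty(cap, dtype=np.float64)
            n_ev = _kernels.simulate_branch_kernel(
                codons, float(length), int(seed),
                ev_site, ev_slot, ev_klass, ev_time, *self._args,
            )
            if n_ev >= 0:
                break
            cap *= 2  # buffer overflow: deterministic re-run with more room
        counts = np.bincount(ev_klass[:n_ev], minlength=6)
        events = (
            self._describe(start.codons, ev_site, ev_slot, ev_klass, ev_time, n_ev)
            if want_events
            else None
        )
        return SequenceState(codons), events, counts

    def burn_in(self, start: SequenceState, n_events: int, seed: int) -> SequenceState:
        if n_events < 0:
            raise ValueError("n_events must be >= 0")
        codons = start.codons.copy()
        if n_events:
            _kernels.burn_in_kernel(codons, int(n_events), int(seed), *self._args)
        return SequenceState(codons)

    def branch_end_states(
        self, start: SequenceState, length: float, n_reps: int, seed: int
    ) -> np.ndarray:
        """(n_reps, n_sites) end states of independent branch realizations."""
        return _kernels.branch_end_states_kernel(
            start.codons.copy(), float(length), int(n_reps), int(seed), *self._args
        )


def simulate_branch_reference(
    params: CpGModelParams,
    start: SequenceState,
    length: float,
    seed: int,
    site_omega: np.ndarray | None = None,
) -> tuple[SequenceState, list[AppliedEvent]]:
    """Pure-Python branch simulation from the single-step operations.

    Consumes uniforms in the same order as the compiled kernel (one for the
    dwell, one for the event) from the same MT19937 stream, so its output is
    identical for the same seed; kept as the readable reference path and the
    kernel's correctness oracle.
    """
    if site_omega is None:
        site_omega = resolve_site_omega(params, start.n_sites)
    rng = np.random.RandomState(seed)
    seq = start.copy()
    table = build_rate_table(params, seq, site_omega)
    t = 0.0
    events: list[AppliedEvent] = []
    while True:
        t += draw_dwell(table.total, rng.random_sample())
        if t > length:
            break
        site, slot = draw_event(table, rng.random_sample())
        ev = table.event_at(site, slot)
        seq.codons[site] = STANDARD_CODE.codon_to_index[ev.to_codon]
        events.append(
            AppliedEvent(
                time=t, site=site, position=ev.position,
                from_codon=ev.from_codon, to_codon=ev.to_codon, klass=ev.klass,
            )
        )
        table = update_rate_table(table, site, seq)
    return seq, events


# ---------------------------------------------------------------------------
# Root draws
# ---------------------------------------------------------------------------

def stationary_root(params: CpGModelParams, n_sites: int, rng) -> SequenceState:
    """Sites drawn independently from the lam=1 stationary distribution."""
    pi = stationary_m0(params.phi_array)
    return SequenceState(rng.choice(pi.size, size=n_sites, p=pi))


def burn_in_root(
    params: CpGModelParams,
    n_sites: int,
    n_events: int,
    rng,
    start: SequenceState | None = None,
    site_omega: np.ndarray | None = None,
) -> SequenceState:
    """Approximate draw from the intractable stationary distribution.

    Simulates `n_events` jump-chain events along an artificial branch (no
    length bound), starting by default from the lam=1 stationary draw.
    """
    if start is None:
        start = stationary_root(params, n_sites, rng)
    if site_omega is None:
        site_omega = resolve_site_omega(params, n_sites, rng)
    engine = JumpChainEngine(params, site_omega)
    seed = int(rng.integers(2**31 - 1))
    return engine.burn_in(start, n_events, seed)


def draw_root(
    mode: str,
    params: CpGModelParams,
    n_sites: int,
    rng,
    fixed: SequenceState | None = None,
    n_burn_in_events: int | None = None,
    site_omega: np.ndarray | None = None,
) -> SequenceState:
    if mode == "stationary_m0":
        return stationary_root(params, n_sites, rng)
    if mode == "burn_in":
        n_events = (
            BURN_IN_EVENTS_PER_SITE * n_sites
            if n_burn_in_events is None
            else n_burn_in_events
        )
        return burn_in_root(params, n_sites, n_events, rng, site_omega=site_omega)
    if mode == "fixed":
        if fixed is None:
            raise ValueError("fixed root mode requires a sequence")
        if fixed.n_sites != n_sites:
            raise ValueError(
                f"fixed root has {fixed.n_sites} codons, expected {n_sites}"
            )
        return fixed.copy()
    raise ValueError(f"unknown root mode {mode!r}")


# ---------------------------------------------------------------------------
# Whole-tree simulation
# ---------------------------------------------------------------------------

def simulate_alignment(
    tree: Phylogeny,
    params: CpGModelParams,
    n_codons: int,
    seed: int | np.random.SeedSequence,
    root_mode: str = "burn_in",
    fixed_root: SequenceState | None = None,
    n_burn_in_events: int | None = None,
    record_history: bool = True,
) -> tuple[Alignment, SubstitutionHistory]:
    """Simulate a codon alignment (and its full event history) over `tree`.

    The root state is drawn once, then the process recurses in preorder:
    every branch starts from its parent's end state and consumes an
    independent, deterministically spawned RNG substream, so the same master
    seed always reproduces the same alignment and history, and altering one
    branch's length leaves the draws of all other branches unchanged.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_nodes = tree.n_nodes
    root_ss, *branch_ss = ss.spawn(n_nodes)
    root_rng = np.random.default_rng(root_ss)

    site_omega = resolve_site_omega(params, n_codons, root_rng)
    root = draw_root(
        root_mode, params, n_codons, root_rng,
        fixed=fixed_root, n_burn_in_events=n_burn_in_events, site_omega=site_omega,
    )

    engine = JumpChainEngine(params, site_omega)
    states: list[SequenceState | None] = [None] * n_nodes
    states[0] = root
    history = SubstitutionHistory()
    history.node_states[tree.names[0]] = root
    for child, parent, length in tree.branches():
        branch_seed = int(branch_ss[child - 1].generate_state(1)[0] & 0x7FFFFFFF)
        end, events, counts = engine.simulate_branch(
            states[parent], length, branch_seed, want_events=record_history
        )
        states[child] = end
        history.node_states[tree.names[child]] = end
        history.class_totals += counts
        if record_history:
            history.branch_events[tree.names[child]] = events
    alignment = Alignment(
        {tree.names[i]: states[i].copy() for i in tree.tip_indices}
    )
    return alignment, history
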