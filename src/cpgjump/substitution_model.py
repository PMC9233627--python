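"""CpG-aware codon substitution rate law and whole-sequence rate tables.

The model assigns a rate to every single-nucleotide change from codon i to
codon j (differing at one position c), as the product of

* ``phi[y]`` — the equilibrium frequency of the target nucleotide y,
* ``kappa`` — multiplied in when the change is a transition,
* ``omega`` — multiplied in when the change is nonsynonymous,
* ``lam``   — multiplied in when the change is a transition in CpG context.

CpG context is what couples neighbouring sites: a C->T transition whose
immediate 3' nucleotide is G, or (on the opposite strand, reading the coding
strand) a G->A transition whose immediate 5' nucleotide is C. The flanking
nucleotide may live in the adjacent codon, so with ``lam != 1`` the rate at a
site depends on the states of its neighbour sites and the process no longer
factorizes over sites. With ``lam == 1`` the model collapses to the classic
site-independent codon model, whose 61x61 generator and closed-form
stationary distribution are built here as well.

Rates can optionally be rescaled by a single global constant chosen so that
the lam=1 site-independent model has mean rate 1 per codon site at its
stationary distribution (``normalization="m0_reference"``). Branch lengths
are then expected substitutions per codon site under the lam=1 reference;
hypermutability (lam>1) inflates the realized rate above that reference,
which is part of what the model is for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genetic_code import (
    CODON_NUCS,
    N_CODONS,
    NEIGHBOR_COUNTS,
    NEIGHBOR_FROM,
    NEIGHBOR_POS,
    NEIGHBOR_STATE,
    NEIGHBOR_SYN,
    NEIGHBOR_TO,
    NEIGHBOR_TS,
    NUC_INDEX,
    STANDARD_CODE,
    is_transition,
)

EVENT_CLASSES = (
    "syn_tv",
    "syn_ts_noncpg",
    "syn_ts_cpg",
    "nonsyn_tv",
    "nonsyn_ts_noncpg",
    "nonsyn_ts_cpg",
)

_A, _C, _G, _T = 0, 1, 2, 3

# CpG-context codes per (codon, neighbour slot): the context of an event is
# static when the flanking nucleotide is inside the same codon, and dynamic
# (depends on the adjacent codon) only at the codon boundary.
_CPG_NEVER = 0
_CPG_ALWAYS = 1
_CPG_IF_NEXT_STARTS_G = 2   # C->T at codon position 3
_CPG_IF_PREV_ENDS_C = 3     # G->A at codon position 1


def _build_cpg_code_table(cpg_mode: str) -> np.ndarray:
    table = np.full((N_CODONS, 9), _CPG_NEVER, dtype=np.int64)
    for i in range(N_CODONS):
        for k in range(NEIGHBOR_COUNTS[i]):
            if not NEIGHBOR_TS[i, k]:
                continue
            p = NEIGHBOR_POS[i, k]
            x, y = NEIGHBOR_FROM[i, k], NEIGHBOR_TO[i, k]
            if x == _C and y == _T:
                if p < 2:
                    if CODON_NUCS[i, p + 1] == _G:
                        table[i, k] = _CPG_ALWAYS
                else:
                    table[i, k] = _CPG_IF_NEXT_STARTS_G
            elif x == _G and y == _A and cpg_mode == "both_strands":
                if p > 0:
                    if CODON_NUCS[i, p - 1] == _C:
                        table[i, k] = _CPG_ALWAYS
                else:
                    table[i, k] = _CPG_IF_PREV_ENDS_C
    return table


_CPG_CODE_TABLES = {
    mode: _build_cpg_code_table(mode) for mode in ("both_strands", "c_to_t_only")
}


@dataclass(frozen=True)
class OmegaMixture:
    """Equal- or given-weight mixture of dN/dS values assigned per site.

    When simulating, each codon site independently draws its omega from the
    mixture (uniformly when weights are equal) and keeps it for the whole
    tree.
    """

    values: tuple[float, ...]
    weights: tuple[float, ...] | None = None

    def __post_init__(self):
        values = tuple(float(v) for v in self.values)
        if not values or any(v <= 0 for v in values):
            raise ValueError("mixture omega values must be positive")
        if self.weights is None:
            weights = tuple(1.0 / len(values) for _ in values)
        else:
            weights = tuple(float(w) for w in self.weights)
            if len(weights) != len(values) or any(w < 0 for w in weights):
                raise ValueError("mixture weights must be nonnegative, one per value")
            if abs(sum(weights) - 1.0) > 1e-9:
                raise ValueError("mixture weights must sum to 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "weights", weights)


@dataclass(frozen=True)
class CpGModelParams:
    """All parameters of the rate law, plus context/normalization switches."""

    phi: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    kappa: float = 1.0
    lam: float = 1.0
    omega: float | OmegaMixture = 1.0
    cpg_mode: str = "both_strands"
    normalization: str = "m0_reference"

    def __post_init__(self):
        phi = tuple(float(p) for p in self.phi)
        if len(phi) != 4 or any(p <= 0 for p in phi):
            raise ValueError("phi must be 4 positive frequencies (A, C, G, T)")
        if abs(sum(phi) - 1.0) > 1e-12:
            raise ValueError(f"phi must sum to 1, got {sum(phi)!r}")
        object.__setattr__(self, "phi", phi)
        if self.kappa <= 0 or self.lam <= 0:
            raise ValueError("kappa and lam must be positive")
        if isinstance(self.omega, (int, float)):
            if self.omega <= 0:
                raise ValueError("omega must be positive")
            object.__setattr__(self, "omega", float(self.omega))
        elif not isinstance(self.omega, OmegaMixture):
            raise ValueError("omega must be a float or an OmegaMixture")
        if self.cpg_mode not in ("both_strands", "c_to_t_only"):
            raise ValueError(f"unknown cpg_mode {self.cpg_mode!r}")
        if self.normalization not in ("m0_reference", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def phi_array(self) -> np.ndarray:
        return np.asarray(self.phi, dtype=float)

    @property
    def omega_values(self) -> tuple[float, ...]:
        if isinstance(self.omega, OmegaMixture):
            return self.omega.values
        return (self.omega,)

    @property
    def omega_weights(self) -> tuple[float, ...]:
        if isinstance(self.omega, OmegaMixture):
            return self.omega.weights
        return (1.0,)

    def cpg_code_table(self) -> np.ndarray:
        return _CPG_CODE_TABLES[self.cpg_mode]

    def with_omega(self, omega) -> "CpGModelParams":
        return replace(self, omega=omega)


@dataclass
class SequenceState:
    """The jump chain's state: a length-N vector of sense-codon indices."""

    codons: np.ndarray

    def __post_init__(self):
        self.codons = np.asarray(self.codons, dtype=np.int64)
        if self.codons.ndim != 1 or self.codons.size < 1:
            raise ValueError("sequence must be a non-empty 1-D codon-index vector")
        if self.codons.min() < 0 or self.codons.max() >= N_CODONS:
            raise ValueError("codon index out of range (stop codons are not representable)")

    @property
    def n_sites(self) -> int:
        return int(self.codons.size)

    @classmethod
    def from_codon_strings(cls, codons) -> "SequenceState":
        idx = []
        for c in codons:
            STANDARD_CODE._require_sense(c)
            idx.append(STANDARD_CODE.codon_to_index[c])
        return cls(np.array(idx, dtype=np.int64))

    @classmethod
    def from_dna(cls, dna: str) -> "SequenceState":
        if len(dna) % 3 != 0:
            raise ValueError("DNA length must be a multiple of 3")
        return cls.from_codon_strings(dna[i:i + 3] for i in range(0, len(dna), 3))

    def to_dna(self) -> str:
        return "".join(STANDARD_CODE.index_to_codon[i] for i in self.codons)

    def copy(self) -> "SequenceState":
        return SequenceState(self.codons.copy())


# ---------------------------------------------------------------------------
# Stationary distribution and mean rate of the site-independent lam=1 model
# ---------------------------------------------------------------------------

def stationary_m0(phi) -> np.ndarray:
    """pi_j proportional to phi[j1] phi[j2] phi[j3] over the 61 sense codons."""
    phi = np.asarray(phi, dtype=float)
    pi = phi[CODON_NUCS].prod(axis=1)
    return pi / pi.sum()


def _m0_mean_rate_single(phi: np.ndarray, kappa: float, omega: float) -> float:
    """Mean rate away per codon site of the unnormalized lam=1 model at pi."""
    pi = stationary_m0(phi)
    slot = np.arange(9)
    valid = slot[None, :] < NEIGHBOR_COUNTS[:, None]
    rates = phi[NEIGHBOR_TO] * np.where(NEIGHBOR_TS, kappa, 1.0)
    rates = rates * np.where(NEIGHBOR_SYN, 1.0, omega)
    rates = np.where(valid, rates, 0.0)
    return float(pi @ rates.sum(axis=1))


def rate_scale(params: CpGModelParams) -> float:
    """Global factor multiplying every rate.

    Under ``m0_reference`` this is 1/mu where mu is the mean rate per codon
    site of the lam=1 site-independent model at its stationary distribution
    (mixture-averaged over omega components, with one common factor for all
    components, so relative rates between components are preserved).
    """
    if params.normalization == "none":
        return 1.0
    phi = params.phi_array
    mu = sum(
        w * _m0_mean_rate_single(phi, params.kappa, v)
        for v, w in zip(params.omega_values, params.omega_weights)
    )
    return 1.0 / mu


# ---------------------------------------------------------------------------
# Event classification and single-event rates
# ---------------------------------------------------------------------------

def classify_event(
    seq: SequenceState,
    site: int,
    position: int,
    from_nuc: str,
    to_nuc: str,
    is_syn: bool,
    cpg_mode: str = "both_strands",
) -> str:
    """Assign a point mutation to one of the six rate classes.

    ``site`` is 0-based, ``position`` is 1-3 within the codon. CpG context is
    read from the current whole sequence: the flanking nucleotide may sit in
    the adjacent codon, and sequence termini have no context beyond the
    sequence (no wraparound).
    """
    n = seq.n_sites
    if not (0 <= site < n):
        raise ValueError(f"site {site} out of range for sequence of {n} codons")
    if position not in (1, 2, 3):
        raise ValueError(f"codon position must be 1-3, got {position}")
    if cpg_mode not in ("both_strands", "c_to_t_only"):
        raise ValueError(f"unknown cpg_mode {cpg_mode!r}")
    if not is_transition(from_nuc, to_nuc):  # also validates the nucleotides
        return "nonsyn_tv" if not is_syn else "syn_tv"

    p = position - 1
    cpg = False
    if from_nuc == "C" and to_nuc == "T":
        if p < 2:
            cpg = CODON_NUCS[seq.codons[site], p + 1] == _G
        elif site + 1 < n:
            cpg = CODON_NUCS[seq.codons[site + 1], 0] == _G
    elif from_nuc == "G" and to_nuc == "A" and cpg_mode == "both_strands":
        if p > 0:
            cpg = CODON_NUCS[seq.codons[site], p - 1] == _C
        elif site > 0:
            cpg = CODON_NUCS[seq.codons[site - 1], 2] == _C
    prefix = "syn" if is_syn else "nonsyn"
    return f"{prefix}_ts_{'cpg' if cpg else 'noncpg'}"


def event_rate(
    params: CpGModelParams,
    klass: str,
    target_nuc: str,
    site_omega: float | None = None,
) -> float:
    """Rate of a single classified event (the six-way product form)."""
    if klass not in EVENT_CLASSES:
        raise ValueError(f"unknown event class {klass!r}")
    if site_omega is None:
        if isinstance(params.omega, OmegaMixture):
            raise ValueError("site_omega is required when omega is a mixture")
        site_omega = params.omega
    rate = params.phi[NUC_INDEX[target_nuc]]
    if klass.startswith("nonsyn"):
        rate *= site_omega
    if "_ts_" in klass:
        rate *= params.kappa
        if klass.endswith("_cpg"):
            rate *= params.lam
    return rate * rate_scale(params)


# ---------------------------------------------------------------------------
# Whole-sequence rate tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeighborEvent:
    """One accessible point mutation of the current sequence."""

    site: int           # 0-based codon site
    position: int       # 1-3 within the codon
    from_codon: str
    to_codon: str
    from_nuc: str
    to_nuc: str
    klass: str          # one of EVENT_CLASSES


@dataclass
class RateTable:
    """Rates of every accessible single-nucleotide event of a sequence.

    ``rates[s, k]`` is the rate of the k-th neighbour event of site s in the
    fixed position-major, target-A<C<G<T enumeration order (zero beyond the
    site's neighbour count); ``site_totals[s]`` its row sum and ``total`` the
    grand rate away R. The table remembers the sequence, parameters and
    per-site omegas it was built from so it can name events and be updated
    incrementally.
    """

    rates: np.ndarray
    site_totals: np.ndarray
    total: float
    codons: np.ndarray
    params: CpGModelParams
    site_omega: np.ndarray

    @property
    def n_events(self) -> int:
        """Number of accessible events (at most 9 per codon site)."""
        return int(np.count_nonzero(self.rates))

    def event_at(self, site: int, slot: int) -> NeighborEvent:
        """Describe the neighbour event in row `site`, slot `slot`."""
        c = int(self.codons[site])
        i = STANDARD_CODE.index_to_codon[c]
        j = STANDARD_CODE.index_to_codon[NEIGHBOR_STATE[c, slot]]
        pos = int(NEIGHBOR_POS[c, slot]) + 1
        x, y = i[pos - 1], j[pos - 1]
        klass = classify_event(
            SequenceState(self.codons), site, pos, x, y,
            bool(NEIGHBOR_SYN[c, slot]), self.params.cpg_mode,
        )
        return NeighborEvent(
            site=site, position=pos, from_codon=i, to_codon=j,
            from_nuc=x, to_nuc=y, klass=klass,
        )


def _site_rates_block(
    params: CpGModelParams,
    codons: np.ndarray,
    site_omega: np.ndarray,
    sites: np.ndarray,
    scale: float,
) -> np.ndarray:
    """Rate rows for the given sites, reading CpG context from `codons`."""
    n = codons.size
    c = codons[sites]                                # (m,)
    phi = params.phi_array
    valid = np.arange(9)[None, :] < NEIGHBOR_COUNTS[c, None]
    rates = phi[NEIGHBOR_TO[c]]
    rates = rates * np.where(NEIGHBOR_TS[c], params.kappa, 1.0)
    rates = rates * np.where(NEIGHBOR_SYN[c], 1.0, site_omega[sites, None])

    code = params.cpg_code_table()[c]
    next_starts_g = np.zeros(sites.size, dtype=bool)
    has_next = sites + 1 < n
    next_starts_g[has_next] = CODON_NUCS[codons[sites[has_next] + 1], 0] == _G
    prev_ends_c = np.zeros(sites.size, dtype=bool)
    has_prev = sites - 1 >= 0
    prev_ends_c[has_prev] = CODON_NUCS[codons[sites[has_prev] - 1], 2] == _C
    cpg = (
        (code == _CPG_ALWAYS)
        | ((code == _CPG_IF_NEXT_STARTS_G) & next_starts_g[:, None])
        | ((code == _CPG_IF_PREV_ENDS_C) & prev_ends_c[:, None])
    )
    rates = rates * np.where(cpg, params.lam, 1.0)
    return np.where(valid, rates * scale, 0.0)


def resolve_site_omega(params: CpGModelParams, n_sites: int, rng=None) -> np.ndarray:
    """Per-site omega vector; mixture components drawn once per site."""
    if isinstance(params.omega, OmegaMixture):
        if rng is None:
            raise ValueError("an rng is required to assign mixture omegas to sites")
        values = np.asarray(params.omega.values)
        weights = np.asarray(params.omega.weights)
        return values[rng.choice(values.size, size=n_sites, p=weights)]
    return np.full(n_sites, params.omega, dtype=float)


def build_rate_table(
    params: CpGModelParams,
    seq: SequenceState,
    site_omega: np.ndarray | None = None,
) -> RateTable:
    """Enumerate every accessible event of `seq` and total the rate away R."""
    if site_omega is None:
        site_omega = resolve_site_omega(params, seq.n_sites)
    sites = np.arange(seq.n_sites)
    scale = rate_scale(params)
    rates = _site_rates_block(params, seq.codons, site_omega, sites, scale)
    site_totals = rates.sum(axis=1)
    return RateTable(
        rates=rates,
        site_totals=site_totals,
        total=float(site_totals.sum()),
        codons=seq.codons.copy(),
        params=params,
        site_omega=np.asarray(site_omega, dtype=float),
    )


def update_rate_table(table: RateTable, site: int, seq_after: SequenceState) -> RateTable:
    """Refresh a rate table after an event at `site` (0-based).

    Only sites site-1, site, site+1 are recomputed: CpG context reaches at
    most one nucleotide across a codon boundary, so no other row can change.
    The result matches a full rebuild on `seq_after`.
    """
    params = table.params
    n = seq_after.n_sites
    sites = np.arange(max(site - 1, 0), min(site + 2, n))
    block = _site_rates_block(
        params, seq_after.codons, table.site_omega, sites, rate_scale(params)
    )
    rates = table.rates.copy()
    site_totals = table.site_totals.copy()
    rates[sites] = block
    site_totals[sites] = block.sum(axis=1)
    return RateTable(
        rates=rates,
        site_totals=site_totals,
        total=float(site_totals.sum()),
        codons=seq_after.codons.copy(),
        params=params,
        site_omega=table.site_omega,
    )


# ---------------------------------------------------------------------------
# Site-independent 61x61 generator (lam treated as 1)
# ---------------------------------------------------------------------------

def build_m0_matrix(params: CpGModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Generator Q and stationary pi of the classic site-independent model.

    Off-diagonals follow the rate law with the CpG multiplier ignored
    (lam treated as 1); diagonals make rows sum to zero. Under
    ``m0_reference`` Q is scaled so that -sum_i pi_i Q_ii = 1, i.e. branch
    lengths count expected substitutions per codon site.
    """
    if isinstance(params.omega, OmegaMixture):
        raise ValueError("build_m0_matrix requires a single omega")
    phi = params.phi_array
    q = np.zeros((N_CODONS, N_CODONS))
    rates = phi[NEIGHBOR_TO] * np.where(NEIGHBOR_TS, params.kappa, 1.0)
    rates = rates * np.where(NEIGHBOR_SYN, 1.0, params.omega)
    for i in range(N_CODONS):
        k = NEIGHBOR_COUNTS[i]
        q[i, NEIGHBOR_STATE[i, :k]] = rates[i, :k]
    np.fill_diagonal(q, -q.sum(axis=1))
    pi = stationary_m0(phi)
    if params.normalization == "m0_reference":
        q = q / float(-(pi * np.diag(q)).sum())
    return q, pi
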