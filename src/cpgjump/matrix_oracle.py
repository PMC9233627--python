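"""Matrix-exponential machinery for the site-independent (lam=1) model.

When sites do not interact, the codon process is an ordinary 61-state CTMC:
transition probabilities P(t) = exp(Qt) are computable, sites are iid, and
the likelihood of an alignment follows from the pruning (post-order
conditional likelihood) recursion. This module provides

* ``transition_matrix`` — P(t) by eigendecomposition of the pi-symmetrized
  generator (the model is time-reversible, asserted at build time);
* ``simulate_alignment_expm`` — the traditional node-by-node simulator,
  used as the distributional oracle the jump-chain engine is validated
  against at lam=1;
* ``CodonLikelihood`` / ``pruning_loglik`` — the log-likelihood under a
  single omega or a mixture of omega site classes, with per-node scaling to
  prevent underflow. This is the engine behind the M0/M7/M8 fits.

Likelihood under the site-interdependent lam!=1 model is deliberately
absent: its intractability is the reason the jump-chain simulator exists.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .genetic_code import (
    N_CODONS,
    NEIGHBOR_COUNTS,
    NEIGHBOR_STATE,
    NEIGHBOR_SYN,
    NEIGHBOR_TO,
    NEIGHBOR_TS,
)
from .phylo_io import Alignment, Phylogeny
from .substitution_model import SequenceState, stationary_m0


def _stationary_of(Q: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(Q.T)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def transition_matrix(Q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """P(t) = exp(Qt) via the pi-symmetrized eigendecomposition."""
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    if t < 0:
        raise ValueError("t must be >= 0")
    off = Q - np.diag(np.diag(Q))
    if off.min() < -1e-12 or np.abs(Q.sum(axis=1)).max() > 1e-8:
        raise ValueError("Q is not a valid rate-matrix generator")
    if pi is None:
        pi = _stationary_of(Q)
    d = np.sqrt(pi)
    S = (d[:, None] * Q) / d[None, :]
    asym = np.abs(S - S.T).max()
    if asym > 1e-8:
        raise ValueError(f"Q is not reversible w.r.t. pi (asymmetry {asym:.2e})")
    S = (S + S.T) / 2
    w, V = np.linalg.eigh(S)
    P = (V * np.exp(w * t)) @ V.T
    P = P / d[:, None] * d[None, :]
    return np.clip(P, 0.0, None)


def simulate_alignment_expm(
    tree: Phylogeny,
    Q: np.ndarray,
    pi: np.ndarray,
    n_sites: int,
    rng,
) -> Alignment:
    """Traditional simulator: root from pi, children from P(branch) rows."""
    n_states = Q.shape[0]
    states = [None] * tree.n_nodes
    states[0] = rng.choice(n_states, size=n_sites, p=pi)
    for child, parent, length in tree.branches():
        P = transition_matrix(Q, length, pi)
        # cumulative-row inverse transform, vectorized over sites
        cum = np.cumsum(P[states[parent]], axis=1)
        cum[:, -1] = 1.0
        u = rng.random(n_sites)
        states[child] = (u[:, None] < cum).argmax(axis=1)
    return Alignment(
        {
            tree.names[i]: SequenceState(np.asarray(states[i], dtype=np.int64))
            for i in tree.tip_indices
        }
    )


class CodonLikelihood:
    """Pruning log-likelihood of a codon alignment under omega site classes.

    Precomputes the site-pattern compression and tree indexing once; each
    call to :meth:`loglik` rebuilds the per-class generators, so it is cheap
    enough to sit inside an optimizer loop. Generators are scaled by one
    common factor (the mixture-averaged mean rate at stationarity), so the
    tree-scale multiplier is measured in expected substitutions per codon
    site, matching the simulator's branch-length convention.
    """

    def __init__(self, alignment: Alignment, tree: Phylogeny, phi):
        tip_idx = tree.tip_indices
        missing = set(tree.tip_labels) ^ set(alignment.taxa)
        if missing:
            raise ValueError(f"alignment/tree taxon mismatch: {sorted(missing)}")
        data = alignment.codon_matrix(taxa_order=[tree.names[i] for i in tip_idx])
        patterns, inverse, counts = np.unique(
            data, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns           # (n_tips, n_patterns)
        self.pattern_counts = counts.astype(float)
        self.n_patterns = patterns.shape[1]
        self.tree = tree
        self.tip_row = {node: r for r, node in enumerate(tip_idx)}
        self.phi = np.asarray(phi, dtype=float)
        self.pi = stationary_m0(self.phi)
        # neighbour-event masks for fast batched Q construction
        slot_ok = np.arange(9)[None, :] < NEIGHBOR_COUNTS[:, None]
        rows = np.repeat(np.arange(N_CODONS), 9).reshape(N_CODONS, 9)
        self._rows = rows[slot_ok]
        self._cols = NEIGHBOR_STATE[slot_ok]
        self._base = self.phi[NEIGHBOR_TO[slot_ok]] * np.where(
            NEIGHBOR_TS[slot_ok], 1.0, 0.0
        )  # transition part, kappa-multiplied later
        self._base_tv = self.phi[NEIGHBOR_TO[slot_ok]] * np.where(
            NEIGHBOR_TS[slot_ok], 0.0, 1.0
        )
        self._nonsyn = ~NEIGHBOR_SYN[slot_ok]

    def _generators(self, omegas: np.ndarray, kappa: float):
        """Batched (K,61,61) generators, plus mean rates at stationarity."""
        vals = self._base * kappa + self._base_tv          # (n_events,)
        vals = vals[None, :] * np.where(
            self._nonsyn[None, :], omegas[:, None], 1.0
        )                                                   # (K, n_events)
        K = omegas.size
        Q = np.zeros((K, N_CODONS, N_CODONS))
        Q[:, self._rows, self._cols] = vals
        diag = Q.sum(axis=2)
        Q[:, np.arange(N_CODONS), np.arange(N_CODONS)] = -diag
        mu = diag @ self.pi                                 # (K,)
        return Q, mu

    def loglik(self, omegas, weights, kappa: float, scale: float = 1.0) -> float:
        """Log-likelihood with per-site omega mixture (equal or given weights)."""
        omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
        weights = np.atleast_1d(np.asarray(weights, dtype=float))
        if omegas.shape != weights.shape:
            raise ValueError("omegas and weights must have the same length")
        Q, mu = self._generators(omegas, kappa)
        mubar = float(weights @ mu)
        d = np.sqrt(self.pi)
        S = (d[None, :, None] * Q) / d[None, None, :]
        S = (S + S.transpose(0, 2, 1)) / 2
        w, V = np.linalg.eigh(S)                            # (K,61), (K,61,61)
        Vd = V / d[:, None]                                 # rows scaled by 1/sqrt(pi)
        Vt = V * d[:, None]                                 # pre-scaled transpose source

        tree = self.tree
        K, P = omegas.size, self.n_patterns
        partial: list[np.ndarray | None] = [None] * tree.n_nodes
        logscale = np.zeros((K, P))
        factor = scale / mubar
        # children have larger preorder indices, so reverse order is postorder
        for node in range(tree.n_nodes - 1, -1, -1):
            if tree.is_tip(node):
                continue
            L = np.ones((K, N_CODONS, P))
            for child in tree.children[node]:
                t = tree.lengths[child] * factor
                E = np.exp(w * t)                           # (K,61)
                Pm = (Vd * E[:, None, :]) @ Vt.transpose(0, 2, 1)
                np.clip(Pm, 0.0, None, out=Pm)
                if tree.is_tip(child):
                    L = L * Pm[:, :, self.patterns[self.tip_row[child]]]
                else:
                    L = L * (Pm @ partial[child])
            m = L.max(axis=1)
            m[m <= 0] = 1.0
            L = L / m[:, None, :]
            logscale = logscale + np.log(m)
            partial[node] = L
        site = np.einsum("j,kjp->kp", self.pi, partial[0])
        site = np.clip(site, 1e-300, None)
        with np.errstate(divide="ignore"):  # zero-weight components drop out
            log_site = logsumexp(
                np.log(weights)[:, None] + np.log(site) + logscale, axis=0
            )
        return float(self.pattern_counts @ log_site)


def pruning_loglik(
    alignment: Alignment,
    tree: Phylogeny,
    phi,
    site_model,
    kappa: float,
    scale: float = 1.0,
) -> float:
    """Log-likelihood of `alignment` under (omega_k, weight_k) site classes."""
    omegas = [c[0] for c in site_model]
    weights = [c[1] for c in site_model]
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("site-class weights must sum to 1")
    return CodonLikelihood(alignment, tree, phi).loglik(omegas, weights, kappa, scale)
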