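"""Rejection ABC for the CpG hypermutability multiplier lambda.

The likelihood of the site-interdependent model is intractable, but the
jump-chain simulator is cheap, so lambda can be estimated likelihood-free:
draw candidate parameter values from a prior, simulate an alignment under
each on the observed data's tree, and keep the draws whose summary
statistics fall closest to the observed summaries. The retained draws
approximate the posterior; we report their mean and the central 95%
credibility interval.

Summaries are chosen to be sensitive to CpG hypermutability (which depletes
CpG dinucleotides and shifts the transition spectrum) while remaining cheap
and taxon-order invariant; distances are Euclidean after standardizing each
summary by its standard deviation across the simulation pool. Nuisance
parameters (kappa, omega, tree scale) default to fixed values — the
generating truth in recovery experiments, or a preceding M0 fit on real
data (two-stage scheme).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
import warnings

import numpy as np
import pandas as pd

from .genetic_code import CODON_NUCS
from .phylo_io import Alignment, Phylogeny
from .substitution_model import CpGModelParams

SUMMARY_NAMES = (
    "cpg_freq",
    "freq_A",
    "freq_C",
    "freq_G",
    "freq_T",
    "variable_columns",
    "pairwise_ts_fraction",
    "pairwise_cpg_ts_fraction",
)

_A, _C, _G, _T = 0, 1, 2, 3


def _nucleotide_matrix(alignment: Alignment) -> np.ndarray:
    """(n_taxa, 3 * n_sites) nucleotide indices, rows in sorted-taxon order
    so the result (and everything derived from it) is independent of the
    alignment's storage order."""
    order = sorted(alignment.taxa)
    return CODON_NUCS[alignment.codon_matrix(order)].reshape(len(order), -1)


def summary_stats(alignment: Alignment) -> np.ndarray:
    """Deterministic, taxon-order-invariant summary vector of an alignment."""
    nucs = _nucleotide_matrix(alignment)
    n_taxa, L = nucs.shape

    cpg = np.mean((nucs[:, :-1] == _C) & (nucs[:, 1:] == _G))
    freqs = np.bincount(nucs.ravel(), minlength=4) / nucs.size
    codons = alignment.codon_matrix()
    variable = np.mean(codons.min(axis=0) != codons.max(axis=0))

    # means over unordered taxon pairs (order-invariant by construction)
    ts_fracs, cpg_fracs = [], []
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            x, y = nucs[a], nucs[b]
            diff = x != y
            n_diff = int(diff.sum())
            if n_diff == 0:
                ts_fracs.append(0.0)
                cpg_fracs.append(0.0)
                continue
            ts = diff & (
                ((x == _A) & (y == _G)) | ((x == _G) & (y == _A))
                | ((x == _C) & (y == _T)) | ((x == _T) & (y == _C))
            )
            ts_fracs.append(ts.sum() / n_diff)
            # CpG-context transitions: a C/T difference whose 3' neighbour is
            # G in either sequence, or an A/G difference whose 5' neighbour
            # is C in either sequence
            ct = diff & (((x == _C) & (y == _T)) | ((x == _T) & (y == _C)))
            ag = diff & (((x == _A) & (y == _G)) | ((x == _G) & (y == _A)))
            next_g = np.zeros(L, dtype=bool)
            next_g[:-1] = (x[1:] == _G) | (y[1:] == _G)
            prev_c = np.zeros(L, dtype=bool)
            prev_c[1:] = (x[:-1] == _C) | (y[:-1] == _C)
            cpg_fracs.append(((ct & next_g) | (ag & prev_c)).sum() / n_diff)
    return np.array([
        cpg, *freqs, variable, float(np.mean(ts_fracs)), float(np.mean(cpg_fracs)),
    ])


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors; only listed parameters are inferred."""

    lam: tuple[float, float] = (1.0, 16.0)

    def __post_init__(self):
        lo, hi = self.lam
        if not (0 <= lo < hi):
            raise ValueError(f"lambda prior bounds must satisfy 0 <= lo < hi, got {self.lam}")


@dataclass
class ABCPosterior:
    accepted: pd.DataFrame
    posterior_mean: float
    ci_low: float
    ci_high: float
    acceptance_fraction: float

    @property
    def credible_interval(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


def abc_reject(
    observed: Alignment,
    tree: Phylogeny,
    base_params: CpGModelParams,
    prior: PriorSpec,
    n_sims: int,
    accept_fraction: float,
    seed: int,
    root_mode: str = "burn_in",
) -> ABCPosterior:
    """Rejection ABC posterior for lambda on the observed alignment's tree.

    Candidate lambdas are drawn from the prior; each drives one jump-chain
    simulation with the same tree and sequence length as the observed data
    and the nuisance parameters held at `base_params`. The `accept_fraction`
    of draws closest in standardized-Euclidean summary distance is retained.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    if not (0 < accept_fraction <= 1):
        raise ValueError("accept_fraction must be in (0, 1]")
    from .jump_chain import simulate_alignment

    ss = np.random.SeedSequence(seed)
    prior_ss, *sim_ss = ss.spawn(n_sims + 1)
    rng = np.random.default_rng(prior_ss)
    lams = rng.uniform(prior.lam[0], prior.lam[1], size=n_sims)

    obs = summary_stats(observed)
    n_codons = observed.n_sites
    pool = np.empty((n_sims, obs.size))
    for i, lam in enumerate(lams):
        params = _dc_replace(base_params, lam=float(lam))
        sim, _ = simulate_alignment(
            tree, params, n_codons, sim_ss[i], root_mode=root_mode,
            record_history=False,
        )
        pool[i] = summary_stats(sim)

    sd = pool.std(axis=0, ddof=1)
    usable = sd > 0
    if not usable.all():
        dropped = [SUMMARY_NAMES[k] for k in np.flatnonzero(~usable)]
        warnings.warn(f"dropping zero-variance summaries: {dropped}")
    dist = np.sqrt(
        (((pool[:, usable] - obs[usable]) / sd[usable]) ** 2).sum(axis=1)
    )
    n_keep = max(1, int(round(accept_fraction * n_sims)))
    keep = np.argsort(dist, kind="stable")[:n_keep]
    accepted = pd.DataFrame({"lambda": lams[keep], "distance": dist[keep]})
    draws = accepted["lambda"].to_numpy()
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return ABCPosterior(
        accepted=accepted,
        posterior_mean=float(draws.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        acceptance_fraction=n_keep / n_sims,
    )
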