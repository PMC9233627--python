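"""Maximum-likelihood codon-model fits (M0, M7, M8) and the M7-vs-M8 LRT.

All three models assume site-independence (the lam=1 world). Fitting data
that was actually generated with CpG hypermutability (lam>1) is exactly the
model-violation experiment this package exists to run: M0's single omega is
biased upward, and the M7-vs-M8 likelihood ratio test (chi-square, 2 df)
starts rejecting its null even though every generating omega is below 1.

Model parameterizations:

* M0 — one omega shared by all sites; free (omega, kappa, tree scale).
* M7 — omega ~ Beta(p, q) on (0, 1), discretized into K equal-weight
  categories at quantile midpoints (k - 0.5)/K.
* M8 — with probability p0 the M7 beta, else a selection class at
  omega_s >= 1.

Branch lengths are not re-optimized individually: a single global tree
scale multiplies all of them (see the package methods note). ``kappa`` and
the scale can optionally be fixed (e.g. profiled from a preceding M0 fit)
when fitting the mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .matrix_oracle import CodonLikelihood
from .phylo_io import Alignment, Phylogeny
from .substitution_model import CpGModelParams, OmegaMixture

# Optimizer bounds (natural scale); optimization runs in log space.
OMEGA_BOUNDS = (1e-4, 20.0)
KAPPA_BOUNDS = (1e-2, 50.0)
SCALE_BOUNDS = (1e-3, 1e3)
PQ_BOUNDS = (5e-3, 100.0)
OMEGA_S_BOUNDS = (1.0, 20.0)

N_BETA_CATEGORIES = 10


@dataclass
class M0Fit:
    omega_hat: float
    kappa_hat: float
    tree_scale_hat: float
    logL: float
    converged: bool
    n_iter: int


@dataclass
class MixtureFit:
    model: str                  # "M7" or "M8"
    p: float
    q: float
    kappa_hat: float
    tree_scale_hat: float
    logL: float
    converged: bool
    n_iter: int
    p0: float | None = None     # M8 only
    omega_s: float | None = None


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


def empirical_f1x4(alignment: Alignment) -> np.ndarray:
    """Nucleotide frequencies counted over all codon positions (F1X4)."""
    from .genetic_code import CODON_NUCS

    mat = alignment.codon_matrix()
    nucs = CODON_NUCS[mat].ravel()
    counts = np.bincount(nucs, minlength=4).astype(float)
    return counts / counts.sum()


def _resolve_phi(alignment, phi, frequencies):
    if frequencies == "empirical_f1x4" or phi is None:
        return empirical_f1x4(alignment)
    if frequencies == "known_phi":
        return np.asarray(phi, dtype=float)
    raise ValueError(f"unknown frequency option {frequencies!r}")


def _optimize(fun, x0s, bounds):
    """Screen the deterministic starts by objective value, then polish the
    best with bounded L-BFGS-B."""
    scored = sorted(x0s, key=fun)
    res = optimize.minimize(
        fun,
        scored[0],
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-9},
    )
    return res


def fit_m0(
    alignment: Alignment,
    tree: Phylogeny,
    phi=None,
    frequencies: str = "known_phi",
) -> M0Fit:
    """ML fit of the single-omega model over (omega, kappa, tree scale)."""
    phi = _resolve_phi(alignment, phi, frequencies)
    cl = CodonLikelihood(alignment, tree, phi)
    one = np.ones(1)

    def nll(x):
        omega, kappa, scale = np.exp(x)
        return -cl.loglik(omega * one, one, kappa, scale)

    starts = [
        np.log([w, k, 1.0]) for w in (0.2, 1.0) for k in (2.0, 5.0)
    ]
    bounds = [np.log(OMEGA_BOUNDS), np.log(KAPPA_BOUNDS), np.log(SCALE_BOUNDS)]
    res = _optimize(nll, starts, bounds)
    omega, kappa, scale = np.exp(res.x)
    return M0Fit(
        omega_hat=float(omega),
        kappa_hat=float(kappa),
        tree_scale_hat=float(scale),
        logL=float(-res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
    )


def discretize_beta(p: float, q: float, K: int) -> np.ndarray:
    """K equal-weight omega categories at beta quantile midpoints."""
    if p <= 0 or q <= 0:
        raise ValueError("beta shape parameters must be positive")
    if K < 1:
        raise ValueError("K must be >= 1")
    return stats.beta.ppf((np.arange(K) + 0.5) / K, p, q)


def m7_components(p: float, q: float, K: int = N_BETA_CATEGORIES):
    omegas = discretize_beta(p, q, K)
    weights = np.full(K, 1.0 / K)
    return omegas, weights


def m8_components(
    p: float, q: float, p0: float, omega_s: float, K: int = N_BETA_CATEGORIES
):
    omegas = np.append(discretize_beta(p, q, K), omega_s)
    weights = np.append(np.full(K, p0 / K), 1.0 - p0)
    return omegas, weights


def fit_m7(
    alignment: Alignment,
    tree: Phylogeny,
    phi=None,
    frequencies: str = "known_phi",
    kappa: float | None = None,
    scale: float | None = None,
    K: int = N_BETA_CATEGORIES,
) -> MixtureFit:
    """ML fit of the beta-omega model; kappa/scale free unless given."""
    phi = _resolve_phi(alignment, phi, frequencies)
    cl = CodonLikelihood(alignment, tree, phi)
    fixed = kappa is not None and scale is not None
    if (kappa is None) != (scale is None):
        raise ValueError("fix kappa and scale together or not at all")

    def nll(x):
        p, q = np.exp(x[:2])
        kap, sc = (kappa, scale) if fixed else np.exp(x[2:])
        om, wt = m7_components(p, q, K)
        return -cl.loglik(np.clip(om, 1e-8, None), wt, kap, sc)

    pq_starts = [(1.0, 1.0), (0.5, 2.0)]
    if fixed:
        starts = [np.log(s) for s in pq_starts]
        bounds = [np.log(PQ_BOUNDS)] * 2
    else:
        starts = [np.log(s + (2.0, 1.0)) for s in pq_starts]
        bounds = [np.log(PQ_BOUNDS)] * 2 + [np.log(KAPPA_BOUNDS), np.log(SCALE_BOUNDS)]
    res = _optimize(nll, starts, bounds)
    p, q = np.exp(res.x[:2])
    kap, sc = (kappa, scale) if fixed else np.exp(res.x[2:])
    return MixtureFit(
        model="M7", p=float(p), q=float(q), kappa_hat=float(kap),
        tree_scale_hat=float(sc), logL=float(-res.fun),
        converged=bool(res.success), n_iter=int(res.nit),
    )


def fit_m8(
    alignment: Alignment,
    tree: Phylogeny,
    phi=None,
    frequencies: str = "known_phi",
    kappa: float | None = None,
    scale: float | None = None,
    K: int = N_BETA_CATEGORIES,
    m7_fit: MixtureFit | None = None,
) -> MixtureFit:
    """ML fit of the beta-plus-selection model.

    The M7 optimum (embedded at p0 -> 1) is always included among the
    candidate solutions, so the fitted M8 log-likelihood can never fall
    below M7's by more than roundoff — the nesting the LRT requires.
    """
    phi = _resolve_phi(alignment, phi, frequencies)
    cl = CodonLikelihood(alignment, tree, phi)
    fixed = kappa is not None and scale is not None
    if (kappa is None) != (scale is None):
        raise ValueError("fix kappa and scale together or not at all")

    def unpack(x):
        p, q = np.exp(x[:2])
        p0 = 1.0 / (1.0 + np.exp(-x[2]))          # logit
        omega_s = 1.0 + np.exp(x[3])               # >= 1
        kap, sc = (kappa, scale) if fixed else np.exp(x[4:])
        return p, q, p0, omega_s, kap, sc

    def nll(x):
        p, q, p0, omega_s, kap, sc = unpack(x)
        om, wt = m8_components(p, q, p0, min(omega_s, OMEGA_S_BOUNDS[1]), K)
        return -cl.loglik(np.clip(om, 1e-8, None), wt, kap, sc)

    if m7_fit is None:
        m7_fit = fit_m7(alignment, tree, phi, "known_phi", kappa, scale, K)
    base = [np.log(m7_fit.p), np.log(m7_fit.q)]
    tail = [] if fixed else [np.log(m7_fit.kappa_hat), np.log(m7_fit.tree_scale_hat)]
    starts = [
        np.array(base + [np.log(0.9 / 0.1), np.log(1.5 - 1.0)] + tail),
        np.array(base + [np.log(0.98 / 0.02), np.log(3.0 - 1.0)] + tail),
    ]
    bounds = (
        [np.log(PQ_BOUNDS)] * 2
        + [(-12.0, 16.0), (np.log(1e-6), np.log(OMEGA_S_BOUNDS[1] - 1.0))]
        + ([] if fixed else [np.log(KAPPA_BOUNDS), np.log(SCALE_BOUNDS)])
    )
    res = _optimize(nll, starts, bounds)
    p, q, p0, omega_s, kap, sc = unpack(res.x)
    logL = float(-res.fun)
    converged = bool(res.success)
    if logL < m7_fit.logL:
        # boundary solution: the best M8 is M7 itself (p0 = 1)
        p, q, p0, omega_s = m7_fit.p, m7_fit.q, 1.0, 1.0
        kap, sc = m7_fit.kappa_hat, m7_fit.tree_scale_hat
        logL = m7_fit.logL
    return MixtureFit(
        model="M8", p=float(p), q=float(q), kappa_hat=float(kap),
        tree_scale_hat=float(sc), logL=logL, converged=converged,
        n_iter=int(res.nit), p0=float(p0), omega_s=float(omega_s),
    )


def lrt_m7_m8(fit7: MixtureFit, fit8: MixtureFit) -> LRTResult:
    """Likelihood ratio test of M7 (null) vs M8, chi-square with 2 df."""
    stat = max(0.0, 2.0 * (fit8.logL - fit7.logL))
    return LRTResult(statistic=stat, df=2, p_value=float(stats.chi2.sf(stat, 2)))


# ---------------------------------------------------------------------------
# Replicated bias / false-positive experiments
# ---------------------------------------------------------------------------

def replicate_seed(master_seed: int, condition_index: int, replicate: int):
    """Deterministic per-replicate seed; rerunning one cell reproduces it."""
    return np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(int(condition_index), int(replicate))
    )


def bias_experiment(
    tree: Phylogeny,
    phi,
    kappa: float,
    conditions,
    n_codons: int,
    n_replicates: int,
    master_seed: int,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate-and-refit grid over (omega condition, lambda) cells.

    Each condition is ``(name, omega_or_mixture, lam)``. Single-omega
    conditions are refit with M0 and scored by whether the estimate exceeds
    the generating omega; mixture conditions run the M7-vs-M8 LRT (with
    kappa and tree scale profiled from a preceding M0 fit) and are scored by
    rejection at level `alpha`. Returns (per-replicate rows, per-cell
    aggregates).
    """
    from .jump_chain import simulate_alignment

    rows = []
    for cond_idx, (name, omega, lam) in enumerate(conditions):
        mixture = isinstance(omega, (OmegaMixture, tuple, list))
        if mixture and not isinstance(omega, OmegaMixture):
            omega = OmegaMixture(tuple(omega))
        params = CpGModelParams(phi=tuple(phi), kappa=kappa, lam=lam, omega=omega)
        for rep in range(n_replicates):
            ss = replicate_seed(master_seed, cond_idx, rep)
            alignment, _ = simulate_alignment(
                tree, params, n_codons, ss, record_history=False
            )
            row = {"condition": name, "lambda": lam, "replicate": rep}
            if mixture:
                m0 = fit_m0(alignment, tree, phi)
                f7 = fit_m7(
                    alignment, tree, phi,
                    kappa=m0.kappa_hat, scale=m0.tree_scale_hat,
                )
                f8 = fit_m8(
                    alignment, tree, phi,
                    kappa=m0.kappa_hat, scale=m0.tree_scale_hat, m7_fit=f7,
                )
                lrt = lrt_m7_m8(f7, f8)
                row.update(
                    logL7=f7.logL, logL8=f8.logL,
                    statistic=lrt.statistic, p_value=lrt.p_value,
                    reject=lrt.p_value < alpha,
                )
            else:
                fit = fit_m0(alignment, tree, phi)
                row.update(
                    omega_true=omega, omega_hat=fit.omega_hat,
                    kappa_hat=fit.kappa_hat, scale_hat=fit.tree_scale_hat,
                    logL=fit.logL, converged=fit.converged,
                    overestimated=fit.omega_hat > omega,
                )
            rows.append(row)
    per_replicate = pd.DataFrame(rows)
    if per_replicate.empty:
        empty = pd.DataFrame(columns=["condition", "lambda", "replicate"])
        return empty, pd.DataFrame(columns=["condition", "lambda", "n"])
    aggs = []
    for (name, lam), grp in per_replicate.groupby(["condition", "lambda"], sort=False):
        agg = {"condition": name, "lambda": lam, "n": len(grp)}
        if "overestimated" in grp and grp["overestimated"].notna().any():
            agg["overestimation_fraction"] = float(grp["overestimated"].mean())
        if "reject" in grp and grp["reject"].notna().any():
            agg["rejection_fraction"] = float(grp["reject"].mean())
        aggs.append(agg)
    return per_replicate, pd.DataFrame(aggs)
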