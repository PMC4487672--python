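"""Empirical-Bayes detection of differentially co-expressed gene pairs.

For m genes and K conditions, a p x K matrix D (p = m(m-1)/2) holds the
biweight midcorrelation of every gene pair computed within each condition.
Correlations are Fisher z-transformed and modeled as draws from a shared
normal mixture; a pair is *equivalently co-expressed* (EC) when all its
condition-wise correlations come from the same (latent) mixture component
and *differentially co-expressed* (DC) when the components may differ
across condition classes.  Patterns (partitions of the conditions) carry
prior weights; EM fits the component parameters and pattern priors, and
Bayes' rule yields each pair's posterior probability of DC.  A soft
threshold on the posteriors controls the posterior expected FDR.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .preprocess import MergedExpression
from .pearson_dc import ScoredPairSet

_SD_FLOOR = 1e-3
_Z_CLIP = 1.0 - 1e-6


@dataclass
class EBInputs:
    """Per-pair, per-condition correlation matrix D plus the pattern set.

    ``d`` is a DataFrame with one row per unordered gene pair (lexicographic
    order, index of ``"gene_i|gene_j"`` strings) and one column per
    condition.  ``patterns`` partitions the condition indices into classes:
    the EC pattern is the single-block partition; every other partition is a
    DC pattern.
    """

    d: pd.DataFrame
    pairs: list[tuple[str, str]]
    patterns: list[tuple[tuple[int, ...], ...]]

    def __post_init__(self) -> None:
        if self.d.shape[1] < 2:
            raise ValueError("need at least 2 conditions")
        vals = self.d.to_numpy()
        if np.abs(vals).max(initial=0.0) > 1.0:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class EBModel:
    """Normal-mixture hyperparameters (on the Fisher-z scale) and posteriors."""

    means: np.ndarray          # component means, z scale
    sds: np.ndarray            # component sds, z scale
    weights: np.ndarray        # component weights, sum to 1
    pattern_priors: np.ndarray # one prior per pattern, sum to 1
    variant: str = "one-step"
    posterior_dc: pd.Series | None = None
    loglik_trace: list[float] = field(default_factory=list)
    bic_by_k: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.pattern_priors = np.asarray(self.pattern_priors, dtype=float)
        if np.any(self.sds <= 0):
            raise ValueError("component sds must be positive")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("component weights must sum to 1")

    @property
    def means_corr(self) -> np.ndarray:
        """Component means back-transformed to the correlation scale."""
        return np.tanh(self.means)


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))


def biweight_midcorrelation(x, y) -> float:
    """Robust correlation with Tukey biweight weights around the median.

    Observations are centered at the median and scaled by 9*MAD; points
    beyond that window get zero weight, the rest the weight (1-u^2)^2.
    When either vector's MAD is zero the biweight is undefined and the
    Pearson correlation is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    mats = _bicor_matrix(np.vstack([x, y]))
    return float(mats[0, 1])


def _bicor_weights(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Biweight-midcovariance terms per row; rows with zero MAD flagged."""
    med = np.median(mat, axis=1, keepdims=True)
    mad = np.median(np.abs(mat - med), axis=1, keepdims=True)
    zero_mad = (mad[:, 0] == 0)
    safe_mad = np.where(mad == 0, 1.0, mad)
    u = (mat - med) / (9.0 * safe_mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    g = (mat - med) * w
    return g, zero_mad


def _bicor_matrix(mat: np.ndarray) -> np.ndarray:
    """Row-by-row biweight midcorrelation matrix (genes x samples input)."""
    g, zero_mad = _bicor_weights(mat)
    norm = np.sqrt((g**2).sum(axis=1, keepdims=True))
    norm_safe = np.where(norm == 0, 1.0, norm)
    r = (g / norm_safe) @ (g / norm_safe).T
    if zero_mad.any():
        warnings.warn(
            f"{int(zero_mad.sum())} profile(s) with zero MAD: "
            "falling back to Pearson for their correlations",
            stacklevel=3,
        )
        with np.errstate(invalid="ignore"):
            pearson = np.corrcoef(mat)
        r[zero_mad, :] = pearson[zero_mad, :]
        r[:, zero_mad] = pearson[:, zero_mad]
    return np.clip(r, -1.0, 1.0)


def _set_partitions(k: int) -> list[tuple[tuple[int, ...], ...]]:
    """All partitions of range(k), EC (single block) first, deterministic."""
    def rec(items):
        if not items:
            yield ()
            return
        first, rest = items[0], items[1:]
        for part in rec(rest):
            # put `first` in each existing block, or in a new block
            for i in range(len(part)):
                yield part[:i] + ((first,) + part[i],) + part[i + 1:]
            yield part + ((first,),)

    parts = {tuple(sorted(tuple(sorted(b)) for b in p)) for p in rec(tuple(range(k)))}
    return sorted(parts, key=lambda p: (len(p), p))


def default_patterns(k: int = 2) -> list[tuple[tuple[int, ...], ...]]:
    """EC/DC pattern set: for K=2, EC={(0,1)} and DC={(0),(1)}."""
    return _set_partitions(k)


def make_d_matrix(
    merged: MergedExpression,
    genes,
    conditions: pd.Series | None = None,
) -> EBInputs:
    """Condition-wise biweight midcorrelations for all m(m-1)/2 gene pairs.

    ``conditions`` defaults to the merged case/control labels; any per-sample
    labeling with K >= 2 levels is accepted.  Rows follow lexicographic pair
    order; column k holds the correlations computed within condition k.
    """
    genes = sorted(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    if conditions is None:
        conditions = merged.condition
    levels = sorted(conditions.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 conditions")
    sub = merged.expr.loc[genes]
    iu, ju = np.triu_indices(len(genes), k=1)
    cols = {}
    for level in levels:
        samples = conditions.index[(conditions == level).to_numpy()]
        if len(samples) < 3:
            raise ValueError(f"condition {level!r} has fewer than 3 samples")
        r = _bicor_matrix(sub[samples].to_numpy())
        cols[str(level)] = r[iu, ju]
    pairs = [(genes[i], genes[j]) for i, j in zip(iu, ju)]
    d = pd.DataFrame(cols, index=[f"{gi}|{gj}" for gi, gj in pairs])
    return EBInputs(d=d, pairs=pairs, patterns=default_patterns(len(levels)))


def initialize_hyperparameters(
    inputs: EBInputs,
    max_components: int = 3,
    seed: int = 0,
) -> EBModel:
    """Initialize the mixture by a BIC-selected Gaussian-mixture fit.

    All entries of D are pooled, Fisher z-transformed and fit with 1 to
    ``max_components`` Gaussian components (seeded k-means initialization);
    the component count minimizing BIC wins.  Pattern priors start uniform.
    """
    if inputs.n_pairs < 10:
        raise ValueError("need at least 10 pairs to initialize the mixture")
    z = _fisher_z(inputs.d.to_numpy()).reshape(-1, 1)
    if np.ptp(z) < 1e-12:  # degenerate single-value input
        model = EBModel(
            means=np.array([z.mean()]),
            sds=np.array([_SD_FLOOR]),
            weights=np.array([1.0]),
            pattern_priors=np.full(len(inputs.patterns), 1.0 / len(inputs.patterns)),
        )
        model.bic_by_k = {1: float("nan")}
        return model
    best = None
    bics: dict[int, float] = {}
    for k in range(1, max_components + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="spherical",
            random_state=seed,
            n_init=3,
        ).fit(z)
        bics[k] = float(gm.bic(z))
        if best is None or bics[k] < bics[best[0]]:
            best = (k, gm)
    k, gm = best
    order = np.argsort(gm.means_.ravel())
    model = EBModel(
        means=gm.means_.ravel()[order],
        sds=np.maximum(np.sqrt(gm.covariances_.ravel()[order]), _SD_FLOOR),
        weights=gm.weights_[order] / gm.weights_[order].sum(),
        pattern_priors=np.full(len(inputs.patterns), 1.0 / len(inputs.patterns)),
    )
    model.bic_by_k = bics
    return model


def _pattern_likelihoods(
    z: np.ndarray,
    patterns,
    means: np.ndarray,
    sds: np.ndarray,
    weights: np.ndarray,
):
    """Marginal likelihood of each pair under each pattern.

    Within a block all condition columns share one latent component, which
    is integrated out against the component weights.  For a multi-block
    (differential) pattern the blocks carry *distinct* components — the
    joint assignment prior is the product of weights renormalized over
    distinct tuples — which is what makes the differential pattern
    identifiable against the equivalent one under a discrete mixture.

    Returns ``L`` of shape (p, n_patterns) plus the per-pattern block
    densities and tuple terms needed by the M-step.
    """
    p, _ = z.shape
    C = len(means)
    phi = stats.norm.pdf(z[:, :, None], means[None, None, :], sds[None, None, :])
    phi = np.maximum(phi, 1e-300)
    L = np.empty((p, len(patterns)))
    details = []
    for pi, pattern in enumerate(patterns):
        bphis = [np.prod(phi[:, list(block), :], axis=1) for block in pattern]
        if len(pattern) == 1:
            joint = weights[None, :] * bphis[0]  # p x C
            L[:, pi] = np.maximum(joint.sum(axis=1), 1e-300)
            details.append((pattern, bphis, None))
            continue
        tuples = [
            t
            for t in itertools.product(range(C), repeat=len(pattern))
            if len(set(t)) == len(t)
        ]
        if not tuples:  # fewer components than blocks: pattern impossible
            L[:, pi] = 1e-300
            details.append((pattern, bphis, ([], None)))
            continue
        z_norm = sum(float(np.prod(weights[list(t)])) for t in tuples)
        terms = np.empty((p, len(tuples)))
        for ti, t in enumerate(tuples):
            term = np.full(p, float(np.prod(weights[list(t)])) / z_norm)
            for b, c in enumerate(t):
                term = term * bphis[b][:, c]
            terms[:, ti] = term
        L[:, pi] = np.maximum(terms.sum(axis=1), 1e-300)
        details.append((pattern, bphis, (tuples, terms)))
    return L, details


def fit_em(
    inputs: EBInputs,
    init: EBModel,
    variant: str = "one-step",
    max_iter: int = 500,
    tol: float = 1e-6,
) -> EBModel:
    """Fit pattern priors and mixture parameters by EM; compute posteriors.

    ``variant`` selects how much fitting happens on top of the initial
    hyperparameters: ``"zero-step"`` evaluates posteriors at the initial
    estimates, ``"one-step"`` (default) performs a single EM update, and
    ``"full"`` iterates to convergence (log-likelihood change below ``tol``
    or ``max_iter`` iterations).  EM refines the component means and sds
    and the pattern priors; the component weights stay at their initialized
    values (they enter the distinct-tuple normalizer of the differential
    patterns, so holding them fixed keeps the M-step exact and the
    observed-data log-likelihood provably non-decreasing, which is recorded
    per iteration).
    """
    if variant not in {"zero-step", "one-step", "full"}:
        raise ValueError(f"unknown EM variant {variant!r}")
    z = _fisher_z(inputs.d.to_numpy())
    patterns = inputs.patterns
    means, sds = init.means.copy(), init.sds.copy()
    weights = init.weights.copy()
    priors = init.pattern_priors.copy()
    n_iter = {"zero-step": 0, "one-step": 1, "full": max_iter}[variant]

    trace: list[float] = []
    p, K = z.shape
    C = len(means)
    for it in range(n_iter):
        L, details = _pattern_likelihoods(z, patterns, means, sds, weights)
        mix = L * priors[None, :]
        tot = np.maximum(mix.sum(axis=1), 1e-300)
        ll = float(np.log(tot).sum())
        if not np.isfinite(ll):
            raise RuntimeError(
                "non-finite log-likelihood during EM "
                f"(iteration {it}, means={means}, sds={sds})"
            )
        trace.append(ll)
        t_pat = mix / tot[:, None]  # p x n_patterns

        # M-step: every observation z[g, k] contributes to component c with
        # weight = pattern posterior x component responsibility inside the
        # pattern (shared per block; distinct across blocks)
        w_sum = np.zeros(C)
        m_sum = np.zeros(C)
        v_sum = np.zeros(C)

        def _accumulate(block, wgt):
            nonlocal w_sum, m_sum, v_sum
            for k in block:
                w_sum += wgt.sum(axis=0)
                m_sum += (wgt * z[:, k][:, None]).sum(axis=0)
                v_sum += (wgt * (z[:, k] ** 2)[:, None]).sum(axis=0)

        for pi, (pattern, bphis, multi) in enumerate(details):
            if multi is None:  # single block: shared assignment
                joint = weights[None, :] * bphis[0]
                rho = joint / np.maximum(joint.sum(axis=1), 1e-300)[:, None]
                _accumulate(pattern[0], t_pat[:, pi][:, None] * rho)
                continue
            tuples, terms = multi
            if not tuples:
                continue
            tuple_resp = terms / np.maximum(terms.sum(axis=1), 1e-300)[:, None]
            for b, block in enumerate(pattern):
                rho = np.zeros((p, C))
                for ti, t in enumerate(tuples):
                    rho[:, t[b]] += tuple_resp[:, ti]
                _accumulate(block, t_pat[:, pi][:, None] * rho)

        w_sum = np.maximum(w_sum, 1e-300)
        means = m_sum / w_sum
        sds = np.maximum(np.sqrt(np.maximum(v_sum / w_sum - means**2, 0.0)), _SD_FLOOR)
        priors = np.maximum(t_pat.mean(axis=0), 1e-12)
        priors = priors / priors.sum()

        if variant == "full" and len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break

    # final posterior evaluation at the fitted parameters
    L, _ = _pattern_likelihoods(z, patterns, means, sds, weights)
    mix = L * priors[None, :]
    tot = np.maximum(mix.sum(axis=1), 1e-300)
    trace.append(float(np.log(tot).sum()))
    t_pat = mix / tot[:, None]
    ec_index = next(i for i, pat in enumerate(patterns) if len(pat) == 1)
    posterior_dc = 1.0 - t_pat[:, ec_index]

    return EBModel(
        means=means,
        sds=sds,
        weights=weights,
        pattern_priors=priors,
        variant=variant,
        posterior_dc=pd.Series(posterior_dc, index=inputs.d.index),
        loglik_trace=trace,
        bic_by_k=init.bic_by_k,
    )


def crit_fun(posteriors, target_fdr: float = 0.05) -> tuple[float, np.ndarray]:
    """Soft threshold controlling the posterior expected FDR.

    Finds the smallest cutoff c such that the mean of (1 - posterior) over
    all pairs with posterior >= c is at most ``target_fdr``, and returns
    ``(c, called)`` where ``called`` is the boolean mask of the called set.
    If no cutoff attains the target the called set is empty and the cutoff
    is reported as ``inf``.
    """
    pp = np.asarray(posteriors, dtype=float)
    if np.any((pp < 0) | (pp > 1)):
        raise ValueError("posteriors must lie in [0, 1]")
    order = np.argsort(-pp, kind="stable")
    sorted_pp = pp[order]
    running_fdr = np.cumsum(1.0 - sorted_pp) / np.arange(1, len(pp) + 1)
    # only cutoffs at tie-group boundaries give a set of the form {pp >= c}
    boundary = np.append(sorted_pp[:-1] > sorted_pp[1:], True)
    valid = np.flatnonzero((running_fdr <= target_fdr) & boundary)
    if len(valid) == 0:
        return float("inf"), np.zeros(len(pp), dtype=bool)
    cutoff = float(sorted_pp[valid[-1]])
    called = pp >= cutoff
    # the construction guarantees posterior-expected FDR control
    assert (1.0 - pp[called]).mean() <= target_fdr + 1e-12
    return cutoff, called


def eb_pairs(
    inputs: EBInputs,
    model: EBModel,
    target_fdr: float = 0.05,
) -> tuple[ScoredPairSet, pd.DataFrame]:
    """Called DC pairs with posterior probability as strength."""
    if model.posterior_dc is None:
        raise ValueError("model has no posteriors; run fit_em first")
    pp = model.posterior_dc.to_numpy()
    cutoff, called = crit_fun(pp, target_fdr)
    table = inputs.d.copy()
    table["posterior_dc"] = pp
    table["called"] = called
    scores = {
        pair: float(p) for pair, p, c in zip(inputs.pairs, pp, called) if c
    }
    return ScoredPairSet(method="eb", scores=scores), table
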