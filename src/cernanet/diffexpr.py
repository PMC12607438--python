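"""Differential expression for count data: TMM normalization, the
conditional negative-binomial exact test, BH correction and per-layer
significance calls, plus the 2^-ddCt qPCR quantification utility.

Model
-----
Counts for feature *f* in sample *s* are negative binomial with mean
``mu_fs`` and variance ``mu_fs + phi * mu_fs**2`` (the common-dispersion
convention of edgeR).  For a two-group comparison the samples are first
scaled to a common effective library size; conditioning on the total
count of a feature, the per-group sums then follow a conditional
distribution free of the nuisance mean, and a two-sided exact p-value
is the summed probability of all splits no more likely than the one
observed (minimum-likelihood two-sided rule).

Layer-specific calling rules follow standard ceRNA screening practice:
circRNA and mRNA use |log2FC| >= lfc_min with BH q <= q_max; miRNA uses
the raw p <= p_max with no fold-change filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .io import group_samples

LAYERS = ("circRNA", "miRNA", "mRNA")

#: relative tolerance when comparing split probabilities to the
#: observed one (discrete ties must count as "as extreme").
_TIE_RTOL = 1e-12


@dataclass
class NormalizationFactors:
    """Per-sample TMM scale factors (geometric mean 1)."""

    factors: pd.Series  # indexed by sample id
    method: str = "TMM"


def tmm_factors(matrix: pd.DataFrame, trim_m: float = 0.3, trim_a: float = 0.05) -> NormalizationFactors:
    """Trimmed mean of M-values normalization factors.

    Re-implements edgeR's default scheme: pick the column whose
    upper-quartile relative abundance is closest to the mean as the
    reference, compute gene-wise log-ratios (M) and average abundances
    (A) against it on library-scaled counts, double-trim (30% of M each
    tail, 5% of A each tail), and take the precision-weighted mean M.
    Factors are rescaled to geometric mean 1.
    """
    if matrix.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    counts = matrix.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = matrix.columns[lib == 0][0]
        raise ValueError(f"all-zero sample column {bad!r}")
    p = counts / lib
    uq = np.array([np.quantile(p[:, j][counts[:, j] > 0], 0.75) if (counts[:, j] > 0).any() else 0.0
                   for j in range(p.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(p.shape[1])
    for j in range(p.shape[1]):
        if j == ref:
            continue
        ok = (counts[:, j] > 0) & (counts[:, ref] > 0)
        if not ok.any():
            continue
        m = np.log2(p[ok, j] / p[ok, ref])
        a = 0.5 * np.log2(p[ok, j] * p[ok, ref])
        # delta-method weight: inverse asymptotic variance of M
        var = ((lib[j] - counts[ok, j]) / (lib[j] * counts[ok, j])
               + (lib[ref] - counts[ok, ref]) / (lib[ref] * counts[ok, ref]))
        with np.errstate(divide="ignore"):
            w = np.where(var > 0, 1.0 / np.maximum(var, np.finfo(float).tiny), 1.0)
        n = m.size
        lo_m, hi_m = np.floor(n * trim_m), np.ceil(n * (1 - trim_m))
        lo_a, hi_a = np.floor(n * trim_a), np.ceil(n * (1 - trim_a))
        rank_m = stats.rankdata(m, method="ordinal")
        rank_a = stats.rankdata(a, method="ordinal")
        keep = (rank_m > lo_m) & (rank_m <= hi_m) & (rank_a > lo_a) & (rank_a <= hi_a)
        if keep.any():
            log_factors[j] = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    factors = 2.0 ** (log_factors - log_factors.mean())
    return NormalizationFactors(pd.Series(factors, index=matrix.columns))


def cpm(matrix: pd.DataFrame, norm: NormalizationFactors | None = None) -> pd.DataFrame:
    """Counts per million on TMM-effective library sizes."""
    if norm is None:
        norm = tmm_factors(matrix)
    eff = matrix.sum(axis=0) * norm.factors
    return matrix / eff * 1e6


def equalize_libraries(matrix: pd.DataFrame, norm: NormalizationFactors) -> pd.DataFrame:
    """Scale every sample's counts to the geometric-mean effective
    library size, rounding half-to-even, so the conditional exact test
    applies exactly."""
    eff = matrix.sum(axis=0).to_numpy(float) * norm.factors.to_numpy(float)
    target = np.exp(np.mean(np.log(eff)))
    scaled = matrix.to_numpy(float) * (target / eff)
    return pd.DataFrame(np.rint(scaled).astype(int), index=matrix.index, columns=matrix.columns)


def _conditional_log_pmf(t: int, n_a: int, n_b: int, dispersion: float) -> np.ndarray:
    """Log-probabilities of the group-A sum s = 0..t given total t.

    With per-sample NB(mean mu, var mu + phi mu^2) counts at equal
    means, the group sums are NB with sizes n_a/phi and n_b/phi sharing
    the success parameter, which cancels on conditioning.  phi = 0 is
    the Poisson limit: Binomial(t, n_a/(n_a+n_b)).
    """
    s = np.arange(t + 1)
    if dispersion == 0.0:
        return stats.binom.logpmf(s, t, n_a / (n_a + n_b))
    r1 = n_a / dispersion
    r2 = n_b / dispersion
    logw = (gammaln(s + r1) - gammaln(s + 1)
            + gammaln(t - s + r2) - gammaln(t - s + 1))
    return logw - logsumexp(logw)


def exact_nb_test(counts_a, counts_b, dispersion: float) -> float:
    """Two-sided conditional exact test for a difference in NB means.

    Counts must be library-equalized.  Returns the summed conditional
    probability of every split of the total whose probability does not
    exceed that of the observed split.
    """
    a = np.asarray(counts_a, dtype=int)
    b = np.asarray(counts_b, dtype=int)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative counts")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    sa, sb = int(a.sum()), int(b.sum())
    t = sa + sb
    if t == 0:
        return 1.0
    logp = _conditional_log_pmf(t, a.size, b.size, dispersion)
    prob = np.exp(logp - logp.max())          # scale-free comparison
    p = prob[prob <= prob[sa] * (1 + _TIE_RTOL)].sum() / prob.sum()
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def estimate_common_dispersion(matrix: pd.DataFrame, design: pd.DataFrame) -> float:
    """Method-of-moments common dispersion on equalized counts.

    Per feature: pooled within-group variance s2 and grand mean xbar
    over all groups with >= 2 replicates give max(0, (s2 - xbar)/xbar^2);
    the estimate is the median across features with xbar > 0.
    """
    groups = [g for g, n in design["group"].value_counts().items() if n >= 2]
    if not groups:
        raise ValueError("no group with >= 2 replicates")
    norm = tmm_factors(matrix)
    eq = equalize_libraries(matrix, norm).to_numpy(float)
    cols = {g: [matrix.columns.get_loc(s) for s in group_samples(design, g)] for g in groups}
    ss = np.zeros(eq.shape[0])
    df = 0
    used: list[int] = []
    for g in groups:
        sub = eq[:, cols[g]]
        ss += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
        df += sub.shape[1] - 1
        used.extend(cols[g])
    s2 = ss / df
    xbar = eq[:, used].mean(axis=1)
    ok = xbar > 0
    if not ok.any():
        return 0.0
    phi = np.maximum(0.0, (s2[ok] - xbar[ok]) / xbar[ok] ** 2)
    return float(np.median(phi))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


def call_de(matrix: pd.DataFrame, design: pd.DataFrame, contrast, layer: str, config,
            dispersion: float | None = None) -> pd.DataFrame:
    """Differential-expression table for one two-group contrast.

    Returns a DataFrame with columns feature_id, mean_a, mean_b,
    log2fc, p, q, call.  log2FC is log2 of group-B over group-A mean
    CPM with a 0.5 pseudocount; the sign convention for contrast
    (A, B) is therefore "positive = up in B".
    """
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}")
    ga, gb = contrast
    samples_a = group_samples(design, ga)
    samples_b = group_samples(design, gb)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each contrast group needs >= 2 samples")
    sub = matrix[samples_a + samples_b]
    norm = tmm_factors(sub)
    if dispersion is None:
        sub_design = design[design["group"].isin([ga, gb])]
        dispersion = estimate_common_dispersion(sub, sub_design)
    eq = equalize_libraries(sub, norm)
    abundance = cpm(sub, norm)
    mean_a = abundance[samples_a].mean(axis=1)
    mean_b = abundance[samples_b].mean(axis=1)
    log2fc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
    p = np.array([
        exact_nb_test(row[: len(samples_a)], row[len(samples_a):], dispersion)
        for row in eq[samples_a + samples_b].to_numpy()
    ])
    q = bh_adjust(p) if p.size else p
    if layer == "miRNA":
        signif = p <= config.p_max
    else:
        signif = (q <= config.q_max) & (np.abs(log2fc) >= config.lfc_min)
    call = np.where(~signif, "ns", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame({
        "feature_id": matrix.index,
        "mean_a": mean_a.to_numpy(),
        "mean_b": mean_b.to_numpy(),
        "log2fc": log2fc.to_numpy(),
        "p": p,
        "q": q,
        "call": call,
    }).reset_index(drop=True)


def relative_quantification(ct_target, ct_reference) -> float:
    """2^-ddCt relative expression of a target gene.

    Both arguments are (treated, control) pairs of Ct values (scalars
    or replicate vectors, averaged).  dCt = Ct_target - Ct_reference in
    each condition; ddCt = dCt_treated - dCt_control; the fold change
    returned is 2**-ddCt.
    """
    (tt, tc) = ct_target
    (rt, rc) = ct_reference
    vals = [np.mean(np.asarray(v, dtype=float)) for v in (tt, tc, rt, rc)]
    if not all(np.isfinite(v) for v in vals):
        raise ValueError("non-finite Ct value")
    tt_m, tc_m, rt_m, rc_m = vals
    ddct = (tt_m - rt_m) - (tc_m - rc_m)
    return float(2.0 ** (-ddct))
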