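"""Significance testing of decomposition terms and effect sizes.

Observed global terms are compared against null ensembles with an add-one
corrected empirical tail probability (so a finite ensemble can never report
p = 0: the floor is ``1/(n_null + 1)``).  Paired comparisons between two
matched samples (e.g. subjects vs. their own rewired surrogates) use a
sign-flip permutation of the paired differences with the paired t statistic,
and effect sizes are Hedges' g (pooled-SD standardized mean difference with
the small-sample correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TermTest",
    "empirical_p",
    "permutation_paired_test",
    "hedges_g",
    "term_tests",
]

_DIRECTIONS = ("two-sided", "greater", "less")


def empirical_p(observed: float, null_values, direction: str = "two-sided") -> float:
    """Add-one-corrected empirical tail probability of ``observed``.

    ``greater``: fraction of nulls >= observed; ``less``: <=; two-sided
    doubles the smaller tail, capped at 1.  With ``n`` null values the
    smallest attainable p is ``1/(n+1)``.
    """
    null_values = np.asarray(list(null_values), dtype=float)
    if null_values.size == 0:
        raise ValueError("need at least one null value")
    n = null_values.size
    p_greater = (1 + np.sum(null_values >= observed)) / (1 + n)
    p_less = (1 + np.sum(null_values <= observed)) / (1 + n)
    if direction == "greater":
        return float(p_greater)
    if direction == "less":
        return float(p_less)
    if direction == "two-sided":
        return float(min(1.0, 2.0 * min(p_greater, p_less)))
    raise ValueError(f"direction must be one of {_DIRECTIONS}")


def _paired_t(d: np.ndarray) -> float:
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(d.mean() / (sd / np.sqrt(len(d))))


def permutation_paired_test(x, y, n_perm: int = 10000,
                            seed: int | np.random.Generator = 0,
                            direction: str = "two-sided",
                            exact: bool | None = None) -> float:
    """Sign-flip permutation test of paired samples with a paired t statistic.

    Under the null of exchangeable pair members, each difference's sign is
    flipped uniformly; the p-value is the add-one-corrected fraction of
    permuted statistics at least as extreme as the observed one.  With
    ``exact=True`` (the default for 10 or fewer pairs) all ``2^n`` sign
    patterns are enumerated instead of sampled, giving the exact
    randomization p-value without the add-one correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matched 1-D samples of equal length")
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    d = x - y
    n = len(d)
    if np.allclose(d, 0):
        return 1.0
    t_obs = _paired_t(d)
    if exact is None:
        exact = n <= 10
    if exact:
        signs = np.array(np.meshgrid(*([[1.0, -1.0]] * n), indexing="ij")
                         ).reshape(n, -1).T
        add_one = 0
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_perm, n))
        add_one = 1

    flipped = signs * d
    means = flipped.mean(axis=1)
    sds = flipped.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(sds > 0, means / (sds / np.sqrt(n)), 0.0)

    if direction == "greater":
        hits = np.sum(t_perm >= t_obs)
    elif direction == "less":
        hits = np.sum(t_perm <= t_obs)
    else:
        hits = np.sum(np.abs(t_perm) >= abs(t_obs))
    return float((add_one + hits) / (add_one + len(t_perm)))


def hedges_g(x, y) -> float:
    """Hedges' g: bias-corrected standardized mean difference of two samples.

    Pooled-SD Cohen's d times the small-sample correction
    ``1 - 3/(4(n1+n2) - 9)``.  Returns ``nan`` when the pooled variance is
    zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        if x.mean() == y.mean():
            return 0.0
        return float("nan")
    d = (x.mean() - y.mean()) / np.sqrt(pooled_var)
    correction = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(d * correction)


@dataclass(frozen=True)
class TermTest:
    """Comparison of one observed decomposition term against its null."""

    term: str
    observed: float
    null_mean: float
    null_sd: float
    p: float
    g: float
    direction: str
    n_null: int


def term_tests(observed, ensemble, direction: str = "two-sided",
               bonferroni: bool = False) -> pd.DataFrame:
    """Test every global term of a decomposition against a null ensemble.

    ``observed`` is a :class:`~pnd.pairwise.DecompositionResult`;
    ``ensemble`` a :class:`~pnd.nullmodels.NullEnsemble` of the same
    multiplex.  Returns one row per term with the empirical p-value and
    Hedges' g of the observed value against the null distribution (g here
    compares the single observed value's offset in pooled-SD units by
    treating it as a degenerate sample is not meaningful, so g is computed
    from the null distribution as ``(obs - null_mean)/null_sd``, a z-style
    effect size).  ``bonferroni=True`` multiplies p-values by the number of
    terms (capped at 1).
    """
    tab = ensemble.null_table()
    obs = {"R": observed.R, "S": observed.S,
           **{f"U_{k}": v for k, v in observed.U.items()}}
    rows = []
    terms = [c for c in tab.columns if c != "surrogate_id"]
    for term in terms:
        nulls = tab[term].to_numpy()
        p = empirical_p(obs[term], nulls, direction=direction)
        if bonferroni:
            p = min(1.0, p * len(terms))
        sd = nulls.std(ddof=1) if len(nulls) > 1 else 0.0
        g = (obs[term] - nulls.mean()) / sd if sd > 0 else float("nan")
        rows.append(TermTest(term=term, observed=float(obs[term]),
                             null_mean=float(nulls.mean()), null_sd=float(sd),
                             p=float(p), g=float(g), direction=direction,
                             n_null=len(nulls)))
    return pd.DataFrame([r.__dict__ for r in rows])
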