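"""Hierarchical bootstrap and thin wrappers around the standard tests.

Pooling neurons across animals violates the independence assumed by
rank tests, so group contrasts are re-assessed with a hierarchical
bootstrap: each replicate resamples animals with replacement within a
group and then, within every drawn animal, that animal's own number of
neurons with replacement; the replicate statistic is the pooled-neuron
mean.  The p-value is the proportion of replicate pairs whose mean
difference is zero or opposite in sign to the observed difference.
No multiple-comparison corrections are applied anywhere.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import BootstrapResult


def _boot_means(
    groups: list[np.ndarray], n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Pooled-neuron bootstrap means for one group (one value per rep)."""
    n_animals = len(groups)
    sizes = np.array([len(g) for g in groups])
    aidx = rng.integers(0, n_animals, size=(n_reps, n_animals))
    if np.all(sizes == sizes[0]):
        # equal neuron counts: fully vectorised gather
        vals = np.stack(groups)  # (A, n)
        vidx = rng.integers(0, sizes[0], size=(n_reps, n_animals, sizes[0]))
        draw = vals[aidx[:, :, None], vidx]
        return draw.reshape(n_reps, -1).mean(axis=1)
    means = np.empty(n_reps)
    for r in range(n_reps):
        parts = []
        for a in aidx[r]:
            g = groups[a]
            parts.append(g[rng.integers(0, len(g), size=len(g))])
        means[r] = np.concatenate(parts).mean()
    return means


def hierarchical_bootstrap(
    group_a: Sequence[np.ndarray],
    group_b: Sequence[np.ndarray],
    n_reps: int = 1000,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> BootstrapResult:
    """Two-group hierarchical bootstrap (animals, then neurons).

    ``group_a``/``group_b`` are per-animal value arrays.  Replicate ``i``
    of group A is paired with replicate ``i`` of group B; ``p`` is the
    proportion of pairs whose difference is zero or opposite in sign to
    the observed pooled-mean difference (resolution ``1/n_reps``).
    """
    groups_a = [np.asarray(g, dtype=float) for g in group_a]
    groups_b = [np.asarray(g, dtype=float) for g in group_b]
    for name, gs in (("a", groups_a), ("b", groups_b)):
        if len(gs) == 0 or any(len(g) == 0 for g in gs):
            raise ValueError(f"group {name} is empty or contains an animal with no values")
    flagged = min(len(groups_a), len(groups_b)) < 2
    if flagged:
        warnings.warn("single-animal group: hierarchical bootstrap is underpowered", stacklevel=2)

    if rng is None:
        rng = np.random.default_rng(seed)
    boot_a = _boot_means(groups_a, n_reps, rng)
    boot_b = _boot_means(groups_b, n_reps, rng)

    observed = float(np.concatenate(groups_a).mean() - np.concatenate(groups_b).mean())
    diff = boot_a - boot_b
    if observed > 0:
        p = float(np.mean(diff <= 0))
    elif observed < 0:
        p = float(np.mean(diff >= 0))
    else:
        # no observed direction: average the two tails (~0.5 under the null)
        p = float(0.5 * (np.mean(diff <= 0) + np.mean(diff >= 0)))
    return BootstrapResult(
        p=p,
        n_reps=n_reps,
        boot_means_a=boot_a,
        boot_means_b=boot_b,
        observed_difference=observed,
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# standard-test wrappers (two-sided, uncorrected)


def rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value."""
    return float(stats.mannwhitneyu(np.asarray(a), np.asarray(b), alternative="two-sided").pvalue)


def sign_rank(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples; p = 1.0
    when all pairwise differences are zero."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.all(d == 0):
        return 1.0
    return float(stats.wilcoxon(d).pvalue)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p-value on a 2x2 count table."""
    return float(stats.fisher_exact(np.asarray(table)).pvalue)


def anova_oneway(*samples) -> float:
    return float(stats.f_oneway(*samples).pvalue)


def anova_twoway(values, factor_a, factor_b) -> dict[str, float]:
    """Two-way ANOVA with interaction; returns p-values for both main
    effects and the interaction."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    frame = pd.DataFrame({"y": values, "fa": factor_a, "fb": factor_b})
    model = ols("y ~ C(fa) * C(fb)", data=frame).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return {
        "factor_a": float(table.loc["C(fa)", "PR(>F)"]),
        "factor_b": float(table.loc["C(fb)", "PR(>F)"]),
        "interaction": float(table.loc["C(fa):C(fb)", "PR(>F)"]),
    }
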