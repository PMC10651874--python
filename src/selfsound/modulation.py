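"""Modulation index and its population summaries.

MI = (S - R) / (S + R) on a unit's mean evoked amplitudes to
self-generated (S) and random (R) sounds: -1 means response only to the
random sound, 0 equal responses, +1 response only to the self-generated
sound.  An MI of -0.25 corresponds to a 40% smaller self-generated
response; -0.08 to ~15% smaller.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import evoked
from .events import BlockSplit
from .types import ModulationResult, ResponseProfile

DEPTH_BIN_EDGES = np.arange(100.0, 1101.0, 200.0)  # five 200 um bins, 100-1100 um


def modulation_index(amp_self: float, amp_random: float) -> float:
    """(S - R) / (S + R); NaN when S + R == 0 (unit dropped from summaries)."""
    total = amp_self + amp_random
    if total == 0 or not np.isfinite(total):
        return float("nan")
    return (amp_self - amp_random) / total


def percent_reduction(mi: float) -> float:
    """Percent reduction of the self-generated response implied by an MI:
    100 * (1 - S/R) with S/R = (1 + MI)/(1 - MI).  Exact inverse of
    :func:`modulation_index` on the amplitude ratio."""
    return 100.0 * (1.0 - (1.0 + mi) / (1.0 - mi))


def mi_outside_bounds(mi: float) -> bool:
    """Negative amplitudes (suppression below baseline) can push MI outside
    [-1, 1]; such units are retained but flagged."""
    return bool(np.isfinite(mi) and abs(mi) > 1.0)


def classify_unit_modulation(
    per_trial_self: np.ndarray,
    per_trial_random: np.ndarray,
    alpha: float = 0.05,
) -> str:
    """Per-unit significance class from a two-sided rank-sum test on the
    per-trial amplitudes: 'attenuated' (self < random, p < alpha),
    'enhanced' (self > random, p < alpha) or 'ns'."""
    a = np.asarray(per_trial_self, dtype=float)
    b = np.asarray(per_trial_random, dtype=float)
    if len(a) == 0 or len(b) == 0:
        return "ns"
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return "ns"
    p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    if p >= alpha:
        return "ns"
    shift = np.median(a) - np.median(b)
    if shift == 0:
        shift = a.mean() - b.mean()
    if shift < 0:
        return "attenuated"
    if shift > 0:
        return "enhanced"
    return "ns"


def depth_bin_label(depth_um: float, edges: np.ndarray = DEPTH_BIN_EDGES) -> Optional[str]:
    """Half-open bins [lo, hi); the last bin is closed at the top so a unit
    at exactly the deepest edge stays in the deepest bin."""
    edges = np.asarray(edges, dtype=float)
    if depth_um < edges[0] or depth_um > edges[-1]:
        return None
    i = int(np.searchsorted(edges, depth_um, side="right")) - 1
    i = min(i, len(edges) - 2)
    return f"{int(edges[i])}-{int(edges[i + 1])}"


def analyze_unit(profile: ResponseProfile, alpha: float = 0.05) -> ModulationResult:
    mi = modulation_index(profile.amp_self, profile.amp_random)
    sig = classify_unit_modulation(profile.per_trial_amp_self, profile.per_trial_amp_random, alpha)
    return ModulationResult(
        unit_id=profile.unit_id, mi=mi, sig_class=sig, flagged=mi_outside_bounds(mi)
    )


def depth_profile(
    mis: np.ndarray, depths: np.ndarray, bin_edges: np.ndarray = DEPTH_BIN_EDGES
) -> pd.DataFrame:
    """Mean +/- SEM MI per depth bin (bins [lo, hi), last closed)."""
    mis = np.asarray(mis, dtype=float)
    depths = np.asarray(depths, dtype=float)
    rows = []
    edges = np.asarray(bin_edges, dtype=float)
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        last = i == len(edges) - 2
        mask = (depths >= lo) & ((depths <= hi) if last else (depths < hi))
        vals = mis[mask & np.isfinite(mis)]
        rows.append(
            {
                "depth_bin": f"{int(lo)}-{int(hi)}",
                "n": len(vals),
                "mean_mi": float(vals.mean()) if len(vals) else np.nan,
                "sem_mi": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def block_modulation(spike_times: np.ndarray, blocks: BlockSplit) -> tuple[float, float]:
    """MI computed independently within the early and late blocks, using
    each block's retained sounds; (nan, nan) for excluded sessions."""
    if blocks.excluded:
        return float("nan"), float("nan")
    out = []
    for s, r in ((blocks.early_self, blocks.early_random), (blocks.late_self, blocks.late_random)):
        amp_s = float(evoked.per_event_amplitudes(spike_times, s).mean())
        amp_r = float(evoked.per_event_amplitudes(spike_times, r).mean())
        out.append(modulation_index(amp_s, amp_r))
    return out[0], out[1]


def genotype_summary(
    table: pd.DataFrame,
    seed: int = 0,
    n_reps: int = 1000,
) -> dict:
    """Population MI contrast between two genotypes.

    ``table`` needs columns ``mi``, ``genotype``, ``animal_id``.  Reports,
    per genotype, the pooled-neuron mean +/- SEM and the animal-averaged
    mean +/- SEM, plus a pooled rank-sum p, an animal-level rank-sum p and
    a hierarchical-bootstrap p (animals resampled before neurons).
    """
    from .hstats import hierarchical_bootstrap, rank_sum

    table = table[np.isfinite(table["mi"])]
    genos = sorted(table["genotype"].unique())
    if len(genos) != 2:
        raise ValueError(f"expected exactly two genotypes, got {genos}")
    out: dict = {"genotypes": genos}
    pooled = {}
    by_animal = {}
    for g in genos:
        sub = table[table["genotype"] == g]
        vals = sub["mi"].to_numpy()
        pooled[g] = vals
        animal_means = sub.groupby("animal_id")["mi"].mean()
        by_animal[g] = {a: sub[sub["animal_id"] == a]["mi"].to_numpy() for a in animal_means.index}
        out[g] = {
            "n_neurons": int(len(vals)),
            "mean_mi": float(vals.mean()),
            "sem_mi": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
            "n_animals": int(len(animal_means)),
            "animal_mean_mi": float(animal_means.mean()),
            "animal_sem_mi": float(animal_means.std(ddof=1) / np.sqrt(len(animal_means)))
            if len(animal_means) > 1
            else np.nan,
        }
    out["p_ranksum_pooled"] = rank_sum(pooled[genos[0]], pooled[genos[1]])
    a_means = [
        np.array([v.mean() for v in by_animal[g].values()]) for g in genos
    ]
    out["underpowered_animal_comparison"] = bool(min(len(m) for m in a_means) < 2)
    out["p_ranksum_animal"] = (
        rank_sum(a_means[0], a_means[1]) if not out["underpowered_animal_comparison"] else np.nan
    )
    if not out["underpowered_animal_comparison"]:
        boot = hierarchical_bootstrap(
            list(by_animal[genos[0]].values()),
            list(by_animal[genos[1]].values()),
            n_reps=n_reps,
            seed=seed,
        )
        out["p_hierarchical_bootstrap"] = boot.p
    else:
        out["p_hierarchical_bootstrap"] = np.nan
    out["bootstrap_n_reps"] = n_reps
    out["bootstrap_seed"] = seed
    return out
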