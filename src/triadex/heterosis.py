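"""Phenotypic heterosis statistics for parent-hybrid triads.

Mid-parent heterosis MPH = ((F1 − MP)/MP)·100 and high-parent (better-
parent) heterosis HPH = ((F1 − HP)/HP)·100, where F1 is the hybrid trait
mean, MP the average of the two parent means and HP the larger parent
mean.  Significance of the hybrid-vs-mid-parent difference is assessed by
a Welch t-test of hybrid replicates against per-replicate mid-parent
pseudo-values (parents paired by replicate index), and multi-genotype
trait differences by one-way ANOVA with Tukey HSD and a compact-letter
display.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


def compute_heterosis(
    pheno: pd.DataFrame,
    triad: Mapping[str, str],
    mp_test: str = "welch-pseudo",
) -> pd.DataFrame:
    """Heterosis table for one triad over every (trait, time_point).

    Parameters
    ----------
    pheno
        Long table with columns genotype, trait, time_point, replicate,
        value.
    triad
        Role map with keys ``female_parent``, ``male_parent``, ``hybrid``
        giving genotype labels.
    mp_test
        ``"welch-pseudo"`` (default): Welch t-test of hybrid replicates
        against replicate-paired mid-parent pseudo-values.
        ``"one-sample"``: one-sample t-test of hybrid replicates against
        the mid-parent mean treated as a constant.

    Returns
    -------
    DataFrame with one row per (trait, time_point): F1, MP, HP, MPH, HPH
    (percent), t_stat, p_value.  Rows where MP or HP is zero report the
    undefined percentages as NaN with a warning.
    """
    for role in ("female_parent", "male_parent", "hybrid"):
        if role not in triad:
            raise ValueError(f"triad is missing role {role!r}")
    f_gen, m_gen, h_gen = (
        triad["female_parent"], triad["male_parent"], triad["hybrid"],
    )
    rows = []
    for (trait, tp), sub in pheno.groupby(["trait", "time_point"], sort=True):
        vals = {
            g: sub.loc[sub["genotype"] == g].sort_values("replicate")["value"].to_numpy()
            for g in (f_gen, m_gen, h_gen)
        }
        if any(len(v) == 0 for v in vals.values()):
            continue  # triad incomplete for this trait/time point
        mean_f, mean_m = vals[f_gen].mean(), vals[m_gen].mean()
        f1 = vals[h_gen].mean()
        mp = 0.5 * (mean_f + mean_m)
        hp = max(mean_f, mean_m)
        if mp == 0 or hp == 0:
            warnings.warn(
                f"mid- or high-parent mean is zero for {trait}/{tp}; "
                "heterosis percentages undefined"
            )
            mph = hph = np.nan
        else:
            mph = (f1 - mp) / mp * 100.0
            hph = (f1 - hp) / hp * 100.0
        t_stat, p_value = test_heterosis(
            vals[h_gen], vals[f_gen], vals[m_gen], mp_test=mp_test
        )
        rows.append(
            dict(
                trait=trait, time_point=tp, F1=f1, MP=mp, HP=hp,
                MPH=mph, HPH=hph, t_stat=t_stat, p_value=p_value,
            )
        )
    return pd.DataFrame(rows)


def test_heterosis(
    hybrid: Sequence[float],
    female: Sequence[float],
    male: Sequence[float],
    mp_test: str = "welch-pseudo",
) -> Tuple[float, float]:
    """t-test of hybrid replicates against the mid-parent value.

    The default pairs parent replicates by index into pseudo-mid-parent
    values MP_i = (F_i + M_i)/2 and runs a Welch two-sample test, so the
    parents' variability enters the null distribution.  With zero
    variance in both samples and unequal means the difference is exact;
    the degenerate case is reported as t = inf (sign of the difference)
    and p = 0.
    """
    hybrid = np.asarray(hybrid, dtype=float)
    female = np.asarray(female, dtype=float)
    male = np.asarray(male, dtype=float)
    if len(hybrid) < 2 or len(female) < 2 or len(male) < 2:
        raise ValueError("need >= 2 replicates per genotype")
    if mp_test == "one-sample":
        mp = 0.5 * (female.mean() + male.mean())
        if hybrid.std(ddof=1) == 0:
            if hybrid.mean() == mp:
                return 0.0, 1.0
            return float(np.sign(hybrid.mean() - mp) * np.inf), 0.0
        t, p = stats.ttest_1samp(hybrid, mp)
        return float(t), float(p)
    if mp_test != "welch-pseudo":
        raise ValueError("mp_test must be 'welch-pseudo' or 'one-sample'")
    k = min(len(female), len(male))
    if len(female) != len(male):
        warnings.warn("unbalanced parent replicate counts; pairing up to the minimum")
    pseudo_mp = 0.5 * (female[:k] + male[:k])
    if hybrid.std(ddof=1) == 0 and pseudo_mp.std(ddof=1) == 0:
        if hybrid.mean() == pseudo_mp.mean():
            return 0.0, 1.0
        return float(np.sign(hybrid.mean() - pseudo_mp.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(hybrid, pseudo_mp, equal_var=False)
    return float(t), float(p)


def anova_tukey(
    pheno: pd.DataFrame,
    groups: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    value_col: str = "value",
    group_col: str = "genotype",
) -> Dict[str, object]:
    """One-way ANOVA with Tukey HSD pairwise comparisons and letters.

    Returns a dict with keys ``f_stat``, ``p_value``, ``tukey`` (a
    DataFrame of pairwise comparisons with mean difference, adjusted p
    and reject flag) and ``letters`` (compact-letter display: groups
    sharing a letter are not significantly different at ``alpha``).
    """
    data = pheno if groups is None else pheno[pheno[group_col].isin(groups)]
    labels = groups if groups is not None else sorted(data[group_col].unique())
    samples = [data.loc[data[group_col] == g, value_col].to_numpy() for g in labels]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    within_var = sum(((s - s.mean()) ** 2).sum() for s in samples)
    means = [s.mean() for s in samples]
    if within_var == 0 and len(set(means)) == 1:
        raise ValueError("zero within-group variance with identical means: F undefined")
    f_stat, p_value = stats.f_oneway(*samples)

    values = np.concatenate(samples)
    grp = np.concatenate([[g] * len(s) for g, s in zip(labels, samples)])
    res = pairwise_tukeyhsd(values, grp, alpha=alpha)
    tukey = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    reject = {}
    for (g1, g2), rej in zip(
        zip(tukey["group1"], tukey["group2"]), tukey["reject"]
    ):
        reject[frozenset((str(g1), str(g2)))] = bool(rej)
    letters = compact_letter_display([str(g) for g in labels], reject)
    return dict(
        f_stat=float(f_stat), p_value=float(p_value), tukey=tukey, letters=letters
    )


def compact_letter_display(
    groups: Sequence[str], different: Mapping[frozenset, bool]
) -> Dict[str, str]:
    """Greedy insert-and-absorb compact-letter display.

    ``different`` maps frozenset pairs of group labels to True when the
    pair is significantly different.  All groups start in one letter set;
    every significantly different pair splits each set containing both
    into two copies (one member removed from each), and redundant sets
    (subsets of another) are absorbed.  Letters are assigned in the order
    each set's first member appears in ``groups`` (deterministic
    tie-break).
    """
    letter_sets: List[set] = [set(groups)]
    for pair, is_diff in sorted(different.items(), key=lambda kv: sorted(kv[0])):
        if not is_diff:
            continue
        g1, g2 = sorted(pair)
        new_sets: List[set] = []
        for s in letter_sets:
            if g1 in s and g2 in s:
                new_sets.extend([s - {g1}, s - {g2}])
            else:
                new_sets.append(s)
        # absorb duplicates and subsets
        kept: List[set] = []
        for s in new_sets:
            if s and not any(s < t for t in new_sets) and s not in kept:
                kept.append(s)
        letter_sets = kept
    order = {g: i for i, g in enumerate(groups)}
    letter_sets.sort(key=lambda s: min(order[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: Dict[str, str] = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out
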