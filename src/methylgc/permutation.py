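"""Label-permutation null distributions of the mean beta-difference.

The null is constructed by randomly reordering the two-group assignment,
recomputing the mean beta-difference of every probe under each reordering
(one shared permutation stream across probes, preserving inter-probe
correlation), and repeating 10,000 times by default.  The approximate
p-value per probe is the proportion of null draws equal to or more
extreme than the observed value, two-sided on |mean difference|.

An exhaustive mode enumerates all distinct group-1 subsets and is the
oracle the sampled mode converges to.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix, ValidationError

EXHAUSTIVE_MAX = 100_000
_CHUNK = 500


def _observed_and_pool(beta: BetaMatrix, group1_ids, group2_ids):
    g1 = list(group1_ids)
    g2 = list(group2_ids)
    if not g1 or not g2:
        raise ValidationError("both groups must be non-empty")
    if set(g1) & set(g2):
        raise ValidationError("groups overlap")
    x = beta.values[g1 + g2].to_numpy(dtype=float)
    n1 = len(g1)
    obs = x[:, :n1].mean(axis=1) - x[:, n1:].mean(axis=1)
    return x, n1, obs


def _null_counts(x, n1, obs_abs, assignments):
    """Count |null diff| >= |observed| for a batch of group-1 index sets."""
    n = x.shape[1]
    n2 = n - n1
    w = np.full((n, len(assignments)), -1.0 / n2)
    for j, idx in enumerate(assignments):
        w[list(idx), j] = 1.0 / n1
    null = x @ w                          # probes x batch
    # tolerance keeps "equal or more extreme" robust to the different
    # summation order of the dot product vs the observed column means
    return (np.abs(null) >= obs_abs[:, None] - 1e-12).sum(axis=1)


def permute_null(beta: BetaMatrix, group1_ids, group2_ids,
                 n_perm: int = 10_000, seed: int = 0,
                 exhaustive: bool = False, add_one: bool = False,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Per-probe permutation p-values for the observed mean beta-difference.

    Sampled mode draws ``n_perm`` label reorderings uniformly (with
    replacement over distinct partitions); exhaustive mode enumerates
    every distinct group-1 subset (requires C(n, n1) <= 100,000) and
    gives the exact randomization p.  ``add_one`` switches to the
    (n_extreme + 1) / (n_perm + 1) estimator, which is strictly
    positive.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    x, n1, obs = _observed_and_pool(beta, group1_ids, group2_ids)
    n = x.shape[1]
    obs_abs = np.abs(obs)
    n_extreme = np.zeros(x.shape[0], dtype=np.int64)

    if exhaustive:
        total = comb(n, n1)
        if total > EXHAUSTIVE_MAX:
            raise ValidationError(
                f"exhaustive enumeration infeasible: C({n},{n1}) = {total}"
            )
        batch = []
        for idx in combinations(range(n), n1):
            batch.append(idx)
            if len(batch) == _CHUNK:
                n_extreme += _null_counts(x, n1, obs_abs, batch)
                batch = []
        if batch:
            n_extreme += _null_counts(x, n1, obs_abs, batch)
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        done = 0
        while done < n_perm:
            b = min(_CHUNK, n_perm - done)
            batch = [tuple(rng.permutation(n)[:n1]) for _ in range(b)]
            n_extreme += _null_counts(x, n1, obs_abs, batch)
            done += b
        n_used = n_perm

    if add_one:
        perm_p = (n_extreme + 1) / (n_used + 1)
    else:
        perm_p = n_extreme / n_used
    out = pd.DataFrame({
        "observed_diff": obs,
        "n_perm": n_used,
        "n_extreme": n_extreme,
        "perm_p": perm_p,
    }, index=beta.probe_ids)
    out["significant_perm"] = out["perm_p"] <= alpha
    return out


def concordance(nominal: pd.DataFrame, perm: pd.DataFrame,
                alpha: float = 0.05, diff_min: float = 0.05) -> float:
    """Fraction of nominally significant probes confirmed by permutation.

    Nominal significance here is the subgroup-comparison rule:
    |beta_diff| >= diff_min and Wilcoxon p <= alpha.  Returns NaN when
    no probe is nominally significant.
    """
    if not nominal.index.equals(perm.index):
        perm = perm.reindex(nominal.index)
        if perm["perm_p"].isna().any():
            raise ValidationError("nominal and permutation probe sets differ")
    nom = ((nominal["beta_diff"].abs() >= diff_min)
           & (nominal["p_wilcoxon"] <= alpha))
    n_nom = int(nom.sum())
    if n_nom == 0:
        return float("nan")
    confirmed = int((perm.loc[nom[nom].index, "perm_p"] <= alpha).sum())
    return confirmed / n_nom
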