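"""Clade symptom profiles and the four-group likelihood-ratio test.

For a clade and a diagnostic category the scored cohort splits into four
disjoint groups: group 4 is the intersection, group 3 the clade outside the
category, group 2 the category outside the clade, and group 1 everyone else.
With per-group trait probabilities p1..p4, the null hypothesis is
p2 = p3 = p4 and the alternative p2 != p3 = p4; at the boundaries the
comparison degenerates to the two informative groups (2 vs 4 when one group
contains the other, 2 vs 3 when they are disjoint). Group 1 contributes the
same factor to both likelihoods and cancels. The statistic is
2(lnL_A - lnL_0) at binomial plug-in MLEs, and significance is assessed by
permuting clade membership within the scored cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import CladelinkError, TraitMatrix
from .nesting import Clade

__all__ = [
    "FourGroupCounts",
    "LRTResult",
    "four_group_counts",
    "symptom_profile",
    "lrt_symptom",
    "permutation_p",
    "clade_symptom_table",
    "prevalence_matrix",
    "bh_adjust",
]


@dataclass(frozen=True)
class FourGroupCounts:
    """Symptom-present counts ``x_i`` and group sizes ``n_i``; see module doc
    for the group definitions."""

    x1: int
    n1: int
    x2: int
    n2: int
    x3: int
    n3: int
    x4: int
    n4: int

    def __post_init__(self):
        for i in (1, 2, 3, 4):
            x, n = getattr(self, f"x{i}"), getattr(self, f"n{i}")
            if not 0 <= x <= n:
                raise CladelinkError(f"group {i}: x={x} outside [0, n={n}]")


@dataclass
class LRTResult:
    counts: FourGroupCounts
    p_null: float
    p_alt: dict[str, float]
    statistic: float
    defined: bool
    perm_p: float | None = None


def _presence(matrix: TraitMatrix, trait: str) -> dict[str, int]:
    """uid -> 1 if state >= 1 (any severity), 0 if state 0; missing omitted."""
    col = matrix.frame[trait]
    out = {}
    for u, v in col.items():
        if not math.isnan(v):
            out[u] = 1 if v >= 1 else 0
    return out


def symptom_profile(clade: Clade, matrix: TraitMatrix,
                    prevalence_threshold: float = 0.70) -> list[str]:
    """Traits present in strictly more than ``prevalence_threshold`` of the
    clade members with a non-missing state."""
    out = []
    members = [u for u in clade.members if matrix.is_scored(u)]
    if not members:
        raise CladelinkError("no scored members in clade")
    sub = matrix.frame.loc[members]
    for trait in matrix.trait_names:
        col = sub[trait].dropna()
        if len(col) and (col >= 1).mean() > prevalence_threshold:
            out.append(trait)
    return out


def four_group_counts(trait: str, matrix: TraitMatrix, clade_members: Iterable[str],
                      category_members: Iterable[str],
                      cohort: Iterable[str] | None = None) -> FourGroupCounts:
    """Tally the four-group layout for one trait over the scored cohort."""
    pres = _presence(matrix, trait)
    if cohort is None:
        cohort = list(pres)
    clade_set = set(clade_members)
    cat_set = set(category_members)
    xs = [0, 0, 0, 0]
    ns = [0, 0, 0, 0]
    for u in cohort:
        if u not in pres:
            continue
        in_c = u in clade_set
        in_d = u in cat_set
        g = 3 if (in_c and in_d) else 2 if in_c else 1 if in_d else 0
        ns[g] += 1
        xs[g] += pres[u]
    return FourGroupCounts(xs[0], ns[0], xs[1], ns[1], xs[2], ns[2], xs[3], ns[3])


def _binom_ll(x: float, n: float, p: float) -> float:
    ll = 0.0
    if x > 0:
        if p == 0:
            return float("-inf")
        ll += x * math.log(p)
    if n - x > 0:
        if p == 1:
            return float("-inf")
        ll += (n - x) * math.log(1 - p)
    return ll


def lrt_symptom(counts: FourGroupCounts) -> LRTResult:
    """Four-group binomial LRT at plug-in MLEs.

    The applicable comparison follows the non-empty groups among {2, 3, 4};
    with fewer than two non-empty groups the test is undefined and flagged
    (``defined=False``), not reported as p = 1.
    """
    c = counts
    active = [(i, x, n) for i, x, n in
              ((2, c.x2, c.n2), (3, c.x3, c.n3), (4, c.x4, c.n4)) if n > 0]
    if len(active) < 2:
        return LRTResult(c, float("nan"), {}, float("nan"), defined=False)
    xt = sum(x for _, x, _ in active)
    nt = sum(n for _, _, n in active)
    p0 = xt / nt
    ll0 = _binom_ll(xt, nt, p0)
    if c.n2 > 0:
        x34 = sum(x for i, x, _ in active if i != 2)
        n34 = sum(n for i, _, n in active if i != 2)
        p2 = c.x2 / c.n2
        p34 = x34 / n34
        llA = _binom_ll(c.x2, c.n2, p2) + _binom_ll(x34, n34, p34)
        p_alt = {"p2": p2, "p34": p34}
    else:  # clade and category disjoint from group 2's perspective: 3 vs 4
        (i3, x3, n3), (i4, x4, n4) = active
        pa, pb = x3 / n3, x4 / n4
        llA = _binom_ll(x3, n3, pa) + _binom_ll(x4, n4, pb)
        p_alt = {f"p{i3}": pa, f"p{i4}": pb}
    stat = max(0.0, 2.0 * (llA - ll0))
    return LRTResult(c, p0, p_alt, stat, defined=True)


def permutation_p(trait: str, matrix: TraitMatrix, clade_members: Iterable[str],
                  category_members: Iterable[str], n_perm: int = 10_000,
                  seed: int | None = 0,
                  cohort: Iterable[str] | None = None) -> LRTResult:
    """Empirical p by permuting clade membership over the scored cohort.

    Group sizes are held fixed: each permutation draws a random subset of the
    cohort of the clade's size, with the diagnostic labels unchanged. The
    p-value uses the (hits + 1) / (n_perm + 1) convention.
    """
    pres = _presence(matrix, trait)
    if cohort is None:
        cohort_l = sorted(pres)
    else:
        cohort_l = [u for u in cohort if u in pres]
    obs = lrt_symptom(four_group_counts(trait, matrix, clade_members,
                                        category_members, cohort_l))
    if not obs.defined:
        return obs
    rng = np.random.default_rng(seed)
    present = np.array([pres[u] for u in cohort_l])
    in_cat = np.array([u in set(category_members) for u in cohort_l])
    clade_size = sum(1 for u in cohort_l if u in set(clade_members))
    n = len(cohort_l)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)[:clade_size]
        in_clade = np.zeros(n, dtype=bool)
        in_clade[perm] = True
        n4 = int((in_clade & in_cat).sum())
        x4 = int(present[in_clade & in_cat].sum())
        n3 = int((in_clade & ~in_cat).sum())
        x3 = int(present[in_clade & ~in_cat].sum())
        n2 = int((~in_clade & in_cat).sum())
        x2 = int(present[~in_clade & in_cat].sum())
        res = lrt_symptom(FourGroupCounts(0, 0, x2, n2, x3, n3, x4, n4))
        if res.defined and res.statistic >= obs.statistic - 1e-12:
            hits += 1
    obs.perm_p = (hits + 1) / (n_perm + 1)
    return obs


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (convenience column)."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    out = np.empty(m)
    out[order] = ranked
    return list(out)


def prevalence_matrix(clades: Sequence[Clade], matrix: TraitMatrix,
                      significant: Mapping[tuple[str, str], bool] | None = None):
    """Clade x trait table of symptom prevalences (fraction with state >= 1
    among non-missing), with an optional ``*`` significance mark appended —
    the familiar profile-matrix view of clade symptom spectra."""
    import pandas as pd

    rows = {}
    for clade in clades:
        members = [u for u in clade.members if matrix.is_scored(u)]
        sub = matrix.frame.loc[members]
        vals = {}
        for t in matrix.trait_names:
            col = sub[t].dropna()
            prev = float((col >= 1).mean()) if len(col) else float("nan")
            mark = "*" if significant and significant.get((clade.label, t)) else ""
            vals[t] = f"{prev:.2f}{mark}"
        rows[clade.label] = vals
    return pd.DataFrame.from_dict(rows, orient="index")


def clade_symptom_table(clade: Clade, matrix: TraitMatrix,
                        category_members: Iterable[str],
                        traits: Sequence[str] | None = None,
                        n_perm: int = 10_000, seed: int | None = 0,
                        adjust: bool = False):
    """Per-trait LRT + permutation p table for one clade vs one category.

    Returns a pandas DataFrame with counts, statistic and permutation p per
    trait (unadjusted significance, as reported at the 0.05 level; a BH
    column is added when ``adjust`` is True).
    """
    import pandas as pd

    if traits is None:
        traits = matrix.trait_names
    rows = []
    for k, trait in enumerate(traits):
        s = None if seed is None else seed + k
        r = permutation_p(trait, matrix, clade.members, category_members,
                          n_perm=n_perm, seed=s)
        c = r.counts
        rows.append({
            "clade": clade.label, "trait": trait,
            "x2": c.x2, "n2": c.n2, "x3": c.x3, "n3": c.n3,
            "x4": c.x4, "n4": c.n4,
            "statistic": r.statistic, "perm_p": r.perm_p,
            "defined": r.defined,
        })
    df = pd.DataFrame(rows)
    if adjust and len(df):
        mask = df["defined"] & df["perm_p"].notna()
        adj = pd.Series(np.nan, index=df.index)
        if mask.any():
            adj[mask] = bh_adjust(list(df.loc[mask, "perm_p"]))
        df["perm_p_bh"] = adj
    return df
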