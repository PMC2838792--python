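"""Reference implementations used for validation.

Small, slow, first-principles versions of the package's core computations:
exhaustive tree enumeration with an independent change-count recursion, a
pedigree likelihood that materializes the full joint genotype table, and a
grid-search maximization of the four-group binomial likelihoods. They are
written without reusing the production code paths so they can serve as
oracles in tests and in the acceptance checks; they are only practical at
toy sizes.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .io import (ORDINAL4, GeneticMap, GenotypeTable, Individual, Marker,
                 Pedigree, TraitMatrix)

__all__ = [
    "all_unrooted_topologies",
    "reference_tree_score",
    "exhaustive_parsimony",
    "brute_force_family_loglik",
    "brute_force_lod",
    "lrt_grid_statistic",
    "random_validation_pedigree",
    "phase_known_family",
]


# ---------------------------------------------------------------------------
# Exhaustive parsimony


def all_unrooted_topologies(n: int):
    """Yield adjacency dicts of every unrooted binary topology on leaves
    ``0..n-1`` (1, 1, 3, 15, 105, 945 ... trees). Leaves have degree 1,
    internal nodes degree 3; internal ids start at ``n``."""
    if n < 3:
        if n == 1:
            yield {0: []}
        elif n == 2:
            yield {0: [1], 1: [0]}
        return
    base = {0: [n], 1: [n], 2: [n], n: [0, 1, 2]}

    def insert(adj, k, next_id):
        if k == n:
            yield adj
            return
        edges = sorted((u, v) for u in adj for v in adj[u] if u < v)
        for (u, v) in edges:
            new = {x: list(ys) for x, ys in adj.items()}
            w = next_id
            new[u] = [x if x != v else w for x in new[u]]
            new[v] = [x if x != u else w for x in new[v]]
            new[w] = [u, v, k]
            new[k] = [w]
            yield from insert(new, k + 1, next_id + 1)

    yield from insert(base, 3, n + 1)


def reference_tree_score(adj: dict[int, list[int]], states: np.ndarray,
                         ordered: np.ndarray) -> int:
    """Minimum change count by per-state recursion (independent scorer).

    ``states``: (n_leaves, n_chars) with -1 for missing; ``ordered``: bool per
    character (ordered cost |i-j| vs unordered 0/1).
    """
    C = states.shape[1]
    INF = 1e17
    big = np.full((C, 4), INF)

    def leaf_vec(i: int) -> np.ndarray:
        v = big.copy()
        for j in range(C):
            s = states[i, j]
            if s < 0:
                v[j, :] = 0.0
            else:
                v[j, s] = 0.0
        return v

    def edge_cost(s: int, t: int) -> np.ndarray:
        out = np.empty(C)
        for j in range(C):
            out[j] = abs(s - t) if ordered[j] else (0.0 if s == t else 1.0)
        return out

    ec = [[edge_cost(s, t) for t in range(4)] for s in range(4)]
    n_leaves = sum(1 for u in adj if len(adj[u]) == 1)

    import sys
    rec_limit = sys.getrecursionlimit()
    if rec_limit < 10 * len(adj) + 100:
        sys.setrecursionlimit(10 * len(adj) + 100)

    def down(u: int, frm: int | None) -> np.ndarray:
        vec = leaf_vec(u) if len(adj[u]) == 1 and u < n_leaves else np.zeros((C, 4))
        for w in adj[u]:
            if w == frm:
                continue
            child = down(w, u)
            contrib = np.empty((C, 4))
            for s in range(4):
                best = None
                for t in range(4):
                    cand = child[:, t] + ec[s][t]
                    best = cand if best is None else np.minimum(best, cand)
                contrib[:, s] = best
            vec = vec + contrib
        return vec

    if len(adj) == 1:
        return 0
    root = 0  # recurse from leaf 0
    vec = down(root, None)
    return int(round(vec.min(axis=1).sum()))


def exhaustive_parsimony(matrix: TraitMatrix, uids: Sequence[str] | None = None,
                         ordered_ordinal: bool = True) -> int:
    """Minimum parsimony score over every unrooted binary topology."""
    if uids is None:
        uids = matrix.individual_ids
    n = len(uids)
    if n > 8:
        raise ValueError("exhaustive search is restricted to <=8 leaves")
    sub = matrix.frame.loc[list(uids)]
    states = np.where(np.isnan(sub.to_numpy()), -1, sub.to_numpy()).astype(int)
    ordered = np.array([ordered_ordinal and matrix.trait_kinds[c] == ORDINAL4
                        for c in sub.columns])
    best = None
    for adj in all_unrooted_topologies(n):
        s = reference_tree_score(adj, states, ordered)
        if best is None or s < best:
            best = s
    return int(best)


# ---------------------------------------------------------------------------
# Brute-force pedigree likelihood (full joint genotype table)


def _transmission(m: int, theta: float) -> np.ndarray:
    """(G, H): probability a parent with ordered two-locus genotype g
    transmits gamete h; haplotype h = d*m + a."""
    H = 2 * m
    G = H * H
    T = np.zeros((G, H))
    for h1 in range(H):
        for h2 in range(H):
            g = h1 * H + h2
            d1, a1 = divmod(h1, m)
            d2, a2 = divmod(h2, m)
            for (dt, at), w in (((d1, a1), 0.5 * (1 - theta)),
                                ((d2, a2), 0.5 * (1 - theta)),
                                ((d1, a2), 0.5 * theta),
                                ((d2, a1), 0.5 * theta)):
                T[g, dt * m + at] += w
    return T


def brute_force_family_loglik(members: Sequence[tuple[str, str | None, str | None]],
                              statuses: dict[str, str],
                              observed: dict[str, tuple[int, int] | None],
                              allele_freqs: Sequence[float],
                              q: float, penetrances: Sequence[float],
                              theta: float) -> float:
    """log10 likelihood of one family by summing the full joint genotype table.

    ``members``: (uid, father_uid, mother_uid) with None for founders, parents
    listed before children. ``observed`` maps uid to an unordered marker
    genotype as 0-based allele indices, or None. Only practical for <=6
    members and 2 marker alleles (16^6 joint states).
    """
    p = np.asarray(allele_freqs, float)
    m = len(p)
    H = 2 * m
    G = H * H
    n = len(members)
    if G ** n > 20_000_000:
        raise ValueError("joint table too large for brute force")
    hap_prior = np.array([(q if d else 1 - q) * p[a]
                          for d in (0, 1) for a in range(m)])
    prior = (hap_prior[:, None] * hap_prior[None, :]).ravel()
    f = np.asarray(penetrances, float)

    def unary(uid: str) -> np.ndarray:
        v = np.empty(G)
        for h1 in range(H):
            for h2 in range(H):
                g = h1 * H + h2
                d1, a1 = divmod(h1, m)
                d2, a2 = divmod(h2, m)
                nd = d1 + d2
                st = statuses.get(uid, "unknown")
                pen = f[nd] if st == "affected" else (1 - f[nd]) if st == "unaffected" else 1.0
                obs = observed.get(uid)
                ok = 1.0
                if obs is not None and tuple(sorted((a1, a2))) != tuple(sorted(obs)):
                    ok = 0.0
                v[g] = pen * ok
        return v

    T = _transmission(m, theta)
    idx = {mem[0]: i for i, mem in enumerate(members)}
    arr = np.ones((G,) * n)
    for (uid, fa, mo) in members:
        i = idx[uid]
        shape = [1] * n
        shape[i] = G
        u = unary(uid)
        if fa is None:
            arr *= (prior * u).reshape(shape)
        else:
            j, k = idx[fa], idx[mo]
            # P(child g | father, mother) = T[gf, h1] * T[gm, h2]
            child = np.zeros((G, G, G))
            for h1 in range(H):
                for h2 in range(H):
                    g = h1 * H + h2
                    child[:, :, g] = T[:, h1][:, None] * T[:, h2][None, :]
            child *= u[None, None, :]
            # broadcast so axis j indexes gf, axis k gm, axis i gc
            full_shape = [1] * n
            for ax in (j, k, i):
                full_shape[ax] = G
            perm = tuple(np.argsort([j, k, i]))
            arr *= np.transpose(child, axes=perm).reshape(full_shape)
    total = arr.sum()
    return float(np.log10(total)) if total > 0 else float("-inf")


def brute_force_lod(members, statuses, observed, allele_freqs, q, penetrances,
                    theta: float) -> float:
    """log10 L(theta)/L(0.5) via the full joint table."""
    l1 = brute_force_family_loglik(members, statuses, observed, allele_freqs,
                                   q, penetrances, theta)
    l0 = brute_force_family_loglik(members, statuses, observed, allele_freqs,
                                   q, penetrances, 0.5)
    return l1 - l0


# ---------------------------------------------------------------------------
# Grid-search LRT oracle

_GRID_CACHE: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _grids(resolution: float):
    n = int(round(1 / resolution))
    if n not in _GRID_CACHE:
        p = np.linspace(0.0, 1.0, n + 1)
        with np.errstate(divide="ignore"):
            _GRID_CACHE[n] = (p, np.log(p), np.log(1 - p))
    return _GRID_CACHE[n]


def _max_binom_ll(pairs: Iterable[tuple[int, int]], resolution: float) -> float:
    """max over p of sum_i [x_i ln p + (n_i - x_i) ln(1-p)] on a grid."""
    p, logp, log1mp = _grids(resolution)
    ll = np.zeros_like(p)
    for x, n in pairs:
        if x > 0:
            ll = ll + x * logp
        if n - x > 0:
            ll = ll + (n - x) * log1mp
    return float(np.max(ll))


def lrt_grid_statistic(x2: int, n2: int, x3: int, n3: int, x4: int, n4: int,
                       resolution: float = 1e-6) -> float:
    """Four-group LRT statistic by grid-search likelihood maximization.

    Null: one shared trait probability for the non-empty groups among
    {2, 3, 4}; alternative: group 2 free vs groups 3+4 pooled (reducing to a
    two-group comparison at the containment/disjoint boundaries). Group 1
    cancels and is omitted.
    """
    active = [(x, n) for x, n in ((x2, n2), (x3, n3), (x4, n4)) if n > 0]
    if len(active) < 2:
        raise ValueError("test undefined: fewer than two non-empty groups")
    ll0 = _max_binom_ll(active, resolution)
    if n2 > 0:
        rest = [(x, n) for x, n in ((x3, n3), (x4, n4)) if n > 0]
        llA = _max_binom_ll([(x2, n2)], resolution) + _max_binom_ll(rest, resolution)
    else:  # group 2 empty: compare the remaining two groups freely
        llA = sum(_max_binom_ll([pair], resolution) for pair in active)
    return max(0.0, 2.0 * (llA - ll0))


# ---------------------------------------------------------------------------
# Validation inputs: pedigrees with known structure for oracle comparisons


def random_validation_pedigree(rng: np.random.Generator, n_max: int = 5):
    """Random loop-free family of 3..n_max members with consistent 2-allele
    genotypes, random affection statuses, and some untyped members.

    Returns (pedigree, genotypes, members, statuses, observed); ``members``
    and ``observed`` use the layout of :func:`brute_force_family_loglik`.
    """
    freqs = (0.6, 0.4)
    n = int(rng.integers(3, n_max + 1))
    inds = [Individual("F", "1", None, None, "male", 0),
            Individual("F", "2", None, None, "female", 0),
            Individual("F", "3", "1", "2", "male", 0)]
    members = [("F:1", None, None), ("F:2", None, None), ("F:3", "F:1", "F:2")]
    k = 4
    while len(inds) < n:
        if rng.random() < 0.3 and not any(i.id == "s" for i in inds) \
                and len(inds) + 2 <= n:
            # spouse of member 3 plus their child (keeps the family connected)
            inds.append(Individual("F", "s", None, None, "female", 0))
            members.append(("F:s", None, None))
            inds.append(Individual("F", "g", "3", "s", "male", 0))
            members.append(("F:g", "F:3", "F:s"))
        else:
            inds.append(Individual("F", str(k), "1", "2", "female", 0))
            members.append((f"F:{k}", "F:1", "F:2"))
            k += 1
    gmap = GeneticMap([Marker("M1", "1", 0.0, (1, 2), freqs)])
    ped = Pedigree(inds)
    gt = GenotypeTable([i.uid for i in inds], gmap)
    haplo = {}
    for (u, fa, mo) in members:
        if fa is None:
            haplo[u] = rng.integers(1, 3, size=2)
        else:
            haplo[u] = np.array([haplo[fa][rng.integers(2)],
                                 haplo[mo][rng.integers(2)]])
    for (u, _, _) in members:
        if rng.random() < 0.85:
            gt.set(u, "M1", tuple(sorted(int(a) for a in haplo[u])))
    statuses = {u: str(rng.choice(["affected", "unaffected", "unknown"]))
                for (u, _, _) in members}
    observed = {u: gt.get(u, "M1") and tuple(a - 1 for a in gt.get(u, "M1"))
                for (u, _, _) in members}
    return ped, gt, members, statuses, observed


def phase_known_family(n_children: int, recombinants: int = 0):
    """Three-generation family giving phase-known paternal meioses.

    The affected grandfather is 1/1 and the unaffected grandmother 2/2, so
    the affected father's disease-1 haplotype phase is certain; the
    unaffected mother is 3/3. The first ``recombinants`` of the children are
    recombinant, the rest not. Under a fully penetrant dominant model with
    no phenocopies, N nonrecombinant children give max LOD = N*log10(2).
    Returns (pedigree, genotypes, statuses).
    """
    inds = [Individual("F", "gf", None, None, "male", 2),
            Individual("F", "gm", None, None, "female", 1),
            Individual("F", "fa", "gf", "gm", "male", 2),
            Individual("F", "mo", None, None, "female", 1)]
    geno = {"F:gf": (1, 1), "F:gm": (2, 2), "F:fa": (1, 2), "F:mo": (3, 3)}
    for k in range(n_children):
        rec = k < recombinants
        affected = k % 2 == 0
        inds.append(Individual("F", f"c{k}", "fa", "mo", "male",
                               2 if affected else 1))
        paternal = (2 if affected else 1) if rec else (1 if affected else 2)
        geno[f"F:c{k}"] = tuple(sorted((paternal, 3)))
    gmap = GeneticMap([Marker("M1", "1", 0.0, (1, 2, 3), (0.4, 0.3, 0.3))])
    ped = Pedigree(inds)
    gt = GenotypeTable([i.uid for i in inds], gmap)
    for u, g in geno.items():
        gt.set(u, "M1", g)
    statuses = {i.uid: "affected" if i.affection == 2 else "unaffected"
                for i in inds}
    return ped, gt, statuses
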