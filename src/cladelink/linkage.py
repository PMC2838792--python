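"""Two-point parametric linkage with heterogeneity (LOD / HLOD).

The likelihood of one family at recombination fraction theta is computed
exactly by Elston-Stewart peeling over joint disease-marker genotypes:
individual states are ordered pairs of haplotypes (disease allele, marker
allele), founders carry Hardy-Weinberg priors at both loci (linkage
equilibrium), transmission recombines with probability theta, penetrance
applies to the clade-derived affection status (unknown contributes a factor
of 1), and untyped marker genotypes are summed over. Messages are batched
over the model and theta grids. Pedigrees with loops are rejected.

HLOD uses the admixture model: HLOD(alpha, theta) =
sum_fam log10(alpha * 10^lod_fam(theta) + 1 - alpha), jointly testing
linkage and heterogeneity against "no linkage, no heterogeneity".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .io import (CladelinkError, GeneticMap, GenotypeTable, Pedigree,
                 StructureError, TraitMatrix, marker_freqs)
from .nesting import AffectionCoding, Clade, affection_coding

__all__ = [
    "GeneticModel", "DOM1", "REC1", "DOM2", "REC2", "STANDARD_MODELS",
    "DEFAULT_THETA_GRID", "LinkageResult", "family_lod_curve", "hlod",
    "run_linkage", "clade_max_statistic", "MendelianInconsistency",
]


@dataclass(frozen=True)
class GeneticModel:
    """Single-locus disease model: allele frequency and penetrances by the
    number of disease alleles carried (f0 = phenocopy rate)."""

    name: str
    disease_allele_freq: float
    penetrances: tuple[float, float, float]


DOM1 = GeneticModel("Dom-1", 0.01, (0.0, 1.0, 1.0))
REC1 = GeneticModel("Rec-1", 0.09, (0.0, 0.0, 1.0))
DOM2 = GeneticModel("Dom-2", 0.01, (0.0005, 0.55, 0.55))
REC2 = GeneticModel("Rec-2", 0.09, (0.0005, 0.0005, 0.55))
STANDARD_MODELS: tuple[GeneticModel, ...] = (DOM1, REC1, DOM2, REC2)

DEFAULT_THETA_GRID: tuple[float, ...] = (
    0.0, 0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50)


class MendelianInconsistency(CladelinkError):
    """Family likelihood is zero at every theta for this marker."""


# ---------------------------------------------------------------------------
# transmission matrices, cached per (n_alleles, theta grid)

_TRANS_CACHE: dict[tuple, np.ndarray] = {}


def _transmission(m: int, thetas: tuple[float, ...]) -> np.ndarray:
    """(n_theta, G, H) gamete probabilities; haplotype h = d*m + a."""
    key = (m, thetas)
    if key in _TRANS_CACHE:
        return _TRANS_CACHE[key]
    H = 2 * m
    G = H * H
    th = np.asarray(thetas)[:, None, None]
    T = np.zeros((len(thetas), G, H))
    for h1 in range(H):
        d1, a1 = divmod(h1, m)
        for h2 in range(H):
            d2, a2 = divmod(h2, m)
            g = h1 * H + h2
            T[:, g, h1] += 0.5 * (1 - th[:, 0, 0])
            T[:, g, h2] += 0.5 * (1 - th[:, 0, 0])
            T[:, g, d1 * m + a2] += 0.5 * th[:, 0, 0]
            T[:, g, d2 * m + a1] += 0.5 * th[:, 0, 0]
    _TRANS_CACHE[key] = T
    return T


# ---------------------------------------------------------------------------
# family structure for peeling


class _FamilyEngine:
    """Nuclear-family decomposition of one loop-free family."""

    def __init__(self, ped: Pedigree, family_id: str):
        self.family_id = family_id
        members = ped.families[family_id]
        self.uids = [i.uid for i in members]
        self.founder = {i.uid: i.is_founder for i in members}
        units: dict[tuple[str, str], list[str]] = {}
        for i in members:
            if not i.is_founder:
                units.setdefault((i.father_uid, i.mother_uid), []).append(i.uid)
        self.units = [(fa, mo, tuple(kids)) for (fa, mo), kids in sorted(units.items())]
        self.parent_units: dict[str, list[int]] = {u: [] for u in self.uids}
        self.child_unit: dict[str, int] = {}
        for k, (fa, mo, kids) in enumerate(self.units):
            self.parent_units[fa].append(k)
            self.parent_units[mo].append(k)
            for c in kids:
                self.child_unit[c] = k
        # loop-free <=> bipartite individual/unit graph is a tree
        n_nodes = len(self.uids) + len(self.units)
        n_edges = sum(2 + len(kids) for _, _, kids in self.units)
        if n_edges != n_nodes - 1 and len(self.units) > 0:
            raise StructureError(
                f"family {family_id} contains a loop; loop-breaking is not supported")


def _marker_obs(engine: _FamilyEngine, genotypes: GenotypeTable, marker: str,
                alleles: tuple[int, ...]) -> dict[str, np.ndarray]:
    """Per-member indicator over ordered two-locus genotypes (G,)."""
    m = len(alleles)
    H = 2 * m
    G = H * H
    pos = {a: i for i, a in enumerate(alleles)}
    a_pat = (np.arange(G) // H) % m
    a_mat = np.arange(G) % H % m
    out = {}
    for u in engine.uids:
        g = genotypes.get(u, marker)
        if g is None:
            out[u] = np.ones(G)
        else:
            i, j = pos[g[0]], pos[g[1]]
            ok = ((a_pat == i) & (a_mat == j)) | ((a_pat == j) & (a_mat == i))
            out[u] = ok.astype(float)
    return out


def _unaries(engine: _FamilyEngine, statuses: Mapping[str, str],
             obs: Mapping[str, np.ndarray], models: Sequence[GeneticModel],
             freqs: np.ndarray) -> dict[str, np.ndarray]:
    """Per-member (n_models, G) factor: founder prior x penetrance x marker obs."""
    m = len(freqs)
    H = 2 * m
    G = H * H
    d_pat = np.arange(G) // H // m
    d_mat = (np.arange(G) % H) // m
    ndis = d_pat + d_mat  # 0..2 disease alleles
    out = {}
    nM = len(models)
    pen = np.empty((nM, G))
    prior = np.empty((nM, G))
    for k, mod in enumerate(models):
        f = np.asarray(mod.penetrances)
        pen[k] = f[ndis]
        q = mod.disease_allele_freq
        hap = np.array([(q if d else 1 - q) * freqs[a]
                        for d in (0, 1) for a in range(m)])
        prior[k] = (hap[:, None] * hap[None, :]).ravel()
    ones = np.ones((nM, G))
    for u in engine.uids:
        st = statuses.get(u, "unknown")
        if st == "affected":
            base = pen
        elif st == "unaffected":
            base = 1.0 - pen
        else:
            base = ones
        v = base * obs[u][None, :]
        if engine.founder[u]:
            v = v * prior
        out[u] = v
    return out


class _Peeler:
    """Recursive peeling with (n_models, n_theta, G) messages and log scaling."""

    def __init__(self, engine: _FamilyEngine, unary: Mapping[str, np.ndarray],
                 T: np.ndarray):
        self.e = engine
        self.unary = unary  # (M, G) each
        self.T = T  # (Th, G, H)
        self.nM = next(iter(unary.values())).shape[0]
        self.nT, self.G, self.H = T.shape

    def _scale(self, arr: np.ndarray, logs: np.ndarray):
        s = arr.max(axis=-1)
        safe = np.where(s > 0, s, 1.0)
        arr = arr / safe[..., None]
        with np.errstate(divide="ignore"):
            logs = logs + np.where(s > 0, np.log10(safe), -np.inf)
        return arr, logs

    def collect(self, uid: str, exclude_unit: int | None):
        arr = np.broadcast_to(self.unary[uid][:, None, :],
                              (self.nM, self.nT, self.G)).copy()
        logs = np.zeros((self.nM, self.nT))
        for k in self.e.parent_units[uid]:
            if k == exclude_unit:
                continue
            msg, lg = self._to_parent(k, uid)
            arr = arr * msg
            logs = logs + lg
            arr, logs = self._scale(arr, logs)
        k = self.e.child_unit.get(uid)
        if k is not None and k != exclude_unit:
            msg, lg = self._to_child(k, uid)
            arr = arr * msg
            logs = logs + lg
            arr, logs = self._scale(arr, logs)
        return arr, logs

    def _child_matrix(self, child: str):
        """M_c[gf, gm] = sum over child states of T T x (child upward factor)."""
        c_arr, c_logs = self.collect(child, self.e.child_unit[child])
        W = c_arr.reshape(self.nM, self.nT, self.H, self.H)
        # Mc[m,t,gf,gm] = sum_ab T[t,gf,a] W[m,t,a,b] T[t,gm,b]
        X = np.matmul(self.T[None], W)
        Mc = np.matmul(X, np.swapaxes(self.T, 1, 2)[None])
        return Mc, c_logs

    def _rescale_matrix(self, A, logs):
        m = A.max(axis=(-2, -1))
        safe = np.where(m > 0, m, 1.0)
        A /= safe[..., None, None]
        with np.errstate(divide="ignore"):
            return A, logs + np.where(m > 0, np.log10(safe), -np.inf)

    def _to_parent(self, k: int, pivot: str):
        fa, mo, kids = self.e.units[k]
        spouse = mo if pivot == fa else fa
        sp_arr, logs = self.collect(spouse, k)
        A = None
        for c in kids:
            Mc, lg = self._child_matrix(c)
            A = Mc.copy() if A is None else A * Mc
            logs = logs + lg
        A, logs = self._rescale_matrix(A, logs)
        if pivot == fa:
            out = np.matmul(A, sp_arr[..., None])[..., 0]
        else:
            out = np.matmul(sp_arr[..., None, :], A)[..., 0, :]
        return out, logs

    def _to_child(self, k: int, pivot: str):
        fa, mo, kids = self.e.units[k]
        fa_arr, fa_logs = self.collect(fa, k)
        mo_arr, mo_logs = self.collect(mo, k)
        A = fa_arr[..., :, None] * mo_arr[..., None, :]
        logs = fa_logs + mo_logs
        for c in kids:
            if c == pivot:
                continue
            Mc, lg = self._child_matrix(c)
            A *= Mc
            logs = logs + lg
        A, logs = self._rescale_matrix(A, logs)
        # msg[m,t,a,b] = sum_fg T[t,f,a] A[m,t,f,g] T[t,g,b]
        X = np.matmul(np.swapaxes(self.T, 1, 2)[None], A)
        msg = np.matmul(X, self.T[None]).reshape(self.nM, self.nT, self.G)
        return msg, logs

    def loglik(self) -> np.ndarray:
        """(n_models, n_theta) log10 likelihood; -inf when inconsistent."""
        pivot = self.e.uids[0]
        arr, logs = self.collect(pivot, None)
        total = arr.sum(axis=-1)
        with np.errstate(divide="ignore"):
            return np.where(total > 0, np.log10(np.where(total > 0, total, 1.0)), -np.inf) + logs


def _family_lods(ped: Pedigree, family_id: str, statuses: Mapping[str, str],
                 genotypes: GenotypeTable, marker: str,
                 models: Sequence[GeneticModel], thetas: Sequence[float],
                 freqs: np.ndarray | None = None) -> np.ndarray:
    """(n_models, n_theta) log10 L(theta)/L(0.5); raises MendelianInconsistency."""
    mk = genotypes.gmap[marker]
    if freqs is None:
        freqs = marker_freqs(ped, genotypes, marker)
    thetas = tuple(thetas)
    full = thetas if 0.5 in thetas else thetas + (0.5,)
    engine = _FamilyEngine(ped, family_id)
    obs = _marker_obs(engine, genotypes, marker, mk.alleles)
    unary = _unaries(engine, statuses, obs, models, np.asarray(freqs))
    T = _transmission(len(mk.alleles), full)
    ll = _Peeler(engine, unary, T).loglik()
    ref = ll[:, full.index(0.5)]
    invalid = np.isneginf(ref)
    if invalid.all():
        raise MendelianInconsistency(
            f"family {family_id} at {marker}: zero likelihood under every model "
            "(Mendelian inconsistency)")
    with np.errstate(invalid="ignore"):
        lods = ll - ref[:, None]
    # a model can be individually impossible (e.g. an unaffected child of two
    # affected parents under a fully penetrant recessive): flag with NaN
    lods[invalid] = np.nan
    return lods[:, :len(thetas)]


def family_lod_curve(ped: Pedigree, family_id: str,
                     affection: AffectionCoding | Mapping[str, str],
                     genotypes: GenotypeTable, marker: str, model: GeneticModel,
                     theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
                     freqs: np.ndarray | None = None) -> np.ndarray:
    """log10 likelihood-ratio curve of one family at one marker.

    ``affection`` maps uid to affected/unaffected/unknown (an
    :class:`AffectionCoding` works directly). lod(0.5) is exactly 0.
    """
    statuses = affection.status if isinstance(affection, AffectionCoding) else affection
    curve = _family_lods(ped, family_id, statuses, genotypes, marker, [model],
                         theta_grid, freqs)[0]
    if np.isnan(curve).any():
        raise MendelianInconsistency(
            f"family {family_id} at {marker}: zero likelihood under {model.name}")
    return curve


def hlod(family_curves: np.ndarray, theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
         alpha_step: float = 0.01, refine: bool = True
         ) -> tuple[float, float, float]:
    """Maximize the admixture HLOD over (alpha, theta).

    ``family_curves``: (n_families, n_theta) per-family LOD curves. Returns
    (hlod, alpha, theta); at alpha = 1 the score equals the homogeneity LOD,
    so the maximum is always >= max(0, homogeneity LOD).
    """
    curves = np.atleast_2d(np.asarray(family_curves, float))
    if curves.shape[0] == 0:
        raise CladelinkError("no family curves")
    R = np.power(10.0, curves)  # (F, Th)
    alphas = np.arange(0.0, 1.0 + 1e-12, alpha_step)

    def value(alpha: float | np.ndarray) -> np.ndarray:
        a = np.atleast_1d(alpha)[:, None, None]
        with np.errstate(divide="ignore"):
            v = np.log10(a * R[None, :, :] + (1 - a))
        return v.sum(axis=1)  # (A, Th)

    vals = value(alphas)
    ai, ti = np.unravel_index(np.argmax(vals), vals.shape)
    best_alpha, best_theta = float(alphas[ai]), float(theta_grid[ti])
    best = float(vals[ai, ti])
    if refine:
        lo = max(0.0, best_alpha - alpha_step)
        hi = min(1.0, best_alpha + alpha_step)
        res = minimize_scalar(lambda a: -value(a)[0, ti], bounds=(lo, hi),
                              method="bounded", options={"xatol": 1e-6})
        if -res.fun > best:
            best, best_alpha = float(-res.fun), float(res.x)
    return best, best_alpha, best_theta


@dataclass
class LinkageResult:
    """One Table-style row: clade x marker x model."""

    clade: str
    marker: str
    model: str
    lods: np.ndarray  # summed over families, per theta
    max_lod: float
    theta_max: float
    hlod: float
    alpha: float
    theta_hlod: float
    n_families: int


def run_linkage(clades: Sequence[Clade], ped: Pedigree, genotypes: GenotypeTable,
                gmap: GeneticMap, models: Sequence[GeneticModel] = STANDARD_MODELS,
                theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
                traits: TraitMatrix | None = None,
                markers: Sequence[str] | None = None) -> list[LinkageResult]:
    """Two-point LOD and HLOD for every clade x marker x model.

    Families with no clade member are excluded per clade; families whose
    genotypes are Mendelian-inconsistent at a marker are dropped from that
    marker with a warning. Clades should already satisfy the family-count
    filter.
    """
    if markers is None:
        markers = gmap.names
    freqs = {mk: marker_freqs(ped, genotypes, mk) for mk in markers}
    thetas = tuple(theta_grid)
    results: list[LinkageResult] = []
    warned: set[tuple[str, str]] = set()
    for clade in clades:
        coding = affection_coding(clade, ped, traits)
        fams = coding.families
        for mk in markers:
            fam_curves = []  # (n_models, n_theta) per family
            fam_ids = []
            for fam in fams:
                try:
                    fam_curves.append(_family_lods(ped, fam, coding.status,
                                                   genotypes, mk, models,
                                                   thetas, freqs[mk]))
                    fam_ids.append(fam)
                except MendelianInconsistency as e:
                    warnings.warn(str(e))
            if not fam_curves:
                continue
            stack = np.stack(fam_curves)  # (F, M, Th)
            for j, model in enumerate(models):
                valid = ~np.isnan(stack[:, j, :]).any(axis=1)
                for fam, ok in zip(fam_ids, valid):
                    if not ok and (fam, model.name) not in warned:
                        warned.add((fam, model.name))
                        warnings.warn(
                            f"family {fam}: zero likelihood under "
                            f"{model.name}; excluded for this model")
                if not valid.any():
                    continue
                curves = stack[valid, j, :]
                total = curves.sum(axis=0)
                ti = int(np.nanargmax(total))
                h, a, th = hlod(curves, thetas)
                results.append(LinkageResult(
                    clade.label, mk, model.name, total,
                    float(total[ti]), float(thetas[ti]), h, a, th,
                    int(valid.sum())))
    return results


def clade_max_statistic(results: Sequence[LinkageResult], clade: str | None = None
                        ) -> tuple[float, LinkageResult]:
    """Z_max: the maximum of LOD and HLOD over markers and genetic models
    (for one clade, or globally when ``clade`` is None)."""
    pool = [r for r in results if clade is None or r.clade == clade]
    if not pool:
        raise CladelinkError("no linkage results for the requested scope")
    best = max(pool, key=lambda r: max(r.max_lod, r.hlod))
    return max(best.max_lod, best.hlod), best
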