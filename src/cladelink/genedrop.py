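"""Gene-dropping replicates and empirical p-values for linkage maxima.

Replicate genotype datasets are simulated under the null of no linkage to
the phenotype: founder haplotypes are drawn marker-by-marker from the
observed (or supplied) allele frequencies assuming linkage equilibrium, and
transmitted through the pedigree with recombination between adjacent markers
given by the Haldane map function on the cM gaps. The observed missingness
pattern is re-applied, so replicates match the real data in pedigree
structure, map, and which cells are typed. Phenotypes and clades are held
fixed; only genotypes are randomized.

The model-based p-value p_M compares a clade's observed maximum score
(over genetic models and markers) with the same maximum in each replicate;
the global p_G compares against replicate maxima taken across clades too.
Both use the (hits + 1) / (R + 1) convention.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .io import CladelinkError, GeneticMap, GenotypeTable, Pedigree, marker_freqs
from .linkage import LinkageResult, clade_max_statistic

__all__ = ["haldane_theta", "kosambi_theta", "gene_drop", "make_replicates",
           "empirical_p"]


def haldane_theta(d_cm: float) -> float:
    """Recombination fraction for a gap of ``d_cm`` centimorgans (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def kosambi_theta(d_cm: float) -> float:
    """Kosambi map function alternative."""
    return 0.5 * np.tanh(2.0 * d_cm / 100.0)


def _founder_freq_matrix(ped: Pedigree, genotypes: GenotypeTable,
                         gmap: GeneticMap) -> list[np.ndarray]:
    return [marker_freqs(ped, genotypes, m.name) for m in gmap]


def _drop_family(ped: Pedigree, fam: str, gmap: GeneticMap,
                 freqs: Sequence[np.ndarray], rng: np.random.Generator,
                 map_fn=haldane_theta) -> dict[str, np.ndarray]:
    """Simulate (n_markers, 2) allele arrays (map labels) for one family."""
    members = ped.families[fam]
    n_mark = len(gmap)
    thetas = np.zeros(n_mark)  # theta between marker j-1 and j; 0.5 across chroms
    prev = None
    for j, mk in enumerate(gmap):
        if prev is not None and mk.chrom == prev.chrom:
            thetas[j] = map_fn(mk.pos_cm - prev.pos_cm)
        else:
            thetas[j] = 0.5
        prev = mk
    haplos: dict[str, np.ndarray] = {}

    def founder_haplotypes() -> np.ndarray:
        h = np.empty((n_mark, 2), dtype=np.int16)
        for j, mk in enumerate(gmap):
            h[:, 0][j], h[:, 1][j] = rng.choice(mk.alleles, size=2, p=freqs[j])
        return h

    def gamete(parent_h: np.ndarray) -> np.ndarray:
        pick = np.empty(n_mark, dtype=np.int8)
        pick[0] = rng.integers(2)
        switch = rng.random(n_mark - 1) < thetas[1:]
        pick[1:] = (pick[0] + np.cumsum(switch)) % 2
        return parent_h[np.arange(n_mark), pick]

    # founders first, then children in dependency order
    pending = list(members)
    guard = 0
    while pending:
        nxt = []
        for ind in pending:
            if ind.is_founder:
                haplos[ind.uid] = founder_haplotypes()
            elif ind.father_uid in haplos and ind.mother_uid in haplos:
                haplos[ind.uid] = np.stack(
                    [gamete(haplos[ind.father_uid]), gamete(haplos[ind.mother_uid])],
                    axis=1)
            else:
                nxt.append(ind)
        if len(nxt) == len(pending):
            raise CladelinkError(f"family {fam}: unresolved parentage")
        pending = nxt
        guard += 1
        if guard > len(members) + 2:
            break
    return haplos


def gene_drop(ped: Pedigree, genotypes: GenotypeTable,
              gmap: GeneticMap | None = None,
              seed: int | None = 0, map_fn=haldane_theta,
              freqs: Sequence[np.ndarray] | None = None) -> GenotypeTable:
    """One randomized replicate of the genotype data.

    Founder genotypes are drawn from the marker allele frequencies
    (map-supplied or founder-estimated), offspring receive recombinant
    gametes, and the observed missingness mask is re-applied.
    """
    if gmap is None:
        gmap = genotypes.gmap
    if freqs is None:
        freqs = _founder_freq_matrix(ped, genotypes, gmap)
    rng = np.random.default_rng(seed)
    out = GenotypeTable(genotypes.uids, gmap)
    typed = genotypes.typed_mask()
    for fam in sorted(ped.families):
        haplos = _drop_family(ped, fam, gmap, freqs, rng, map_fn)
        for u, h in haplos.items():
            r = out.row(u)
            out.data[r] = h
    out.data[~typed] = 0
    return out


def make_replicates(ped: Pedigree, genotypes: GenotypeTable, n_replicates: int = 100,
                    seed: int | None = 0, map_fn=haldane_theta) -> list[GenotypeTable]:
    """``n_replicates`` gene-drop replicates with per-replicate derived seeds."""
    gmap = genotypes.gmap
    freqs = _founder_freq_matrix(ped, genotypes, gmap)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_replicates)
    return [gene_drop(ped, genotypes, gmap, int(s) % (2 ** 31), map_fn, freqs)
            for s in seeds]


def _score(r: LinkageResult) -> float:
    return max(r.max_lod, r.hlod)


def empirical_p(observed: Sequence[LinkageResult],
                replicate_results: Sequence[Sequence[LinkageResult]]
                ) -> tuple[dict[str, float], dict[str, float]]:
    """Model-based (p_M) and global (p_G) empirical p-values.

    Each replicate must have been analyzed with the identical clades, models
    and markers as the observed data. Returns ``(p_M, p_G)`` keyed by clade
    label; p_G compares each clade's observed maximum against the replicate
    maxima across all clades, so p_M <= p_G holds for the clade attaining the
    global observed maximum.
    """
    if not replicate_results:
        raise CladelinkError("at least one replicate is required")
    clades = sorted({r.clade for r in observed})
    R = len(replicate_results)
    obs_max = {c: clade_max_statistic(observed, c)[0] for c in clades}
    rep_clade_max = {c: np.array([clade_max_statistic(rep, c)[0]
                                  for rep in replicate_results]) for c in clades}
    rep_global_max = np.array([max(clade_max_statistic(rep, c)[0] for c in clades)
                               for rep in replicate_results])
    p_m = {c: float((np.sum(rep_clade_max[c] >= obs_max[c] - 1e-12) + 1) / (R + 1))
           for c in clades}
    p_g = {c: float((np.sum(rep_global_max >= obs_max[c] - 1e-12) + 1) / (R + 1))
           for c in clades}
    return p_m, p_g
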