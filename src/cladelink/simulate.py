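"""Synthetic family studies with known truth.

Emulates the statistical structure of the GAW14 "Kofendred Personality
Disorder" (KPD) simulation: three populations of ascertained families, four
major disease loci D1-D4 interacting epistatically plus two penetrance
modifiers D5-D6, three latent phenotypes P1-P3 expressed as overlapping sets
of twelve behavioral traits (a-l), and a microsatellite panel at roughly
7.5 cM spacing. The exact GAW14 generating tables are not public, so the
penetrance values and epistatic predicates here are this package's own
documented choices that reproduce the qualitative architecture:

* P1 requires carrying disease alleles at both D1 and D2 and expresses
  traits {b, e, f, h};
* P2 requires homozygosity at D2 (recessive) plus a D3 copy (dominant) and
  expresses {c, d, e, f, g, h};
* P3 is the mirror image (D2 dominant, D3 recessive) and expresses
  {b, c, d, e, f, g, h} - P2 and P3 differ only by trait b;
* D4 carriers have full latent-phenotype penetrance for P2/P3, non-carriers
  a reduced one, so D4 adds linkage signal to those clades;
* D5/D6 carriers multiply penetrance by a modifier factor;
* D2 alone, in individuals with no latent phenotype, expresses traits
  {e, f, h} with 20% penetrance (a dominant sub-clinical effect);
* every trait is additionally present at a small background rate in
  everyone, creating the symptom continuum into unaffecteds.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genedrop import haldane_theta
from .io import (CladelinkError, GeneticMap, GenotypeTable, Individual, Marker,
                 Pedigree, TraitMatrix, uid)

__all__ = [
    "DiseaseLocus", "PopulationSpec", "KPDConfig", "KPDTruth",
    "simulate_marker_panel", "simulate_kpd_study", "make_toy_fixture",
    "simulate_symptom_cohort", "TRAITS",
]

TRAITS = tuple("abcdefghijkl")

TRAIT_MAP: dict[str, tuple[str, ...]] = {
    "P1": ("b", "e", "f", "h"),
    "P2": ("c", "d", "e", "f", "g", "h"),
    "P3": ("b", "c", "d", "e", "f", "g", "h"),
}


@dataclass(frozen=True)
class DiseaseLocus:
    name: str
    chrom: str
    pos_cm: float
    allele_freq: float  # frequency of the disease allele


@dataclass(frozen=True)
class PopulationSpec:
    """Ascertainment: at least ``min_count`` family members with a latent
    phenotype drawn from ``phenotypes``."""

    name: str
    n_families: int
    phenotypes: tuple[str, ...]
    min_count: int = 2


@dataclass
class KPDConfig:
    """Study-design parameters; defaults follow the simulated-study design
    (three populations of 100 families, 416 markers on 10 chromosomes at
    7.5 cM)."""

    populations: tuple[PopulationSpec, ...] = (
        PopulationSpec("Aipotu", 100, ("P1", "P2", "P3")),
        PopulationSpec("Karangar", 100, ("P2", "P3")),
        PopulationSpec("Danacaa", 100, ("P1",)),
    )
    loci: tuple[DiseaseLocus, ...] = (
        DiseaseLocus("D1", "1", 26.0, 0.12),
        DiseaseLocus("D2", "3", 30.0, 0.18),
        DiseaseLocus("D3", "5", 22.0, 0.18),
        DiseaseLocus("D4", "9", 37.0, 0.20),
        DiseaseLocus("D5", "2", 60.0, 0.20),
        DiseaseLocus("D6", "7", 60.0, 0.20),
    )
    base_penetrance: float = 0.95
    d4_noncarrier_factor: float = 0.6  # P2/P3 penetrance multiplier without D4
    modifier_factor: float = 0.85  # per modifier locus carried (D5, D6)
    d2_subclinical_penetrance: float = 0.20
    background_rate: float = 0.02
    n_children: int = 4
    n_chrom: int = 10
    spacing_cm: float = 7.5
    n_markers: int = 416
    n_alleles: int = 4
    max_redraws: int = 5000
    seed: int = 0

    @classmethod
    def scaled(cls, n_families_per_pop: int = 30, n_chrom: int = 4,
               markers_per_chrom: int = 8, seed: int = 0) -> "KPDConfig":
        """A desk-scale study: same architecture, fewer families and a
        smaller panel (loci on chromosomes 1-3; chromosome 4 unlinked)."""
        pops = (
            PopulationSpec("Aipotu", n_families_per_pop, ("P1", "P2", "P3")),
            PopulationSpec("Karangar", n_families_per_pop, ("P2", "P3")),
            PopulationSpec("Danacaa", n_families_per_pop, ("P1",)),
        )
        loci = (
            DiseaseLocus("D1", "1", 26.0, 0.12),
            DiseaseLocus("D2", "2", 30.0, 0.18),
            DiseaseLocus("D3", "3", 22.0, 0.18),
            DiseaseLocus("D4", "3", 45.0, 0.20),
            DiseaseLocus("D5", "2", 7.0, 0.20),
            DiseaseLocus("D6", "1", 50.0, 0.20),
        )
        return cls(populations=pops, loci=loci, n_chrom=n_chrom,
                   spacing_cm=7.5, n_markers=n_chrom * markers_per_chrom,
                   seed=seed)


@dataclass
class KPDTruth:
    """Generating-model record emitted alongside a simulated study."""

    latent: dict[str, str | None]
    disease_genotypes: dict[str, dict[str, int]]  # uid -> locus -> allele count
    loci: dict[str, tuple[str, float]]  # locus -> (chrom, pos_cm)
    origins: dict[str, np.ndarray]  # uid -> (n_markers, 2) founder-haplotype ids

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for u, ph in self.latent.items():
            row = {"uid": u, "latent": ph or "none"}
            row.update({k: v for k, v in self.disease_genotypes[u].items()})
            rows.append(row)
        return pd.DataFrame(rows)


def simulate_marker_panel(n_chrom: int = 10, spacing_cm: float = 7.5,
                          n_markers: int = 416, n_alleles: int = 4,
                          seed: int | None = 0) -> GeneticMap:
    """Evenly spaced microsatellite panel with Dirichlet allele frequencies."""
    rng = np.random.default_rng(seed)
    per = [n_markers // n_chrom + (1 if c < n_markers % n_chrom else 0)
           for c in range(n_chrom)]
    markers = []
    for c, k in enumerate(per, start=1):
        for j in range(k):
            freqs = rng.dirichlet(np.full(n_alleles, 2.0))
            freqs = np.round(freqs, 6)
            freqs[-1] = 1.0 - freqs[:-1].sum()
            markers.append(Marker(f"C{c}M{j + 1}", str(c), j * spacing_cm,
                                  tuple(range(1, n_alleles + 1)),
                                  tuple(float(f) for f in freqs)))
    return GeneticMap(markers)


# ---------------------------------------------------------------------------
# haplotype dropping over markers + disease loci, with origin tracking


class _LociLayout:
    """Merged marker + disease-locus positions with inter-locus thetas."""

    def __init__(self, gmap: GeneticMap, loci: Sequence[DiseaseLocus]):
        entries = []  # (chrom, pos, kind, index/name, freqs)
        for j, m in enumerate(gmap):
            entries.append((m.chrom, m.pos_cm, "marker", j,
                            np.asarray(m.freqs)))
        for l in loci:
            entries.append((l.chrom, l.pos_cm, "locus", l.name,
                            np.array([1 - l.allele_freq, l.allele_freq])))
        entries.sort(key=lambda e: (_chrom_key(e[0]), e[1]))
        self.entries = entries
        self.n = len(entries)
        self.thetas = np.full(self.n, 0.5)
        for i in range(1, self.n):
            c0, p0 = entries[i - 1][0], entries[i - 1][1]
            c1, p1 = entries[i][0], entries[i][1]
            if c0 == c1:
                self.thetas[i] = haldane_theta(p1 - p0)
        # cumulative allele frequencies padded to a common width, for
        # vectorized founder sampling
        width = max(len(e[4]) for e in entries)
        self.cum_freqs = np.ones((self.n, width))
        for i, e in enumerate(entries):
            self.cum_freqs[i, :len(e[4])] = np.cumsum(e[4])
        self.marker_rows = [i for i, e in enumerate(entries) if e[2] == "marker"]
        self.marker_index = [e[3] for e in entries if e[2] == "marker"]
        self.locus_rows = {e[3]: i for i, e in enumerate(entries) if e[2] == "locus"}


def _chrom_key(c: str):
    return (0, int(c)) if c.isdigit() else (1, c)


def _drop_haplotypes(layout: _LociLayout, structure: Sequence[tuple[int, int, int]],
                     rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Drop haplotypes for one family.

    ``structure``: per member (index, father_index, mother_index) with -1 for
    founder parents, parents before children. Returns (alleles, origins) of
    shape (n_members, n_loci, 2); alleles are 0-based indices; origins are
    distinct founder-haplotype ids.
    """
    n = len(structure)
    L = layout.n
    alleles = np.zeros((n, L, 2), dtype=np.int16)
    origins = np.zeros((n, L, 2), dtype=np.int16)
    next_origin = 0
    cum = layout.cum_freqs
    for (i, fa, mo) in structure:
        if fa < 0:
            u = rng.random((L, 2))
            for h in (0, 1):
                alleles[i, :, h] = (u[:, h, None] > cum).sum(axis=1)
                origins[i, :, h] = next_origin
                next_origin += 1
        else:
            for h, parent in ((0, fa), (1, mo)):
                pick = np.empty(L, dtype=np.int64)
                pick[0] = rng.integers(2)
                switch = rng.random(L - 1) < layout.thetas[1:]
                pick[1:] = (pick[0] + np.cumsum(switch)) % 2
                rows = np.arange(L)
                alleles[i, :, h] = alleles[parent, rows, pick]
                origins[i, :, h] = origins[parent, rows, pick]
    return alleles, origins


def _latent_phenotype(dg: Mapping[str, int], cfg: KPDConfig,
                      rng: np.random.Generator) -> str | None:
    """Assign a latent phenotype from disease genotypes (priority P1>P2>P3)."""
    mod = 1.0
    for m in ("D5", "D6"):
        if dg.get(m, 0) >= 1:
            mod *= cfg.modifier_factor
    candidates = []
    if dg["D1"] >= 1 and dg["D2"] >= 1:
        candidates.append(("P1", cfg.base_penetrance * mod))
    d4 = 1.0 if dg.get("D4", 0) >= 1 else cfg.d4_noncarrier_factor
    if dg["D2"] == 2 and dg["D3"] >= 1:
        candidates.append(("P2", cfg.base_penetrance * d4 * mod))
    if dg["D2"] >= 1 and dg["D3"] == 2:
        candidates.append(("P3", cfg.base_penetrance * d4 * mod))
    for name, pen in candidates:
        if rng.random() < pen:
            return name
    return None


def simulate_kpd_study(config: KPDConfig | None = None
                       ) -> tuple[Pedigree, GenotypeTable, TraitMatrix, KPDTruth]:
    """Simulate a full ascertained multi-population family study.

    Families (two founders, ``n_children`` offspring) are redrawn until the
    population's ascertainment rule holds; raises after ``max_redraws``
    failed attempts (e.g. when penetrance is zero). Returns the pedigree,
    marker genotypes, trait matrix, and the truth record.
    """
    cfg = config or KPDConfig()
    rng = np.random.default_rng(cfg.seed)
    gmap = simulate_marker_panel(cfg.n_chrom, cfg.spacing_cm, cfg.n_markers,
                                 cfg.n_alleles, seed=cfg.seed)
    layout = _LociLayout(gmap, cfg.loci)
    nc = cfg.n_children
    structure = [(0, -1, -1), (1, -1, -1)] + [(2 + k, 0, 1) for k in range(nc)]

    individuals: list[Individual] = []
    geno_rows: list[np.ndarray] = []
    latent: dict[str, str | None] = {}
    dgeno: dict[str, dict[str, int]] = {}
    origins: dict[str, np.ndarray] = {}
    trait_rows: dict[str, np.ndarray] = {}

    fam_counter = 0
    for pop in cfg.populations:
        for _ in range(pop.n_families):
            fam_counter += 1
            fam = f"{pop.name[:3].upper()}{fam_counter:04d}"
            accepted = None
            for _attempt in range(cfg.max_redraws):
                alleles, orig = _drop_haplotypes(layout, structure, rng)
                phenos = []
                dgs = []
                for i in range(len(structure)):
                    dg = {name: int(alleles[i, row, 0] + alleles[i, row, 1])
                          for name, row in layout.locus_rows.items()}
                    ph = _latent_phenotype(dg, cfg, rng)
                    phenos.append(ph)
                    dgs.append(dg)
                hits = sum(1 for p in phenos if p in pop.phenotypes)
                if hits >= pop.min_count:
                    accepted = (alleles, orig, phenos, dgs)
                    break
            if accepted is None:
                raise CladelinkError(
                    f"population {pop.name}: ascertainment rule unattainable "
                    f"after {cfg.max_redraws} redraws")
            alleles, orig, phenos, dgs = accepted
            ids = ["1", "2"] + [str(3 + k) for k in range(nc)]
            sexes = ["male", "female"] + \
                [("male" if rng.random() < 0.5 else "female") for _ in range(nc)]
            for i, (iid, sex) in enumerate(zip(ids, sexes)):
                fa = None if structure[i][1] < 0 else ids[structure[i][1]]
                mo = None if structure[i][2] < 0 else ids[structure[i][2]]
                aff = 2 if phenos[i] else 1
                individuals.append(Individual(fam, iid, fa, mo, sex, aff,
                                              "KPD" if phenos[i] else "unaffected"))
                u = uid(fam, iid)
                latent[u] = phenos[i]
                dgeno[u] = dgs[i]
                origins[u] = orig[i, layout.marker_rows, :]
                geno_rows.append(alleles[i, layout.marker_rows, :] + 1)  # 1-based labels
                # traits
                tv = np.zeros(len(TRAITS), dtype=float)
                present = set()
                if phenos[i]:
                    present |= set(TRAIT_MAP[phenos[i]])
                elif dgs[i]["D2"] >= 1 and rng.random() < cfg.d2_subclinical_penetrance:
                    present |= {"e", "f", "h"}
                for j, t in enumerate(TRAITS):
                    if t in present or rng.random() < cfg.background_rate:
                        tv[j] = 1.0
                trait_rows[u] = tv

    ped = Pedigree(individuals)
    genotypes = GenotypeTable([i.uid for i in individuals], gmap,
                              np.stack(geno_rows))
    frame = pd.DataFrame.from_dict(trait_rows, orient="index",
                                   columns=list(TRAITS))
    traits = TraitMatrix(frame)
    truth = KPDTruth(latent, dgeno, {l.name: (l.chrom, l.pos_cm) for l in cfg.loci},
                     origins)
    return ped, genotypes, traits, truth


# ---------------------------------------------------------------------------
# small fixtures and cohort simulators


def make_toy_fixture() -> tuple[TraitMatrix, dict]:
    """Eight patients x ten binary symptoms in two compatible blocks.

    Patients A1-A4 carry the first symptom block, B1-B4 the second; the
    blocks are disjoint, so every variable character is compatible and the
    optimal network separates the two groups with one change per character.
    Returns the matrix and the expected description (optimal score and the
    A-side split).
    """
    rows = {
        "T:A1": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
        "T:A2": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
        "T:A3": [1, 1, 1, 1, 0, 0, 0, 0, 0, 0],
        "T:A4": [1, 1, 1, 1, 0, 0, 0, 0, 0, 0],
        "T:B1": [0, 0, 0, 0, 0, 1, 1, 1, 1, 1],
        "T:B2": [0, 0, 0, 0, 0, 1, 1, 1, 1, 1],
        "T:B3": [0, 0, 0, 0, 0, 1, 1, 1, 1, 0],
        "T:B4": [0, 0, 0, 0, 0, 1, 1, 1, 1, 0],
    }
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=[f"s{i}" for i in range(1, 11)])
    matrix = TraitMatrix(frame)
    expected = {
        "score": 10,  # ten variable, mutually compatible characters
        "split": frozenset({"T:A1", "T:A2", "T:A3", "T:A4"}),
    }
    return matrix, expected


def simulate_symptom_cohort(group_sizes: Mapping[str, int],
                            trait_probs: Mapping[str, Mapping[str, float]],
                            overlap: float = 0.0, seed: int | None = 0
                            ) -> tuple[TraitMatrix, dict[str, str]]:
    """Bernoulli symptom cohort with known group labels.

    ``trait_probs[group][trait]`` is the presence probability. With
    ``overlap`` > 0 each individual draws each trait from a uniformly random
    other group's probability with that chance, blurring group boundaries.
    Returns the trait matrix and uid -> group labels.
    """
    rng = np.random.default_rng(seed)
    groups = list(group_sizes)
    traits = sorted({t for g in groups for t in trait_probs[g]})
    rows = {}
    labels = {}
    k = 0
    for g in groups:
        for _ in range(group_sizes[g]):
            k += 1
            u = uid("C", str(k))
            labels[u] = g
            vals = []
            for t in traits:
                src = g
                if overlap > 0 and rng.random() < overlap:
                    src = groups[rng.integers(len(groups))]
                vals.append(1.0 if rng.random() < trait_probs[src].get(t, 0.0)
                            else 0.0)
            rows[u] = vals
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=traits)
    return TraitMatrix(frame), labels
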