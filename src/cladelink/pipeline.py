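"""End-to-end pipeline: network -> clades -> symptom tests -> linkage -> p-values.

Each stage writes plain-text outputs (Newick, TSV, JSON manifest) that later
stages can re-load, so a run can be resumed mid-way. Every random stage takes
its own named seed; identical configs and seeds give identical outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genedrop import empirical_p, make_replicates
from .io import (GeneticMap, GenotypeTable, Pedigree, TraitMatrix, read_diagnoses,
                 read_map, read_ped, read_traits, FormatError)
from .linkage import (DEFAULT_THETA_GRID, STANDARD_MODELS, GeneticModel,
                      LinkageResult, clade_max_statistic, run_linkage)
from .nesting import ASYMPTOMATIC, Clade, filter_clades, nest_tree
from .parsimony import PhenoTree, TreeSet, majority_consensus, ratchet_search
from .symptoms import clade_symptom_table, prevalence_matrix, symptom_profile

__all__ = ["RunConfig", "run_all", "build_network", "extract_clades",
           "write_clades_tsv", "read_clades_tsv", "linkage_results_frame"]

_MODELS_BY_NAME = {m.name: m for m in STANDARD_MODELS}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serializable)."""

    ped: str
    map: str
    traits: str
    outdir: str
    diagnoses: str | None = None
    ratchet_iterations: int = 200
    reweight_fraction: float = 0.25
    consensus_threshold: float = 0.51
    min_families: int = 40
    models: tuple[str, ...] = tuple(m.name for m in STANDARD_MODELS)
    theta_grid: tuple[float, ...] = DEFAULT_THETA_GRID
    markers: tuple[str, ...] | None = None
    n_replicates: int = 100
    n_permutations: int = 10_000
    seed_network: int = 0
    seed_replicates: int = 1
    seed_permutations: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    def model_objects(self) -> list[GeneticModel]:
        return [_MODELS_BY_NAME[n] for n in self.models]


def build_network(traits: TraitMatrix, iterations: int = 200,
                  reweight_fraction: float = 0.25, seed: int | None = 0,
                  threshold: float = 0.51,
                  add_root: bool = True) -> tuple[TreeSet, PhenoTree]:
    """Stage 1: ratchet search plus majority-rule consensus.

    An artificial all-zero asymptomatic pseudo-individual is appended as a
    rooting outgroup (removed again during nesting).
    """
    frame = traits.frame
    if add_root and ASYMPTOMATIC not in frame.index:
        frame = pd.concat([frame, pd.DataFrame(
            [[0.0] * len(frame.columns)], index=[ASYMPTOMATIC],
            columns=frame.columns)])
    matrix = TraitMatrix(frame, traits.trait_kinds)
    trees = ratchet_search(matrix, n_iterations=iterations,
                           reweight_fraction=reweight_fraction, seed=seed)
    consensus = majority_consensus(trees, threshold)
    return trees, consensus


def extract_clades(consensus: PhenoTree, min_families: int = 40,
                   outgroup: str = ASYMPTOMATIC) -> tuple[list[Clade], list[Clade]]:
    """Stage 2: nested clades (all, and those passing the family filter)."""
    clades = nest_tree(consensus, outgroup)
    return clades, filter_clades(clades, min_families)


def write_clades_tsv(path: str | Path, clades: Sequence[Clade]) -> None:
    with open(path, "w") as fh:
        fh.write("label\tlevel\tindex\tsize\tn_families\tmembers\n")
        for c in clades:
            fh.write(f"{c.label}\t{c.level}\t{c.index}\t{len(c)}\t"
                     f"{c.n_families}\t{','.join(sorted(c.members))}\n")


def read_clades_tsv(path: str | Path) -> list[Clade]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        out.append(Clade(row["label"], int(row["level"]), int(row["index"]),
                         frozenset(row["members"].split(","))))
    return out


def linkage_results_frame(results: Sequence[LinkageResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "clade": r.clade, "marker": r.marker, "model": r.model,
        "max_lod": r.max_lod, "theta_max": r.theta_max,
        "hlod": r.hlod, "alpha": r.alpha, "theta_hlod": r.theta_hlod,
        "n_families": r.n_families,
    } for r in results])


def _majority_category(clade: Clade, diagnoses: Mapping[str, str]) -> str | None:
    counts: dict[str, int] = {}
    for u in clade.members:
        d = diagnoses.get(u)
        if d is not None and d not in ("unknown",):
            counts[d] = counts.get(d, 0) + 1
    if not counts:
        return None
    return max(sorted(counts), key=lambda k: counts[k])


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write a report bundle to ``outdir``.

    Outputs: ``trees.nwk`` (all equally parsimonious trees), ``consensus.nwk``,
    ``clades.tsv``, ``symptoms.tsv``, ``linkage.tsv``, ``summary.tsv``
    (Table-style per-clade maxima with p_M/p_G), and ``manifest.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[tuple[str, float]] = []
    t0 = time.time()

    gmap = read_map(config.map)
    ped, genotypes = read_ped(config.ped, gmap)
    traits = read_traits(config.traits)
    if len(traits) == 0:
        raise FormatError(f"{config.traits}: empty trait matrix")
    diagnoses = read_diagnoses(config.diagnoses) if config.diagnoses else \
        {i.uid: i.diagnosis for i in ped.individuals if i.diagnosis}
    log.append(("load", time.time() - t0))

    t = time.time()
    trees, consensus = build_network(
        traits, config.ratchet_iterations, config.reweight_fraction,
        config.seed_network, config.consensus_threshold)
    with open(out / "trees.nwk", "w") as fh:
        for tr in trees.trees:
            fh.write(tr.to_newick() + "\n")
    with open(out / "consensus.nwk", "w") as fh:
        fh.write(consensus.to_newick() + "\n")
    log.append(("network", time.time() - t))

    t = time.time()
    all_clades, kept = extract_clades(consensus, config.min_families)
    write_clades_tsv(out / "clades.tsv", all_clades)
    write_clades_tsv(out / "clades_filtered.tsv", kept)
    log.append(("clades", time.time() - t))

    t = time.time()
    symptom_frames = []
    for clade in kept:
        profile = symptom_profile(clade, traits)
        cat = _majority_category(clade, diagnoses)
        if cat is None or not profile:
            continue
        members_cat = {u for u, d in diagnoses.items() if d == cat}
        df = clade_symptom_table(clade, traits, members_cat, profile,
                                 n_perm=config.n_permutations,
                                 seed=config.seed_permutations)
        df.insert(1, "category", cat)
        symptom_frames.append(df)
    symptoms = pd.concat(symptom_frames, ignore_index=True) if symptom_frames \
        else pd.DataFrame()
    symptoms.to_csv(out / "symptoms.tsv", sep="\t", index=False)
    sig = {(r["clade"], r["trait"]): bool(r["perm_p"] is not None
                                          and r["perm_p"] <= 0.05)
           for _, r in symptoms.iterrows()} if len(symptoms) else {}
    prevalence_matrix(kept, traits, sig).to_csv(out / "profile_matrix.tsv",
                                                sep="\t")
    log.append(("symptoms", time.time() - t))

    t = time.time()
    models = config.model_objects()
    observed = run_linkage(kept, ped, genotypes, gmap, models,
                           config.theta_grid, traits, config.markers)
    linkage_results_frame(observed).to_csv(out / "linkage.tsv", sep="\t",
                                           index=False, float_format="%.4f")
    log.append(("linkage", time.time() - t))

    t = time.time()
    p_m: dict[str, float] = {}
    p_g: dict[str, float] = {}
    if observed and config.n_replicates > 0:
        reps = make_replicates(ped, genotypes, config.n_replicates,
                               config.seed_replicates)
        rep_results = [run_linkage(kept, ped, rep, gmap, models,
                                   config.theta_grid, traits, config.markers)
                       for rep in reps]
        p_m, p_g = empirical_p(observed, rep_results)
    log.append(("pvalues", time.time() - t))

    rows = []
    for clade in kept:
        pool = [r for r in observed if r.clade == clade.label]
        if not pool:
            continue
        z, best = clade_max_statistic(pool)
        diag_counts: dict[str, int] = {}
        for u in clade.members:
            d = diagnoses.get(u, "unknown")
            diag_counts[d] = diag_counts.get(d, 0) + 1
        rows.append({
            "clade": clade.label, "n_individuals": len(clade),
            "n_families": clade.n_families,
            "z_max": round(z, 4), "alpha": round(best.alpha, 4),
            "theta": best.theta_hlod, "marker": best.marker,
            "model": best.model,
            "p_M": p_m.get(clade.label), "p_G": p_g.get(clade.label),
            "diagnoses": ";".join(f"{k}={v}" for k, v in sorted(diag_counts.items())),
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)

    manifest = {
        "config": asdict(config),
        "n_trees": len(trees.trees),
        "parsimony_score": trees.score,
        "n_clades": len(all_clades),
        "n_clades_analyzed": len(kept),
        "stage_seconds": {k: round(v, 2) for k, v in log},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {
        "trees": trees, "consensus": consensus, "clades": all_clades,
        "clades_analyzed": kept, "symptoms": symptoms, "linkage": observed,
        "p_M": p_m, "p_G": p_g, "summary": summary, "manifest": manifest,
    }
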