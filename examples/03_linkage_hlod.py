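"""Two-point LOD and heterogeneity HLOD from pedigree likelihoods.

First a textbook check: ten phase-known nonrecombinant meioses under a fully
penetrant dominant model give LOD = 10*log10(2) ~= 3.01 at theta = 0. Then a
clade-conditioned scan on a simulated study localizes the causal locus.
"""

import warnings

import numpy as np

from cladelink import DOM1, KPDConfig, simulate_kpd_study
from cladelink.linkage import (clade_max_statistic, family_lod_curve,
                               run_linkage)
from cladelink.pipeline import build_network, extract_clades
from cladelink.reference import phase_known_family

warnings.simplefilter("ignore")

ped, gt, statuses = phase_known_family(10)
curve = family_lod_curve(ped, "F", statuses, gt, "M1", DOM1)
print(f"closed-form check: LOD(theta=0) = {curve[0]:.4f} "
      f"(expected 10*log10 2 = {10 * np.log10(2):.4f})")

cfg = KPDConfig.scaled(30, seed=3)
ped, genotypes, traits, truth = simulate_kpd_study(cfg)
trees, cons = build_network(traits, iterations=15, seed=0)
_, kept = extract_clades(cons, min_families=12)
target = max(kept, key=lambda c: sum(truth.latent.get(u) == "P1"
                                     for u in c.members) / len(c))
results = run_linkage([target], ped, genotypes, genotypes.gmap, traits=traits)
z, best = clade_max_statistic(results)
mk = genotypes.gmap[best.marker]
print(f"\nclade {target.label} ({len(target)} members): "
      f"Z_max = {z:.2f} at {best.marker} under {best.model} "
      f"(alpha = {best.alpha:.2f}, theta = {best.theta_hlod:g})")
print(f"peak marker sits on chromosome {mk.chrom} at {mk.pos_cm:g} cM; "
      f"the generating loci were D1 at {truth.loci['D1']} and "
      f"D2 at {truth.loci['D2']}")
print("a peak within ~15 cM of either locus means the clade-conditioned "
      "scan localized the epistatic architecture behind phenotype P1")
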