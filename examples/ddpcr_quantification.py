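"""Poisson quantification of a droplet-digital PCR experiment.

Simulates the four-condition design (WT / mutant x uninjured /
regenerating) in which the target transcript is induced 4.3-fold by
regeneration in wild type but only 2.4-fold in the enhancer-deletion
mutant, quantifies each pooled sample with the Poisson estimator, and
reports reference-normalized ratios.
"""

import heartregen as hr
from heartregen.ddpcr import pool_wells, poisson_concentration, normalized_ratio

cfg = hr.SimulationConfig(seed=3)
wells, truth = hr.simulate_droplet_experiment(cfg)

groups, no_rt = {}, {}
for w in wells:
    key = (w.sample, w.target)
    if w.is_no_rt_control:
        no_rt[key] = w
    else:
        groups.setdefault(key, []).append(w)

quants = {}
for (sample, target), ws in sorted(groups.items()):
    pooled = pool_wells(ws)
    q = poisson_concentration(pooled, no_rt=no_rt.get((sample, target)))
    quants[(sample, target)] = q
    print(f"{sample:18s} {target:10s} lambda={q.lam:.4f} "
          f"{q.concentration:8.1f} copies/ul  QC={'pass' if q.qc.passed else q.qc.reasons}")

ratios = {
    s: normalized_ratio(quants[(s, "target")], quants[(s, "reference")])
    for s in ("WT_uninjured", "WT_regenerating", "MUT_uninjured", "MUT_regenerating")
}
wt_fold = ratios["WT_regenerating"] / ratios["WT_uninjured"]
mut_fold = ratios["MUT_regenerating"] / ratios["MUT_uninjured"]
print(f"\nregeneration induction (reference-normalized): "
      f"WT {wt_fold:.2f}-fold, mutant {mut_fold:.2f}-fold (planted 4.3 / 2.4)")
# lambda is mean template copies per droplet, estimated from the fraction
# of negative droplets; concentrations are dilution-corrected copies/ul.
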