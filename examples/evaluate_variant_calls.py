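"""Score an imperfect call set against simulated truth.

Uses the synthetic caller (10% dropouts, 30 false positives, VAF jitter) and
reports precision/recall/F1, the score-thresholded precision-recall curve,
and recall stratified by true VAF — low-VAF (deeply subclonal) variants are
the hard ones.
"""

import numpy as np

import clonebench as cb
from clonebench.eval_calls import (
    match_calls, pr_curve, precision_recall_f1, stratified_metrics,
)

rng = np.random.default_rng(7)
ref = cb.toy_reference(cb.FixtureSpec(seed=7))
tree = cb.parse_structure(cb.EIGHT_CLONE_STRUCTURE)
cfg = cb.SimulationConfig(snvgermline=0, indgermline=0, cnvrepgermline=0,
                          cnvdelgermline=0, cnvsomatic_rep=0, cnvsomatic_del=0,
                          aneuploid=0, wgdprob=0, dbsnpsnvproportion=0,
                          dbsnpindelproportion=0)
events = cb.simulate_somatic_events(cfg, tree, ref, rng)
profiles = cb.build_clone_profiles(tree, [], events, ref, rng)
comp = cb.BulkComposition.from_weights({c: 1.0 for c in tree.clones}, purity=1.0)
_, truth = cb.compose_bulk(profiles, tree, comp, 100, rng)

spec = cb.FixtureSpec(fn_rate=0.1, fp_count=30, vaf_noise=0.02)
calls, labels = cb.perturbed_callset(truth, spec, rng, reference=ref)

match = match_calls(truth, calls)
prf = precision_recall_f1(match)
print(f"calls: {len(calls)}  TP={len(match.tp)} FP={len(match.fp)} FN={len(match.fn)}")
print(f"precision={prf.precision:.3f} recall={prf.recall:.3f} f1={prf.f1:.3f}")
print()
print("precision-recall curve (per score threshold):")
print(pr_curve(match).head(5).to_string(index=False))
print()
print("recall by true VAF bin (subclonal variants are hardest):")
print(stratified_metrics(match, [0, 0.1, 0.25, 0.5, 1.0]).to_string(index=False))
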