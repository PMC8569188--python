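"""Compare a copy-number caller's output against simulated truth.

Simulates a whole-genome-duplicated tumour with focal somatic CNVs, bins the
true per-clone profiles (plus the tumour-proportion-weighted bulk track) on
a 1 kb grid, and scores a deliberately imperfect "caller" that reports a
flat diploid genome: its ploidy lands in the "halved" class (a missed WGD)
and the binned mean absolute error quantifies what it misses.
"""

import numpy as np
import pandas as pd

import clonebench as cb
from clonebench.eval_cna import bin_copy_numbers, copy_number_agreement, ploidy_class, purity_error
from clonebench.genome_sim import WGDEvent
from clonebench.io_formats import SegmentProfile

rng = np.random.default_rng(3)
ref = cb.toy_reference(cb.FixtureSpec(seed=3))
tree = cb.parse_structure("A,1,germline,B,1,A")
cfg = cb.SimulationConfig(snvgermline=0, indgermline=0, snvsomatic_total=100,
                          indsomatic_total=0, cnvsomatic_rep=2, cnvsomatic_del=2,
                          cnvsomaticmultiply=3e3,  # focal CNVs on the toy contigs
                          cnvrepgermline=0, cnvdelgermline=0, aneuploid=0,
                          wgdprob=0, dbsnpsnvproportion=0, dbsnpindelproportion=0)
events = cb.simulate_somatic_events(cfg, tree, ref, rng)
events["A"].append(WGDEvent(clone="A", time=0.9))  # clonal WGD
profiles = cb.build_clone_profiles(tree, [], events, ref, rng)

comp = cb.BulkComposition.from_weights({"A": 1, "B": 1}, purity=1.0)
true_matrix = bin_copy_numbers({c: profiles[c] for c in tree.clones},
                               ref.lengths, bin_width=1000, composition=comp)

# a lazy "caller": whole genome diploid, purity slightly off
pred = SegmentProfile(
    segments=pd.DataFrame([(c, 0, L, 2, 1, 1, 1.0) for c, L in ref.lengths.items()],
                          columns=["chrom", "start", "end", "total_cn",
                                   "major_cn", "minor_cn", "cellular_fraction"]),
    purity=0.95, ploidy=2.0)
pred_matrix = bin_copy_numbers(pred, ref.lengths, bin_width=1000)

true_ploidy = sum(comp.tumour_proportions[c] * profiles[c].ploidy()
                  for c in tree.clones)
agree = copy_number_agreement(pred_matrix, true_matrix, "pred", "bulk")
print(f"true bulk ploidy {true_ploidy:.2f}, predicted {pred.ploidy:.2f} "
      f"-> class: {ploidy_class(pred.ploidy, true_ploidy)}")
print(f"purity error: {purity_error(pred.purity, comp.purity):.3f}")
print(f"binned agreement: MAE(total)={agree.mae_total:.3f} "
      f"MAE(minor)={agree.mae_minor:.3f} exact bins={agree.exact_fraction:.2%}")
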