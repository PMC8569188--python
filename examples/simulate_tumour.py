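"""Simulate a clonal tumour and compose a bulk sample with ground truth.

Builds a toy reference, parses the default eight-clone architecture,
simulates germline + somatic events, propagates them into per-clone genome
profiles and mixes a 75%-purity bulk sample at 100x.  Prints the truth-table
head: each row is one somatic variant with its origin clone, true cancer
cell fraction (CCF), expected bulk VAF, and mutated/total copy numbers.
"""

import numpy as np

import clonebench as cb

rng = np.random.default_rng(7)

ref = cb.toy_reference(cb.FixtureSpec(n_contigs=2, contig_length=100_000, seed=7))
known = cb.toy_known_sites(ref, density=0.002, seed=8)
tree = cb.parse_structure(cb.EIGHT_CLONE_STRUCTURE)
cfg = cb.SimulationConfig(cnvrepgermline=20, cnvdelgermline=50)  # toy-scale germline CNVs

germline = cb.simulate_germline_variants(cfg, ref, known, rng)
germline_cnas = cb.simulate_germline_cnas(cfg, ref, rng)
events = cb.simulate_somatic_events(cfg, tree, ref, rng)
profiles = cb.build_clone_profiles(tree, germline, events, ref, rng, germline_cnas)

comp = cb.BulkComposition.from_weights({c: 1.0 for c in tree.clones}, purity=0.75)
sample, truth = cb.compose_bulk(profiles, tree, comp, target_depth=100, rng=rng)

print(f"simulated {len(germline)} germline variants, "
      f"{len(truth)} somatic truth variants")
print(f"purity {comp.purity:.2f}, clone1 ploidy {profiles['clone1'].ploidy():.2f}")
print()
print(truth.head(8).to_string(index=False))
print()
print("observations (sampled depths and alt counts):")
print(sample.observations.head(4).to_string(index=False))
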