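"""Forward simulation of selection on standing variation.

Runs the split model at Ne = 65 for 5 generations: first drift-only (the
validation mode, whose replicate-mean theta should sit near
t/(2 Ne) = 0.0385), then with directional selection (fitnesses 1 / 0.7 /
0.4 favouring the minor allele) at one locus with a completely linked
flanking marker, and prints box-plot summaries of the per-locus theta
across 25 replicates — the shape of the classic hitchhiking footprint.
"""

import numpy as np

from hitchmap import (
    SimConfig,
    founder_sample_linked,
    replicate_boxplot_stats,
    run_split_experiment,
)

# drift-only validation at 100 unlinked loci
rng = np.random.default_rng(1)
L = 100
mafs = rng.uniform(0.05, 0.5, L)
cfg = SimConfig(ne=65, t_split=5, loci=[f"L{j}" for j in range(L)],
                positions_cM=np.zeros(L), linkage_groups=np.arange(L),
                burnin=0, sample_size=16, n_replicates=100, seed=2)
reps = run_split_experiment(cfg, ancestral_freqs=[np.array([1 - m, m]) for m in mafs])
mean_theta = np.nanmean([r.multilocus_theta for r in reps])
print(f"drift-only replicate-mean multilocus theta = {mean_theta:.4f} "
      f"(expectation t/(2Ne) = {5 / 130:.4f})")

# selection with a tightly linked and a distant flank
loci = ["sel", "flank0", "flank33"]
pos = np.array([10.0, 10.0, 43.6])
thetas = {l: [] for l in loci}
for k in range(25):
    src = founder_sample_linked(np.full(3, 0.25), 16, 0,
                                np.array([0.0, 1.0, 0.0]),
                                np.random.default_rng(50 + k))
    scfg = SimConfig(ne=65, t_split=5, loci=loci, positions_cM=pos,
                     selected_locus="sel", s=0.6, h=0.5, burnin=3,
                     sample_size=16, n_replicates=1, seed=500 + k)
    rep = run_split_experiment(scfg, source_calls=src)[0]
    for l in loci:
        thetas[l].append(rep.per_locus_theta[l])

print("\nper-locus theta across 25 selection replicates (box-plot stats):")
for l in loci:
    st = replicate_boxplot_stats(np.array(thetas[l]))
    print(f"  {l:8s} median {st['median']:.3f}  IQR [{st['q1']:.3f}, {st['q3']:.3f}]")
print("the 0-cM flank hitchhikes with the selected locus; 33.6 cM away the")
print("footprint is gone within 5 generations of recombination.")
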