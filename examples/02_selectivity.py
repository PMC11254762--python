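"""Find semantically selective neurons and quantify their tuning.

Simulates a session (133 units, ~15% tuned to a preferred domain), aligns
spikes to each word in a 100-500 ms window, tests every unit against every
domain (rank-sum, BH-FDR), and reports the selectivity index
SI = |FR_domain - FR_other| / (FR_domain + FR_other).
"""

import numpy as np

import neurosem as ns

session = ns.generate_session(ns.GeneratorConfig(seed=1))
matrix = ns.align_responses(session.spikes, session.events, window=(0.1, 0.5))
sentences = ns.select_events(matrix, conditions="sentence")

result = ns.domain_selectivity(sentences, session.partition, alpha=0.05)
selective = result.selective_units()
planted = set(session.spikes.selective_units())
sis = [result.units[u].si for u in selective if np.isfinite(result.units[u].si)]
print(f"{len(selective)}/{matrix.n_units} units selective "
      f"({100 * len(selective) / matrix.n_units:.0f}%); "
      f"{len(set(selective) & planted)}/{len(planted)} planted units recovered")
print(f"mean SI of selective units: {np.mean(sis):.2f} "
      f"(0 = untuned, 1 = responds to a single domain only)")

u = sorted(set(selective) & planted)[0]
dist, cross = ns.bootstrap_si(sentences, session.partition, u, n_iter=30, seed=2)
print(f"unit {u}: SI {result.units[u].si:.2f}, bootstrap mean over 60% "
      f"sentence subsamples {dist.mean():.2f} (stability check)")

curve = ns.specificity_curve(sentences, session.partition, session.table,
                             units=selective, n_boot=200)
print("meaning specificity (keeping only centroid-nearest words per domain):")
for row in curve.itertuples(index=False):
    print(f"  top {100 * row.fraction:.0f}% of words -> mean SI {row.mean_si:.2f}")

nonword = ns.word_nonword_test(matrix, alpha=0.05)
print(f"{int(nonword['discriminating'].sum())}/{matrix.n_units} units "
      f"distinguish words from nonwords (Welch t-test)")
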