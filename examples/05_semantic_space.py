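"""The neuronal-semantic space and its hierarchy.

Regresses each unit's z-scored per-word response onto the word's embedding
vector (ridge, lambda = 1e-4), PCA-reduces the stacked weights along the
neuronal dimension, and asks how much of the embedding geometry — pairwise
distances and the single-linkage cophenetic hierarchy — the population
response carries.
"""

import neurosem as ns

session = ns.generate_session(ns.GeneratorConfig(seed=2, geometry_mode=True))
matrix = ns.align_responses(session.spikes, session.events)
sentences = ns.select_events(matrix, conditions="sentence")
selective = ns.domain_selectivity(sentences, session.partition).selective_units()
msel = ns.select_events(matrix.subset_units(selective), conditions="sentence")

theta, words = ns.fit_embedding_regression(msel.zscore(), session.table)
space = ns.pca_space(theta, session.table, n_pc=5, words=words)
print(f"regression weights: {theta.shape[0]} units x {theta.shape[1]} dims; "
      f"first 5 PCs explain {100 * space.explained_variance.sum():.0f}% "
      f"of weight variance")

r, p = ns.distance_correlation(space, session.table, n_perm=100, seed=2)
print(f"projection-space vs embedding-space pair distances: r = {r:.3f} "
      f"(p = {p:.3g})")

rdc = ns.rate_distance_correlation(msel, session.table, n_perm=200, seed=2)
print(f"|delta population rate| vs embedding distance ({rdc['n_pairs']} word "
      f"pairs, 100 bins): r = {rdc['r']:.2f} (one-sided p = {rdc['p']:.3g}) — "
      f"similar words evoke similar activity")

coph = ns.cophenetic_hierarchy(session.table, msel)
print(f"cophenetic (merge-height) distance vs |delta rate|: r = {coph['r']:.2f}"
      f" — the population tracks the hierarchy, not just proximity")

newick = ns.dendrogram_to_newick(coph["linkage"], coph["words"])
print(f"dendrogram exported as Newick ({len(newick)} chars), e.g. "
      f"{newick[:60]}...")
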