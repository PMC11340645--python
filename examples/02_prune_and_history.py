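"""Prune a tree by size and split distance, with a replayable history.

Generates a random 12-leaf tree, inspects the split-distance
distribution to pick a cutoff, applies distance then size pruning as a
recorded history, and shows that replaying the history reproduces the
same tree. The printed node counts shrink monotonically: pruning only
ever merges populations.
"""

import celltree as ct

tree = ct.simulate_random_tree(n_leaves=12, cells_per_leaf=8, seed=4)
print(f"original tree: {tree.n_nodes()} nodes, {tree.root.n_cells()} cells")

dist = ct.distance_distribution(tree)
print("top split distances:", [f"{d:.3f}" for _, d in dist[:4]])

history = ct.PruneHistory([
    ct.PruneStep(ct.PruneKind.MIN_DISTANCE_SEARCH, 0.3),
    ct.PruneStep(ct.PruneKind.MIN_CELLS, 16),
])
pruned = ct.apply_history(tree, history)
print(f"after distance<0.3 and min-16-cell pruning: {pruned.n_nodes()} nodes")

replayed = ct.apply_history(tree, history)
same = [n.node_id for n in pruned.nodes()] == [n.node_id for n in replayed.nodes()]
print(f"replaying the breadcrumb history reproduces the tree: {same}")

stats = ct.node_statistics(pruned, pruned.root.node_id)
print(f"root tooltip record: {stats}")
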