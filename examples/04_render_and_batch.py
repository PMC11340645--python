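"""Render radial figures, then batch-render several features at once.

Builds a labeled tree, draws it as an SVG pie-glyph figure plus a PNG,
and uses the batch runner to emit one overlay figure per marker feature
after a single store import — the tree is parsed once and the source
matrix never reopened.
"""

import tempfile
from pathlib import Path

import celltree as ct

matrix, true_labels = ct.simulate_block_counts(ct.BlockSpec(seed=1))
normalized = ct.tfidf_normalize(ct.filter_matrix(matrix))
tree = ct.build_tree(normalized)
labels = ct.LabelMap(true_labels)

config = ct.RenderConfig(width_px=500, height_px=500)
layout = ct.radial_layout(tree, config.scale_by_distance)
doc = ct.render_svg(tree, layout, config, labels=labels)

out = Path(tempfile.mkdtemp())
doc.save(out / "tree.svg")
(out / "tree.png").write_bytes(ct.render_png(doc, 500))
print(f"wrote {out / 'tree.svg'} ({len(doc.xml)} bytes of SVG)")

ct.write_tree_json(tree, out / "tree.json")
ct.build_feature_store(matrix, out / "store")
written = ct.run_batch(ct.BatchJob(
    tree_path=out / "tree.json", store_path=out / "store",
    out_dir=out / "figures",
    feature_list=["feat_0000", "feat_0025", "feat_0050", "feat_0100", "feat_0499"],
    base_config=config))
print(f"batch rendered {len(written)} figures after one import:")
for path in written:
    print(f"  {path.name}")
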