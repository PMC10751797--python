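# pathstrings

Cluster molecular transition pathways into distinct mechanistic classes.
Each successful source→target pathway is encoded as a string of visited
state ids, pathway pairs are scored with a length-corrected Gestalt
(longest-common-subsequence) similarity, and the resulting distance
matrix (d = 1 − similarity) is clustered with Ward-linkage hierarchical
agglomeration. Class probabilities, event-duration distributions, and
directed state-transition networks summarize each pathway class.

The workflow has three stages plus a fixture generator:

1. **discretize** — assign every trajectory frame a state label, via a
   rectilinear bin/point map, a user hook, or a two-stage
   cluster-then-classify scheme (average-linkage agglomerative
   clustering of a subset, then a k-nearest-neighbors classifier for
   the remainder).
2. **extract** — find every successful source→target transition (last
   source exit to first target entry) in flat label series or
   weighted-ensemble trajectory trees, and emit weighted pathway
   strings.
3. **match** — condense repeated state patterns, score all pairs,
   cluster with Ward linkage, and cut the dendrogram at the largest
   merge-height gap (overridable) to define pathway classes.

## CLI

```bash
# generate a seeded synthetic fixture set (label series, WE tree, blobs)
pathstrings synthesize --out-dir work --seed 0

# assign states (choose one mode)
pathstrings discretize --features work/blob_features.npy \
    --two-stage two_stage.toml --output work/labels.npy
pathstrings discretize --features feats.npy --rectilinear states.toml \
    --stride 10 --output work/labels.npy
pathstrings discretize --features feats.npy \
    --assign-function mymodule:my_hook --output work/labels.npy

# extract successful pathways (flat series or WE tree)
pathstrings extract --labels work/cmd_labels.npy --source 0 --target 5 \
    --stride 1 --exclude-length 10 --output-dir work/extracted
pathstrings extract --tree work/tree.csv --source 0 --target 5 \
    --output-dir work/extracted

# score, cluster, classify
pathstrings match --pathways work/extracted/pathways.json \
    --condense 2 --match-metric gestalt --output-dir work/matched
```

`--match-metric` accepts `gestalt` (corrected LCS score, default),
`gestalt-uncorrected`, `gestalt-blocks` (Ratcliff–Obershelp matching
blocks), or any `module:function` returning a similarity in [0, 1].
`--cut-height` / `--n-classes` override the automatic max-gap cut.
Every stage writes a JSON run report (counts, warnings, parameters)
beside its outputs; a full pipeline is also available programmatically
via `pathstrings.cli.run_pipeline(RunConfig(...))`, resumable per stage.

Rectilinear state maps are TOML files:

```toml
source = 0
target = 1
bin_edges = [[0.0, 1.0, 2.0, 3.0]]
periodic_shift = [[360.0, -210.0]]   # optional per-dimension remap

[state_points]
0 = [0.5]
1 = [1.5]
```

## File formats

All interchange is plain text or NPY: label arrays as NPY/CSV,
trajectory trees as CSV (`iteration, seg_id, parent_id, weight,
frame_0..frame_{tau-1}`) or flat HDF5, pathways as JSON records plus
one-string-per-line text with a documented 94-character printable
display alphabet, distance matrices as NPY/CSV, linkage tables and
class/edge tables as CSV.
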