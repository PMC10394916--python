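# rlcomplex

Seed-and-extend detection of protein complexes (communities) in weighted
protein–protein interaction networks, driven by tabular value iteration.

The agent's state is the weighted density of the current subgraph,
`2m / (n(n-1))`, discretized into 20 bins on [0, 1]. Training replays
growth episodes over known complexes: starting from a seed edge (a node
plus its heaviest in-complex neighbor), every neighbor of the subgraph is
scored as an action (+0.2 for a complex member, −0.2 otherwise, 0 for the
terminal "stop" action), the current bin is overwritten with the
max-over-actions Bellman value (discount 0.5), and the argmax neighbor is
added. Prediction reuses the learned table with lookups only, growing one
candidate per seed edge in parallel, continuing while the best neighbor
does not lower the subgraph's value. Candidates are deduplicated, merged
with a two-sided (Qi) overlap criterion whose threshold is picked by a
matching-F-score sweep, and scored against gold standards with a full
metric suite (matching-based F-score, community-wise F-score, SPA/UnSPA,
Qi et al. F1, k-clique F-scores).

## Command line

All stages are subcommands of a single entry point:

```bash
# generate a toy-scale planted network (14 disjoint complexes,
# 62 nodes / 78 edges, 7/7 train-test split)
rlcomplex simulate --preset fig5 --seed 1 --out-prefix toy

# learn a value table from the training complexes
rlcomplex train --network toy_network.tsv --complexes toy_complexes.txt \
    --out value_table.json --seed 1

# grow candidates, pick the merge threshold, merge, evaluate
rlcomplex predict --network toy_network.tsv --value-table value_table.json \
    --out predictions.txt --workers 4
rlcomplex sweep --predictions predictions.txt --known toy_complexes.txt \
    --value-table value_table.json --network toy_network.tsv \
    --grid 0.2:0.9:0.025 --out sweep.tsv
rlcomplex merge --predictions predictions.txt --value-table value_table.json \
    --network toy_network.tsv --threshold 0.325 --out merged.txt
rlcomplex evaluate --predictions merged.txt --known toy_complexes.txt \
    --out report.tsv

# or everything at once, including diagnostics and a re-run manifest
rlcomplex run --preset fig5 --seed 1 --out-dir runs/toy
```

`rlcomplex run --value-table TABLE ...` skips training and reuses a
previously learned table on a new network (transfer mode).

### File formats

* **Network** — 3-column edge list `node node weight`, whitespace or tab
  separated, `#` comments allowed; weights in (0, 1]. Duplicate pairs
  keep the maximum weight; self-loops are dropped with a warning.
* **Complexes** — one complex per line, members whitespace-separated.
* **Value table** — versioned JSON (bins, values, discount, rewards);
  round-trips bit-exactly for transfer learning.
* **Predictions** — one candidate per line: members, then a final column
  with the candidate's value score.

## Layout

| module | role |
| --- | --- |
| `rlcomplex.network_io` | file formats, gold-standard preprocessing (size/connectivity filters, 0.6-Jaccard merge), value-table persistence |
| `rlcomplex.state_value` | density state, 20-bin discretization, Bellman update |
| `rlcomplex.training` | episode replay and epoch-level convergence |
| `rlcomplex.prediction` | value-walk candidate growth, parallel over seeds |
| `rlcomplex.postprocess` | Qi-overlap merging and the threshold sweep |
| `rlcomplex.evaluation` | the full metric suite plus node filtering |
| `rlcomplex.synthetic` | planted-complex generator, toy presets, golden fixtures |
| `rlcomplex.pipeline` / `rlcomplex.cli` | orchestration, manifests, diagnostics |
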