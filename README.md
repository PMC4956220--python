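# locshift

Unsupervised detection of protein subcellular-localization changes between
paired high-throughput imaging screens.

Proteome-wide GFP-collection screens image thousands of tagged proteins under
a wild-type and a perturbed condition. Finding the proteins whose subcellular
localization actually changed is the bottleneck: raw feature differences
between screens are dominated by *global effects* — systematic shifts from
imaging conditions or cell-morphology changes that hit whole localization
classes at once without reflecting any real relocalization. `locshift`
implements a simple, fast k-nearest-neighbour method that corrects for these
effects locally in feature space, for screening groups who want a ranked hit
list without curating training sets for supervised classifiers.

## Method

Each gene is summarized per screen as a 60-feature profile: its segmented
cells are split by type (bud / mother) and five cell-size bins (a cell-cycle
proxy), and six per-cell features — GFP intensity (INT) and five spread
measures (SEF, MCT, EDG, CEN, NEC: average distance between proteins, to the
protein mass centre, to the cell periphery, to the cell centre, and to the
bud neck) — are aggregated (mean, truncated mean, or median) within each of
the ten (type, bin) cells. Genes with fewer than 5 cells in any bin of either
screen are dropped; intensity features are divided by 100 and localization
features multiplied by 10 to equalize ranges.

For gene *a* the change vector is `x_a = a_wt − a_pert`. The *k* = 50 nearest
neighbours of *a* in wild-type profile space (Euclidean distance) are mostly
static genes, so their change vectors capture the local global effect. Each
feature of `x_a` is scored against the neighbours' change vectors with the
modified z-score

    M_i = 0.6745 (x_i − x̃_i) / MAD_i

where `x̃_i` and `MAD_i` are the median and median absolute deviation over the
neighbours. Genes are ranked by descending RMS of `M` over the 50
localization features (intensity excluded). The signed `M` vector itself
indicates the direction and magnitude of each feature's change, which makes
hits interpretable. A naive baseline (column-standardized change vectors,
same RMS ranking) and recall-vs-fraction-retrieved evaluation curves are
included, along with a synthetic screen generator with ground truth.

## Worked example

```python
from locshift import (SyntheticConfig, generate_screens, build_profiles,
                      rank_genes, change_matrix, naive_rank, recall_curve, recall_at)

cfg = SyntheticConfig(n_genes=300, n_clusters=6, seed=42)
screens = generate_screens(cfg)
wt, pert = build_profiles(screens.wt_cells, screens.pert_cells, spec=screens.bin_spec)

results = rank_genes(wt, pert, k=50)
known = set(screens.changed_genes)
curve = recall_curve([r.gene_id for r in results], known, method_label="kNN")
naive = naive_rank(change_matrix(wt, pert))
naive_curve = recall_curve(list(naive["gene_id"]), known, method_label="naive")

print(f"genes profiled: {len(wt.gene_ids)}, injected changes: {len(known)}")
for r in results[:5]:
    flag = "*" if r.gene_id in known else " "
    print(f"  rank {r.rank:2d}  {r.gene_id}{flag}  RMS = {r.rms:.2f}")
print(f"kNN recall in top 10%:   {recall_at(curve, 0.10):.2f}")
print(f"naive recall in top 10%: {recall_at(naive_curve, 0.10):.2f}")
```

Output:

```
genes profiled: 300, injected changes: 15
  rank  1  gene0218*  RMS = 2.71
  rank  2  gene0275*  RMS = 2.57
  rank  3  gene0053*  RMS = 2.55
  rank  4  gene0197*  RMS = 2.45
  rank  5  gene0290*  RMS = 2.40
kNN recall in top 10%:   0.87
naive recall in top 10%: 0.20
```

All five top hits are genuinely changed genes (`*`), and the kNN ranking
recovers 87% of the injected changes within the top decile where the naive
change-vector ranking — confused by cluster-specific global shifts — finds
only 20%.

The same workflow is available from the shell:

```sh
locshift simulate --seed 42 --out-dir sim/
locshift profile --wt-cells sim/wt_cells.tsv --pert-cells sim/pert_cells.tsv \
    --config sim/bin_spec.yaml --out-wt wt.tsv --out-pert pert.tsv
locshift detect --wt wt.tsv --pert pert.tsv --k 50 --out ranking.tsv
locshift baseline --wt wt.tsv --pert pert.tsv --out naive.tsv
locshift evaluate --ranking ranking.tsv --known known.txt --out curve.tsv
locshift heatmap --matrix wt.tsv --threshold 2.0 --out wt.cdt
```

`detect --k-sweep 10,25,50,100,200` writes one ranking per k; `heatmap`
exports Java TreeView CDT files (with a TSV mirror) for visual inspection of
profile, change and z-score matrices.

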