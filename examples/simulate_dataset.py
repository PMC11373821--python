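"""Generate a planted-motif benchmark and write it as labeled FASTA.

Positives carry the 8-mer TGACGTCA (in 90% of cases, uniform position) on
a uniform background; negatives are pure background.  This mirrors the
structure of CLIP-derived binding-site benchmarks: fixed-length fragments,
balanced classes, signal carried by a short degenerate motif.
"""

from icrbp import SplitSpec, SyntheticSpec, generate_dataset, split_train_test, write_fasta

spec = SyntheticSpec(n_per_class=200, length=101, motif="TGACGTCA",
                     motif_prob=0.9, seed=42)
ds = generate_dataset(spec)
print(f"dataset: {len(ds)} fragments, {sum(ds.labels)} positives")

train, test = split_train_test(ds, SplitSpec(test_fraction=0.2, seed=42))
print(f"stratified split: {len(train)} train / {len(test)} test "
      f"({sum(train.labels)} / {sum(test.labels)} positives)")

write_fasta(ds, "scratch_demo.fa")
print("wrote scratch_demo.fa  (headers carry 'label=0|1' tokens)")
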