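"""Encode one fragment with the five schemes and inspect the matrices.

Builds a short fragment, trains a toy k-mer embedding on a small synthetic
corpus, and prints the shape and first row of each feature matrix.  The
five matrices are position-aligned: row i of every matrix describes
position i of the fragment.
"""

from icrbp import EncodingConfig, SyntheticSpec, encode_all, generate_dataset, train_doc2vec
from icrbp.sequence_io import NucleotideSequence

corpus = generate_dataset(SyntheticSpec(n_per_class=50, length=40, seed=0)).sequences
cfg = EncodingConfig(doc2vec_dim=8, doc2vec_epochs=3, doc2vec_min_count=2, seed=0)
embedding = train_doc2vec(corpus, cfg)
print(f"embedding vocabulary: {len(embedding.vocabulary)} recurring 10-mers")

frag = NucleotideSequence("demo", "TACCGAATACCGAATACCGA")
bundle = encode_all(frag, embedding, cfg)
for m in bundle.matrices:
    print(f"{m.scheme:8s} shape {m.values.shape}  row0 {m.values[0].round(4)}")
print(f"concatenated feature matrix: {bundle.as_array().shape}")
# EIIP row0 is the per-base free-electron energy of T (0.1335); CCN row0 is
# T's (ring, chemical, hydrogen) code (0,0,1); ANF row0 is always 1.
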