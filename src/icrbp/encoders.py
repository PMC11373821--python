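"""Five position-aligned feature encodings for nucleotide fragments.

Every scheme maps a standardized fragment of length L to an (L x channels)
matrix, so the five matrices stay aligned position by position and can be
consumed by per-scheme 1D convolutions downstream:

* KNF  — k-nucleotide frequency: channel c holds, at position i, the
  frequency (among the L-k+1 k-mers of the fragment) of the k-mer starting
  at i, for each k in ``k_values`` (default 1, 2, 3).
* Doc2Vec-style embedding — each overlapping 10-mer token carries a learned
  distributed vector; position i holds the vector of the token starting at i.
  The embedding is trained on the corpus with a skip-gram
  negative-sampling objective (implemented in numpy, deterministic per seed).
* EIIP — electron-ion interaction pseudopotential, one scalar per base
  (A 0.1260, T 0.1335, G 0.0806, C 0.1340) modelling free-electron energy.
* CCN  — chemical characteristics of the nucleotide: three binary channels
  for ring structure (A/G), chemical function (A/C) and hydrogen bonding
  (A/T).
* ANF  — accumulated nucleotide frequency: the density d_i of the base at
  position i within the prefix s_1..s_i, i.e. d_i = #{j <= i : s_j = s_i}/i.

N (ambiguous base) policy: zero contribution in KNF/EIIP/CCN and the
embedding; counted as a fifth symbol in ANF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .sequence_io import NucleotideSequence, SequenceError

SCHEME_ORDER = ("KNF", "DOC2VEC", "EIIP", "CCN", "ANF")

EIIP_VALUES = {"A": 0.1260, "T": 0.1335, "G": 0.0806, "C": 0.1340, "N": 0.0}

# (ring structure, chemical function, hydrogen bond)
CCN_CODES = {
    "A": (1, 1, 1),
    "C": (0, 1, 0),
    "G": (1, 0, 0),
    "T": (0, 0, 1),
    "N": (0, 0, 0),
}


@dataclass(frozen=True)
class EncodingConfig:
    """Hyperparameters of the encoding stage."""

    k_values: tuple[int, ...] = (1, 2, 3)
    doc2vec_dim: int = 100
    doc2vec_kmer: int = 10
    doc2vec_epochs: int = 20
    doc2vec_window: int = 5
    doc2vec_min_count: int = 5
    doc2vec_negative: int = 5
    seed: int = 0

    def __post_init__(self):
        if not self.k_values or any(k < 1 for k in self.k_values):
            raise ValueError("k_values must be positive")
        for name in ("doc2vec_dim", "doc2vec_kmer", "doc2vec_epochs",
                     "doc2vec_window", "doc2vec_min_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def small(cls, seed: int = 0) -> "EncodingConfig":
        """Reduced embedding size for CPU-scale experiments."""
        return cls(doc2vec_dim=16, doc2vec_epochs=5, seed=seed)

    def scheme_channels(self) -> dict[str, int]:
        return {
            "KNF": len(self.k_values),
            "DOC2VEC": self.doc2vec_dim,
            "EIIP": 1,
            "CCN": 3,
            "ANF": 1,
        }


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-position numeric channels for one encoding scheme."""

    scheme: str
    values: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self):
        if self.scheme not in SCHEME_ORDER:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channel_names):
            raise ValueError("values must be (length x channels)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.scheme}: non-finite feature values")


@dataclass(frozen=True)
class FeatureBundle:
    """The five matrices of one fragment, in the fixed scheme order."""

    matrices: tuple[FeatureMatrix, ...]

    def __post_init__(self):
        schemes = tuple(m.scheme for m in self.matrices)
        if schemes != SCHEME_ORDER:
            raise ValueError(f"expected schemes {SCHEME_ORDER}, got {schemes}")
        rows = {m.values.shape[0] for m in self.matrices}
        if len(rows) != 1:
            raise ValueError(f"row counts differ across schemes: {rows}")

    @property
    def length(self) -> int:
        return self.matrices[0].values.shape[0]

    def as_array(self) -> np.ndarray:
        """Concatenate the five matrices channel-wise: (L x total_channels)."""
        return np.concatenate([m.values for m in self.matrices], axis=1)


def encode_knf(seq: NucleotideSequence, k_values=(1, 2, 3)) -> FeatureMatrix:
    """Positional k-mer frequencies, one channel per k.

    Positions with no k-mer starting there (the last k-1) hold 0, as do
    k-mers containing N, which are also excluded from the counts.  The
    denominator is always L-k+1, the number of k-mer slots.
    """
    r = seq.residues
    L = len(r)
    out = np.zeros((L, len(k_values)))
    for c, k in enumerate(k_values):
        if k > L:
            raise SequenceError(f"k={k} exceeds sequence length {L}")
        n_slots = L - k + 1
        kmers = [r[i : i + k] for i in range(n_slots)]
        counts: dict[str, int] = {}
        for km in kmers:
            if "N" not in km:
                counts[km] = counts.get(km, 0) + 1
        for i, km in enumerate(kmers):
            out[i, c] = counts.get(km, 0) / n_slots
    names = tuple(f"knf_k{k}" for k in k_values)
    return FeatureMatrix("KNF", out, names)


def encode_eiip(seq: NucleotideSequence) -> FeatureMatrix:
    vals = np.array([[EIIP_VALUES[ch]] for ch in seq.residues])
    return FeatureMatrix("EIIP", vals, ("eiip",))


def encode_ccn(seq: NucleotideSequence) -> FeatureMatrix:
    vals = np.array([CCN_CODES[ch] for ch in seq.residues], dtype=float)
    return FeatureMatrix("CCN", vals, ("ring", "chemical", "hydrogen"))


def encode_anf(seq: NucleotideSequence) -> FeatureMatrix:
    """Prefix-relative density of the base at each position (one channel)."""
    r = seq.residues
    counts: dict[str, int] = {}
    out = np.empty((len(r), 1))
    for i, ch in enumerate(r):
        counts[ch] = counts.get(ch, 0) + 1
        out[i, 0] = counts[ch] / (i + 1)
    return FeatureMatrix("ANF", out, ("anf",))


# ---------------------------------------------------------------------------
# k-mer embedding (Doc2Vec-style distributed vectors for 10-mer tokens)
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingModel:
    """Trained k-mer vectors plus the config they were trained under."""

    vocabulary: dict[str, np.ndarray]
    dim: int
    training_config: EncodingConfig

    def __post_init__(self):
        for km, v in self.vocabulary.items():
            if v.shape != (self.dim,) or not np.all(np.isfinite(v)):
                raise ValueError(f"vector for {km!r} is not a finite {self.dim}-vector")

    def save(self, path) -> None:
        path = Path(path)
        kmers = sorted(self.vocabulary)
        mat = np.stack([self.vocabulary[k] for k in kmers]) if kmers else np.zeros((0, self.dim))
        np.savez_compressed(
            path,
            kmers=np.array(kmers),
            vectors=mat,
            config=json.dumps(asdict(self.training_config)),
        )

    @classmethod
    def load(cls, path) -> "EmbeddingModel":
        with np.load(path, allow_pickle=False) as z:
            cfg_d = json.loads(str(z["config"]))
            cfg_d["k_values"] = tuple(cfg_d["k_values"])
            cfg = EncodingConfig(**cfg_d)
            vocab = {str(k): v for k, v in zip(z["kmers"], z["vectors"])}
        return cls(vocab, cfg.doc2vec_dim, cfg)


def _tokenize(seq: NucleotideSequence, k: int) -> list[str]:
    if seq.length < k:
        raise SequenceError(
            f"sequence {seq.id!r} (length {seq.length}) is shorter than the "
            f"{k}-mer token size"
        )
    return [seq.residues[i : i + k] for i in range(seq.length - k + 1)]


def train_doc2vec(corpus: list[NucleotideSequence], cfg: EncodingConfig) -> EmbeddingModel:
    """Train distributed 10-mer vectors on the corpus.

    Tokens are the overlapping ``doc2vec_kmer``-mers of every sequence
    (stride 1); tokens containing N are excluded.  Vectors are fit with a
    skip-gram objective and negative sampling (unigram^0.75 noise), single
    threaded and fully deterministic given ``cfg.seed``.
    """
    if not corpus:
        raise SequenceError("empty corpus")
    k = cfg.doc2vec_kmer
    streams = [[t for t in _tokenize(s, k) if "N" not in t] for s in corpus]

    counts: dict[str, int] = {}
    for st in streams:
        for t in st:
            counts[t] = counts.get(t, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= cfg.doc2vec_min_count)
    index = {t: i for i, t in enumerate(vocab)}
    V, D = len(vocab), cfg.doc2vec_dim

    rng = np.random.default_rng(cfg.seed)
    w_in = rng.uniform(-0.5 / D, 0.5 / D, size=(V, D))
    w_out = np.zeros((V, D))

    if V > 0:
        centers, contexts = [], []
        w = cfg.doc2vec_window
        for st in streams:
            ids = np.array([index[t] for t in st if t in index], dtype=np.int64)
            n = len(ids)
            for off in range(1, w + 1):
                if n > off:
                    centers.append(ids[:-off]); contexts.append(ids[off:])
                    centers.append(ids[off:]); contexts.append(ids[:-off])
        if centers:
            centers = np.concatenate(centers)
            contexts = np.concatenate(contexts)
            freq = np.array([counts[t] for t in vocab], dtype=float) ** 0.75
            noise_cdf = np.cumsum(freq / freq.sum())
            n_pairs = len(centers)
            total_steps = cfg.doc2vec_epochs * n_pairs
            lr0, lr_min = 0.025, 1e-4
            step = 0
            chunk = 8192
            for _ in range(cfg.doc2vec_epochs):
                order = rng.permutation(n_pairs)
                for lo in range(0, n_pairs, chunk):
                    sel = order[lo : lo + chunk]
                    c, o = centers[sel], contexts[sel]
                    lr = max(lr_min, lr0 * (1 - step / total_steps))
                    step += len(sel)
                    neg = np.searchsorted(
                        noise_cdf, rng.random((len(sel), cfg.doc2vec_negative))
                    ).clip(max=V - 1)
                    vc = w_in[c]                      # (B, D)
                    vo = w_out[o]                     # (B, D)
                    vn = w_out[neg]                   # (B, K, D)
                    g_pos = 1.0 / (1.0 + np.exp(-(vc * vo).sum(1))) - 1.0  # (B,)
                    s_neg = 1.0 / (1.0 + np.exp(-np.einsum("bd,bkd->bk", vc, vn)))
                    d_in = g_pos[:, None] * vo + np.einsum("bk,bkd->bd", s_neg, vn)
                    np.add.at(w_out, o, -lr * g_pos[:, None] * vc)
                    np.add.at(
                        w_out, neg.ravel(),
                        (-lr * s_neg[:, :, None] * vc[:, None, :]).reshape(-1, D),
                    )
                    np.add.at(w_in, c, -lr * d_in)

    vocabulary = {t: w_in[i].copy() for t, i in index.items()}
    return EmbeddingModel(vocabulary, D, cfg)


def encode_doc2vec(seq: NucleotideSequence, model: EmbeddingModel) -> FeatureMatrix:
    """Token-vector lookup: position i holds the vector of the k-mer at i.

    Positions past the last token slot, and out-of-vocabulary tokens, hold
    the zero vector.
    """
    k = model.training_config.doc2vec_kmer
    L = seq.length
    out = np.zeros((L, model.dim))
    for i in range(max(L - k + 1, 0)):
        vec = model.vocabulary.get(seq.residues[i : i + k])
        if vec is not None:
            out[i] = vec
    names = tuple(f"d2v_{j:03d}" for j in range(model.dim))
    return FeatureMatrix("DOC2VEC", out, names)


def encode_all(
    seq: NucleotideSequence, model: EmbeddingModel, cfg: EncodingConfig
) -> FeatureBundle:
    """All five schemes, in the fixed order (KNF, DOC2VEC, EIIP, CCN, ANF)."""
    if seq.length < cfg.doc2vec_kmer:
        raise SequenceError(
            f"sequence {seq.id!r} shorter than doc2vec_kmer={cfg.doc2vec_kmer}"
        )
    return FeatureBundle((
        encode_knf(seq, cfg.k_values),
        encode_doc2vec(seq, model),
        encode_eiip(seq),
        encode_ccn(seq),
        encode_anf(seq),
    ))


def encode_dataset(
    sequences: list[NucleotideSequence], model: EmbeddingModel, cfg: EncodingConfig
) -> np.ndarray:
    """Stack encoded fragments into a (n, L, channels) batch array."""
    return np.stack([encode_all(s, model, cfg).as_array() for s in sequences])


def save_bundle(bundle: FeatureBundle, path) -> None:
    """One named array per scheme in a compressed container."""
    np.savez_compressed(path, **{m.scheme: m.values for m in bundle.matrices})


def bundle_to_tsv(bundle: FeatureBundle, path) -> None:
    """Wide TSV for inspection: one row per position, one column per channel."""
    import pandas as pd

    cols = {}
    for m in bundle.matrices:
        for j, name in enumerate(m.channel_names):
            cols[f"{m.scheme}.{name}"] = m.values[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
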