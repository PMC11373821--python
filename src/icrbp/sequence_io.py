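"""Reading, validating, normalizing and partitioning labeled sequence fragments.

Input fragments are short (typically 101 nt) windows around candidate
protein-binding sites on circRNAs, with a binary interaction label.  The
FASTA dialect used throughout the package encodes the label as a header
token, e.g. ``>frag_001 label=1``.  On ingest every sequence is normalized
to the DNA alphabet: uppercased, U mapped to T, and anything outside
{A,C,G,T} mapped to N.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.model_selection import KFold, train_test_split

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")
_LABEL_RE = re.compile(r"\blabel=([01])\b")


class SequenceError(ValueError):
    """Raised for malformed sequences, headers or degenerate datasets."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated fragment over {A,C,G,T,N}; the unit of encoding."""

    id: str
    residues: str

    def __post_init__(self):
        bad = set(self.residues) - VALID_ALPHABET
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains invalid residues {sorted(bad)}; "
                "call normalize_sequence first"
            )
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """Parallel lists of sequences and {0,1} labels."""

    sequences: list[NucleotideSequence]
    labels: list[int]
    name: str = ""

    def __post_init__(self):
        if len(self.sequences) != len(self.labels):
            raise SequenceError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        if any(l not in (0, 1) for l in self.labels):
            raise SequenceError("labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.sequences)

    def subset(self, indices, name: str | None = None) -> "LabeledDataset":
        return LabeledDataset(
            [self.sequences[i] for i in indices],
            [self.labels[i] for i in indices],
            name if name is not None else self.name,
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/test and cross-validation partitioning parameters."""

    test_fraction: float = 0.2
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_folds < 1:
            raise ValueError("n_folds must be positive")


def normalize_sequence(raw: str) -> tuple[str, int]:
    """Uppercase, map U->T, and map anything else outside ACGT to N.

    Returns the normalized string and the number of residues replaced by N.
    """
    if not raw:
        raise SequenceError("empty sequence")
    up = raw.upper().replace("U", "T")
    out = []
    n_replaced = 0
    for ch in up:
        if ch in "ACGT":
            out.append(ch)
        else:
            out.append("N")
            n_replaced += ch != "N"
    return "".join(out), n_replaced


def standardize_length(seq: NucleotideSequence, target_len: int) -> NucleotideSequence:
    """Center-crop long fragments; pad short ones symmetrically with N."""
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    r = seq.residues
    L = len(r)
    if L == target_len:
        return seq
    if L > target_len:
        start = (L - target_len) // 2
        r = r[start : start + target_len]
    else:
        pad = target_len - L
        left = pad // 2
        r = "N" * left + r + "N" * (pad - left)
    return NucleotideSequence(seq.id, r)


def _label_from_header(header: str) -> int:
    m = _LABEL_RE.search(header)
    if m is None:
        raise SequenceError(f"header {header!r} has no 'label=0|1' token")
    return int(m.group(1))


def read_fasta(path) -> LabeledDataset:
    """Read the labeled-FASTA dialect (``>id label={0|1}`` headers)."""
    sequences, labels = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels.append(_label_from_header(rec.description))
        residues, n_rep = normalize_sequence(str(rec.seq))
        if n_rep:
            logger.info("sequence %s: %d residues replaced by N", rec.id, n_rep)
        sequences.append(NucleotideSequence(rec.id, residues))
    if not sequences:
        logger.warning("no records read from %s", path)
    return LabeledDataset(sequences, labels, name=str(path))


def write_fasta(ds: LabeledDataset, path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=f"label={y}")
        for s, y in zip(ds.sequences, ds.labels)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_tsv(path) -> LabeledDataset:
    """Read a TSV with header row and columns id, sequence, label."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = {"id", "sequence", "label"} - set(df.columns)
    if missing:
        raise SequenceError(f"TSV {path} missing columns {sorted(missing)}")
    sequences = [
        NucleotideSequence(str(i), normalize_sequence(str(s))[0])
        for i, s in zip(df["id"], df["sequence"])
    ]
    return LabeledDataset(sequences, [int(l) for l in df["label"]], name=str(path))


def split_train_test(
    ds: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified train/test split, deterministic given the spec seed."""
    if len(ds) == 0:
        raise SequenceError("cannot split an empty dataset")
    counts = np.bincount(ds.labels, minlength=2)
    if counts.min() < 2:
        raise SequenceError(
            f"stratified split needs >=2 members per class, got {counts.tolist()}"
        )
    idx = np.arange(len(ds))
    tr, te = train_test_split(
        idx,
        test_size=spec.test_fraction,
        stratify=np.asarray(ds.labels),
        random_state=spec.seed % (2**32),
        shuffle=True,
    )
    return ds.subset(tr, f"{ds.name}/train"), ds.subset(te, f"{ds.name}/test")


def kfold_indices(n: int, spec: SplitSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """K disjoint validation folds covering 0..n-1, sizes differing by <=1."""
    if n < spec.n_folds:
        raise SequenceError(f"cannot make {spec.n_folds} folds from {n} samples")
    kf = KFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed % (2**32))
    return [(tr, va) for tr, va in kf.split(np.arange(n))]
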