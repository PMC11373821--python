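"""Planted-motif synthetic datasets emulating the CLIP-derived benchmarks.

Real benchmark datasets pair fixed-length fragments around verified binding
sites (positives) with equally many background fragments (negatives).  The
generator mirrors that structure: i.i.d. background sequences drawn from a
base composition, with a short (possibly degenerate IUPAC) motif written
into a fraction ``motif_prob`` of the positives at a uniform or centered
position.  Negatives are pure background — they are not screened for chance
motif matches, just as real negative fragments are not screened for binding
signal; for an 8-mer under uniform composition the chance-match rate is
(L-8+1)/4^8, about 0.14% at L=101.

Defaults are the study conditions used throughout the package's tests:
500 fragments per class, length 101, uniform composition, a fixed
non-degenerate 8-mer planted in 90% of positives at a uniform position.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values

from .sequence_io import LabeledDataset, NucleotideSequence

ALPHABET = "ACGT"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-motif generator."""

    n_per_class: int = 500
    length: int = 101
    background_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif: str = "TGACGTCA"
    motif_prob: float = 0.9
    position_mode: str = "uniform"   # or "center"
    seed: int = 0

    def __post_init__(self):
        comp = np.asarray(self.background_composition, dtype=float)
        if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-8:
            raise ValueError("background_composition must be 4 probabilities summing to 1")
        if not 0.0 <= self.motif_prob <= 1.0:
            raise ValueError("motif_prob must be in [0, 1]")
        if len(self.motif) > self.length:
            raise ValueError("motif longer than sequence length")
        bad = set(self.motif.upper()) - set(ambiguous_dna_values)
        if bad:
            raise ValueError(f"motif contains non-IUPAC symbols {sorted(bad)}")
        if self.position_mode not in ("uniform", "center"):
            raise ValueError("position_mode must be 'uniform' or 'center'")
        if self.n_per_class < 1 or self.length < 1:
            raise ValueError("n_per_class and length must be positive")

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["background_composition"] = tuple(d["background_composition"])
        return cls(**d)


def generate_background(spec: SyntheticSpec,
                        rng: np.random.Generator | None = None,
                        prefix: str = "bg") -> list[NucleotideSequence]:
    """``n_per_class`` i.i.d. sequences drawn per-position from the composition."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    letters = np.array(list(ALPHABET))
    draws = rng.choice(4, size=(spec.n_per_class, spec.length),
                       p=np.asarray(spec.background_composition))
    return [
        NucleotideSequence(f"{prefix}_{i:05d}", "".join(letters[row]))
        for i, row in enumerate(draws)
    ]


def realize_motif(motif: str, rng: np.random.Generator) -> str:
    """Draw a concrete instance of a degenerate IUPAC motif (uniform per code)."""
    return "".join(rng.choice(list(ambiguous_dna_values[ch.upper()]))
                   for ch in motif)


def plant_motif(seq: NucleotideSequence, spec: SyntheticSpec,
                rng: np.random.Generator) -> NucleotideSequence:
    """With probability ``motif_prob``, overwrite a window with the motif."""
    if rng.random() >= spec.motif_prob:
        return seq
    m = realize_motif(spec.motif, rng)
    span = seq.length - len(m)
    if spec.position_mode == "center":
        start = span // 2
    else:
        start = int(rng.integers(0, span + 1))
    residues = seq.residues[:start] + m + seq.residues[start + len(m):]
    return NucleotideSequence(seq.id, residues)


def generate_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Balanced planted-motif dataset: n positives (label 1) + n negatives."""
    rng = np.random.default_rng(spec.seed)
    positives = [
        plant_motif(s, spec, rng)
        for s in generate_background(spec, rng, prefix="pos")
    ]
    negatives = generate_background(spec, rng, prefix="neg")
    seqs = positives + negatives
    labels = [1] * spec.n_per_class + [0] * spec.n_per_class
    order = rng.permutation(len(seqs))
    return LabeledDataset(
        [seqs[i] for i in order], [labels[i] for i in order],
        name=f"synthetic(seed={spec.seed})",
    )
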