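"""Sequence encoding, activity-label scaling, and file I/O.

Guides are strings over {A, C, G, T}; the fixed channel order of the one-hot
encoding is alphabetical (A, C, G, T) and is used consistently everywhere in
the package (model inputs, ALE matrices, sequence logos).

External coordinates (gene annotations) are interpreted as 1-based inclusive,
the convention of genome-browser CSV exports; internally everything is
0-based half-open.  The conversion lives in :func:`to_internal_coords` only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

__all__ = [
    "ALPHABET",
    "GuideSequence",
    "ActivityScale",
    "LabeledDataset",
    "encode_guide",
    "encode_batch",
    "decode_guide",
    "encode_pair",
    "encode_pair_batch",
    "scale_activities",
    "read_sequences",
    "read_annotation",
    "extract_genes",
    "read_labeled_tsv",
    "write_labeled_tsv",
    "to_internal_coords",
    "reverse_complement",
]


@dataclass(frozen=True)
class GuideSequence:
    """A named DNA sequence over the 4-letter alphabet (upper-cased on ingest)."""

    name: str
    seq: str

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)

    def validate(self) -> "GuideSequence":
        for i, ch in enumerate(self.seq):
            if ch not in _BASE_INDEX:
                raise ValueError(
                    f"sequence {self.name!r}: invalid character {ch!r} at position {i}"
                )
        return self


@dataclass(frozen=True)
class ActivityScale:
    """Affine label rescaling: scaled = (v - min) / (max - min)."""

    observed_min: float
    observed_max: float

    def __post_init__(self):
        if not self.observed_max > self.observed_min:
            raise ValueError("degenerate activity scale: max must exceed min")

    def transform(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return (v - self.observed_min) / (self.observed_max - self.observed_min)

    def inverse(self, scaled) -> np.ndarray:
        v = np.asarray(scaled, dtype=float)
        return v * (self.observed_max - self.observed_min) + self.observed_min


@dataclass
class LabeledDataset:
    """Encoded inputs with activity labels rescaled to [0, 1].

    ``inputs`` has shape (n, 4, N) for guides or (n, 2, 4, N) for pairs.
    """

    inputs: np.ndarray
    labels: np.ndarray
    scale: ActivityScale
    sequences: list[str] | None = None

    def __post_init__(self):
        if len(self.inputs) != len(self.labels):
            raise ValueError("inputs and labels must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def is_pair(self) -> bool:
        return self.inputs.ndim == 4


def encode_guide(guide: GuideSequence | str) -> np.ndarray:
    """One-hot encode a guide to a binary (4, N) matrix, channel order A,C,G,T."""
    if isinstance(guide, str):
        guide = GuideSequence("", guide)
    guide.validate()
    n = len(guide.seq)
    out = np.zeros((4, n))
    for j, ch in enumerate(guide.seq):
        out[_BASE_INDEX[ch], j] = 1.0
    return out


def decode_guide(onehot: np.ndarray) -> str:
    """Inverse of :func:`encode_guide`."""
    onehot = np.asarray(onehot)
    if onehot.ndim != 2 or onehot.shape[0] != 4:
        raise ValueError(f"expected (4, N) matrix, got {onehot.shape}")
    if not np.allclose(onehot.sum(axis=0), 1.0):
        raise ValueError("columns of a one-hot matrix must each sum to 1")
    return "".join(ALPHABET[i] for i in onehot.argmax(axis=0))


def encode_pair(guide: GuideSequence | str, target: GuideSequence | str) -> np.ndarray:
    """Encode a guide-target pair as a two-channel (2, 4, N) image."""
    g = encode_guide(guide)
    t = encode_guide(target)
    if g.shape != t.shape:
        raise ValueError(
            f"guide and target lengths differ: {g.shape[1]} vs {t.shape[1]}"
        )
    return np.stack([g, t])


def encode_batch(seqs) -> np.ndarray:
    return np.stack([encode_guide(s) for s in seqs])


def encode_pair_batch(pairs) -> np.ndarray:
    return np.stack([encode_pair(g, t) for g, t in pairs])


def scale_activities(values) -> tuple[np.ndarray, ActivityScale]:
    """Rescale raw activities so the minimum maps to 0 and the maximum to 1."""
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.ptp(v) == 0:
        raise ValueError("need at least two distinct activity values to rescale")
    scale = ActivityScale(float(v.min()), float(v.max()))
    return scale.transform(v), scale


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_sequences(path) -> list[GuideSequence]:
    """Read a (possibly multi-record, wrapped) FASTA file."""
    records = [
        GuideSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_annotation(path) -> pd.DataFrame:
    """Read a gene annotation table with columns gene,start,end,strand.

    Delimiter is sniffed between comma and tab.  Coordinates are 1-based
    inclusive as exported by genome browsers.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"gene", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation is missing columns: {sorted(missing)}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(
            f"unknown strand symbol(s): {sorted(df.loc[bad, 'strand'].unique())}"
        )
    return df


def to_internal_coords(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_1based


def extract_genes(genome: GuideSequence, annotation: pd.DataFrame) -> list[GuideSequence]:
    """Slice per-gene subsequences out of a chromosome/contig.

    Minus-strand genes are reverse-complemented so the returned sequence reads
    5'->3' on the gene's coding strand.
    """
    genes = []
    for row in annotation.itertuples(index=False):
        start, end = to_internal_coords(int(row.start), int(row.end))
        if start < 0 or end > len(genome.seq) or start >= end:
            raise ValueError(
                f"gene {row.gene!r}: coordinates [{row.start}, {row.end}] outside "
                f"sequence of length {len(genome.seq)}"
            )
        sub = genome.seq[start:end]
        if row.strand == "-":
            sub = reverse_complement(sub)
        genes.append(GuideSequence(str(row.gene), sub))
    return genes


def read_labeled_tsv(path) -> LabeledDataset:
    """Read a labeled dataset TSV with columns sequence[,target],activity.

    Activities are rescaled to [0, 1]; the fitted :class:`ActivityScale` is
    stored on the returned dataset so predictions can be mapped back.
    """
    df = pd.read_csv(path, sep="\t")
    if "sequence" not in df.columns or "activity" not in df.columns:
        raise ValueError("labeled TSV needs 'sequence' and 'activity' columns")
    labels, scale = scale_activities(df["activity"].to_numpy())
    if "target" in df.columns:
        inputs = encode_pair_batch(list(zip(df["sequence"], df["target"])))
    else:
        inputs = encode_batch(df["sequence"])
    return LabeledDataset(inputs, labels, scale, sequences=list(df["sequence"]))


def write_labeled_tsv(path, sequences, activities, targets=None) -> None:
    data = {"sequence": list(sequences)}
    if targets is not None:
        data["target"] = list(targets)
    data["activity"] = np.asarray(activities, dtype=float)
    pd.DataFrame(data).to_csv(Path(path), sep="\t", index=False)
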