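"""PAM-mask target scanning, mismatch off-target enumeration, model scoring
and off-target categorization.

The scanner finds every window, on either strand, whose reading-strand
sequence matches a PAM mask such as ``NNNNNNNNNNNNNNNNNNNNNRG`` (Cas9,
3' NGG-type PAM) or ``TTTNNNNNNNNNNNNNNNNNNNNN`` (Cas12a, 5' TTTN-type PAM).
Minus-strand hits are reported with reference-strand coordinates and the
reverse-complemented (reading-strand) sequence.  Off-targets of a guide are
mask-matching windows whose protospacer differs from the guide at no more
than ``max_mm`` positions; PAM-constrained positions must match the mask
exactly and never count as mismatches.

Categorization follows a four-way split by strict thresholds on predicted
mean cleavage efficiency (< 0.15 is "low efficiency") and predicted variance
(< 0.015 is "low variance"); equality lands in the "high" class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import TrainedModel
from .sequence_io import GuideSequence, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "PAMMask",
    "CAS9_MASK",
    "CAS12A_MASK",
    "TargetSite",
    "scan_targets",
    "enumerate_offtargets",
    "score_and_rank",
    "categorize_offtargets",
    "CATEGORIES",
]

_MASK_ALPHABET = {
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "T": {"T"},
    "R": {"A", "G"},
    "N": {"A", "C", "G", "T"},
}

CATEGORIES = ("lowE_lowV", "lowE_highV", "highE_lowV", "highE_highV")


@dataclass(frozen=True)
class PAMMask:
    """A scanning mask over {A, C, G, T, R, N}; N positions are the protospacer."""

    pattern: str

    def __post_init__(self):
        object.__setattr__(self, "pattern", self.pattern.upper())
        bad = set(self.pattern) - set(_MASK_ALPHABET)
        if bad:
            raise ValueError(f"invalid mask characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def protospacer_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.pattern) if c == "N")

    @property
    def pam_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.pattern) if c != "N")


CAS9_MASK = PAMMask("N" * 21 + "RG")
CAS12A_MASK = PAMMask("TTT" + "N" * 21)


@dataclass(frozen=True)
class TargetSite:
    """A mask-matching genomic window.

    ``start`` is 0-based on the reference strand; ``seq`` is the match read
    on the strand it occurs on (reverse-complemented for minus-strand hits).
    """

    start: int
    strand: str
    seq: str
    gene: str = ""


def _match_positions(seq: str, mask: str, positions) -> np.ndarray:
    """Boolean array over window starts: do all `positions` of the mask match?"""
    L, K = len(seq), len(mask)
    n_win = L - K + 1
    if n_win <= 0:
        return np.zeros(0, dtype=bool)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    ok = np.ones(n_win, dtype=bool)
    for p in positions:
        allowed = np.array(sorted(_MASK_ALPHABET[mask[p]]), dtype="S1")
        ok &= np.isin(arr[p : p + n_win], allowed)
    return ok


def _warn_ambiguous(seq: str, name: str) -> None:
    if set(seq) - {"A", "C", "G", "T"}:
        logger.warning(
            "sequence %r contains non-ACGT characters; windows covering them are skipped",
            name,
        )


def scan_targets(seq: GuideSequence | str, mask: PAMMask) -> list[TargetSite]:
    """All mask-matching windows on both strands, sorted by reference start."""
    if isinstance(seq, str):
        seq = GuideSequence("", seq)
    s = seq.seq
    _warn_ambiguous(s, seq.name)
    K = len(mask)
    sites: list[TargetSite] = []
    fwd = _match_positions(s, mask.pattern, range(K))
    for start in np.flatnonzero(fwd):
        sites.append(TargetSite(int(start), "+", s[start : start + K], seq.name))
    rc = reverse_complement(s)
    rev = _match_positions(rc, mask.pattern, range(K))
    for j in np.flatnonzero(rev):
        ref_start = len(s) - int(j) - K
        sites.append(TargetSite(ref_start, "-", rc[j : j + K], seq.name))
    return sorted(sites, key=lambda t: (t.start, t.strand))


def enumerate_offtargets(
    guide: GuideSequence | str,
    seq: GuideSequence | str,
    mask: PAMMask,
    max_mm: int = 6,
) -> list[tuple[TargetSite, int]]:
    """Mask-matching windows with protospacer Hamming distance <= max_mm.

    The guide must be exactly as long as the mask's protospacer (its N run);
    PAM positions are required to match the mask and are never counted as
    mismatches.
    """
    if isinstance(guide, str):
        guide = GuideSequence("guide", guide)
    guide.validate()
    proto = mask.protospacer_positions
    if len(guide.seq) != len(proto):
        raise ValueError(
            f"guide length {len(guide.seq)} does not match the mask's "
            f"{len(proto)} protospacer positions"
        )
    if isinstance(seq, str):
        seq = GuideSequence("", seq)
    s = seq.seq
    _warn_ambiguous(s, seq.name)
    K = len(mask)
    garr = np.frombuffer(guide.seq.encode(), dtype="S1")
    out: list[tuple[TargetSite, int]] = []

    def _collect(text: str, strand: str):
        n_win = len(text) - K + 1
        if n_win <= 0:
            return
        # PAM positions must match; protospacer positions must be real bases
        ok = _match_positions(text, mask.pattern, range(K))
        arr = np.frombuffer(text.encode(), dtype="S1")
        mm = np.zeros(n_win, dtype=int)
        for rank, p in enumerate(proto):
            mm += arr[p : p + n_win] != garr[rank]
        for j in np.flatnonzero(ok & (mm <= max_mm)):
            start = int(j) if strand == "+" else len(s) - int(j) - K
            out.append(
                (TargetSite(start, strand, text[j : j + K], seq.name), int(mm[j]))
            )

    _collect(s, "+")
    _collect(reverse_complement(s), "-")
    out.sort(key=lambda r: (r[0].start, r[0].strand))
    return out


def guide_with_site_pam(guide: str, site_seq: str, mask: PAMMask) -> str:
    """Embed a protospacer-length guide into a full-mask-length sequence.

    The guide occupies the mask's N positions; PAM positions are copied from
    the site, so a pair model sees equal-length guide and target channels.
    """
    proto = mask.protospacer_positions
    if len(guide) != len(proto):
        raise ValueError("guide length must equal the mask's protospacer length")
    chars = list(site_seq)
    for rank, p in enumerate(proto):
        chars[p] = guide[rank]
    return "".join(chars)


def score_and_rank(
    model: TrainedModel,
    sites: list[TargetSite],
    top_k: int | None = None,
    n_samples: int | None = None,
    seed: int = 0,
    one_based: bool = False,
) -> pd.DataFrame:
    """Score sites with the model and rank by mean efficiency, descending.

    Pair models receive the site sequence on both channels (the site acts as
    its own target).  Sites whose length does not match the model input are
    logged and skipped.  Ties break by variance ascending, then start
    ascending, so output order is deterministic.
    """
    if not sites:
        raise ValueError("no sites to score")
    usable, skipped = [], 0
    for site in sites:
        if len(site.seq) != model.input_length:
            skipped += 1
            continue
        usable.append(site)
    if skipped:
        logger.warning("skipped %d sites with length != model input %d",
                       skipped, model.input_length)
    if not usable:
        raise ValueError("no sites match the model input length")
    if model.is_pair:
        X = [(t.seq, t.seq) for t in usable]
    else:
        X = [t.seq for t in usable]
    pred = model.predict(X, n_samples=n_samples, seed=seed)
    offset = 1 if one_based else 0
    table = pd.DataFrame(
        {
            "Start": [t.start + offset for t in usable],
            "Sequence": [t.seq for t in usable],
            "Strand": [t.strand for t in usable],
            "Mean": pred.mean,
            "Variance": pred.std**2,
        }
    )
    order = np.lexsort((table["Start"], table["Variance"], -table["Mean"]))
    table = table.iloc[order].reset_index(drop=True)
    if top_k is not None:
        table = table.head(top_k)
    return table


def categorize_offtargets(
    records: pd.DataFrame,
    eff_thr: float = 0.15,
    var_thr: float = 0.015,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Four-way off-target classification plus per-guide category fractions.

    ``records`` needs columns guide, mean, variance.  "low" means strictly
    below the threshold on that axis.  Per-guide proportions sum to 1.
    """
    required = {"guide", "mean", "variance"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if (records["variance"] < 0).any():
        raise ValueError("negative predictive variance")
    low_e = records["mean"] < eff_thr
    low_v = records["variance"] < var_thr
    cat = np.where(
        low_e,
        np.where(low_v, "lowE_lowV", "lowE_highV"),
        np.where(low_v, "highE_lowV", "highE_highV"),
    )
    records = records.copy()
    records["category"] = cat
    counts = (
        records.groupby("guide")["category"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(CATEGORIES), fill_value=0)
    )
    proportions = counts.div(counts.sum(axis=1), axis=0)
    return records, proportions
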