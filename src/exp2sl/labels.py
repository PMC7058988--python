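"""SL label construction from pairwise CRISPR-screen scores.

Positive pairs must score above zero (a synergistic lethal effect) AND rank in
the top ``pos_top_frac`` of all scored pairs; negative pairs must score below
zero AND rank in the bottom ``neg_bottom_frac``. Everything else is unknown.
The unknown set U is never materialized: it is the complement of P and N over
the gene universe and is only ever sampled from.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Unordered pair as a sorted tuple; gene order in the input never matters."""
    if a == b:
        raise ValueError(f"self-pair {a!r} is not a valid gene pair")
    return (a, b) if a <= b else (b, a)


@dataclass
class SLLabelSet:
    """Partition of unordered gene pairs into positives P, negatives N, unknown U.

    U is implicit: all unordered pairs over ``gene_universe`` not in P or N.
    """

    positives: set[Pair]
    negatives: set[Pair]
    gene_universe: set[str]

    def __post_init__(self):
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"pairs labeled both positive and negative: {sorted(overlap)[:5]}")

    @property
    def n_labeled(self) -> int:
        return len(self.positives) + len(self.negatives)

    def labeled_pairs(self) -> list[Pair]:
        return sorted(self.positives) + sorted(self.negatives)

    def labels(self) -> dict[Pair, int]:
        out = {p: 1 for p in self.positives}
        out.update({p: -1 for p in self.negatives})
        return out

    def sample_unknown(self, k: int, rng: np.random.Generator, genes=None) -> list[Pair]:
        """Draw ``k`` unknown pairs uniformly, restricted to ``genes`` if given.

        Rejection sampling against the labeled sets; U is O(genes^2) and never
        built explicitly.
        """
        pool = sorted(genes) if genes is not None else sorted(self.gene_universe)
        if len(pool) < 2:
            raise ValueError("need at least two genes to sample unknown pairs")
        labeled = self.positives | self.negatives
        out: list[Pair] = []
        while len(out) < k:
            i, j = rng.integers(0, len(pool), size=2)
            if i == j:
                continue
            pair = canonical_pair(pool[i], pool[j])
            if pair not in labeled:
                out.append(pair)
        return out


def label_pairs(
    scores: pd.DataFrame,
    pos_top_frac: float = 0.05,
    neg_bottom_frac: float = 0.5,
) -> tuple[set[Pair], set[Pair]]:
    """Split scored pairs into positives and negatives by sign and rank.

    P = {score > 0 and descending rank <= ceil(pos_top_frac * M)};
    N = {score < 0 and ascending rank <= floor(neg_bottom_frac * M)},
    with M the number of scored pairs. Ties are broken by score then by pair
    name so the cut is deterministic.
    """
    if len(scores) == 0:
        raise ValueError("empty score table")
    if not (0 < pos_top_frac < neg_bottom_frac <= 1):
        raise ValueError("need 0 < pos_top_frac < neg_bottom_frac <= 1")
    if scores["score"].isna().any():
        raise ValueError("NaN scores are not allowed")

    pairs = [canonical_pair(a, b) for a, b in zip(scores["gene_a"], scores["gene_b"])]
    if len(set(pairs)) != len(pairs):
        seen, dups = set(), set()
        for p in pairs:
            (dups if p in seen else seen).add(p)
        raise ValueError(f"duplicate unordered pairs in score table: {sorted(dups)[:5]}")

    m = len(pairs)
    vals = scores["score"].to_numpy(dtype=float)
    order_desc = sorted(range(m), key=lambda i: (-vals[i], pairs[i]))
    order_asc = sorted(range(m), key=lambda i: (vals[i], pairs[i]))

    n_pos = math.ceil(pos_top_frac * m)
    n_neg = math.floor(neg_bottom_frac * m)
    positives = {pairs[i] for i in order_desc[:n_pos] if vals[i] > 0}
    negatives = {pairs[i] for i in order_asc[:n_neg] if vals[i] < 0}
    return positives, negatives


def assemble_dataset(
    labels: SLLabelSet,
    signatures: pd.DataFrame,
    min_labeled: int = 100,
) -> SLLabelSet:
    """Restrict a label set to genes that have an L1000 signature.

    Labeled pairs lacking a signature for either gene are dropped; the gene
    universe becomes the signatured genes. Emits a warning when fewer than
    ``min_labeled`` labeled pairs survive (the modeling dataset is then too
    small to be trustworthy, mirroring the >100-pair cell-line filter).
    """
    have = set(signatures.index)
    pos = {p for p in labels.positives if p[0] in have and p[1] in have}
    neg = {p for p in labels.negatives if p[0] in have and p[1] in have}
    out = SLLabelSet(positives=pos, negatives=neg, gene_universe=have)
    if out.n_labeled <= min_labeled:
        logger.warning(
            "only %d labeled pairs survive the signature filter (threshold %d)",
            out.n_labeled, min_labeled,
        )
    return out


def merge_label_sources(
    sources: list[tuple[set[Pair], set[Pair]]],
    conflict_policy: str = "positive_wins",
) -> tuple[set[Pair], set[Pair]]:
    """Union label sets from multiple screens of the same cell line.

    A pair positive in one source and negative in another is resolved by
    ``conflict_policy``: "positive_wins" keeps it positive, "negative_wins"
    keeps it negative, "drop" discards it.
    """
    if not sources:
        raise ValueError("need at least one label source")
    pos = set().union(*(p for p, _ in sources))
    neg = set().union(*(n for _, n in sources))
    conflict = pos & neg
    if conflict:
        logger.warning("%d pairs conflict across sources (%s)", len(conflict), conflict_policy)
    if conflict_policy == "positive_wins":
        neg -= conflict
    elif conflict_policy == "negative_wins":
        pos -= conflict
    elif conflict_policy == "drop":
        pos -= conflict
        neg -= conflict
    else:
        raise ValueError(f"unknown conflict policy {conflict_policy!r}")
    return pos, neg
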