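"""CD-HIT-style greedy redundancy reduction.

Sequence identity between two peptides is the maximum number of identical
matched residues over all global alignments under match=1, mismatch=0,
gap=0 scoring — i.e. the length of their longest common subsequence —
divided by the shorter length, which is CD-HIT's default identity
definition.  Reduction is greedy incremental clustering: records are
visited longest-first and discarded when they exceed the identity
threshold against an already-kept (longer) representative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_io import Dataset, PeptideRecord

__all__ = ["DEFAULT_IDENTITY_THRESHOLD", "pairwise_identity", "reduce_redundancy"]

DEFAULT_IDENTITY_THRESHOLD = 0.90


def _lcs_length(a: str, b: str) -> int:
    """Longest-common-subsequence length via a row-rolling numpy DP."""
    if not a or not b:
        return 0
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    prev = np.zeros(len(b) + 1, dtype=np.int32)
    for ch in a.encode("ascii"):
        cur = np.empty_like(prev)
        cur[0] = 0
        match = prev[:-1] + (bb == ch)
        np.maximum(match, prev[1:], out=cur[1:])
        np.maximum.accumulate(cur, out=cur)  # carry cur[j-1] forward
        prev = cur
    return int(prev[-1])


def pairwise_identity(a: PeptideRecord | str, b: PeptideRecord | str) -> float:
    """Identity in [0, 1]: LCS match count over the shorter sequence length."""
    sa = a.sequence if isinstance(a, PeptideRecord) else a
    sb = b.sequence if isinstance(b, PeptideRecord) else b
    if not sa or not sb:
        raise ValueError("identity is undefined for empty sequences")
    return _lcs_length(sa, sb) / min(len(sa), len(sb))


@dataclass(frozen=True)
class RedundancyReport:
    """Which records were discarded and which representative absorbed each."""

    discarded: tuple[tuple[str, str, float], ...]  # (discarded id, representative id, identity)


def reduce_redundancy(
    dataset: Dataset,
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    return_report: bool = False,
) -> Dataset | tuple[Dataset, RedundancyReport]:
    """Discard peptides whose identity to a kept representative exceeds
    ``threshold`` (strictly greater), keeping longer sequences first.

    Survivors are returned in the original dataset order.  Idempotent, and
    monotone in the threshold: a higher threshold never discards more.
    """
    if len(dataset) == 0:
        raise ValueError("cannot reduce an empty dataset")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"identity threshold must lie in (0, 1], got {threshold}")

    order = sorted(dataset, key=lambda r: (-r.length, r.id))
    representatives: list[PeptideRecord] = []
    discarded: list[tuple[str, str, float]] = []
    for rec in order:
        hit = None
        for rep in representatives:
            ident = pairwise_identity(rec, rep)
            if ident > threshold:
                hit = (rec.id, rep.id, ident)
                break
        if hit is None:
            representatives.append(rec)
        else:
            discarded.append(hit)

    kept_ids = {r.id for r in representatives}
    reduced = Dataset(
        records=tuple(r for r in dataset if r.id in kept_ids),
        name=dataset.name,
    )
    if return_report:
        return reduced, RedundancyReport(discarded=tuple(discarded))
    return reduced
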