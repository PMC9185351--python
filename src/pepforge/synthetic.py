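"""Seedable two-class synthetic peptide generator.

NACP residues are drawn i.i.d. from a background composition (uniform 1/20
by default); ACP residues come from the same background exponentially
tilted toward the residues enriched in real anticancer peptides — the
cationic and hydrophobic set {K, R, L, A, G, F, W} that drives their
interaction with anionic cancer-cell membranes.  ``effect_size`` is the
tilting strength: 0 makes the classes identically distributed (an exact
null), larger values separate their compositions further.  Lengths are
uniform on 10..50 residues by default, matching the short peptides
(under 50 residues) the task concerns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import ACP, AMINO_ACIDS, NACP
from .sequence_io import Dataset, PeptideRecord

__all__ = ["ACP_ENRICHED_RESIDUES", "SyntheticSpec", "generate", "generate_benchmark_shaped"]

ACP_ENRICHED_RESIDUES = frozenset("KRLAGFW")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic two-class dataset."""

    n_acp: int = 200
    n_nacp: int = 200
    length_range: tuple[int, int] = (10, 50)
    effect_size: float = 2.0
    seed: int = 0
    background: tuple[float, ...] | None = None  # composition over A..Y; uniform if None
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_acp <= 0 or self.n_nacp <= 0:
            raise ValueError("class counts must be positive")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length range {self.length_range}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or np.any(bg < 0) or not np.isclose(bg.sum(), 1.0):
                raise ValueError("background must be a 20-component probability vector")


def _class_compositions(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    bg = (
        np.full(20, 1 / 20)
        if spec.background is None
        else np.asarray(spec.background, dtype=float)
    )
    tilt = np.array([1.0 if aa in ACP_ENRICHED_RESIDUES else 0.0 for aa in AMINO_ACIDS])
    acp = bg * np.exp(spec.effect_size * tilt)
    acp /= acp.sum()
    return acp, bg


def generate(spec: SyntheticSpec) -> Dataset:
    """Draw a labeled two-class dataset; byte-identical output per seed."""
    rng = np.random.default_rng(spec.seed)
    acp_p, nacp_p = _class_compositions(spec)
    lo, hi = spec.length_range
    alphabet = np.array(list(AMINO_ACIDS))

    records: list[PeptideRecord] = []
    for label, count, probs in ((ACP, spec.n_acp, acp_p), (NACP, spec.n_nacp, nacp_p)):
        width = len(str(count))
        lengths = rng.integers(lo, hi + 1, size=count)
        for i, L in enumerate(lengths, start=1):
            seq = "".join(alphabet[rng.choice(20, size=L, p=probs)])
            records.append(PeptideRecord(id=f"{label}_{i:0{width}d}", sequence=seq, label=label))
    return Dataset(records=tuple(records), name=spec.name)


def generate_benchmark_shaped(seed: int = 0, effect_size: float = 2.0) -> tuple[Dataset, Dataset]:
    """Two datasets mirroring the shapes of the published benchmark corpora:
    138 ACP / 206 NACP (344 total) and 225 ACP / 2250 NACP (2475 total,
    1:10 class imbalance)."""
    psd1 = generate(
        SyntheticSpec(
            n_acp=138, n_nacp=206, effect_size=effect_size, seed=seed, name="PSD1-shaped"
        )
    )
    psd2 = generate(
        SyntheticSpec(
            n_acp=225, n_nacp=2250, effect_size=effect_size, seed=seed + 1, name="PSD2-shaped"
        )
    )
    return psd1, psd2
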