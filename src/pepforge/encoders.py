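"""Fixed-length peptide feature encoders and their fusions.

Four encoders map a peptide of length L to a probability vector:

* AAC — 20 single-residue frequencies, n_j / L.
* DPC — 400 adjacent ordered-pair frequencies, counts / (L - 1).
* TPC — 8000 ordered-triple frequencies from a width-3 sliding window,
  counts / (L - 2).
* IPseAAC — the 20 residue frequencies augmented with lambda sequence-order
  correlation factors built from nine standardized physicochemical scales,
  jointly normalized with weight w so the 20 + lambda components again sum
  to one.

Fused feature spaces are plain horizontal concatenations with
encoder-prefixed column names.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AMINO_ACIDS
from .properties import PropertyTable, load_property_table
from .sequence_io import Dataset, PeptideRecord

__all__ = [
    "ENCODER_NAMES",
    "FeatureMatrix",
    "IPseAACConfig",
    "encode_aac",
    "encode_dpc",
    "encode_tpc",
    "sequence_correlation",
    "encode_ipseaac",
    "encode_dataset",
]

ENCODER_NAMES = ("AAC", "DPC", "TPC", "IPseAAC")

AAC_COLUMNS = tuple(f"AAC:{a}" for a in AMINO_ACIDS)
DPC_COLUMNS = tuple(f"DPC:{a}{b}" for a, b in product(AMINO_ACIDS, repeat=2))
TPC_COLUMNS = tuple(f"TPC:{a}{b}{c}" for a, b, c in product(AMINO_ACIDS, repeat=3))


@dataclass(frozen=True)
class FeatureMatrix:
    """Row-per-peptide descriptor matrix with named columns and provenance."""

    row_ids: tuple[str, ...]
    column_names: tuple[str, ...]
    values: np.ndarray
    encoder_tag: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("feature matrix must be 2-dimensional")
        if values.shape != (len(self.row_ids), len(self.column_names)):
            raise ValueError(
                f"shape {values.shape} does not match {len(self.row_ids)} ids "
                f"x {len(self.column_names)} columns"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("feature matrix contains non-finite values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "row_ids", tuple(self.row_ids))
        object.__setattr__(self, "column_names", tuple(self.column_names))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_ids), columns=list(self.column_names))

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# pepforge feature matrix; encoder={self.encoder_tag}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index_label="id")
        return path

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        tag = ""
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                tag = first.split("encoder=", 1)[-1].strip() if "encoder=" in first else ""
            else:
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col="id")
        return cls(
            row_ids=tuple(str(i) for i in df.index),
            column_names=tuple(df.columns),
            values=df.to_numpy(dtype=float),
            encoder_tag=tag,
        )


@dataclass(frozen=True)
class IPseAACConfig:
    """Improved-PseAAC settings.

    lam
        Number of sequence-order correlation tiers appended to the 20
        composition components; tier n correlates residues n positions
        apart.  Must stay below the length of every encoded peptide.
    weight
        Chou's weight w balancing composition against correlation factors
        in the joint normalization.
    property_subset
        Names of the physicochemical scales to use (default: all nine).
    tier_mode
        ``canonical`` computes tier n from pairs n apart; ``literal``
        reproduces the adjacent-pair-only variant in which every tier
        averages I(k, k+1) over its own window count.
    """

    lam: int = 1
    weight: float = 0.05
    property_subset: tuple[str, ...] | None = None
    tier_mode: str = "canonical"

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError("lam must be a positive integer")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        if self.tier_mode not in ("canonical", "literal"):
            raise ValueError("tier_mode must be 'canonical' or 'literal'")


def _indices(sequence: str) -> np.ndarray:
    return np.fromiter((AA_INDEX[c] for c in sequence), dtype=np.int64, count=len(sequence))


def encode_aac(record: PeptideRecord) -> np.ndarray:
    """20 residue frequencies n_j / L, alphabetical order; sums to 1."""
    idx = _indices(record.sequence)
    return np.bincount(idx, minlength=20) / record.length


def encode_dpc(record: PeptideRecord) -> np.ndarray:
    """400 adjacent-dipeptide frequencies, counts / (L-1); sums to 1."""
    if record.length < 2:
        raise ValueError(f"record {record.id!r}: DPC requires length >= 2")
    idx = _indices(record.sequence)
    pair = idx[:-1] * 20 + idx[1:]
    return np.bincount(pair, minlength=400) / (record.length - 1)


def encode_tpc(record: PeptideRecord) -> np.ndarray:
    """8000 sliding-window tripeptide frequencies, counts / (L-2); sums to 1."""
    if record.length < 3:
        raise ValueError(f"record {record.id!r}: TPC requires length >= 3")
    idx = _indices(record.sequence)
    triple = idx[:-2] * 400 + idx[1:-1] * 20 + idx[2:]
    return np.bincount(triple, minlength=8000) / (record.length - 2)


def sequence_correlation(
    record: PeptideRecord,
    n: int,
    table: PropertyTable,
    subset: Sequence[str] | None = None,
    tier_mode: str = "canonical",
) -> float:
    """Tier-n sequence-order correlation factor theta_n.

    theta_n = (1/(L-n)) * sum_{k=1..L-n} I(R_k, R_{k+n}) with
    I(Ri, Rj) the mean squared difference of the selected standardized
    property values between the two residues.  Non-negative, and invariant
    under sequence reversal.
    """
    L = record.length
    if n < 1 or n >= L:
        raise ValueError(f"record {record.id!r}: tier n={n} must satisfy 1 <= n < L={L}")
    props = table.matrix(tuple(subset) if subset is not None else None)  # (20, m)
    idx = _indices(record.sequence)
    step = 1 if tier_mode == "literal" else n
    diff = props[idx[: L - n]] - props[idx[step : step + L - n]]
    return float(np.mean(diff**2, axis=1).sum() / (L - n))


def encode_ipseaac(
    record: PeptideRecord,
    config: IPseAACConfig | None = None,
    table: PropertyTable | None = None,
) -> np.ndarray:
    """(20 + lambda)-component improved PseAAC vector; sums to 1.

    Components 1..20 are f_u / (sum f + w * sum theta); components 20+j are
    w * theta_j / (sum f + w * sum theta).
    """
    config = config or IPseAACConfig()
    table = table if table is not None else load_property_table()
    if config.lam >= record.length:
        raise ValueError(
            f"record {record.id!r}: lam={config.lam} must be below sequence length {record.length}"
        )
    freqs = encode_aac(record)  # sums to 1
    thetas = np.array(
        [
            sequence_correlation(record, n, table, config.property_subset, config.tier_mode)
            for n in range(1, config.lam + 1)
        ]
    )
    denom = freqs.sum() + config.weight * thetas.sum()
    return np.concatenate([freqs, config.weight * thetas]) / denom


def _ipseaac_columns(lam: int) -> tuple[str, ...]:
    return tuple(f"PSE:{a}" for a in AMINO_ACIDS) + tuple(f"PSE:theta{j}" for j in range(1, lam + 1))


def encode_dataset(
    dataset: Dataset,
    encoder_names: Iterable[str] = ("AAC", "DPC", "TPC", "IPseAAC"),
    config: IPseAACConfig | None = None,
    table: PropertyTable | None = None,
) -> FeatureMatrix:
    """Encode every record with the selected encoders, concatenated in order.

    Length preconditions (DPC: L>=2, TPC: L>=3, IPseAAC: L>lambda) are checked
    up front; a single error lists every offending record id.
    """
    names = tuple(encoder_names)
    unknown = set(names) - set(ENCODER_NAMES)
    if unknown:
        raise ValueError(f"unknown encoder(s): {sorted(unknown)}")
    if not names:
        raise ValueError("at least one encoder is required")
    config = config or IPseAACConfig()
    if "IPseAAC" in names and table is None:
        table = load_property_table()

    min_len = {"AAC": 1, "DPC": 2, "TPC": 3, "IPseAAC": config.lam + 1}
    needed = max(min_len[n] for n in names)
    bad = [r.id for r in dataset if r.length < needed]
    if bad:
        raise ValueError(
            f"record(s) too short for encoder set {names} (need L >= {needed}): {bad}"
        )

    columns: tuple[str, ...] = ()
    for n in names:
        columns += {
            "AAC": AAC_COLUMNS,
            "DPC": DPC_COLUMNS,
            "TPC": TPC_COLUMNS,
            "IPseAAC": _ipseaac_columns(config.lam),
        }[n]

    encoder_fns = {
        "AAC": encode_aac,
        "DPC": encode_dpc,
        "TPC": encode_tpc,
        "IPseAAC": lambda r: encode_ipseaac(r, config, table),
    }
    rows = [
        np.concatenate([encoder_fns[n](rec) for n in names])
        for rec in dataset
    ]
    values = np.vstack(rows) if rows else np.empty((0, len(columns)))
    return FeatureMatrix(
        row_ids=tuple(dataset.ids),
        column_names=columns,
        values=values,
        encoder_tag="+".join(names),
    )
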