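"""Physicochemical property scales for the improved PseAAC encoder.

Nine per-residue scales ship with the package (see ``data/property_scales.tsv``
for sources): hydrophobicity, hydrophilicity, charge, flexibility,
irreplaceability, solvent-accessible surface area, polarity, polarizability
and rigidity.  Each scale is standardized to mean 0 and population standard
deviation 1 across the 20 residues before entering the sequence-order
correlation function, which makes the correlation scale-free — the standard
normalization in pseudo amino acid composition work.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS

__all__ = ["PROPERTY_NAMES", "PropertyTable", "load_property_table"]

PROPERTY_NAMES = (
    "hydrophobicity",
    "hydrophilicity",
    "charge",
    "flexibility",
    "irreplaceability",
    "solvent_accessible_surface_area",
    "polarity",
    "polarizability",
    "rigidity",
)


@dataclass(frozen=True)
class PropertyTable:
    """Raw and standardized per-residue property values.

    ``raw`` and ``normalized`` are DataFrames indexed by residue (A..Y in
    alphabetical order) with one column per property; ``normalized`` columns
    have mean 0 and population SD 1 across the 20 residues.
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.raw.index) != list(AMINO_ACIDS):
            raise ValueError("property table must cover exactly the 20 canonical residues")
        if self.raw.isna().any().any():
            raise ValueError("property table contains missing values")
        mu = self.normalized.mean(axis=0).to_numpy()
        sd = self.normalized.std(axis=0, ddof=0).to_numpy()
        if not (np.all(np.abs(mu) < 1e-9) and np.all(np.abs(sd - 1) < 1e-9)):
            raise ValueError("normalized scales must have mean 0 and population SD 1")

    @property
    def property_names(self) -> tuple[str, ...]:
        return tuple(self.raw.columns)

    def matrix(self, subset: tuple[str, ...] | list[str] | None = None) -> np.ndarray:
        """Standardized values as a (20, m) array in residue alphabetical order."""
        cols = list(subset) if subset is not None else list(self.normalized.columns)
        missing = set(cols) - set(self.normalized.columns)
        if missing:
            raise KeyError(f"unknown property name(s): {sorted(missing)}")
        return self.normalized[cols].to_numpy(dtype=float)


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    mu = df.mean(axis=0)
    sd = df.std(axis=0, ddof=0)
    if (sd == 0).any():
        flat = list(df.columns[sd == 0])
        raise ValueError(f"property scale(s) constant across residues: {flat}")
    return (df - mu) / sd


def load_property_table(path: str | Path | None = None) -> PropertyTable:
    """Load the shipped property TSV, or a user-supplied one with the same
    layout (``residue`` column + one column per property, 20 data rows)."""
    if path is None:
        source = resources.files("pepforge.data").joinpath("property_scales.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    if "residue" not in df.columns:
        raise ValueError("property table needs a 'residue' column")
    df = df.set_index("residue").sort_index()
    return PropertyTable(raw=df, normalized=_standardize(df))
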