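"""Labeled peptide FASTA input/output and train/test partitioning.

Peptides are short (typically under 50 residues) single-letter amino-acid
sequences over the 20 canonical letters.  Class labels (ACP = anticancer
peptide, NACP = non-anticancer peptide) travel either as a header prefix
(``>ACP_1 ...``) or in an external two-column table ``id<TAB>label``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from Bio import SeqIO

from .alphabet import ACP, AMINO_ACIDS, LABELS, NACP

__all__ = [
    "PeptideRecord",
    "Dataset",
    "FastaError",
    "read_fasta",
    "read_label_table",
    "write_fasta",
    "write_label_table",
    "split_dataset",
]

_CANONICAL = frozenset(AMINO_ACIDS)

LabelPolicy = Literal["from_header_prefix", "from_table", "unlabeled"]


class FastaError(ValueError):
    """Malformed FASTA input or an invalid peptide record."""


@dataclass(frozen=True)
class PeptideRecord:
    """One validated peptide: identifier, sequence, optional class label."""

    id: str
    sequence: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("peptide record requires a non-empty id")
        seq = self.sequence.upper()
        if not seq:
            raise FastaError(f"record {self.id!r}: empty sequence")
        bad = sorted(set(seq) - _CANONICAL)
        if bad:
            raise FastaError(
                f"record {self.id!r}: non-canonical residue(s) {', '.join(bad)}"
            )
        object.__setattr__(self, "sequence", seq)
        if self.label is not None and self.label not in LABELS:
            raise FastaError(
                f"record {self.id!r}: label must be one of {LABELS}, got {self.label!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Dataset:
    """An ordered collection of peptide records with unique ids."""

    records: tuple[PeptideRecord, ...]
    name: str = "dataset"

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise FastaError(f"duplicate record id {rec.id!r} in dataset {self.name!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[Optional[str]]:
        return [r.label for r in self.records]

    def class_counts(self) -> dict[str, int]:
        counts = {ACP: 0, NACP: 0}
        for rec in self.records:
            if rec.label is not None:
                counts[rec.label] += 1
        return counts


def _prescan(path: Path) -> None:
    # SeqIO silently skips junk before the first header; the contract wants a
    # line-numbered parse error instead.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaError(
                    f"{path}: line {lineno}: expected FASTA header, got {stripped[:40]!r}"
                )
            return


def read_fasta(
    path: str | Path,
    label_policy: LabelPolicy = "from_header_prefix",
    label_table: str | Path | dict[str, str] | None = None,
    name: str | None = None,
) -> Dataset:
    """Read a peptide FASTA file into a validated :class:`Dataset`.

    ``label_policy`` controls label attachment: ``from_header_prefix`` reads
    the label from an ``ACP``/``NACP`` prefix of the record id,
    ``from_table`` looks ids up in ``label_table`` (path to a two-column TSV
    or a dict), ``unlabeled`` attaches none.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan(path)
    table: dict[str, str] | None = None
    if label_policy == "from_table":
        if label_table is None:
            raise FastaError("label_policy='from_table' requires a label_table")
        table = label_table if isinstance(label_table, dict) else read_label_table(label_table)

    records: list[PeptideRecord] = []
    for seqrec in SeqIO.parse(str(path), "fasta"):
        rid = seqrec.id
        label: Optional[str] = None
        if label_policy == "from_header_prefix":
            if rid.upper().startswith(NACP):
                label = NACP
            elif rid.upper().startswith(ACP):
                label = ACP
            else:
                raise FastaError(
                    f"record {rid!r}: header does not start with ACP/NACP "
                    "(use label_policy='unlabeled' for unlabeled input)"
                )
        elif label_policy == "from_table":
            assert table is not None
            if rid not in table:
                raise FastaError(f"record {rid!r}: missing from label table")
            label = table[rid]
        records.append(PeptideRecord(id=rid, sequence=str(seqrec.seq), label=label))
    return Dataset(records=tuple(records), name=name or path.stem)


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read a two-column ``id<TAB>label`` table."""
    table: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FastaError(f"{path}: line {lineno}: expected 'id<TAB>label'")
        rid, label = parts[0].strip(), parts[1].strip().upper()
        if label not in LABELS:
            raise FastaError(f"{path}: line {lineno}: unknown label {label!r}")
        table[rid] = label
    return table


def write_fasta(dataset: Dataset, path: str | Path) -> Path:
    """Write a non-empty dataset as unwrapped FASTA; round-trips with
    :func:`read_fasta` (labels preserved when ids carry the class prefix)."""
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    buf = io.StringIO()
    for rec in dataset:
        buf.write(f">{rec.id}\n{rec.sequence}\n")
    path.write_text(buf.getvalue())
    return path


def write_label_table(dataset: Dataset, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"{r.id}\t{r.label}" for r in dataset if r.label is not None]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def _allocate_stratified(class_sizes: dict[str, int], n_train: int, fraction: float) -> dict[str, int]:
    # Largest-remainder allocation of the (already fixed) total training count
    # across classes, so per-class proportions track the overall fraction.
    ideal = {c: fraction * n for c, n in class_sizes.items()}
    base = {c: int(np.floor(v)) for c, v in ideal.items()}
    short = n_train - sum(base.values())
    order = sorted(class_sizes, key=lambda c: (-(ideal[c] - base[c]), c))
    for c in order:
        if short <= 0:
            break
        if base[c] < class_sizes[c]:
            base[c] += 1
            short -= 1
    # degenerate rounding corner: trim if floor already overshot
    for c in sorted(class_sizes, key=lambda c: (ideal[c] - base[c], c)):
        if short >= 0:
            break
        if base[c] > 0:
            base[c] -= 1
            short += 1
    return base


def split_dataset(
    dataset: Dataset,
    train_fraction: float = 0.7,
    stratified: bool = True,
    seed: int = 0,
) -> tuple[Dataset, Dataset]:
    """Partition into train/test with ``round(train_fraction * total)``
    training records (round-half-to-even), deterministically per seed.

    With ``stratified`` (default) the per-class training counts follow the
    overall fraction as closely as integer rounding allows; this requires a
    fully labeled dataset.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    total = len(dataset)
    n_train = round(train_fraction * total)
    rng = np.random.default_rng(seed)

    if stratified:
        if any(r.label is None for r in dataset):
            raise ValueError("stratified split requires a fully labeled dataset")
        by_class: dict[str, list[int]] = {}
        for i, rec in enumerate(dataset):
            by_class.setdefault(rec.label, []).append(i)  # type: ignore[arg-type]
        sizes = {c: len(ix) for c, ix in by_class.items()}
        alloc = _allocate_stratified(sizes, n_train, train_fraction)
        train_idx: set[int] = set()
        for c in sorted(by_class):
            ix = np.array(by_class[c])
            rng.shuffle(ix)
            train_idx.update(ix[: alloc[c]].tolist())
    else:
        perm = rng.permutation(total)
        train_idx = set(perm[:n_train].tolist())

    train = [r for i, r in enumerate(dataset) if i in train_idx]
    test = [r for i, r in enumerate(dataset) if i not in train_idx]
    return (
        Dataset(records=tuple(train), name=f"{dataset.name}:train"),
        Dataset(records=tuple(test), name=f"{dataset.name}:test"),
    )
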