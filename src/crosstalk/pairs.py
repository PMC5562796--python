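"""Ligand-receptor interaction database.

A curated table of ligand -> receptor interactions (in the style of the
Ramilowski et al. resource of ~2,500 human pairs) is the anchor of every
downstream analysis: bulk differential expression is classified pair-wise,
correlations are computed per cognate pair, and the single-cell network is
labeled by pairs.  Relations are not bijective: one ligand may bind several
receptors and vice versa.  Each (ligand, receptor) record is kept as an
independent pair; the per-ligand receptor group is exposed for the
sum-over-receptors correlation rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LRPair",
    "PairDB",
    "load_pairs",
    "count_unordered_pairs",
    "sample_random_pairs",
]


@dataclass(frozen=True, order=True)
class LRPair:
    """A single ligand-receptor interaction record.

    Gene symbols are upper-cased; a pair whose ligand and receptor symbol
    coincide is rejected (self-correlation is meaningless downstream).
    """

    ligand: str
    receptor: str

    def __post_init__(self) -> None:
        lig = str(self.ligand).strip().upper()
        rec = str(self.receptor).strip().upper()
        if not lig or not rec:
            raise ValueError("ligand and receptor symbols must be non-empty")
        if lig == rec:
            raise ValueError(f"ligand equals receptor symbol: {lig!r}")
        object.__setattr__(self, "ligand", lig)
        object.__setattr__(self, "receptor", rec)


class PairDB:
    """Deduplicated, ordered collection of :class:`LRPair` records.

    Parameters
    ----------
    pairs
        Iterable of :class:`LRPair` or ``(ligand, receptor)`` tuples.
        Duplicate records raise a warning and are dropped, keeping first
        occurrence order.
    """

    def __init__(self, pairs: Iterable[LRPair | tuple[str, str]]):
        seen: dict[LRPair, None] = {}
        n_dup = 0
        for p in pairs:
            if not isinstance(p, LRPair):
                p = LRPair(*p)
            if p in seen:
                n_dup += 1
            else:
                seen[p] = None
        if n_dup:
            warnings.warn(f"dropped {n_dup} duplicate ligand-receptor records")
        self._pairs: tuple[LRPair, ...] = tuple(seen)
        if not self._pairs:
            raise ValueError("pair database is empty")
        groups: dict[str, set[str]] = {}
        for p in self._pairs:
            groups.setdefault(p.ligand, set()).add(p.receptor)
        self._groups: Mapping[str, frozenset[str]] = {
            lig: frozenset(rs) for lig, rs in groups.items()
        }
        self._pair_set = frozenset((p.ligand, p.receptor) for p in self._pairs)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[LRPair]:
        return iter(self._pairs)

    def __contains__(self, item: object) -> bool:
        if isinstance(item, LRPair):
            return (item.ligand, item.receptor) in self._pair_set
        if isinstance(item, tuple) and len(item) == 2:
            return (str(item[0]).upper(), str(item[1]).upper()) in self._pair_set
        return False

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PairDB) and self._pairs == other._pairs

    def __repr__(self) -> str:
        return (
            f"PairDB({len(self)} pairs, {len(self.ligands)} ligands, "
            f"{len(self.receptors)} receptors)"
        )

    # -- views ---------------------------------------------------------------
    @property
    def pairs(self) -> tuple[LRPair, ...]:
        return self._pairs

    @property
    def ligands(self) -> frozenset[str]:
        return frozenset(self._groups)

    @property
    def receptors(self) -> frozenset[str]:
        return frozenset(r for rs in self._groups.values() for r in rs)

    @property
    def receptor_groups(self) -> Mapping[str, frozenset[str]]:
        """Map ligand -> set of cognate receptors."""
        return dict(self._groups)

    @property
    def genes(self) -> frozenset[str]:
        return self.ligands | self.receptors

    def receptor_group(self, ligand: str) -> frozenset[str]:
        """All receptors recorded for ``ligand`` (sum-over-receptors rule)."""
        lig = str(ligand).strip().upper()
        if lig not in self._groups:
            raise KeyError(f"unknown ligand: {ligand!r}")
        return self._groups[lig]

    def n_noninteracting(self) -> int:
        """Number of non-interacting (ligand, receptor) combinations.

        The cross product minus the curated pairs and the cells where the
        ligand and receptor would be the same gene symbol — the pool
        :func:`sample_random_pairs` draws from with ``exclude_known``.
        """
        return (
            len(self.ligands) * len(self.receptors)
            - len(self)
            - len(self.ligands & self.receptors)
        )

    def summary(self) -> dict[str, int]:
        return {
            "n_pairs": len(self),
            "n_ligands": len(self.ligands),
            "n_receptors": len(self.receptors),
        }

    # -- I/O -----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.ligand, p.receptor) for p in self._pairs],
            columns=["ligand", "receptor"],
        )

    def write(self, path: str | Path) -> None:
        """Write the normalized 2-column TSV (with header)."""
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_pairs(path: str | Path, header: bool | str = "auto") -> PairDB:
    """Load a ligand-receptor pair table from a 2-column TSV.

    Parameters
    ----------
    path
        TSV with at least two columns: ligand symbol, receptor symbol.
    header : bool or "auto"
        Whether the first line is a header.  ``"auto"`` treats the first
        line as a header when its second field is exactly ``"receptor"``
        (case-insensitive).

    Raises
    ------
    ValueError
        On an empty file or a row with a missing field (the error names
        the 1-based line number).
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    # drop trailing blank lines but flag interior malformed ones
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise ValueError(f"empty pair file: {path}")
    start = 0
    if header == "auto":
        fields = lines[0].rstrip("\n").split("\t")
        if len(fields) >= 2 and fields[1].strip().lower() == "receptor":
            start = 1
    elif header:
        start = 1
    if start == len(lines):
        raise ValueError(f"pair file has a header but no data rows: {path}")
    for lineno, line in enumerate(lines[start:], start=start + 1):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ValueError(f"malformed pair row at line {lineno} of {path}")
        rows.append((fields[0], fields[1]))
    return PairDB(rows)


def count_unordered_pairs(n: int) -> int:
    """Number of unordered pairs among ``n`` items, ``n*(n-1)/2``.

    This is the arithmetic behind the size of the all-random-pairs
    background set (2,558 curated pairs give 3,270,403 combinations).
    Exact integer arithmetic; ``n`` must be >= 1.
    """
    n = int(n)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return n * (n - 1) // 2


def sample_random_pairs(
    db: PairDB,
    n_sample: int,
    seed: int | np.random.Generator,
    exclude_known: bool = True,
) -> list[tuple[str, str]]:
    """Sample non-interacting (ligand, receptor) pairs for a null distribution.

    Draws uniformly without replacement from the cross product
    ``ligands x receptors``, excluding pairs where ligand and receptor are
    the same gene symbol and, when ``exclude_known`` is set, all curated
    interacting pairs.  Reproducible under a fixed seed.
    """
    if n_sample < 1:
        raise ValueError("n_sample must be >= 1")
    rng = np.random.default_rng(seed)
    ligands = sorted(db.ligands)
    receptors = sorted(db.receptors)
    n_rec = len(receptors)
    rec_index = {r: i for i, r in enumerate(receptors)}
    forbidden: set[int] = set()
    for li, lig in enumerate(ligands):
        if lig in rec_index:  # same molecule on both sides
            forbidden.add(li * n_rec + rec_index[lig])
    if exclude_known:
        for p in db.pairs:
            li = ligands.index(p.ligand)
            forbidden.add(li * n_rec + rec_index[p.receptor])
    total = len(ligands) * n_rec
    allowed = np.setdiff1d(
        np.arange(total), np.fromiter(forbidden, dtype=int, count=len(forbidden))
    )
    if n_sample > allowed.size:
        raise ValueError(
            f"requested {n_sample} random pairs but only {allowed.size} "
            "non-interacting combinations exist"
        )
    chosen = rng.choice(allowed, size=n_sample, replace=False)
    return [(ligands[i // n_rec], receptors[i % n_rec]) for i in chosen]
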