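"""Intron sets.

An intron is identified by ``(sequence, start, end)`` with 1-based inclusive
coordinates of its first and last intronic base.  Sets are mathematical sets
(each intron counted once) but carry an optional per-intron support count —
the number of spliced alignments that induced it — for downstream filtering
and hints export.  Identity is strand-agnostic: inferring the strand of a
spliced alignment requires splice-site sequence inspection, which is out of
scope here.
"""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, Tuple

import pandas as pd

Intron = Tuple[str, int, int]


class IntronSet:
    """A set of genomic introns with per-intron support counts."""

    __slots__ = ("_support",)

    def __init__(self, introns: Iterable[Intron] = ()):
        self._support: Dict[Intron, int] = {}
        for intron in introns:
            self.add(*intron)

    def add(self, sequence: str, start: int, end: int, count: int = 1) -> None:
        if end < start:
            raise ValueError(f"intron end {end} < start {start}")
        if count < 1:
            raise ValueError("support count must be >= 1")
        key = (sequence, int(start), int(end))
        self._support[key] = self._support.get(key, 0) + count

    def update(self, other: "IntronSet") -> None:
        for key, count in other._support.items():
            self._support[key] = self._support.get(key, 0) + count

    def support(self, sequence: str, start: int, end: int) -> int:
        return self._support.get((sequence, start, end), 0)

    def filtered(self, min_support: int = 1) -> "IntronSet":
        """Subset of introns supported by at least ``min_support`` alignments."""
        out = IntronSet()
        out._support = {k: v for k, v in self._support.items() if v >= min_support}
        return out

    def keys(self) -> set:
        return set(self._support)

    def __contains__(self, key: Intron) -> bool:
        return key in self._support

    def __len__(self) -> int:
        return len(self._support)

    def __iter__(self) -> Iterator[Intron]:
        return iter(self._support)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntronSet):
            return NotImplemented
        return self.keys() == other.keys()

    def __repr__(self) -> str:  # pragma: no cover
        return f"IntronSet({len(self)} introns)"

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self._support.items())
        return pd.DataFrame(
            [(s, a, b, n) for (s, a, b), n in rows],
            columns=["sequence", "start", "end", "support"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "IntronSet":
        df = pd.read_csv(path, sep="\t")
        out = cls()
        for row in df.itertuples(index=False):
            out.add(str(row.sequence), int(row.start), int(row.end), int(getattr(row, "support", 1)))
        return out
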