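"""Rank-ordered taxonomic lineages.

Every reference barcode and every classified read ultimately resolves to a
lineage over the seven classical ranks (kingdom through species). The unit of
assignment throughout the pipeline is the genus; families matter for the
host-plant arithmetic (Rosaceae and Fabaceae for *Osmia cornifrons*) and the
class label matters for the Magnoliopsida plausibility filter during
reference cleaning.

A lineage may be truncated: once a rank is unknown, every deeper rank is
unknown too. Unknown ranks are represented as ``None`` in memory and as empty
cells in the 8-column lineage TSV (id + seven ranks).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
_RANK_INDEX = {rank: i for i, rank in enumerate(RANKS)}

#: In-memory marker for an unknown taxon at a rank.
UNKNOWN = None


def _normalize(name: Optional[str]) -> Optional[str]:
    if name is None:
        return None
    name = name.strip()
    return name if name else None


@dataclass(frozen=True)
class Lineage:
    """An ordered (kingdom → species) taxonomic lineage.

    Parameters
    ----------
    names:
        Seven taxon names in rank order; ``None`` (or an empty/whitespace
        string, normalised to ``None``) marks an unknown rank. Once a rank is
        unknown all deeper ranks must be unknown.
    """

    names: tuple[Optional[str], ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise ValueError(
                f"lineage needs {len(RANKS)} ranks, got {len(self.names)}"
            )
        cleaned = tuple(_normalize(n) for n in self.names)
        object.__setattr__(self, "names", cleaned)
        seen_unknown = False
        for rank, name in zip(RANKS, cleaned):
            if name is None:
                seen_unknown = True
            elif seen_unknown:
                raise ValueError(
                    f"rank '{rank}' is named ('{name}') below an unknown rank"
                )

    @classmethod
    def from_taxa(
        cls,
        kingdom: Optional[str] = None,
        phylum: Optional[str] = None,
        class_: Optional[str] = None,
        order: Optional[str] = None,
        family: Optional[str] = None,
        genus: Optional[str] = None,
        species: Optional[str] = None,
    ) -> "Lineage":
        return cls((kingdom, phylum, class_, order, family, genus, species))

    def taxon_at_rank(self, rank: str) -> Optional[str]:
        """Name stored at ``rank``, or ``None`` if unknown."""
        try:
            idx = _RANK_INDEX[rank]
        except KeyError:
            raise ValueError(
                f"unrecognized rank '{rank}'; expected one of {', '.join(RANKS)}"
            ) from None
        return self.names[idx]

    # Convenience accessors for the ranks the pipeline actually branches on.
    @property
    def genus(self) -> Optional[str]:
        return self.names[_RANK_INDEX["genus"]]

    @property
    def family(self) -> Optional[str]:
        return self.names[_RANK_INDEX["family"]]

    @property
    def class_(self) -> Optional[str]:
        return self.names[_RANK_INDEX["class"]]


def taxon_at_rank(lineage: Lineage, rank: str) -> Optional[str]:
    """Module-level alias of :meth:`Lineage.taxon_at_rank`."""
    return lineage.taxon_at_rank(rank)


def lowest_common_ancestor(lineages: Iterable[Lineage]) -> Lineage:
    """Deepest lineage on which all inputs agree.

    Agreement is exact, case-sensitive string equality rank by rank from
    kingdom downwards; the result is unknown from the first rank where any
    two inputs disagree (or any input is unknown). The LCA of a single
    lineage is itself.
    """
    items = list(lineages)
    if not items:
        raise ValueError("lowest_common_ancestor of an empty collection")
    names: list[Optional[str]] = []
    disagreed = False
    for i in range(len(RANKS)):
        first = items[0].names[i]
        if disagreed or first is None or any(l.names[i] != first for l in items):
            disagreed = True
            names.append(None)
        else:
            names.append(first)
    return Lineage(tuple(names))


def read_lineage_table(path) -> dict[str, Lineage]:
    """Read an 8-column lineage TSV (id + the seven ranks; header required).

    Empty cells mean unknown. Returns a mapping id → :class:`Lineage`.
    """
    out: dict[str, Lineage] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) != 8 or [h.lower() for h in header[1:]] != list(RANKS):
            raise ValueError(
                f"{path}: expected header 'id\\t" + "\\t".join(RANKS) + "'"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 8:
                raise ValueError(f"{path}:{lineno}: expected 8 columns, got {len(row)}")
            seq_id = row[0].strip()
            if seq_id in out:
                raise ValueError(f"{path}:{lineno}: duplicate id '{seq_id}'")
            out[seq_id] = Lineage(tuple(row[1:]))
    return out


def write_lineage_table(lineages: Mapping[str, Lineage], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("id",) + RANKS)
        for seq_id in lineages:
            lin = lineages[seq_id]
            writer.writerow([seq_id] + [n if n is not None else "" for n in lin.names])
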