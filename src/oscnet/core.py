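"""Shared domain types: edge hypotheses, annotations and ranking tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

ACTIVATION = "activation"
REPRESSION = "repression"


@dataclass(frozen=True, order=True)
class EdgeHypothesis:
    """A signed candidate regulation ``source -> target``."""

    target: str
    source: str
    sign: str  # ACTIVATION or REPRESSION

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, REPRESSION):
            raise ValueError(f"sign must be activation/repression, got {self.sign!r}")

    @property
    def is_self_repression(self) -> bool:
        return self.source == self.target and self.sign == REPRESSION

    @property
    def key(self) -> str:
        arrow = "->" if self.sign == ACTIVATION else "-|"
        return f"{self.source}{arrow}{self.target}"

    @classmethod
    def from_key(cls, key: str) -> "EdgeHypothesis":
        if "->" in key:
            src, tgt = key.split("->")
            return cls(tgt, src, ACTIVATION)
        if "-|" in key:
            src, tgt = key.split("-|")
            return cls(tgt, src, REPRESSION)
        raise ValueError(f"not an edge key: {key!r}")


@dataclass(frozen=True)
class GeneAnnotation:
    """Prior knowledge about a gene's possible regulatory roles.

    ``regulator_role`` is one of ``activator_only``, ``repressor_only``,
    ``either`` or ``none``; ``may_be_target`` says whether the gene may
    have in-edges.  A gene with role ``none`` and ``may_be_target=False``
    takes part in no edge hypothesis.
    """

    gene: str
    may_be_target: bool = True
    regulator_role: str = "either"

    VALID_ROLES = ("activator_only", "repressor_only", "either", "none")

    def __post_init__(self) -> None:
        if self.regulator_role not in self.VALID_ROLES:
            raise ValueError(f"unknown regulator_role {self.regulator_role!r}")

    def allows(self, sign: str, as_source: bool) -> bool:
        if not as_source:
            return self.may_be_target
        if self.regulator_role == "none":
            return False
        if self.regulator_role == "activator_only":
            return sign == ACTIVATION
        if self.regulator_role == "repressor_only":
            return sign == REPRESSION
        return True


def read_annotations(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read a gene annotation TSV: ``gene  may_be_target  regulator_role``."""
    out: dict[str, GeneAnnotation] = {}
    with open(path, encoding="utf-8") as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#") or ln.startswith("gene\t"):
                continue
            gene, target_flag, role = ln.split("\t")
            out[gene] = GeneAnnotation(gene, target_flag.strip().lower() in ("1", "true", "yes"), role.strip())
    return out


@dataclass
class RankingTable:
    """An ordered list of scored items with 1-based ranks.

    ``direction`` states whether lower or higher scores are better; ties
    are broken by the documented rule (lexicographic item key by default)
    and the rule is recorded in ``tiebreak_note``.
    """

    items: list[tuple[str, float, float]]  # (item_key, score, rank)
    direction: str = "lower_is_better"
    tiebreak_note: str = "ties broken by lexicographic item key"

    def __post_init__(self) -> None:
        if self.direction not in ("lower_is_better", "higher_is_better"):
            raise ValueError(f"bad direction {self.direction!r}")

    @classmethod
    def from_scores(cls, scores: dict[str, float] | Iterable[tuple[str, float]],
                    direction: str = "lower_is_better",
                    tiebreak_note: str = "ties broken by lexicographic item key",
                    ) -> "RankingTable":
        """Rank items by score (best first), breaking ties by item key."""
        pairs = list(scores.items()) if isinstance(scores, dict) else list(scores)
        sign = 1.0 if direction == "lower_is_better" else -1.0
        ordered = sorted(pairs, key=lambda kv: (sign * kv[1], kv[0]))
        items = [(k, s, float(r)) for r, (k, s) in enumerate(ordered, start=1)]
        return cls(items, direction, tiebreak_note)

    def rank_of(self, key: str) -> float:
        for k, _, r in self.items:
            if k == key:
                return r
        raise KeyError(key)

    def score_of(self, key: str) -> float:
        for k, s, _ in self.items:
            if k == key:
                return s
        raise KeyError(key)

    @property
    def keys(self) -> list[str]:
        return [k for k, _, _ in self.items]

    def top(self, n: int) -> list[str]:
        return self.keys[:n]

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)


def write_ranking(table: RankingTable, path: str | Path,
                  item_column: str = "item",
                  extra_columns: dict[str, Sequence] | None = None) -> None:
    """Write a ranking as a TSV with columns ``item, score, rank`` (+extras)."""
    extra = extra_columns or {}
    with open(path, "w", encoding="utf-8") as fh:
        header = [item_column, "score", "rank"] + list(extra)
        fh.write("\t".join(header) + "\n")
        for i, (key, score, rank) in enumerate(table.items):
            row = [key, f"{score:.10g}", f"{rank:g}"]
            row += [str(extra[c][i]) for c in extra]
            fh.write("\t".join(row) + "\n")
        fh.write(f"# direction: {table.direction}; {table.tiebreak_note}\n")


def read_ranking(path: str | Path) -> RankingTable:
    items: list[tuple[str, float, float]] = []
    direction, note = "lower_is_better", ""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        for ln in fh:
            ln = ln.rstrip("\n")
            if ln.startswith("#"):
                body = ln.lstrip("# ")
                if body.startswith("direction:"):
                    direction, _, note = body[len("direction:"):].partition(";")
                    direction, note = direction.strip(), note.strip()
                continue
            cells = ln.split("\t")
            items.append((cells[0], float(cells[1]), float(cells[2])))
    return RankingTable(items, direction, note)
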