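"""Time-series expression containers and delimited-text I/O.

The universal input of the pipeline is a matrix of gene expression traces
sampled on a shared time grid.  On disk this is a tab-delimited text file
whose first row holds the (strictly increasing) sampling times and whose
first column holds unique gene names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class TimeSeriesError(ValueError):
    """Raised for malformed expression matrices."""


@dataclass
class TimeSeriesSet:
    """A named collection of expression traces on a shared time grid.

    Parameters
    ----------
    gene_names:
        Unique gene identifiers, one per trace.
    times:
        Strictly increasing sampling times (arbitrary units).
    values:
        Array of shape ``(n_genes, n_times)``; ``values[i]`` is the trace
        of ``gene_names[i]``.
    replicate_id:
        Label distinguishing replicate datasets.
    """

    gene_names: list[str]
    times: np.ndarray
    values: np.ndarray
    replicate_id: str = "rep1"
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.gene_names) != len(set(self.gene_names)):
            raise TimeSeriesError("duplicate gene names in replicate")
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise TimeSeriesError("sampling times must be strictly increasing")
        if self.values.shape != (len(self.gene_names), self.times.size):
            raise TimeSeriesError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_names)} genes x {self.times.size} times"
            )
        self._index = {g: i for i, g in enumerate(self.gene_names)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_times(self) -> int:
        return self.times.size

    def trace(self, gene: str) -> np.ndarray:
        """Return the expression trace of ``gene``."""
        try:
            return self.values[self._index[gene]]
        except KeyError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def subset(self, genes: list[str]) -> "TimeSeriesSet":
        """Restrict to ``genes`` (kept in the given order)."""
        rows = [self._index[g] for g in genes]
        return TimeSeriesSet(list(genes), self.times.copy(),
                             self.values[rows].copy(), self.replicate_id)

    def window(self, t_lo: float, t_hi: float) -> "TimeSeriesSet":
        """Restrict to sample times in ``[t_lo, t_hi]``."""
        keep = (self.times >= t_lo) & (self.times <= t_hi)
        return TimeSeriesSet(list(self.gene_names), self.times[keep],
                             self.values[:, keep], self.replicate_id)


def read_timeseries(path: str | Path, replicate_id: str | None = None) -> TimeSeriesSet:
    """Read an expression matrix from a tab-delimited text file.

    The first row is the numeric header of sampling times; each following
    row is ``gene<TAB>v1<TAB>v2...``.  Non-numeric cells and non-increasing
    times are rejected with errors naming the offending location.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise TimeSeriesError(f"{path}: empty file")
    header = lines[0].split("\t")
    # allow an optional leading label cell in the header row
    if header and not _is_number(header[0]):
        header = header[1:]
    times = []
    for j, cell in enumerate(header):
        if not _is_number(cell):
            raise TimeSeriesError(f"{path}: non-numeric time in header column {j + 1}: {cell!r}")
        times.append(float(cell))
    genes: list[str] = []
    rows: list[list[float]] = []
    for i, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        gene, data = cells[0], cells[1:]
        if gene in genes:
            raise TimeSeriesError(f"{path}: duplicate gene {gene!r} at row {i}")
        if len(data) != len(times):
            raise TimeSeriesError(
                f"{path}: row {i} has {len(data)} values, expected {len(times)}")
        row = []
        for j, cell in enumerate(data):
            if not _is_number(cell):
                raise TimeSeriesError(
                    f"{path}: non-numeric cell at row {i}, column {j + 2}: {cell!r}")
            row.append(float(cell))
        genes.append(gene)
        rows.append(row)
    return TimeSeriesSet(genes, np.array(times), np.array(rows),
                         replicate_id or path.stem)


def write_timeseries(ts: TimeSeriesSet, path: str | Path) -> None:
    """Write a :class:`TimeSeriesSet` in the tab-delimited input format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time\t" + "\t".join(f"{t:.10g}" for t in ts.times) + "\n")
        for g, row in zip(ts.gene_names, ts.values):
            fh.write(g + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def align_replicates(replicates: list[TimeSeriesSet]) -> list[TimeSeriesSet]:
    """Restrict all replicates to their common gene set.

    Genes missing from any replicate are dropped (the caller is expected to
    log the drop); the order of the first replicate is kept.
    """
    if not replicates:
        return []
    common = set(replicates[0].gene_names)
    for rep in replicates[1:]:
        common &= set(rep.gene_names)
    order = [g for g in replicates[0].gene_names if g in common]
    return [rep.subset(order) for rep in replicates]


def _is_number(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return False
    return True
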