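"""Keyword validation of neighborhoods and positional occurrence matrices.

The discovery screen keeps only neighborhoods whose gene names contain both
"CRISPR" and "Cas1" (case-insensitive substrings; one gene may satisfy both),
then pools product names per signed position relative to the focal gene and
computes, for each keyword, the percentage of validated regions carrying a
matching gene at that position.  The resulting keyword x position matrix is
the tabular form of the neighboring-gene heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cappscan.neighborhood import Neighborhood

DEFAULT_KEYWORDS = (
    "CRISPR",
    "Cas1",
    "Cas2",
    "primase",
    "polymerase",
    "helicase",
    "nuclease",
    "transposase",
    "argonaute",
)

DEFAULT_FIRST_FILTER = "CRISPR"
DEFAULT_SECOND_FILTER = "Cas1"


def match_keyword(product_name: str, keyword: str) -> bool:
    """True iff ``keyword`` occurs as a case-insensitive substring of the name."""
    if not product_name or not keyword:
        raise ValueError("product_name and keyword must be non-empty")
    return keyword.lower() in product_name.lower()


def validate_region(
    nbhd: Neighborhood,
    first_filter: str = DEFAULT_FIRST_FILTER,
    second_filter: str = DEFAULT_SECOND_FILTER,
) -> bool:
    """Two-stage keyword screen over neighbor gene names.

    A region passes iff some neighbor matches ``first_filter`` AND some
    neighbor matches ``second_filter``; a single gene may satisfy both
    (e.g. "CRISPR-associated endonuclease Cas1").
    """
    names = [rec.product_name for _, rec in nbhd.neighbors]
    return any(match_keyword(n, first_filter) for n in names) and any(
        match_keyword(n, second_filter) for n in names
    )


def _position_axis(window: int) -> list[int]:
    return [p for p in range(-window, window + 1) if p != 0]


@dataclass
class KeywordOccurrenceMatrix:
    """Keyword x relative-position occurrence counts over validated regions.

    ``counts[k, p]`` is the number of regions whose gene at position ``p``
    exists and matches keyword ``k``.  Percentages use the global region
    count as denominator by default; regions with a truncated window simply
    contribute no count at missing positions.  ``position_denominators``
    holds, per position, the number of regions that have a gene there, for
    the alternative per-position normalisation.
    """

    keywords: tuple[str, ...]
    window: int
    counts: pd.DataFrame
    n_regions: int
    position_denominators: pd.Series = field(repr=False, default=None)

    @property
    def positions(self) -> list[int]:
        return _position_axis(self.window)

    def percentages(self, per_position_denominator: bool = False) -> pd.DataFrame:
        if per_position_denominator:
            denom = self.position_denominators.replace(0, np.nan)
            return 100.0 * self.counts.div(denom, axis=1).fillna(0.0)
        return 100.0 * self.counts / self.n_regions


def build_occurrence_matrix(
    validated: Sequence[Neighborhood],
    keywords: Iterable[str] = DEFAULT_KEYWORDS,
) -> KeywordOccurrenceMatrix:
    """Count keyword matches per signed position over validated regions.

    All regions must share the same window.  Raises ``ValueError`` on an
    empty region list (percentages would be undefined).
    """
    validated = list(validated)
    if not validated:
        raise ValueError("no validated regions: occurrence percentages are undefined")
    keywords = tuple(keywords)
    windows = {n.window for n in validated}
    if len(windows) != 1:
        raise ValueError(f"regions mix window sizes: {sorted(windows)}")
    window = windows.pop()
    positions = _position_axis(window)
    counts = pd.DataFrame(0, index=list(keywords), columns=positions, dtype=int)
    denominators = pd.Series(0, index=positions, dtype=int)
    for nbhd in validated:
        for p, rec in nbhd.neighbors:
            denominators[p] += 1
            for kw in keywords:
                if match_keyword(rec.product_name, kw):
                    counts.loc[kw, p] += 1
    return KeywordOccurrenceMatrix(
        keywords=keywords,
        window=window,
        counts=counts,
        n_regions=len(validated),
        position_denominators=denominators,
    )


def write_heatmap_table(matrix: KeywordOccurrenceMatrix, path, precision: int = 1) -> None:
    """Write percentages as TSV (keyword rows, position columns, 1 decimal).

    The header comment carries ``n_regions`` so a reader can reconstruct the
    integer counts exactly (for region counts up to a few hundred, the
    1-decimal rounding is invertible).
    """
    pct = matrix.percentages()
    with open(path, "w") as fh:
        fh.write(f"# n_regions={matrix.n_regions}\twindow={matrix.window}\n")
        fh.write("keyword\t" + "\t".join(str(p) for p in pct.columns) + "\n")
        for kw in pct.index:
            cells = "\t".join(f"{v:.{precision}f}" for v in pct.loc[kw])
            fh.write(f"{kw}\t{cells}\n")


def read_heatmap_table(path) -> KeywordOccurrenceMatrix:
    """Read a heatmap TSV written by :func:`write_heatmap_table`."""
    with open(path) as fh:
        meta = fh.readline().strip().lstrip("# ").split("\t")
        kv = dict(item.split("=") for item in meta)
        n_regions = int(kv["n_regions"])
        window = int(kv["window"])
        header = fh.readline().rstrip("\n").split("\t")
        positions = [int(p) for p in header[1:]]
        keywords, rows = [], []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            keywords.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    pct = pd.DataFrame(rows, index=keywords, columns=positions)
    counts = (pct * n_regions / 100.0).round().astype(int)
    return KeywordOccurrenceMatrix(
        keywords=tuple(keywords),
        window=window,
        counts=counts,
        n_regions=n_regions,
        position_denominators=pd.Series(n_regions, index=positions, dtype=int),
    )


def render_heatmap(matrix: KeywordOccurrenceMatrix, path) -> None:
    """Optional PNG rendering of the occurrence matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pct = matrix.percentages()
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(pct.columns)), 0.5 * len(pct.index) + 2))
    im = ax.imshow(pct.values, aspect="auto", cmap="viridis", vmin=0, vmax=100)
    ax.set_xticks(range(len(pct.columns)), [str(c) for c in pct.columns], rotation=90, fontsize=6)
    ax.set_yticks(range(len(pct.index)), pct.index)
    ax.set_xlabel("position relative to focal gene")
    fig.colorbar(im, ax=ax, label="occurrence (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
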