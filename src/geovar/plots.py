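"""GeoVar stacked-abundance plots and binned allele-frequency heatmaps.

The figure-planning step (:func:`plan_geovar`, :func:`bin_table`) is a pure
function of its inputs and is what the tests exercise; rendering wraps the
plan in matplotlib. Vector output is kept byte-reproducible by pinning the
SVG hash salt and stripping the date metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap
from matplotlib.patches import Rectangle

from .freqtable import FrequencyTable
from .geocode import CodeTally

plt.rcParams["svg.hashsalt"] = "geovar"

LETTER_COLORS = {"u": "#f2f2f2", "R": "#74a9cf", "C": "#045a8d"}
REMAINDER_COLOR = "#bdbdbd"

#: Default nonlinear minor-allele-frequency bins: the singleton {0} bin,
#: then (0,1%], (1%,5%], (5%,10%], (10%,20%], (20%,50%], (50%,100%].
DEFAULT_BIN_EDGES = (0.0, 0.01, 0.05, 0.10, 0.20, 0.50, 1.00)


@dataclass(frozen=True)
class BinLegend:
    """Ordered frequency bins: {0}, then half-open intervals (lo, hi].

    ``edges`` are the interval boundaries after the zero bin; colors run from
    lightest (frequency zero) to darkest (highest frequency).
    """

    edges: tuple[float, ...] = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) < 2 or e[0] != 0.0 or e[-1] != 1.0 or any(
            a >= b for a, b in zip(e, e[1:])
        ):
            raise ValueError("edges must increase from 0.0 to 1.0")

    @property
    def n_bins(self) -> int:
        return len(self.edges)  # zero bin + len(edges)-1 intervals

    @property
    def labels(self) -> list[str]:
        labs = ["0"]
        for a, b in zip(self.edges, self.edges[1:]):
            labs.append(f"({a:g}, {b:g}]")
        return labs

    def bin_of(self, freq) -> np.ndarray:
        """Bin index per frequency: 0 for exactly zero, then interval index."""
        f = np.asarray(freq, dtype=float)
        if np.any((f < 0) | (f > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        # side='left' puts f == edge into the lower (lo, hi] interval
        idx = np.searchsorted(self.edges, f, side="left")
        return np.where(f == 0, 0, idx)

    def colors(self) -> list[str]:
        cmap = plt.get_cmap("Blues")
        return [matplotlib.colors.to_hex(cmap(x)) for x in np.linspace(0.04, 1.0, self.n_bins)]


@dataclass(frozen=True)
class GeoVarFigure:
    """Plan for a stacked code-abundance plot: blocks bottom-up by rank."""

    blocks: tuple[tuple[str, int, float], ...]  # (code, count, proportion)
    remainder_count: int
    remainder_proportion: float
    total: int

    def __post_init__(self) -> None:
        s = sum(p for _, _, p in self.blocks) + self.remainder_proportion
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"displayed proportions plus remainder must sum to 1 (got {s})")


def plan_geovar(tally: CodeTally, display_cutoff: float = 0.005) -> GeoVarFigure:
    """Select codes to display individually; collapse the rest into one block.

    Codes with proportion >= ``display_cutoff`` are kept, ordered from the
    most abundant (bottom of the stack) upward; everything rarer is merged
    into a single remainder block.
    """
    if not 0 <= display_cutoff < 1:
        raise ValueError("display_cutoff must lie in [0, 1)")
    total = tally.total
    shown = []
    rem = 0
    for code in tally.rank_order:
        n = tally.counts[code]
        if display_cutoff == 0 or n / total >= display_cutoff:
            shown.append((code, n, n / total))
        else:
            rem += n
    return GeoVarFigure(
        blocks=tuple(shown),
        remainder_count=rem,
        remainder_proportion=rem / total,
        total=total,
    )


def render_geovar(
    tally: CodeTally,
    display_cutoff: float = 0.005,
    path=None,
    group_labels=None,
    title: str | None = None,
    figsize=(5.0, 7.0),
):
    """Draw the stacked code-abundance plot; returns (plan, figure).

    Each displayed code is a horizontal band whose height is its proportion,
    with one colored cell per group letter and a count/percentage annotation
    on the right; rarer codes are collapsed into a gray remainder block at
    the top.
    """
    plan = plan_geovar(tally, display_cutoff)
    k = len(plan.blocks[0][0]) if plan.blocks else (
        len(next(iter(tally.counts))) if tally.counts else 0
    )
    fig, ax = plt.subplots(figsize=figsize)
    y = 0.0
    for code, count, prop in plan.blocks:
        for j, letter in enumerate(code):
            ax.add_patch(
                Rectangle((j, y), 1.0, prop, facecolor=LETTER_COLORS[letter],
                          edgecolor="white", linewidth=0.4)
            )
            if prop > 0.02:
                ax.text(j + 0.5, y + prop / 2, letter, ha="center", va="center",
                        fontsize=8, color="black" if letter != "C" else "white")
        ax.text(k + 0.15, y + prop / 2, f"{count:,} ({100 * prop:.1f}%)",
                va="center", fontsize=8)
        y += prop
    if plan.remainder_count:
        ax.add_patch(Rectangle((0, y), k, plan.remainder_proportion,
                               facecolor=REMAINDER_COLOR, edgecolor="white"))
        ax.text(k + 0.15, y + plan.remainder_proportion / 2,
                f"{plan.remainder_count:,} ({100 * plan.remainder_proportion:.1f}%)",
                va="center", fontsize=8)
    ax.set_xlim(0, k + 2.2)
    ax.set_ylim(0, 1)
    if group_labels is not None:
        ax.set_xticks(np.arange(k) + 0.5)
        ax.set_xticklabels(group_labels, rotation=90, fontsize=8)
    else:
        ax.set_xticks([])
    ax.set_yticks([])
    for s in ax.spines.values():
        s.set_visible(False)
    ax.set_ylabel("cumulative proportion of variants (most abundant code at bottom)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        _save(fig, path)
    return plan, fig


def bin_table(table: FrequencyTable, legend: BinLegend | None = None,
              n_variants: int | None = 100, seed: int = 0) -> np.ndarray:
    """Bin per-group frequencies of a (sub)sampled set of variants.

    Returns an integer matrix (variants x groups) of bin indices; sampling
    without replacement is reproducible from ``seed``.
    """
    legend = legend or BinLegend()
    if len(table) == 0:
        raise ValueError("empty table")
    freqs = table.freqs
    if n_variants is not None and n_variants < len(table):
        rng = np.random.default_rng(seed)
        rows = np.sort(rng.choice(len(table), size=n_variants, replace=False))
        freqs = freqs[rows]
    return legend.bin_of(freqs)


def render_heatmap(
    table: FrequencyTable,
    legend: BinLegend | None = None,
    n_variants: int | None = 100,
    seed: int = 0,
    path=None,
    figsize=(6.0, 8.0),
):
    """Binned allele-frequency heatmap: sampled variants x groups."""
    legend = legend or BinLegend()
    bins = bin_table(table, legend, n_variants, seed)
    cmap = ListedColormap(legend.colors())
    fig, ax = plt.subplots(figsize=figsize)
    ax.imshow(bins, aspect="auto", cmap=cmap, vmin=0, vmax=legend.n_bins - 1,
              interpolation="nearest")
    ax.set_xticks(range(len(table.group_order)))
    ax.set_xticklabels(table.group_order, rotation=90, fontsize=8)
    ax.set_yticks([])
    ax.set_ylabel("variants")
    handles = [Rectangle((0, 0), 1, 1, facecolor=c) for c in legend.colors()]
    ax.legend(handles, legend.labels, title="minor allele frequency",
              loc="upper left", bbox_to_anchor=(1.02, 1.0), fontsize=7)
    fig.tight_layout()
    if path is not None:
        _save(fig, path)
    return bins, fig


def _save(fig, path) -> None:
    """Save with reproducible bytes for SVG output."""
    p = str(path)
    if p.endswith(".svg"):
        fig.savefig(p, metadata={"Date": None})
    else:
        fig.savefig(p)
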