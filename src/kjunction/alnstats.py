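"""Structure-guided alignment conservation statistics.

Works on multiple sequence alignments (Stockholm or aligned FASTA, read
with Bio.AlignIO) of a structured RNA family.  Columns of interest are
designated by a *mask* mapping k-turn role labels (as produced by the
annotation module against a crystal structure) to alignment columns;
per-column base composition, information content and joint
base-combination frequencies at role pairs (e.g. 1b.1n) are computed.

Information content is the sequence-logo quantity
``IC = 2 + sum_b f_b log2 f_b`` in bits over the gap-excluded base
frequencies; T is normalised to U and IUPAC ambiguity codes count as
gaps.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

BASES = ("A", "C", "G", "U")


def read_alignment(path: str | Path, fmt: str | None = None):
    """Load a Stockholm or aligned-FASTA alignment (format auto-detected
    from the first line unless given)."""
    path = Path(path)
    if fmt is None:
        first = path.open().readline()
        fmt = "stockholm" if first.startswith("# STOCKHOLM") else "fasta"
    return AlignIO.read(str(path), fmt)


@dataclass
class ColumnMask:
    """Role label -> 0-based alignment column (1-based in reports)."""

    columns: dict[str, int]

    def __post_init__(self) -> None:
        vals = list(self.columns.values())
        if len(set(vals)) != len(vals):
            raise ValueError("mask is not injective")

    @classmethod
    def from_json(cls, path: str | Path) -> "ColumnMask":
        raw = json.loads(Path(path).read_text())
        return cls({k: int(v) for k, v in raw.items()})

    def validate(self, alignment) -> None:
        width = alignment.get_alignment_length()
        for role, col in self.columns.items():
            if not 0 <= col < width:
                raise ValueError(f"mask column {col} for {role!r} outside "
                                 f"alignment of width {width}")


@dataclass
class ColumnStats:
    """Composition of one alignment column."""

    column: int                       # 0-based
    counts: dict[str, int]            # per base, gap-excluded
    gap_count: int
    n_sequences: int

    @property
    def gap_fraction(self) -> float:
        return self.gap_count / self.n_sequences if self.n_sequences else 1.0

    @property
    def frequencies(self) -> dict[str, float]:
        total = sum(self.counts.values())
        if total == 0:
            return {b: float("nan") for b in BASES}
        return {b: self.counts[b] / total for b in BASES}

    @property
    def information_content(self) -> float | None:
        """2 + sum f log2 f in bits; None for an all-gap column."""
        total = sum(self.counts.values())
        if total == 0:
            return None
        ic = 2.0
        for b in BASES:
            f = self.counts[b] / total
            if f > 0:
                ic += f * np.log2(f)
        return float(ic)


def _symbol(ch: str) -> str | None:
    """Map an alignment character to A/C/G/U or None (gap/ambiguity)."""
    ch = ch.upper()
    if ch == "T":
        ch = "U"
    return ch if ch in BASES else None


def column_stats(alignment, column: int) -> ColumnStats:
    """Composition, gap fraction and information content of one column."""
    n = len(alignment)
    if n == 0:
        raise ValueError("empty alignment")
    if not 0 <= column < alignment.get_alignment_length():
        raise IndexError(f"column {column} out of range")
    counts = {b: 0 for b in BASES}
    gaps = 0
    for rec in alignment:
        sym = _symbol(rec.seq[column])
        if sym is None:
            gaps += 1
        else:
            counts[sym] += 1
    return ColumnStats(column, counts, gaps, n)


def pair_stats(alignment, col_i: int, col_j: int) -> pd.DataFrame:
    """Joint base-combination frequencies at two columns.

    Counts run over sequences ungapped at both columns; the returned
    frame has one row per observed combination with counts and
    percentages (2 dp).  Marginals of this table equal the column
    compositions restricted to the co-ungapped subset.
    """
    for col in (col_i, col_j):
        if not 0 <= col < alignment.get_alignment_length():
            raise IndexError(f"column {col} out of range")
    counts: dict[tuple[str, str], int] = {}
    total = 0
    for rec in alignment:
        si = _symbol(rec.seq[col_i])
        sj = _symbol(rec.seq[col_j])
        if si is None or sj is None:
            continue
        counts[(si, sj)] = counts.get((si, sj), 0) + 1
        total += 1
    rows = []
    for (si, sj), cnt in sorted(counts.items(), key=lambda kv: -kv[1]):
        rows.append({"base_i": si, "base_j": sj, "count": cnt,
                     "percent": round(100.0 * cnt / total, 2)})
    df = pd.DataFrame(rows, columns=["base_i", "base_j", "count", "percent"])
    df.attrs["n_co_ungapped"] = total
    df.attrs["empty"] = total == 0
    return df


def columns_table(alignment, mask: ColumnMask) -> pd.DataFrame:
    """Per-role column statistics as a table (1-based column numbers)."""
    mask.validate(alignment)
    rows = []
    for role, col in mask.columns.items():
        st = column_stats(alignment, col)
        freqs = st.frequencies
        ic = st.information_content
        rows.append({
            "role": role, "column": col + 1,
            **{f"freq_{b}": round(freqs[b], 4) for b in BASES},
            "gap_fraction": round(st.gap_fraction, 4),
            "information_bits": None if ic is None else round(ic, 4),
        })
    return pd.DataFrame(rows)


def plot_logo(alignment, columns: list[int], path: str | Path,
              labels: list[str] | None = None) -> None:
    """Frequency-scaled letter plot (sequence-logo style) of selected
    columns, letter heights scaled so the stack totals the column's
    information content in bits."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "U": "#d62728"}
    fig, ax = plt.subplots(figsize=(max(3, 0.6 * len(columns)), 3))
    for x, col in enumerate(columns):
        st = column_stats(alignment, col)
        ic = st.information_content or 0.0
        y = 0.0
        for b, f in sorted(st.frequencies.items(), key=lambda kv: kv[1]):
            if not np.isfinite(f) or f <= 0:
                continue
            h = f * ic
            ax.text(x, y + h / 2, b, ha="center", va="center",
                    fontsize=8 + 16 * f, color=colors[b],
                    fontweight="bold")
            y += h
    ax.set_xticks(range(len(columns)))
    ax.set_xticklabels(labels or [str(c + 1) for c in columns], rotation=90)
    ax.set_ylim(0, 2)
    ax.set_ylabel("information (bits)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
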