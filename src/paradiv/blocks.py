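"""Conserved ungapped block extraction and per-column information content.

Blocks are maximal runs of alignment columns that are gap-free among the
retained rows and at least as informative as a per-column bit threshold;
rows that are mostly gaps (very divergent or fragmentary sequences) are
dropped first, mirroring how block-based conservation displays exclude them.
Column information content is IC = log2(20) - H with H the Shannon entropy of
the observed residue frequencies, optionally with the standard small-sample
correction 19 / (2 ln2 n). Letter heights for a sequence-logo rendering are
f_a * IC per column.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .seqio import GAP, AlignedSet

MAX_IC = math.log2(20)


class BlockError(ValueError):
    pass


def column_information(
    residues: str, correction: str = "none"
) -> float:
    """Information content (bits) of one alignment column.

    Gap characters are ignored; at least one non-gap residue is required.
    ``correction="small-sample"`` subtracts 19/(2 ln2 n), floored at 0.
    """
    observed = [ch for ch in residues if ch != GAP]
    if not observed:
        raise BlockError("empty column (all gaps)")
    n = len(observed)
    counts = Counter(observed)
    h = -sum((c / n) * math.log2(c / n) for c in counts.values())
    ic = MAX_IC - h
    if correction == "small-sample":
        ic -= 19.0 / (2.0 * math.log(2.0) * n)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return max(0.0, ic)


@dataclass
class Block:
    start_col: int  # 1-based inclusive alignment columns
    end_col: int
    member_rows: list[str]
    column_ic: list[float]
    frequencies: list[dict[str, float]]  # per column, residue -> frequency

    @property
    def width(self) -> int:
        return self.end_col - self.start_col + 1

    @property
    def mean_ic(self) -> float:
        return sum(self.column_ic) / len(self.column_ic)


def find_blocks(
    msa: AlignedSet,
    min_width: int = 6,
    min_mean_ic: float = 2.0,
    max_gap_rows_frac: float = 0.5,
    correction: str = "none",
) -> list[Block]:
    """Deterministic conserved-block extraction.

    1. Rows with more than ``max_gap_rows_frac`` gaps are dropped.
    2. A column is eligible iff it has zero gaps among retained rows and its
       information content reaches ``min_mean_ic`` bits.
    3. Maximal runs of eligible columns of length >= ``min_width`` become
       blocks, reported N-terminal to C-terminal.
    """
    if min_width < 3:
        raise ValueError("min_width must be >= 3")
    ncols = msa.ncols
    retained = [
        rid for rid, row in msa.rows.items()
        if row.count(GAP) / ncols <= max_gap_rows_frac
    ]
    if not retained:
        raise BlockError("no rows retained after gap filtering")
    rows = [msa.rows[rid] for rid in retained]

    eligible = []
    ic_by_col = []
    for c in range(ncols):
        col = "".join(r[c] for r in rows)
        if GAP in col:
            eligible.append(False)
            ic_by_col.append(0.0)
            continue
        ic = column_information(col, correction)
        ic_by_col.append(ic)
        eligible.append(ic >= min_mean_ic)

    blocks: list[Block] = []
    run_start = None
    for c in range(ncols + 1):
        if c < ncols and eligible[c]:
            if run_start is None:
                run_start = c
            continue
        if run_start is not None and c - run_start >= min_width:
            cols = range(run_start, c)
            freqs = []
            for cc in cols:
                col = "".join(r[cc] for r in rows)
                counts = Counter(col)
                freqs.append({aa: k / len(col) for aa, k in sorted(counts.items())})
            blocks.append(
                Block(
                    start_col=run_start + 1,
                    end_col=c,
                    member_rows=list(retained),
                    column_ic=[ic_by_col[cc] for cc in cols],
                    frequencies=freqs,
                )
            )
        run_start = None
    return blocks


def logo_table(block: Block) -> pd.DataFrame:
    """Letter heights f_a * IC, one row per block position (1-based within the
    block), one column per residue; row sums equal the column IC."""
    records = []
    for pos, (ic, freqs) in enumerate(zip(block.column_ic, block.frequencies), start=1):
        row = {"position": pos, "alignment_col": block.start_col + pos - 1}
        for aa, f in freqs.items():
            row[aa] = f * ic
        records.append(row)
    df = pd.DataFrame(records).set_index("position")
    return df.fillna(0.0)


def block_spacing(blocks: list[Block]) -> list[int]:
    """Columns between consecutive blocks (N-to-C), for spacing reports."""
    return [
        blocks[i + 1].start_col - blocks[i].end_col - 1 for i in range(len(blocks) - 1)
    ]


def blocks_to_frame(blocks: list[Block]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "block": i + 1,
                "start_col": b.start_col,
                "end_col": b.end_col,
                "width": b.width,
                "mean_ic": round(b.mean_ic, 4),
                "n_rows": len(b.member_rows),
            }
            for i, b in enumerate(blocks)
        ]
    )
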