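"""Paralog rate-asymmetry analysis.

After a duplication, each species carries one ortholog in each paralog clade,
so every species pair (i, j) yields two "equivalent" distances: d_A between
the clade-A orthologs and d_B between the clade-B orthologs. Systematically
larger d_B indicates faster evolution of clade B. The summary reports mean
distances per clade, the arithmetic mean of the per-pair d_B/d_A ratios (and,
separately, the ratio of the two means — the two aggregates differ and both
are emitted), direction counts, and a two-sided exact binomial sign test on
the non-tied pairs. The sign test is an interpretive extension of the raw
direction counts, not something the counts themselves presuppose.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import binomtest

from .phylo import DistanceMatrix


class CladeTableError(ValueError):
    pass


@dataclass
class CladeTable:
    """Sequence-to-(clade, species) assignments with an explicit exclusion list."""

    rows: list[tuple[str, str, str]]  # (sequence id, clade 'A'|'B', species)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    def __post_init__(self) -> None:
        seen_ids = set()
        per_clade: dict[tuple[str, str], str] = {}
        excluded_ids = {i for i, _ in self.excluded}
        for sid, clade, species in self.rows:
            if clade not in ("A", "B"):
                raise CladeTableError(f"clade must be A or B, got {clade!r} for {sid!r}")
            if sid in seen_ids:
                raise CladeTableError(f"duplicate sequence id {sid!r}")
            if sid in excluded_ids:
                raise CladeTableError(f"excluded id {sid!r} still present in rows")
            seen_ids.add(sid)
            key = (clade, species)
            if key in per_clade:
                raise CladeTableError(
                    f"species {species!r} appears twice in clade {clade}: "
                    f"{per_clade[key]!r} and {sid!r}"
                )
            per_clade[key] = sid

    def id_for(self, clade: str, species: str) -> str | None:
        for sid, cl, sp in self.rows:
            if cl == clade and sp == species:
                return sid
        return None

    def species_in(self, clade: str) -> set[str]:
        return {sp for _, cl, sp in self.rows if cl == clade}

    def exclude(self, sid: str, reason: str) -> "CladeTable":
        rows = [r for r in self.rows if r[0] != sid]
        if len(rows) == len(self.rows):
            raise CladeTableError(f"id {sid!r} not present")
        return CladeTable(rows, excluded=self.excluded + [(sid, reason)])


def read_clade_table(path: str | Path) -> CladeTable:
    """TSV with header and columns label, clade, species."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    try:
        label, clade, species = cols["label"], cols["clade"], cols["species"]
    except KeyError as exc:
        raise CladeTableError("clade table needs columns label, clade, species") from exc
    rows = [
        (str(r[label]), str(r[clade]).upper(), str(r[species]))
        for _, r in df.iterrows()
    ]
    return CladeTable(rows)


def clade_table_from_labels(labels: dict[str, tuple[str, str]]) -> CladeTable:
    """Build a CladeTable from simulator truth labels (id -> (species, clade))."""
    return CladeTable([(sid, clade, species) for sid, (species, clade) in labels.items()])


def match_species(clades: CladeTable) -> list[str]:
    """Species represented in both clades, sorted; requires at least 3."""
    common = sorted(clades.species_in("A") & clades.species_in("B"))
    if len(common) < 3:
        raise CladeTableError(
            f"only {len(common)} species common to both clades; need >= 3"
        )
    return common


@dataclass(frozen=True)
class PairComparison:
    species_i: str
    species_j: str
    d_a: float
    d_b: float

    @property
    def ratio(self) -> float | None:
        return self.d_b / self.d_a if self.d_a > 0 else None

    def direction(self, tie_epsilon: float = 1e-12) -> str:
        if abs(self.d_b - self.d_a) <= tie_epsilon:
            return "tie"
        return "B>A" if self.d_b > self.d_a else "A>B"


def pair_table(dm: DistanceMatrix, clades: CladeTable) -> list[PairComparison]:
    """One comparison per unordered species pair common to both clades."""
    common = match_species(clades)
    known = set(dm.labels)
    pairs = []
    for sp_i, sp_j in itertools.combinations(common, 2):
        ids = [
            clades.id_for("A", sp_i), clades.id_for("A", sp_j),
            clades.id_for("B", sp_i), clades.id_for("B", sp_j),
        ]
        missing = [i for i in ids if i not in known]
        if missing:
            raise CladeTableError(f"ids missing from distance matrix: {missing}")
        a_i, a_j, b_i, b_j = ids
        pairs.append(
            PairComparison(sp_i, sp_j, d_a=dm.get(a_i, a_j), d_b=dm.get(b_i, b_j))
        )
    return pairs


@dataclass
class AsymmetrySummary:
    n_pairs: int
    mean_d_a: float
    mean_d_b: float
    mean_ratio: float | None  # arithmetic mean of per-pair d_B/d_A
    ratio_of_means: float | None  # mean_d_B / mean_d_A, emitted for transparency
    n_b_greater: int
    n_a_greater: int
    n_ties: int
    sign_test_p: float
    n_informative: int  # non-tie pairs entering the sign test

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "mean_d_A": self.mean_d_a,
            "mean_d_B": self.mean_d_b,
            "mean_ratio": self.mean_ratio,
            "ratio_of_means": self.ratio_of_means,
            "n_B_greater": self.n_b_greater,
            "n_A_greater": self.n_a_greater,
            "n_ties": self.n_ties,
            "sign_test_p": self.sign_test_p,
            "n_informative": self.n_informative,
        }


def summarize(
    pairs: list[PairComparison], tie_epsilon: float = 1e-12
) -> AsymmetrySummary:
    """Aggregate pair comparisons; the sign test is exact binomial, two-sided,
    P(success) = 0.5 on the non-tie pairs. With zero informative pairs the
    p-value is reported as 1."""
    if not pairs:
        raise ValueError("need at least one pair comparison")
    mean_a = sum(p.d_a for p in pairs) / len(pairs)
    mean_b = sum(p.d_b for p in pairs) / len(pairs)
    ratios = [p.ratio for p in pairs if p.ratio is not None]
    mean_ratio = sum(ratios) / len(ratios) if ratios else None
    ratio_of_means = mean_b / mean_a if mean_a > 0 else None
    dirs = [p.direction(tie_epsilon) for p in pairs]
    n_b = dirs.count("B>A")
    n_a = dirs.count("A>B")
    n_tie = dirs.count("tie")
    informative = n_b + n_a
    if informative:
        p_value = binomtest(n_b, informative, 0.5, alternative="two-sided").pvalue
    else:
        p_value = 1.0
    return AsymmetrySummary(
        n_pairs=len(pairs),
        mean_d_a=mean_a,
        mean_d_b=mean_b,
        mean_ratio=mean_ratio,
        ratio_of_means=ratio_of_means,
        n_b_greater=n_b,
        n_a_greater=n_a,
        n_ties=n_tie,
        sign_test_p=float(p_value),
        n_informative=informative,
    )


def pairs_to_frame(pairs: list[PairComparison], tie_epsilon: float = 1e-12) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_i": p.species_i,
                "species_j": p.species_j,
                "d_A": p.d_a,
                "d_B": p.d_b,
                "ratio": p.ratio if p.ratio is not None else math.nan,
                "direction": p.direction(tie_epsilon),
            }
            for p in pairs
        ]
    )
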