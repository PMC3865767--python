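"""Homolog triage: architecture features, motif counting and classification.

The classifier re-expresses, as explicit computable predicates, the evidence
used to call a candidate ORF BACE-like rather than cathepsin-like: reciprocal
best-hit similarity, identity/coverage/gap thresholds, a length excess over
cathepsins, an N-terminal signal peptide, a C-terminal transmembrane stretch
(CTM), and the count of aspartyl active-site (PS00141) motif matches. The
signal peptide and CTM calls are fixed Kyte-Doolittle hydropathy-window
heuristics, deliberate approximations of SignalP/TMHMM-style predictors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from statistics import median

import numpy as np
import pandas as pd

from .align import DEFAULT_SCORING, LocalAlignmentResult, ScoringScheme, local_align
from .seqio import Sequence

# Kyte & Doolittle hydropathy scale; 'X' treated as neutral (0).
KD_SCALE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

# PROSITE PS00141, the eukaryotic aspartyl protease active-site signature.
PS00141 = "[LIVMFGAC]-[LIVMTADN]-[LIVFSA]-D-[ST]-G-[STAV]-[STAPDENQ]-x-[LIVMFSTNC]-x-[LIVMFGTA]"


def hydropathy_profile(seq: Sequence | str, window: int) -> np.ndarray:
    """Sliding-window mean Kyte-Doolittle hydropathy, one value per residue.

    Windows are truncated at the ends (the mean runs over the residues that
    actually fall inside the sequence).
    """
    residues = seq.residues if isinstance(seq, Sequence) else seq
    n = len(residues)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    vals = np.array([KD_SCALE[ch] for ch in residues])
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def _window_means(vals: np.ndarray, width: int) -> np.ndarray:
    """Mean of every full ``width`` window; index i = window starting at i."""
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    return (csum[width:] - csum[:-width]) / width


def predict_signal_peptide(
    seq: Sequence | str, *, window: int = 8, search_span: int = 40,
    threshold: float = 1.5,
) -> tuple[bool, tuple[int, int] | None]:
    """Signal-peptide heuristic: an 8-residue window fully inside the first 40
    residues with mean hydropathy >= 1.5. Returns (present, 1-based span of
    the best such window).
    """
    residues = seq.residues if isinstance(seq, Sequence) else seq
    if len(residues) < 25:
        raise ValueError("sequence too short for signal-peptide prediction (< 25)")
    span = min(search_span, len(residues))
    vals = np.array([KD_SCALE[ch] for ch in residues[:span]])
    if len(vals) < window:
        return False, None
    means = _window_means(vals, window)
    best = int(np.argmax(means))
    if means[best] >= threshold:
        return True, (best + 1, best + window)
    return False, None


def predict_ctm(
    seq: Sequence | str, *, window: int = 19, tail_span: int = 80,
    threshold: float = 1.6,
) -> tuple[bool, tuple[int, int] | None]:
    """C-terminal transmembrane heuristic: a 19-residue window starting within
    the final 80 residues with mean hydropathy >= 1.6.
    """
    residues = seq.residues if isinstance(seq, Sequence) else seq
    n = len(residues)
    if n < 60:
        raise ValueError("sequence too short for CTM prediction (< 60)")
    vals = np.array([KD_SCALE[ch] for ch in residues])
    means = _window_means(vals, window)  # index = 0-based window start
    first_start = max(0, n - tail_span)  # starts within the final tail_span residues
    tail_means = means[first_start:]
    if tail_means.size == 0:
        return False, None
    best = first_start + int(np.argmax(tail_means))
    if means[best] >= threshold:
        return True, (best + 1, best + window)
    return False, None


def prosite_to_regex(pattern: str) -> str:
    """Convert a PROSITE-syntax pattern to a Python regular expression."""
    out = []
    body = pattern.rstrip(".")
    if body.startswith("<"):
        out.append("^")
        body = body[1:]
    anchored_end = body.endswith(">")
    if anchored_end:
        body = body[:-1]
    for element in body.split("-"):
        m = re.fullmatch(r"(.+?)(?:\((\d+)(?:,(\d+))?\))?", element)
        if not m:
            raise ValueError(f"malformed PROSITE element {element!r}")
        token, lo, hi = m.groups()
        if token == "x":
            core = "."
        elif token.startswith("[") and token.endswith("]"):
            core = token
        elif token.startswith("{") and token.endswith("}"):
            core = "[^" + token[1:-1] + "]"
        elif len(token) == 1 and token.isalpha():
            core = token
        else:
            raise ValueError(f"malformed PROSITE element {element!r}")
        if lo is not None:
            core += f"{{{lo},{hi}}}" if hi else f"{{{lo}}}"
        out.append(core)
    if anchored_end:
        out.append("$")
    return "".join(out)


@dataclass(frozen=True)
class MotifHit:
    start: int  # 1-based position of the match
    matched: str
    asp_position: int  # 1-based position of the catalytic Asp in the D-[ST]-G core


def find_active_site_motifs(
    seq: Sequence | str, pattern: str = PS00141
) -> list[MotifHit]:
    """Non-overlapping, leftmost-first matches of an active-site pattern."""
    residues = seq.residues if isinstance(seq, Sequence) else seq
    regex = re.compile(prosite_to_regex(pattern))
    hits = []
    for m in regex.finditer(residues):
        text = m.group(0)
        asp = None
        for i in range(len(text) - 2):
            if text[i] == "D" and text[i + 1] in "ST" and text[i + 2] == "G":
                asp = m.start() + i + 1
                break
        hits.append(MotifHit(start=m.start() + 1, matched=text,
                             asp_position=asp if asp is not None else m.start() + 1))
    return hits


@dataclass
class FeatureAnnotation:
    length: int
    signal_peptide: bool
    signal_span: tuple[int, int] | None
    ctm: bool
    ctm_span: tuple[int, int] | None
    motif_hits: list[MotifHit]


def annotate_features(seq: Sequence, pattern: str = PS00141) -> FeatureAnnotation:
    sp, sp_span = predict_signal_peptide(seq)
    ctm, ctm_span = predict_ctm(seq)
    return FeatureAnnotation(
        length=len(seq),
        signal_peptide=sp,
        signal_span=sp_span,
        ctm=ctm,
        ctm_span=ctm_span,
        motif_hits=find_active_site_motifs(seq, pattern),
    )


# ---------------------------------------------------------------------------
# Reciprocal best hit
# ---------------------------------------------------------------------------

def best_hit(
    query: Sequence,
    db: list[Sequence],
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> tuple[Sequence, LocalAlignmentResult]:
    """Best database member by local-alignment score; ties broken by identity
    percentage, then lexicographic id."""
    if not db:
        raise ValueError("empty database")
    scored = []
    for member in db:
        res = local_align(query, member, scoring)
        scored.append((res.score, res.identity_pct, member.id, member, res))
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    _, _, _, member, res = scored[0]
    return member, res


def reciprocal_best_hit(
    query: Sequence,
    forward_db: list[Sequence],
    home_db: list[Sequence] | None = None,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> tuple[Sequence, LocalAlignmentResult, bool]:
    """Forward best hit plus the reciprocal flag.

    The reciprocal flag is true iff aligning the forward hit against the
    query's home set (the query itself when no home set is given) returns the
    query as top hit.
    """
    hit, res = best_hit(query, forward_db, scoring)
    home = home_db if home_db else [query]
    if not any(s.id == query.id for s in home):
        home = home + [query]
    back, _ = best_hit(hit, home, scoring)
    return hit, res, back.id == query.id


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class TriageCriteria:
    """Thresholds of the nine-point triage, with the defaults used throughout."""

    min_identity_pct: float = 35.0
    min_coverage_frac: float = 0.7  # of the shorter ORF
    max_gap_pct: float = 15.0
    min_length_delta: int = 60  # vs the cathepsin reference median length
    require_sp: bool = True
    require_ctm: bool = True
    expected_motif_count_bace: int = 1  # single proximal match
    expected_motif_count_cathepsin: int = 2
    proximal_frac: float = 0.4  # "proximal" = within the first 40% of the ORF
    min_exons: int = 9  # metadata-only; never computed from sequence

    def __post_init__(self) -> None:
        if not (0 <= self.min_identity_pct <= 100):
            raise ValueError("min_identity_pct out of range")
        if not (0 < self.min_coverage_frac <= 1):
            raise ValueError("min_coverage_frac out of range")
        if not (0 <= self.max_gap_pct <= 100):
            raise ValueError("max_gap_pct out of range")


@dataclass
class TriageVerdict:
    candidate_id: str
    label: str  # bace-like | borderline | cathepsin-like
    checks: dict[str, bool]
    identity_pct: float
    coverage_frac: float
    gap_pct: float
    length_delta: float
    motif_count: int
    rbh: bool
    features: FeatureAnnotation

    def to_row(self) -> dict:
        row = {
            "id": self.candidate_id,
            "label": self.label,
            "identity_pct": round(self.identity_pct, 2),
            "coverage_frac": round(self.coverage_frac, 3),
            "gap_pct": round(self.gap_pct, 2),
            "length_delta": self.length_delta,
            "motif_count": self.motif_count,
            "rbh": self.rbh,
        }
        row.update({f"crit_{k}": v for k, v in self.checks.items()})
        return row


MANDATORY = ("rbh", "identity", "ctm")


def classify(
    candidate: Sequence,
    reference_bace: Sequence,
    reference_cathepsins: list[Sequence],
    criteria: TriageCriteria | None = None,
    metadata: dict | None = None,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> TriageVerdict:
    """Evaluate the triage criteria against one candidate.

    Mandatory evidence: reciprocal best hit into the BACE reference,
    identity/coverage/gap thresholds against it, and a C-terminal
    transmembrane stretch. All criteria met -> bace-like; mandatory met but
    corroborative evidence missing -> borderline; otherwise cathepsin-like.
    Exon counts, when supplied via ``metadata={"n_exons": ...}``, act as a
    corroborative criterion only.
    """
    if not reference_cathepsins:
        raise ValueError("need at least one cathepsin reference")
    criteria = criteria or TriageCriteria()

    to_bace = local_align(candidate, reference_bace, scoring)
    cath_results = [local_align(candidate, c, scoring) for c in reference_cathepsins]

    shorter = min(len(candidate), len(reference_bace))
    coverage = to_bace.query_coverage / shorter if len(candidate) <= len(
        reference_bace
    ) else to_bace.subject_coverage / shorter

    _, _, reciprocal = reciprocal_best_hit(
        candidate,
        [reference_bace] + reference_cathepsins,
        home_db=[candidate] + reference_cathepsins,
        scoring=scoring,
    )
    forward_hit, _ = best_hit(candidate, [reference_bace] + reference_cathepsins, scoring)
    rbh_ok = reciprocal and forward_hit.id == reference_bace.id

    features = annotate_features(candidate)
    motif_count = len(features.motif_hits)
    proximal = bool(
        features.motif_hits
        and features.motif_hits[0].start <= criteria.proximal_frac * len(candidate)
    )
    length_delta = len(candidate) - median(len(c) for c in reference_cathepsins)

    checks = {
        "rbh": rbh_ok,
        "identity": (
            to_bace.identity_pct >= criteria.min_identity_pct
            and coverage >= criteria.min_coverage_frac
            and to_bace.gap_pct <= criteria.max_gap_pct
        ),
        "cathepsin_lower": all(
            r.identity_pct < to_bace.identity_pct for r in cath_results
        ),
        "length_delta": length_delta >= criteria.min_length_delta,
        "signal_peptide": features.signal_peptide or not criteria.require_sp,
        "ctm": features.ctm or not criteria.require_ctm,
        "motif_count": motif_count == criteria.expected_motif_count_bace and proximal,
    }
    if metadata and "n_exons" in metadata:
        checks["exons"] = int(metadata["n_exons"]) >= criteria.min_exons

    mandatory_ok = all(checks[k] for k in MANDATORY)
    if mandatory_ok and all(checks.values()):
        label = "bace-like"
    elif mandatory_ok:
        label = "borderline"
    else:
        label = "cathepsin-like"

    return TriageVerdict(
        candidate_id=candidate.id,
        label=label,
        checks=checks,
        identity_pct=to_bace.identity_pct,
        coverage_frac=coverage,
        gap_pct=to_bace.gap_pct,
        length_delta=length_delta,
        motif_count=motif_count,
        rbh=rbh_ok,
        features=features,
    )


def presence_absence(
    substrates: list[Sequence],
    proteomes: dict[str, list[Sequence]],
    min_identity_pct: float = 25.0,
    min_coverage_frac: float = 0.5,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> pd.DataFrame:
    """Presence/absence matrix of substrate homologs across proteomes.

    A substrate is present in a proteome iff its reciprocal-best-hit-confirmed
    local alignment reaches the identity threshold over at least the stated
    fraction of the substrate. Supporting numbers travel in the cell payload.
    """
    if not substrates:
        raise ValueError("no substrates given")
    records = []
    for name, proteome in proteomes.items():
        for substrate in substrates:
            if not proteome:
                records.append(
                    dict(proteome=name, substrate=substrate.id, present=False,
                         identity_pct=0.0, coverage_frac=0.0, hit="")
                )
                continue
            hit, res, reciprocal = reciprocal_best_hit(
                substrate, proteome, home_db=substrates, scoring=scoring
            )
            coverage = res.query_coverage / len(substrate)
            present = (
                reciprocal
                and res.identity_pct >= min_identity_pct
                and coverage >= min_coverage_frac
            )
            records.append(
                dict(proteome=name, substrate=substrate.id, present=present,
                     identity_pct=round(res.identity_pct, 2),
                     coverage_frac=round(coverage, 3), hit=hit.id)
            )
    return pd.DataFrame.from_records(records)
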