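"""Truth-set matching and caller performance statistics.

Sensitivity is the fraction of truth events a caller detected,
``tp / (tp + fn)``.  The false-positive rate reported here follows the
operational definition used in multi-caller SV evaluations without a
matched normal, ``fp / (fp + tp)`` over the evaluated candidate set —
formally a false-discovery proportion, so the same quantity is also
exposed under the name ``fdr``.

Matching is greedy one-to-one: a candidate matches a truth event of the
same SV type on the same chromosome pair with both breakpoints within a
tolerance (default 1 kb, the consensus distance); ties are broken by the
smallest breakpoint-distance sum, then input order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .fusionscreen import FusionCandidate, FusionPanel
from .records import SvRecord


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), matching how percentages
    are conventionally printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class MatchLabel(str, enum.Enum):
    TP = "TP"
    FP = "FP"
    FN = "FN"


@dataclass
class MatchResult:
    candidate_labels: list[tuple[SvRecord, MatchLabel, Optional[int]]]
    unmatched_truth: list[int]  # indices into the truth list

    @property
    def tp(self) -> int:
        return sum(1 for _, lab, _ in self.candidate_labels if lab is MatchLabel.TP)

    @property
    def fp(self) -> int:
        return sum(1 for _, lab, _ in self.candidate_labels if lab is MatchLabel.FP)

    @property
    def fn(self) -> int:
        return len(self.unmatched_truth)


def _canonical_ends(r: SvRecord) -> tuple[str, int, str, int]:
    if (r.chrom2, r.pos2) < (r.chrom1, r.pos1):
        return (r.chrom2, r.pos2, r.chrom1, r.pos1)
    return (r.chrom1, r.pos1, r.chrom2, r.pos2)


def match_sv_truth(
    candidates: Sequence[SvRecord],
    truth: Sequence[SvRecord],
    tolerance: int = 1000,
) -> MatchResult:
    """Greedy one-to-one matching of candidates against a truth set.

    Each truth event absorbs at most one candidate, so a second
    candidate near the same truth event counts as a false positive and
    ``tp`` can never exceed ``len(truth)``.
    """
    # bucket truth by (svtype, canonical chrom pair) for near-linear matching
    buckets: dict[tuple, list[int]] = {}
    truth_ends = [_canonical_ends(t) for t in truth]
    for j, t in enumerate(truth):
        c1, _, c2, _ = truth_ends[j]
        buckets.setdefault((t.svtype, c1, c2), []).append(j)

    pairs: list[tuple[int, int, int]] = []  # (distance sum, cand idx, truth idx)
    for i, cand in enumerate(candidates):
        cc1, cp1, cc2, cp2 = _canonical_ends(cand)
        for j in buckets.get((cand.svtype, cc1, cc2), ()):
            _, tp1, _, tp2 = truth_ends[j]
            d1, d2 = abs(cp1 - tp1), abs(cp2 - tp2)
            if d1 <= tolerance and d2 <= tolerance:
                pairs.append((d1 + d2, i, j))
    pairs.sort()

    cand_match: dict[int, int] = {}
    truth_match: dict[int, int] = {}
    for _, i, j in pairs:
        if i not in cand_match and j not in truth_match:
            cand_match[i] = j
            truth_match[j] = i

    labels = [
        (
            cand,
            MatchLabel.TP if i in cand_match else MatchLabel.FP,
            cand_match.get(i),
        )
        for i, cand in enumerate(candidates)
    ]
    missed = [j for j in range(len(truth)) if j not in truth_match]
    return MatchResult(candidate_labels=labels, unmatched_truth=missed)


@dataclass
class EvalResult:
    """TP/FP/FN tallies and the derived percentages for one caller."""

    caller: str
    tp: int
    fp: int
    fn: int
    percent_passing: Optional[float] = None

    @property
    def n_truth(self) -> int:
        return self.tp + self.fn

    @property
    def sensitivity(self) -> Optional[float]:
        """Percent of truth events detected, 2 decimals."""
        if self.n_truth == 0:
            return None
        return round_half_up(100.0 * self.tp / self.n_truth, 2)

    @property
    def fpr(self) -> Optional[float]:
        """fp / (fp + tp) as a percent, 2 decimals; None when no calls."""
        if self.tp + self.fp == 0:
            return None
        return round_half_up(100.0 * self.fp / (self.fp + self.tp), 2)

    #: the conventional name for the same ratio
    fdr = fpr

    def as_dict(self) -> dict:
        return {
            "caller": self.caller,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "fpr": self.fpr,
            "fdr": self.fpr,
            "percent_passing": self.percent_passing,
        }


def compute_sv_metrics(labels: MatchResult, caller: str = "") -> EvalResult:
    return EvalResult(caller=caller, tp=labels.tp, fp=labels.fp, fn=labels.fn)


def compute_fusion_metrics(
    per_caller: dict[str, list[FusionCandidate]],
    truth: Sequence[tuple[str, str]],
    panel: Optional[FusionPanel] = None,
) -> dict[str, EvalResult]:
    """Per-caller sensitivity/FPR against ordered truth gene pairs.

    Candidates whose unordered pair occurs in the panel of normals are
    discounted entirely — they count as neither TP nor FP.  Duplicate
    gene pairs within one caller are counted once.
    """
    panel = panel or FusionPanel()
    truth_set = {tuple(p) for p in truth}
    results: dict[str, EvalResult] = {}
    for caller, candidates in per_caller.items():
        seen: set[tuple[str, str]] = set()
        tp = fp = 0
        for c in candidates:
            if c.pair in seen or c in panel:
                continue
            seen.add(c.pair)
            if c.pair in truth_set:
                tp += 1
            else:
                fp += 1
        results[caller] = EvalResult(
            caller=caller, tp=tp, fp=fp, fn=len(truth_set) - tp
        )
    return results


def percent_passing(found: int, passed: int) -> Optional[float]:
    """Percent of a caller's candidates that survive automated filtering."""
    if passed > found:
        raise ValueError(f"passed ({passed}) > found ({found})")
    if found == 0:
        return None
    return round_half_up(100.0 * passed / found, 2)


def mean_read_support(records: Iterable[SvRecord]) -> Optional[float]:
    """Arithmetic mean read support, 1 decimal; None on empty input."""
    supports = [r.support for r in records]
    if not supports:
        return None
    return round_half_up(sum(supports) / len(supports), 1)
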