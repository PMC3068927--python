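"""Case/control ("multiple antitheses") off-target prioritization.

Many drugs cause the adverse event of interest (cases) and many comparable
drugs do not (controls).  Z'-scores are binarized at an empirical threshold
(-0.48, calibrated on a prior training set to capture 70% of true bindings)
into interactive / not interactive calls, and each pocket gets a 2x2 table:

              interactive   not interactive
    case           a               c
    control        b               d

A pocket preferentially bound by case drugs has relative ratio
RR = [a/(a+b)] / [c/(c+d)] above one; such pockets are scored with the
one-sided Fisher exact test and ranked by p.  Companion routines test
functional-class enrichment among the prioritized pockets and compare
adverse-event report rates between two drugs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cpi_data import BinaryMatrix, DrugRoster, PocketAnnotation, ZMatrix
from .stats_core import Table2x2, chi_square_2x2, fisher_one_sided, hypergeom_upper_tail

__all__ = [
    "DEFAULT_THRESHOLD",
    "MultiResult",
    "binarize",
    "count_pocket",
    "relative_ratio",
    "prioritize",
    "results_table",
    "class_enrichment",
    "report_rate_test",
]

#: Z' below this value counts as an interactive (binding) call.
DEFAULT_THRESHOLD = -0.48


@dataclass(frozen=True)
class MultiResult:
    """Contingency counts, relative ratio and one-sided exact p for a pocket.

    ``p`` is NaN when RR <= 1 (the test is only run for case-enriched
    pockets).
    """

    pocket_id: str
    counts: Table2x2
    rr: float
    p: float


def binarize(z: ZMatrix, threshold: float = DEFAULT_THRESHOLD) -> BinaryMatrix:
    """Call interactions: interactive iff Z' < threshold (strict).

    Missing entries stay missing.  Equality at the threshold is
    not-interactive by the strict-< convention.
    """
    vals = np.where(z.values < threshold, 1.0, 0.0)
    vals = np.where(z.missing, np.nan, vals)
    return BinaryMatrix(
        drug_ids=z.drug_ids,
        pocket_ids=z.pocket_ids,
        values=vals,
        missing=z.missing.copy(),
    )


def count_pocket(binary: BinaryMatrix, pocket: str, roster: DrugRoster) -> Table2x2:
    """The (a, b, c, d) counts for one pocket.

    a/c: interactive / not-interactive case drugs; b/d: same for controls.
    Background drugs and missing entries are excluded, so missing scores
    shrink the margins.
    """
    roster.check_covers(binary.drug_ids)
    i = binary.pocket_index(pocket)
    a = b = c = d = 0
    for j, drug in enumerate(binary.drug_ids):
        if binary.missing[i, j]:
            continue
        role = roster.roles[drug]
        if role == "background":
            continue
        hit = binary.values[i, j] == 1.0
        if role == "case":
            a, c = a + hit, c + (not hit)
        else:
            b, d = b + hit, d + (not hit)
    if a + b + c + d == 0:
        raise ValueError(f"pocket {pocket!r}: all case/control entries missing")
    return Table2x2(a=a, b=b, c=c, d=d)


def relative_ratio(t: Table2x2) -> float:
    """RR = [a/(a+b)] / [c/(c+d)]; +inf when c = 0 and a > 0."""
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValueError(f"relative ratio undefined for counts {t}")
    num = t.a / (t.a + t.b)
    den = t.c / (t.c + t.d)
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def prioritize(
    z: ZMatrix,
    roster: DrugRoster,
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = 0.05,
) -> list[MultiResult]:
    """Pockets preferentially bound by case drugs, ranked by exact p.

    Per pocket: counts -> RR -> one-sided Fisher, computed only when
    RR > 1.  Pockets with p < alpha are kept, sorted ascending by p, ties
    broken by descending RR, then pocket id.  Pockets whose case/control
    entries are all missing, or with an empty margin, are skipped.
    """
    if not roster.cases or not roster.controls:
        raise ValueError("need at least one case and one control drug")
    binary = binarize(z, threshold)
    out: list[MultiResult] = []
    for pocket in z.pocket_ids:
        try:
            t = count_pocket(binary, pocket, roster)
            rr = relative_ratio(t)
        except ValueError:
            continue
        if not rr > 1.0:  # also excludes NaN
            continue
        p = fisher_one_sided(t)
        if p < alpha:
            out.append(MultiResult(pocket_id=pocket, counts=t, rr=rr, p=p))
    out.sort(key=lambda r: (r.p, -r.rr, r.pocket_id))
    return out


def results_table(
    results: list[MultiResult], annotations: PocketAnnotation | None = None
) -> pd.DataFrame:
    """Flatten prioritization results into a TSV-ready frame."""
    rows = [
        {
            "pocket_id": r.pocket_id,
            "a": r.counts.a,
            "b": r.counts.b,
            "c": r.counts.c,
            "d": r.counts.d,
            "rr": r.rr,
            "p_value": r.p,
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=["pocket_id", "a", "b", "c", "d", "rr", "p_value"])
    if annotations is not None and len(df):
        df["pdb_id"] = [
            annotations[p].pdb_id if p in annotations else "" for p in df.pocket_id
        ]
        df["genes"] = [
            "|".join(annotations[p].gene_symbols) if p in annotations else ""
            for p in df.pocket_id
        ]
        df["classes"] = [
            ",".join(sorted(annotations[p].classes)) if p in annotations else ""
            for p in df.pocket_id
        ]
    return df


def class_enrichment(
    prioritized: set[str],
    class_tag: str,
    annotations: PocketAnnotation,
    universe: set[str],
) -> tuple[int, int, int, int, float]:
    """Hypergeometric enrichment of a functional class among prioritized
    pockets.

    Returns (k, n, K, N, p): k class members among the n prioritized
    pockets, K class members in the N-pocket universe; p is the upper-tail
    hypergeometric probability P(X >= k).
    """
    if not universe:
        raise ValueError("empty universe")
    if not prioritized <= universe:
        raise ValueError("prioritized pockets must be a subset of the universe")
    members = annotations.pockets_in_class(class_tag)
    k = len(prioritized & members)
    n = len(prioritized)
    K = len(universe & members)
    N = len(universe)
    return k, n, K, N, hypergeom_upper_tail(k, N, K, n)


def report_rate_test(
    events1: int, total1: int, events2: int, total2: int
) -> tuple[float, float, float, float]:
    """Compare adverse-event report rates of two drugs.

    Returns (rate1 %, rate2 %, chi-square statistic, p) from the df=1
    chi-square without continuity correction on
    [[events1, total1-events1], [events2, total2-events2]].
    """
    if total1 <= 0 or total2 <= 0:
        raise ValueError("totals must be positive")
    if events1 > total1 or events2 > total2:
        raise ValueError("events cannot exceed totals")
    t = Table2x2(a=events1, b=total1 - events1, c=events2, d=total2 - events2)
    stat, p = chi_square_2x2(t)
    return 100.0 * events1 / total1, 100.0 * events2 / total2, stat, p
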