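"""Analog-pair ("binomial antithesis") off-target prioritization.

Two structurally related drugs with divergent safety profiles -- the
motivating case is clozapine versus olanzapine and agranulocytosis -- should
have broadly similar Z'-score binding profiles across a pocket panel.
Pockets where the profiles split are candidate off-targets of the riskier
analog.  The per-pocket statistic is the A-score, the Z'-score difference
between the two analogs; its significance is the one-tailed probability that
a randomly chosen ordered drug pair at the same pocket achieves an A-score
below the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cpi_data import DrugRoster, PocketAnnotation, ZMatrix
from .stats_core import ks_two_sample, pearson_pairwise

__all__ = [
    "AntithesisResult",
    "SimilarityResult",
    "a_score",
    "permutation_p",
    "exact_pair_p",
    "analyze_pair",
    "rank_pockets",
    "profile_similarity",
    "ks_case_control",
    "select_variant_pair",
]


@dataclass(frozen=True)
class AntithesisResult:
    """A-score and permutation p value for one pocket and one drug pair."""

    pocket_id: str
    z_drug1: float
    z_drug2: float
    a_score: float
    p_perm: float
    n_iter: int
    n_extreme: int


@dataclass(frozen=True)
class SimilarityResult:
    """Binding-profile similarity of drug pairs against a random-pair null."""

    pairs: tuple[tuple[str, str], ...]
    pair_pcc: tuple[float, ...]
    mean_pcc: float
    p_perm: float
    n_iter: int
    n_extreme: int


def a_score(z1: float, z2: float) -> float:
    """Antithesis score: z1 - z2.

    Z' is smaller for stronger theoretical binding, so a large negative
    A-score flags a pocket bound preferentially by drug 1.  A missing input
    yields NaN and the pocket is excluded downstream.
    """
    if np.isnan(z1) or np.isnan(z2):
        return float("nan")
    return float(z1) - float(z2)


def _eligible_z(z: ZMatrix, pocket: str) -> np.ndarray:
    row = z.pocket_row(pocket)
    vals = row[~np.isnan(row)]
    if vals.size < 2:
        raise ValueError(
            f"pocket {pocket!r} has {vals.size} non-missing drugs; need >= 2"
        )
    return vals


def _sample_ordered_pairs(
    rng: np.random.Generator, n: int, n_iter: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform ordered distinct index pairs from range(n), with replacement
    across iterations."""
    i = rng.integers(0, n, size=n_iter)
    j = rng.integers(0, n - 1, size=n_iter)
    j = np.where(j >= i, j + 1, j)
    return i, j


def permutation_p(
    z: ZMatrix,
    pocket: str,
    observed: float,
    n_iter: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, int]:
    """One-tailed permutation p for an observed A-score at one pocket.

    Draws ``n_iter`` ordered pairs of distinct drugs (uniformly, with
    replacement across iterations) from the drugs non-missing at the pocket
    and counts pairs whose A-score is strictly below the observed score:
    p = n_extreme / n_iter.  A p of exactly 0.0 is reportable.
    """
    vals = _eligible_z(z, pocket)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    i, j = _sample_ordered_pairs(rng, vals.size, n_iter)
    null = vals[i] - vals[j]
    n_extreme = int(np.sum(null < observed))
    return n_extreme / n_iter, n_extreme


def exact_pair_p(z: ZMatrix, pocket: str, observed: float) -> float:
    """Exact fraction of ordered distinct drug pairs with A-score < observed.

    Enumeration oracle for :func:`permutation_p`; limited to pockets with at
    most 2000 eligible drugs.
    """
    vals = _eligible_z(z, pocket)
    if vals.size > 2000:
        raise ValueError("exact enumeration limited to <= 2000 eligible drugs")
    diffs = vals[:, None] - vals[None, :]
    mask = ~np.eye(vals.size, dtype=bool)
    return float(np.sum(diffs[mask] < observed) / mask.sum())


def analyze_pair(
    z: ZMatrix,
    drug1: str,
    drug2: str,
    n_iter: int = 10_000,
    seed: int = 0,
) -> list[AntithesisResult]:
    """A-score and permutation p at every pocket where both drugs have Z'."""
    rng = np.random.default_rng(seed)
    col1 = z.drug_column(drug1)
    col2 = z.drug_column(drug2)
    out: list[AntithesisResult] = []
    for i, pocket in enumerate(z.pocket_ids):
        obs = a_score(col1[i], col2[i])
        if np.isnan(obs):
            continue
        p, n_extreme = permutation_p(z, pocket, obs, n_iter=n_iter, seed=rng)
        out.append(
            AntithesisResult(
                pocket_id=pocket,
                z_drug1=float(col1[i]),
                z_drug2=float(col2[i]),
                a_score=obs,
                p_perm=p,
                n_iter=n_iter,
                n_extreme=n_extreme,
            )
        )
    return out


def rank_pockets(
    results: list[AntithesisResult],
    alpha: float = 0.05,
    annotations: PocketAnnotation | None = None,
) -> pd.DataFrame:
    """Significant pockets (p < alpha) sorted by p, then more-negative
    A-score, then pocket id."""
    rows = [
        {
            "pocket_id": r.pocket_id,
            "z_drug1": r.z_drug1,
            "z_drug2": r.z_drug2,
            "a_score": r.a_score,
            "p_value": r.p_perm,
        }
        for r in results
        if r.p_perm < alpha
    ]
    df = pd.DataFrame(
        rows, columns=["pocket_id", "z_drug1", "z_drug2", "a_score", "p_value"]
    )
    df = df.sort_values(
        ["p_value", "a_score", "pocket_id"], ascending=[True, True, True]
    ).reset_index(drop=True)
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


def profile_similarity(
    z: ZMatrix,
    pairs: list[tuple[str, str]],
    n_iter: int = 10_000,
    seed: int = 0,
) -> SimilarityResult:
    """Mean Pearson similarity of drug-pair binding profiles vs a random null.

    Each pair's correlation is Pearson over pairwise-complete pockets.  The
    null recruits ``n_iter`` sets of ``len(pairs)`` ordered distinct drug
    pairs; p is the fraction of null sets with mean correlation at least the
    observed mean.
    """
    if not pairs:
        raise ValueError("need at least one drug pair")
    cols = {d: z.drug_column(d) for d in z.drug_ids}

    def pcc(x: np.ndarray, y: np.ndarray) -> float:
        # same code path for observed and null values so that ties between
        # an observed pair and its own appearance in the null are exact
        ok = ~(np.isnan(x) | np.isnan(y))
        xs, ys = x[ok], y[ok]
        if xs.size < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
            return float("nan")
        xs = xs - xs.mean()
        ys = ys - ys.mean()
        return float((xs @ ys) / np.sqrt((xs @ xs) * (ys @ ys)))

    observed = []
    for d1, d2 in pairs:
        try:
            pearson_pairwise(cols[d1], cols[d2])  # validates with clear errors
        except ValueError as e:
            raise ValueError(f"pair ({d1}, {d2}): {e}") from None
        observed.append(pcc(cols[d1], cols[d2]))
    mean_obs = float(np.mean(observed))

    rng = np.random.default_rng(seed)
    mat = np.column_stack([cols[d] for d in z.drug_ids])
    n = mat.shape[1]
    k = len(pairs)
    i, j = _sample_ordered_pairs(rng, n, n_iter * k)
    null_pcc = np.empty(n_iter * k)
    for t in range(n_iter * k):
        null_pcc[t] = pcc(mat[:, i[t]], mat[:, j[t]])
    null_means = np.nanmean(null_pcc.reshape(n_iter, k), axis=1)
    n_extreme = int(np.sum(null_means >= mean_obs))
    return SimilarityResult(
        pairs=tuple((d1, d2) for d1, d2 in pairs),
        pair_pcc=tuple(observed),
        mean_pcc=mean_obs,
        p_perm=n_extreme / n_iter,
        n_iter=n_iter,
        n_extreme=n_extreme,
    )


def ks_case_control(
    z: ZMatrix, pocket: str, roster: DrugRoster
) -> tuple[float, float]:
    """Kolmogorov-Smirnov test of case vs control Z'-scores at one pocket."""
    row = z.pocket_row(pocket)
    idx = {d: i for i, d in enumerate(z.drug_ids)}
    cases = np.array(
        [row[idx[d]] for d in roster.cases if d in idx and not np.isnan(row[idx[d]])]
    )
    controls = np.array(
        [row[idx[d]] for d in roster.controls if d in idx and not np.isnan(row[idx[d]])]
    )
    if cases.size == 0 or controls.size == 0:
        raise ValueError(
            f"pocket {pocket!r}: need >=1 non-missing case and control Z'"
        )
    return ks_two_sample(cases, controls)


def select_variant_pair(
    z: ZMatrix,
    variants1: list[str],
    variants2: list[str],
    known_genes: set[str],
    annotations: PocketAnnotation,
    alpha: float = 0.05,
    n_iter: int = 10_000,
    seed: int = 0,
) -> tuple[str, str]:
    """Pick the variant cross-pair that recalls the most known risk genes.

    Each drug may dock as several ionization states or metabolites.  Every
    (variant1, variant2) cross pair is run through the analog-pair analysis;
    the pair whose significant pockets (p < alpha) cover the most known
    genes wins.  Ties break on the smaller mean p over the recalled
    known-gene pockets, then lexicographically on the pair ids.
    """
    if not variants1 or not variants2:
        raise ValueError("both variant lists must be non-empty")
    best: tuple[int, float, tuple[str, str]] | None = None
    for d1 in variants1:
        for d2 in variants2:
            results = analyze_pair(z, d1, d2, n_iter=n_iter, seed=seed)
            hits = [r for r in results if r.p_perm < alpha]
            recalled_ps: dict[str, list[float]] = {}
            for r in hits:
                if r.pocket_id in annotations:
                    for g in annotations[r.pocket_id].gene_symbols:
                        if g in known_genes:
                            recalled_ps.setdefault(g, []).append(r.p_perm)
            count = len(recalled_ps)
            mean_p = (
                float(np.mean([p for ps in recalled_ps.values() for p in ps]))
                if recalled_ps
                else 1.0
            )
            key = (-count, mean_p, (d1, d2))
            if best is None or key < best:
                best = key
    assert best is not None
    return best[2]
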