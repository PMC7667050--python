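"""Dosage expectations, deviation scores, intermediacy and bias tests.

The comparative question: does a hybrid's repeat abundance follow the
dosage of its parental genomes?  With all samples subsampled to the same
per-1C coverage, each cluster's expected hybrid read count is the
dosage-weighted sum of the parental counts divided by two (a hybrid's 1C
holds (d_A + d_B)/2 monoploid complements), and the departure is scored
as (observed / expected) - 1.

Expectations are computed on read *counts*, not proportions: under
equalized coverage a cluster's count depends only on the repeat's
absolute amount of DNA, so an amplification in one family cannot drag
every other family's score away from zero through the total-genome-size
denominator (which a proportion-based expectation would do).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DeviationRecord:
    cluster_id: int
    observed: float
    expected: float
    score: float
    annotation: str = "unclassified"


@dataclass(frozen=True, eq=False)
class IntermediacyResult:
    mean_delta1: float  # mean |parent1 - hybrid| over clusters
    mean_delta2: float  # mean |parent2 - hybrid|
    delta: float  # mean_delta1 - mean_delta2
    p_value: float
    closer_parent: str  # "parent1" | "parent2" | "neither"
    delta1: "pd.Series" = None  # per-cluster |parent1 - hybrid|
    delta2: "pd.Series" = None  # per-cluster |parent2 - hybrid|


@dataclass(frozen=True)
class BiasComparison:
    tier: str
    per_cluster: pd.Series  # percent difference per cluster
    mean: float


def expected_hybrid_counts(
    parent_a: pd.Series,
    parent_b: pd.Series,
    dosage: tuple[int, int],
) -> pd.Series:
    """Dosage-expected hybrid read counts per cluster.

    ``parent_a``/``parent_b`` are per-cluster read counts from samples
    subsampled to equal 1C coverage.  expected = (d_A*n_A + d_B*n_B) / 2,
    the count a hybrid holding d_A + d_B parental complements in its 2C
    nucleus would show at the same coverage.  Clusters absent from both
    parents get expected 0 and are excluded from scoring downstream.
    """
    d_a, d_b = dosage
    if d_a == 0 and d_b == 0:
        raise ValueError("dosage (0, 0) is not a hybrid")
    idx = parent_a.index.union(parent_b.index)
    a = parent_a.reindex(idx, fill_value=0.0)
    b = parent_b.reindex(idx, fill_value=0.0)
    return (d_a * a + d_b * b) / 2.0


def expected_hybrid_proportions(
    p_a: pd.Series,
    p_b: pd.Series,
    dosage: tuple[int, int],
    g_a: float,
    g_b: float,
) -> pd.Series:
    """Dosage- and genome-size-weighted expected hybrid proportions.

    pi(c) = (d_A G_A p_A + d_B G_B p_B) / (d_A G_A + d_B G_B).  Exact when
    the hybrid genome is dosage-additive; under a burst the shared
    denominator biases all clusters, which is why count-based expectations
    are the default.
    """
    d_a, d_b = dosage
    if d_a == 0 and d_b == 0:
        raise ValueError("dosage (0, 0) is not a hybrid")
    idx = p_a.index.union(p_b.index)
    a = p_a.reindex(idx, fill_value=0.0)
    b = p_b.reindex(idx, fill_value=0.0)
    return (d_a * g_a * a + d_b * g_b * b) / (d_a * g_a + d_b * g_b)


def monoploid_rescale(counts: pd.Series, ploidy: int) -> pd.Series:
    """Rescale 1C-coverage counts to the monoploid (1Cx) scale.

    A triploid's 1C holds 1.5 monoploid complements, so its counts shrink
    by 2/3 to be comparable with diploid parents (whose 1C = 1Cx).
    """
    if ploidy == 2:
        return counts.astype(float)
    if ploidy == 3:
        return counts * (2.0 / 3.0)
    raise ValueError(f"unsupported ploidy {ploidy}")


def deviation_scores(
    observed: pd.Series,
    expected: pd.Series,
    annotations: dict[int, str] | None = None,
) -> tuple[list[DeviationRecord], float, list[int]]:
    """Per-cluster deviation scores (observed/expected - 1).

    Returns records sorted by decreasing |score|, the cumulative score
    (sum over scored clusters), and the ids of "novel" clusters (expected
    0 but observed > 0) which are flagged rather than scored.
    """
    if (observed < 0).any() or (expected < 0).any():
        raise ValueError("negative counts")
    annotations = annotations or {}
    idx = observed.index.union(expected.index)
    obs = observed.reindex(idx, fill_value=0.0)
    exp = expected.reindex(idx, fill_value=0.0)
    records = []
    novel = []
    for cid in idx:
        if exp[cid] <= 0:
            if obs[cid] > 0:
                novel.append(int(cid))
            continue
        score = obs[cid] / exp[cid] - 1.0
        records.append(
            DeviationRecord(
                cluster_id=int(cid),
                observed=float(obs[cid]),
                expected=float(exp[cid]),
                score=float(score),
                annotation=annotations.get(int(cid), "unclassified"),
            )
        )
    records.sort(key=lambda r: (-abs(r.score), r.cluster_id))
    cumulative = float(sum(r.score for r in records))
    return records, cumulative, novel


def _wilcoxon(diffs: np.ndarray) -> float:
    """Two-sided paired signed-rank test; exact for n <= 25."""
    diffs = diffs[diffs != 0]
    if diffs.size < 2:
        return 1.0
    method = "exact" if diffs.size <= 25 else "approx"
    try:
        return float(stats.wilcoxon(diffs, method=method, correction=True).pvalue)
    except ValueError:
        return 1.0


def intermediacy_analysis(
    parent1: pd.Series,
    parent2: pd.Series,
    hybrid: pd.Series,
    hybrid_ploidy: int = 2,
    alpha: float = 0.05,
) -> IntermediacyResult:
    """Which parent is the hybrid's repeat profile closer to?

    Hybrid counts are rescaled to the monoploid (1Cx) scale first, then
    per-cluster absolute count differences to each parent are compared
    with a paired Wilcoxon signed-rank test.  ``closer_parent`` is the
    parent with the smaller mean difference; "neither" when the test is
    not significant at ``alpha``.
    """
    h = monoploid_rescale(hybrid, hybrid_ploidy)
    idx = parent1.index.union(parent2.index).union(h.index)
    if len(idx) < 10:
        import warnings

        warnings.warn(f"intermediacy over only {len(idx)} clusters", stacklevel=2)
    p1 = parent1.reindex(idx, fill_value=0.0)
    p2 = parent2.reindex(idx, fill_value=0.0)
    hh = h.reindex(idx, fill_value=0.0)
    d1 = (p1 - hh).abs()
    d2 = (p2 - hh).abs()
    delta = float(d1.mean() - d2.mean())
    p = _wilcoxon((d1 - d2).to_numpy(dtype=float))
    # closer_parent is the argmin of the mean distances; whether the
    # asymmetry is decisive is reported separately through p_value.
    if delta < 0:
        closer = "parent1"
    elif delta > 0:
        closer = "parent2"
    else:
        closer = "neither"
    return IntermediacyResult(
        mean_delta1=float(d1.mean()),
        mean_delta2=float(d2.mean()),
        delta=delta,
        p_value=p,
        closer_parent=closer,
        delta1=d1,
        delta2=d2,
    )


def percent_difference(p1: pd.Series, p2: pd.Series) -> pd.Series:
    """Symmetric relative percent difference of two proportion profiles.

    |p1 - p2| / ((p1 + p2)/2) * 100 per cluster; clusters absent from
    both samples are dropped.
    """
    idx = p1.index.union(p2.index)
    a = p1.reindex(idx, fill_value=0.0)
    b = p2.reindex(idx, fill_value=0.0)
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    return ((a - b).abs() / ((a + b) / 2.0) * 100.0).rename("percent_difference")


def bias_assessment(
    runs: list[tuple[str, pd.Series, pd.Series]],
    holm: bool = False,
) -> tuple[list[BiasComparison], pd.DataFrame]:
    """Quantify tier-wise variation of cluster proportions.

    Each run is (tier, proportions1, proportions2) from a two-sample
    comparative clustering of equal-size datasets.  Returns per-tier
    comparisons and a table of pairwise Wilcoxon tests between tiers on
    the per-cluster percent differences (Holm-adjusted on request; raw
    p-values by default).
    """
    tiers: dict[str, list[pd.Series]] = {}
    for tier, p1, p2 in runs:
        tiers.setdefault(tier, []).append(percent_difference(p1, p2))
    comparisons = []
    pooled: dict[str, np.ndarray] = {}
    for tier, diffs in tiers.items():
        allvals = pd.concat(diffs, ignore_index=True)
        pooled[tier] = allvals.to_numpy(dtype=float)
        comparisons.append(
            BiasComparison(tier=tier, per_cluster=allvals, mean=float(allvals.mean()))
        )
    rows = []
    names = sorted(pooled)
    for i, t1 in enumerate(names):
        for t2 in names[i + 1 :]:
            x, y = pooled[t1], pooled[t2]
            n = min(x.size, y.size)
            p = _wilcoxon(x[:n] - y[:n]) if n >= 2 else 1.0
            rows.append({"tier1": t1, "tier2": t2, "p_value": p})
    table = pd.DataFrame(rows, columns=["tier1", "tier2", "p_value"])
    if holm and len(table):
        from statsmodels.stats.multitest import multipletests

        table["p_adjusted"] = multipletests(table["p_value"], method="holm")[1]
    return comparisons, table


def group_deviation_stats(
    natural: dict[str, list[DeviationRecord]],
    synthetic: dict[str, list[DeviationRecord]],
    category_of: dict[int, str] | None = None,
) -> pd.DataFrame:
    """ANOVA on mean deviation scores and Levene test on their spread.

    Groups are natural vs synthetic hybrids; each sample contributes its
    per-cluster scores.  Optional ``category_of`` adds per-category
    sub-reports (e.g. a two-cluster pararetrovirus category).  Degenerate
    variance yields NaN statistics rather than an error.
    """
    def collect(group: dict[str, list[DeviationRecord]], cat: str | None):
        out = []
        for sample, recs in group.items():
            vals = [
                r.score
                for r in recs
                if cat is None
                or (category_of or {}).get(r.cluster_id, "unclassified") == cat
            ]
            if vals:
                out.append((sample, np.array(vals, float)))
        return out

    cats: list[str | None] = [None]
    if category_of:
        cats += sorted(set(category_of.values()))
    rows = []
    for cat in cats:
        nat = collect(natural, cat)
        syn = collect(synthetic, cat)
        nat_means = [v.mean() for _, v in nat]
        syn_means = [v.mean() for _, v in syn]
        row = {
            "category": cat or "all",
            "n_natural": len(nat_means),
            "n_synthetic": len(syn_means),
            "mean_natural": float(np.mean(nat_means)) if nat_means else np.nan,
            "mean_synthetic": float(np.mean(syn_means)) if syn_means else np.nan,
        }
        if len(nat_means) >= 2 and len(syn_means) >= 2:
            if np.var(nat_means) + np.var(syn_means) == 0:
                row["anova_F"], row["anova_p"] = (
                    (np.nan, np.nan)
                    if np.mean(nat_means) == np.mean(syn_means)
                    else (np.inf, 0.0)
                )
            else:
                f = stats.f_oneway(nat_means, syn_means)
                row["anova_F"], row["anova_p"] = float(f.statistic), float(f.pvalue)
            try:
                with np.errstate(invalid="ignore", divide="ignore"):
                    lv = stats.levene(nat_means, syn_means)
                row["levene_F"], row["levene_p"] = float(lv.statistic), float(lv.pvalue)
            except Exception:
                row["levene_F"], row["levene_p"] = np.nan, np.nan
        else:
            row.update(anova_F=np.nan, anova_p=np.nan, levene_F=np.nan, levene_p=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def rank_deviating_clusters(
    records_by_sample: dict[str, list[DeviationRecord]],
    category_of: dict[int, str] | None = None,
    flag_threshold: float = 0.2,
) -> tuple[pd.DataFrame, list[str]]:
    """Rank clusters by |score| and flag concordant category deviations.

    A category is flagged when every one of its clusters deviates in the
    same direction by more than ``flag_threshold`` in every sample — the
    pattern of a group-specific amplification or loss.
    """
    rows = []
    for sample, recs in records_by_sample.items():
        for r in recs:
            cat = (category_of or {}).get(r.cluster_id, r.annotation)
            rows.append(
                {
                    "sample": sample,
                    "cluster_id": r.cluster_id,
                    "score": r.score,
                    "annotation": r.annotation,
                    "category": cat,
                }
            )
    table = pd.DataFrame(
        rows, columns=["sample", "cluster_id", "score", "annotation", "category"]
    )
    flags: list[str] = []
    if len(table):
        table = table.reindex(
            table["score"].abs().sort_values(ascending=False).index
        ).reset_index(drop=True)
        for cat, sub in table.groupby("category"):
            if cat in ("unclassified", "background"):
                continue
            if (sub["score"] > flag_threshold).all() or (
                sub["score"] < -flag_threshold
            ).all():
                flags.append(str(cat))
    return table, sorted(flags)
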