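"""Clone-tier × cluster enrichment and exhaustion-by-abundance statistics.

This module asks the study's headline question: do the cells of expanded
TCR clones sit in different phenotypic clusters than cells with unique
TCRs?  Per cluster, a 2×2 Pearson χ² (no continuity correction) compares
the focal tier against a reference — either the unique-TCR cells or the
all-cells marginal — with Bonferroni correction over the comparison
groups (default 9, one per cluster of the combined map); sparse tables
fall back to the hypergeometric exact test.  The exhaustion score is
summarized by tier with one-way ANOVA + Tukey HSD and Kruskal-Wallis,
and per-cluster cell-cycle enrichment contrasts each cluster's
cycling fraction (S ∪ G2/M) with the remaining cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clonotype import TIERS

DEFAULT_N_COMPARISONS = 9


@dataclass
class TierClusterTable:
    counts: pd.DataFrame  # tiers × clusters, integer
    n_dropped: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def tier_cluster_table(cell_tiers, cell_clusters,
                       tier_order=TIERS) -> TierClusterTable:
    """Contingency table of clone tier × cluster over cells with both labels."""
    tiers = pd.Series(np.asarray(cell_tiers, dtype=object), name="tier")
    clusters = pd.Series(np.asarray(cell_clusters, dtype=object),
                         name="cluster")
    if len(tiers) != len(clusters):
        raise ValueError("tier and cluster vectors are not aligned")
    ok = tiers.notna() & clusters.notna()
    n_dropped = int((~ok).sum())
    if ok.sum() == 0:
        raise ValueError("no cell has both a tier and a cluster label")
    tab = pd.crosstab(tiers[ok], clusters[ok])
    present = [t for t in tier_order if t in tab.index]
    extra = [t for t in tab.index if t not in tier_order]
    return TierClusterTable(counts=tab.loc[present + extra],
                            n_dropped=n_dropped)


def _chi2_2x2(table: np.ndarray) -> tuple[float, float, str]:
    """(statistic, p, method); hypergeometric exact when an expectation < 1."""
    table = np.asarray(table, dtype=float)
    if table.sum() == 0:
        return 0.0, 1.0, "chi2"
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    if (expected < 1).any():
        _, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
        return float("nan"), float(p), "exact"
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), "chi2"


def cluster_enrichment(
    table: TierClusterTable,
    focal_tier: str = "high",
    reference: str = "unique",
    n_comparisons: int = DEFAULT_N_COMPARISONS,
) -> tuple[pd.DataFrame, dict]:
    """Per-cluster 2×2 χ² of focal-tier vs reference cluster occupancy.

    ``reference`` is a tier name or ``"all"`` for the all-cells marginal
    (focal cells excluded from the reference rows so the two groups are
    disjoint).  Also returns the single global tiers × clusters χ².
    """
    counts = table.counts
    if focal_tier not in counts.index:
        raise ValueError(f"focal tier {focal_tier!r} absent from table")
    focal = counts.loc[focal_tier]
    if reference == "all":
        ref = counts.sum(axis=0) - focal
        ref_label = "all_other_cells"
    else:
        if reference not in counts.index:
            raise ValueError(f"reference tier {reference!r} absent from table")
        ref = counts.loc[reference]
        ref_label = reference
    nf, nr = int(focal.sum()), int(ref.sum())

    rows = []
    for cl in counts.columns:
        f_in, r_in = int(focal[cl]), int(ref[cl])
        t2 = np.array([[f_in, nf - f_in], [r_in, nr - r_in]])
        chi2, p, method = _chi2_2x2(t2)
        rows.append({
            "cluster": cl,
            "obs_prop": f_in / nf if nf else np.nan,
            "ref_prop": r_in / nr if nr else np.nan,
            "chi2": chi2, "df": 1, "p": p,
            "p_adj": min(1.0, p * n_comparisons),
            "n_comparisons": n_comparisons,
            "method": method,
            "direction": "enriched" if (nf and nr and f_in / nf >= r_in / nr)
                         else "depleted",
        })
    g_chi2, g_p, g_dof, _ = stats.chi2_contingency(
        counts.to_numpy(), correction=False)
    global_test = {"chi2": float(g_chi2), "df": int(g_dof), "p": float(g_p)}
    return pd.DataFrame(rows), global_test


def score_by_tier(scores, tiers, tier_order=TIERS,
                  min_cells: int = 3) -> dict:
    """Exhaustion score by clone-frequency tier.

    Per-tier summaries plus the omnibus one-way ANOVA, Kruskal-Wallis,
    and all-pairs Tukey HSD.
    """
    scores = np.asarray(scores, dtype=float)
    tiers = np.asarray(tiers, dtype=object)
    groups, names = [], []
    summary = []
    for t in tier_order:
        vals = scores[tiers == t]
        if len(vals) < min_cells:
            if len(vals):
                warnings.warn(f"tier {t!r} has {len(vals)} cells; excluded",
                              stacklevel=2)
            continue
        groups.append(vals)
        names.append(t)
        summary.append({"tier": t, "n": int(len(vals)),
                        "mean": float(vals.mean()),
                        "median": float(np.median(vals))})
    if len(groups) < 2:
        raise ValueError("need at least 2 tiers with enough cells")
    if np.ptp(np.concatenate(groups)) == 0:
        f_stat, f_p, h_stat, h_p = 0.0, 1.0, 0.0, 1.0
    else:
        f_stat, f_p = stats.f_oneway(*groups)
        h_stat, h_p = stats.kruskal(*groups)
    tukey = stats.tukey_hsd(*groups)
    pairs = [
        {"tier_a": names[i], "tier_b": names[j],
         "diff": float(np.mean(groups[i]) - np.mean(groups[j])),
         "p_adj": float(tukey.pvalue[i, j])}
        for i in range(len(groups)) for j in range(i + 1, len(groups))
    ]
    return {
        "summary": summary,
        "anova": {"F": float(f_stat), "p": float(f_p)},
        "kruskal": {"H": float(h_stat), "p": float(h_p)},
        "tukey": pairs,
    }


def cycle_enrichment(phase_table: pd.DataFrame,
                     n_comparisons: int | None = None) -> pd.DataFrame:
    """Per-cluster χ² of cycling (S ∪ G2/M) vs G1 against all other cells."""
    tab = phase_table
    cycling = tab.get("S", 0) + tab.get("G2M", 0)
    g1 = tab.get("G1", 0)
    cyc_tot, g1_tot = int(cycling.sum()), int(g1.sum())
    if n_comparisons is None:
        n_comparisons = len(tab)
    rows = []
    for cl in tab.index:
        c_in, g_in = int(cycling[cl]), int(g1[cl])
        t2 = np.array([[c_in, g_in],
                       [cyc_tot - c_in, g1_tot - g_in]])
        chi2, p, method = _chi2_2x2(t2)
        n_in = c_in + g_in
        n_out = (cyc_tot + g1_tot) - n_in
        obs = c_in / n_in if n_in else np.nan
        exp = (cyc_tot - c_in) / n_out if n_out else np.nan
        rows.append({
            "cluster": cl, "cycling_frac": obs, "rest_cycling_frac": exp,
            "chi2": chi2, "df": 1, "p": p,
            "p_adj": min(1.0, p * n_comparisons),
            "n_comparisons": n_comparisons, "method": method,
            "direction": "cycling_enriched" if obs >= exp else "g1_enriched",
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _row_percent(counts: pd.DataFrame) -> pd.DataFrame:
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


def linkage_report(
    table: TierClusterTable,
    cluster_groups: dict[str, list[str]] | None = None,
    scores=None,
    score_tiers=None,
    phase_table: pd.DataFrame | None = None,
    n_comparisons: int = DEFAULT_N_COMPARISONS,
    focal_tier: str = "high",
    reference_tier: str = "unique",
) -> dict:
    """Machine-readable linkage summary.

    ``cluster_percent`` maps each tier (plus ``"all"``, the all-cells
    marginal) to its percentage distribution over clusters;
    ``group_percent`` aggregates those percentages over named cluster
    groups (e.g. exhausted = early ∪ terminal exhaustion).  Enrichment is
    reported against both the reference tier and the all-cells baseline.
    """
    counts = table.counts
    pct = _row_percent(counts)
    pct.loc["all"] = counts.sum(axis=0) / counts.to_numpy().sum() * 100.0

    cluster_percent = {str(t): {str(c): float(pct.loc[t, c])
                                for c in pct.columns}
                       for t in pct.index}
    group_percent: dict[str, dict[str, float]] = {}
    if cluster_groups:
        for t in pct.index:
            group_percent[str(t)] = {
                g: float(sum(pct.loc[t, c] for c in members
                             if c in pct.columns))
                for g, members in cluster_groups.items()}

    report: dict = {
        "n_cells": table.total,
        "n_dropped": table.n_dropped,
        "tier_counts": {str(t): int(counts.loc[t].sum())
                        for t in counts.index},
        "cluster_percent": cluster_percent,
        "group_percent": group_percent,
    }
    if focal_tier in counts.index and reference_tier in counts.index:
        enr_ref, global_test = cluster_enrichment(
            table, focal_tier, reference_tier, n_comparisons)
        enr_all, _ = cluster_enrichment(table, focal_tier, "all",
                                        n_comparisons)
        report["enrichment_vs_reference"] = enr_ref.to_dict("records")
        report["enrichment_vs_all"] = enr_all.to_dict("records")
        report["global_chi2"] = global_test
    if scores is not None and score_tiers is not None:
        report["score_by_tier"] = score_by_tier(scores, score_tiers)
    if phase_table is not None:
        report["cycle_enrichment"] = cycle_enrichment(
            phase_table).to_dict("records")
    return report


def round_report(obj, sig: int = 3):
    """Round every float to ``sig`` significant digits (serialization only)."""
    if isinstance(obj, float):
        if obj == 0 or not np.isfinite(obj):
            return obj
        from math import floor, log10
        return round(obj, -int(floor(log10(abs(obj)))) + (sig - 1))
    if isinstance(obj, dict):
        return {k: round_report(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_report(v, sig) for v in obj]
    return obj
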