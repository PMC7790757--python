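"""Multi-group splice-pattern similarity protocol and experimental-model stats.

The core question: do two small alteration groups (A, B) share a splice
aberration pattern relative to a large control group?  The protocol:

1. per-junction two-sided Wilcoxon rank-sum tests of SI (A vs controls,
   B vs controls, A vs B) within each aberration category, with a Fisher
   test for enrichment of low p-values over the uniform null expectation;
2. supervised PCA on the candidate junctions (p < 0.05, uncorrected):
   among principal components explaining > 5% of variance, those whose
   scores separate the altered group from controls (complete rank
   separation, AUC = 1, by default) are group-associated, and junctions
   correlated with them (|Pearson r| > 0.2 or |loading| > 0.05) are the
   group's differential junctions;
3. the overlap of the two groups' junction sets is compared to the random
   expectation by resampling plus a closed-form hypergeometric tail;
4. the union of selected junctions is re-evaluated by maximal SI per group
   against control quantiles: shared if SI_max exceeds the control 95th
   percentile in both groups, group-specific if one group exceeds Q95 while
   the other stays below Q75, not determined otherwise.

Experimental-model helpers: the relative shift of maximal SI
``dSI_max = (max SI_exp - max SI_ctl) / max SI_ctl``, cryptic-acceptor
distance histograms, reading-frame classification of proximal-3' offsets,
and replicate-based differential junction calling (Welch t + fold-change).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .junction_core import JunctionPair, SIMatrix

__all__ = [
    "wilcoxon_per_junction",
    "wilcoxon_matrix",
    "lowp_enrichment",
    "supervised_pca",
    "SupervisedPCAResult",
    "overlap_test",
    "overlap_significance",
    "OverlapResult",
    "classify_shared",
    "delta_si_max",
    "distance_profile",
    "DistanceProfile",
    "frame_fraction",
    "differential_junctions",
    "compare_patterns",
    "CategoryTestResult",
    "SimilarityReport",
]


def _clean(values) -> np.ndarray:
    """Missing SI means the aberrant form is unexpressed: treat as 0."""
    return np.nan_to_num(np.asarray(values, dtype=float), nan=0.0)


def wilcoxon_per_junction(group_si, control_si) -> float:
    """Two-sided rank-sum p-value comparing SI between two sample sets.

    Uses the exact null distribution when the smaller set has <= 10 samples
    and the pooled values are tie-free; otherwise the normal approximation
    with tie correction.
    """
    g = _clean(group_si)
    c = _clean(control_si)
    if g.size < 2 or c.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([g, c])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(g.size, c.size) <= 10 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(g, c, alternative="two-sided", method=method).pvalue)


def wilcoxon_matrix(si: pd.DataFrame, mask_a, mask_b) -> pd.Series:
    """Per-junction (column) Wilcoxon p-values between two boolean sample masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    return pd.Series(
        [wilcoxon_per_junction(si.loc[a, col], si.loc[b, col]) for col in si.columns],
        index=si.columns,
    )


def lowp_enrichment(pvalues, alpha: float = 0.05) -> float:
    """Fisher-test p for enrichment of p-values below ``alpha``.

    The observed split (``< alpha`` vs ``>= alpha``) is compared against the
    uniform-null expected split (``round(alpha * N)`` vs the rest),
    one-sided toward enrichment.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    n = p.size
    k = int((p < alpha).sum())
    exp_low = int(round(alpha * n))
    table = [[k, n - k], [exp_low, n - exp_low]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


@dataclass
class SupervisedPCAResult:
    """Outcome of the supervised-PCA junction selection.

    ``pcs`` has one row per retained component (explained-variance fraction
    above the threshold) with its separation AUC and association flag;
    ``selected`` has one row per selected junction with the component and
    rule (correlation / loading) that picked it.
    """

    candidates: list[str]
    pcs: pd.DataFrame
    selected: pd.DataFrame

    @property
    def selected_ids(self) -> list[str]:
        return list(dict.fromkeys(self.selected["junction_id"])) if len(self.selected) else []

    @property
    def associated_pcs(self) -> list[str]:
        if len(self.pcs) == 0:
            return []
        return list(self.pcs.loc[self.pcs["associated"], "pc"])


def supervised_pca(
    si: pd.DataFrame,
    group_mask,
    var_min: float = 0.05,
    auc_min: float = 1.0,
    r_min: float = 0.2,
    loading_min: float = 0.05,
) -> SupervisedPCAResult:
    """Select group-differential junctions via group-associated components.

    ``si`` holds the candidate junctions (columns) over the altered-group
    plus control samples (rows); ``group_mask`` is a boolean vector marking
    the altered samples.  A component is group-associated when its scores
    separate the groups with AUC >= ``auc_min`` (default: complete rank
    separation).  If no component passes the variance threshold the result
    is empty, not an error.
    """
    if si.shape[1] < 1:
        raise ValueError("need at least one candidate junction")
    mask = np.asarray(group_mask, dtype=bool)
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("need at least 2 samples on each side")
    X = si.fillna(0.0).to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    k = min(Xc.shape[0] - 1, Xc.shape[1])
    if k < 1 or np.allclose(Xc, 0):
        return SupervisedPCAResult(list(si.columns), pd.DataFrame(), pd.DataFrame())
    from sklearn.decomposition import PCA

    pca = PCA(n_components=k)
    scores = pca.fit_transform(Xc)
    evr = pca.explained_variance_ratio_

    pc_rows, sel_rows = [], []
    col_sd = Xc.std(axis=0)
    for i in range(k):
        if evr[i] <= var_min:
            continue
        auc = roc_auc_score(mask, scores[:, i])
        auc = max(auc, 1.0 - auc)  # sign of a PC is arbitrary
        associated = auc >= auc_min
        pc_rows.append({"pc": f"PC{i + 1}", "evr": float(evr[i]), "auc": float(auc),
                        "associated": bool(associated)})
        if not associated:
            continue
        sc = scores[:, i]
        sc_sd = sc.std()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc * sc[:, None]).mean(axis=0) / np.where(col_sd > 0, col_sd * sc_sd, np.nan)
        load = pca.components_[i]
        for j, col in enumerate(si.columns):
            hit_r = np.isfinite(r[j]) and abs(r[j]) > r_min
            hit_l = abs(load[j]) > loading_min
            if hit_r or hit_l:
                sel_rows.append(
                    {
                        "junction_id": col,
                        "pc": f"PC{i + 1}",
                        "r": float(r[j]) if np.isfinite(r[j]) else np.nan,
                        "loading": float(load[j]),
                        "reason": "correlation" if hit_r else "loading",
                    }
                )
    return SupervisedPCAResult(
        candidates=list(si.columns),
        pcs=pd.DataFrame(pc_rows),
        selected=pd.DataFrame(sel_rows, columns=["junction_id", "pc", "r", "loading", "reason"]),
    )


@dataclass(frozen=True)
class OverlapResult:
    observed: int
    expected: float
    empirical_p: float
    hypergeom_p: float
    n_resamples: int
    universe_size: int
    n_a: int
    n_b: int


def overlap_significance(
    n_a: int,
    n_b: int,
    observed: int,
    universe_size: int,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> OverlapResult:
    """Null distribution of |A n B| for random same-size sets in a universe.

    ``expected = n_a * n_b / universe``; the empirical tail probability is
    ``(1 + #{resamples with overlap >= observed}) / (n_resamples + 1)`` and
    the closed-form hypergeometric upper tail is reported alongside.
    """
    if max(n_a, n_b) > universe_size:
        raise ValueError("universe smaller than one of the sets")
    rng = np.random.default_rng(seed)
    # fixing A = {0..n_a-1} and resampling B is distribution-equivalent to
    # resampling both sets
    hits = 0
    for _ in range(n_resamples):
        b = rng.permutation(universe_size)[:n_b]
        if int((b < n_a).sum()) >= observed:
            hits += 1
    empirical = (1 + hits) / (n_resamples + 1)
    hyper = float(stats.hypergeom.sf(observed - 1, universe_size, n_a, n_b))
    return OverlapResult(
        observed=int(observed),
        expected=n_a * n_b / universe_size,
        empirical_p=float(empirical),
        hypergeom_p=hyper,
        n_resamples=int(n_resamples),
        universe_size=int(universe_size),
        n_a=int(n_a),
        n_b=int(n_b),
    )


def overlap_test(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe_size: int,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> OverlapResult:
    """Observed-overlap significance for two concrete junction sets."""
    a, b = set(set_a), set(set_b)
    return overlap_significance(
        len(a), len(b), len(a & b), universe_size, n_resamples=n_resamples, seed=seed
    )


SHARED_LABELS = ("shared", "A_specific", "B_specific", "not_determined")


def classify_shared(
    si: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    control: str,
    q_hi: float = 0.95,
    q_lo: float = 0.75,
    min_controls: int = 20,
) -> pd.DataFrame:
    """Label junctions shared / group-specific by group maxima vs control quantiles.

    shared:       SI_max > Q95(controls) in both groups;
    X_specific:   group X's SI_max > Q95 while the other group's SI_max < Q75;
    not_determined otherwise (excluded from shared-fraction summaries).
    """
    groups = groups.reindex(si.index)
    ctl = si[groups == control]
    if len(ctl) == 0:
        raise ValueError("empty control group")
    if len(ctl) < min_controls:
        raise ValueError(f"need >= {min_controls} control samples for stable quantiles")
    a = si[groups == group_a].fillna(0.0)
    b = si[groups == group_b].fillna(0.0)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both comparison groups must be non-empty")
    ctl = ctl.fillna(0.0)
    q95 = ctl.quantile(q_hi)
    q75 = ctl.quantile(q_lo)
    max_a = a.max()
    max_b = b.max()
    labels = []
    for j in si.columns:
        hi_a, hi_b = max_a[j] > q95[j], max_b[j] > q95[j]
        if hi_a and hi_b:
            labels.append("shared")
        elif hi_a and max_b[j] < q75[j]:
            labels.append("A_specific")
        elif hi_b and max_a[j] < q75[j]:
            labels.append("B_specific")
        else:
            labels.append("not_determined")
    return pd.DataFrame(
        {
            "junction_id": si.columns,
            "si_max_a": max_a.to_numpy(),
            "si_max_b": max_b.to_numpy(),
            "si_q95": q95.to_numpy(),
            "si_q75": q75.to_numpy(),
            "label": labels,
        }
    )


def delta_si_max(
    si: pd.DataFrame,
    groups: pd.Series,
    exp_label: str,
    control_label: str,
) -> pd.DataFrame:
    """Relative shift of maximal SI: (max SI_exp - max SI_ctl) / max SI_ctl.

    The value is NaN (undefined sentinel) where the control maximum is 0;
    such junctions are excluded from dSI rankings.
    """
    groups = groups.reindex(si.index)
    for label in (exp_label, control_label):
        if not (groups == label).any():
            raise ValueError(f"unknown or empty group {label!r}")
    exp_max = si[groups == exp_label].fillna(0.0).max()
    ctl_max = si[groups == control_label].fillna(0.0).max()
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(ctl_max > 0, (exp_max - ctl_max) / ctl_max, np.nan)
    return pd.DataFrame(
        {
            "junction_id": si.columns,
            "si_max_exp": exp_max.to_numpy(),
            "si_max_control": ctl_max.to_numpy(),
            "delta_si_max": delta,
        }
    )


@dataclass
class DistanceProfile:
    counts: pd.Series  # signed distance -> junction count, within the window
    overflow: int  # |distance| beyond the window
    frac_upstream_10_30: float


def distance_profile(pairs: Iterable[JunctionPair], window: int = 50) -> DistanceProfile:
    """Histogram of cryptic-acceptor offsets around the canonical 3'ss.

    Distances are transcript-oriented (x = 0 at the canonical acceptor,
    negative = upstream); only proximal-3' pairs are counted.  The summary
    fraction covers the hallmark 10-30 nt upstream window.
    """
    dists = [p.distance for p in pairs if p.category == "proximal3"]
    idx = np.arange(-window, window + 1)
    counts = pd.Series(0, index=idx)
    overflow = 0
    in_hallmark = 0
    for d in dists:
        if abs(d) <= window:
            counts[d] += 1
        else:
            overflow += 1
        if -30 <= d <= -10:
            in_hallmark += 1
    total = len(dists)
    return DistanceProfile(
        counts=counts,
        overflow=overflow,
        frac_upstream_10_30=in_hallmark / total if total else float("nan"),
    )


def frame_fraction(pairs: Iterable[JunctionPair]) -> tuple[int, int, float]:
    """(out_of_frame, total, fraction): offsets not divisible by 3 shift frame."""
    dists = [p.distance for p in pairs if p.category == "proximal3" and p.distance is not None]
    out = sum(1 for d in dists if abs(d) % 3 != 0)
    total = len(dists)
    return out, total, out / total if total else float("nan")


def differential_junctions(
    si: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    p_max: float = 0.05,
    log2fc_min: float = 1.0,
    use_fdr: bool = False,
    fdr_max: float = 0.01,
) -> pd.DataFrame:
    """Differential junctions between replicate groups (Welch t + fold change).

    Selection requires both the location test (raw p <= ``p_max``, or
    Benjamini-Hochberg FDR <= ``fdr_max`` when ``use_fdr``) and
    ``|log2(mean SI_a / mean SI_b)| >= log2fc_min``.  Junctions with zero
    mean SI in both groups are skipped (NaN, never selected).
    """
    groups = groups.reindex(si.index)
    a = si[groups == group_a].fillna(0.0)
    b = si[groups == group_b].fillna(0.0)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicates per group")
    mean_a, mean_b = a.mean(), b.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        log2fc = np.log2(mean_a.to_numpy() / mean_b.to_numpy())
    pvals = np.full(si.shape[1], np.nan)
    for j in range(si.shape[1]):
        if mean_a.iloc[j] == 0 and mean_b.iloc[j] == 0:
            continue
        av, bv = a.iloc[:, j], b.iloc[:, j]
        if av.std() == 0 and bv.std() == 0:
            pvals[j] = 1.0 if av.mean() == bv.mean() else 0.0
            continue
        pvals[j] = stats.ttest_ind(av, bv, equal_var=False).pvalue
    tested = np.isfinite(pvals)
    fdr = np.full_like(pvals, np.nan)
    if tested.any():
        fdr[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    crit = fdr <= fdr_max if use_fdr else pvals <= p_max
    with np.errstate(invalid="ignore"):
        selected = tested & np.nan_to_num(crit, nan=False) & (np.abs(log2fc) >= log2fc_min)
    return pd.DataFrame(
        {
            "junction_id": si.columns,
            "mean_si_a": mean_a.to_numpy(),
            "mean_si_b": mean_b.to_numpy(),
            "log2fc": log2fc,
            "p": pvals,
            "fdr": fdr,
            "selected": selected,
        }
    )


@dataclass
class CategoryTestResult:
    """Per-category Wilcoxon screens and their low-p enrichment."""

    category: str
    pvalues: pd.DataFrame  # junctions x {a_vs_control, b_vs_control, a_vs_b}
    enrichment_p: dict[str, float]


@dataclass
class SimilarityReport:
    """Full output of the two-group similarity protocol for one category."""

    category: str
    tests: CategoryTestResult
    pca_a: SupervisedPCAResult
    pca_b: SupervisedPCAResult
    overlap: OverlapResult | None
    shared: pd.DataFrame | None

    @property
    def selected_a(self) -> list[str]:
        return self.pca_a.selected_ids

    @property
    def selected_b(self) -> list[str]:
        return self.pca_b.selected_ids

    def shared_counts(self) -> dict[str, int]:
        if self.shared is None:
            return {}
        return self.shared["label"].value_counts().to_dict()


def compare_patterns(
    matrix: SIMatrix,
    group_a: str,
    group_b: str,
    control: str,
    category: str = "proximal3",
    alpha: float = 0.05,
    n_resamples: int = 10_000,
    seed: int = 0,
    var_min: float = 0.05,
    auc_min: float = 1.0,
    r_min: float = 0.2,
    loading_min: float = 0.05,
    q_hi: float = 0.95,
    q_lo: float = 0.75,
    min_controls: int = 20,
) -> SimilarityReport:
    """Run the whole similarity protocol for one aberration category."""
    if matrix.groups is None:
        raise ValueError("matrix needs group labels")
    cat_ids = [j for j, p in matrix.pairs.items() if p.category == category]
    if not cat_ids:
        raise ValueError(f"no junctions of category {category!r}")
    sub = matrix.restrict(cat_ids)
    g = matrix.groups
    masks = {name: (g == name).to_numpy() for name in (group_a, group_b, control)}

    pv = pd.DataFrame(index=cat_ids)
    comparisons = {
        "a_vs_control": (group_a, control),
        "b_vs_control": (group_b, control),
        "a_vs_b": (group_a, group_b),
    }
    for name, (x, y) in comparisons.items():
        pv[name] = [
            wilcoxon_per_junction(sub.si.loc[masks[x], j], sub.si.loc[masks[y], j])
            for j in cat_ids
        ]
    tests = CategoryTestResult(
        category=category,
        pvalues=pv,
        enrichment_p={name: lowp_enrichment(pv[name], alpha) for name in comparisons},
    )

    results = {}
    for name, grp in (("a", group_a), ("b", group_b)):
        cands = pv.index[pv[f"{name}_vs_control"] < alpha].tolist()
        rows = masks[grp] | masks[control]
        if cands:
            res = supervised_pca(
                sub.si.loc[rows, cands],
                group_mask=masks[grp][rows],
                var_min=var_min,
                auc_min=auc_min,
                r_min=r_min,
                loading_min=loading_min,
            )
        else:
            res = SupervisedPCAResult([], pd.DataFrame(), pd.DataFrame())
        results[name] = res

    sel_a, sel_b = results["a"].selected_ids, results["b"].selected_ids
    overlap = shared = None
    if sel_a and sel_b:
        overlap = overlap_test(sel_a, sel_b, len(cat_ids), n_resamples=n_resamples, seed=seed)
        union = sorted(set(sel_a) | set(sel_b), key=cat_ids.index)
        shared = classify_shared(
            sub.si[union], g, group_a, group_b, control,
            q_hi=q_hi, q_lo=q_lo, min_controls=min_controls,
        )
    return SimilarityReport(
        category=category,
        tests=tests,
        pca_a=results["a"],
        pca_b=results["b"],
        overlap=overlap,
        shared=shared,
    )
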