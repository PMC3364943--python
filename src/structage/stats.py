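"""Statistical layer: binned correlations, linear/interaction fits,
Wilcoxon comparisons and length-matched pairing.

The central quantities are bin series — per-RSA-bin dN values obtained by
concatenating all residues in one of the 20 equal-width RSA bins — and
group-level samples (per-structure rates, delta_G, Z-scores) compared
across age classes.

Regression is fit on the binned points by ordinary least squares
(weighting by per-bin codon count is available but off by default); the
age interaction model dN ~ RSA + age + RSA:age is fit per age pair with
age as a two-level factor. Wilcoxon tests use exact enumeration for small
tie-free samples (min n <= 25) and the tie-corrected, continuity-corrected
normal approximation otherwise; raw p-values are reported (a
Benjamini-Hochberg option exists but is off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .rates import CodonAlignment, RateEstimate, estimate_from_indices

__all__ = [
    "BinSeries",
    "ModelFit",
    "StatsError",
    "DegenerateDataError",
    "bin_series_from_estimates",
    "pearson_binned_correlation",
    "fit_rsa_age_model",
    "wilcoxon_test",
    "length_bin_pairing",
    "benjamini_hochberg",
]

EXACT_WILCOXON_MAX_N = 25


class StatsError(ValueError):
    pass


class DegenerateDataError(StatsError):
    """Constant input where variation is required (e.g. all-zero differences)."""


@dataclass
class BinSeries:
    """Per-RSA-bin dN with standard errors, optionally for one age class."""

    bin_mid: np.ndarray
    dn: np.ndarray
    dn_se: np.ndarray
    n_codons: np.ndarray
    age: str | None = None

    def __post_init__(self) -> None:
        self.bin_mid = np.asarray(self.bin_mid, dtype=float)
        self.dn = np.asarray(self.dn, dtype=float)
        self.dn_se = np.asarray(self.dn_se, dtype=float)
        self.n_codons = np.asarray(self.n_codons)
        if len({len(self.bin_mid), len(self.dn), len(self.dn_se), len(self.n_codons)}) != 1:
            raise StatsError("bin series arrays differ in length")
        if len(np.unique(self.bin_mid)) != len(self.bin_mid):
            raise StatsError("duplicate bins in series")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "bin_mid": self.bin_mid,
                "dn": self.dn,
                "dn_se": self.dn_se,
                "n_codons": self.n_codons,
            }
        )
        if self.age is not None:
            out["age"] = self.age
        return out


@dataclass
class ModelFit:
    """OLS fit summary for the binned dN models."""

    formula: str
    params: dict[str, float]
    pvalues: dict[str, float]
    rsquared: float
    resid_sd: float

    @property
    def slope(self) -> float:
        return self.params["rsa"]

    @property
    def interaction_p(self) -> float:
        return self.pvalues["rsa:age"]


def _dn_standard_error(idx_a: np.ndarray, idx_b: np.ndarray, n_boot: int, rng) -> float:
    """Codon-bootstrap standard error of dN for one concatenated alignment."""
    n = idx_a.size
    vals = np.empty(n_boot)
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        vals[b] = estimate_from_indices(idx_a[take], idx_b[take]).dn
    return float(np.std(vals, ddof=1))


def bin_series_from_estimates(
    per_bin: dict[int, tuple[np.ndarray, np.ndarray]],
    age: str | None = None,
    n_bins: int = 20,
    n_boot: int = 200,
    seed: int = 0,
) -> BinSeries:
    """Estimate dN per RSA bin from codon-index pairs, with bootstrap SEs.

    ``per_bin`` maps bin number (1..n_bins) to a pair of codon index
    arrays (the concatenated alignment for that bin).
    """
    rng = np.random.default_rng(seed)
    mids, dns, ses, ns = [], [], [], []
    for b in sorted(per_bin):
        idx_a, idx_b = per_bin[b]
        if idx_a.size == 0:
            continue
        est = estimate_from_indices(idx_a, idx_b)
        mids.append((b - 0.5) / n_bins)
        dns.append(est.dn)
        ses.append(_dn_standard_error(idx_a, idx_b, n_boot, rng) if n_boot else 0.0)
        ns.append(idx_a.size)
    return BinSeries(np.array(mids), np.array(dns), np.array(ses), np.array(ns), age=age)


def pearson_binned_correlation(series: BinSeries) -> tuple[float, float]:
    """Pearson correlation of dN with RSA bin midpoint (two-sided p)."""
    if len(series.bin_mid) < 3:
        raise StatsError("need at least 3 bins")
    if np.ptp(series.dn) == 0 or np.ptp(series.bin_mid) == 0:
        raise DegenerateDataError("constant series: correlation undefined")
    r, p = sps.pearsonr(series.bin_mid, series.dn)
    return float(r), float(p)


def fit_rsa_age_model(
    series_by_age: dict[str, BinSeries] | BinSeries,
    formula: str = "dN~RSA",
    weighted: bool = False,
) -> dict:
    """Fit the binned dN models.

    ``formula="dN~RSA"`` fits one OLS line per age series (or a single
    series) and returns {age: ModelFit}. ``formula="dN~RSA+RSA*age+age"``
    fits the interaction model for every pair of ages (age as a 0/1
    factor, older class as baseline) and returns
    {(age_older, age_younger): ModelFit}.
    """
    if isinstance(series_by_age, BinSeries):
        series_by_age = {series_by_age.age or "all": series_by_age}

    def _ols(x: np.ndarray, y: np.ndarray, w: np.ndarray | None, names: list[str]):
        design = sm.add_constant(x, has_constant="add")
        if w is not None:
            res = sm.WLS(y, design, weights=w).fit()
        else:
            res = sm.OLS(y, design).fit()
        params = dict(zip(names, np.atleast_1d(res.params)))
        pvals = dict(zip(names, np.atleast_1d(res.pvalues)))
        resid_sd = float(np.std(res.resid, ddof=min(len(names), len(y) - 1)))
        rsq = float(res.rsquared) if len(y) > len(names) else 1.0
        return params, pvals, rsq, resid_sd

    if formula == "dN~RSA":
        fits = {}
        for age, s in series_by_age.items():
            if len(s.bin_mid) < 2:
                raise StatsError(f"age {age}: need >= 2 bins")
            w = s.n_codons.astype(float) if weighted else None
            params, pvals, rsq, rsd = _ols(
                s.bin_mid[:, None], s.dn, w, ["intercept", "rsa"]
            )
            fits[age] = ModelFit("dN~RSA", params, pvals, rsq, rsd)
        return fits

    if formula == "dN~RSA+RSA*age+age":
        ages = list(series_by_age)
        if len(ages) < 2:
            raise StatsError("interaction model needs >= 2 age series")
        fits = {}
        for i in range(len(ages)):
            for j in range(i + 1, len(ages)):
                s0, s1 = series_by_age[ages[i]], series_by_age[ages[j]]
                x = np.concatenate([s0.bin_mid, s1.bin_mid])
                a = np.concatenate([np.zeros(len(s0.bin_mid)), np.ones(len(s1.bin_mid))])
                y = np.concatenate([s0.dn, s1.dn])
                w = (
                    np.concatenate([s0.n_codons, s1.n_codons]).astype(float)
                    if weighted
                    else None
                )
                design = np.column_stack([x, a, x * a])
                params, pvals, rsq, rsd = _ols(
                    design, y, w, ["intercept", "rsa", "age", "rsa:age"]
                )
                fits[(ages[i], ages[j])] = ModelFit(
                    "dN~RSA+RSA*age+age", params, pvals, rsq, rsd
                )
        return fits

    raise StatsError(f"unknown formula {formula!r}")


def wilcoxon_test(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    paired: bool = False,
) -> tuple[float, float]:
    """Wilcoxon comparison of two samples.

    Unpaired: rank-sum (Mann-Whitney U). Paired: signed-rank on the
    differences. Exact null enumeration is used for small tie-free samples
    (min n <= 25); otherwise the normal approximation with continuity and
    tie correction. Returns ``(statistic, two_sided_p)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise StatsError("empty sample")
    if paired:
        if a.size != b.size:
            raise StatsError("paired samples must have equal length")
        diffs = a - b
        if np.all(diffs == 0):
            raise DegenerateDataError("all paired differences are zero")
        nz = diffs[diffs != 0]
        exact = nz.size <= EXACT_WILCOXON_MAX_N and np.unique(np.abs(nz)).size == nz.size
        res = sps.wilcoxon(
            a, b, zero_method="wilcox", correction=True,
            mode="exact" if exact else "approx",
        )
        return float(res.statistic), float(res.pvalue)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size != pooled.size
    exact = min(a.size, b.size) <= EXACT_WILCOXON_MAX_N and not has_ties
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def length_bin_pairing(
    groups: dict[str, list[tuple[int, float]]],
    bin_width: int = 25,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Down-sample groups to identical length distributions at bin resolution.

    ``groups`` maps a group label (age class) to (length, value) records.
    Within each length bin present in *all* groups, every group is
    down-sampled (seeded) to the smallest per-group count, so the compared
    groups share the same length distribution. Bins missing any group are
    dropped. Returns the retained records and the labels of groups that
    had to be excluded entirely (no shared bin with the others).
    """
    rng = np.random.default_rng(seed)
    binned: dict[str, dict[int, list[tuple[int, float]]]] = {}
    for g, records in groups.items():
        by_bin: dict[int, list[tuple[int, float]]] = {}
        for length, value in records:
            by_bin.setdefault(length // bin_width, []).append((length, value))
        binned[g] = by_bin

    # drop groups (fewest shared bins first) until the rest overlap somewhere
    labels = list(groups)
    excluded: list[str] = []
    while len(labels) >= 2:
        shared = set.intersection(*(set(binned[g]) for g in labels))
        if shared:
            break
        worst = min(
            labels,
            key=lambda g: sum(
                len(set(binned[g]) & set(binned[h])) for h in labels if h != g
            ),
        )
        labels.remove(worst)
        excluded.append(worst)
    else:
        excluded = list(groups)
        return (
            pd.DataFrame(columns=["group", "length_bin", "length", "value"]),
            excluded,
        )

    rows = []
    for bin_id in sorted(shared):
        m = min(len(binned[g][bin_id]) for g in labels)
        for g in labels:
            recs = binned[g][bin_id]
            take = rng.choice(len(recs), size=m, replace=False)
            for t in sorted(take):
                rows.append((g, bin_id, recs[t][0], recs[t][1]))
    table = pd.DataFrame(rows, columns=["group", "length_bin", "length", "value"])
    return table, excluded


def benjamini_hochberg(pvalues: list[float]) -> list[float]:
    """FDR-adjusted p-values (off by default in all reports)."""
    return list(multipletests(pvalues, method="fdr_bh")[1])
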