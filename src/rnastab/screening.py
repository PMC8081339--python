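"""Statistical screening of feature-half-life relationships.

Spearman rank correlation (exact permutation p for very small n, the usual
t approximation otherwise), two-sample Kolmogorov-Smirnov, one-way ANOVA
and Bonferroni adjustment, plus the screening workflows built on them:
per-feature screens with directional "a/b" summaries, exon-number
stratification, subsampling power curves, and the all-pairs factor
regulation network.

Note on naming: adjusted values are reported under the column name ``fdr``
to match the conventional output of this analysis, but the adjustment is
Bonferroni, i.e. family-wise error control, not a false-discovery rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman_test",
    "ks_two_sample",
    "anova_oneway",
    "bonferroni_adjust",
    "stratify_by_exon",
    "ScreenHit",
    "screen_features",
    "subsample_stability",
    "build_network",
]

_EXACT_N = 8  # at or below this, Spearman p is exact permutation


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    return float(rx @ ry / denom)


def spearman_test(x, y) -> tuple[float, float]:
    """Spearman rho (average-rank Pearson) with two-sided p.

    p is exact (full permutation enumeration) for n <= 8 and the t
    approximation with n - 2 df otherwise. Constant input is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rho undefined")
    rho = _spearman_rho(x, y)
    if n <= _EXACT_N:
        ry = stats.rankdata(y)
        obs = abs(rho)
        hits = total = 0
        for perm in permutations(ry):
            total += 1
            if abs(_spearman_rho(x, np.array(perm))) >= obs - 1e-12:
                hits += 1
        return rho, hits / total
    if 1.0 - rho * rho < 1e-15:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return rho, float(min(p, 1.0))


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample KS: D = sup|ECDF_x - ECDF_y|, asymptotic two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across >= 2 groups of >= 2 values."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n_total = sum(g.size for g in groups)
    if n_total - len(groups) < 1:
        raise ValueError("degenerate degrees of freedom")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def bonferroni_adjust(ps, m: int | None = None) -> np.ndarray:
    """min(p * m, 1) elementwise; m defaults to the number of tests."""
    ps = np.asarray(ps, dtype=float)
    if np.any((ps < 0) | (ps > 1) | ~np.isfinite(ps)):
        raise ValueError("p values must be in [0, 1]")
    if m is None:
        m = ps.size
    return np.minimum(ps * m, 1.0)


def stratify_by_exon(records) -> dict[str, list]:
    """Split records into the single-exon and multi-exon strata per biotype.

    Keys follow the lnc-human1/lnc-human2 (m-human1/m-human2) naming:
    ``lnc1``/``lnc2`` for lncRNAs and ``m1``/``m2`` for mRNAs.
    """
    out: dict[str, list] = {"lnc1": [], "lnc2": [], "m1": [], "m2": []}
    for rec in records:
        if rec.exon_count < 1:
            raise ValueError(f"{rec.transcript_id}: exon_count < 1")
        prefix = "lnc" if rec.biotype == "lncRNA" else "m"
        out[prefix + ("1" if rec.exon_count == 1 else "2")].append(rec)
    return out


@dataclass(frozen=True)
class ScreenHit:
    """One feature's screen result."""

    feature_name: str
    rho: float
    p: float
    fdr: float
    direction: str
    n: int


def screen_features(halflives, feature_matrix: pd.DataFrame,
                    method: str = "spearman", alpha: float = 0.01
                    ) -> tuple[list[ScreenHit], str]:
    """Screen every feature column against half-lives.

    method="spearman": rank correlation per numeric feature.
    method="ks_binary": the feature is presence/absence and the half-life
    subsets of carriers vs non-carriers are compared by KS (rho is then the
    signed mean difference direction, from the carrier mean minus the
    non-carrier mean).

    Returns hits (one per testable feature, Bonferroni-adjusted over the
    features tested) and the directional summary "a/b" where b counts
    features with adjusted p < alpha and a those among them with the
    majority sign.
    """
    if isinstance(halflives, pd.DataFrame):
        halflives = halflives.set_index("transcript_id")["t_half_mean"]
    common = feature_matrix.index.intersection(halflives.index)
    if len(common) == 0:
        raise ValueError("no shared transcript ids")
    y = halflives.loc[common].to_numpy(float)
    results = []
    for name in feature_matrix.columns:
        x = feature_matrix.loc[common, name].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 4 or np.ptp(x[ok]) == 0:
            warnings.warn(f"skipping feature {name!r}: too few values or zero variance")
            continue
        if method == "spearman":
            rho, p = spearman_test(x[ok], y[ok])
        elif method == "ks_binary":
            carrier = y[ok][x[ok] > 0]
            rest = y[ok][x[ok] <= 0]
            if carrier.size == 0 or rest.size == 0:
                warnings.warn(f"skipping feature {name!r}: one-sided presence")
                continue
            _, p = ks_two_sample(carrier, rest)
            rho = float(np.sign(carrier.mean() - rest.mean()))
        else:
            raise ValueError(f"unknown method {method!r}")
        results.append((name, rho, p, int(ok.sum())))
    if not results:
        return [], "0/0"
    fdrs = bonferroni_adjust([r[2] for r in results])
    hits = [ScreenHit(name, rho, p, float(fdr),
                      "positive" if rho >= 0 else "negative", n)
            for (name, rho, p, n), fdr in zip(results, fdrs)]
    sig = [h for h in hits if h.fdr < alpha]
    b = len(sig)
    n_pos = sum(1 for h in sig if h.direction == "positive")
    a = max(n_pos, b - n_pos)
    return hits, f"{a}/{b}"


def hits_to_frame(hits) -> pd.DataFrame:
    return pd.DataFrame([h.__dict__ for h in hits])


def subsample_stability(halflives, feature, sample_sizes, reps: int = 1000,
                        alpha: float = 0.1, seed: int = 0) -> pd.DataFrame:
    """Power-by-subsampling curve: how often a correlation is missed.

    For each n in ``sample_sizes``, draw n transcripts without replacement
    ``reps`` times, test Spearman correlation between the feature and the
    half-life, and count draws with p > alpha (the relationship missed).
    """
    y = np.asarray(halflives, dtype=float)
    x = np.asarray(feature, dtype=float)
    if x.shape != y.shape:
        raise ValueError("feature and halflives differ in length")
    rng = np.random.default_rng(seed)
    rows = []
    for n in sample_sizes:
        if n > y.size:
            raise ValueError(f"sample size {n} exceeds population {y.size}")
        misses = 0
        for _ in range(reps):
            idx = rng.choice(y.size, size=n, replace=False)
            _, p = spearman_test(x[idx], y[idx])
            if p > alpha:
                misses += 1
        rows.append({"n": n, "reps": reps, "n_p_above_alpha": misses})
    return pd.DataFrame(rows)


#: raw-p bins for edge strength in the regulation network
STRENGTH_BINS = {"strong": (0.0, 1e-33), "medium": (1e-33, 1e-26),
                 "weak": (1e-26, 1e-5)}


def _strength(p: float) -> str:
    if p < 1e-33:
        return "strong"
    if p <= 1e-26:
        return "medium"
    return "weak"


def build_network(factor_table: pd.DataFrame, edge_fdr: float = 0.01
                  ) -> dict:
    """All-pairs Spearman regulation network over factor columns.

    An edge joins two factors when the Bonferroni-adjusted p over all pairs
    is below ``edge_fdr`` and the raw p is below 1e-5 (the weak-bin bound);
    its sign comes from rho and its strength bin from the raw p. Factors
    with all-missing values are excluded with a warning.
    """
    cols = []
    for c in factor_table.columns:
        vals = factor_table[c].dropna()
        if len(vals) == 0:
            warnings.warn(f"excluding all-missing factor {c!r}")
        elif vals.nunique() == 1:
            warnings.warn(f"excluding constant factor {c!r}")
        else:
            cols.append(c)
    if len(cols) < 2:
        raise ValueError("need >= 2 usable factor columns")
    pairs = list(combinations(cols, 2))
    raw = []
    for a, b in pairs:
        sub = factor_table[[a, b]].dropna()
        rho, p = spearman_test(sub[a].to_numpy(), sub[b].to_numpy())
        raw.append((a, b, rho, p))
    fdrs = bonferroni_adjust([r[3] for r in raw])
    edges = []
    for (a, b, rho, p), fdr in zip(raw, fdrs):
        if fdr < edge_fdr and p < 1e-5:
            edges.append({"source": a, "target": b,
                          "sign": "+" if rho >= 0 else "-",
                          "strength": _strength(p),
                          "rho": rho, "p": p, "fdr": float(fdr)})
    return {"nodes": cols, "edges": edges}
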