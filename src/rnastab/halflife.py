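"""Transcript half-life estimation from transcription-inhibition time courses.

Abundance of a transcript after transcription shut-off follows first-order
decay, so ln(FPKM) is linear in time over the terminal phase and the
half-life is t1/2 = ln(2)/lambda_z where lambda_z is the negated slope.
The terminal phase is found the way noncompartmental pharmacokinetics
packages do it: every suffix of the usable (positive, non-missing) points
with at least ``min_points`` members is fitted by OLS and the fit with the
best adjusted R-squared wins.

Replicate time courses are combined by resampling: each resampled series
takes, at every time point, the value of one replicate chosen uniformly at
random; each resampled series is fitted, fits passing the adjusted-R-squared
gate are averaged, and the whole procedure is repeated over independent
simulations to attach a confidence interval.

:class:`HalfLifeModel` / :class:`HalfLifeResults` wrap the pipeline in a
statsmodels-style model/results pair.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DecayProfile",
    "LambdaZFit",
    "fit_lambda_z",
    "resample_profile",
    "estimate_half_life",
    "direct_half_life",
    "run_halflife_pipeline",
    "HalfLifeModel",
    "HalfLifeResults",
    "profiles_from_long_table",
]

LN2 = float(np.log(2.0))

#: ties in adjusted R-squared closer than this are resolved in favour of the
#: fit using more points (the convention of PK lambda-z selectors)
_ADJ_R2_TIE = 1e-4


@dataclass(frozen=True)
class DecayProfile:
    """Replicated FPKM time course for one transcript.

    ``replicates`` has shape (n_rep, n_times); values are FPKM >= 0 with 0
    meaning below the detection limit.
    """

    transcript_id: str
    times: np.ndarray
    replicates: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        reps = np.atleast_2d(np.asarray(self.replicates, dtype=float))
        if t.ndim != 1 or t.size < 3:
            raise ValueError("need at least 3 time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if reps.shape[1] != t.size:
            raise ValueError("replicate matrix width must match times")
        if np.any(reps[np.isfinite(reps)] < 0):
            raise ValueError("negative FPKM")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "replicates", reps)

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[0]


@dataclass(frozen=True)
class LambdaZFit:
    """One terminal log-linear fit."""

    n_points: int
    slope: float
    intercept: float
    adj_r2: float
    point_indices: tuple[int, ...]

    @property
    def lambda_z(self) -> float:
        return -self.slope

    @property
    def t_half(self) -> float:
        return LN2 / self.lambda_z


def _usable_mask(concs: np.ndarray) -> np.ndarray:
    # missing values dropped (conc.na) and non-positive values dropped as
    # below the detection limit (conc.blq) before the log transform
    return np.isfinite(concs) & (concs > 0)


def fit_lambda_z(times, concs, min_points: int = 3) -> LambdaZFit | None:
    """Best terminal log-linear fit over suffixes of the usable points.

    Returns ``None`` when no suffix of >= ``min_points`` usable points gives
    a negative slope (no measurable decay).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.shape != c.shape:
        raise ValueError("times and concentrations differ in length")
    if min_points < 3:
        raise ValueError("min_points must be >= 3")
    usable = np.flatnonzero(_usable_mask(c))
    n = usable.size
    if n < min_points:
        return None
    logc = np.log(c[usable])
    tt = t[usable]

    # suffix OLS in closed form from reversed cumulative sums: one pass
    # yields slope, intercept and R^2 for every candidate suffix
    xr, yr = tt[::-1], logc[::-1]
    sx = np.cumsum(xr)
    sy = np.cumsum(yr)
    sxx = np.cumsum(xr * xr)
    syy = np.cumsum(yr * yr)
    sxy = np.cumsum(xr * yr)

    best: LambdaZFit | None = None
    for k in range(min_points, n + 1):
        i = k - 1
        vx = k * sxx[i] - sx[i] * sx[i]
        vy = k * syy[i] - sy[i] * sy[i]
        cov = k * sxy[i] - sx[i] * sy[i]
        if vx <= 0:
            continue
        slope = cov / vx
        if not np.isfinite(slope) or slope >= 0:
            continue
        r2 = 1.0 if vy <= 0 else min(cov * cov / (vx * vy), 1.0)
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        if best is None or adj > best.adj_r2 + _ADJ_R2_TIE or (
                adj >= best.adj_r2 - _ADJ_R2_TIE and k > best.n_points):
            intercept = (sy[i] - slope * sx[i]) / k
            best = LambdaZFit(k, float(slope), float(intercept), float(adj),
                              tuple(int(j) for j in usable[n - k:]))
    return best


def resample_profile(profile: DecayProfile, rng: np.random.Generator) -> np.ndarray:
    """One resampled series: at each time, one replicate's value, uniformly."""
    picks = rng.integers(0, profile.n_replicates, size=profile.times.size)
    return profile.replicates[picks, np.arange(profile.times.size)]


def estimate_half_life(profile: DecayProfile, n_resamples: int = 1000,
                       r2_min: float = 0.7,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[float, int] | None:
    """Mean half-life over gated resample fits, or None when none pass.

    Each of ``n_resamples`` resampled series is fitted; fits with adjusted
    R-squared >= ``r2_min`` contribute their t1/2 to the arithmetic mean.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    total = 0.0
    n_valid = 0
    for _ in range(n_resamples):
        series = resample_profile(profile, rng)
        fit = fit_lambda_z(profile.times, series)
        if fit is not None and fit.adj_r2 >= r2_min:
            total += fit.t_half
            n_valid += 1
    if n_valid == 0:
        return None
    return total / n_valid, n_valid


def direct_half_life(times, concs, r2_min: float = 0.7) -> LambdaZFit | None:
    """Single-series half-life (compartment time courses), gated on adj R2."""
    fit = fit_lambda_z(times, concs)
    if fit is None or fit.adj_r2 < r2_min:
        return None
    return fit


def _transcript_rng(seed: int, transcript_id: str, sim: int) -> np.random.Generator:
    # stable per-transcript stream: results do not depend on profile order
    digest = hashlib.sha256(transcript_id.encode()).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([seed, key, sim]))


def run_halflife_pipeline(profiles, n_sim: int = 10, n_resamples: int = 1000,
                          r2_min: float = 0.7, max_halflife: float = 50.0,
                          seed: int = 0) -> pd.DataFrame:
    """Replicated resampling pipeline over many transcripts.

    For each transcript and each of ``n_sim`` independent simulations the
    resampling estimate is computed; only transcripts estimated in every
    simulation are kept; the mean across simulation means, its t-based 95%
    confidence interval, the per-simulation means and the minimum count of
    gated fits are reported; transcripts with mean >= ``max_halflife`` hours
    are dropped as biologically unresolvable on the sampled window.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles")
    rows = []
    sim_matrix: dict[str, np.ndarray] = {}
    for prof in profiles:
        means = np.full(n_sim, np.nan)
        n_valid = np.zeros(n_sim, dtype=int)
        ok = True
        for s in range(n_sim):
            rng = _transcript_rng(seed, prof.transcript_id, s)
            est = estimate_half_life(prof, n_resamples=n_resamples,
                                     r2_min=r2_min, rng=rng)
            if est is None:
                ok = False
                break
            means[s], n_valid[s] = est
        if not ok:
            continue
        mean = float(means.mean())
        if mean >= max_halflife:
            continue
        if n_sim > 1:
            sem = means.std(ddof=1) / np.sqrt(n_sim)
            tq = stats.t.ppf(0.975, n_sim - 1)
            lo, hi = mean - tq * sem, mean + tq * sem
        else:
            lo = hi = mean
        sim_matrix[prof.transcript_id] = means
        rows.append({
            "transcript_id": prof.transcript_id,
            "t_half_mean": mean,
            "ci95_low": float(lo),
            "ci95_high": float(hi),
            "n_valid_min": int(n_valid.min()),
        })
    out = pd.DataFrame(rows, columns=["transcript_id", "t_half_mean",
                                      "ci95_low", "ci95_high", "n_valid_min"])
    out.attrs["sim_means"] = sim_matrix
    return out


def profiles_from_long_table(table: pd.DataFrame) -> list[DecayProfile]:
    """Build profiles from a long table (transcript_id, time_h, replicate, fpkm)."""
    required = {"transcript_id", "time_h", "replicate", "fpkm"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    for tid, grp in table.groupby("transcript_id", sort=True):
        wide = grp.pivot_table(index="replicate", columns="time_h",
                               values="fpkm", sort=True)
        out.append(DecayProfile(str(tid), wide.columns.to_numpy(float),
                                wide.to_numpy(float)))
    return out


class HalfLifeModel:
    """Half-life estimation model over a collection of decay profiles.

    Parameters
    ----------
    profiles
        Iterable of :class:`DecayProfile`.
    n_sim, n_resamples, r2_min, max_halflife
        Pipeline settings; defaults follow the resampling design of ten
        simulations of one thousand resamples gated at adjusted R2 >= 0.7
        with a 50 h half-life cap.
    """

    def __init__(self, profiles, n_sim: int = 10, n_resamples: int = 1000,
                 r2_min: float = 0.7, max_halflife: float = 50.0):
        self.profiles = list(profiles)
        self.n_sim = n_sim
        self.n_resamples = n_resamples
        self.r2_min = r2_min
        self.max_halflife = max_halflife

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "HalfLifeModel":
        return cls(profiles_from_long_table(table), **kwargs)

    def fit(self, seed: int = 0) -> "HalfLifeResults":
        estimates = run_halflife_pipeline(
            self.profiles, n_sim=self.n_sim, n_resamples=self.n_resamples,
            r2_min=self.r2_min, max_halflife=self.max_halflife, seed=seed)
        return HalfLifeResults(self, estimates, seed)


@dataclass
class HalfLifeResults:
    """Estimates, confidence intervals and diagnostics from a fitted model."""

    model: HalfLifeModel
    estimates: pd.DataFrame
    seed: int
    _anova: tuple[float, float] | None = field(default=None, repr=False)

    @property
    def sim_means(self) -> dict[str, np.ndarray]:
        return self.estimates.attrs.get("sim_means", {})

    def anova_across_simulations(self) -> tuple[float, float]:
        """Robustness check: one-way ANOVA of estimates across simulations.

        A well-behaved resampling procedure gives statistically
        indistinguishable half-life datasets in every simulation (p near 1).
        """
        if self._anova is None:
            mat = np.array([v for v in self.sim_means.values()])
            if mat.shape[0] < 2:
                raise ValueError("need >= 2 retained transcripts")
            f, p = stats.f_oneway(*(mat[:, s] for s in range(mat.shape[1])))
            self._anova = (float(f), float(p))
        return self._anova

    def summary(self) -> str:
        est = self.estimates
        lines = [
            "Half-life estimation (replicate-resampling lambda-z)",
            "=" * 54,
            f"profiles in          {len(self.model.profiles):>8d}",
            f"transcripts retained {len(est):>8d}",
            f"simulations          {self.model.n_sim:>8d}",
            f"resamples/simulation {self.model.n_resamples:>8d}",
            f"adj R2 gate          {self.model.r2_min:>8.2f}",
            f"half-life cap (h)    {self.model.max_halflife:>8.1f}",
        ]
        if len(est):
            lines += [
                f"mean t1/2 (h)        {est.t_half_mean.mean():>8.2f}",
                f"median t1/2 (h)      {est.t_half_mean.median():>8.2f}",
                f"mean CI width (h)    {(est.ci95_high - est.ci95_low).mean():>8.3f}",
            ]
        if len(self.sim_means) >= 2 and self.model.n_sim >= 2:
            f, p = self.anova_across_simulations()
            lines.append(f"ANOVA across sims    F={f:.3g} p={p:.3g}")
        return "\n".join(lines)
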