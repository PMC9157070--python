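"""Trajectory-level statistics for pooled-sequencing mutation time series.

Frequencies are estimated with the naive estimator ``f = F/G`` from
alternate-read counts ``F`` and depths ``G``.  On top of the estimated
trajectories this module computes the sum of derived allele frequencies
``M(t)``, a hyperbolic (Michaelis-Menten-like) model of diversity
accumulation on the log10 scale, per-mutation summary measures (``f_max``,
per-generation magnitude of frequency change, direction-of-change ratios),
empirical survival distributions with Kolmogorov-Smirnov comparisons,
threshold-based fate calling, pairwise trajectory correlations (a
recombination proxy), site-class-weighted pN/pS, serial-transfer generation
arithmetic, and relative log fitness from colony counts.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryMatrix",
    "DiversityModelFit",
    "TrajectoryMeasures",
    "GenerationEstimate",
    "SurvivalCurve",
    "estimate_frequencies",
    "sum_derived_frequencies",
    "fit_diversity_model",
    "bootstrap_diversity_fit",
    "trajectory_measures",
    "survival_distribution",
    "ks_compare",
    "ks_compare_batch",
    "classify_fate",
    "fate_table",
    "prob_extinct_given_detected",
    "pairwise_trajectory_correlation",
    "pn_ps",
    "estimate_generations",
    "relative_log_fitness",
    "fitness_assay",
]

#: canonical column order of the trajectory table dialect
TRAJECTORY_COLUMNS = [
    "mutation_id",
    "population_id",
    "strain",
    "regime",
    "gene_id",
    "annotation_class",
    "day",
    "generations",
    "alt_count",
    "depth",
]

_OPTIONAL_DEFAULTS = {
    "strain": "NA",
    "regime": "NA",
    "gene_id": "NA",
    "annotation_class": "other",
    "generations": np.nan,
}


@dataclass
class TrajectoryMatrix:
    """Tidy mutations-by-timepoints table of pooled-sequencing counts.

    One row per mutation x population x timepoint, with integer alternate
    read count ``alt_count`` and depth ``depth``.  ``frequency`` is filled by
    :func:`estimate_frequencies` (NaN where depth is 0, i.e. missing
    coverage).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = ["mutation_id", "population_id", "day", "alt_count", "depth"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory table is missing columns: {missing}")
        for col, default in _OPTIONAL_DEFAULTS.items():
            if col not in df.columns:
                df[col] = default
        bad = df[df["alt_count"] > df["depth"]]
        if len(bad):
            rec = bad.iloc[0]
            raise ValueError(
                "alt_count exceeds depth for mutation "
                f"{rec['mutation_id']!r} in population {rec['population_id']!r} "
                f"at day {rec['day']!r}"
            )
        if (df["alt_count"] < 0).any() or (df["depth"] < 0).any():
            raise ValueError("negative read counts")
        dup = df.duplicated(subset=["mutation_id", "population_id", "day"])
        if dup.any():
            rec = df[dup].iloc[0]
            raise ValueError(
                f"duplicate record for mutation {rec['mutation_id']!r}, "
                f"population {rec['population_id']!r}, day {rec['day']!r}"
            )
        self.data = df.sort_values(["population_id", "mutation_id", "day"]).reset_index(
            drop=True
        )

    @property
    def populations(self) -> list:
        return sorted(self.data["population_id"].unique())

    @property
    def days(self) -> list:
        return sorted(self.data["day"].unique())

    def __len__(self) -> int:
        return len(self.data)


def estimate_frequencies(counts: TrajectoryMatrix) -> TrajectoryMatrix:
    """Fill the naive frequency estimate ``f = F/G``; depth-0 cells become NaN."""
    df = counts.data.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        df["frequency"] = np.where(
            df["depth"] > 0, df["alt_count"] / df["depth"], np.nan
        )
    return TrajectoryMatrix(df)


def _need_frequencies(traj: TrajectoryMatrix) -> pd.DataFrame:
    if "frequency" not in traj.data.columns:
        traj = estimate_frequencies(traj)
    return traj.data


def sum_derived_frequencies(traj: TrajectoryMatrix) -> pd.DataFrame:
    """Sum of derived allele frequencies M(t) per population per timepoint.

    Cells with missing coverage contribute 0 (the estimator sums detected
    derived alleles); a warning is logged when any are present.
    """
    df = _need_frequencies(traj)
    n_missing = int(df["frequency"].isna().sum())
    if n_missing:
        logger.warning(
            "%d trajectory cells have no coverage; they contribute 0 to M(t)",
            n_missing,
        )
    filled = df.assign(frequency=df["frequency"].fillna(0.0))
    out = (
        filled.groupby(["population_id", "day"], sort=True)["frequency"]
        .sum()
        .rename("M")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# Hyperbolic diversity-accumulation model
# ---------------------------------------------------------------------------

@dataclass
class DiversityModelFit:
    """Best fit of log10 M(t*) = intercept + amplitude * t*/(halftime + t*).

    ``t*`` is time shifted so the first sampled day maps to 0; ``halftime``
    (``t*_1/2``) is the shifted time at which log10 M has risen by half the
    amplitude.  ``tau_half`` converts the half-time to generations using the
    caller-supplied per-day generation rate.
    """

    intercept: float
    amplitude: float
    halftime_days: float
    tau_half: float
    per_day_generations: float
    t_shift: float
    objective: float
    n_starts: int
    n_converged: int
    converged: bool
    standard_errors: tuple = (math.nan, math.nan, math.nan)

    def predict(self, t_days: np.ndarray) -> np.ndarray:
        """Model value of log10 M at (unshifted) days ``t_days``."""
        ts = np.asarray(t_days, dtype=float) - self.t_shift
        return self.intercept + self.amplitude * ts / (self.halftime_days + ts)


def _hyperbolic(tstar: np.ndarray, b0: float, amp: float, th: float) -> np.ndarray:
    return b0 + amp * tstar / (th + tstar)


def fit_diversity_model(
    times_days: Sequence[float],
    M_values: Sequence[float],
    per_day_generations: float = 1.0,
) -> DiversityModelFit:
    """Least-squares fit of the hyperbolic diversity-accumulation model.

    A quasi-Newton (BFGS) optimizer is launched from a fixed 54-point grid of
    initial conditions (3 intercepts x 3 amplitudes x 6 log-spaced
    half-times); the best objective is retained.  The half-time is optimized
    on a log scale, which keeps it positive without changing the model.
    """
    t = np.asarray(times_days, dtype=float)
    M = np.asarray(M_values, dtype=float)
    if t.shape != M.shape or t.ndim != 1:
        raise ValueError("times and M values must be 1-D and equally long")
    keep = np.isfinite(t) & np.isfinite(M) & (M > 0)
    t, M = t[keep], M[keep]
    if len(t) < 4:
        raise ValueError("need at least 4 timepoints with M > 0")
    order = np.argsort(t)
    t, M = t[order], M[order]
    t_shift = t[0]
    tstar = t - t_shift
    y = np.log10(M)

    def objective(theta: np.ndarray) -> float:
        b0, amp, u = theta
        r = y - _hyperbolic(tstar, b0, amp, math.exp(u))
        return float(r @ r)

    y_range = max(y.max() - y.min(), 0.1)
    t_hi = tstar.max()
    t_lo = max(tstar[tstar > 0].min() if (tstar > 0).any() else 1.0, 1e-3)
    starts = [
        (b0, a_mult * y_range, math.log(th))
        for b0 in (y.min(), y.mean(), y.max())
        for a_mult in (0.5, 1.0, 2.0)
        for th in np.geomspace(t_lo, t_hi, 6)
    ]

    best = None
    n_converged = 0
    for x0 in starts:
        res = optimize.minimize(
            objective, np.asarray(x0), method="BFGS", options={"gtol": 1e-8}
        )
        if res.success:
            n_converged += 1
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res

    if best is None or not np.isfinite(best.fun):
        return DiversityModelFit(
            intercept=math.nan,
            amplitude=math.nan,
            halftime_days=math.nan,
            tau_half=math.nan,
            per_day_generations=per_day_generations,
            t_shift=t_shift,
            objective=math.inf,
            n_starts=len(starts),
            n_converged=0,
            converged=False,
        )

    b0, amp, u = best.x
    th = math.exp(u)
    ses = _gauss_newton_se(tstar, y, b0, amp, th)
    return DiversityModelFit(
        intercept=float(b0),
        amplitude=float(amp),
        halftime_days=float(th),
        tau_half=float(th * per_day_generations),
        per_day_generations=per_day_generations,
        t_shift=float(t_shift),
        objective=float(best.fun),
        n_starts=len(starts),
        n_converged=n_converged,
        converged=n_converged > 0,
        standard_errors=ses,
    )


def _gauss_newton_se(tstar, y, b0, amp, th) -> tuple:
    """Asymptotic standard errors of (intercept, amplitude, half-time)."""
    n = len(tstar)
    if n <= 3:
        return (math.nan, math.nan, math.nan)
    frac = tstar / (th + tstar)
    J = np.column_stack([np.ones(n), frac, -amp * tstar / (th + tstar) ** 2])
    r = y - _hyperbolic(tstar, b0, amp, th)
    s2 = float(r @ r) / (n - 3)
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        return (math.nan, math.nan, math.nan)
    d = np.diag(cov)
    return tuple(math.sqrt(v) if v >= 0 else math.nan for v in d)


def bootstrap_diversity_fit(
    fit: DiversityModelFit,
    times_days: Sequence[float],
    M_values: Sequence[float],
    n_boot: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Residual-bootstrap sample of (intercept, amplitude, half-time).

    Refits start from the point estimate (single start) -- the objective is
    smooth near the optimum and the full start grid is unnecessary here.
    """
    t = np.asarray(times_days, dtype=float)
    M = np.asarray(M_values, dtype=float)
    keep = np.isfinite(t) & np.isfinite(M) & (M > 0)
    t, M = t[keep], M[keep]
    order = np.argsort(t)
    t, M = t[order], M[order]
    tstar = t - fit.t_shift
    y = np.log10(M)
    yhat = _hyperbolic(tstar, fit.intercept, fit.amplitude, fit.halftime_days)
    resid = y - yhat
    rng = np.random.default_rng(seed)
    x_hat = np.array([fit.intercept, fit.amplitude, math.log(fit.halftime_days)])
    out = np.empty((n_boot, 3))
    for b in range(n_boot):
        yb = yhat + rng.choice(resid, size=len(resid), replace=True)

        def objective(theta: np.ndarray) -> float:
            b0, amp, u = theta
            r = yb - _hyperbolic(tstar, b0, amp, math.exp(u))
            return float(r @ r)

        res = optimize.minimize(objective, x_hat, method="BFGS", options={"gtol": 1e-8})
        out[b] = res.x[0], res.x[1], math.exp(res.x[2])
    return out


# ---------------------------------------------------------------------------
# Per-mutation trajectory measures
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryMeasures:
    """Per-mutation f_max and per-interval rate / direction measures.

    ``fmax``: one row per mutation x population with its maximum estimated
    frequency over the first ``t_max_points`` observations.  ``intervals``:
    one row per consecutive observation pair with |df|/dtau and the direction
    ratio f(tau+dtau)/f(tau) (NaN where f(tau)=0, where the ratio is
    undefined).
    """

    fmax: pd.DataFrame
    intervals: pd.DataFrame
    t_max_points: int


def trajectory_measures(
    traj: TrajectoryMatrix,
    generations_per_timepoint: Mapping | None = None,
    t_max_points: int = 6,
) -> TrajectoryMeasures:
    """Compute f_max, |df|/dtau, and direction ratios per mutation.

    ``generations_per_timepoint`` optionally maps day -> cumulative
    generations; when omitted the table's ``generations`` column is used, and
    failing that the day itself.
    """
    df = _need_frequencies(traj)
    group_cols = ["population_id", "mutation_id", "strain", "regime"]

    fmax_rows = []
    interval_rows = []
    for keys, sub in df.groupby(group_cols, sort=True):
        sub = sub.sort_values("day")
        obs = sub[sub["frequency"].notna()]
        if len(obs) == 0:
            continue
        head = obs.head(t_max_points)
        fmax_rows.append((*keys, float(head["frequency"].max())))
        if len(obs) < 2:
            continue
        days = obs["day"].to_numpy(dtype=float)
        if generations_per_timepoint is not None:
            tau = np.array([generations_per_timepoint[d] for d in days], dtype=float)
        elif obs["generations"].notna().all():
            tau = obs["generations"].to_numpy(dtype=float)
        else:
            tau = days
        f = obs["frequency"].to_numpy(dtype=float)
        dtau = np.diff(tau)
        dfreq = np.diff(f)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(f[:-1] > 0, f[1:] / f[:-1], np.nan)
        for i in range(len(dtau)):
            interval_rows.append(
                (*keys, tau[i], dtau[i], abs(dfreq[i]) / dtau[i], ratio[i])
            )

    fmax = pd.DataFrame(fmax_rows, columns=group_cols + ["f_max"])
    intervals = pd.DataFrame(
        interval_rows, columns=group_cols + ["tau", "dtau", "rate", "ratio"]
    )
    return TrajectoryMeasures(fmax=fmax, intervals=intervals, t_max_points=t_max_points)


def simulation_measures(result, detection_floor: float = 0.0) -> dict:
    """Trajectory measures straight from a simulator result (no read noise).

    Returns arrays of per-mutation ``f_max``, per-interval ``|df|/dtau`` over
    intervals where the mutation segregates at the left endpoint, and the
    direction ratio over intervals where it segregates at both endpoints
    (the direction of change is degenerate once the allele is lost, so lost
    intervals are excluded here; the read-count path in
    :func:`trajectory_measures` keeps the ratio-0 convention instead).
    """
    ids, mat = result.frequency_array()
    if len(ids) == 0:
        return {"f_max": np.array([]), "rate": np.array([]), "ratio": np.array([])}
    fmax = mat.max(axis=1)
    keep = fmax > detection_floor
    mat = mat[keep]
    dtau = np.diff(np.asarray(result.sample_generations, dtype=float))
    left = mat[:, :-1]
    right = mat[:, 1:]
    seg_left = left > 0
    both = seg_left & (right > 0)
    rate = (np.abs(right - left) / dtau)[seg_left]
    ratio = (right[both] / left[both])
    return {"f_max": fmax[keep], "rate": rate, "ratio": ratio}


# ---------------------------------------------------------------------------
# Survival distributions, KS comparisons, fates
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Empirical survival function S(x) = P(value > x) (1 - ECDF)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        v = v[np.isfinite(v)]
        if len(v) == 0:
            raise ValueError("survival distribution requires at least one finite value")
        self.values = np.sort(v)

    def __call__(self, x) -> np.ndarray:
        idx = np.searchsorted(self.values, np.asarray(x, dtype=float), side="right")
        out = 1.0 - idx / len(self.values)
        return out if out.ndim else float(out)

    @property
    def median(self) -> float:
        return float(np.median(self.values))


def survival_distribution(values: Sequence[float]) -> SurvivalCurve:
    """Empirical survival distribution (complement of the ECDF)."""
    return SurvivalCurve(np.asarray(values))


def ks_compare(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple:
    """Two-sample Kolmogorov-Smirnov D statistic and p-value."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def ks_compare_batch(comparisons: Mapping) -> pd.DataFrame:
    """KS tests over a family of comparisons with Benjamini-Hochberg control.

    ``comparisons`` maps a label (e.g. a strain/regime pair) to a
    ``(sample_a, sample_b)`` tuple.  Returns a tidy frame with D, raw p, and
    BH-adjusted p.
    """
    labels, ds, ps = [], [], []
    for label, (a, b) in comparisons.items():
        d, p = ks_compare(a, b)
        labels.append(label)
        ds.append(d)
        ps.append(p)
    _, p_adj, _, _ = multipletests(ps, method="fdr_bh")
    return pd.DataFrame(
        {"comparison": labels, "D": ds, "pvalue": ps, "pvalue_bh": p_adj}
    )


def classify_fate(
    trajectory: Sequence[float],
    detect_threshold: float = 0.05,
    fix_threshold: float = 0.95,
    extinct_threshold: float = 0.01,
) -> str:
    """Threshold-based fate call: ``fixed``, ``extinct``, or ``segregating``.

    A transparent replacement for HMM-based fate inference: fixed if the
    final observed frequency reaches ``fix_threshold``; extinct if the
    mutation was ever detected (>= ``detect_threshold``) and its final
    observed frequency falls to ``extinct_threshold`` or below; segregating
    otherwise.
    """
    if not 0 < extinct_threshold < detect_threshold < fix_threshold < 1:
        raise ValueError(
            "thresholds must satisfy 0 < extinct < detect < fix < 1"
        )
    f = np.asarray(trajectory, dtype=float)
    f = f[np.isfinite(f)]
    if len(f) == 0:
        raise ValueError("empty trajectory")
    if f[-1] >= fix_threshold:
        return "fixed"
    if f.max() >= detect_threshold and f[-1] <= extinct_threshold:
        return "extinct"
    return "segregating"


def fate_table(
    traj: TrajectoryMatrix,
    detect_threshold: float = 0.05,
    fix_threshold: float = 0.95,
    extinct_threshold: float = 0.01,
) -> pd.DataFrame:
    """Fate call and detection flag for every mutation in the table."""
    df = _need_frequencies(traj)
    rows = []
    for (pop, mid), sub in df.groupby(["population_id", "mutation_id"], sort=True):
        f = sub.sort_values("day")["frequency"].dropna().to_numpy()
        if len(f) == 0:
            continue
        fate = classify_fate(f, detect_threshold, fix_threshold, extinct_threshold)
        rows.append((pop, mid, fate, bool(f.max() >= detect_threshold)))
    return pd.DataFrame(rows, columns=["population_id", "mutation_id", "fate", "detected"])


def prob_extinct_given_detected(fates: Iterable[str]) -> float:
    """Fraction of detected mutations whose inferred fate is extinction."""
    fates = list(fates)
    if not fates:
        raise ValueError("no detected mutations")
    return sum(f == "extinct" for f in fates) / len(fates)


def pairwise_trajectory_correlation(
    traj: TrajectoryMatrix, min_shared: int = 3
) -> pd.DataFrame:
    """Pearson correlation between simultaneously segregating mutation pairs.

    For each within-population pair of mutations, timepoints where both are
    strictly in (0, 1) are pooled; pairs sharing at least ``min_shared`` such
    timepoints contribute one correlation (both r and r^2 are reported, the
    latter being the usual recombination-rate proxy).  Pairs with zero
    variance over the shared window are skipped and logged.
    """
    df = _need_frequencies(traj)
    rows = []
    for pop, sub in df.groupby("population_id", sort=True):
        wide = sub.pivot(index="mutation_id", columns="day", values="frequency")
        ids = list(wide.index)
        mat = wide.to_numpy(dtype=float)
        seg = (mat > 0) & (mat < 1)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                shared = seg[i] & seg[j]
                n = int(shared.sum())
                if n < min_shared:
                    continue
                xi, xj = mat[i, shared], mat[j, shared]
                if np.std(xi) == 0 or np.std(xj) == 0:
                    logger.info(
                        "skipping zero-variance pair (%r, %r) in population %r",
                        ids[i], ids[j], pop,
                    )
                    continue
                r = float(np.corrcoef(xi, xj)[0, 1])
                rows.append((pop, ids[i], ids[j], n, r, r * r))
    return pd.DataFrame(
        rows, columns=["population_id", "mutation_a", "mutation_b", "n_shared", "r", "r2"]
    )


# ---------------------------------------------------------------------------
# pN/pS, generations, fitness
# ---------------------------------------------------------------------------

def pn_ps(
    n_nonsyn: int,
    n_syn: int,
    nonsyn_site_fraction: float,
    syn_site_fraction: float,
) -> float:
    """Site-class-weighted ratio of nonsynonymous to synonymous mutations.

    ``(nN/nS) * (syn_fraction/nonsyn_fraction)``; values below 1 indicate
    purifying selection.  Returns NaN (with a warning) when no synonymous
    mutations were observed.
    """
    if nonsyn_site_fraction <= 0 or syn_site_fraction <= 0:
        raise ValueError("site fractions must be positive")
    if nonsyn_site_fraction + syn_site_fraction > 1 + 1e-9:
        raise ValueError("site fractions of the two classes cannot exceed 1")
    if n_syn == 0:
        warnings.warn("pN/pS undefined with zero synonymous mutations", stacklevel=2)
        return math.nan
    return (n_nonsyn / n_syn) * (syn_site_fraction / nonsyn_site_fraction)


@dataclass
class GenerationEstimate:
    """Generations accrued per serial-transfer cycle, ``dtau = log2(Nf/Ni)``.

    Per-replicate ratios are averaged on the log2 scale; ``total_generations``
    multiplies the mean by the number of transfers.
    """

    delta_tau: float
    delta_tau_se: float
    total_generations: float
    n_transfers: int
    Nf: np.ndarray
    Ni: np.ndarray


def estimate_generations(
    N_f: Sequence[float] | float,
    N_i: Sequence[float] | float,
    n_transfers: int = 1,
) -> GenerationEstimate:
    """Estimate generations per transfer from final/initial population sizes."""
    Nf = np.atleast_1d(np.asarray(N_f, dtype=float))
    Ni = np.atleast_1d(np.asarray(N_i, dtype=float))
    if Nf.shape != Ni.shape:
        raise ValueError("N_f and N_i must have the same shape")
    if (Nf <= 0).any() or (Ni <= 0).any():
        raise ValueError("population sizes must be positive")
    per_rep = np.log2(Nf / Ni)
    dtau = float(per_rep.mean())
    se = float(per_rep.std(ddof=1) / math.sqrt(len(per_rep))) if len(per_rep) > 1 else 0.0
    return GenerationEstimate(
        delta_tau=dtau,
        delta_tau_se=se,
        total_generations=dtau * n_transfers,
        n_transfers=n_transfers,
        Nf=Nf,
        Ni=Ni,
    )


def relative_log_fitness(
    counts_mut_t: float,
    counts_wt_t: float,
    counts_mut_0: float,
    counts_wt_0: float,
    base: float = math.e,
) -> float:
    """Relative log fitness X(t) = log[(Nmut(t)/Nwt(t)) * (Nwt(0)/Nmut(0))].

    Natural log by default (standard for selection-coefficient-like
    quantities); pass ``base`` to change the convention.
    """
    counts = (counts_mut_t, counts_wt_t, counts_mut_0, counts_wt_0)
    if any(c <= 0 for c in counts):
        raise ValueError("all colony counts must be positive")
    x = math.log((counts_mut_t / counts_wt_t) * (counts_wt_0 / counts_mut_0))
    return x / math.log(base)


def fitness_assay(
    days: Sequence[float],
    counts_mut: np.ndarray,
    counts_wt: np.ndarray,
    base: float = math.e,
) -> pd.DataFrame:
    """Replicate-averaged relative log fitness over a competition assay.

    ``counts_mut`` and ``counts_wt`` are replicates x days count arrays whose
    first column is the day-0 baseline (so X(0) = 0 by construction).
    Returns per-day mean X(t) and its standard error across replicates.
    """
    cm = np.asarray(counts_mut, dtype=float)
    cw = np.asarray(counts_wt, dtype=float)
    if cm.shape != cw.shape or cm.ndim != 2 or cm.shape[1] != len(days):
        raise ValueError("count arrays must be replicates x days matching `days`")
    X = np.empty_like(cm)
    for r in range(cm.shape[0]):
        for t in range(cm.shape[1]):
            X[r, t] = relative_log_fitness(cm[r, t], cw[r, t], cm[r, 0], cw[r, 0], base)
    mean = X.mean(axis=0)
    se = X.std(axis=0, ddof=1) / math.sqrt(cm.shape[0]) if cm.shape[0] > 1 else np.zeros(len(days))
    return pd.DataFrame({"day": list(days), "X_mean": mean, "X_se": se})
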