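"""Method-agreement statistics for paired duration measurements.

Compares two ways of timing the same trials (e.g. clinician stopwatch
vs. depth-camera algorithm) on data with repeated trials per subject:

* Bland–Altman bias and limits of agreement, with the SD of differences
  estimated from a one-way random-effects decomposition (between- plus
  within-subject variance) so repeated trials do not understate the
  spread.  Limits use bias ± 2·SD.
* Percentage error: 100 × (2·SD of differences) / grand mean of the two
  methods.
* Spearman correlation with a BCa bootstrap confidence interval; the
  bootstrap resamples whole subjects (cluster bootstrap) to respect the
  repeated-measures structure.
* Concordance correlation coefficient adjusted for repeated measures via
  a variance-components (mixed-model moment) estimator; with one trial
  per subject it reduces to Lin's classical formula.
* ICC as two-way random-effects, absolute agreement, single measure,
  with each (subject, trial) pair as the rated target.
* Ordinary least-squares regression of method B on method A, and
  a Shapiro–Wilk normality test of the differences.

Input is a tidy table with columns ``subject``, ``trial``, and the two
duration columns (method A = reference/expert, method B = algorithm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

logger = logging.getLogger(__name__)


def _validate(df: pd.DataFrame, col_a: str, col_b: str) -> pd.DataFrame:
    req = {"subject", "trial", col_a, col_b}
    missing = req - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (df[col_a] <= 0).any() or (df[col_b] <= 0).any():
        raise ValueError("durations must be positive")
    if df.duplicated(["subject", "trial"]).any():
        raise ValueError("duplicate (subject, trial) pairs")
    return df


def bland_altman_rm(
    df: pd.DataFrame, col_a: str = "expert_s", col_b: str = "algorithm_s"
) -> tuple[float, float, float, float]:
    """(bias, loa_low, loa_high, sd_of_differences), repeated-measures.

    Differences d = B − A.  Var(d) = between-subject + within-subject
    components from a one-way ANOVA of d grouped by subject (the
    random-effects adjustment for repeated measurements); limits of
    agreement are bias ± 2·SD.  With a single subject the naive SD is
    used and a warning logged.
    """
    df = _validate(df, col_a, col_b)
    d = (df[col_b] - df[col_a]).to_numpy(float)
    bias = float(np.mean(d))
    groups = df["subject"].to_numpy()
    uniq = np.unique(groups)
    if uniq.size < 2:
        logger.warning("single subject: falling back to naive SD of differences")
        sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    else:
        sd = _random_effects_sd(d, groups)
    return bias, bias - 2 * sd, bias + 2 * sd, sd


def _random_effects_sd(d: np.ndarray, groups: np.ndarray) -> float:
    """Total SD of single differences from a one-way random-effects fit.

    One-way ANOVA of d on subject: MSW estimates the within-subject
    variance; (MSB − MSW)/n0 the between-subject variance, with
    n0 = (N − Σn_i²/N) / (k − 1) for unbalanced groups.
    """
    uniq, counts = np.unique(groups, return_counts=True)
    k, N = uniq.size, d.size
    grand = d.mean()
    means = np.array([d[groups == g].mean() for g in uniq])
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(sum(np.sum((d[groups == g] - m) ** 2) for g, m in zip(uniq, means)))
    msb = ssb / (k - 1)
    dfw = N - k
    if dfw == 0:  # one trial per subject: all variance is between
        return float(np.std(d, ddof=1))
    msw = ssw / dfw
    n0 = (N - np.sum(counts**2) / N) / (k - 1)
    var_between = max(0.0, (msb - msw) / n0)
    return float(np.sqrt(var_between + msw))


def percentage_error(sd_of_differences: float, mean_a: float, mean_b: float) -> float:
    """PE (%) = 100 × (2·SD of differences) / ((mean_a + mean_b) / 2)."""
    grand = (mean_a + mean_b) / 2.0
    if grand <= 0:
        raise ValueError("invalid means")
    return 100.0 * (2.0 * sd_of_differences) / grand


def lin_ccc(a: np.ndarray, b: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = np.var(a), np.var(b)
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    denom = va + vb + (a.mean() - b.mean()) ** 2
    if denom == 0:
        raise ValueError("constant series: CCC undefined")
    return float(2.0 * cov / denom)


def ccc_repeated_measures(
    df: pd.DataFrame, col_a: str = "expert_s", col_b: str = "algorithm_s"
) -> float:
    """Variance-components CCC for subjects with repeated trials.

    Three-way mixed-model moment estimator (subject random; method and
    trial fixed) under balanced-data expected mean squares:

        CCC = (s²_subj + s²_subj×trial) /
              (s²_subj + s²_subj×trial + s²_subj×method + s²_err + φ_method)

    Trial-to-trial variation shared by both methods (subject×trial) is
    concordant and counts in the numerator; method offsets and
    subject×method disagreement penalise.  With one trial per subject
    this reduces to Lin's formula, which is then used directly.
    """
    df = _validate(df, col_a, col_b)
    trials_per_subject = df.groupby("subject")["trial"].count()
    if (trials_per_subject == 1).all():
        return lin_ccc(df[col_a].to_numpy(), df[col_b].to_numpy())
    if trials_per_subject.nunique() > 1:
        logger.warning("unbalanced trials: balanced-EMS approximation used for CCC")

    long = df.melt(
        id_vars=["subject", "trial"],
        value_vars=[col_a, col_b],
        var_name="method",
        value_name="y",
    )
    n = long["subject"].nunique()
    m = float(trials_per_subject.mean())
    J = 2
    y = long["y"].to_numpy(float)

    def ms(by: list[str]) -> float:
        """Mean square of the (possibly interaction) factor via cell means."""
        return float(long.groupby(by)["y"].mean().var(ddof=1))

    # balanced EMS algebra on cell means (per-factor sample variances
    # of marginal means, scaled by the number of observations per mean)
    mean_s = long.groupby("subject")["y"].mean()
    mean_m = long.groupby("method")["y"].mean()
    mean_t = long.groupby("trial")["y"].mean()
    cell_sm = long.groupby(["subject", "method"])["y"].mean()
    cell_st = long.groupby(["subject", "trial"])["y"].mean()
    grand = y.mean()

    ss_s = J * m * float(((mean_s - grand) ** 2).sum())
    ss_m = n * m * float(((mean_m - grand) ** 2).sum())
    ss_t = n * J * float(((mean_t - grand) ** 2).sum())
    ss_sm = m * float(((cell_sm.unstack() - mean_s.values[:, None]
                        - mean_m.values[None, :] + grand) ** 2).to_numpy().sum())
    st_resid = cell_st.unstack().to_numpy() - mean_s.to_numpy()[:, None] \
        - mean_t.to_numpy()[None, :] + grand
    ss_st = J * float(np.nansum(st_resid**2))
    ss_tot = float(((y - grand) ** 2).sum())
    ss_err = max(0.0, ss_tot - ss_s - ss_m - ss_t - ss_sm - ss_st)

    m_int = int(round(m))
    df_err = max(1, (n - 1) * (J - 1) * (m_int - 1) + (J - 1) * (m_int - 1))
    mse = ss_err / df_err
    ms_sm = ss_sm / ((n - 1) * (J - 1))
    ms_st = ss_st / max(1, (n - 1) * (m_int - 1))
    ms_s = ss_s / (n - 1)
    ms_m = ss_m / (J - 1)

    var_e = mse
    var_st = max(0.0, (ms_st - mse) / J)
    var_sm = max(0.0, (ms_sm - mse) / m)
    var_s = max(0.0, (ms_s - ms_sm - ms_st + mse) / (J * m))
    phi_m = max(0.0, (ms_m - ms_sm) / (n * m))

    denom = var_s + var_st + var_sm + var_e + phi_m
    if denom == 0:
        raise ValueError("constant series: CCC undefined")
    return float((var_s + var_st) / denom)


def icc_absolute(
    df: pd.DataFrame, col_a: str = "expert_s", col_b: str = "algorithm_s"
) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measure, each (subject, trial) pair rated once by each method."""
    df = _validate(df, col_a, col_b)
    long = df.assign(pair=df["subject"].astype(str) + "_" + df["trial"].astype(str))
    long = long.melt(
        id_vars=["pair"], value_vars=[col_a, col_b], var_name="method", value_name="y"
    )
    res = pg.intraclass_corr(
        data=long, targets="pair", raters="method", ratings="y"
    )
    row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]
    return float(row["ICC"].iloc[0])


def _bca_interval(
    stat_hat: float,
    boot: np.ndarray,
    jack: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval."""
    boot = boot[np.isfinite(boot)]
    if boot.size == 0:
        return float("nan"), float("nan")
    prop = (np.sum(boot < stat_hat) + 0.5 * np.sum(boot == stat_hat)) / boot.size
    prop = min(max(prop, 1.0 / (2 * boot.size)), 1 - 1.0 / (2 * boot.size))
    z0 = stats.norm.ppf(prop)
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * (np.sum((jm - jack) ** 2) ** 1.5)
    a = num / den if den > 0 else 0.0
    out = []
    for z in (stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)):
        adj = stats.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
        out.append(float(np.quantile(boot, adj)))
    return out[0], out[1]


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement battery between two duration-measurement methods."""

    bias: float
    loa_low: float
    loa_high: float
    sd_of_differences: float
    pe: float
    spearman_rho: float
    bca_ci_low: float
    bca_ci_high: float
    ccc: float
    icc: float
    slope: float
    intercept: float
    r_squared: float
    shapiro_p_differences: float
    n_pairs: int
    n_subjects: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def correlation_agreement(
    df: pd.DataFrame,
    col_a: str = "expert_s",
    col_b: str = "algorithm_s",
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Spearman (+BCa CI), CCC, ICC, regression and normality test.

    The BCa interval bootstraps subjects (cluster bootstrap, ``n_boot``
    resamples, seeded); regression is method B on method A.
    """
    df = _validate(df, col_a, col_b)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    a = df[col_a].to_numpy(float)
    b = df[col_b].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant series: correlation undefined")

    rho = float(stats.spearmanr(a, b).statistic)

    subjects = df["subject"].unique()
    by_subject = {s: df[df["subject"] == s] for s in subjects}
    rng = np.random.default_rng(seed)

    def rho_of(frames: list[pd.DataFrame]) -> float:
        cat = pd.concat(frames)
        av, bv = cat[col_a].to_numpy(), cat[col_b].to_numpy()
        if np.ptp(av) == 0 or np.ptp(bv) == 0:
            return np.nan
        return float(stats.spearmanr(av, bv).statistic)

    boot = np.array([
        rho_of([by_subject[s] for s in rng.choice(subjects, size=subjects.size)])
        for _ in range(n_boot)
    ])
    jack = np.array([
        rho_of([by_subject[s] for s in subjects if s != left_out])
        for left_out in subjects
    ])
    ci_low, ci_high = _bca_interval(rho, boot, jack)

    reg = stats.linregress(a, b)
    d = b - a
    if np.ptp(d) == 0:
        shapiro_p = float("nan")  # SW undefined on constant differences
    else:
        shapiro_p = float(stats.shapiro(d).pvalue)

    return {
        "spearman_rho": rho,
        "bca_ci_low": ci_low,
        "bca_ci_high": ci_high,
        "ccc": ccc_repeated_measures(df, col_a, col_b),
        "icc": icc_absolute(df, col_a, col_b),
        "slope": float(reg.slope),
        "intercept": float(reg.intercept),
        "r_squared": float(reg.rvalue**2),
        "shapiro_p": shapiro_p,
    }


def agreement_report(
    df: pd.DataFrame,
    col_a: str = "expert_s",
    col_b: str = "algorithm_s",
    n_boot: int = 2000,
    seed: int = 0,
) -> AgreementReport:
    """Run the whole agreement battery on a paired-durations table."""
    bias, lo, hi, sd = bland_altman_rm(df, col_a, col_b)
    pe = percentage_error(sd, float(df[col_a].mean()), float(df[col_b].mean()))
    corr = correlation_agreement(df, col_a, col_b, n_boot=n_boot, seed=seed)
    return AgreementReport(
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        sd_of_differences=sd,
        pe=pe,
        spearman_rho=corr["spearman_rho"],
        bca_ci_low=corr["bca_ci_low"],
        bca_ci_high=corr["bca_ci_high"],
        ccc=corr["ccc"],
        icc=corr["icc"],
        slope=corr["slope"],
        intercept=corr["intercept"],
        r_squared=corr["r_squared"],
        shapiro_p_differences=corr["shapiro_p"],
        n_pairs=int(len(df)),
        n_subjects=int(df["subject"].nunique()),
    )


def bland_altman_plot(
    df: pd.DataFrame,
    path: str | Path,
    col_a: str = "expert_s",
    col_b: str = "algorithm_s",
) -> None:
    """Bland–Altman scatter with bias and limits of agreement lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bias, lo, hi, _ = bland_altman_rm(df, col_a, col_b)
    mean = (df[col_a] + df[col_b]) / 2
    diff = df[col_b] - df[col_a]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, diff, s=14, alpha=0.7)
    for yv, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(yv, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of methods (s)")
    ax.set_ylabel("difference B − A (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
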