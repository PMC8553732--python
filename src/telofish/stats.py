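"""Group-level telomere brightness statistics.

The central objects follow the model/results idiom: build a
:class:`TelomereStudy` from a table of accepted telomere measurements
(columns ``condition``, ``nucleus_id``, ``brightness``), call
:meth:`TelomereStudy.fit`, and read estimates off the returned
:class:`TelomereStudyResults` (per-nucleus summaries, nested ANOVA of
log brightness, per-condition lognormal fits, dark-telomere fractions,
percent shortening vs a reference condition, detection-efficiency
equality).

The nested ANOVA treats the nucleus as the experimental unit: telomere
log-brightness values are averaged per nucleus and a one-way ANOVA is
run across conditions on those means. This is exact for balanced
designs and a documented approximation otherwise; a mixed-model variant
(random nucleus intercept) is available via ``anova_method="mixed"``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NucleusSummary",
    "LognormalFit",
    "DetectionEfficiencyResult",
    "TelomereStudy",
    "TelomereStudyResults",
    "summarize_nuclei",
    "nested_anova_log",
    "fit_lognormal",
    "dark_fraction",
    "dark_threshold_from_reference",
    "detection_efficiency_test",
    "percent_shortening",
    "simulate_brightness_frame",
]


@dataclass(frozen=True)
class NucleusSummary:
    condition: str
    nucleus_id: int
    n_accepted: int
    mean_brightness_counts: float
    std_brightness_counts: float
    mean_log_brightness: float


@dataclass(frozen=True)
class LognormalFit:
    """Maximum-likelihood lognormal fit with a KS goodness-of-fit check.

    ``mu_log``/``sigma_log`` are the mean and (MLE, ddof=0) standard
    deviation of the natural logs. The KS test compares the data against
    the fitted lognormal; because the parameters are estimated from the
    same data its p-value is approximate (anti-conservative).
    """

    mu_log: float
    sigma_log: float
    n: int
    ks_statistic: float
    ks_pvalue: float

    @property
    def mean_counts(self) -> float:
        return math.exp(self.mu_log + 0.5 * self.sigma_log**2)


@dataclass(frozen=True)
class DetectionEfficiencyResult:
    statistic: float
    p_value: float
    group_stats: pd.DataFrame  # columns condition, n_nuclei, mean_count, std_count

    def formatted(self) -> str:
        parts = [
            f"{row.mean_count:.1f} ± {row.std_count:.1f}"
            for row in self.group_stats.itertuples()
        ]
        return "n = " + ", ".join(parts) + " (mean ± std)"


def summarize_nuclei(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-(condition, nucleus) summaries of accepted brightness values.

    Nuclei with zero accepted telomeres keep a row with ``n_accepted=0``
    and NaN means (flagged, not dropped).
    """
    _require_columns(measurements, ("condition", "nucleus_id", "brightness"))
    rows = []
    for (cond, nuc), grp in measurements.groupby(["condition", "nucleus_id"], sort=True):
        vals = grp["brightness"].to_numpy(dtype=float)
        n = len(vals)
        rows.append(
            {
                "condition": cond,
                "nucleus_id": nuc,
                "n_accepted": n,
                "mean_brightness_counts": float(np.mean(vals)) if n else np.nan,
                "std_brightness_counts": float(np.std(vals, ddof=1)) if n > 1 else (0.0 if n == 1 else np.nan),
                "mean_log_brightness": float(np.mean(np.log(vals))) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _one_way_anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA robust to degenerate variance cases."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    if k < 2:
        raise ValueError("need at least two groups")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    df_between = k - 1
    df_within = int(ns.sum()) - k
    if df_within <= 0:
        raise ValueError("no residual degrees of freedom (need more replicates per group)")
    # floating-point noise floor: identical inputs can leave SS ~ (eps*|x|)^2
    noise_floor = 1e-24 * max(float(np.sum(all_vals**2)), 1e-300)
    if ss_between <= noise_floor:
        return 0.0, 1.0
    if ss_within <= noise_floor:
        return float("inf"), 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return float(f), p


def nested_anova_log(
    measurements: pd.DataFrame,
    method: str = "nucleus-means",
) -> tuple[float, float]:
    """Nested one-way ANOVA of log-transformed brightness, subgrouped by nucleus.

    ``method="nucleus-means"`` (default): average log brightness per
    nucleus and run a one-way ANOVA across conditions on the nucleus
    means, so the condition effect is tested against between-nucleus
    variation. ``method="mixed"``: linear mixed model with a random
    nucleus intercept on the raw telomere logs; the condition effect is
    Wald-tested.

    Requires at least two conditions and at least two nuclei in every
    condition (otherwise there is no error degree of freedom).
    """
    _require_columns(measurements, ("condition", "nucleus_id", "brightness"))
    vals = measurements["brightness"].to_numpy(dtype=float)
    if np.any(vals <= 0):
        raise ValueError("brightness values must be positive for the log transform")
    df = measurements.assign(log_brightness=np.log(vals))

    counts = df.groupby("condition")["nucleus_id"].nunique()
    if len(counts) < 2:
        raise ValueError("need at least two conditions")
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(f"condition(s) with a single nucleus (no error df): {list(thin.index)}")

    if method == "nucleus-means":
        per_nucleus = df.groupby(["condition", "nucleus_id"])["log_brightness"].mean().reset_index()
        groups = [g["log_brightness"].to_numpy() for _, g in per_nucleus.groupby("condition")]
        return _one_way_anova(groups)
    if method == "mixed":
        import statsmodels.formula.api as smf

        df = df.copy()
        df["unit"] = df["condition"].astype(str) + "/" + df["nucleus_id"].astype(str)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("log_brightness ~ C(condition)", data=df, groups=df["unit"])
            res = model.fit(reml=True)
            wald = res.wald_test_terms(skip_single=False)
        table = wald.table
        row = table.loc[[i for i in table.index if "condition" in i][0]]
        stat = float(np.squeeze(np.asarray(row["statistic"])))
        pval = float(np.squeeze(np.asarray(row["pvalue"])))
        return stat, pval
    raise ValueError(f"unknown method {method!r}; use 'nucleus-means' or 'mixed'")


def fit_lognormal(values: Sequence[float] | np.ndarray) -> LognormalFit:
    """MLE lognormal fit (mean/sd of natural logs) plus a KS check."""
    vals = np.asarray(values, dtype=float)
    n_bad = int(np.sum(vals <= 0))
    if n_bad:
        raise ValueError(f"{n_bad} nonpositive value(s): lognormal requires strictly positive data")
    if len(vals) < 10:
        raise ValueError(f"need at least 10 values for a lognormal fit, got {len(vals)}")
    logs = np.log(vals)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=0))
    if sigma < 1e-12:
        sigma = 0.0
    if sigma == 0:
        return LognormalFit(mu_log=mu, sigma_log=0.0, n=len(vals), ks_statistic=0.0, ks_pvalue=1.0)
    ks = sps.kstest(vals, "lognorm", args=(sigma, 0.0, math.exp(mu)))
    return LognormalFit(mu_log=mu, sigma_log=sigma, n=len(vals),
                        ks_statistic=float(ks.statistic), ks_pvalue=float(ks.pvalue))


def dark_threshold_from_reference(reference_values: Sequence[float] | np.ndarray, quantile: float = 0.10) -> float:
    """Brightness cutoff for "dark" telomeres: a low quantile of the reference.

    The dark cutoff is a definition of this pipeline (default: the 10th
    percentile of the pooled reference condition), and is always reported
    alongside any dark fraction.
    """
    vals = np.asarray(reference_values, dtype=float)
    if len(vals) == 0:
        raise ValueError("empty reference distribution")
    if not 0 < quantile < 0.5:
        raise ValueError("quantile must be in (0, 0.5)")
    return float(np.quantile(vals, quantile))


def dark_fraction(values: Sequence[float] | np.ndarray, threshold_counts: float) -> float:
    """Fraction of brightness values strictly below the dark threshold."""
    vals = np.asarray(values, dtype=float)
    if len(vals) == 0:
        raise ValueError("empty brightness input")
    if not threshold_counts > 0:
        raise ValueError("threshold must be positive")
    return float(np.mean(vals < threshold_counts))


def detection_efficiency_test(
    counts_by_condition: Mapping[str, Sequence[int]] | pd.DataFrame,
) -> DetectionEfficiencyResult:
    """Test equality of per-nucleus accepted-telomere counts across conditions.

    One-way ANOVA on the per-nucleus counts; a non-significant result
    supports brightness comparisons being unbiased by detection.
    """
    if isinstance(counts_by_condition, pd.DataFrame):
        _require_columns(counts_by_condition, ("condition", "n_accepted"))
        counts_by_condition = {
            str(c): g["n_accepted"].to_numpy() for c, g in counts_by_condition.groupby("condition")
        }
    names = sorted(counts_by_condition)
    if len(names) < 2:
        raise ValueError("need at least two conditions")
    groups = [np.asarray(counts_by_condition[n], dtype=float) for n in names]
    for name, g in zip(names, groups):
        if len(g) < 2:
            raise ValueError(f"condition {name!r} has fewer than two nuclei")
    f, p = _one_way_anova(groups)
    stats_df = pd.DataFrame(
        {
            "condition": names,
            "n_nuclei": [len(g) for g in groups],
            "mean_count": [float(g.mean()) for g in groups],
            "std_count": [float(g.std(ddof=1)) for g in groups],
        }
    )
    return DetectionEfficiencyResult(statistic=f, p_value=p, group_stats=stats_df)


def percent_shortening(mean_reference: float, mean_case: float) -> float:
    """Percent telomere shortening of a case relative to a reference.

    ``100 * (ref - case) / ref``; valid as a length change because probe
    brightness is linear in telomere length.
    """
    if not mean_reference > 0:
        raise ValueError(f"reference mean must be positive, got {mean_reference}")
    return 100.0 * (mean_reference - mean_case) / mean_reference


def simulate_brightness_frame(
    condition_means: Mapping[str, float],
    n_nuclei: int = 6,
    n_per_nucleus: int = 60,
    between_nucleus_sd_counts: float | Mapping[str, float] = 13.2,
    sigma_log: float = 0.5,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Simulate a per-telomere brightness table at the distribution level.

    Each nucleus gets a mean drawn around its condition mean with the
    given between-nucleus spread (counts); telomere brightness within a
    nucleus is lognormal with that nucleus mean and log-scale spread
    ``sigma_log``. Used for statistical calibration runs where rendering
    images would be wasteful.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    rows = []
    for cond in sorted(condition_means):
        mean = condition_means[cond]
        sd_b = (
            between_nucleus_sd_counts[cond]
            if isinstance(between_nucleus_sd_counts, Mapping)
            else between_nucleus_sd_counts
        )
        for nuc in range(n_nuclei):
            m_i = max(rng.normal(mean, sd_b), 1e-6)
            mu_i = math.log(m_i) - 0.5 * sigma_log**2
            vals = rng.lognormal(mu_i, sigma_log, size=n_per_nucleus)
            rows.append(pd.DataFrame({"condition": cond, "nucleus_id": nuc, "brightness": vals}))
    return pd.concat(rows, ignore_index=True)


def _require_columns(df: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing column(s) {missing}")


class TelomereStudy:
    """Model object for a multi-condition telomere brightness study.

    Parameters
    ----------
    data
        Per-telomere table with columns ``condition``, ``nucleus_id``
        and ``brightness`` (accepted measurements only; photon counts).
    reference
        Name of the reference (control) condition for shortening and the
        dark-telomere threshold. Defaults to the alphabetically first
        condition.
    """

    def __init__(self, data: pd.DataFrame, reference: Optional[str] = None):
        _require_columns(data, ("condition", "nucleus_id", "brightness"))
        if len(data) == 0:
            raise ValueError("empty measurement table")
        if np.any(data["brightness"].to_numpy(dtype=float) <= 0):
            raise ValueError("brightness values must be positive")
        self.data = data.reset_index(drop=True)
        self.conditions = sorted(self.data["condition"].unique())
        self.reference = reference if reference is not None else self.conditions[0]
        if self.reference not in self.conditions:
            raise ValueError(f"reference {self.reference!r} not among conditions {self.conditions}")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, reference: Optional[str] = None) -> "TelomereStudy":
        """Build from a measurements table; rows with ``accepted == False`` are dropped."""
        if "accepted" in data.columns:
            data = data[data["accepted"].astype(bool)]
        if "brightness" not in data.columns and "amplitude_counts" in data.columns:
            data = data.rename(columns={"amplitude_counts": "brightness"})
        if "condition" not in data.columns and "sample_id" in data.columns:
            data = data.rename(columns={"sample_id": "condition"})
        return cls(data, reference=reference)

    @classmethod
    def from_measurements(
        cls,
        measurements_by_condition: Mapping[str, Mapping[int, Sequence]],
        reference: Optional[str] = None,
    ) -> "TelomereStudy":
        """Build from pipeline output: {condition: {nucleus_id: [TelomereMeasurement]}}."""
        rows = []
        for cond, per_nucleus in measurements_by_condition.items():
            for nuc, ms in per_nucleus.items():
                for m in ms:
                    if m.accepted:
                        rows.append({"condition": cond, "nucleus_id": nuc, "brightness": m.brightness_counts})
        return cls(pd.DataFrame(rows), reference=reference)

    def fit(
        self,
        dark_quantile: float = 0.10,
        anova_method: str = "nucleus-means",
    ) -> "TelomereStudyResults":
        """Estimate all group-level quantities and return a results object."""
        summaries = summarize_nuclei(self.data)
        anova_f, anova_p = nested_anova_log(self.data, method=anova_method)
        efficiency = detection_efficiency_test(summaries)

        lognormal_fits = {
            cond: fit_lognormal(g["brightness"].to_numpy())
            for cond, g in self.data.groupby("condition")
        }
        ref_vals = self.data.loc[self.data["condition"] == self.reference, "brightness"].to_numpy()
        dark_thr = dark_threshold_from_reference(ref_vals, quantile=dark_quantile)
        dark = {
            cond: dark_fraction(g["brightness"].to_numpy(), dark_thr)
            for cond, g in self.data.groupby("condition")
        }

        cond_means = summaries.groupby("condition")["mean_brightness_counts"].mean()
        shortening = {
            cond: percent_shortening(cond_means[self.reference], cond_means[cond])
            for cond in self.conditions
            if cond != self.reference
        }
        return TelomereStudyResults(
            model=self,
            nucleus_summaries=summaries,
            anova_f=anova_f,
            anova_p=anova_p,
            anova_method=anova_method,
            efficiency=efficiency,
            lognormal_fits=lognormal_fits,
            dark_threshold_counts=dark_thr,
            dark_fractions=dark,
            condition_means={c: float(cond_means[c]) for c in self.conditions},
            percent_shortening=shortening,
        )


@dataclass
class TelomereStudyResults:
    """Fitted group comparison for a telomere brightness study."""

    model: TelomereStudy
    nucleus_summaries: pd.DataFrame
    anova_f: float
    anova_p: float
    anova_method: str
    efficiency: DetectionEfficiencyResult
    lognormal_fits: dict[str, LognormalFit]
    dark_threshold_counts: float
    dark_fractions: dict[str, float]
    condition_means: dict[str, float]
    percent_shortening: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "conditions": self.model.conditions,
            "reference": self.model.reference,
            "condition_mean_brightness_counts": self.condition_means,
            "nested_anova": {"F": self.anova_f, "p": self.anova_p, "method": self.anova_method},
            "detection_efficiency": {
                "F": self.efficiency.statistic,
                "p": self.efficiency.p_value,
                "per_condition": self.efficiency.group_stats.to_dict(orient="records"),
            },
            "lognormal_fits": {
                c: {"mu_log": f.mu_log, "sigma_log": f.sigma_log, "n": f.n,
                    "ks_statistic": f.ks_statistic, "ks_pvalue": f.ks_pvalue}
                for c, f in self.lognormal_fits.items()
            },
            "dark_threshold_counts": self.dark_threshold_counts,
            "dark_fractions": self.dark_fractions,
            "percent_shortening_vs_reference": self.percent_shortening,
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        """Human-readable report of the group comparison."""
        lines = []
        lines.append("Telomere brightness study" + " " * 14 + f"reference: {self.model.reference}")
        lines.append("=" * 64)
        lines.append(f"{'condition':<12}{'nuclei':>7}{'telomeres':>11}{'mean':>9}{'dark frac':>11}{'shortening':>12}")
        per_cond = self.nucleus_summaries.groupby("condition")
        for cond in self.model.conditions:
            g = per_cond.get_group(cond)
            short = self.percent_shortening.get(cond)
            lines.append(
                f"{cond:<12}{len(g):>7}{int(g['n_accepted'].sum()):>11}"
                f"{self.condition_means[cond]:>9.1f}{self.dark_fractions[cond]:>11.3f}"
                + (f"{short:>11.1f}%" if short is not None else f"{'—':>12}")
            )
        lines.append("-" * 64)
        lines.append(
            f"nested ANOVA (log brightness, by nucleus): F = {self.anova_f:.3f}, p = {self.anova_p:.3g}"
        )
        lines.append(
            f"detection efficiency: F = {self.efficiency.statistic:.3f}, "
            f"p = {self.efficiency.p_value:.3g}; {self.efficiency.formatted()}"
        )
        lines.append(f"dark-telomere threshold: {self.dark_threshold_counts:.1f} counts "
                     f"(reference {self.model.reference} quantile)")
        for cond, f in sorted(self.lognormal_fits.items()):
            lines.append(
                f"lognormal fit [{cond}]: mu={f.mu_log:.3f}, sigma={f.sigma_log:.3f}, "
                f"KS={f.ks_statistic:.3f} (p={f.ks_pvalue:.3g}, n={f.n})"
            )
        return "\n".join(lines)

    def plot_brightness(self, ax=None):
        """Per-nucleus brightness scatter with condition medians (Fig-style)."""
        from .plotting import plot_brightness_scatter

        return plot_brightness_scatter(self, ax=ax)

    def plot_distributions(self, ax=None, bins: int = 40):
        """Brightness histograms with fitted lognormal densities overlaid."""
        from .plotting import plot_brightness_distributions

        return plot_brightness_distributions(self, ax=ax, bins=bins)
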