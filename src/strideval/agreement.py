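"""Method-comparison (concurrent validity) statistics.

The central objects follow the statsmodels model/results convention:
:class:`MethodComparison` is built from paired device/criterion measurements
of one variable and its :meth:`~MethodComparison.fit` returns a
:class:`MethodComparisonResults` carrying the full agreement battery —
mean absolute error, RMSE, mean bias with 95 % limits of agreement
(Bland–Altman, bias ± 1.96 × SD of the differences, both on the pooled
sample and on one first-trial row per participant), log-ratio Bland–Altman
back-transformed to percent, Spearman rank correlation with a magnitude
label, a Kolmogorov–Smirnov normality screen and a heteroscedasticity check
— plus ``summary()`` and a Bland–Altman plot.

Differences are always taken as device − criterion, so a negative bias
means the device underestimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSample",
    "AgreementResult",
    "LogBAResult",
    "MethodComparison",
    "MethodComparisonResults",
    "mae",
    "rmse",
    "mean_bias_loa",
    "spearman_with_magnitude",
    "magnitude_label",
    "log_bland_altman",
    "heteroscedasticity_check",
    "ks_normality",
    "build_report",
]

LOA_MULTIPLIER = 1.96
MAGNITUDE_BANDS = (
    (0.1, "trivial"),
    (0.3, "small"),
    (0.5, "moderate"),
    (0.7, "large"),
    (0.9, "very large"),
    (np.inf, "nearly perfect"),
)


@dataclass(frozen=True)
class PairedSample:
    """Paired device/criterion measurements of one variable."""

    variable: str
    units: str
    data: pd.DataFrame  # participant_id, trial_id, device, criterion

    def __post_init__(self) -> None:
        required = {"participant_id", "trial_id", "device", "criterion"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"paired data needs columns {sorted(required)}")
        vals = self.data[["device", "criterion"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("paired values must be finite")

    @classmethod
    def from_arrays(
        cls,
        device,
        criterion,
        participant_id=None,
        trial_id=None,
        variable: str = "",
        units: str = "",
    ) -> "PairedSample":
        device = np.asarray(device, dtype=float)
        criterion = np.asarray(criterion, dtype=float)
        n = len(device)
        df = pd.DataFrame(
            {
                "participant_id": participant_id if participant_id is not None else ["P"] * n,
                "trial_id": trial_id if trial_id is not None else ["T"] * n,
                "device": device,
                "criterion": criterion,
            }
        )
        return cls(variable, units, df)

    @property
    def differences(self) -> np.ndarray:
        return (self.data["device"] - self.data["criterion"]).to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class AgreementResult:
    """Flat record of the absolute-scale agreement statistics."""

    variable: str
    units: str
    mae: float
    rmse: float
    mean_bias: float
    loa_low: float
    loa_high: float
    rho: float
    rho_magnitude: str
    n: int
    loa_mode: str


@dataclass(frozen=True)
class LogBAResult:
    """Log-ratio Bland–Altman agreement expressed in percent."""

    percent_bias: float
    percent_loa_low: float
    percent_loa_high: float
    n_excluded_nonpositive: int
    n: int


def mae(p: PairedSample) -> float:
    """Mean absolute device − criterion error."""
    if len(p) < 1:
        raise ValueError("empty paired sample")
    return float(np.mean(np.abs(p.differences)))


def rmse(p: PairedSample) -> float:
    """Root mean square device − criterion error."""
    if len(p) < 1:
        raise ValueError("empty paired sample")
    return float(np.sqrt(np.mean(p.differences**2)))


def _first_trial_rows(data: pd.DataFrame) -> pd.DataFrame:
    """Collapse to one row per participant: the earliest trial, averaged.

    Variables sampled many times per trial (strides, instantaneous series)
    contribute the within-trial mean of each system, which keeps the
    repeated-measures correction to exactly one independent row per
    participant.
    """
    rows = []
    for pid, grp in data.groupby("participant_id", sort=True):
        first = min(grp["trial_id"])
        sel = grp[grp["trial_id"] == first]
        rows.append(
            {
                "participant_id": pid,
                "trial_id": first,
                "device": sel["device"].mean(),
                "criterion": sel["criterion"].mean(),
            }
        )
    return pd.DataFrame(rows)


def mean_bias_loa(p: PairedSample, mode: str = "pooled") -> AgreementResult:
    """Mean bias with 95 % limits of agreement (bias ± 1.96 × SD of diffs).

    ``mode='pooled'`` uses every row; ``mode='first_trial'`` reduces to one
    row per participant (earliest trial) before computing, avoiding the
    dependency of repeated measures.
    """
    if mode == "pooled":
        data = p.data
    elif mode == "first_trial":
        data = _first_trial_rows(p.data)
    else:
        raise ValueError(f"unknown LoA mode {mode!r}")
    d = (data["device"] - data["criterion"]).to_numpy(dtype=float)
    if len(d) < 2:
        raise ValueError("need at least two rows for limits of agreement")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    rho, label = _safe_spearman(p)
    return AgreementResult(
        variable=p.variable,
        units=p.units,
        mae=mae(p),
        rmse=rmse(p),
        mean_bias=bias,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        rho=rho,
        rho_magnitude=label,
        n=len(d),
        loa_mode=mode,
    )


def magnitude_label(rho: float) -> str:
    """Correlation-magnitude band: trivial <0.1, small <0.3, moderate <0.5,
    large <0.7, very large <0.9, nearly perfect 0.9–1.0 (lower bounds
    inclusive)."""
    r = abs(rho)
    for upper, label in MAGNITUDE_BANDS:
        if r < upper:
            return label
    return "nearly perfect"


def _safe_spearman(p: PairedSample) -> tuple[float, str]:
    dev = p.data["device"].to_numpy(dtype=float)
    crit = p.data["criterion"].to_numpy(dtype=float)
    if len(dev) < 3 or np.std(dev) == 0 or np.std(crit) == 0:
        return float("nan"), "undefined"
    rho = float(stats.spearmanr(dev, crit).statistic)
    return rho, magnitude_label(rho)


def spearman_with_magnitude(p: PairedSample) -> tuple[float, str]:
    """Spearman rank correlation between systems with its magnitude label."""
    if len(p) < 3:
        raise ValueError("need at least three rows for a rank correlation")
    return _safe_spearman(p)


def log_bland_altman(p: PairedSample, positivity_floor: float = 1e-6) -> LogBAResult:
    """Bland–Altman analysis on ln(device/criterion), reported in percent.

    Rows in which either value is at or below ``positivity_floor`` are
    excluded and counted; the log-ratio method assumes strictly positive
    measurements, so near-zero and negative variables (e.g. instantaneous
    acceleration) must not be analysed this way.
    """
    dev = p.data["device"].to_numpy(dtype=float)
    crit = p.data["criterion"].to_numpy(dtype=float)
    keep = (dev > positivity_floor) & (crit > positivity_floor)
    n_excl = int((~keep).sum())
    if keep.sum() < 2:
        raise ValueError("fewer than two strictly positive pairs")
    logratio = np.log(dev[keep] / crit[keep])
    bias = float(np.mean(logratio))
    sd = float(np.std(logratio, ddof=1))
    to_pct = lambda x: float(100.0 * (np.exp(x) - 1.0))
    return LogBAResult(
        percent_bias=to_pct(bias),
        percent_loa_low=to_pct(bias - LOA_MULTIPLIER * sd),
        percent_loa_high=to_pct(bias + LOA_MULTIPLIER * sd),
        n_excluded_nonpositive=n_excl,
        n=int(keep.sum()),
    )


def heteroscedasticity_check(
    p: PairedSample, alpha: float = 0.05
) -> tuple[float, float, str]:
    """Spearman correlation of |difference| against the pair means.

    Returns ``(rho, p_value, verdict)`` with verdict ``detected`` when the
    correlation is significant at ``alpha`` (two-sided), ``none_detected``
    otherwise, and ``undefined`` for degenerate samples.
    """
    if len(p) < 3:
        raise ValueError("need at least three rows")
    absd = np.abs(p.differences)
    means = (p.data["device"] + p.data["criterion"]).to_numpy(dtype=float) / 2.0
    if np.std(absd) == 0 or np.std(means) == 0:
        return float("nan"), float("nan"), "undefined"
    res = stats.spearmanr(absd, means)
    verdict = "detected" if res.pvalue < alpha else "none_detected"
    return float(res.statistic), float(res.pvalue), verdict


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    normal: bool
    degenerate: bool = False


def ks_normality(
    sample, alpha: float = 0.05, lilliefors_corrected: bool = True
) -> NormalityResult:
    """Kolmogorov–Smirnov normality screen with sample-estimated moments.

    The Lilliefors correction (default) accounts for estimating the mean and
    SD from the data; the uncorrected variant plugs the estimates into a
    plain KS test.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least five values")
    if np.std(x) == 0:
        return NormalityResult(float("nan"), float("nan"), False, degenerate=True)
    if lilliefors_corrected:
        from statsmodels.stats.diagnostic import lilliefors

        stat, pval = lilliefors(x, dist="norm", pvalmethod="table")
    else:
        stat, pval = stats.kstest(x, "norm", args=(np.mean(x), np.std(x, ddof=1)))
    return NormalityResult(float(stat), float(pval), bool(pval >= alpha))


class MethodComparison:
    """Agreement model for one variable measured by two systems.

    Parameters
    ----------
    sample : PairedSample
        Paired device/criterion rows tagged by participant and trial.
    log_ba : bool
        Whether the log-ratio Bland–Altman analysis applies (it must be
        disabled for variables containing negative or near-zero values).
    """

    def __init__(self, sample: PairedSample, log_ba: bool = True):
        self.sample = sample
        self.log_ba = log_ba

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        device_col: str = "device",
        criterion_col: str = "criterion",
        participant_col: str = "participant_id",
        trial_col: str = "trial_id",
        variable: str = "",
        units: str = "",
        log_ba: bool = True,
    ) -> "MethodComparison":
        data = pd.DataFrame(
            {
                "participant_id": df[participant_col],
                "trial_id": df[trial_col],
                "device": df[device_col],
                "criterion": df[criterion_col],
            }
        )
        return cls(PairedSample(variable, units, data), log_ba=log_ba)

    def fit(self, loa_modes: tuple[str, ...] = ("first_trial", "pooled")) -> "MethodComparisonResults":
        p = self.sample
        results = {mode: mean_bias_loa(p, mode) for mode in loa_modes}
        log_result = log_bland_altman(p) if self.log_ba else None
        het = heteroscedasticity_check(p)
        dev = p.data["device"].to_numpy(dtype=float)
        crit = p.data["criterion"].to_numpy(dtype=float)
        ks = {}
        for name, x in (("device", dev), ("criterion", crit), ("differences", p.differences)):
            try:
                ks[name] = ks_normality(x)
            except ValueError:
                ks[name] = None
        return MethodComparisonResults(
            model=self,
            by_mode=results,
            log_ba=log_result,
            heteroscedasticity=het,
            normality=ks,
        )


@dataclass
class MethodComparisonResults:
    """Fitted agreement battery; see :class:`MethodComparison`."""

    model: MethodComparison
    by_mode: dict[str, AgreementResult]
    log_ba: LogBAResult | None
    heteroscedasticity: tuple[float, float, str]
    normality: dict[str, NormalityResult | None] = field(default_factory=dict)

    # -- convenience accessors (pooled scale unless stated otherwise) -------
    @property
    def sample(self) -> PairedSample:
        return self.model.sample

    @property
    def n(self) -> int:
        return len(self.sample)

    @property
    def mae(self) -> float:
        return next(iter(self.by_mode.values())).mae

    @property
    def rmse(self) -> float:
        return next(iter(self.by_mode.values())).rmse

    @property
    def mean_bias(self) -> float:
        return self._pooled.mean_bias

    @property
    def loa(self) -> tuple[float, float]:
        return self._pooled.loa_low, self._pooled.loa_high

    @property
    def rho(self) -> float:
        return self._pooled.rho

    @property
    def rho_magnitude(self) -> str:
        return self._pooled.rho_magnitude

    @property
    def _pooled(self) -> AgreementResult:
        if "pooled" in self.by_mode:
            return self.by_mode["pooled"]
        return next(iter(self.by_mode.values()))

    def system_descriptives(self) -> dict[str, tuple[float, float]]:
        data = self.sample.data
        return {
            "device": (float(data["device"].mean()), float(data["device"].std(ddof=1))),
            "criterion": (
                float(data["criterion"].mean()),
                float(data["criterion"].std(ddof=1)),
            ),
        }

    def to_rows(self) -> list[dict]:
        """One flat report row per LoA mode."""
        desc = self.system_descriptives()
        rows = []
        for mode, r in self.by_mode.items():
            row = {
                "variable": r.variable,
                "units": r.units,
                "loa_mode": mode,
                "n": r.n,
                "n_pairs": self.n,
                "device_mean": desc["device"][0],
                "device_sd": desc["device"][1],
                "criterion_mean": desc["criterion"][0],
                "criterion_sd": desc["criterion"][1],
                "mae": r.mae,
                "rmse": r.rmse,
                "mean_bias": r.mean_bias,
                "loa_low": r.loa_low,
                "loa_high": r.loa_high,
                "rho": r.rho,
                "rho_magnitude": r.rho_magnitude,
                "heteroscedasticity": self.heteroscedasticity[2],
            }
            if self.log_ba is not None:
                row.update(
                    {
                        "log_percent_bias": self.log_ba.percent_bias,
                        "log_percent_loa_low": self.log_ba.percent_loa_low,
                        "log_percent_loa_high": self.log_ba.percent_loa_high,
                        "log_n_excluded": self.log_ba.n_excluded_nonpositive,
                    }
                )
            rows.append(row)
        return rows

    def summary(self) -> str:
        p = self.sample
        desc = self.system_descriptives()
        lines = [
            f"Method comparison: {p.variable or '(unnamed)'}"
            + (f" [{p.units}]" if p.units else ""),
            "=" * 64,
            f"{'n pairs':<28}{self.n:>10d}",
            f"{'device mean ± SD':<28}{desc['device'][0]:>10.3f} ± {desc['device'][1]:.3f}",
            f"{'criterion mean ± SD':<28}{desc['criterion'][0]:>10.3f} ± {desc['criterion'][1]:.3f}",
            f"{'MAE':<28}{self.mae:>10.3f}",
            f"{'RMSE':<28}{self.rmse:>10.3f}",
        ]
        for mode, r in self.by_mode.items():
            lines.append(
                f"{'bias (95% LoA), ' + mode:<28}{r.mean_bias:>10.3f} "
                f"({r.loa_low:.3f}; {r.loa_high:.3f})  n={r.n}"
            )
        rho = self._pooled
        lines.append(f"{'Spearman rho':<28}{rho.rho:>10.3f}  ({rho.rho_magnitude})")
        if self.log_ba is not None:
            lb = self.log_ba
            lines.append(
                f"{'log-BA bias % (95% LoA)':<28}{lb.percent_bias:>10.2f} "
                f"({lb.percent_loa_low:.2f}; {lb.percent_loa_high:.2f})"
                + (f"  excluded={lb.n_excluded_nonpositive}" if lb.n_excluded_nonpositive else "")
            )
        het = self.heteroscedasticity
        lines.append(f"{'heteroscedasticity':<28}{het[2]:>10s}  (rho={het[0]:.3f})")
        for name, res in self.normality.items():
            if res is None:
                continue
            tag = "degenerate" if res.degenerate else ("normal" if res.normal else "non-normal")
            lines.append(f"{'KS ' + name:<28}{tag:>10s}  (p={res.p_value:.3f})")
        return "\n".join(lines)

    def plot_bland_altman(self, ax=None, color_by_participant: bool = True):
        """Bland–Altman plot: pair means vs differences, dashed bias line,
        dotted 95 % LoA lines, one colour per participant."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4.2))
        data = self.sample.data
        means = (data["device"] + data["criterion"]) / 2.0
        diffs = data["device"] - data["criterion"]
        if color_by_participant:
            pids = sorted(data["participant_id"].unique())
            cmap = plt.get_cmap("tab20", max(len(pids), 1))
            colors = {pid: cmap(i) for i, pid in enumerate(pids)}
            for pid in pids:
                sel = data["participant_id"] == pid
                ax.scatter(means[sel], diffs[sel], s=14, color=colors[pid], alpha=0.8)
        else:
            ax.scatter(means, diffs, s=14, alpha=0.8)
        r = self._pooled
        ax.axhline(r.mean_bias, linestyle="--", color="k", label="mean difference")
        ax.axhline(r.loa_low, linestyle=":", color="k", label="95% LoA")
        ax.axhline(r.loa_high, linestyle=":", color="k")
        unit = f" ({self.sample.units})" if self.sample.units else ""
        ax.set_xlabel(f"Mean of systems{unit}")
        ax.set_ylabel(f"Device − criterion{unit}")
        ax.set_title(self.sample.variable)
        return ax


def build_report(
    results: dict[str, MethodComparisonResults],
) -> tuple[pd.DataFrame, dict[str, MethodComparisonResults]]:
    """Assemble the per-variable agreement table (one row per variable and
    LoA mode) plus the plotting handles, in input order."""
    if not results:
        raise ValueError("no variables to report")
    rows: list[dict] = []
    for res in results.values():
        rows.extend(res.to_rows())
    return pd.DataFrame(rows), results
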