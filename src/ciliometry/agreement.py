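"""Method-agreement statistics: ICC, Bland–Altman, and population t-tests.

The intraclass correlation is the two-way, single-measure,
absolute-agreement variant ICC(A,1): the methods being compared are fixed
(not a random sample of raters), each cilium is measured once per method,
and absolute agreement — rather than mere consistency — is what matters
because a systematic projection bias between methods must be penalised.
ICC values are read on the Landis–Koch scale.

Bland–Altman analysis summarises the paired differences A−B: the mean
difference is the bias between methods and bias ± 1.96·SD are the 95%
limits of agreement.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .measure import ANGLED, FLAT, LengthMeasurement, average_replicates

__all__ = [
    "PairedLengths",
    "AgreementResult",
    "BlandAltman",
    "TTestResult",
    "ComparisonReport",
    "icc_absolute_agreement",
    "landis_koch_label",
    "bland_altman",
    "ttest_independent",
    "compare_all",
]

#: Landis–Koch interpretation bands: exact boundary values fall in the
#: lower band (the scale is printed with strict lower inequalities).
LANDIS_KOCH_BANDS = (
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
)


@dataclass(frozen=True)
class PairedLengths:
    """Per-cilium paired lengths for two methods (aligned by cilium)."""

    cilium_ids: tuple
    lengths_a: np.ndarray
    lengths_b: np.ndarray
    method_a: str = "A"
    method_b: str = "B"

    def __post_init__(self) -> None:
        a = np.asarray(self.lengths_a, float)
        b = np.asarray(self.lengths_b, float)
        ids = tuple(self.cilium_ids)
        if not (len(ids) == a.size == b.size):
            raise ValueError("cilium_ids, lengths_a and lengths_b must have equal length")
        if a.size < 2:
            raise ValueError("need at least 2 paired measurements")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("paired lengths must be finite")
        object.__setattr__(self, "lengths_a", a)
        object.__setattr__(self, "lengths_b", b)
        object.__setattr__(self, "cilium_ids", ids)

    @property
    def n(self) -> int:
        return len(self.cilium_ids)


def icc_absolute_agreement(pairs: PairedLengths) -> float:
    """ICC(A,1): two-way, single-measure, absolute-agreement ICC.

    Computed from the two-way mean squares of the n×k layout (k = 2
    methods)::

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

    where MSR, MSC and MSE are the row (cilium), column (method) and
    residual mean squares.  A layout with zero total variance is perfect
    agreement by convention (returns 1.0 with a warning).
    """
    y = np.column_stack([pairs.lengths_a, pairs.lengths_b])
    n, k = y.shape
    grand = y.mean()
    if np.allclose(y, grand):
        warnings.warn("zero total variance: ICC defined as 1.0", stacklevel=2)
        return 1.0
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = y - row_means[:, None] - col_means[None, :] + grand
    mse = (resid**2).sum() / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    return float((msr - mse) / denom)


def landis_koch_label(icc: float) -> str:
    """Landis–Koch agreement band for an ICC / kappa value."""
    if not np.isfinite(icc):
        raise ValueError("icc must be finite")
    for upper, label in LANDIS_KOCH_BANDS:
        if icc <= upper:
            return label
    return "almost perfect"


@dataclass(frozen=True)
class BlandAltman:
    """Bland–Altman summary of the paired differences A−B (µm)."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    means: np.ndarray  # per-cilium (A+B)/2, the plot's x-axis
    diffs: np.ndarray  # per-cilium A−B, the plot's y-axis
    multiplier: float = 1.96


def bland_altman(pairs: PairedLengths, multiplier: float = 1.96) -> BlandAltman:
    """Bias, SD of differences and 95% limits of agreement.

    The SD uses the n−1 denominator; limits are bias ± ``multiplier``·SD
    (1.96 for the 95% agreement interval).
    """
    diffs = pairs.lengths_a - pairs.lengths_b
    means = 0.5 * (pairs.lengths_a + pairs.lengths_b)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(bias=bias, sd=sd, loa_low=bias - multiplier * sd,
                       loa_high=bias + multiplier * sd, means=means, diffs=diffs,
                       multiplier=multiplier)


@dataclass(frozen=True)
class TTestResult:
    """Two-sided independent-samples t-test with per-group summaries."""

    t: float
    p: float
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def summary(self) -> str:
        return (f"{self.mean1:.2f} ± {self.sd1:.2f} (n={self.n1}) vs "
                f"{self.mean2:.2f} ± {self.sd2:.2f} (n={self.n2}): "
                f"t={self.t:.3f}, p={self.p:.4g}")


def ttest_independent(group1: Sequence[float], group2: Sequence[float],
                      welch: bool = False) -> TTestResult:
    """Independent two-sided Student's t-test (pooled variance by default).

    ``welch=True`` drops the equal-variance assumption.
    """
    g1 = np.asarray(group1, float)
    g2 = np.asarray(group2, float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not welch and g1.std(ddof=1) == 0 and g2.std(ddof=1) == 0:
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(g1, g2, equal_var=not welch)
    return TTestResult(t=float(t), p=float(p),
                       mean1=float(g1.mean()), sd1=float(g1.std(ddof=1)), n1=g1.size,
                       mean2=float(g2.mean()), sd2=float(g2.std(ddof=1)), n2=g2.size)


@dataclass(frozen=True)
class AgreementResult:
    """ICC + Bland–Altman summary for one method pair."""

    method_a: str
    method_b: str
    icc: float
    icc_label: str
    ba_bias: float
    ba_sd: float
    ba_loa_low: float
    ba_loa_high: float
    n: int


def _agreement(pairs: PairedLengths) -> AgreementResult:
    icc = icc_absolute_agreement(pairs)
    ba = bland_altman(pairs)
    return AgreementResult(method_a=pairs.method_a, method_b=pairs.method_b, icc=icc,
                           icc_label=landis_koch_label(icc), ba_bias=ba.bias, ba_sd=ba.sd,
                           ba_loa_low=ba.loa_low, ba_loa_high=ba.loa_high, n=pairs.n)


@dataclass(frozen=True)
class ComparisonReport:
    """Full method/population comparison of a measured cohort.

    ``population_summary``: per-population per-method mean ± SD of the
    replicate-averaged lengths.  ``agreement``: ICC + Bland–Altman for
    every method pair within each population.  ``ttests``: flat-vs-angled
    test per method.  ``per_cilium``: the replicate-averaged wide table the
    statistics were computed from.
    """

    population_summary: pd.DataFrame
    agreement: pd.DataFrame
    ttests: pd.DataFrame
    per_cilium: pd.DataFrame

    def save(self, prefix: str, header_lines: Sequence[str] = ()) -> list[str]:
        """Write the report tables as CSV files ``<prefix>_*.csv``."""
        written = []
        for name, df in (("summary", self.population_summary), ("agreement", self.agreement),
                         ("ttests", self.ttests), ("per_cilium", self.per_cilium)):
            path = f"{prefix}_{name}.csv"
            with open(path, "w", encoding="utf-8", newline="") as fh:
                for line in header_lines:
                    fh.write(f"# {line}\n")
                df.to_csv(fh, index=False)
            written.append(path)
        return written

    def get_agreement(self, population: str, method_a: str, method_b: str) -> AgreementResult:
        """Look up one method pair's agreement within a population."""
        df = self.agreement
        sel = df[(df.population == population)
                 & (df.method_a.isin([method_a, method_b]))
                 & (df.method_b.isin([method_a, method_b]))]
        if sel.empty:
            raise KeyError(f"no agreement entry for {population}: {method_a} vs {method_b}")
        r = sel.iloc[0]
        return AgreementResult(method_a=r.method_a, method_b=r.method_b, icc=r.icc,
                               icc_label=r.icc_label, ba_bias=r.ba_bias, ba_sd=r.ba_sd,
                               ba_loa_low=r.ba_loa_low, ba_loa_high=r.ba_loa_high, n=int(r.n))


def _replicate_average(measurements: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (cid, method), grp in measurements.groupby(["cilium_id", "method"], sort=False):
        ms = [LengthMeasurement(str(cid), method, int(r.replicate), float(r.length_um))
              for r in grp.itertuples()]
        summ = average_replicates(ms)
        labels = grp["classification"].unique()
        if len(labels) != 1:
            raise ValueError(f"inconsistent classification for cilium {cid!r}")
        rows.append((str(cid), method, summ.mean_um, summ.range_um, summ.n, labels[0]))
    return pd.DataFrame(rows, columns=["cilium_id", "method", "length_um", "range_um",
                                       "n_replicates", "classification"])


def compare_all(measurements: pd.DataFrame, require_all_methods: bool = True
                ) -> ComparisonReport:
    """Reproduce the full comparison protocol on a measurement table.

    ``measurements`` is the tidy per-replicate table (columns ``cilium_id,
    method, replicate, length_um, classification``).  Replicates are
    averaged per cilium and method first; every cilium must then carry
    every method present in the table (unless ``require_all_methods`` is
    off, in which case the ICC/Bland–Altman matrix is restricted to cilia
    with complete pairs).
    """
    avg = _replicate_average(measurements)
    methods = sorted(avg["method"].unique(), key=list(("MIP", "PYT", "DAAS")).index)
    wide = avg.pivot(index="cilium_id", columns="method", values="length_um")
    if require_all_methods and wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"cilia missing a method: {missing}")
    labels = avg.drop_duplicates("cilium_id").set_index("cilium_id")["classification"]
    wide = wide.join(labels)

    pop_rows = []
    for pop in (FLAT, ANGLED):
        sub = wide[wide.classification == pop]
        for m in methods:
            vals = sub[m].dropna()
            if len(vals):
                pop_rows.append((pop, m, len(vals), vals.mean(), vals.std(ddof=1),
                                 f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f}"))
    population_summary = pd.DataFrame(
        pop_rows, columns=["population", "method", "n", "mean_um", "sd_um", "mean_sd"])

    agr_rows = []
    if len(methods) >= 2:
        for pop in (FLAT, ANGLED):
            sub = wide[wide.classification == pop]
            for ma, mb in itertools.combinations(methods, 2):
                paired = sub[[ma, mb]].dropna()
                if len(paired) < 2:
                    continue
                res = _agreement(PairedLengths(tuple(paired.index), paired[ma].to_numpy(),
                                               paired[mb].to_numpy(), ma, mb))
                agr_rows.append((pop, ma, mb, res.icc, res.icc_label, res.ba_bias,
                                 res.ba_sd, res.ba_loa_low, res.ba_loa_high, res.n))
    else:
        warnings.warn("fewer than two methods: ICC/Bland–Altman matrix skipped", stacklevel=2)
    agreement_df = pd.DataFrame(
        agr_rows, columns=["population", "method_a", "method_b", "icc", "icc_label",
                           "ba_bias", "ba_sd", "ba_loa_low", "ba_loa_high", "n"])

    tt_rows = []
    for m in methods:
        flat_vals = wide[wide.classification == FLAT][m].dropna()
        ang_vals = wide[wide.classification == ANGLED][m].dropna()
        if len(flat_vals) >= 2 and len(ang_vals) >= 2:
            r = ttest_independent(flat_vals, ang_vals)
            tt_rows.append((m, r.t, r.p, r.mean1, r.sd1, r.n1, r.mean2, r.sd2, r.n2))
    ttests = pd.DataFrame(tt_rows, columns=["method", "t", "p", "mean_flat", "sd_flat",
                                            "n_flat", "mean_angled", "sd_angled", "n_angled"])
    per_cilium = wide.reset_index()
    return ComparisonReport(population_summary=population_summary, agreement=agreement_df,
                            ttests=ttests, per_cilium=per_cilium)


def plot_report(report: ComparisonReport, prefix: str) -> list[str]:
    """Write boxplot and Bland–Altman PNGs for a comparison report."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    methods = [m for m in ("MIP", "PYT", "DAAS") if m in report.per_cilium.columns]
    fig, axes = plt.subplots(1, len(methods), figsize=(3.2 * len(methods), 3.6), squeeze=False)
    for ax, m in zip(axes[0], methods):
        data = [report.per_cilium[report.per_cilium.classification == pop][m].dropna()
                for pop in (FLAT, ANGLED)]
        ax.boxplot(data, tick_labels=["flat", "angled"], whis=(0, 100))
        ax.set_title(m)
        ax.set_ylabel("length (µm)")
    fig.tight_layout()
    path = f"{prefix}_boxplots.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    if len(report.agreement):
        rows = list(report.agreement.itertuples())
        fig, axes = plt.subplots(1, len(rows), figsize=(3.2 * len(rows), 3.2), squeeze=False)
        for ax, r in zip(axes[0], rows):
            pop = report.per_cilium[report.per_cilium.classification == r.population]
            a, b = pop[r.method_a], pop[r.method_b]
            ax.scatter((a + b) / 2, a - b, s=12)
            for yv, ls in ((r.ba_bias, "-"), (r.ba_loa_low, "--"), (r.ba_loa_high, "--")):
                ax.axhline(yv, color="k", ls=ls, lw=0.8)
            ax.set_title(f"{r.population}: {r.method_a}−{r.method_b}\nICC={r.icc:.2f}",
                         fontsize=9)
            ax.set_xlabel("mean (µm)")
            ax.set_ylabel("difference (µm)")
        fig.tight_layout()
        path = f"{prefix}_bland_altman.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
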