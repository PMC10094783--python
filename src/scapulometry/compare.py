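"""Paired software-variant comparison statistics.

The protocol used to audit two versions of an automated measurement on
the same shoulders: paired t-tests (from raw pairs or from printed
summary statistics), Bland-Altman bias and 95% limits of agreement,
clinically motivated difference bins (<5 deg, 5-10 deg, >10 deg; 5 deg
being the smallest clinically relevant gap), and subgroup analysis by
glenoid morphology class.

Differences are taken as ``b - a`` (updated minus legacy software)
throughout; tests are two-tailed with alpha = 0.05 and no
multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "PairedComparison",
    "BlandAltman",
    "DiffBins",
    "paired_t_test",
    "paired_t_from_summary",
    "bland_altman",
    "bin_differences",
    "subgroup_compare",
    "comparison_table",
    "format_p",
]

ALPHA = 0.05


@dataclass
class PairedSample:
    """Measurements of one metric on the same subjects under two variants."""

    ids: np.ndarray
    values_a: np.ndarray
    values_b: np.ndarray
    metric_name: str = ""
    group_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        n = len(self.ids)
        if len(self.values_a) != n or len(self.values_b) != n:
            raise ValueError("ids, values_a and values_b must have equal length")
        if len(np.unique(self.ids)) != n:
            raise ValueError("subject ids must be unique")
        if not (np.all(np.isfinite(self.values_a)) and np.all(np.isfinite(self.values_b))):
            raise ValueError("missing or non-finite paired values")
        if self.group_labels is not None:
            self.group_labels = np.asarray(self.group_labels)
            if len(self.group_labels) != n:
                raise ValueError("group_labels must align with ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def differences(self) -> np.ndarray:
        return self.values_b - self.values_a

    def subset(self, mask: np.ndarray) -> "PairedSample":
        return PairedSample(
            self.ids[mask],
            self.values_a[mask],
            self.values_b[mask],
            self.metric_name,
            None if self.group_labels is None else self.group_labels[mask],
        )


@dataclass
class PairedComparison:
    """Summary of one paired t-test (one table row)."""

    metric_name: str
    n: int
    mean_a: float | None
    sd_a: float | None
    mean_b: float | None
    sd_b: float | None
    mean_diff: float
    sd_diff: float
    t_statistic: float
    df: int
    p_value: float
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


@dataclass
class BlandAltman:
    """Bias and 95% limits of agreement, plus per-pair plot coordinates."""

    metric_name: str
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    differences: np.ndarray


@dataclass
class DiffBins:
    """|difference| counts in [0, 5), [5, 10] and (10, inf) degrees."""

    n: int
    counts: tuple[int, int, int]
    percentages: tuple[float, float, float] = field(init=False)

    def __post_init__(self) -> None:
        if sum(self.counts) != self.n:
            raise ValueError("bin counts must sum to n")
        self.percentages = tuple(100.0 * c / self.n for c in self.counts)


def _t_summary(
    metric_name: str,
    n: int,
    mean_diff: float,
    sd_diff: float,
    mean_a=None,
    sd_a=None,
    mean_b=None,
    sd_b=None,
) -> PairedComparison:
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    df = n - 1
    if sd_diff > 0:
        t = mean_diff / (sd_diff / np.sqrt(n))
        p = 2.0 * sps.t.sf(abs(t), df)
    else:
        # all differences identical; zero mean => no evidence of change
        t = 0.0 if mean_diff == 0 else np.inf * np.sign(mean_diff)
        p = 1.0 if mean_diff == 0 else 0.0
    return PairedComparison(
        metric_name=metric_name,
        n=n,
        mean_a=mean_a,
        sd_a=sd_a,
        mean_b=mean_b,
        sd_b=sd_b,
        mean_diff=float(mean_diff),
        sd_diff=float(sd_diff),
        t_statistic=float(t),
        df=df,
        p_value=float(min(p, 1.0)),
    )


def paired_t_test(sample: PairedSample) -> PairedComparison:
    """Two-tailed paired t-test on raw pairs (differences b - a)."""
    d = sample.differences
    return _t_summary(
        sample.metric_name,
        sample.n,
        float(d.mean()),
        float(d.std(ddof=1)),
        mean_a=float(sample.values_a.mean()),
        sd_a=float(sample.values_a.std(ddof=1)),
        mean_b=float(sample.values_b.mean()),
        sd_b=float(sample.values_b.std(ddof=1)),
    )


def paired_t_from_summary(mean_diff: float, sd_diff: float, n: int, metric_name: str = "") -> PairedComparison:
    """Paired t-test from printed summary statistics (mean +/- SD of the
    paired differences and the sample size)."""
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    if not sd_diff > 0:
        raise ValueError("sd_diff must be > 0 in summary mode")
    return _t_summary(metric_name, int(n), float(mean_diff), float(sd_diff))


def bland_altman(sample: PairedSample) -> BlandAltman:
    """Bias and 95% limits of agreement (bias +/- 1.96 sample SD)."""
    if sample.n < 2:
        raise ValueError("Bland-Altman needs n >= 2")
    d = sample.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        metric_name=sample.metric_name,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=0.5 * (sample.values_a + sample.values_b),
        differences=d,
    )


def bin_differences(sample: PairedSample) -> DiffBins:
    """Bin |b - a| into [0, 5), [5, 10] and (10, inf) degrees.

    Both boundary values land in the middle bin: a 5.0-degree change is
    already clinically relevant, a 10.0-degree change is not yet "more
    than 10".
    """
    if sample.n < 1:
        raise ValueError("need at least one pair")
    ad = np.abs(sample.differences)
    lt5 = int((ad < 5.0).sum())
    mid = int(((ad >= 5.0) & (ad <= 10.0)).sum())
    gt10 = int((ad > 10.0).sum())
    return DiffBins(n=sample.n, counts=(lt5, mid, gt10))


def subgroup_compare(
    sample: PairedSample, groups: dict[str, set[str]]
) -> dict[str, PairedComparison | None]:
    """Paired t-test within each requested label subset.

    ``groups`` maps a subgroup name to the set of per-subject class
    labels it pools (e.g. concentric vs eroded morphologies).  Subgroups
    with fewer than 2 subjects are reported as ``None`` (not computable)
    rather than raising.
    """
    if sample.group_labels is None:
        raise ValueError("sample has no group labels")
    out: dict[str, PairedComparison | None] = {}
    for name, labels in groups.items():
        mask = np.isin(sample.group_labels, sorted(labels))
        if int(mask.sum()) < 2:
            out[name] = None
            continue
        sub = sample.subset(mask)
        cmp_ = paired_t_test(sub)
        cmp_.metric_name = f"{sample.metric_name}[{name}]" if sample.metric_name else name
        out[name] = cmp_
    return out


def format_p(p: float, decimals: int = 3) -> str:
    """Display-style p value: three decimals, '<0.001' below that."""
    floor = 10.0 ** (-decimals)
    if p < floor:
        return f"<{floor:.{decimals}f}"
    return f"{p:.{decimals}f}"


def bland_altman_plot(ba: BlandAltman, path, title: str | None = None) -> None:
    """Write a Bland-Altman scatter (pair means vs differences) to disk."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.means, ba.differences, s=12, alpha=0.7)
    for yv, style, lab in (
        (ba.bias, "-", f"bias {ba.bias:+.2f}"),
        (ba.loa_low, "--", f"LoA {ba.loa_low:+.2f}"),
        (ba.loa_high, "--", f"LoA {ba.loa_high:+.2f}"),
    ):
        ax.axhline(yv, linestyle=style, color="k", linewidth=1)
        ax.annotate(lab, (0.99, yv), xycoords=("axes fraction", "data"),
                    ha="right", va="bottom", fontsize=8)
    ax.set_xlabel("pair mean")
    ax.set_ylabel("difference (b − a)")
    ax.set_title(title or ba.metric_name)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def comparison_table(comparisons: list[PairedComparison], decimals: int = 1) -> pd.DataFrame:
    """Report table with one row per metric, display-rounded."""

    def ms(mean, sd):
        if mean is None or sd is None:
            return ""
        return f"{mean:+.{decimals}f} ± {sd:.{decimals}f}"

    rows = []
    for c in comparisons:
        rows.append(
            {
                "metric": c.metric_name,
                "n": c.n,
                "variant_a": ms(c.mean_a, c.sd_a),
                "variant_b": ms(c.mean_b, c.sd_b),
                "difference": ms(c.mean_diff, c.sd_diff),
                "t": round(c.t_statistic, 2),
                "df": c.df,
                "p_value": format_p(c.p_value),
            }
        )
    return pd.DataFrame(rows)
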