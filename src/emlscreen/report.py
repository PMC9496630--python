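"""Univariate metabolite reporting: volcano analysis and VIP ranking.

The volcano compares each metabolite's abundance between CTRL and EC on the
internal-standard-normalized scale: fold change as the ratio of geometric
means (EC over CTRL) and a two-sample t-test on the log values. A
metabolite is flagged when its fold change exceeds 2 (raised in EC) or
falls below 0.5 (lowered in EC) AND its raw p-value is below 0.05; both
bounds are strict. A Benjamini-Hochberg column is emitted alongside but
does not enter the flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import PLSDADiagnostics
from .peaktable import CTRL, EC, PeakTable


def volcano(
    table: PeakTable,
    labels: pd.Series | None = None,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-metabolite fold change and significance between EC and CTRL.

    Parameters
    ----------
    table : PeakTable
        IS-normalized peak table. Missing values are ignored per feature.
    labels : pandas.Series, optional
        Class labels; defaults to the table's own. Only CTRL and EC samples
        enter the comparison.
    fc_hi, fc_lo : float
        Strict fold-change bounds for flagging (default >2 or <0.5).
    alpha : float
        Significance level for the (raw) p-value (default 0.05).
    equal_var : bool
        Student's t when True; Welch's unequal-variance t by default.

    Returns
    -------
    pandas.DataFrame
        Columns: ``fold_change`` (EC geometric mean / CTRL geometric mean),
        ``p_value``, ``q_value`` (Benjamini-Hochberg), ``significant`` and
        ``direction`` ("up"/"down" for flagged metabolites, "" otherwise).
    """
    labels = table.labels if labels is None else labels
    ec_ids = labels.index[labels == EC]
    ctrl_ids = labels.index[labels == CTRL]
    if len(ec_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("need at least 2 samples per class")

    log_ec = np.log(table.areas.loc[ec_ids])
    log_ctrl = np.log(table.areas.loc[ctrl_ids])
    fc = np.exp(log_ec.mean(axis=0, skipna=True) - log_ctrl.mean(axis=0, skipna=True))
    t = stats.ttest_ind(
        log_ec, log_ctrl, axis=0, equal_var=equal_var, nan_policy="omit"
    )
    p = pd.Series(np.asarray(t.pvalue), index=table.features)
    q = pd.Series(
        stats.false_discovery_control(p.fillna(1.0), method="bh"), index=table.features
    )
    flagged = ((fc > fc_hi) | (fc < fc_lo)) & (p < alpha)
    direction = pd.Series("", index=table.features)
    direction[flagged & (fc > fc_hi)] = "up"
    direction[flagged & (fc < fc_lo)] = "down"
    return pd.DataFrame(
        {
            "fold_change": fc,
            "p_value": p,
            "q_value": q,
            "significant": flagged,
            "direction": direction,
        }
    )


def vip_table(diag: PLSDADiagnostics, cutoff: float = 2.0) -> pd.Series:
    """Metabolites with VIP score strictly above `cutoff`, descending."""
    above = diag.vip[diag.vip > cutoff]
    return above.sort_values(ascending=False)


# ----------------------------------------------------------------- plotting


def plot_volcano(volcano_df: pd.DataFrame, path, fc_hi=2.0, fc_lo=0.5, alpha=0.05):
    """Save a volcano plot (log2 FC vs -log10 p) highlighting flagged metabolites."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    x = np.log2(volcano_df["fold_change"])
    ylog = -np.log10(volcano_df["p_value"])
    sig = volcano_df["significant"]
    ax.scatter(x[~sig], ylog[~sig], s=10, c="grey", alpha=0.6)
    ax.scatter(x[sig], ylog[sig], s=18, c="crimson")
    ax.axhline(-np.log10(alpha), ls="--", lw=0.8, c="k")
    for v in (np.log2(fc_hi), np.log2(fc_lo)):
        ax.axvline(v, ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change (EC / CTRL)")
    ax.set_ylabel("-log10 p-value")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_score_distribution(summary_scores: pd.DataFrame, threshold: float, path):
    """Save EML score distributions per true class with the decision cut."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for cls, grp in summary_scores.groupby("true_class"):
        ax.hist(grp["score"], bins=30, alpha=0.5, label=str(cls))
    ax.axvline(threshold, ls="--", c="red", label="threshold")
    ax.set_xlabel("EML score")
    ax.set_ylabel("samples")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(roc: pd.DataFrame, auc: float, path):
    """Save the ROC curve from a threshold sweep."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    fpr = 1.0 - roc["specificity"]
    order = np.argsort(fpr.to_numpy())
    ax.plot(fpr.to_numpy()[order], roc["sensitivity"].to_numpy()[order], lw=1.5)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {auc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
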