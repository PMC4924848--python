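"""Plot-ready tables for scatter, funnel and forest displays.

Rendering is deliberately separated from computation: every function here
returns a plain :class:`pandas.DataFrame` that is itself the artifact
(written as TSV by the CLI), so figures are pure views of stored results
and can be regenerated from the results JSON alone.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from mr2s.harmonize import HarmonizedInstrument
from mr2s.mr_core import MRResult, RatioEstimate
from mr2s.sensitivity import SuiteRow


def scatter_data(
    instruments: Sequence[HarmonizedInstrument],
    ivw: MRResult,
    egger_intercept: MRResult,
    egger_slope: MRResult,
) -> pd.DataFrame:
    """Per-SNP (gamma, Gamma, se_Gamma) points for the effect-effect scatter.

    The two fitted lines are attached in ``df.attrs["lines"]``: the IVW
    line passes through the origin with slope beta_IVW; the Egger line has
    the fitted intercept and slope.
    """
    df = pd.DataFrame(
        {
            "snp_id": [i.snp_id for i in instruments],
            "gamma": [i.gamma for i in instruments],
            "Gamma": [i.Gamma for i in instruments],
            "se_Gamma": [i.se_Gamma for i in instruments],
        }
    )
    df.attrs["lines"] = {
        "IVW": {"intercept": 0.0, "slope": ivw.beta},
        "Egger": {"intercept": egger_intercept.beta, "slope": egger_slope.beta},
    }
    return df


def funnel_data(
    instruments: Sequence[HarmonizedInstrument],
    ratios: Sequence[RatioEstimate],
) -> pd.DataFrame:
    """Per-SNP causal estimate against precision, for asymmetry inspection.

    ``precision`` is the standard meta-analysis funnel ordinate
    1/se(ratio).  ``exposure_precision`` is an experimental alternate
    ordinate — the exposure association scaled by its own SE
    (gamma/se_gamma), an allele-frequency-driven precision proxy since
    rarer alleles are measured less precisely.  Directional pleiotropy
    shows up as asymmetry: low-precision ratios drifting to one side.
    """
    by_id = {r.snp_id: r for r in ratios}
    rows = []
    for inst in instruments:
        r = by_id[inst.snp_id]
        rows.append(
            {
                "snp_id": inst.snp_id,
                "ratio": r.ratio,
                "precision": 1.0 / r.se_ratio,
                "exposure_precision": inst.gamma / inst.se_gamma,
            }
        )
    return pd.DataFrame(rows)


def forest_data(suite_rows: Sequence[SuiteRow]) -> pd.DataFrame:
    """One row per analysis x method with OR-scale estimate and CI, in
    suite order (failed analyses are skipped)."""
    rows = []
    for row in suite_rows:
        if row.result is None:
            continue
        if row.method == "Egger_intercept":
            continue  # a pleiotropy test statistic, not a causal OR
        rows.append(
            {
                "analysis": row.spec_name,
                "method": row.method,
                "or": row.result.or_,
                "or_ci_low": row.result.or_ci_low,
                "or_ci_high": row.result.or_ci_high,
                "n_snps": row.n_snps,
                "n_proxies": row.n_proxies,
            }
        )
    return pd.DataFrame(rows)


def render_plots(out_dir, scatter: pd.DataFrame, funnel: pd.DataFrame, forest: pd.DataFrame) -> list:
    """Optional PNG rendering of the three displays (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    written = []

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(scatter["gamma"], scatter["Gamma"], yerr=1.959964 * scatter["se_Gamma"],
                fmt="o", ms=3, lw=0.5, color="grey", alpha=0.7)
    xs = [0, scatter["gamma"].max() * 1.05]
    for name, color in (("IVW", "red"), ("Egger", "blue")):
        line = scatter.attrs.get("lines", {}).get(name)
        if line:
            ax.plot(xs, [line["intercept"] + line["slope"] * x for x in xs], color=color, label=name)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("SNP effect on exposure (SD/allele)")
    ax.set_ylabel("SNP effect on outcome (log-odds/allele)")
    ax.legend()
    p = out_dir / "scatter.png"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(funnel["ratio"], funnel["precision"], s=10)
    ax.set_xlabel("Wald ratio (causal estimate)")
    ax.set_ylabel("precision (1/SE)")
    p = out_dir / "funnel.png"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(6, 0.4 * max(len(forest), 4) + 1))
    labels = forest["analysis"] + " / " + forest["method"]
    y = range(len(forest))[::-1]
    ax.errorbar(
        forest["or"],
        list(y),
        xerr=[forest["or"] - forest["or_ci_low"], forest["or_ci_high"] - forest["or"]],
        fmt="s",
        color="k",
    )
    ax.axvline(1.0, color="grey", lw=0.5)
    ax.set_yticks(list(y), labels)
    ax.set_xlabel("OR per SD exposure")
    p = out_dir / "forest.png"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(p)
    return written
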