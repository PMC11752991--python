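"""Static HTML risk reports and PNG plots (the CLI's visualization layer)."""

from __future__ import annotations

import datetime as _dt
import json
import os
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402
from sklearn.metrics import precision_recall_curve, roc_curve  # noqa: E402

from . import __version__  # noqa: E402
from .pdo import VariantComparison  # noqa: E402

__all__ = ["write_manifest", "plot_convergence", "plot_roc_pr",
           "render_risk_report"]


def write_manifest(output_dir: str, command: str, params: dict,
                   inputs: list[str], outputs: list[str]) -> str:
    """One manifest per artifact-producing command, enough to re-run it."""
    manifest = {
        "command": command,
        "params": params,
        "inputs": inputs,
        "outputs": outputs,
        "package_version": __version__,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    path = os.path.join(output_dir, f"{command}.manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def plot_convergence(summary: VariantComparison, path: str) -> None:
    """Mean best-fitness trace per variant, log-scaled when all positive."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    colors = {"pdo": "tab:red", "ipdo": "tab:blue"}
    positive = all(np.all(t > 0) for t in summary.mean_trace.values())
    for variant, trace in summary.mean_trace.items():
        ax.plot(np.arange(1, trace.size + 1), trace,
                label=variant.upper(), color=colors.get(variant))
    if positive:
        ax.set_yscale("log")
    ax.set_xlabel("iteration")
    ax.set_ylabel("mean best fitness")
    ax.set_title(f"{summary.function_name} ({summary.repeats} repeats)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc_pr(y_true, scores, path: str, title: str = "") -> None:
    y = np.asarray(y_true, int)
    s = np.asarray(scores, float)
    fpr, tpr, _ = roc_curve(y, s)
    pre, rec, _ = precision_recall_curve(y, s)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5))
    ax1.plot(fpr, tpr)
    ax1.plot([0, 1], [0, 1], ls="--", c="grey")
    ax1.set_xlabel("1 - specificity")
    ax1.set_ylabel("sensitivity")
    ax1.set_title(f"ROC {title}")
    ax2.plot(rec, pre)
    ax2.set_xlabel("recall")
    ax2.set_ylabel("precision")
    ax2.set_title(f"PR {title}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Prognosis risk report</title>
<style>
 body {{ font-family: sans-serif; max-width: 46em; margin: 2em auto; }}
 .gauge {{ background:#eee; border-radius:6px; height:26px; width:100%; }}
 .fill {{ background:{color}; border-radius:6px; height:26px; width:{pct}%; }}
 .label {{ font-size:1.4em; font-weight:bold; color:{color}; }}
 table {{ border-collapse: collapse; }}
 td, th {{ border:1px solid #ccc; padding:4px 10px; text-align:left; }}
</style></head><body>
<h1>Poor-prognosis risk report</h1>
<p>Estimated probability of poor prognosis (GOS 1&ndash;3 at six months)
after endovascular aneurysm treatment:</p>
<div class="gauge"><div class="fill"></div></div>
<p><span class="label">{pct:.1f}% &mdash; {label}</span></p>
<h2>Patient values (selected predictors)</h2>
<table><tr><th>feature</th><th>value</th><th>model weight</th></tr>
{rows}
</table>
<p style="color:#777">affwdi {version}</p>
</body></html>
"""


def render_risk_report(probability: float, label: int, record: dict,
                       feature_weights: dict, path: str) -> None:
    """Render one patient's risk as a static HTML page."""
    rows = "\n".join(
        f"<tr><td>{f}</td><td>{record[f]}</td>"
        f"<td>{feature_weights[f]:.3f}</td></tr>"
        for f in feature_weights)
    html = _PAGE.format(
        pct=100.0 * probability,
        color="#b22222" if label == 1 else "#228b22",
        label="poor prognosis" if label == 1 else "good prognosis",
        rows=rows, version=__version__)
    with open(path, "w") as fh:
        fh.write(html)
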