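"""Static HTML report over the pipeline's TSV outputs.

Every number shown is taken from the already-computed result tables, so
re-rendering from the same results is byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd

__all__ = ["render_report", "load_results"]

_PAGE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>TF prioritization report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; color: #222; }}
table {{ border-collapse: collapse; margin: 1em 0; }}
th, td {{ border: 1px solid #bbb; padding: 4px 8px; text-align: right; }}
th {{ background: #eee; }}
td:first-child, th:first-child {{ text-align: left; }}
h2 {{ border-bottom: 1px solid #ccc; padding-bottom: 4px; }}
</style>
</head>
<body>
<h1>TF prioritization report</h1>
{body}
</body>
</html>
"""


def _table(df: pd.DataFrame, max_rows: int = 50) -> str:
    shown = df.head(max_rows)
    return shown.to_html(float_format=lambda v: f"{v:.4g}", border=0)


def render_report(result) -> str:
    sections: list[str] = []

    ranking = result.global_ranking.table
    if ranking.empty:
        sections.append("<h2>Global ranking</h2><p><b>No TFs prioritized.</b> "
                        "No TF passed the per-assay significance gate.</p>")
    else:
        sections.append(
            "<h2>Global ranking</h2>"
            "<p>TFs significant in at least one assay, ascending by the "
            "rank-aggregation score f (0 = top-ranked in every assay where "
            "the TF was assessed).</p>" + _table(ranking)
        )

    for hm in result.per_hm:
        body = (
            _table(hm.stats.sort_values("fg_mean", ascending=False))
            if not hm.stats.empty
            else "<p>No positive combined scores for this assay.</p>"
        )
        sections.append(
            f"<h2>Assay {hm.assay}: foreground vs background</h2>"
            f"<p>Background: {hm.bg.size} positive scores pooled over all "
            f"TFs; {len(hm.significant)} TFs significant.</p>" + body
        )

    for pair, diff in result.differential.items():
        up = diff.table.nlargest(10, "log2fc")
        sections.append(
            f"<h2>Differential expression {pair[0]} vs {pair[1]}</h2>"
            f"<p>{len(diff.table)} retained genes; 10 most upregulated "
            "shown.</p>" + _table(up)
        )

    if result.validation is not None and not result.validation.empty:
        sections.append(
            "<h2>Validation against experimental peaks</h2>" + _table(result.validation)
        )

    if result.cooccurrence is not None:
        sections.append(
            "<h2>TF co-occurrence (G&sup2;)</h2>" + _table(result.cooccurrence["g2"])
        )

    return _PAGE.format(body="\n".join(sections))


def load_results(out_dir: str | Path):
    """Rebuild a renderable view of a result directory from its TSVs.

    Re-rendering the report from this view is byte-identical to the HTML
    written during the original run.
    """
    from .prioritization import GlobalRanking, HMPrioritization

    out = Path(out_dir)
    ranking = GlobalRanking(
        pd.read_csv(out / "global_ranking.tsv", sep="\t", index_col=0)
    )
    per_hm = []
    for path in sorted(out.glob("prioritization_*.tsv")):
        stats = pd.read_csv(path, sep="\t", index_col=0)
        assay = path.stem.removeprefix("prioritization_")
        n_bg = int(stats["n_bg"].iloc[0]) if len(stats) else 0
        per_hm.append(
            HMPrioritization(
                assay=assay,
                fg={},
                bg=np.zeros(n_bg),
                stats=stats,
                significant=list(stats.index[stats["significant"]])
                if len(stats)
                else [],
            )
        )
    differential = {}
    for path in sorted(out.glob("differential_*.tsv")):
        a, b = path.stem.removeprefix("differential_").split("_vs_")
        table = pd.read_csv(path, sep="\t", index_col=0)
        table.index.name = None
        differential[(a, b)] = SimpleNamespace(table=table)
    validation = None
    if (out / "validation_metrics.tsv").exists():
        validation = pd.read_csv(out / "validation_metrics.tsv", sep="\t")
    cooccurrence = None
    g2_path = out / "cooccurrence_g2.tsv"
    if g2_path.exists():
        cooccurrence = {
            p.stem.removeprefix("cooccurrence_"): pd.read_csv(
                p, sep="\t", index_col=0
            )
            for p in sorted(out.glob("cooccurrence_*.tsv"))
        }
    return SimpleNamespace(
        out_dir=out,
        global_ranking=ranking,
        per_hm=per_hm,
        differential=differential,
        validation=validation,
        cooccurrence=cooccurrence,
    )
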