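"""Per-taxon prevalence of the four families.

Aggregates family calls into one row per taxonomic group with counts
for APX / APX-R / APX-L / hybrid / ambiguous and percentages computed
over the classifiable calls (ambiguous excluded from the denominator,
so the four family percentages sum to 100).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .classify import FamilyCall
from .records import ProteinRecord, TAXON_GROUPS

COUNT_COLUMNS = ["n_APX", "n_APX-R", "n_APX-L", "n_hybrid", "n_ambiguous"]
PCT_COLUMNS = ["pct_APX", "pct_APX-R", "pct_APX-L", "pct_hybrid"]
_LABEL_TO_COUNT = {
    "APX": "n_APX",
    "APX-R": "n_APX-R",
    "APX-L": "n_APX-L",
    "hybrid": "n_hybrid",
    "ambiguous": "n_ambiguous",
}


def tabulate(
    calls: list[FamilyCall], records: list[ProteinRecord]
) -> pd.DataFrame:
    """Build the prevalence table: one row per taxon group present.

    Rows appear in the fixed taxon order (rhodophytes ... angiosperms,
    other).  Percentages are computed over non-ambiguous calls and
    rounded to one decimal; a group whose calls are all ambiguous gets
    NA percentages.  A call whose seq_id is absent from *records* is an
    error.
    """
    return tabulate_labels(
        [(c.seq_id, c.label) for c in calls],
        {rec.seq_id: rec.taxon_group for rec in records},
    )


def tabulate_labels(
    calls: list[tuple[str, str]], taxon_of: dict[str, str]
) -> pd.DataFrame:
    """Frame-level core of :func:`tabulate`: (seq_id, label) pairs plus a
    seq_id -> taxon_group mapping."""
    counts: dict[str, dict[str, int]] = {}
    for seq_id, label in calls:
        if seq_id not in taxon_of:
            raise ValueError(f"call {seq_id!r} has no matching record")
        row = counts.setdefault(taxon_of[seq_id], {c: 0 for c in COUNT_COLUMNS})
        row[_LABEL_TO_COUNT[label]] += 1

    out_rows = []
    for group in TAXON_GROUPS:
        if group not in counts:
            continue
        row = counts[group]
        n_total = sum(row.values())
        n_classified = n_total - row["n_ambiguous"]
        entry: dict[str, object] = {"taxon_group": group, "n_total": n_total, **row}
        for count_col, pct_col in zip(COUNT_COLUMNS[:4], PCT_COLUMNS):
            entry[pct_col] = (
                round(100.0 * row[count_col] / n_classified, 1)
                if n_classified
                else pd.NA
            )
        out_rows.append(entry)
    columns = ["taxon_group", "n_total"] + COUNT_COLUMNS + PCT_COLUMNS
    return pd.DataFrame(out_rows, columns=columns)


def write_prevalence(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def plot_prevalence(table: pd.DataFrame, path: str | Path) -> None:
    """Stacked-bar figure of family percentages per taxon group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {  # family colour code used throughout the field's figures
        "pct_APX": "#7b4fa6",  # purple
        "pct_APX-R": "#e6872e",  # orange
        "pct_APX-L": "#4fc3d9",  # cyan
        "pct_hybrid": "#5aa02c",  # green
    }
    plotted = table.dropna(subset=PCT_COLUMNS)
    fig, ax = plt.subplots(figsize=(7, 4))
    bottom = [0.0] * len(plotted)
    for col in PCT_COLUMNS:
        values = plotted[col].astype(float).tolist()
        ax.bar(
            plotted["taxon_group"],
            values,
            bottom=bottom,
            label=col.removeprefix("pct_"),
            color=colors[col],
        )
        bottom = [b + v for b, v in zip(bottom, values)]
    ax.set_ylabel("% of classifiable sequences")
    ax.legend(fontsize=8)
    plt.xticks(rotation=30, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
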