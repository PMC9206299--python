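"""Genotype-differential hit ranking across a compound panel.

The screen pairs an anchor compound (here EZH2 inhibition) with each
panel compound in every cell line; per-condition synergy scores are
summarized over replicates, averaged per genotype (unweighted over cell
lines), and compounds are ranked by the difference

    mean score in deficient lines - mean score in proficient lines,

descending — the computation behind a genotype-differential hit map.  A
hit is a top-ranked compound whose deficient-genotype mean score also
clears the >15 synergy threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from synletscreen.bliss import SYNERGY_THRESHOLD, replicate_summary, score_matrix
from synletscreen.errors import GroupingError, IncompleteGridError
from synletscreen.screen_model import GROUP_KEYS, assemble_matrices, validate_records


@dataclass
class ScreenResult:
    """Per-condition synergy summaries plus completeness QC for one screen.

    ``summaries`` has one row per (compound, cell line) with columns
    compound, cell_line, genotype, mean_score, sd_score, n_replicates.
    ``qc`` lists skipped conditions with the reason; nothing is silently
    dropped.
    """

    summaries: pd.DataFrame
    qc: list[dict] = field(default_factory=list)

    @property
    def genotype_map(self) -> dict[str, str]:
        return dict(
            self.summaries[["cell_line", "genotype"]].drop_duplicates().itertuples(index=False)
        )


@dataclass
class DifferentialRanking:
    """Compound ranking by deficient-minus-proficient mean synergy score.

    ``table`` columns: compound, mean_deficient, mean_proficient,
    difference, rank (1 = largest difference), hit.  ``excluded`` lists
    compounds missing a genotype entirely.
    """

    table: pd.DataFrame
    excluded: list[str] = field(default_factory=list)


def score_screen(
    records: pd.DataFrame,
    *,
    domain: str = "combinations_only",
    clip: bool = True,
    expected_shape: tuple[int, int] | None = (6, 6),
) -> ScreenResult:
    """Assemble, delta-score, and replicate-summarize every screen condition.

    ``records`` is the canonical normalized long table.  Conditions whose
    grid cannot be assembled are skipped with a QC entry rather than
    aborting the screen.
    """
    records = validate_records(records)
    rows, qc = [], []
    for (compound, cell_line), grp in records.groupby(["compound_b", "cell_line"], sort=False):
        try:
            matrices = assemble_matrices(grp, expected_shape=expected_shape)
        except IncompleteGridError as exc:
            qc.append({"compound": compound, "cell_line": cell_line, "reason": str(exc)})
            continue
        results = [score_matrix(m, domain=domain, clip=clip) for m in matrices]
        summary = replicate_summary(results)
        rows.append(
            {
                "compound": compound,
                "cell_line": cell_line,
                "genotype": matrices[0].genotype,
                "mean_score": summary.mean_score,
                "sd_score": summary.sd_score,
                "n_replicates": summary.n_replicates,
            }
        )
    return ScreenResult(summaries=pd.DataFrame(rows), qc=qc)


def genotype_difference_ranking(
    s: ScreenResult, *, hit_threshold: float = SYNERGY_THRESHOLD
) -> DifferentialRanking:
    """Rank compounds by genotype difference in mean synergy score.

    Per compound, cell-line summaries are averaged (unweighted) within
    each genotype; the difference deficient - proficient sorts the table
    descending.  Ties break by higher deficient mean, then by compound
    name.  Compounds lacking one genotype are excluded and reported.  The
    hit flag marks rank-1 compound(s, including exact rank-1 ties) whose
    deficient mean exceeds ``hit_threshold``.
    """
    if s.summaries.empty:
        raise GroupingError("screen result has no scored conditions")
    per_geno = (
        s.summaries.groupby(["compound", "genotype"])["mean_score"].mean().unstack("genotype")
    )
    excluded = per_geno.index[per_geno.isna().any(axis=1)].tolist()
    per_geno = per_geno.dropna()
    if per_geno.empty:
        raise GroupingError("no compound has scores in both genotypes")
    for g in ("deficient", "proficient"):
        if g not in per_geno.columns:
            raise GroupingError(f"no cell line labeled {g!r} in the screen")
    table = pd.DataFrame(
        {
            "compound": per_geno.index,
            "mean_deficient": per_geno["deficient"].to_numpy(),
            "mean_proficient": per_geno["proficient"].to_numpy(),
        }
    )
    table["difference"] = table["mean_deficient"] - table["mean_proficient"]
    table = table.sort_values(
        ["difference", "mean_deficient", "compound"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    top_diff = table["difference"].iloc[0]
    table["hit"] = (table["difference"] == top_diff) & (table["mean_deficient"] > hit_threshold)
    return DifferentialRanking(table=table, excluded=excluded)


def plot_ranking_heatmap(s: ScreenResult, ranking: DifferentialRanking, path) -> None:
    """Scores heatmap: compounds (rows, ordered by difference) x cell lines
    (columns, grouped deficient then proficient)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    geno = s.genotype_map
    lines = sorted(geno, key=lambda cl: (geno[cl] != "deficient", cl))
    compounds = ranking.table["compound"].tolist()
    grid = (
        s.summaries.pivot(index="compound", columns="cell_line", values="mean_score")
        .reindex(index=compounds, columns=lines)
        .to_numpy()
    )
    fig, ax = plt.subplots(figsize=(4.5, 0.28 * len(compounds) + 1.5))
    im = ax.imshow(grid, cmap="RdYlGn_r", aspect="auto")
    ax.set_xticks(range(len(lines)), lines, rotation=45, ha="right")
    ax.set_yticks(range(len(compounds)), compounds, fontsize=7)
    fig.colorbar(im, ax=ax, label="mean synergy score")
    ax.set_title("Synergy by genotype difference")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
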