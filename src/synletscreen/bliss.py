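"""Bliss-independence synergy scoring of combination dose matrices.

Under Bliss independence two inhibitors acting as independent
probabilistic events produce the expected combined inhibition

    alpha_exp = alpha_A + alpha_B - alpha_A * alpha_B.

The excess of the observed combination effect over this null,
``delta = alpha_obs - alpha_exp``, is computed cell by cell over the dose
matrix using the matrix's own single-agent edge row/column as alpha_A and
alpha_B.  The scalar synergy score is 100x the mean delta — by default
over the 25 cells where both drugs are present (the edge cells are
identically zero by construction and would only dilute the mean) — and a
score strictly above 15 points is called synergistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from synletscreen.errors import GroupingError, ScreenError
from synletscreen.screen_model import CombinationMatrix, effect_matrix

#: Score (percentage points) strictly above which an interaction is synergistic.
SYNERGY_THRESHOLD = 15.0

AGGREGATION_DOMAINS = ("combinations_only", "full_matrix")


@dataclass
class SynergyResult:
    """Delta matrix and (optionally) aggregated score for one dose matrix."""

    delta: np.ndarray
    conc_a: np.ndarray
    conc_b: np.ndarray
    cell_line: str
    genotype: str
    compound_a: str
    compound_b: str
    replicate: int
    score: float | None = None
    aggregation_domain: str | None = None
    synergistic: bool | None = None

    def metadata(self) -> dict:
        return {
            "cell_line": self.cell_line,
            "genotype": self.genotype,
            "compound_a": self.compound_a,
            "compound_b": self.compound_b,
            "replicate": self.replicate,
        }


@dataclass
class SynergySummary:
    """Replicate mean +/- sample SD of a condition's synergy scores."""

    mean_score: float
    sd_score: float | None
    n_replicates: int


def bliss_expected(alpha_a, alpha_b):
    """Bliss-expected combined inhibition of two independent effects.

    Accepts scalars or arrays; symmetric in its arguments; (0, x) -> x and
    (1, x) -> 1 (an absorbing full effect).
    """
    alpha_a = np.asarray(alpha_a, dtype=float)
    alpha_b = np.asarray(alpha_b, dtype=float)
    if not (np.all(np.isfinite(alpha_a)) and np.all(np.isfinite(alpha_b))):
        raise ValueError("non-finite single-agent effect")
    out = alpha_a + alpha_b - alpha_a * alpha_b
    return float(out) if out.ndim == 0 else out


def delta_matrix(m: CombinationMatrix, *, clip: bool = True) -> SynergyResult:
    """Observed-minus-expected effect for every cell of a dose matrix.

    Single-agent effects are taken from the matrix's own edges (row with
    conc_b = 0 and column with conc_a = 0), so edge cells evaluate to 0 by
    construction.  If the effect grid is absent it is derived first with
    ``effect_matrix(m, clip)``.
    """
    if m.effect is None:
        m = effect_matrix(m, clip=clip)
    eff = m.effect
    alpha_a = eff[:, 0][:, None]  # compound A alone, down the rows
    alpha_b = eff[0, :][None, :]  # compound B alone, across the columns
    delta = eff - bliss_expected(alpha_a, alpha_b)
    return SynergyResult(
        delta=delta, conc_a=m.conc_a, conc_b=m.conc_b, **m.metadata()
    )


def synergy_score(r: SynergyResult, domain: str = "combinations_only") -> SynergyResult:
    """Aggregate a delta matrix to the scalar score (percentage points).

    ``combinations_only`` averages the cells where both concentrations are
    positive (25 of 36 in the standard design); ``full_matrix`` averages
    all cells including the identically-zero edges.  ``synergistic`` is
    True iff score > 15 strictly.
    """
    if domain not in AGGREGATION_DOMAINS:
        raise ScreenError(f"unknown aggregation domain {domain!r}")
    if domain == "combinations_only":
        cells = r.delta[1:, 1:]
    else:
        cells = r.delta
    if cells.size == 0:
        raise ScreenError("empty aggregation domain")
    score = 100.0 * float(np.mean(cells))
    r.score = score
    r.aggregation_domain = domain
    r.synergistic = score > SYNERGY_THRESHOLD
    return r


def score_matrix(
    m: CombinationMatrix, *, domain: str = "combinations_only", clip: bool = True
) -> SynergyResult:
    """Convenience: ``synergy_score(delta_matrix(m))`` in one call."""
    return synergy_score(delta_matrix(m, clip=clip), domain=domain)


def replicate_summary(results: list[SynergyResult]) -> SynergySummary:
    """Mean and sample SD (n-1) of per-replicate scores for one condition.

    All results must share (cell line, compound pair); the SD is reported
    as None for a single replicate.
    """
    if not results:
        raise GroupingError("no replicates to summarize")
    meta = {k: v for k, v in results[0].metadata().items() if k != "replicate"}
    for r in results[1:]:
        other = {k: v for k, v in r.metadata().items() if k != "replicate"}
        if other != meta:
            raise GroupingError(f"mixed metadata in replicate group: {meta} vs {other}")
    scores = [r.score for r in results]
    if any(s is None for s in scores):
        raise GroupingError("all results must be scored before summarizing")
    mean = float(np.mean(scores))
    sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else None
    return SynergySummary(mean_score=mean, sd_score=sd, n_replicates=len(scores))


def plot_synergy_heatmap(m: CombinationMatrix, path, *, annotate: bool = True):
    """Write a percent-growth-inhibition heatmap for one dose matrix.

    Diverging red/green map: red marks stronger inhibition, green lower
    inhibition, mirroring standard combination-screen heatmaps.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mm = effect_matrix(m) if m.effect is None else m
    inhibition = 100.0 * mm.effect
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(inhibition, cmap="RdYlGn_r", vmin=0, vmax=100, origin="lower")
    ax.set_xticks(range(len(m.conc_b)), [f"{c:g}" for c in m.conc_b])
    ax.set_yticks(range(len(m.conc_a)), [f"{c:g}" for c in m.conc_a])
    ax.set_xlabel(f"{m.compound_b} (uM)")
    ax.set_ylabel(f"{m.compound_a} (uM)")
    ax.set_title(f"{m.cell_line} growth inhibition (%)")
    if annotate:
        for i in range(inhibition.shape[0]):
            for j in range(inhibition.shape[1]):
                ax.text(j, i, f"{inhibition[i, j]:.0f}", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="inhibition (%)  red = stronger")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
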