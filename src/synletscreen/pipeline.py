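"""One-command screen reproduction: normalize -> matrices -> synergy -> ranking.

Manifest-first design: every run writes a machine-readable
``manifest.json`` (package version, seed, parameters, QC tallies) next to
its TSV outputs so downstream checks diff outputs, not logs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import synletscreen
from synletscreen.differential import genotype_difference_ranking, plot_ranking_heatmap, score_screen
from synletscreen.errors import ScreenError
from synletscreen.screen_model import normalize_viability, parse_screen_table


@dataclass
class RunConfig:
    """Configuration of a full screen analysis run."""

    input_path: str
    out_dir: str
    value_kind: str = "normalized"
    unit: str = "uM"
    domain: str = "combinations_only"
    clip: bool = True
    expected_shape: tuple[int, int] | None = (6, 6)
    heatmap: bool = False
    seed: int | None = None  # recorded in the manifest for generated inputs

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ScreenError(f"unknown run-config key(s): {sorted(unknown)}")
        if "expected_shape" in raw and raw["expected_shape"] is not None:
            raw["expected_shape"] = tuple(raw["expected_shape"])
        return cls(**raw)


def run_full_screen(config: RunConfig) -> dict:
    """Run the full analysis path and write the report bundle.

    Outputs in ``config.out_dir``: ``scores.tsv`` (per-condition replicate
    summaries), ``ranking.tsv`` (genotype-differential compound ranking),
    ``qc.tsv`` (skipped conditions), ``manifest.json``, and optionally a
    ranking heatmap PNG.  Returns the manifest dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = parse_screen_table(config.input_path, unit=config.unit, value_kind=config.value_kind)
    if (records["value_kind"] == "raw").any():
        records = normalize_viability(records)
    screen = score_screen(
        records, domain=config.domain, clip=config.clip, expected_shape=config.expected_shape
    )
    ranking = genotype_difference_ranking(screen)

    screen.summaries.to_csv(out / "scores.tsv", sep="\t", index=False)
    ranking.table.to_csv(out / "ranking.tsv", sep="\t", index=False)
    pd.DataFrame(screen.qc).to_csv(out / "qc.tsv", sep="\t", index=False)
    if config.heatmap:
        plot_ranking_heatmap(screen, ranking, out / "ranking_heatmap.png")

    manifest = {
        "package": "synletscreen",
        "version": synletscreen.__version__,
        "seed": config.seed,
        "parameters": {
            "input_path": str(config.input_path),
            "value_kind": config.value_kind,
            "unit": config.unit,
            "domain": config.domain,
            "clip": config.clip,
            "expected_shape": list(config.expected_shape) if config.expected_shape else None,
        },
        "n_conditions": int(len(screen.summaries)),
        "n_compounds_ranked": int(len(ranking.table)),
        "excluded_compounds": ranking.excluded,
        "qc": {"skipped_conditions": len(screen.qc)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
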