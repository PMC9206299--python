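"""Ground-truth generators emulating every input of the screen pipeline.

Every generator is a pure function of its spec and a mandatory seed:

* :func:`gen_screen` — normalized 6x6 combination-viability tables on a
  multiplicative (Bliss-null) surface with configurable injected synergy
  and Gaussian viability noise;
* :func:`gen_dose_response_curve` — 4PL single-agent curves on the
  screen's 10-point two-fold ladder (20 nM - 20 uM);
* :func:`gen_foci_image` — two-channel microscopy fields with
  disc-shaped nuclei and point-like planted foci plus a ground-truth
  table;
* :func:`gen_growth_trajectories` — exponential tumor-volume series with
  per-arm growth rates rendered as caliper (length, width) pairs.

The default screen panel mirrors a four-cell-line (two per genotype),
27-compound design with an EZH2-inhibitor anchor, so bookkeeping matches
the study scale the package targets; the default viability noise sigma
of 0.05 is of the order of the replicate scatter such screens report on
the score scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from synletscreen.dose_response import SCREEN_CONCENTRATIONS_UM, DoseResponseProfile, logistic4
from synletscreen.errors import ConfigurationError
from synletscreen.imaging import FociImage
from synletscreen.screen_model import validate_records
from synletscreen.survival import TumorTrajectory

#: Default cell-line panel: two BRCA1-deficient clones, two proficient.
DEFAULT_CELL_LINES = {
    "KB1P-G3": "deficient",
    "KB1P-B11": "deficient",
    "KP-3.33": "proficient",
    "KP-6.3": "proficient",
}

#: Anchor-compound (EZH2 inhibitor) IC50s per cell line, uM — the 3-11x
#: genotype sensitivity gap the screen design exploits.
DEFAULT_ANCHOR_IC50_UM = {
    "KB1P-G3": 13.4,
    "KB1P-B11": 17.6,
    "KP-3.33": 44.9,
    "KP-6.3": 148.9,
}


@dataclass
class ScreenSpec:
    """Design of a synthetic combination screen.

    ``injected`` maps (compound, cell line) or (compound, genotype) to the
    delta added to combination-cell inhibition (fraction scale, in
    [-1, 1]); a cell-line key wins over a genotype key.  ``sigma`` is the
    additive Gaussian viability noise, truncated so viability stays
    nonnegative.  ``anchor`` is compound A on every plate.
    """

    seed: int
    cell_lines: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CELL_LINES))
    compounds: tuple[str, ...] = tuple(f"CMP-{i:02d}" for i in range(1, 28))
    anchor: str = "GSK126"
    injected: dict[tuple[str, str], float] = field(default_factory=dict)
    sigma: float = 0.05
    replicates: int = 1
    n_concentrations: int = 5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        for key, delta in self.injected.items():
            if not -1.0 <= delta <= 1.0:
                raise ConfigurationError(f"injected delta {delta} for {key} outside [-1, 1]")
        bad_geno = set(self.cell_lines.values()) - {"deficient", "proficient"}
        if bad_geno:
            raise ConfigurationError(f"unknown genotype label(s): {sorted(bad_geno)}")

    def injected_delta(self, compound: str, cell_line: str) -> float:
        if (compound, cell_line) in self.injected:
            return self.injected[(compound, cell_line)]
        return self.injected.get((compound, self.cell_lines[cell_line]), 0.0)


def _ladder(center_um: float, n: int) -> np.ndarray:
    """Two-fold-spaced concentration ladder titrated around a center.

    The center is clipped so the whole ladder stays inside the screen's
    0.02-20 uM range without creating duplicate rungs.
    """
    half = (n - 1) / 2.0
    exponents = np.linspace(-half / 2.0, half / 2.0, n)
    center_um = float(np.clip(center_um, 0.02 * 2.0 ** (-exponents[0]), 20.0 * 2.0 ** (-exponents[-1])))
    return center_um * 2.0**exponents


def _potencies(spec: ScreenSpec, rng: np.random.Generator) -> dict:
    """Seeded 4PL parameters per (compound, cell line).

    Plateaus sit in [0.45, 0.6] and hills in [1, 1.8]: shallow
    partial-response curves typical of a 72-h viability screen titrated
    around the IC50, which also keeps the multiplicative null surface
    comfortably positive so injected deltas up to 0.25 survive the >= 0
    viability floor unclipped.
    """
    params = {}
    for cell_line in spec.cell_lines:
        ic = DEFAULT_ANCHOR_IC50_UM.get(cell_line, float(rng.uniform(5.0, 50.0)))
        params[(spec.anchor, cell_line)] = {
            "top": 1.0, "bottom": float(rng.uniform(0.45, 0.6)),
            "ic50": ic, "hill": float(rng.uniform(1.0, 1.8)),
        }
    for compound in spec.compounds:
        base_ic = float(10.0 ** rng.uniform(-1.0, 1.2))  # 0.1 - 16 uM
        for cell_line in spec.cell_lines:
            params[(compound, cell_line)] = {
                "top": 1.0, "bottom": float(rng.uniform(0.45, 0.6)),
                "ic50": base_ic * float(10.0 ** rng.uniform(-0.15, 0.15)),
                "hill": float(rng.uniform(1.0, 1.8)),
            }
    return params


def gen_screen(spec: ScreenSpec) -> pd.DataFrame:
    """Generate a normalized combination-screen long table.

    Viability is multiplicative in the single-agent responses,
    ``v[i, j] = v_a[i] * v_b[j] - delta * [i>0][j>0] + noise``, clipped at
    0, with the single-agent responses sampled from seeded 4PL potencies
    on per-compound ladders titrated around the IC50.  The vehicle cell is
    1 + noise.  Deterministic for a fixed spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    params = _potencies(spec, rng)
    n = spec.n_concentrations
    rows = []
    # anchor ladder: shared across cell lines, centered on the geometric
    # mean anchor IC50 (a plate design is one ladder for all lines)
    anchor_center = float(
        np.exp(np.mean([np.log(params[(spec.anchor, cl)]["ic50"]) for cl in spec.cell_lines]))
    )
    conc_a = np.concatenate([[0.0], _ladder(anchor_center, n)])
    for compound in spec.compounds:
        center = float(
            np.exp(np.mean([np.log(params[(compound, cl)]["ic50"]) for cl in spec.cell_lines]))
        )
        conc_b = np.concatenate([[0.0], _ladder(center, n)])
        for cell_line, genotype in spec.cell_lines.items():
            pa = params[(spec.anchor, cell_line)]
            pb = params[(compound, cell_line)]
            va = np.concatenate([[1.0], logistic4(conc_a[1:], **pa)])
            vb = np.concatenate([[1.0], logistic4(conc_b[1:], **pb)])
            delta = spec.injected_delta(compound, cell_line)
            base = np.outer(va, vb)
            base[1:, 1:] -= delta
            for rep in range(1, spec.replicates + 1):
                noise = rng.normal(0.0, spec.sigma, base.shape) if spec.sigma > 0 else 0.0
                viability = np.clip(base + noise, 0.0, None)
                ai, bj = np.meshgrid(range(n + 1), range(n + 1), indexing="ij")
                rows.append(
                    pd.DataFrame(
                        {
                            "cell_line": cell_line,
                            "genotype": genotype,
                            "compound_a": spec.anchor,
                            "compound_b": compound,
                            "conc_a": conc_a[ai.ravel()],
                            "conc_b": conc_b[bj.ravel()],
                            "replicate": rep,
                            "value": viability.ravel(),
                            "value_kind": "normalized",
                        }
                    )
                )
    return validate_records(pd.concat(rows, ignore_index=True))


def gen_dose_response_curve(
    *,
    ic50: float,
    hill: float = 1.0,
    top: float = 1.0,
    bottom: float = 0.0,
    concentrations: np.ndarray = SCREEN_CONCENTRATIONS_UM,
    sigma: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    compound: str = "compound",
    cell_line: str = "cell-line",
) -> DoseResponseProfile:
    """Sample a 4PL curve at a concentration ladder with Gaussian noise."""
    if hill == 0:
        raise ConfigurationError("hill must be nonzero")
    conc = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    clean = logistic4(conc, top, bottom, ic50, hill)
    v = np.tile(clean, (replicates, 1))
    if sigma > 0:
        v = v + rng.normal(0.0, sigma, v.shape)
    v = np.clip(v, 0.0, None)
    if replicates == 1:
        v = v[0]
    return DoseResponseProfile(conc, v, compound=compound, cell_line=cell_line)


def gen_foci_image(
    *,
    n_nuclei: int = 5,
    foci_per_nucleus: int = 3,
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.65,
    nucleus_area_um2: float = 400.0,
    nucleus_intensity: float = 2000.0,
    nuclear_base: float = 100.0,
    foci_diffuse: float = 600.0,
    foci_amplitude: float = 3000.0,
    focus_sigma_px: float = 1.2,
    background_slope: float = 0.0,
    noise: str | None = None,
    noise_sigma: float = 0.0,
    n_undersized: int = 0,
    undersized_area_um2: float = 50.0,
    n_oversized_foci: int = 0,
    oversized_focus_area_um2: float = 40.0,
    min_separation_px: float = 10.0,
    seed: int = 0,
    field_id: str = "field-1",
    condition: str = "synthetic",
) -> tuple[FociImage, dict[str, pd.DataFrame]]:
    """Synthesize a two-channel field with known nuclei and planted foci.

    Nuclei are non-overlapping uniform discs in the nuclear channel; the
    focus channel carries a diffuse nuclear signal plus Gaussian point
    foci planted well inside each disc with a minimum pairwise separation
    so they stay resolvable.  ``background_slope`` adds a planar gradient
    to both channels (exercises background correction); ``noise`` is None,
    ``"gaussian"`` (additive, ``noise_sigma``) or ``"poisson"`` (counts).
    Undersized nuclei and oversized foci can be planted to exercise the
    acceptance windows; the ground truth flags them ``expected_retained
    = False``.

    Returns the image and ``{"nuclei": ..., "foci": ...}`` ground-truth
    tables (positions in pixels, areas in um^2).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    nuclear = np.full(shape, nuclear_base, dtype=float)
    foci_chan = np.full(shape, nuclear_base / 2.0, dtype=float)

    radius_px = np.sqrt(nucleus_area_um2 / np.pi) / pixel_size
    small_radius_px = np.sqrt(undersized_area_um2 / np.pi) / pixel_size

    # rejection-sample non-overlapping centers with an image margin
    centers: list[tuple[float, float, float]] = []  # (y, x, radius)
    todo = [(radius_px, True)] * n_nuclei + [(small_radius_px, False)] * n_undersized
    for r, _ in todo:
        for _attempt in range(10000):
            cy = rng.uniform(r + 8, h - r - 8)
            cx = rng.uniform(r + 8, w - r - 8)
            if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr + 6) ** 2 for y, x, rr in centers):
                centers.append((cy, cx, r))
                break
        else:
            raise ConfigurationError("could not place non-overlapping nuclei; reduce n_nuclei")

    nuc_rows, foci_rows = [], []
    focus_margin = 6.0  # px inside the nucleus edge, keeps the box window interior
    for idx, ((cy, cx, r), (_, full_size)) in enumerate(zip(centers, todo), start=1):
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        nuclear[mask] += nucleus_intensity
        foci_chan[mask] += foci_diffuse
        nuc_rows.append(
            {
                "nucleus_id": idx,
                "cy": cy,
                "cx": cx,
                "radius_px": r,
                "area_um2": np.pi * (r * pixel_size) ** 2,
                "expected_retained": bool(full_size),
            }
        )
        if not full_size:
            continue
        n_spots = foci_per_nucleus + (n_oversized_foci if idx == 1 else 0)
        spot_extent = max(3.0 * focus_sigma_px, 3.6)
        over_extent = np.sqrt(oversized_focus_area_um2 / np.pi) / pixel_size
        # oversized blobs first so point foci keep clear of their plateaus;
        # dart-throwing with whole-set restarts so a bad early draw cannot
        # deadlock a dense packing
        kinds = [True] * (n_spots - foci_per_nucleus) + [False] * foci_per_nucleus
        placed: list[tuple[float, float, float]] = []
        for _restart in range(500):
            placed = []
            for oversized in kinds:
                ext = over_extent if oversized else spot_extent
                for _attempt in range(200):
                    rho = max(r - focus_margin - (ext - spot_extent), 1.0) * np.sqrt(rng.uniform())
                    ang = rng.uniform(0, 2 * np.pi)
                    fy, fx = cy + rho * np.sin(ang), cx + rho * np.cos(ang)
                    sep_ok = all(
                        (fy - y) ** 2 + (fx - x) ** 2
                        > max(min_separation_px, ext + e + 3.0) ** 2
                        for y, x, e in placed
                    )
                    if sep_ok:
                        placed.append((fy, fx, ext))
                        break
                else:
                    break
            if len(placed) == n_spots:
                break
        else:
            raise ConfigurationError("could not place separated foci; reduce foci_per_nucleus")
        for oversized, (fy, fx, _ext) in zip(kinds, placed):
            if oversized:
                fr = np.sqrt(oversized_focus_area_um2 / np.pi) / pixel_size
                fmask = (yy - fy) ** 2 + (xx - fx) ** 2 <= fr**2
                foci_chan[fmask] += foci_amplitude
            else:
                dist2 = (yy - fy) ** 2 + (xx - fx) ** 2
                foci_chan += foci_amplitude * np.exp(-dist2 / (2 * focus_sigma_px**2)) * (
                    dist2 <= (6 * focus_sigma_px) ** 2
                )
            foci_rows.append(
                {
                    "nucleus_id": idx,
                    "y": fy,
                    "x": fx,
                    "amplitude": foci_amplitude,
                    "expected_retained": not oversized,
                }
            )

    if background_slope:
        ramp = background_slope * (xx / max(w - 1, 1) + 0.5 * yy / max(h - 1, 1))
        nuclear += ramp
        foci_chan += ramp
    if noise == "gaussian":
        nuclear = np.clip(nuclear + rng.normal(0, noise_sigma, shape), 0, None)
        foci_chan = np.clip(foci_chan + rng.normal(0, noise_sigma, shape), 0, None)
    elif noise == "poisson":
        nuclear = rng.poisson(np.clip(nuclear, 0, None)).astype(float)
        foci_chan = rng.poisson(np.clip(foci_chan, 0, None)).astype(float)
    elif noise is not None:
        raise ConfigurationError(f"unknown noise model {noise!r}")

    image = FociImage(
        nuclear_channel=nuclear, foci_channel=foci_chan,
        pixel_size=pixel_size, field_id=field_id, condition=condition,
    )
    truth = {"nuclei": pd.DataFrame(nuc_rows), "foci": pd.DataFrame(foci_rows)}
    return image, truth


#: Reference synergy scores (percentage points) built into the stand-in
#: screen of :func:`gen_reference_screen_standin`.
REFERENCE_STANDIN_SCORES = {"KB1P-G3": 26.6, "KB1P-B11": 22.9}


def gen_reference_screen_standin(seed: int = 0) -> pd.DataFrame:
    """Synthetic stand-in for a published normalized-viability supplement.

    The real supplementary viability matrices behind the reference
    ATM-inhibitor synergy scores are not redistributable here, so this
    noise-free screen in the same long-table layout injects
    construction-known combination deltas of 0.266 and 0.229 for AZD1390
    in the two BRCA1-deficient lines (and none elsewhere): a correct
    normalization -> delta -> score path must therefore return 26.6 and
    22.9 on the percentage scale.  Synthetic data; exercises the format
    and the arithmetic, not the unpublished measurements.
    """
    injected = {
        ("AZD1390", line): score / 100.0 for line, score in REFERENCE_STANDIN_SCORES.items()
    }
    spec = ScreenSpec(
        seed=seed,
        sigma=0.0,
        compounds=("AZD1390", "KU60019", "CMP-03"),
        injected=injected,
    )
    return gen_screen(spec)


def poisson_amplitude_for_snr(snr: float, base: float) -> float:
    """Focus amplitude giving a peak signal-to-noise ratio ``snr`` under
    Poisson counting noise on a local background of ``base`` counts.

    Solves ``A = snr * sqrt(base + A)`` (the noise at the spot peak
    includes the spot's own shot noise).
    """
    return float((snr**2 + snr * np.sqrt(snr**2 + 4.0 * base)) / 2.0)


def detection_f1(
    records: list, truth_foci: pd.DataFrame, *, tol_px: float = 4.0
) -> tuple[float, int, int, int]:
    """Match detected focus centroids to planted positions; return (F1, TP, FP, FN).

    Greedy nearest-neighbor matching within ``tol_px``; only ground-truth
    foci flagged ``expected_retained`` count as positives.
    """
    detected = [(y, x) for r in records for (y, x) in r.positions]
    truth = truth_foci[truth_foci["expected_retained"]]
    true_pos = list(zip(truth["y"], truth["x"]))
    used = [False] * len(true_pos)
    tp = 0
    for dy, dx in detected:
        best, best_d2 = None, tol_px**2
        for i, (ty, tx) in enumerate(true_pos):
            if used[i]:
                continue
            d2 = (dy - ty) ** 2 + (dx - tx) ** 2
            if d2 <= best_d2:
                best, best_d2 = i, d2
        if best is not None:
            used[best] = True
            tp += 1
    fp = len(detected) - tp
    fn = len(true_pos) - tp
    f1 = 2.0 * tp / (2.0 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    return f1, tp, fp, fn


def gen_growth_trajectories(
    *,
    n_per_arm: int = 8,
    growth_rates: dict[str, float] | None = None,
    measurement_days: np.ndarray | None = None,
    initial_volume_mm3: float = 100.0,
    sigma_log: float = 0.1,
    aspect_ratio: float = 1.3,
    censoring: dict[str, list[tuple[int, float, str]]] | None = None,
    seed: int = 0,
) -> list[TumorTrajectory]:
    """Exponential tumor growth rendered as caliper (length, width) series.

    Volume follows ``V(day) = V0 * exp(r * day)`` with multiplicative
    lognormal measurement noise (``sigma_log`` on the log scale) and is
    rendered as length = aspect * width with ``V = 0.5 * L * W^2``.
    Default arms: a vehicle arm at r = 0.11 / day (10x RTV around day 21)
    and a treated arm at half that rate; measurements twice weekly from
    day 0 through day 60.  ``censoring`` maps arm -> list of (animal
    index, day, reason) removals.  Deterministic per seed.
    """
    if growth_rates is None:
        growth_rates = {"vehicle": 0.11, "combination": 0.055}
    if measurement_days is None:
        measurement_days = np.array(
            [0, 3, 7, 10, 14, 17, 21, 24, 28, 31, 35, 38, 42, 45, 49, 52, 56, 60], dtype=float
        )
    rng = np.random.default_rng(seed)
    censoring = censoring or {}
    out = []
    for arm, rate in growth_rates.items():
        removals = {idx: (day, reason) for idx, day, reason in censoring.get(arm, [])}
        for i in range(n_per_arm):
            days = np.asarray(measurement_days, dtype=float)
            censor_day, censor_reason = removals.get(i, (None, None))
            if censor_day is not None:
                days = days[days <= censor_day]
            noise = rng.normal(0.0, sigma_log, days.size) if sigma_log > 0 else np.zeros(days.size)
            noise[0] = 0.0  # day-0 volume is the (exact) baseline
            vols = initial_volume_mm3 * np.exp(rate * days) * np.exp(noise)
            widths = (2.0 * vols / aspect_ratio) ** (1.0 / 3.0)
            lengths = aspect_ratio * widths
            out.append(
                TumorTrajectory(
                    animal=f"{arm}-{i + 1:02d}", arm=arm,
                    days=days, lengths_mm=lengths, widths_mm=widths,
                    censor_day=censor_day, censor_reason=censor_reason,
                )
            )
    return out


def trajectories_to_table(trajectories: list[TumorTrajectory]) -> pd.DataFrame:
    """Long caliper table (animal, arm, day, length_mm, width_mm, censor_*)."""
    rows = []
    for t in trajectories:
        for day, length, width in zip(t.days, t.lengths_mm, t.widths_mm):
            rows.append(
                {
                    "animal": t.animal, "arm": t.arm, "day": day,
                    "length_mm": length, "width_mm": width,
                    "censor_day": t.censor_day, "censor_reason": t.censor_reason,
                }
            )
    return pd.DataFrame(rows)
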