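"""End-to-end in-silico replication of the method-agreement study design.

Two emulated observers measure every synthetic field twice (timepoints T1,
T2) with both estimators:

* digital count (DC): each observer-timepoint samples its own reference
  color — the true stain color plus a small RGB jitter, standing in for the
  human eyedropper step — and applies a fuzziness-100 color-range selection
  saved once and reused across all fields;
* manual count (MC): the 594-point systematic grid read against the ground
  truth mask, with a small per-point lapse probability standing in for human
  counting error. A human point-counter distinguishes diffuse haze from true
  stain, which is why the lapse model (rather than a color rule) is the
  default observer here.

The report mirrors the study's agreement tables: intraobserver ICC per
observer and method, interobserver ICC per method and image-quality regime,
Bland–Altman MC-vs-DC per regime, and Pearson correlations. Everything is a
deterministic function of the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agreement import bland_altman, bland_altman_plot, icc_oneway, pearson_r
from .digital import ColorRangeSpec, dc_area_fraction
from .manual import GridSpec, _pixel_indices, build_grid
from .synthetic import DAB_BROWN, generate_study_fixtures

__all__ = ["StudyConfig", "StudyReport", "run_study"]


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of the simulated agreement study.

    Defaults reproduce the study design: 100 GOOD + 100 NOISE fields, two
    observers, two timepoints. ``observer_color_jitter_sd`` (RGB units) and
    ``mc_lapse_prob`` (per-point misclassification probability) inject the
    human variability that makes ICC < 1 and measurable.
    """

    n_good: int = 100
    n_noise: int = 100
    extent: tuple[int, int] = (512, 512)
    fraction_range: tuple[float, float] = (1.0, 30.0)
    noise_intensity: float = 0.5
    grid: GridSpec = dc_field(default_factory=GridSpec)
    fuzziness: float = 100.0
    observer_color_jitter_sd: float = 8.0
    mc_lapse_prob: float = 0.02
    n_observers: int = 2
    n_timepoints: int = 2
    alpha: float = 0.05
    loa_multiplier: float = 1.96
    seed: int = 0
    output_dir: str | None = None
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.n_good < 1 or self.n_noise < 1:
            raise ValueError("n_good and n_noise must be positive")
        if self.n_observers != 2 or self.n_timepoints != 2:
            raise ValueError("the agreement design is defined for 2 observers x 2 timepoints")
        if not (0.0 <= self.mc_lapse_prob < 0.5):
            raise ValueError("mc_lapse_prob must be in [0, 0.5)")

    # -- lossless serialization --------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["extent"] = list(self.extent)
        d["fraction_range"] = list(self.fraction_range)
        d["grid"] = dataclasses.asdict(self.grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        d["extent"] = tuple(d["extent"])
        d["fraction_range"] = tuple(d["fraction_range"])
        d["grid"] = GridSpec(**d["grid"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class StudyReport:
    measurements: pd.DataFrame
    icc_intra: pd.DataFrame
    icc_inter: pd.DataFrame
    bland_altman: pd.DataFrame
    pearson: pd.DataFrame
    summary: dict


def _icc_row(a, b, **labels) -> dict:
    r = icc_oneway((np.asarray(a), np.asarray(b)))
    return {
        **labels,
        "icc": r.icc, "label": r.label, "p_value": r.p_value,
        "variance_between": r.variance_between, "variance_error": r.variance_error,
        "n_subjects": r.n_subjects,
    }


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full simulated agreement study for one master seed."""
    ss = np.random.SeedSequence(config.seed)
    s_fixtures, s_observers, s_lapse = ss.spawn(3)
    fields = generate_study_fixtures(
        config.n_good, config.n_noise,
        seed=int(s_fixtures.generate_state(1)[0] % (2**31)),
        extent=config.extent,
        fraction_range=config.fraction_range,
        noise_intensity=config.noise_intensity,
    )

    # one saved color-range criterion per observer-timepoint (the eyedropper
    # step happens once and the selection is reused across all slides)
    obs_rng = np.random.default_rng(s_observers)
    dc_specs: dict[tuple[int, int], ColorRangeSpec] = {}
    for obs in (1, 2):
        for t in (1, 2):
            jitter = np.rint(obs_rng.normal(0.0, config.observer_color_jitter_sd, size=3))
            ref = tuple(int(v) for v in np.clip(np.asarray(DAB_BROWN) + jitter, 0, 255))
            dc_specs[(obs, t)] = ColorRangeSpec(sampled_colors=(ref,), fuzziness=config.fuzziness)

    grid = build_grid(config.grid, config.extent)
    lapse_rng = np.random.default_rng(s_lapse)

    rows = []
    t_mc = t_dc = 0.0
    r_idx, c_idx = _pixel_indices(grid.points, grid.extent)
    for fld in fields:
        base_hits = fld.truth_mask[r_idx, c_idx]
        for obs in (1, 2):
            for t in (1, 2):
                t0 = time.perf_counter()
                dc_val = dc_area_fraction(fld.image, dc_specs[(obs, t)])
                t1 = time.perf_counter()
                # oracle point reads, then per-point lapses flip a small share
                if config.mc_lapse_prob > 0:
                    flips = lapse_rng.random(len(grid)) < config.mc_lapse_prob
                    mc_val = 100.0 * (base_hits ^ flips).mean()
                else:
                    mc_val = 100.0 * base_hits.mean()
                t2 = time.perf_counter()
                t_dc += t1 - t0
                t_mc += t2 - t1
                for method, value in (("MC", mc_val), ("DC", dc_val)):
                    rows.append(
                        {"field_id": fld.field_id, "regime": fld.regime,
                         "marker": fld.marker, "true_fraction": fld.true_fraction,
                         "method": method, "observer": obs, "timepoint": t,
                         "value": value}
                    )
    meas = pd.DataFrame(rows)

    wide = meas.pivot_table(
        index=["field_id", "regime", "true_fraction"],
        columns=["method", "observer", "timepoint"], values="value",
    )

    icc_intra = pd.DataFrame(
        [
            _icc_row(wide[(m, o, 1)], wide[(m, o, 2)], observer=o, method=m)
            for o in (1, 2)
            for m in ("MC", "DC")
        ]
    )

    inter_rows = []
    for m in ("MC", "DC"):
        for regime in ("GOOD", "NOISE"):
            sub = wide.xs(regime, level="regime")
            a = (sub[(m, 1, 1)] + sub[(m, 1, 2)]) / 2.0
            b = (sub[(m, 2, 1)] + sub[(m, 2, 2)]) / 2.0
            inter_rows.append(_icc_row(a, b, method=m, regime=regime))
    icc_inter = pd.DataFrame(inter_rows)

    ba_rows, pearson_rows, ba_pairs = [], [], {}
    for regime in ("GOOD", "NOISE"):
        sub = wide.xs(regime, level="regime")
        mc_mean = sub["MC"].mean(axis=1).to_numpy()
        dc_mean = sub["DC"].mean(axis=1).to_numpy()
        ba = bland_altman((mc_mean, dc_mean), multiplier=config.loa_multiplier)
        ba_pairs[regime] = (mc_mean, dc_mean)
        ba_rows.append(
            {"regime": regime, "bias": ba.bias, "sd_diff": ba.sd_diff,
             "loa_low": ba.loa_low, "loa_high": ba.loa_high,
             "coverage": ba.coverage, "n": ba.n}
        )
        pearson_rows.append(
            {"regime": regime,
             "r_plain": pearson_r(mc_mean, dc_mean),
             "r_diff_vs_mean": pearson_r(mc_mean, dc_mean, mode="diff_vs_mean")}
        )
    ba_df = pd.DataFrame(ba_rows)
    pearson_df = pd.DataFrame(pearson_rows)

    n_meas = len(fields) * 2 * config.n_observers * config.n_timepoints
    summary = {
        "config": config.to_dict(),
        "n_fields": len(fields),
        "n_measurements": len(meas),
        "icc_intra": icc_intra.to_dict(orient="records"),
        "icc_inter": icc_inter.to_dict(orient="records"),
        "bland_altman": ba_df.to_dict(orient="records"),
        "pearson": pearson_df.to_dict(orient="records"),
        # informational only: wall-clock is hardware-dependent metadata
        "timing_seconds_per_measurement": {
            "MC": t_mc / (n_meas / 2), "DC": t_dc / (n_meas / 2)
        },
    }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        meas.to_csv(out / "measurements.csv", index=False)
        icc_intra.to_csv(out / "icc_intra.csv", index=False)
        icc_inter.to_csv(out / "icc_inter.csv", index=False)
        ba_df.to_csv(out / "bland_altman.csv", index=False)
        pearson_df.to_csv(out / "pearson.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        if config.make_plots:
            for regime in ("GOOD", "NOISE"):
                bland_altman_plot(
                    ba_pairs[regime], path=out / f"ba_{regime.lower()}.png"
                )

    return StudyReport(
        measurements=meas, icc_intra=icc_intra, icc_inter=icc_inter,
        bland_altman=ba_df, pearson=pearson_df, summary=summary,
    )
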