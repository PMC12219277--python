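"""End-to-end pipeline: simulate (or load) → detrend → fit → compare.

One :func:`run_pipeline` call reproduces the full analysis for a scenario,
per variable:

* per-subset 24 h signal strength (proportion of sum of squares),
* Lomb-Scargle period estimates on a 6-d raw-data span,
* cosinor fits (mesor, amplitude, corrected acrophase, R², zero-amplitude F)
  for every 3-d subset of each labelled interval,
* pooled interval phase samples with von Mises fits, rose bins, Watson
  goodness-of-fit, and all pairwise two-sample Watson contrasts,
* median phase ± median deviation and mean best-fit period per 3-d block
  across the whole span,
* Wilcoxon signed-rank contrast families on signal strength and a
  Kruskal-Wallis test on periods.

All outputs are plain CSV tables plus a JSON manifest carrying row counts
and a config hash; rerunning with the same config reproduces the files
byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import circular as circ
from . import compare as cmp
from .core import HiveSeries, Interval, ValidationError, split_subsets, subsets_for_days
from .cosinor import estimate_period, fit_cosinor
from .detrend import detrend
from .simulate import Scenario, config_hash, gen_experiment, get_scenario
from .spectral import average_periodograms, classical_periodogram, lomb_scargle

log = logging.getLogger("hiverhythm")

TWO_PI = 2.0 * np.pi

#: interval designs: label -> (first day, last day, regime), 1-based inclusive days
WINTER_INTERVALS = {
    "interval1": (7, 12, "dark"),
    "interval2": (25, 30, "light12"),
    "interval3": (40, 45, "light12"),
    "post": (52, 57, "ambient"),
}
SUMMER_INTERVALS = {
    "interval1": (1, 6, "dark"),
    "interval2": (7, 12, "light12"),
    "interval3": (13, 18, "light12"),
    "post": (19, 24, "ambient"),
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``intervals`` maps labels to (first_day, last_day, regime); each range
    must span exactly two 3-d subsets.  ``ls_days`` picks the raw-data span
    for Lomb-Scargle period estimation.  ``strength_subsets`` is the number
    of leading 3-d subsets entering the signal-strength table.
    """

    scenario: str = "winter_csu"
    n_hives: int | None = None
    seed: int = 0
    out_dir: str | Path | None = None
    sampling_interval: int | None = None
    variables: tuple[str, ...] = ("temperature", "co2")
    intervals: dict[str, tuple[int, int, str]] | None = None
    ls_days: tuple[int, int] | None = None
    ls_oversample: int = 12
    strength_subsets: int = 6
    cosinor_period_h: float = 24.0
    noise_scale: float = 1.0
    entrain_rate_per_day: float | None = None
    phase_dispersion_kappa: float | None = None

    def resolve_intervals(self) -> dict[str, tuple[int, int, str]]:
        if self.intervals is not None:
            return self.intervals
        if self.scenario.startswith("summer"):
            return SUMMER_INTERVALS
        if self.scenario.startswith("winter"):
            return WINTER_INTERVALS
        # rhythm-strength-only designs (fall experiments) have no light
        # regime and hence no phase intervals
        return {}

    def resolve_ls_days(self) -> tuple[int, int]:
        if self.ls_days is not None:
            return self.ls_days
        # period estimation span: the darkness portion with 5-min sampling —
        # first 6 d for the summer design, second 6 d of darkness for winter
        return (1, 6) if self.scenario.startswith("summer") else (7, 12)

    def validate(self) -> None:
        ivs = self.resolve_intervals()
        spans = []
        for label, (d0, d1, regime) in ivs.items():
            if d1 - d0 + 1 != 6:
                raise ValidationError(
                    f"interval {label!r} spans {d1 - d0 + 1} d; must span 6 d (two 3-d subsets)"
                )
            Interval(label=label, subset_indices=(1, 2), regime=regime)
            spans.append((d0, d1, label))
        spans.sort()
        for (_, e0, l0), (s1, _, l1) in zip(spans, spans[1:]):
            if s1 <= e0:
                raise ValidationError(f"intervals {l0!r} and {l1!r} overlap")

    def as_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "n_hives": self.n_hives,
            "seed": self.seed,
            "sampling_interval": self.sampling_interval,
            "variables": list(self.variables),
            "intervals": {k: list(v) for k, v in self.resolve_intervals().items()},
            "ls_days": list(self.resolve_ls_days()),
            "ls_oversample": self.ls_oversample,
            "strength_subsets": self.strength_subsets,
            "cosinor_period_h": self.cosinor_period_h,
            "noise_scale": self.noise_scale,
            "entrain_rate_per_day": self.entrain_rate_per_day,
            "phase_dispersion_kappa": self.phase_dispersion_kappa,
        }


def _build_scenario(config: RunConfig) -> Scenario:
    overrides: dict = {"seed": config.seed}
    if config.n_hives is not None:
        overrides["n_hives"] = config.n_hives
    if config.sampling_interval is not None:
        overrides["sampling_interval"] = config.sampling_interval
    if config.entrain_rate_per_day is not None:
        overrides["entrain_rate_per_day"] = config.entrain_rate_per_day
    if config.phase_dispersion_kappa is not None:
        overrides["phase_dispersion_kappa"] = config.phase_dispersion_kappa
    sc = get_scenario(config.scenario, **overrides)
    if config.noise_scale != 1.0:
        presets = {}
        for var, p in sc.presets.items():
            from dataclasses import replace

            presets[var] = replace(
                p,
                noise_sd=p.noise_sd * config.noise_scale,
                ar_sd=p.ar_sd * config.noise_scale,
            )
        from dataclasses import replace as _rep

        sc = _rep(sc, presets=presets)
    return sc


def run_pipeline(
    config: RunConfig, series: list[HiveSeries] | None = None
) -> dict[str, pd.DataFrame | pd.Series | dict]:
    """Run the full analysis; return tables keyed by name.

    When ``series`` is None the configured scenario is simulated (the truth
    table is then included under ``"truth"``).  If ``config.out_dir`` is
    set, every table is written as CSV together with ``manifest.json``.
    """
    config.validate()
    truth = None
    if series is None:
        scenario = _build_scenario(config)
        series, truth = gen_experiment(scenario, variables=config.variables)
        origin = pd.Timestamp(scenario.start)
    else:
        origin = series[0].timestamps[0].normalize()

    intervals = config.resolve_intervals()
    ls_d0, ls_d1 = config.resolve_ls_days()

    strength_rows, ls_results, cos_rows, traj_rows = [], {}, [], []
    detrended: dict[tuple[str, str], HiveSeries] = {}
    for s in series:
        stage = f"{s.variable}/{s.hive_id}"
        try:
            det = detrend(s)
            detrended[(s.variable, s.hive_id)] = det

            # --- per-subset 24 h strength (classical periodogram) ---------
            subs = subsets_for_days(
                det,
                [(1 + 3 * k, 3 + 3 * k) for k in range(config.strength_subsets)],
                origin=origin,
            )
            for sub in subs:
                pg = classical_periodogram(sub)
                i24 = int(np.argmin(np.abs(pg.periods - 24.0)))
                strength_rows.append(
                    {
                        "variable": s.variable,
                        "hive_id": s.hive_id,
                        "subset": sub.index,
                        "period_h": pg.periods[i24],
                        "proportion_ss_24h": pg.proportion_ss[i24],
                    }
                )

            # --- Lomb-Scargle on the raw 6-d darkness span ----------------
            off_h = (s.timestamps[0] - origin).total_seconds() / 3600.0
            span = s.slice_hours((ls_d0 - 1) * 24.0 - off_h, ls_d1 * 24.0 - off_h)
            ls = lomb_scargle(span, oversample=config.ls_oversample)
            ls_results.setdefault(s.variable, []).append(ls)

            # --- cosinor on every interval subset -------------------------
            day_ranges = [(d0, d1) for d0, d1, _ in intervals.values()]
            labels = list(intervals)
            isubs = subsets_for_days(det, day_ranges, origin=origin) if intervals else []
            for k, sub in enumerate(isubs):
                label = labels[k // 2]
                fit = fit_cosinor(sub, period_h=config.cosinor_period_h)
                best_tau, _ = estimate_period(sub)
                cos_rows.append(
                    {
                        "variable": s.variable,
                        "hive_id": s.hive_id,
                        "interval": label,
                        "regime": intervals[label][2],
                        "subset_in_interval": k % 2 + 1,
                        "day_start": intervals[label][0] + 3 * (k % 2),
                        "mesor": fit.mesor,
                        "amplitude": fit.amplitude,
                        "acrophase_rad": fit.acrophase,
                        "peak_clock_h": fit.peak_clock_h,
                        "r2": fit.r_squared,
                        "f_stat": fit.f_stat,
                        "p_value": fit.p_value,
                        "period_best_h": best_tau,
                    }
                )

            # --- whole-span trajectories (median phase / period figures) --
            n_blocks = int(len(det) * det.sampling_interval / 60.0 // 72.0)
            for sub in split_subsets(det, n_blocks):
                fit = fit_cosinor(sub, period_h=config.cosinor_period_h)
                best_tau, _ = estimate_period(sub)
                mid = sub.timestamps[len(sub) // 2]
                traj_rows.append(
                    {
                        "variable": s.variable,
                        "hive_id": s.hive_id,
                        "block": sub.index,
                        "day_mid": (mid - origin).total_seconds() / 86400.0 + 1.0,
                        "acrophase_rad": fit.acrophase,
                        "amplitude": fit.amplitude,
                        "period_best_h": best_tau,
                    }
                )
        except ValidationError as err:
            raise ValidationError(f"stage failed at {stage}: {err}") from err

    strength = pd.DataFrame(strength_rows)
    cosinor_fits = pd.DataFrame(
        cos_rows,
        columns=[
            "variable", "hive_id", "interval", "regime", "subset_in_interval",
            "day_start", "mesor", "amplitude", "acrophase_rad", "peak_clock_h",
            "r2", "f_stat", "p_value", "period_best_h",
        ],
    )
    trajectories = pd.DataFrame(traj_rows)

    # --- Lomb-Scargle summary ---------------------------------------------
    ls_rows = []
    for variable, results in ls_results.items():
        _, _, _, mean_peak, se_peak = average_periodograms(results)
        for r in results:
            ls_rows.append(
                {
                    "variable": variable,
                    "hive_id": r.hive_id,
                    "peak_period_h": r.peak_period,
                    "mean_peak_period_h": mean_peak,
                    "se_peak_period_h": se_peak,
                }
            )
    ls_summary = pd.DataFrame(ls_rows)

    # --- pooled interval phase samples, rose bins, Watson tests -----------
    site = series[0].site
    samples: dict[tuple[str, str], circ.PhaseSample] = {}
    phase_rows, rose_rows, gof_rows = [], [], []
    for (variable, label), grp in cosinor_fits.groupby(["variable", "interval"]):
        angles = np.mod(grp["acrophase_rad"].to_numpy(), TWO_PI)
        sample = circ.PhaseSample(
            angles=angles, interval=label, site=site, variable=variable
        )
        samples[(variable, label)] = sample
        mu, kappa = circ.vonmises_mle(sample)
        med, mad = circ.circular_median_mad(sample)
        gof = circ.watson_gof_vonmises(sample, n_boot=1000, seed=config.seed)
        phase_rows.append(
            {
                "variable": variable,
                "interval": label,
                "regime": intervals[label][2],
                "n": sample.n,
                "mean_direction_rad": mu,
                "kappa": kappa,
                "median_rad": med,
                "median_deviation_rad": mad,
            }
        )
        gof_rows.append(
            {
                "variable": variable,
                "interval": label,
                "u2": gof.statistic,
                "p_range": gof.p_range,
                "p_boot": gof.p_exact,
                "n": gof.n1,
            }
        )
        for b, count in enumerate(circ.rose_bins(sample, n_bins=24)):
            rose_rows.append(
                {
                    "variable": variable,
                    "interval": label,
                    "bin_start_h": b,
                    "count": int(count),
                }
            )
    interval_phases = pd.DataFrame(
        phase_rows,
        columns=["variable", "interval", "regime", "n", "mean_direction_rad",
                 "kappa", "median_rad", "median_deviation_rad"],
    )
    rose = pd.DataFrame(rose_rows, columns=["variable", "interval", "bin_start_h", "count"])
    watson_gof = pd.DataFrame(gof_rows, columns=["variable", "interval", "u2", "p_range", "p_boot", "n"])

    # --- Table-1 analog: pairwise Watson contrasts among intervals --------
    watson_rows = []
    for variable in config.variables:
        for l1, l2 in combinations(intervals, 2):
            a, b = samples[(variable, l1)], samples[(variable, l2)]
            res = circ.watson_two_sample(a, b, seed=config.seed)
            contrast = circ.phase_contrast(a, b)
            hh, mm = circ.rad_to_clock(contrast)
            watson_rows.append(
                {
                    "variable": variable,
                    "group1": l1,
                    "group2": l2,
                    "n1": a.n,
                    "n2": b.n,
                    "contrast_rad": contrast,
                    "contrast_clock": f"{hh:d}h{mm:02d}m",
                    "watson_u2": res.statistic,
                    "p_range": res.p_range,
                }
            )
    watson_contrasts = pd.DataFrame(
        watson_rows,
        columns=["variable", "group1", "group2", "n1", "n2", "contrast_rad",
                 "contrast_clock", "watson_u2", "p_range"],
    )

    # --- Wilcoxon families on 24 h strength, KW on periods ----------------
    fam_site = "csu" if site == "CSU" else "ambient"
    wil_tables = []
    for variable in config.variables:
        wide = (
            strength[strength.variable == variable]
            .pivot(index="hive_id", columns="subset", values="proportion_ss_24h")
        )
        fam = cmp.ContrastFamily.all_pairs(
            f"{'temp' if variable == 'temperature' else 'co2'}_{fam_site}",
            list(wide.columns),
        )
        wil_tables.append(cmp.pairwise_wilcoxon(wide, fam))
    wilcoxon = pd.concat(wil_tables, ignore_index=True)

    # period ("daylength") comparison across variables, one estimate per 3-d
    # block over the whole span
    kw_groups = {
        v: trajectories.loc[trajectories.variable == v, "period_best_h"].to_numpy()
        for v in config.variables
    }
    if len(kw_groups) >= 2:
        h_stat, dof, p = cmp.kruskal_wallis(kw_groups)
        kw = pd.DataFrame(
            [{"grouping": "variable", "H": h_stat, "df": dof, "p": p}]
        )
    else:
        kw = pd.DataFrame(columns=["grouping", "H", "df", "p"])

    tables: dict = {
        "strength": strength,
        "ls_summary": ls_summary,
        "cosinor_fits": cosinor_fits,
        "interval_phases": interval_phases,
        "rose_bins": rose,
        "watson_gof": watson_gof,
        "watson_contrasts": watson_contrasts,
        "trajectories": trajectories,
        "wilcoxon": wilcoxon,
        "kruskal_wallis": kw,
    }
    if truth is not None:
        tables["truth"] = truth

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {"config": config.as_dict(), "config_hash": config_hash(config.as_dict()), "files": {}}
        for name, df in tables.items():
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            manifest["files"][f"{name}.csv"] = {"rows": int(len(df))}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        log.info("wrote %d tables to %s (config %s)", len(tables), out, manifest["config_hash"])
    return tables
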