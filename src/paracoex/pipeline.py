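"""End-to-end orchestration: data -> descriptives -> fits -> extrapolation ->
coextinction -> report tables.

``run_pipeline`` takes a single :class:`PipelineConfig` (real input files
or a synthetic generator config, never both) and produces a
:class:`ReportBundle` of comma-delimited tables shaped like the study's
summary tables: per-group power-law coefficients, predicted richness with
CIs and undescribed percentages, scenario extinction projections, the
observation-effort regression band, and the loss curves. Identical config
and seed give identical tables.
"""
from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import child_seeds, round_half_away
from .coextinction import (
    CoextinctionEstimate,
    ExtinctionScenario,
    aggregate_total,
    coextinction_curve,
    evaluate_scenario,
)
from .data_model import (
    AssociationDataset,
    ParasiteGroup,
    Region,
    Scenario,
    filter_records,
    read_association_data,
    scenario_host_proportion,
)
from .descriptive import (
    MarginalAxis,
    kruskal_wallis,
    marginal_counts,
    range_vs_observations_fit,
)
from .errors import ComputationError, ConfigurationError, ParacoexError
from .richness import PowerLawFit, RichnessPrediction, extrapolate_richness, fit_group
from .synthetic import GroupSpec, RangeDistribution, SyntheticConfig, simulate_dataset

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one data source must be set."""

    seed: int
    hosts_path: Optional[str] = None
    parasites_path: Optional[str] = None
    associations_path: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    require_species_level: bool = True
    require_obligate: bool = True
    n_boot: int = 1000
    h_total: Optional[int] = None  # default: full host registry
    scenarios: Sequence[Union[str, ExtinctionScenario]] = ("EN", "EN+TH")
    include_unassessed: bool = False
    grid_size: int = 101
    out_dir: Optional[str] = None

    def __post_init__(self):
        file_source = all(
            p is not None
            for p in (self.hosts_path, self.parasites_path, self.associations_path)
        )
        partial = not file_source and any(
            p is not None
            for p in (self.hosts_path, self.parasites_path, self.associations_path)
        )
        if partial:
            raise ConfigurationError(
                "hosts_path, parasites_path and associations_path must be given together"
            )
        if file_source == (self.synthetic is not None):
            raise ConfigurationError(
                "exactly one of (input file paths, synthetic config) must be set"
            )
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be >= 1")


@dataclass
class ReportBundle:
    """All output tables of one run plus a machine-readable provenance log."""

    table1_coefficients: pd.DataFrame
    table2_predictions: pd.DataFrame
    table3_scenarios: pd.DataFrame
    fig2_fit: pd.DataFrame
    fig3_curves: pd.DataFrame
    kw_tests: pd.DataFrame
    richness_per_host: pd.DataFrame
    host_range_per_parasite: pd.DataFrame
    run_log: dict
    fits: dict = field(default_factory=dict, repr=False)
    predictions: dict = field(default_factory=dict, repr=False)
    dataset: Optional[AssociationDataset] = field(default=None, repr=False)

    _TABLE_FILES = {
        "table1_coefficients": "table1_coefficients.csv",
        "table2_predictions": "table2_predictions.csv",
        "table3_scenarios": "table3_scenarios.csv",
        "fig2_fit": "fig2_fit.csv",
        "fig3_curves": "fig3_curves.csv",
        "kw_tests": "kw_tests.csv",
        "richness_per_host": "richness_per_host.csv",
        "host_range_per_parasite": "host_range_per_parasite.csv",
    }

    def write(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for attr, fname in self._TABLE_FILES.items():
            getattr(self, attr).to_csv(out_dir / fname, index=False)
        with open(out_dir / "run_log.json", "w") as fh:
            json.dump(self.run_log, fh, indent=2, default=str)
        return out_dir


def load_config(path) -> PipelineConfig:
    """Load a YAML run configuration.

    The ``synthetic`` block, when present, mirrors :class:`SyntheticConfig`;
    its ``groups`` entries are mappings with n_parasites,
    range_distribution and range_params.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "synthetic" in raw and raw["synthetic"] is not None:
        syn = dict(raw["synthetic"])
        syn.setdefault("seed", raw.get("seed", 0))
        if "groups" in syn:
            syn["groups"] = {
                name: GroupSpec(
                    n_parasites=int(g["n_parasites"]),
                    range_distribution=RangeDistribution(g["range_distribution"]),
                    range_params=dict(g.get("range_params", {})),
                )
                for name, g in syn["groups"].items()
            }
        raw["synthetic"] = SyntheticConfig(**syn)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _stage(name):
    """Decorator-free stage wrapper: re-raise package errors with a stage label."""
    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, ParacoexError):
                exc.args = (f"[stage:{name}] {exc.args[0] if exc.args else ''}",)
            return False

    return _ctx()


def _descriptive_tables(ds: AssociationDataset):
    kw_rows = []
    richness_frames = []
    range_frames = []

    regions_present = [
        reg for reg in Region if any(h.region == reg for h in (ds.hosts[x] for x in ds.hosts_with_records))
    ]
    per_region_richness = {}
    for reg in regions_present:
        mc = marginal_counts(ds, MarginalAxis.PER_HOST_RICHNESS, region=reg)
        per_region_richness[reg] = mc
        richness_frames.append(
            pd.DataFrame(
                {"host": list(mc.entries), "region": reg.value, "richness": list(mc.entries.values())}
            )
        )
    if len(per_region_richness) == 2:
        res = kruskal_wallis([mc.values for mc in per_region_richness.values()])
        means = {reg.value: (mc.mean(), mc.se()) for reg, mc in per_region_richness.items()}
        kw_rows.append(
            {
                "comparison": "richness_per_host_by_region",
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "group_sizes": "/".join(map(str, res.group_sizes)),
                "group_means": "/".join(f"{m:.2f}(SE {s:.2f})" for m, s in means.values()),
            }
        )

    for reg in [None, *regions_present]:
        sub = ds.restrict(reg)
        groups = sub.groups_present()
        samples, labels = [], []
        for g in groups:
            mc = marginal_counts(sub, MarginalAxis.PER_PARASITE_HOST_RANGE, group=g)
            if reg is None:
                range_frames.append(
                    pd.DataFrame(
                        {
                            "parasite": list(mc.entries),
                            "group": g.value,
                            "host_range": list(mc.entries.values()),
                        }
                    )
                )
            samples.append(mc.values)
            labels.append(g.value)
        if len(samples) >= 2 and sum(len(s) for s in samples) >= 3:
            res = kruskal_wallis(samples)
            kw_rows.append(
                {
                    "comparison": "host_range_by_group"
                    + ("" if reg is None else f"_{reg.value}"),
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "group_sizes": "/".join(map(str, res.group_sizes)),
                    "group_means": "/".join(labels),
                }
            )

    fig2_rows = []
    for reg in [None, *regions_present]:
        try:
            fit = range_vs_observations_fit(ds, region=reg)
        except ComputationError:
            continue
        label = "pooled" if reg is None else reg.value
        fig2_rows.append(
            pd.DataFrame(
                {
                    "subset": label,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "above_isometry": fit.above_isometry,
                    "log10_observations": fit.x,
                    "log10_range_fitted": fit.fitted,
                    "ci_low": fit.ci_low,
                    "ci_high": fit.ci_high,
                }
            )
        )
    fig2 = (
        pd.concat(fig2_rows, ignore_index=True)
        if fig2_rows
        else pd.DataFrame(
            columns=[
                "subset",
                "slope",
                "intercept",
                "above_isometry",
                "log10_observations",
                "log10_range_fitted",
                "ci_low",
                "ci_high",
            ]
        )
    )
    return (
        pd.DataFrame(kw_rows),
        fig2,
        pd.concat(richness_frames, ignore_index=True),
        pd.concat(range_frames, ignore_index=True),
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis; see module docstring for the stage order."""
    truth = None
    with _stage("read"):
        if config.synthetic is not None:
            ds, truth = simulate_dataset(config.synthetic)
        else:
            ds = read_association_data(
                config.hosts_path, config.parasites_path, config.associations_path
            )

    with _stage("filter"):
        filtered = filter_records(
            ds,
            require_species_level=config.require_species_level,
            require_obligate=config.require_obligate,
        )
        if not filtered.records:
            raise ComputationError("no records remain after filtering")

    with _stage("descriptive"):
        kw_tests, fig2, richness_ph, range_pp = _descriptive_tables(filtered)

    h_total = config.h_total or filtered.n_hosts
    groups = filtered.groups_present()
    seeds = dict(zip((g.value for g in ParasiteGroup), child_seeds(config.seed, len(ParasiteGroup))))

    fits: dict[ParasiteGroup, PowerLawFit] = {}
    predictions: dict[ParasiteGroup, RichnessPrediction] = {}
    t1_rows, t2_rows, fig3_frames = [], [], []
    with _stage("fit"):
        for g in groups:
            observed = len(
                {r.parasite for r in filtered.group_records(g)}
            )
            try:
                fit = fit_group(filtered, g, n_boot=config.n_boot, seed=seeds[g.value])
            except ComputationError:
                continue  # group too thin to fit; logged via absence
            fits[g] = fit
            pred = extrapolate_richness(fit, h_total, observed)
            predictions[g] = pred
            zlo, zhi = np.percentile(fit.replicate_z, [2.5, 97.5])
            blo, bhi = np.percentile(fit.replicate_b, [2.5, 97.5])
            t1_rows.append(
                {
                    "group": g.value,
                    "b": fit.b_hat,
                    "z": fit.z_hat,
                    "b_ci_low": blo,
                    "b_ci_high": bhi,
                    "z_ci_low": zlo,
                    "z_ci_high": zhi,
                    "n_boot": fit.n_boot,
                    "n_hosts_fit": fit.n_hosts_fit,
                }
            )
            t2_rows.append(
                {
                    "group": g.value,
                    "observed": pred.observed_richness,
                    "predicted": pred.rounded_estimate,
                    "predicted_unrounded": pred.point_estimate,
                    "ci_low": pred.ci_low,
                    "ci_high": pred.ci_high,
                    "undescribed_percent": pred.undescribed_percent,
                }
            )
            curve = coextinction_curve(fit, grid_size=config.grid_size)
            fig3_frames.append(
                pd.DataFrame(
                    {
                        "group": g.value,
                        "p_host": curve.grid,
                        "proportion_extinct": curve.mean_line,
                        "ci_low": curve.ci_low,
                        "ci_high": curve.ci_high,
                    }
                )
            )
        if not fits:
            raise ComputationError("no parasite group could be fitted")
        # total row from unrounded group values; CI bounds summed per group
        tot_obs = sum(p.observed_richness for p in predictions.values())
        tot_pred = sum(p.point_estimate for p in predictions.values())
        from .richness import undescribed_percent as _upct

        t2_rows.append(
            {
                "group": "total",
                "observed": tot_obs,
                "predicted": round_half_away(tot_pred),
                "predicted_unrounded": tot_pred,
                "ci_low": sum(p.ci_low for p in predictions.values()),
                "ci_high": sum(p.ci_high for p in predictions.values()),
                "undescribed_percent": _upct(tot_obs, tot_pred),
            }
        )

    with _stage("coextinction"):
        t3_rows = []
        for sc in config.scenarios:
            if isinstance(sc, ExtinctionScenario):
                scenario = sc
            else:
                scenario = ExtinctionScenario(
                    name=str(Scenario(sc).value),
                    p_host=scenario_host_proportion(
                        filtered, Scenario(sc), include_unassessed=config.include_unassessed
                    ),
                )
            ests = []
            for g in fits:
                est = evaluate_scenario(fits[g], predictions[g], scenario)
                ests.append(est)
                t3_rows.append(
                    {
                        "scenario": scenario.name,
                        "p_host": scenario.p_host,
                        "group": g.value,
                        "percent_extinct": est.percent,
                        "ci_low_percent": round(100 * est.ci_low, 1),
                        "ci_high_percent": round(100 * est.ci_high, 1),
                        "species_extinct": est.rounded_species,
                        "species_extinct_unrounded": est.species_extinct,
                    }
                )
            total = aggregate_total(ests, [predictions[g] for g in fits])
            t3_rows.append(
                {
                    "scenario": scenario.name,
                    "p_host": scenario.p_host,
                    "group": "total",
                    "percent_extinct": total.percent,
                    "ci_low_percent": round(100 * total.ci_low, 1),
                    "ci_high_percent": round(100 * total.ci_high, 1),
                    "species_extinct": total.rounded_species,
                    "species_extinct_unrounded": total.species_extinct,
                }
            )

    run_log = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "timestamp_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": config.seed,
        "n_boot": config.n_boot,
        "h_total": h_total,
        "group_seeds": seeds,
        "config": {
            k: (v.to_dict() if isinstance(v, SyntheticConfig) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "dataset_summary": {
            "n_hosts": filtered.n_hosts,
            "n_hosts_with_records": filtered.n_hosts_with_records,
            "n_parasites_recorded": len(filtered.recorded_parasites),
            "n_pairs": filtered.n_pairs,
        },
    }
    if truth is not None:
        run_log["synthetic_truth"] = truth

    bundle = ReportBundle(
        table1_coefficients=pd.DataFrame(t1_rows),
        table2_predictions=pd.DataFrame(t2_rows),
        table3_scenarios=pd.DataFrame(t3_rows),
        fig2_fit=fig2,
        fig3_curves=pd.concat(fig3_frames, ignore_index=True),
        kw_tests=kw_tests,
        richness_per_host=richness_ph,
        host_range_per_parasite=range_pp,
        run_log=run_log,
        fits=fits,
        predictions=predictions,
        dataset=filtered,
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
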