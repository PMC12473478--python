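"""Pipeline orchestration: simulate/read panels, fit sources, compute burden.

``run_pipeline`` wires the whole chain — panel acquisition, composition QC,
per-site receptor modelling, annual exposure means, burden with source and
stratum attribution, and city-year aggregation — into one deterministic run
that writes CSV artifacts plus a checksum manifest. The run log is excluded
from the manifest so reruns with identical seeds produce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .core_data import (
    ConcentrationPanel,
    ExposureConstants,
    ValidationError,
    read_concentration_csv,
    write_burden_csv,
    write_concentration_csv,
)
from .burden import (
    aggregate_city_year,
    attribute_burden_to_sources,
    burden_for_city_year,
    stratify_burden,
    BurdenTable,
)
from .exposure import annual_mean_table
from .pmf import build_uncertainty, fit_pmf, label_factors, source_contribution_shares
from .synthetic import (
    _STRATUM_DALY_WEIGHTS,
    generate_panel,
    make_daly_fixture,
    make_population_fixture,
    make_toxicity_fixture,
)


@dataclass
class SiteSpec:
    site_id: str
    region_class: str = "inland"
    population: float = 5.0e6


@dataclass
class RunConfig:
    """Everything a pipeline run needs; loadable from YAML."""

    out_dir: str
    seed: int = 0
    sites: list[SiteSpec] = field(default_factory=lambda: [
        SiteSpec("Inland-A", "inland", 9.2e6),
        SiteSpec("Coastal-A", "coastal", 10.1e6),
    ])
    panel_csvs: list[str] = field(default_factory=list)  # if set, read instead of simulate
    n_times: int = 365
    start: str = "2022-01-01"
    noise_cv: float = 0.05
    missing_frac: float = 0.02
    heating_amplitude: float = 0.8
    n_factors: int = 5
    restarts: int = 5
    max_iter: int = 200
    tol: float = 1e-8
    constants: ExposureConstants = field(default_factory=ExposureConstants)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sites = [SiteSpec(**s) for s in raw.pop("sites", [])]
        constants = ExposureConstants(**raw.pop("constants", {})).validate()
        cfg = cls(**raw, constants=constants)
        if sites:
            cfg.sites = sites
        return cfg

    def validate(self) -> "RunConfig":
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")
        for p in self.panel_csvs:
            if not Path(p).exists():
                raise ValidationError(f"panel CSV not found: {p}")
        return self


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def summarize_composition(
    panels: Sequence[ConcentrationPanel] | ConcentrationPanel,
) -> pd.DataFrame:
    """Per-species relative shares of mean total metal mass, by group.

    Groups are the overall panel, its region class, and its heating /
    non-heating split; means are over non-missing observations with
    below-MDL cells at MDL/2. Shares sum to 1 within each group.
    """
    if isinstance(panels, ConcentrationPanel):
        panels = [panels]
    rows = []
    for panel in panels:
        panel.validate()
        work = panel.values.copy()
        for sp in panel.species:
            work.loc[panel.below_mdl[sp].to_numpy(), sp] = panel.mdl[sp] / 2.0
        groups = {
            "all": pd.Series(True, index=work.index),
            panel.region_class: pd.Series(True, index=work.index),
            "heating": panel.heating_mask,
            "non-heating": ~panel.heating_mask,
        }
        for name, mask in groups.items():
            sub = work.loc[mask.to_numpy()]
            if sub.dropna(how="all").empty:
                raise ValidationError(f"{panel.site_id}: group {name!r} has no observations")
            means = sub.mean(axis=0, skipna=True)
            shares = means / means.sum()
            for sp in panel.species:
                rows.append(
                    {"site": panel.site_id, "group": name, "species": sp,
                     "mean_ngm3": means[sp], "share": shares[sp]}
                )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full chain; returns the output directory.

    Deterministic given ``config.seed``: rerunning with the same
    configuration reproduces byte-identical CSVs and manifest checksums.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t0 = time.time()

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{time.time() - t0:8.2f}s] {stage}: {msg}")

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    artifacts: list[Path] = []

    # -- panels ------------------------------------------------------------
    panels: list[ConcentrationPanel] = []
    with stage("panels"):
        if config.panel_csvs:
            for p in config.panel_csvs:
                panels.append(read_concentration_csv(p))
        else:
            for s in config.sites:
                panels.append(
                    generate_panel(
                        site_id=s.site_id, region_class=s.region_class,
                        n_times=config.n_times, start=config.start,
                        noise_cv=config.noise_cv, missing_frac=config.missing_frac,
                        heating_amplitude=config.heating_amplitude, seed=config.seed,
                    )
                )
        for panel in panels:
            path = out / f"panel_{panel.site_id}.csv"
            write_concentration_csv(panel, path)
            artifacts.append(path)
        log("panels", f"{len(panels)} site panels, {sum(p.n_times for p in panels)} rows")

    # -- composition QC ----------------------------------------------------
    with stage("composition"):
        comp = summarize_composition(panels)
        path = out / "composition.csv"
        comp.to_csv(path, index=False, float_format="%.12g")
        artifacts.append(path)
        log("composition", f"{len(comp)} rows")

    # -- receptor model per site -------------------------------------------
    site_shares: dict[str, pd.DataFrame] = {}
    diagnostics: dict[str, dict] = {}
    with stage("pmf"):
        for panel in panels:
            u = build_uncertainty(panel)
            model = fit_pmf(
                panel, u=u, p=config.n_factors, restarts=config.restarts,
                seed=config.seed, max_iter=config.max_iter, tol=config.tol,
            )
            labels = label_factors(model.F)
            f_named = model.F.copy()
            f_named.index = labels
            g_named = model.G.copy()
            g_named.columns = labels
            per_species, total_shares = source_contribution_shares(model)
            per_species.columns = labels
            site_shares[panel.site_id] = per_species
            fp = out / f"F_{panel.site_id}.csv"
            gp = out / f"G_{panel.site_id}.csv"
            f_named.to_csv(fp, float_format="%.12g")
            g_named.to_csv(gp, float_format="%.12g")
            artifacts.extend([fp, gp])
            diagnostics[panel.site_id] = {
                "Q": model.Q, "Q_expected": model.Q_expected,
                "converged": model.converged, "labels": labels,
                "total_mass_shares": {l: total_shares.iloc[i] for i, l in enumerate(labels)},
            }
            log("pmf", f"{panel.site_id}: Q={model.Q:.4g} Q/Qexp={model.Q / model.Q_expected:.3f}")
        dpath = out / "diagnostics.json"
        dpath.write_text(json.dumps(diagnostics, indent=2, sort_keys=True))
        artifacts.append(dpath)

    # -- exposure ----------------------------------------------------------
    with stage("exposure"):
        means = pd.concat([annual_mean_table(p) for p in panels], ignore_index=True)
        path = out / "annual_means.csv"
        means.to_csv(path, index=False, float_format="%.12g")
        artifacts.append(path)
        log("exposure", f"{len(means)} city-year-metal means")

    # -- burden ------------------------------------------------------------
    with stage("burden"):
        toxicity = make_toxicity_fixture()
        daly_weights = make_daly_fixture()
        pops = {
            r.city: r
            for r in make_population_fixture(
                [(s.site_id, s.region_class, s.population) for s in config.sites]
                if not config.panel_csvs
                else [(p.site_id, p.region_class, 5.0e6) for p in panels]
            )
        }
        tables = []
        for (site, year), grp in means.groupby(["site", "year"]):
            conc = dict(zip(grp["metal"], grp["mean_ngm3"]))
            tab = burden_for_city_year(
                site, int(year), conc, toxicity, daly_weights, pops[site],
                config.constants,
            )
            tab = attribute_burden_to_sources(tab, site_shares[site])
            tab = stratify_burden(tab, pops[site], _STRATUM_DALY_WEIGHTS)
            tables.append(tab.data)
        burden_table = BurdenTable(pd.concat(tables, ignore_index=True)).validate()
        path = out / "burden.csv"
        write_burden_csv(burden_table, path)
        artifacts.append(path)
        log("burden", f"{len(burden_table.data)} rows")

    # -- aggregation -------------------------------------------------------
    with stage("aggregate"):
        summary = aggregate_city_year(burden_table)
        path = out / "summary.csv"
        tbl = summary.table.copy()
        tbl["city_mean"] = summary.city_means
        tbl.loc["average"] = list(summary.year_means) + [float("nan")]
        tbl.to_csv(path, float_format="%.12g")
        artifacts.append(path)
        log("aggregate", f"{summary.table.shape[0]} cities x {summary.table.shape[1]} years")

    # -- manifest (log excluded so checksums are reproducible) -------------
    manifest = {
        "seed": config.seed,
        "files": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
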