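"""End-to-end orchestration: simulate -> split -> tabulate -> fit -> report.

Runs both censoring variants and both diabetes-term parametrizations,
writes HR tables (CSV), model-comparison tests (JSON), duration-profile
figures and a run manifest with digests, so a completed run is
reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .bands import POP_LEVEL
from .lexis import split_cohort, tabulate
from .model import (APCRateModel, eligibility, heterogeneity_test)
from .plots import duration_profile_plot
from .simulate import (FIG3_LIKE_MULTIPLIERS, SimConfig, TrueEffect,
                       simulate_registry_tables, simulate_t1d_cohort)

log = logging.getLogger("t1dapc")


def default_effects(config: SimConfig, binary_hr: float = 1.5,
                    duration_multipliers: dict | None = None) -> list:
    """One TrueEffect per configured site, shared across sexes."""
    dm = FIG3_LIKE_MULTIPLIERS if duration_multipliers is None else duration_multipliers
    return [TrueEffect(site=s, sex="*", binary_multiplier=binary_hr,
                       duration_multipliers=dict(dm), bands=config.bands)
            for s in sorted(config.sites)]


def pop_model_rows(pop: pd.DataFrame, site=None) -> pd.DataFrame:
    """Population table -> model rows with duration level 'pop'.

    ``site=None`` pools case counts over sites ("all cancers"); the
    person-years denominator is the (age, period) population and is not
    summed over sites.
    """
    if site is None:
        g = (pop.groupby(["country", "sex", "age", "period"], sort=True)
             .agg(events=("cases", "sum"), pyrs=("person_years", "first"))
             .reset_index())
    else:
        sub = pop[pop["site"] == site]
        if len(sub) == 0:
            raise KeyError(f"site {site!r} not in population table")
        g = sub.rename(columns={"cases": "events", "person_years": "pyrs"})[
            ["country", "sex", "age", "period", "events", "pyrs"]]
    g["duration"] = POP_LEVEL
    g["dx_age_band"] = None
    return g


def model_table(pop: pd.DataFrame, t1d_cells: pd.DataFrame, site=None,
                sex=None) -> pd.DataFrame:
    """Stack population reference rows and T1D cells for one model fit."""
    rows = pop_model_rows(pop, site=site)
    cells = t1d_cells.copy()
    if sex is not None:
        rows = rows[rows["sex"] == sex]
        cells = cells[cells["sex"] == sex]
    keep = ["country", "sex", "age", "period", "duration", "events", "pyrs"]
    if "dx_age_band" in cells.columns:
        keep.append("dx_age_band")
        if "dx_age_band" not in rows.columns:
            rows["dx_age_band"] = None
    out = pd.concat([rows[keep], cells[keep]], ignore_index=True)
    return out[out["pyrs"] > 0].reset_index(drop=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: SimConfig) -> str:
    d = asdict(config)
    d["bands"] = list(d["bands"]["cuts"])
    return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()


def run_pipeline(config: SimConfig, effects=None, out_dir="t1dapc-run",
                 model_kw: dict | None = None, min_cases: int = 200,
                 override_sites=("kidney",), make_figures: bool = True) -> dict:
    """Execute all stages for both model variants; returns the output bundle.

    Any stage failure raises with the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model_kw = dict(model_kw or {})
    effects = effects if effects is not None else default_effects(config)
    known = set(config.sites)
    for e in effects:
        if e.site not in known and e.site != "*":
            raise KeyError(f"effect refers to unknown site {e.site!r}; "
                           f"configured sites: {sorted(known)}")
    bundle = {"out_dir": str(out), "files": [], "hr_tables": {}, "tests": {}}
    stage = "simulate"
    try:
        persons = simulate_t1d_cohort(config, effects)
        pop = simulate_registry_tables(config)
        log.info("simulate: %d persons, %.0f T1D PY, %d population cells",
                 len(persons), (persons["exit"] - persons["entry"]).sum(), len(pop))
        tio.write_persons(persons, out / "persons.csv")
        tio.write_population(pop, out / "population.csv")

        stage = "split"
        seg_all = split_cohort(persons, bands=config.bands, variant="all_sites",
                               max_age=config.max_age)
        seg_ss = split_cohort(persons, bands=config.bands, variant="site_specific",
                              max_age=config.max_age)
        log.info("split: %.1f PY (all-sites), %.1f PY (site-specific)",
                 seg_all["pyrs"].sum(), seg_ss["pyrs"].sum())

        stage = "tabulate"
        by = ("country", "sex", "age", "period", "duration", "dx_age_band")
        cells_all = _tab(seg_all, by)
        tio.write_cells(cells_all, out / "lexis_all_sites.csv")
        site_cells, site_counts = {}, {}
        for site in sorted(config.sites):
            sc = _tab(seg_ss, by, site=site)
            site_cells[site] = sc
            t1d_ev = sc["events"].groupby(sc["sex"]).sum()
            site_counts[site] = t1d_ev.to_dict()
        tio.write_cells(pd.concat([c.assign(site=s) for s, c in site_cells.items()],
                                  ignore_index=True), out / "lexis_site_specific.csv")
        log.info("tabulate: %d all-sites cells, %d events",
                 len(cells_all), cells_all["events"].sum())

        stage = "fit"
        for sex in config.sexes:
            for term in ("binary", "duration"):
                tab = model_table(pop, cells_all, site=None, sex=sex)
                m = APCRateModel(diabetes_term=term, bands=config.bands,
                                 **model_kw).fit(tab)
                key = f"all_{sex}_{term}"
                bundle["hr_tables"][key] = m.hr_table()
            if len(config.countries) >= 2:
                bundle["tests"][f"heterogeneity_all_{sex}"] = heterogeneity_test(
                    model_table(pop, cells_all, site=None, sex=sex),
                    bands=config.bands, **model_kw)
            for site in sorted(config.sites):
                tab = model_table(pop, site_cells[site], site=site, sex=sex)
                m = APCRateModel(diabetes_term="binary", bands=config.bands,
                                 **model_kw).fit(tab)
                bundle["hr_tables"][f"{site}_{sex}_binary"] = m.hr_table()
                if eligibility(site_counts[site], site=site, min_cases=min_cases,
                               overrides=override_sites):
                    m = APCRateModel(diabetes_term="duration", bands=config.bands,
                                     **model_kw).fit(tab)
                    bundle["hr_tables"][f"{site}_{sex}_duration"] = m.hr_table()

        stage = "report"
        for key, tab in bundle["hr_tables"].items():
            p = out / f"hr_{key}.csv"
            tab.assign(site=key.rsplit("_", 2)[0], sex=key.rsplit("_", 2)[1]).rename(
                columns={"label": "level"}).to_csv(p, index=False)
            bundle["files"].append(p.name)
        (out / "tests.json").write_text(json.dumps(bundle["tests"], indent=2))
        if make_figures:
            for sex in config.sexes:
                tab = bundle["hr_tables"].get(f"all_{sex}_duration")
                if tab is not None and len(tab):
                    duration_profile_plot(
                        tab, out / f"duration_profile_{sex}.png", bands=config.bands,
                        title=f"HR of all cancers by duration of diabetes ({sex})")
                    bundle["files"].append(f"duration_profile_{sex}.png")
        manifest = {
            "seed": config.seed,
            "config_sha256": _config_hash(config),
            "package": "t1dapc",
            "digests": {f.name: _sha256(f) for f in sorted(out.glob("*.csv"))},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        bundle["manifest"] = manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle


def _tab(seg, by, site=None):
    cells = tabulate(seg, by=[b for b in by if b in seg.columns], site=site)
    return cells
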