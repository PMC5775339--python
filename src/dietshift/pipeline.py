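"""End-to-end orchestration: load (or simulate) -> indices -> regimes ->
permutation comparisons -> correlations -> ordination -> morphometrics ->
summary report.

Every output CSV starts with comment headers recording the package version,
the root seed and a hash of the configuration, so two runs with the same
config and seed produce byte-identical artifacts.  A MANIFEST lists the
stages that completed; a stage failure aborts the run with the stage name
while keeping the artifacts already written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import bray_curtis, nmds, species_scores, ward_cluster
from .environment import AnnualSeries, correlation_table
from .indices import index_table
from .morphometrics import MorphometricsConfig, morphometrics_table
from .permutation import annual_group_comparison
from .records import (SampleTable, TaxonCatalog, default_catalog,
                      occurrence_frequencies, read_samples)
from .regimes import regime_report, select_model
from .synthetic import GeneratorConfig, generate_env, generate_samples

log = logging.getLogger("dietshift")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    outdir: str = "dietshift_out"
    seed: int = 42
    samples_csv: str | None = None   # None -> simulate
    catalog_csv: str | None = None
    env_csv: str | None = None       # year-indexed covariate CSV
    morphometrics_yaml: str | None = None
    alpha: float = 0.05
    n_perm: int = 9_999
    nmds_dimensions: int = 2
    #: explanatory-variable changepoints are not searched before this year
    env_window_start: int = 1997
    run_morphometrics: bool = True
    min_fo_for_ordination: float = 0.0  # drop taxa never above this FO

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        # analysis settings only: the output location does not alter results
        settings = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(settings, sort_keys=True).encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig,
               index: bool = False, extra: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"# dietshift {__version__} seed={config.seed} "
                 f"config={config.digest()}\n")
        if extra:
            fh.write(f"# {extra}\n")
        df.to_csv(fh, index=index)


def _load_env(config: RunConfig, seed: int) -> dict[str, AnnualSeries]:
    if config.env_csv is None:
        return generate_env(GeneratorConfig(), seed=seed)
    df = pd.read_csv(config.env_csv, comment="#").set_index("year")
    return {c: AnnualSeries(c, df[c].dropna()) for c in df.columns}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the artifact bundle into ``config.outdir``.

    Returns a dict with the in-memory results (sample table, fits, tables).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(filename=out / "run.log", level=logging.INFO,
                        format="%(asctime)s %(levelname)s %(message)s",
                        force=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage_seed = [int(s.generate_state(1)[0] % 2**31) for s in seeds]
    completed: list[str] = []
    results: dict = {}
    catalog = TaxonCatalog.from_csv(config.catalog_csv) \
        if config.catalog_csv else default_catalog()

    def stage(name):
        def deco(fn):
            def run():
                log.info("stage %s: start", name)
                try:
                    fn()
                except Exception as exc:
                    _write_manifest(out, completed, failed=name)
                    raise PipelineError(name, exc) from exc
                completed.append(name)
                log.info("stage %s: done", name)
            return run
        return deco

    @stage("load")
    def _load():
        if config.samples_csv:
            table = read_samples(config.samples_csv, catalog)
        else:
            table = generate_samples(GeneratorConfig(), seed=stage_seed[0])
        results["table"] = table
        results["env"] = _load_env(config, seed=stage_seed[1])
        log.info("loaded %d samples over %d years", table.n_samples,
                 len(table.years))

    @stage("indices")
    def _indices():
        table: SampleTable = results["table"]
        taxa = sorted({i.taxon for s in table for i in s.items})
        categories = taxa + ["arctic", "atlantic"]
        pooled = index_table(table, categories, catalog, by_year=False)
        per_year = index_table(table, categories, catalog, by_year=True)
        results["index_table"] = pooled
        _write_csv(pooled, out / "index_table.csv", config)
        _write_csv(per_year, out / "index_table_by_year.csv", config)

    @stage("regimes")
    def _regimes():
        table: SampleTable = results["table"]
        fo = occurrence_frequencies(table, level="origin", catalog=catalog)
        fits = {}
        for origin in ("arctic", "atlantic"):
            if origin in fo.columns:
                s = AnnualSeries(f"{origin}_fo", fo[origin])
                fits[f"{origin}_fo"] = select_model(s)
                results[f"{origin}_fo_series"] = s
        for name, series in results["env"].items():
            try:
                fits[name] = select_model(
                    series, window=(config.env_window_start, None))
            except ValueError as exc:
                log.warning("regime fit skipped for %s: %s", name, exc)
        results["regime_fits"] = fits
        _write_csv(regime_report(fits), out / "regimes.csv", config)

    @stage("compare")
    def _compare():
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            comparison = annual_group_comparison(
                results["table"], catalog, alpha=config.alpha,
                n_perm=config.n_perm, seed=stage_seed[2])
        for w in caught:  # presence-only years are expected; log, don't warn
            log.info("compare: %s", w.message)
        results["comparison"] = comparison
        _write_csv(comparison, out / "comparison.csv", config)

    @stage("correlate")
    def _correlate():
        env = results["env"]
        diet = [results[k] for k in ("arctic_fo_series", "atlantic_fo_series")
                if k in results]
        pairs = [(d, env[e]) for d in diet
                 for e in ("sea_ice_index", "temperature") if e in env]
        corr = correlation_table(pairs)
        results["correlations"] = corr
        _write_csv(corr, out / "correlations.csv", config)

    @stage("ordinate")
    def _ordinate():
        table: SampleTable = results["table"]
        fo = occurrence_frequencies(table, level="taxon", catalog=catalog)
        fo = fo.loc[:, fo.max() > config.min_fo_for_ordination]
        D = bray_curtis(fo)
        dend = ward_cluster(D)
        ord_res = nmds(D, k=config.nmds_dimensions, seed=stage_seed[3])
        results["dissimilarity"] = D
        results["dendrogram"] = dend
        results["ordination"] = ord_res
        _write_csv(D.to_dataframe(), out / "dissimilarity.csv", config,
                   index=True)
        (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
        _write_csv(ord_res.coordinates, out / "ordination.csv", config,
                   index=True,
                   extra=f"stress={ord_res.stress:.6f} "
                         f"converged={ord_res.converged}")
        _write_csv(species_scores(ord_res.coordinates, fo),
                   out / "species_scores.csv", config, index=True)

    @stage("morphometrics")
    def _morpho():
        table: SampleTable = results["table"]
        rows = [
            {"sample_id": s.sample_id, "species": i.taxon, "otolith_mm": v}
            for s in table for i in s.items for v in i.otolith_lengths
        ]
        morpho_config = (
            MorphometricsConfig.from_yaml(config.morphometrics_yaml)
            if config.morphometrics_yaml
            else MorphometricsConfig.placeholders())
        df = morphometrics_table(pd.DataFrame(
            rows, columns=["sample_id", "species", "otolith_mm"]),
            morpho_config)
        results["morphometrics"] = df
        _write_csv(df, out / "morphometrics.csv", config)

    @stage("report")
    def _report():
        lines = [f"dietshift {__version__} run (seed={config.seed}, "
                 f"config={config.digest()})", ""]
        fits = results.get("regime_fits", {})
        for name, fit in fits.items():
            cp = f", changepoint {fit.changepoint_year}" \
                if fit.changepoint_year else ""
            lines.append(f"{name}: best model {fit.form}{cp} "
                         f"(AICc {fit.aicc:.2f})")
        comp = results.get("comparison")
        if comp is not None and len(comp):
            sig = comp.loc[comp["significant"], "year"].tolist()
            lines.append(f"years with significant Arctic-Atlantic wet-weight "
                         f"difference (alpha={config.alpha}): {sig}")
        corr = results.get("correlations")
        if corr is not None and len(corr):
            for r in corr.itertuples():
                tag = "detrended" if r.detrended else "raw"
                star = "*" if r.significant else ""
                lines.append(f"corr {r.x} ~ {r.y} ({tag}): r={r.r:.2f}{star}")
        ord_res = results.get("ordination")
        if ord_res is not None:
            lines.append(f"nMDS stress: {ord_res.stress:.4f}")
        (out / "summary.txt").write_text("\n".join(lines) + "\n")

    stages = [_load, _indices, _regimes, _compare, _correlate, _ordinate]
    if config.run_morphometrics:
        stages.append(_morpho)
    stages.append(_report)
    for run in stages:
        run()
    _write_manifest(out, completed,
                    skipped=[] if config.run_morphometrics
                    else ["morphometrics"])
    return results


def _write_manifest(out: Path, completed: list[str], failed: str | None = None,
                    skipped: list[str] = ()) -> None:
    lines = [f"completed: {s}" for s in completed]
    lines += [f"skipped: {s}" for s in skipped]
    if failed:
        lines.append(f"FAILED: {failed}")
    (out / "MANIFEST").write_text("\n".join(lines) + "\n")
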