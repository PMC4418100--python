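"""File formats, run configuration and the end-to-end report pipeline.

Two CSV dialects are accepted for input (long-format daily fixes
``individual,date,easting,northing`` or long-format daily distances
``individual,date,distance``); results are written as JSON (machine-readable
summaries, each stamped with the config hash and seed), CSV (tables) and
optional PNG figures. The ``run_report`` pipeline chains every analysis
stage: power transform, spectral decomposition, DIC cutoff scan,
hierarchical colour fit, residual diagnostics, and the prior sensitivity
grid.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import colour as colour_mod
from . import preprocess, spectral, synchrony
from .priors import PriorSpec, default_priors

__all__ = ["RunConfig", "read_panel", "write_panel", "write_decomposition", "run_report"]

log = logging.getLogger("movespec")


@dataclass
class RunConfig:
    """Settings for the end-to-end report run."""

    input_path: str
    out_dir: str
    seed: int
    chains: int = 4
    iterations: int = 20_000
    burn_in_frac: float = 0.5
    n_realizations: int = 1000
    sensitivity: bool = True
    make_plots: bool = True
    quiet: bool = False

    def config_hash(self) -> str:
        # hash covers only the analysis-determining settings, not where or
        # how verbosely results are written
        d = {k: v for k, v in asdict(self).items()
             if k not in ("out_dir", "quiet", "make_plots")}
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _fail(path: Path, line: int | None, msg: str):
    where = f"{path}" + (f", line {line}" if line is not None else "")
    raise ValueError(f"{where}: {msg}")


def read_panel(path) -> preprocess.DisplacementPanel:
    """Read a displacement panel from either documented CSV dialect.

    Fixes dialect (``individual,date,easting,northing``) is reduced to
    distances via consecutive-day Euclidean steps; distances dialect
    (``individual,date,distance``) is validated (non-negative, one value per
    individual per day, shared contiguous dates) and pivoted.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise ValueError(f"{path}: cannot parse CSV ({exc})") from exc
    cols = set(df.columns)
    if {"individual", "date", "easting", "northing"} <= cols:
        return preprocess.compute_displacements(df)
    if {"individual", "date", "distance"} <= cols:
        bad = df.index[pd.to_numeric(df["distance"], errors="coerce").isna()]
        if len(bad):
            _fail(path, int(bad[0]) + 2, "non-numeric distance value")
        neg = df.index[df["distance"].astype(float) < 0]
        if len(neg):
            _fail(path, int(neg[0]) + 2, "negative displacement distance")
        df = df.copy()
        df["date"] = pd.to_datetime(df["date"])
        dup = df.duplicated(subset=["individual", "date"], keep=False)
        if dup.any():
            row = df.loc[dup].iloc[0]
            _fail(path, None, f"duplicate distance for individual "
                  f"{row['individual']!r} on {row['date'].date()}")
        all_dates = pd.date_range(df["date"].min(), df["date"].max(), freq="D")
        ids = list(pd.unique(df["individual"]))
        for ind, grp in df.groupby("individual", sort=False):
            absent = all_dates.difference(pd.DatetimeIndex(grp["date"]))
            if len(absent):
                _fail(path, None, f"missing day for individual {ind!r}: "
                      f"{absent[0].date()} ({len(absent)} missing in total)")
        wide = df.pivot(index="individual", columns="date", values="distance")
        wide = wide.loc[ids, all_dates]
        return preprocess.DisplacementPanel(
            distances=wide.to_numpy(dtype=float),
            individual_ids=ids,
            dates=all_dates,
        )
    _fail(path, 1, "header must be individual,date,easting,northing or "
          "individual,date,distance")


def write_distances_long(panel: preprocess.DisplacementPanel, path):
    """Write a displacement panel in the long distances dialect read_panel accepts."""
    rows = [
        {"individual": ind, "date": date.date().isoformat(),
         "distance": panel.distances[i, j]}
        for i, ind in enumerate(panel.individual_ids)
        for j, date in enumerate(panel.dates)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_panel(panel, path, sidecar: dict | None = None):
    """Write a panel as CSV (individuals as columns) with a JSON sidecar."""
    path = Path(path)
    values = panel.values if hasattr(panel, "values") else panel.distances
    df = pd.DataFrame(
        values.T,
        columns=panel.individual_ids,
        index=pd.Index(panel.dates, name="date") if panel.dates is not None else None,
    )
    df.to_csv(path)
    meta = dict(sidecar or {})
    if hasattr(panel, "exponent"):
        meta.setdefault("exponent", panel.exponent)
        meta.setdefault("objective_value", panel.objective_value)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=float))


def read_transformed_panel(path) -> preprocess.TransformedPanel:
    path = Path(path)
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    meta = json.loads(path.with_suffix(".json").read_text())
    return preprocess.TransformedPanel(
        values=df.to_numpy(dtype=float).T,
        exponent=float(meta["exponent"]),
        objective_value=float(meta.get("objective_value", "nan")),
        individual_ids=list(df.columns),
        dates=pd.DatetimeIndex(df.index),
    )


def write_decomposition(dec: spectral.SpectralDecomposition, prefix):
    """Write theta/psi matrices as CSV with a frequency column, plus metadata."""
    prefix = Path(prefix)
    for name, mat in (("phases", dec.phases), ("ordinates", dec.ordinates)):
        df = pd.DataFrame(mat, index=pd.Index(dec.frequencies, name="frequency"))
        df.columns = [f"ind{j + 1}" for j in range(mat.shape[1])]
        df.to_csv(prefix.parent / f"{prefix.name}_{name}.csv")
    meta = {"L": dec.L, "N": dec.n_individuals, "l": dec.l, "m": dec.m,
            "normalization": "|F|^2/L"}
    (prefix.parent / f"{prefix.name}_meta.json").write_text(json.dumps(meta, indent=2))


def read_matrix_csv(path) -> np.ndarray:
    """Read a (frequency x individual) matrix written by write_decomposition."""
    return pd.read_csv(path, index_col=0, float_precision="round_trip").to_numpy(dtype=float)


def _json_dump(obj, path: Path, cfg: RunConfig):
    obj = {"config_hash": cfg.config_hash(), "seed": cfg.seed, **obj}
    path.write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return json.loads(x.to_json(orient="index"))
    return str(x)


def _scan_summary(scan: synchrony.DicScan) -> dict:
    return {
        "selected_phi": scan.selected,
        "runner_up_clearly_worse": bool(scan.runner_up_clearly_worse),
        "dic": scan.table["dic"].tolist(),
        "delta_dic": scan.table["delta_dic"].tolist(),
    }


def run_report(cfg: RunConfig) -> dict:
    """Run the full pipeline and write the report bundle to cfg.out_dir.

    Stages: read input -> power transform -> spectral decomposition -> DIC
    cutoff scan -> hierarchical colour fit -> residual diagnostics ->
    (optionally) prior sensitivity grid: three nu-prior intervals x three
    M priors, re-running the scan for each combination and recording whether
    the selected cutoff agrees across the grid.
    """
    if not cfg.quiet:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                            format="%(levelname)s %(name)s: %(message)s")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}
    stage = "read"
    try:
        t0 = time.perf_counter()
        panel = read_panel(cfg.input_path)
        timings[stage] = time.perf_counter() - t0

        stage = "transform"
        t0 = time.perf_counter()
        if panel.n_days % 2 != 0:
            # drop the last day so the even-length FFT convention applies
            panel = preprocess.DisplacementPanel(
                distances=panel.distances[:, :-1],
                individual_ids=panel.individual_ids,
                dates=panel.dates[:-1],
            )
        tp = preprocess.estimate_transform_exponent(panel)
        write_panel(tp, out / "transformed_panel.csv")
        timings[stage] = time.perf_counter() - t0
        log.info("transform: c = %.4f (objective %.4f)", tp.exponent, tp.objective_value)

        stage = "decompose"
        t0 = time.perf_counter()
        dec = spectral.decompose(tp)
        write_decomposition(dec, out / "spectral")
        timings[stage] = time.perf_counter() - t0

        mcfg = synchrony.McmcConfig(chains=cfg.chains, iterations=cfg.iterations,
                                    burn_in_frac=cfg.burn_in_frac, seed=cfg.seed)
        priors = default_priors()

        stage = "synchrony-scan"
        t0 = time.perf_counter()
        scan = synchrony.scan_cutoff(dec.phases, priors, mcfg)
        timings[stage] = time.perf_counter() - t0
        log.info("scan: selected phi = %d (time scale %s days)", scan.selected,
                 dec.timescale_days(scan.selected) if scan.selected else "inf")
        _json_dump({"scan": _scan_summary(scan),
                    "timescale_days": dec.timescale_days(scan.selected)
                    if scan.selected else None},
                   out / "synchrony_scan.json", cfg)
        scan.table.to_csv(out / "dic_table.csv", index=False)

        stage = "colour"
        t0 = time.perf_counter()
        cfit = colour_mod.run_colour_mcmc(dec.ordinates, priors,
                                          synchrony.McmcConfig(
                                              chains=cfg.chains,
                                              iterations=cfg.iterations,
                                              burn_in_frac=cfg.burn_in_frac,
                                              seed=cfg.seed + 1))
        timings[stage] = time.perf_counter() - t0
        cfit.summaries.to_csv(out / "colour_table.csv")
        _json_dump({"summaries": cfit.summaries, "diagnostics": {
            k: v for k, v in cfit.diagnostics.items()}},
            out / "colour.json", cfg)
        log.info("colour: gammabar = %.3f [%.3f, %.3f]",
                 cfit.summaries.loc["gammabar", "mean"],
                 cfit.summaries.loc["gammabar", "lo95"],
                 cfit.summaries.loc["gammabar", "hi95"])

        stage = "residuals"
        t0 = time.perf_counter()
        lags = tuple(lag for lag in (1, 5, 10) if lag < dec.m)
        rep = colour_mod.residual_diagnostics(
            dec.ordinates, cfit, n_realizations=cfg.n_realizations,
            seed=cfg.seed + 2, lags=lags, individual_ids=panel.individual_ids)
        timings[stage] = time.perf_counter() - t0
        _json_dump({"fractions": rep.fractions, "verdicts": rep.verdicts,
                    "n_realizations": rep.n_realizations},
                   out / "residuals.json", cfg)

        sens = None
        if cfg.sensitivity:
            stage = "sensitivity"
            t0 = time.perf_counter()
            sens = {}
            nu_intervals = [(5.0, 200.0), (5.0, 10.0), (100.0, 200.0)]
            m_priors = [(1.0, 1.0), (0.5, 0.5), (5.0, 5.0)]
            for nu_iv in nu_intervals:
                for mp in m_priors:
                    pri = default_priors(nu_interval=nu_iv, m_prior=mp)
                    s = synchrony.scan_cutoff(dec.phases, pri, mcfg)
                    sens[f"nu{nu_iv[0]:g}-{nu_iv[1]:g}_M{mp[0]:g}-{mp[1]:g}"] = (
                        _scan_summary(s))
            selected = {v["selected_phi"] for v in sens.values()}
            selected.add(scan.selected)
            sens["selected_phi_consistent"] = len(selected) == 1
            _json_dump({"sensitivity": sens}, out / "sensitivity.json", cfg)
            timings[stage] = time.perf_counter() - t0

        if cfg.make_plots:
            stage = "plots"
            _make_plots(scan, cfit, dec, out, cfg.seed)

        for name, dt in timings.items():  # wall times go to the log, not the
            log.info("stage %s: %.2fs", name, dt)  # byte-reproducible JSON
        bundle = {
            "stages": list(timings),
            "transform": {"c": tp.exponent, "objective": tp.objective_value},
            "scan": _scan_summary(scan),
            "selected_timescale_days": dec.timescale_days(scan.selected)
            if scan.selected else None,
            "colour": json.loads(cfit.summaries.to_json(orient="index")),
            "residual_verdicts": json.loads(rep.verdicts.to_json(orient="index")),
            "sensitivity_consistent": sens["selected_phi_consistent"] if sens else None,
        }
        _json_dump(bundle, out / "report.json", cfg)
        return bundle
    except Exception as exc:
        raise RuntimeError(f"report pipeline failed at stage '{stage}': {exc}") from exc


def _make_plots(scan, cfit, dec, out: Path, seed: int):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(scan.table["phi"], scan.table["delta_dic"], "o-")
    ax.axhline(synchrony.DIC_SUPPORT_THRESHOLD, ls=":", color="grey")
    ax.set_xlabel(r"cutoff frequency $\varphi$")
    ax.set_ylabel(r"$\Delta_{DIC}$")
    fig.tight_layout()
    fig.savefig(out / "delta_dic.png", dpi=120)
    plt.close(fig)

    band = colour_mod.posterior_predictive_periodogram(cfit, n_reps=2000, seed=seed)
    fig, ax = plt.subplots(figsize=(6, 4))
    fmean = band["mean"].mean(axis=1)
    ax.loglog(band["frequencies"], fmean, "-", label="predictive mean")
    ax.fill_between(band["frequencies"], band["lo95"].mean(axis=1),
                    band["hi95"].mean(axis=1), alpha=0.3, label="95% band")
    ax.loglog(np.arange(1, dec.m + 1), dec.ordinates, ".", ms=3, alpha=0.5)
    ax.set_xlabel("frequency (cycles per record)")
    ax.set_ylabel(r"periodogram $\psi$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "periodogram_band.png", dpi=120)
    plt.close(fig)
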