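"""Report rendering: HTML pages, figures, parameter tables, phenotype XML.

Outputs for one analysis run form a self-contained local directory:

* ``index.html`` ranking every fitted model per condition by both MAPE
  and reduced chi-square, with layperson model descriptions;
* one page per (condition, model) with the parameter table (value, SEM,
  confidence interval), metrics, and the model equations (also emitted
  as LaTeX fragments);
* growth-curve figures in linear, log-linear and black-and-white
  variants, plus dose-response panels (net / birth / death rate vs dose)
  for drug screens;
* parameter tables as CSV and XLSX;
* a minimal hierarchical XML phenotype record per condition (documented
  in ``docs/phenotype_xml.md``), a deliberately small stand-in schema
  for a full digital-cell-line standard.

All content is deterministic given identical inputs; wall-clock state is
confined to the single provenance timestamp field, which callers may
pin.  Plotted numbers are read from FitResult — nothing is recomputed
here.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "cellphenofit"

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import openpyxl  # noqa: E402
from lxml import etree  # noqa: E402

from . import __version__  # noqa: E402
from .data_io import ExperimentDataset, _deterministic_save  # noqa: E402
from .fitting import FitResult, confidence_interval, rank_models  # noqa: E402
from .growth_models import doubling_time, get_model  # noqa: E402

__all__ = [
    "ReportBundle",
    "render_report",
    "plot_growth_curves",
    "plot_dose_response",
    "write_parameter_tables",
    "write_phenotype_xml",
    "read_phenotype_xml",
    "MODEL_EQUATIONS_LATEX",
]

DEFAULT_FORMATS = ("png", "svg")
ALL_FORMATS = ("png", "jpg", "svg", "eps", "pdf")

MODEL_EQUATIONS_LATEX = {
    "live": r"\frac{d[\mathrm{Live}]}{dt} = r\,[\mathrm{Live}]",
    "live_logistic":
        r"\frac{d[\mathrm{Live}]}{dt} = r\left(1 - "
        r"\frac{[\mathrm{Live}]}{L_{\mathrm{cap}}}\right)[\mathrm{Live}]",
    "live_dead":
        r"\frac{d[\mathrm{Live}]}{dt} = (b - d)\,[\mathrm{Live}],\quad "
        r"\frac{d[\mathrm{Dead}]}{dt} = d\,[\mathrm{Live}] - c\,[\mathrm{Dead}]",
    "live_dead_logistic":
        r"\frac{d[\mathrm{Live}]}{dt} = b\left(1 - "
        r"\frac{[\mathrm{Live}]}{L_{\mathrm{cap}}}\right)[\mathrm{Live}] "
        r"- d\,[\mathrm{Live}],\quad "
        r"\frac{d[\mathrm{Dead}]}{dt} = d\,[\mathrm{Live}] - c\,[\mathrm{Dead}]",
    "total": r"\frac{d[\mathrm{Total}]}{dt} = r\,[\mathrm{Total}]",
    "total_logistic":
        r"\frac{d[\mathrm{Total}]}{dt} = r\left(1 - "
        r"\frac{[\mathrm{Total}]}{T_{\mathrm{cap}}}\right)[\mathrm{Total}]",
}

PARAMETER_MEANINGS = {
    "growth_rate": "net population growth rate (birth minus death)",
    "birth_rate": "cell birth (division) rate; 1/birth_rate is the mean "
                  "time between divisions",
    "death_rate": "cell death rate",
    "clearance_rate": "rate at which dead cells degrade or stop being "
                      "recognized by cell detection",
    "L_cap": "carrying capacity of the live population",
    "T_cap": "carrying capacity of the total population",
    "initial_live": "live cells at the first observation",
    "initial_dead": "dead cells at the first observation",
    "initial_total": "total cells at the first observation",
}

_CSS = """body{font-family:sans-serif;margin:2em;max-width:70em}
table{border-collapse:collapse}td,th{border:1px solid #999;padding:4px 8px}
th{background:#eee}figure{margin:1em 0}code{background:#f4f4f4}"""


@dataclass
class ReportBundle:
    output_dir: Path
    index_page: Path
    model_pages: list[Path] = field(default_factory=list)
    figures: list[Path] = field(default_factory=list)
    tables: list[Path] = field(default_factory=list)
    xml_files: list[Path] = field(default_factory=list)
    latex_files: list[Path] = field(default_factory=list)


def _slug(text: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in text)


def _fmt(x, digits=6):
    if x is None:
        return "n/a"
    return f"{x:.{digits}g}"


# ---------------------------------------------------------------------------
# figures

def _save_fig(fig, stem: Path, formats) -> list[Path]:
    out = []
    for ext in formats:
        p = stem.with_suffix(f".{ext}")
        fig.savefig(p, dpi=150, metadata=None if ext not in ("png",)
                    else {"Software": "cellphenofit"})
        out.append(p)
    plt.close(fig)
    return out


def plot_growth_curves(cond_label: str, series_by_obs, fits: list[FitResult],
                       out_dir: Path, formats=DEFAULT_FORMATS) -> list[Path]:
    """Linear, log-linear and black-and-white growth-curve figures.

    ``series_by_obs`` maps observable -> AggregatedSeries (data points
    with error bars); fitted trajectories are drawn from each FitResult.
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    variants = [("growth", False, True), ("growth_log", True, True),
                ("growth_bw", False, False)]
    markers = ["o", "s", "^", "D", "v", "P"]
    styles = ["-", "--", "-.", ":", (0, (3, 1, 1, 1)), (0, (5, 2))]
    for stem_name, logscale, color in variants:
        fig, ax = plt.subplots(figsize=(6, 4))
        for i, (obs, s) in enumerate(sorted(series_by_obs.items())):
            kw = {} if color else {"color": "black"}
            ax.errorbar(s.times, s.mean,
                        yerr=np.where(np.isfinite(s.sd), s.sd, 0.0),
                        fmt=markers[i % len(markers)], capsize=3,
                        label=f"{obs} (data)", **kw)
        dense = None
        for j, fit in enumerate(fits):
            t = fit.fitted_trajectory.times
            dense = np.linspace(t[0], t[-1], 100)
            from .growth_models import simulate_model
            traj = simulate_model(fit.model_name, fit.estimates, dense)
            for obs, vals in sorted(traj.values.items()):
                kw = {} if color else {"color": "black"}
                ax.plot(dense, vals, linestyle=styles[j % len(styles)],
                        label=f"{obs} ({fit.model_name})", **kw)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("cell count")
        if logscale:
            ax.set_yscale("log")
        ax.set_title(cond_label)
        ax.legend(fontsize=7)
        fig.tight_layout()
        written += _save_fig(fig, out_dir / f"{stem_name}_{_slug(cond_label)}",
                             formats)
    return written


def plot_dose_response(drug_name: str, doses, fits: list[FitResult],
                       out_dir: Path, formats=DEFAULT_FORMATS,
                       truth=None) -> list[Path]:
    """Three-panel dose-response figure: net, birth and death rate vs dose.

    ``fits`` are live_dead fits aligned with ``doses``; SEM error bars
    are drawn where available.  Requires at least 2 doses.
    """
    if len(doses) < 2:
        raise ValueError("need at least 2 doses for a dose-response panel")
    out_dir.mkdir(parents=True, exist_ok=True)
    doses = np.asarray(doses, float)

    def series(getter, sem_getter):
        vals = np.array([getter(f) for f in fits])
        sems = np.array([sem_getter(f) if f.sem else np.nan for f in fits])
        return vals, sems

    birth, birth_sem = series(lambda f: f.estimates["birth_rate"],
                              lambda f: f.sem.get("birth_rate", np.nan))
    death, death_sem = series(lambda f: f.estimates["death_rate"],
                              lambda f: f.sem.get("death_rate", np.nan))
    net = birth - death
    net_sem = np.sqrt(np.nan_to_num(birth_sem) ** 2 + np.nan_to_num(death_sem) ** 2)

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    panels = [("net growth rate", net, net_sem),
              ("birth rate", birth, birth_sem),
              ("death rate", death, death_sem)]
    for ax, (title, vals, sems) in zip(axes, panels):
        ax.errorbar(doses, vals, yerr=np.where(np.isfinite(sems), sems, 0.0),
                    fmt="o-", capsize=3)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_title(f"{drug_name}: {title}")
        ax.set_xlabel("dose")
        ax.set_ylabel("rate (1/h)")
        ax.set_xscale("log" if np.all(doses > 0) else "linear")
    if truth is not None:
        tb = [truth[i]["birth_rate"] for i in range(len(doses))]
        td = [truth[i]["death_rate"] for i in range(len(doses))]
        axes[0].plot(doses, np.array(tb) - np.array(td), "k--", lw=0.8)
        axes[1].plot(doses, tb, "k--", lw=0.8)
        axes[2].plot(doses, td, "k--", lw=0.8)
    fig.tight_layout()
    return _save_fig(fig, out_dir / f"dose_response_{_slug(drug_name)}", formats)


# ---------------------------------------------------------------------------
# tables

def _parameter_rows(fit: FitResult, ci_level: float):
    rows = []
    for name, entry in fit.estimates.entries.items():
        sem = fit.sem.get(name) if fit.sem else None
        if sem is not None:
            lo, hi = confidence_interval(entry.value, sem, ci_level)
            ci = f"[{_fmt(lo)}, {_fmt(hi)}]"
        else:
            ci = "n/a"
        rows.append([name, entry.unit, entry.value,
                     sem if sem is not None else "n/a", ci,
                     PARAMETER_MEANINGS.get(name, "")])
    return rows


def write_parameter_tables(cond_label: str, fits: list[FitResult],
                           out_dir: Path, ci_level: float = 95.0) -> list[Path]:
    """Emit the per-condition parameter table as CSV and XLSX."""
    out_dir.mkdir(parents=True, exist_ok=True)
    header = ["model", "parameter", "unit", "estimate", "sem",
              f"ci_{ci_level:g}", "meaning", "wsse", "mape_pct",
              "reduced_chi2", "n_data", "n_parameters"]
    rows = []
    for fit in fits:
        for prow in _parameter_rows(fit, ci_level):
            rows.append([fit.model_name, *prow, fit.wsse, fit.mape,
                         fit.reduced_chi2 if fit.reduced_chi2 is not None
                         else "n/a", fit.n_data, fit.n_parameters])

    base = out_dir / f"parameters_{_slug(cond_label)}"
    csv_path = base.with_suffix(".csv")
    import csv as _csv
    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        w = _csv.writer(fh)
        w.writerow(header)
        for row in rows:
            w.writerow([repr(v) if isinstance(v, float) else v for v in row])

    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = "parameters"
    ws.append(header)
    for row in rows:
        ws.append(["n/a" if v is None else v for v in row])
    xlsx_path = base.with_suffix(".xlsx")
    _deterministic_save(wb, xlsx_path)
    return [csv_path, xlsx_path]


# ---------------------------------------------------------------------------
# phenotype XML

def write_phenotype_xml(best_fit: FitResult, metadata: dict, user_info: dict,
                        path, timestamp: str = "unspecified") -> Path:
    """Write a minimal hierarchical phenotype record for the best fit.

    The schema (documented in docs/phenotype_xml.md) records cell-line
    identity, the winning model, every parameter with value/units/SEM,
    fit metrics, and provenance.  Float values are serialized with
    ``repr`` so a round trip through :func:`read_phenotype_xml` is exact.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    root = etree.Element("cell_phenotype_record", version="1")
    cl = etree.SubElement(root, "cell_line")
    cl.set("name", str(metadata.get("cell_line_name", "unknown")))
    cl.set("media", str(metadata.get("media", "")))
    prov = etree.SubElement(root, "provenance")
    prov.set("tool", "cellphenofit")
    prov.set("tool_version", __version__)
    prov.set("timestamp", timestamp)
    user = etree.SubElement(prov, "user")
    user.set("name", str(user_info.get("name", "")))
    user.set("contact", str(user_info.get("contact", "")))
    model = etree.SubElement(root, "model", name=best_fit.model_name)
    desc = etree.SubElement(model, "description")
    desc.text = get_model(best_fit.model_name).description
    params = etree.SubElement(model, "parameters")
    for name, entry in best_fit.estimates.entries.items():
        p = etree.SubElement(params, "parameter", name=name, units=entry.unit)
        p.set("value", repr(entry.value))
        sem = best_fit.sem.get(name) if best_fit.sem else None
        if sem is not None:
            p.set("sem", repr(sem))
    metrics = etree.SubElement(model, "metrics")
    metrics.set("wsse", repr(best_fit.wsse))
    metrics.set("mape_percent", repr(best_fit.mape))
    if best_fit.reduced_chi2 is not None:
        metrics.set("reduced_chi2", repr(best_fit.reduced_chi2))
    metrics.set("n_data", str(best_fit.n_data))
    metrics.set("n_parameters", str(best_fit.n_parameters))
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True,
               encoding="UTF-8")
    return path


def read_phenotype_xml(path) -> dict:
    """Parse a phenotype record back to a plain dict (round-trip exact)."""
    root = etree.parse(str(path)).getroot()
    model = root.find("model")
    params = {}
    for p in model.find("parameters"):
        params[p.get("name")] = {
            "value": float(p.get("value")),
            "units": p.get("units"),
            "sem": float(p.get("sem")) if p.get("sem") is not None else None,
        }
    metrics = model.find("metrics")
    return {
        "cell_line": root.find("cell_line").get("name"),
        "model": model.get("name"),
        "parameters": params,
        "metrics": {k: (int(v) if k.startswith("n_") else float(v))
                    for k, v in metrics.attrib.items()},
    }


# ---------------------------------------------------------------------------
# HTML report

def _rank_table(fits: list[FitResult], metric: str, cond_slug: str) -> str:
    ranked = rank_models(fits, metric)
    rows = []
    for i, f in enumerate(ranked, 1):
        chi2 = _fmt(f.reduced_chi2) if f.reduced_chi2 is not None else "n/a"
        rows.append(
            f"<tr><td>{i}</td>"
            f"<td><a href='model_{cond_slug}_{f.model_name}.html'>"
            f"{f.model_name}</a></td>"
            f"<td>{_fmt(f.mape)}</td><td>{chi2}</td>"
            f"<td>{f.n_parameters}</td>"
            f"<td>{'yes' if f.converged else 'no'}</td></tr>"
        )
    return ("<table><tr><th>rank</th><th>model</th><th>MAPE (%)</th>"
            "<th>reduced &chi;&sup2;</th><th>parameters</th>"
            "<th>converged</th></tr>" + "".join(rows) + "</table>")


def _model_page(cond_label: str, fit: FitResult, ci_level: float) -> str:
    spec = get_model(fit.model_name)
    prow_html = []
    for name, unit, value, sem, ci, meaning in _parameter_rows(fit, ci_level):
        prow_html.append(
            f"<tr><td>{name}</td><td>{unit}</td><td>{_fmt(value)}</td>"
            f"<td>{_fmt(sem) if isinstance(sem, float) else sem}</td>"
            f"<td>{ci}</td><td>{html.escape(meaning)}</td></tr>")
    extras = ""
    rate = None
    for rn in ("growth_rate",):
        if rn in fit.estimates and fit.estimates[rn] > 0:
            rate = fit.estimates[rn]
    if rate is None and "birth_rate" in fit.estimates:
        net = fit.estimates["birth_rate"] - fit.estimates["death_rate"]
        rate = net if net > 0 else None
    if rate is not None:
        extras = (f"<p>Implied population doubling time: "
                  f"<b>{_fmt(doubling_time(rate), 3)} h</b>.</p>")
    chi2 = _fmt(fit.reduced_chi2) if fit.reduced_chi2 is not None else \
        "n/a (no spare degrees of freedom)"
    return f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{cond_label}: {fit.model_name}</title>
<style>{_CSS}</style></head><body>
<h1>{html.escape(cond_label)} &mdash; {fit.model_name}</h1>
<p>{html.escape(spec.description)}</p>
<p>Model equations: <code>{html.escape(MODEL_EQUATIONS_LATEX[fit.model_name])}</code></p>
<h2>Estimated parameters (CI level {ci_level:g} %)</h2>
<table><tr><th>parameter</th><th>unit</th><th>estimate</th><th>SEM</th>
<th>CI</th><th>meaning</th></tr>{''.join(prow_html)}</table>
{extras}
<h2>Fit quality</h2>
<table>
<tr><th>WSSE</th><td>{_fmt(fit.wsse)}</td></tr>
<tr><th>MAPE</th><td>{_fmt(fit.mape)} %</td></tr>
<tr><th>reduced &chi;&sup2;</th><td>{chi2}</td></tr>
<tr><th>data points</th><td>{fit.n_data}</td></tr>
<tr><th>parameters</th><td>{fit.n_parameters}</td></tr>
</table>
<p><a href="index.html">back to index</a></p>
</body></html>"""


def render_report(fits_by_condition: dict[str, list[FitResult]],
                  dataset: ExperimentDataset, output_dir,
                  series_by_condition=None, formats=DEFAULT_FORMATS,
                  ci_level: float = 95.0,
                  timestamp: str = "unspecified") -> ReportBundle:
    """Render the full report directory for all fitted conditions.

    ``fits_by_condition`` maps condition label -> list of FitResult;
    ``series_by_condition`` (optional) maps condition label ->
    {observable: AggregatedSeries} to draw data points in figures.
    Content is byte-deterministic given identical inputs and timestamp.
    """
    if not any(f.converged for fits in fits_by_condition.values() for f in fits):
        raise ValueError("no converged fit to report")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(output_dir=out, index_page=out / "index.html")

    sections = []
    for cond_label, fits in fits_by_condition.items():
        cond_slug = _slug(cond_label)
        for fit in fits:
            page = out / f"model_{cond_slug}_{fit.model_name}.html"
            page.write_text(_model_page(cond_label, fit, ci_level),
                            encoding="utf-8")
            bundle.model_pages.append(page)
            tex = out / f"equations_{fit.model_name}.tex"
            if not tex.exists():
                tex.write_text(MODEL_EQUATIONS_LATEX[fit.model_name] + "\n",
                               encoding="utf-8")
                bundle.latex_files.append(tex)
        bundle.tables += write_parameter_tables(cond_label, fits, out, ci_level)

        best = rank_models(fits, "reduced_chi2")[0]
        xml_path = out / f"phenotype_{cond_slug}.xml"
        write_phenotype_xml(best, dataset.metadata, dataset.user_info,
                            xml_path, timestamp=timestamp)
        bundle.xml_files.append(xml_path)

        if series_by_condition and cond_label in series_by_condition:
            bundle.figures += plot_growth_curves(
                cond_label, series_by_condition[cond_label], fits, out, formats)

        fig_html = ""
        for ext in ("png", "svg"):
            p = out / f"growth_{cond_slug}.{ext}"
            if p.exists():
                fig_html = (f"<figure><img src='{p.name}' width='480'>"
                            f"<figcaption>Growth curves for "
                            f"{html.escape(cond_label)}: replicate means "
                            f"&plusmn; sd with fitted model trajectories."
                            f"</figcaption></figure>")
                break
        sections.append(f"""
<h2>Condition: {html.escape(cond_label)}</h2>
<h3>Ranked by reduced &chi;&sup2;</h3>
{_rank_table(fits, "reduced_chi2", cond_slug)}
<h3>Ranked by MAPE</h3>
{_rank_table(fits, "mape", cond_slug)}
{fig_html}
<p>Tables: <a href='parameters_{cond_slug}.csv'>CSV</a>,
<a href='parameters_{cond_slug}.xlsx'>XLSX</a>;
phenotype record: <a href='phenotype_{cond_slug}.xml'>XML</a></p>""")

    cell_line = html.escape(str(dataset.metadata.get("cell_line_name", "unknown")))
    index = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Growth-model report</title>
<style>{_CSS}</style></head><body>
<h1>Cell population dynamics report</h1>
<p>Cell line: <b>{cell_line}</b>.
Models are ranked ascending by each metric (lower is better); the
reduced &chi;&sup2; ranking penalizes model complexity, MAPE measures
average percent deviation per data point.</p>
<p>Generated by cellphenofit {__version__}; timestamp: {timestamp}.</p>
{''.join(sections)}
</body></html>"""
    bundle.index_page.write_text(index, encoding="utf-8")
    return bundle
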