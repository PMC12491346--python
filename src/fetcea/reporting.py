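"""Report bundles, run manifest, and the pipeline driver.

Machine outputs (CSV/JSON) carry full-precision numbers; the human-readable
text report applies the display conventions (whole-percent effectiveness,
euro amounts with comma thousands separators, cents) exactly once.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from importlib import metadata
from pathlib import Path

import pandas as pd

from . import dsa as _dsa
from . import psa as _psa
from .config import ModelSpec, config_hash, load_model_spec
from .cost_model import format_eur, format_pct
from .errors import StageError

__all__ = [
    "base_case_report",
    "write_base_case",
    "write_dsa",
    "write_psa",
    "run_base_case",
    "run_full",
]

log = logging.getLogger("fetcea")


def _version() -> str:
    try:
        return metadata.version("fetcea")
    except metadata.PackageNotFoundError:  # running from a source tree
        return "unknown"


def base_case_report(spec: ModelSpec) -> dict:
    """Base-case quantities as a plain dict (exact values as floats +
    display strings); numbers match the module-level operations exactly."""
    result = spec.base_effectiveness()
    ratio = spec.base_ratio()
    report = {
        "model": spec.model_id,
        "label": spec.label,
        "nodes": {
            n: {"value": float(v), "display_pct": format_pct(v)}
            for n, v in spec.nodes.values.items()
        },
        "effectiveness": {
            s: {
                "label": spec.strategy_labels[s],
                "value": float(result.eff_by_strategy[s]),
                "display_pct": format_pct(result.eff_by_strategy[s]),
            }
            for s in spec.strategy_ids
        },
        "incremental_effectiveness": None,
        "costs": {
            "per_scan_eur": {m: float(spec.cost_profile.scan_cost(m)) for m in spec.cost_profile.items_by_modality},
            "per_lesion_eur": {s: float(spec.lesion_cost(s)) for s in spec.strategy_ids},
            "scan_factor": float(spec.cost_profile.scan_factor),
            "n_scans": spec.cost_profile.n_scans,
            "n_lesions": spec.cost_profile.n_lesions,
        },
        "ratio": {
            "kind": spec.ratio_kind,
            "value": float(ratio),
            "display": format_eur(ratio),
            "dominated": spec.is_incremental and result.incremental < 0,
        },
        "theoretical": result.theoretical,
    }
    if spec.is_incremental:
        report["incremental_effectiveness"] = {
            "value": float(result.incremental),
            "display_pct": format_pct(result.incremental),
        }
        report["costs"]["incremental_per_lesion_eur"] = float(spec.incremental_cost())
    return report


def _base_case_text(report: dict) -> str:
    lines = [f"Base case — {report['label']}", ""]
    lines.append("Chance nodes:")
    for n, entry in report["nodes"].items():
        lines.append(f"  {n}: {entry['display_pct']}%")
    lines.append("")
    for s, entry in report["effectiveness"].items():
        lines.append(f"Effectiveness [{entry['label']}]: {entry['display_pct']}%")
    ie = report["incremental_effectiveness"]
    if ie is not None:
        lines.append(f"Incremental effectiveness: {ie['display_pct']}%")
    lines.append("")
    for m, v in report["costs"]["per_scan_eur"].items():
        lines.append(f"Cost per {m.upper()} scan: {format_eur(v)}")
    for s, v in report["costs"]["per_lesion_eur"].items():
        lines.append(f"Cost per lesion [{s}]: {format_eur(v)}")
    cohort = report["costs"]
    lines.append(f"Scan factor: {cohort['n_scans']}/{cohort['n_lesions']}")
    lines.append("")
    ratio = report["ratio"]
    lines.append(f"{ratio['kind']}: {ratio['display']} per correctly identified TRC lesion")
    if ratio["dominated"]:
        lines.append("NOTE: negative incremental effectiveness — index strategy dominated")
    lines.append("")
    return "\n".join(lines)


def write_base_case(spec: ModelSpec, out_dir: Path) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    report = base_case_report(spec)
    ratio = report["ratio"]
    ie = report["incremental_effectiveness"]
    log.info(
        "%s base case: eff=%s IE=%s cost=%s %s=%s",
        spec.model_id,
        {s: e["display_pct"] for s, e in report["effectiveness"].items()},
        None if ie is None else ie["display_pct"],
        {s: format_eur(v) for s, v in report["costs"]["per_lesion_eur"].items()},
        ratio["kind"],
        ratio["display"],
    )
    paths = []
    p = out_dir / "base_case.json"
    p.write_text(json.dumps(report, indent=2) + "\n")
    paths.append(p)

    rows = [
        {"quantity": f"effectiveness_{s}", "value": e["value"], "display": e["display_pct"] + "%"}
        for s, e in report["effectiveness"].items()
    ]
    if ie is not None:
        rows.append({"quantity": "incremental_effectiveness", "value": ie["value"], "display": ie["display_pct"] + "%"})
    for s, v in report["costs"]["per_lesion_eur"].items():
        rows.append({"quantity": f"cost_per_lesion_{s}", "value": v, "display": format_eur(v)})
    rows.append({"quantity": ratio["kind"].lower(), "value": ratio["value"], "display": ratio["display"]})
    p = out_dir / "base_case.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    paths.append(p)

    p = out_dir / "base_case.txt"
    p.write_text(_base_case_text(report))
    paths.append(p)

    breakdown = []
    for modality, items in spec.cost_profile.items_by_modality.items():
        for item in items:
            breakdown.append(
                {"modality": modality, "code": item.code, "label": item.label, "amount_eur": str(item.amount)}
            )
        breakdown.append(
            {"modality": modality, "code": "TOTAL", "label": "per-scan total",
             "amount_eur": str(spec.cost_profile.scan_cost(modality))}
        )
    p = out_dir / "cost_breakdown.csv"
    pd.DataFrame(breakdown).to_csv(p, index=False)
    paths.append(p)
    return paths


def write_dsa(spec: ModelSpec, out_dir: Path, plot: bool = False) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = _dsa.tornado_table(spec, _dsa.default_intervals(spec))
    frame = _dsa.rows_to_frame(spec, rows)
    paths = [out_dir / "dsa.csv"]
    frame.to_csv(paths[0], index=False)
    if plot:
        paths.append(_dsa.tornado_plot(spec, rows, out_dir / "tornado.svg"))
    return paths


def write_psa(
    spec: ModelSpec,
    config: _psa.PsaConfig,
    out_dir: Path,
    write_draws: bool = True,
    plot: bool = False,
) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    result = _psa.run_psa(spec, config)
    s = result.summary
    paths = []
    if write_draws:
        p = out_dir / "psa_draws.csv"
        result.draws.to_csv(p, index=False)
        paths.append(p)
    p = out_dir / "psa_summary.csv"
    s.table.rename_axis("statistic").to_csv(p)
    paths.append(p)
    meta = {
        "model": s.model_id,
        "n_draws": s.n_draws,
        "seed": config.seed,
        "ratio_kind": s.ratio_kind,
        "summary_ratio_eur": s.summary_ratio,
        "summary_ratio_display": format_eur(s.summary_ratio),
        "mean_of_per_draw_ratios_eur": s.mean_of_ratios,
        "n_excluded": s.n_excluded,
        "n_ratio_undefined": s.n_ratio_undefined,
        "theoretical_fraction": dict(s.theoretical_fraction),
    }
    p = out_dir / "psa_summary.json"
    p.write_text(json.dumps(meta, indent=2) + "\n")
    paths.append(p)
    if plot:
        paths.append(_psa.scatter_plot(result, spec, out_dir / "psa_scatter.svg"))
    return paths


def _write_manifest(out_dir: Path, config_path: Path, seeds: dict, outputs: list[Path]) -> Path:
    manifest = {
        "config": str(config_path),
        "config_sha256": config_hash(config_path),
        "seeds": seeds,
        "package_version": _version(),
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "outputs": {
            str(p.relative_to(out_dir)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(outputs)
        },
    }
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2) + "\n")
    return p


def run_base_case(config_path: str | Path, out_dir: str | Path) -> dict:
    """Load a model spec, emit the base-case bundle, return the report dict."""
    spec = load_model_spec(config_path)
    write_base_case(spec, Path(out_dir))
    return base_case_report(spec)


def run_full(
    config_path: str | Path,
    out_dir: str | Path,
    seed: int,
    n_draws: int = 10_000,
    write_draws: bool = True,
    plot: bool = False,
) -> Path:
    """Base case + DSA + PSA in one run; the manifest is written last.

    A failing stage raises :class:`~fetcea.errors.StageError` naming the
    stage; outputs of earlier stages are left intact.
    """
    config_path = Path(config_path)
    out_dir = Path(out_dir)
    spec = load_model_spec(config_path)
    outputs: list[Path] = []
    stages = [
        ("base_case", lambda: write_base_case(spec, out_dir)),
        ("dsa", lambda: write_dsa(spec, out_dir, plot=plot)),
        (
            "psa",
            lambda: write_psa(
                spec,
                _psa.PsaConfig(seed=seed, n_draws=n_draws),
                out_dir,
                write_draws=write_draws,
                plot=plot,
            ),
        ),
    ]
    for name, fn in stages:
        try:
            outputs.extend(fn())
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc
    return _write_manifest(out_dir, config_path, {"psa": seed, "n_draws": n_draws}, outputs)
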