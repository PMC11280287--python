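"""One-shot orchestration of the full IVPT analysis from a YAML bundle.

A bundle lists the input CSVs, the cell config, the replicate→group map,
needle metadata and prediction targets::

    config: cell.yaml
    receptor: receptor.csv
    group_map: groups.csv          # columns: replicate,group
    pores: pores.csv               # optional
    integrity: integrity.csv       # optional
    disposition: disposition.csv   # optional
    rheology: rheology.csv         # optional
    needle:                        # optional, used with pores
      length_um: 449.82
      base_side_um: 164.03
      n_needles: 100
    css_target_ug_per_l: 337       # optional
    n_actual:                      # observed channel count per group
      PLGA-50-8A: 100
    r2_threshold: 0.95
    min_points: 3

Outputs land in one directory: ``table2.csv`` (per-group permeation
parameters, mean ± SD), ``replicates.json``, ``geometry.json``,
``integrity_report.json``, ``disposition.csv``, ``rheo.json``,
``manifest.json`` and ``summary.txt``. Identical inputs give byte-identical
outputs (the manifest records input digests, not wall-clock times).
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__, disposition as dispo, geometry, integrity, io, permeation, rheology
from .errors import IVPTError, SchemaError

logger = logging.getLogger(__name__)

__all__ = ["run_full_analysis", "build_manifest"]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_manifest(bundle: dict, bundle_dir: Path, cfg) -> dict:
    """Run manifest: config snapshot, input digests, package version."""
    inputs = {}
    for key in ("config", "receptor", "group_map", "pores", "integrity", "disposition", "rheology"):
        if key in bundle and bundle[key]:
            p = bundle_dir / bundle[key]
            inputs[key] = {"path": str(bundle[key]), "sha256": _digest(p)}
    return {
        "package": "ivpt",
        "version": __version__,
        "config": {k: v for k, v in asdict(cfg).items() if v is not None},
        "inputs": inputs,
        "parameters": {
            k: bundle[k]
            for k in ("r2_threshold", "min_points", "css_target_ug_per_l", "n_actual", "needle")
            if k in bundle
        },
    }


def _read_group_map(path: Path) -> dict:
    import pandas as pd

    df = pd.read_csv(path, dtype=str)
    for col in ("replicate", "group"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return dict(zip(df["replicate"], df["group"]))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_full_analysis(bundle_path, out_dir) -> Path:
    """Run every configured stage and write the report directory.

    Raises :class:`~ivpt.errors.IVPTError` (with the stage name in the
    message) on any failure; partial outputs are discarded — the output
    directory is populated atomically via a temp directory.
    """
    bundle_path = Path(bundle_path)
    bundle_dir = bundle_path.parent
    bundle = yaml.safe_load(bundle_path.read_text())
    if not isinstance(bundle, dict):
        raise SchemaError(f"{bundle_path}: bundle must be a mapping")
    for key in ("config", "receptor", "group_map"):
        if key not in bundle:
            raise SchemaError(f"{bundle_path}: bundle missing required key {key!r}")

    out_dir = Path(out_dir)
    r2_threshold = float(bundle.get("r2_threshold", 0.95))
    min_points = int(bundle.get("min_points", 3))
    css_target = bundle.get("css_target_ug_per_l")
    n_actual_map = bundle.get("n_actual") or {}
    needle = bundle.get("needle") or {}

    tmp = Path(tempfile.mkdtemp(prefix="ivpt-report-"))
    try:
        cfg = _stage("config", io.load_config, bundle_dir / bundle["config"])
        manifest = build_manifest(bundle, bundle_dir, cfg)
        group_map = _stage("group_map", _read_group_map, bundle_dir / bundle["group_map"])
        series = _stage("receptor", io.read_receptor_csv, bundle_dir / bundle["receptor"])

        pore_sets = []
        if bundle.get("pores"):
            pore_sets = _stage("pores", io.read_pores_csv, bundle_dir / bundle["pores"])
        dense_factors = {}
        geometry_report = {}
        for ps in pore_sets:
            n_act = int(n_actual_map.get(ps.group, len(ps)))
            n_dense = permeation.dense_channel_count(float(np.mean(ps.areas)))
            dense_factors[ps.group] = n_dense / n_act
            summary = geometry.summarize_pores(
                ps,
                base_side_um=needle.get("base_side_um"),
                permeation_area_cm2=cfg.permeation_area,
                needle_length_um=needle.get("length_um"),
                n_channels=n_act,
            )
            geometry_report[ps.group] = {**asdict(summary), "n_dense_per_cm2": n_dense}

        # group the receptor replicates and fit each group
        by_group: dict[str, list] = {}
        for s in series:
            grp = group_map.get(s.replicate_id)
            if grp is None:
                raise SchemaError(f"replicate {s.replicate_id!r} missing from group map")
            by_group.setdefault(grp, []).append(s)

        logger.info(
            "permeation stage: %d groups, cell V=%.3g mL Vi=%.3g mL A=%.3g sq·cm "
            "C=%.4g µg/mL h=%.4g cm Cl=%.4g mL/h",
            len(by_group), cfg.receptor_volume, cfg.sample_volume, cfg.permeation_area,
            cfg.donor_concentration, cfg.skin_thickness, cfg.clearance,
        )
        summaries = {}
        for grp, reps in sorted(by_group.items()):
            summaries[grp] = _stage(
                f"permeation[{grp}]",
                permeation.summarize_group,
                grp,
                reps,
                cfg,
                r2_threshold=r2_threshold,
                min_points=min_points,
                dense_factor=dense_factors.get(grp, 1.0),
            )
        _write_table2(tmp / "table2.csv", summaries, dense_factors, css_target, cfg)
        replicates = {
            grp: s.replicates.to_dict(orient="records") for grp, s in summaries.items()
        }
        (tmp / "replicates.json").write_text(
            json.dumps(replicates, indent=2, default=_json_default, sort_keys=True)
        )
        if geometry_report:
            (tmp / "geometry.json").write_text(
                json.dumps(geometry_report, indent=2, default=_json_default, sort_keys=True)
            )

        if bundle.get("integrity"):
            records = _stage("integrity", io.read_integrity_csv, bundle_dir / bundle["integrity"])
            res = integrity.resistance_summary(records, cfg)
            tewl_groups = {}
            for rec in records:
                tewl_groups.setdefault(rec.group, []).append(rec.tewl)
            report = {"groups": res}
            if len(tewl_groups) >= 2 and all(len(v) >= 2 for v in tewl_groups.values()):
                tests = integrity.group_tests(tewl_groups)
                report["tewl_anova"] = {"f": tests.anova_f, "p": tests.anova_p}
                report["tewl_tukey"] = {f"{a}|{b}": p for (a, b), p in tests.tukey.items()}
            (tmp / "integrity_report.json").write_text(
                json.dumps(report, indent=2, default=_json_default, sort_keys=True)
            )

        if bundle.get("disposition"):
            records = _stage(
                "disposition", io.read_disposition_csv, bundle_dir / bundle["disposition"]
            )
            table = dispo.summarize_disposition(records, cfg)
            table.to_csv(tmp / "disposition.csv", index=False)

        if bundle.get("rheology"):
            sweeps = _stage("rheology", io.read_rheology_csv, bundle_dir / bundle["rheology"])
            rheo_report = {}
            for sweep in sweeps:
                if sweep.kind == "amplitude":
                    entry = {"lve_limit_strain": rheology.lve_limit(sweep)}
                    try:
                        strain, modulus = rheology.flow_point(sweep)
                        entry.update(flow_point_strain=strain, flow_point_modulus=modulus)
                    except IVPTError as exc:
                        entry["flow_point_error"] = str(exc)
                    rheo_report["amplitude"] = entry
                elif sweep.kind == "thixotropy":
                    rheo_report["thixotropy"] = {
                        "recovery_percent": rheology.thixotropic_recovery(sweep)
                    }
                elif sweep.kind == "frequency":
                    rheo_report["frequency"] = {
                        "elastic_dominant": bool(np.all(sweep.g_prime > sweep.g_double_prime))
                    }
            (tmp / "rheo.json").write_text(
                json.dumps(rheo_report, indent=2, default=_json_default, sort_keys=True)
            )

        (tmp / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=_json_default, sort_keys=True)
        )
        _write_summary(tmp / "summary.txt", summaries, cfg)

        out_dir.mkdir(parents=True, exist_ok=True)
        for f in sorted(tmp.iterdir()):
            shutil.copy2(f, out_dir / f.name)
        return out_dir
    finally:
        shutil.rmtree(tmp, ignore_errors=True)


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except IVPTError as exc:
        raise type(exc)(f"stage {name!r}: {exc}") from exc


def _write_table2(path, summaries, dense_factors, css_target, cfg):
    import pandas as pd

    rows = []
    for grp, s in sorted(summaries.items()):
        row = {"group": grp, "n": s.n}
        for metric, label, scale in (
            ("q24", "q24_ug_cm2", 1.0),
            ("lag", "lag_h", 1.0),
            ("flux", "flux_ug_cm2_h", 1.0),
            ("d", "d_1e5_cm2_h", 1e5),
            ("kp", "kp_1e4_cm_h", 1e4),
            ("css", "css_ug_l", 1.0),
        ):
            row[f"{label}_mean"] = s.mean[metric] * scale
            row[f"{label}_sd"] = s.sd[metric] * scale
        if grp in dense_factors:
            row["j_dense_ug_cm2_h"] = s.mean["flux"] * dense_factors[grp]
            if css_target is not None:
                row["required_area_cm2"] = permeation.required_array_area(
                    float(css_target), cfg.clearance, row["j_dense_ug_cm2_h"]
                )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def _write_summary(path, summaries, cfg):
    lines = [
        "IVPT analysis summary",
        f"cell: V={cfg.receptor_volume} mL, Vi={cfg.sample_volume} mL, "
        f"A={cfg.permeation_area} sq·cm, C={cfg.donor_concentration} µg/mL, "
        f"h={cfg.skin_thickness} cm, Cl={cfg.clearance} mL/h",
        "",
    ]
    for grp, s in sorted(summaries.items()):
        lines.append(
            f"{grp}: Q24 = {s.mean['q24']:.2f} ± {s.sd['q24']:.2f} µg/sq·cm, "
            f"lag = {s.mean['lag']:.2f} ± {s.sd['lag']:.2f} h, "
            f"J = {s.mean['flux']:.2f} ± {s.sd['flux']:.2f} µg/sq·cm/h, "
            f"Kp = {s.mean['kp'] * 1e4:.2f} ± {s.sd['kp'] * 1e4:.2f} ×10⁻⁴ cm/h, "
            f"Css = {s.mean['css']:.2f} ± {s.sd['css']:.2f} µg/L (n={s.n})"
        )
    Path(path).write_text("\n".join(lines) + "\n")
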