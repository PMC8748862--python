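"""End-to-end orchestration: config validation, stage execution, run report.

A pipeline run is described by a plain YAML/dict config:

.. code-block:: yaml

    seed: 1
    output_dir: out
    simulate:                 # optional: generate inputs before any stage
      rrna_fasta: {path: rrna.fasta}
      de_table: {path: de.tsv, n_genes: 1000, n_up: 50, n_down: 20}
      qpcr: {path: qpcr.csv, te_map: {IGF1R: {NT: 2.0, FU10: 2.0}}, ct_sd: 0.1}
      growth: {path: growth.csv, slope: 0.5, intercept: 3.0,
               timepoints: [0, 12, 24, 36, 48, 60, 72]}
    stages:
      composition: {fasta: rrna.fasta, output: composition.csv}
      translatome: {de_table: de.tsv, log2fc_threshold: 1.0, alpha: 0.05}
      te: {input: qpcr.csv, control: NT}
      growth: {input: growth.csv, window: [0, 72]}

Validation is complete before execution: every stage input must either
exist on disk, be declared as a simulate target, or be produced by an
earlier stage; parameter ranges are checked up front, so an invalid
config never leaves partial outputs.  Stages run in fixed dependency
order (composition, quantify, te, reporter, growth, translatome).  All
tabular outputs are written with six significant digits and the run
report (seed, parameters actually used, per-stage summaries, package
version) goes to ``report.json`` — identical config and seed give
byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from fluoribo import __version__, composition, lchrms, polysome, reporters, translatome
from fluoribo import simulate as sim
from fluoribo.errors import ConfigError, DataError

FLOAT_FORMAT = "%.6g"

_STAGE_ORDER = ("composition", "quantify", "te", "reporter", "growth", "translatome")

#: stage -> config keys holding input paths
_STAGE_INPUTS = {
    "composition": ("fasta",),
    "quantify": ("standards", "samples", "composition"),
    "te": ("input",),
    "reporter": ("plate",),
    "growth": ("input",),
    "translatome": ("de_table", "de_table_b"),
}

#: stage -> default output file name
_STAGE_OUTPUTS = {
    "composition": "composition.csv",
    "quantify": "estimates.csv",
    "te": "te.csv",
    "reporter": "reporter.csv",
    "growth": "growth_rates.csv",
    "translatome": "classification.tsv",
}


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline config."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def _write_csv(df: pd.DataFrame, path: Path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)


def _validate(config: Mapping[str, Any], outdir: Path) -> dict[str, Path]:
    """Check the whole config up front; return resolved stage-input paths."""
    stages = config.get("stages", {})
    if not stages:
        raise ConfigError("config declares no stages")
    unknown = set(stages) - set(_STAGE_ORDER)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")

    produced: set[Path] = set()
    for params in (config.get("simulate") or {}).values():
        if "path" not in params:
            raise ConfigError("every simulate target needs a 'path'")
        produced.add((outdir / params["path"]).resolve())
    for name in _STAGE_ORDER:
        if name in stages:
            out_name = stages[name].get("output", _STAGE_OUTPUTS[name])
            produced.add((outdir / out_name).resolve())

    resolved: dict[str, Path] = {}
    for name, params in stages.items():
        for key in _STAGE_INPUTS[name]:
            if key not in params:
                if key == "de_table_b":  # optional second condition
                    continue
                raise ConfigError(f"stage {name!r} missing input {key!r}")
            raw = Path(params[key])
            candidates = [raw, outdir / raw]
            hit = next(
                (c for c in candidates if c.exists() or c.resolve() in produced), None
            )
            if hit is None:
                raise ConfigError(f"stage {name!r}: input file not found: {raw}")
            resolved[f"{name}.{key}"] = outdir / raw if not raw.exists() else raw

    # parameter ranges
    t = stages.get("translatome", {})
    if not 0 < t.get("alpha", 0.05) <= 1:
        raise ConfigError("translatome alpha outside (0, 1]")
    if t.get("log2fc_threshold", 1.0) < 0:
        raise ConfigError("translatome log2fc_threshold must be non-negative")
    g = stages.get("growth", {})
    window = g.get("window", [0.0, 72.0])
    if len(window) != 2 or not window[0] < window[1]:
        raise ConfigError("growth window must be [start, end] with start < end")
    return resolved


def _run_simulate(config: Mapping[str, Any], outdir: Path, seed: int) -> dict:
    """Generate declared synthetic inputs; one derived seed per target."""
    report = {}
    targets = config.get("simulate") or {}
    for i, (kind, params) in enumerate(sorted(targets.items())):
        p = dict(params)
        path = outdir / p.pop("path")
        sub_seed = (seed + 1000 * (i + 1)) % (2**31)
        if kind == "rrna_fasta":
            seqs = sim.simulate_rrna_set(seed=p.pop("seed", sub_seed))
            with open(path, "w") as fh:
                for s in seqs:
                    fh.write(f">{s.id}\n{s.residues}\n")
            report[kind] = {"n_records": len(seqs)}
        elif kind == "de_table":
            df = sim.simulate_de_table(seed=p.pop("seed", sub_seed), **p)
            _write_csv(df, path, sep="\t")
            report[kind] = {"n_genes": len(df)}
        elif kind == "qpcr":
            records = sim.simulate_qpcr_dataset(seed=p.pop("seed", sub_seed), **p)
            rows = [
                {
                    "gene": r.gene,
                    "condition": r.condition,
                    "fraction": r.fraction,
                    "replicate": r.replicate,
                    "ct": r.ct,
                }
                for r in records
            ]
            _write_csv(pd.DataFrame(rows), path)
            report[kind] = {"n_records": len(rows)}
        elif kind == "growth":
            curve = sim.simulate_growth_curve(seed=p.pop("seed", sub_seed), **p)
            rows = pd.DataFrame(
                {
                    "sample_id": curve.sample_id,
                    "condition": curve.condition,
                    "time_h": curve.timepoints,
                    "index": curve.index,
                }
            )
            _write_csv(rows, path)
            report[kind] = {"n_timepoints": len(curve.timepoints)}
        elif kind == "calibration_standards":
            standards = sim.simulate_calibration_standards(seed=p.pop("seed", sub_seed), **p)
            rows = [
                {
                    "analyte": s.analyte,
                    "concentration": s.known_concentration,
                    "peak_area": s.peak_area,
                    "is_area": s.internal_standard_area,
                }
                for s in standards
            ]
            _write_csv(pd.DataFrame(rows), path)
            report[kind] = {"n_standards": len(rows)}
        else:
            raise ConfigError(f"unknown simulate target {kind!r}")
    return report


def _resolve(outdir: Path, raw: str) -> Path:
    p = Path(raw)
    return p if p.exists() else outdir / raw


def run_pipeline(config: Mapping[str, Any], output_dir: str | Path | None = None) -> dict:
    """Validate and execute a pipeline config; return the run report.

    ``output_dir`` overrides the config's ``output_dir``.  The report
    records the seed, every threshold actually used and a per-stage
    summary, and is also written to ``<output_dir>/report.json``.
    """
    outdir = Path(output_dir or config.get("output_dir", "."))
    seed = int(config.get("seed", 0))
    outdir.mkdir(parents=True, exist_ok=True)
    _validate(config, outdir)

    report: dict[str, Any] = {"version": __version__, "seed": seed, "stages": {}}
    report["simulated"] = _run_simulate(config, outdir, seed)
    stages = config["stages"]

    for name in _STAGE_ORDER:
        if name not in stages:
            continue
        params = stages[name]
        out_path = outdir / params.get("output", _STAGE_OUTPUTS[name])
        if name == "composition":
            seqs = composition.read_fasta(_resolve(outdir, params["fasta"]))
            pairs = [(s.id, composition.nucleotide_composition(s)) for s in seqs]
            _write_csv(composition.compositions_to_frame(pairs), out_path)
            ribo = composition.ribosome_composition(pairs)
            report["stages"][name] = {
                "n_sequences": len(pairs),
                "total_length": ribo.total_length,
                "output": str(out_path),
            }
        elif name == "quantify":
            standards = lchrms.read_standards_csv(_resolve(outdir, params["standards"]))
            curves = {a: lchrms.fit_calibration(s) for a, s in standards.items()}
            samples = pd.read_csv(_resolve(outdir, params["samples"]))
            measurements, flags = lchrms.measurements_from_areas(samples, curves)
            comp = composition.composition_from_frame(
                pd.read_csv(_resolve(outdir, params["composition"]))
            )
            refs = tuple(params.get("references", "ACG"))
            estimates = [
                lchrms.fuird_per_ribosome(
                    m,
                    comp,
                    references=refs,
                    method=params.get("method", "per_reference"),
                    lod=params.get("lod"),
                )
                for m in measurements
            ]
            _write_csv(lchrms.estimates_to_frame(estimates), out_path)
            report["stages"][name] = {
                "references": "".join(refs),
                "n_samples": len(estimates),
                "mean_estimate": float(pd.Series([e.mean for e in estimates]).mean()),
                "n_out_of_range": int(len(flags)),
                "output": str(out_path),
            }
        elif name == "te":
            records = polysome.read_qpcr_csv(_resolve(outdir, params["input"]))
            control = params.get("control", "NT")
            results = polysome.translation_efficiency(
                records, control, efficiency=params.get("efficiency", 2.0)
            )
            _write_csv(polysome.te_to_frame(results), out_path)
            report["stages"][name] = {
                "control": control,
                "n_results": len(results),
                "output": str(out_path),
            }
        elif name == "reporter":
            readings = reporters.read_plate_csv(_resolve(outdir, params["plate"]))
            bl_f, bl_r = reporters.blank_means(readings)
            wells = [r for r in readings if not r.is_blank]
            ratios = [reporters.luciferase_ratio(r, bl_f, bl_r) for r in wells]
            fold = reporters.normalize_to_control(
                ratios, [r.condition for r in wells], params.get("control", "NT")
            )
            df = pd.DataFrame(
                {
                    "well_id": [r.well_id for r in wells],
                    "condition": [r.condition for r in wells],
                    "ratio": ratios,
                    "fold_change": fold,
                }
            )
            _write_csv(df, out_path)
            report["stages"][name] = {
                "control": params.get("control", "NT"),
                "n_wells": len(wells),
                "output": str(out_path),
            }
        elif name == "growth":
            curves = reporters.read_growth_csv(_resolve(outdir, params["input"]))
            lo, hi = params.get("window", [0.0, 72.0])
            rows = [
                {
                    "sample_id": c.sample_id,
                    "condition": c.condition,
                    "growth_rate": reporters.growth_rate(c, lo, hi),
                }
                for c in curves
            ]
            _write_csv(pd.DataFrame(rows), out_path)
            report["stages"][name] = {
                "window": [lo, hi],
                "n_curves": len(curves),
                "output": str(out_path),
            }
        elif name == "translatome":
            lfc = params.get("log2fc_threshold", 1.0)
            alpha = params.get("alpha", 0.05)
            df_a = translatome.read_de_table(_resolve(outdir, params["de_table"]))
            c_a = translatome.classify_translation(df_a, lfc, alpha)
            _write_csv(translatome.classification_to_frame(c_a), out_path, sep="\t")
            c_b = None
            if params.get("de_table_b"):
                df_b = translatome.read_de_table(_resolve(outdir, params["de_table_b"]))
                c_b = translatome.classify_translation(df_b, lfc, alpha)
            summary = translatome.summarize_classification(
                c_a, c_b, labels=tuple(params.get("labels", ("A", "B")))
            )
            stage_report = {
                "log2fc_threshold": lfc,
                "alpha": alpha,
                "n_up": len(c_a.up),
                "n_down": len(c_a.down),
                "summary": summary,
                "output": str(out_path),
            }
            report["stages"][name] = stage_report

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
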