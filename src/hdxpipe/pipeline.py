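"""End-to-end orchestration: ingest -> uptake -> differential -> EX1 -> reports.

A run is driven by a TOML config (see :data:`CONFIG_SCHEMA` for the
recognized keys) and produces, under one output directory, the per-peptide
summary table, per-comparison difference tables (and optional figures),
residue classification maps, an EX1 report, and a JSON run manifest
recording the config snapshot, input digests, seed, stage timings and the
complete output inventory. Partial failures (a peptide that cannot be
classified, an envelope that cannot be fit) are logged and skipped; they
never abort the run.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import differential, ex1 as ex1_mod, io, report, simulate, uptake
from .core import LabelingDesign, ValidationError, get_logger

log = get_logger(__name__)

#: Recognized config sections/keys with defaults; "required" marks keys that
#: must be present for a comparison run.
CONFIG_SCHEMA: dict[str, dict[str, Any]] = {
    "design": {"d_frac": 0.85, "time_grid_min": [0.25, 1.0, 10.0, 60.0, 480.0], "temperature_C": 25.0},
    "conventions": {"n_amides": "skip_first"},
    "comparison": {"reference": "required", "tests": "required", "alpha": 0.01, "confidence": 0.95, "n": 3},
    "ex1": {"min_separation_D": 2.0, "min_fraction": 0.15, "min_improvement": 3.0, "min_consecutive": 2},
    "simulate": {"seed": 0, "noise_sd": simulate.DEFAULT_NOISE_SD_D, "back_exchange": simulate.DEFAULT_BACK_EXCHANGE},
    "io": {"plots": False},
}


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    """Fill defaults and reject missing required keys, naming the field."""
    merged: dict[str, Any] = {}
    for section, keys in CONFIG_SCHEMA.items():
        user = config.get(section, {})
        if not isinstance(user, dict):
            raise ValidationError(f"config section [{section}] must be a table")
        merged[section] = {}
        for key, default in keys.items():
            if key in user:
                merged[section][key] = user[key]
            elif default == "required":
                raise ValidationError(f"config missing required field [{section}].{key}")
            else:
                merged[section][key] = default
        for key in user:
            if key not in keys:
                merged[section][key] = user[key]  # pass through unknown keys
    for section in config:
        if section not in CONFIG_SCHEMA:
            merged[section] = config[section]
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict[str, Any]
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "input_digests": self.input_digests,
                    "stage_seconds": self.stage_seconds,
                    "outputs": sorted(self.outputs),
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def build_summary(
    series: dict,
    comparisons: list[differential.ComparisonResult],
    be_results: dict | None = None,
    d_frac: float = 0.85,
) -> pd.DataFrame:
    """Assemble the community-style per-peptide summary table.

    Fixed column order: peptide bounds/sequence/n_amides, back-exchange,
    then mean/SD/n per (state, time), then CI/verdict/rule per comparison.
    """
    keys = sorted({key for (key, _state) in series})
    states = sorted({state for (_key, state) in series})
    times = sorted({float(t) for s in series.values() for t in s.times})
    rows = []
    for key in keys:
        row: dict[str, Any] = {
            "start": key[0],
            "end": key[1],
            "sequence": key[2],
            "n_amides": None,
            "d_frac": d_frac,
            "back_exchange_percent": None,
        }
        for state in states:
            s = series.get((key, state))
            if s is not None:
                row["n_amides"] = s.peptide.n_amides
            for t in times:
                stem = f"{state}_{t:g}min"
                if s is not None and any(abs(s.times - t) < 1e-9):
                    i = int(abs(s.times - t).argmin())
                    row[f"mean_D_{stem}"] = s.mean_D[i]
                    row[f"sd_D_{stem}"] = s.sd_D[i]
                    row[f"n_{stem}"] = int(s.n[i])
                else:
                    row[f"mean_D_{stem}"] = None
                    row[f"sd_D_{stem}"] = None
                    row[f"n_{stem}"] = 0
        if be_results and key in be_results:
            row["back_exchange_percent"] = be_results[key].be_percent
        for comp in comparisons:
            stem = f"{comp.state_ref}_vs_{comp.state_test}"
            call = comp.calls.get(key)
            row[f"ci_D_{stem}"] = comp.ci.ci
            row[f"verdict_{stem}"] = call.verdict if call else None
            row[f"rule_{stem}"] = call.rule_fired if call else None
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    config: dict[str, Any] | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> RunManifest:
    """Execute the full pipeline under one output directory.

    ``config`` is a TOML path or an equivalent dict. When the config has a
    ``[simulate]`` input mode (``config["input"]["mode"] == "simulate"`` or
    no input files given), the synthetic study is generated first and then
    analyzed exactly like read data.
    """
    config_path: Path | None = None
    if not isinstance(config, dict):
        config_path = Path(config)
        config = io.read_config(config_path)
    cfg = validate_config(config)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(cfg["simulate"]["seed"])
    manifest = RunManifest(config=cfg, seed=seed)
    if config_path is not None:
        manifest.input_digests[str(config_path)] = _sha256(config_path)

    design = LabelingDesign(
        d_frac=float(cfg["design"]["d_frac"]),
        time_grid_min=tuple(cfg["design"]["time_grid_min"]),
        temperature_C=float(cfg["design"]["temperature_C"]),
    )
    convention = cfg["conventions"]["n_amides"]
    input_cfg = cfg.get("input", {})
    mode = input_cfg.get("mode", "simulate" if "uptake_table" not in input_cfg else "files")

    def _register(path: Path) -> Path:
        manifest.outputs.append(str(path.relative_to(out_dir)))
        return path

    # -- stage 1: ingest or simulate ---------------------------------------
    t0 = time.perf_counter()
    envelopes: list[ex1_mod.IsotopeEnvelope] = []
    ex1_truth_keys: set[tuple[int, int]] = set()
    if mode == "simulate":
        regions = tuple(
            simulate.DesignedRegion(int(r["start"]), int(r["end"]), float(r["delta_D"]))
            for r in cfg["simulate"].get("designed_regions", [])
        )
        truth = simulate.default_study_truth(
            seed=seed,
            designed_regions=regions,
            include_ex1=bool(cfg["simulate"].get("include_ex1", True)),
            noise_sd=float(cfg["simulate"]["noise_sd"]),
            back_exchange=float(cfg["simulate"]["back_exchange"]),
            convention=convention,
        )
        data = simulate.generate_study(truth, design, out_dir=out_dir / "inputs")
        for p in sorted((out_dir / "inputs").rglob("*")):
            if p.is_file():
                _register(p)
        measurements = data.measurements
        peptides = data.peptide_records()
        controls = {
            (int(r.start), int(r.end), str(r.sequence)): io.MaxLabelControl(
                peptide=peptides[(int(r.start), int(r.end), str(r.sequence))],
                m_max=float(r.m_max),
            )
            for r in data.max_label.itertuples(index=False)
        }
        envelopes = data.envelopes
        ex1_truth_keys = {(k[0], k[1]) for (k, _s) in truth.ex1}
    else:
        protein = io.read_protein(input_cfg["protein"])
        for key in ("protein", "uptake_table", "max_label_table"):
            if key in input_cfg:
                manifest.input_digests[input_cfg[key]] = _sha256(Path(input_cfg[key]))
        measurements, peptides = io.read_uptake_table(
            input_cfg["uptake_table"], protein, design, convention
        )
        controls = (
            io.read_max_label_table(input_cfg["max_label_table"], peptides)
            if "max_label_table" in input_cfg
            else {}
        )
        for env_path in sorted(input_cfg.get("envelopes", [])):
            envelopes.append(io.read_envelope(env_path))
    manifest.stage_seconds["ingest"] = time.perf_counter() - t0

    # -- stage 2: uptake statistics ----------------------------------------
    t0 = time.perf_counter()
    series = uptake.summarize_uptake(measurements, peptides, controls)
    be_results = {
        key: uptake.back_exchange_from_control(ctrl, design.d_frac)
        for key, ctrl in controls.items()
    }
    manifest.stage_seconds["uptake"] = time.perf_counter() - t0

    # -- stage 3: differential comparisons ---------------------------------
    t0 = time.perf_counter()
    comp_cfg = cfg["comparison"]
    tests = comp_cfg["tests"]
    if isinstance(tests, str):
        tests = [tests]
    comparisons: list[differential.ComparisonResult] = []
    if mode == "simulate":
        protein = truth.protein
    for test_state in tests:
        try:
            comp = differential.compare_states(
                measurements,
                series,
                comp_cfg["reference"],
                test_state,
                n=int(comp_cfg["n"]),
                confidence=float(comp_cfg["confidence"]),
                alpha=float(comp_cfg["alpha"]),
            )
        except ValidationError as exc:
            log.warning("comparison %s vs %s skipped: %s", comp_cfg["reference"], test_state, exc)
            continue
        comparisons.append(comp)
        stem = f"{comp.state_ref}_vs_{comp.state_test}"
        fig = out_dir / f"difference_{stem}.png" if cfg["io"]["plots"] else None
        report.render_difference_plot(
            comp, _register(out_dir / f"difference_{stem}.csv"), fig, ex1_truth_keys
        )
        if fig is not None:
            _register(fig)
        res_map = differential.consolidate_residues(comp.calls, peptides, protein)
        res_map.write_attributes(_register(out_dir / f"residue_map_{stem}.csv"))
    manifest.stage_seconds["differential"] = time.perf_counter() - t0

    # -- stage 4: EX1 detection --------------------------------------------
    t0 = time.perf_counter()
    ex1_rows = []
    by_pep_state: dict[tuple[tuple[int, int, str], str], list] = {}
    for env in envelopes:
        by_pep_state.setdefault((env.peptide.key, env.state), []).append(env)
    ex1_cfg = cfg["ex1"]
    for (key, state), envs in sorted(by_pep_state.items()):
        if len(envs) < 2:
            continue
        try:
            fits = [(env.exposure_min, ex1_mod.fit_bimodal(env)) for env in envs]
            call = ex1_mod.call_ex1(
                fits,
                peptides[key],
                min_separation_D=float(ex1_cfg["min_separation_D"]),
                min_fraction=float(ex1_cfg["min_fraction"]),
                min_improvement=float(ex1_cfg["min_improvement"]),
                min_consecutive=int(ex1_cfg["min_consecutive"]),
            )
        except Exception as exc:  # isolate failures to the offending peptide
            log.warning("EX1 analysis failed for %s-%s %s: %s", key[0], key[1], state, exc)
            continue
        ex1_rows.append(
            {
                "start": key[0],
                "end": key[1],
                "sequence": key[2],
                "state": state,
                "verdict": call.verdict,
                "mean_separation_D": call.mean_separation_D,
                "k_open_per_min": call.k_open_per_min,
                "supporting_times": ";".join(f"{t:g}" for t in call.supporting_times),
            }
        )
    pd.DataFrame(
        ex1_rows,
        columns=[
            "start",
            "end",
            "sequence",
            "state",
            "verdict",
            "mean_separation_D",
            "k_open_per_min",
            "supporting_times",
        ],
    ).to_csv(_register(out_dir / "ex1_report.csv"), index=False)
    manifest.stage_seconds["ex1"] = time.perf_counter() - t0

    # -- stage 5: summary + manifest ---------------------------------------
    t0 = time.perf_counter()
    summary = build_summary(series, comparisons, be_results, design.d_frac)
    io.write_summary_table(summary, _register(out_dir / "summary.csv"), {"seed": seed})
    manifest.stage_seconds["report"] = time.perf_counter() - t0
    manifest.outputs.append("manifest.json")
    manifest.write(out_dir / "manifest.json")
    log.info(
        "pipeline done: %d peptides, %d comparisons, %d EX1 candidates -> %s",
        len(peptides),
        len(comparisons),
        len(ex1_rows),
        out_dir,
    )
    return manifest
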