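"""End-to-end orchestration of the footprinting analyses.

Three workflows chain the library modules:

* ``run_free_state``   rates -> protection factors -> structure fSASA ->
  ln PF vs fSASA calibration (the reference-state workflow).
* ``run_bound_state``  rates of a liganded state -> protection factors ->
  inverse calibration -> predicted accessibility and burial change.
* ``run_state_compare`` two rate tables -> per-residue log rate ratios,
  classification, and optionally a B-factor-annotated structure.

Each run writes its outputs as CSV plus a JSON manifest (input hashes,
config, seed, package version, timestamps) sufficient to reproduce the
run byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .calibration import (
    CalibrationModel, calibrate, delta_accessibility, predict_bound_fsasa,
    summary_text,
)
from .kinetics import fit_rate_table
from .protection import ReactivityTable, load_reactivity_table, protection_table
from .sasa import RadiusTable, residue_fsasa_table
from .statecomp import aggregate_per_residue, classify_activation_sites, rate_ratios
from .structio import (
    RATES_TABLE_SCHEMA, ResidueId, Structure, read_structure, read_table,
    write_annotated_structure,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    subcommand: str
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    config: dict = field(default_factory=dict)
    version: str = __version__
    seed: int | None = None
    started: str = ""
    finished: str = ""

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        # a missing input is recorded, not fatal here: the stage that
        # consumes it raises the properly attributed error
        self.inputs[str(p)] = _sha256(p) if p.exists() else "missing"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def run_free_state(
    rates_path: str | Path,
    structure_path: str | Path,
    out_dir: str | Path,
    reactivity: str | Path = "default",
    mod_mass: float = 16.0,
    probe: float = 1.4,
    n_points: int = 960,
    seed: int | None = None,
) -> CalibrationModel:
    """Reference-state workflow: fit rates, convert to PFs, compute fSASA
    from the structure, and calibrate ln PF against fSASA."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest("free-state", seed=seed, started=_now(),
                           config={"mod_mass": mod_mass, "probe": probe,
                                   "n_points": n_points})
    for p in (rates_path, structure_path):
        manifest.add_input(p)

    try:
        table = read_table(rates_path, RATES_TABLE_SCHEMA)
        rates = fit_rate_table(table)
    except Exception as exc:
        raise PipelineError("kinetics", exc) from exc
    rates.to_csv(out / "rates.csv", index=False)

    try:
        reactivities = load_reactivity_table(reactivity)
        pf = protection_table(rates, reactivities, mod_mass=mod_mass)
    except Exception as exc:
        raise PipelineError("protection", exc) from exc
    pf.to_csv(out / "protection.csv", index=False)

    try:
        structure = read_structure(structure_path)
        fsasa = residue_fsasa_table(
            structure, radii=RadiusTable(probe=probe), n_points=n_points
        )
    except Exception as exc:
        raise PipelineError("sasa", exc) from exc
    fsasa.to_csv(out / "fsasa.csv", index=False)

    try:
        merged = pf.merge(
            fsasa[["residue", "fSASA"]], left_on="site", right_on="residue"
        )
        model = calibrate(list(zip(merged["fSASA"], merged["lnPF"])))
    except Exception as exc:
        raise PipelineError("calibration", exc) from exc

    pd.DataFrame(
        [{"slope": model.slope, "intercept": model.intercept,
          "pearson_r": model.pearson_r, "n": model.n,
          "residual_se": model.residual_se}]
    ).to_csv(out / "calibration.csv", index=False)
    (out / "calibration.txt").write_text(summary_text(model) + "\n")

    manifest.finished = _now()
    manifest.write(out / "manifest.json")
    return model


def run_bound_state(
    rates_path: str | Path,
    calibration_path: str | Path,
    out_dir: str | Path,
    free_fsasa_path: str | Path | None = None,
    reactivity: str | Path = "default",
    mod_mass: float = 16.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Bound-state workflow: PFs of the liganded state through the inverse
    calibration, plus burial change against the free state if its fSASA
    table is supplied."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest("bound-state", seed=seed, started=_now(),
                           config={"mod_mass": mod_mass})
    manifest.add_input(rates_path)
    manifest.add_input(calibration_path)

    try:
        cal = pd.read_csv(calibration_path).iloc[0]
        model = CalibrationModel(
            slope=float(cal["slope"]), intercept=float(cal["intercept"]),
            pearson_r=float(cal["pearson_r"]), n=int(cal["n"]),
            residual_se=float(cal["residual_se"]),
        )
    except Exception as exc:
        raise PipelineError("calibration-model", exc) from exc

    try:
        table = read_table(rates_path, RATES_TABLE_SCHEMA)
        rates = fit_rate_table(table)
        reactivities = load_reactivity_table(reactivity)
        pf = protection_table(rates, reactivities, mod_mass=mod_mass)
    except Exception as exc:
        raise PipelineError("protection", exc) from exc

    rows = []
    for _, row in pf.iterrows():
        pred = predict_bound_fsasa(row["lnPF"], model)
        rows.append(
            {
                "site": row["site"],
                "lnPF_bound": row["lnPF"],
                "fSASA_pred_raw": pred.fsasa_raw,
                "fSASA_pred": pred.fsasa,
                "clipped": pred.clipped,
            }
        )
    predicted = pd.DataFrame(rows)
    predicted.to_csv(out / "predicted_fsasa.csv", index=False)

    if free_fsasa_path is not None:
        manifest.add_input(free_fsasa_path)
        free = pd.read_csv(free_fsasa_path)
        free_map = dict(zip(free["residue"], free["fSASA"]))
        bound_map = dict(zip(predicted["site"], predicted["fSASA_pred"]))
        shared = set(free_map) & set(bound_map)
        delta = delta_accessibility(
            {k: free_map[k] for k in shared}, {k: bound_map[k] for k in shared}
        )
        delta.to_csv(out / "delta_fsasa.csv", index=False)

    manifest.finished = _now()
    manifest.write(out / "manifest.json")
    return predicted


def run_state_compare(
    rates_a_path: str | Path,
    rates_b_path: str | Path,
    out_dir: str | Path,
    structure_path: str | Path | None = None,
    threshold_fold: float = 1.4,
    seed: int | None = None,
) -> pd.DataFrame:
    """Two-state workflow: fit both rate tables, form log10 rate ratios,
    aggregate to residues, classify at the fold threshold, and (optionally)
    write the per-residue ratio onto the structure's B-factors."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest("compare", seed=seed, started=_now(),
                           config={"threshold_fold": threshold_fold})
    manifest.add_input(rates_a_path)
    manifest.add_input(rates_b_path)

    try:
        rates_a = fit_rate_table(read_table(rates_a_path, RATES_TABLE_SCHEMA))
        rates_b = fit_rate_table(read_table(rates_b_path, RATES_TABLE_SCHEMA))
    except Exception as exc:
        raise PipelineError("kinetics", exc) from exc

    try:
        records, orphans = rate_ratios(rates_a, rates_b)
        per_res = aggregate_per_residue(records)
        labelled = classify_activation_sites(per_res, threshold_fold=threshold_fold)
    except Exception as exc:
        raise PipelineError("statecomp", exc) from exc
    labelled.to_csv(out / "comparison.csv", index=False)
    orphans.to_csv(out / "orphans.csv", index=False)

    if structure_path is not None:
        manifest.add_input(structure_path)
        try:
            structure = read_structure(structure_path)
            values = {}
            by_key = {(r.chain, r.number): None for r in structure.residues}
            for _, row in labelled.iterrows():
                key = (row["chain"], int(row["number"]))
                if key in by_key:
                    res = next(
                        r for r in structure.residues
                        if (r.chain, r.number) == key
                    )
                    values[res] = float(row["mean_log10_ratio"])
            write_annotated_structure(structure, values, out / "annotated.pdb")
        except Exception as exc:
            raise PipelineError("structio", exc) from exc

    manifest.finished = _now()
    manifest.write(out / "manifest.json")
    return labelled
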