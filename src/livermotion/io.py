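"""File formats, run configuration and the end-to-end pipeline.

Cohort CSV schema (fixed header, one row per patient x segment)::

    patient_id,segment,helical_lr,helical_ap,helical_si,
    phase0_lr,phase0_ap,phase0_si,phase50_lr,phase50_ap,phase50_si

Lung-volume CSV: ``patient_id,state,left_ml,right_ml,total_ml`` with state
in {helical, phase0, phase50}.  A JSON mirror bundles both.  Floats are
written with 17 significant digits so write -> read round-trips bit-exactly.

``run_pipeline`` ties the stages together: simulate (or load) a cohort,
summarise displacements for all three state pairs, derive the margin table,
and run the validation battery, writing CSV/text/JSON reports plus a run
log with the seed and a configuration hash.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cohort import (
    AXES,
    SEGMENTS,
    STATES,
    Cohort,
    LungVolumes,
    Patient,
    PointObservation,
    SimulationParams,
    StateVolumes,
    generate_cohort,
)
from .margin import MarginConfig, margin_table
from .stats import StatePair, amplitude_table
from .validation import (
    VolumeTriple,
    coverage_simulation,
    lung_bracket_check,
    voi,
)

__all__ = [
    "COHORT_CSV_HEADER",
    "LUNG_CSV_HEADER",
    "RunConfig",
    "StageError",
    "read_cohort",
    "write_cohort",
    "read_lung_volumes",
    "write_lung_volumes",
    "write_cohort_json",
    "read_cohort_json",
    "run_pipeline",
]

log = logging.getLogger("livermotion")

COHORT_CSV_HEADER = [
    "patient_id",
    "segment",
    *(f"{state}_{axis}" for state in STATES for axis in AXES),
]
LUNG_CSV_HEADER = ["patient_id", "state", "left_ml", "right_ml", "total_ml"]


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def _parse_float(token: str, path, line_no: int, column: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValueError(
            f"{path}:{line_no}: malformed number {token!r} in column {column}"
        ) from None


# ---------------------------------------------------------------------------
# cohort CSV / JSON


def write_cohort(cohort: Cohort, path) -> None:
    """Write the point observations to the cohort CSV schema."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(COHORT_CSV_HEADER)
        for p in cohort.patients:
            for seg in SEGMENTS:
                obs = p.points[seg]
                w.writerow(
                    [
                        p.patient_id,
                        seg,
                        *(_fmt(v) for v in obs.pos_helical),
                        *(_fmt(v) for v in obs.pos_phase0),
                        *(_fmt(v) for v in obs.pos_phase50),
                    ]
                )


def read_cohort(path, lung_path=None) -> Cohort:
    """Read a cohort from CSV (with optional lung-volume CSV) or from JSON.

    Rows are normalised to (patient, canonical segment order); every patient
    must supply all nine segments exactly once.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_cohort_json(path)
    by_patient: dict[str, dict[str, PointObservation]] = {}
    order: list[str] = []
    with path.open("r", newline="", encoding="utf-8-sig") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty cohort file") from None
        if header != COHORT_CSV_HEADER:
            raise ValueError(
                f"{path}: unexpected header {header!r}; expected {COHORT_CSV_HEADER!r}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(COHORT_CSV_HEADER):
                raise ValueError(
                    f"{path}:{line_no}: expected {len(COHORT_CSV_HEADER)} fields, "
                    f"got {len(row)}"
                )
            pid, seg = row[0], row[1]
            vals = [
                _parse_float(tok, path, line_no, col)
                for tok, col in zip(row[2:], COHORT_CSV_HEADER[2:])
            ]
            if pid not in by_patient:
                by_patient[pid] = {}
                order.append(pid)
            if seg in by_patient[pid]:
                raise ValueError(
                    f"{path}:{line_no}: duplicate segment {seg} for patient {pid}"
                )
            by_patient[pid][seg] = PointObservation(
                patient_id=pid,
                segment=seg,
                pos_helical=vals[0:3],
                pos_phase0=vals[3:6],
                pos_phase50=vals[6:9],
            )
    lungs = read_lung_volumes(lung_path) if lung_path is not None else {}
    patients = []
    for pid in order:
        missing = sorted(set(SEGMENTS) - set(by_patient[pid]))
        if missing:
            raise ValueError(
                f"{path}: patient {pid!r} is missing segment(s) {missing}"
            )
        patients.append(
            Patient(
                patient_id=pid,
                points=by_patient[pid],
                lung_volumes=lungs.get(pid),
            )
        )
    return Cohort(patients=patients)


def write_lung_volumes(cohort: Cohort, path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(LUNG_CSV_HEADER)
        for p in cohort.patients:
            if p.lung_volumes is None:
                continue
            for state in STATES:
                sv = getattr(p.lung_volumes, state)
                w.writerow(
                    [p.patient_id, state, _fmt(sv.left), _fmt(sv.right), _fmt(sv.total)]
                )


def read_lung_volumes(path) -> dict[str, LungVolumes]:
    """Read per-patient lung volumes keyed by patient id."""
    path = Path(path)
    acc: dict[str, dict[str, StateVolumes]] = {}
    with path.open("r", newline="", encoding="utf-8-sig") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != LUNG_CSV_HEADER:
            raise ValueError(
                f"{path}: unexpected header {header!r}; expected {LUNG_CSV_HEADER!r}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            pid, state = row[0], row[1]
            if state not in STATES:
                raise ValueError(f"{path}:{line_no}: unknown imaging state {state!r}")
            vals = [
                _parse_float(tok, path, line_no, col)
                for tok, col in zip(row[2:], LUNG_CSV_HEADER[2:])
            ]
            acc.setdefault(pid, {})[state] = StateVolumes(*vals)
    out = {}
    for pid, states in acc.items():
        missing = sorted(set(STATES) - set(states))
        if missing:
            raise ValueError(f"{path}: patient {pid!r} is missing state(s) {missing}")
        out[pid] = LungVolumes(**states)
    return out


def write_cohort_json(cohort: Cohort, path) -> None:
    """JSON mirror of the cohort and lung-volume tables."""
    doc = {"patients": []}
    for p in cohort.patients:
        entry = {
            "patient_id": p.patient_id,
            "points": {
                seg: {
                    state: [float(v) for v in getattr(p.points[seg], f"pos_{state}")]
                    for state in STATES
                }
                for seg in SEGMENTS
            },
        }
        if p.lung_volumes is not None:
            entry["lung_volumes"] = {
                state: list(getattr(p.lung_volumes, state)) for state in STATES
            }
        if p.helical_fraction is not None:
            entry["helical_fraction"] = p.helical_fraction
        doc["patients"].append(entry)
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_cohort_json(path) -> Cohort:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    patients = []
    for entry in doc["patients"]:
        pid = entry["patient_id"]
        points = {
            seg: PointObservation(
                patient_id=pid,
                segment=seg,
                pos_helical=states["helical"],
                pos_phase0=states["phase0"],
                pos_phase50=states["phase50"],
            )
            for seg, states in entry["points"].items()
        }
        lungs = None
        if "lung_volumes" in entry:
            lungs = LungVolumes(
                **{
                    state: StateVolumes(*vals)
                    for state, vals in entry["lung_volumes"].items()
                }
            )
        patients.append(
            Patient(
                patient_id=pid,
                points=points,
                lung_volumes=lungs,
                helical_fraction=entry.get("helical_fraction"),
            )
        )
    return Cohort(patients=patients)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Fully serialisable description of one pipeline run."""

    seed: int = 0
    n_patients: int = 20
    outdir: str = "livermotion_out"
    simulation: dict = field(default_factory=dict)  # SimulationParams overrides
    coverage_t: float | None = None
    overall_rule: str = "pooled"
    coverage_reps: int = 200
    cohort_csv: str | None = None  # external cohort instead of simulation
    lung_csv: str | None = None
    voi_volumes: list | None = None  # optional [[v_a, v_b, v_intersection], ...]
    report_round_mm: int = 1

    def params(self) -> SimulationParams:
        return SimulationParams.from_dict(self.simulation) if self.simulation else SimulationParams()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(doc)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    def scientific_dict(self) -> dict:
        """Config without the output location: what determines the results."""
        d = self.to_dict()
        d.pop("outdir")
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.scientific_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute simulate -> amplitudes -> margins -> validation, writing reports.

    Returns a mapping of artifact names to file paths.  Deterministic: the
    same config produces byte-identical reports.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "configure"
    try:
        params = config.params()
        nd = config.report_round_mm

        stage = "cohort"
        if config.cohort_csv:
            cohort = read_cohort(config.cohort_csv, lung_path=config.lung_csv)
            log.info("loaded cohort of %d patients from %s", cohort.n, config.cohort_csv)
        else:
            cohort = generate_cohort(params, config.n_patients, seed=config.seed)
            log.info("simulated cohort of %d patients (seed %d)", cohort.n, config.seed)
        write_cohort(cohort, outdir / "cohort.csv")
        artifacts["cohort_csv"] = str(outdir / "cohort.csv")
        if any(p.lung_volumes is not None for p in cohort.patients):
            write_lung_volumes(cohort, outdir / "lung_volumes.csv")
            artifacts["lung_csv"] = str(outdir / "lung_volumes.csv")
        write_cohort_json(cohort, outdir / "cohort.json")
        artifacts["cohort_json"] = str(outdir / "cohort.json")

        stage = "amplitudes"
        for pair in StatePair:
            table = amplitude_table(cohort, pair, overall=config.overall_rule)
            base = outdir / f"amplitudes_{pair.value.lower()}"
            table.to_frame(ndigits=None).to_csv(base.with_suffix(".csv"), index=False)
            base.with_suffix(".txt").write_text(table.to_text() + "\n", encoding="utf-8")
            artifacts[f"amplitudes_{pair.value.lower()}"] = str(base.with_suffix(".csv"))

        stage = "margins"
        cfg = MarginConfig(n=cohort.n, coverage_t=config.coverage_t)
        mt = margin_table(cohort, cfg)
        mt.to_frame(ndigits=None).to_csv(outdir / "margins.csv", index=False)
        (outdir / "margins.txt").write_text(mt.to_text() + "\n", encoding="utf-8")
        artifacts["margins_csv"] = str(outdir / "margins.csv")
        artifacts["margins_txt"] = str(outdir / "margins.txt")

        stage = "validation"
        report: dict = {"seed": config.seed, "config_hash": config.config_hash()}
        report["lung_bracket"] = {
            p.patient_id: lung_bracket_check(p.lung_volumes)
            for p in cohort.patients
            if p.lung_volumes is not None
        }
        if config.voi_volumes:
            report["voi"] = [
                {"v_a": va, "v_b": vb, "v_intersection": vi, "voi": voi(VolumeTriple(va, vb, vi))}
                for va, vb, vi in config.voi_volumes
            ]
        if config.coverage_reps > 0:
            cov = coverage_simulation(
                params,
                cfg=MarginConfig(n=config.n_patients, coverage_t=config.coverage_t),
                n_patients=config.n_patients,
                n_reps=config.coverage_reps,
                seed=config.seed,
            )
            report["coverage"] = {
                "coverage_pct": cov.coverage_pct,
                "per_tumor_pct": cov.per_tumor_pct,
                "per_axis": cov.per_axis,
                "n_reps": cov.n_reps,
                "n_patients": cov.n_patients,
                "seed": cov.seed,
            }
        (outdir / "validation.json").write_text(
            json.dumps(report, indent=1, sort_keys=True), encoding="utf-8"
        )
        artifacts["validation_json"] = str(outdir / "validation.json")

        stage = "log"
        run_log = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.scientific_dict(),
            "package_version": __version__,
            "artifacts": sorted(artifacts),
            "status": "complete",
        }
        (outdir / "run.json").write_text(
            json.dumps(run_log, indent=1, sort_keys=True), encoding="utf-8"
        )
        artifacts["run_json"] = str(outdir / "run.json")
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        (outdir / "run.json").write_text(
            json.dumps(
                {
                    "status": "failed",
                    "stage": stage,
                    "error": str(exc),
                    "config_hash": config.config_hash(),
                    "partial_artifacts": sorted(artifacts),
                },
                indent=1,
                sort_keys=True,
            ),
            encoding="utf-8",
        )
        raise StageError(stage, exc) from exc
    return artifacts
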