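"""Cohort directory layout, run manifests, and (de)serialization.

A cohort directory holds one CSV per subject x variant plus
``manifest.json`` describing the scenario, the seeds, and every file
written, and ``true_params.csv`` with the generating parameters when the
cohort is synthetic.  Everything is plain text and round-trips exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .cohort import Cohort, CohortScenario, RatingParams
from .data import SubjectDataset
from .task import TaskConfig


def scenario_to_dict(s: CohortScenario) -> dict:
    return {
        "name": s.name, "n_subjects": s.n_subjects,
        "configs": {v: c.to_dict() for v, c in s.configs.items()},
        "omega": {v: list(m) for v, m in s.omega.items()},
        "alpha": {v: list(m) for v, m in s.alpha.items()},
        "lam": list(s.lam), "pi_stick": list(s.pi_stick),
        "beta": list(s.beta), "ratings": asdict(s.ratings),
    }


def scenario_from_dict(d: dict) -> CohortScenario:
    return CohortScenario(
        name=d["name"], n_subjects=d["n_subjects"],
        configs={v: TaskConfig.from_dict(c) for v, c in d["configs"].items()},
        omega={v: tuple(m) for v, m in d["omega"].items()},
        alpha={v: tuple(m) for v, m in d["alpha"].items()},
        lam=tuple(d["lam"]), pi_stick=tuple(d["pi_stick"]),
        beta=tuple(d["beta"]), ratings=RatingParams(**d["ratings"]),
    )


def load_scenario_file(path: str | Path) -> CohortScenario:
    """Read a scenario from JSON or YAML."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml
        return scenario_from_dict(yaml.safe_load(text))
    return scenario_from_dict(json.loads(text))


@dataclass
class RunManifest:
    command: str
    seed: int
    scenario: dict | None = None
    outputs: list[str] = field(default_factory=list)
    subjects: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = field(default_factory=lambda: time.strftime(
        "%Y-%m-%dT%H:%M:%S"))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1,
                                         sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        d.pop("timestamp_read", None)
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


def write_cohort(cohort: Cohort, out_dir: str | Path,
                 command: str = "simulate") -> RunManifest:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(command=command, seed=cohort.seed,
                           scenario=scenario_to_dict(cohort.scenario))
    for s in cohort.subjects:
        entry = {"order": list(s.order), "rating_slope": s.rating_slope,
                 "files": {}, "session_seeds": {}}
        for v, ds in s.datasets.items():
            fname = f"{s.subject_id}_{v}.csv"
            ds.to_csv(out / fname)
            entry["files"][v] = fname
            entry["session_seeds"][v] = int(s.internals[v]["walks"].seed)
            manifest.outputs.append(fname)
        manifest.subjects[s.subject_id] = entry
    cohort.true_param_table().to_csv(out / "true_params.csv", index=False)
    manifest.outputs.append("true_params.csv")
    manifest.write(out / "manifest.json")
    return manifest


def read_cohort_dir(data_dir: str | Path
                    ) -> tuple[dict[str, list[SubjectDataset]], RunManifest]:
    """Load every subject's sessions (presentation order preserved)."""
    root = Path(data_dir)
    mpath = root / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.json in {root}")
    manifest = RunManifest.read(mpath)
    cohort: dict[str, list[SubjectDataset]] = {}
    for sid, entry in manifest.subjects.items():
        sessions = []
        for v in entry["order"]:
            sessions.append(SubjectDataset.from_csv(
                root / entry["files"][v], subject_id=sid, variant=v))
        cohort[sid] = sessions
    return cohort, manifest
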