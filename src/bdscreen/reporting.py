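"""Report writers and the run manifest.

Numbers are rounded exactly once, here at serialisation: dollars to the
nearest dollar, person counts to whole persons, proportions to two
decimals — the granularity of the published tables. The library itself
carries full precision everywhere.

Every output directory receives one ``manifest.json`` recording the
command, the full parameter snapshot, digests of any input files, seeds
and the artifact paths, so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .cohort import CohortTrajectory
from .params import ModelParams, round_half_up

__all__ = ["RunManifest", "write_manifest", "trajectory_summary",
            "trajectory_ledger_frame", "dollars", "persons", "proportion"]


def dollars(x: float) -> int:
    return round_half_up(x)


def persons(x: float) -> int:
    return round_half_up(x)


def proportion(x: float) -> float:
    return round(float(x), 2)


@dataclass
class RunManifest:
    command: str
    params: dict[str, Any]
    inputs: dict[str, str] = field(default_factory=dict)    # path -> sha256
    seeds: dict[str, int] = field(default_factory=dict)
    artifacts: list[str] = field(default_factory=list)
    version: str = __version__


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir: str | Path, command: str, params: ModelParams,
                   inputs: dict[str, str | Path] | None = None,
                   seeds: dict[str, int] | None = None,
                   artifacts: list[str] | None = None) -> Path:
    manifest = RunManifest(
        command=command,
        params=params.model_dump(),
        inputs={str(p): _sha256(p) for p in (inputs or {}).values()},
        seeds=dict(seeds or {}),
        artifacts=[str(a) for a in (artifacts or [])],
    )
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(asdict(manifest), indent=2, sort_keys=True) + "\n")
    return path


def trajectory_ledger_frame(traj: CohortTrajectory) -> pd.DataFrame:
    """Per-year ledger as a table (full precision)."""
    return pd.DataFrame([{
        "year": y.year, "n_alive": y.n_alive, "mdd": y.mdd, "rbp": y.rbp,
        "ubp": y.ubp, "mdd_as_bd": y.mdd_as_bd,
        "undiscounted_cost": y.undiscounted_cost,
        "discount_factor": y.discount_factor,
        "discounted_cost": y.discounted_cost,
    } for y in traj.years])


def trajectory_summary(traj: CohortTrajectory) -> dict[str, Any]:
    """End-of-horizon summary, rounded at reporting granularity."""
    return {
        "scenario": traj.scenario,
        "one_time_cost": dollars(traj.one_time_cost),
        "total_discounted_cost": dollars(traj.total_discounted_cost),
        "per_patient_cost": dollars(traj.per_patient_cost),
        "survivors_end": persons(traj.survivors_end),
        "correct_end": persons(traj.correct_end),
        "misdiagnosed_end": persons(traj.misdiagnosed_end),
        "cost_by_state_per_patient": {k: dollars(v) for k, v in traj.cost_by_state.items()},
    }
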