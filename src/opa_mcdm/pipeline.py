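"""End-to-end run: load, rank experts if needed, solve, aggregate, write."""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from .aggregate import build_report, DecisionReport
from .core import solve
from .experts import DEFAULT_POLICY, rank_experts
from .io import read_instance, write_report, write_tensor_csv, write_tensor_json

log = logging.getLogger("opa_mcdm")


class RunConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    instance_json: Optional[Path] = None
    experts_csv: Optional[Path] = None
    attr_ranks_csv: Optional[Path] = None
    alt_ranks_csv: Optional[Path] = None
    solver: str = "auto"  # lp | closed-form | auto
    tolerance: float = Field(default=1e-9, gt=0)
    digits: int = Field(default=4, ge=0)
    out_dir: Path = Path("opa_out")
    log_level: str = "INFO"


def run_pipeline(config: RunConfig) -> DecisionReport:
    """Execute the whole analysis and write the report files.

    Stages: read and validate the instance; derive expert ranks from the
    profiles when the input does not supply them; build and solve the weight
    model; aggregate and write the expert/attribute/alternative significance
    tables.  Each stage is logged to standard error with its wall time.
    """
    logging.basicConfig(level=config.log_level)
    t0 = time.perf_counter()
    instance = read_instance(
        path=config.instance_json,
        experts_csv=config.experts_csv,
        attr_ranks_csv=config.attr_ranks_csv,
        alt_ranks_csv=config.alt_ranks_csv,
    )
    log.info(
        "stage=read p=%d n=%d m=%d (%.3fs)",
        instance.p, instance.n, instance.m, time.perf_counter() - t0,
    )

    if instance.expert_rank is None:
        t = time.perf_counter()
        result = rank_experts(list(instance.experts), DEFAULT_POLICY)
        instance = instance.with_expert_rank(result.rank_of)
        log.info("stage=rank-experts ties=%s (%.3fs)", result.has_ties, time.perf_counter() - t)

    t = time.perf_counter()
    tensor = solve(instance, solver=config.solver, tol=config.tolerance)
    log.info("stage=solve solver=%s z=%.6g (%.3fs)", tensor.solver_tag, tensor.z,
             time.perf_counter() - t)

    t = time.perf_counter()
    report = build_report(instance, tensor, tolerance=config.tolerance)
    paths = write_report(report, config.out_dir, digits=config.digits)
    write_tensor_csv(tensor, Path(config.out_dir) / "tensor.csv")
    write_tensor_json(tensor, Path(config.out_dir) / "tensor.json")
    log.info("stage=report wrote %d files to %s (%.3fs)", len(paths) + 2,
             config.out_dir, time.perf_counter() - t)
    return report
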