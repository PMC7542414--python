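"""End-to-end workflow: encode, stage, plan, split, match, merge, group.

A local state machine mirroring a managed-cloud step function.  The
privacy boundary of the original deployment becomes a directory boundary:
everything past the encode stage operates only on privacy-preserved
artifacts, and the run report records which files each stage read so the
boundary is testable.

Matching jobs are independent single-bin tasks communicating only via
files; a worker pool dispatches at most ``workers`` of them concurrently,
each with a configurable retry policy (five attempts by default).  Because
bins partition the comparison space per strategy, the merged output is
independent of worker count and scheduling order.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from . import binning, blocking, matching, pairs_store, synthetic
from .config import LinkageConfig
from .encoding import encode_dataset, read_encoded, write_encoded

__all__ = [
    "PipelineError",
    "JobTimeoutError",
    "StagingError",
    "WorkflowState",
    "stage_files",
    "unstage_file",
    "run_pipeline",
]

log = logging.getLogger("binlink")

STAGES = ("encoded", "staged", "planned", "split", "matched", "merged", "grouped")


class PipelineError(RuntimeError):
    pass


class JobTimeoutError(PipelineError):
    pass


class StagingError(PipelineError):
    pass


@dataclass
class WorkflowState:
    """Run progress: last completed stage, artifact paths, job attempts."""

    stage: str = ""
    artifacts: dict[str, list[str]] = field(default_factory=dict)
    stage_inputs: dict[str, list[str]] = field(default_factory=dict)
    job_attempts: dict[str, int] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def advance(self, stage: str, artifacts: list[str],
                inputs: list[str], seconds: float) -> None:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        if self.stage and STAGES.index(stage) <= STAGES.index(self.stage):
            raise ValueError(f"stage {stage!r} does not advance from {self.stage!r}")
        for p in artifacts:
            if not Path(p).exists():
                raise PipelineError(f"stage {stage!r} artifact missing: {p}")
        self.stage = stage
        self.artifacts[stage] = artifacts
        self.stage_inputs[stage] = inputs
        self.timings[stage] = seconds

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


# ---------------------------------------------------------------------------
# staging

def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def stage_files(paths: Sequence, staging_dir) -> list[Path]:
    """Copy files into a content-addressed, gzip-compressed staging layout.

    The staged name is the SHA-256 of the uncompressed content, so restaging
    an unchanged file is a logged no-op and corruption is detectable on
    retrieval.
    """
    staging_dir = Path(staging_dir)
    out: list[Path] = []
    for path in paths:
        path = Path(path)
        raw = path.read_bytes()
        if path.suffix == ".gz":
            raw = gzip.decompress(raw)
        digest = _sha256(raw)
        dest = staging_dir / digest[:2] / f"{digest}.gz"
        if dest.exists():
            log.info("staging no-op (already staged): %s", path.name)
        else:
            dest.parent.mkdir(parents=True, exist_ok=True)
            # fixed mtime so staging is byte-deterministic
            dest.write_bytes(gzip.compress(raw, mtime=0))
        out.append(dest)
    return out


def unstage_file(staged_path, out_path) -> Path:
    """Decompress a staged file, verifying its content address."""
    staged_path = Path(staged_path)
    raw = gzip.decompress(staged_path.read_bytes())
    expect = staged_path.name.removesuffix(".gz")
    actual = _sha256(raw)
    if actual != expect:
        raise StagingError(
            f"checksum mismatch for {staged_path.name}: content hash {actual}")
    out_path = Path(out_path)
    out_path.write_bytes(raw)
    return out_path


# ---------------------------------------------------------------------------
# matching jobs

def _match_one_bin(
    bin_path: Path,
    pairs_path: Path,
    plan: binning.BinPlan,
    bin_index: int,
    config: LinkageConfig,
    specs,
) -> int:
    records = read_encoded(bin_path)
    assigned = plan.keys_of_bin(bin_index)
    pairs = matching.match_bin(records, specs, config.thresholds,
                               config.strategy_names, assigned)
    pairs_store.write_pairs(pairs, pairs_path, config.field_names)
    return len(pairs)


def _run_job_with_retry(
    job_id: str,
    fn: Callable[[], int],
    config: LinkageConfig,
    state: WorkflowState,
    fault_injector: Callable[[str, int], None] | None,
) -> int:
    policy = config.retry
    last_error: Exception | None = None
    for attempt in range(1, policy.max_attempts + 1):
        state.job_attempts[job_id] = attempt
        start = time.monotonic()
        try:
            if fault_injector is not None:
                fault_injector(job_id, attempt)
            result = fn()
        except Exception as exc:  # noqa: BLE001 - job isolation boundary
            last_error = exc
            log.warning("job %s attempt %d/%d failed: %s",
                        job_id, attempt, policy.max_attempts, exc)
            continue
        elapsed = time.monotonic() - start
        if elapsed > policy.timeout_seconds:
            raise JobTimeoutError(
                f"job {job_id} exceeded timeout "
                f"({elapsed:.1f}s > {policy.timeout_seconds}s)")
        return result
    raise PipelineError(
        f"job {job_id} failed after {policy.max_attempts} attempts: {last_error}")


# ---------------------------------------------------------------------------
# pipeline

def run_pipeline(
    config: LinkageConfig,
    dataset_path,
    out_dir,
    workers: int = 1,
    fault_injector: Callable[[str, int], None] | None = None,
) -> dict:
    """Run the full deduplication workflow on one raw dataset file.

    Returns a run report with per-stage wall times, bin count, pair counts
    and discarded-key accounting.  The merged output is deterministic for a
    fixed config and input, whatever ``workers`` is.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    state = WorkflowState()
    state_path = out_dir / "state.json"

    def timed(stage: str, inputs: list, artifacts_fn):
        start = time.monotonic()
        artifacts = artifacts_fn()
        state.advance(stage, [str(a) for a in artifacts],
                      [str(i) for i in inputs], time.monotonic() - start)
        state.save(state_path)
        return artifacts

    # 1. encode (the on-premises step: the only stage that reads raw data)
    raw_records = synthetic.read_dataset(dataset_path)
    encoded = encode_dataset(raw_records, config.bloom_params, config.strategies)
    encoded_path = out_dir / "encoded.csv.gz"
    timed("encoded", [dataset_path],
          lambda: (write_encoded(encoded, encoded_path), [encoded_path])[1])
    del raw_records

    # 2. stage into the privacy-preserved zone
    staged = timed("staged", [encoded_path],
                   lambda: stage_files([encoded_path], out_dir / "staging"))
    working_path = out_dir / "encoded-staged.csv"
    unstage_file(staged[0], working_path)
    encoded = read_encoded(working_path)

    # 3. plan bins from block-key frequencies
    stats = [blocking.block_frequencies(encoded, s) for s in config.strategy_names]
    plan = binning.plan_bins(stats, config.max_bin_space, config.discard_rule)
    plan_path = out_dir / "plan.csv"
    freq_path = out_dir / "frequencies.csv"
    timed("planned", [working_path], lambda: (
        binning.write_plan(plan, plan_path),
        blocking.write_frequencies(stats, freq_path),
        [plan_path, freq_path])[2])

    # 4. split into bins
    bin_dir = out_dir / "bins"
    bin_paths = timed("split", [working_path, plan_path],
                      lambda: binning.split_dataset(encoded, plan, bin_dir))

    # 5. match each bin on the worker pool
    specs = config.field_specs
    if config.estimate_u_from_data:
        specs = tuple(config.with_field_u(
            matching.estimate_u(encoded, specs)).field_specs)
    pairs_dir = out_dir / "pairs"
    pairs_dir.mkdir(exist_ok=True)

    def make_job(b: int, bin_path: Path):
        pairs_path = pairs_dir / f"pairs-{b:04d}.csv.gz"
        return pairs_path, (lambda: _match_one_bin(
            bin_path, pairs_path, plan, b, config, specs))

    def run_matching():
        jobs = [make_job(b, p) for b, p in enumerate(bin_paths)]
        with ThreadPoolExecutor(max_workers=max(1, workers)) as pool:
            futures = [
                pool.submit(_run_job_with_retry, f"match-{b:04d}", fn,
                            config, state, fault_injector)
                for b, (_pp, fn) in enumerate(jobs)
            ]
            for fut in futures:
                fut.result()   # re-raise job failures
        return [pp for pp, _fn in jobs]

    pairs_paths = timed("matched", [str(p) for p in bin_paths], run_matching)

    # 6. merge and catalogue
    merged_dir = out_dir / "merged"
    table_holder: dict = {}

    def run_merge():
        table_holder["table"] = pairs_store.merge_pairs(
            pairs_paths, merged_dir, keep=config.dedupe_keep)
        return [merged_dir / "pairs.csv.gz", merged_dir / "manifest.json"]

    timed("merged", [str(p) for p in pairs_paths], run_merge)
    table = table_holder["table"]

    # 7. group entities
    groups_path = out_dir / "groups.csv"
    groups = None

    def run_group():
        nonlocal groups
        groups = pairs_store.group_entities(table, config.thresholds.match)
        pairs_store.write_groups(groups, groups_path)
        return [groups_path]

    timed("grouped", [str(merged_dir / "pairs.csv.gz")], run_group)

    report = {
        "stages_seconds": dict(state.timings),
        "n_records": len(encoded),
        "bin_count": plan.bin_count,
        "bin_spaces": list(plan.bin_spaces),
        "comparison_space_total": plan.total_assigned_space + plan.discarded_space,
        "comparison_space_assigned": plan.total_assigned_space,
        "discarded_keys": len(plan.discarded),
        "discarded_space": plan.discarded_space,
        "total_pairs": table.total_pairs,
        "unique_pairs": table.unique_pairs,
        "n_groups": len(groups),
        "job_attempts": dict(state.job_attempts),
        "stage_inputs": dict(state.stage_inputs),
        "artifacts": dict(state.artifacts),
        "out_dir": str(out_dir),
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report
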