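"""Simulated federated server/node/task orchestration.

A central server coordinates computing tasks; each participating site runs a
node holding its own patient-level table and a registry of executable
operations. Researchers submit tasks ("compute the sums over all columns",
"compute risk-set aggregates at these event times given this coefficient
vector"); nodes execute them on local data and return only aggregate
payloads. Tasks can be chained: the combined aggregates of round *i* become
the payload of round *i+1*, which is how the iterative estimators work.

The privacy contract is structural: the only objects that cross the
node/server boundary are Task and TaskResult, and every returned aggregate
is audited — its array dimensions may depend on the model size p and the
number of distinct event times K, never on a site's record count. Nodes here
are in-process actors with queue semantics; a socket transport could replace
the in-process dispatch behind the same interface.
"""

from __future__ import annotations

import json
import secrets
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd

__all__ = [
    "Task",
    "TaskResult",
    "Node",
    "FederatedServer",
    "audit_payload",
    "PayloadAuditError",
    "FederationError",
]


class FederationError(RuntimeError):
    pass


class PayloadAuditError(FederationError):
    """An aggregate payload had a dimension tied to a site's record count."""


@dataclass(frozen=True)
class Task:
    """A unit of computation dispatched to nodes."""

    task_id: str
    operation_name: str
    payload: dict[str, Any]
    target_sites: tuple[str, ...]


@dataclass(frozen=True)
class TaskResult:
    """A node's answer: aggregate data only."""

    task_id: str
    site_id: str
    aggregate: dict[str, Any]
    status: str = "ok"  # ok | error
    message: str = ""


# Operations are pure functions of (local DataFrame, payload) -> aggregate.
Operation = Callable[[pd.DataFrame, dict[str, Any]], dict[str, Any]]


class Node:
    """A site's compute agent: local data plus registered operations.

    The local table is private to the node; the only way data influences the
    outside world is through the aggregates its operations return.
    """

    def __init__(self, site_id: str, data: pd.DataFrame, token: str | None = None):
        self.site_id = site_id
        self._data = data
        self.token = token or secrets.token_hex(8)
        self._operations: dict[str, Operation] = {}

    @property
    def n_records(self) -> int:
        return len(self._data)

    def register(self, name: str, fn: Operation) -> None:
        self._operations[name] = fn

    def registered(self, name: str) -> bool:
        return name in self._operations

    def execute(self, task: Task) -> TaskResult:
        fn = self._operations.get(task.operation_name)
        if fn is None:
            return TaskResult(
                task.task_id, self.site_id, {}, status="error",
                message=f"operation {task.operation_name!r} not registered at {self.site_id}",
            )
        try:
            aggregate = fn(self._data, task.payload)
        except Exception as exc:  # surfaced, never crashes the federation
            return TaskResult(task.task_id, self.site_id, {}, status="error", message=str(exc))
        return TaskResult(task.task_id, self.site_id, aggregate)


def _array_shapes(aggregate: dict[str, Any]) -> dict[str, tuple[int, ...]]:
    shapes = {}
    for key, value in aggregate.items():
        arr = np.asarray(value)
        shapes[key] = arr.shape
    return shapes


def audit_payload(result: TaskResult, site_n: int, p: int, K: int) -> bool:
    """Check that no array dimension in a result leaks a site's record count.

    Legitimate aggregate dimensions are functions of the model width p and
    the event-grid length K (scalars, length-p vectors, p x p matrices,
    length-K vectors, K x p, K x p x p). A dimension equal to the site's
    record count while the count is not itself one of those sizes indicates
    a record-level payload.
    """
    allowed = {0, 1, p, K, p * p, p + 1, K + 1}
    if site_n in allowed:
        return True  # coincidence with a legitimate size: cannot distinguish
    for shape in _array_shapes(result.aggregate).values():
        if site_n in shape:
            return False
    return True


class FederatedServer:
    """Central coordinator: task queueing, result collection, payload audit.

    Every result that crosses the boundary is logged (task id, site, shape
    summary, byte size) to the in-memory audit trail and, when configured,
    to a JSON-lines audit file.
    """

    def __init__(self, audit_path=None, timeout: float = 60.0):
        self._nodes: dict[str, Node] = {}
        self._tasks: dict[str, Task] = {}
        self._results: dict[str, list[TaskResult]] = {}
        self._audit: list[dict[str, Any]] = []
        self._audit_path = audit_path
        self.timeout = timeout

    # -- registration -------------------------------------------------------

    def register_node(self, node: Node) -> None:
        if node.site_id in self._nodes:
            raise FederationError(f"site {node.site_id!r} already registered")
        self._nodes[node.site_id] = node

    @property
    def site_ids(self) -> list[str]:
        return sorted(self._nodes)

    def node(self, site_id: str) -> Node:
        return self._nodes[site_id]

    # -- task lifecycle -----------------------------------------------------

    def submit_task(self, task: Task) -> str:
        if not task.target_sites:
            raise FederationError("task has no target sites")
        if task.task_id in self._tasks:
            raise FederationError(f"duplicate task_id {task.task_id!r}")
        unknown = [s for s in task.target_sites if s not in self._nodes]
        if unknown:
            raise FederationError(f"unknown site(s): {unknown}")
        self._tasks[task.task_id] = task
        # In-process simulation: nodes pick the task up immediately.
        results = [self._nodes[s].execute(task) for s in task.target_sites]
        for res in results:
            self._log_payload(res)
        self._results[task.task_id] = results
        return task.task_id

    def collect_results(self, task_id: str, expected: int | None = None) -> list[TaskResult]:
        if task_id not in self._tasks:
            raise FederationError(f"no such task {task_id!r}")
        results = sorted(self._results.get(task_id, []), key=lambda r: r.site_id)
        if expected is not None and len(results) < expected:
            missing = set(self._tasks[task_id].target_sites) - {r.site_id for r in results}
            raise FederationError(
                f"timeout after {self.timeout}s: missing results from {sorted(missing)}"
            )
        return results

    def run(
        self,
        operation_name: str,
        payload: dict[str, Any] | None = None,
        sites: list[str] | None = None,
        task_id: str | None = None,
    ) -> list[TaskResult]:
        """Submit one task to the given sites (default: all) and collect.

        Raises if any node reports an error, so chained scripts abort
        cleanly at the failing round.
        """
        targets = tuple(sites if sites is not None else self.site_ids)
        tid = task_id or f"task-{len(self._tasks):06d}-{operation_name}"
        self.submit_task(Task(tid, operation_name, payload or {}, targets))
        results = self.collect_results(tid, expected=len(targets))
        errors = [r for r in results if r.status != "ok"]
        if errors:
            msgs = "; ".join(f"{r.site_id}: {r.message}" for r in errors)
            raise FederationError(f"operation {operation_name!r} failed at node(s): {msgs}")
        return results

    # -- audit --------------------------------------------------------------

    def _log_payload(self, result: TaskResult) -> None:
        shapes = _array_shapes(result.aggregate)
        entry = {
            "task_id": result.task_id,
            "site_id": result.site_id,
            "status": result.status,
            "shapes": {k: list(v) for k, v in shapes.items()},
            "nbytes": int(sum(np.asarray(v).nbytes for v in result.aggregate.values())),
            "site_n": self._nodes[result.site_id].n_records,
        }
        self._audit.append(entry)
        if self._audit_path is not None:
            with open(self._audit_path, "a") as fh:
                fh.write(json.dumps(entry) + "\n")

    @property
    def audit_log(self) -> list[dict[str, Any]]:
        return list(self._audit)

    def audit_violations(self, p: int, K: int) -> list[dict[str, Any]]:
        """Re-check every logged payload against the aggregate-only contract."""
        bad = []
        for entry in self._audit:
            site_n = entry["site_n"]
            allowed = {0, 1, p, K, p * p, p + 1, K + 1}
            if site_n in allowed:
                continue
            if any(site_n in shape for shape in entry["shapes"].values()):
                bad.append(entry)
        return bad
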