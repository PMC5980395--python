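"""Tabular writers, run manifests, and config round-tripping.

All tabular outputs are UTF-8 CSV with a header row; missing values are
written as empty fields (never 0 — the metrics distinguish "no groups" from
a zero). Field order is fixed so checksums are stable across platforms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .baseline import BaselineResult
from .metrics import MetricsRecord, StabilityAccumulator
from .params import SimulationParams
from .pedigree import Pedigree
from .reproductive import DemographicEvent, ReproductiveResult

__all__ = [
    "write_metrics_csv",
    "write_stability_edges",
    "write_relatedness_series",
    "write_pedigree_edges",
    "write_events",
    "write_exclusivity",
    "write_summary_json",
    "sha256_of",
    "RunManifest",
]

METRICS_COLUMNS = [
    "replicate",
    "step",
    "n_alive",
    "n_groups",
    "mean_group_size",
    "mean_payoff",
    "exclusivity_to_date",
]


def _frame(rows: list[dict[str, Any]], columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=columns)


def write_metrics_csv(
    path: str | Path, runs: Sequence[list[MetricsRecord]]
) -> None:
    """One row per replicate x step."""
    rows = []
    for rep, records in enumerate(runs):
        for m in records:
            rows.append(
                {
                    "replicate": rep,
                    "step": m.step,
                    "n_alive": m.n_alive,
                    "n_groups": m.n_groups,
                    "mean_group_size": m.mean_group_size,
                    "mean_payoff": m.mean_payoff,
                    "exclusivity_to_date": m.exclusivity,
                }
            )
    _frame(rows, METRICS_COLUMNS).to_csv(path, index=False, na_rep="")


def write_stability_edges(path: str | Path, acc: StabilityAccumulator) -> None:
    """Final-step stability network: i, j, s_ij over nonzero dyads."""
    rows = [
        {"i": i, "j": j, "s_ij": w}
        for (i, j), w in sorted(acc.weights().items())
    ]
    _frame(rows, ["i", "j", "s_ij"]).to_csv(path, index=False)


def write_relatedness_series(
    path: str | Path, records: list[MetricsRecord]
) -> None:
    rows = [
        {
            "step": m.step,
            "l_m": m.l_m,
            "l_r": m.l_r,
            "L_t": m.log_ratio,
            "lt_flag": m.lt_flag,
            "n_alive": m.n_alive,
        }
        for m in records
        if m.lt_flag is not None
    ]
    _frame(rows, ["step", "l_m", "l_r", "L_t", "lt_flag", "n_alive"]).to_csv(
        path, index=False, na_rep=""
    )


def write_pedigree_edges(path: str | Path, ped: Pedigree) -> None:
    rows = [
        {
            "parent_id": parent,
            "offspring_id": child,
            "birth_step": ped.birth_step[child],
        }
        for child, parent in ped.edges()
    ]
    _frame(rows, ["parent_id", "offspring_id", "birth_step"]).to_csv(
        path, index=False
    )


def write_events(path: str | Path, events: list[DemographicEvent]) -> None:
    rows = [
        {"step": e.step, "kind": e.kind, "subject": e.subject, "parent": e.parent}
        for e in events
    ]
    _frame(rows, ["step", "kind", "subject", "parent"]).to_csv(
        path, index=False, na_rep=""
    )


def write_exclusivity(path: str | Path, finals: list[float | None]) -> None:
    rows = [{"replicate": k, "E_final": e} for k, e in enumerate(finals)]
    _frame(rows, ["replicate", "E_final"]).to_csv(path, index=False, na_rep="")


def write_summary_json(path: str | Path, summary: dict[str, Any]) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Everything needed to regenerate an output directory bit-for-bit."""

    params: dict[str, Any]
    seed: int
    version: str
    files: dict[str, str] = field(default_factory=dict)  # name -> sha256

    @classmethod
    def collect(
        cls, params: SimulationParams, out_dir: str | Path, version: str
    ) -> "RunManifest":
        out_dir = Path(out_dir)
        files = {
            p.name: sha256_of(p)
            for p in sorted(out_dir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        }
        return cls(
            params=params.to_dict(), seed=params.seed, version=version, files=files
        )

    def write(self, out_dir: str | Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def write_baseline_outputs(
    out_dir: str | Path,
    results: Sequence[BaselineResult],
    version: str = "0",
) -> None:
    """Standard output bundle for a batch of baseline replicates.

    Per-step metrics cover every replicate; the stability network and final
    tie network are written for replicate 0 (each replicate is independently
    regenerable from the manifest's seed rule).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_metrics_csv(out / "metrics.csv", [r.metrics for r in results])
    write_stability_edges(out / "stability_edges.csv", results[0].stability)
    results[0].final_ties.to_graphml(out / "final_network.graphml")
    write_exclusivity(
        out / "exclusivity.csv", [r.final.exclusivity for r in results]
    )
    from .params import save_config

    save_config(results[0].params, out / "params.yaml")
    finals = [r.final for r in results]
    write_summary_json(
        out / "summary.json",
        {
            "n_replicates": len(results),
            "mean_final_payoff": _mean([m.mean_payoff for m in finals]),
            "mean_final_E": _mean([m.exclusivity for m in finals]),
            "mean_final_n_groups": _mean([float(m.n_groups) for m in finals]),
            "mean_final_group_size": _mean([m.mean_group_size for m in finals]),
        },
    )
    RunManifest.collect(results[0].params, out, version).write(out)


def write_reproductive_outputs(
    out_dir: str | Path,
    results: Sequence[ReproductiveResult],
    version: str = "0",
) -> None:
    """Standard output bundle for a batch of reproductive replicates."""
    from .metrics import pedigree_diameter

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_metrics_csv(out / "metrics.csv", [r.metrics for r in results])
    first = results[0]
    write_stability_edges(out / "stability_edges.csv", first.stability)
    write_relatedness_series(out / "relatedness_series.csv", first.metrics)
    write_pedigree_edges(out / "pedigree_edges.csv", first.pedigree)
    write_events(out / "events.csv", first.events)
    first.final_state.ties.to_graphml(out / "final_network.graphml")
    write_exclusivity(
        out / "exclusivity.csv", [r.final.exclusivity for r in results]
    )
    from .params import save_config

    save_config(first.params, out / "params.yaml")
    finals = [r.final for r in results]
    write_summary_json(
        out / "summary.json",
        {
            "n_replicates": len(results),
            "n_extinct": sum(1 for r in results if r.extinct),
            "mean_final_payoff": _mean([m.mean_payoff for m in finals]),
            "mean_final_E": _mean([m.exclusivity for m in finals]),
            "mean_final_n_groups": _mean([float(m.n_groups) for m in finals]),
            "mean_pedigree_diameter": _mean(
                [float(pedigree_diameter(r.pedigree)) for r in results]
            ),
            "mean_final_L": _mean([m.log_ratio for m in finals]),
        },
    )
    RunManifest.collect(first.params, out, version).write(out)


def _mean(values: list[float | None]) -> float | None:
    vals = [v for v in values if v is not None]
    return sum(vals) / len(vals) if vals else None
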