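"""Named regression fixtures: small configs plus golden outputs.

Each fixture is regenerated programmatically from its seed — nothing is
stored in the repository — and writing the same fixture twice with the same
seed produces identical checksums.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .io import write_baseline_outputs, write_reproductive_outputs
from .metrics import relatedness
from .params import ModelKind, ParameterError, SimulationParams
from .pedigree import Pedigree
from .reproductive import run_reproductive
from .baseline import run_baseline

__all__ = ["FIXTURE_NAMES", "make_fixture", "chain_pedigree"]

FIXTURE_NAMES = (
    "tiny_baseline",
    "small_cell_baseline",
    "small_cell_reproductive",
    "chain_pedigree",
)


def chain_pedigree() -> Pedigree:
    """A worked four-generation matriline plus an unrelated founder.

    Ids 0..3 are the chain founder -> child -> grandchild -> great-grandchild;
    id 10 is a second, unrelated founder. Useful anchor values:
    l(0,1) = 0.5, l(0,2) = 0.25, l(0,3) = 0.125, l(0,10) = 0.
    """
    ped = Pedigree()
    ped.add_founder(0)
    ped.add_founder(10)
    ped.add_birth(0, 1, step=1)
    ped.add_birth(1, 2, step=2)
    ped.add_birth(2, 3, step=3)
    return ped


def make_fixture(name: str, seed: int, out_dir: str | Path) -> Path:
    """Write fixture ``name`` (config + golden outputs) under ``out_dir``."""
    out = Path(out_dir) / name
    out.mkdir(parents=True, exist_ok=True)
    if name == "tiny_baseline":
        params = SimulationParams(n=6, r=3, t_prob=0.5, n_steps=10, seed=seed)
        write_baseline_outputs(out, [run_baseline(params)])
    elif name == "small_cell_baseline":
        params = SimulationParams(n=40, r=5, t_prob=0.2, n_steps=200, seed=seed)
        write_baseline_outputs(out, [run_baseline(params)])
    elif name == "small_cell_reproductive":
        params = SimulationParams(
            n=40,
            r=15,
            t_prob=0.2,
            n_steps=1000,
            seed=seed,
            model=ModelKind.REPRODUCTIVE,
        )
        write_reproductive_outputs(out, [run_reproductive(params)])
    elif name == "chain_pedigree":
        ped = chain_pedigree()
        ids = ped.ids
        rows = [
            {"i": i, "j": j, "relatedness": relatedness(ped, i, j)}
            for k, i in enumerate(ids)
            for j in ids[k + 1 :]
        ]
        pd.DataFrame(rows, columns=["i", "j", "relatedness"]).to_csv(
            out / "relatedness_table.csv", index=False
        )
    else:
        raise ParameterError(
            f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}"
        )
    return out
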