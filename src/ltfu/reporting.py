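"""Report rendering and run provenance.

Builds the three report shapes used throughout the pipeline — the attrition
accounting table, the corrected-estimates comparison (crude / IPW complete
cases / IPW imputed / MI total / MI responders / MI non-responders with
percent-change rows, per region and total) and the MNAR scenario grid — and a
JSON run manifest (config hash, seeds, version, stage timings, output
inventory) so every run is reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._util import round_half_up
from .pooling import PooledEstimate, percent_change

__all__ = ["config_hash", "RunManifest", "StageTimer", "estimates_frame", "render_markdown"]


def config_hash(obj) -> str:
    """Stable sha256 of a JSON-serialisable configuration (order-insensitive)."""
    payload = json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    timings: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        path = Path(path)
        for out in self.outputs:
            if not Path(out).exists():
                raise FileNotFoundError(f"manifest lists missing output {out}")
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "package_version": self.package_version,
            "timings_s": {k: round(v, 3) for k, v in self.timings.items()},
            "outputs": self.outputs,
            **self.extra,
        }
        path.write_text(json.dumps(payload, indent=2))


class StageTimer:
    """Context-manager accumulator for per-stage wall-clock timings."""

    def __init__(self, manifest: RunManifest):
        self.manifest = manifest

    def stage(self, name: str):
        timer = self

        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, *exc):
                timer.manifest.timings[name] = time.perf_counter() - self_inner.t0
                return False

        return _Ctx()


def estimates_frame(estimates: dict[str, dict[str, PooledEstimate]],
                    regions=("PT", "UK")) -> pd.DataFrame:
    """Corrected-estimates comparison table.

    ``estimates`` maps a method label (first key must be ``"Crude"``) to a
    mapping subgroup -> PooledEstimate with subgroups ``"total"`` and each
    region.  Percent-change rows are derived against the crude row.
    """
    if "Crude" not in estimates:
        raise ValueError("estimates must include a 'Crude' row")
    subgroups = list(regions) + ["total"]
    crude_pct = {s: estimates["Crude"][s].estimate_pct for s in subgroups
                 if s in estimates["Crude"]}
    recs = []
    for method, ests in estimates.items():
        rec = {"method": method}
        for s in subgroups:
            if s in ests:
                rec[s] = str(ests[s])
        recs.append(rec)
        if method != "Crude" and not method.startswith("MI (Non-responders"):
            chg = {"method": f"  % change vs crude ({method})"}
            for s in subgroups:
                if s in ests and s in crude_pct and crude_pct[s] > 0:
                    chg[s] = f"{round_half_up(percent_change(ests[s].estimate_pct, crude_pct[s]), 1):.1f}%"
            recs.append(chg)
    return pd.DataFrame(recs)


def render_markdown(frame: pd.DataFrame) -> str:
    return frame.to_markdown(index=False)
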