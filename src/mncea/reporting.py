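"""Report assembly: file outputs, run manifests and optional plots."""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Provenance of one command invocation."""

    command: str
    config_digest: str
    seed: int | None
    started: str = ""
    finished: str = ""
    version: str = __version__
    outputs: list[str] = field(default_factory=list)
    notes: dict = field(default_factory=dict)

    def start(self) -> "RunManifest":
        self.started = datetime.now(timezone.utc).isoformat()
        return self

    def record(self, path: Path) -> None:
        self.outputs.append(str(path))

    def write(self, path: Path) -> None:
        self.finished = datetime.now(timezone.utc).isoformat()
        missing = [p for p in self.outputs if not Path(p).exists()]
        self.notes["missing_outputs"] = missing
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))
        log.info("manifest written to %s (%d outputs)", path, len(self.outputs))


def config_digest(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()[:16]


def write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest | None = None) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    if manifest is not None:
        manifest.record(path)
    return path


def write_json(obj, path: Path, manifest: RunManifest | None = None) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=float))
    if manifest is not None:
        manifest.record(path)
    return path


# ---------------------------------------------------------------------------
# Plots (optional; written only when requested)
# ---------------------------------------------------------------------------

def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_tornado(tornado: pd.DataFrame, path: Path, top: int = 15) -> Path:
    plt = _pyplot()
    df = tornado.head(top).iloc[::-1]
    base = float(df["base_icer"].iloc[0]) if len(df) else 0.0
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(df) + 1.5))
    ax.barh(
        df["parameter"],
        df["icer_at_high"] - df["icer_at_low"],
        left=df["icer_at_low"],
        color="steelblue",
    )
    ax.axvline(base, color="k", lw=1, ls="--", label="base case")
    ax.set_xlabel("ICER (CNY/QALY)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_ce_plane(scatter: pd.DataFrame, wtp: float, path: Path) -> Path:
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(scatter["delta_qaly"], scatter["delta_cost"], s=3, alpha=0.25)
    lim = max(abs(scatter["delta_qaly"]).max(), 1e-6)
    xs = pd.Series([-lim, lim])
    ax.plot(xs, wtp * xs, "r--", lw=1, label=f"WTP {wtp:,.0f} CNY/QALY")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (CNY)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_ceac(ceac: pd.DataFrame, path: Path) -> Path:
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac["horizon"], 100.0 * ceac["probability"], "o-")
    ax.set_xlabel("Time horizon (years)")
    ax.set_ylabel("Probability cost-effective (%)")
    ax.set_ylim(0, 100)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
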