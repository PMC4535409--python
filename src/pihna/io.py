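"""Result serialization and run manifests.

Every experiment run writes its tables as CSV plus a JSON manifest that
records the fully resolved configuration, the package version, per-patient
status, and a SHA-256 checksum of every written file -- enough to rerun
the experiment bit-identically and to verify that a rerun did so.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["RunManifest", "write_results", "format_count"]

MANIFEST_NAME = "manifest.json"

# columns holding raw cell counts; they get a 2-significant-figure
# scientific-notation companion column for human readers
_COUNT_PREFIXES = ("N_", "H_", "R1", "R2", "kill_", "delta_cell_kill")


def format_count(x: float, sig: int = 2) -> str:
    """Scientific notation at reporting precision (e.g. 1.4e+10)."""
    if pd.isna(x):
        return ""
    return f"{float(x):.{sig - 1}e}"


def _with_readable_counts(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for col in table.columns:
        if any(col.startswith(p) for p in _COUNT_PREFIXES):
            out[f"{col}_2sf"] = table[col].map(format_count)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one experiment run."""

    config: dict
    experiment: str
    package_version: str = ""
    patient_status: list[dict] = field(default_factory=list)
    files: dict[str, str] = field(default_factory=dict)   # name -> sha256

    def __post_init__(self) -> None:
        if not self.package_version:
            from . import __version__
            self.package_version = __version__

    @classmethod
    def for_run(cls, config, experiment: str,
                tables: dict[str, pd.DataFrame]) -> "RunManifest":
        status = []
        for name, table in tables.items():
            if "status" in table.columns:
                for _, row in table.iterrows():
                    status.append({
                        "table": name,
                        "patient_id": row.get("patient_id", ""),
                        "start_size_cm": row.get("start_size_cm", ""),
                        "status": row["status"]})
        cfg = config.resolved() if hasattr(config, "resolved") else dict(config)
        return cls(config=cfg, experiment=experiment, patient_status=status)

    def to_json(self) -> str:
        return json.dumps({
            "experiment": self.experiment,
            "package_version": self.package_version,
            "config": self.config,
            "patient_status": self.patient_status,
            "files": self.files,
        }, indent=2, sort_keys=True, default=str)


def write_results(tables: dict[str, pd.DataFrame], manifest: RunManifest,
                  out_dir: str | Path) -> dict[str, str]:
    """Write CSV tables plus the JSON manifest; return the file inventory.

    Each table is written as ``<name>.csv`` with full-precision values and
    2-significant-figure companion columns for counts.  The manifest is
    written last so it can list the checksum of every output.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inventory: dict[str, str] = {}
    for name, table in tables.items():
        path = out_dir / f"{name}.csv"
        try:
            _with_readable_counts(table).to_csv(path, index=False)
        except OSError as exc:
            raise OSError(f"failed writing results table {path}: {exc}") from exc
        inventory[path.name] = _sha256(path)
    manifest.files = dict(inventory)
    manifest_path = out_dir / MANIFEST_NAME
    manifest_path.write_text(manifest.to_json())
    inventory[MANIFEST_NAME] = _sha256(manifest_path)
    return inventory
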