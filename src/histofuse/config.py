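"""Run configuration: a YAML file keyed by pipeline stage.

The file holds one mapping per subcommand (``synth``, ``prepare``, ``train``,
``predict``, ``evaluate``, ``ablate``), each containing that stage's options
under the same names as the command-line flags. Values given on the command
line take precedence. ``resolve`` validates the structure and returns the
mapping; ``dump_resolved`` serializes the options a run actually used into
its output directory for provenance.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml

KNOWN_SECTIONS = ("synth", "prepare", "train", "predict", "evaluate",
                  "ablate", "mcnemar", "ledger")


def load_run_config(path) -> dict:
    """Load and validate a run-configuration file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"run config {path} must be a mapping")
    unknown = set(raw) - set(KNOWN_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}; "
                         f"expected a subset of {KNOWN_SECTIONS}")
    for section, value in raw.items():
        if not isinstance(value, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
    return raw


def config_hash(options: dict) -> str:
    """Short stable hash of resolved options, for log lines."""
    blob = yaml.safe_dump(options, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def dump_resolved(options: dict, out_dir) -> Path:
    """Write the resolved options of a run into its output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "resolved_config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(options, fh, sort_keys=True)
    return path
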