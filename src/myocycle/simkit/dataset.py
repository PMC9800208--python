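"""Container pairing simulated observables with their ground truth."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np


def _jsonable(obj: Any):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dict__"):
        return _jsonable(vars(obj))
    return obj


@dataclass
class SyntheticDataset:
    """Simulated observables plus the latent truth that produced them.

    ``observables`` is whatever the assay's analysis module consumes (a
    DataFrame of wells, a list of traces, an image stack); ``ground_truth``
    holds the generating parameters and per-realization latent variables and
    is never consumed by analysis code outside of tests.
    """

    observables: Any
    ground_truth: dict = field(default_factory=dict)
    seed: int | None = None
    noise_model: dict = field(default_factory=dict)

    def write_ground_truth(self, path: str | Path) -> None:
        """Serialize the ground-truth sidecar as JSON."""
        payload = {
            "seed": self.seed,
            "noise_model": _jsonable(self.noise_model),
            "ground_truth": _jsonable(self.ground_truth),
        }
        Path(path).write_text(json.dumps(payload, indent=2))
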