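"""The trained episignature model and its linear MVP classifier.

An :class:`EpisignatureModel` carries the ordered selected-probe set, the
per-probe reference medians of the case and control training groups (used by
the per-sample concordance statistic), training metadata, and optionally a
trained :class:`MVPClassifier`.

The classifier is a linear-kernel margin classifier with a Platt-style
probability calibration, stored explicitly as weights ``(w, b)`` plus the
calibration pair ``(A, B)``:

    decision(x) = w . x + b
    score(x)    = 1 / (1 + exp(-(A * decision(x) + B)))

Keeping the parameters explicit makes the model a plain JSON document that
round-trips bit-faithfully, independent of any fitted library object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

MODEL_FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    """Raised when a serialised model cannot be loaded."""


@dataclass
class MVPClassifier:
    """Linear decision function with logistic probability calibration."""

    probe_ids: list[str]
    weights: np.ndarray
    bias: float
    platt_a: float
    platt_b: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.probe_ids),):
            raise ValueError("weight vector length must match probe list")

    def decision(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return x @ self.weights + self.bias

    def score(self, x: np.ndarray) -> np.ndarray:
        """Calibrated probability of the case class, in [0, 1]."""
        z = self.platt_a * self.decision(x) + self.platt_b
        return 1.0 / (1.0 + np.exp(-z))

    def to_dict(self) -> dict[str, Any]:
        return {
            "probe_ids": list(self.probe_ids),
            "weights": [float(w) for w in self.weights],
            "bias": float(self.bias),
            "platt_a": float(self.platt_a),
            "platt_b": float(self.platt_b),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "MVPClassifier":
        return cls(probe_ids=list(d["probe_ids"]),
                   weights=np.asarray(d["weights"], dtype=float),
                   bias=float(d["bias"]), platt_a=float(d["platt_a"]),
                   platt_b=float(d["platt_b"]))


@dataclass
class EpisignatureModel:
    """Ordered signature probes with reference statistics and classifier."""

    probe_ids: list[str]
    case_median: np.ndarray
    control_median: np.ndarray
    thresholds: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    classifier: MVPClassifier | None = None

    def __post_init__(self) -> None:
        self.case_median = np.asarray(self.case_median, dtype=float)
        self.control_median = np.asarray(self.control_median, dtype=float)
        n = len(self.probe_ids)
        if self.case_median.shape != (n,) or self.control_median.shape != (n,):
            raise ValueError("median vectors must match the probe list length")

    def __len__(self) -> int:
        return len(self.probe_ids)

    def to_json(self) -> str:
        payload = {
            "format": "episig-model",
            "version": MODEL_FORMAT_VERSION,
            "probe_ids": list(self.probe_ids),
            "case_median": [float(v) for v in self.case_median],
            "control_median": [float(v) for v in self.control_median],
            "thresholds": self.thresholds,
            "seed": int(self.seed),
            "classifier": self.classifier.to_dict() if self.classifier else None,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EpisignatureModel":
        try:
            d = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"model file is not valid JSON: {exc}") from exc
        if not isinstance(d, dict) or d.get("format") != "episig-model":
            raise ModelFormatError("not an episignature model file")
        if d.get("version") != MODEL_FORMAT_VERSION:
            raise ModelFormatError(
                f"model format version {d.get('version')!r} not supported "
                f"(expected {MODEL_FORMAT_VERSION})")
        try:
            clf = d["classifier"]
            return cls(
                probe_ids=list(d["probe_ids"]),
                case_median=np.asarray(d["case_median"], dtype=float),
                control_median=np.asarray(d["control_median"], dtype=float),
                thresholds=dict(d.get("thresholds", {})),
                seed=int(d.get("seed", 0)),
                classifier=MVPClassifier.from_dict(clf) if clf else None,
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ModelFormatError(f"truncated or corrupted model file: {exc}") from exc
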