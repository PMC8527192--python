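"""PUL model registry.

A polysaccharide utilization locus (PUL) model describes, for one fiber, the
gene families expected in the locus: which families are *core* (mandatory for
a growth-positive call), how many distinct gene copies each core family
requires, and the genomic gap threshold used when clustering hit genes.

Models are declarative configuration: one human-editable YAML file per fiber.
Seven reconstructed models for common dietary and host-derived fibers
(arabinoxylan, inulin, levan, heparin, laminarin, mucin, starch) ship with
the package under ``model_configs/``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import ModelConfigError

#: Fibers with a model shipped in the package.
SHIPPED_FIBERS = (
    "arabinoxylan",
    "heparin",
    "inulin",
    "laminarin",
    "levan",
    "mucin",
    "starch",
)

DEFAULT_GAP_BP = 5000

_SLOT_FIELDS = {"family_label", "hmm_id", "is_core", "min_copies"}
_MODEL_FIELDS = {"fiber", "gap_threshold_bp", "slots", "description"}


@dataclass(frozen=True)
class FamilySlot:
    """One expected gene family in a PUL model.

    Parameters
    ----------
    family_label:
        CAZy- or Pfam-style family name (``"GH32"``, ``"susC-like"``,
        ``"sulfatase"`` ...).
    hmm_id:
        Profile identifier matched against :class:`~pulscan.annotation.DomainHit`
        family labels. Defaults to ``family_label``.
    is_core:
        Whether the family is mandatory for a growth-positive call.
    min_copies:
        Number of distinct genes required to satisfy the slot within a single
        candidate locus (copies are genes, not domains).
    """

    family_label: str
    hmm_id: str = ""
    is_core: bool = False
    min_copies: int = 1

    def __post_init__(self):
        if not self.hmm_id:
            object.__setattr__(self, "hmm_id", self.family_label)


@dataclass(frozen=True)
class PULModel:
    """A fiber's reference locus: an ordered list of family slots."""

    fiber_name: str
    slots: tuple[FamilySlot, ...]
    gap_threshold_bp: int = DEFAULT_GAP_BP
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "slots", tuple(self.slots))

    @property
    def core_slots(self) -> tuple[FamilySlot, ...]:
        return tuple(s for s in self.slots if s.is_core)

    @property
    def hmm_ids(self) -> tuple[str, ...]:
        return tuple(s.hmm_id for s in self.slots)

    def slot_for_hmm(self, hmm_id: str) -> FamilySlot | None:
        for s in self.slots:
            if s.hmm_id == hmm_id:
                return s
        return None

    def slot_labels(self) -> tuple[str, ...]:
        return tuple(s.family_label for s in self.slots)


def validate_model(model: PULModel) -> list[str]:
    """Return a list of invariant-violation descriptions (empty when valid)."""
    violations: list[str] = []
    if not model.fiber_name:
        violations.append("fiber_name must be non-empty")
    if model.gap_threshold_bp <= 0:
        violations.append(
            f"gap_threshold_bp must be positive, got {model.gap_threshold_bp}"
        )
    if not any(s.is_core for s in model.slots):
        violations.append(
            f"model '{model.fiber_name}' has no core slot; at least one "
            "family must be core"
        )
    seen_hmm: set[str] = set()
    for i, slot in enumerate(model.slots):
        where = f"model '{model.fiber_name}' slot {i} ('{slot.family_label}')"
        if not slot.family_label:
            violations.append(f"{where}: family_label must be non-empty")
        if slot.min_copies < 1:
            violations.append(
                f"{where}: min_copies must be >= 1, got {slot.min_copies}"
            )
        if slot.hmm_id in seen_hmm:
            violations.append(f"{where}: duplicate hmm_id '{slot.hmm_id}'")
        seen_hmm.add(slot.hmm_id)
    return violations


def _model_from_mapping(doc: dict, source: str) -> PULModel:
    if not isinstance(doc, dict):
        raise ModelConfigError(f"{source}: model document must be a mapping")
    unknown = set(doc) - _MODEL_FIELDS
    if unknown:
        raise ModelConfigError(
            f"{source}: unknown field(s) {sorted(unknown)} in model "
            f"'{doc.get('fiber', '?')}'"
        )
    if "fiber" not in doc:
        raise ModelConfigError(f"{source}: missing required field 'fiber'")
    if "slots" not in doc or not isinstance(doc["slots"], list):
        raise ModelConfigError(
            f"{source}: model '{doc['fiber']}' must define a 'slots' list"
        )
    slots = []
    for i, raw in enumerate(doc["slots"]):
        if not isinstance(raw, dict):
            raise ModelConfigError(
                f"{source}: model '{doc['fiber']}' slot {i} must be a mapping"
            )
        unknown = set(raw) - _SLOT_FIELDS
        if unknown:
            raise ModelConfigError(
                f"{source}: unknown field(s) {sorted(unknown)} in slot {i} "
                f"of model '{doc['fiber']}'"
            )
        if "family_label" not in raw:
            raise ModelConfigError(
                f"{source}: slot {i} of model '{doc['fiber']}' is missing "
                "'family_label'"
            )
        slots.append(
            FamilySlot(
                family_label=str(raw["family_label"]),
                hmm_id=str(raw.get("hmm_id", "") or ""),
                is_core=bool(raw.get("is_core", False)),
                min_copies=int(raw.get("min_copies", 1)),
            )
        )
    model = PULModel(
        fiber_name=str(doc["fiber"]),
        slots=tuple(slots),
        gap_threshold_bp=int(doc.get("gap_threshold_bp", DEFAULT_GAP_BP)),
        description=str(doc.get("description", "")),
    )
    violations = validate_model(model)
    if violations:
        raise ModelConfigError(f"{source}: " + "; ".join(violations))
    return model


def load_models(path: str | Path) -> list[PULModel]:
    """Load validated PUL models from a YAML file or a directory of them.

    A file may contain several ``---``-separated model documents; a directory
    is read as its ``*.yaml`` files in sorted name order. Ordering of models
    within a file is preserved. Unknown fields are rejected.
    """
    path = Path(path)
    if path.is_dir():
        models: list[PULModel] = []
        for f in sorted(path.glob("*.yaml")):
            models.extend(load_models(f))
        return models
    try:
        docs = list(yaml.safe_load_all(path.read_text()))
    except yaml.YAMLError as exc:
        raise ModelConfigError(f"{path}: invalid YAML: {exc}") from exc
    models = []
    for doc in docs:
        if doc is None:  # empty document / empty file
            continue
        models.append(_model_from_mapping(doc, source=str(path)))
    return models


def model_to_mapping(model: PULModel) -> dict:
    doc: dict = {"fiber": model.fiber_name}
    if model.description:
        doc["description"] = model.description
    doc["gap_threshold_bp"] = model.gap_threshold_bp
    doc["slots"] = [
        {
            "family_label": s.family_label,
            "hmm_id": s.hmm_id,
            "is_core": s.is_core,
            "min_copies": s.min_copies,
        }
        for s in model.slots
    ]
    return doc


def dump_models(models: Iterable[PULModel], path: str | Path) -> None:
    """Serialize models to a multi-document YAML file (round-trips losslessly)."""
    text = yaml.safe_dump_all(
        [model_to_mapping(m) for m in models], sort_keys=False
    )
    Path(path).write_text(text)


def shipped_models_dir() -> Path:
    """Path to the package's shipped model configuration directory."""
    return Path(resources.files("pulscan") / "model_configs")


def load_shipped_models() -> list[PULModel]:
    """Load the seven reconstructed fiber models shipped with the package."""
    return load_models(shipped_models_dir())


def get_model(fiber: str, models: Sequence[PULModel] | None = None) -> PULModel:
    """Look up one model by fiber name (shipped models by default)."""
    if models is None:
        models = load_shipped_models()
    for m in models:
        if m.fiber_name == fiber:
            return m
    raise KeyError(f"no model for fiber '{fiber}'")
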